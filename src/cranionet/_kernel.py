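"""Compiled inner loop of the simulated-annealing Potts optimizer.

The kernel is shared by the unconstrained and the symmetry-constrained
detector.  Update units are *groups*: a singleton group relabels one node,
a pair group relabels a node and its mirror to the same spin, with the
Metropolis test applied to the joint energy change (computed sequentially,
which accounts exactly for the A_ij term between the two members).

In unconstrained mode groups are drawn uniformly at random; in constrained
mode each sweep visits groups in their given order (axis nodes first, then
left/right pairs).  All randomness comes from numba's Mersenne-Twister
state seeded once at entry, so a run is fully determined by its seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["anneal", "schedule_length"]


def schedule_length(start_temp: float, stop_temp: float, cooling_factor: float) -> int:
    """Number of temperature steps the geometric schedule will execute."""
    steps = 0
    T = start_temp
    while T > stop_temp:
        steps += 1
        T *= cooling_factor
    return steps


@njit(cache=True)
def _node_delta(i, s, t, indptr, indices, deg, labels, comm_deg, gamma, two_m):
    """Energy change of moving node i (0-based) from spin s to spin t."""
    e_s = 0.0
    e_t = 0.0
    for p in range(indptr[i], indptr[i + 1]):
        lj = labels[indices[p]]
        if lj == s:
            e_s += 1.0
        elif lj == t:
            e_t += 1.0
    k_i = deg[i]
    return -(e_t - e_s) + gamma * k_i * (comm_deg[t] - comm_deg[s] + k_i) / two_m


@njit(cache=True)
def anneal(
    indptr,
    indices,
    deg,
    two_m,
    labels,
    q,
    gamma,
    start_temp,
    stop_temp,
    cooling_factor,
    sweeps_per_temp,
    group_a,
    group_b,
    ordered,
    seed,
    H0,
    n_steps,
):
    """Run the full annealing schedule in place on ``labels`` (0-based spins).

    ``group_b[g] < 0`` marks a singleton group.  Returns the final energy
    and per-temperature traces (T, H, acceptance rate) of length n_steps.
    """
    np.random.seed(seed)
    n = labels.size
    n_groups = group_a.size
    comm_deg = np.zeros(q, dtype=np.float64)
    for i in range(n):
        comm_deg[labels[i]] += deg[i]

    trace_T = np.empty(n_steps, dtype=np.float64)
    trace_H = np.empty(n_steps, dtype=np.float64)
    trace_acc = np.empty(n_steps, dtype=np.float64)

    H = H0
    T = start_temp
    step = 0
    while T > stop_temp:
        accepted = 0
        proposed = 0
        for _ in range(sweeps_per_temp):
            for gi in range(n_groups):
                g = gi if ordered else np.random.randint(n_groups)
                a = group_a[g]
                b = group_b[g]
                s = labels[a]
                t = np.random.randint(q - 1)
                if t >= s:
                    t += 1
                d = _node_delta(a, s, t, indptr, indices, deg, labels, comm_deg, gamma, two_m)
                if b >= 0:
                    # joint move: apply a provisionally, add b's delta, revert
                    labels[a] = t
                    comm_deg[s] -= deg[a]
                    comm_deg[t] += deg[a]
                    d += _node_delta(b, s, t, indptr, indices, deg, labels, comm_deg, gamma, two_m)
                    labels[a] = s
                    comm_deg[s] += deg[a]
                    comm_deg[t] -= deg[a]
                proposed += 1
                if d <= 0.0 or np.random.random() < np.exp(-d / T):
                    labels[a] = t
                    comm_deg[s] -= deg[a]
                    comm_deg[t] += deg[a]
                    if b >= 0:
                        labels[b] = t
                        comm_deg[s] -= deg[b]
                        comm_deg[t] += deg[b]
                    H += d
                    accepted += 1
        trace_T[step] = T
        trace_H[step] = H
        trace_acc[step] = accepted / proposed if proposed > 0 else 0.0
        step += 1
        T *= cooling_factor
    return H, trace_T, trace_H, trace_acc
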