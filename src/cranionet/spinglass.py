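"""Spin-glass community detection by simulated annealing.

Each node carries a Potts spin (community label) out of at most ``spins``
states; the annealer minimizes the configuration-model Hamiltonian of
:mod:`cranionet.modularity` under a geometric temperature schedule with
Metropolis acceptance.  With ``spins=2`` the detector searches the space
of at-most-two-community partitions, the setting used for the head
network.

Runs are exactly reproducible from their seed.  Because a single annealing
run of a stochastic optimizer can land in a local optimum,
:func:`run_ensemble` runs many seeds; consensus across an ensemble is
taken by :func:`cranionet.compare.consensus_partition`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import scipy.sparse as sp

from . import _kernel
from .errors import ConfigError, DataError
from .modularity import Partition, hamiltonian, modularity
from .network import AnatomicalNetwork

__all__ = ["SpinglassConfig", "DetectionResult", "detect_spinglass", "run_ensemble"]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class SpinglassConfig:
    """Annealing parameters.

    Defaults mirror the conventional settings of the widely used
    spin-glass implementation this detector follows: start at T=1, cool by
    1% per temperature step down to T=0.01, with 50 update attempts per
    node (per group, in the constrained variant) at each temperature.
    """

    spins: int = 2
    gamma: float = 1.0
    start_temp: float = 1.0
    stop_temp: float = 0.01
    cooling_factor: float = 0.99
    sweeps_per_temp: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.spins < 2:
            raise ConfigError("spins must be at least 2")
        if not (0 < self.stop_temp < self.start_temp):
            raise ConfigError("need 0 < stop_temp < start_temp")
        if not (0 < self.cooling_factor < 1):
            raise ConfigError("cooling_factor must lie in (0, 1)")
        if self.sweeps_per_temp < 1:
            raise ConfigError("sweeps_per_temp must be at least 1")
        if self.gamma <= 0:
            raise ConfigError("gamma must be positive")
        if not (0 <= self.seed <= _MAX_SEED):
            raise ConfigError(f"seed must lie in [0, {_MAX_SEED}]")


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of one community-detection run."""

    partition: Partition
    Q: float
    H: float
    seed: int
    n_sweeps: int
    trace: Optional[tuple[tuple[float, float, float], ...]] = field(
        default=None, repr=False
    )


def _csr_arrays(network: AnatomicalNetwork):
    A = sp.csr_array(np.asarray(network.adjacency))
    return (
        A.indptr.astype(np.int64),
        A.indices.astype(np.int64),
        network.degrees.astype(np.float64),
    )


def _finish(
    network: AnatomicalNetwork,
    labels0: np.ndarray,
    config: SpinglassConfig,
    n_steps: int,
    H_final: float,
    traces,
    trace: bool,
) -> DetectionResult:
    partition = Partition.from_labels(labels0 + 1).canonical()
    Q = modularity(network, partition)
    H = hamiltonian(network, partition, config.gamma)
    trace_T, trace_H, trace_acc = traces
    return DetectionResult(
        partition=partition,
        Q=Q,
        H=H,
        seed=config.seed,
        n_sweeps=n_steps * config.sweeps_per_temp,
        trace=tuple(zip(trace_T.tolist(), trace_H.tolist(), trace_acc.tolist()))
        if trace
        else None,
    )


def detect_spinglass(
    network: AnatomicalNetwork,
    config: SpinglassConfig = SpinglassConfig(),
    trace: bool = False,
) -> DetectionResult:
    """One seeded annealing run of the unconstrained spin-glass detector.

    Spins are initialized uniformly at random; each temperature performs
    ``sweeps_per_temp * n`` single-node proposals on uniformly random
    nodes.  Empty spin states are dropped from the output, whose labels
    are compacted to ``1..k`` by first appearance in node-id order.
    """
    config.validate()
    if network.m == 0:
        raise DataError("spin-glass detection requires at least one edge")
    indptr, indices, deg = _csr_arrays(network)
    rng = np.random.default_rng(config.seed)
    labels = rng.integers(0, config.spins, size=network.n).astype(np.int64)
    H0 = hamiltonian(network, Partition.from_labels(labels + 1), config.gamma)
    group_a = np.arange(network.n, dtype=np.int64)
    group_b = np.full(network.n, -1, dtype=np.int64)
    n_steps = _kernel.schedule_length(
        config.start_temp, config.stop_temp, config.cooling_factor
    )
    H_final, *traces = _kernel.anneal(
        indptr,
        indices,
        deg,
        2.0 * network.m,
        labels,
        config.spins,
        config.gamma,
        config.start_temp,
        config.stop_temp,
        config.cooling_factor,
        config.sweeps_per_temp,
        group_a,
        group_b,
        False,
        config.seed,
        H0,
        n_steps,
    )
    return _finish(network, labels, config, n_steps, H_final, traces, trace)


def run_ensemble(
    network: AnatomicalNetwork,
    config: SpinglassConfig = SpinglassConfig(),
    n_runs: int = 100,
    symmetry=None,
) -> list[DetectionResult]:
    """Independent detections with seeds ``seed, seed+1, ...``.

    Results are ordered by descending Q (ties keep seed order).  When a
    :class:`~cranionet.network.SymmetryMap` is given, the constrained
    detector of :mod:`cranionet.symmetric` is used for every run.
    """
    if n_runs < 1:
        raise ConfigError("n_runs must be at least 1")
    config.validate()
    if config.seed + n_runs - 1 > _MAX_SEED:
        raise ConfigError("seed range exceeds the 32-bit seed domain")
    if symmetry is None:
        detect = detect_spinglass
    else:
        from .symmetric import detect_symmetric_spinglass

        def detect(net, cfg):
            return detect_symmetric_spinglass(net, symmetry, cfg)

    results = [
        detect(network, replace(config, seed=config.seed + i)) for i in range(n_runs)
    ]
    return sorted(results, key=lambda r: -r.Q)
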