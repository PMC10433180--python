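# cranionet

Anatomical network analysis (AnNA) of the human central-nervous-system +
craniofacial-skeleton composite, packaged as a tested Python library and
CLI.

AnNA models an anatomical system as a graph — anatomical units as nodes,
physical contacts and peripheral-nerve connections as edges — and asks how
the system decomposes into *modules*: groups of elements more densely
connected to each other than to the rest.  For the head, modular structure
is read as a signature of shared developmental and genetic regulation.
`cranionet` ships a 39-node model of the head (nine brain subdivisions,
three spinal-cord portions, 27 craniofacial bones; 145 binary links) and
the detectors needed to analyze it and networks like it.

## What it computes

Module quality is Newman modularity under the configuration-model null,

    Q = Σ_c [ L_c/m − (d_c/(2m))² ],

or equivalently the Potts spin-glass energy

    H(σ) = − Σ_{i<j} (A_ij − γ·k_i k_j/(2m)) δ(σ_i, σ_j),

which satisfies `H + mQ = −Σ_i k_i²/(4m)` at γ = 1, so minimizing H
maximizes Q.  On top of this the package provides:

* **Spin-glass detection** — simulated annealing over Potts spins
  (`spins = 2` for the head analysis), fully reproducible from a seed,
  with ensembles and consensus (modal-partition) stabilization.
* **Bilaterally symmetric spin-glass detection** — the same annealer
  constrained by a left/right mirror map: mirrored nodes are initialized
  together, each sweep updates axis (midline) nodes first, and a paired
  node always moves jointly with its mirror under a single Metropolis
  test.  Every returned partition co-assigns every left/right pair — a
  structural guarantee, not a tendency.
* **Leading-eigenvector detection** — deterministic recursive spectral
  bisection of the (generalized) modularity matrix, used as an
  independent cross-check.
* **Partition analysis** — label-permutation-invariant comparison
  (optimal label matching, Rand index, NMI), symmetry audits, consensus
  over stochastic runs, per-module summaries.
* **Synthetic benchmarks** — mirror-symmetric planted-partition networks
  with known truth, so every detector is testable without external data.

## Worked example

```python
from cranionet import (builtin_head_network, SpinglassConfig, run_ensemble,
                       consensus_partition, detect_leading_eigenvector,
                       compare_partitions, module_summary)

network, symmetry = builtin_head_network()
print(f"{network.n} nodes, {network.m} edges, "
      f"{len(symmetry.pairs)} mirror pairs, {len(symmetry.axis_ids)} axis nodes")

ensemble = run_ensemble(network, SpinglassConfig(spins=2, seed=1),
                        n_runs=100, symmetry=symmetry)
consensus = consensus_partition(ensemble)
print(f"consensus support: {consensus.support:.2f}, "
      f"modal Q = {ensemble[0].Q:.4f}, sizes = {consensus.modal_partition.sizes()}")

for report in module_summary(network, consensus.modal_partition):
    cns = report.members_by_class.get("central_nervous", ())
    print(f"module {report.label}: {report.size} nodes "
          f"({len(cns)} central-nervous), "
          f"{report.internal_edges} internal / {report.external_edges} external edges")

spectral = detect_leading_eigenvector(network, max_communities=2)
diff = compare_partitions(spectral.partition, consensus.modal_partition)
print("spectral cross-check moves:",
      [network.name_of(i) for i in diff.disagreement_ids])
```

prints

```
39 nodes, 145 edges, 14 mirror pairs, 11 axis nodes
consensus support: 1.00, modal Q = 0.2274, sizes = (17, 22)
module 1: 17 nodes (3 central-nervous), 64 internal / 38 external edges
module 2: 22 nodes (9 central-nervous), 43 internal / 38 external edges
spectral cross-check moves: ['Sphenoid']
```

Read: all 100 symmetry-constrained annealing runs agree on one two-module
split (support 1.00) with modularity Q = 0.2274.  The anterior module
(17 nodes) holds the forebrain plus the mid/upper face; the posterior
module (22 nodes) holds midbrain, hindbrain, spinal cord, cranial vault
and ear.  The deterministic spectral method reproduces this split except
for a single node — the sphenoid, a bone sitting exactly at the interface
of the two modules.

The same pipeline from the shell:

```bash
cranionet fixture --out fixtures/
cranionet detect --algorithm symmetric-spinglass --builtin \
    --spins 2 --seed 1 --runs 100 --out modules.json
cranionet compare modules.json fixtures/modules_spinglass.json --builtin
cranionet simulate --blocks 6:5,8:6 --p-in 0.3 --p-out 0.05 --seed 7 \
    --out net.csv --truth truth.json --symmetry sym.csv
cranionet report modules.json --builtin --plot modules.png
```

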