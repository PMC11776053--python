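# alchemap

Perturbation-map construction with alchemical intermediates, for planning
relative binding free energy (RBFEP) calculations between structurally
distant ligands.

## The problem

RBFEP estimates the binding free energy difference ΔΔG between two ligands
by alchemically transforming one into the other during a molecular
simulation. The method is accurate when the transformation is small; large
topological changes (inserting or deleting whole rings, scaffold hops) make
the simulation unstable and the estimates unreliable. The standard remedy is
to insert *intermediates* — auxiliary compounds between the two ligands —
so each simulated step is chemically small, and to close *thermodynamic
cycles* in the resulting compound graph so that errors can be detected
(every cycle's ΔΔG values must sum to zero).

`alchemap` plans such campaigns for medicinal/computational chemists. It
does not run any simulation; it produces the **perturbation map**: which
compounds to simulate and which transformations (links) to compute.

## The method

1. **Exhaustive intermediate generation.** Given ligands A and B with equal
   net charge, the maximum common substructure (MCS) is computed with
   *incomplete atom-type matching* — atoms may be paired even when their
   elements differ, so an aromatic C→N swap counts as one perturbed atom
   instead of a delete + insert. Starting from A (and again from B), every
   applicable single graph edit toward the common core is applied
   recursively through a compound pool until it empties: mutate a
   mismatched core atom (a), delete an acyclic non-core atom (b), delete a
   non-core ring branch capping with H (c) or with methyl (d), or trim the
   non-core ring of a fused system (e). Candidates are deduplicated by
   canonical SMILES and discarded if their net charge differs from the
   inputs'.

2. **Link and path scores.** Each candidate pair gets a link score

       S_e = exp(−β · (N_A + N_B − 2·N_MCS)),    β = 0.1

   where the exponent is the number of heavy atoms inserted or deleted by
   the perturbation; S_e ∈ (0, 1], with 1 exactly for a zero-atom change. A
   path P is scored by

       S_P = 1 / Σ_{e∈P} S_e⁻²

   (the harmonic mean of the squared link scores divided by the path
   length). The **optimal intermediate path** maximizes S_P among simple
   A→B paths whose links all satisfy S_e ≥ MIN_SCORE and whose length is at
   most MAX_DIST.

3. **Map construction.** All candidate links below a prune threshold are
   discarded, the rest are removed worst-first; a removal is kept only if
   every optimal link remains present and lies on a cycle of size ≤
   MAX_CYCLE. Finally only compounds on A→B paths within MAX_SUBGRAPH_DIST
   are retained.

4. **Series mode.** For a congeneric series, a Lomap-style map is built
   over the members; every member–member link scoring below a threshold is
   repaired by injecting the optimal intermediate path between its
   endpoints (deduplicated), rebuilding incrementally with constraints that
   exempt intermediates, and pruning leaf/disconnected intermediates, until
   no weak member links remain.

## Worked example

Biphenyl → phenol deletes one ring and mutates an attachment into a
hydroxyl — a direct link scores only exp(−0.7) ≈ 0.50:

```bash
alchemap pair "c1ccc(-c2ccccc2)cc1" "Oc1ccccc1" -o pm
```

prints

```
INFO alchemap: generated 4 candidates
INFO alchemap: optimal path: A -> A_i1 -> B (worst link 0.549, length 2, score 0.2202)
map: 3 nodes, 3 links, worst link 0.497, A-B distance 1
```

The generator found benzene and toluene en route to the core; with
MIN_SCORE = 0.5 the direct link (0.497) is not allowed on the path, so the
optimal path goes through benzene (`A_i1`): biphenyl → benzene (0.549,
drop the second ring) → phenol (0.905, add the hydroxyl). The final map is
the triangle {biphenyl, benzene, phenol}: the direct biphenyl–phenol edge
is kept because it closes a 3-cycle over both optimal links, enabling
cycle-closure error checks, and toluene is pruned as unnecessary. Outputs:
`pm.graphml`, `pm_edges.csv`, `pm_candidates.smi`, `pm_report.json`.

Series mode on the built-in toy congeneric series (benzene scaffold with
small substituents plus one distant anthracene member whose links score
below 0.4):

```bash
python -c "from alchemap.fixtures import make_congeneric_series;
from alchemap.io import write_smiles_file;
write_smiles_file(make_congeneric_series(), 'series.smi')"
alchemap series series.smi -o sm
```

prints

```
series map: 9 nodes (1 intermediates), 10 links, 0 links <= 0.6, 0 links <= 0.4
```

— a single injected naphthalene bridges the distant member, and no
member–member link remains below the 0.6 threshold.

Other commands: `alchemap score <mol> <mol>` prints a link score;
`alchemap stats <map.graphml>` summarizes a written map. Thresholds can be
set by flags or a YAML config (flags win).

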