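# phyloconflict

Diagnostics for conflicting phylogenetic signal in concatenated protein
supermatrices.

Deep phylogenomic questions — for instance whether eukaryotes are the
sister group of a monophyletic Archaea (the three-domain topology) or
emerge from *within* Archaea next to a particular lineage (the eocyte
topology) — are usually answered by concatenating dozens of universal
protein markers into one supermatrix. That procedure silently assumes the
markers share one evolutionary history. When they do not (horizontal
transfer, fast-evolving taxa, or contaminated / chimeric sequences in
metagenome-assembled genomes), a single marker, or even a single
contaminated sequence, can decide the global topology.

`phyloconflict` implements the complete desk-scale diagnostic workflow for
this failure mode:

- **Per-marker inference** — maximum likelihood under LG+Γ4 (Felsenstein
  pruning; neighbor-joining start, NNI hill-climbing, nonparametric
  bootstrap), with BLOSUM-based column trimming.
- **Topology interrogation** — outgroup rooting, monophyly queries with
  supports, classification of each marker tree as `woese` / `eocyte` /
  `unresolved`, and a comparative marker table.
- **AU topology test** — Shimodaira's approximately unbiased test via the
  multiscale RELL bootstrap: `Φ⁻¹(1 − BP(r)) = d√r + c/√r` fitted by
  weighted least squares, `p = 1 − Φ(d − c)`, confidence set `{p ≥ α}`.
- **Chimera screens** — anchored-insertion detection (focal-specific
  indels flanked by conserved 40-column anchors), donor attribution by
  Smith–Waterman local alignment, and a sliding-window clade-affinity
  breakpoint scan with a permutation test.
- **Ablation experiments** — leave-one-marker-out and
  leave-one-sequence-out re-runs of the whole trim→infer→classify
  pipeline over the concatenation.
- **Gene-architecture parsimony** — Fitch/Sankoff minimum-change analysis
  of the fused vs split RNA-polymerase A-subunit character, including a
  rooting scan over all outgroup attachment points.
- **Synthetic data generator** — markers evolved under LG+Γ4 on
  conflicting species histories, fast-evolving-taxon branch scaling, and
  injected segment/insertion chimeras with a machine-readable truth set.

## Worked example

The fused vs split RNA-polymerase A-subunit character: archaea carry the
largest subunit either as one polypeptide ("fused", as in Thaumarchaeota
and Korarchaeum) or split in two ("split", as in Euryarchaeota,
Crenarchaeota and credible Lokiarchaeota). How many fusion/split events
each rooting of the archaeal tree requires is a compact parsimony
argument:

```python
from phyloconflict.examples import thaum_rooted_example, loki_ancestor_example
from phyloconflict.parsimony import fitch_min_changes, reconstruct_events

tree, states = thaum_rooted_example()
print(fitch_min_changes(tree, states))
# 1
print(reconstruct_events(tree, states).events_per_mpr[0])
# (Event(edge_child_leafset=frozenset({'Crenarchaeota', 'Lokiarchaeota',
#  'Euryarchaeota'}), from_state='fused', to_state='split', kind='split'),)
# (one MPR; set-element order may vary)

tree2, states2 = loki_ancestor_example()
print(fitch_min_changes(tree2, states2))
# 4
```

Rooting the archaeal tree on the Thaumarchaeota branch explains the
character with a **single split** placed right after the Korarchaeum
divergence, while the alternative topology (eukaryotes inside
Lokiarchaeota, fast-evolving Methanopyrus at the archaeal base) needs
**four** events.

The flagship end-to-end experiment is the bundled `ef2_like` preset: eight
clean markers simulated on the three-domain history plus one long marker
whose focal archaeal sequence carries an injected eukaryote-derived
segment. The full concatenation classifies `eocyte` (Eukarya attracted to
the contaminated lineage); removing that single marker — or merely gapping
out the single contaminated row — restores `woese`:

```python
from phyloconflict import ef2_like_preset, make_conflicting_marker_set
from phyloconflict.ablation import MarkerSet, PipelineConfig, leave_one_marker_out
# ... see docs/methods.md; the acceptance script runs this exact experiment
```

A `phyloconflict` console script exposes the pieces (`trim`, `infer`,
`boot`, `autest`, `scan-insertions`, `scan-breakpoint`, `fitch`, `run`).

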