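# Methods

## The problem

A concatenated ("supermatrix") phylogenomic analysis assumes its markers
share one evolutionary history. This package provides the diagnostics for
the case where they do not: per-marker tree inference and classification,
formal topology tests, screens for chimeric sequences, and perturbation
(ablation) experiments that measure how much of the global signal rests on
single markers or single rows. Everything runs at desk scale on synthetic
data whose generating process is fully known, so each diagnostic can be
validated against ground truth.

## Substitution model and likelihood

Sequences evolve under a general time-reversible amino-acid CTMC,
`Q = S·diag(π)` with the LG exchangeabilities and stationary frequencies,
rows filled to sum to zero and the generator normalized to one expected
substitution per site (`Σ π_i |Q_ii| = 1`). Rate heterogeneity is Yang's
equal-probability discrete gamma: `K` categories (default 4) whose rates
are the conditional means of a Gamma(α, α) variable inside each 1/K
quantile band, so they average exactly 1. The shape α is a configuration
value (default 1.0), not optimized per marker: desk-scale datasets rarely
constrain α strongly, and a fixed value keeps runs comparable. Transition
matrices come from the symmetric eigendecomposition of
`diag(√π) Q diag(1/√π)` (reversibility guarantees a real spectrum), cached
once per model.

Likelihoods use Felsenstein pruning over unique site patterns with
per-pattern rescaling. Gaps and `X` contribute all-ones partial vectors.
Branch lengths are optimized one edge at a time against inside/outside
conditional likelihoods (`L(t) = Σ_k w_k (π∘h_k)·P_k(t)·d_k`), with
per-sweep cached partials and a safeguard that redoes a sweep exactly
(fresh partials per edge) if the cached sweep ever fails to improve; the
reported trace is non-decreasing. Lengths live in `[1e-8, 20]`
substitutions/site.

Tree search is deliberately modest: a neighbor-joining start from
Poisson-corrected distances (`d = −ln(1−p)`, capped at 10), then NNI
hill-climbing that evaluates both alternatives at every internal edge with
local re-optimization of the central branch, accepting the single best
improving move per round. SPR is not implemented; on the simulated problem
sizes used here NNI from an NJ start recovers the generating topology
reliably, and the restriction keeps full ablation sweeps tractable on one
CPU. Bootstrap supports re-run the entire NJ+NNI inference on each
column-resampled replicate and attach bipartition percentages to the ML
tree's edges.

## Column trimming

A BMGE-inspired filter, not a re-implementation of any external tool: per
column, the gap fraction `g` and a conservation score `c` (mean
min-max-normalized similarity-matrix score over ungapped residue pairs;
BLOSUM30 by default), `c` smoothed by a centred 3-column moving average; a
column is kept iff `g ≤ 0.2` and smoothed `c ≥ 0.3`. The 0.3 default is
deliberate: on this min-max scale an all-identical column of a common
residue (e.g. Ala, diagonal 4 in BLOSUM30 with range −7..20) scores 0.407,
so thresholds near 0.5 would discard perfectly conserved columns;
0.3 keeps every identity column while removing near-random columns
(≈0.2–0.25). Smoothing means the filter is not formally idempotent in
adversarial cases; on generator output it is (covered by a test).

## AU test

Per marker, candidate topologies get branch lengths optimized (topology
fixed) and per-site log-likelihoods recorded. The multiscale RELL
bootstrap resamples `round(r·n)` sites at scales r = 0.5…1.4 (step 0.1,
1000 replicates per scale); exact ties in the per-replicate winner are
split fractionally so duplicated topologies receive identical
proportions. `Φ⁻¹(1 − BP(r)) = d√r + c/√r` is fitted by weighted least
squares with binomial delta-method weights (BP clamped to
[0.5/B, 1−0.5/B]); `p = 1 − Φ(d − c)`; the confidence set collects
candidates with `p ≥ α` (0.05). A lone candidate gets p = 1; a candidate
with BP identically 0 (or 1) at every scale is clamped to p = 0 (or 1)
and flagged degenerate. Markers are then partitioned: a marker is
*woese-relevant* iff it rejects the eocyte topology while not rejecting
the woese one, and symmetrically; both-rejected markers are flagged and
treated as unresolved.

## Chimera screens

**Anchored insertions.** A hit is a maximal run of ≥ 5 columns where the
focal sequence carries residues while ≥ 80% of reference rows are gapped,
flanked on both sides by 40-column anchors whose mean reference
conservation is ≥ 0.55. The threshold lives on the same min-max
conservation scale as trimming, where an identical column averages ≈0.63
under BLOSUM62; 0.55 separates rate-damped anchor regions (≈0.6) from
background (≈0.5). Runs too close to the alignment edge for full anchors
are dropped with a warning.

**Donor attribution.** The query (left anchor + insertion + right anchor,
gaps stripped) is aligned against candidate donor peptides with an in-repo
Smith–Waterman (affine gaps, cost `open + extend·L`, deterministic
traceback preferring diagonal, then up, then left; tied maxima resolved to
the smallest (i, j)). Candidates are ranked by score, then identity over
the insertion span. This replaces an external database search: donors are
user-supplied sequences, which keeps the analysis closed and reproducible.

**Breakpoint scan.** Sliding-window (50 columns, step 10) Poisson-corrected
distances from the focal row to each reference clade give a window×clade
affinity matrix. The statistic Δ is the drop in total assignment cost when
windows left and right of a boundary may choose different clades versus
one clade for all windows. Both Δ and its permutation p-value (199
window-order shuffles, add-one corrected) are computed on the
*non-overlapping* window subset — overlapping windows are correlated and
not exchangeable under the null — while the breakpoint itself is then
refined to column resolution by a mismatch change-point fit between the
two assigned clades across the boundary region.

## Ablations

Concatenation appends markers column-wise with 0-based half-open partition
intervals; taxa missing from a marker get all-gap rows. Columns where a
taxon is gapped are uninformative about that taxon's placement (its
partial vector is all-ones), which is exactly why sparse marker coverage
makes a concatenation vulnerable to one contaminated marker.
Leave-one-marker-out re-runs trim → infer → classify once per removed
marker (the concatenation is re-trimmed after each removal);
leave-one-sequence-out replaces a single row of a single marker with gaps,
so the taxon keeps its placement signal from every other marker.

## Gene-architecture parsimony

The fused vs split RNA-polymerase A-subunit character is binary,
unordered and reversible (unit costs both ways). Minimum changes come
from generalized (multi-child) Fitch; all most-parsimonious
reconstructions are enumerated by a unit-cost Sankoff backtrace (capped
at 10,000, flagged if truncated), each change typed `split`
(fused→split) or `fusion`. The rooting scan attaches a pendant outgroup
leaf carrying a fixed state to every edge of the unrooted ingroup tree
and reports per-edge minimum counts. The bundled worked example encodes
the published character distribution on two rooted topologies; under the
Thaumarchaeota rooting one split (placed after the Korarchaeum
divergence) suffices, under the alternative rooting four events are
required. Reproducing the four-event count requires Korarchaeum nested
between Thaumarchaeota and Crenarchaeota, which is how the corresponding
source tree is drawn.

## Synthetic data

The generator evolves markers directly on species trees under the model
above, so sequences are born aligned; no natural indel process is
simulated (the pipeline consumes alignments, and indel realism is out of
scope). Two 20-taxon reference histories are bundled — four bacteria,
four eukaryotes and twelve archaea in four named phyla — identical except
for where the focal deep "Loki" lineage L3 and the eukaryote clade
attach. Branch lengths put substantial depth on the bacterial outgroup
(0.45) and deliberately little (0.03–0.1) on the stems around the
Archaea–Eukarya divergence: those are exactly the nodes that carry weak
signal in real deep phylogenies, and the diagnostics are only interesting
in that regime.

Chimeras are injected with full truth records. Segment chimeras replace a
window of the target row with the sequence of a *hidden donor leaf*
simulated inside the same run (grafted next to a donor taxon, or on the
stem above a donor clade for a paralog-like source), giving realistically
diverged donor residues rather than random peptides. Anchored insertions
add new columns carrying a donor-specific peptide in the target row and
gaps elsewhere; the generator damps the local substitution rate
(multiplier 0.05 over ±40 columns) so the flanks form detectable anchors,
and records the donor's own sequence with the peptide spliced in at the
homologous position — this is what makes donor attribution meaningful,
mirroring paralogs that carry such segments between the same conserved
anchors. Insertion lengths default to uniform on 5–31 residues.

The `ef2_like` preset is the flagship experiment: eight 300-column clean
markers on the three-domain history plus one 600-column marker whose
focal archaeal row carries a eukaryote-stem donor segment over columns
0–450. The focal taxon is covered by only two markers (the chimeric one
and one clean one), as is typical for partial metagenome-assembled
genomes; since gap columns carry no placement signal, the contest over
where L3 attaches is 450 donor columns against ~400 clean columns, and
the donor side wins — the full concatenation classifies `eocyte` with the
eukaryote clade sister to the contaminated lineage, while removing the
chimeric marker, or only its contaminated row, restores `woese`. Problem
sizes (20 taxa, 9 markers, 300–600 columns) are chosen so a full ablation
sweep completes in minutes on one CPU while every signal the experiment
needs remains clearly above sampling noise.

What passing these experiments does and does not show: the generator
matches the analysis model (LG+Γ4, no alignment error, no compositional
heterogeneity, no natural indels), so the experiments validate the
*diagnostics* — that the pipeline detects and attributes exactly the
conflicts that were injected — not the robustness of the inference to
model misspecification in real data.

## Numerical choices and limitations

- Branch lengths clamped to `[1e-8, 20]`; likelihood floors at 1e-300
  before logs; Q normalized to unit expected rate.
- NJ ties in the Q criterion break to the lowest index pair; negative
  intermediate branch lengths clamp to zero.
- Canonical Newick output orders children by smallest contained leaf
  label and prints lengths to 6 significant digits, so topologically
  identical trees serialize byte-identically. Supports are stored on
  edges (bipartition properties) and survive rerooting.
- Monophyly at polytomies is strict: the exact bipartition must exist.
- Every stage derives its RNG stream from the master seed via
  `numpy.random.SeedSequence`, and reports contain no timestamps, so runs
  are byte-reproducible.
- Not implemented (out of scope): SPR search, Bayesian inference,
  free-rate models, profile-HMM chimera detection, alignment
  construction, nucleotide models.
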