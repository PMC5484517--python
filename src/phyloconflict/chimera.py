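"""Screens for foreign-origin patches in marker alignments.

Two complementary detectors:

* anchored insertions - runs of columns where a focal sequence carries
  residues while the reference rows are gapped, flanked on both sides by
  highly conserved "anchor" regions.  Anchors make the insertion locatable
  and give the query context for donor attribution by local alignment.
* segment affinity scanning - sliding-window corrected distances from a
  focal sequence to candidate reference clades; a two-segment assignment
  that beats the best single-clade assignment by a large margin indicates a
  recombination/assembly breakpoint, assessed by a window-permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alignment import Alignment, GAP, UNKNOWN
from .trim import SimilarityMatrix, column_statistics, load_similarity_matrix

logger = logging.getLogger(__name__)


class ChimeraScanError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Anchored insertions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InsertionHit:
    focal_taxon: str
    start: int                      # insertion interval, 0-based half-open
    end: int
    length: int                     # focal residues inside the interval
    left_anchor: tuple[int, int]
    right_anchor: tuple[int, int]
    left_conservation: float
    right_conservation: float
    ref_gap_fraction: float


def detect_anchored_insertions(
    aln: Alignment,
    focal,
    reference,
    min_len: int = 5,
    anchor_len: int = 40,
    anchor_min_conservation: float = 0.55,
    ref_gap_min: float = 0.8,
    matrix: SimilarityMatrix | str = "BLOSUM62",
) -> list[InsertionHit]:
    """Find focal-specific insertions flanked by conserved anchors.

    A candidate run is a maximal block of >= ``min_len`` columns where the
    focal taxon is ungapped and at least ``ref_gap_min`` of the reference
    rows are gapped.  Both flanking ``anchor_len``-column windows must have
    mean reference conservation >= ``anchor_min_conservation``; runs too
    close to the alignment edge are dropped with a warning.
    """
    focal, reference = set(focal), set(reference)
    if focal & reference:
        raise ChimeraScanError("focal and reference taxon sets overlap")
    for t in focal | reference:
        if t not in aln.taxon_ids:
            raise ChimeraScanError(f"taxon {t!r} not in alignment")
    if isinstance(matrix, str):
        matrix = load_similarity_matrix(matrix)
    ref_aln = aln.select_taxa(sorted(reference))
    _, ref_cons = column_statistics(ref_aln, matrix)
    ref_gap = np.array([
        sum(1 for ch in ref_aln.column(j) if ch == GAP) / ref_aln.n_taxa
        for j in range(aln.n_columns)
    ])
    hits = []
    for taxon in sorted(focal):
        row = aln.row(taxon)
        qualifies = np.array([
            row[j] != GAP and ref_gap[j] >= ref_gap_min
            for j in range(aln.n_columns)
        ])
        j = 0
        while j < aln.n_columns:
            if not qualifies[j]:
                j += 1
                continue
            start = j
            while j < aln.n_columns and qualifies[j]:
                j += 1
            end = j
            n_res = sum(1 for ch in row[start:end] if ch != GAP)
            if n_res < min_len:
                continue
            if start < anchor_len or end > aln.n_columns - anchor_len:
                logger.warning(
                    "insertion run [%d,%d) of %s too close to the alignment "
                    "edge for %d-column anchors; dropped", start, end, taxon,
                    anchor_len,
                )
                continue
            left = (start - anchor_len, start)
            right = (end, end + anchor_len)
            lc = float(ref_cons[left[0]:left[1]].mean())
            rc = float(ref_cons[right[0]:right[1]].mean())
            if lc < anchor_min_conservation or rc < anchor_min_conservation:
                continue
            hits.append(InsertionHit(
                focal_taxon=taxon, start=start, end=end, length=n_res,
                left_anchor=left, right_anchor=right,
                left_conservation=lc, right_conservation=rc,
                ref_gap_fraction=float(ref_gap[start:end].mean()),
            ))
    return hits


# ---------------------------------------------------------------------------
# Smith-Waterman local alignment with affine gaps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalAlignment:
    score: float
    query_interval: tuple[int, int]     # 0-based half-open
    subject_interval: tuple[int, int]
    identity: float                     # identical / aligned residue pairs
    aligned_pairs: tuple                # ((qi, sj) or (qi, None)/(None, sj))


def local_align(query: str, subject: str, matrix: SimilarityMatrix | str = "BLOSUM62",
                gap_open: float = 11.0, gap_extend: float = 1.0) -> LocalAlignment:
    """Smith-Waterman with affine gap costs ``open + extend * L``.

    Deterministic: the traceback starts at the highest-scoring cell (ties:
    smallest (i, j)) and prefers diagonal over up over left moves.  A
    scoreless comparison returns score 0 and an empty alignment.
    """
    if isinstance(matrix, str):
        matrix = load_similarity_matrix(matrix)
    for name, seq in (("query", query), ("subject", subject)):
        if not seq:
            raise ChimeraScanError(f"{name} sequence is empty")
        bad = set(seq) - set("ACDEFGHIKLMNPQRSTVWY")
        if bad:
            raise ChimeraScanError(f"{name} contains illegal characters {sorted(bad)}")
    n, m = len(query), len(subject)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)   # gap in query (left moves)
    F = np.full((n + 1, m + 1), NEG)   # gap in subject (up moves)
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open - gap_extend,
                          E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open - gap_extend,
                          F[i - 1, j] - gap_extend)
            diag = H[i - 1, j - 1] + matrix.score(qi, subject[j - 1])
            H[i, j] = max(0.0, diag, E[i, j], F[i, j])
    best = float(H.max())
    if best <= 0.0:
        return LocalAlignment(0.0, (0, 0), (0, 0), 0.0, ())
    flat = int(np.argmax(H))            # row-major: smallest (i, j) tie-break
    i, j = divmod(flat, m + 1)
    pairs = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0.0:
                break
            diag = H[i - 1, j - 1] + matrix.score(query[i - 1], subject[j - 1])
            if H[i, j] == diag:
                pairs.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":              # gap in subject, consume query
            pairs.append((i - 1, None))
            if F[i, j] == H[i - 1, j] - gap_open - gap_extend:
                state = "H"
            i -= 1
        else:                            # E: gap in query, consume subject
            pairs.append((None, j - 1))
            if E[i, j] == H[i, j - 1] - gap_open - gap_extend:
                state = "H"
            j -= 1
    pairs.reverse()
    q_idx = [p[0] for p in pairs if p[0] is not None]
    s_idx = [p[1] for p in pairs if p[1] is not None]
    matched = [(a, b) for a, b in pairs if a is not None and b is not None]
    ident = (sum(1 for a, b in matched if query[a] == subject[b]) / len(matched)
             if matched else 0.0)
    return LocalAlignment(
        score=best,
        query_interval=(min(q_idx), max(q_idx) + 1) if q_idx else (0, 0),
        subject_interval=(min(s_idx), max(s_idx) + 1) if s_idx else (0, 0),
        identity=ident,
        aligned_pairs=tuple(pairs),
    )


# ---------------------------------------------------------------------------
# Donor attribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DonorAttribution:
    ranked: tuple      # (donor_id, donor_set_label, score, identity) desc
    top_label: str | None


def attribute_insertion_donor(hit: InsertionHit, aln: Alignment, donor_sets: dict,
                              matrix: SimilarityMatrix | str = "BLOSUM62",
                              donor_sequences: dict | None = None,
                              gap_open: float = 11.0,
                              gap_extend: float = 1.0) -> DonorAttribution:
    """Rank candidate donors by local alignment against the insertion+anchors.

    ``donor_sets`` maps a set label to a collection of donor ids;
    ``donor_sequences`` optionally supplies ungapped peptides for donor ids
    not present in the alignment.  The query is the focal row across
    left anchor + insertion + right anchor, gaps stripped.
    """
    if not donor_sets or all(not v for v in donor_sets.values()):
        raise ChimeraScanError("empty donor set")
    if isinstance(matrix, str):
        matrix = load_similarity_matrix(matrix)
    row = aln.row(hit.focal_taxon)
    query = row[hit.left_anchor[0]:hit.right_anchor[1]].replace(GAP, "").replace(UNKNOWN, "")
    if not query:
        raise ChimeraScanError("empty query after gap stripping")
    insertion_q = row[hit.start:hit.end].replace(GAP, "").replace(UNKNOWN, "")
    results = []
    for label, donors in donor_sets.items():
        for donor in donors:
            if donor_sequences and donor in donor_sequences:
                subject = donor_sequences[donor]
            else:
                subject = aln.row(donor)
            subject = subject.replace(GAP, "").replace(UNKNOWN, "")
            if not subject:
                continue
            res = local_align(query, subject, matrix, gap_open, gap_extend)
            # identity restricted to the insertion portion of the query
            ins_lo = len(row[hit.left_anchor[0]:hit.start].replace(GAP, "").replace(UNKNOWN, ""))
            ins_hi = ins_lo + len(insertion_q)
            matched = [(a, b) for a, b in res.aligned_pairs
                       if a is not None and b is not None and ins_lo <= a < ins_hi]
            if matched:
                ident = sum(1 for a, b in matched if query[a] == subject[b]) / len(matched)
            else:
                ident = 0.0
            results.append((donor, label, res.score, ident))
    results.sort(key=lambda r: (-r[2], -r[3], r[0]))
    top = results[0][1] if results else None
    return DonorAttribution(ranked=tuple(results), top_label=top)


# ---------------------------------------------------------------------------
# Segment affinity scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffinityProfile:
    window_starts: tuple
    window: int
    step: int
    clade_labels: tuple
    affinities: np.ndarray         # (n_windows, n_clades), NaN when unusable
    breakpoint_column: int | None
    breakpoint_window: int | None  # first window index of the right segment
    delta: float
    p_value: float
    left_clade: str | None
    right_clade: str | None
    joint_clade: str | None


def _corrected_distance(a: str, b: str) -> float:
    shared = [
        (x, y) for x, y in zip(a, b)
        if x not in (GAP, UNKNOWN) and y not in (GAP, UNKNOWN)
    ]
    if not shared:
        return np.nan
    p = sum(1 for x, y in shared if x != y) / len(shared)
    if p >= 1.0 - np.exp(-10.0):
        return 10.0
    return -np.log(1.0 - p)


def _two_segment_delta(aff: np.ndarray):
    """Best single-clade cost minus best split-at-b cost, maximized over b."""
    totals = aff.sum(axis=0)
    joint_cost = totals.min()
    joint_clade = int(totals.argmin())
    n = aff.shape[0]
    best = (0.0, None, joint_clade, joint_clade)
    prefix = aff.cumsum(axis=0)
    for b in range(1, n):
        left = prefix[b - 1]
        right = totals - left
        cost = left.min() + right.min()
        delta = joint_cost - cost
        if delta > best[0] + 1e-12:
            best = (delta, b, int(left.argmin()), int(right.argmin()))
    return best, joint_clade


def segment_affinity_scan(aln: Alignment, focal_taxon: str, clades: dict,
                          window: int = 50, step: int = 10,
                          n_permutations: int = 199, seed: int = 0) -> AffinityProfile:
    """Sliding-window clade affinities and a permutation breakpoint test.

    Affinity of the focal row to a clade within a window is the mean
    Poisson-corrected distance to the clade members over shared ungapped
    columns.  The breakpoint statistic Delta is the improvement in total
    assignment cost when windows left and right of a boundary may choose
    different clades; its null distribution comes from random permutations
    of the window order.
    """
    if len(clades) < 2:
        raise ChimeraScanError("need at least two reference clades")
    for label, members in clades.items():
        if focal_taxon in members:
            raise ChimeraScanError(f"focal taxon inside clade {label!r}")
    if window > aln.n_columns:
        raise ChimeraScanError("window wider than the alignment")
    labels = tuple(sorted(clades))
    focal_row = aln.row(focal_taxon)
    starts = tuple(range(0, aln.n_columns - window + 1, max(1, step)))
    aff = np.full((len(starts), len(labels)), np.nan)
    for wi, s in enumerate(starts):
        fseg = focal_row[s:s + window]
        for ci, label in enumerate(labels):
            ds = []
            for member in clades[label]:
                d = _corrected_distance(fseg, aln.row(member)[s:s + window])
                if not np.isnan(d):
                    ds.append(d)
            if ds:
                aff[wi, ci] = float(np.mean(ds))
    usable = ~np.isnan(aff).any(axis=1)
    aff_u = aff[usable]
    starts_u = tuple(s for s, u in zip(starts, usable) if u)
    if aff_u.shape[0] < 2:
        return AffinityProfile(starts, window, step, labels, aff, None, None,
                               0.0, 1.0, None, None,
                               labels[int(np.nanargmin(aff_u.sum(axis=0)))]
                               if aff_u.size else None)
    # the test statistic uses NON-overlapping windows only: overlapping
    # windows are correlated and would not be exchangeable under the null
    coarse_idx = [0]
    for wi, s in enumerate(starts_u):
        if s >= starts_u[coarse_idx[-1]] + window:
            coarse_idx.append(wi)
    aff_c = aff_u[coarse_idx]
    if aff_c.shape[0] < 2:
        aff_c = aff_u[:2]
        coarse_idx = [0, 1]
    (delta, b_c, left_c, right_c), joint_c = _two_segment_delta(aff_c)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(aff_c.shape[0])
        (d_perm, *_), _ = _two_segment_delta(aff_c[perm])
        if d_perm >= delta:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    bp_col = None
    b = None
    if b_c is not None:
        b = coarse_idx[b_c]
        # refine the window-grid boundary to column resolution with a
        # change-point fit between the two assigned clades; the zone spans
        # one extra coarse window each side so that a single misassigned
        # boundary window cannot push the truth outside it
        lo_idx = coarse_idx[max(b_c - 2, 0)]
        lo = starts_u[lo_idx]
        hi = min(aln.n_columns, starts_u[b] + 2 * window)
        all_members = sorted({t for v in clades.values() for t in v})
        bp_col = _refine_breakpoint(aln, focal_taxon, all_members, lo, hi,
                                    coarse_boundary=starts_u[b])
    return AffinityProfile(
        window_starts=starts_u, window=window, step=step, clade_labels=labels,
        affinities=aff_u, breakpoint_column=bp_col, breakpoint_window=b,
        delta=float(delta), p_value=float(p),
        left_clade=labels[left_c] if b is not None else None,
        right_clade=labels[right_c] if b is not None else None,
        joint_clade=labels[joint_c],
    )


def _refine_breakpoint(aln: Alignment, focal: str, members, lo: int,
                       hi: int, coarse_boundary: int, buffer: int = 25) -> int:
    """Column-resolution change point of the focal row's affinity profile.

    Per reference taxon, the focal-vs-taxon mismatch indicators over
    columns [lo, hi) form a two-segment Bernoulli series.  The before/after
    rates are estimated *once* per taxon from the coarse segmentation
    (excluding a ``buffer`` around the coarse boundary, which may be
    misplaced), and the breakpoint is the argmax of the fixed-rates
    log-likelihood - a cumulative sum of per-column scores with no free
    parameters, hence no overfitting toward spurious local optima.
    Modeling taxa individually preserves sharp single-taxon contrasts (a
    donor nearly identical to one reference) that pooling into clade means
    would wash out.  Ties pick the smallest column.
    """
    frow = aln.row(focal)
    n = hi - lo
    eps = 1e-3
    xs = []
    for t in members:
        row = aln.row(t)
        x = np.full(n, -1, dtype=np.int8)   # -1 = not comparable
        for i, j in enumerate(range(lo, hi)):
            if frow[j] in (GAP, UNKNOWN) or row[j] in (GAP, UNKNOWN):
                continue
            x[i] = 1 if row[j] != frow[j] else 0
        xs.append(x)

    score = np.zeros(n)
    for x in xs:
        left = x[: max(coarse_boundary - buffer - lo, 0)]
        right = x[min(coarse_boundary + buffer - lo, n):]
        lv, rv = left[left >= 0], right[right >= 0]
        if lv.size < 10 or rv.size < 10:
            continue
        pL = min(max(lv.mean(), eps), 1 - eps)
        pR = min(max(rv.mean(), eps), 1 - eps)
        # per-column evidence that the column belongs to the left segment
        s = np.where(x == 1, np.log(pL / pR), np.log((1 - pL) / (1 - pR)))
        score += np.where(x >= 0, s, 0.0)
    # LL(c) = sum_{j<c} score_j + const; argmax of the prefix sum
    prefix = np.concatenate([[0.0], score.cumsum()])
    return lo + int(np.argmax(prefix))


def split_alignment_at(aln: Alignment, column: int):
    """Split into columns [0, column) and [column, n); concatenation restores."""
    if not (0 < column < aln.n_columns):
        raise ChimeraScanError(f"split column {column} out of range")
    left = aln.select_columns(range(0, column))
    right = aln.select_columns(range(column, aln.n_columns))
    return left, right
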