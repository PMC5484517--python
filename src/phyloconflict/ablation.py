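"""Concatenation bookkeeping and perturbation experiments.

The supermatrix approach concatenates per-marker alignments column-wise,
gap-filling taxa missing from a marker.  The ablation experiments probe how
much the inferred topology class depends on single markers or single
sequences: leave-one-marker-out re-runs the full trim / infer / classify
pipeline with one marker removed; leave-one-sequence-out replaces a single
row of a single marker with gaps (the taxon keeps its other markers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import Alignment, GAP, PartitionedAlignment, TaxonGroupMap
from .diagnostics import TopologyClass, classify_topology
from .model import SubstitutionModel
from .search import infer_ml_tree
from .trim import trim_columns


class AblationError(ValueError):
    pass


@dataclass
class MarkerSet:
    """Ordered collection of (marker_id, Alignment) over a shared namespace."""

    markers: list

    def __post_init__(self):
        ids = [m for m, _ in self.markers]
        if len(set(ids)) != len(ids):
            raise AblationError("duplicate marker ids")

    @property
    def marker_ids(self) -> list:
        return [m for m, _ in self.markers]

    def alignment(self, marker_id: str) -> Alignment:
        for mid, aln in self.markers:
            if mid == marker_id:
                return aln
        raise KeyError(marker_id)

    def all_taxa(self) -> list:
        seen = {}
        for _, aln in self.markers:
            for t in aln.taxon_ids:
                seen.setdefault(t, None)
        return list(seen)

    def coverage(self) -> dict:
        return {
            mid: tuple(aln.taxon_ids) for mid, aln in self.markers
        }


def concatenate_markers(markers: MarkerSet, fill_missing: bool = True) -> PartitionedAlignment:
    """Column-wise concatenation with partition bookkeeping.

    Taxa absent from a marker get all-gap rows for that partition (unless
    ``fill_missing`` is False, in which case identical taxon sets are
    required).
    """
    if not markers.markers:
        raise AblationError("no markers to concatenate")
    taxa = markers.all_taxa()
    if not fill_missing:
        for mid, aln in markers.markers:
            if set(aln.taxon_ids) != set(taxa):
                missing = sorted(set(taxa) - set(aln.taxon_ids))
                raise AblationError(
                    f"marker {mid!r} missing taxa {missing} with fill_missing=False"
                )
    parts = []
    rows = {t: [] for t in taxa}
    pos = 0
    for mid, aln in markers.markers:
        width = aln.n_columns
        for t in taxa:
            if t in aln.taxon_ids:
                rows[t].append(aln.row(t))
            else:
                rows[t].append(GAP * width)
        parts.append((mid, pos, pos + width))
        pos += width
    aln = Alignment.from_pairs((t, "".join(rows[t])) for t in taxa)
    return PartitionedAlignment(alignment=aln, partitions=tuple(parts))


def remove_taxa(markers: MarkerSet, taxa, min_taxa: int = 4) -> MarkerSet:
    """Drop named taxa from every marker (absent names are ignored)."""
    drop = set(taxa)
    out = []
    for mid, aln in markers.markers:
        kept = aln.drop_taxa(drop)
        if kept.n_taxa < min_taxa:
            raise AblationError(
                f"removing {sorted(drop)} leaves marker {mid!r} with "
                f"{kept.n_taxa} < {min_taxa} taxa"
            )
        out.append((mid, kept))
    return MarkerSet(out)


@dataclass
class PipelineConfig:
    """Settings shared by every (re-)inference inside an ablation."""

    model: SubstitutionModel
    groups: TaxonGroupMap
    trim: bool = True
    trim_kwargs: dict = field(default_factory=dict)
    search_kwargs: dict = field(default_factory=dict)
    support_min: float = 0.0


@dataclass
class AblationRecord:
    removed: tuple                      # (marker_id,) or (marker_id, taxon)
    before: TopologyClass
    after: TopologyClass
    flipped: bool
    log_likelihood: float


def _classify_concatenation(markers: MarkerSet, config: PipelineConfig):
    pa = concatenate_markers(markers)
    aln = pa.alignment
    if config.trim:
        aln = trim_columns(aln, **config.trim_kwargs).trimmed
    result = infer_ml_tree(aln, config.model, **config.search_kwargs)
    cls = classify_topology(result.tree, config.groups,
                            support_min=config.support_min)
    return cls, result


def leave_one_marker_out(markers: MarkerSet, config: PipelineConfig,
                         before: tuple | None = None) -> list:
    """Re-run the pipeline once per removed marker.

    ``before`` optionally supplies a pre-computed (class, SearchResult) for
    the full set so callers can reuse it.  Returns one
    :class:`AblationRecord` per marker.
    """
    if len(markers.markers) < 2:
        raise AblationError("need at least two markers to leave one out")
    if before is None:
        before = _classify_concatenation(markers, config)
    before_cls, _ = before
    records = []
    for mid, _ in markers.markers:
        reduced = MarkerSet([(m, a) for m, a in markers.markers if m != mid])
        after_cls, result = _classify_concatenation(reduced, config)
        records.append(AblationRecord(
            removed=(mid,), before=before_cls, after=after_cls,
            flipped=before_cls.label != after_cls.label,
            log_likelihood=result.log_likelihood,
        ))
    return records


def leave_one_sequence_out(markers: MarkerSet, target, config: PipelineConfig,
                           before: tuple | None = None) -> AblationRecord:
    """Gap out one row of one marker and re-run the pipeline.

    The taxon keeps its rows in every other marker, so it stays in the tree
    through the rest of the concatenation.
    """
    marker_id, taxon = target
    aln = markers.alignment(marker_id)
    if taxon not in aln.taxon_ids:
        raise AblationError(f"taxon {taxon!r} not present in marker {marker_id!r}")
    row = aln.row(taxon)
    if set(row) == {GAP}:
        raise AblationError(f"{taxon!r} already gapped in {marker_id!r}")
    if before is None:
        before = _classify_concatenation(markers, config)
    before_cls, _ = before
    gapped = aln.with_row(taxon, GAP * aln.n_columns)
    reduced = MarkerSet([
        (m, gapped if m == marker_id else a) for m, a in markers.markers
    ])
    after_cls, result = _classify_concatenation(reduced, config)
    return AblationRecord(
        removed=(marker_id, taxon), before=before_cls, after=after_cls,
        flipped=before_cls.label != after_cls.label,
        log_likelihood=result.log_likelihood,
    )
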