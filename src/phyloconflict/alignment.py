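"""Aligned protein matrices and the taxon metadata that travels with them.

The central container is :class:`Alignment`, an immutable taxa-by-columns
residue matrix over the 20 amino-acid letters plus ``-`` (gap) and ``X``
(unknown).  All column coordinates in this package are 0-based, half-open.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALLOWED_CHARS = frozenset(AMINO_ACIDS) | {GAP, UNKNOWN}

DOMAINS = ("Archaea", "Bacteria", "Eukarya")


class AlignmentFormatError(ValueError):
    """Raised for ragged rows, duplicate ids or illegal residue characters."""


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", GAP)


@dataclass(frozen=True)
class Alignment:
    """Immutable multiple alignment of protein sequences.

    Parameters
    ----------
    taxon_ids:
        Unique sequence identifiers, in display order.
    rows:
        One residue string per taxon, all of equal length.
    """

    taxon_ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.taxon_ids) != len(self.rows):
            raise AlignmentFormatError("taxon_ids and rows differ in length")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            dupes = {t for t in self.taxon_ids if self.taxon_ids.count(t) > 1}
            raise AlignmentFormatError(f"duplicate taxon ids: {sorted(dupes)}")
        if self.rows:
            width = len(self.rows[0])
            for tid, row in zip(self.taxon_ids, self.rows):
                if len(row) != width:
                    raise AlignmentFormatError(
                        f"ragged alignment: record {tid!r} has length "
                        f"{len(row)}, expected {width}"
                    )
                bad = set(row) - ALLOWED_CHARS
                if bad:
                    raise AlignmentFormatError(
                        f"record {tid!r} contains illegal characters {sorted(bad)}"
                    )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        ids, rows = [], []
        for tid, row in pairs:
            ids.append(tid)
            rows.append(_normalize(row))
        return cls(tuple(ids), tuple(rows))

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        try:
            return self.rows[self.taxon_ids.index(taxon)]
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def select_columns(self, columns: Sequence[int]) -> "Alignment":
        rows = tuple("".join(r[j] for j in columns) for r in self.rows)
        return Alignment(self.taxon_ids, rows)

    def select_taxa(self, taxa: Sequence[str]) -> "Alignment":
        keep = [t for t in self.taxon_ids if t in set(taxa)]
        return Alignment(tuple(keep), tuple(self.row(t) for t in keep))

    def drop_taxa(self, taxa: Iterable[str]) -> "Alignment":
        drop = set(taxa)
        keep = [t for t in self.taxon_ids if t not in drop]
        return Alignment(tuple(keep), tuple(self.row(t) for t in keep))

    def with_row(self, taxon: str, row: str) -> "Alignment":
        """Return a copy with one row replaced (same width enforced)."""
        if len(row) != self.n_columns:
            raise AlignmentFormatError("replacement row has wrong width")
        i = self.taxon_ids.index(taxon)
        rows = list(self.rows)
        rows[i] = _normalize(row)
        return Alignment(self.taxon_ids, tuple(rows))


def read_alignment_fasta(path) -> Alignment:
    """Read an aligned FASTA file.

    Sequences are upper-cased and ``.`` is normalized to ``-``.  Records are
    kept in file order.  Ragged records or duplicate ids raise
    :class:`AlignmentFormatError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise AlignmentFormatError(f"{path}: need >=2 FASTA records, got {len(records)}")
    return Alignment.from_pairs((r.id, str(r.seq)) for r in records)


def write_alignment_fasta(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(row), id=tid, description="")
        for tid, row in zip(aln.taxon_ids, aln.rows)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def alignment_to_fasta_text(aln: Alignment) -> str:
    buf = _io.StringIO()
    for tid, row in zip(aln.taxon_ids, aln.rows):
        buf.write(f">{tid}\n{row}\n")
    return buf.getvalue()


@dataclass(frozen=True)
class PartitionedAlignment:
    """A concatenated alignment plus its marker partition table.

    ``partitions`` is an ordered list of ``(marker_id, start, end)`` with
    0-based half-open column intervals that are disjoint, contiguous and
    cover ``[0, n_columns)``.
    """

    alignment: Alignment
    partitions: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        pos = 0
        seen = set()
        for marker_id, start, end in self.partitions:
            if marker_id in seen:
                raise ValueError(f"duplicate marker id {marker_id!r}")
            seen.add(marker_id)
            if start != pos or end < start:
                raise ValueError(
                    f"partition {marker_id!r} [{start},{end}) not contiguous at {pos}"
                )
            pos = end
        if pos != self.alignment.n_columns:
            raise ValueError(
                f"partitions cover [0,{pos}) but alignment has "
                f"{self.alignment.n_columns} columns"
            )

    def marker_interval(self, marker_id: str) -> tuple[int, int]:
        for mid, start, end in self.partitions:
            if mid == marker_id:
                return start, end
        raise KeyError(marker_id)

    def marker_alignment(self, marker_id: str) -> Alignment:
        start, end = self.marker_interval(marker_id)
        return self.alignment.select_columns(range(start, end))


def write_partition_tsv(pa: PartitionedAlignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tstart\tend\n")
        for mid, start, end in pa.partitions:
            fh.write(f"{mid}\t{start}\t{end}\n")


def read_partition_tsv(path) -> tuple[tuple[str, int, int], ...]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("marker_id"):
            raise ValueError(f"{path}: expected header 'marker_id\\tstart\\tend'")
        for line in fh:
            if not line.strip():
                continue
            mid, start, end = line.rstrip("\n").split("\t")
            out.append((mid, int(start), int(end)))
    return tuple(out)


@dataclass(frozen=True)
class TaxonGroupMap:
    """Maps each taxon to a (group, domain) pair.

    Domains are restricted to the fixed three-domain set Archaea / Bacteria /
    Eukarya; groups are free-form labels (archaeal phyla, etc.).
    """

    mapping: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        for taxon, (group, domain) in self.mapping.items():
            if domain not in DOMAINS:
                raise ValueError(
                    f"taxon {taxon!r}: domain {domain!r} not in {DOMAINS}"
                )

    def group(self, taxon: str) -> str:
        return self.mapping[taxon][0]

    def domain(self, taxon: str) -> str:
        return self.mapping[taxon][1]

    def taxa(self) -> list[str]:
        return list(self.mapping)

    def taxa_in_domain(self, domain: str, subset: Iterable[str] | None = None) -> set[str]:
        pool = self.mapping if subset is None else subset
        return {t for t in pool if self.mapping[t][1] == domain}

    def taxa_in_group(self, group: str, subset: Iterable[str] | None = None) -> set[str]:
        pool = self.mapping if subset is None else subset
        return {t for t in pool if self.mapping[t][0] == group}

    def check_covers(self, taxa: Iterable[str]) -> None:
        missing = [t for t in taxa if t not in self.mapping]
        if missing:
            raise KeyError(f"taxa missing from group map: {sorted(missing)}")


def read_taxon_group_tsv(path) -> TaxonGroupMap:
    mapping = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("taxon"):
            raise ValueError(f"{path}: expected header 'taxon\\tgroup\\tdomain'")
        for line in fh:
            if not line.strip():
                continue
            taxon, group, domain = line.rstrip("\n").split("\t")
            mapping[taxon] = (group, domain)
    return TaxonGroupMap(mapping)


def write_taxon_group_tsv(groups: TaxonGroupMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tgroup\tdomain\n")
        for taxon, (group, domain) in groups.mapping.items():
            fh.write(f"{taxon}\t{group}\t{domain}\n")
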