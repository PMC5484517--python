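"""Synthetic marker sets with the statistical structure the pipeline assumes.

Sequences are evolved under the package's reversible model (LG+Gamma by
default) directly on a species tree, so they are born aligned: no natural
indel process is simulated.  The generator can place markers on
*conflicting* species histories (an "archaea-monophyletic" tree and an
"eukaryotes-inside-archaea" tree), scale pendant branches of designated
fast-evolving taxa, and inject two kinds of chimeric contamination with a
machine-readable truth record:

* segment chimeras - a window of a target row replaced by residues of a
  donor lineage (simulated as a hidden leaf grafted next to the donor);
* anchored insertions - new columns carrying a donor-derived peptide in the
  target row and gaps everywhere else, placed inside a locally conserved
  region (the generator suppresses the local substitution rate so the
  flanking anchors are conserved).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import Alignment
from .model import MODEL_ALPHABET, SubstitutionModel, lg_model
from .tree import Node, PhyloTree, leafset_below, parse_newick


class SimulationError(ValueError):
    pass


def _spawn_seed(master: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master), *key]))


def simulate_alignment(tree: PhyloTree, model: SubstitutionModel, n_sites: int,
                       seed: int | np.random.Generator,
                       site_rate_multipliers: np.ndarray | None = None) -> Alignment:
    """Evolve ``n_sites`` residues down ``tree`` under the model.

    Root states are drawn from the stationary frequencies; each site draws a
    gamma category once; transitions use P(t * r_k).  Optional per-site rate
    multipliers (e.g. to carve conserved anchor regions) multiply the
    category rate.  Output rows follow the tree's leaf order.
    """
    if n_sites < 1:
        raise SimulationError("n_sites must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pi = model.frequencies
    cats = rng.integers(0, model.n_categories, n_sites)
    rates = model.category_rates[cats]
    if site_rate_multipliers is not None:
        mult = np.asarray(site_rate_multipliers, dtype=float)
        if mult.shape != (n_sites,):
            raise SimulationError("site_rate_multipliers has wrong length")
        rates = rates * mult
    # group sites by effective rate for vectorized transition sampling
    uniq_rates, rate_idx = np.unique(rates, return_inverse=True)
    states = {tree.root: rng.choice(20, size=n_sites, p=pi)}
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_states = states[node.parent]
        child = np.empty(n_sites, dtype=np.int64)
        u = rng.random(n_sites)
        for ri, r in enumerate(uniq_rates):
            idx = np.nonzero(rate_idx == ri)[0]
            if idx.size == 0:
                continue
            P = model.transition_matrix(node.length * r)
            cum = P.cumsum(axis=1)
            child[idx] = (u[idx, None] > cum[parent_states[idx]]).sum(axis=1)
        states[node] = child
    pairs = []
    for leaf in tree.leaves():
        row = "".join(MODEL_ALPHABET[s] for s in states[leaf])
        pairs.append((leaf.name, row))
    return Alignment.from_pairs(pairs)


def scale_branches(tree: PhyloTree, taxa, factor: float) -> PhyloTree:
    """Multiply the pendant branches of the named taxa by ``factor`` (>= 1)."""
    if factor < 1:
        raise SimulationError("branch multiplier must be >= 1")
    out = tree.copy()
    names = set(taxa)
    found = set()
    for leaf in out.leaves():
        if leaf.name in names:
            leaf.length *= factor
            found.add(leaf.name)
    missing = names - found
    if missing:
        raise SimulationError(f"unknown taxa for branch scaling: {sorted(missing)}")
    return out


def graft_leaf(tree: PhyloTree, at_taxon: str, new_name: str,
               stem: float = 0.05, pendant: float = 0.05) -> PhyloTree:
    """Attach a new leaf on the pendant edge of ``at_taxon``.

    The pendant edge is split at ``stem`` below its parent; the new leaf
    hangs from the junction with length ``pendant``.
    """
    out = tree.copy()
    leaf = out.find_leaf(at_taxon)
    return _graft_at(out, leaf, new_name, stem, pendant)


def graft_on_stem(tree: PhyloTree, clade_taxa, new_name: str,
                  stem: float = 0.05, pendant: float = 0.1) -> PhyloTree:
    """Attach a new leaf on the stem edge above the MRCA of ``clade_taxa``.

    Models a lineage that diverged just before the crown of a clade (for
    eukaryotes: a paralog-like donor splitting off on the stem).
    """
    out = tree.copy()
    want = frozenset(clade_taxa)
    mrca = None
    for node in out.postorder():          # postorder: first hit is minimal
        if want <= leafset_below(node):
            mrca = node
            break
    if mrca is None or mrca.parent is None:
        raise SimulationError(f"no stem edge above the MRCA of {sorted(want)}")
    return _graft_at(out, mrca, new_name, stem, pendant)


def _graft_at(out: PhyloTree, node: Node, new_name: str,
              stem: float, pendant: float) -> PhyloTree:
    parent = node.parent
    junction = Node(length=min(stem, node.length))
    idx = parent.children.index(node)
    parent.children[idx] = junction
    junction.parent = parent
    node.length = max(node.length - junction.length, 1e-6)
    junction.add_child(node)
    junction.add_child(Node(name=new_name, length=pendant))
    return PhyloTree(out.root, rooted=out.rooted)


@dataclass(frozen=True)
class ChimeraSpec:
    """One planned contamination event.

    ``kind`` is ``segment`` (replace ``interval`` of the target row with
    donor residues) or ``insertion`` (insert ``length`` new donor columns at
    ``position``; drawn uniformly from 5-31 when ``length`` is None).
    ``donor`` names the lineage whose simulated sequence supplies residues.
    ``anchor_multiplier`` (< 1) damps the local substitution rate around an
    insertion point so the flanks form conserved anchors.
    """

    kind: str
    marker: str
    taxon: str
    donor: str
    interval: tuple[int, int] | None = None   # segment kind
    position: int | None = None               # insertion kind
    length: int | None = None
    anchor_multiplier: float = 0.05
    anchor_len: int = 40
    donor_stem: float = 0.05                  # where the hidden donor grafts
    donor_pendant: float = 0.05

    def __post_init__(self):
        if self.kind not in ("segment", "insertion"):
            raise SimulationError(f"unknown chimera kind {self.kind!r}")
        if self.kind == "segment" and self.interval is None:
            raise SimulationError("segment chimera needs an interval")
        if self.kind == "insertion" and self.position is None:
            raise SimulationError("insertion chimera needs a position")
        if not (0 < self.anchor_multiplier < 1):
            raise SimulationError("anchor_multiplier must be in (0, 1)")


@dataclass
class SimConfig:
    """Complete description of one synthetic study."""

    species_trees: dict            # history label -> PhyloTree
    markers: list                  # (marker_id, n_sites, history label)
    model: SubstitutionModel = field(default_factory=lg_model)
    fes: dict = field(default_factory=dict)      # taxon -> multiplier (>= 1)
    chimeras: list = field(default_factory=list)
    missing: dict = field(default_factory=dict)  # marker_id -> taxa absent
    seed: int = 0

    def __post_init__(self):
        histories = set(self.species_trees)
        for mid, n_sites, history in self.markers:
            if history not in histories:
                raise SimulationError(f"marker {mid!r}: unknown history {history!r}")
        ids = [m[0] for m in self.markers]
        if len(set(ids)) != len(ids):
            raise SimulationError("duplicate marker ids")
        for mult in self.fes.values():
            if mult < 1:
                raise SimulationError("FES multipliers must be >= 1")
        marker_ids = set(ids)
        for spec in self.chimeras:
            if spec.marker not in marker_ids:
                raise SimulationError(f"chimera targets unknown marker {spec.marker!r}")
            if spec.taxon in self.missing.get(spec.marker, ()):
                raise SimulationError(
                    f"chimera target {spec.taxon!r} is absent from {spec.marker!r}"
                )


@dataclass
class TruthSet:
    """Machine-readable record of everything the generator injected."""

    marker_histories: dict = field(default_factory=dict)
    chimeras: list = field(default_factory=list)   # realized dicts
    fes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "marker_histories": dict(self.marker_histories),
            "chimeras": [dict(c) for c in self.chimeras],
            "fes": dict(self.fes),
        }


def inject_segment_chimera(aln: Alignment, spec: ChimeraSpec, donor_row: str):
    """Replace the target row over ``spec.interval`` with donor residues."""
    start, end = spec.interval
    if not (0 <= start <= end <= aln.n_columns):
        raise SimulationError(f"interval [{start},{end}) out of bounds")
    if len(donor_row) != end - start:
        raise SimulationError("donor segment width mismatch")
    row = aln.row(spec.taxon)
    new_row = row[:start] + donor_row + row[end:]
    truth = {
        "kind": "segment", "marker": spec.marker, "taxon": spec.taxon,
        "donor": spec.donor if isinstance(spec.donor, str) else list(spec.donor),
        "start": start, "end": end,
    }
    return aln.with_row(spec.taxon, new_row), truth


def inject_anchored_insertion(aln: Alignment, spec: ChimeraSpec, donor_peptide: str):
    """Insert donor-only columns at ``spec.position``.

    The target taxon carries the donor peptide across the new columns; every
    other row gets gaps.  The caller is responsible for having simulated a
    conserved neighbourhood (see :class:`ChimeraSpec.anchor_multiplier`).
    """
    pos = spec.position
    if not (0 < pos < aln.n_columns):
        raise SimulationError("insertion position must be strictly inside the alignment")
    if pos < spec.anchor_len or pos > aln.n_columns - spec.anchor_len:
        raise SimulationError(
            f"cannot build {spec.anchor_len}-column anchors around position {pos}"
        )
    width = len(donor_peptide)
    gaps = "-" * width
    pairs = []
    for tid, row in zip(aln.taxon_ids, aln.rows):
        ins = donor_peptide if tid == spec.taxon else gaps
        pairs.append((tid, row[:pos] + ins + row[pos:]))
    truth = {
        "kind": "insertion", "marker": spec.marker, "taxon": spec.taxon,
        "donor": spec.donor if isinstance(spec.donor, str) else list(spec.donor),
        "start": pos, "end": pos + width, "length": width,
    }
    return Alignment.from_pairs(pairs), truth


def _site_rate_profile(n_sites: int, specs, default: float = 1.0) -> np.ndarray | None:
    """Damped-rate zones around planned insertion points."""
    ins = [s for s in specs if s.kind == "insertion"]
    if not ins:
        return None
    mult = np.full(n_sites, default)
    for s in ins:
        lo = max(0, s.position - s.anchor_len)
        hi = min(n_sites, s.position + s.anchor_len)
        mult[lo:hi] = s.anchor_multiplier
    return mult


def make_conflicting_marker_set(config: SimConfig):
    """Simulate every marker on its assigned history and inject chimeras.

    Returns ``(markers, truth)`` where ``markers`` is a list of
    ``(marker_id, Alignment)`` in config order and ``truth`` a
    :class:`TruthSet`.  Fully reproducible from ``config.seed``.
    """
    truth = TruthSet(fes=dict(config.fes))
    out = []
    by_marker: dict[str, list[ChimeraSpec]] = {}
    for spec in config.chimeras:
        by_marker.setdefault(spec.marker, []).append(spec)
    for m_idx, (mid, n_sites, history) in enumerate(config.markers):
        tree = config.species_trees[history]
        if config.fes:
            tree = scale_branches(tree, list(config.fes), 1.0)
            for taxon, mult in config.fes.items():
                tree = scale_branches(tree, [taxon], mult)
        specs = by_marker.get(mid, [])
        # hidden donor leaves give realistically diverged donor sequences
        donor_names = {}
        sim_tree = tree.copy()
        for c_idx, spec in enumerate(specs):
            hidden = f"__donor_{c_idx}__"
            if isinstance(spec.donor, str):
                sim_tree = graft_leaf(sim_tree, spec.donor, hidden,
                                      spec.donor_stem, spec.donor_pendant)
            else:                         # clade: graft on its stem edge
                sim_tree = graft_on_stem(sim_tree, spec.donor, hidden,
                                         spec.donor_stem, spec.donor_pendant)
            donor_names[id(spec)] = hidden
        rng = _spawn_seed(config.seed, 1, m_idx)
        profile = _site_rate_profile(n_sites, specs)
        aln = simulate_alignment(sim_tree, config.model, n_sites, rng, profile)
        donor_rows = {h: aln.row(h) for h in donor_names.values()}
        aln = aln.drop_taxa(donor_names.values())
        absent = config.missing.get(mid, ())
        if absent:
            aln = aln.drop_taxa(absent)
        truth.marker_histories[mid] = history
        # segments first (coordinates refer to the simulated matrix), then
        # insertions right-to-left so earlier coordinates stay valid
        for spec in sorted(specs, key=lambda s: (s.kind != "segment",
                                                 -(s.position or 0))):
            donor_row = donor_rows[donor_names[id(spec)]]
            if spec.kind == "segment":
                start, end = spec.interval
                aln, entry = inject_segment_chimera(aln, spec, donor_row[start:end])
            else:
                length = spec.length
                if length is None:
                    length = int(rng.integers(5, 32))
                # the insertion is a donor-specific segment: novel residues
                # that the donor lineage carries at the homologous position
                # (between the same anchors), absent from everyone else
                pi = config.model.frequencies
                peptide = "".join(
                    MODEL_ALPHABET[i]
                    for i in rng.choice(20, size=length, p=pi)
                )
                spec2 = replace(spec, length=length)
                pos = spec.position
                entry_donor_seq = (donor_row[:pos] + peptide
                                   + donor_row[pos:])
                aln, entry = inject_anchored_insertion(aln, spec2, peptide)
                entry["donor_sequence"] = entry_donor_seq
            truth.chimeras.append(entry)
        out.append((mid, aln))
    return out, truth


# ---------------------------------------------------------------------------
# Reference topologies and the bundled presets
# ---------------------------------------------------------------------------

# Building blocks of the preset species trees.
_BACT = "((B1:0.25,B2:0.25):0.15,(B3:0.25,B4:0.25):0.15)"
_EUK = "((E1:0.15,E2:0.15):0.1,(E3:0.15,E4:0.15):0.1)"
_LOKI = "(L1:0.15,L2:0.15)"
_YCT = ("((Y1:0.12,(Y2:0.12,Y3:0.12):0.05):0.06,"
        "((C1:0.12,(C2:0.12,C3:0.12):0.05):0.06,"
        "(T1:0.12,(T2:0.12,T3:0.12):0.05):0.06):0.04)")

#: Three-domain history: Archaea monophyletic, sister to Eukarya
#: ("archaea-monophyletic" / Woese-style tree).  The focal Loki lineage L3
#: branches deep in Archaea on a long pendant with no close sister, and the
#: stems around the Archaea-Eukarya divergence are short - mirroring real
#: deep phylogenies where exactly these nodes carry little signal.
WOESE_NEWICK = (
    f"({_BACT}:0.45,({_EUK}:0.06,"
    f"(L3:0.08,({_LOKI}:0.06,{_YCT}:0.04):0.03):0.04):0.1);"
)

#: Eocyte-style history: the same taxa, the Eukarya clade nested inside
#: Archaea as sister group to the deep Loki lineage (Archaea paraphyletic).
EOCYTE_NEWICK = (
    f"({_BACT}:0.45,((L3:0.08,{_EUK}:0.06):0.03,"
    f"({_LOKI}:0.06,{_YCT}:0.04):0.03):0.14);"
)

#: Taxon -> (group, domain) for the bundled presets.
PRESET_GROUPS = {
    **{f"B{i}": ("Bacteria", "Bacteria") for i in range(1, 5)},
    **{f"E{i}": ("Eukarya", "Eukarya") for i in range(1, 5)},
    **{f"L{i}": ("Lokiarchaeota", "Archaea") for i in range(1, 4)},
    **{f"Y{i}": ("Euryarchaeota", "Archaea") for i in range(1, 4)},
    **{f"C{i}": ("Crenarchaeota", "Archaea") for i in range(1, 4)},
    **{f"T{i}": ("Thaumarchaeota", "Archaea") for i in range(1, 4)},
}


def preset_trees() -> dict:
    return {
        "woese": parse_newick(WOESE_NEWICK),
        "eocyte": parse_newick(EOCYTE_NEWICK),
    }


def ef2_like_preset(seed: int = 0, n_clean_sites: int = 300,
                    n_chimeric_sites: int = 600,
                    segment: tuple[int, int] = (0, 550),
                    focal_taxon: str = "L3",
                    donor=("E1", "E2", "E3", "E4"),
                    focal_present_in: tuple = ("M8", "M9")) -> SimConfig:
    """Eight clean markers on the three-domain history plus one long marker
    carrying a eukaryote-donor segment chimera in one archaeal taxon.

    The donor lineage diverges on the Eukarya stem (an EF2-paralog-like
    source), so the contaminated segment pulls the focal deep archaeal
    lineage toward the base of the Eukarya clade.  As in real metagenomic
    bins, the focal taxon is covered by only a subset of the markers
    (``focal_present_in``); columns where it is absent say nothing about
    its placement, which is what lets one long contaminated marker dominate
    a concatenation.
    """
    markers = [(f"M{i}", n_clean_sites, "woese") for i in range(1, 9)]
    markers.append(("M9", n_chimeric_sites, "woese"))
    chimera = ChimeraSpec(kind="segment", marker="M9", taxon=focal_taxon,
                          donor=donor, interval=segment,
                          donor_stem=0.05, donor_pendant=0.05)
    missing = {
        mid: (focal_taxon,)
        for mid, _, _ in markers
        if mid not in focal_present_in
    }
    return SimConfig(
        species_trees=preset_trees(),
        markers=markers,
        chimeras=[chimera],
        missing=missing,
        seed=seed,
    )


def insertion_screen_preset(seed: int = 0, n_sites: int = 400,
                            n_insertions: int = 1,
                            focal_taxon: str = "L3", donor: str = "E1") -> SimConfig:
    """A single marker with anchored donor insertions for screening tests."""
    rng = np.random.default_rng(seed)
    positions = sorted(
        rng.choice(np.arange(60, n_sites - 60), size=n_insertions, replace=False)
    )
    # keep insertion neighbourhoods disjoint
    specs = [
        ChimeraSpec(kind="insertion", marker="M1", taxon=focal_taxon,
                    donor=donor, position=int(p))
        for p in positions
    ]
    return SimConfig(
        species_trees=preset_trees(),
        markers=[("M1", n_sites, "woese")],
        chimeras=specs,
        seed=seed,
    )
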