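"""Bundled worked example: the fused vs split RNA-polymerase A subunit.

The largest RNA-polymerase subunit occurs either as a single polypeptide
(A-type, "fused") - as in Bacteria, Eukarya, Thaumarchaeota and
Korarchaeota - or split into A' and A'' ("split"), as in Euryarchaeota,
Crenarchaeota and the credible Lokiarchaeota sequences.  Which rooting of
the archaeal tree explains this distribution with the fewest fusion/split
events is a compact parsimony argument:

* under an archaeal tree rooted on the Thaumarchaeota branch (with
  Korarchaeum diverging next and Lokiarchaeota sister to Euryarchaeota), a
  single split event suffices, placed after the Korarchaeum divergence;
* under the alternative topology in which Eukarya emerge inside
  Lokiarchaeota (with the fast-evolving M. kandleri at the base of
  Archaea and Korarchaeum inside the TACK group), four events are needed.
"""

from __future__ import annotations

from .parsimony import FUSED, SPLIT, CharacterStateMap
from .tree import PhyloTree, parse_newick

#: Archaea rooted between Thaumarchaeota and everything else (bacterial
#: outgroup at the base); Lokiarchaeota sister to Euryarchaeota.
THAUM_ROOTED_NEWICK = (
    "(Bacteria:1.0,(Thaumarchaeota:0.3,(Korarchaeum:0.3,"
    "(Crenarchaeota:0.3,(Lokiarchaeota:0.3,Euryarchaeota:0.3):0.2):0.2):0.2):0.5);"
)

#: The alternative shape: M. kandleri at the base of Archaea, Korarchaeum
#: between Thaumarchaeota and Crenarchaeota, Eukarya sister to Loki 3
#: inside a paraphyletic Lokiarchaeota.
LOKI_ANCESTOR_NEWICK = (
    "(Bacteria:1.0,(Mkandleri:0.4,(Euryarchaeota:0.3,(Thaumarchaeota:0.3,"
    "(Korarchaeum:0.3,(Crenarchaeota:0.3,(Loki1:0.2,(Loki2:0.2,"
    "(Loki3:0.2,Eukarya:0.4):0.1):0.1):0.2):0.2):0.2):0.2):0.2):0.3);"
)

THAUM_ROOTED_STATES = {
    "Bacteria": FUSED,
    "Thaumarchaeota": FUSED,
    "Korarchaeum": FUSED,
    "Crenarchaeota": SPLIT,
    "Lokiarchaeota": SPLIT,
    "Euryarchaeota": SPLIT,
}

LOKI_ANCESTOR_STATES = {
    "Bacteria": FUSED,
    "Mkandleri": SPLIT,
    "Euryarchaeota": SPLIT,
    "Thaumarchaeota": FUSED,
    "Korarchaeum": FUSED,
    "Crenarchaeota": SPLIT,
    "Loki1": SPLIT,
    "Loki2": SPLIT,
    "Loki3": FUSED,
    "Eukarya": FUSED,
}


def thaum_rooted_example() -> tuple[PhyloTree, CharacterStateMap]:
    tree = parse_newick(THAUM_ROOTED_NEWICK)
    tree.rooted = True
    return tree, CharacterStateMap(dict(THAUM_ROOTED_STATES),
                                   alphabet=(FUSED, SPLIT))


def loki_ancestor_example() -> tuple[PhyloTree, CharacterStateMap]:
    tree = parse_newick(LOKI_ANCESTOR_NEWICK)
    tree.rooted = True
    return tree, CharacterStateMap(dict(LOKI_ANCESTOR_STATES),
                                   alphabet=(FUSED, SPLIT))
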