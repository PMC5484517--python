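"""End-to-end orchestration: generate/load markers, curate, trim, infer,
classify, AU-partition, ablate, chimera-scan and summarize.

Every stage draws its randomness from a seed derived deterministically from
the master seed, and the report contains no timestamps, so identical
configurations reproduce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .ablation import (MarkerSet, PipelineConfig, _classify_concatenation,
                       leave_one_marker_out, leave_one_sequence_out,
                       remove_taxa)
from .alignment import (TaxonGroupMap, read_alignment_fasta,
                        read_taxon_group_tsv)
from .autest import au_test, site_loglik_table
from .chimera import detect_anchored_insertions, segment_affinity_scan
from .diagnostics import (classify_topology, partition_markers_by_au,
                          tabulate_marker_trees)
from .examples import loki_ancestor_example, thaum_rooted_example
from .model import lg_model
from .parsimony import fitch_min_changes, reconstruct_events
from .search import bootstrap_support, infer_ml_tree
from .simulate import (PRESET_GROUPS, ef2_like_preset,
                       make_conflicting_marker_set, preset_trees)
from .tree import write_newick
from .trim import trim_columns

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (seed is mandatory)."""

    seed: int
    preset: str | None = "ef2_like"       # or None with explicit input paths
    marker_fastas: dict = field(default_factory=dict)   # marker_id -> path
    groups_tsv: str | None = None
    output_dir: str | None = None
    fes: tuple = ()                        # taxa to drop before anything else
    gamma_shape: float = 1.0
    n_categories: int = 4
    trim: bool = True
    gap_max: float = 0.2
    score_min: float = 0.3
    bootstrap_B: int = 0                   # 0 disables bootstrap supports
    au_alpha: float = 0.05
    au_B_per_scale: int = 1000
    search_max_rounds: int = 20
    stages: tuple = ("classify", "tabulate", "au", "chimera", "ablation",
                     "parsimony")
    loo_sequence: tuple | None = None      # (marker_id, taxon) or None = auto
    chimera_focal_group: str = "Lokiarchaeota"
    chimera_alpha: float = 0.05


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence([int(master), stage]).generate_state(1)[0]
               % (2 ** 31))


def _load_inputs(config: RunConfig):
    if config.preset == "ef2_like":
        sim = ef2_like_preset(seed=_stage_seed(config.seed, 0))
        markers, truth = make_conflicting_marker_set(sim)
        groups = TaxonGroupMap(PRESET_GROUPS)
        return MarkerSet(markers), groups, truth.to_dict()
    if config.preset is not None:
        raise PipelineError(f"unknown preset {config.preset!r}")
    if not config.marker_fastas or not config.groups_tsv:
        raise PipelineError("need marker_fastas and groups_tsv without a preset")
    markers = [(mid, read_alignment_fasta(path))
               for mid, path in sorted(config.marker_fastas.items())]
    groups = read_taxon_group_tsv(config.groups_tsv)
    return MarkerSet(markers), groups, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages and return the (JSON-serializable) report."""
    model = lg_model(gamma_shape=config.gamma_shape,
                     n_categories=config.n_categories)
    report: dict = {"provenance": _provenance(config)}
    markers, groups, truth = _load_inputs(config)
    if truth is not None:
        report["generator_truth"] = truth

    if config.fes:
        markers = remove_taxa(markers, config.fes)
        report["curation"] = {"removed_taxa": sorted(config.fes)}

    trimmed_markers = []
    trim_info = {}
    for mid, aln in markers.markers:
        if config.trim:
            res = trim_columns(aln, gap_max=config.gap_max,
                               score_min=config.score_min)
            trimmed_markers.append((mid, res.trimmed))
            trim_info[mid] = {"before": aln.n_columns,
                              "after": res.trimmed.n_columns}
        else:
            trimmed_markers.append((mid, aln))
            trim_info[mid] = {"before": aln.n_columns, "after": aln.n_columns}
    trimmed = MarkerSet(trimmed_markers)
    report["trim"] = trim_info

    marker_trees = []
    if "classify" in config.stages:
        section = {}
        for i, (mid, aln) in enumerate(trimmed.markers):
            result = infer_ml_tree(aln, model,
                                   max_rounds=config.search_max_rounds)
            if config.bootstrap_B > 0:
                bootstrap_support(aln, model, B=config.bootstrap_B,
                                  seed=_stage_seed(config.seed, 100 + i),
                                  ml_result=result,
                                  max_rounds=config.search_max_rounds)
            cls = classify_topology(result.tree, groups)
            marker_trees.append((mid, result.tree))
            section[mid] = {
                "class": cls.label,
                "sister_of_eukarya": sorted(cls.sister_of_eukarya),
                "archaea_support": cls.archaea_monophyly_support,
                "log_likelihood": round(result.log_likelihood, 4),
                "newick": write_newick(result.tree),
            }
        report["markers"] = section

    if "tabulate" in config.stages and marker_trees:
        phyla = sorted({g for g, d in groups.mapping.values() if d == "Archaea"})
        table = tabulate_marker_trees(marker_trees, groups, phyla)
        report["marker_table"] = table.summary
        report["marker_table_text"] = render_table1_style(table.summary, phyla)

    if "au" in config.stages:
        refs = _reference_topologies(config, markers)
        au_section = {}
        p_pairs = {}
        for i, (mid, aln) in enumerate(trimmed.markers):
            cand = {}
            for label, ref in refs.items():
                cand[label] = _restrict_tree(ref, aln.taxon_ids)
            table = site_loglik_table(list(cand.values()), aln, model,
                                      marker_id=mid,
                                      tree_ids=tuple(cand.keys()))
            res = au_test(table, B_per_scale=config.au_B_per_scale,
                          seed=_stage_seed(config.seed, 200 + i),
                          alpha=config.au_alpha)
            ps = dict(zip(res.tree_ids, (float(p) for p in res.p_values)))
            au_section[mid] = {"p_values": ps,
                               "confidence_set": list(res.confidence_set)}
            p_pairs[mid] = (ps.get("woese", 1.0), ps.get("eocyte", 1.0))
        part = partition_markers_by_au(p_pairs, alpha=config.au_alpha)
        report["au"] = {
            "per_marker": au_section,
            "partition": {
                "woese_relevant": list(part.woese_relevant),
                "eocyte_relevant": list(part.eocyte_relevant),
                "unresolved": list(part.unresolved),
                "both_rejected": list(part.both_rejected),
            },
        }

    chimera_flags = []
    if "chimera" in config.stages:
        section = {"insertions": [], "segment_scans": []}
        focal_taxa = sorted(groups.taxa_in_group(config.chimera_focal_group,
                                                 markers.all_taxa()))
        for mi, (mid, aln) in enumerate(markers.markers):   # untrimmed
            present_focal = [t for t in focal_taxa if t in aln.taxon_ids]
            if not present_focal:
                continue
            reference = [t for t in aln.taxon_ids if t not in focal_taxa]
            hits = detect_anchored_insertions(aln, present_focal, reference)
            for h in hits:
                section["insertions"].append({
                    "marker": mid, "taxon": h.focal_taxon,
                    "start": h.start, "end": h.end, "length": h.length,
                })
            clades = _scan_clades(groups, aln.taxon_ids)
            for fi, focal in enumerate(focal_taxa):
                if focal not in aln.taxon_ids:
                    continue
                cl = {k: [t for t in v if t != focal]
                      for k, v in clades.items()}
                cl = {k: v for k, v in cl.items() if v}
                if len(cl) < 2 or aln.n_columns < 120:
                    continue
                prof = segment_affinity_scan(
                    aln, focal, cl,
                    seed=_stage_seed(config.seed, 300 + 10 * mi + fi))
                entry = {
                    "marker": mid, "taxon": focal,
                    "breakpoint": prof.breakpoint_column,
                    "delta": round(prof.delta, 4),
                    "p_value": prof.p_value,
                    "left_clade": prof.left_clade,
                    "right_clade": prof.right_clade,
                    "significant": prof.p_value < config.chimera_alpha
                    and prof.left_clade != prof.right_clade,
                }
                section["segment_scans"].append(entry)
                if entry["significant"]:
                    chimera_flags.append((mid, focal))
        report["chimera"] = section

    if "ablation" in config.stages and len(markers.markers) >= 2:
        pc = PipelineConfig(
            model=model, groups=groups, trim=config.trim,
            trim_kwargs={"gap_max": config.gap_max,
                         "score_min": config.score_min},
            search_kwargs={"max_rounds": config.search_max_rounds},
        )
        before = _classify_concatenation(markers, pc)
        records = leave_one_marker_out(markers, pc, before=before)
        section = {
            "before_class": before[0].label,
            "before_sister_of_eukarya": sorted(before[0].sister_of_eukarya),
            "leave_one_marker_out": [
                {"removed": r.removed[0], "after_class": r.after.label,
                 "flipped": r.flipped}
                for r in records
            ],
        }
        target = config.loo_sequence
        if target is None and chimera_flags:
            target = chimera_flags[0]
        if target is not None:
            rec = leave_one_sequence_out(markers, tuple(target), pc,
                                         before=before)
            section["leave_one_sequence_out"] = {
                "removed": list(rec.removed),
                "after_class": rec.after.label,
                "flipped": rec.flipped,
            }
        report["ablation"] = section

    if "parsimony" in config.stages:
        report["parsimony"] = _parsimony_section()

    if config.output_dir:
        _write_outputs(config, report)
    return report


def _reference_topologies(config: RunConfig, markers: MarkerSet) -> dict:
    trees = preset_trees()
    return {"woese": trees["woese"], "eocyte": trees["eocyte"]}


def _restrict_tree(tree, taxa):
    keep = set(taxa)
    work = tree.copy()
    drop = [n for n in work.leaves() if n.name not in keep]
    for leaf in drop:
        parent = leaf.parent
        parent.children.remove(leaf)
        leaf.parent = None
        while parent is not None and len(parent.children) == 1 \
                and parent.parent is not None:
            child = parent.children[0]
            child.length += parent.length
            gp = parent.parent
            gp.children[gp.children.index(parent)] = child
            child.parent = gp
            parent.children = []
            parent.parent = None
            parent = gp
    # root may be left with a single child
    root = work.root
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.length = 0.0
    work.root = root
    return work


def _scan_clades(groups: TaxonGroupMap, taxa) -> dict:
    clades: dict = {}
    for t in taxa:
        g, d = groups.mapping[t]
        label = g if d == "Archaea" else d
        if d == "Bacteria":
            continue               # outgroup: not a plausible donor pool here
        clades.setdefault(label, []).append(t)
    return {k: sorted(v) for k, v in clades.items() if len(v) >= 2}


def _parsimony_section() -> dict:
    t1, s1 = thaum_rooted_example()
    t2, s2 = loki_ancestor_example()
    r1 = reconstruct_events(t1, s1)
    return {
        "thaum_rooted_min_changes": fitch_min_changes(t1, s1),
        "loki_ancestor_min_changes": fitch_min_changes(t2, s2),
        "thaum_rooted_events": [
            {"edge_below": sorted(e.edge_child_leafset), "type": e.kind}
            for e in (r1.events_per_mpr[0] if r1.events_per_mpr else ())
        ],
    }


def _provenance(config: RunConfig) -> dict:
    cfg = asdict(config)
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "version": __version__,
    }


def render_table1_style(summary: dict, phyla) -> str:
    """Fixed-width text table of the marker-tree tabulation."""
    lines = []
    w = 34
    lines.append(f"{'':{w}}  count")
    for phylum in phyla:
        entry = summary.get(f"monophyly_{phylum}")
        if entry is None:
            continue
        lines.append(f"{'Monophyly of ' + phylum:{w}}  {entry['any']}")
        for key, val in entry.items():
            if key.startswith(">"):
                lines.append(f"{'  BS ' + key:{w}}  {val}")
    lines.append(f"{'Monophyly of Archaea (BS = 100)':{w}}  "
                 f"{summary.get('archaea_monophyly_100', 0)}")
    loki = summary.get("loki_eukarya_sister", {})
    lines.append(f"{'Loki-Eukarya sister group':{w}}  {loki.get('any', 0)}")
    for key, val in loki.items():
        if key.startswith(">"):
            lines.append(f"{'  BS ' + key:{w}}  {val}")
    return "\n".join(lines) + "\n"


def _write_outputs(config: RunConfig, report: dict) -> None:
    os.makedirs(config.output_dir, exist_ok=True)
    path = os.path.join(config.output_dir, "report.json")
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    if "marker_table_text" in report:
        with open(os.path.join(config.output_dir, "marker_table.txt"), "w") as fh:
            fh.write(report["marker_table_text"])


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, default=str)
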