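"""End-to-end pipeline: simulate (optional) -> infer linkage groups ->
paint -> detect events -> map to tree, with a flat key=value config, a
run manifest and per-stage seeds derived by stable hashing."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional

import dendropy

from . import infer, paint, events, simulate
from .io_formats import (read_ortholog_table, read_tree, write_event_table,
                         write_ortholog_table, write_tree)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    tables_dir: Optional[str] = None
    tree_path: Optional[str] = None
    simulate_n_tips: int = 0  # >0 switches on simulation of inputs
    simulate_n_elements: int = 32
    simulate_n_events: int = 10
    min_orthologs: int = 5
    window: int = 17
    n_sims: int = 100_000
    bootstrap_n: int = 0
    bootstrap_frac: float = 0.5
    seed: int = 0
    sex_element: str = "MZ"
    outgroup_tips: List[str] = field(default_factory=list)
    small_elements: List[str] = field(default_factory=lambda: ["M25", "M29", "M30", "M31"])

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Flat ``key = value`` config; unknown keys are rejected."""
        known = {f.name: f for f in fields(cls)}
        kwargs: Dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                typ = known[key].type
                if typ in ("int", int):
                    kwargs[key] = int(val)
                elif typ in ("float", float):
                    kwargs[key] = float(val)
                elif "List" in str(typ):
                    kwargs[key] = [v for v in val.replace(",", " ").split() if v]
                else:
                    kwargs[key] = val
        return cls(**kwargs)

    def manifest(self) -> str:
        lines = ["# lepkaryo run manifest"]
        for f in fields(self):
            val = getattr(self, f.name)
            if isinstance(val, list):
                val = ",".join(str(v) for v in val)
            lines.append(f"{f.name} = {val}")
        return "\n".join(lines) + "\n"


def stage_seed(base_seed: int, stage: str) -> int:
    """Per-stage seed derived by stable hashing, below 2**31."""
    digest = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def run_pipeline(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.txt").write_text(config.manifest())

    params = infer.InferenceParams(config.min_orthologs, config.window)

    if config.simulate_n_tips:
        tree = simulate.simulate_tree(config.simulate_n_tips,
                                      stage_seed(config.seed, "tree"))
        ancestor = simulate.simulate_ancestral_genome(
            config.simulate_n_elements, seed=stage_seed(config.seed, "ancestor"))
        outgroup = config.outgroup_tips or simulate.basal_outgroup(tree)
        script = simulate.random_simple_script(
            tree, ancestor, config.simulate_n_events,
            stage_seed(config.seed, "script"), outgroup_tips=outgroup,
            min_fragment=config.window)
        ev_params = simulate.EvolutionParams(seed=stage_seed(config.seed, "evolve"))
        tables, truth = simulate.evolve_genomes(tree, ancestor, ev_params,
                                                script=script)
        write_tree(tree, out / "tree.nwk")
        sim_dir = out / "tables"
        sim_dir.mkdir(exist_ok=True)
        for sp, table in tables.items():
            write_ortholog_table(table, sim_dir / f"{sp}.tsv",
                                 metadata={"seed": config.seed})
        truth_rows = [f"{e.branch_id}\t{e.kind}\t{','.join(e.elements)}\t"
                      f"{'' if e.breakpoint_index is None else e.breakpoint_index}"
                      for e in truth.entries]
        (out / "truth_log.tsv").write_text(
            "# branch\tkind\telements\tbreakpoint_index\n"
            + "\n".join(truth_rows) + ("\n" if truth_rows else ""))
    else:
        if not (config.tables_dir and config.tree_path):
            raise ValueError("either simulate_n_tips or tables_dir+tree_path required")
        tree = read_tree(config.tree_path)
        tables = {}
        for path in sorted(Path(config.tables_dir).glob("*.tsv")):
            t = read_ortholog_table(path)
            tables[t.species_id] = t
        outgroup = config.outgroup_tips
        if not outgroup:
            raise ValueError("outgroup_tips required for inference")

    results, branch_events, root_id = infer.infer_algs(
        tables, tree, params, outgroup_tips=outgroup)
    root = results[root_id]
    sex_orths = None
    if config.simulate_n_tips:
        sex_orths = {o for label, ids, _ in ancestor.elements
                     for o in ids if label == ancestor.sex_element}
    mapping = infer.name_elements(root, sex_orths)
    root = infer.relabel(root, mapping)
    with open(out / "root_elements.tsv", "w") as fh:
        fh.write("# element\tn_orthologs\tmembers\n")
        for label in sorted(root.groups, key=_element_sort_key):
            members = sorted(root.groups[label])
            fh.write(f"{label}\t{len(members)}\t{','.join(members)}\n")

    if config.bootstrap_n:
        report = infer.bootstrap_algs(
            tables, tree, params, config.bootstrap_n, config.bootstrap_frac,
            mandatory=set(outgroup), seed=stage_seed(config.seed, "bootstrap"),
            outgroup_tips=outgroup)
        with open(out / "bootstrap.tsv", "w") as fh:
            fh.write("# replicate\tn_root_groups\n")
            for i, c in enumerate(report.group_counts):
                fh.write(f"{i}\t{c}\n")
            fh.write(f"# modal={report.modal_count} unanimous={report.unanimous} "
                     f"consistency={report.assignment_consistency:.4f}\n")

    paintings = {sp: paint.paint_species(t, root) for sp, t in tables.items()}
    frames = [paint.painting_to_frame(p) for p in paintings.values()]
    import pandas as pd
    pd.concat(frames).to_csv(out / "painting.tsv", sep="\t", index=False)

    calls = {sp: events.detect_events_species(p, config.window)
             for sp, p in paintings.items()}
    mapped = events.map_events_to_tree(calls, _pruned(tree, set(tables)))
    write_event_table(mapped, out / "events.tsv",
                      metadata={"seed": config.seed, "window": config.window})
    logger.info("pipeline complete: %d root groups, %d events",
                root.n_groups, len(mapped))
    return out


def _element_sort_key(label: str):
    if label == "MZ":
        return (1, 0)
    try:
        return (0, int(label.lstrip("M")))
    except ValueError:
        return (2, label)


def _pruned(tree: dendropy.Tree, keep):
    present = {l.taxon.label for l in tree.leaf_node_iter()}
    if present - keep:
        tree = tree.clone(depth=1)
        tree.retain_taxa_with_labels(sorted(present & keep))
    return tree
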