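"""End-to-end orchestration: simulate -> classify -> collapse -> summarize.

``run_pipeline`` executes the stages in order, writes every tabular output
as TSV plus a ``headline.json`` and a ``manifest.json`` recording the
config hash, seed, package versions and SHA-256 checksums of all outputs.
Identical config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    classify_trials,
    discordance_counts,
    records_to_frame,
    tabulate_categories,
    transition_matrix,
)
from .diversity import diversity_metrics, group_summary
from .io import read_inocula, read_otu_table, write_inocula, write_otu_table
from .model import to_proportions
from .simulate import SimConfig, default_kernels, simulate_experiment, simulate_plant_cover, simulate_support_tree
from .tree import read_support_tree
from .votu import assign_trials, collapse_tree, consistency_summary

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class RunConfig:
    """All knobs of one pipeline run (YAML-serializable)."""

    out_dir: str = "amfspread_run"
    seed: int = 0
    alpha: float = 0.05
    marginal_alpha: float = 0.10
    bridge_override: bool = True
    include_block: bool = True
    support_threshold: float = 70.0
    distance_epsilon: float = 0.0
    min_trials: int = 2
    min_member_otus: int = 2
    # input paths; None means "simulate this input"
    otu_table: str | None = None
    metadata: str | None = None
    inocula: str | None = None
    tree: str | None = None
    plant_cover: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["distances"] = list(d["sim"]["distances"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def save_tsv(df: pd.DataFrame, name: str, index: bool = False) -> Path:
        p = out / name
        df.to_csv(p, sep="\t", index=index)
        outputs.append(p)
        return p

    # --- stage: inputs (simulate anything not provided) -------------------
    stage = "simulate"
    try:
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        need_sim = config.otu_table is None or config.metadata is None
        if need_sim:
            sim = simulate_experiment(sim_cfg)
            counts_path = out / "otu_counts.tsv"
            meta_path = out / "metadata.tsv"
            write_otu_table(sim.table, counts_path, meta_path)
            outputs += [counts_path, meta_path]
            write_inocula(sim.profiles, out / "inocula.tsv")
            outputs.append(out / "inocula.tsv")
            save_tsv(sim.truth, "truth.tsv")
            table = sim.table
            profiles = sim.profiles
        else:
            table = read_otu_table(config.otu_table, config.metadata)
            if config.inocula is None:
                raise PipelineError(stage, "inocula path required with real inputs")
            profiles = read_inocula(config.inocula)

        if config.tree is None:
            otu_ids = sorted({o for p in profiles.values() for o in p.amf_otus | p.whole_otus})
            stree, _ = simulate_support_tree(
                n_leaves=len(otu_ids), seed=config.seed, labels=otu_ids
            )
            tree_path = out / "tree.nwk"
            tree_path.write_text(stree.as_newick() + "\n")
            outputs.append(tree_path)
        else:
            stree = read_support_tree(config.tree)

        if config.plant_cover is None:
            cover = simulate_plant_cover(
                n_quadrats=20, species_pool=30, effect=2.0, seed=config.seed
            )
        else:
            cover = pd.read_csv(config.plant_cover, sep="\t")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: classify --------------------------------------------------
    stage = "classify"
    try:
        prop = to_proportions(table)
        records = []
        md = prop.metadata
        for site, profile in profiles.items():
            for year in sorted(md.loc[md["site"] == site, "year"].unique()):
                records += classify_trials(
                    prop,
                    profile,
                    site,
                    int(year),
                    alpha=config.alpha,
                    bridge_override=config.bridge_override,
                    include_block=config.include_block,
                )
        trials = [r.trial for r in records]
        save_tsv(records_to_frame(records), "trials.tsv")
        save_tsv(tabulate_categories(trials), "categories_by_site_year.tsv")
        years = sorted({t.year for t in trials})
        if len(years) >= 2:
            tm = transition_matrix(trials, years[0], years[1])
            save_tsv(tm, "transitions.tsv", index=True)
        else:
            logger.info("single year: transition table omitted")
        save_tsv(discordance_counts(trials), "discordance.tsv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: collapse --------------------------------------------------
    stage = "collapse"
    try:
        partition = collapse_tree(
            stree,
            support_threshold=config.support_threshold,
            distance_epsilon=config.distance_epsilon,
        )
        votu_map = pd.DataFrame(
            [
                {"otu_id": otu, "votu_id": f"vOTU{i + 1}"}
                for i, members in enumerate(partition)
                for otu in sorted(members)
            ]
        )
        save_tsv(votu_map, "votu_map.tsv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: summarize -------------------------------------------------
    stage = "summarize"
    try:
        classified_otus = {t.otu for t in trials}
        part_covered = [m for m in partition]
        missing = classified_otus - {o for m in partition for o in m}
        if missing:
            part_covered += [frozenset([o]) for o in sorted(missing)]
        votus = assign_trials(part_covered, trials)
        summary, headline = consistency_summary(
            votus, min_trials=config.min_trials, min_member_otus=config.min_member_otus
        )
        save_tsv(summary, "votu_summary.tsv")
        headline_path = out / "headline.json"
        headline_path.write_text(json.dumps(headline, indent=2, sort_keys=True) + "\n")
        outputs.append(headline_path)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: diversity -------------------------------------------------
    stage = "diversity"
    try:
        metrics = diversity_metrics(cover)
        save_tsv(metrics, "plant_metrics.tsv")
        save_tsv(group_summary(metrics, by=["treatment"]), "plant_group_summary.tsv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- manifest ---------------------------------------------------------
    cfg_dict = config.to_dict()
    cfg_dict.pop("out_dir")  # analysis identity must not depend on where it ran
    manifest = {
        "amfspread_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {p.name: _sha256(p) for p in sorted(set(outputs))},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def render_report(out_dir) -> str:
    """Human-readable markdown summary of a completed run.

    Renders whatever outputs exist and lists the missing ones.
    """
    out = Path(out_dir)
    lines = ["# AMF dispersal run summary", ""]
    missing = []

    def table_block(name: str, title: str, index_col=None) -> None:
        p = out / name
        if not p.exists():
            missing.append(name)
            return
        lines.append(f"## {title}\n")
        try:
            df = pd.read_csv(p, sep="\t", index_col=index_col)
            lines.append(df.to_string(index=index_col is not None))
        except pd.errors.EmptyDataError:
            lines.append("(empty)")
        lines.append("")

    table_block("categories_by_site_year.tsv", "Spread-category counts per site and year")
    table_block("transitions.tsv", "Year-to-year category transitions", index_col=0)
    table_block("discordance.tsv", "Shared-OTU discordance between inocula")
    table_block("votu_summary.tsv", "Virtual-OTU cross-site consistency")
    hp = out / "headline.json"
    if hp.exists():
        head = json.loads(hp.read_text())
        lines.append("## Headline\n")
        if head["n_selected"]:
            lines.append(
                f"{head['n_dominant']} of {head['n_selected']} selected virtual OTUs "
                f"({100 * head['fraction_dominant']:.0f}%) have a strict-majority "
                "spread category."
            )
            lines.append(f"Breakdown: {head['dominant_breakdown']}")
        else:
            lines.append("No virtual OTUs passed the selection filters.")
        lines.append("")
    else:
        missing.append("headline.json")
    table_block("plant_group_summary.tsv", "Plant community metrics by treatment")
    if missing:
        lines.append("## Missing outputs\n")
        lines += [f"- {m}" for m in missing]
        lines.append("")
    return "\n".join(lines)
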