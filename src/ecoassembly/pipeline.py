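"""End-to-end orchestration.

Stages in dependency order: load-or-simulate -> rarefy -> classify ->
alpha diversity -> beta diversity (distances, PCoA, PERMANOVA/ANOSIM,
distance decay) -> neutral model -> null models & process partition ->
co-occurrence network. Each stage writes plain-text outputs plus a manifest
entry (stage, output digests, seed, wall time); a rerun with the same
config and seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .betadiv import anosim, bray_curtis, distance_decay, pcoa, permanova
from .community import alpha_diversity, classify_taxa, rarefy, relative_abundance
from .errors import InvalidArgumentError
from .micstat import mic_matrix
from .network import build_network, keystoneness, network_topology, prevalence_filter
from .neutral import SloanNCM
from .synthetic import (
    MetacommunityModel,
    RegimeSpec,
    default_design,
    simulate_dataset,
)
from .turnover import AssemblyModel

__all__ = ["PipelineConfig", "run_pipeline"]

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips through YAML."""

    # inputs: either paths...
    counts_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    # ...or a simulation spec
    simulate: bool = False
    n_taxa: int = 300
    regime: str = "neutral"
    m: float = 0.3
    selection_strength: float = 1.0
    dispersal_scale: float = 500.0
    sites_per_location: int = 6

    rarefaction_depth: int = 19206
    rare_cutoff: float = 1e-4
    dominant_cutoff: float = 1e-2
    n_null: int = 999
    mantel_permutations: int = 9999
    mic_alpha: float = 0.6
    mic_clumps: int = 15
    mic_cutoff: float = 0.5
    q_cutoff: float = 0.001
    prevalence: float = 0.5
    network_permutations: int = 1000
    network_max_otus: int = 75
    group_by: str | None = None
    per_class: bool = False
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _stage_seed(seed: int, idx: int) -> int:
    return int((seed * 1_000_003 + idx * 7_919) % 2**31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_df(df: pd.DataFrame, path: Path, index_label=None) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label=index_label)


def _regime_from_config(cfg: PipelineConfig) -> RegimeSpec:
    if cfg.regime == "neutral":
        return RegimeSpec("neutral", m=cfg.m)
    if cfg.regime == "selection":
        return RegimeSpec("selection", m=cfg.m, selection_strength=cfg.selection_strength)
    if cfg.regime == "dispersal_limited":
        return RegimeSpec("dispersal_limited", m=cfg.m, dispersal_scale=cfg.dispersal_scale)
    raise InvalidArgumentError(f"unknown regime {cfg.regime!r} in config")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage, write outputs under ``outdir``, return the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": []}

    def record(stage: str, paths: list[Path], seed: int | None, t0: float) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": {p.name: _digest(p) for p in sorted(paths)},
                "seed": seed,
                "wall_time_s": round(time.time() - t0, 3),
            }
        )

    # stage 0: data
    t0 = time.time()
    if config.simulate:
        seed0 = _stage_seed(config.seed, 0)
        model = MetacommunityModel.simulate(config.n_taxa, seed=seed0)
        design = default_design(sites_per_location=config.sites_per_location)
        counts, meta, tree = simulate_dataset(
            design, model, _regime_from_config(config), seed=_stage_seed(config.seed, 1)
        )
        eio.write_count_table(counts, out / "counts.tsv")
        eio.write_metadata(meta, out / "metadata.tsv")
        eio.write_tree(tree, out / "tree.nwk")
        record("simulate", [out / "counts.tsv", out / "metadata.tsv", out / "tree.nwk"], seed0, t0)
    else:
        if not (config.counts_path and config.tree_path and config.metadata_path):
            raise InvalidArgumentError("provide counts/tree/metadata paths or simulate=true")
        counts = eio.read_count_table(config.counts_path)
        meta = eio.read_metadata(config.metadata_path)
        tree = eio.read_tree(config.tree_path)
        record("load", [], None, t0)

    # stage 1: rarefaction
    t0 = time.time()
    seed1 = _stage_seed(config.seed, 2)
    rare = rarefy(counts, config.rarefaction_depth, seed=seed1)
    meta = meta.loc[rare.columns]
    eio.write_count_table(rare, out / "rarefied.tsv")
    record("rarefy", [out / "rarefied.tsv"], seed1, t0)

    # stage 2: classification
    t0 = time.time()
    rel = relative_abundance(rare)
    classes = classify_taxa(rel, config.rare_cutoff, config.dominant_cutoff)
    _write_df(classes.to_frame(), out / "classification.tsv")
    record("classify", [out / "classification.tsv"], None, t0)

    # stage 3: alpha diversity
    t0 = time.time()
    alpha = alpha_diversity(rare)
    _write_df(alpha, out / "alpha.tsv")
    record("alpha", [out / "alpha.tsv"], None, t0)

    # stage 4: beta diversity
    t0 = time.time()
    seed4 = _stage_seed(config.seed, 3)
    bc = bray_curtis(rare, hellinger=True)
    _write_df(bc, out / "bray_curtis.tsv")
    ord_res = pcoa(bc)
    _write_df(ord_res.coordinates, out / "pcoa.tsv", index_label="sample_id")
    beta_tests = {}
    if "location" in meta.columns and meta["location"].nunique() > 1:
        f, p = permanova(bc, meta["location"], n_perm=999, seed=seed4)
        r, pa = anosim(bc, meta["location"], n_perm=999, seed=seed4)
        beta_tests["permanova_location"] = {"pseudo_F": f, "p": p}
        beta_tests["anosim_location"] = {"R": r, "p": pa}
    if {"latitude", "longitude"}.issubset(meta.columns):
        dr, dp, slope = distance_decay(
            rare, meta["latitude"], meta["longitude"],
            n_perm=min(config.mantel_permutations, 999), seed=seed4,
        )
        beta_tests["distance_decay"] = {"pearson_r": dr, "p": dp, "slope_per_km": slope}
    (out / "beta_tests.json").write_text(json.dumps(beta_tests, indent=2, sort_keys=True))
    record("betadiv", [out / "bray_curtis.tsv", out / "pcoa.tsv", out / "beta_tests.json"], seed4, t0)

    # stage 5: neutral model
    t0 = time.time()
    ncm = SloanNCM(rare).fit()
    (out / "ncm.json").write_text(json.dumps(ncm.report(), indent=2, sort_keys=True))
    _write_df(ncm.otu_table, out / "ncm_otus.tsv")
    record("ncm", [out / "ncm.json", out / "ncm_otus.tsv"], None, t0)

    # stage 6: assembly null models
    t0 = time.time()
    seed6 = _stage_seed(config.seed, 4)
    subsets: dict[str, pd.DataFrame] = {"all": rare}
    if config.per_class:
        for label in ("dominant", "conditionally_rare", "always_rare"):
            members = classes.members(label)
            sub = rare.loc[rare.index.intersection(members)]
            sub = sub.loc[:, sub.sum(axis=0) > 0]
            if sub.shape[0] >= 5 and sub.shape[1] >= 3:
                subsets[label] = sub
    summaries = []
    turnover_paths = []
    for key, sub in subsets.items():
        res = AssemblyModel(sub, tree).fit(n_null=config.n_null, seed=seed6, group=key)
        path = out / f"turnover_{key}.tsv"
        res.turnover.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        turnover_paths.append(path)
        summaries.append(res.summary_.to_frame())
        if config.group_by and key == "all" and config.group_by in meta.columns:
            for gval, gmeta in meta.groupby(config.group_by):
                cols = [c for c in sub.columns if c in gmeta.index]
                if len(cols) < 3:
                    continue
                gsub = sub[cols]
                gsub = gsub.loc[gsub.sum(axis=1) > 0]
                gres = AssemblyModel(gsub, tree).fit(
                    n_null=config.n_null, seed=seed6, group=str(gval)
                )
                summaries.append(gres.summary_.to_frame())
    summary_df = pd.concat(summaries, ignore_index=True)
    summary_df.to_csv(out / "process_summary.tsv", sep="\t", index=False,
                      float_format=_FLOAT_FMT)
    record("assembly", turnover_paths + [out / "process_summary.tsv"], seed6, t0)

    # stage 7: co-occurrence network
    t0 = time.time()
    seed7 = _stage_seed(config.seed, 5)
    try:
        filt = prevalence_filter(rare, config.prevalence)
    except InvalidArgumentError as exc:
        warnings.warn(f"network stage skipped: {exc}", stacklevel=2)
        record("network", [], seed7, t0)
        return _finish(manifest, out)
    if filt.shape[0] > config.network_max_otus:
        keep = (
            filt.sum(axis=1).sort_values(ascending=False)
            .index[: config.network_max_otus]
        )
        filt = filt.loc[filt.index.intersection(keep)].sort_index()
    mic_df = mic_matrix(
        filt, alpha=config.mic_alpha, c=config.mic_clumps,
        n_perm=config.network_permutations, seed=seed7,
    )
    mic_df.to_csv(out / "mic.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    net = build_network(mic_df, config.mic_cutoff, config.q_cutoff)
    paths = [out / "mic.tsv"]
    if not net.empty:
        network_topology(net, seed=seed7)
        keystoneness(net)
        net.edges.to_csv(out / "edges.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        _write_df(net.nodes, out / "nodes.tsv")
        (out / "network.json").write_text(
            json.dumps(net.metrics, indent=2, sort_keys=True)
        )
        paths += [out / "edges.tsv", out / "nodes.tsv", out / "network.json"]
    record("network", paths, seed7, t0)
    return _finish(manifest, out)


def _finish(manifest: dict, out: Path) -> dict:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
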