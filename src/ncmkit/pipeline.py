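"""End-to-end orchestration of the community-assembly analysis.

One config drives the whole study: read (or synthesize) OTU tables, apply
the read-depth filter, fit the neutral-model chains for the two designs
(gut-compartment stepping-stone and life-stage common-source), compute
NRI/NTI dispersion, alpha diversity, generalized UniFrac + PERMANOVA +
PCoA, and emit a structured, fully deterministic report bundle.  Every
stochastic stage receives a sub-seed derived from the global seed and a
stable stage tag, so adding a stage never shifts another stage's
randomness.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import (OtuTable, SampleMetadata, filter_min_reads,
                      read_metadata, read_otu_table, read_tree,
                      to_relative_abundance, write_metadata, write_otu_table)
from .beta import gunifrac, pcoa, permanova
from .dispersion import compare_dispersion, dispersion_table, ses_dispersion
from .diversity import alpha_diversity, alpha_table, bh_adjust, kruskal_wallis, pairwise_wilcoxon_bh
from .neutral import neutral_fraction, sequential_chain
from .synthetic import (SimConfig, _largest_remainder, _sample_totals,
                        make_metacommunity, simulate_neutral_samples,
                        simulate_tree)

log = logging.getLogger("ncmkit")

FARMED_LABELS = ["FW", "S", "PC", "MG", "BD"]   # feed+water, stomach, pyloric cecum, midgut, bile duct
WILD_SOURCE = "W"                               # freshwater
WILD_STAGES = ["Pa", "Sm", "MA", "RA"]          # parr, smolt, marine adult, returning adult


def stage_seed(global_seed: int, tag: str) -> int:
    """Deterministic sub-seed: mix the global seed with a stage tag."""
    return (global_seed * 1000003 + zlib.crc32(tag.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Paths or synthesis parameters plus every analysis knob."""

    seed: int = 0
    # either file inputs ...
    table: str | None = None
    tree: str | None = None
    metadata: str | None = None
    # ... or a self-generated synthetic study
    synthetic: dict | None = None
    farmed_chain: list[str] = field(default_factory=lambda: list(FARMED_LABELS))
    wild_chain: dict = field(default_factory=lambda: {
        "source": WILD_SOURCE, "stages": list(WILD_STAGES)})
    min_total: int = 8000
    bootstrap: int = 1000
    runs: int = 999
    gunifrac_alpha: float = 0.5
    n_perm: int = 999
    level: float = 0.95

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


_SYN_DEFAULTS = dict(S=150, n_source=8, n_per_group=12, N=10000,
                     Nm_true=1000.0, sigma=2.0, n_shallow=2, source_nm=1e8,
                     depth_jitter=0.2)


def _neutral_from(p_hat: np.ndarray, Nm: float, totals, rng,
                  taxon_ids, sample_ids) -> OtuTable:
    """Neutral draw from an estimated metacommunity that may contain zeros."""
    support = p_hat > 0
    sub = simulate_neutral_samples(
        p_hat[support] / p_hat[support].sum(), Nm, totals,
        seed=int(rng.integers(0, 2**31 - 1)),
        taxon_ids=[t for t, s in zip(taxon_ids, support) if s],
        sample_ids=sample_ids)
    counts = np.zeros((len(taxon_ids), len(sample_ids)), dtype=np.int64)
    counts[support, :] = sub.counts
    return OtuTable(tuple(taxon_ids), tuple(sample_ids), counts)


def simulate_design_study(syn: Mapping, farmed_chain: Sequence[str],
                          wild_chain: Mapping, seed: int):
    """Synthetic study covering both designs.

    The farmed design is a stepping-stone chain: the environmental group is
    a faithful metacommunity replicate, and every later compartment is a
    neutral draw from the realized composition of the preceding one.  The
    wild design draws every life stage from one common freshwater source.
    A couple of deliberately shallow samples exercise the depth filter.
    """
    prm = {**_SYN_DEFAULTS, **dict(syn or {})}
    rng = np.random.default_rng(stage_seed(seed, "simulate"))
    S = int(prm["S"])
    taxon_ids = tuple(f"OTU_{i + 1:04d}" for i in range(S))
    p = make_metacommunity(S, ("lognormal", 0.0, float(prm["sigma"])),
                           seed=int(rng.integers(0, 2**31 - 1)))
    tree = simulate_tree(taxon_ids, seed=int(rng.integers(0, 2**31 - 1)))

    tables: dict[str, OtuTable] = {}
    meta_rows = []

    def add_group(label, tbl):
        tables[label] = tbl
        for s in tbl.sample_ids:
            meta_rows.append((s, label))

    def totals(n):
        return _sample_totals(n, int(prm["N"]), float(prm["depth_jitter"]), rng)

    def source_group(label, n):
        tbl = simulate_neutral_samples(
            p, float(prm["source_nm"]), totals(n),
            seed=int(rng.integers(0, 2**31 - 1)), taxon_ids=taxon_ids,
            sample_ids=[f"{label}_{j + 1:03d}" for j in range(n)])
        return tbl

    # farmed stepping-stone chain
    env = source_group(farmed_chain[0], int(prm["n_source"]))
    add_group(farmed_chain[0], env)
    prev = env
    for label in farmed_chain[1:]:
        n = int(prm["n_per_group"])
        tbl = _neutral_from(to_relative_abundance(prev).mean_abundance(),
                            float(prm["Nm_true"]), totals(n), rng, taxon_ids,
                            [f"{label}_{j + 1:03d}" for j in range(n)])
        add_group(label, tbl)
        prev = tbl

    # wild common-source design
    wsrc = source_group(wild_chain["source"], int(prm["n_source"]))
    add_group(wild_chain["source"], wsrc)
    p_w = to_relative_abundance(wsrc).mean_abundance()
    for label in wild_chain["stages"]:
        n = int(prm["n_per_group"])
        tbl = _neutral_from(p_w, float(prm["Nm_true"]), totals(n), rng,
                            taxon_ids,
                            [f"{label}_{j + 1:03d}" for j in range(n)])
        add_group(label, tbl)

    # shallow samples (dropped by the read-depth filter)
    n_shallow = int(prm["n_shallow"])
    if n_shallow:
        shallow = simulate_neutral_samples(
            p, float(prm["source_nm"]),
            [int(prm["N"]) // 3] * n_shallow,
            seed=int(rng.integers(0, 2**31 - 1)), taxon_ids=taxon_ids,
            sample_ids=[f"SHALLOW_{j + 1:02d}" for j in range(n_shallow)])
        first = farmed_chain[0]
        merged = OtuTable(taxon_ids,
                          tables[first].sample_ids + shallow.sample_ids,
                          np.hstack([tables[first].counts, shallow.counts]))
        tables[first] = merged
        for s in shallow.sample_ids:
            meta_rows.append((s, first))

    all_ids, all_groups = zip(*meta_rows)
    cols = []
    for s, g in meta_rows:
        j = list(tables[g].sample_ids).index(s)
        cols.append(tables[g].counts[:, j])
    combined = OtuTable(taxon_ids, tuple(all_ids), np.column_stack(cols))
    meta = SampleMetadata(pd.DataFrame({"group": list(all_groups)},
                                       index=list(all_ids)))
    return combined, tree, meta


def _split_by_group(table: OtuTable, meta: SampleMetadata,
                    labels: Sequence[str]) -> list[tuple[str, OtuTable]]:
    out = []
    avail = set(table.sample_ids)
    for label in labels:
        sids = [s for s in meta.samples_in_group(label) if s in avail]
        if not sids:
            raise ValueError(f"design group {label!r} has no samples after filtering")
        out.append((label, table.select_samples(sids)))
    return out


def _fit_summary(key: str, fit) -> dict:
    pct = neutral_fraction(fit.records)
    return {
        "comparison": key, "m": fit.m, "Nm": fit.Nm, "N": fit.N, "d": fit.d,
        "r2": fit.r2, "m_ci": list(fit.m_ci) if fit.m_ci else None,
        "saturated": fit.saturated, "n_otus": len(fit.records),
        "n_excluded": len(fit.excluded_taxa),
        "pct_neutral": pct[0], "pct_above": pct[1], "pct_below": pct[2],
    }


def _records_frame(fits) -> pd.DataFrame:
    rows = []
    for (src, tgt), fit in fits.items():
        for r in fit.records:
            rows.append({"comparison": f"{src}->{tgt}", **r.__dict__})
    return pd.DataFrame(rows)


def make_report_tables(panels: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Combine per-panel comparison tables into one summary.

    Each input frame must have columns (comparison, statistic, p); BH
    adjustment is applied within each panel family.  Returns an empty
    frame with the standard header when there is nothing to report.
    """
    out = []
    for panel, df in panels.items():
        df = df.copy()
        if df.empty:
            continue
        df.insert(0, "panel", panel)
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
        out.append(df[["panel", "comparison", "statistic", "p", "p_adj"]])
    if not out:
        return pd.DataFrame(columns=["panel", "comparison", "statistic", "p", "p_adj"])
    return pd.concat(out, ignore_index=True)


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")


def _analyze_design(name: str, chain: list[tuple[str, OtuTable]], mode: str,
                    common_source: OtuTable | None, tree, meta, cfg,
                    outdir: Path) -> dict:
    ddir = outdir / name
    ddir.mkdir(parents=True, exist_ok=True)
    seed_tag = lambda s: stage_seed(cfg.seed, f"{name}:{s}")  # noqa: E731

    # --- neutral model chain
    if mode == "stepping_stone":
        fits = sequential_chain(chain, mode="stepping_stone",
                                bootstrap=cfg.bootstrap, seed=seed_tag("ncm"))
    else:
        fits = sequential_chain(chain[1:], mode="common_source",
                                common_source=chain[0][1],
                                bootstrap=cfg.bootstrap, seed=seed_tag("ncm"))
        fits = {(chain[0][0], tgt): f for (_, tgt), f in fits.items()}
    summaries = [_fit_summary(f"{s}->{t}", fit) for (s, t), fit in fits.items()]
    _write_json(ddir / "ncm_fits.json", summaries)
    _records_frame(fits).to_csv(ddir / "ncm_records.tsv", sep="\t", index=False)
    pd.DataFrame([{k: s[k] for k in
                   ("comparison", "pct_neutral", "pct_above", "pct_below")}
                  for s in summaries]).to_csv(
        ddir / "neutral_fractions.tsv", sep="\t", index=False)

    # --- per-design combined table (target groups only for group stats)
    target_chain = chain[1:] if mode == "common_source" else chain
    sids = [s for _, tbl in target_chain for s in tbl.sample_ids]
    combined = OtuTable(
        chain[0][1].taxon_ids, tuple(sids),
        np.hstack([tbl.counts for _, tbl in target_chain])).drop_empty_taxa()

    # --- dispersion (NRI from MPD, NTI from MNTD)
    disp_frames, disp_panels = [], {}
    for metric in ("MPD", "MNTD"):
        res = ses_dispersion(combined, tree, metric=metric, runs=cfg.runs,
                             seed=seed_tag(f"dispersion:{metric}"))
        disp_frames.append(dispersion_table(res))
        H, p, pairs = compare_dispersion(res, meta)
        pairs = pairs.assign(metric=metric)
        disp_panels[metric] = pairs
    pd.concat(disp_frames, ignore_index=True).to_csv(
        ddir / "dispersion.tsv", sep="\t", index=False)
    pd.concat(disp_panels.values(), ignore_index=True).to_csv(
        ddir / "dispersion_tests.tsv", sep="\t", index=False)

    # --- alpha diversity
    alpha = alpha_table(alpha_diversity(combined))
    alpha["group"] = meta.group_of(list(alpha["sample_id"]))
    alpha.to_csv(ddir / "alpha.tsv", sep="\t", index=False)
    a_vals = alpha["richness"].to_numpy(dtype=float)
    a_groups = alpha["group"].to_numpy()
    H, p = kruskal_wallis(a_vals, a_groups)
    alpha_pairs = pairwise_wilcoxon_bh(a_vals, a_groups)
    alpha_pairs.to_csv(ddir / "alpha_tests.tsv", sep="\t", index=False)

    # --- beta diversity
    dist = gunifrac(combined, tree, alpha=cfg.gunifrac_alpha)
    dist.to_dataframe().to_csv(ddir / "gunifrac.tsv", sep="\t")
    groups = meta.group_of(list(dist.ids))
    perm = permanova(dist, groups, n_perm=cfg.n_perm, seed=seed_tag("permanova"))
    _write_json(ddir / "permanova.json", perm.__dict__)
    ord_res = pcoa(dist, k=2)
    ord_res.coordinates.to_csv(ddir / "pcoa.tsv", sep="\t")

    # --- summary report (one BH family per panel)
    panels = {
        "alpha_richness": alpha_pairs.assign(
            comparison=lambda d: d["group1"].astype(str) + " vs " + d["group2"],
            statistic=lambda d: d["U"])[["comparison", "statistic", "p"]],
    }
    for metric, pairs in disp_panels.items():
        panels[f"dispersion_{metric}"] = pairs.assign(
            comparison=lambda d: d["group1"].astype(str) + " vs " + d["group2"],
            statistic=lambda d: d["U"])[["comparison", "statistic", "p"]]
    make_report_tables(panels).to_csv(ddir / "summary_tests.tsv", sep="\t",
                                      index=False)

    return {"design": name, "mode": mode,
            "comparisons": [s["comparison"] for s in summaries],
            "kruskal_richness": {"H": H, "p": p},
            "permanova": perm.__dict__}


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full analysis; returns the manifest dictionary."""
    cfg = config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.synthetic is not None:
        table, tree, meta = simulate_design_study(
            cfg.synthetic, cfg.farmed_chain, cfg.wild_chain, cfg.seed)
        idir = outdir / "inputs"
        idir.mkdir(exist_ok=True)
        write_otu_table(table, idir / "table.tsv")
        write_metadata(meta, idir / "metadata.tsv")
        tree.write(str(idir / "tree.nwk"))
    elif cfg.table and cfg.tree and cfg.metadata:
        table = read_otu_table(cfg.table)
        tree = read_tree(cfg.tree)
        meta = read_metadata(cfg.metadata)
    else:
        raise ValueError("config needs either file inputs or a synthetic block")

    n_before = table.n_samples
    table = filter_min_reads(table, cfg.min_total)
    n_dropped = n_before - table.n_samples
    log.info("pipeline: %d samples dropped by depth filter", n_dropped)

    farmed = _split_by_group(table, meta, cfg.farmed_chain)
    wild = _split_by_group(table, meta,
                           [cfg.wild_chain["source"]] + list(cfg.wild_chain["stages"]))

    manifest = {
        "ncmkit_version": __version__,
        "seed": cfg.seed,
        "parameters": {k: v for k, v in asdict(cfg).items()},
        "n_samples_input": n_before,
        "n_samples_dropped_depth_filter": n_dropped,
        "n_taxa": table.n_taxa,
        "designs": [],
    }
    manifest["designs"].append(_analyze_design(
        "farmed", farmed, "stepping_stone", None, tree, meta, cfg, outdir))
    manifest["designs"].append(_analyze_design(
        "wild", wild, "common_source", wild[0][1], tree, meta, cfg, outdir))
    _write_json(outdir / "manifest.json", manifest)
    return manifest
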