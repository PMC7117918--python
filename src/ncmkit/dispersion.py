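"""Phylogenetic dispersion: MPD/MNTD and their null-standardized indices.

For each sample, the mean pairwise cophenetic distance (MPD) and mean
nearest-taxon distance (MNTD) of the taxa present are compared against a
null distribution obtained by redrawing the same number of taxa uniformly
from the table's taxon pool.  The standardized effect size
ses = (obs - null_mean) / null_sd is reported together with its negation,
the net relatedness index (NRI, from MPD) or nearest taxon index (NTI,
from MNTD).  Under the Webb sign convention positive index values mean
phylogenetic clustering (habitat filtering), negative values
overdispersion (competition); neutral assembly should sit near zero.
Both the signed ses and the index are reported explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import DistanceMatrix, OtuTable, PhyloTree, SampleMetadata, check_taxa_in_tree
from .diversity import kruskal_wallis, pairwise_wilcoxon_bh

_NULL_CHUNK = 128  # null draws processed per vectorized block


@dataclass(frozen=True)
class DispersionResult:
    sample_id: str
    metric: str          # MPD | MNTD
    obs: float
    null_mean: float
    null_sd: float
    ses: float
    index: float         # NRI (from MPD) or NTI (from MNTD) = -ses
    n_taxa: int
    runs: int
    defined: bool
    reason: str = ""


def cophenetic_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Tip-to-tip path-length (cophenetic) distances."""
    tips = [t.name for t in tree.tips()]
    if len(tips) < 2:
        raise ValueError("tree needs at least 2 tips")
    dm = tree.tip_tip_distances()
    return DistanceMatrix(tuple(dm.ids), np.asarray(dm.data, dtype=float))


def _index_of(taxa: Sequence[str], dist: DistanceMatrix) -> np.ndarray:
    pos = {t: i for i, t in enumerate(dist.ids)}
    missing = [t for t in taxa if t not in pos]
    if missing:
        raise KeyError(f"taxa missing from distance matrix: {missing[:5]}")
    return np.array([pos[t] for t in taxa])


def mpd(taxa_present: Sequence[str], dist: DistanceMatrix) -> float:
    """Mean cophenetic distance over all unordered pairs (presence-based)."""
    idx = _index_of(list(taxa_present), dist)
    k = len(idx)
    if k < 2:
        return float("nan")
    sub = dist.values[np.ix_(idx, idx)]
    return float(sub.sum() / (k * (k - 1)))


def mntd(taxa_present: Sequence[str], dist: DistanceMatrix) -> float:
    """Mean distance from each present taxon to its nearest present neighbor."""
    idx = _index_of(list(taxa_present), dist)
    k = len(idx)
    if k < 2:
        return float("nan")
    sub = dist.values[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _metric_on_blocks(D: np.ndarray, draws: np.ndarray, metric: str) -> np.ndarray:
    """Vectorized MPD/MNTD over a (runs, k) index matrix."""
    out = np.empty(len(draws))
    k = draws.shape[1]
    for start in range(0, len(draws), _NULL_CHUNK):
        blk = draws[start:start + _NULL_CHUNK]
        sub = D[blk[:, :, None], blk[:, None, :]]
        if metric == "MPD":
            out[start:start + _NULL_CHUNK] = sub.sum(axis=(1, 2)) / (k * (k - 1))
        else:
            ii = np.arange(k)
            sub[:, ii, ii] = np.inf
            out[start:start + _NULL_CHUNK] = sub.min(axis=2).mean(axis=1)
    return out


def ses_dispersion(table: OtuTable, tree: PhyloTree, metric: str = "MPD",
                   runs: int = 999, seed: int | None = None) -> list[DispersionResult]:
    """Standardized effect sizes of MPD or MNTD per sample.

    The null redraws, for each sample, the same number of taxa uniformly
    without replacement from the pool of taxa observed anywhere in the
    table (a taxon-label shuffle for presence data).  ``defined`` is False
    when the null is degenerate (sd = 0) or the sample has < 2 taxa.
    """
    metric = metric.upper()
    if metric not in ("MPD", "MNTD"):
        raise ValueError("metric must be MPD or MNTD")
    check_taxa_in_tree(table, tree)
    present_any = table.counts.sum(axis=1) > 0
    pool = [t for t, keep in zip(table.taxon_ids, present_any) if keep]
    full = cophenetic_matrix(tree)
    D = full.submatrix(pool).values
    pool_pos = {t: i for i, t in enumerate(pool)}

    rng = np.random.default_rng(seed)
    index_name = "NRI" if metric == "MPD" else "NTI"
    results = []
    for j, sid in enumerate(table.sample_ids):
        taxa = [t for t, c in zip(table.taxon_ids, table.counts[:, j]) if c > 0]
        k = len(taxa)
        if k < 2:
            results.append(DispersionResult(sid, metric, float("nan"),
                                            float("nan"), float("nan"),
                                            float("nan"), float("nan"),
                                            k, runs, False, "too few taxa"))
            continue
        idx = np.array([pool_pos[t] for t in taxa])
        sub = D[np.ix_(idx, idx)]
        if metric == "MPD":
            obs = float(sub.sum() / (k * (k - 1)))
        else:
            sub = sub.copy()
            np.fill_diagonal(sub, np.inf)
            obs = float(sub.min(axis=1).mean())
        draws = np.empty((runs, k), dtype=np.intp)
        for r in range(runs):
            draws[r] = rng.choice(len(pool), size=k, replace=False)
        null = _metric_on_blocks(D, draws, metric)
        mu, sd = float(null.mean()), float(null.std(ddof=1))
        # summation-order noise: a null that only permutes the same taxon set
        # differs at the 1e-16 level; treat it as degenerate
        if sd <= 1e-10 * max(abs(mu), 1.0):
            results.append(DispersionResult(sid, metric, obs, mu, 0.0,
                                            float("nan"), float("nan"),
                                            k, runs, False, "degenerate null"))
            continue
        ses = (obs - mu) / sd
        results.append(DispersionResult(sid, metric, obs, mu, sd, ses, -ses,
                                        k, runs, True))
    return results


def dispersion_table(results: Sequence[DispersionResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def compare_dispersion(results: Sequence[DispersionResult],
                       metadata: SampleMetadata,
                       group_column: str = "group",
                       value: str = "index") -> tuple[float, float, pd.DataFrame]:
    """Group-level comparison of dispersion indices.

    Kruskal-Wallis across groups on the chosen value ("index" or "ses"),
    then pairwise Wilcoxon rank-sum tests with Benjamini-Hochberg
    adjustment.  Groups with no defined results are excluded.
    Returns (H, p, pairwise table).
    """
    rows = [(r.sample_id, getattr(r, value)) for r in results if r.defined]
    if not rows:
        raise ValueError("no defined dispersion results")
    sids = [s for s, _ in rows]
    vals = np.array([v for _, v in rows])
    groups = metadata.group_of(sids, group_column)

    counts = pd.Series(groups).value_counts()
    usable = counts[counts >= 2].index
    skipped = [g for g in counts.index if g not in set(usable)]
    if len(usable) < 2:
        raise ValueError("need >= 2 groups with >= 2 defined results each")
    if skipped:
        import logging
        logging.getLogger("ncmkit").warning(
            "groups excluded from dispersion comparison: %s", skipped)
    mask = np.isin(groups, usable)
    H, p = kruskal_wallis(vals[mask], groups[mask])
    pairs = pairwise_wilcoxon_bh(vals[mask], groups[mask])
    return H, p, pairs
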