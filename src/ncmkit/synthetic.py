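"""Synthetic OTU tables with the marginal structure the neutral model assumes.

Local communities are drawn as composition ~ Dirichlet(Nm * p) followed by
counts ~ Multinomial(N_j, composition).  The taxon-wise marginal of the
Dirichlet is exactly Beta(Nm*p_i, Nm*(1-p_i)) — the distribution the Sloan
model fits — which makes parameter recovery a well-posed test rather than
an approximation.  On top of the neutral backbone the generator can inject
"selected" taxa whose occurrence departs from the neutral prediction in
either direction (the *Mycoplasma*-style signature of host selection) and
restrict communities to a tight clade of the simulated phylogeny to create
phylogenetic clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skbio import TreeNode

import pandas as pd

from .core_io import OtuTable, PhyloTree, SampleMetadata

#: default metacommunity log-abundance spread (natural log units); typical
#: of lognormal fits to 16S OTU abundance distributions.
DEFAULT_META_DIST = ("lognormal", 0.0, 2.0)


@dataclass(frozen=True)
class SimConfig:
    """Study-level knobs for the generative model.

    ``Nm_true`` is the product of local community size and migration rate
    that governs how faithfully local communities track the metacommunity;
    ``N`` is the mean reads per sample, with per-sample totals jittered
    +/-20% uniformly.  ``selected_above`` entries are (taxon_index,
    forced_relative_abundance) — the taxon is planted in every target
    sample; ``selected_below`` entries are (taxon_index, occurrence_cap_q)
    — the taxon is confined to a fraction q of target samples.
    """

    S: int = 300
    n_source: int = 10
    n_target: int = 50
    N: int = 10000
    Nm_true: float = 1000.0
    meta_dist: tuple = DEFAULT_META_DIST
    selected_above: tuple[tuple[int, float], ...] = ()
    selected_below: tuple[tuple[int, float], ...] = ()
    clade_filter: tuple[float, str] | None = None  # (tip fraction, group)
    source_nm: float = 1e8
    depth_jitter: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.S < 2:
            raise ValueError("need S >= 2 taxa")
        if self.Nm_true <= 0:
            raise ValueError("Nm_true must be positive")
        if min(self.n_source, self.n_target) < 1 or self.N < 1:
            raise ValueError("sample counts and N must be >= 1")
        above = {i for i, _ in self.selected_above}
        below = {i for i, _ in self.selected_below}
        if above & below:
            raise ValueError("selected_above and selected_below must be disjoint")


@dataclass(frozen=True)
class SimStudy:
    """Generated source/target tables with per-taxon ground truth."""

    source_table: OtuTable
    target_table: OtuTable
    tree: PhyloTree
    metadata: SampleMetadata
    truth: dict[str, str]  # taxon -> neutral | above | below
    config: SimConfig
    metacommunity: np.ndarray | None = None  # true p, aligned with taxon order


def make_metacommunity(S: int, meta_dist: tuple = DEFAULT_META_DIST,
                       seed: int | None = None) -> np.ndarray:
    """Relative-abundance vector of the source metacommunity.

    ``meta_dist`` is ``("lognormal", mu, sigma)`` or
    ``("geometric_series", k)``.  Returned sorted descending, summing to 1.
    """
    if S < 2:
        raise ValueError("need S >= 2 taxa")
    kind = meta_dist[0]
    if kind == "lognormal":
        _, mu, sigma = meta_dist
        rng = np.random.default_rng(seed)
        raw = rng.lognormal(mu, sigma, S)
    elif kind == "geometric_series":
        _, k = meta_dist
        if not 0 < k <= 1:
            raise ValueError("geometric series ratio must lie in (0, 1]")
        raw = k ** np.arange(S, dtype=float)
    else:
        raise ValueError(f"unknown metacommunity distribution {kind!r}")
    p = raw / raw.sum()
    return np.sort(p)[::-1]


def _sample_totals(n: int, N: int, jitter: float, rng) -> np.ndarray:
    lo, hi = int(round(N * (1 - jitter))), int(round(N * (1 + jitter)))
    return rng.integers(lo, hi + 1, size=n)


def simulate_neutral_samples(p: np.ndarray, Nm: float,
                             sample_totals: Sequence[int],
                             seed: int | None = None,
                             taxon_ids: Sequence[str] | None = None,
                             sample_ids: Sequence[str] | None = None) -> OtuTable:
    """Draw neutral local communities from metacommunity ``p``.

    One Dirichlet(Nm*p) composition per sample, then multinomial counts at
    the requested depth; column sums equal ``sample_totals`` exactly.
    """
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("p must sum to 1")
    if Nm <= 0:
        raise ValueError("Nm must be positive")
    totals = np.asarray(sample_totals, dtype=np.int64)
    if np.any(totals < 1):
        raise ValueError("all sample totals must be >= 1")
    rng = np.random.default_rng(seed)
    S, n = len(p), len(totals)
    counts = np.empty((S, n), dtype=np.int64)
    alpha = Nm * p
    for j in range(n):
        comp = rng.dirichlet(alpha)
        comp = comp / comp.sum()
        counts[:, j] = rng.multinomial(totals[j], comp)
    taxon_ids = taxon_ids or [f"OTU_{i + 1:04d}" for i in range(S)]
    sample_ids = sample_ids or [f"SAMPLE_{j + 1:03d}" for j in range(n)]
    return OtuTable(tuple(taxon_ids), tuple(sample_ids), counts)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to ``weights`` summing to ``total``."""
    w = np.asarray(weights, dtype=float)
    if total == 0 or len(w) == 0:
        return np.zeros(len(w), dtype=np.int64)
    if w.sum() <= 0:
        w = np.ones_like(w)
    quota = w / w.sum() * total
    alloc = np.floor(quota).astype(np.int64)
    short = total - alloc.sum()
    if short > 0:
        order = np.argsort(-(quota - alloc), kind="stable")
        alloc[order[:short]] += 1
    return alloc


def inject_selected(table: OtuTable,
                    selected_above: Sequence[tuple[int, float]] = (),
                    selected_below: Sequence[tuple[int, float]] = (),
                    seed: int | None = None) -> tuple[OtuTable, dict[str, str]]:
    """Plant non-neutral taxa into a (neutral) target table.

    "Above" taxa are made present in every sample at a forced relative
    abundance; "below" taxa are confined to a ``round(q * n_samples)``
    subset of samples (present there, zero elsewhere).  Remaining counts
    are reallocated proportionally so each column keeps its original total.
    """
    above = list(selected_above)
    below = list(selected_below)
    if {i for i, _ in above} & {i for i, _ in below}:
        raise ValueError("selected sets must be disjoint")
    for idx, _ in above + below:
        if not 0 <= idx < table.n_taxa:
            raise ValueError(f"taxon index {idx} out of range")
    forced_total = sum(f for _, f in above)
    if forced_total > 0.9:
        raise ValueError("selection spec exceeds community capacity")

    truth = {t: "neutral" for t in table.taxon_ids}
    if not above and not below:
        return table, truth

    rng = np.random.default_rng(seed)
    counts = np.array(table.counts, dtype=np.int64)
    totals = counts.sum(axis=0)
    n = table.n_samples
    fixed_idx = [i for i, _ in above] + [i for i, _ in below]

    for idx, frac in above:
        truth[table.taxon_ids[idx]] = "above"
        counts[idx, :] = np.maximum(1, np.round(frac * totals).astype(np.int64))
    for idx, q in below:
        if not 0 <= q < 1:
            raise ValueError("occurrence cap q must lie in [0, 1)")
        truth[table.taxon_ids[idx]] = "below"
        n_keep = int(round(q * n))
        keep = rng.choice(n, size=n_keep, replace=False)
        newrow = np.zeros(n, dtype=np.int64)
        newrow[keep] = np.maximum(1, counts[idx, keep])
        counts[idx, :] = newrow

    free = np.setdiff1d(np.arange(table.n_taxa), fixed_idx)
    for j in range(n):
        remaining = totals[j] - counts[fixed_idx, j].sum()
        if remaining < 0:
            raise ValueError("selection spec exceeds community capacity")
        counts[free, j] = _largest_remainder(table.counts[free, j], remaining)
    return OtuTable(table.taxon_ids, table.sample_ids, counts), truth


def simulate_tree(taxon_ids: Sequence[str], seed: int | None = None,
                  clade_spec: Sequence[str] | None = None) -> PhyloTree:
    """Random binary rooted tree by sequential random joins.

    Each join extends the two subtree roots by independent Exponential(1)
    branch increments.  Taxa listed in ``clade_spec`` are joined first and
    their internal branch increments are scaled by 0.1, producing a tight
    monophyletic clade (phylogenetically clustered signal).
    """
    ids = list(taxon_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)

    def join_all(roots: list[TreeNode], scale: float) -> TreeNode:
        roots = list(roots)
        while len(roots) > 1:
            i, j = sorted(rng.choice(len(roots), size=2, replace=False))
            b = roots.pop(j)
            a = roots.pop(i)
            a.length = (a.length or 0.0) + scale * rng.exponential(1.0)
            b.length = (b.length or 0.0) + scale * rng.exponential(1.0)
            parent = TreeNode(children=[a, b])
            parent.length = 0.0
            roots.append(parent)
        return roots[0]

    clade = set(clade_spec or ())
    missing = clade - set(ids)
    if missing:
        raise ValueError(f"clade taxa not in taxon set: {sorted(missing)[:5]}")
    subtrees = [TreeNode(name=t) for t in ids if t not in clade]
    for node in subtrees:
        node.length = 0.0
    if clade:
        clade_tips = [TreeNode(name=t) for t in ids if t in clade]
        for node in clade_tips:
            node.length = 0.0
        if len(clade_tips) == 1:
            subtrees.append(clade_tips[0])
        else:
            subtrees.append(join_all(clade_tips, 0.1))
    root = join_all(subtrees, 1.0)
    root.length = None
    return root


def simulate_study(config: SimConfig) -> SimStudy:
    """End-to-end synthetic study: source + target tables, tree, truth.

    Source samples are drawn at a very high Nm (faithful metacommunity
    replicates, mirroring pooled environmental samples); target samples at
    ``Nm_true``, then selected taxa are injected.  When ``clade_filter``
    is set, target communities of the flagged group are restricted to a
    random clade of the given tip fraction.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    p = make_metacommunity(cfg.S, cfg.meta_dist, seed=sub())
    taxon_ids = tuple(f"OTU_{i + 1:04d}" for i in range(cfg.S))

    src = simulate_neutral_samples(
        p, cfg.source_nm,
        _sample_totals(cfg.n_source, cfg.N, cfg.depth_jitter, rng),
        seed=sub(), taxon_ids=taxon_ids,
        sample_ids=[f"SRC_{j + 1:03d}" for j in range(cfg.n_source)])
    tgt = simulate_neutral_samples(
        p, cfg.Nm_true,
        _sample_totals(cfg.n_target, cfg.N, cfg.depth_jitter, rng),
        seed=sub(), taxon_ids=taxon_ids,
        sample_ids=[f"TGT_{j + 1:03d}" for j in range(cfg.n_target)])

    above = tuple((i, f) for i, f in cfg.selected_above)
    below = tuple((i, q) for i, q in cfg.selected_below)
    tgt, truth = inject_selected(tgt, above, below, seed=sub())

    clade_taxa: list[str] = []
    if cfg.clade_filter is not None:
        frac, group = cfg.clade_filter
        n_clade = max(2, int(round(frac * cfg.S)))
        clade_taxa = list(rng.choice(cfg.S, size=n_clade, replace=False))
        clade_ids = [taxon_ids[i] for i in clade_taxa]
        if group == "target":
            counts = np.array(tgt.counts)
            mask = np.ones(cfg.S, dtype=bool)
            mask[clade_taxa] = False
            totals = counts.sum(axis=0)
            counts[mask, :] = 0
            for j in range(tgt.n_samples):
                counts[~mask, j] = _largest_remainder(counts[~mask, j], totals[j])
            tgt = OtuTable(tgt.taxon_ids, tgt.sample_ids, counts)
        tree = simulate_tree(taxon_ids, seed=sub(), clade_spec=clade_ids)
    else:
        tree = simulate_tree(taxon_ids, seed=sub())

    meta = pd.DataFrame(
        {"group": ["source"] * src.n_samples + ["target"] * tgt.n_samples},
        index=list(src.sample_ids) + list(tgt.sample_ids))
    return SimStudy(src, tgt, tree, SampleMetadata(meta), truth, cfg, p)
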