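"""Sloan neutral community model for source -> target comparisons.

The model treats the occurrence frequency of a taxon across local
communities as a function of its mean relative abundance ``p`` in the
source metacommunity.  Under neutral immigration-drift dynamics the
local relative abundance of a taxon is Beta(Nm*p, Nm*(1-p)) distributed,
where ``N`` is the local community size (reads per sample) and ``m`` the
migration rate: the probability that a random death in the local
community is replaced by an immigrant from the source rather than by
local reproduction.  A taxon is detected when its relative abundance
exceeds the detection limit ``d`` (conventionally one read, 1/N), so its
predicted occurrence frequency is the upper tail of that beta
distribution.  ``m`` is fitted by nonlinear least squares on the
(p, occurrence) cloud, and each taxon is then classified as consistent
with the neutral prediction ("neutral") or falling above/below its 95%
confidence band ("above" = selected for, "below" = selected against).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .core_io import OtuTable, to_relative_abundance

log = logging.getLogger("ncmkit")


@dataclass(frozen=True)
class NcmInput:
    """Per-OTU quantities entering the fit for one source->target pair."""

    otu_ids: tuple[str, ...]
    p: np.ndarray            # source mean relative abundance, all > 0
    f_obs: np.ndarray        # occurrence frequency in target samples, in [0,1]
    n_samples: int           # number of target samples
    N: int                   # mean reads per target sample (rounded)
    d: float                 # detection limit (relative abundance)
    excluded_taxa: tuple[str, ...] = ()  # p == 0 in source; not fitted

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        f = np.asarray(self.f_obs, dtype=float)
        if p.shape != f.shape or p.ndim != 1 or len(p) != len(self.otu_ids):
            raise ValueError("p, f_obs and otu_ids must have equal length")
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("all included p must lie in (0, 1)")
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("f_obs must lie in [0, 1]")
        if self.n_samples < 2:
            raise ValueError("need at least 2 target samples")
        if self.N < 1 or not (0 < self.d < 1):
            raise ValueError("require N >= 1 and 0 < d < 1")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "f_obs", f)


@dataclass(frozen=True)
class OtuNeutralityRecord:
    otu_id: str
    p: float
    f_obs: float
    f_pred: float
    ci_low: float
    ci_high: float
    partition: str  # neutral | above | below


@dataclass(frozen=True)
class NcmFit:
    """Fitted migration rate and per-OTU neutrality partition."""

    m: float
    N: int
    d: float
    r2: float
    m_ci: tuple[float, float] | None
    records: tuple[OtuNeutralityRecord, ...]
    excluded_taxa: tuple[str, ...]
    saturated: bool = False  # optimizer pinned at m = 1 with descent direction

    @property
    def Nm(self) -> float:
        return self.N * self.m


def predict_frequency(p, Nm, d):
    """Predicted occurrence frequency 1 - I_d(Nm*p, Nm*(1-p)).

    ``I_d`` is the regularized incomplete beta function (beta CDF at the
    detection limit ``d``).  Accepts scalars or arrays in ``p``; monotone
    increasing in ``p`` at fixed ``Nm`` and ``d``.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    if not Nm > 0:
        raise ValueError("Nm must be positive")
    if not 0 < d < 1:
        raise ValueError("d must lie in (0, 1)")
    out = 1.0 - special.betainc(Nm * p, Nm * (1.0 - p), d)
    return float(out) if out.ndim == 0 else out


def build_ncm_input(source: OtuTable, target: OtuTable,
                    detection: float | str = "auto") -> NcmInput:
    """Assemble the fit input from a source and a target table.

    ``p`` is the mean over source samples of per-sample relative abundance
    (so deep samples do not dominate); occurrence counts a taxon as present
    at count >= 1; ``N`` is the rounded mean target depth and the detection
    limit defaults to 1/N.  Taxa absent from the source (p = 0) cannot be
    predicted and are reported in ``excluded_taxa``.
    """
    if target.n_samples < 2:
        raise ValueError("need at least 2 target samples")
    shared = [t for t in source.taxon_ids if t in set(target.taxon_ids)]
    if not shared:
        raise ValueError("source and target share no taxa")
    src_rel = to_relative_abundance(source)
    p_all = dict(zip(source.taxon_ids, src_rel.mean_abundance()))
    tgt_pos = {t: i for i, t in enumerate(target.taxon_ids)}
    presence = target.counts > 0

    otu_ids, p, f_obs, excluded = [], [], [], []
    for t in target.taxon_ids:
        pi = p_all.get(t, 0.0)
        if pi <= 0:
            excluded.append(t)
            continue
        otu_ids.append(t)
        p.append(pi)
        f_obs.append(presence[tgt_pos[t]].mean())
    if not otu_ids:
        raise ValueError("no taxa with positive source abundance")
    N = int(round(target.sample_totals().mean()))
    d = 1.0 / N if detection == "auto" else float(detection)
    return NcmInput(tuple(otu_ids), np.array(p), np.array(f_obs),
                    target.n_samples, N, d, tuple(excluded))


def _sse(m: float, inp: NcmInput) -> float:
    f_hat = predict_frequency(inp.p, inp.N * m, inp.d)
    return float(np.sum((inp.f_obs - f_hat) ** 2))


def _fit_m(inp: NcmInput) -> float:
    res = optimize.minimize_scalar(
        _sse, bounds=(1e-8, 1.0), args=(inp,), method="bounded",
        options={"xatol": 1e-10})
    return float(res.x)


def fit_ncm(inp: NcmInput, bootstrap: int = 1000, seed: int | None = None,
            level: float = 0.95) -> NcmFit:
    """Fit the migration rate by bounded scalar least squares.

    R^2 is the coefficient of determination of the occurrence frequencies
    (1 - SSE/SStot; may be negative).  ``bootstrap`` resamples of the OTU
    set give a percentile confidence interval for ``m``; pass 0 to skip.
    """
    n_otus = len(inp.otu_ids)
    if n_otus < 10:
        raise ValueError("need at least 10 OTUs with positive source abundance")
    if n_otus < 50:
        log.warning("only %d OTUs in NCM fit; estimates will be noisy", n_otus)

    m = _fit_m(inp)
    sse = _sse(m, inp)
    sstot = float(np.sum((inp.f_obs - inp.f_obs.mean()) ** 2))
    r2 = 1.0 - sse / sstot if sstot > 0 else (1.0 if sse == 0 else -np.inf)

    # saturation check: still descending at the m = 1 bound
    saturated = bool(m > 1 - 1e-6 and _sse(1.0, inp) < _sse(1.0 - 1e-4, inp))
    if saturated:
        log.warning("migration saturated: optimum at the m = 1 bound")

    m_ci = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        ms = np.empty(bootstrap)
        for b in range(bootstrap):
            idx = rng.integers(0, n_otus, n_otus)
            sub = NcmInput(tuple(f"b{i}" for i in range(n_otus)),
                           inp.p[idx], inp.f_obs[idx],
                           inp.n_samples, inp.N, inp.d)
            ms[b] = _fit_m(sub)
        lo, hi = np.percentile(ms, [50 * (1 - level), 50 * (1 + level)])
        m_ci = (min(float(lo), m), max(float(hi), m))

    fit = NcmFit(m=m, N=inp.N, d=inp.d, r2=r2, m_ci=m_ci, records=(),
                 excluded_taxa=inp.excluded_taxa, saturated=saturated)
    records = partition_otus(inp, fit, level=level)
    return NcmFit(m=m, N=inp.N, d=inp.d, r2=r2, m_ci=m_ci,
                  records=tuple(records), excluded_taxa=inp.excluded_taxa,
                  saturated=saturated)


def wilson_interval(f: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a proportion ``f`` with ``n`` trials."""
    if not 0 <= f <= 1:
        raise ValueError("f must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    z = stats.norm.ppf(0.5 + level / 2)
    denom = 1.0 + z * z / n
    center = (f + z * z / (2 * n)) / denom
    half = (z / denom) * np.sqrt(f * (1 - f) / n + z * z / (4 * n * n))
    return (max(0.0, center - half), min(1.0, center + half))


def partition_otus(inp: NcmInput, fit: NcmFit,
                   level: float = 0.95) -> list[OtuNeutralityRecord]:
    """Classify each OTU against the Wilson band around its prediction.

    The band is the Wilson score interval at ``level`` around the predicted
    occurrence frequency with n = number of target samples; an OTU is
    "above" when its observed frequency exceeds the upper bound, "below"
    when it falls short of the lower bound, else "neutral".
    """
    f_pred = predict_frequency(inp.p, fit.Nm, fit.d)
    records = []
    for i, otu in enumerate(inp.otu_ids):
        lo, hi = wilson_interval(float(f_pred[i]), inp.n_samples, level)
        fo = float(inp.f_obs[i])
        part = "above" if fo > hi else ("below" if fo < lo else "neutral")
        records.append(OtuNeutralityRecord(otu, float(inp.p[i]), fo,
                                           float(f_pred[i]), lo, hi, part))
    return records


def neutral_fraction(records: Sequence[OtuNeutralityRecord]) -> tuple[float, float, float]:
    """Percentages (neutral, above, below); sums to 100."""
    if not records:
        raise ValueError("no records")
    n = len(records)
    cnt = {"neutral": 0, "above": 0, "below": 0}
    for r in records:
        cnt[r.partition] += 1
    return tuple(100.0 * cnt[k] / n for k in ("neutral", "above", "below"))


def sequential_chain(tables: Sequence[tuple[str, OtuTable]],
                     mode: str = "stepping_stone",
                     common_source: OtuTable | None = None,
                     detection: float | str = "auto",
                     bootstrap: int = 1000,
                     seed: int | None = None) -> dict[tuple[str, str], NcmFit]:
    """Chain NCM fits through an ordered series of communities.

    ``stepping_stone`` treats each table as the source for the next one
    (gut-compartment design: environment -> stomach -> pyloric cecum -> ...);
    ``common_source`` fits every table against one fixed external source
    (life-stage design: water -> each stage).  Returns fits keyed by
    (source_label, target_label).
    """
    tables = list(tables)
    if mode == "stepping_stone":
        if len(tables) < 2:
            raise ValueError("stepping_stone needs at least 2 tables")
        pairs = [((tables[i][0], tables[i + 1][0]),
                  (tables[i][1], tables[i + 1][1]))
                 for i in range(len(tables) - 1)]
    elif mode == "common_source":
        if common_source is None:
            raise ValueError("common_source mode requires a source table")
        pairs = [(("source", label), (common_source, tbl)) for label, tbl in tables]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    fits: dict[tuple[str, str], NcmFit] = {}
    for key, (src, tgt) in pairs:
        inp = build_ncm_input(src, tgt, detection=detection)
        fits[key] = fit_ncm(inp, bootstrap=bootstrap, seed=seed)
    return fits
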