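"""Alpha diversity and nonparametric group statistics.

Richness counts taxa with at least one read; Shannon entropy uses the
natural log; evenness is Pielou's J = H / ln(richness).  No rarefaction is
applied before richness — the read-depth filter is the only normalization
(documented caveat).  Group comparisons are rank-based (Kruskal-Wallis,
pairwise Wilcoxon rank-sum) with Benjamini-Hochberg control within each
family of pairwise tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import OtuTable, SampleMetadata, to_relative_abundance


@dataclass(frozen=True)
class AlphaRecord:
    sample_id: str
    richness: int
    shannon: float
    pielou_evenness: float | None  # undefined at richness <= 1


def alpha_diversity(table: OtuTable) -> list[AlphaRecord]:
    """Richness, Shannon entropy and Pielou evenness per sample."""
    records = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        nz = col[col > 0]
        richness = int(len(nz))
        if richness == 0:
            records.append(AlphaRecord(sid, 0, 0.0, None))
            continue
        q = nz / nz.sum()
        shannon = float(-(q * np.log(q)).sum())
        pielou = shannon / np.log(richness) if richness >= 2 else None
        records.append(AlphaRecord(sid, richness, shannon, pielou))
    return records


def alpha_table(records: Sequence[AlphaRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def _split_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    parts = [values[groups == g] for g in labels]
    if len(parts) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(p) == 0 for p in parts):
        raise ValueError("every group needs at least 1 value")
    return labels, parts


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    _, parts = _split_groups(values, groups)
    flat = np.concatenate(parts)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*parts)
    return float(H), float(p)


def _ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # exact rank-sum for small tie-free groups, normal approximation with
    # tie correction otherwise
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pairwise_wilcoxon_bh(values: Sequence[float], groups: Sequence) -> pd.DataFrame:
    """All pairwise rank-sum tests with BH adjustment across the family."""
    labels, parts = _split_groups(values, groups)
    rows = []
    for (i, gi), (j, gj) in combinations(enumerate(labels), 2):
        U, p = _ranksum(parts[i], parts[j])
        rows.append({"group1": gi, "group2": gj, "U": U, "p": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def genus_differential_abundance(table: OtuTable,
                                 taxonomy: Mapping[str, str],
                                 metadata: SampleMetadata,
                                 group_column: str = "group") -> pd.DataFrame:
    """Genus-level differential relative abundance across groups.

    OTU counts are collapsed by genus (sum), converted to per-sample
    relative abundance, tested per genus with Kruskal-Wallis across the
    groups and BH-adjusted across genera.  ``direction`` names the group
    with the highest median relative abundance.  OTUs without a taxonomy
    entry are pooled under "unassigned"; genera with zero total are
    skipped.
    """
    if not taxonomy:
        raise ValueError("taxonomy map is empty")
    genera = [taxonomy.get(t, "unassigned") for t in table.taxon_ids]
    rel = to_relative_abundance(table).values
    df = pd.DataFrame(rel, index=genera, columns=list(table.sample_ids))
    collapsed = df.groupby(level=0).sum()
    groups = metadata.group_of(list(table.sample_ids), group_column)

    rows = []
    for genus, series in collapsed.iterrows():
        vals = series.to_numpy()
        if vals.sum() == 0:
            continue
        H, p = kruskal_wallis(vals, groups)
        med = pd.Series(vals).groupby(groups).median()
        rows.append({"genus": genus, "H": H, "p": p,
                     "direction": med.idxmax()})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out = out[["genus", "H", "p", "p_adj", "direction"]]
        out = out.sort_values("p_adj", kind="stable").reset_index(drop=True)
    return out
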