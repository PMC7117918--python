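"""Domain types and readers/writers shared by every analysis stage.

The universal currency is the :class:`OtuTable`: an integer count matrix
with taxa as rows and samples as columns.  Tables are read from a plain
TSV dialect (first cell ``#OTU_ID``) or from BIOM v1 JSON (sparse or
dense).  Trees are rooted newick files with branch lengths, parsed with
scikit-bio.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

log = logging.getLogger("ncmkit")

#: A rooted phylogeny with branch lengths; tip names are OTU ids.
PhyloTree = TreeNode


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} ID: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class OtuTable:
    """Integer OTU count matrix, rows = taxa, columns = samples."""

    taxon_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray  # shape (n_taxa, n_samples), non-negative integers

    def __post_init__(self):
        object.__setattr__(self, "taxon_ids", tuple(self.taxon_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if counts.size == 0:
            raise ValueError("table needs at least 1 taxon and 1 sample")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                bad = np.argwhere(~np.isfinite(counts) | (counts != np.floor(counts)))[0]
                raise ValueError(
                    f"non-integer count at taxon {self.taxon_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at taxon {self.taxon_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        counts = np.ascontiguousarray(counts.astype(np.int64))
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    def __eq__(self, other) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (self.taxon_ids == other.taxon_ids
                and self.sample_ids == other.sample_ids
                and np.array_equal(self.counts, other.counts))

    __hash__ = None

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.taxon_ids),
                            columns=list(self.sample_ids))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OtuTable":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                   df.to_numpy())

    def select_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        wanted = list(sample_ids)
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in idx]
        if missing:
            raise KeyError(f"unknown sample IDs: {missing}")
        cols = [idx[s] for s in wanted]
        return OtuTable(self.taxon_ids, tuple(wanted), self.counts[:, cols])

    def drop_empty_taxa(self) -> "OtuTable":
        keep = self.counts.sum(axis=1) > 0
        if not keep.any():
            raise ValueError("all taxa are empty")
        return OtuTable(tuple(np.array(self.taxon_ids)[keep]), self.sample_ids,
                        self.counts[keep])


@dataclass(frozen=True)
class RelAbundanceTable:
    """Per-sample relative abundances; every column sums to 1."""

    taxon_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "taxon_ids", tuple(self.taxon_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        vals = np.ascontiguousarray(np.asarray(self.values, dtype=float))
        if vals.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match IDs")
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("relative abundances must lie in [0, 1]")
        colsums = vals.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            j = int(np.argmax(np.abs(colsums - 1.0)))
            raise ValueError(
                f"column {self.sample_ids[j]!r} sums to {colsums[j]}, not 1"
            )
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    def mean_abundance(self) -> np.ndarray:
        """Mean over samples of the per-sample relative abundances."""
        return self.values.mean(axis=1)


@dataclass(frozen=True)
class SampleMetadata:
    """sample_id -> categorical group labels (one or more columns)."""

    frame: pd.DataFrame  # index = sample_id

    def __post_init__(self):
        df = self.frame
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate sample ID in metadata: {dup!r}")
        object.__setattr__(self, "frame", df)

    def group_of(self, sample_ids: Sequence[str], column: str = "group") -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise KeyError(f"samples missing from metadata: {missing}")
        return self.frame.loc[list(sample_ids), column].to_numpy()

    def samples_in_group(self, label: str, column: str = "group") -> list[str]:
        return list(self.frame.index[self.frame[column] == label])


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ids", tuple(self.ids))
        vals = np.ascontiguousarray(np.asarray(self.values, dtype=float))
        n = len(self.ids)
        if vals.shape != (n, n):
            raise ValueError("distance matrix shape does not match IDs")
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(vals)) > 1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        _check_unique(self.ids, "sample/taxon")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        pos = {t: i for i, t in enumerate(self.ids)}
        idx = [pos[t] for t in ids]
        return DistanceMatrix(tuple(ids), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    df.index = df.index.map(str)
    try:
        numeric = df.apply(pd.to_numeric)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in OTU table ({exc})") from exc
    return numeric


def _read_biom_json(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        doc = json.load(fh)
    shape = doc["shape"]
    rows = [str(r["id"]) for r in doc["rows"]]
    cols = [str(c["id"]) for c in doc["columns"]]
    mat = np.zeros((shape[0], shape[1]))
    if doc.get("matrix_type", "sparse") == "sparse":
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    return pd.DataFrame(mat, index=rows, columns=cols)


def read_otu_table(path: str | Path, orientation: str = "taxa_rows") -> OtuTable:
    """Read an OTU count table from TSV or BIOM v1 JSON.

    Parameters
    ----------
    path
        TSV (first cell ``#OTU_ID``) or BIOM JSON file.
    orientation
        ``taxa_rows`` (default) or ``samples_rows``; the returned table is
        always taxa x samples.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    head = path.open("rb").read(1).decode("utf-8", "replace")
    if path.suffix in (".json", ".biom") or head == "{":
        df = _read_biom_json(path)
    else:
        df = _read_tsv_table(path)
    if orientation == "samples_rows":
        df = df.T
    bad = df.to_numpy()
    if np.any(bad != np.floor(bad)):
        i, j = np.argwhere(bad != np.floor(bad))[0]
        raise ValueError(
            f"{path}: non-integer count at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return OtuTable.from_dataframe(df)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write as the TSV dialect (first cell ``#OTU_ID``, no quoting)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#OTU_ID\t" + "\t".join(table.sample_ids) + "\n")
        for i, tid in enumerate(table.taxon_ids):
            fh.write(tid + "\t" + "\t".join(str(int(v)) for v in table.counts[i]) + "\n")


def write_biom_json(table: OtuTable, path: str | Path, sparse: bool = True) -> None:
    """Write as BIOM v1 JSON (sparse by default)."""
    data: list
    if sparse:
        rr, cc = np.nonzero(table.counts)
        data = [[int(r), int(c), int(table.counts[r, c])] for r, c in zip(rr, cc)]
        mtype = "sparse"
    else:
        data = table.counts.tolist()
        mtype = "dense"
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "ncmkit",
        "matrix_type": mtype,
        "matrix_element_type": "int",
        "shape": [table.n_taxa, table.n_samples],
        "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample metadata TSV (columns: sample_id, group, ...)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: metadata needs a 'sample_id' column")
    return SampleMetadata(df.set_index("sample_id"))


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.frame.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


def read_tree(path: str | Path, assume_unit_branch_lengths: bool = False) -> PhyloTree:
    """Read a rooted newick tree and validate branch lengths.

    Missing branch lengths are an error unless ``assume_unit_branch_lengths``
    is set (the dispersion and UniFrac metrics are meaningless without
    lengths); negative lengths are always an error.
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise ValueError(f"unparseable newick in {path}: {exc}") from exc
    return validate_tree(tree, assume_unit_branch_lengths)


def validate_tree(tree: PhyloTree, assume_unit_branch_lengths: bool = False) -> PhyloTree:
    tips = [t.name for t in tree.tips()]
    _check_unique(tips, "tip")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if assume_unit_branch_lengths:
                node.length = 1.0
            else:
                raise ValueError(
                    f"missing branch length on node {node.name!r}; "
                    "pass assume_unit_branch_lengths=True to use length 1"
                )
        elif node.length < 0:
            raise ValueError(f"negative branch length on node {node.name!r}")
    return tree


def check_taxa_in_tree(table: OtuTable, tree: PhyloTree) -> None:
    """Hard error when a taxon with nonzero counts is not a tree tip."""
    tips = {t.name for t in tree.tips()}
    present = np.array(table.taxon_ids)[table.counts.sum(axis=1) > 0]
    missing = [t for t in present if t not in tips]
    if missing:
        raise ValueError(
            f"{len(missing)} taxa missing from tree (e.g. {missing[:5]}); "
            "silent pruning would change denominators"
        )


# ---------------------------------------------------------------------------
# elementary transforms


def filter_min_reads(table: OtuTable, min_total: int = 8000,
                     drop_empty_taxa: bool = False) -> OtuTable:
    """Discard samples whose total read count is strictly below ``min_total``.

    A sample with exactly ``min_total`` reads is kept.  Taxa that become
    all-zero are retained unless ``drop_empty_taxa`` is set.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    totals = table.sample_totals()
    keep = totals >= min_total
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError("no samples survive depth filter")
    log.info("depth filter (>= %d reads): removed %d of %d samples",
             min_total, n_removed, table.n_samples)
    out = OtuTable(table.taxon_ids,
                   tuple(np.array(table.sample_ids)[keep]),
                   table.counts[:, keep])
    if drop_empty_taxa:
        out = out.drop_empty_taxa()
    return out


def to_relative_abundance(table: OtuTable) -> RelAbundanceTable:
    """Column-normalize counts; zero-total columns are an error."""
    totals = table.sample_totals()
    if np.any(totals == 0):
        j = int(np.argmax(totals == 0))
        raise ValueError(f"sample {table.sample_ids[j]!r} has zero total count")
    vals = table.counts / totals[np.newaxis, :]
    return RelAbundanceTable(table.taxon_ids, table.sample_ids, vals)
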