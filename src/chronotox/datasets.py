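"""Expression datasets: gene x timepoint tables and paralog lumping.

An :class:`ExpressionDataset` holds a CPM-scale gene-by-timepoint matrix
with sampling times in hours. The model's dynamical variables for PER,
CRY and NR1D are fitted to the *sum* of the corresponding paralogs'
expression (paralog compensation keeps the family sum stable after a
single-paralog knock-out); :func:`lump_paralogs` performs that summation
on the data side. ARNTL shows no paralog compensation and is not lumped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "PARALOG_FAMILIES",
    "lump_paralogs",
    "read_expression",
    "write_expression",
    "rescale_to_reference",
]

# family -> paralogs summed into the lumped dynamical variable
PARALOG_FAMILIES = {
    "PER": ["PER1", "PER2", "PER3"],
    "CRY": ["CRY1", "CRY2"],
    "NR1D": ["NR1D1", "NR1D2"],
}


@dataclass
class ExpressionDataset:
    """Gene x timepoint expression matrix (CPM scale, times in hours)."""

    genes: list
    times: np.ndarray
    values: np.ndarray
    cell_line: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.genes = [str(g) for g in self.genes]
        self.times = np.asarray(self.times, float)
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if len(set(self.genes)) != len(self.genes):
            dup = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValueError(f"duplicate gene identifiers: {dup}")
        if self.values.shape != (len(self.genes), self.times.size):
            raise ValueError("values must have shape (n_genes, n_times)")
        if self.times.size < 2:
            raise ValueError("need at least two timepoints per gene")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no NA)")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    # -- access --------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def series(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.genes.index(gene)]
        except ValueError:
            raise KeyError(f"unknown gene: {gene!r}") from None

    def gene_max(self, gene: str) -> float:
        """Per-gene normalizer: the maximum of the gene's series."""
        return float(np.max(self.series(gene)))

    def subset(self, genes) -> "ExpressionDataset":
        rows = [self.genes.index(g) for g in genes]
        return ExpressionDataset(list(genes), self.times.copy(),
                                 self.values[rows], self.cell_line,
                                 dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.genes,
                          columns=[f"{t:g}" for t in self.times])
        df.index.name = "gene"
        return df


def lump_paralogs(dataset: ExpressionDataset,
                  mapping: dict | None = None,
                  knocked_out=()) -> ExpressionDataset:
    """Sum paralog families into one row per lumped dynamical variable.

    ``mapping`` maps the lumped name to its paralog list (default:
    PER/CRY/NR1D families). Unmapped genes pass through unchanged. A
    paralog missing from the dataset is an error unless it is listed in
    ``knocked_out`` (its contribution is then simply absent from the sum,
    which is the knock-out fitting convention).
    """
    if mapping is None:
        mapping = PARALOG_FAMILIES
    seen: dict = {}
    for lump, paralogs in mapping.items():
        for g in paralogs:
            if g in seen:
                raise ValueError(
                    f"paralog {g!r} appears in both {seen[g]!r} and {lump!r}")
            seen[g] = lump

    knocked_out = set(knocked_out)
    genes_out, rows = [], []
    for lump, paralogs in mapping.items():
        present = [g for g in paralogs if g in dataset.genes]
        missing = [g for g in paralogs if g not in dataset.genes]
        bad = [g for g in missing if g not in knocked_out]
        if bad:
            raise ValueError(
                f"paralog(s) {bad} of {lump!r} absent from dataset and not "
                f"flagged as knocked out")
        if not present:
            raise ValueError(f"no paralog of {lump!r} present in dataset")
        genes_out.append(lump)
        rows.append(dataset.values[[dataset.genes.index(g) for g in present]]
                    .sum(axis=0))
    for g in dataset.genes:
        if g not in seen:
            genes_out.append(g)
            rows.append(dataset.series(g))
    return ExpressionDataset(genes_out, dataset.times.copy(), np.array(rows),
                             dataset.cell_line,
                             {**dataset.meta, "lumped": list(mapping)})


# ---------------------------------------------------------------------------
# file I/O: TSV/CSV with a 'gene' id column and numeric hour columns
# ---------------------------------------------------------------------------

def read_expression(path, fmt: str | None = None,
                    cell_line: str = "") -> ExpressionDataset:
    """Read a gene x timepoint table (TSV or CSV; hours in the header)."""
    if fmt is None:
        fmt = "tsv" if str(path).endswith((".tsv", ".txt")) else "csv"
    if fmt not in ("tsv", "csv"):
        raise ValueError("format must be 'tsv' or 'csv'")
    df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",")
    if df.shape[1] < 3:
        raise ValueError("expected a gene column plus >= 2 timepoint columns")
    gene_col = df.columns[0]
    genes = df[gene_col].astype(str).tolist()
    try:
        times = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric timepoint column header: {exc}") from exc
    vals = df.iloc[:, 1:]
    if vals.isna().any().any():
        raise ValueError("missing values (NA) are not allowed")
    values = vals.to_numpy(dtype=float)
    return ExpressionDataset(genes, times, values, cell_line=cell_line,
                             meta={"path": str(path)})


def write_expression(dataset: ExpressionDataset, path,
                     fmt: str | None = None) -> None:
    if fmt is None:
        fmt = "tsv" if str(path).endswith((".tsv", ".txt")) else "csv"
    dataset.to_frame().to_csv(path, sep="\t" if fmt == "tsv" else ",")


def rescale_to_reference(dataset: ExpressionDataset,
                         reference: ExpressionDataset,
                         mode: str = "per_gene") -> ExpressionDataset:
    """Rescale one platform's values to another's mean (e.g. microarray to
    RNA-seq).

    ``per_gene`` matches each gene series' mean to the reference gene's
    mean; ``global`` applies one common factor matching the overall means.
    """
    if mode not in ("per_gene", "global"):
        raise ValueError("mode must be 'per_gene' or 'global'")
    shared = [g for g in dataset.genes if g in reference.genes]
    if not shared:
        raise ValueError("datasets share no gene identifiers")
    if mode == "global":
        m = float(np.mean([dataset.series(g).mean() for g in shared]))
        r = float(np.mean([reference.series(g).mean() for g in shared]))
        if m == 0:
            raise ValueError("zero overall mean; cannot rescale")
        factor = r / m
        values = dataset.values * factor
    else:
        values = dataset.values.copy()
        for g in shared:
            i = dataset.genes.index(g)
            m = float(dataset.series(g).mean())
            if m == 0:
                raise ValueError(f"gene {g!r} has zero mean; cannot rescale")
            values[i] *= reference.series(g).mean() / m
    return ExpressionDataset(list(dataset.genes), dataset.times.copy(), values,
                             dataset.cell_line,
                             {**dataset.meta, "rescaled": mode})
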