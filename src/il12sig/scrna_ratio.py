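"""Receptor-expression skew analysis of single-cell RNA-seq data.

Canonical IL-12 responders (T and NK cells) express the two receptor
subunits IL12RB1 and IL12RB2 with IL12RB1 dominant, while malignant
melanocytes skew toward IL12RB2. This module quantifies that skew from a
TPM expression matrix and per-cell type annotations:

* every annotated cell is classified by strict non-zero expression of
  each subunit (both, IL12RB1-only, IL12RB2-only, neither);
* within the both-non-zero subset, the per-cell IL12RB2:IL12RB1 TPM
  ratio distribution is summarized per cell type;
* class distributions are compared across cell types with a Pearson
  chi-squared test on the cells expressing at least one subunit (a
  Fisher-style exact/Monte-Carlo alternative is provided), and ratio
  distributions with a Wilcoxon rank-sum test on log ratios.

The deposited human-melanoma study (Gene Expression Omnibus accession
GSE115978: TPM matrix plus cell-type annotations) is the intended real
input; it is fetched outside the package and read through
:func:`load_expression`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionRecord",
    "ReceptorClassTable",
    "load_expression",
    "classify_cells",
    "ratio_distribution",
    "chi_squared_contingency",
    "fisher_contingency",
    "compare_ratios",
]

CLASSES = ("both", "rb1_only", "rb2_only", "neither")


@dataclass(frozen=True)
class ExpressionRecord:
    """One annotated cell: type label and TPM of the two receptor genes."""

    cell_id: str
    cell_type: str
    il12rb1: float
    il12rb2: float

    def __post_init__(self) -> None:
        if self.il12rb1 < 0 or self.il12rb2 < 0:
            raise ValueError("TPM values must be >= 0")


@dataclass
class ReceptorClassTable:
    """Per-cell-type counts of the four non-zero-expression classes."""

    counts: pd.DataFrame  # index = cell_type, columns = CLASSES

    def fractions(self) -> pd.DataFrame:
        """Class fractions per cell type, as percentages."""
        totals = self.counts.sum(axis=1)
        return 100.0 * self.counts.div(totals, axis=0)

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def _read_matrix(matrix_source: str | Path) -> pd.DataFrame:
    """Read a genes x cells matrix from CSV/TSV or an MTX triplet.

    For MTX, sibling files ``<stem>.rows`` and ``<stem>.cols`` (one name
    per line) supply gene and cell names.
    """
    path = Path(matrix_source)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        m = mmread(path)
        genes = Path(str(path.with_suffix("")) + ".rows").read_text().split()
        cells = Path(str(path.with_suffix("")) + ".cols").read_text().split()
        return pd.DataFrame(np.asarray(m.todense()), index=genes, columns=cells)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def load_expression(
    matrix_source: str | Path | pd.DataFrame,
    annotation_source: str | Path | pd.DataFrame,
    gene_names: tuple[str, str] = ("IL12RB1", "IL12RB2"),
    type_map: Mapping[str, str] | None = None,
    known_types: Sequence[str] | None = None,
) -> list[ExpressionRecord]:
    """Build one record per annotated cell from a matrix and annotations.

    ``annotation_source`` is a CSV (or DataFrame) with columns
    ``cell_id, cell_type``. ``type_map`` optionally renames deposited
    annotation labels to the analysis labels (e.g. ``{"Mal":
    "malignant"}``). When ``known_types`` is given, cells whose (mapped)
    type is not listed are relabeled ``"other"`` and retained. Raises
    when a gene is absent from the matrix or when annotated cells are
    missing from the matrix.
    """
    matrix = (
        matrix_source
        if isinstance(matrix_source, pd.DataFrame)
        else _read_matrix(matrix_source)
    )
    ann = (
        annotation_source
        if isinstance(annotation_source, pd.DataFrame)
        else pd.read_csv(annotation_source)
    )
    if not {"cell_id", "cell_type"} <= set(ann.columns):
        raise ValueError("annotations need columns cell_id, cell_type")
    for g in gene_names:
        if g not in matrix.index:
            raise KeyError(f"gene {g!r} not found in expression matrix")
    cell_ids = ann["cell_id"].astype(str)
    missing = [c for c in cell_ids if c not in matrix.columns]
    if missing:
        raise ValueError(
            f"cell-id reconciliation failed: {len(missing)} annotated cells "
            f"absent from the matrix (first: {missing[:5]})"
        )
    g1 = matrix.loc[gene_names[0], cell_ids].to_numpy(dtype=float)
    g2 = matrix.loc[gene_names[1], cell_ids].to_numpy(dtype=float)
    types = ann["cell_type"].astype(str)
    if type_map is not None:
        types = types.map(lambda t: type_map.get(t, t))
    if known_types is not None:
        allowed = set(known_types)
        types = types.map(lambda t: t if t in allowed else "other")
    return [
        ExpressionRecord(cell_id=c, cell_type=t, il12rb1=a, il12rb2=b)
        for c, t, a, b in zip(cell_ids, types, g1, g2)
    ]


def classify_cells(records: Sequence[ExpressionRecord]) -> ReceptorClassTable:
    """Classify cells by strict non-zero (TPM > 0) expression of each gene."""
    if not records:
        raise ValueError("records must be non-empty")
    rows: dict[str, dict[str, int]] = {}
    for r in records:
        row = rows.setdefault(r.cell_type, {c: 0 for c in CLASSES})
        has1, has2 = r.il12rb1 > 0, r.il12rb2 > 0
        if has1 and has2:
            row["both"] += 1
        elif has1:
            row["rb1_only"] += 1
        elif has2:
            row["rb2_only"] += 1
        else:
            row["neither"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")[list(CLASSES)]
    return ReceptorClassTable(counts=df)


def ratio_distribution(
    records: Sequence[ExpressionRecord],
) -> dict[str, np.ndarray]:
    """Per-cell-type IL12RB2:IL12RB1 TPM ratios, both-non-zero cells only.

    Cells with zero in either gene are excluded, never imputed. A type
    with no both-non-zero cells maps to an empty array (its median is
    undefined).
    """
    out: dict[str, list[float]] = {}
    for r in records:
        out.setdefault(r.cell_type, [])
        if r.il12rb1 > 0 and r.il12rb2 > 0:
            out[r.cell_type].append(r.il12rb2 / r.il12rb1)
    return {t: np.array(v) for t, v in out.items()}


def ratio_summary(ratios: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Median and count per cell type; median is NaN when no ratios exist."""
    rows = [
        (t, len(v), float(np.median(v)) if len(v) else float("nan"))
        for t, v in ratios.items()
    ]
    return pd.DataFrame(rows, columns=["cell_type", "n", "median_ratio"]).set_index(
        "cell_type"
    )


def _expressing_table(table: ReceptorClassTable, classes: Sequence[str]) -> np.ndarray:
    counts = table.counts[list(classes)].to_numpy()
    if counts.shape[0] < 2:
        raise ValueError("need >= 2 cell types to compare distributions")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("degenerate table: zero marginal count")
    return counts


def chi_squared_contingency(
    table: ReceptorClassTable,
    classes: Sequence[str] = ("both", "rb1_only", "rb2_only"),
) -> tuple[float, float, int]:
    """Pearson chi-squared test of class distribution across cell types.

    Restricted by default to cells expressing at least one gene. Returns
    ``(statistic, p_value, dof)`` with no continuity correction.
    """
    counts = _expressing_table(table, classes)
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


def fisher_contingency(
    table: ReceptorClassTable,
    classes: Sequence[str] = ("both", "rb1_only", "rb2_only"),
    n_montecarlo: int = 10_000,
    seed: int = 0,
) -> float:
    """Exact-style alternative to the chi-squared test.

    2x2 tables use the exact Fisher test; larger tables use a seeded
    Monte-Carlo p-value: the fraction of random tables with the observed
    margins whose Pearson statistic is at least as extreme.
    """
    counts = _expressing_table(table, classes)
    if counts.shape == (2, 2):
        return float(stats.fisher_exact(counts)[1])
    obs_stat = stats.chi2_contingency(counts, correction=False).statistic
    rng = np.random.default_rng(seed)
    dist = stats.random_table(counts.sum(axis=1), counts.sum(axis=0))
    sims = dist.rvs(n_montecarlo, random_state=rng)
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / counts.sum()
    stats_sim = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
    # add-one correction keeps the Monte-Carlo p-value away from zero
    return float((1 + np.sum(stats_sim >= obs_stat - 1e-9)) / (1 + n_montecarlo))


def compare_ratios(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample location test between ratio collections.

    Wilcoxon rank-sum (Mann–Whitney U, two-sided) on log ratios; the
    log transform changes nothing about the ranks but matches the scale
    on which the skew is interpreted.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both ratio collections must be non-empty")
    return float(stats.mannwhitneyu(np.log(a), np.log(b), alternative="two-sided").pvalue)


def write_records_csv(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    """Write per-cell records (``cell_id, cell_type, il12rb1, il12rb2``)."""
    df = pd.DataFrame(
        [(r.cell_id, r.cell_type, r.il12rb1, r.il12rb2) for r in records],
        columns=["cell_id", "cell_type", "il12rb1", "il12rb2"],
    )
    df.to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[ExpressionRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        ExpressionRecord(str(r.cell_id), str(r.cell_type), float(r.il12rb1), float(r.il12rb2))
        for r in df.itertuples()
    ]
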