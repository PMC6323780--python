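"""Cross-classification of misalignment- versus aging-regulated genes.

Takes two differential-expression result tables — the week-3 CCM
contrast (misaligned vs control) and the aging contrast (control week 3
vs week 2) — each a per-gene (log2 fold change, BH-adjusted p) pair,
and asks whether each CCM-responsive gene moves in the same or the
opposite direction with normal aging:

* ``convergent``   — same sign, aging FDR < 0.1
* ``trend_same``   — same sign, aging FDR in [0.1, 0.3)
* ``opposite``     — opposite sign, aging FDR < 0.3 (the relaxed cutoff
  that isolates genes specifically regulated by misalignment)
* ``not_ccm_significant`` — CCM FDR >= 0.1
* ``unclassified`` — missing values, zero fold change, or same sign
  with aging FDR >= 0.3

All padj intervals are half-open ``[lower, upper)``.  A gene filtered
out of one table (padj NA, typically low counts) cannot be classified.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sleep_activity import CorrelationResult

__all__ = [
    "ClassThresholds",
    "REGULATION_CLASSES",
    "classify_gene",
    "classify_table",
    "fc_correlation",
    "read_de_table",
    "opposite_regulation_reference",
]

REGULATION_CLASSES = (
    "convergent",
    "trend_same",
    "opposite",
    "not_ccm_significant",
    "unclassified",
)


@dataclass(frozen=True)
class ClassThresholds:
    ccm_fdr: float = 0.1
    aging_strict_fdr: float = 0.1
    aging_trend_upper: float = 0.3
    aging_opposite_fdr: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.ccm_fdr <= self.aging_trend_upper <= 1:
            raise ValueError("need 0 < ccm_fdr <= aging_trend_upper <= 1")


def classify_gene(
    ccm_log2fc: Optional[float],
    ccm_padj: Optional[float],
    aging_log2fc: Optional[float],
    aging_padj: Optional[float],
    thresholds: ClassThresholds = ClassThresholds(),
) -> str:
    """Regulation class of one gene from its two (log2FC, padj) pairs."""
    values = (ccm_log2fc, ccm_padj, aging_log2fc, aging_padj)
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in values):
        return "unclassified"
    if ccm_padj >= thresholds.ccm_fdr:
        return "not_ccm_significant"
    if ccm_log2fc == 0.0 or aging_log2fc == 0.0:
        return "unclassified"  # sign undefined
    same_sign = (ccm_log2fc > 0) == (aging_log2fc > 0)
    if same_sign:
        if aging_padj < thresholds.aging_strict_fdr:
            return "convergent"
        if aging_padj < thresholds.aging_trend_upper:
            return "trend_same"
        return "unclassified"
    if aging_padj < thresholds.aging_opposite_fdr:
        return "opposite"
    return "unclassified"


def classify_table(
    ccm_table: pd.DataFrame,
    aging_table: pd.DataFrame,
    thresholds: ClassThresholds = ClassThresholds(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join two DE tables on gene and classify every gene.

    Tables need columns ``gene``, ``log2FC``, ``padj`` (padj may be NA).
    Genes absent from one table get missing values there.  Returns the
    per-gene classification table plus counts keyed by
    ``{class}_{up|down}`` according to the sign of the CCM fold change
    (direction-free classes are keyed by class name alone).
    """
    for name, tbl in (("ccm", ccm_table), ("aging", aging_table)):
        dupes = tbl["gene"][tbl["gene"].duplicated()].unique()
        if dupes.size:
            raise ValueError(f"duplicate gene ids in {name} table: {sorted(dupes)}")
    merged = pd.merge(
        ccm_table.rename(columns={"log2FC": "ccm_log2FC", "padj": "ccm_padj"}),
        aging_table.rename(columns={"log2FC": "aging_log2FC", "padj": "aging_padj"}),
        on="gene",
        how="outer",
    ).sort_values("gene", kind="stable").reset_index(drop=True)
    merged["regulation_class"] = [
        classify_gene(
            row.ccm_log2FC, row.ccm_padj, row.aging_log2FC, row.aging_padj, thresholds
        )
        for row in merged.itertuples()
    ]
    counts: dict[str, int] = {}
    for row in merged.itertuples():
        cls = row.regulation_class
        if cls in ("convergent", "trend_same", "opposite"):
            direction = "down" if row.ccm_log2FC < 0 else "up"
            key = f"{cls}_{direction}"
        else:
            key = cls
        counts[key] = counts.get(key, 0) + 1
    return merged, counts


def fc_correlation(
    fc_a: Mapping[str, float],
    fc_b: Mapping[str, float],
    gene_subset: Optional[Iterable[str]] = None,
    method: str = "spearman",
) -> CorrelationResult:
    """Correlation of two contrasts' log2 fold changes on shared genes.

    Defaults to the Spearman rank correlation (Fisher-z 95% CI);
    ``method="pearson"`` is available for the linear version.
    """
    genes = set(fc_a) & set(fc_b)
    if gene_subset is not None:
        genes &= set(gene_subset)
    genes = sorted(genes)
    if len(genes) < 4:
        raise ValueError("need at least 4 shared genes")
    x = np.array([fc_a[g] for g in genes])
    y = np.array([fc_b[g] for g in genes])
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("degenerate fold-change vector")
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    n = len(genes)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    half = 1.959963984540054 / np.sqrt(n - 3)
    return CorrelationResult(
        rho=float(rho), ci=(float(np.tanh(z - half)), float(np.tanh(z + half))), p=float(p), n=n
    )


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a 3-column DE result TSV (gene, log2FC, padj; 'NA' allowed)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"gene": str})
    missing = {"gene", "log2FC", "padj"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# curated reference set

# Sixteen fly genes oppositely regulated by chronic circadian misalignment
# and normal aging (whole-fly RNA-seq; DESeq2 shrunken log2FC, BH-adjusted
# p): 12 downregulated by misalignment yet upregulated with age, 4 the
# reverse.  Useful as a worked example and as a fixed input for the
# classification filter.
_OPPOSITE_REGULATION_GENES = [
    # gene, ccm_log2FC, ccm_padj, aging_log2FC, aging_padj
    ("CG3739", -0.90, 3.70e-13, 0.20, 2.38e-01),
    ("CG18609", -0.80, 7.72e-13, 0.56, 4.94e-04),
    ("CG34180", -0.75, 1.46e-03, 0.50, 1.04e-01),
    ("CG10960", -0.67, 1.49e-06, 0.51, 4.81e-03),
    ("CG11741", -0.56, 4.57e-02, 0.67, 3.26e-02),
    ("b6", -0.55, 4.23e-02, 0.38, 1.79e-01),
    ("Uro", -0.54, 2.75e-02, 0.57, 3.79e-02),
    ("rost", -0.51, 2.96e-02, 0.35, 1.14e-01),
    ("CG4607", -0.48, 7.35e-03, 0.58, 1.96e-04),
    ("CG15096", -0.46, 9.90e-02, 0.48, 4.42e-02),
    ("CG9459", -0.35, 8.04e-02, 0.71, 1.34e-03),
    ("CG14464", -0.33, 9.77e-02, 0.46, 1.09e-02),
    ("CG5804", 0.51, 7.70e-03, -0.36, 1.68e-01),
    ("CG5767", 0.45, 4.87e-02, -0.65, 6.97e-03),
    ("CG34330", 0.41, 3.14e-02, -0.22, 2.57e-01),
    ("AsnS", 0.37, 7.58e-02, -0.36, 8.08e-02),
]


def opposite_regulation_reference() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The curated 16-gene set as (ccm_table, aging_table) DE frames."""
    ccm = pd.DataFrame(
        [(g, c_fc, c_p) for g, c_fc, c_p, _, _ in _OPPOSITE_REGULATION_GENES],
        columns=["gene", "log2FC", "padj"],
    )
    aging = pd.DataFrame(
        [(g, a_fc, a_p) for g, _, _, a_fc, a_p in _OPPOSITE_REGULATION_GENES],
        columns=["gene", "log2FC", "padj"],
    )
    return ccm, aging
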