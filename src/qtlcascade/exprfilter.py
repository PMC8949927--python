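"""Differential-expression filtering and candidate-gene cascade.

Per-contrast log2 fold changes with Welch t-tests, the strict |LFC| > 1
filter, qPCR relative quantification (2^-dCt), and the intersection of
interval membership, haplotype polymorphism and expression evidence into
a per-gene candidate table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_LFC_THRESHOLD = 1.0
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class ExpressionMatrix:
    """Genes x samples of non-negative normalized intensities.

    ``groups`` maps each sample (column) to one of exactly two group
    labels; the contrast orientation is group order of first appearance.
    """

    values: pd.DataFrame
    groups: pd.Series
    contrast: str = ""

    def __post_init__(self):
        self.values = pd.DataFrame(self.values)
        self.groups = pd.Series(self.groups)
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if set(self.groups.index) != set(self.values.columns):
            raise ValueError("group labels must cover exactly the sample columns")
        self.groups = self.groups.loc[self.values.columns]
        levels = self.group_levels
        if len(levels) != 2:
            raise ValueError(f"expected exactly two groups, got {levels}")
        counts = self.groups.value_counts()
        if counts.min() < 2:
            raise ValueError("each group needs >= 2 samples")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression intensities must be non-negative")

    @property
    def group_levels(self) -> list:
        seen = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def genes(self) -> list:
        return list(self.values.index)


@dataclass
class DEResult:
    """LFC and Welch-t result for one gene in one contrast."""

    gene: str
    lfc: float
    p_value: float
    passed: bool


def compute_lfc(
    expr: ExpressionMatrix,
    gene: str | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    threshold: float = DEFAULT_LFC_THRESHOLD,
):
    """LFC and Welch p per gene (all genes if ``gene`` is None).

    LFC = mean(log2(x + c)) in group 1 minus the same in group 2, with
    pseudocount c (default 1).  The p-value is a two-sided Welch t-test
    on the same log2 values.  A gene that is all-zero in both groups
    gets LFC 0 and p 1.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    g1, g2 = expr.group_levels
    cols1 = expr.groups.index[expr.groups == g1]
    cols2 = expr.groups.index[expr.groups == g2]
    x1 = np.log2(expr.values[cols1].to_numpy(dtype=float) + pseudocount)
    x2 = np.log2(expr.values[cols2].to_numpy(dtype=float) + pseudocount)
    lfc = x1.mean(axis=1) - x2.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(x1, x2, axis=1, equal_var=False).pvalue
    allzero = (expr.values[cols1].to_numpy() == 0).all(axis=1) & (
        expr.values[cols2].to_numpy() == 0
    ).all(axis=1)
    lfc = np.where(allzero, 0.0, lfc)
    p = np.where(allzero | np.isnan(p), 1.0, p)
    table = pd.DataFrame(
        {"lfc": lfc, "p_value": p, "passed": np.abs(lfc) > threshold},
        index=expr.values.index,
    )
    if gene is None:
        return table
    if gene not in table.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    row = table.loc[gene]
    return DEResult(gene, float(row.lfc), float(row.p_value), bool(row.passed))


def de_filter(results: pd.DataFrame, threshold: float = DEFAULT_LFC_THRESHOLD) -> list:
    """Genes with |LFC| strictly greater than ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    mask = results["lfc"].abs() > threshold
    return list(results.index[mask])


@dataclass
class CtTable:
    """qPCR Ct values: one row per sample with target and reference Ct."""

    data: pd.DataFrame  # columns: sample, target_ct, reference_ct

    def __post_init__(self):
        self.data = pd.DataFrame(self.data)
        required = {"sample", "target_ct", "reference_ct"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"CtTable requires columns {sorted(required)}")
        finite = self.data[["target_ct", "reference_ct"]].apply(
            lambda c: np.isfinite(c) | c.isna()
        )
        if not finite.all().all():
            raise ValueError("Ct values must be finite or missing")
        for col in ("target_ct", "reference_ct"):
            if (self.data[col].dropna() <= 0).any():
                raise ValueError("Ct values must be > 0")


def ddct(ct: CtTable) -> pd.Series:
    """Relative expression 2^-(Ct_target - Ct_reference) per sample.

    Samples with a missing reference Ct are dropped with a warning.
    """
    df = ct.data
    missing = df["reference_ct"].isna() | df["target_ct"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} sample(s) dropped for missing Ct",
            RuntimeWarning,
            stacklevel=2,
        )
    df = df[~missing]
    rel = np.power(2.0, -(df["target_ct"] - df["reference_ct"]))
    rel.index = df["sample"]
    return rel.rename("relative_expression")


def build_cascade(
    interval_genes,
    polymorphic_genes,
    de_parental,
    de_congenic,
    de_obob=(),
    sc_top_cluster=None,
) -> pd.DataFrame:
    """Combine filter memberships into a per-gene evidence table.

    Final candidates are the intersection interval & polymorphic &
    DE-parental & DE-congenic; the ob/ob flag and the single-cell
    top-expression cluster are annotations, not filters.  One row per
    interval gene, sorted by gene id.
    """
    interval_genes = list(interval_genes)
    interval = set(interval_genes)
    if len(interval) != len(interval_genes):
        raise ValueError("duplicate interval gene ids")
    named = {
        "in_polymorphic_block": set(polymorphic_genes),
        "de_parental": set(de_parental),
        "de_congenic": set(de_congenic),
        "de_obob": set(de_obob),
    }
    for label, genes in named.items():
        stray = genes - interval
        if stray:
            raise ValueError(
                f"{label} contains genes absent from the interval annotation: "
                f"{sorted(stray)[:5]}"
            )
    sc_top_cluster = dict(sc_top_cluster or {})
    rows = []
    for gid in sorted(interval_genes):
        flags = {label: gid in genes for label, genes in named.items()}
        rows.append(
            {
                "gene": gid,
                "in_interval": True,
                **flags,
                "sc_top_cluster": sc_top_cluster.get(gid, ""),
                "final_candidate": flags["in_polymorphic_block"]
                and flags["de_parental"]
                and flags["de_congenic"],
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    # cascade nestedness sanity: final subset of each contributing filter
    final = set(table.index[table.final_candidate])
    assert final <= named["de_parental"] & named["de_congenic"]
    assert final <= named["in_polymorphic_block"]
    return table


def final_candidates(evidence: pd.DataFrame) -> list:
    return list(evidence.index[evidence["final_candidate"]])
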