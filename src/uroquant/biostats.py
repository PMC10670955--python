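"""Small-sample statistics and normalizations for the assay tables.

Covers qPCR relative expression as a negative delta-Ct against an
endogenous control, urinary potassium normalized to creatinine,
normality-routed two-group testing (Shapiro-Wilk deciding between a
pooled-variance t test and the Mann-Whitney U), and adjusted-p filtering
of differential-expression tables into up-/down-regulated gene sets with
shared/unique accounting across two contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .teer import mann_whitney_u

__all__ = [
    "TestResult",
    "DGEFilterResult",
    "negative_delta_ct",
    "qpcr_neg_delta_ct_table",
    "k_per_creatinine",
    "urine_table_normalize",
    "shapiro_route_test",
    "filter_deregulated",
]


# --------------------------------------------------------------------------
# qPCR and urine normalizations
# --------------------------------------------------------------------------

def negative_delta_ct(
    target_cts: Sequence[float], control_cts: Sequence[float]
) -> float:
    """-(mean target Ct - mean endogenous-control Ct).

    Higher values mean more target transcript.  Technical duplicates are
    plain-averaged.
    """
    target = np.asarray(target_cts, dtype=float)
    control = np.asarray(control_cts, dtype=float)
    if target.size == 0 or control.size == 0:
        raise ValueError("Ct lists must be non-empty")
    if (target <= 0).any() or (control <= 0).any():
        raise ValueError("Ct values must be positive")
    return float(-(target.mean() - control.mean()))


def qpcr_neg_delta_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample -dCt from a duplicate-Ct table.

    Expects columns ``sample_id, group, target_ct_1, target_ct_2,
    control_ct_1, control_ct_2`` (single-replicate tables may omit the
    ``_2`` columns).
    """
    required = {"sample_id", "group", "target_ct_1", "control_ct_1"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    tgt_cols = [c for c in ("target_ct_1", "target_ct_2") if c in table.columns]
    ctl_cols = [c for c in ("control_ct_1", "control_ct_2") if c in table.columns]
    out = table[["sample_id", "group"]].copy()
    out["neg_delta_ct"] = [
        negative_delta_ct(row[tgt_cols].to_numpy(float), row[ctl_cols].to_numpy(float))
        for _, row in table.iterrows()
    ]
    return out


def k_per_creatinine(k_mmol_per_l: float, creatinine_g_per_l: float) -> float:
    """Urinary K+ (mmol/L) per creatinine (g/L), in mmol/g."""
    if creatinine_g_per_l <= 0:
        raise ValueError("creatinine concentration must be positive")
    if k_mmol_per_l < 0:
        raise ValueError("K+ concentration must be non-negative")
    return k_mmol_per_l / creatinine_g_per_l


def urine_table_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``k_per_creatinine_mmol_per_g`` to a urine-chemistry table."""
    required = {"k_mmol_per_l", "creatinine_g_per_l"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = table.copy()
    out["k_per_creatinine_mmol_per_g"] = [
        k_per_creatinine(k, c)
        for k, c in zip(table["k_mmol_per_l"], table["creatinine_g_per_l"])
    ]
    return out


# --------------------------------------------------------------------------
# normality-routed two-group testing
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    test_name: str                  # mann_whitney_exact | mann_whitney_approx | t_unpaired
    statistic: float
    p_value: float
    normality_p_a: float
    normality_p_b: float


def shapiro_route_test(
    group_a: Sequence[float], group_b: Sequence[float], alpha: float = 0.05
) -> TestResult:
    """Shapiro-Wilk-routed two-group comparison, two-tailed.

    Both groups normal at ``alpha`` -> unpaired pooled-variance t test;
    otherwise Mann-Whitney U (exact enumeration at small combined n).  A
    group smaller than 3 cannot be normality-tested: choose a test
    directly instead.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError(
            "normality routing needs n >= 3 per group; call the t test or "
            "Mann-Whitney directly for smaller samples"
        )
    p_a = float(stats.shapiro(a).pvalue)
    p_b = float(stats.shapiro(b).pvalue)
    if p_a >= alpha and p_b >= alpha:
        res = stats.ttest_ind(a, b, equal_var=True, alternative="two-sided")
        return TestResult("t_unpaired", float(res.statistic), float(res.pvalue),
                          p_a, p_b)
    name, u, p = mann_whitney_u(a, b)
    return TestResult(name, u, p, p_a, p_b)


# --------------------------------------------------------------------------
# deregulated-gene set logic
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DGEFilterResult:
    """Per-contrast up/down gene sets at an adjusted-p threshold.

    Genes with log2fc = 0 passing the threshold belong to neither set and
    are counted in ``n_zero_fc``.  ``shared`` / ``unique`` are filled when
    the table holds exactly two contrasts.
    """

    threshold: float
    up: dict[str, frozenset[str]]
    down: dict[str, frozenset[str]]
    n_zero_fc: dict[str, int]
    shared: frozenset[str] | None = None
    unique: dict[str, frozenset[str]] = field(default_factory=dict)

    def deregulated(self, contrast: str) -> frozenset[str]:
        return self.up[contrast] | self.down[contrast]


def filter_deregulated(
    table: pd.DataFrame, threshold: float = 0.05
) -> DGEFilterResult:
    """Split a DE table into significantly up/down gene sets per contrast.

    Significance is ``p_adj < threshold``; direction is the sign of
    ``log2fc``.  With exactly two contrasts the shared deregulated genes
    and each contrast's unique genes are reported as well.
    """
    required = {"gene", "log2fc", "p_adj"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = table.copy()
    if "contrast" not in df.columns:
        df["contrast"] = "all"
    if df.duplicated(["gene", "contrast"]).any():
        raise ValueError("duplicate (gene, contrast) rows")

    up: dict[str, frozenset[str]] = {}
    down: dict[str, frozenset[str]] = {}
    zero: dict[str, int] = {}
    for contrast, sub in df.groupby("contrast", sort=False):
        sig = sub[sub["p_adj"] < threshold]
        up[contrast] = frozenset(sig.loc[sig["log2fc"] > 0, "gene"])
        down[contrast] = frozenset(sig.loc[sig["log2fc"] < 0, "gene"])
        zero[contrast] = int((sig["log2fc"] == 0).sum())

    shared = None
    unique: dict[str, frozenset[str]] = {}
    contrasts = list(up)
    if len(contrasts) == 2:
        c1, c2 = contrasts
        d1, d2 = up[c1] | down[c1], up[c2] | down[c2]
        shared = frozenset(d1 & d2)
        unique = {c1: frozenset(d1 - d2), c2: frozenset(d2 - d1)}
    return DGEFilterResult(
        threshold=threshold, up=up, down=down, n_zero_fc=zero,
        shared=shared, unique=unique,
    )
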