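"""Test-retest and group-comparison statistics.

Per-subject test-retest variability (TRV, aTRV), intra-animal COV,
Bland-Altman agreement on percent differences, absolute-agreement ICC
with genotype as a fixed effect, Pearson correlation, pooled-variance
t-test, Cohen's d from group summaries, and percent group difference.

TRV is signed: 100*(retest - test)/mean(test, retest); aTRV is its
magnitude. Bland-Altman is computed on these percent differences (not raw
units) so bias and limits of agreement are percentages.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "trv",
    "atrv",
    "cov_group",
    "inter_subject_cov",
    "bland_altman",
    "icc_absolute_agreement",
    "pearson_r2",
    "unpaired_t",
    "cohen_d",
    "percent_group_diff",
    "repro_report",
]


def trv(test: float, retest: float) -> float:
    """Signed test-retest variability in percent of the pair mean."""
    m = (test + retest) / 2.0
    if m <= 0:
        raise ValueError(f"non-positive pair mean {m}")
    return 100.0 * (retest - test) / m


def atrv(test: float, retest: float) -> float:
    """Absolute test-retest variability, |TRV|."""
    return abs(trv(test, retest))


def cov_group(pairs) -> float:
    """Mean intra-animal coefficient of variation (percent) over subjects.

    For two sessions the per-subject sample SD equals |diff|/sqrt(2).
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 1:
        raise ValueError("pairs must be an (n, 2) array of (test, retest)")
    means = pairs.mean(axis=1)
    if np.any(means == 0):
        raise ValueError("a subject has zero mean value")
    sds = pairs.std(axis=1, ddof=1)
    return float(np.mean(sds / means) * 100.0)


def inter_subject_cov(mean: float, sd: float) -> float:
    """Between-subject COV in percent, 100*SD/mean."""
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    return 100.0 * sd / mean


def bland_altman(pairs) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement of percent test-retest differences.

    Returns ``(bias, lower, upper)`` with limits at bias +/- 1.96*SD of the
    per-subject TRV values.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 2:
        raise ValueError("need >= 2 (test, retest) pairs")
    diffs = np.array([trv(t, r) for t, r in pairs])
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def icc_absolute_agreement(table: pd.DataFrame) -> float:
    """Single-measurement absolute-agreement ICC of test-retest values.

    ``table`` is long-format with columns subject_id, genotype, session,
    value (both sessions per subject). The genotype group means are removed
    first (genotype as fixed effect), then the two-way absolute-agreement
    ICC (ICC2 in the Shrout-Fleiss taxonomy) is computed on the residual
    values, estimating sigma2_subject/(sigma2_subject + sigma2_error).
    """
    import pingouin as pg

    required = {"subject_id", "session", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    df = table.copy()
    counts = df.groupby("subject_id")["session"].nunique()
    if (counts < 2).any():
        missing = counts[counts < 2].index.tolist()
        raise ValueError(f"subjects missing a session: {missing}")
    if df["subject_id"].nunique() < 3:
        raise ValueError("need >= 3 subjects for ICC")
    if np.ptp(df["value"].to_numpy()) == 0:
        raise ValueError("all values identical: ICC undefined")
    if "genotype" in df.columns:
        df["value"] = df["value"] - df.groupby("genotype")["value"].transform("mean")
    import warnings

    with warnings.catch_warnings():
        # perfect agreement makes pingouin's internal F-ratio divide by zero
        warnings.simplefilter("ignore", RuntimeWarning)
        res = pg.intraclass_corr(
            data=df, targets="subject_id", raters="session", ratings="value"
        )
    row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])]
    return float(row["ICC"].iloc[0])


def pearson_r2(x, y) -> tuple[float, float]:
    """Squared Pearson correlation and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r * r), float(p)


def unpaired_t(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sided unpaired t-test (pooled variance; Welch behind a flag)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def cohen_d(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """Effect size d = (mean_a - mean_b)/sqrt((sd_a^2 + sd_b^2)/2)."""
    if sd_a < 0 or sd_b < 0 or (sd_a == 0 and sd_b == 0):
        raise ValueError("need at least one positive SD")
    return (mean_a - mean_b) / math.sqrt((sd_a**2 + sd_b**2) / 2.0)


def percent_group_diff(mean_a: float, mean_b: float) -> float:
    """Percent difference of group means relative to group A, 100*(a-b)/a."""
    if mean_a <= 0:
        raise ValueError("reference group mean must be positive")
    return 100.0 * (mean_a - mean_b) / mean_a


def repro_report(table: pd.DataFrame) -> dict:
    """Full test-retest summary from a long-format cohort table.

    Per genotype: mean signed TRV with SEM, mean aTRV, intra-animal COV;
    combined: Bland-Altman bias and limits of agreement, ICC, Pearson r^2
    of test vs retest. Returns a plain dict (JSON-serializable).
    """
    wide = table.pivot_table(
        index=["subject_id", "genotype"], columns="session", values="value"
    ).reset_index()
    if not {"test", "retest"}.issubset(wide.columns):
        raise ValueError("table needs both 'test' and 'retest' sessions")
    wide = wide.dropna(subset=["test", "retest"])
    wide["trv"] = [trv(t, r) for t, r in zip(wide["test"], wide["retest"])]
    wide["atrv"] = wide["trv"].abs()

    per_genotype = {}
    for g, sub in wide.groupby("genotype"):
        n = len(sub)
        per_genotype[g] = {
            "n": n,
            "test_mean": float(sub["test"].mean()),
            "test_sem": float(sub["test"].std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan,
            "retest_mean": float(sub["retest"].mean()),
            "retest_sem": float(sub["retest"].std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan,
            "trv_mean": float(sub["trv"].mean()),
            "trv_sem": float(sub["trv"].std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan,
            "atrv_mean": float(sub["atrv"].mean()),
            "cov_pct": cov_group(sub[["test", "retest"]].to_numpy()),
        }
    bias, lo, hi = bland_altman(wide[["test", "retest"]].to_numpy())
    r2, p = pearson_r2(wide["test"], wide["retest"])
    return {
        "per_genotype": per_genotype,
        "combined": {
            "n": int(len(wide)),
            "bias_pct": bias,
            "loa_lower_pct": lo,
            "loa_upper_pct": hi,
            "icc": icc_absolute_agreement(table),
            "r2": r2,
            "r2_p": p,
        },
    }
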