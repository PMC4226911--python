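"""Per-treatment effect estimation and significance testing for the screen.

Each treatment's corrected DLK1 amounts are compared against a reference
group — either the pooled negative-control measures (NC1 + NC2) or all
other non-siRNA measures ("global") — with a two-sided Welch t-test, a
Bonferroni-corrected significance flag, and a 95% interval for the fold
effect. A one-way fixed-effects ANOVA quantifies the overall miRNA effect
across treatments (controls excluded).

The point estimate ``ratio`` is the ratio of arithmetic means (how screen
folds are conventionally reported); the confidence interval is computed on
the log scale (ratio of geometric means), which under a multiplicative
error model brackets the true planted fold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

NC_TREATMENTS = ("NC1", "NC2")
SIRNA = "siRNA"
CONTROLS = frozenset(NC_TREATMENTS) | {SIRNA}
REFERENCES = ("nc_mean", "global_mean")

EFFECT_COLUMNS = [
    "treatment", "n_measures", "mean_corrected", "ratio", "ci_low", "ci_high",
    "p_value", "significant", "testable", "fold_text", "reference",
]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return alpha / m


def fold_text(ratio: float) -> str:
    """Render a mean ratio the way screen effects are reported.

    Ratios below 1 are phrased as a k-fold reduction with k = 1 / ratio.
    """
    if ratio <= 0:
        raise ValueError(f"ratio must be > 0, got {ratio}")
    if math.isclose(ratio, 1.0):
        return "no change"
    if ratio < 1:
        return f"{1 / ratio:.2f}-fold reduction"
    return f"{ratio:.2f}-fold increase"


def welch_p_value(x: np.ndarray, y: np.ndarray, pooled_var: bool = False) -> float:
    """Two-sided two-sample t-test p-value with degenerate-variance conventions.

    Both groups constant: p = 1 when the means agree (no evidence), p = 0
    when they differ (an exact separation). Both conventions are logged.
    """
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 and vy == 0:
        equal = math.isclose(float(np.mean(x)), float(np.mean(y)), rel_tol=1e-12)
        logger.info("zero variance in both groups: p set to %s by convention", 1.0 if equal else 0.0)
        return 1.0 if equal else 0.0
    res = stats.ttest_ind(x, y, equal_var=pooled_var)
    return float(res.pvalue)


def log_ratio_interval(
    x: np.ndarray, y: np.ndarray, confidence: float = 0.95
) -> tuple[float, float]:
    """Welch interval for the ratio of geometric means of x over y."""
    lx, ly = np.log(x), np.log(y)
    diff = float(lx.mean() - ly.mean())
    nx, ny = len(lx), len(ly)
    vx, vy = np.var(lx, ddof=1) if nx > 1 else 0.0, np.var(ly, ddof=1) if ny > 1 else 0.0
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return math.exp(diff), math.exp(diff)
    df = se2**2 / (
        (vx / nx) ** 2 / max(nx - 1, 1) + (vy / ny) ** 2 / max(ny - 1, 1)
    )
    half = stats.t.ppf(0.5 + confidence / 2, df) * math.sqrt(se2)
    return math.exp(diff - half), math.exp(diff + half)


def _require_corrected(corrected: pd.DataFrame) -> None:
    for col in ("treatment", "corrected"):
        if col not in corrected.columns:
            raise ValueError(f"corrected table missing column {col!r}")
    if (corrected["corrected"] <= 0).any():
        raise ValueError("corrected amounts must be positive")


def _maybe_average_transfections(corrected: pd.DataFrame, average: bool) -> pd.DataFrame:
    if not average:
        return corrected
    keys = ["treatment", "transfection_id"]
    return corrected.groupby(keys, as_index=False)["corrected"].mean()


def _estimate_one(
    name: str,
    values: np.ndarray,
    reference_values: np.ndarray,
    reference_mean: float,
    threshold: float,
    reference: str,
    pooled_var: bool,
) -> dict:
    n = len(values)
    row = {
        "treatment": name,
        "n_measures": n,
        "mean_corrected": float(np.mean(values)) if n else float("nan"),
        "reference": reference,
    }
    if n < 2:
        logger.warning("treatment %r has %d measure(s): flagged untestable", name, n)
        row.update(
            ratio=float(np.mean(values) / reference_mean) if n else float("nan"),
            ci_low=float("nan"), ci_high=float("nan"), p_value=float("nan"),
            significant=False, testable=False,
            fold_text="untestable",
        )
        return row
    ratio = float(np.mean(values) / reference_mean)
    lo, hi = log_ratio_interval(values, reference_values)
    p = welch_p_value(values, reference_values, pooled_var=pooled_var)
    row.update(
        ratio=ratio, ci_low=lo, ci_high=hi, p_value=p,
        significant=bool(p <= threshold), testable=True, fold_text=fold_text(ratio),
    )
    return row


def effect_vs_reference(
    corrected: pd.DataFrame,
    reference: str = "nc_mean",
    alpha: float = 0.05,
    m_tests: int | None = None,
    *,
    pooled_var: bool = False,
    nc_mean_of_means: bool = False,
    average_transfections: bool = False,
) -> pd.DataFrame:
    """Estimate each treatment's fold effect against a reference group.

    reference="nc_mean": tested treatments are everything except NC1/NC2;
    the reference measures are the pooled NC1 + NC2 corrected amounts
    (``nc_mean_of_means=True`` instead uses the mean of the two NC group
    means as the ratio denominator, testing still against pooled measures).

    reference="global_mean": tested treatments are everything except the
    siRNA; each treatment is compared against all other non-siRNA measures
    (leaving the treatment itself out of its own reference).

    ``m_tests`` defaults to the number of non-control treatments present,
    the screen's multiple-testing burden.
    """
    if reference not in REFERENCES:
        raise ValueError(f"reference must be one of {REFERENCES}, got {reference!r}")
    _require_corrected(corrected)
    df = _maybe_average_transfections(corrected, average_transfections)
    treatments = pd.unique(df["treatment"])
    n_candidates = sum(1 for t in treatments if t not in CONTROLS)
    if m_tests is None:
        m_tests = max(n_candidates, 1)
    threshold = bonferroni_threshold(alpha, m_tests)

    by_treatment = {t: g["corrected"].to_numpy(float) for t, g in df.groupby("treatment")}
    rows = []
    if reference == "nc_mean":
        nc_values = np.concatenate(
            [by_treatment.get(t, np.empty(0)) for t in NC_TREATMENTS]
        )
        if nc_values.size == 0:
            raise ValueError("no negative-control measures present")
        if nc_mean_of_means:
            nc_means = [by_treatment[t].mean() for t in NC_TREATMENTS if t in by_treatment]
            ref_mean = float(np.mean(nc_means))
        else:
            ref_mean = float(nc_values.mean())
        for t in treatments:
            if t in NC_TREATMENTS:
                continue
            rows.append(
                _estimate_one(t, by_treatment[t], nc_values, ref_mean, threshold,
                              reference, pooled_var)
            )
    else:
        non_sirna = df.loc[df["treatment"] != SIRNA]
        for t in treatments:
            if t == SIRNA:
                continue
            others = non_sirna.loc[non_sirna["treatment"] != t, "corrected"].to_numpy(float)
            if others.size == 0:
                raise ValueError("global reference is empty")
            rows.append(
                _estimate_one(t, by_treatment[t], others, float(others.mean()),
                              threshold, reference, pooled_var)
            )
    out = pd.DataFrame(rows, columns=EFFECT_COLUMNS)
    out.attrs["alpha"] = alpha
    out.attrs["m_tests"] = m_tests
    out.attrs["threshold"] = threshold
    return out


def grouped_effect(
    corrected: pd.DataFrame,
    treatment_set: Iterable[str],
    reference: str = "nc_mean",
    alpha: float = 0.05,
    m_tests: int | None = None,
    **kwargs,
) -> pd.Series:
    """Pool the measures of several treatments and score them as one group.

    Mirrors testing a mixture of miRNAs jointly (e.g. the closely related
    miR-329a-3p / miR-329b-3p pair, or a seven-miRNA mix).
    """
    names = sorted(set(treatment_set))
    if not names:
        raise ValueError("treatment_set is empty")
    present = set(corrected["treatment"])
    unknown = [t for t in names if t not in present]
    if unknown:
        raise ValueError(f"unknown treatment(s): {unknown}")
    joint = "+".join(names)
    pooled = corrected.copy()
    pooled.loc[pooled["treatment"].isin(names), "treatment"] = joint
    keep = pooled["treatment"].isin({joint} | CONTROLS | (present - set(names)))
    table = effect_vs_reference(
        pooled.loc[keep], reference=reference, alpha=alpha, m_tests=m_tests, **kwargs
    )
    return table.loc[table["treatment"] == joint].iloc[0]


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


def anova_mirna_effect(corrected: pd.DataFrame, min_measures: int = 2) -> AnovaResult:
    """One-way fixed-effects ANOVA of corrected amounts across miRNA treatments.

    NC1, NC2 and the siRNA are excluded; groups with fewer than
    ``min_measures`` measures are dropped with a warning.
    """
    _require_corrected(corrected)
    df = corrected.loc[~corrected["treatment"].isin(CONTROLS)]
    groups, dropped = [], []
    for name, g in df.groupby("treatment"):
        vals = g["corrected"].to_numpy(float)
        (groups if len(vals) >= min_measures else dropped).append(
            vals if len(vals) >= min_measures else name
        )
    if dropped:
        logger.warning("ANOVA: excluded %d group(s) with <%d measures: %s",
                       len(dropped), min_measures, dropped)
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 usable treatment groups")
    f, p = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    return AnovaResult(
        f_statistic=float(f), df_between=k - 1, df_within=n - k, p_value=float(p)
    )
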