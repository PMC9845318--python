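"""Group comparison of gap distances and glottal-area-waveform summaries.

Distances from repeated frames of one recording are not independent, so the
two groups (rear glottal gap vs normal closure) are compared with a linear
mixed-effects model fitted by REML: group as the fixed effect and a random
intercept per subject.  Group means are reported as least-squares means
with Wald 95% confidence intervals; the p-value for the group difference
uses a t reference distribution with N - 2 between-subject denominator
degrees of freedom (the containment choice for a between-subject contrast
in a two-level design).  On balanced data the LS mean of a group equals
the arithmetic mean of its subject means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

log = logging.getLogger(__name__)


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GroupComparisonResult:
    """Least-squares means and the group contrast at one fraction line."""

    fraction: float
    N_normal: int
    N_gap: int
    n_normal: int
    n_gap: int
    lsmean_normal: float
    lsmean_gap: float
    se_normal: float
    se_gap: float
    diff: float
    diff_se: float
    ci95_low: float
    ci95_high: float
    p_value: float
    degenerate: bool = False


def _prepare(table: pd.DataFrame, fraction: float) -> pd.DataFrame:
    sub = table[np.isclose(table["fraction"], fraction)].copy()
    n_flagged = int(sub["flagged"].sum()) if len(sub) else 0
    if n_flagged:
        log.info(
            "excluding %d flagged observations at fraction %.2f", n_flagged, fraction
        )
    sub = sub[~sub["flagged"].astype(bool) & np.isfinite(sub["distance_px"])]
    if sub.empty:
        raise StatsError(f"no usable observations at fraction {fraction}")
    for grp in ("normal", "gap"):
        n_subj = sub.loc[sub["group"] == grp, "subject_id"].nunique()
        if n_subj < 2:
            raise StatsError(
                f"group {grp!r} has {n_subj} subjects with data; need at least 2"
            )
    return sub


def _subject_means_estimate(
    y: np.ndarray, is_gap: np.ndarray, subjects: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample analysis on subject means (pooled between-subject variance).

    Returns (beta, cov) in the same parametrization as the mixed model:
    beta = (normal mean, gap - normal difference).
    """
    df = pd.DataFrame({"y": y, "gap": is_gap, "subject": subjects})
    means = df.groupby("subject").agg(y=("y", "mean"), gap=("gap", "first"))
    m0 = means.loc[means["gap"] == 0, "y"].to_numpy()
    m1 = means.loc[means["gap"] == 1, "y"].to_numpy()
    dof = len(m0) + len(m1) - 2
    ss = float(np.sum((m0 - m0.mean()) ** 2) + np.sum((m1 - m1.mean()) ** 2))
    pooled = ss / dof if dof > 0 else 0.0
    v0, v1 = pooled / len(m0), pooled / len(m1)
    beta = np.array([m0.mean(), m1.mean() - m0.mean()])
    cov = np.array([[v0, -v0], [-v0, v0 + v1]])
    return beta, cov


def fit_group_comparison(table: pd.DataFrame, fraction: float) -> GroupComparisonResult:
    """REML mixed-model comparison of gap vs normal at one fraction line.

    ``table`` is a measurement table as produced by
    :func:`glottalgap.geometry.measure_sequence` (rows from several
    subjects concatenated).  Flagged observations are excluded listwise.
    A degenerate table (zero residual and zero between-subject variance)
    is reported with ``degenerate=True`` rather than raising.
    """
    sub = _prepare(table, fraction)
    y = sub["distance_px"].to_numpy(dtype=float)
    is_gap = (sub["group"] == "gap").to_numpy().astype(float)
    subjects = sub["subject_id"].to_numpy()
    N_normal = sub.loc[sub["group"] == "normal", "subject_id"].nunique()
    N_gap = sub.loc[sub["group"] == "gap", "subject_id"].nunique()
    n_normal = int((is_gap == 0).sum())
    n_gap = int((is_gap == 1).sum())
    dof = N_normal + N_gap - 2

    X = np.column_stack([np.ones_like(y), is_gap])
    if np.ptp(y) == 0.0:
        # constant response: variances are zero, nothing to estimate
        c = float(y[0])
        return GroupComparisonResult(
            fraction=fraction,
            N_normal=N_normal,
            N_gap=N_gap,
            n_normal=n_normal,
            n_gap=n_gap,
            lsmean_normal=c,
            lsmean_gap=c,
            se_normal=0.0,
            se_gap=0.0,
            diff=0.0,
            diff_se=0.0,
            ci95_low=0.0,
            ci95_high=0.0,
            p_value=1.0,
            degenerate=True,
        )

    with warnings.catch_warnings():
        # variance components at the boundary (sigma_subject -> 0) trigger
        # optimizer chatter; the NaN check below handles the fallout
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = MixedLM(y, X, groups=subjects)
        try:
            fit = model.fit(reml=True)
            # the convergence flag is unreliable at variance boundaries;
            # judge the fit by its estimates instead
            beta = np.asarray(fit.fe_params, dtype=float)
            cov = np.asarray(fit.cov_params())[:2, :2]
        except Exception:
            beta = cov = np.array([np.nan])
    if not (
        np.all(np.isfinite(beta))
        and np.all(np.isfinite(cov))
        and np.all(np.diag(cov) > 0)
    ):
        # REML put the between-subject variance on the boundary and the
        # Hessian degenerated; fall back to the subject-means analysis,
        # which coincides with the mixed-model GLS solution on balanced
        # data for every value of the variance ratio.
        log.info(
            "mixed-model fit degenerate at fraction %.2f; "
            "using subject-means analysis",
            fraction,
        )
        beta, cov = _subject_means_estimate(y, is_gap, subjects)

    lsmean_normal = float(beta[0])
    lsmean_gap = float(beta[0] + beta[1])
    se_normal = float(np.sqrt(cov[0, 0]))
    se_gap = float(np.sqrt(cov[0, 0] + cov[1, 1] + 2.0 * cov[0, 1]))
    diff = float(beta[1])
    diff_se = float(np.sqrt(cov[1, 1]))
    if diff_se > 0:
        tstat = diff / diff_se
        p = float(2.0 * sps.t.sf(abs(tstat), dof))
        tq = float(sps.t.ppf(0.975, dof))
        lo, hi = diff - tq * diff_se, diff + tq * diff_se
        degenerate = False
    else:
        p, lo, hi, degenerate = 1.0, diff, diff, True
    return GroupComparisonResult(
        fraction=fraction,
        N_normal=N_normal,
        N_gap=N_gap,
        n_normal=n_normal,
        n_gap=n_gap,
        lsmean_normal=lsmean_normal,
        lsmean_gap=lsmean_gap,
        se_normal=se_normal,
        se_gap=se_gap,
        diff=diff,
        diff_se=diff_se,
        ci95_low=float(lo),
        ci95_high=float(hi),
        p_value=p,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class WaveformSummary:
    """Per-subject extremes of the relative glottal area and cohort summaries."""

    per_subject: pd.DataFrame  # columns subject_id, group, highest, lowest
    mean_highest: float
    mean_lowest: float
    overall_max: float
    overall_min: float


def summarize_waveforms(table: pd.DataFrame) -> WaveformSummary:
    """Highest/lowest relative glottal area per subject plus cohort means.

    The relative area is a per-frame quantity repeated across fraction
    rows, so duplicates are collapsed before aggregation.
    """
    sub = table[np.isfinite(table["relative_glottal_area"])]
    if sub.empty:
        raise StatsError("empty measurement table")
    frames = sub.drop_duplicates(subset=["subject_id", "frame_index"])
    per = (
        frames.groupby(["subject_id", "group"], as_index=False)["relative_glottal_area"]
        .agg(highest="max", lowest="min")
        .rename(columns=str)
    )
    return WaveformSummary(
        per_subject=per,
        mean_highest=float(per["highest"].mean()),
        mean_lowest=float(per["lowest"].mean()),
        overall_max=float(per["highest"].max()),
        overall_min=float(per["lowest"].min()),
    )


def comparison_report(results: list[GroupComparisonResult]) -> str:
    """Markdown table of LS means, group differences, CIs and p-values."""
    lines = [
        "| Line | Group | N | n | LS mean | SE | 95% CI | p |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for r in results:
        pct = f"{100 * r.fraction:g}%"
        lines.append(
            f"| {pct} | normal | {r.N_normal} | {r.n_normal} | "
            f"{r.lsmean_normal:.2f} | {r.se_normal:.2f} |  |  |"
        )
        lines.append(
            f"| {pct} | gap | {r.N_gap} | {r.n_gap} | "
            f"{r.lsmean_gap:.2f} | {r.se_gap:.2f} |  |  |"
        )
        p_str = "<0.0001" if r.p_value < 1e-4 else f"{r.p_value:.2g}"
        lines.append(
            f"| {pct} | diff (gap-normal) |  |  | {r.diff:.2f} | {r.diff_se:.2f} | "
            f"({r.ci95_low:.2f}, {r.ci95_high:.2f}) | {p_str} |"
        )
    return "\n".join(lines)
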