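"""Longitudinal cohort statistics for perfusion and opacity tables.

Per metric and plexus, the change across the four visits (baseline and
three postoperative follow-ups) is tested with a one-way
repeated-measures ANOVA: the within-subject decomposition removes the
subject main effect, F = MS_time / MS_error with (k-1) and (n-1)(k-1)
degrees of freedom. Sphericity of the within-subject covariance is
assessed with Mauchly's W on the orthonormal-contrast covariance; when
rejected, the Greenhouse-Geisser epsilon rescales both degrees of
freedom before the p-value is taken from the F distribution. Shapiro-
Wilk normality is reported as a diagnostic only.

The correlation screen relates each metric's change (configurable delta,
default final follow-up minus baseline) to the preoperative predictors
(whole-lens and nuclear opacity, CDE, IOP change, phaco time, fluid
volume) via Pearson's r with a two-sided t-test p-value. Raw p-values
carry the significance flag, matching the study-style table; a
Holm-adjusted column is emitted alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import METRICS, PLEXUSES, TIMEPOINTS, metric_column


class StatsInputError(ValueError):
    """Design matrix violates a precondition (missing cells, too few rows)."""


PREDICTORS = ("lens_opacity", "nuclear_opacity", "cde", "iop_change", "phaco_time", "fluid")


@dataclass
class SphericityResult:
    """Mauchly's test of sphericity on the contrast covariance."""

    w_stat: float
    chi2_stat: float
    df: int
    p_value: float
    applicable: bool = True

    def __post_init__(self) -> None:
        if self.applicable and not 0.0 < self.w_stat <= 1.0 + 1e-12:
            raise ValueError("Mauchly's W must lie in (0, 1]")


@dataclass
class RMAnovaResult:
    """One-way within-subject ANOVA with optional Greenhouse-Geisser correction."""

    f_stat: float
    df_num: float
    df_den: float
    p_value: float
    epsilon: float
    sphericity: SphericityResult
    sphericity_ok: bool
    correction_applied: bool
    ss_time: float = float("nan")
    ss_error: float = float("nan")
    ss_subject: float = float("nan")

    def __post_init__(self) -> None:
        if self.f_stat < 0:
            raise ValueError("F statistic cannot be negative")
        if self.correction_applied and self.sphericity_ok:
            raise ValueError("correction implies sphericity was rejected")


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("Pearson r must lie in [-1, 1]")
        if self.n < 3:
            raise ValueError("Pearson correlation needs at least 3 pairs")


def _as_matrix(data: np.ndarray | pd.DataFrame) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise StatsInputError("expected a subjects x timepoints matrix")
    if np.isnan(arr).any():
        raise StatsInputError("missing cells are not allowed (complete-case design)")
    n, k = arr.shape
    if n < 2 or k < 2:
        raise StatsInputError("need at least 2 subjects and 2 timepoints")
    return arr


def _contrast_matrix(k: int) -> np.ndarray:
    """Orthonormal contrasts spanning the within-subject space (k-1 x k)."""
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, : i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1.0)
        helmert[i] /= np.linalg.norm(helmert[i])
    return helmert


def mauchly_test(data: np.ndarray | pd.DataFrame) -> SphericityResult:
    """Mauchly's W with the standard chi-square approximation.

    W is the ratio of the geometric to arithmetic mean (to the power
    k-1) of the eigenvalues of the orthonormal-contrast covariance. For
    k = 2 sphericity holds trivially and the result is flagged as not
    applicable.
    """
    arr = _as_matrix(data)
    n, k = arr.shape
    if k == 2:
        return SphericityResult(w_stat=1.0, chi2_stat=0.0, df=0, p_value=1.0, applicable=False)
    if n <= k - 1:
        raise StatsInputError("Mauchly's test needs more subjects than contrasts")
    c = _contrast_matrix(k)
    s = np.cov(arr, rowvar=False, ddof=1)
    t = c @ s @ c.T
    eig = np.linalg.eigvalsh(t)
    if (eig <= 0).any():
        raise StatsInputError("contrast covariance is singular")
    p = k - 1
    w = float(np.prod(eig) / (eig.mean() ** p))
    d = 1.0 - (2.0 * p**2 + p + 2.0) / (6.0 * p * (n - 1.0))
    chi2 = -(n - 1.0) * d * np.log(w)
    df = p * (p + 1) // 2 - 1
    p_value = float(stats.chi2.sf(chi2, df))
    return SphericityResult(w_stat=w, chi2_stat=float(chi2), df=df, p_value=p_value)


def gg_epsilon(data: np.ndarray | pd.DataFrame) -> float:
    """Greenhouse-Geisser epsilon from the contrast covariance eigenvalues,
    clamped to [1/(k-1), 1]."""
    arr = _as_matrix(data)
    n, k = arr.shape
    if k < 3:
        return 1.0
    c = _contrast_matrix(k)
    s = np.cov(arr, rowvar=False, ddof=1)
    t = c @ s @ c.T
    eig = np.linalg.eigvalsh(t)
    if (eig <= 1e-300).all():
        raise StatsInputError("degenerate contrast covariance")
    eps = float(eig.sum() ** 2 / ((k - 1) * (eig**2).sum()))
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova(data: np.ndarray | pd.DataFrame, alpha: float = 0.05) -> RMAnovaResult:
    """One-way repeated-measures ANOVA across timepoints.

    Sum-of-squares decomposition: SS_time over column means, SS_subject
    over row means, SS_error as the subject x time interaction. When
    Mauchly's test rejects sphericity at ``alpha`` (k >= 3), both
    degrees of freedom are scaled by the Greenhouse-Geisser epsilon.
    A design with no within-subject variation returns F = 0, p = 1.
    """
    arr = _as_matrix(data)
    n, k = arr.shape
    grand = arr.mean()
    col_means = arr.mean(axis=0)
    row_means = arr.mean(axis=1)
    ss_time = n * float(((col_means - grand) ** 2).sum())
    ss_subject = k * float(((row_means - grand) ** 2).sum())
    ss_total = float(((arr - grand) ** 2).sum())
    ss_error = ss_total - ss_time - ss_subject
    df_num = float(k - 1)
    df_den = float((n - 1) * (k - 1))
    ms_time = ss_time / df_num
    ms_error = ss_error / df_den

    try:
        sph = mauchly_test(arr) if k >= 3 else SphericityResult(1.0, 0.0, 0, 1.0, applicable=False)
        eps = gg_epsilon(arr) if k >= 3 else 1.0
    except StatsInputError:
        # singular contrast covariance (e.g. no within-subject variation):
        # sphericity is moot, no correction
        sph = SphericityResult(1.0, 0.0, 0, 1.0, applicable=False)
        eps = 1.0
    sphericity_ok = (not sph.applicable) or sph.p_value > alpha
    correction = not sphericity_ok

    if ms_error <= 0:
        # no interaction variance: degenerate but legal designs (all
        # subjects change identically) — F is 0 when there is no time
        # effect, infinite otherwise
        f = 0.0 if ss_time <= 1e-12 else float("inf")
        p = 1.0 if f == 0.0 else 0.0
    else:
        f = ms_time / ms_error
        d1, d2 = (df_num * eps, df_den * eps) if correction else (df_num, df_den)
        p = float(stats.f.sf(f, d1, d2))
    if ss_time <= 1e-12:
        f, p = 0.0, 1.0
    return RMAnovaResult(
        f_stat=float(f),
        df_num=df_num * eps if correction else df_num,
        df_den=df_den * eps if correction else df_den,
        p_value=float(p),
        epsilon=eps,
        sphericity=sph,
        sphericity_ok=sphericity_ok,
        correction_applied=correction,
        ss_time=ss_time,
        ss_error=ss_error,
        ss_subject=ss_subject,
    )


def shapiro_diagnostic(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk normality (W, p) — reported, never gating."""
    w, p = stats.shapiro(np.asarray(values, dtype=float))
    return float(w), float(p)


def pearson_corr(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsInputError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise StatsInputError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsInputError("correlation undefined for a constant variable")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=len(x))


# --------------------------------------------------------------------------
# cohort-table level operations
# --------------------------------------------------------------------------


def validate_cohort(frame: pd.DataFrame) -> pd.DataFrame:
    """Check the one-row-per-eye longitudinal schema."""
    if frame.index.has_duplicates:
        raise StatsInputError("cohort must have one row per eye")
    return frame


def timepoint_matrix(frame: pd.DataFrame, metric: str, plexus: str) -> np.ndarray:
    cols = [metric_column(metric, plexus, tp) for tp in TIMEPOINTS]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise StatsInputError(f"cohort lacks columns {missing}")
    return frame[cols].to_numpy(dtype=float)


def delta_metrics(frame: pd.DataFrame, from_tp: str = "T0", to_tp: str = "T3") -> pd.DataFrame:
    """Per-eye change table: value(to_tp) - value(from_tp) per metric and
    plexus, plus the IOP change, keyed by eye id."""
    for tp in (from_tp, to_tp):
        if tp not in TIMEPOINTS:
            raise StatsInputError(f"unknown timepoint label {tp!r}")
    out = {}
    for metric in METRICS:
        for plexus in PLEXUSES:
            a = metric_column(metric, plexus, from_tp)
            b = metric_column(metric, plexus, to_tp)
            if a in frame.columns and b in frame.columns:
                out[f"d_{metric}_{plexus}"] = frame[b] - frame[a]
    if f"iop_{from_tp}" in frame.columns and f"iop_{to_tp}" in frame.columns:
        out["iop_change"] = frame[f"iop_{to_tp}"] - frame[f"iop_{from_tp}"]
    return pd.DataFrame(out, index=frame.index)


def _holm(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def correlation_screen(
    frame: pd.DataFrame,
    from_tp: str = "T0",
    to_tp: str = "T3",
    predictors: tuple[str, ...] = PREDICTORS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson screen of metric changes against preoperative predictors.

    Returns a long-form table with one row per (metric, plexus,
    predictor): r, raw p, pairs used, significance flag at ``alpha`` on
    the raw p (study convention), and a Holm-adjusted p for reference.
    Cells with fewer than 3 complete pairs or a constant variable are
    marked unavailable (NaN r/p, flag False).
    """
    validate_cohort(frame)
    deltas = delta_metrics(frame, from_tp, to_tp)
    rows = []
    for col in deltas.columns:
        if col == "iop_change":
            continue
        _, metric, plexus = col.split("_")
        for pred in predictors:
            series = deltas["iop_change"] if pred == "iop_change" else frame.get(pred)
            if series is None:
                continue
            pair = pd.concat([deltas[col], series], axis=1).dropna()
            rec = {"metric": metric, "plexus": plexus, "predictor": pred, "n": len(pair)}
            try:
                res = pearson_corr(pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy())
                rec.update(r=res.r, p_value=res.p_value, n=res.n)
            except StatsInputError:
                rec.update(r=float("nan"), p_value=float("nan"))
            rows.append(rec)
    table = pd.DataFrame(rows)
    valid = table["p_value"].notna()
    adj = np.full(len(table), np.nan)
    if valid.any():
        adj[valid.to_numpy()] = _holm(table.loc[valid, "p_value"].to_numpy())
    table["p_holm"] = adj
    table["significant"] = table["p_value"] < alpha
    return table


def anova_table(frame: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Study-style longitudinal summary: per metric and plexus the
    mean +/- SD at each visit plus the RM-ANOVA F, p and epsilon."""
    validate_cohort(frame)
    rows = []
    for metric in METRICS:
        for plexus in PLEXUSES:
            cols = [metric_column(metric, plexus, tp) for tp in TIMEPOINTS]
            if any(c not in frame.columns for c in cols):
                continue
            sub = frame[cols].dropna()  # complete-case per metric and plexus
            if len(sub) < 2:
                continue
            mat = sub.to_numpy(dtype=float)
            res = rm_anova(mat, alpha=alpha)
            rec = {"metric": metric, "plexus": plexus, "n": len(sub)}
            for j, tp in enumerate(TIMEPOINTS):
                rec[f"mean_{tp}"] = float(mat[:, j].mean())
                rec[f"sd_{tp}"] = float(mat[:, j].std(ddof=1))
            rec.update(
                f_stat=res.f_stat,
                p_value=res.p_value,
                epsilon=res.epsilon,
                sphericity_ok=res.sphericity_ok,
                correction_applied=res.correction_applied,
                significant=res.p_value <= alpha,
            )
            rows.append(rec)
    return pd.DataFrame(rows)
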