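"""Survival statistics used throughout the scoring pipeline.

Kaplan–Meier, log-rank and Cox proportional hazards are delegated to
lifelines (Efron tie handling, Newton solver tightened to 1e-9 so small
analytically solvable instances reproduce to ~1e-10); Harrell's
concordance comes from scikit-survival. The IPCW time-dependent AUC,
paired-bootstrap AUC comparison, optimism-corrected Somers' Dxy,
calibration table and Youden cut-off are composed here.

Score orientation: every function taking a ``score`` treats larger values
as higher risk (earlier failure). Protective scores should be negated by
the caller before evaluation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from sksurv.metrics import concordance_index_censored

from .errors import (
    CollinearityError,
    DegenerateDataError,
    FitError,
    SeparationError,
)

log = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "CoxFit",
    "km_fit",
    "logrank_test",
    "cox_fit",
    "c_index",
    "dxy_optimism",
    "td_auc_ipcw",
    "compare_td_auc",
    "calibration_table",
    "youden_optimal_cutoff",
    "YoudenResult",
    "mann_whitney_u",
    "chisquare_independence",
    "spearman_corr",
]

_COX_FIT_OPTIONS = {"precision": 1e-9}


def _as_arrays(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.shape != e.shape:
        raise ValueError("time and event must have the same length")
    if (t <= 0).any():
        raise ValueError("all times must be positive")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return t, e


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank


@dataclass
class KMCurve:
    """Product-limit estimate at the distinct observed event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    _step: pd.Series = field(repr=False, default=None)

    def survival_at(self, t: float | np.ndarray) -> np.ndarray:
        """Right-continuous step-function value S(t)."""
        tq = np.atleast_1d(np.asarray(t, dtype=float))
        times = self._step.index.to_numpy(dtype=float)
        vals = self._step.to_numpy(dtype=float)
        idx = np.searchsorted(times, tq, side="right") - 1
        return np.where(idx < 0, 1.0, vals[np.clip(idx, 0, None)])


def km_fit(time, event) -> KMCurve:
    """Kaplan–Meier estimator of the survival function."""
    t, e = _as_arrays(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    tbl = kmf.event_table
    sf = kmf.survival_function_["KM_estimate"]
    ev = tbl[tbl["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = sf.loc[ev.index].to_numpy(dtype=float)
    at_risk = ev["at_risk"].to_numpy(dtype=float)
    step = sf.drop(index=[0.0], errors="ignore")
    return KMCurve(times=times, survival=surv, at_risk=at_risk, _step=step)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank (Mantel–Cox) test: (chi-square, p), 1 df."""
    t, e = _as_arrays(time, event)
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise DegenerateDataError(f"log-rank needs exactly 2 groups, got {levels.size}")
    m0, m1 = (g == levels[0]), (g == levels[1])
    if m0.sum() == 0 or m1.sum() == 0:
        raise DegenerateDataError("each group needs >= 1 subject")
    res = _ll_logrank(t[m0], t[m1], e[m0], e[m1])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    """Result of a Cox PH fit (Efron ties).

    ``summary`` has one row per covariate: coef, se, hr, ci_lo, ci_hi, p.
    """

    summary: pd.DataFrame
    loglik: float
    n: int
    n_events: int
    _fitter: CoxPHFitter = field(repr=False, default=None)

    @property
    def coef(self) -> pd.Series:
        return self.summary["coef"]

    @property
    def se(self) -> pd.Series:
        return self.summary["se"]

    @property
    def hr(self) -> pd.Series:
        return self.summary["hr"]

    @property
    def p(self) -> pd.Series:
        return self.summary["p"]

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        """X @ beta (covariates centered as fitted)."""
        X = pd.DataFrame(X).reset_index(drop=True)
        return self._fitter.predict_log_partial_hazard(X).to_numpy(dtype=float)

    def predicted_survival(self, X: pd.DataFrame, horizon: float) -> np.ndarray:
        """Per-subject model survival at ``horizon`` (Breslow baseline)."""
        X = pd.DataFrame(X).reset_index(drop=True)
        sf = self._fitter.predict_survival_function(X, times=[horizon])
        return sf.iloc[0].to_numpy(dtype=float)

    def to_dict(self) -> dict:
        return {
            "covariates": {
                name: {
                    "coef": float(r["coef"]),
                    "se": float(r["se"]),
                    "hr": float(r["hr"]),
                    "ci95": [float(r["ci_lo"]), float(r["ci_hi"])],
                    "p": float(r["p"]),
                }
                for name, r in self.summary.iterrows()
            },
            "loglik": self.loglik,
            "n": self.n,
            "n_events": self.n_events,
        }


_SEPARATION_COEF = 10.0  # |log HR| beyond any plausible biological effect


def cox_fit(X: pd.DataFrame, time, event) -> CoxFit:
    """Cox proportional hazards via the Efron partial likelihood.

    Raises :class:`CollinearityError` for constant or exactly collinear
    columns, :class:`SeparationError` for monotone likelihood (naming the
    covariate), :class:`FitError` otherwise on failure.
    """
    t, e = _as_arrays(time, event)
    X = pd.DataFrame(X).reset_index(drop=True).astype(float)
    if e.sum() < 1:
        raise DegenerateDataError("Cox fit requires >= 1 event")
    xv = X.to_numpy(dtype=float)
    sds = xv.std(axis=0)
    if (sds == 0).any():
        bad = list(X.columns[sds == 0])
        raise CollinearityError(f"constant covariate column(s): {bad}")
    centered = xv - xv.mean(axis=0)
    if np.linalg.matrix_rank(centered) < X.shape[1]:
        raise CollinearityError(
            f"exactly collinear covariate columns among {list(X.columns)}"
        )
    df = X.copy()
    df["_time"] = t
    df["_event"] = e
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event",
                    fit_options=_COX_FIT_OPTIONS)
    except ConvergenceError as exc:
        msg = str(exc)
        if "separation" in msg.lower() or "delta contains nan" in msg.lower():
            raise SeparationError(f"monotone partial likelihood: {msg}") from exc
        raise FitError(msg) from exc
    coef = cph.params_
    se = cph.standard_errors_
    big = coef.index[np.abs(coef.to_numpy()) > _SEPARATION_COEF]
    if len(big):
        raise SeparationError(
            f"perfect separation suspected for covariate(s) {list(big)}: "
            f"|log HR| > {_SEPARATION_COEF}"
        )
    summary = pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "hr": np.exp(coef),
            "ci_lo": np.exp(coef - 1.96 * se),
            "ci_hi": np.exp(coef + 1.96 * se),
            "p": 2 * stats.norm.sf(np.abs(coef / se)),
        }
    )
    return CoxFit(
        summary=summary,
        loglik=float(cph.log_likelihood_),
        n=int(len(df)),
        n_events=int(e.sum()),
        _fitter=cph,
    )


# ---------------------------------------------------------------------------
# Concordance and Dxy


def c_index(score, time, event) -> float:
    """Harrell's concordance: larger score = higher risk; ties count 1/2."""
    t, e = _as_arrays(time, event)
    s = np.asarray(score, dtype=float)
    try:
        ci, n_conc, n_disc, n_tied, _ = concordance_index_censored(
            e.astype(bool), t, s
        )
    except ValueError as exc:  # pragma: no cover - message passthrough
        raise DegenerateDataError(str(exc)) from exc
    if n_conc + n_disc + n_tied == 0:
        raise DegenerateDataError("no comparable pairs for concordance")
    return float(ci)


def dxy_optimism(
    X: pd.DataFrame,
    time,
    event,
    B: int = 200,
    seed: int | None = None,
) -> tuple[float, float]:
    """Apparent and optimism-corrected Somers' Dxy of a Cox model.

    Dxy = 2C - 1. Optimism is the mean over ``B`` bootstrap refits of
    (Dxy on the bootstrap sample - Dxy of that fit evaluated on the
    original data); corrected = apparent - optimism. Resamples with zero
    events are redrawn (logged).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    t, e = _as_arrays(time, event)
    X = pd.DataFrame(X).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    full = cox_fit(X, t, e)
    lp = full.linear_predictor(X)
    apparent = 2 * c_index(lp, t, e) - 1
    n = len(t)
    optimisms = []
    attempts = 0
    while len(optimisms) < B:
        attempts += 1
        if attempts > 20 * B:
            raise FitError("too many failed bootstrap resamples")
        idx = rng.integers(0, n, n)
        if e[idx].sum() == 0:
            log.warning("bootstrap resample with zero events redrawn")
            continue
        try:
            bfit = cox_fit(X.iloc[idx], t[idx], e[idx])
        except (CollinearityError, SeparationError, FitError):
            log.warning("bootstrap refit failed; resample redrawn")
            continue
        lp_b = bfit.linear_predictor(X.iloc[idx])
        dxy_b = 2 * c_index(lp_b, t[idx], e[idx]) - 1
        lp_o = bfit.linear_predictor(X)
        dxy_o = 2 * c_index(lp_o, t, e) - 1
        optimisms.append(dxy_b - dxy_o)
    corrected = apparent - float(np.mean(optimisms))
    return float(apparent), float(corrected)


# ---------------------------------------------------------------------------
# IPCW time-dependent AUC


def _censoring_survival(t: np.ndarray, e: np.ndarray):
    """KM estimate of the censoring distribution G(u) = P(C > u).

    Returns (G_at, G_left): right-continuous evaluation and left limit.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(t, 1 - e)
    sf = kmf.survival_function_["KM_estimate"]
    times = sf.index.to_numpy(dtype=float)
    vals = sf.to_numpy(dtype=float)

    def g_at(u: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(times, np.atleast_1d(u), side="right") - 1
        return np.where(idx < 0, 1.0, vals[np.clip(idx, 0, None)])

    def g_left(u: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(times, np.atleast_1d(u), side="left") - 1
        return np.where(idx < 0, 1.0, vals[np.clip(idx, 0, None)])

    return g_at, g_left


def td_auc_ipcw(score, time, event, horizon: float) -> float:
    """Cumulative-case / dynamic-control AUC at ``horizon`` with IPCW.

    Cases are subjects with an observed event at or before the horizon,
    controls those event-free past it; weights come from the Kaplan–Meier
    estimator of the censoring distribution (case i: 1/G(T_i−); control:
    1/G(horizon)). Tied scores count 1/2. With no censoring this reduces
    exactly to the empirical Mann–Whitney AUC of cases vs controls.
    """
    t, e = _as_arrays(time, event)
    s = np.asarray(score, dtype=float)
    cases = (t <= horizon) & (e == 1)
    controls = t > horizon
    if cases.sum() == 0 or controls.sum() == 0:
        raise DegenerateDataError(
            f"horizon {horizon}: need >=1 case and >=1 control "
            f"(got {int(cases.sum())}, {int(controls.sum())})"
        )
    g_at, g_left = _censoring_survival(t, e)
    g_tau = float(g_at(np.array([horizon]))[0])
    g_cases = g_left(t[cases])
    if g_tau <= 0 or (g_cases <= 0).any():
        raise DegenerateDataError("censoring survival reaches 0 before horizon")
    w_case = 1.0 / g_cases
    w_ctrl = np.full(int(controls.sum()), 1.0 / g_tau)
    sc, sk = s[cases], s[controls]
    gt = (sc[:, None] > sk[None, :]).astype(float)
    gt += 0.5 * (sc[:, None] == sk[None, :])
    num = float(w_case @ gt @ w_ctrl)
    den = float(w_case.sum() * w_ctrl.sum())
    return num / den


def compare_td_auc(
    score1, score2, time, event, horizon: float, B: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Paired-bootstrap comparison of two markers' IPCW AUCs at a horizon.

    Returns (AUC1 - AUC2, two-sided p) with p from the normal
    approximation of the bootstrap distribution of the difference. A zero
    bootstrap variance (e.g. identical markers) gives p = 1.
    """
    t, e = _as_arrays(time, event)
    s1 = np.asarray(score1, dtype=float)
    s2 = np.asarray(score2, dtype=float)
    if s1.shape != s2.shape or s1.shape != t.shape:
        raise ValueError("scores must be defined on the same samples")
    delta = td_auc_ipcw(s1, t, e, horizon) - td_auc_ipcw(s2, t, e, horizon)
    rng = np.random.default_rng(seed)
    n = len(t)
    deltas = []
    attempts = 0
    while len(deltas) < B:
        attempts += 1
        if attempts > 20 * B:
            raise FitError("too many degenerate bootstrap resamples")
        idx = rng.integers(0, n, n)
        try:
            d = td_auc_ipcw(s1[idx], t[idx], e[idx], horizon) - td_auc_ipcw(
                s2[idx], t[idx], e[idx], horizon
            )
        except DegenerateDataError:
            continue
        deltas.append(d)
    sd = float(np.std(deltas, ddof=1))
    if sd == 0:
        return float(delta), 1.0
    p = 2 * stats.norm.sf(abs(delta) / sd)
    return float(delta), float(p)


# ---------------------------------------------------------------------------
# Calibration


def calibration_table(
    X: pd.DataFrame,
    time,
    event,
    horizon: float,
    n_bins: int = 4,
) -> pd.DataFrame:
    """Predicted vs observed survival at a horizon, by risk bin.

    Subjects are binned by quantiles of the Cox linear predictor;
    predicted = mean model survival at the horizon per bin (Breslow
    baseline), observed = per-bin Kaplan–Meier at the horizon. Empty bins
    trigger a logged reduction of ``n_bins``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    t, e = _as_arrays(time, event)
    X = pd.DataFrame(X).reset_index(drop=True)
    fit = cox_fit(X, t, e)
    lp = fit.linear_predictor(X)
    pred = fit.predicted_survival(X, horizon)
    while n_bins >= 2:
        try:
            bins = pd.qcut(lp, n_bins, labels=False, duplicates="raise")
            break
        except ValueError:
            log.warning("empty calibration bin; reducing n_bins to %d", n_bins - 1)
            n_bins -= 1
    else:
        raise DegenerateDataError("cannot form >= 2 non-empty risk bins")
    rows = []
    for b in range(n_bins):
        m = bins == b
        km = km_fit(t[m], e[m])
        rows.append(
            {
                "bin": b,
                "n": int(m.sum()),
                "predicted": float(pred[m].mean()),
                "observed": float(km.survival_at(horizon)[0]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Youden cut-off and simple two-sample statistics


class YoudenResult(NamedTuple):
    cutoff: float
    j: float
    sensitivity: float
    specificity: float


def youden_optimal_cutoff(score, outcome) -> YoudenResult:
    """Cut-off maximizing Youden's J = sensitivity + specificity - 1.

    Larger scores are taken to predict ``outcome == 1``; a subject is
    called positive when score > cutoff. Candidates are midpoints between
    adjacent sorted unique scores; ties in J break toward the cutoff with
    higher sensitivity.
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if not np.isin(y, [0, 1]).all():
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise DegenerateDataError("both outcome classes must be present")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise DegenerateDataError("all scores identical")
    cands = (uniq[:-1] + uniq[1:]) / 2
    best: YoudenResult | None = None
    for c in cands:
        pos = s > c
        sens = float((pos & (y == 1)).sum() / (y == 1).sum())
        spec = float((~pos & (y == 0)).sum() / (y == 0).sum())
        j = sens + spec - 1
        if best is None or j > best.j + 1e-12 or (
            abs(j - best.j) <= 1e-12 and sens > best.sensitivity
        ):
            best = YoudenResult(float(c), j, sens, spec)
    return best


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann–Whitney U, normal approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DegenerateDataError("both groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def chisquare_independence(table) -> tuple[float, float]:
    """Pearson chi-square on a contingency table (no continuity correction)."""
    tbl = np.asarray(table, dtype=float)
    if tbl.sum() == 0 or (tbl.sum(axis=0) == 0).any() or (tbl.sum(axis=1) == 0).any():
        raise DegenerateDataError("contingency table has an empty margin")
    chi2, p, _, _ = stats.chi2_contingency(tbl, correction=False)
    return float(chi2), float(p)


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman's rho with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant input to correlation")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
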