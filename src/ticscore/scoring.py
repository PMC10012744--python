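"""Applying a TICS model to a cohort and the evaluation battery.

The per-sample score is the dot product of the model weights with the
sample's signature enrichment scores. Higher TICS indicates a more
favorable immune contexture (protective signatures carry positive
weights), so risk-oriented metrics are evaluated on the negated score.

Risk groups are assigned against the median computed within the cohort
being scored — the dichotomization travels with the cohort, not with the
training data — or against an explicit cut-off (e.g. from a Youden
analysis on a treatment-response outcome).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, TicsError
from .meta import TICSModel
from .survival import (
    c_index,
    chisquare_independence,
    compare_td_auc,
    cox_fit,
    dxy_optimism,
    mann_whitney_u,
    spearman_corr,
    td_auc_ipcw,
)

log = logging.getLogger(__name__)

__all__ = [
    "score_samples",
    "assign_risk_groups",
    "subgroup_hr",
    "added_value_comparison",
    "multicollinearity_check",
    "clinicopathological_associations",
]


def score_samples(es: pd.DataFrame, model: TICSModel) -> pd.Series:
    """Per-sample TICS = sum_i w_i * ES_i over the model's signatures.

    ``es`` is signatures × samples. Raises naming the first missing
    signature.
    """
    missing = [s for s in model.signatures if s not in es.index]
    if missing:
        raise KeyError(f"signature(s) missing from enrichment matrix: {missing}")
    w = np.asarray(model.weights, dtype=float)
    mat = es.loc[model.signatures].to_numpy(dtype=float)
    return pd.Series(w @ mat, index=es.columns, name="tics")


def assign_risk_groups(
    tics: pd.Series,
    cutoff: float | str = "median",
) -> pd.DataFrame:
    """Label samples high/low TICS relative to a cut-off.

    ``cutoff="median"`` uses the within-cohort median (ties go low);
    otherwise the explicit value is used. Returns a frame with columns
    ``tics``, ``group``, ``cutoff``.
    """
    vals = np.asarray(tics, dtype=float)
    if cutoff == "median":
        if vals.size < 2:
            raise DegenerateDataError("median cutoff requires >= 2 samples")
        if np.ptp(vals) == 0:
            raise DegenerateDataError("all scores identical: cannot stratify")
        cut = float(np.median(vals))
    else:
        cut = float(cutoff)
    group = np.where(vals > cut, "high", "low")
    return pd.DataFrame(
        {"tics": vals, "group": group, "cutoff": cut}, index=tics.index
    )


def _high_vs_low_fit(groups: pd.Series, surv: pd.DataFrame):
    x = pd.DataFrame({"high_tics": (groups == "high").astype(float)})
    return cox_fit(x, surv["time_months"].to_numpy(), surv["event"].to_numpy())


def subgroup_hr(
    scores: pd.DataFrame,
    surv: pd.DataFrame,
    strata: Mapping[str, Sequence[bool]],
) -> pd.DataFrame:
    """Univariable high-vs-low Cox fit within each named stratum.

    ``strata`` maps a stratum label to a boolean mask over the samples.
    Strata where the fit is degenerate are reported as NA with a reason
    instead of failing the whole table.
    """
    rows = []
    for name, mask in strata.items():
        mask = np.asarray(mask, dtype=bool)
        row = {"stratum": name, "n": int(mask.sum()), "hr": np.nan,
               "ci_lo": np.nan, "ci_hi": np.nan, "p": np.nan, "reason": ""}
        if mask.sum() == 0:
            row["reason"] = "empty stratum"
        else:
            try:
                fit = _high_vs_low_fit(
                    scores.loc[mask, "group"], surv.loc[mask]
                )
                s = fit.summary.loc["high_tics"]
                row.update(hr=s["hr"], ci_lo=s["ci_lo"], ci_hi=s["ci_hi"], p=s["p"])
            except (TicsError, ValueError) as exc:
                row["reason"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def added_value_comparison(
    surv: pd.DataFrame,
    tics: pd.Series,
    covariate_cols: Sequence[str],
    horizons_months: Sequence[float] = (12, 24, 36, 48, 60),
    B: int = 500,
    seed: int | None = None,
    dxy_B: int = 100,
) -> dict:
    """Does adding the continuous TICS to the clinical model help?

    Fits two multivariable Cox models — clinical covariates with and
    without the TICS — and compares their linear predictors' IPCW AUCs at
    each horizon via paired bootstrap. Also reports apparent and
    optimism-corrected Dxy for both models.
    """
    missing = [c for c in covariate_cols if c not in surv.columns]
    if missing:
        raise KeyError(f"covariate column(s) missing: {missing}")
    t = surv["time_months"].to_numpy()
    e = surv["event"].to_numpy()
    X_without = surv[list(covariate_cols)].astype(float).reset_index(drop=True)
    X_with = X_without.copy()
    X_with["tics"] = np.asarray(tics, dtype=float)
    fit_with = cox_fit(X_with, t, e)
    fit_without = cox_fit(X_without, t, e)
    lp_with = fit_with.linear_predictor(X_with)
    lp_without = fit_without.linear_predictor(X_without)
    rng = np.random.default_rng(seed)
    rows = []
    for h in horizons_months:
        auc_with = td_auc_ipcw(lp_with, t, e, h)
        auc_without = td_auc_ipcw(lp_without, t, e, h)
        delta, p = compare_td_auc(
            lp_with, lp_without, t, e, h, B=B,
            seed=int(rng.integers(2**31 - 1)),
        )
        rows.append(
            {"horizon_months": h, "auc_with": auc_with,
             "auc_without": auc_without, "delta": delta, "p": p}
        )
    dxy_with = dxy_optimism(X_with, t, e, B=dxy_B,
                            seed=int(rng.integers(2**31 - 1)))
    dxy_without = dxy_optimism(X_without, t, e, B=dxy_B,
                               seed=int(rng.integers(2**31 - 1)))
    return {
        "auc_table": pd.DataFrame(rows),
        "dxy_with": {"apparent": dxy_with[0], "corrected": dxy_with[1]},
        "dxy_without": {"apparent": dxy_without[0], "corrected": dxy_without[1]},
    }


def multicollinearity_check(es: pd.DataFrame) -> dict:
    """VIF per signature and condition number of the standardized scores.

    ``es`` is signatures × samples restricted to the model's signatures.
    VIF_i = 1/(1 - R^2_i) from regressing signature i's scores on the
    others; kappa is the ratio of extreme singular values of the
    column-standardized samples × signatures matrix. Exactly collinear
    columns yield infinite VIF with an error flag rather than an
    exception.
    """
    if es.shape[0] < 2:
        raise ValueError("need >= 2 signatures")
    if es.shape[1] <= es.shape[0]:
        raise ValueError("need more samples than signatures")
    M = es.to_numpy(dtype=float).T  # samples × signatures
    sd = M.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise DegenerateDataError("constant signature score column")
    Z = (M - M.mean(axis=0)) / sd
    sv = np.linalg.svd(Z, compute_uv=False)
    kappa = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
    vifs = []
    for i in range(M.shape[1]):
        yv = Z[:, i]
        Xo = np.column_stack([Z[:, [j for j in range(M.shape[1]) if j != i]],
                              np.ones(len(yv))])
        beta, _, _, _ = np.linalg.lstsq(Xo, yv, rcond=None)
        resid = yv - Xo @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(yv @ yv)
        r2 = 1 - ss_res / ss_tot
        vifs.append(float("inf") if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2))
    table = pd.DataFrame(
        {"vif": vifs, "collinear": [not np.isfinite(v) for v in vifs]},
        index=es.index,
    )
    if table["collinear"].any():
        log.error(
            "exactly collinear signature columns: %s",
            list(table.index[table["collinear"]]),
        )
    return {"vif": table, "kappa": kappa}


def clinicopathological_associations(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_types: Mapping[str, str],
) -> pd.DataFrame:
    """Association of the TICS with each clinical covariate.

    Type ``binary`` → Mann–Whitney of TICS between levels; ``continuous``
    → Spearman correlation; ``categorical`` → chi-square of covariate ×
    high/low group. Degenerate covariates yield NA rows with a reason.
    """
    rows = []
    tics = scores["tics"].to_numpy(dtype=float)
    group = scores["group"]
    for name, kind in covariate_types.items():
        row = {"covariate": name, "type": kind, "test": "", "statistic": np.nan,
               "p": np.nan, "reason": ""}
        if name not in covariates.columns:
            row["reason"] = "column missing"
            rows.append(row)
            continue
        col = covariates[name]
        try:
            if kind == "binary":
                levels = pd.unique(col.dropna())
                if len(levels) != 2:
                    raise DegenerateDataError(
                        f"expected 2 levels, got {len(levels)}"
                    )
                a = tics[(col == levels[0]).to_numpy()]
                b = tics[(col == levels[1]).to_numpy()]
                stat, p = mann_whitney_u(a, b)
                row.update(test="mann-whitney", statistic=stat, p=p)
            elif kind == "continuous":
                stat, p = spearman_corr(tics, col.to_numpy(dtype=float))
                row.update(test="spearman", statistic=stat, p=p)
            elif kind == "categorical":
                tbl = pd.crosstab(col, group)
                if min(tbl.shape) < 2:
                    raise DegenerateDataError("single-level covariate")
                stat, p = chisquare_independence(tbl.to_numpy())
                row.update(test="chi-square", statistic=stat, p=p)
            else:
                raise ValueError(f"unknown covariate type {kind!r}")
        except (TicsError, ValueError) as exc:
            row["reason"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
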