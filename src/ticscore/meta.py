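"""Derivation of the tumor immune contexture score (TICS) model.

For each signature, the enrichment score is median-dichotomized within
each training cohort, a univariable Cox model of the high-vs-low
indicator gives a per-cohort log hazard ratio, and the cohort effects are
pooled by inverse-variance meta-analysis on the log-HR scale (fixed
effect by default; DerSimonian–Laird random effects available).
Signatures with pooled P < alpha are selected, and each receives the
weight

    w_i = (1 - HR_i) / SE_i

with ``HR_i`` the pooled hazard ratio and ``SE_i`` the standard error of
the pooled log hazard ratio. A protective signature (HR < 1) therefore
gets a positive weight and an adverse one a negative weight, scaled by
the precision of its pooled effect.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, TicsError
from .gene_sets import GeneSetCollection
from .ssgsea import SsgseaParams, median_dichotomize, ssgsea_matrix
from .survival import cox_fit

log = logging.getLogger(__name__)

__all__ = [
    "StudyEffect",
    "MetaResult",
    "TICSModel",
    "se_from_ci",
    "per_cohort_effect",
    "pool_fixed",
    "pool_random",
    "select_prognostic",
    "compute_weight",
    "build_tics_model",
    "forest_table",
]

_Z95 = 1.96  # printed CIs use the conventional 1.96, so back-conversion does too


def se_from_ci(hr: float, lo: float, hi: float) -> float:
    """SE of the log hazard ratio from a printed 95% CI: (ln hi − ln lo)/3.92."""
    if not (0 < lo <= hr <= hi):
        raise ValueError(f"require 0 < lo <= hr <= hi, got ({hr}, {lo}, {hi})")
    return (math.log(hi) - math.log(lo)) / (2 * _Z95)


@dataclass(frozen=True)
class StudyEffect:
    """One cohort's contribution to a signature's meta-analysis."""

    cohort_id: str
    log_hr: float
    se: float
    n: int = 0
    n_events: int = 0

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("standard error must be positive")


@dataclass
class MetaResult:
    """Pooled effect of one signature across cohorts."""

    signature_name: str
    studies: list[StudyEffect]
    pooled_log_hr: float
    pooled_se: float
    p: float
    q: float
    i2: float
    method: str = "fixed"

    @property
    def pooled_hr(self) -> float:
        return math.exp(self.pooled_log_hr)

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            math.exp(self.pooled_log_hr - _Z95 * self.pooled_se),
            math.exp(self.pooled_log_hr + _Z95 * self.pooled_se),
        )


def per_cohort_effect(es, surv: pd.DataFrame, cohort_id: str = "") -> StudyEffect:
    """Univariable Cox effect of median-dichotomized enrichment (high = 1).

    ``surv`` requires columns ``time_months`` and ``event`` aligned with
    ``es``. Degenerate stratification or separation propagates as the
    corresponding package error; callers building a model skip and log.
    """
    es = np.asarray(es, dtype=float)
    if len(es) != len(surv):
        raise ValueError("enrichment vector and survival table lengths differ")
    labels = median_dichotomize(es)
    x = pd.DataFrame({"high": (labels == "high").astype(float)})
    fit = cox_fit(x, surv["time_months"].to_numpy(), surv["event"].to_numpy())
    return StudyEffect(
        cohort_id=cohort_id,
        log_hr=float(fit.coef["high"]),
        se=float(fit.se["high"]),
        n=fit.n,
        n_events=fit.n_events,
    )


def _heterogeneity(y: np.ndarray, w: np.ndarray, pooled: float) -> tuple[float, float]:
    q = float(np.sum(w * (y - pooled) ** 2))
    k = len(y)
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    return q, i2


def pool_fixed(studies: list[StudyEffect], signature_name: str = "") -> MetaResult:
    """Inverse-variance fixed-effect pooling on the log-HR scale."""
    if not studies:
        raise ValueError("need >= 1 study")
    y = np.array([s.log_hr for s in studies])
    w = np.array([1.0 / s.se**2 for s in studies])
    pooled = float(np.sum(w * y) / w.sum())
    se = float(w.sum() ** -0.5)
    p = float(2 * stats.norm.sf(abs(pooled / se)))
    q, i2 = _heterogeneity(y, w, pooled)
    return MetaResult(signature_name, list(studies), pooled, se, p, q, i2, "fixed")


def pool_random(studies: list[StudyEffect], signature_name: str = "") -> MetaResult:
    """DerSimonian–Laird random-effects pooling on the log-HR scale."""
    if not studies:
        raise ValueError("need >= 1 study")
    y = np.array([s.log_hr for s in studies])
    w = np.array([1.0 / s.se**2 for s in studies])
    fixed = float(np.sum(w * y) / w.sum())
    q, _ = _heterogeneity(y, w, fixed)
    k = len(y)
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    wr = 1.0 / (np.array([s.se**2 for s in studies]) + tau2)
    pooled = float(np.sum(wr * y) / wr.sum())
    se = float(wr.sum() ** -0.5)
    p = float(2 * stats.norm.sf(abs(pooled / se)))
    _, i2 = _heterogeneity(y, w, fixed)
    return MetaResult(signature_name, list(studies), pooled, se, p, q, i2, "random")


def select_prognostic(
    metas: list[MetaResult],
    alpha: float = 0.05,
    require_consistent_direction: bool = False,
) -> list[MetaResult]:
    """Signatures with meta-analytic P < alpha, order preserved.

    With ``require_consistent_direction`` the per-cohort log HRs must all
    share the pooled effect's sign. An empty selection raises with a
    diagnostic table of every signature's p-value.
    """
    if not metas:
        raise ValueError("no meta-analysis results supplied")
    chosen = []
    for m in metas:
        if m.p >= alpha:
            continue
        if require_consistent_direction:
            sign = np.sign(m.pooled_log_hr)
            if any(np.sign(s.log_hr) != sign for s in m.studies):
                continue
        chosen.append(m)
    if not chosen:
        diag = "\n".join(f"  {m.signature_name}: p={m.p:.4g}" for m in metas)
        raise DegenerateDataError(
            f"no signature reached P < {alpha} in meta-analysis:\n{diag}"
        )
    return chosen


def compute_weight(m: MetaResult) -> float:
    """w = (1 − pooled HR) / SE(pooled log HR)."""
    return (1.0 - m.pooled_hr) / m.pooled_se


@dataclass
class TICSModel:
    """Selected signatures and their meta-analytic weights."""

    signatures: list[str]
    weights: list[float]
    ssgsea_params: SsgseaParams
    meta: list[MetaResult] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.signatures) != len(self.weights) or not self.signatures:
            raise ValueError("need equally many signatures and weights, >= 1")
        if not all(np.isfinite(w) and w != 0 for w in self.weights):
            raise ValueError("weights must be finite and nonzero")

    def to_dict(self) -> dict:
        return {
            "signatures": [
                {
                    "name": name,
                    "weight": w,
                    **(
                        {
                            "pooled_hr": m.pooled_hr,
                            "pooled_se": m.pooled_se,
                            "p": m.p,
                            "q": m.q,
                            "i2": m.i2,
                            "method": m.method,
                        }
                        if m is not None
                        else {}
                    ),
                }
                for name, w, m in zip(
                    self.signatures,
                    self.weights,
                    self.meta or [None] * len(self.signatures),
                )
            ],
            "ssgsea_params": self.ssgsea_params.to_dict(),
            "provenance": self.provenance,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "TICSModel":
        return cls(
            signatures=[s["name"] for s in d["signatures"]],
            weights=[float(s["weight"]) for s in d["signatures"]],
            ssgsea_params=SsgseaParams.from_dict(d["ssgsea_params"]),
            provenance=d.get("provenance", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "TICSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_tics_model(
    cohorts: list,
    collection: GeneSetCollection,
    params: SsgseaParams = SsgseaParams(),
    alpha: float = 0.05,
    method: str = "fixed",
    min_cohorts: int = 2,
    min_set_size: int = 3,
    require_consistent_direction: bool = False,
) -> TICSModel:
    """End-to-end model derivation over >= 2 training cohorts.

    ``cohorts`` is a list of objects with attributes ``cohort_id``,
    ``expression`` (genes × samples DataFrame) and ``survival``
    (DataFrame with ``time_months``, ``event``). Signatures with fewer
    than ``min_cohorts`` successful per-cohort fits are excluded (logged).
    """
    if len(cohorts) < 2:
        raise ValueError("model derivation requires >= 2 training cohorts")
    pool = pool_fixed if method == "fixed" else pool_random
    effects: dict[str, list[StudyEffect]] = {}
    order: list[str] = []
    for cohort in cohorts:
        es = ssgsea_matrix(cohort.expression, collection, params, min_set_size)
        surv = cohort.survival
        for sig in es.index:
            if sig not in effects:
                effects[sig] = []
                order.append(sig)
            try:
                eff = per_cohort_effect(es.loc[sig], surv, cohort.cohort_id)
            except TicsError as exc:
                log.warning(
                    "cohort %s skipped for signature %s: %s",
                    cohort.cohort_id, sig, exc,
                )
                continue
            effects[sig].append(eff)
    metas: list[MetaResult] = []
    for sig in order:
        if len(effects[sig]) < min_cohorts:
            log.warning(
                "signature %s excluded: only %d contributing cohort(s)",
                sig, len(effects[sig]),
            )
            continue
        metas.append(pool(effects[sig], sig))
    selected = select_prognostic(metas, alpha, require_consistent_direction)
    model = TICSModel(
        signatures=[m.signature_name for m in selected],
        weights=[compute_weight(m) for m in selected],
        ssgsea_params=params,
        meta=selected,
        provenance={
            "cohorts": [c.cohort_id for c in cohorts],
            "alpha": alpha,
            "method": method,
            "n_signatures_tested": len(metas),
            "min_cohorts": min_cohorts,
            "min_set_size": min_set_size,
        },
    )
    return model


def forest_table(metas: list[MetaResult]) -> pd.DataFrame:
    """Audit table: one row per (signature, cohort) plus a pooled row."""
    rows = []
    for m in metas:
        for s in m.studies:
            rows.append(
                {
                    "signature": m.signature_name,
                    "cohort": s.cohort_id,
                    "log_hr": s.log_hr,
                    "se": s.se,
                    "hr": math.exp(s.log_hr),
                    "n": s.n,
                    "n_events": s.n_events,
                    "pooled": False,
                }
            )
        lo, hi = m.ci95
        rows.append(
            {
                "signature": m.signature_name,
                "cohort": f"pooled ({m.method})",
                "log_hr": m.pooled_log_hr,
                "se": m.pooled_se,
                "hr": m.pooled_hr,
                "n": sum(s.n for s in m.studies),
                "n_events": sum(s.n_events for s in m.studies),
                "pooled": True,
            }
        )
    return pd.DataFrame(rows)
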