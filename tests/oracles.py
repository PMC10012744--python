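"""Independent brute-force reference implementations used by the tests.

These deliberately use explicit loops and elementary formulas, sharing no
code with the package, so that agreement is evidence of correctness.
"""

from __future__ import annotations

import numpy as np


def brute_force_es(values, members, alpha, gene_ids=None) -> float:
    """ssGSEA enrichment score via an explicit double loop."""
    n = len(values)
    if gene_ids is None:
        gene_ids = [f"{i:09d}" for i in range(n)]
    order = sorted(range(n), key=lambda i: (-values[i], gene_ids[i]))
    in_set = [bool(members[i]) for i in order]
    weights = [float(n - pos) ** alpha for pos in range(n)]  # r = n - pos
    total_in = sum(w for w, m in zip(weights, in_set) if m)
    n_out = sum(1 for m in in_set if not m)
    es = 0.0
    for i in range(n):
        p_in = sum(weights[j] for j in range(i + 1) if in_set[j]) / total_in
        p_out = sum(1 for j in range(i + 1) if not in_set[j]) / n_out
        es += p_in - p_out
    return es


def brute_force_cindex(score, time, event) -> float:
    """Harrell's C by exhaustive pair enumeration (ties in score = 1/2)."""
    n = len(time)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # i must have the observed, earlier event
            if event[i] != 1 or time[i] >= time[j]:
                continue
            den += 1
            if score[i] > score[j]:
                num += 1
            elif score[i] == score[j]:
                num += 0.5
    return num / den


def brute_force_auc(score_cases, score_controls) -> float:
    """Empirical Mann–Whitney AUC, ties counted 1/2."""
    num = 0.0
    for a in score_cases:
        for b in score_controls:
            if a > b:
                num += 1.0
            elif a == b:
                num += 0.5
    return num / (len(score_cases) * len(score_controls))


def brute_force_logrank(time, event, group) -> float:
    """Two-group log-rank chi-square via explicit O-E bookkeeping."""
    levels = sorted(set(group))
    assert len(levels) == 2
    o_minus_e = 0.0
    var = 0.0
    for t in sorted({time[i] for i in range(len(time)) if event[i] == 1}):
        at_risk = [i for i in range(len(time)) if time[i] >= t]
        deaths = [i for i in at_risk if time[i] == t and event[i] == 1]
        n = len(at_risk)
        d = len(deaths)
        n1 = sum(1 for i in at_risk if group[i] == levels[1])
        d1 = sum(1 for i in deaths if group[i] == levels[1])
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def cox_score_test_no_ties(time, event, x) -> float:
    """Cox partial-likelihood score test statistic at beta = 0 (no ties)."""
    order = np.argsort(time)
    t, e, xv = np.asarray(time)[order], np.asarray(event)[order], np.asarray(
        x, dtype=float
    )[order]
    u = v = 0.0
    n = len(t)
    for i in range(n):
        if e[i] != 1:
            continue
        risk = xv[i:]
        m = risk.mean()
        u += xv[i] - m
        v += np.mean(risk**2) - m**2
    return u**2 / v
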