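"""Agreement between checklist-derived and severity-derived person scores.

The two scoring routes estimate related but distinct constructs (lifetime
symptom propensity vs clinician-rated worst-period severity), both on a mean
0 / SD 1 latent metric with per-person posterior SEs. With no gold standard,
agreement is assessed Bland-Altman style: per person the difference of the
two estimates is compared against z times the joint standard error
sqrt(SE_1^2 + SE_2^2); rank agreement uses Spearman correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ItemResponseMatrix
from .tables import FLOAT_FMT, PersonScoreTable


def spearman(x, y) -> float:
    """Spearman rank correlation with average-rank tie handling.

    Raises for constant inputs, where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    # identical (or exactly reversed) rank vectors are +/-1 by definition;
    # return them exactly rather than through floating-point Pearson
    if np.array_equal(rx, ry):
        return 1.0
    if np.array_equal(rx, len(rx) + 1 - ry):
        return -1.0
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def bland_altman(
    scores1: PersonScoreTable,
    scores2: PersonScoreTable,
    z: float = 1.96,
    exclude_flags: tuple = ("no_administered_ratings", "no_observed_responses"),
) -> tuple[pd.DataFrame, dict]:
    """Per-person agreement records and a summary.

    Differences are oriented ``scores1 - scores2`` (checklist minus
    severity). Persons absent from either table, or flagged as having no
    observed data for either score, are excluded and counted. A person whose
    two SEs are both zero degenerates to an exact-equality check and is
    flagged in the record.
    """
    idx2 = {p: i for i, p in enumerate(scores2.person_ids)}
    rows = []
    n_excluded = 0
    for i, pid in enumerate(scores1.person_ids):
        if pid not in idx2:
            n_excluded += 1
            continue
        if scores1.flags.get(pid) in exclude_flags or scores2.flags.get(
            pid
        ) in exclude_flags:
            n_excluded += 1
            continue
        k = idx2[pid]
        e1, s1 = scores1.mean[i], scores1.sd[i]
        e2, s2 = scores2.mean[k], scores2.sd[k]
        joint = float(np.sqrt(s1**2 + s2**2))
        diff = float(e1 - e2)
        degenerate = joint == 0.0
        agree = (diff == 0.0) if degenerate else (abs(diff) <= z * joint)
        rows.append(
            {
                "person_id": pid,
                "estimate_1": e1,
                "se_1": s1,
                "estimate_2": e2,
                "se_2": s2,
                "common_mean": (e1 + e2) / 2.0,
                "difference": diff,
                "joint_se": joint,
                "agree": bool(agree),
                "degenerate_se": degenerate,
            }
        )
    records = pd.DataFrame(rows)
    n = len(records)
    if n == 0:
        raise ValueError("no persons shared between the two score tables")
    n_agree = int(records["agree"].sum())
    try:
        rho = spearman(records["estimate_1"], records["estimate_2"])
    except ValueError:
        rho = np.nan
    summary = {
        "n_compared": n,
        "n_excluded": n_excluded,
        "n_agree": n_agree,
        "percent_agree": 100.0 * n_agree / n,
        "spearman": rho,
        "z": z,
        "disagreements": list(records.loc[~records["agree"], "person_id"]),
    }
    return records, summary


def score_vs_raw_rank_check(
    model_scores: PersonScoreTable, resp: ItemResponseMatrix
) -> float:
    """Spearman correlation of model scores with raw symptom counts."""
    if model_scores.person_ids != resp.person_ids:
        raise ValueError("person ids misaligned between scores and checklist")
    return spearman(model_scores.mean, resp.symptom_counts())


def write_plot_coords(records: pd.DataFrame, path) -> None:
    """Bland-Altman plot coordinates (common mean vs difference) as text."""
    records[["person_id", "common_mean", "difference", "joint_se", "agree"]].to_csv(
        path, index=False, float_format=FLOAT_FMT
    )
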