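"""Cohort-level statistics: propensity-score matching, group tests,
severity-strata comparisons and covariate-adjusted correlations.

The cohort is a tidy :class:`pandas.DataFrame` with one row per trial:

``subject_id, trial_id, group ('patient'|'control'), age, gait_speed``
plus optional clinical columns (``UPDRS_III``, ``HY``, ``disease_duration``,
``faller``) and feature columns (entropy values, gait indexes).

Control subjects may contribute two trials (self-selected and slower
walking speed) *before* matching; 1:1 optimal matching on the propensity
score selects exactly one trial per matched control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MatchResult",
    "propensity_scores",
    "optimal_match",
    "greedy_match",
    "two_group_test",
    "mann_whitney_hedges",
    "disability_strata_test",
    "dunn_posthoc",
    "holm_adjust",
    "partial_spearman",
]

REQUIRED_COLUMNS = ("subject_id", "group", "age", "gait_speed")


def validate_cohort(cohort: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    groups = set(cohort["group"].unique())
    if not groups <= {"patient", "control"}:
        raise ValueError(f"group must be 'patient' or 'control', got {groups}")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of 1:1 optimal propensity-score matching.

    ``pairs`` lists (patient_id, control_trial_id); each patient appears
    exactly once and each control subject contributes at most one trial.
    """

    pairs: tuple
    total_ps_distance: float
    ps_model_coefficients: tuple | None = None


def propensity_scores(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = ("age", "gait_speed"),
) -> pd.Series:
    """Fitted probability of patient membership given the covariates.

    Logistic regression of group on the covariates by maximum likelihood.
    Under (quasi-)perfect separation the ML fit diverges; a ridge-penalised
    fit is used instead and a warning is issued.  Returns one score per row,
    indexed like ``cohort``.
    """
    import statsmodels.api as sm

    validate_cohort(cohort)
    X = cohort.loc[:, list(covariates)].astype(float)
    if X.isna().any().any():
        raise ValueError("covariates contain missing values")
    y = (cohort["group"] == "patient").astype(int).to_numpy()
    # Zero-variance covariates carry no information and make the design
    # singular; dropping them reduces cleanly to an intercept-only fit.
    informative = X.loc[:, X.std(ddof=0) > 0]
    if informative.shape[1] == 0:
        frac = y.mean()
        scores = pd.Series(np.full(len(y), frac), index=cohort.index)
        scores.attrs["coefficients"] = (math.log(frac / (1 - frac)),)
        return scores
    exog = sm.add_constant(informative.to_numpy(), has_constant="add")
    fitted = None
    try:
        res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        # diverging coefficients or a failed optimisation signal separation
        if res.mle_retvals.get("converged", False) and np.all(
            np.abs(res.params) < 1e3
        ):
            fitted = np.asarray(res.predict(exog))
            coefs = tuple(res.params)
    except Exception:
        pass
    if fitted is None or not np.all((fitted > 0) & (fitted < 1)):
        warnings.warn(
            "logistic ML fit failed (perfect separation?); "
            "falling back to an L2-penalised fit",
            stacklevel=2,
        )
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1.0, max_iter=1000)
        clf.fit(informative.to_numpy(), y)
        fitted = clf.predict_proba(informative.to_numpy())[:, 1]
        coefs = tuple(np.concatenate([clf.intercept_, clf.coef_.ravel()]))
    scores = pd.Series(np.asarray(fitted, dtype=float), index=cohort.index)
    scores.attrs["coefficients"] = coefs
    return scores


def optimal_match(
    patient_ps: Mapping[str, float],
    control_ps: Mapping[str, float],
    trial_subject: Mapping[str, str] | None = None,
) -> MatchResult:
    """Globally optimal 1:1 matching on propensity-score differences.

    Minimises the *total* absolute propensity-score difference over all
    one-to-one assignments of patients to control trials (an assignment
    problem, solved exactly — not greedy nearest-neighbour), under the
    constraint that each control *subject* contributes at most one trial.

    Parameters
    ----------
    patient_ps : mapping patient_id -> propensity score
    control_ps : mapping control trial_id -> propensity score
    trial_subject : mapping trial_id -> subject_id, optional
        When omitted every trial is its own subject.
    """
    patients = list(patient_ps)
    trials = list(control_ps)
    if trial_subject is None:
        trial_subject = {t: t for t in trials}
    subjects: dict[str, list[str]] = {}
    for t in trials:
        subjects.setdefault(trial_subject[t], []).append(t)
    subject_ids = list(subjects)
    if len(subject_ids) < len(patients):
        raise ValueError(
            f"cannot 1:1 match {len(patients)} patients to "
            f"{len(subject_ids)} control subjects "
            f"(deficit {len(patients) - len(subject_ids)})"
        )
    # Since a subject contributes at most one trial, the optimal pairing
    # for a (patient, subject) pair always uses that subject's closest
    # trial; the assignment then runs over subjects.
    cost = np.empty((len(patients), len(subject_ids)))
    best_trial = np.empty((len(patients), len(subject_ids)), dtype=object)
    for i, p in enumerate(patients):
        for j, s in enumerate(subject_ids):
            diffs = [(abs(patient_ps[p] - control_ps[t]), t) for t in subjects[s]]
            d, t = min(diffs)
            cost[i, j] = d
            best_trial[i, j] = t
    rows, cols = linear_sum_assignment(cost)
    pairs = tuple(
        (patients[i], best_trial[i, j]) for i, j in zip(rows, cols)
    )
    total = float(cost[rows, cols].sum())
    return MatchResult(pairs=pairs, total_ps_distance=total)


def greedy_match(
    patient_ps: Mapping[str, float],
    control_ps: Mapping[str, float],
    trial_subject: Mapping[str, str] | None = None,
) -> MatchResult:
    """Greedy nearest-neighbour matching in patient order.

    Kept as a baseline: its total distance is an upper bound on the optimal
    assignment's and is used to demonstrate why global matching matters.
    """
    trials = list(control_ps)
    if trial_subject is None:
        trial_subject = {t: t for t in trials}
    used_subjects: set[str] = set()
    pairs = []
    total = 0.0
    for p, ps in patient_ps.items():
        avail = [t for t in trials if trial_subject[t] not in used_subjects]
        if not avail:
            raise ValueError("ran out of control subjects during greedy matching")
        d, t = min((abs(ps - control_ps[t]), t) for t in avail)
        used_subjects.add(trial_subject[t])
        pairs.append((p, t))
        total += d
    return MatchResult(pairs=tuple(pairs), total_ps_distance=total)


def mann_whitney_hedges(a: Sequence[float], b: Sequence[float]) -> dict:
    """Mann–Whitney U test plus Hedges-corrected Cohen's d.

    The U test is exact when n1*n2 <= 400 and the data are tie-free,
    otherwise the normal approximation with tie correction is used.
    Effect size: d = (mean_a − mean_b)/pooled SD, shrunk by the
    small-sample factor 1 − 3/(4N − 9).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (n1 * n2 <= 400 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    s1, s2 = np.var(a, ddof=1), np.var(b, ddof=1)
    pooled_sd = math.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    if pooled_sd == 0.0:
        d = 0.0
    else:
        d = (a.mean() - b.mean()) / pooled_sd
    g = d * (1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0))
    return {
        "U": float(res.statistic), "p": float(res.pvalue),
        "cohen_d": float(d), "hedges_g": float(g),
        "n1": n1, "n2": n2, "method": method,
    }


def two_group_test(cohort: pd.DataFrame, feature: str) -> dict:
    """Patient-vs-control comparison of one feature column."""
    validate_cohort(cohort)
    sub = cohort.dropna(subset=[feature])
    a = sub.loc[sub["group"] == "patient", feature].to_numpy(dtype=float)
    b = sub.loc[sub["group"] == "control", feature].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError(f"feature {feature!r} has an empty group")
    out = mann_whitney_hedges(a, b)
    out["feature"] = feature
    out["median_patient"] = float(np.median(a))
    out["median_control"] = float(np.median(b))
    out["iqr_patient"] = float(np.subtract(*np.percentile(a, [75, 25])))
    out["iqr_control"] = float(np.subtract(*np.percentile(b, [75, 25])))
    return out


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, never below raw)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, dtype=float), method="holm")[1]


def dunn_posthoc(groups: Sequence[np.ndarray], labels: Sequence[str]) -> pd.DataFrame:
    """All pairwise Dunn z tests on the pooled ranks, Holm-adjusted.

    z_{ij} = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T/(12(N−1))) (1/n_i + 1/n_j))
    with the tie term T = Σ(t³ − t); two-sided normal p-values.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(float(ranks[start : start + g.size].mean()))
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        base_var -= tie_term / (12.0 * (n_total - 1))
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = math.sqrt(base_var * (1.0 / groups[i].size + 1.0 / groups[j].size))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group1": labels[i], "group2": labels[j], "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_holm"] = holm_adjust(df["p_raw"].to_numpy())
    return df


def disability_strata_test(
    cohort: pd.DataFrame,
    feature: str,
    severity_col: str = "UPDRS_III",
    cuts: tuple[float, float] = (32.0, 58.0),
) -> dict:
    """Kruskal–Wallis across motor-severity strata with Dunn/Holm post hoc.

    Patients are binned into mild (< cuts[0]), moderate (>= cuts[0] and
    < cuts[1]) and severe (>= cuts[1]) strata of the severity score.
    Empty strata are dropped with a warning; at least two non-empty strata
    are required.
    """
    sub = cohort.dropna(subset=[feature, severity_col])
    sev = sub[severity_col].to_numpy(dtype=float)
    vals = sub[feature].to_numpy(dtype=float)
    lo, hi = cuts
    bins = {
        "mild": vals[sev < lo],
        "moderate": vals[(sev >= lo) & (sev < hi)],
        "severe": vals[sev >= hi],
    }
    kept = {k: v for k, v in bins.items() if v.size > 0}
    if len(kept) < len(bins):
        warnings.warn(
            f"empty severity strata dropped: {sorted(set(bins) - set(kept))}",
            stacklevel=2,
        )
    if len(kept) < 2:
        raise ValueError("need at least two non-empty severity strata")
    labels = list(kept)
    arrays = [kept[k] for k in labels]
    h_stat, p = stats.kruskal(*arrays)
    return {
        "feature": feature,
        "H": float(h_stat),
        "p": float(p),
        "strata": {k: int(v.size) for k, v in kept.items()},
        "pairwise": dunn_posthoc(arrays, labels),
    }


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | None = None,
) -> dict:
    """Partial Spearman correlation of x and y given covariates.

    All variables are rank-transformed; the x- and y-ranks are residualised
    on the covariate ranks (least squares with intercept) and the Pearson
    correlation of the residuals is returned.  With no covariates this is
    exactly Spearman's rho.  The p-value uses the t approximation with
    df = n − 2 − n_covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    k = 0
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == n and cov.shape[1] != n:
            cov = cov.T  # accept (n, k) or (k, n)
        elif cov.shape[1] == n:
            pass
        else:
            raise ValueError("covariates must have length n along one axis")
        k = cov.shape[0]
        design = np.column_stack(
            [np.ones(n)] + [stats.rankdata(c) for c in cov]
        )
        rx = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
        ry = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    if np.std(rx) == 0.0 or np.std(ry) == 0.0:
        return {"rho_partial": math.nan, "p": math.nan, "n": n, "df": n - 2 - k}
    rho = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    if df <= 0:
        return {"rho_partial": rho, "p": math.nan, "n": n, "df": df}
    rho_c = min(max(rho, -1.0), 1.0)
    if abs(rho_c) == 1.0:
        p = 0.0
    else:
        t = rho_c * math.sqrt(df / (1.0 - rho_c**2))
        p = 2.0 * stats.t.sf(abs(t), df)
    return {"rho_partial": rho, "p": float(p), "n": n, "df": df}


def cohort_partial_spearman(
    cohort: pd.DataFrame,
    feature_x: str,
    feature_y: str,
    covariates: Sequence[str] = ("age", "gait_speed"),
) -> dict:
    """Partial Spearman between two cohort columns, excluding covariates."""
    cols = [feature_x, feature_y, *covariates]
    sub = cohort.dropna(subset=cols)
    cov = sub.loc[:, list(covariates)].to_numpy(dtype=float).T if covariates else None
    out = partial_spearman(
        sub[feature_x].to_numpy(dtype=float),
        sub[feature_y].to_numpy(dtype=float),
        cov,
    )
    out["x"] = feature_x
    out["y"] = feature_y
    return out
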