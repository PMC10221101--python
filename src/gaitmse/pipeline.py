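"""End-to-end analysis: matching → entropy → tests → ROC/OCP → strata →
partial correlations.

The pipeline evaluates every entropy feature (method × axis × scale, plus
complexity indices) as a candidate marker separating patients from
controls, mirroring a speed-matched case–control gait study:

1. propensity-score optimal matching selects one trial per control subject;
2. multiscale entropy profiles are extracted per trial and axis;
3. each feature gets a Mann–Whitney test with Hedges g;
4. each feature gets ROC/AUC, an optimal cutoff and the post-test
   probability panel at every configured prevalence;
5. features with sufficient AUC are ranked by the PTP+ − PTP− difference,
   then by diagnostic odds ratio;
6. top features get severity-strata tests and covariate-adjusted
   (partial Spearman) correlations with the clinical columns.

All written artifacts are deterministic functions of the configuration and
seed (no timestamps), so a rerun is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort as cs
from . import diagnostics as dx
from .entropy import EntropyConfig, SignalTrace, is_undefined, multiscale_profiles
from .io import profiles_to_long

__all__ = ["AnalysisConfig", "RunReport", "run_pipeline", "rank_features",
           "match_cohort", "feature_name"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Resolved settings of one analysis run (YAML round-trippable)."""

    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    prevalences: tuple = ("sample", 0.35)
    auc_threshold: float = 0.70
    updrs_cuts: tuple = (32.0, 58.0)
    covariates: tuple = ("age", "gait_speed")
    methods: tuple = ("MSE", "CMSE", "RCMSE")
    axes: tuple = ("AP", "ML", "V")
    n_top_features: int = 3
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["entropy"] = asdict(self.entropy)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        if "entropy" in d and isinstance(d["entropy"], Mapping):
            d["entropy"] = EntropyConfig(**d["entropy"])
        for key in ("prevalences", "updrs_cuts", "covariates", "methods", "axes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def feature_name(method: str, axis: str, tau: int | None) -> str:
    """Canonical feature column name, e.g. ``MSE_AP_t4`` or ``CI_MSE_AP``."""
    if tau is None:
        return f"CI_{method}_{axis}"
    return f"{method}_{axis}_t{tau}"


@dataclass
class RunReport:
    """All tables produced by one pipeline run."""

    config: AnalysisConfig
    matching: pd.DataFrame
    cohort: pd.DataFrame           # matched analysis set with feature columns
    entropy_long: pd.DataFrame
    group_tests: pd.DataFrame
    diagnostics: pd.DataFrame
    ranking: list
    strata_tests: pd.DataFrame
    partial_correlations: pd.DataFrame
    undefined_entries: pd.DataFrame

    def summary(self) -> dict:
        return {
            "config_hash": self.config.config_hash,
            "seed": self.config.seed,
            "n_patients": int((self.cohort["group"] == "patient").sum()),
            "n_controls": int((self.cohort["group"] == "control").sum()),
            "n_features": int(self.group_tests.shape[0]),
            "n_sufficient": int(
                self.diagnostics.loc[
                    self.diagnostics["prevalence_label"] == "sample", "sufficient"
                ].sum()
            ),
            "ranking": list(self.ranking),
            "n_undefined_entropy": int(self.undefined_entries.shape[0]),
        }

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        kw = dict(index=False, na_rep="NA", float_format="%.10g")
        self.config.to_yaml(out / "config.yaml")
        self.matching.to_csv(out / "matching.csv", **kw)
        self.cohort.to_csv(out / "cohort_features.csv", **kw)
        self.entropy_long.to_csv(out / "entropy_long.csv", **kw)
        self.group_tests.to_csv(out / "group_tests.csv", **kw)
        self.diagnostics.to_csv(out / "diagnostics.csv", **kw)
        self.strata_tests.to_csv(out / "strata_tests.csv", **kw)
        self.partial_correlations.to_csv(out / "partial_correlations.csv", **kw)
        self.undefined_entries.to_csv(out / "undefined_entropy.csv", **kw)
        (out / "summary.json").write_text(
            json.dumps(self.summary(), indent=1, sort_keys=True)
        )


def match_cohort(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Propensity-score matching stage of the pipeline.

    Fits the propensity model on all trials and selects one trial per
    control subject by globally optimal assignment against the patient
    pool.  When there are at least as many control subjects as patients,
    this is 1:1 matching proper; with fewer control subjects every subject
    is matched to a distinct patient and the remaining (unmatched) patients
    stay in the analysis set, as in a design that retains the full patient
    group and selects which control trials enter the comparison.

    Returns (analysis set, matching table).
    """
    cs.validate_cohort(cohort)
    ps = cs.propensity_scores(cohort)
    patients = cohort[cohort["group"] == "patient"]
    controls = cohort[cohort["group"] == "control"]
    if patients.empty or controls.empty:
        raise ValueError("matching needs both groups")
    patient_ps = dict(zip(patients["subject_id"], ps[patients.index]))
    control_ps = dict(zip(controls["trial_id"], ps[controls.index]))
    trial_subject = dict(zip(controls["trial_id"], controls["subject_id"]))
    n_subjects = controls["subject_id"].nunique()
    if n_subjects >= len(patient_ps):
        result = cs.optimal_match(patient_ps, control_ps, trial_subject)
        pairs = result.pairs
    else:
        # Transposed assignment: every control subject to a distinct patient.
        logger.info(
            "%d patients vs %d control subjects: matching all control "
            "subjects, retaining unmatched patients",
            len(patient_ps), n_subjects,
        )
        from scipy.optimize import linear_sum_assignment

        pat_ids = list(patient_ps)
        subjects: dict[str, list[str]] = {}
        for t, s in trial_subject.items():
            subjects.setdefault(s, []).append(t)
        sub_ids = list(subjects)
        cost = np.empty((len(pat_ids), len(sub_ids)))
        best = np.empty_like(cost, dtype=object)
        for i, p in enumerate(pat_ids):
            for j, s in enumerate(sub_ids):
                d, t = min(
                    (abs(patient_ps[p] - control_ps[t]), t) for t in subjects[s]
                )
                cost[i, j] = d
                best[i, j] = t
        rows, cols = linear_sum_assignment(cost)
        pairs = tuple((pat_ids[i], best[i, j]) for i, j in zip(rows, cols))

    matched_trials = {t for _, t in pairs}
    keep = cohort["group"].eq("patient") | cohort["trial_id"].isin(matched_trials)
    analysis = cohort[keep].reset_index(drop=True)
    table = pd.DataFrame(
        [
            {
                "patient_id": p,
                "control_trial_id": t,
                "ps_patient": patient_ps[p],
                "ps_control": control_ps[t],
                "abs_diff": abs(patient_ps[p] - control_ps[t]),
            }
            for p, t in pairs
        ]
    ).sort_values("patient_id", ignore_index=True)
    return analysis, table


def _extract_features(
    analysis: pd.DataFrame,
    traces: Mapping[str, Mapping[str, SignalTrace]],
    config: AnalysisConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Entropy profiles for every trial; wide feature table + long table."""
    all_profiles = []
    feat_rows = []
    for _, row in analysis.iterrows():
        trial = traces[row["trial_id"]]
        feats: dict = {"trial_id": row["trial_id"]}
        for axis in config.axes:
            profs = multiscale_profiles(trial[axis], config.entropy)
            for method in config.methods:
                p = profs[method]
                all_profiles.append(p)
                for tau, v in p.values.items():
                    feats[feature_name(method, axis, tau)] = v
                feats[feature_name(method, axis, None)] = p.ci
        feat_rows.append(feats)
    wide = analysis.merge(pd.DataFrame(feat_rows), on="trial_id")
    long = profiles_to_long(all_profiles)
    undefined = long[long["value"].isna()].reset_index(drop=True)
    return wide, long, undefined


def _feature_columns(config: AnalysisConfig) -> list[str]:
    names = []
    for method in config.methods:
        for axis in config.axes:
            for tau in range(1, config.entropy.tau_max + 1):
                names.append(feature_name(method, axis, tau))
            names.append(feature_name(method, axis, None))
    return names


def run_pipeline(
    config: AnalysisConfig,
    cohort: pd.DataFrame,
    traces: Mapping[str, Mapping[str, SignalTrace]],
    outdir: str | Path | None = None,
) -> RunReport:
    """Execute all analysis stages in order on a cohort with raw traces."""
    analysis, match_table = match_cohort(cohort)
    logger.info("stage matching done: %d pairs", len(match_table))

    wide, entropy_long, undefined = _extract_features(analysis, traces, config)
    logger.info("stage entropy done: %d undefined values", len(undefined))

    features = _feature_columns(config)
    labels_all = (wide["group"] == "patient").astype(int).to_numpy()

    test_rows = []
    for f in features:
        try:
            test_rows.append(cs.two_group_test(wide, f))
        except ValueError as e:
            logger.warning("skipping group test for %s: %s", f, e)
    group_tests = pd.DataFrame(test_rows)

    diag_rows = []
    sample_prev = labels_all.mean()
    for f in features:
        mask = wide[f].notna().to_numpy()
        scores = wide.loc[mask, f].to_numpy(dtype=float)
        labels = labels_all[mask]
        if not (np.any(labels == 1) and np.any(labels == 0)):
            logger.warning("feature %s lacks a class after NaN removal", f)
            continue
        data = dx.LabeledScores(scores, labels)
        roc = dx.roc_auc(data, config.auc_threshold)
        for prev_spec in config.prevalences:
            label = "sample" if prev_spec == "sample" else f"{float(prev_spec):g}"
            prev = data.prevalence if prev_spec == "sample" else float(prev_spec)
            rep = dx.select_ocp(data, prev)
            diag_rows.append({
                "feature": f,
                "prevalence_label": label,
                "prevalence": prev,
                "auc": roc.auc, "auc_ci_low": roc.ci_low,
                "auc_ci_high": roc.ci_high, "sufficient": roc.sufficient,
                "cutoff": rep.cutoff, "sens": rep.sens, "spec": rep.spec,
                "youden": rep.youden, "f1": rep.f1,
                "lr_pos": rep.lr_pos, "lr_neg": rep.lr_neg,
                "ptp_pos": rep.ptp_pos, "ptp_neg": rep.ptp_neg,
                "ptp_diff": rep.ptp_diff, "dor": rep.dor,
                "zero_cell": rep.zero_cell,
            })
    diagnostics = pd.DataFrame(diag_rows)

    ranking = rank_features_table(diagnostics)
    top = ranking[: config.n_top_features]

    strata_rows = []
    patients_only = wide[wide["group"] == "patient"]
    for f in top:
        try:
            res = cs.disability_strata_test(
                patients_only, f, cuts=tuple(config.updrs_cuts)
            )
        except (ValueError, KeyError) as e:
            logger.warning("strata test skipped for %s: %s", f, e)
            continue
        for _, pw in res["pairwise"].iterrows():
            strata_rows.append({
                "feature": f, "H": res["H"], "p_kw": res["p"],
                "group1": pw["group1"], "group2": pw["group2"],
                "z": pw["z"], "p_raw": pw["p_raw"], "p_holm": pw["p_holm"],
            })
    strata_tests = pd.DataFrame(strata_rows)

    clinical_cols = [
        c for c in ("UPDRS_III", "disease_duration") if c in wide.columns
    ]
    pc_rows = []
    for f in top:
        for c in clinical_cols:
            try:
                pc_rows.append(cs.cohort_partial_spearman(
                    patients_only, f, c, covariates=tuple(config.covariates)
                ))
            except (ValueError, KeyError) as e:
                logger.warning("partial correlation skipped %s~%s: %s", f, c, e)
    partial_correlations = pd.DataFrame(pc_rows)

    report = RunReport(
        config=config,
        matching=match_table,
        cohort=wide,
        entropy_long=entropy_long,
        group_tests=group_tests,
        diagnostics=diagnostics,
        ranking=ranking,
        strata_tests=strata_tests,
        partial_correlations=partial_correlations,
        undefined_entries=undefined,
    )
    if outdir is not None:
        report.write(outdir)
    return report


def rank_features_table(diagnostics: pd.DataFrame) -> list:
    """Features with sufficient AUC ordered by (PTP+ − PTP−, then DOR).

    Uses the sample-prevalence rows; empty when nothing reaches the AUC
    threshold.
    """
    if diagnostics.empty:
        return []
    d = diagnostics[
        (diagnostics["prevalence_label"] == "sample") & diagnostics["sufficient"]
    ].copy()
    if d.empty:
        return []
    d = d.sort_values(
        ["ptp_diff", "dor", "feature"], ascending=[False, False, True]
    )
    return list(d["feature"])


def rank_features(report: RunReport) -> list:
    """Ranking of sufficient features from a finished run."""
    return rank_features_table(report.diagnostics)
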