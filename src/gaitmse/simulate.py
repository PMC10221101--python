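"""Synthetic trunk-acceleration signals and two-group gait cohorts.

The signal model is a quasi-periodic harmonic sum: each axis is a set of
harmonics of the stride frequency whose phase drifts as a per-cycle random
walk (cycle-to-cycle timing irregularity) and whose amplitude is rescaled
every cycle (amplitude irregularity), plus additive white or 1/f noise.
Antero-posterior and vertical axes weight the even (step-frequency)
harmonics; the medio-lateral axis weights the odd (stride-frequency)
harmonics — the standard phenomenology of lumbar-mounted accelerometry.

Cohorts pair a patient group, whose irregularity parameters are scaled up
by a multiplier (optionally modulated by a motor-severity score), with a
control pool in which every subject walks twice: once at a self-selected
speed and once slower.  The two control trials feed the propensity-score
matching stage exactly the way a speed-matched study design would.

The generator emulates the *statistical* structure the analysis assumes —
group differences in cycle-to-cycle irregularity, covariate overlap, two
trials per control — not the biomechanics of walking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .entropy import AXES, SignalTrace

__all__ = [
    "GaitSimParams",
    "CohortSimParams",
    "gen_noise",
    "gen_trunk_signal",
    "gen_cohort",
    "PRESETS",
    "preset_params",
]

#: Default per-axis harmonic amplitudes (harmonics 1..6 of the stride
#: frequency).  AP/V emphasise even harmonics (step frequency), ML odd.
DEFAULT_HARMONIC_AMPS: Dict[str, Tuple[float, ...]] = {
    "AP": (0.10, 1.00, 0.08, 0.40, 0.05, 0.15),
    "ML": (1.00, 0.12, 0.45, 0.08, 0.18, 0.05),
    "V": (0.08, 1.20, 0.06, 0.50, 0.04, 0.20),
}

#: Patient irregularity multiplier of the "paper-like" preset, calibrated
#: once by a pilot sweep so the antero-posterior sample-entropy feature
#: discriminates patients from controls with AUC ~ 0.8 at n = 50 per group.
CALIBRATED_EFFECT_MULTIPLIER = 1.65


@dataclass(frozen=True)
class GaitSimParams:
    """Parameters of one synthetic walking trial.

    Defaults: 100 Hz sampling, 2000 samples (20 s), stride frequency
    0.86 Hz (cadence ~103 steps/min), six harmonics.  ``phase_jitter_sd``
    is the per-cycle standard deviation (radians) of the random-walk phase
    drift; ``amp_jitter_cv`` the coefficient of variation of the per-cycle
    amplitude factor; ``noise_sd`` the additive noise SD in the same
    arbitrary acceleration units as the harmonic amplitudes.
    """

    fs: float = 100.0
    n_samples: int = 2000
    stride_freq: float = 0.86
    n_harmonics: int = 6
    harmonic_amps: Dict[str, Tuple[float, ...]] | None = None
    phase_jitter_sd: float = 0.12
    amp_jitter_cv: float = 0.08
    noise_sd: float = 0.10
    noise_color: str = "white"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.n_samples < 2 or self.stride_freq <= 0:
            raise ValueError("fs, n_samples and stride_freq must be positive")
        if min(self.phase_jitter_sd, self.amp_jitter_cv, self.noise_sd) < 0:
            raise ValueError("jitter and noise parameters must be >= 0")
        if self.noise_color not in ("white", "pink"):
            raise ValueError("noise_color must be 'white' or 'pink'")

    def amps(self, axis: str) -> np.ndarray:
        table = self.harmonic_amps or DEFAULT_HARMONIC_AMPS
        a = np.asarray(table[axis], dtype=float)[: self.n_harmonics]
        if a.size < self.n_harmonics:
            a = np.pad(a, (0, self.n_harmonics - a.size))
        return a

    def scaled(self, irregularity: float) -> "GaitSimParams":
        """Copy with all irregularity sources scaled by one factor."""
        return replace(
            self,
            phase_jitter_sd=self.phase_jitter_sd * irregularity,
            amp_jitter_cv=self.amp_jitter_cv * irregularity,
            noise_sd=self.noise_sd * irregularity,
        )


@dataclass(frozen=True)
class CohortSimParams:
    """Two-group cohort design.

    Defaults mirror a typical speed-matched case–control gait study:
    51 patients, 50 controls contributing two walking-speed trials each,
    ages ~71±5 vs ~69±5 years, self-selected speed ~1.08±0.25 m/s.
    ``patient_irregularity_multiplier`` scales every irregularity source of
    the patient trials; ``severity_slope`` lets the multiplier grow with the
    motor-severity score so severity strata differ in entropy.  Every
    subject additionally carries a lognormal irregularity factor
    (``between_subject_sigma`` on the log scale, both groups), the
    between-subject heterogeneity that keeps groups overlapping.
    """

    n_patients: int = 51
    n_controls: int = 50
    control_trials_per_subject: int = 2
    patient_irregularity_multiplier: float = CALIBRATED_EFFECT_MULTIPLIER
    between_subject_sigma: float = 0.4
    severity_slope: float = 0.25
    age_mean_patient: float = 71.0
    age_sd_patient: float = 5.0
    age_mean_control: float = 69.0
    age_sd_control: float = 5.0
    speed_mean: float = 1.08
    speed_sd: float = 0.25
    slow_factor_range: Tuple[float, float] = (0.75, 0.9)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.patient_irregularity_multiplier <= 0:
            raise ValueError("irregularity multiplier must be positive")
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("group sizes must be positive")


def gen_noise(
    kind: str, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """White (iid Gaussian) or pink (1/f spectral shaping) noise.

    Pink noise is produced by scaling the rFFT of white noise by
    1/sqrt(f) and is renormalised to unit sample variance.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    w = rng.standard_normal(n)
    if kind == "white":
        return w
    if kind != "pink":
        raise ValueError("kind must be 'white' or 'pink'")
    spec = np.fft.rfft(w)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * scale, n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _cycle_track(
    rng: np.random.Generator, t_cycles: np.ndarray, n_cycles: int,
    sd: float, walk: bool,
) -> np.ndarray:
    """Per-cycle random values linearly interpolated to sample times.

    ``walk=True`` accumulates (phase drift); ``walk=False`` stays iid
    around zero (amplitude wobble).
    """
    steps = rng.normal(0.0, sd, n_cycles)
    track = np.cumsum(steps) if walk else steps
    return np.interp(t_cycles, np.arange(n_cycles), track)


def gen_trunk_signal(
    params: GaitSimParams,
    rng: np.random.Generator | None = None,
    subject_id: str = "",
) -> Dict[str, SignalTrace]:
    """One triaxial synthetic walking trial.

    Per axis: a(t) = A(t) · Σ_h A_h sin(2π h f0 t + φ_h + h·ε(t)) + noise,
    where ε(t) is a per-cycle random-walk phase shared across axes (the
    same gait cycles drive all three), A(t) a per-cycle amplitude factor
    and φ_h random initial phases.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_samples
    t = np.arange(n) / params.fs
    f0 = params.stride_freq
    t_cycles = t * f0
    n_cycles = int(math.ceil(t_cycles[-1])) + 2

    eps = _cycle_track(rng, t_cycles, n_cycles, params.phase_jitter_sd, walk=True)
    traces: Dict[str, SignalTrace] = {}
    for axis in AXES:
        amps = params.amps(axis)
        phases = rng.uniform(0.0, 2.0 * math.pi, params.n_harmonics)
        amp_t = 1.0 + _cycle_track(
            rng, t_cycles, n_cycles, params.amp_jitter_cv, walk=False
        )
        amp_t = np.clip(amp_t, 0.1, None)
        sig = np.zeros(n)
        for h in range(1, params.n_harmonics + 1):
            sig += amps[h - 1] * np.sin(
                2.0 * math.pi * h * f0 * t + phases[h - 1] + h * eps
            )
        sig *= amp_t
        if params.noise_sd > 0:
            sig += params.noise_sd * gen_noise(params.noise_color, n, rng)
        traces[axis] = SignalTrace(
            samples=sig, fs=params.fs, axis=axis, subject_id=subject_id
        )
    return traces


def _patient_severity(rng: np.random.Generator) -> dict:
    """Clinical profile of one synthetic patient."""
    updrs = float(np.clip(rng.normal(32.0, 14.0), 5.0, 80.0))
    hy = 1 + int(updrs >= 25) + int(updrs >= 45)
    duration = float(np.clip(rng.lognormal(1.7, 0.6), 0.5, 25.0))
    faller = bool(rng.random() < 0.35)
    return {
        "UPDRS_III": updrs, "HY": hy,
        "disease_duration": duration, "faller": faller,
    }


def gen_cohort(
    params: CohortSimParams = CohortSimParams(),
    gait: GaitSimParams = GaitSimParams(),
) -> Tuple[pd.DataFrame, Dict[str, Dict[str, SignalTrace]]]:
    """Full synthetic cohort: trial table plus raw triaxial traces.

    Returns a tidy DataFrame with one row per trial (patients contribute
    one trial, controls ``control_trials_per_subject``) and a dict mapping
    trial_id -> axis -> :class:`SignalTrace`.  The stride frequency of each
    trial scales with the subject's walking speed (square-root walk-ratio
    scaling), so slower control trials are slower in both senses.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    traces: Dict[str, Dict[str, SignalTrace]] = {}

    def trial_gait(speed: float, irregularity: float) -> GaitSimParams:
        f0 = gait.stride_freq * math.sqrt(max(speed, 0.3) / 1.08)
        return replace(gait.scaled(irregularity), stride_freq=f0)

    for i in range(params.n_patients):
        sid = f"P{i:03d}"
        age = rng.normal(params.age_mean_patient, params.age_sd_patient)
        speed = float(np.clip(rng.normal(params.speed_mean, params.speed_sd), 0.4, 2.0))
        clin = _patient_severity(rng)
        subject_factor = math.exp(rng.normal(0.0, params.between_subject_sigma))
        mult = params.patient_irregularity_multiplier * (
            1.0 + params.severity_slope * (clin["UPDRS_III"] - 32.0) / 28.0
        )
        mult = max(mult, 1.0) * subject_factor
        tid = f"{sid}_T1"
        traces[tid] = gen_trunk_signal(trial_gait(speed, mult), rng, subject_id=sid)
        rows.append({
            "subject_id": sid, "trial_id": tid, "group": "patient",
            "age": float(age), "gait_speed": speed, **clin,
        })

    for i in range(params.n_controls):
        sid = f"C{i:03d}"
        age = rng.normal(params.age_mean_control, params.age_sd_control)
        speed = float(np.clip(rng.normal(params.speed_mean, params.speed_sd), 0.4, 2.0))
        subject_factor = math.exp(rng.normal(0.0, params.between_subject_sigma))
        speeds = [speed]
        for _ in range(params.control_trials_per_subject - 1):
            speeds.append(speed * rng.uniform(*params.slow_factor_range))
        for j, sp in enumerate(speeds, start=1):
            tid = f"{sid}_T{j}"
            traces[tid] = gen_trunk_signal(
                trial_gait(sp, subject_factor), rng, subject_id=sid
            )
            rows.append({
                "subject_id": sid, "trial_id": tid, "group": "control",
                "age": float(age), "gait_speed": float(sp),
                "UPDRS_III": math.nan, "HY": 0,
                "disease_duration": math.nan, "faller": False,
            })

    return pd.DataFrame(rows), traces


#: Named study conditions for the command-line interface and tests.
PRESETS = ("null", "paper-like", "strong-effect")


def preset_params(name: str, seed: int | None = None) -> CohortSimParams:
    """Cohort parameters for a named preset.

    ``null`` — no group effect, identical covariate distributions (for
    type-I-error calibration); ``paper-like`` — the calibrated defaults;
    ``strong-effect`` — a larger irregularity contrast.
    """
    if name == "null":
        return CohortSimParams(
            patient_irregularity_multiplier=1.0, severity_slope=0.0,
            age_mean_patient=70.0, age_mean_control=70.0, seed=seed,
        )
    if name == "paper-like":
        return CohortSimParams(seed=seed)
    if name == "strong-effect":
        return CohortSimParams(
            patient_irregularity_multiplier=1.6 * CALIBRATED_EFFECT_MULTIPLIER,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
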