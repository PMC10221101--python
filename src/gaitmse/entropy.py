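"""Sample entropy and its multiscale variants for physiological time series.

Sample entropy (SampEn) quantifies the irregularity of a time series as the
negative logarithm of the conditional probability that two sequences which
match for ``m`` consecutive points (within a tolerance ``r``, Chebyshev
distance) also match for ``m + 1`` points.  Self-matches are excluded and
each unordered template pair is counted once.

The multiscale variants operate on coarse-grained versions of the signal:
non-overlapping windows of width ``tau`` are averaged, producing one shorter
series per window offset ``k`` (``1 <= k <= tau``).

* **MSE** — SampEn of the first (``k = 1``) coarse-grained series at each
  scale.
* **CMSE** — mean of the ``tau`` per-offset SampEn values; undefined as soon
  as any single offset yields no matches.
* **RCMSE** — pools the template match counts across all offsets before
  taking the logarithm, which keeps the estimate defined unless *every*
  offset produced zero matches.  This is the variant of choice for short
  series.
* **Complexity index (CI)** — trapezoid-rule integral of an entropy-vs-scale
  profile over a scale range; summarises irregularity across time scales.

Undefined entropy values are represented as ``math.nan`` and propagate
explicitly; they are never silently replaced by zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Sequence

import numpy as np

__all__ = [
    "UNDEFINED",
    "is_undefined",
    "AXES",
    "SignalTrace",
    "EntropyConfig",
    "MatchCounts",
    "MultiscaleProfile",
    "InsufficientLengthError",
    "count_matched_pairs",
    "sample_entropy",
    "coarse_grain",
    "mse_profile",
    "cmse_profile",
    "rcmse_profile",
    "multiscale_profiles",
    "complexity_index",
]

logger = logging.getLogger(__name__)

#: Canonical value for an entropy that could not be estimated (zero matches).
UNDEFINED = math.nan

#: Acceleration axes of a lumbar-mounted sensor: antero-posterior,
#: medio-lateral, vertical.
AXES = ("AP", "ML", "V")

#: Number of leading samples entropy is computed on when a trace is longer.
#: 2000 points at 100 Hz (20 s of steady-state walking) balances estimator
#: stability against stationarity of the gait bout.
ANALYSIS_LENGTH = 2000


def is_undefined(value: float) -> bool:
    """True when ``value`` is the UNDEFINED marker (NaN)."""
    return isinstance(value, float) and math.isnan(value)


class InsufficientLengthError(ValueError):
    """Raised when a series is too short to form any template pair."""


@dataclass(frozen=True)
class SignalTrace:
    """One axis of an acceleration recording.

    Parameters
    ----------
    samples : array-like
        Acceleration samples, arbitrary units.  Missing values are rejected,
        never imputed.
    fs : float
        Sampling rate in Hz (default 100, the typical trunk-IMU rate).
    axis : str
        One of ``AP``, ``ML``, ``V``.
    subject_id : str
        Opaque label used in reports.
    """

    samples: np.ndarray
    fs: float = 100.0
    axis: str = "AP"
    subject_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if arr.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not np.all(np.isfinite(arr)):
            raise ValueError("trace contains missing/non-finite samples")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class EntropyConfig:
    """Estimator parameters shared by all entropy variants.

    Defaults follow common practice for trunk-acceleration gait analysis:
    embedding dimension ``m = 2``, tolerance ``r = 0.2 * SD``, unit time lag,
    scale factors 1–6 for series of ~2000 points.

    ``r_mode`` controls whether the tolerance is fixed once from the SD of
    the original series (``sd_original``, the Costa convention, default) or
    recomputed from each coarse-grained series (``sd_per_scale``, provided
    for sensitivity analysis).
    """

    m: int = 2
    r_fraction: float = 0.2
    lag: int = 1
    tau_max: int = 6
    r_mode: str = "sd_original"

    def __post_init__(self) -> None:
        if self.m < 1 or self.lag < 1 or self.tau_max < 1:
            raise ValueError("m, lag and tau_max must be positive integers")
        if self.r_fraction <= 0:
            raise ValueError("r_fraction must be positive")
        if self.r_mode not in ("sd_original", "sd_per_scale"):
            raise ValueError("r_mode must be 'sd_original' or 'sd_per_scale'")


@dataclass(frozen=True)
class MatchCounts:
    """Counts of matched template pairs at dimensions m and m+1.

    Both template sets use the same index range, so every (m+1)-dimensional
    match is also an m-dimensional match under the Chebyshev norm and
    ``n_m1 <= n_m`` holds structurally.
    """

    n_m: int
    n_m1: int

    def __post_init__(self) -> None:
        if self.n_m < 0 or self.n_m1 < 0 or self.n_m1 > self.n_m:
            raise ValueError("invalid match counts (need 0 <= n_m1 <= n_m)")


@dataclass(frozen=True)
class MultiscaleProfile:
    """Entropy value per scale factor for one method on one axis.

    ``values`` maps every scale ``1..tau_max`` to an entropy value, with NaN
    marking scales where the estimate is undefined.  ``ci`` is the trapezoid
    complexity index over the full scale range (NaN if any scale in the
    range is undefined).
    """

    method: str
    axis: str
    values: Mapping[int, float]
    ci: float
    config: EntropyConfig
    subject_id: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.values[t] for t in sorted(self.values)])


def _pair_counts(x: np.ndarray, m: int, r_abs: float, lag: int) -> MatchCounts:
    """Vectorised template-pair counting over the shared index range.

    Templates x_i = (x[i], x[i+lag], ..., x[i+(m-1)lag]) are formed for
    i = 0..T-1 with T = N - m*lag, for both dimensions m and m+1, so the
    counts are directly comparable.
    """
    n = x.size
    n_templates = n - m * lag
    # Chebyshev distance accumulated one embedding coordinate at a time.
    dist = np.abs(np.subtract.outer(x[:n_templates], x[:n_templates]))
    for k in range(1, m):
        seg = x[k * lag : k * lag + n_templates]
        np.maximum(dist, np.abs(np.subtract.outer(seg, seg)), out=dist)
    # The full matrix counts every unordered pair twice and the (zero)
    # diagonal once; correct rather than materialising a triangle index.
    n_m = (int(np.count_nonzero(dist <= r_abs)) - n_templates) // 2
    seg = x[m * lag : m * lag + n_templates]
    np.maximum(dist, np.abs(np.subtract.outer(seg, seg)), out=dist)
    n_m1 = (int(np.count_nonzero(dist <= r_abs)) - n_templates) // 2
    return MatchCounts(n_m=n_m, n_m1=n_m1)


def count_matched_pairs(
    x: Sequence[float], m: int, r_abs: float, lag: int = 1
) -> MatchCounts:
    """Count matched m- and (m+1)-dimensional template pairs.

    A pair of templates matches when their Chebyshev (infinity-norm)
    distance is at most ``r_abs``; each unordered pair is counted once and
    self-matches are excluded.

    Raises
    ------
    InsufficientLengthError
        If the series cannot form at least two (m+1)-dimensional templates.
    """
    arr = np.asarray(x, dtype=float)
    if m < 1 or lag < 1:
        raise ValueError("m and lag must be positive integers")
    if r_abs < 0:
        raise ValueError("tolerance must be non-negative")
    if arr.size < lag * (m + 1) + 1:
        raise InsufficientLengthError(
            f"series of length {arr.size} is too short for m={m}, lag={lag} "
            f"(need at least {lag * (m + 1) + 1} samples)"
        )
    return _pair_counts(arr, m, float(r_abs), lag)


def sample_entropy(
    x: Sequence[float],
    cfg: EntropyConfig = EntropyConfig(),
    r_abs: float | None = None,
) -> float:
    """Sample entropy −ln(n_m1 / n_m) of a series.

    When ``r_abs`` is None the tolerance is ``cfg.r_fraction`` times the
    sample standard deviation (ddof=1) of ``x``.  Returns UNDEFINED (NaN)
    when either count is zero — never an exception for zero matches.
    """
    arr = np.asarray(x, dtype=float)
    if r_abs is None:
        r_abs = cfg.r_fraction * float(np.std(arr, ddof=1))
    counts = count_matched_pairs(arr, cfg.m, r_abs, cfg.lag)
    if counts.n_m == 0 or counts.n_m1 == 0:
        return UNDEFINED
    return -math.log(counts.n_m1 / counts.n_m)


def coarse_grain(x: Sequence[float], tau: int, k: int = 1) -> np.ndarray:
    """Coarse-grained series: means of non-overlapping width-``tau`` windows
    starting at offset ``k`` (1-based).  Output length floor((N-k+1)/tau);
    trailing samples that do not fill a window are discarded.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if not 1 <= k <= tau:
        raise ValueError(f"offset k must satisfy 1 <= k <= tau, got k={k}, tau={tau}")
    arr = np.asarray(x, dtype=float)
    if tau == 1:
        return arr.copy()
    n_windows = (arr.size - k + 1) // tau
    if n_windows < 1:
        return np.empty(0)
    return arr[k - 1 : k - 1 + n_windows * tau].reshape(n_windows, tau).mean(axis=1)


def _analysis_samples(trace: SignalTrace) -> np.ndarray:
    """First ANALYSIS_LENGTH samples of a trace (never padded)."""
    x = trace.samples
    if x.size > ANALYSIS_LENGTH:
        return x[:ANALYSIS_LENGTH]
    if x.size < ANALYSIS_LENGTH:
        logger.warning(
            "trace %s/%s has %d samples (< %d); entropy estimates may be unstable",
            trace.subject_id, trace.axis, x.size, ANALYSIS_LENGTH,
        )
    return x


def _scale_counts(
    x: np.ndarray, cfg: EntropyConfig, tau: int, r_original: float
) -> list[MatchCounts | None]:
    """Match counts for every offset series at scale ``tau``.

    Entries are None when a coarse-grained series is too short to embed.
    """
    out: list[MatchCounts | None] = []
    for k in range(1, tau + 1):
        y = coarse_grain(x, tau, k)
        if cfg.r_mode == "sd_per_scale" and y.size > 1:
            r_abs = cfg.r_fraction * float(np.std(y, ddof=1))
        else:
            r_abs = r_original
        try:
            out.append(count_matched_pairs(y, cfg.m, r_abs, cfg.lag))
        except InsufficientLengthError:
            out.append(None)
    return out


def _entropy_from_counts(counts: MatchCounts | None) -> float:
    if counts is None or counts.n_m == 0 or counts.n_m1 == 0:
        return UNDEFINED
    return -math.log(counts.n_m1 / counts.n_m)


def _finish_profile(
    method: str, trace: SignalTrace, cfg: EntropyConfig, values: Dict[int, float]
) -> MultiscaleProfile:
    for tau, v in values.items():
        if is_undefined(v):
            logger.warning(
                "%s undefined at tau=%d for %s/%s",
                method, tau, trace.subject_id, trace.axis,
            )
    ci = _trapezoid(values, 1, cfg.tau_max) if cfg.tau_max > 1 else UNDEFINED
    return MultiscaleProfile(
        method=method, axis=trace.axis, values=dict(values), ci=ci,
        config=cfg, subject_id=trace.subject_id,
    )


def multiscale_profiles(
    trace: SignalTrace, cfg: EntropyConfig = EntropyConfig()
) -> Dict[str, MultiscaleProfile]:
    """MSE, CMSE and RCMSE profiles computed from one pass over the counts.

    The per-offset match counts at each scale are shared: MSE uses the first
    offset only, CMSE averages the per-offset entropies, RCMSE pools the
    counts before the logarithm.  At scale 1 all three coincide with the
    plain sample entropy of the series, bit-exactly.
    """
    x = _analysis_samples(trace)
    r_original = cfg.r_fraction * float(np.std(x, ddof=1))
    mse_vals: Dict[int, float] = {}
    cmse_vals: Dict[int, float] = {}
    rcmse_vals: Dict[int, float] = {}
    for tau in range(1, cfg.tau_max + 1):
        counts = _scale_counts(x, cfg, tau, r_original)
        mse_vals[tau] = _entropy_from_counts(counts[0])
        per_offset = [_entropy_from_counts(c) for c in counts]
        if any(is_undefined(v) for v in per_offset):
            cmse_vals[tau] = UNDEFINED
        else:
            cmse_vals[tau] = float(np.mean(per_offset)) if tau > 1 else per_offset[0]
        defined = [c for c in counts if c is not None]
        if not defined:
            rcmse_vals[tau] = UNDEFINED
        elif tau == 1:
            rcmse_vals[tau] = per_offset[0]  # bit-exact agreement at scale 1
        else:
            pooled_m = sum(c.n_m for c in defined)
            pooled_m1 = sum(c.n_m1 for c in defined)
            if pooled_m == 0 or pooled_m1 == 0:
                rcmse_vals[tau] = UNDEFINED
            else:
                rcmse_vals[tau] = -math.log(pooled_m1 / pooled_m)
    return {
        "MSE": _finish_profile("MSE", trace, cfg, mse_vals),
        "CMSE": _finish_profile("CMSE", trace, cfg, cmse_vals),
        "RCMSE": _finish_profile("RCMSE", trace, cfg, rcmse_vals),
    }


def mse_profile(
    trace: SignalTrace, cfg: EntropyConfig = EntropyConfig()
) -> MultiscaleProfile:
    """Multiscale entropy: SampEn of the first coarse-grained series per scale."""
    x = _analysis_samples(trace)
    r_original = cfg.r_fraction * float(np.std(x, ddof=1))
    values: Dict[int, float] = {}
    for tau in range(1, cfg.tau_max + 1):
        y = coarse_grain(x, tau, 1)
        if cfg.r_mode == "sd_per_scale" and y.size > 1:
            r_abs = cfg.r_fraction * float(np.std(y, ddof=1))
        else:
            r_abs = r_original
        try:
            values[tau] = sample_entropy(y, cfg, r_abs)
        except InsufficientLengthError:
            values[tau] = UNDEFINED
    return _finish_profile("MSE", trace, cfg, values)


def cmse_profile(
    trace: SignalTrace, cfg: EntropyConfig = EntropyConfig()
) -> MultiscaleProfile:
    """Composite multiscale entropy: mean of per-offset SampEn values.

    Undefined at a scale as soon as any single offset series yields zero
    matches — the fragility that motivates the refined variant below.
    """
    return multiscale_profiles(trace, cfg)["CMSE"]


def rcmse_profile(
    trace: SignalTrace, cfg: EntropyConfig = EntropyConfig()
) -> MultiscaleProfile:
    """Refined composite multiscale entropy.

    Pools matched-pair counts over all ``tau`` offsets before the logarithm:
    −ln(Σ_k n_{k}^{m+1} / Σ_k n_{k}^{m}).  Undefined only when a pooled sum
    is zero, i.e. when every offset failed — hence defined whenever CMSE is.
    """
    return multiscale_profiles(trace, cfg)["RCMSE"]


def _trapezoid(values: Mapping[int, float], tau_lo: int, tau_hi: int) -> float:
    vs = [values[t] for t in range(tau_lo, tau_hi + 1)]
    if any(is_undefined(v) for v in vs):
        return UNDEFINED
    return float(np.trapezoid(vs))


def complexity_index(
    profile: MultiscaleProfile, tau_lo: int = 1, tau_hi: int | None = None
) -> float:
    """Trapezoid-rule integral of the entropy profile over unit-spaced scales.

    Returns UNDEFINED if any value in the integration range is undefined.
    """
    if tau_hi is None:
        tau_hi = profile.config.tau_max
    if not (1 <= tau_lo < tau_hi <= profile.config.tau_max):
        raise ValueError(
            f"invalid scale range [{tau_lo}, {tau_hi}] for tau_max="
            f"{profile.config.tau_max}"
        )
    return _trapezoid(profile.values, tau_lo, tau_hi)
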