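"""Estimators and classifiers for simulated cluster dynamics.

Covers ensemble trajectory statistics, position-conditioned profile
averaging, the extreme-value flux-difference estimator, force-velocity
(friction) fitting, and the two oscillation classifiers: a histogram
bimodality rule and an FFT peak rule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .engine import ConditionedAccumulator, Trajectory
from .params import ModelParams

__all__ = ["binned_trajectory_stats", "conditioned_profiles",
           "ConditionedProfiles", "flux_difference_estimator",
           "force_velocity_fit", "position_histogram_classifier",
           "fft_oscillation_detector", "OscillationReport"]


def _frames(trajectories) -> list[pd.DataFrame]:
    out = []
    for tr in trajectories:
        out.append(tr.frame if isinstance(tr, Trajectory) else tr)
    return out


def binned_trajectory_stats(trajectories, bin_s: float = 199.8) -> pd.DataFrame:
    """Ensemble mean and standard deviation of ``x_c`` per time bin.

    Samples from all runs are pooled and grouped into intervals of
    ``bin_s`` seconds (default 3.33 min).  Returns one row per bin with
    ``t_mid_s``, ``mean_um``, ``sd_um`` and the sample count.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be > 0")
    frames = _frames(trajectories)
    if not frames:
        raise ValueError("no trajectories given")
    t = np.concatenate([f["t_s"].to_numpy() for f in frames])
    x = np.concatenate([f["x_c_um"].to_numpy() for f in frames])
    ibin = np.floor(t / bin_s).astype(int)
    df = pd.DataFrame({"bin": ibin, "x": x})
    g = df.groupby("bin")["x"]
    out = pd.DataFrame({
        "t_mid_s": (g.mean().index + 0.5) * bin_s,
        "mean_um": g.mean().to_numpy(),
        "sd_um": g.std(ddof=1).fillna(0.0).to_numpy(),
        "n": g.size().to_numpy()})
    return out.reset_index(drop=True)


@dataclass
class ConditionedProfiles:
    """Dwell-weighted average profiles around a target cluster position."""

    absolute: pd.DataFrame       # x_um, c, c_b, j
    relative: pd.DataFrame       # dx_um (offset from x_c), c, c_b, j
    force_mean: float
    n_bound_mean: float
    dwell: float
    n_epochs: int
    empty: bool = False


def conditioned_profiles(acc: ConditionedAccumulator,
                         params: ModelParams) -> ConditionedProfiles:
    """Convert raw conditioned sums into time-averaged density/flux profiles.

    The accumulator already weights every profile by the time the cluster
    dwelt in the window, so dividing by the total dwell time realizes the
    dwell-weighted ensemble average.  A zero dwell time yields a flagged
    empty result instead of NaNs.
    """
    a, M = params.a, params.n_sites
    if acc.dwell <= 0:
        empty_abs = pd.DataFrame({"x_um": params.nucleoid_sites(),
                                  "c": np.zeros(M), "c_b": np.zeros(M),
                                  "j": np.zeros(M)})
        return ConditionedProfiles(absolute=empty_abs,
                                   relative=empty_abs.rename(
                                       columns={"x_um": "dx_um"}),
                                   force_mean=0.0, n_bound_mean=0.0,
                                   dwell=0.0, n_epochs=acc.n_epochs,
                                   empty=True)
    x = params.nucleoid_sites()
    j_abs = np.zeros(M)
    j_abs[:-1] = acc.flux_net / acc.dwell
    absolute = pd.DataFrame({
        "x_um": x,
        "c": acc.occ_n / (acc.dwell * a),
        "c_b": acc.occ_c / (acc.dwell * a),
        "j": j_abs})
    dx = (np.arange(2 * M + 1) - M) * a
    relative = pd.DataFrame({
        "dx_um": dx,
        "c": acc.occ_n_rel / (acc.dwell * a),
        "c_b": acc.occ_c_rel / (acc.dwell * a),
        "j": acc.flux_rel / acc.dwell})
    return ConditionedProfiles(
        absolute=absolute, relative=relative,
        force_mean=acc.force_dt / acc.dwell,
        n_bound_mean=acc.nb_dt / acc.dwell,
        dwell=acc.dwell, n_epochs=acc.n_epochs)


def flux_difference_estimator(flux: np.ndarray) -> tuple[float, bool]:
    """Flux difference from the two extreme values of a flux profile.

    The maximal (inflow from the left, positive) and minimal (inflow from
    the right, negative) values of the nucleoid-only flux profile sit just
    outside the cluster edges; their sum estimates ``j_L - j_R``.  To keep
    the same sign convention as the RD model (positive = net inflow from
    the right) the negated sum is returned.  If both extremes have the
    same sign the value is returned with a degeneracy flag.
    """
    flux = np.asarray(flux, dtype=float)
    if flux.size == 0:
        raise ValueError("empty flux profile")
    fmax = float(flux.max())
    fmin = float(flux.min())
    degenerate = not (fmax > 0 > fmin)
    return -(fmax + fmin), degenerate


def force_velocity_fit(table: pd.DataFrame, alpha: float = 0.05):
    """Friction coefficient from the linear force-velocity relation.

    ``table`` needs columns ``F_ext_pN`` and ``v_mean_um_s`` (at least
    three points).  The applied force is exact while the velocity is a
    stochastic measurement, so the OLS regression runs velocity on force
    (no attenuation from noise in the regressor) and the friction
    coefficient is the inverse slope.  Returns
    ``(gamma, (ci_lo, ci_hi), fit_result)`` with the confidence interval
    at level ``1 - alpha``.
    """
    import statsmodels.api as sm

    if len(table) < 3:
        raise ValueError("need at least three force-velocity points")
    X = sm.add_constant(table["F_ext_pN"].to_numpy())
    fit = sm.OLS(table["v_mean_um_s"].to_numpy(), X).fit()
    slope = float(fit.params[1])
    if slope <= 0:
        raise ValueError("non-positive force-velocity slope: no "
                         "meaningful friction coefficient")
    gamma = 1.0 / slope
    ci = fit.conf_int(alpha=alpha)
    lo, hi = float(ci[1][0]), float(ci[1][1])
    gamma_hi = math.inf if lo <= 0 else 1.0 / lo
    return gamma, (1.0 / hi, gamma_hi), fit


def position_histogram_classifier(positions: np.ndarray, L: float,
                                  n_bins: int = 100,
                                  sigma_bins: float = 2.0,
                                  threshold: float = 0.02):
    """Classify the pooled cluster-position distribution.

    The histogram over ``[0, L]`` is smoothed with a Gaussian moving
    average; the profile is bimodal iff a local minimum exists, the
    difference between the maximal and the minimal peak exceeds
    ``threshold`` (2%) of the maximal count (strict inequality), and the
    maximum lies farther from midnucleoid than the minimum.  Returns
    ``(shape, details)`` with ``shape`` in {"monomodal", "bimodal"}.
    """
    positions = np.asarray(positions, dtype=float)
    counts, edges = np.histogram(positions, bins=n_bins, range=(0.0, L))
    smooth = gaussian_filter1d(counts.astype(float), sigma_bins,
                               mode="nearest")
    centers = 0.5 * (edges[:-1] + edges[1:])
    shape, details = _classify_smoothed(smooth, centers, L, threshold)
    details.update({"n_bins": n_bins, "sigma_bins": sigma_bins})
    return shape, details


def _plateau_extrema(y: np.ndarray):
    """Interior local maxima/minima with plateau handling.

    Runs of equal values count as one extremum (index at the plateau
    middle); plateaus touching the array ends are not extrema.
    """
    n = len(y)
    maxima: list[int] = []
    minima: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        if i > 0 and j < n - 1:
            left, right = y[i - 1], y[j + 1]
            mid = (i + j) // 2
            if left < y[i] > right:
                maxima.append(mid)
            elif left > y[i] < right:
                minima.append(mid)
        i = j + 1
    return maxima, minima


def _classify_smoothed(smooth: np.ndarray, centers: np.ndarray, L: float,
                       threshold: float = 0.02):
    """Apply the peak rule to an already smoothed histogram profile."""
    maxima, minima = _plateau_extrema(np.asarray(smooth, dtype=float))
    details = {"centers": centers, "smoothed": smooth,
               "maxima": maxima, "minima": minima, "threshold": threshold}
    if not minima or not maxima:
        return "monomodal", details
    i_hi = max(maxima, key=lambda i: smooth[i])
    i_lo = min(minima, key=lambda i: smooth[i])
    peak_hi = smooth[i_hi]
    peak_lo = smooth[i_lo]
    mid = L / 2
    if ((peak_hi - peak_lo) > threshold * smooth.max()
            and abs(centers[i_hi] - mid) > abs(centers[i_lo] - mid)):
        return "bimodal", details
    return "monomodal", details


@dataclass
class OscillationReport:
    """Outcome of the FFT oscillation analysis of a trajectory ensemble."""

    classification: str                  # "oscillatory" | "non-oscillatory"
    frequency_per_min: Optional[float]
    f_min_per_min: float
    histogram_shape: Optional[str]
    settings: dict
    freq_per_min: np.ndarray = field(repr=False, default=None)
    spectrum: np.ndarray = field(repr=False, default=None)
    spectrum_smoothed: np.ndarray = field(repr=False, default=None)

    def to_json(self) -> str:
        d = {"classification": self.classification,
             "frequency_per_min": self.frequency_per_min,
             "f_min_per_min": self.f_min_per_min,
             "histogram_shape": self.histogram_shape,
             "settings": self.settings}
        return json.dumps(d, indent=2)


def _resample_previous(t: np.ndarray, x: np.ndarray,
                       grid: np.ndarray) -> np.ndarray:
    """Previous-value (zero-order hold) resampling onto ``grid``."""
    idx = np.searchsorted(t, grid, side="right") - 1
    idx = np.clip(idx, 0, len(t) - 1)
    return x[idx]


def fft_oscillation_detector(trajectories, T_max: Optional[float] = None,
                             resample_dt: float = 12.0,
                             sigma_bins: float = 2.0,
                             peak_factor: float = 1.2,
                             L: Optional[float] = None,
                             t_start: float = 0.0) -> OscillationReport:
    """Detect oscillatory cluster motion from an ensemble of runs.

    Per run the temporal mean of ``x_c`` is subtracted and the trajectory
    (resampled by previous-value interpolation onto a uniform grid of
    ``resample_dt`` seconds, default 0.2 min) is Fourier transformed.
    The moduli are summed across runs and smoothed with a Gaussian moving
    average; the ensemble is oscillatory iff an interior local maximum of
    the smoothed spectrum exceeds ``peak_factor`` times its value at the
    lowest resolvable frequency ``f_min = 1/T_max``.  If ``L`` is given
    the pooled-position histogram shape is classified as well.
    """
    frames = _frames(trajectories)
    if not frames:
        raise ValueError("no trajectories given")
    t_ends = [f["t_s"].to_numpy()[-1] for f in frames]
    if T_max is None:
        T_max = min(t_ends) - t_start
    if T_max <= 2 * resample_dt:
        raise ValueError("T_max too short for the requested resampling")
    grid = np.arange(t_start, t_start + T_max, resample_dt)
    n = len(grid)
    spec = None
    pooled = []
    for f in frames:
        t = f["t_s"].to_numpy()
        x = f["x_c_um"].to_numpy()
        xs = _resample_previous(t, x, grid)
        pooled.append(xs)
        mod = np.abs(np.fft.rfft(xs - xs.mean()))
        spec = mod if spec is None else spec + mod
    # the zero-frequency bin vanishes by mean subtraction and is not part
    # of the spectrum considered; the reference is the smoothed value at
    # the lowest resolvable frequency f_min = 1/T_max
    spec = spec[1:]
    freqs_hz = np.fft.rfftfreq(n, d=resample_dt)[1:]
    smooth = gaussian_filter1d(spec, sigma_bins, mode="nearest")
    f_min_idx = 0
    ref = smooth[f_min_idx]
    maxima, _ = _plateau_extrema(smooth)
    best_idx = None
    for i in maxima:
        if i > f_min_idx and smooth[i] > peak_factor * ref:
            if best_idx is None or smooth[i] > smooth[best_idx]:
                best_idx = i
    settings = {"resample_dt_s": resample_dt, "sigma_bins": sigma_bins,
                "peak_factor": peak_factor, "T_max_s": float(T_max),
                "n_runs": len(frames), "t_start_s": t_start}
    hist_shape = None
    if L is not None:
        hist_shape, _ = position_histogram_classifier(
            np.concatenate(pooled), L)
    freq_per_min = freqs_hz * 60.0
    if best_idx is None:
        return OscillationReport(
            classification="non-oscillatory", frequency_per_min=None,
            f_min_per_min=float(freqs_hz[f_min_idx] * 60.0),
            histogram_shape=hist_shape, settings=settings,
            freq_per_min=freq_per_min, spectrum=spec,
            spectrum_smoothed=smooth)
    return OscillationReport(
        classification="oscillatory",
        frequency_per_min=float(freqs_hz[best_idx] * 60.0),
        f_min_per_min=float(freqs_hz[f_min_idx] * 60.0),
        histogram_shape=hist_shape, settings=settings,
        freq_per_min=freq_per_min, spectrum=spec, spectrum_smoothed=smooth)
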