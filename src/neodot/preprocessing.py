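"""Channel QC, step-artifact correction, temporal filtering, OD conversion.

The optical pre-processing chain, in the order it is applied:

1. ``prune_channels`` — flag channels with very low mean intensity (poor
   optode coupling) or poor SNR; flagging only, data untouched.
2. ``spline_correct`` — remove a step discontinuity (e.g. from an acquisition
   software error) from a flagged time window using smoothing-spline level
   estimates on either side of the jump.
3. ``lowpass_dot`` — zero-phase 5th-order Butterworth low-pass at 1 Hz,
   removing the cardiac pulsation (~2.5 Hz in a neonate) and high-frequency
   noise.
4. ``to_optical_density`` — convert intensities to optical-density changes
   relative to each channel's mean over the whole acquisition.

EEG traces get the clinical-standard 0.3-70 Hz band-pass plus 50 Hz notch
(``filter_eeg``), all zero-phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import make_smoothing_spline

from .probe_and_io import RecordingBundle

__all__ = [
    "ODSeries",
    "prune_channels",
    "spline_correct",
    "lowpass_dot",
    "to_optical_density",
    "filter_eeg",
    "detect_step_artifacts",
    "preprocess_bundle",
]


@dataclass
class ODSeries:
    """Optical-density changes relative to each channel's mean intensity.

    ``delta_od`` is (time, channel, wavelength), dimensionless;
    ``reference`` the per-channel/wavelength mean intensity used as baseline.
    """

    delta_od: np.ndarray
    reference: np.ndarray
    sample_rate_hz: float
    channel_retained: np.ndarray = field(default_factory=lambda: np.empty(0, bool))

    def __post_init__(self) -> None:
        self.delta_od = np.asarray(self.delta_od, float)
        self.reference = np.asarray(self.reference, float)
        if not np.all(np.isfinite(self.delta_od)):
            raise ValueError("delta_od contains non-finite values")
        if self.reference.mean() <= 0:
            raise ValueError("reference intensities must be positive on average")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.delta_od.shape[0]) / self.sample_rate_hz


# ---------------------------------------------------------------------------
# Channel pruning
# ---------------------------------------------------------------------------

def prune_channels(
    bundle: RecordingBundle,
    min_mean_intensity: float | None = None,
    min_snr: float | None = None,
) -> tuple[RecordingBundle, pd.DataFrame]:
    """Flag channels with inadequate signal; never alters retained data.

    ``min_mean_intensity`` defaults to 1% of the median channel mean (per
    wavelength).  A channel is excluded if its mean intensity falls below the
    floor at either wavelength, or (when ``min_snr`` is given) if its
    mean/std ratio is below ``min_snr``.

    Returns the updated bundle (a copy) and a QC report with one row per
    channel and wavelength.
    """
    if (min_mean_intensity is not None and min_mean_intensity <= 0) or (
        min_snr is not None and min_snr <= 0
    ):
        raise ValueError("thresholds must be positive")
    out = bundle.copy()
    means = bundle.intensity.mean(axis=0)  # (ch, wl)
    stds = bundle.intensity.std(axis=0)
    floors = (
        np.full(means.shape[1], min_mean_intensity)
        if min_mean_intensity is not None
        else 0.01 * np.median(means, axis=0)
    )
    rows = []
    for c in range(means.shape[0]):
        reasons = []
        if np.any(means[c] < floors):
            reasons.append("low_intensity")
        if min_snr is not None:
            snr = means[c] / np.where(stds[c] > 0, stds[c], np.inf)
            if np.any(snr < min_snr):
                reasons.append("low_snr")
        if reasons:
            out.channel_retained[c] = False
            out.channel_quality_reason[c] = "+".join(reasons)
        for w in range(means.shape[1]):
            rows.append(
                {
                    "channel": c,
                    "wavelength_nm": bundle.probe.wavelengths[w],
                    "mean_intensity": means[c, w],
                    "retained": not reasons,
                    "reason": "+".join(reasons),
                }
            )
    if not out.channel_retained.any():
        raise RuntimeError(
            "all channels excluded by pruning; check thresholds and data "
            f"(median channel mean {np.median(means):.3g}, floor {floors})"
        )
    return out, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Step-artifact correction
# ---------------------------------------------------------------------------

def spline_correct(
    trace: np.ndarray,
    sample_rate_hz: float,
    artifact_window: tuple[float, float],
    smoothing: float = 0.99,
) -> np.ndarray:
    """Remove a step discontinuity inside a flagged time window.

    The discontinuity is located at the largest sample-to-sample jump inside
    the window; smoothing splines fitted separately to the data before and
    after the jump estimate the underlying smooth signal on each side, and
    their gap at the jump is the step size, which is subtracted from the
    post-jump data onward.  Because the step is estimated from the *difference
    of two smooth fits*, a smooth artifact-free trace passes through almost
    unchanged, and a pure level shift is removed exactly.

    ``smoothing`` follows the usual smoothing-spline convention (p close to 1
    follows the data closely).
    """
    y = np.asarray(trace, float)
    t = np.arange(len(y)) / sample_rate_hz
    t0, t1 = artifact_window
    if t1 <= t0:
        raise ValueError("artifact window must have t1 > t0")
    if t0 < 0 or t1 > t[-1]:
        raise ValueError("artifact window outside recording")
    i0, i1 = int(np.ceil(t0 * sample_rate_hz)), int(np.floor(t1 * sample_rate_hz)) + 1
    if i1 - i0 < 2:
        warnings.warn("empty artifact window; trace returned unchanged", stacklevel=2)
        return y.copy()
    w = y[i0:i1]
    m = int(np.argmax(np.abs(np.diff(w)))) + 1  # first sample after the jump
    lam = (1.0 - smoothing) / smoothing
    t_jump = (t[i0 + m - 1] + t[i0 + m]) / 2.0

    def side_value(idx_lo, idx_hi):
        ts, ys = t[idx_lo:idx_hi], y[idx_lo:idx_hi]
        if len(ts) < 4:
            return float(np.mean(ys))
        spl = make_smoothing_spline(ts, ys, lam=lam)
        return float(spl(t_jump))

    # use up to 30 s of context on each side of the jump (within the trace)
    ctx = int(round(30.0 * sample_rate_hz))
    lo = max(0, i0 + m - ctx)
    hi = min(len(y), i0 + m + ctx)
    step = side_value(i0 + m, hi) - side_value(lo, i0 + m)
    out = y.copy()
    out[i0 + m :] -= step
    return out


def detect_step_artifacts(
    intensity: np.ndarray,
    sample_rate_hz: float,
    window_s: float = 5.0,
    threshold: float = 8.0,
) -> list[tuple[float, int]]:
    """Optional moving-variance step detector (off by default in the pipeline).

    Flags (time, channel) pairs where the absolute log-intensity jump exceeds
    ``threshold`` times the channel's median absolute successive difference.
    """
    logi = np.log(np.asarray(intensity, float))
    d = np.abs(np.diff(logi, axis=0))
    med = np.median(d, axis=0) + 1e-12
    hits = []
    for c in range(d.shape[1]):
        idx = np.where(d[:, c] > threshold * med[c])[0]
        for i in idx:
            hits.append(((i + 1) / sample_rate_hz, c))
    return hits


# ---------------------------------------------------------------------------
# Temporal filtering
# ---------------------------------------------------------------------------

def lowpass_dot(series: np.ndarray, sample_rate_hz: float, cutoff_hz: float = 1.0,
                order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the time axis (DC gain 1)."""
    nyq = sample_rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    sos = signal.butter(order, cutoff_hz / nyq, btype="low", output="sos")
    return signal.sosfiltfilt(sos, np.asarray(series, float), axis=0)


def filter_eeg(eeg_trace: np.ndarray, sample_rate_hz: float,
               band_hz: tuple[float, float] = (0.3, 70.0),
               notch_hz: float = 50.0, notch_q: float = 35.0) -> np.ndarray:
    """Clinical EEG filtering: zero-phase band-pass then mains notch."""
    lo, hi = band_hz
    nyq = sample_rate_hz / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    if sample_rate_hz < 256:
        raise ValueError("EEG sample rate must be >= 256 Hz")
    x = np.asarray(eeg_trace, float)
    sos = signal.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    x = signal.sosfiltfilt(sos, x, axis=0)
    b, a = signal.iirnotch(notch_hz / nyq, notch_q)
    return signal.filtfilt(b, a, x, axis=0)


# ---------------------------------------------------------------------------
# Optical density
# ---------------------------------------------------------------------------

def to_optical_density(bundle: RecordingBundle) -> ODSeries:
    """dOD(t, c, l) = -ln(I / mean_t I), per channel and wavelength.

    The reference is each channel's mean intensity over the entire
    acquisition, so dOD is invariant under per-channel rescaling.
    """
    I = bundle.intensity
    bad = I[:, bundle.channel_retained, :] <= 0
    if np.any(bad):
        ch = np.where(bundle.channel_retained)[0][np.unique(np.where(bad)[1])]
        raise ValueError(f"non-positive intensity on retained channel(s) {ch.tolist()}")
    ref = I.mean(axis=0)
    safe = np.where(I > 0, I, np.nan)
    od = -np.log(safe / ref)
    od[:, ~bundle.channel_retained, :] = 0.0  # excluded channels carry no signal
    return ODSeries(
        delta_od=np.nan_to_num(od),
        reference=ref,
        sample_rate_hz=bundle.sample_rate_hz,
        channel_retained=bundle.channel_retained.copy(),
    )


# ---------------------------------------------------------------------------
# Pipeline convenience
# ---------------------------------------------------------------------------

def preprocess_bundle(
    bundle: RecordingBundle,
    artifact_windows: list[tuple[float, float, list[int]]] | None = None,
    min_mean_intensity: float | None = None,
    min_snr: float | None = None,
    lowpass_cutoff_hz: float = 1.0,
) -> tuple[ODSeries, pd.DataFrame]:
    """Full optical chain: prune -> spline-correct -> low-pass -> OD.

    ``artifact_windows`` lists ``(t0, t1, channel_ids)`` windows to correct;
    the correction runs on log-intensity (the step artifact is multiplicative
    in intensity), preserving positivity.
    """
    pruned, report = prune_channels(bundle, min_mean_intensity, min_snr)
    work = pruned.copy()
    for (t0, t1, channels) in artifact_windows or []:
        for c in channels:
            for w in range(work.intensity.shape[2]):
                logi = np.log(work.intensity[:, c, w])
                logi = spline_correct(logi, work.sample_rate_hz, (t0, t1))
                work.intensity[:, c, w] = np.exp(logi)
    work.intensity = np.exp(
        lowpass_dot(np.log(work.intensity), work.sample_rate_hz, lowpass_cutoff_hz)
    )
    return to_optical_density(work), report
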