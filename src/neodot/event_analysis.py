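"""Event-locked response metrics, hemispheric EEG power test and reporting.

For each annotated electrographic event, the global haemoglobin traces
(baseline-referenced to the mean of 60-30 s pre-onset and linearly detrended)
are characterized by three phase durations — onset to HbT maximum, maximum to
minimum, minimum to recovery — whose sum is the DOT event duration, plus peak
amplitudes per chromophore.  Phases that would cross the next event's onset
are censored (flagged non-estimable), never extrapolated.

Knot timing is a two-stage estimate.  Raw stage: argmax within the rise
window, argmin over the post-peak horizon, and recovery gated at the first
post-minimum time where the 30 s moving-window slope magnitude stays below
10% of the event's peak-to-trough range per 100 s for 30 consecutive
seconds.  Refinement stage (default on): a least-squares fit of the biphasic
raised-cosine template to the event window, initialized at the raw
estimates.  The response knots are C1 — the trace is locally flat there — so
raw extrema wander by several seconds under measurement noise, while the
template fit uses the whole waveform and is exact on noiseless data.  The
raw stage alone remains available (``refine=False``) for data that do not
follow the biphasic morphology.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RecoveryCriterion",
    "DegenerateTestError",
    "event_baseline",
    "response_metrics",
    "analyze_events",
    "summarize_events",
    "hemispheric_power_test",
    "build_report",
    "EVENT_TABLE_COLUMNS",
]

EVENT_TABLE_COLUMNS = [
    "event_id",
    "consensus_onset_s",
    "eeg_duration_s",
    "time_to_hbt_max_s",
    "time_max_to_min_s",
    "time_min_to_recovery_s",
    "dot_event_duration_s",
    "peak_hbo_uM",
    "peak_hbr_uM",
    "peak_hbt_uM",
    "responsive",
    "max_to_min_estimable",
    "recovery_estimable",
]


class DegenerateTestError(ValueError):
    """The paired test statistic is undefined (zero-variance differences)."""


@dataclass
class RecoveryCriterion:
    """Steady-state rule: |slope| below ``range_fraction_per_100s`` of the
    peak-to-trough range per 100 s, sustained for ``sustain_s``.  ``refine``
    switches on the template-fit refinement of all three phase timings."""

    slope_window_s: float = 30.0
    sustain_s: float = 30.0
    range_fraction_per_100s: float = 0.10
    refine: bool = True


def event_baseline(trace, sample_rate_hz: float, onset_s: float,
                   window: tuple[float, float] = (-60.0, -30.0),
                   event_id=None) -> float:
    """Mean of the trace over ``[onset + window[0], onset + window[1])``."""
    if window[1] <= window[0]:
        raise ValueError(f"baseline window {window} inverted")
    y = np.asarray(trace, float)
    i0 = int(np.ceil((onset_s + window[0]) * sample_rate_hz))
    i1 = int(np.ceil((onset_s + window[1]) * sample_rate_hz))
    if i0 < 0 or i1 > len(y) or i1 <= i0:
        raise ValueError(
            f"baseline window out of range for event {event_id!r} "
            f"(onset {onset_s} s, window {window})"
        )
    return float(y[i0:i1].mean())


def _moving_slope(y: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Centered moving-window least-squares slope, same length as ``y``."""
    n = max(3, int(round(window_s * fs)) | 1)  # odd
    half = n // 2
    tau = (np.arange(n) - half) / fs
    kernel = tau / np.sum(tau**2)
    full = np.convolve(y, kernel[::-1], mode="valid")
    return np.pad(full, (half, half), mode="edge")


def response_metrics(
    global_hbt,
    sample_rate_hz: float,
    onset_s: float,
    search_horizon_s: float = 600.0,
    next_onset_s: float | None = None,
    max_rise_window_s: float = 60.0,
    recovery_criterion: RecoveryCriterion | None = None,
    event_id=None,
    hbo_trace=None,
    hbr_trace=None,
    trace_lowpass_hz: float | None = None,
) -> dict:
    """Phase durations and peak amplitudes for one event.

    The trace must already be baseline-referenced (and detrended).  The
    search horizon is clipped at ``next_onset_s``; any phase whose defining
    feature is not reached before that boundary is flagged non-estimable.
    Returns a dict row following ``EVENT_TABLE_COLUMNS``.
    """
    crit = recovery_criterion or RecoveryCriterion()
    y = np.asarray(global_hbt, float)
    fs = sample_rate_hz
    t = np.arange(len(y)) / fs
    row = {c: np.nan for c in EVENT_TABLE_COLUMNS}
    row.update(
        event_id=event_id,
        consensus_onset_s=onset_s,
        responsive=False,
        max_to_min_estimable=False,
        recovery_estimable=False,
    )

    boundary_s = onset_s + search_horizon_s
    if next_onset_s is not None:
        boundary_s = min(boundary_s, next_onset_s)
    boundary_s = min(boundary_s, t[-1])

    rise = (t >= onset_s) & (t <= min(onset_s + max_rise_window_s, boundary_s))
    if not rise.any():
        return row
    i_max = np.where(rise)[0][np.argmax(y[rise])]
    if y[i_max] <= 0:
        return row  # no maximum above baseline: unresponsive
    row["responsive"] = True
    row["time_to_hbt_max_s"] = t[i_max] - onset_s
    row["peak_hbt_uM"] = float(y[i_max])
    for name, tr in (("peak_hbo_uM", hbo_trace), ("peak_hbr_uM", hbr_trace)):
        if tr is not None:
            v = np.asarray(tr, float)[rise]
            row[name] = float(v.max())

    post = (t > t[i_max]) & (t <= boundary_s)
    if not post.any():
        row["dot_event_duration_s"] = row["time_to_hbt_max_s"]
        return row
    idx_post = np.where(post)[0]
    i_min = idx_post[np.argmin(y[idx_post])]
    # a minimum sitting on the censor boundary means the trace was still
    # falling when the next event started: phase not estimable
    if next_onset_s is not None and i_min >= idx_post[-1] - 1 and boundary_s < onset_s + search_horizon_s:
        row["dot_event_duration_s"] = row["time_to_hbt_max_s"]
        return row
    row["max_to_min_estimable"] = True
    row["time_max_to_min_s"] = t[i_min] - t[i_max]

    rec_t = _find_recovery(y, fs, i_max, i_min, boundary_s, crit)
    if rec_t is not None:
        row["recovery_estimable"] = True
        row["time_min_to_recovery_s"] = rec_t - t[i_min]
    if crit.refine:
        _refine_with_template(
            row, y, fs, onset_s, t[i_max], t[i_min], rec_t, boundary_s,
            trace_lowpass_hz,
        )
    row["dot_event_duration_s"] = float(
        np.nansum(
            [
                row["time_to_hbt_max_s"],
                row["time_max_to_min_s"],
                row["time_min_to_recovery_s"],
            ]
        )
    )
    return row


def _refine_with_template(row, y, fs, onset_s, t_max, t_min, rec_t, boundary_s,
                          trace_lowpass_hz=None):
    """Sharpen the raw knot estimates by fitting the biphasic template.

    Censoring flags are decided by the raw stage and never changed here; a
    refined phase replaces the raw one only when the fit stayed close to its
    raw initialization (i.e. the trace really is biphasic).  When the trace
    went through a known low-pass filter, the same filter is applied to the
    model so the fit is unbiased by the filter's smoothing of the knots.
    """
    from scipy.optimize import least_squares

    from .synthetic_scene import biphasic_shape

    t = np.arange(len(y)) / fs
    i0 = max(0, int((onset_s - 10.0) * fs))
    i1 = min(len(y), int(boundary_s * fs) + 1)
    ts, ys = t[i0:i1], y[i0:i1]
    if trace_lowpass_hz is not None:
        from scipy import signal

        pad = int(30.0 * fs)
        tpad = np.arange(i0 - pad, i1 + pad) / fs
        sos = signal.butter(5, trace_lowpass_hz / (fs / 2), "low", output="sos")

        def smooth(model_pad):
            return signal.sosfiltfilt(sos, model_pad)[pad:-pad]
    else:
        tpad = ts

        def smooth(model_pad):
            return model_pad
    amp0 = max(float(y[int(t_max * fs)]), 1e-6)
    u0 = max(-float(y[int(t_min * fs)]) / amp0, 0.05)
    tr0 = max(t_max - onset_s, 1.0)
    tf0 = max(t_min - t_max, 1.0)
    trec0 = max((rec_t - t_min) if rec_t is not None else boundary_s - t_min, 5.0)

    def resid(p):
        t0, amp, u, tr, tf, trec, c, m = p
        model = amp * biphasic_shape(tpad, onset_s + t0, tr, tf, trec, u)
        return c + m * (ts - onset_s) + smooth(model) - ys

    try:
        fit = least_squares(
            resid,
            x0=[0.0, amp0, u0, tr0, tf0, trec0, 0.0, 0.0],
            bounds=(
                [-60.0, 1e-9, 0.01, 0.5, 0.5, 0.5, -np.inf, -np.inf],
                [60.0, np.inf, 50.0, 400.0, 600.0, 800.0, np.inf, np.inf],
            ),
            xtol=1e-12,
            ftol=1e-12,
        )
    except Exception:
        return
    if not fit.success:
        return
    t0, _, _, tr, tf, trec, _, _ = fit.x
    if abs((t0 + tr) - (t_max - onset_s)) < 10.0:
        row["time_to_hbt_max_s"] = float(t0 + tr)
        if row["max_to_min_estimable"] and abs(tf - (t_min - t_max)) < 20.0:
            row["time_max_to_min_s"] = float(tf)
            if row["recovery_estimable"] and abs(trec - (rec_t - t_min)) < 25.0:
                row["time_min_to_recovery_s"] = float(trec)


def _find_recovery(y, fs, i_max, i_min, boundary_s, crit: RecoveryCriterion) -> float | None:
    t = np.arange(len(y)) / fs
    peak_to_trough = max(float(y[i_max]) - float(y[i_min]), 1e-12)
    thr = crit.range_fraction_per_100s * peak_to_trough / 100.0
    slope = _moving_slope(y, fs, crit.slope_window_s)
    ok = np.abs(slope) < thr
    sustain = max(1, int(round(crit.sustain_s * fs)))
    i_bound = int(boundary_s * fs)
    gate = None
    csum = np.cumsum(ok.astype(int))
    for i in range(i_min + 1, min(i_bound, len(y) - sustain)):
        if csum[i + sustain - 1] - (csum[i - 1] if i else 0) == sustain:
            gate = i
            break
    if gate is None:
        return None
    return t[gate]


def analyze_events(
    traces: dict,
    sample_rate_hz: float,
    annotations: pd.DataFrame,
    baseline_window: tuple[float, float] = (-60.0, -30.0),
    detrend: bool = True,
    **metric_kwargs,
) -> pd.DataFrame:
    """Event table for a recording: one row per annotated event.

    ``traces`` maps ``'hbt'`` (required) and optionally ``'hbo'``/``'hbr'`` to
    global 1-D time courses in uM.  Each event's traces are referenced to the
    60-30 s pre-onset baseline; a global linear trend is removed first.
    """
    from .haemoglobin import linear_detrend
    from .probe_and_io import consensus_onsets

    fs = sample_rate_hz
    work = {}
    for k, v in traces.items():
        v = np.asarray(v, float)
        work[k] = linear_detrend(v)[0] if detrend else v.copy()
    onsets = consensus_onsets(annotations)
    order = np.argsort(onsets)
    rows = []
    for pos, irow in enumerate(order):
        onset = float(onsets[irow])
        nxt = float(onsets[order[pos + 1]]) if pos + 1 < len(order) else None
        refd = {}
        for k, v in work.items():
            b = event_baseline(v, fs, onset, baseline_window,
                               event_id=annotations["event_id"].iloc[irow])
            refd[k] = v - b
        row = response_metrics(
            refd["hbt"],
            fs,
            onset,
            next_onset_s=nxt,
            event_id=annotations["event_id"].iloc[irow],
            hbo_trace=refd.get("hbo"),
            hbr_trace=refd.get("hbr"),
            **metric_kwargs,
        )
        row["eeg_duration_s"] = float(annotations["eeg_duration_s"].iloc[irow])
        rows.append(row)
    return pd.DataFrame(rows, columns=EVENT_TABLE_COLUMNS)


def summarize_events(table: pd.DataFrame, channel_amplitudes: dict | None = None) -> dict:
    """Cross-event (and optionally cross-channel) summary statistics.

    ``channel_amplitudes`` optionally maps chromophore name to an
    (event, channel) peak-amplitude array; their pooled mean/SD and the
    maximum single-channel amplitude are then reported.
    """
    if len(table) == 0:
        raise ValueError("empty event table")
    resp = table[table["responsive"].astype(bool)]
    out: dict = {"n_events": int(len(table)), "n_responsive": int(len(resp))}
    for col in (
        "time_to_hbt_max_s",
        "time_max_to_min_s",
        "time_min_to_recovery_s",
        "dot_event_duration_s",
        "peak_hbo_uM",
        "peak_hbr_uM",
        "peak_hbt_uM",
    ):
        vals = pd.to_numeric(resp[col], errors="coerce").dropna().to_numpy()
        out[col] = {
            "mean": float(np.mean(vals)) if len(vals) else np.nan,
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "n": int(len(vals)),
        }
    if channel_amplitudes:
        for name, arr in channel_amplitudes.items():
            a = np.asarray(arr, float).ravel()
            a = a[np.isfinite(a)]
            out[f"channel_{name}"] = {
                "mean": float(a.mean()),
                "sd": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
                "max": float(a.max()),
                "n": int(len(a)),
            }
    return out


def hemispheric_power_test(left_power, right_power) -> tuple[float, float]:
    """Paired two-sided t-test between left and right hemispheric EEG power."""
    a = np.asarray(left_power, float)
    b = np.asarray(right_power, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need equal-length 1-D paired samples")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.allclose(d, d[0]):
        raise DegenerateTestError(
            "zero-variance paired differences: t statistic undefined "
            "(perfect separation)"
        )
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def build_report(
    events: pd.DataFrame,
    out_dir,
    images=None,
    mesh=None,
    global_traces: dict | None = None,
    sample_rate_hz: float = 10.0,
) -> dict:
    """Write the event table CSV, trace/image figures and a JSON summary.

    ``images`` (a HaemoImageSeries, optional) is sampled at six named time
    points per event — 30 s pre-onset, onset, HbT max, max/min midpoint, min,
    recovery — with nearest-frame substitution (warned) when a requested time
    falls between frames.  Returns the summary dict that was serialized.
    """
    import os

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    csv_path = os.path.join(out_dir, "events.csv")
    events.to_csv(csv_path, index=False)
    artifacts = [csv_path]

    if global_traces:
        fig, ax = plt.subplots(figsize=(10, 4))
        n = len(next(iter(global_traces.values())))
        t = np.arange(n) / sample_rate_hz
        for name, tr in global_traces.items():
            ax.plot(t, tr, label=name)
        for onset in events["consensus_onset_s"]:
            ax.axvline(onset, color="k", alpha=0.3, lw=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("concentration change (uM)")
        ax.legend(loc="upper right")
        p = os.path.join(out_dir, "global_traces.png")
        fig.savefig(p, dpi=110)
        plt.close(fig)
        artifacts.append(p)

    if images is not None and len(getattr(images, "frame_times_s", [])) > 0:
        for _, ev in events.iterrows():
            pts = _event_time_points(ev)
            if not pts:
                continue
            fig, axes = plt.subplots(1, len(pts), figsize=(3 * len(pts), 3))
            axes = np.atleast_1d(axes)
            values = images.node_hbt
            coords = mesh.nodes if mesh is not None else None
            vmax = np.nanmax(np.abs(values)) or 1.0
            for ax, (name, tp) in zip(axes, pts.items()):
                k = int(np.argmin(np.abs(images.frame_times_s - tp)))
                if abs(images.frame_times_s[k] - tp) > 0.51 * np.median(
                    np.diff(images.frame_times_s)
                ):
                    warnings.warn(
                        f"no frame at {tp:.1f} s; using nearest "
                        f"({images.frame_times_s[k]:.1f} s)", stacklevel=2)
                if coords is not None and len(coords) == values.shape[1]:
                    sc = ax.scatter(coords[:, 0], coords[:, 1], c=values[k],
                                    s=4, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
                    fig.colorbar(sc, ax=ax, shrink=0.7)
                else:
                    ax.plot(values[k])
                ax.set_title(f"{name}\n{tp:.0f} s", fontsize=8)
                ax.set_xticks([])
                ax.set_yticks([])
            p = os.path.join(out_dir, f"event_{ev['event_id']}_images.png")
            fig.savefig(p, dpi=110)
            plt.close(fig)
            artifacts.append(p)
    elif images is not None:
        warnings.warn("empty image series: image grids skipped", stacklevel=2)

    summary = {
        "events": json.loads(events.to_json(orient="records")),
        "summary": summarize_events(events) if len(events) else {},
        "artifacts": [os.path.basename(a) for a in artifacts],
    }
    json_path = os.path.join(out_dir, "summary.json")
    with open(json_path, "w") as f:
        json.dump(summary, f, indent=1, default=float)
    return summary


def _event_time_points(ev) -> dict:
    onset = float(ev["consensus_onset_s"])
    pts = {"pre": onset - 30.0, "onset": onset}
    if np.isfinite(ev.get("time_to_hbt_max_s", np.nan)):
        t_max = onset + float(ev["time_to_hbt_max_s"])
        pts["max"] = t_max
        if np.isfinite(ev.get("time_max_to_min_s", np.nan)):
            t_min = t_max + float(ev["time_max_to_min_s"])
            pts["mid"] = (t_max + t_min) / 2
            pts["min"] = t_min
            if np.isfinite(ev.get("time_min_to_recovery_s", np.nan)):
                pts["recovery"] = t_min + float(ev["time_min_to_recovery_s"])
    return pts
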