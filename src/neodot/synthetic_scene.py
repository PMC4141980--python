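"""Ground-truth seizure haemodynamics and realistic dual-wavelength rendering.

A *scene* is a schedule of electrographic events, a biphasic haemodynamic
response template (raised-cosine segments with exact knot timings: rise to a
peak increase, fall to an undershoot larger than the peak, recovery to
steady state), a spatial pattern (cortical node weights, or per-channel
weights for channel-space scenes), and a nuisance model (linear drift,
cardiac pulsation, multiplicative intensity noise, a step artifact and dead
channels).

Rendering inverts the measurement chain used in analysis: concentrations →
dOD (via the same stacked multispectral Jacobian convention used in
reconstruction, or via the channel-wise MBLL when no Jacobian is given) →
intensities ``baseline * exp(-dOD) * noise``.  Ground truth is stored in the
bundle's ``truth`` group so recovery tests never re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .haemoglobin import mbll_forward
from .probe_and_io import ProbeGeometry, RecordingBundle, consensus_onsets

__all__ = [
    "BiphasicResponseParams",
    "SpatialPattern",
    "NuisanceModel",
    "Scene",
    "biphasic_shape",
    "make_response_waveform",
    "make_event_schedule",
    "default_event_schedule",
    "default_scene",
    "render_intensities",
    "align_annotations",
    "make_hemispheric_power",
    "SYNC_PULSE_PATTERN",
]

# Aperiodic pulse pattern injected into both instruments (distinct consecutive
# intervals make the pairing between the two streams unambiguous).
SYNC_PULSE_PATTERN = np.array([12.0, 25.0, 46.0, 80.0, 88.0, 117.0, 134.0])


@dataclass
class BiphasicResponseParams:
    """Knot-parameterized biphasic response; amplitudes in uM.

    HbT parameters are always derived as HbO + HbR, never stored.
    ``undershoot_scale`` is the trough magnitude as a multiple of the peak
    (> 1 means the undershoot exceeds the initial increase).
    ``pre_onset_lead_s`` shifts the haemodynamic rise ahead of the
    electrographic onset.
    """

    onset_s: float
    amplitude_hbo_uM: float = 1.7
    amplitude_hbr_uM: float = 1.0
    undershoot_scale: float = 1.5
    t_rise_s: float = 12.5
    t_fall_s: float = 116.0
    t_recover_s: float = 123.0
    pre_onset_lead_s: float = 0.0

    def __post_init__(self) -> None:
        if min(self.t_rise_s, self.t_fall_s, self.t_recover_s) <= 0:
            raise ValueError("all response durations must be > 0")
        if self.pre_onset_lead_s < 0:
            raise ValueError("pre_onset_lead_s must be >= 0")
        for a in (self.amplitude_hbo_uM, self.amplitude_hbr_uM, self.undershoot_scale):
            if not np.isfinite(a):
                raise ValueError("amplitudes must be finite")

    @property
    def total_duration_s(self) -> float:
        return self.t_rise_s + self.t_fall_s + self.t_recover_s


@dataclass
class SpatialPattern:
    """Cortical weight map: a focal positive region and a negative surround.

    Weights are normalized to peak magnitude 1; the two regions are disjoint.
    """

    focal_nodes: np.ndarray
    focal_weights: np.ndarray
    surround_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    surround_weights: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.focal_nodes = np.asarray(self.focal_nodes, int)
        self.surround_nodes = np.asarray(self.surround_nodes, int)
        self.focal_weights = np.asarray(self.focal_weights, float)
        self.surround_weights = np.asarray(self.surround_weights, float)
        if np.intersect1d(self.focal_nodes, self.surround_nodes).size:
            raise ValueError("focal and surround regions must be disjoint")
        if np.any(self.focal_weights < 0) or np.any(self.surround_weights > 0):
            raise ValueError("focal weights must be >= 0, surround weights <= 0")
        peak = max(
            self.focal_weights.max(initial=0.0),
            np.abs(self.surround_weights).max(initial=0.0),
        )
        if peak > 0:
            self.focal_weights = self.focal_weights / peak
            self.surround_weights = self.surround_weights / peak

    def node_vector(self, n_nodes: int) -> np.ndarray:
        v = np.zeros(n_nodes)
        v[self.focal_nodes] = self.focal_weights
        v[self.surround_nodes] = self.surround_weights
        return v


@dataclass
class NuisanceModel:
    """Physiological and instrumental nuisance terms added at render time."""

    drift_slope_uM_per_s: float = 0.001
    cardiac_freq_hz: float = 2.5
    cardiac_amplitude_uM: float = 0.2
    noise_sd: float = 0.01
    step_time_s: float | None = None
    step_channels: tuple = ()
    step_log_size: float = 0.2
    dead_channels: tuple = ()

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Scene:
    """Everything needed to render one synthetic recording."""

    schedule: pd.DataFrame
    response: BiphasicResponseParams
    nuisance: NuisanceModel = field(default_factory=NuisanceModel)
    pattern: SpatialPattern | None = None
    channel_weights: np.ndarray | None = None
    baseline_intensity: float = 1.0
    eeg_clock_offset_s: float = 3.2
    duration_s: float = 3600.0
    sample_rate_hz: float = 10.0


def make_response_waveform(params: BiphasicResponseParams, time_axis: np.ndarray) -> dict:
    """Evaluate the biphasic response on a uniform time axis.

    Returns ``{'hbo': ..., 'hbr': ...}`` concentration courses (uM).  Each is
    zero before ``onset - lead``, rises along a raised cosine to its peak
    amplitude over ``t_rise``, falls to ``-undershoot_scale * amplitude`` over
    ``t_fall`` and recovers to zero over ``t_recover``; the raised-cosine
    segments have zero slope at every knot, so the waveform is C1 and its
    argmax/argmin sit exactly at the programmed knots.
    """
    t = np.asarray(time_axis, float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("need a 1-D time axis with >= 2 samples")
    dt = np.diff(t)
    if np.max(np.abs(dt - dt[0])) > 1e-9 * dt[0]:
        raise ValueError("time axis must be uniform")
    start = params.onset_s - params.pre_onset_lead_s
    if t[0] > params.onset_s - 120.0 or t[-1] < start + params.total_duration_s + 60.0:
        raise ValueError(
            "time axis too short: must cover onset - 120 s to onset + response "
            f"duration + 60 s (got [{t[0]}, {t[-1]}] for onset {params.onset_s})"
        )
    base = biphasic_shape(
        t, start, params.t_rise_s, params.t_fall_s, params.t_recover_s,
        params.undershoot_scale,
    )
    return {"hbo": params.amplitude_hbo_uM * base, "hbr": params.amplitude_hbr_uM * base}


def biphasic_shape(t, start, t_rise, t_fall, t_recover, undershoot) -> np.ndarray:
    """Unit-amplitude biphasic template (peak +1, trough ``-undershoot``).

    Raised-cosine segments with zero slope at every knot; zero outside
    ``[start, start + t_rise + t_fall + t_recover]``.
    """
    tau = np.asarray(t, float) - start
    u = undershoot
    w = np.zeros_like(tau)
    s = tau / t_rise
    m = (s >= 0) & (s < 1)
    w[m] = 0.5 * (1 - np.cos(np.pi * s[m]))
    s = (tau - t_rise) / t_fall
    m = (s >= 0) & (s < 1)
    w[m] = 1.0 - (1 + u) * 0.5 * (1 - np.cos(np.pi * s[m]))
    s = (tau - t_rise - t_fall) / t_recover
    m = (s >= 0) & (s < 1)
    w[m] = -u * 0.5 * (1 + np.cos(np.pi * s[m]))
    return w


# ---------------------------------------------------------------------------
# Event schedules
# ---------------------------------------------------------------------------

def make_event_schedule(
    n_events: int,
    spacing_stats: tuple[float, float] = (440.0, 150.0),
    seed: int = 0,
    start_s: float = 150.0,
    duration_range_s: tuple[float, float] = (30.0, 90.0),
    disagreement_range_s: tuple[float, float] = (0.0, 13.0),
    non_overlap: bool = True,
) -> pd.DataFrame:
    """Draw a reproducible annotation table with two annotator onsets per event.

    Gaps between consensus onsets are normal with the given mean/SD (floored
    at 30 s); the two annotators disagree by a uniform 0-13 s draw, split
    symmetrically around the consensus; EEG durations are uniform in
    ``duration_range_s``.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    gaps = np.maximum(30.0, rng.normal(*spacing_stats, size=n_events - 1))
    onsets = start_s + np.concatenate([[0.0], np.cumsum(gaps)])
    durations = rng.uniform(*duration_range_s, size=n_events)
    if non_overlap and np.any(onsets[1:] < onsets[:-1] + durations[:-1]):
        raise ValueError("overlapping EEG events drawn with non_overlap=True")
    dis = rng.uniform(*disagreement_range_s, size=n_events)
    return pd.DataFrame(
        {
            "event_id": np.arange(1, n_events + 1),
            "am_onset_s": onsets - dis / 2,
            "dh_onset_s": onsets + dis / 2,
            "eeg_duration_s": durations,
            "label": ["seizure"] * n_events,
        }
    )


def default_event_schedule() -> pd.DataFrame:
    """The reference seven-event schedule (times in s on the optical clock).

    Event 6 was marked by a single annotator, as happens in clinical practice.
    """
    return pd.DataFrame(
        {
            "event_id": [1, 2, 3, 4, 5, 6, 7],
            "am_onset_s": [136.0, 692.0, 1442.0, 1920.0, 2384.0, 2539.0, 2780.0],
            "dh_onset_s": [141.0, 694.0, 1443.0, 1923.0, 2386.0, np.nan, 2793.0],
            "eeg_duration_s": [85.0, 57.0, 69.0, 54.0, 75.0, 32.0, 60.0],
            "label": ["seizure"] * 7,
        }
    )


def default_scene(seed: int = 0) -> Scene:
    """The reference scene: 7 events at the reference spacings, biphasic
    response on all channels, drift + cardiac + 1% noise, a step artifact on
    5 channels mid-recording and 4 dead channels."""
    rng = np.random.default_rng(seed)
    step_channels = tuple(int(c) for c in rng.choice(58, size=5, replace=False))
    remaining = [c for c in range(58) if c not in step_channels]
    dead = tuple(int(c) for c in rng.choice(remaining, size=4, replace=False))
    return Scene(
        schedule=default_event_schedule(),
        response=BiphasicResponseParams(onset_s=0.0),
        nuisance=NuisanceModel(
            step_time_s=1080.0, step_channels=step_channels, dead_channels=dead
        ),
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _scene_waveforms(scene: Scene, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    onsets = consensus_onsets(scene.schedule)
    w_hbo = np.zeros_like(t)
    w_hbr = np.zeros_like(t)
    for onset in onsets:
        p = replace(scene.response, onset_s=float(onset))
        w = make_response_waveform(p, t)
        w_hbo += w["hbo"]
        w_hbr += w["hbr"]
    return w_hbo, w_hbr


def render_intensities(
    scene: Scene,
    probe: ProbeGeometry,
    mesh=None,
    jac=None,
    seed: int = 0,
) -> RecordingBundle:
    """Render a scene into a synchronized dual-wavelength recording bundle.

    With ``jac`` — the stacked multispectral matrix from
    ``stack_multispectral`` — cortical patterns are mapped to channel dOD by
    the same linear operator the reconstruction inverts.  Without it
    (``jac=None``) the scene's per-channel weights are rendered through the
    channel-wise MBLL.  Identical seeds give bit-identical bundles.
    """
    fs = scene.sample_rate_hz
    nt = int(round(scene.duration_s * fs))
    t = np.arange(nt) / fs
    nch = probe.n_channels
    nwl = len(probe.wavelengths)
    rng = np.random.default_rng(seed)
    nui = scene.nuisance

    w_hbo, w_hbr = _scene_waveforms(scene, t)

    if jac is not None:
        S = np.asarray(jac, float)
        if S.shape[0] != nwl * nch:
            raise ValueError(
                f"stacked Jacobian has {S.shape[0]} rows, probe implies {nwl * nch}"
            )
        if scene.pattern is None:
            raise ValueError("Jacobian-space rendering needs scene.pattern")
        n_nodes = S.shape[1] // 2
        p = scene.pattern.node_vector(n_nodes)
        a_hbo = S @ np.concatenate([p, np.zeros(n_nodes)])  # dOD per unit dHbO
        a_hbr = S @ np.concatenate([np.zeros(n_nodes), p])
        od_stack = np.outer(w_hbo, a_hbo) + np.outer(w_hbr, a_hbr)
        od = np.stack(
            [od_stack[:, w * nch : (w + 1) * nch] for w in range(nwl)], axis=2
        )
        clean_hbo = clean_hbr = None
    else:
        cw = (
            np.ones(nch)
            if scene.channel_weights is None
            else np.asarray(scene.channel_weights, float)
        )
        if len(cw) != nch:
            raise ValueError("channel_weights length does not match probe channels")
        clean_hbo = np.outer(w_hbo, cw)
        clean_hbr = np.outer(w_hbr, cw)
        od = mbll_forward(
            clean_hbo, clean_hbr, probe.separations(), probe.wavelengths
        )

    # physiological nuisances, expressed as channel-space concentrations (uM)
    drift = nui.drift_slope_uM_per_s * (t - t.mean())
    cardiac = nui.cardiac_amplitude_uM * np.sin(2 * np.pi * nui.cardiac_freq_hz * t)
    phys = np.broadcast_to(((drift + cardiac) / 2.0)[:, None], (nt, nch))
    od = od + mbll_forward(phys, phys, probe.separations(), probe.wavelengths)

    intensity = scene.baseline_intensity * np.exp(-od)
    if nui.step_time_s is not None and nui.step_channels:
        if not 0 <= nui.step_time_s < scene.duration_s:
            raise ValueError("step artifact time outside recording")
        i0 = int(round(nui.step_time_s * fs))
        intensity[i0:, list(nui.step_channels), :] *= np.exp(-nui.step_log_size)
    retained = np.ones(nch, bool)
    reasons = [""] * nch
    for c in nui.dead_channels:
        # noise floor: tiny strictly positive values uncorrelated with signal
        intensity[:, c, :] = 1e-4 * scene.baseline_intensity * np.exp(
            0.5 * rng.standard_normal((nt, nwl))
        )
        retained[c] = False
        reasons[c] = "dead"
    if nui.noise_sd > 0:
        intensity = intensity * np.exp(
            nui.noise_sd * rng.standard_normal(intensity.shape)
        )

    onsets_dot = consensus_onsets(scene.schedule)
    annotations = scene.schedule.copy()
    for col in ("am_onset_s", "dh_onset_s"):
        annotations[col] = annotations[col] + scene.eeg_clock_offset_s

    truth: dict = {
        "waveform_hbo": w_hbo,
        "waveform_hbr": w_hbr,
        "consensus_onsets_s": onsets_dot,
        "eeg_clock_offset_s": np.float64(scene.eeg_clock_offset_s),
        "response": {
            "amplitude_hbo_uM": scene.response.amplitude_hbo_uM,
            "amplitude_hbr_uM": scene.response.amplitude_hbr_uM,
            "undershoot_scale": scene.response.undershoot_scale,
            "t_rise_s": scene.response.t_rise_s,
            "t_fall_s": scene.response.t_fall_s,
            "t_recover_s": scene.response.t_recover_s,
            "pre_onset_lead_s": scene.response.pre_onset_lead_s,
        },
        "nuisance": {
            "drift_slope_uM_per_s": nui.drift_slope_uM_per_s,
            "cardiac_freq_hz": nui.cardiac_freq_hz,
            "cardiac_amplitude_uM": nui.cardiac_amplitude_uM,
            "noise_sd": nui.noise_sd,
            "step_time_s": np.nan if nui.step_time_s is None else nui.step_time_s,
            "step_channels": np.asarray(nui.step_channels, int),
            "step_log_size": nui.step_log_size,
            "dead_channels": np.asarray(nui.dead_channels, int),
        },
    }
    if clean_hbo is not None:
        truth["channel_weights"] = (
            np.ones(nch) if scene.channel_weights is None
            else np.asarray(scene.channel_weights, float)
        )
    if scene.pattern is not None:
        truth["pattern"] = {
            "focal_nodes": scene.pattern.focal_nodes,
            "focal_weights": scene.pattern.focal_weights,
            "surround_nodes": scene.pattern.surround_nodes,
            "surround_weights": scene.pattern.surround_weights,
        }

    return RecordingBundle(
        intensity=intensity,
        sample_rate_hz=fs,
        probe=probe,
        eeg_annotations=annotations,
        sync_pulses_dot=SYNC_PULSE_PATTERN.copy(),
        sync_pulses_eeg=SYNC_PULSE_PATTERN + scene.eeg_clock_offset_s,
        channel_retained=retained,
        channel_quality_reason=reasons,
        truth=truth,
    )


def align_annotations(bundle: RecordingBundle) -> pd.DataFrame:
    """Express the EEG-side annotations on the optical clock using the shared
    synchronization pulses.  Returns a corrected copy of the table."""
    from .probe_and_io import align_clocks

    offset, _ = align_clocks(bundle.sync_pulses_eeg, bundle.sync_pulses_dot)
    out = bundle.eeg_annotations.copy()
    for col in ("am_onset_s", "dh_onset_s"):
        out[col] = out[col] + offset
    return out


def make_hemispheric_power(
    n_channels: int = 6,
    base_power: float = 100.0,
    effect: float = 0.0,
    noise_sd: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired left/right per-channel EEG band power fixture for the t-test."""
    rng = np.random.default_rng(seed)
    common = base_power + rng.normal(0, noise_sd, n_channels)
    left = common + rng.normal(0, noise_sd, n_channels)
    right = common + effect + rng.normal(0, noise_sd, n_channels)
    return np.abs(left), np.abs(right)
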