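"""Probe geometry, synchronized recordings, container I/O and clock alignment.

The optical acquisition modelled here is a continuous-wave, whole-scalp array:
16 dual-wavelength (780/850 nm) laser-diode sources and 16 detectors coupled
to a soft cap, giving 58 usable source-detector channels at 20-40 mm
separations, sampled at 10 Hz.  EEG is recorded by a separate clinical system;
the two instruments share a pattern of synchronization pulses injected into
both data streams, from which a clock offset is recovered.

Recordings travel as :class:`RecordingBundle` objects and are serialized to an
HDF5 container whose tree mirrors SNIRF naming where practical (intensities
under ``nirs/data1``, geometry under ``nirs/probe``), so that real SNIRF files
can be adapted by a thin mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ProbeGeometry",
    "RecordingBundle",
    "BundleFormatError",
    "BundleValidationError",
    "ClockAlignmentError",
    "read_bundle",
    "write_bundle",
    "read_event_table",
    "write_event_table",
    "align_clocks",
    "consensus_onset",
    "consensus_onsets",
]


class BundleFormatError(ValueError):
    """A container is missing a required dataset or has the wrong layout."""


class BundleValidationError(ValueError):
    """A bundle's contents violate an invariant (e.g. negative intensity)."""


class ClockAlignmentError(RuntimeError):
    """No consistent (or a non-unique) pulse pairing could be found."""


# ---------------------------------------------------------------------------
# Probe geometry
# ---------------------------------------------------------------------------

@dataclass
class ProbeGeometry:
    """Optode layout in a common scalp frame (mm).

    Parameters
    ----------
    source_positions, detector_positions
        ``(n, 3)`` arrays of positions in mm.
    channel_list
        Ordered ``(source_id, detector_id)`` integer pairs (0-based).
    wavelengths
        Illumination wavelengths in nm (distinct, positive).
    landmark_positions
        Optional named fiducials (nasion, inion, preauricular points).
    """

    source_positions: np.ndarray
    detector_positions: np.ndarray
    channel_list: np.ndarray
    wavelengths: np.ndarray
    landmark_positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.source_positions = np.atleast_2d(np.asarray(self.source_positions, float))
        self.detector_positions = np.atleast_2d(np.asarray(self.detector_positions, float))
        self.channel_list = np.atleast_2d(np.asarray(self.channel_list, int))
        self.wavelengths = np.asarray(self.wavelengths, float)
        if self.channel_list.size and (
            self.channel_list[:, 0].max() >= len(self.source_positions)
            or self.channel_list[:, 1].max() >= len(self.detector_positions)
            or self.channel_list.min() < 0
        ):
            raise BundleValidationError("channel references a non-existent optode id")
        if len(np.unique(self.wavelengths)) != len(self.wavelengths) or np.any(
            self.wavelengths <= 0
        ):
            raise BundleValidationError("wavelengths must be distinct and positive")
        if np.any(self.separations() <= 0):
            raise BundleValidationError("source-detector separation must be > 0")

    @property
    def n_sources(self) -> int:
        return len(self.source_positions)

    @property
    def n_detectors(self) -> int:
        return len(self.detector_positions)

    @property
    def n_channels(self) -> int:
        return len(self.channel_list)

    def separations(self) -> np.ndarray:
        """Per-channel geometric source-detector distance (mm)."""
        s = self.source_positions[self.channel_list[:, 0]]
        d = self.detector_positions[self.channel_list[:, 1]]
        return np.linalg.norm(s - d, axis=1)


# ---------------------------------------------------------------------------
# Recording bundle
# ---------------------------------------------------------------------------

@dataclass
class RecordingBundle:
    """A synchronized dual-wavelength recording plus its EEG-side annotations.

    ``intensity`` has shape ``(time, channel, wavelength)`` in arbitrary
    detector units; retained channels must be strictly positive.  Annotation
    onsets are expressed on the optical clock once alignment has been applied.
    """

    intensity: np.ndarray
    sample_rate_hz: float
    probe: ProbeGeometry
    eeg_annotations: pd.DataFrame
    sync_pulses_dot: np.ndarray = field(default_factory=lambda: np.empty(0))
    sync_pulses_eeg: np.ndarray = field(default_factory=lambda: np.empty(0))
    channel_retained: np.ndarray | None = None
    channel_quality_reason: list[str] | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, float)
        if self.intensity.ndim != 3:
            raise BundleValidationError("intensity must be (time, channel, wavelength)")
        nch = self.intensity.shape[1]
        if nch != self.probe.n_channels:
            raise BundleValidationError(
                f"intensity has {nch} channels but probe defines {self.probe.n_channels}"
            )
        if self.intensity.shape[2] != len(self.probe.wavelengths):
            raise BundleValidationError("wavelength axis does not match probe")
        if self.channel_retained is None:
            self.channel_retained = np.ones(nch, bool)
        else:
            self.channel_retained = np.asarray(self.channel_retained, bool)
        if self.channel_quality_reason is None:
            self.channel_quality_reason = [""] * nch
        self.sync_pulses_dot = np.asarray(self.sync_pulses_dot, float)
        self.sync_pulses_eeg = np.asarray(self.sync_pulses_eeg, float)
        if self.sample_rate_hz <= 0:
            raise BundleValidationError("sample_rate_hz must be positive")
        bad = self.intensity[:, self.channel_retained, :] <= 0
        if np.any(bad):
            ch = np.where(self.channel_retained)[0][np.unique(np.where(bad)[1])]
            raise BundleValidationError(
                f"non-positive intensity on retained channel(s) {ch.tolist()}"
            )

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def copy(self) -> "RecordingBundle":
        return replace(
            self,
            intensity=self.intensity.copy(),
            channel_retained=self.channel_retained.copy(),
            channel_quality_reason=list(self.channel_quality_reason),
            eeg_annotations=self.eeg_annotations.copy(),
        )


_ANNOT_COLUMNS = ["event_id", "am_onset_s", "dh_onset_s", "eeg_duration_s", "label"]


def empty_annotations() -> pd.DataFrame:
    return pd.DataFrame(columns=_ANNOT_COLUMNS)


def _validate_annotations(tab: pd.DataFrame) -> pd.DataFrame:
    tab = tab.copy()
    for c in _ANNOT_COLUMNS:
        if c not in tab.columns:
            raise BundleFormatError(f"annotation table missing column '{c}'")
    if len(tab):
        both_missing = tab["am_onset_s"].isna() & tab["dh_onset_s"].isna()
        if both_missing.any():
            raise BundleValidationError("event with no annotator onset")
        if (tab["eeg_duration_s"] <= 0).any():
            raise BundleValidationError("event durations must be > 0")
    return tab


# ---------------------------------------------------------------------------
# Container I/O (SNIRF-like HDF5)
# ---------------------------------------------------------------------------

def write_bundle(bundle: RecordingBundle, path, overwrite: bool = True) -> None:
    """Serialize a bundle to the package's HDF5 container.

    The layout mirrors SNIRF naming: ``nirs/data1/dataTimeSeries`` holds the
    flattened (time x channel*wavelength) intensities with a measurement list,
    geometry sits under ``nirs/probe``, annotations under ``annotations`` and
    synchronization pulses under ``sync``.  Optional ground truth (from the
    synthetic generator) is stored under ``truth``.
    """
    import os

    if not overwrite and os.path.exists(path):
        raise FileExistsError(f"{path} exists and overwrite=False")
    nt, nch, nwl = bundle.intensity.shape
    with h5py.File(path, "w") as f:
        d = f.create_group("nirs/data1")
        d.create_dataset("dataTimeSeries", data=bundle.intensity.reshape(nt, nch * nwl))
        d.create_dataset("time", data=bundle.times)
        ml = d.create_group("measurementList")
        src = np.repeat(bundle.probe.channel_list[:, 0], nwl)
        det = np.repeat(bundle.probe.channel_list[:, 1], nwl)
        wl = np.tile(np.arange(nwl), nch)
        ml.create_dataset("sourceIndex", data=src)
        ml.create_dataset("detectorIndex", data=det)
        ml.create_dataset("wavelengthIndex", data=wl)
        p = f.create_group("nirs/probe")
        p.create_dataset("sourcePos3D", data=bundle.probe.source_positions)
        p.create_dataset("detectorPos3D", data=bundle.probe.detector_positions)
        p.create_dataset("wavelengths", data=bundle.probe.wavelengths)
        if bundle.probe.landmark_positions:
            lm = p.create_group("landmarks")
            for name, pos in bundle.probe.landmark_positions.items():
                lm.create_dataset(name, data=np.asarray(pos, float))
        f.attrs["sample_rate_hz"] = float(bundle.sample_rate_hz)
        a = f.create_group("annotations")
        tab = bundle.eeg_annotations
        a.create_dataset("event_id", data=np.asarray(tab.get("event_id", []), float))
        for col in ("am_onset_s", "dh_onset_s", "eeg_duration_s"):
            a.create_dataset(col, data=np.asarray(tab.get(col, []), float))
        labels = [str(x) for x in tab.get("label", [])]
        a.create_dataset("label", data=np.array(labels, dtype=h5py.string_dtype()))
        s = f.create_group("sync")
        s.create_dataset("dot", data=bundle.sync_pulses_dot)
        s.create_dataset("eeg", data=bundle.sync_pulses_eeg)
        q = f.create_group("qc")
        q.create_dataset("retained", data=bundle.channel_retained.astype(np.int8))
        q.create_dataset(
            "reason",
            data=np.array(bundle.channel_quality_reason, dtype=h5py.string_dtype()),
        )
        if bundle.truth:
            _write_dict(f.create_group("truth"), bundle.truth)


def _write_dict(grp: h5py.Group, d: dict) -> None:
    for k, v in d.items():
        if isinstance(v, dict):
            _write_dict(grp.create_group(k), v)
        elif isinstance(v, str):
            grp.attrs[k] = v
        else:
            grp.create_dataset(k, data=np.asarray(v))


def _read_dict(grp: h5py.Group) -> dict:
    out = dict(grp.attrs)
    for k, v in grp.items():
        out[k] = _read_dict(v) if isinstance(v, h5py.Group) else np.asarray(v)
    return out


def read_bundle(path) -> RecordingBundle:
    """Read and validate a bundle written by :func:`write_bundle`."""
    with h5py.File(path, "r") as f:
        for key in ("nirs/data1/dataTimeSeries", "nirs/data1/time", "nirs/probe"):
            if key not in f:
                raise BundleFormatError(f"container missing required dataset '{key}'")
        t = np.asarray(f["nirs/data1/time"])
        if len(t) > 2:
            dt = np.diff(t)
            if np.max(np.abs(dt - dt[0])) > 1e-9 * max(dt[0], 1e-12):
                raise BundleValidationError("non-uniform time axis")
        fs = float(f.attrs["sample_rate_hz"])
        p = f["nirs/probe"]
        wavelengths = np.asarray(p["wavelengths"])
        nwl = len(wavelengths)
        ml = f["nirs/data1/measurementList"]
        src = np.asarray(ml["sourceIndex"])[::nwl]
        det = np.asarray(ml["detectorIndex"])[::nwl]
        landmarks = {}
        if "landmarks" in p:
            landmarks = {k: np.asarray(v) for k, v in p["landmarks"].items()}
        probe = ProbeGeometry(
            np.asarray(p["sourcePos3D"]),
            np.asarray(p["detectorPos3D"]),
            np.column_stack([src, det]),
            wavelengths,
            landmarks,
        )
        flat = np.asarray(f["nirs/data1/dataTimeSeries"])
        intensity = flat.reshape(flat.shape[0], probe.n_channels, nwl)
        a = f["annotations"]
        tab = pd.DataFrame(
            {
                "event_id": np.asarray(a["event_id"]),
                "am_onset_s": np.asarray(a["am_onset_s"]),
                "dh_onset_s": np.asarray(a["dh_onset_s"]),
                "eeg_duration_s": np.asarray(a["eeg_duration_s"]),
                "label": [x.decode() if isinstance(x, bytes) else str(x) for x in a["label"]],
            }
        )
        retained = np.asarray(f["qc/retained"]).astype(bool)
        reason = [x.decode() if isinstance(x, bytes) else str(x) for x in f["qc/reason"]]
        truth = _read_dict(f["truth"]) if "truth" in f else None
        bundle = RecordingBundle(
            intensity=intensity,
            sample_rate_hz=fs,
            probe=probe,
            eeg_annotations=_validate_annotations(tab) if len(tab) else tab,
            sync_pulses_dot=np.asarray(f["sync/dot"]),
            sync_pulses_eeg=np.asarray(f["sync/eeg"]),
            channel_retained=retained,
            channel_quality_reason=reason,
            truth=truth,
        )
    return bundle


def write_event_table(table: pd.DataFrame, path) -> None:
    _validate_annotations(table).to_csv(path, index=False)


def read_event_table(path) -> pd.DataFrame:
    return _validate_annotations(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Clock alignment
# ---------------------------------------------------------------------------

def align_clocks(
    pulses_a: np.ndarray,
    pulses_b: np.ndarray,
    tolerance_s: float = 0.25,
) -> tuple[float, float]:
    """Recover the clock offset between two recordings of the same pulse train.

    Both instruments record the same aperiodic pattern of electrical pulses;
    because consecutive inter-pulse intervals are distinct, the interval
    sequences can be matched unambiguously, after which the offset is the
    least-squares shift over matched pulse pairs.

    Returns ``(offset, residual)`` such that ``pulses_a + offset`` matches
    ``pulses_b``; ``residual`` is the maximum absolute pairwise mismatch after
    the shift.

    Raises
    ------
    ClockAlignmentError
        If fewer than 3 pulses are available, no lag yields a consistent
        pairing, or more than one lag does (periodic pattern).
    """
    a = np.sort(np.asarray(pulses_a, float))
    b = np.sort(np.asarray(pulses_b, float))
    if len(a) < 3 or len(b) < 3:
        raise ClockAlignmentError("need at least 3 sync pulses per stream")
    candidates = []
    # slide the shorter index range over the longer: pair a[i] with b[i + lag]
    for lag in range(-(len(a) - 3), len(b) - 2):
        i0, i1 = max(0, -lag), min(len(a), len(b) - lag)
        if i1 - i0 < 3:
            continue
        deltas = b[i0 + lag : i1 + lag] - a[i0:i1]
        spread = deltas.max() - deltas.min()
        if spread <= 2 * tolerance_s:
            candidates.append((lag, float(np.mean(deltas)), deltas))
    if not candidates:
        raise ClockAlignmentError("no consistent pulse pairing found")
    if len(candidates) > 1:
        raise ClockAlignmentError(
            "ambiguous pulse pairing (periodic pattern?): "
            f"{len(candidates)} consistent lags"
        )
    _, offset, deltas = candidates[0]
    residual = float(np.max(np.abs(deltas - offset)))
    return offset, residual


# ---------------------------------------------------------------------------
# Consensus onsets
# ---------------------------------------------------------------------------

def consensus_onset(am_onset_s: float | None, dh_onset_s: float | None) -> float:
    """Electrographic onset of one event: the mean of the available annotator
    onsets.  When only one neurophysiologist marked the event, that onset is
    returned unchanged."""
    vals = [
        v
        for v in (am_onset_s, dh_onset_s)
        if v is not None and np.isfinite(v)
    ]
    if not vals:
        raise ValueError("event has no annotator onset")
    return float(np.mean(vals))


def consensus_onsets(table: pd.DataFrame) -> np.ndarray:
    """Consensus onset per row of an event annotation table."""
    return np.array(
        [
            consensus_onset(
                row["am_onset_s"] if pd.notna(row["am_onset_s"]) else None,
                row["dh_onset_s"] if pd.notna(row["dh_onset_s"]) else None,
            )
            for _, row in table.iterrows()
        ]
    )
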