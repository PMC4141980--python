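"""Channel-wise modified Beer-Lambert conversion and global signal handling.

The modified Beer-Lambert law (MBLL) relates a change in optical density at
wavelength lambda on a channel with source-detector separation ``d`` to the
underlying chromophore concentration changes::

    dOD(lambda) = [eps_HbO(lambda) * dHbO + eps_HbR(lambda) * dHbR] * d * DPF

where ``eps`` are natural-log specific extinction coefficients
(mm^-1 uM^-1), ``d`` the geometric separation in mm and ``DPF`` the
differential pathlength factor (4.9 for the neonatal head here).  With two
distinct wavelengths the 2x2 spectral system is solved exactly per channel and
sample; with more wavelengths a least-squares solution is used.  Total
haemoglobin is always derived as HbT = HbO + HbR, never stored independently.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExtinctionTable",
    "HaemoSeries",
    "default_extinction_table",
    "mbll_convert",
    "global_mean",
    "linear_detrend",
]


@dataclass
class ExtinctionTable:
    """Specific extinction coefficients per wavelength.

    ``eps_hbo``/``eps_hbr`` map wavelength (nm) to natural-log coefficients in
    mm^-1 uM^-1.  The 2x2 spectral matrix of any two distinct wavelengths must
    be nonsingular; its condition number is exposed for diagnostics.
    """

    eps_hbo: dict[float, float]
    eps_hbr: dict[float, float]
    citation: str = ""

    def __post_init__(self) -> None:
        for eps in (self.eps_hbo, self.eps_hbr):
            if any(v <= 0 for v in eps.values()):
                raise ValueError("extinction coefficients must be positive")

    def matrix(self, wavelengths) -> np.ndarray:
        """Spectral matrix E with rows [eps_hbo(l), eps_hbr(l)] per wavelength."""
        rows = []
        for wl in np.asarray(wavelengths, float):
            key = self._lookup(wl)
            rows.append([self.eps_hbo[key], self.eps_hbr[key]])
        return np.asarray(rows)

    def condition_number(self, wavelengths) -> float:
        return float(np.linalg.cond(self.matrix(wavelengths)))

    def _lookup(self, wl: float) -> float:
        for key in self.eps_hbo:
            if abs(key - wl) <= 1.0:
                return key
        raise KeyError(f"no extinction entry within 1 nm of {wl} nm")


def default_extinction_table() -> ExtinctionTable:
    """The packaged haemoglobin extinction table (780/850 nm, natural log)."""
    ref = importlib.resources.files("neodot") / "_data" / "extinction_coefficients.csv"
    with importlib.resources.as_file(ref) as p:
        tab = pd.read_csv(p)
    return ExtinctionTable(
        eps_hbo=dict(zip(tab["wavelength_nm"].astype(float), tab["eps_hbo"])),
        eps_hbr=dict(zip(tab["wavelength_nm"].astype(float), tab["eps_hbr"])),
        citation=str(tab["citation"].iloc[0]),
    )


@dataclass
class HaemoSeries:
    """Per-channel haemoglobin concentration changes (uM) over time.

    ``hbo``/``hbr`` have shape (time, channel); ``hbt`` is always computed as
    their sum.  ``separations`` are the per-channel source-detector distances
    (mm) and ``dpf`` the differential pathlength factor used in conversion.
    """

    hbo: np.ndarray
    hbr: np.ndarray
    sample_rate_hz: float
    dpf: float
    separations: np.ndarray = field(default_factory=lambda: np.empty(0))
    channel_retained: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, float)
        self.hbr = np.asarray(self.hbr, float)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must have identical shape")
        if self.dpf <= 0:
            raise ValueError("dpf must be positive")
        if self.channel_retained is None:
            self.channel_retained = np.ones(self.hbo.shape[1], bool)

    @property
    def hbt(self) -> np.ndarray:
        return self.hbo + self.hbr

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.hbo.shape[0]) / self.sample_rate_hz


def mbll_convert(od, probe, ext: ExtinctionTable | None = None, dpf: float = 4.9) -> HaemoSeries:
    """Invert the MBLL per channel: dOD (time, channel, wavelength) -> uM.

    Exact for two wavelengths, least squares for more.  Raises on a singular
    spectral matrix or missing channel separations.
    """
    if ext is None:
        ext = default_extinction_table()
    delta_od = od.delta_od if hasattr(od, "delta_od") else np.asarray(od, float)
    if delta_od.ndim != 3 or delta_od.shape[2] < 2:
        raise ValueError("need (time, channel, wavelength) dOD with >= 2 wavelengths")
    seps = probe.separations()
    if len(seps) != delta_od.shape[1]:
        raise ValueError("separation count does not match channel count")
    E = ext.matrix(probe.wavelengths)
    if np.linalg.cond(E) > 1e8:
        raise np.linalg.LinAlgError("spectral extinction matrix is singular")
    # dOD[t, c, :] = E @ conc[t, c, :] * (sep_c * dpf); solve per channel
    pinv = np.linalg.pinv(E)  # (2, n_wl)
    conc = np.einsum("kw,tcw->tck", pinv, delta_od) / (seps[None, :, None] * dpf)
    retained = getattr(od, "channel_retained", None)
    fs = getattr(od, "sample_rate_hz", np.nan)
    return HaemoSeries(
        hbo=conc[:, :, 0],
        hbr=conc[:, :, 1],
        sample_rate_hz=fs,
        dpf=dpf,
        separations=seps,
        channel_retained=retained,
    )


def mbll_forward(hbo, hbr, separations, wavelengths, ext: ExtinctionTable | None = None,
                 dpf: float = 4.9) -> np.ndarray:
    """Forward MBLL: concentrations (time, channel) -> dOD (time, channel, wl)."""
    if ext is None:
        ext = default_extinction_table()
    E = ext.matrix(wavelengths)
    conc = np.stack([np.asarray(hbo, float), np.asarray(hbr, float)], axis=-1)
    od = np.einsum("wk,tck->tcw", E, conc)
    return od * (np.asarray(separations, float)[None, :, None] * dpf)


def global_mean(series: HaemoSeries, channel_mask=None):
    """Unweighted mean over retained channels, per chromophore.

    Returns a dict with 'hbo', 'hbr', 'hbt' 1-D time courses (uM).
    """
    mask = series.channel_retained if channel_mask is None else np.asarray(channel_mask, bool)
    if mask.sum() == 0:
        raise ValueError("no retained channels to average")
    hbo = series.hbo[:, mask].mean(axis=1)
    hbr = series.hbr[:, mask].mean(axis=1)
    return {"hbo": hbo, "hbr": hbr, "hbt": hbo + hbr}


def linear_detrend(trace, times=None):
    """Remove the least-squares line from a trace.

    Returns ``(detrended, slope, intercept)``; adding ``slope*t + intercept``
    back reproduces the input.
    """
    y = np.asarray(trace, float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("need a 1-D trace with >= 2 samples")
    t = np.arange(len(y), dtype=float) if times is None else np.asarray(times, float)
    A = np.column_stack([t, np.ones_like(t)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    return y - (slope * t + intercept), float(slope), float(intercept)
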