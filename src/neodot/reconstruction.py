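"""Multispectral linear Tikhonov image reconstruction and cortical projection.

Given the stacked multispectral sensitivity matrix ``S`` (all-wavelength
channel dOD against stacked (dHbO, dHbR) node vectors), each time frame is
inverted with the minimum-norm Tikhonov solution

    x = S^T (S S^T + lambda^2 I)^(-1) y,

with the regularization parameter set to 1% of the largest singular value of
``S``.  The Gram matrix is small (twice the channel count squared), so its
Cholesky factorization is computed once and reused across all frames.

Volume images are projected to the grey-matter surface by averaging all
volume nodes within 3 mm of each surface node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial import cKDTree

__all__ = [
    "HaemoImageSeries",
    "choose_lambda",
    "reconstruct_frame",
    "reconstruct_series",
    "project_to_surface",
    "stack_od_frames",
]


@dataclass
class HaemoImageSeries:
    """HbO/HbR (and derived HbT) node images over time (uM).

    ``space_tag`` records whether node values live on the tetrahedral volume
    mesh or on the grey-matter surface.
    """

    node_hbo: np.ndarray
    node_hbr: np.ndarray
    frame_times_s: np.ndarray
    regularization_lambda: float
    space_tag: str = "volume"

    def __post_init__(self) -> None:
        self.node_hbo = np.asarray(self.node_hbo, float)
        self.node_hbr = np.asarray(self.node_hbr, float)
        self.frame_times_s = np.asarray(self.frame_times_s, float)
        if self.node_hbo.shape != self.node_hbr.shape:
            raise ValueError("hbo/hbr image shapes differ")
        if len(self.frame_times_s) != len(self.node_hbo):
            raise ValueError("frame count does not match time stamps")
        if not self.regularization_lambda > 0:
            raise ValueError("regularization_lambda must be positive and recorded")

    @property
    def node_hbt(self) -> np.ndarray:
        return self.node_hbo + self.node_hbr


def choose_lambda(stacked_J: np.ndarray, fraction: float = 0.01) -> float:
    """Regularization parameter: ``fraction`` of the largest singular value.

    Uses an iterative (Lanczos) estimate on large systems and a dense SVD on
    small ones; both agree to solver tolerance.
    """
    S = np.asarray(stacked_J, float)
    if not np.any(S):
        raise ValueError("zero sensitivity matrix")
    if min(S.shape) <= 200:
        smax = float(np.linalg.svd(S, compute_uv=False)[0])
    else:
        from scipy.sparse.linalg import svds

        smax = float(svds(S, k=1, return_singular_vectors=False, random_state=0)[0])
    return fraction * smax


def _gram_factor(stacked_J: np.ndarray, lam: float):
    S = np.asarray(stacked_J, float)
    G = S @ S.T + lam**2 * np.eye(S.shape[0])
    return cho_factor(G)


def reconstruct_frame(stacked_J: np.ndarray, delta_od_frame: np.ndarray,
                      lam: float, _factor=None) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-norm Tikhonov inversion of one stacked dOD frame.

    Returns ``(dHbO, dHbR)`` node vectors (uM).  Deterministic for fixed
    inputs; the optional precomputed Cholesky factor lets callers amortize the
    Gram factorization across frames.
    """
    S = np.asarray(stacked_J, float)
    y = np.asarray(delta_od_frame, float)
    if y.shape[-1] != S.shape[0]:
        raise ValueError(
            f"dOD frame has {y.shape[-1]} rows, system expects {S.shape[0]}")
    factor = _gram_factor(S, lam) if _factor is None else _factor
    x = S.T @ cho_solve(factor, y.T)
    n = S.shape[1] // 2
    return x[:n].T, x[n:].T


def stack_od_frames(delta_od: np.ndarray, channel_mask=None) -> np.ndarray:
    """(time, channel, wavelength) dOD -> (time, wavelength*channel) stacked
    rows, wavelength-major, matching the stacked Jacobian's row order.
    Excluded channels are zeroed (their Jacobian rows are zero too)."""
    od = np.asarray(delta_od, float)
    if channel_mask is not None:
        od = od.copy()
        od[:, ~np.asarray(channel_mask, bool), :] = 0.0
    return np.concatenate([od[:, :, w] for w in range(od.shape[2])], axis=1)


def reconstruct_series(
    stacked_J: np.ndarray,
    od,
    lam: float | None = None,
    baseline_spec: str | tuple = "global_mean",
    frame_rate_hz: float = 1.0,
    channel_mask=None,
) -> HaemoImageSeries:
    """Frame-by-frame multispectral reconstruction of an optical-density series.

    ``baseline_spec`` selects the measurement-space reference subtracted
    before inversion: ``'global_mean'`` (the temporal mean, matching the
    channel-wise OD convention) or a ``(t0, t1)`` window in seconds (event-
    locked baselines, e.g. 60-30 s before an onset).  Frames are down-sampled
    to ``frame_rate_hz`` (the series was low-passed at 1 Hz upstream).
    """
    delta_od = od.delta_od if hasattr(od, "delta_od") else np.asarray(od, float)
    fs = getattr(od, "sample_rate_hz", frame_rate_hz)
    if channel_mask is None:
        channel_mask = getattr(od, "channel_retained", None)
    y = stack_od_frames(delta_od, channel_mask)
    times = np.arange(len(y)) / fs
    if isinstance(baseline_spec, str):
        if baseline_spec != "global_mean":
            raise ValueError(f"unknown baseline_spec '{baseline_spec}'")
        baseline = y.mean(axis=0)
    else:
        t0, t1 = baseline_spec
        sel = (times >= t0) & (times < t1)
        if not sel.any():
            raise ValueError(f"baseline window ({t0}, {t1}) s outside recording")
        baseline = y[sel].mean(axis=0)
    y = y - baseline
    step = max(1, int(round(fs / frame_rate_hz)))
    y = y[::step]
    times = times[::step]
    if lam is None:
        lam = choose_lambda(stacked_J)
    factor = _gram_factor(stacked_J, lam)
    hbo, hbr = reconstruct_frame(stacked_J, y, lam, _factor=factor)
    return HaemoImageSeries(hbo, hbr, times, lam, space_tag="volume")


def project_to_surface(volume_frames: np.ndarray, mesh, radius_mm: float = 3.0,
                       warn_empty_fraction: float = 0.5):
    """Average volume-node values within ``radius_mm`` of each surface node.

    ``volume_frames`` is (frames, volume_nodes) or (volume_nodes,).  Surface
    nodes with no volume node in range are returned as NaN and flagged; a
    warning is raised if more than half the surface is empty.
    Returns ``(surface_frames, missing_mask)``.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    frames = np.atleast_2d(np.asarray(volume_frames, float))
    tree = cKDTree(mesh.nodes)
    groups = tree.query_ball_point(mesh.gm_nodes, r=radius_mm)
    out = np.full((frames.shape[0], len(mesh.gm_nodes)), np.nan)
    missing = np.zeros(len(mesh.gm_nodes), bool)
    for i, idx in enumerate(groups):
        if idx:
            out[:, i] = frames[:, idx].mean(axis=1)
        else:
            missing[i] = True
    if missing.mean() > warn_empty_fraction:
        import warnings

        warnings.warn(
            f"{missing.mean():.0%} of surface nodes have no volume node within "
            f"{radius_mm} mm", stacklevel=2)
    if np.asarray(volume_frames).ndim == 1:
        return out[0], missing
    return out, missing
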