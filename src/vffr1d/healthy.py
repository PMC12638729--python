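"""Healthy-lumen estimation and stenosis segmentation.

The hypothetical disease-free lumen is estimated by low-pass Fourier
filtration of the cross-sectional area signal.  A single quality
parameter — the number of retained harmonics — controls the filtration.

A plain low-pass would dip into stenoses, and focal lesions wider than
the cutoff wavelength are spectrally indistinguishable from taper, so
the estimate is built in two stages:

1. *Detection*: a coarse-to-fine upper-envelope pass.  Starting from
   the smoothest fit (one harmonic) the working signal is repeatedly
   lifted to the fit wherever the observed area falls below it, then
   re-filtered; the cutoff is raised one harmonic at a time up to
   ``n_harmonics``.  Lesions are erased while they are out of band, so
   the converged envelope rides over dips of any width.
2. *Refinement*: points falling below ``area_threshold`` of the
   envelope are provisionally lesioned; the area signal with those
   intervals bridged by linear interpolation between their healthy
   neighbours is re-filtered at the full cutoff.  This removes the
   upward bias the ratcheting envelope leaves on curved or stepped
   (bifurcation) tapers, because unflagged points revert to their
   observed values.

Stenosed regions are then the points where the reconstructed area falls
strictly below ``area_threshold`` (default 80%) of the estimated
healthy area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, FiltrationWarning, MalformedGeometry
from .geometry import CentrelineProfile


@dataclass(frozen=True)
class FiltrationConfig:
    """Tunable parameters of healthy-lumen estimation and segmentation.

    n_harmonics:
        Low-pass cutoff: number of Fourier modes of the (mirror-extended,
        detrended) working signal retained; the single quality knob.
    max_iterations / tolerance:
        Per-scale stopping rule of the envelope iteration (max relative
        change of the fit between iterations).
    area_threshold:
        Stenosis rule: a point is stenosed when area / healthy area is
        strictly below this fraction.
    min_run:
        Flagged runs shorter than this many points are discarded;
        single-point gaps inside a run are bridged first.
    """

    n_harmonics: int = 8
    max_iterations: int = 300
    tolerance: float = 1e-6
    area_threshold: float = 0.80
    min_run: int = 2

    def __post_init__(self) -> None:
        if self.n_harmonics < 1:
            raise DomainError("n_harmonics must be >= 1")
        if not (0.0 < self.area_threshold < 1.0):
            raise DomainError("area_threshold must lie in (0, 1)")
        if self.max_iterations < 1 or self.tolerance <= 0:
            raise DomainError("invalid envelope stopping rule")
        if self.min_run < 1:
            raise DomainError("min_run must be >= 1")


@dataclass(frozen=True, eq=False)
class HealthySegmentation:
    """Estimated healthy lumen plus per-point stenosed/healthy labels.

    ``stenosis_intervals`` are half-open index pairs [start, end)
    covering exactly the True entries of ``stenosed_mask`` (after
    morphological cleanup).
    """

    r_healthy: np.ndarray
    area_ratio: np.ndarray
    stenosed_mask: np.ndarray
    stenosis_intervals: tuple[tuple[int, int], ...]

    @property
    def any_stenosis(self) -> bool:
        return len(self.stenosis_intervals) > 0

    @classmethod
    def all_healthy(cls, profile: CentrelineProfile,
                    r_healthy: np.ndarray | None = None) -> "HealthySegmentation":
        """Segmentation declaring every point healthy (used for calibration runs)."""
        r_h = profile.r if r_healthy is None else np.asarray(r_healthy, dtype=float)
        n = profile.n_points
        return cls(
            r_healthy=r_h,
            area_ratio=(profile.r / r_h) ** 2,
            stenosed_mask=np.zeros(n, dtype=bool),
            stenosis_intervals=(),
        )


def _lowpass_detrended(x: np.ndarray, n_harmonics: int) -> np.ndarray:
    """Low-pass keeping the linear trend plus the lowest ``n_harmonics`` modes.

    The straight line through the endpoints is removed, the residual is
    mirror-extended to an even signal before the DFT (no periodicity
    artefacts), truncated, and the trend restored.  A final linear
    correction pins both endpoints exactly, so inlet and outlet calibre
    — which set the side-branch flow budget — survive filtration.
    """
    n = x.size
    t = np.linspace(0.0, 1.0, n)
    trend = x[0] + (x[-1] - x[0]) * t
    resid = x - trend
    ext = np.concatenate([resid, resid[::-1]])
    spec = np.fft.rfft(ext)
    spec[n_harmonics + 1:] = 0.0
    smooth = np.fft.irfft(spec, 2 * n)[:n]
    smooth -= smooth[0] + (smooth[-1] - smooth[0]) * t
    return trend + smooth


def _envelope_at_scale(work: np.ndarray, area: np.ndarray, n_harmonics: int,
                       cfg: FiltrationConfig) -> tuple[np.ndarray, np.ndarray, bool]:
    """Ratchet the working signal against its low-pass fit at one cutoff."""
    fit = _lowpass_detrended(work, n_harmonics)
    for _ in range(cfg.max_iterations):
        work = np.maximum(work, fit)
        new_fit = _lowpass_detrended(work, n_harmonics)
        scale = float(np.max(np.abs(new_fit))) or 1.0
        delta = float(np.max(np.abs(new_fit - fit))) / scale
        fit = new_fit
        if delta < cfg.tolerance:
            return work, fit, True
    return work, fit, False


#: Hysteresis bound for lesion excision: a detected core is dilated
#: outward while the observed area stays below this fraction of the
#: envelope, so the whole lesion (core plus flanks) is bridged before
#: re-filtration.
_BRIDGE_RATIO = 0.98


def _dilate_runs(mask: np.ndarray, ratio: np.ndarray, high: float) -> np.ndarray:
    """Extend each flagged run outward while ``ratio`` stays below ``high``."""
    out = mask.copy()
    n = mask.size
    for start, end in _runs(mask):
        i = start
        while i > 0 and ratio[i - 1] < high:
            i -= 1
        j = end
        while j < n and ratio[j] < high:
            j += 1
        out[i:j] = True
    return out


def _bridge_intervals(area: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace flagged runs by linear interpolation between healthy neighbours."""
    if not mask.any():
        return area
    bridged = area.copy()
    idx = np.arange(area.size)
    bridged[mask] = np.interp(idx[mask], idx[~mask], area[~mask])
    return bridged


def estimate_healthy(profile: CentrelineProfile,
                     cfg: FiltrationConfig | None = None) -> np.ndarray:
    """Estimate the per-point healthy radius (m) of a vessel.

    Coarse-to-fine envelope detection followed by re-filtration of the
    lesion-bridged area signal (see module docstring).  If an envelope
    scale fails to reach ``cfg.tolerance`` within ``cfg.max_iterations``
    a :class:`FiltrationWarning` is raised and the last iterate is used;
    the function never fails silently.
    """
    cfg = cfg or FiltrationConfig()
    area = np.pi * profile.r ** 2

    # Stage 1: coarse-to-fine upper envelope for lesion detection.
    work = area.copy()
    fit = area
    all_converged = True
    for k in range(1, cfg.n_harmonics + 1):
        work, fit, ok = _envelope_at_scale(work, area, k, cfg)
        all_converged &= ok
    floor = float(np.min(area)) * 1e-6
    envelope = np.maximum(fit, floor)
    env_ratio = area / envelope
    provisional = env_ratio < cfg.area_threshold
    provisional = _bridge_and_prune(provisional, cfg.min_run)
    provisional = _dilate_runs(provisional, env_ratio, _BRIDGE_RATIO)

    # Stage 2: re-filter the bridged signal at the full cutoff; the
    # short envelope pass keeps the upper-envelope character without
    # re-introducing the coarse-scale bias on healthy points.
    bridged = _bridge_intervals(area, provisional)
    _, fit, ok = _envelope_at_scale(bridged, bridged, cfg.n_harmonics, cfg)
    all_converged &= ok

    if not all_converged:
        warnings.warn(
            "healthy-lumen envelope did not reach tolerance "
            f"{cfg.tolerance:g} within {cfg.max_iterations} iterations per scale",
            FiltrationWarning,
            stacklevel=2,
        )
    return np.sqrt(np.maximum(fit, floor) / np.pi)


def _bridge_and_prune(mask: np.ndarray, min_run: int) -> np.ndarray:
    """Bridge single-point gaps inside runs, then drop runs shorter than min_run."""
    mask = mask.copy()
    if mask.size >= 3:
        gaps = ~mask[1:-1] & mask[:-2] & mask[2:]
        mask[1:-1] |= gaps
    out = mask.copy()
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i < min_run:
                out[i:j] = False
            i = j
        else:
            i += 1
    return out


def _runs(mask: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Half-open [start, end) index intervals of the True runs of a mask."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return tuple((int(a), int(b)) for a, b in zip(idx[::2], idx[1::2]))


def segment_stenoses(profile: CentrelineProfile,
                     r_healthy: np.ndarray,
                     cfg: FiltrationConfig | None = None) -> HealthySegmentation:
    """Label stenosed points from the area ratio against the healthy lumen.

    ``area_ratio = (r / r_healthy)^2``; a point is flagged when the
    ratio is *strictly* below ``cfg.area_threshold`` (a point exactly at
    the threshold is healthy).  Single-point gaps inside a flagged run
    are bridged, then runs shorter than ``cfg.min_run`` are discarded.
    """
    cfg = cfg or FiltrationConfig()
    r_healthy = np.asarray(r_healthy, dtype=float)
    if r_healthy.shape != profile.r.shape:
        raise MalformedGeometry("r_healthy length must match the profile")
    if not np.all(r_healthy > 0):
        raise MalformedGeometry("healthy radius must be positive everywhere")
    area_ratio = (profile.r / r_healthy) ** 2
    raw = area_ratio < cfg.area_threshold
    mask = _bridge_and_prune(raw, cfg.min_run)
    return HealthySegmentation(
        r_healthy=r_healthy,
        area_ratio=area_ratio,
        stenosed_mask=mask,
        stenosis_intervals=_runs(mask),
    )


def estimate_and_segment(profile: CentrelineProfile,
                         cfg: FiltrationConfig | None = None) -> HealthySegmentation:
    """Convenience: healthy-lumen estimation followed by segmentation."""
    cfg = cfg or FiltrationConfig()
    r_h = estimate_healthy(profile, cfg)
    return segment_stenoses(profile, r_h, cfg)
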