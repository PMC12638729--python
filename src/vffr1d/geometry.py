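"""Centreline geometry I/O, unit conversions and fluid properties.

Conventions
-----------
Profiles are stored inlet -> outlet: index 0 corresponds to the aortic
pressure (Pa) measurement location and the last index to the distal
pressure (Pd) location.  All internal quantities are SI (m, m^3/s, Pa);
clinical units (mm, mL/min, mmHg, Wood units) appear only at I/O
boundaries.

Geometry CSV dialect: header ``s_mm,r_mm``, one row per centreline
point, UTF-8, decimal point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, MalformedGeometry

# Unit conversion factors (clinical -> SI).
MMHG_TO_PA = 133.322387415
#: Wood unit = mmHg * min / L
WOOD_UNIT_TO_PA_S_M3 = MMHG_TO_PA / (1e-3 / 60.0)
ML_PER_MIN_TO_M3_S = 1e-6 / 60.0
MM_TO_M = 1e-3

#: Assumed viscosity of plasma (Pa*s), the haematocrit-free intercept of
#: the personalised whole-blood viscosity relation.
PLASMA_VISCOSITY = 0.0014
#: Standard whole-blood dynamic viscosity (Pa*s).
STANDARD_VISCOSITY = 0.0035
#: Standard blood density (kg/m^3).
STANDARD_DENSITY = 1050.0

#: Number of centreline samples used for routine simulations.
DEFAULT_N_POINTS = 200


def personalised_viscosity(hct: float) -> float:
    """Whole-blood dynamic viscosity (Pa*s) personalised to haematocrit.

    mu = 0.0014 + 0.0035 * hct, where the intercept is the assumed
    plasma viscosity and the haematocrit term the erythrocyte
    contribution.

    Parameters
    ----------
    hct:
        Haematocrit as a fraction in [0, 1).
    """
    if not np.isfinite(hct) or not (0.0 <= hct < 1.0):
        raise DomainError(f"haematocrit must lie in [0, 1), got {hct!r}")
    return PLASMA_VISCOSITY + STANDARD_VISCOSITY * hct


@dataclass(frozen=True)
class FluidProperties:
    """Dynamic viscosity mu (Pa*s), density rho (kg/m^3), optional haematocrit."""

    mu: float = STANDARD_VISCOSITY
    rho: float = STANDARD_DENSITY
    hct: float | None = None

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise DomainError(f"viscosity must be positive, got {self.mu!r}")
        if not self.rho > 0:
            raise DomainError(f"density must be positive, got {self.rho!r}")
        if self.hct is not None and not (0.0 <= self.hct < 1.0):
            raise DomainError(f"haematocrit must lie in [0, 1), got {self.hct!r}")

    @classmethod
    def from_haematocrit(cls, hct: float, rho: float = STANDARD_DENSITY) -> "FluidProperties":
        """Fluid with viscosity personalised to the patient's haematocrit."""
        return cls(mu=personalised_viscosity(hct), rho=rho, hct=hct)


@dataclass(frozen=True, eq=False)
class CentrelineProfile:
    """Arc-length/radius description of one vessel (SI units).

    ``s`` is arc length from the inlet in metres (s[0] == 0, strictly
    increasing); ``r`` is the lumen radius in metres (all positive).
    """

    s: np.ndarray
    r: np.ndarray
    case_id: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        r = np.asarray(self.r, dtype=float)
        if s.ndim != 1 or r.ndim != 1 or s.shape != r.shape:
            raise MalformedGeometry("s and r must be 1-D arrays of equal length")
        if s.size < 2:
            raise MalformedGeometry("a profile needs at least 2 points")
        if not np.all(np.isfinite(s)) or not np.all(np.isfinite(r)):
            raise MalformedGeometry("s and r must be finite")
        if not np.all(np.diff(s) > 0):
            raise MalformedGeometry("arc length s must be strictly increasing")
        if not np.all(r > 0):
            raise MalformedGeometry("all radii must be positive")
        s = s - s[0]  # the inlet defines the arc-length origin
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "r", r)

    @property
    def n_points(self) -> int:
        return int(self.s.size)

    @property
    def length(self) -> float:
        """Vessel length L (m)."""
        return float(self.s[-1])

    @property
    def r_in(self) -> float:
        return float(self.r[0])

    @property
    def r_out(self) -> float:
        return float(self.r[-1])

    def resample(self, n: int = DEFAULT_N_POINTS) -> "CentrelineProfile":
        """Piecewise-linear resampling onto ``n`` uniformly spaced points.

        Endpoints are preserved exactly; resampling an already-uniform
        profile of the same size is the identity.
        """
        if n < 2:
            raise DomainError(f"resample_n must be >= 2, got {n}")
        s_new = np.linspace(0.0, self.length, n)
        r_new = np.interp(s_new, self.s, self.r)
        return CentrelineProfile(s=s_new, r=r_new, case_id=self.case_id)

    def to_mm_frame(self) -> pd.DataFrame:
        """Clinical-unit view of the profile (columns ``s_mm``, ``r_mm``)."""
        return pd.DataFrame({"s_mm": self.s / MM_TO_M, "r_mm": self.r / MM_TO_M})


def read_profile(path, resample_n: int | None = DEFAULT_N_POINTS) -> CentrelineProfile:
    """Read a centreline radius profile from a ``s_mm,r_mm`` CSV.

    The profile is converted to SI units and, unless ``resample_n`` is
    None, linearly resampled to ``resample_n`` uniformly spaced points.
    """
    df = pd.read_csv(path)
    missing = {"s_mm", "r_mm"} - set(df.columns)
    if missing:
        raise FormatError(f"geometry CSV is missing columns: {sorted(missing)}")
    try:
        s = df["s_mm"].to_numpy(dtype=float) * MM_TO_M
        r = df["r_mm"].to_numpy(dtype=float) * MM_TO_M
    except (TypeError, ValueError) as exc:
        raise FormatError(f"geometry CSV contains non-numeric data: {exc}") from exc
    case_id = str(df["case_id"].iloc[0]) if "case_id" in df.columns else ""
    profile = CentrelineProfile(s=s, r=r, case_id=case_id)
    if resample_n is not None:
        profile = profile.resample(resample_n)
    return profile


def write_profile(profile: CentrelineProfile, path) -> None:
    """Write a profile as a ``s_mm,r_mm`` CSV (full float precision).

    Given identical inputs the writer emits byte-identical files, and a
    written profile reads back exactly (float64 round-trip).
    """
    profile.to_mm_frame().to_csv(path, index=False, lineterminator="\n")
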