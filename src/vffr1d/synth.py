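"""Synthetic coronary geometries and virtual cohorts.

Vessels are tapered tubes (smooth linear taper or stepped,
bifurcation-like taper) with superimposed focal Gaussian stenoses, at
the calibre scales of reconstructed human coronary arteries (inlet
diameter about 2.7 mm, outlet about 1.9 mm).  Cohorts draw geometry
and boundary conditions from seeded distributions and attach a
reference FFR computed by this package's own solver on a fine
(2000-point) grid, giving downstream statistics a self-consistent
ground truth without patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InfeasibleSpec
from .geometry import MM_TO_M, CentrelineProfile, FluidProperties, write_profile
from .solver import BoundaryConditions, SimulationResult, simulate_case


@dataclass(frozen=True)
class Stenosis:
    """One focal stenosis: Gaussian radius reduction.

    centre_frac:
        Centre position as a fraction of vessel length, in (0, 1).
    severity:
        Diameter stenosis DS in [0, 1): the radius at the centre is
        multiplied by (1 - DS).
    width_mm:
        Gaussian standard deviation of the lesion (mm).
    """

    centre_frac: float
    severity: float
    width_mm: float


@dataclass(frozen=True)
class VesselSpec:
    """Recipe for one synthetic vessel (clinical units, mm)."""

    length_mm: float = 30.0
    r_in_mm: float = 1.35
    r_out_mm: float = 0.95
    stenoses: tuple[Stenosis, ...] = ()
    taper_mode: str = "smooth"
    n_steps: int = 3
    n_points: int = 200
    case_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.r_out_mm <= self.r_in_mm):
            raise InfeasibleSpec("need 0 < r_out <= r_in")
        if self.length_mm <= 0:
            raise InfeasibleSpec("vessel length must be positive")
        if self.taper_mode not in ("smooth", "stepped"):
            raise InfeasibleSpec(f"unknown taper_mode {self.taper_mode!r}")
        if self.taper_mode == "stepped" and self.n_steps < 1:
            raise InfeasibleSpec("stepped taper needs n_steps >= 1")
        if self.n_points < 2:
            raise InfeasibleSpec("n_points must be >= 2")
        for st in self.stenoses:
            if not (0.0 <= st.severity < 1.0):
                raise InfeasibleSpec("diameter stenosis must lie in [0, 1)")
            if not (0.0 < st.centre_frac < 1.0):
                raise InfeasibleSpec("stenosis centre must lie inside the vessel")
            if st.width_mm <= 0:
                raise InfeasibleSpec("stenosis width must be positive")


def generate_vessel(spec: VesselSpec) -> CentrelineProfile:
    """Deterministically build the centreline profile a spec describes.

    The baseline radius interpolates r_in -> r_out (linearly, or in
    ``n_steps`` equal decrements at evenly spaced positions for the
    stepped mode); each stenosis multiplies the radius by
    ``1 - DS * gaussian(centre, width)``.
    """
    s_mm = np.linspace(0.0, spec.length_mm, spec.n_points)
    if spec.taper_mode == "smooth":
        r_mm = np.linspace(spec.r_in_mm, spec.r_out_mm, spec.n_points)
    else:
        frac = s_mm / spec.length_mm
        k = np.minimum((frac * (spec.n_steps + 1)).astype(int), spec.n_steps)
        r_mm = spec.r_in_mm - (spec.r_in_mm - spec.r_out_mm) * k / spec.n_steps
    for st in spec.stenoses:
        centre = st.centre_frac * spec.length_mm
        r_mm = r_mm * (1.0 - st.severity * np.exp(-((s_mm - centre) ** 2)
                                                  / (2.0 * st.width_mm ** 2)))
    if np.any(r_mm <= 0):
        raise InfeasibleSpec("spec produced a non-positive radius")
    return CentrelineProfile(s=s_mm * MM_TO_M, r=r_mm * MM_TO_M, case_id=spec.case_id)


@dataclass(frozen=True)
class CohortRanges:
    """Sampling distributions of a virtual cohort (clinical units).

    Geometry calibres follow the reconstruction scales of intermediate
    coronary disease (inlet diameter 2.7 +/- 0.5 mm, outlet
    1.9 +/- 0.4 mm; normal draws winsorised at 1.5 sd).  Aortic
    pressure is physiological; microvascular resistance is lognormal
    around a 361 Wood-unit median and scaled inversely with the cube of
    the outlet calibre (a Murray-type distal-bed size coupling, so
    small vessels face proportionally higher bed resistance);
    haematocrit is normal around the cohort mean 0.42.
    """

    length_mm: tuple[float, float] = (20.0, 45.0)
    r_in_mean_sd_mm: tuple[float, float] = (1.35, 0.25)
    r_out_mean_sd_mm: tuple[float, float] = (0.95, 0.20)
    ds_range: tuple[float, float] = (0.2, 0.65)
    width_mm_range: tuple[float, float] = (1.0, 2.5)
    centre_frac_range: tuple[float, float] = (0.3, 0.7)
    pa_mean_sd_mmhg: tuple[float, float] = (90.0, 10.0)
    pa_clip_mmhg: tuple[float, float] = (70.0, 120.0)
    mvr_median_wu: float = 361.0
    mvr_log_sd: float = 0.15
    #: Outlet radius (mm) at which the MVR median applies.
    mvr_reference_r_out_mm: float = 0.95
    hct_mean_sd: tuple[float, float] = (0.42, 0.04)
    hct_clip: tuple[float, float] = (0.25, 0.55)
    winsor_sd: float = 1.5


@dataclass(frozen=True)
class CohortCase:
    """One virtual case: geometry, boundary conditions and reference FFR."""

    case_id: str
    spec: VesselSpec
    profile: CentrelineProfile
    pa_mmhg: float
    mvr_wu: float
    hct: float
    ref_ffr: float | None
    ref_result: SimulationResult


def _winsor_normal(rng: np.random.Generator, mean: float, sd: float, k: float) -> float:
    return float(np.clip(rng.normal(mean, sd), mean - k * sd, mean + k * sd))


def generate_cohort(n: int,
                    seed: int = 0,
                    ranges: CohortRanges | None = None,
                    stenosed: bool = True,
                    ref_model: str = "localized",
                    ref_n_points: int = 2000) -> list[CohortCase]:
    """Seeded virtual cohort with solver-derived reference FFR.

    Each case is a tapered vessel (one Gaussian stenosis when
    ``stenosed``), aortic pressure, MVR and haematocrit drawn from
    ``ranges``.  The reference FFR re-runs this package's own pipeline
    on a fine ``ref_n_points`` grid with the ``ref_model`` leakage
    model and standard fluid properties.
    """
    if n < 1:
        raise InfeasibleSpec("cohort size must be >= 1")
    ranges = ranges or CohortRanges()
    rng = np.random.default_rng(seed)
    k = ranges.winsor_sd
    cases: list[CohortCase] = []
    for i in range(n):
        r_in = _winsor_normal(rng, *ranges.r_in_mean_sd_mm, k)
        r_out = _winsor_normal(rng, *ranges.r_out_mean_sd_mm, k)
        r_out = min(r_out, 0.9 * r_in)
        length = float(rng.uniform(*ranges.length_mm))
        stenoses: tuple[Stenosis, ...] = ()
        if stenosed:
            stenoses = (Stenosis(
                centre_frac=float(rng.uniform(*ranges.centre_frac_range)),
                severity=float(rng.uniform(*ranges.ds_range)),
                width_mm=float(rng.uniform(*ranges.width_mm_range)),
            ),)
        spec = VesselSpec(length_mm=length, r_in_mm=r_in, r_out_mm=r_out,
                          stenoses=stenoses, n_points=200,
                          case_id=f"case{i:03d}", seed=seed)
        pa = float(np.clip(rng.normal(*ranges.pa_mean_sd_mmhg), *ranges.pa_clip_mmhg))
        mvr = float(ranges.mvr_median_wu * np.exp(rng.normal(0.0, ranges.mvr_log_sd))
                    * (ranges.mvr_reference_r_out_mm / r_out) ** 3)
        hct = float(np.clip(rng.normal(*ranges.hct_mean_sd), *ranges.hct_clip))
        profile = generate_vessel(spec)
        fine = generate_vessel(replace(spec, n_points=ref_n_points))
        bc = BoundaryConditions(pa_mmhg=pa, mvr_wu=mvr)
        ref = simulate_case(fine, bc, ref_model, fluid=FluidProperties())
        cases.append(CohortCase(case_id=spec.case_id, spec=spec, profile=profile,
                                pa_mmhg=pa, mvr_wu=mvr, hct=hct,
                                ref_ffr=ref.vffr, ref_result=ref))
    return cases


def write_cohort(cases: list[CohortCase], outdir) -> pd.DataFrame:
    """Write per-case geometry CSVs plus a manifest CSV; returns the manifest."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        geom = f"{case.case_id}.csv"
        write_profile(case.profile, outdir / geom)
        rows.append({
            "case_id": case.case_id,
            "geometry": geom,
            "pa_mmhg": case.pa_mmhg,
            "mvr_wu": case.mvr_wu,
            "hct": case.hct,
            "ref_ffr": case.ref_ffr,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False, lineterminator="\n")
    return manifest
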