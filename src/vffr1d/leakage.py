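"""Side-branch leakage models.

In the 1-D abstraction, daughter branches too small to reconstruct are
represented as distributed outflow ("leakage") through the vessel wall.
The total side-branch budget follows from vessel taper via the
Huo-Kassab morphometric scaling law

    Q_in / Q_out = (R_in / R_out)^(7/3)

evaluated on the *healthy* (filtered) radii, so stenoses do not
masquerade as taper.  Five models distribute that budget:

``none``         no leakage at all;
``homogenous``   budget spread uniformly over healthy points;
``localized``    budget weighted by local healthy taper, so leakage
                 concentrates at bifurcation steps; radius-recovery
                 regions do not leak;
``conductance``  localized weights modulated by the simulated local
                 pressure, lowering leakage distal to stenosis-induced
                 pressure loss (fixed-point coupled to the solver);
``porosity``     the wall is treated as a porous medium obeying the
                 Darcy-Forchheimer relation; wall flux responds to
                 local transmural pressure, with the permeability
                 calibrated so an unstenosed vessel reproduces the
                 Huo-Kassab flow ratio.

No leakage occurs at stenosed points in any model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, LeakageError, SimulationFailure
from .geometry import CentrelineProfile, FluidProperties
from .healthy import HealthySegmentation

#: Huo-Kassab exponent linking radius to the flow a vessel carries.
HK_EXPONENT = 7.0 / 3.0

MODEL_IDS = ("none", "homogenous", "localized", "conductance", "porosity")


def huo_kassab_flow_ratio(r_in: float, r_out: float) -> float:
    """Inlet/outlet flow ratio (R_in / R_out)^(7/3) from vessel taper."""
    if not (r_in > 0 and r_out > 0):
        raise DomainError(f"radii must be positive, got r_in={r_in!r}, r_out={r_out!r}")
    return (r_in / r_out) ** HK_EXPONENT


def side_branch_budget(q_in: float, r_in_healthy: float, r_out_healthy: float) -> float:
    """Total side-branch outflow (m^3/s) implied by healthy taper.

    total_leak = Q_in * (1 - 1/ratio).  A non-tapering (or expanding)
    vessel has no resolvable side branches and yields zero budget;
    leakage never reverses into the main vessel.
    """
    if q_in < 0:
        raise DomainError(f"inlet flow must be non-negative, got {q_in!r}")
    ratio = huo_kassab_flow_ratio(r_in_healthy, r_out_healthy)
    if ratio <= 1.0:
        return 0.0
    return q_in * (1.0 - 1.0 / ratio)


@dataclass(frozen=True, eq=False)
class LeakageProfile:
    """Per-point leakage per unit length q(s) (m^3/s per m), all >= 0."""

    q: np.ndarray
    total_leak: float
    model_id: str
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class PorosityConfig:
    """Darcy-Forchheimer wall-porosity parameters.

    darcy_kappa:
        Lumped linear wall mobility (wall permeability over thickness
        and viscosity absorbed into one coefficient, m/(Pa*s)): wall
        velocity v satisfies ``P = v/kappa + beta*rho*v^2``.  ``None``
        requests calibration against the Huo-Kassab budget of the
        unstenosed vessel.
    forchheimer_beta:
        Quadratic (inertial) coefficient (1/m); 0 recovers a pure
        Darcy wall.
    calibration_mode:
        ``"uniform"`` — one wall mobility everywhere; ``"taper"`` —
        mobility weighted by local healthy taper.
    """

    darcy_kappa: float | None = None
    forchheimer_beta: float = 0.0
    calibration_mode: str = "uniform"

    def __post_init__(self) -> None:
        if self.darcy_kappa is not None and self.darcy_kappa < 0:
            raise DomainError("darcy_kappa must be >= 0")
        if self.forchheimer_beta < 0:
            raise DomainError("forchheimer_beta must be >= 0")
        if self.calibration_mode not in ("uniform", "taper"):
            raise DomainError(f"unknown calibration_mode {self.calibration_mode!r}")


def leak_none(profile: CentrelineProfile,
              segmentation: HealthySegmentation | None = None) -> LeakageProfile:
    """The no-leak model: q(s) identically zero."""
    return LeakageProfile(q=np.zeros(profile.n_points), total_leak=0.0, model_id="none")


def _healthy_budget(segmentation: HealthySegmentation, q_in: float) -> float:
    r_h = segmentation.r_healthy
    return side_branch_budget(q_in, float(r_h[0]), float(r_h[-1]))


def leak_homogenous(profile: CentrelineProfile,
                    segmentation: HealthySegmentation,
                    q_in: float) -> LeakageProfile:
    """Side-branch budget distributed uniformly over healthy points."""
    budget = _healthy_budget(segmentation, q_in)
    healthy = (~segmentation.stenosed_mask).astype(float)
    coverage = float(np.trapezoid(healthy, profile.s))
    if coverage <= 0.0:
        raise LeakageError("no healthy arc length to distribute leakage over")
    q = healthy * (budget / coverage)
    return LeakageProfile(q=q, total_leak=budget, model_id="homogenous")


def taper_weights(profile: CentrelineProfile,
                  segmentation: HealthySegmentation) -> np.ndarray:
    """Localized leak weights: w = max(0, -d/ds r_healthy^(7/3)), zero on stenoses.

    Using the gradient of r^(7/3) makes the local distribution
    consistent with the scaling law that sets the total budget;
    radius-recovery regions (locally non-decreasing healthy radius)
    carry zero weight and therefore do not leak.
    """
    r73 = segmentation.r_healthy ** HK_EXPONENT
    w = -np.gradient(r73, profile.s)
    w = np.clip(w, 0.0, None)
    # discard round-off noise well below the vessel's own taper scale
    scale = (float(np.max(r73)) - float(np.min(r73))) / profile.length
    w[w < 1e-9 * scale] = 0.0
    w[segmentation.stenosed_mask] = 0.0
    return w


def leak_localized(profile: CentrelineProfile,
                   segmentation: HealthySegmentation,
                   q_in: float) -> LeakageProfile:
    """Budget distributed proportionally to local healthy taper.

    If the taper weights vanish everywhere while the budget is positive
    (e.g. all taper falls inside stenosed intervals) the distribution
    falls back to the homogenous model and the result is flagged.
    """
    budget = _healthy_budget(segmentation, q_in)
    w = taper_weights(profile, segmentation)
    total_w = float(np.trapezoid(w, profile.s))
    if budget > 0.0 and total_w <= 0.0:
        fallback = leak_homogenous(profile, segmentation, q_in)
        return LeakageProfile(q=fallback.q, total_leak=fallback.total_leak,
                              model_id="localized", notes=("uniform fallback",))
    q = budget * w / total_w if budget > 0.0 else np.zeros_like(w)
    return LeakageProfile(q=q, total_leak=budget, model_id="localized")


def conductance_field(profile: CentrelineProfile,
                      segmentation: HealthySegmentation,
                      q_in: float,
                      p_reference: np.ndarray) -> np.ndarray:
    """Per-point wall conductance g(s) = q_localized(s) / P_reference(s).

    ``p_reference`` is the pressure field of the *unstenosed* (healthy
    lumen) configuration of the vessel at the same inlet flow, so that
    a disease-free vessel leaks exactly its anatomical (localized)
    budget and the Huo-Kassab flow ratio is reproduced; any positive
    pressure field may be supplied to study other references.
    """
    p_reference = np.asarray(p_reference, dtype=float)
    if p_reference.shape != profile.s.shape:
        raise DomainError("reference pressure length must match the profile")
    if np.any(p_reference <= 0.0):
        raise SimulationFailure("negative pressure")
    base = leak_localized(profile, segmentation, q_in)
    return base.q / p_reference


def leak_conductance(profile: CentrelineProfile,
                     segmentation: HealthySegmentation,
                     q_in: float,
                     pressure: np.ndarray,
                     p_reference: np.ndarray | None = None) -> LeakageProfile:
    """One conductance-model update: q(s) = g(s) * P(s).

    The conductance field fixes how much each point would leak at the
    reference (healthy-configuration) pressure; scaling by the current
    pressure iterate lowers leakage for equivalent regions of taper
    distal to stenosis-induced pressure loss.  The solver iterates this
    update to a fixed point, starting from the pressure field of a
    localized-leak simulation.  With ``p_reference`` omitted the inlet
    pressure is used as a uniform reference.
    """
    pressure = np.asarray(pressure, dtype=float)
    if pressure.shape != profile.s.shape:
        raise DomainError("pressure iterate length must match the profile")
    if np.any(pressure <= 0.0):
        raise SimulationFailure("negative pressure")
    if p_reference is None:
        p_reference = np.full(profile.n_points, float(pressure[0]))
    g = conductance_field(profile, segmentation, q_in, p_reference)
    q = g * pressure
    q[segmentation.stenosed_mask] = 0.0
    total = float(np.trapezoid(q, profile.s))
    return LeakageProfile(q=q, total_leak=total, model_id="conductance")


def darcy_forchheimer_velocity(pressure: np.ndarray,
                               kappa: np.ndarray,
                               beta: float,
                               fluid: FluidProperties) -> np.ndarray:
    """Wall velocity v (m/s) solving P = v/kappa + beta*rho*v^2, elementwise.

    ``kappa`` is the lumped linear mobility (m/(Pa*s)); points with
    kappa == 0 are impermeable.  The transmural pressure is the local
    luminal pressure referenced to zero venous pressure.
    """
    pressure = np.asarray(pressure, dtype=float)
    kappa = np.broadcast_to(np.asarray(kappa, dtype=float), pressure.shape)
    v = np.zeros_like(pressure)
    open_wall = kappa > 0.0
    if beta > 0.0:
        a = 1.0 / np.where(open_wall, kappa, np.inf)
        disc = a ** 2 + 4.0 * beta * fluid.rho * pressure
        v = np.where(open_wall, (-a + np.sqrt(disc)) / (2.0 * beta * fluid.rho), 0.0)
    else:
        v = np.where(open_wall, kappa * pressure, 0.0)
    return v


def porosity_shape(profile: CentrelineProfile,
                   segmentation: HealthySegmentation,
                   cfg: PorosityConfig) -> np.ndarray:
    """Per-point relative wall mobility (max 1) for the porosity model."""
    if cfg.calibration_mode == "uniform":
        return np.ones(profile.n_points)
    w = taper_weights(profile, segmentation)
    peak = float(np.max(w))
    return w / peak if peak > 0 else np.zeros_like(w)


def leak_porosity(profile: CentrelineProfile,
                  segmentation: HealthySegmentation,
                  pressure: np.ndarray,
                  cfg: PorosityConfig,
                  fluid: FluidProperties) -> LeakageProfile:
    """One porosity-model update: Darcy-Forchheimer wall flux at the current pressure.

    q(s) = v(s) * wall perimeter, with the perimeter taken from the
    healthy radius; stenosed points do not leak.  ``cfg.darcy_kappa``
    must hold a concrete (calibrated) value; the calibration itself
    lives in the solver because it requires coupled pressure solves.
    """
    if cfg.darcy_kappa is None:
        raise DomainError("porosity leak requires a calibrated darcy_kappa")
    pressure = np.asarray(pressure, dtype=float)
    if pressure.shape != profile.s.shape:
        raise DomainError("pressure iterate length must match the profile")
    if np.any(pressure <= 0.0):
        raise SimulationFailure("negative pressure")
    kappa = cfg.darcy_kappa * porosity_shape(profile, segmentation, cfg)
    v = darcy_forchheimer_velocity(pressure, kappa, cfg.forchheimer_beta, fluid)
    q = 2.0 * np.pi * segmentation.r_healthy * v
    q[segmentation.stenosed_mask] = 0.0
    total = float(np.trapezoid(q, profile.s))
    return LeakageProfile(q=q, total_leak=total, model_id="porosity")
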