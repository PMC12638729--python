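"""1-D steady-flow pressure solver and vFFR computation.

Pressure is marched from the inlet (aortic pressure Pa) to the outlet
(distal pressure Pd) along the sampled centreline.  In healthy sections
the gradient is Poiseuille plus an optional advective (momentum) term
with parabolic-profile correction alpha = 4/3; across each stenosed
interval an empirically derived lumped sub-model adds an expansion loss
on top of the viscous integral over the actual stenosis radii.  Axial
flow Q(s) decreases along the vessel by the cumulative side-branch
leakage; no leakage occurs inside stenoses.

Inlet flow is not prescribed directly: it is optimised so that the
simulated distal pressure over outlet flow equals the microvascular
resistance (MVR) boundary condition, within admissible flow bounds
(default 50-450 mL/min).  vFFR = Pd / Pa.

Pressure-coupled leakage models (conductance, porosity) wrap the march
in a fixed-point iteration; an iterate reaching non-positive pressure
makes the run *fail* with reason "negative pressure" — a recorded
outcome, never an exception escaping a batch run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DomainError, VffrUnavailable
from .geometry import (
    ML_PER_MIN_TO_M3_S,
    MMHG_TO_PA,
    WOOD_UNIT_TO_PA_S_M3,
    CentrelineProfile,
    FluidProperties,
)
from .healthy import FiltrationConfig, HealthySegmentation, estimate_and_segment
from .leakage import (
    MODEL_IDS,
    PorosityConfig,
    darcy_forchheimer_velocity,
    leak_homogenous,
    leak_localized,
    leak_none,
    porosity_shape,
    side_branch_budget,
)

#: Momentum-correction factor for a parabolic (Poiseuille) velocity profile.
PARABOLIC_ALPHA = 4.0 / 3.0


@dataclass(frozen=True)
class BoundaryConditions:
    """Aortic pressure, microvascular resistance and admissible flow range.

    Clinical units at the interface: Pa in mmHg, MVR in Wood units
    (mmHg*min/L), flow bounds in mL/min.
    """

    pa_mmhg: float
    mvr_wu: float
    q_bounds_ml_min: tuple[float, float] = (50.0, 450.0)

    def __post_init__(self) -> None:
        if not self.pa_mmhg > 0:
            raise DomainError("aortic pressure must be positive")
        if not self.mvr_wu > 0:
            raise DomainError("microvascular resistance must be positive")
        lo, hi = self.q_bounds_ml_min
        if not (0 < lo < hi):
            raise DomainError("flow bounds must satisfy 0 < lo < hi")

    @property
    def pa(self) -> float:
        """Aortic pressure (Pa, SI)."""
        return self.pa_mmhg * MMHG_TO_PA

    @property
    def mvr(self) -> float:
        """Microvascular resistance (Pa*s/m^3, SI)."""
        return self.mvr_wu * WOOD_UNIT_TO_PA_S_M3

    @property
    def q_bounds(self) -> tuple[float, float]:
        """Admissible inlet-flow interval (m^3/s, SI)."""
        lo, hi = self.q_bounds_ml_min
        return (lo * ML_PER_MIN_TO_M3_S, hi * ML_PER_MIN_TO_M3_S)


@dataclass(frozen=True)
class StenosisModelConfig:
    """Lumped stenosis pressure-drop sub-model coefficients.

    The drop across a stenosed interval is the Poiseuille integral over
    the interval's actual radii plus an expansion (separation) loss

        kt * (rho/2) * (A_healthy/A_min - 1)^2 * (Q/A_healthy)^2.

    ``kt`` is the empirical expansion-loss coefficient of the
    Young-Tsai lineage of lumped stenosis models.
    """

    kt: float = 1.52
    viscous_mode: str = "integrated"
    source_note: str = "Young-Tsai lumped stenosis model lineage"

    def __post_init__(self) -> None:
        if self.kt < 0:
            raise DomainError("kt must be >= 0")
        if self.viscous_mode != "integrated":
            raise DomainError(f"unknown viscous_mode {self.viscous_mode!r}")


@dataclass(frozen=True)
class SolverConfig:
    """Marching and fixed-point iteration controls."""

    advection: bool = True
    alpha: float = PARABOLIC_ALPHA
    ptol: float = 1e-6
    max_iterations: int = 100
    #: Relative tolerance of the MVR flow-matching residual.
    flow_rtol: float = 1e-9
    max_flow_iterations: int = 200

    def __post_init__(self) -> None:
        if self.ptol <= 0 or self.max_iterations < 1:
            raise DomainError("invalid fixed-point controls")


@dataclass(frozen=True, eq=False)
class SimulationResult:
    """Pressure and flow fields, vFFR, and convergence/failure status.

    ``status`` is ``"converged"`` or ``"failed"``; failed runs carry a
    ``reason`` (e.g. ``"negative pressure"``) and ``vffr`` is None.
    The pressure/flow arrays of the last iterate are retained for
    diagnostics even on failure.
    """

    p: np.ndarray | None
    qflow: np.ndarray | None
    vffr: float | None
    status: str
    reason: str | None
    iterations: int
    model_id: str
    q_in: float | None = None
    notes: tuple[str, ...] = ()

    @property
    def converged(self) -> bool:
        return self.status == "converged"

    @property
    def q_out(self) -> float | None:
        return None if self.qflow is None else float(self.qflow[-1])


def healthy_pressure_gradient(r, q, fluid: FluidProperties, dq_ds=0.0, dr_ds=0.0,
                              advection: bool = True,
                              alpha: float = PARABOLIC_ALPHA):
    """Pressure-loss rate -dP/ds (Pa/m) of the healthy 1-D steady-flow model.

    Poiseuille term 8*mu*Q/(pi*r^4) plus, when ``advection`` is on, the
    momentum term (rho*alpha/2) d(u^2)/ds with u = Q/(pi r^2), expanded
    with the supplied local derivatives of flow and radius.
    Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    q = np.asarray(q, dtype=float)
    area = np.pi * r ** 2
    grad = 8.0 * fluid.mu * q / (np.pi * r ** 4)
    if advection:
        u = q / area
        du_ds = np.asarray(dq_ds, dtype=float) / area \
            - 2.0 * q * np.asarray(dr_ds, dtype=float) / (np.pi * r ** 3)
        grad = grad + fluid.rho * alpha * u * du_ds
    if grad.ndim == 0:
        return float(grad)
    return grad


def stenosis_pressure_drop(s_seg: np.ndarray,
                           r_seg: np.ndarray,
                           a_healthy: float,
                           q: float,
                           fluid: FluidProperties,
                           cfg: StenosisModelConfig | None = None) -> float:
    """Lumped pressure drop (Pa) across one stenosed interval.

    Viscous term: Poiseuille integrated (trapezoid) over the interval's
    actual radii.  Expansion term: kt*(rho/2)*(A_h/A_min - 1)^2*(Q/A_h)^2
    with A_h the healthy reference area and A_min the minimal lumen
    area.  No leakage occurs inside the interval, so Q is constant.
    """
    cfg = cfg or StenosisModelConfig()
    s_seg = np.asarray(s_seg, dtype=float)
    r_seg = np.asarray(r_seg, dtype=float)
    if s_seg.size == 0:
        raise DomainError("stenosis interval is empty")
    if q < 0:
        raise DomainError("flow through a stenosis must be non-negative")
    a_min = np.pi * float(np.min(r_seg)) ** 2
    if not a_min > 0:
        raise DomainError("minimal stenosis area must be positive")
    visc = float(np.trapezoid(8.0 * fluid.mu * q / (np.pi * r_seg ** 4), s_seg))
    expansion = cfg.kt * (fluid.rho / 2.0) * (a_healthy / a_min - 1.0) ** 2 \
        * (q / a_healthy) ** 2
    return visc + expansion


def march_pressure(profile: CentrelineProfile,
                   segmentation: HealthySegmentation,
                   q_leak: np.ndarray,
                   q_in: float,
                   pa: float,
                   fluid: FluidProperties,
                   sten_cfg: StenosisModelConfig | None = None,
                   solver_cfg: SolverConfig | None = None):
    """Single pressure march for a frozen leakage field.

    Returns ``(p, qflow, reason)`` where ``reason`` is None on success,
    or a failure string ("negative pressure", "non-positive flow").
    ``p[0] = pa``; the axial flow is Q(s) = q_in minus the cumulative
    leak; trapezoidal integration of the healthy gradient between
    adjacent points; each stenosed interval contributes its lumped drop,
    with the expansion loss applied at the interval exit.
    """
    sten_cfg = sten_cfg or StenosisModelConfig()
    scfg = solver_cfg or SolverConfig()
    s, r = profile.s, profile.r
    n = profile.n_points
    q_leak = np.asarray(q_leak, dtype=float)

    ds = np.diff(s)
    leak_cum = np.concatenate(([0.0], np.cumsum(0.5 * (q_leak[:-1] + q_leak[1:]) * ds)))
    qflow = q_in - leak_cum
    if np.any(qflow <= 0.0):
        return None, qflow, "non-positive flow"

    integrand = 8.0 * fluid.mu * qflow / (np.pi * r ** 4)
    drop_edge = 0.5 * (integrand[:-1] + integrand[1:]) * ds

    mask = segmentation.stenosed_mask
    if scfg.advection:
        u = qflow / (np.pi * r ** 2)
        adv_edge = scfg.alpha * fluid.rho * 0.5 * (u[1:] ** 2 - u[:-1] ** 2)
        healthy_edge = ~mask[:-1] & ~mask[1:]  # lumped sub-model owns stenosed edges
        drop_edge = drop_edge + np.where(healthy_edge, adv_edge, 0.0)

    p = pa - np.concatenate(([0.0], np.cumsum(drop_edge)))

    for start, end in segmentation.stenosis_intervals:
        i_min = start + int(np.argmin(r[start:end]))
        a_min = np.pi * r[i_min] ** 2
        a_h = np.pi * segmentation.r_healthy[i_min] ** 2
        q_through = qflow[start]
        expansion = sten_cfg.kt * (fluid.rho / 2.0) * (a_h / a_min - 1.0) ** 2 \
            * (q_through / a_h) ** 2
        apply_from = end if end < n else n - 1
        p[apply_from:] -= expansion

    if np.any(p <= 0.0):
        return p, qflow, "negative pressure"
    return p, qflow, None


def _result(profile, model_id, p, qflow, reason, iterations, q_in, notes=()):
    if reason is None:
        vffr = float(p[-1] / p[0])
        return SimulationResult(p=p, qflow=qflow, vffr=vffr, status="converged",
                                reason=None, iterations=iterations,
                                model_id=model_id, q_in=q_in, notes=tuple(notes))
    return SimulationResult(p=p, qflow=qflow, vffr=None, status="failed",
                            reason=reason, iterations=iterations,
                            model_id=model_id, q_in=q_in, notes=tuple(notes))


def _calibrate_porosity_kappa(profile: CentrelineProfile,
                              segmentation: HealthySegmentation,
                              q_in: float,
                              pa: float,
                              fluid: FluidProperties,
                              cfg: PorosityConfig,
                              sten_cfg: StenosisModelConfig,
                              scfg: SolverConfig):
    """Fit the Darcy mobility scale so the *unstenosed* vessel meets Huo-Kassab.

    The coupled wall-flux/pressure problem is solved on the healthy
    configuration (radius = healthy radius, no stenosed intervals) and
    the mobility scale is updated multiplicatively until the integrated
    wall flux matches the taper budget.  Returns ``(kappa, p_init,
    reason)``; ``p_init`` seeds the fixed point on the real vessel.
    """
    r_h = segmentation.r_healthy
    budget = side_branch_budget(q_in, float(r_h[0]), float(r_h[-1]))
    healthy_profile = CentrelineProfile(s=profile.s, r=r_h, case_id=profile.case_id)
    healthy_seg = HealthySegmentation.all_healthy(healthy_profile)
    if budget <= 0.0:
        p, _, reason = march_pressure(healthy_profile, healthy_seg,
                                      np.zeros(profile.n_points), q_in, pa,
                                      fluid, sten_cfg, scfg)
        return 0.0, p, reason
    shape = porosity_shape(healthy_profile, healthy_seg, cfg)
    perimeter = 2.0 * np.pi * r_h
    # Initial guess from a uniform pressure field at Pa (exact for beta = 0).
    kappa = budget / float(np.trapezoid(perimeter * shape * pa, profile.s))
    p = np.full(profile.n_points, pa)
    for _ in range(scfg.max_iterations):
        v = darcy_forchheimer_velocity(p, kappa * shape, cfg.forchheimer_beta, fluid)
        q = perimeter * v
        p_new, _, reason = march_pressure(healthy_profile, healthy_seg, q, q_in, pa,
                                          fluid, sten_cfg, scfg)
        if reason is not None:
            return kappa, p, reason
        total = float(np.trapezoid(q, profile.s))
        if total <= 0.0:
            return kappa, p_new, "porosity calibration collapsed"
        dp = float(np.max(np.abs(p_new - p))) / pa
        dq = abs(total / budget - 1.0)
        p = p_new
        kappa *= budget / total
        if dp < 1e-12 and dq < 1e-12:
            break
    return kappa, p, None


def simulate_at_flow(profile: CentrelineProfile,
                     segmentation: HealthySegmentation,
                     model_id: str,
                     q_in: float,
                     pa: float,
                     fluid: FluidProperties,
                     sten_cfg: StenosisModelConfig | None = None,
                     solver_cfg: SolverConfig | None = None,
                     porosity_cfg: PorosityConfig | None = None) -> SimulationResult:
    """Run one leakage model at a prescribed inlet flow (SI units).

    Uncoupled models (none / homogenous / localized) need a single
    march.  The conductance model starts from the localized pressure
    field and iterates pressure-weighted, budget-renormalised leak
    updates; the porosity model first calibrates its wall mobility on
    the unstenosed configuration, then iterates Darcy-Forchheimer wall
    flux against pressure.  Non-physical iterates yield a failed
    result, never an exception.
    """
    if model_id not in MODEL_IDS:
        raise DomainError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")
    sten_cfg = sten_cfg or StenosisModelConfig()
    scfg = solver_cfg or SolverConfig()
    s = profile.s
    notes: tuple[str, ...] = ()

    if model_id in ("none", "homogenous", "localized"):
        if model_id == "none":
            leak = leak_none(profile, segmentation)
        elif model_id == "homogenous":
            leak = leak_homogenous(profile, segmentation, q_in)
        else:
            leak = leak_localized(profile, segmentation, q_in)
        p, qflow, reason = march_pressure(profile, segmentation, leak.q, q_in, pa,
                                          fluid, sten_cfg, scfg)
        return _result(profile, model_id, p, qflow, reason, 1, q_in, leak.notes)

    if model_id == "conductance":
        base = leak_localized(profile, segmentation, q_in)
        notes = base.notes
        # Initial pressure iterate: the localized-leak simulation.
        p, qflow, reason = march_pressure(profile, segmentation, base.q, q_in, pa,
                                          fluid, sten_cfg, scfg)
        if reason is not None or base.total_leak <= 0.0:
            return _result(profile, "conductance", p, qflow, reason, 1, q_in, notes)
        # Conductance field from the unstenosed (healthy-lumen) configuration.
        r_h = segmentation.r_healthy
        healthy_profile = CentrelineProfile(s=s, r=r_h, case_id=profile.case_id)
        healthy_seg = HealthySegmentation.all_healthy(healthy_profile)
        base_h = leak_localized(healthy_profile, healthy_seg, q_in)
        p_h, _, reason_h = march_pressure(healthy_profile, healthy_seg, base_h.q, q_in,
                                          pa, fluid, sten_cfg, scfg)
        if reason_h is not None:
            return _result(profile, "conductance", p, qflow, reason_h, 1, q_in, notes)
        g = base_h.q / p_h
        mask = segmentation.stenosed_mask
        for it in range(1, scfg.max_iterations + 1):
            q_leak = g * p
            q_leak[mask] = 0.0
            p_new, qflow, reason = march_pressure(profile, segmentation, q_leak, q_in,
                                                  pa, fluid, sten_cfg, scfg)
            if reason is not None:
                return _result(profile, "conductance", p_new, qflow, reason, it, q_in, notes)
            delta = float(np.max(np.abs(p_new - p))) / pa
            p = p_new
            if delta < scfg.ptol:
                return _result(profile, "conductance", p, qflow, None, it, q_in, notes)
        return _result(profile, "conductance", p, qflow, "fixed point not converged",
                       scfg.max_iterations, q_in, notes)

    # porosity
    cfg = porosity_cfg or PorosityConfig()
    if cfg.darcy_kappa is None:
        kappa, p, reason = _calibrate_porosity_kappa(profile, segmentation, q_in, pa,
                                                     fluid, cfg, sten_cfg, scfg)
        if reason is not None:
            return _result(profile, "porosity", None, None, reason, 1, q_in, notes)
    else:
        kappa, p = cfg.darcy_kappa, np.full(profile.n_points, pa)
    shape = porosity_shape(profile, segmentation, cfg)
    perimeter = 2.0 * np.pi * segmentation.r_healthy
    mask = segmentation.stenosed_mask
    qflow = None
    for it in range(1, scfg.max_iterations + 1):
        if np.any(p <= 0.0):
            return _result(profile, "porosity", p, qflow, "negative pressure", it, q_in, notes)
        v = darcy_forchheimer_velocity(p, kappa * shape, cfg.forchheimer_beta, fluid)
        q_leak = perimeter * v
        q_leak[mask] = 0.0
        p_new, qflow, reason = march_pressure(profile, segmentation, q_leak, q_in, pa,
                                              fluid, sten_cfg, scfg)
        if reason is not None:
            return _result(profile, "porosity", p_new, qflow, reason, it, q_in, notes)
        delta = float(np.max(np.abs(p_new - p))) / pa
        p = p_new
        if delta < scfg.ptol:
            return _result(profile, "porosity", p, qflow, None, it, q_in, notes)
    return _result(profile, "porosity", p, qflow, "fixed point not converged",
                   scfg.max_iterations, q_in, notes)


def optimise_inlet_flow(profile: CentrelineProfile,
                        segmentation: HealthySegmentation,
                        model_id: str,
                        bc: BoundaryConditions,
                        fluid: FluidProperties,
                        sten_cfg: StenosisModelConfig | None = None,
                        solver_cfg: SolverConfig | None = None,
                        porosity_cfg: PorosityConfig | None = None) -> SimulationResult:
    """Find the inlet flow matching the MVR boundary condition.

    Solves Pd(q)/Q_out(q) = MVR for q within the admissible bounds by
    bisection on the monotone residual (distal pressure falls and
    outlet flow rises with q, so the residual decreases).  If the root
    lies outside the bounds the flow is clamped to the nearer bound and
    the result is flagged ``"flow clamped"``.  If every probe fails,
    the failed result is propagated.
    """
    scfg = solver_cfg or SolverConfig()
    q_lo, q_hi = bc.q_bounds
    pa, mvr = bc.pa, bc.mvr

    def run(q: float) -> SimulationResult:
        return simulate_at_flow(profile, segmentation, model_id, q, pa, fluid,
                                sten_cfg, scfg, porosity_cfg)

    def residual(sim: SimulationResult) -> float:
        return float(sim.p[-1]) / float(sim.qflow[-1]) - mvr

    def finish(sim: SimulationResult, extra: tuple[str, ...] = ()) -> SimulationResult:
        return replace(sim, notes=sim.notes + extra)

    sim_lo = run(q_lo)
    if not sim_lo.converged:
        # Failure at minimal flow: scan upward once for any feasible probe.
        for q in np.linspace(q_lo, q_hi, 12)[1:]:
            sim = run(q)
            if sim.converged:
                sim_lo, q_lo = sim, q
                break
        else:
            return finish(sim_lo, ("all probes failed",))
    res_lo = residual(sim_lo)
    if res_lo <= 0.0:
        # Even the minimum admissible flow overshoots the target resistance.
        return finish(sim_lo, ("flow clamped",))

    sim_hi = run(q_hi)
    if sim_hi.converged and residual(sim_hi) >= 0.0:
        return finish(sim_hi, ("flow clamped",))

    # Bisection; a failed probe (excess flow collapsing the pressure) is
    # treated like an overshoot and moves the upper bracket down.
    a, sim_a = q_lo, sim_lo
    b = q_hi
    sim_mid = sim_a
    for _ in range(scfg.max_flow_iterations):
        mid = 0.5 * (a + b)
        sim_mid = run(mid)
        if not sim_mid.converged:
            b = mid
            continue
        res = residual(sim_mid)
        if abs(res) <= scfg.flow_rtol * mvr:
            return finish(sim_mid)
        if res > 0.0:
            a, sim_a = mid, sim_mid
        else:
            b = mid
        if (b - a) <= 1e-14 * max(b, 1e-30):
            break
    final = sim_mid if sim_mid.converged else sim_a
    return finish(final, ("flow tolerance not reached",))


def compute_vffr(result: SimulationResult) -> float:
    """vFFR = Pd / Pa of a converged simulation."""
    if not result.converged:
        raise VffrUnavailable(f"simulation failed: {result.reason}")
    return float(result.p[-1] / result.p[0])


def simulate_case(profile: CentrelineProfile,
                  bc: BoundaryConditions,
                  model_id: str,
                  fluid: FluidProperties | None = None,
                  hct: float | None = None,
                  filtration_cfg: FiltrationConfig | None = None,
                  sten_cfg: StenosisModelConfig | None = None,
                  solver_cfg: SolverConfig | None = None,
                  porosity_cfg: PorosityConfig | None = None,
                  segmentation: HealthySegmentation | None = None) -> SimulationResult:
    """Full pipeline for one vessel and one model.

    Healthy-lumen filtration and stenosis segmentation (unless a
    precomputed ``segmentation`` is supplied), then MVR-coupled flow
    optimisation.  ``hct`` switches to haematocrit-personalised
    viscosity when no explicit fluid is given.
    """
    if fluid is None:
        fluid = FluidProperties() if hct is None else FluidProperties.from_haematocrit(hct)
    if segmentation is None:
        segmentation = estimate_and_segment(profile, filtration_cfg)
    return optimise_inlet_flow(profile, segmentation, model_id, bc, fluid,
                               sten_cfg, solver_cfg, porosity_cfg)
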