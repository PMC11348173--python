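"""Minimal systemic IgG disposition model and its calibration.

The whole body is lumped into plasma, a central lymph-node compartment and
one permeability-limited tissue (vascular / endothelial-endosome /
interstitial spaces with two-pore exchange and FcRn salvage).  Endogenous
IgG is produced by zero-order synthesis into plasma and eliminated by
endosomal catabolism, which keeps the endothelial FcRn pool partially
occupied at baseline — the competition backdrop against which the dosed
antibody is salvaged.

Three constants are not published and are calibrated once, then frozen:
the endogenous synthesis rate (anchored to a 12 g/L plasma IgG baseline),
the tissue fluid-phase uptake clearance (anchored to a 21-day terminal IgG
half-life) and the APC endosomal FcRn concentration (anchored to the
predicted 65.1% arm bioavailability of a 10 mg IgG dose).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fcrn_engine import EndosomePool, endosome_derivatives
from .physiology import BodyPhysiology, SitePhysiology
from .two_pore import TwoPoreParams, net_solute_flux, pore_fluid_flows

__all__ = [
    "SystemicParams",
    "CompiledSystemic",
    "build_systemic",
    "systemic_derivatives",
    "terminal_half_life",
    "calibrate",
    "CalibrationResult",
]

# Column order of the systemic state block (per species).
PLASMA, CNODE, CNF, CNC, TVAS, TINT, TF, TC = range(8)


@dataclass(frozen=True)
class SystemicParams:
    """Unpublished whole-body constants (standard human values)."""

    v_tissue_vascular: float = 0.4  # L, microvascular plasma in contact with tissue
    v_tissue_interstitial: float = 5.2  # L, IgG-accessible lumped interstitium
    v_tissue_endosome: float = 0.015  # L
    v_central_node: float = 0.219  # L, total node volume minus site-draining nodes
    v_central_node_endosome: float = 2.2e-4  # L
    # Fluid-phase endocytosis of endothelial endosomes (SC site, central
    # node), same 25%-of-endosomal-volume-per-hour convention as the APCs.
    k_endothelial_uptake: float = 0.25  # 1/h per endosomal volume
    cl_up_tissue: float = 0.022  # L/h, calibrated
    synthesis_rate: float = 82.0  # mg/h, calibrated

    def __post_init__(self) -> None:
        for name in ("v_tissue_vascular", "v_tissue_interstitial",
                     "v_tissue_endosome", "v_central_node",
                     "v_central_node_endosome"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("k_endothelial_uptake", "cl_up_tissue", "synthesis_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CompiledSystemic:
    v_plasma: float  # L, central plasma (total plasma minus tissue microvasculature)
    v_cnode: float
    v_tvas: float
    v_tint: float
    q_sc: float  # L/h, perfusion diverted to the SC site
    q_tis: float  # L/h
    l_tissue: float  # L/h
    l_out_cn: float  # L/h, central-node efferent to plasma
    cl_tissue: float  # L/h
    cl_cnode: float  # L/h
    j_small: float
    j_large: float
    two_pore: TwoPoreParams
    synthesis: np.ndarray  # mg/h per species
    pool_cn: EndosomePool
    pool_tissue: EndosomePool


def build_systemic(sp: SystemicParams, body: BodyPhysiology, site: SitePhysiology,
                   two_pore: TwoPoreParams, pool_cn: EndosomePool,
                   pool_tissue: EndosomePool) -> CompiledSystemic:
    l_aff = site.l_aff * body.total_lymph_flow
    l_eff = site.f_efferent * l_aff
    l_tissue = body.total_lymph_flow - l_aff
    if l_tissue <= 0:
        raise ValueError("site lymph flow exceeds total lymph flow")
    q_sc = site.q_sc * body.cardiac_output
    v_plasma = body.plasma_volume - sp.v_tissue_vascular
    if v_plasma <= 0:
        raise ValueError("tissue vascular volume exceeds total plasma volume")
    j_small, j_large = pore_fluid_flows(l_tissue, two_pore)
    return CompiledSystemic(
        v_plasma=v_plasma,
        v_cnode=sp.v_central_node,
        v_tvas=sp.v_tissue_vascular,
        v_tint=sp.v_tissue_interstitial,
        q_sc=q_sc,
        q_tis=body.cardiac_output - q_sc,
        l_tissue=l_tissue,
        l_out_cn=l_tissue + l_eff,
        cl_tissue=sp.cl_up_tissue,
        cl_cnode=sp.k_endothelial_uptake * pool_cn.volume,
        j_small=j_small,
        j_large=j_large,
        two_pore=two_pore,
        synthesis=np.array([0.0, 0.0, sp.synthesis_rate]),
        pool_cn=pool_cn,
        pool_tissue=pool_tissue,
    )


def systemic_derivatives(cy: CompiledSystemic, amounts: np.ndarray,
                         efferent_in: np.ndarray, sc_venous_in: np.ndarray,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Right-hand side of the systemic block for all species.

    ``amounts`` has shape ``(n_species, 8)``; see module constants for the
    column order.  All fluxes *into* plasma are returned separately
    (``plasma_in``) rather than added to the plasma derivative, so the
    caller can relabel dose-origin arrivals; plasma outflows (perfusion of
    the SC site and the tissue) remain in the derivative.  Also returns the
    catabolized mass fluxes of the central-node and tissue endosomes.
    """
    c_pl = amounts[:, PLASMA] / cy.v_plasma
    c_cn = amounts[:, CNODE] / cy.v_cnode
    c_tv = amounts[:, TVAS] / cy.v_tvas
    c_ti = amounts[:, TINT] / cy.v_tint

    tp = cy.two_pore
    n_sp = amounts.shape[0]
    flux_tp = np.empty(n_sp)
    for s in range(n_sp):
        flux_tp[s] = net_solute_flux(
            c_tv[s], c_ti[s], cy.j_small, tp.ps_small, tp.sigma_v_small
        ) + net_solute_flux(
            c_tv[s], c_ti[s], cy.j_large, tp.ps_large, tp.sigma_v_large
        )

    # Central lymph node: endothelial-type endosome, vascular face -> plasma.
    cn_uptake = cy.cl_cnode * c_cn
    d_cnf, d_cnc, cn_endo = endosome_derivatives(
        cy.pool_cn, amounts[:, CNF], amounts[:, CNC], cn_uptake
    )
    # Lumped tissue endothelium draws equally from both faces.
    t_uptake = 0.5 * cy.cl_tissue * (c_tv + c_ti)
    d_tf, d_tc, t_endo = endosome_derivatives(
        cy.pool_tissue, amounts[:, TF], amounts[:, TC], t_uptake
    )

    tissue_lymph = cy.l_tissue * (1.0 - tp.sigma_lymph) * c_ti

    d = np.empty_like(amounts)
    d[:, PLASMA] = -(cy.q_sc + cy.q_tis) * c_pl
    d[:, CNODE] = (efferent_in + tissue_lymph - cy.l_out_cn * c_cn
                   - cn_uptake + cn_endo.recycled_to_interstitial)
    d[:, CNF] = d_cnf
    d[:, CNC] = d_cnc
    d[:, TVAS] = (cy.q_tis * (c_pl - c_tv) - flux_tp
                  - 0.5 * cy.cl_tissue * c_tv + t_endo.recycled_to_vascular)
    d[:, TINT] = (flux_tp - tissue_lymph - 0.5 * cy.cl_tissue * c_ti
                  + t_endo.recycled_to_interstitial)
    d[:, TF] = d_tf
    d[:, TC] = d_tc

    plasma_in = (cy.l_out_cn * c_cn + cy.q_tis * c_tv
                 + cn_endo.recycled_to_vascular + sc_venous_in + cy.synthesis)
    return d, plasma_in, cn_endo.catabolized, t_endo.catabolized


def terminal_half_life(model) -> float:
    """Terminal half-life (h) of a tracer dose of the drug.

    Linearizes the systemic-label drug subsystem about the endogenous
    steady state (the tracer does not perturb receptor occupancy, so the
    drug block of the Jacobian decouples) and returns ``ln 2`` over the
    slowest eigenvalue.
    """
    y_ss = model.initialize_steady_state()
    n = model.n_compartments
    sl = slice(model.SYS * n, (model.SYS + 1) * n)
    base = y_ss.copy()
    f0 = model.rhs(0.0, base)[sl]
    jac = np.empty((n, n))
    for j in range(n):
        eps = 1e-6 * max(1.0, abs(base[sl][j]))
        y = base.copy()
        y[sl.start + j] += eps
        jac[:, j] = (model.rhs(0.0, y)[sl] - f0) / eps
    eigs = np.linalg.eigvals(jac)
    rates = -eigs.real[eigs.real < -1e-12]
    if rates.size == 0:
        raise RuntimeError("no decaying mode found in the drug subsystem")
    return float(np.log(2.0) / rates.min())


@dataclass(frozen=True)
class CalibrationResult:
    synthesis_rate: float  # mg/h
    cl_up_tissue: float  # L/h
    fcrn_total_apc: float  # uM
    residuals: dict  # relative residual per target
    targets: dict

    @property
    def converged(self) -> bool:
        return all(abs(r) < 0.02 for r in self.residuals.values())


def _secant(func, x0, x1, *, rtol=1e-3, max_iter=25, bounds=None):
    f0, f1 = func(x0), func(x1)
    for _ in range(max_iter):
        if abs(f1) < rtol:
            return x1, f1
        if f1 == f0:
            break
        x2 = x1 - f1 * (x1 - x0) / (f1 - f0)
        if bounds is not None:
            x2 = min(max(x2, bounds[0]), bounds[1])
        x0, f0, x1 = x1, f1, x2
        f1 = func(x1)
    return x1, f1


def calibrate(targets: dict | None = None, *, outer_iterations: int = 3,
              base_overrides: dict | None = None,
              verbose: bool = False) -> CalibrationResult:
    """Fit the three unpublished constants to their anchors, once.

    ``targets`` may override ``terminal_half_life`` (days), ``baseline_igg``
    (g/L) and ``base_bioavailability`` (fraction, arm, 10 mg).  The returned
    parameter set is intended to be frozen to the packaged calibration file
    and never tuned again.
    """
    from .simulation_engine import (ScenarioSpec, apply_overrides, build_model,
                                    default_parameters, simulate)
    from .physiology import DrugProperties

    t = {"terminal_half_life": 21.0, "baseline_igg": 12.0,
         "base_bioavailability": 0.651}
    if targets:
        t.update(targets)

    drug = DrugProperties(dose=10.0, injection_site="arm")
    params = default_parameters("arm", calibrated=False)
    if base_overrides:
        params = apply_overrides(params, base_overrides)

    def with_knobs(synthesis, cl_up, fcrn_apc):
        sp = replace(params.systemic, synthesis_rate=synthesis, cl_up_tissue=cl_up)
        apc = replace(params.apc, fcrn_total_endosomal=fcrn_apc)
        return replace(params, systemic=sp, apc=apc)

    synthesis = params.systemic.synthesis_rate
    cl_up = params.systemic.cl_up_tissue
    fcrn_apc = params.apc.fcrn_total_endosomal

    def plasma_igg(synth, cl):
        m = build_model(with_knobs(synth, cl, fcrn_apc), drug)
        y = m.initialize_steady_state()
        return m.plasma_concentration(y, m.ENDO) / 1000.0  # g/L

    def half_life_days(cl):
        m = build_model(with_knobs(synthesis, cl, fcrn_apc), drug)
        return terminal_half_life(m) / 24.0

    def bioavailability_of(fcrn):
        scenario = ScenarioSpec(drug=drug, rtol=1e-8, atol=1e-10)
        res = simulate(scenario, parameters=with_knobs(synthesis, cl_up, fcrn))
        return res.bioavailability

    def solve_synthesis(cl):
        nonlocal synthesis
        synthesis, _ = _secant(
            lambda s: plasma_igg(s, cl) / t["baseline_igg"] - 1.0,
            synthesis, synthesis * 1.2, rtol=5e-4, bounds=(1.0, 1e4),
        )
        return synthesis

    def half_life_consistent(cl):
        # The terminal half-life of a tracer depends on the endogenous
        # occupancy backdrop, so the synthesis rate is re-anchored to the
        # 12 g/L baseline at every trial uptake clearance.
        solve_synthesis(cl)
        return half_life_days(cl)

    for it in range(outer_iterations):
        cl_up, _ = _secant(
            lambda cl: half_life_consistent(cl) / t["terminal_half_life"] - 1.0,
            cl_up, cl_up * 1.3, rtol=2e-3, bounds=(1e-4, 10.0),
        )
        solve_synthesis(cl_up)
        fcrn_apc, f_res = _secant(
            lambda f: bioavailability_of(f) / t["base_bioavailability"] - 1.0,
            fcrn_apc, fcrn_apc * 1.3, rtol=5e-4, bounds=(0.1, 5e3),
        )
        if verbose:
            print(f"iteration {it}: synthesis={synthesis:.3f} mg/h, "
                  f"cl_up_tissue={cl_up:.5f} L/h, fcrn_apc={fcrn_apc:.3f} uM")

    residuals = {
        "terminal_half_life": half_life_days(cl_up) / t["terminal_half_life"] - 1.0,
        "baseline_igg": plasma_igg(synthesis, cl_up) / t["baseline_igg"] - 1.0,
        "base_bioavailability": f_res,
    }
    result = CalibrationResult(
        synthesis_rate=synthesis, cl_up_tissue=cl_up, fcrn_total_apc=fcrn_apc,
        residuals=residuals, targets=t,
    )
    if not result.converged:
        raise RuntimeError(f"calibration failed; residuals: {residuals}")
    return result
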