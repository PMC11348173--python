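"""The subcutaneous injection site: vascular, endothelial-endosomal and
interstitial spaces.

The site is permeability-limited: plasma perfuses the vascular space at
``Q_sc``, macromolecules reach the interstitium through the two-pore
pathway, and the interstitium drains into the lymph capillaries at the
afferent lymph flow (hindered by the lymphatic reflection coefficient).
Endothelial cells pinocytose from both faces into an endosomal space (5% of
the vascular volume times a 25% endosomal fraction, i.e. 0.06% of the site)
where FcRn salvage operates.  The bolus dose is placed in the interstitial
space at t = 0.

Only a fraction of the anatomical interstitial volume is accessible to an
IgG-sized solute (steric exclusion by the collagen/glycosaminoglycan
matrix); amounts are divided by the accessible volume to obtain the
concentrations driving the fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fcrn_engine import EndosomePool, endosome_derivatives
from .physiology import BodyPhysiology, SitePhysiology
from .two_pore import TwoPoreParams, net_solute_flux, pore_fluid_flows

__all__ = ["CompiledScSite", "build_sc_site", "sc_site_derivatives"]

# Column order of the site state block (per species).
VAS, ENDF, ENDC, INT = 0, 1, 2, 3


@dataclass(frozen=True)
class CompiledScSite:
    """Absolute volumes, flows and rate constants of one injection site."""

    v_vascular: float  # L
    v_interstitial: float  # L, accessible to the solute
    q_sc: float  # L/h
    l_aff: float  # L/h
    sigma_lymph: float
    cl_endosomal: float  # L/h, fluid-phase uptake into the endothelial endosome
    j_small: float  # L/h
    j_large: float
    two_pore: TwoPoreParams
    pool: EndosomePool


def build_sc_site(site: SitePhysiology, body: BodyPhysiology,
                  two_pore: TwoPoreParams, pool: EndosomePool,
                  k_endothelial_uptake: float,
                  interstitial_access: float) -> CompiledScSite:
    """Resolve per-kg fractions into absolute volumes and flows."""
    v_site = site.v_site * body.body_weight
    l_aff = site.l_aff * body.total_lymph_flow
    j_small, j_large = pore_fluid_flows(l_aff, two_pore)
    if not 0 < interstitial_access <= 1:
        raise ValueError("interstitial_access must lie in (0, 1]")
    return CompiledScSite(
        v_vascular=site.f_vascular * v_site,
        v_interstitial=site.f_interstitial * v_site * interstitial_access,
        q_sc=site.q_sc * body.cardiac_output,
        l_aff=l_aff,
        sigma_lymph=two_pore.sigma_lymph,
        cl_endosomal=k_endothelial_uptake * pool.volume,
        j_small=j_small,
        j_large=j_large,
        two_pore=two_pore,
        pool=pool,
    )


def sc_site_derivatives(cs: CompiledScSite, amounts: np.ndarray,
                        c_arterial: np.ndarray,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Right-hand side of the site block for all species at once.

    ``amounts`` has shape ``(n_species, 4)`` with columns (vascular,
    endosome free, endosome bound, interstitial) in mg.  Returns the state
    derivatives plus three boundary fluxes (mg/h, per species): outflow to
    the lymph capillary, venous outflow to plasma, and catabolized mass.
    """
    c_vas = amounts[:, VAS] / cs.v_vascular
    c_int = amounts[:, INT] / cs.v_interstitial
    tp = cs.two_pore
    n_sp = amounts.shape[0]
    flux_tp = np.empty(n_sp)
    for s in range(n_sp):
        flux_tp[s] = net_solute_flux(
            c_vas[s], c_int[s], cs.j_small, tp.ps_small, tp.sigma_v_small
        ) + net_solute_flux(
            c_vas[s], c_int[s], cs.j_large, tp.ps_large, tp.sigma_v_large
        )
    uptake = 0.5 * cs.cl_endosomal * (c_vas + c_int)
    d_free, d_cplx, endo = endosome_derivatives(
        cs.pool, amounts[:, ENDF], amounts[:, ENDC], uptake
    )
    lymph_out = cs.l_aff * (1.0 - cs.sigma_lymph) * c_int
    venous_out = cs.q_sc * c_vas

    d = np.empty_like(amounts)
    d[:, VAS] = (cs.q_sc * c_arterial - venous_out - flux_tp
                 - 0.5 * cs.cl_endosomal * c_vas + endo.recycled_to_vascular)
    d[:, ENDF] = d_free
    d[:, ENDC] = d_cplx
    d[:, INT] = (flux_tp - lymph_out - 0.5 * cs.cl_endosomal * c_int
                 + endo.recycled_to_interstitial)
    return d, lymph_out, venous_out, endo.catabolized
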