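"""Lymphatic first-pass path: lymph capillary and draining-node compartments.

Afferent lymph carries the drained interstitial fluid through the lymph
capillaries into the peripheral lymph nodes, where the resident
antigen-presenting cells (APCs: macrophages, dendritic cells, B cells —
lumped as one high-macropinocytosis population) continuously sample the
node fluid.  The APC population turns the node fluid over at the
fluid-phase endocytosis rate ``k_up``, so the uptake clearance is
``k_up x V_node``; internalized material enters the APC endosomal pool
(24.5% APC volume x 25% endosomal fraction of the node volume) where
saturable FcRn salvage decides between recycling back to the node fluid and
lysosomal catabolism.  Recycled material re-enters the node fluid on both
routing branches because node-resident APCs have no vascular face.

Only ``f_efferent`` (93%) of the afferent flow leaves as efferent lymph;
the remainder is resorbed to plasma through aquaporins as solute-free
water, concentrating the node fluid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fcrn_engine import EndosomePool, endosome_derivatives
from .physiology import APCParams, BodyPhysiology, SitePhysiology
from .two_pore import aquaporin_water_flux

__all__ = [
    "CompiledLymphPath",
    "build_lymph_path",
    "lymph_path_derivatives",
    "apc_uptake_clearance",
    "apc_uptake_flux",
]

# Column order of the lymph-path state block (per species).
CAP, NODE, APCF, APCC = 0, 1, 2, 3


def apc_uptake_clearance(site: SitePhysiology, apc: APCParams,
                         body: BodyPhysiology, k_up_multiplier: float = 1.0) -> float:
    """Fluid-phase uptake clearance of the node-resident APC population (L/h).

    The lumped APC population processes the node fluid at ``k_up`` per hour
    of the node volume: lymph percolates through the APC-lined sinuses, so
    the sampling domain of the population is the node compartment itself.
    """
    if k_up_multiplier < 0:
        raise ValueError("k_up_multiplier must be non-negative")
    v_node = site.v_node * body.body_weight
    return k_up_multiplier * apc.k_up * v_node


def apc_uptake_flux(c_node: float, site: SitePhysiology, apc: APCParams,
                    body: BodyPhysiology, k_up_multiplier: float = 1.0) -> float:
    """Mass uptake into APCs (mg/h) at a node-fluid concentration (mg/L)."""
    if c_node < 0:
        raise ValueError("c_node must be non-negative")
    return apc_uptake_clearance(site, apc, body, k_up_multiplier) * c_node


@dataclass(frozen=True)
class CompiledLymphPath:
    """Absolute volumes and flows of the capillary/node path."""

    v_capillary: float  # L
    v_node_fluid: float  # L, node volume outside the APCs
    l_aff: float  # L/h
    l_eff: float  # L/h
    q_aquaporin: float  # L/h, water only
    cl_apc: float  # L/h
    pool: EndosomePool
    # Per-species gate on APC uptake.  The APC pathway is pre-systemic
    # clearance of the dosed protein only: endogenous IgG passes the node
    # convectively without entering the APC endosomes, so the APC
    # compartment plays no part in endogenous-IgG homeostasis.
    uptake_gate: np.ndarray = None  # type: ignore[assignment]


def build_lymph_path(site: SitePhysiology, apc: APCParams, body: BodyPhysiology,
                     pool: EndosomePool, k_up_multiplier: float = 1.0,
                     uptake_gate=None) -> CompiledLymphPath:
    l_aff = site.l_aff * body.total_lymph_flow
    if uptake_gate is None:
        uptake_gate = np.array([1.0, 1.0, 0.0])  # dose, systemic, endogenous
    return CompiledLymphPath(
        v_capillary=site.v_lymph_capillary * body.body_weight,
        v_node_fluid=(1.0 - apc.f_apc_of_node) * site.v_node * body.body_weight,
        l_aff=l_aff,
        l_eff=site.f_efferent * l_aff,
        q_aquaporin=aquaporin_water_flux(l_aff, site.f_efferent),
        cl_apc=apc_uptake_clearance(site, apc, body, k_up_multiplier),
        pool=pool,
        uptake_gate=np.asarray(uptake_gate, dtype=float),
    )


def lymph_path_derivatives(lp: CompiledLymphPath, amounts: np.ndarray,
                           inflow_from_site: np.ndarray,
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-hand side of the capillary/node/APC block.

    ``amounts`` has shape ``(n_species, 4)`` with columns (capillary fluid,
    node fluid, APC endosome free, APC endosome bound) in mg.  Returns the
    derivatives plus the efferent boundary flux to the central lymph and the
    catabolized mass flux (both mg/h per species).  The aquaporin water flux
    carries no solute and therefore does not appear in the solute balance.
    """
    c_cap = amounts[:, CAP] / lp.v_capillary
    c_node = amounts[:, NODE] / lp.v_node_fluid
    uptake = lp.cl_apc * c_node * lp.uptake_gate
    d_free, d_cplx, endo = endosome_derivatives(
        lp.pool, amounts[:, APCF], amounts[:, APCC], uptake
    )
    # Both recycling branches re-enter the node fluid.
    recycled = endo.recycled_to_vascular + endo.recycled_to_interstitial
    efferent_out = lp.l_eff * c_node

    d = np.empty_like(amounts)
    d[:, CAP] = inflow_from_site - lp.l_aff * c_cap
    d[:, NODE] = lp.l_aff * c_cap - efferent_out - uptake + recycled
    d[:, APCF] = d_free
    d[:, APCC] = d_cplx
    return d, efferent_out, endo.catabolized
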