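"""Physiological parameters of the subcutaneous injection sites and the body.

The injection-site parameter set (volumes, perfusion, lymph flows, draining
lymph-node geometry) is reproduced from published measurements: the site
volume from the travel distance of labeled albumin to sentinel lymph nodes
(circular spread times a subcutaneous thickness of 1.91 mm), perfusion from
tissue-specific blood flow per 100 g of skin, the draining-node compartment
from the mean single-node volume (0.284 mL) times the per-site node count,
and the antigen-presenting-cell (APC) fraction of the node from mouse
subcapsular-sinus macrophage counts.  The module exposes both the derivation
functions and the resulting per-site default tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "BodyPhysiology",
    "SitePhysiology",
    "APCParams",
    "FcRnKinetics",
    "DrugProperties",
    "SITE_NAMES",
    "derive_site_volume",
    "derive_node_volume",
    "derive_macrophage_fraction",
    "blood_flow_fraction",
    "site_defaults",
]

SITE_NAMES = ("arm", "abdomen", "back", "thigh")

#: Subcutaneous thickness used for the site-volume derivation (mm).
SC_THICKNESS_MM = 1.91
#: Mean volume of a single (cervical) lymph node (mL).
SINGLE_NODE_VOLUME_ML = 0.284
#: Midpoints of the published per-site draining-node-count ranges.
NODE_COUNT = {"arm": 30.5, "abdomen": 22.0, "back": 24.5, "thigh": 22.0}
#: Tissue-specific skin blood flow (mL/min/100 g).
SPECIFIC_BLOOD_FLOW = {"arm": 9.2, "abdomen": 2.9, "back": 7.4, "thigh": 6.0}


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class BodyPhysiology:
    """Whole-body constants of the population-representative individual.

    The body weight is back-solved from the published site volumes and their
    geometric inputs; cardiac output and total lymph flow are the simulator
    population-representative values.
    """

    body_weight: float = 74.8  # kg
    cardiac_output: float = 397.5  # L/h
    total_lymph_flow: float = 0.391  # L/h
    plasma_volume: float = 2.9  # L
    baseline_endogenous_igg: float = 12.0  # g/L
    skin_density: float = 1.1  # g/mL

    def __post_init__(self) -> None:
        _require_positive(
            body_weight=self.body_weight,
            cardiac_output=self.cardiac_output,
            total_lymph_flow=self.total_lymph_flow,
            plasma_volume=self.plasma_volume,
            baseline_endogenous_igg=self.baseline_endogenous_igg,
            skin_density=self.skin_density,
        )
        if not self.total_lymph_flow < self.cardiac_output:
            raise ValueError("total_lymph_flow must be smaller than cardiac_output")


@dataclass(frozen=True)
class SitePhysiology:
    """One injection site: volumes, flows and draining-lymphatic geometry.

    Volumes are per kg body weight; flows are fractions of cardiac output
    (``q_sc``) or of total lymph flow (``l_aff``).  ``f_efferent`` is the
    efferent/afferent lymph-flow ratio; the remaining fluid leaves the node
    through aquaporins, which exclude macromolecules.
    """

    site_name: str
    v_site: float  # L/kg
    q_sc: float  # fraction of cardiac output
    l_aff: float  # fraction of total lymph flow
    v_lymph_capillary: float  # L/kg
    v_node: float  # L/kg
    n_nodes: float
    f_vascular: float = 0.05
    f_endosomal: float = 0.0006
    f_interstitial: float = 0.595
    f_efferent: float = 0.93

    def __post_init__(self) -> None:
        _require_positive(
            v_site=self.v_site,
            q_sc=self.q_sc,
            l_aff=self.l_aff,
            v_lymph_capillary=self.v_lymph_capillary,
            v_node=self.v_node,
            n_nodes=self.n_nodes,
            f_vascular=self.f_vascular,
            f_endosomal=self.f_endosomal,
            f_interstitial=self.f_interstitial,
        )
        if self.f_vascular + self.f_endosomal + self.f_interstitial > 1.0:
            raise ValueError("compartment fractions of the site volume exceed 1")
        if not 0 < self.f_efferent <= 1:
            raise ValueError("f_efferent must lie in (0, 1]")


@dataclass(frozen=True)
class APCParams:
    """Antigen-presenting-cell compartment of the draining lymph nodes.

    ``k_up`` is the fluid-phase (macropinocytotic) uptake rate; the APC
    population of the model turns over the node fluid at this rate, so the
    uptake clearance is ``k_up x node volume``.  ``f_apc_of_node`` sets the
    APC volume (and with ``f_endosome_of_apc`` the endosomal volume where
    FcRn binding and catabolism take place).  ``fcrn_total_endosomal`` is the
    total FcRn concentration in APC endosomes; it is the designated
    calibration constant of the model.
    """

    f_apc_of_node: float = 0.245
    k_up: float = 0.25  # 1/h
    f_endosome_of_apc: float = 0.25
    fcrn_total_endosomal: float = 49.8  # uM, overwritten by calibration
    # Fraction of the FcRn-bound recycling traffic in APC macropinosomes
    # missorted to degradation (recycling from large macropinosomes is less
    # efficient than from endothelial sorting endosomes); overwritten by
    # calibration.
    recycling_missort: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.f_apc_of_node < 1:
            raise ValueError("f_apc_of_node must lie in [0, 1)")
        if self.k_up < 0:
            raise ValueError("k_up must be non-negative")
        if not 0 < self.f_endosome_of_apc <= 1:
            raise ValueError("f_endosome_of_apc must lie in (0, 1]")
        if self.fcrn_total_endosomal < 0:
            raise ValueError("fcrn_total_endosomal must be non-negative")
        if not 0 <= self.recycling_missort <= 1:
            raise ValueError("recycling_missort must lie in [0, 1]")


@dataclass(frozen=True)
class FcRnKinetics:
    """Binding, recycling and catabolism constants of the FcRn salvage path.

    Binding is kinetic (``k_on``/``k_off``) because the transient saturation
    of the receptor is the mechanism of interest; ``k_off`` is tied to the
    equilibrium constant via ``k_off = k_on * kd_ph6``.  The endosomal
    maturation rate ``k_int`` feeds the catabolic branch: the unbound species
    is degraded at ``k_cat = f_cat * k_int``.  ``fr`` routes the recycled
    (receptor-bound) material between the vascular (``fr``) and interstitial
    (``1 - fr``) faces of the cell.
    """

    kd_ph6: float = 0.728  # uM
    k_on: float = 360.0  # 1/(uM h)  (~1e5 1/(M s))
    k_rc: float = 1.0  # 1/h
    k_int: float = 1.0  # 1/h
    f_cat: float = 1.0
    fr: float = 0.715

    def __post_init__(self) -> None:
        _require_positive(kd_ph6=self.kd_ph6, k_on=self.k_on)
        for name in ("k_rc", "k_int"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.f_cat <= 1:
            raise ValueError("f_cat must lie in [0, 1]")
        if not 0 <= self.fr <= 1:
            raise ValueError("fr must lie in [0, 1]")

    @property
    def k_off(self) -> float:
        """Dissociation rate (1/h), ``k_on * kd_ph6`` exactly."""
        return self.k_on * self.kd_ph6

    @property
    def k_cat(self) -> float:
        """Catabolism rate of the unbound endosomal species (1/h)."""
        return self.f_cat * self.k_int

    def cl_cat(self, v_endosome: float) -> float:
        """Catabolic clearance (L/h) for an endosomal volume in litres."""
        return self.k_cat * v_endosome

    def with_kd(self, kd_ph6: float) -> "FcRnKinetics":
        return replace(self, kd_ph6=kd_ph6)


@dataclass(frozen=True)
class DrugProperties:
    """The dosed therapeutic protein."""

    name: str = "IgG"
    molecular_weight: float = 150_000.0  # g/mol
    kd_ph6: float = 0.728  # uM
    dose: float = 10.0  # mg
    injection_site: str = "arm"
    k_up_multiplier: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(molecular_weight=self.molecular_weight, kd_ph6=self.kd_ph6)
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.injection_site not in SITE_NAMES:
            raise KeyError(f"unknown injection site {self.injection_site!r}")
        if self.k_up_multiplier < 0:
            raise ValueError("k_up_multiplier must be non-negative")


def derive_site_volume(travel_distance_cm: float, sc_thickness_mm: float,
                       body_weight_kg: float) -> float:
    """Injection-site volume per body mass (L/kg) from lymphatic spread.

    The measured travel distance of labeled albumin to the sentinel node is
    taken as the *diameter* of a circular distribution region of the given
    subcutaneous thickness; this is the convention that reproduces the
    published per-site volumes.
    """
    _require_positive(
        travel_distance_cm=travel_distance_cm,
        sc_thickness_mm=sc_thickness_mm,
        body_weight_kg=body_weight_kg,
    )
    radius_cm = travel_distance_cm / 2.0
    volume_ml = math.pi * radius_cm**2 * (sc_thickness_mm / 10.0)  # cm^3 == mL
    return volume_ml / 1000.0 / body_weight_kg


def derive_node_volume(n_nodes: float, single_node_volume_ml: float,
                       body_weight_kg: float) -> float:
    """Draining-node compartment volume per body mass (L/kg)."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be at least 1")
    _require_positive(
        single_node_volume_ml=single_node_volume_ml, body_weight_kg=body_weight_kg
    )
    return n_nodes * single_node_volume_ml / 1000.0 / body_weight_kg


def derive_macrophage_fraction(n_scs_macrophages: float, scs_fraction: float,
                               v_macrophage_ml: float, v_node_mouse_ml: float) -> float:
    """APC volume fraction of a lymph node from subcapsular-sinus counts.

    Scales the counted subcapsular-sinus macrophages by their share of the
    total macrophage lineage, multiplies by the single-cell volume and
    divides by the (mouse) node volume.
    """
    if not 0 < scs_fraction <= 1:
        raise ValueError("scs_fraction must lie in (0, 1]")
    if n_scs_macrophages < 0:
        raise ValueError("n_scs_macrophages must be non-negative")
    _require_positive(v_macrophage_ml=v_macrophage_ml, v_node_mouse_ml=v_node_mouse_ml)
    return (n_scs_macrophages / scs_fraction) * v_macrophage_ml / v_node_mouse_ml


def blood_flow_fraction(specific_flow_ml_min_100g: float, v_site: float,
                        body_weight_kg: float, skin_density_g_ml: float,
                        cardiac_output_l_h: float) -> float:
    """Convert skin perfusion (mL/min/100 g) to a fraction of cardiac output."""
    if specific_flow_ml_min_100g < 0:
        raise ValueError("specific_flow must be non-negative")
    _require_positive(
        v_site=v_site,
        body_weight_kg=body_weight_kg,
        skin_density_g_ml=skin_density_g_ml,
        cardiac_output_l_h=cardiac_output_l_h,
    )
    site_mass_g = v_site * body_weight_kg * 1000.0 * skin_density_g_ml
    flow_l_h = specific_flow_ml_min_100g * (site_mass_g / 100.0) * 60.0 / 1000.0
    return flow_l_h / cardiac_output_l_h


# Published per-site table, as printed (volumes L/kg, flows as fractions).
_SITE_TABLE = {
    "arm": dict(v_site=0.00077, q_sc=0.00088, l_aff=0.00191,
                v_lymph_capillary=0.000352, v_node=0.000116),
    "abdomen": dict(v_site=0.00099, q_sc=0.00035, l_aff=0.00205,
                    v_lymph_capillary=0.000392, v_node=8.38e-5),
    "back": dict(v_site=0.00115, q_sc=0.00105, l_aff=0.00262,
                 v_lymph_capillary=0.000415, v_node=9.52e-5),
    "thigh": dict(v_site=0.00099, q_sc=0.00073, l_aff=0.00272,
                  v_lymph_capillary=0.000387, v_node=8.38e-5),
}


def site_defaults(site_name: str) -> SitePhysiology:
    """Published parameter row for one of the four injection sites."""
    try:
        row = _SITE_TABLE[site_name]
    except KeyError:
        raise KeyError(
            f"unknown site {site_name!r}; expected one of {SITE_NAMES}"
        ) from None
    return SitePhysiology(site_name=site_name, n_nodes=NODE_COUNT[site_name], **row)


def load_site_table(path=None) -> dict[str, SitePhysiology]:
    """Site parameter sets from a structured text config.

    Without a path, reads the bundled file, which reproduces the published
    per-site table exactly (asserted by the test suite).
    """
    import yaml

    if path is None:
        from importlib import resources

        with resources.files("scpbpk").joinpath("data/sites.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return {name: SitePhysiology(site_name=name, **row) for name, row in raw.items()}
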