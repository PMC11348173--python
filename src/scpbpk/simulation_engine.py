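"""Full-model assembly, integration and analysis.

The state vector concatenates three species — the dose-origin drug label,
the systemic-origin drug label and endogenous IgG — over sixteen
compartments (SC site, lymphatic first-pass path, systemic backdrop), plus
a cumulative elimination ledger.  Bioavailability is computed by
dose-origin splitting: any dose-label mass arriving in systemic plasma
(efferent central-lymph outflow, SC venous return, vascular-face recycling
of the central node) is relabeled to the systemic label at that instant, so
drug returning to the injection site is systemic-origin by construction and

    F = cumulative dose-label arrival in plasma / dose.

The ledger tracks catabolized mass per pathway (SC endothelium, draining-
node APCs, central lymph node, systemic tissue) per species, which closes
the mass balance against F exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from functools import cached_property
from importlib import resources
from itertools import permutations

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

from .fcrn_engine import EndosomePool, FreeFcRnSeries, free_fcrn_percent
from .lymph_path_model import (CompiledLymphPath, build_lymph_path,
                               lymph_path_derivatives)
from .physiology import (APCParams, BodyPhysiology, DrugProperties,
                         FcRnKinetics, SitePhysiology, site_defaults)
from .sc_site_model import build_sc_site, sc_site_derivatives
from .two_pore import TwoPoreParams, igg_two_pore_params
from .whole_body_model import (CompiledSystemic, SystemicParams,
                               build_systemic, systemic_derivatives)

__all__ = [
    "ModelParameters",
    "default_parameters",
    "apply_overrides",
    "ScenarioSpec",
    "SimulationResult",
    "PopulationResult",
    "CompiledModel",
    "build_model",
    "simulate",
    "pk_metrics",
    "site_comparison",
    "knockout_cohorts",
    "sensitivity_sweep",
    "population_sample",
    "ConfigError",
    "InitializationError",
    "IntegrationError",
]

ENDOGENOUS_IGG_MW = 150_000.0  # g/mol

# Species indices.
DOSE, SYS, ENDO = 0, 1, 2
N_COMP = 16
# Compartment indices within one species block.
SC_VAS, SC_ENDF, SC_ENDC, SC_INT = 0, 1, 2, 3
CAP, NODE, APCF, APCC = 4, 5, 6, 7
PLASMA, CNODE, CNF, CNC, TVAS, TINT, TF, TC = 8, 9, 10, 11, 12, 13, 14, 15

PATHWAYS = ("sc_endothelium", "draining_node_apc", "central_lymph_node",
            "systemic_tissue")


@dataclass(frozen=True)
class StateLayout:
    """Index bookkeeping for the flattened state vector.

    Each species occupies ``n_comp`` columns: the 16 canonical compartments
    (indices above) followed by any extra lymph-capillary transit stages
    appended at the end of the block (the canonical ``CAP`` column is the
    *last* stage of the chain).  The cumulative elimination ledger sits
    after the three species blocks.
    """

    extra_stages: int  # transit stages before the canonical capillary column

    @property
    def n_comp(self) -> int:
        return N_COMP + self.extra_stages

    @property
    def n_state(self) -> int:
        return 3 * self.n_comp

    @property
    def led_sc(self) -> int:
        return self.n_state

    @property
    def led_apc(self) -> int:
        return self.n_state + 3

    @property
    def led_cn(self) -> int:
        return self.n_state + 6

    @property
    def led_tis(self) -> int:
        return self.n_state + 9

    @property
    def led_arrival(self) -> int:
        return self.n_state + 12

    @property
    def n_total(self) -> int:
        return self.n_state + 13

    @property
    def ledgers(self) -> tuple[int, int, int, int]:
        return (self.led_sc, self.led_apc, self.led_cn, self.led_tis)

    def idx(self, species: int, compartment: int) -> int:
        return species * self.n_comp + compartment

    def species_slice(self, species: int) -> slice:
        return slice(species * self.n_comp, (species + 1) * self.n_comp)


class ConfigError(ValueError):
    """Invalid scenario configuration or override path."""


class InitializationError(RuntimeError):
    """Pre-dose steady state could not be established."""


class IntegrationError(RuntimeError):
    """The stiff solver failed, or the horizon left too much residual dose."""


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set of the coupled model (drug excluded)."""

    body: BodyPhysiology
    site: SitePhysiology
    apc: APCParams
    drug_kinetics: FcRnKinetics
    endo_kinetics: FcRnKinetics
    two_pore_site: TwoPoreParams
    two_pore_tissue: TwoPoreParams
    systemic: SystemicParams
    fcrn_total_endothelial: float = 49.8  # uM
    # IgG is sterically excluded from roughly half the interstitial matrix.
    interstitial_access: float = 0.48
    # Lymph capillaries are valved conduits, closer to a transit line than
    # to a mixing tank: the printed capillary volume over the afferent flow
    # is a residence time (35 h for the arm), modeled as an Erlang chain.
    capillary_transit_stages: int = 12


def _load_calibration() -> dict:
    ref = resources.files("scpbpk").joinpath("data/calibration.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def default_parameters(site_name: str = "arm", *, calibrated: bool = True,
                       body: BodyPhysiology | None = None) -> ModelParameters:
    """Default parameter set for one injection site.

    With ``calibrated=True`` (the normal mode) the frozen calibration of the
    unpublished constants — endogenous synthesis rate, tissue uptake
    clearance, APC endosomal FcRn — is applied on top of the physiological
    defaults.
    """
    body = body or BodyPhysiology()
    site = site_defaults(site_name)
    l_aff = site.l_aff * body.total_lymph_flow
    l_tissue = body.total_lymph_flow - l_aff
    params = ModelParameters(
        body=body,
        site=site,
        apc=APCParams(),
        drug_kinetics=FcRnKinetics(),
        endo_kinetics=FcRnKinetics(),
        two_pore_site=igg_two_pore_params(l_aff),
        # The lumped tissue stands in for the whole body, including the
        # leaky fenestrated beds (liver, spleen, gut) that dominate IgG
        # distribution, hence the larger permeability fractions than the
        # continuous-capillary skin site.
        two_pore_tissue=igg_two_pore_params(
            l_tissue, ps_small_fraction=0.05, ps_large_fraction=0.5
        ),
        systemic=SystemicParams(),
    )
    if calibrated:
        cal = _load_calibration()
        params = replace(
            params,
            apc=replace(params.apc, fcrn_total_endosomal=cal["fcrn_total_apc"]),
            systemic=replace(params.systemic,
                             synthesis_rate=cal["synthesis_rate"],
                             cl_up_tissue=cal["cl_up_tissue"]),
        )
    return params


def apply_overrides(params: ModelParameters, overrides: dict) -> ModelParameters:
    """Apply dotted-path parameter overrides, e.g. ``{"apc.k_up": 0.5}``."""
    for path, value in overrides.items():
        parts = path.split(".")
        params = _replace_path(params, parts, value, path)
    return params


def _replace_path(obj, parts, value, full_path):
    name = parts[0]
    if not dataclasses.is_dataclass(obj) or not hasattr(obj, name):
        raise ConfigError(f"unknown parameter path {full_path!r}")
    if len(parts) == 1:
        current = getattr(obj, name)
        if dataclasses.is_dataclass(current):
            raise ConfigError(f"{full_path!r} names a parameter group, not a value")
        return replace(obj, **{name: type(current)(value)})
    return replace(obj, **{name: _replace_path(getattr(obj, name), parts[1:],
                                               value, full_path)})


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation run: drug, site, knockouts, overrides, numerics."""

    drug: DrugProperties = field(default_factory=DrugProperties)
    knockout_apc_fcrn: bool = False
    knockout_endothelial_fcrn: bool = False
    overrides: dict = field(default_factory=dict)
    horizon_days: float = 60.0
    rtol: float = 1e-8
    atol: float = 1e-10  # mg
    seed: int = 0
    population: int = 1

    def __post_init__(self) -> None:
        if self.horizon_days <= 0:
            raise ConfigError("horizon must be positive")
        if self.population < 1:
            raise ConfigError("population must be at least 1")

    @property
    def site_name(self) -> str:
        return self.drug.injection_site


class CompiledModel:
    """Assembled ODE system for one scenario's parameter set."""

    DOSE, SYS, ENDO = DOSE, SYS, ENDO

    def __init__(self, params: ModelParameters, drug: DrugProperties):
        self.params = params
        self.drug = drug
        if params.capillary_transit_stages < 1:
            raise ConfigError("capillary_transit_stages must be at least 1")
        self.layout = StateLayout(extra_stages=params.capillary_transit_stages - 1)
        body, site = params.body, params.site
        drug_k = replace(params.drug_kinetics, kd_ph6=drug.kd_ph6)
        kinetics = (drug_k, drug_k, params.endo_kinetics)
        mw = (drug.molecular_weight, drug.molecular_weight, ENDOGENOUS_IGG_MW)

        v_site = site.v_site * body.body_weight
        pool_sc = EndosomePool.build(
            site.f_endosomal * v_site, params.fcrn_total_endothelial, kinetics, mw
        )
        pool_apc = EndosomePool.build(
            apc_endosome_volume(site, params.apc, body),
            params.apc.fcrn_total_endosomal, kinetics, mw,
            missort=params.apc.recycling_missort,
        )
        pool_cn = EndosomePool.build(
            params.systemic.v_central_node_endosome,
            params.fcrn_total_endothelial, kinetics, mw,
        )
        pool_tis = EndosomePool.build(
            params.systemic.v_tissue_endosome,
            params.fcrn_total_endothelial, kinetics, mw,
        )
        self.site = build_sc_site(
            site, body, params.two_pore_site, pool_sc,
            params.systemic.k_endothelial_uptake, params.interstitial_access,
        )
        lymph = build_lymph_path(site, params.apc, body, pool_apc,
                                 drug.k_up_multiplier)
        # Split the capillary volume over the transit stages; the canonical
        # capillary column is the last stage of the chain.
        self.lymph = dataclasses.replace(
            lymph, v_capillary=lymph.v_capillary / params.capillary_transit_stages
        )
        self.systemic = build_systemic(params.systemic, body, site,
                                       params.two_pore_tissue, pool_cn, pool_tis)
        self._steady_state: np.ndarray | None = None

    @property
    def n_compartments(self) -> int:
        return self.layout.n_comp

    # ------------------------------------------------------------------ RHS
    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        L = self.layout
        A = y[:L.n_state].reshape(3, L.n_comp)
        c_arterial = A[:, PLASMA] / self.systemic.v_plasma
        d_site, lymph_out, venous, cat_sc = sc_site_derivatives(
            self.site, A[:, 0:4], c_arterial
        )
        dy = np.empty(L.n_total)
        dA = dy[:L.n_state].reshape(3, L.n_comp)
        # Capillary transit chain (extra stages, then the canonical column).
        inflow = lymph_out
        for k in range(L.extra_stages):
            col = N_COMP + k
            out_k = self.lymph.l_aff * A[:, col] / self.lymph.v_capillary
            dA[:, col] = inflow - out_k
            inflow = out_k
        d_lp, efferent, cat_apc = lymph_path_derivatives(
            self.lymph, A[:, 4:8], inflow
        )
        d_sys, plasma_in, cat_cn, cat_tis = systemic_derivatives(
            self.systemic, A[:, 8:16], efferent, venous
        )
        # Dose-origin relabeling at the moment of systemic arrival.
        arrival = plasma_in[DOSE]
        d_sys[SYS, PLASMA - 8] += plasma_in[SYS] + arrival
        d_sys[ENDO, PLASMA - 8] += plasma_in[ENDO]

        dA[:, 0:4] = d_site
        dA[:, 4:8] = d_lp
        dA[:, 8:16] = d_sys
        dy[L.led_sc:L.led_sc + 3] = cat_sc
        dy[L.led_apc:L.led_apc + 3] = cat_apc
        dy[L.led_cn:L.led_cn + 3] = cat_cn
        dy[L.led_tis:L.led_tis + 3] = cat_tis
        dy[L.led_arrival] = arrival
        return dy

    def plasma_concentration(self, y: np.ndarray, species: int) -> float:
        """Plasma concentration (mg/L) of one species."""
        return y[self.layout.idx(species, PLASMA)] / self.systemic.v_plasma

    # --------------------------------------------------------- steady state
    def _rhs_endo(self, t: float, x: np.ndarray) -> np.ndarray:
        y = np.zeros(self.layout.n_total)
        sl = self.layout.species_slice(ENDO)
        y[sl] = x
        return self.rhs(t, y)[sl]

    def _newton_polish(self, x: np.ndarray, max_iter: int = 20) -> np.ndarray:
        """Damped Newton iteration on the endogenous subsystem."""
        for _ in range(max_iter):
            f = self._rhs_endo(0.0, x)
            if np.max(np.abs(f) / (np.abs(x) + 1.0)) < 1e-12:
                break
            n = self.layout.n_comp
            jac = np.empty((n, n))
            for j in range(n):
                eps = 1e-7 * max(1.0, abs(x[j]))
                xp = x.copy()
                xp[j] += eps
                jac[:, j] = (self._rhs_endo(0.0, xp) - f) / eps
            try:
                step = np.linalg.solve(jac, -f)
            except np.linalg.LinAlgError:
                break
            lam = 1.0
            f0 = np.linalg.norm(f)
            while lam > 1e-4:
                x_new = x + lam * step
                if np.linalg.norm(self._rhs_endo(0.0, x_new)) < f0:
                    x = x_new
                    break
                lam *= 0.5
            else:
                break
        return x

    def initialize_steady_state(self) -> np.ndarray:
        """Pre-dose steady state of the endogenous-IgG subsystem.

        Integrates the autonomous endogenous subsystem to near-equilibrium
        and polishes with a damped Newton solve; raises
        ``InitializationError`` if the fixed point cannot be certified.
        Drug states are zero.  The result is cached per compiled model.
        """
        if self._steady_state is not None:
            return self._steady_state.copy()
        c = self.params.body.baseline_endogenous_igg * 1000.0  # mg/L guess
        x0 = np.zeros(self.layout.n_comp)
        x0[PLASMA] = c * self.systemic.v_plasma
        x0[TVAS] = c * self.systemic.v_tvas
        x0[SC_VAS] = c * self.site.v_vascular
        for idx, vol in ((SC_INT, self.site.v_interstitial),
                         (CAP, self.lymph.v_capillary),
                         (NODE, self.lymph.v_node_fluid),
                         (TINT, self.systemic.v_tint),
                         (CNODE, self.systemic.v_cnode)):
            x0[idx] = 0.3 * c * vol
        x0[N_COMP:] = 0.3 * c * self.lymph.v_capillary  # transit stages
        # Coarse equilibration rounds; the Newton polish supplies precision.
        x_ss = x0
        fnorm = np.inf
        for _ in range(4):
            sol = solve_ivp(self._rhs_endo, (0.0, 5e4), x_ss, method="BDF",
                            rtol=1e-6, atol=1e-6)
            if not sol.success:
                raise InitializationError(f"equilibration failed: {sol.message}")
            x_ss = self._newton_polish(np.maximum(sol.y[:, -1], 0.0))
            fnorm = np.max(np.abs(self._rhs_endo(0.0, x_ss))
                           / (np.abs(x_ss) + 1.0))
            if fnorm <= 1e-8:
                break
        if fnorm > 1e-8:
            raise InitializationError(
                f"steady state not converged; max residual {fnorm:.3e} per hour"
            )
        y = np.zeros(self.layout.n_total)
        y[self.layout.species_slice(ENDO)] = np.maximum(x_ss, 0.0)
        self._steady_state = y
        return y.copy()


def apc_endosome_volume(site: SitePhysiology, apc: APCParams,
                        body: BodyPhysiology) -> float:
    """Endosomal volume of the lumped APC population (L)."""
    return (apc.f_apc_of_node * apc.f_endosome_of_apc
            * site.v_node * body.body_weight)


def build_model(params: ModelParameters, drug: DrugProperties) -> CompiledModel:
    return CompiledModel(params, drug)


# ============================================================== simulation
@dataclass
class SimulationResult:
    """Time grid, trajectories and derived metrics of one run."""

    scenario: ScenarioSpec
    parameters: ModelParameters
    times: np.ndarray  # h
    states: np.ndarray  # (n_times, N_TOTAL), mg
    baseline: np.ndarray  # pre-dose steady state, (N_TOTAL,)
    model: CompiledModel

    @property
    def dose(self) -> float:
        return self.scenario.drug.dose

    def amounts(self, species: int, compartment: int) -> np.ndarray:
        return self.states[:, self.model.layout.idx(species, compartment)]

    @property
    def plasma_concentration(self) -> np.ndarray:
        """Total drug (both labels) plasma concentration, mg/L."""
        a = self.amounts(DOSE, PLASMA) + self.amounts(SYS, PLASMA)
        return a / self.model.systemic.v_plasma

    @property
    def residual_dose_label(self) -> float:
        """Dose-label mass still in transit at the horizon (mg)."""
        return float(self.states[-1, self.model.layout.species_slice(DOSE)].sum())

    @cached_property
    def bioavailability(self) -> float | None:
        """Fraction of the dose that reached systemic plasma; None if dose 0.

        Cross-checked against the complementary route (1 minus the
        pre-systemic catabolized fraction); disagreement beyond 0.2%
        absolute or residual dose-label mass above 0.1% of the dose raises
        ``IntegrationError``.
        """
        if self.dose == 0:
            return None
        if self.residual_dose_label > 1e-3 * self.dose:
            raise IntegrationError(
                "dose label not cleared at the horizon; extend horizon_days "
                f"(residual {self.residual_dose_label:.3g} mg)"
            )
        L = self.model.layout
        f = float(self.states[-1, L.led_arrival]) / self.dose
        presys = sum(float(self.states[-1, led + DOSE]) for led in L.ledgers)
        f_complement = 1.0 - presys / self.dose
        if abs(f - f_complement) > 2e-3:
            raise IntegrationError(
                f"bioavailability accountings disagree: {f:.5f} vs {f_complement:.5f}"
            )
        return f

    @cached_property
    def free_fcrn(self) -> FreeFcRnSeries:
        """Baseline-normalized free FcRn in the draining-node APC endosomes."""
        cols = [self.model.layout.idx(s, APCC) for s in (DOSE, SYS, ENDO)]
        return free_fcrn_percent(
            self.times, self.states[:, cols], self.lymph_pool,
            self.baseline[cols],
        )

    @property
    def lymph_pool(self) -> EndosomePool:
        return self.model.lymph.pool

    @cached_property
    def metrics(self) -> dict:
        return pk_metrics(self, self.parameters.body)

    @cached_property
    def ledger(self) -> pd.DataFrame:
        """Pathway-resolved cumulative eliminated mass at the horizon."""
        rows = {}
        for name, led in zip(PATHWAYS, self.model.layout.ledgers):
            end = self.states[-1, led:led + 3]
            start = self.baseline[led:led + 3]
            rows[name] = end - start
        df = pd.DataFrame(rows, index=["dose_mg", "systemic_mg", "endogenous_mg"]).T
        if self.dose > 0:
            df["dose_pct_of_dose"] = 100.0 * df["dose_mg"] / self.dose
        return df

    def site_depot_percent(self) -> np.ndarray:
        """Dose-label % of dose remaining at the SC site over time."""
        i0 = self.model.layout.idx(DOSE, SC_VAS)
        depot = self.states[:, i0:i0 + SC_INT + 1]
        return 100.0 * depot.sum(axis=1) / max(self.dose, np.finfo(float).tiny)


def _time_grid(horizon_h: float, dense_until: float = 120.0,
               dense_step: float = 0.1, coarse_step: float = 6.0) -> np.ndarray:
    dense_until = min(dense_until, horizon_h)
    dense = np.arange(0.0, dense_until, dense_step)
    coarse = np.arange(dense_until, horizon_h + 1e-9, coarse_step)
    return np.unique(np.concatenate([dense, coarse, [horizon_h]]))


def _scenario_parameters(scenario: ScenarioSpec,
                         parameters: ModelParameters | None) -> ModelParameters:
    params = parameters if parameters is not None else default_parameters(
        scenario.site_name
    )
    non_drug = {p: v for p, v in scenario.overrides.items()
                if not p.startswith("drug.")}
    if non_drug:
        params = apply_overrides(params, non_drug)
    if scenario.knockout_apc_fcrn:
        params = replace(params, apc=replace(params.apc, fcrn_total_endosomal=0.0))
    if scenario.knockout_endothelial_fcrn:
        params = replace(params, fcrn_total_endothelial=0.0)
    return params


def simulate(scenario: ScenarioSpec, *,
             parameters: ModelParameters | None = None) -> SimulationResult:
    """Run one scenario: equilibrate, apply the bolus at t = 0, integrate.

    Knockout cohorts are equilibrated *with* their knockout, i.e. they are
    virtual individuals at their own endogenous-IgG homeostasis.
    """
    drug = scenario.drug
    if "drug" in {p.split(".")[0] for p in scenario.overrides}:
        drug_over = {p.split(".", 1)[1]: v for p, v in scenario.overrides.items()
                     if p.startswith("drug.")}
        try:
            drug = replace(drug, **drug_over)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None
    params = _scenario_parameters(scenario, parameters)
    model = build_model(params, drug)
    y0 = model.initialize_steady_state()
    baseline = y0.copy()
    y0[model.layout.idx(DOSE, SC_INT)] += drug.dose
    horizon_h = scenario.horizon_days * 24.0
    t_eval = _time_grid(horizon_h)
    sol = solve_ivp(model.rhs, (0.0, horizon_h), y0, method="BDF",
                    rtol=scenario.rtol, atol=scenario.atol, t_eval=t_eval)
    if not sol.success:
        raise IntegrationError(f"stiff integration failed: {sol.message}")
    return SimulationResult(
        scenario=scenario, parameters=params, times=sol.t, states=sol.y.T,
        baseline=baseline, model=model,
    )


def pk_metrics(result: SimulationResult, body: BodyPhysiology) -> dict:
    """Cmax/tmax/AUC of the plasma drug concentration.

    The peak is refined by a local quadratic fit around the discrete
    maximum; ``cmax_percent_dose`` converts the peak concentration to the
    peak vascular amount as a percentage of the dose.
    """
    conc = result.plasma_concentration
    if conc.max() <= 0:
        raise ValueError("flat plasma trajectory; PK metrics undefined")
    from .fcrn_engine import _quadratic_refine

    i = int(np.argmax(conc))
    tmax, cmax = _quadratic_refine(result.times, conc, i)
    auc = float(np.trapezoid(conc, result.times))
    out = {
        "cmax_mg_per_l": float(cmax),
        "tmax_h": float(tmax),
        "tmax_days": float(tmax) / 24.0,
        "auc_mg_h_per_l": auc,
    }
    if result.dose > 0:
        out["cmax_percent_dose"] = 100.0 * cmax * body.plasma_volume / result.dose
    return out


def site_comparison(drug: DrugProperties, sites: list[str], *,
                    scenario_kwargs: dict | None = None) -> pd.DataFrame:
    """Pairwise Cmax/tmax/AUC ratios between injection sites.

    Runs the identical drug at every site and returns one row per ordered
    site pair.  Ratios largely cancel the systemic backdrop, which is why
    they are the robust cross-site observable.
    """
    if len(sites) < 2:
        raise ValueError("need at least two sites to compare")
    kwargs = scenario_kwargs or {}
    metrics = {}
    for site in sites:
        scenario = ScenarioSpec(drug=replace(drug, injection_site=site), **kwargs)
        res = simulate(scenario)
        metrics[site] = res.metrics | {"bioavailability": res.bioavailability}
    rows = []
    for a, b in permutations(sites, 2):
        rows.append({
            "pair": f"{a}/{b}",
            "cmax_ratio": metrics[a]["cmax_mg_per_l"] / metrics[b]["cmax_mg_per_l"],
            "tmax_ratio": metrics[a]["tmax_h"] / metrics[b]["tmax_h"],
            "auc_ratio": metrics[a]["auc_mg_h_per_l"] / metrics[b]["auc_mg_h_per_l"],
        })
    return pd.DataFrame(rows).set_index("pair")


def knockout_cohorts(drug: DrugProperties, *, scenario_kwargs: dict | None = None,
                     ) -> dict[str, float]:
    """Bioavailability of the four FcRn-knockout cohorts.

    cohort1 wildtype; cohort2 FcRn removed from draining-node APCs
    (hematopoietic analogue); cohort3 FcRn removed from every endothelial
    endosome; cohort4 global knockout.  Each cohort is simulated at its own
    endogenous steady state.
    """
    kwargs = scenario_kwargs or {}
    flags = {
        "cohort1": (False, False),
        "cohort2": (True, False),
        "cohort3": (False, True),
        "cohort4": (True, True),
    }
    out = {}
    for name, (apc_ko, endo_ko) in flags.items():
        scenario = ScenarioSpec(drug=drug, knockout_apc_fcrn=apc_ko,
                                knockout_endothelial_fcrn=endo_ko, **kwargs)
        out[name] = simulate(scenario).bioavailability
    return out


def sensitivity_sweep(scenario: ScenarioSpec, parameter_path: str,
                      values) -> pd.DataFrame:
    """One simulation per parameter value, all else identical."""
    rows = []
    for v in values:
        sc = replace(scenario, overrides={**scenario.overrides,
                                          parameter_path: v})
        res = simulate(sc)
        row = {"value": v, "bioavailability": res.bioavailability}
        row.update(res.metrics)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PopulationResult:
    """Per-individual results plus pointwise mean and 95% bands."""

    individuals: list[SimulationResult]
    times: np.ndarray
    plasma_mean: np.ndarray
    plasma_lo: np.ndarray
    plasma_hi: np.ndarray
    bioavailabilities: np.ndarray
    multipliers: pd.DataFrame


DEFAULT_POPULATION_CV = {
    "apc.k_up": 0.3,
    "site.v_site": 0.3,
    "site.v_node": 0.3,
    "site.v_lymph_capillary": 0.3,
    "site.l_aff": 0.3,
}


def population_sample(scenario: ScenarioSpec, n: int,
                      cv_map: dict[str, float] | None = None,
                      seed: int | None = None) -> PopulationResult:
    """Virtual population by median-preserving log-normal perturbation.

    Each listed physiological parameter is multiplied per individual by
    ``exp(sigma Z)`` with ``sigma = sqrt(ln(1 + CV^2))``; draws are fully
    reproducible from the seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    cvs = DEFAULT_POPULATION_CV if cv_map is None else cv_map
    for cv in cvs.values():
        if cv < 0:
            raise ValueError("coefficients of variation must be non-negative")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    base = _scenario_parameters(scenario, None)
    draws = []
    results = []
    for _ in range(n):
        mult = {p: float(np.exp(np.sqrt(np.log1p(cv**2)) * rng.standard_normal()))
                for p, cv in cvs.items()}
        draws.append(mult)
        params = base
        for path, m in mult.items():
            current = _get_path(base, path)
            params = apply_overrides(params, {path: current * m})
        results.append(simulate(replace(scenario, overrides={}),
                               parameters=params))
    times = results[0].times
    conc = np.stack([r.plasma_concentration for r in results])
    return PopulationResult(
        individuals=results,
        times=times,
        plasma_mean=conc.mean(axis=0),
        plasma_lo=np.percentile(conc, 2.5, axis=0),
        plasma_hi=np.percentile(conc, 97.5, axis=0),
        bioavailabilities=np.array([r.bioavailability for r in results]),
        multipliers=pd.DataFrame(draws),
    )


def _get_path(params: ModelParameters, path: str):
    obj = params
    for part in path.split("."):
        if not hasattr(obj, part):
            raise ConfigError(f"unknown parameter path {path!r}")
        obj = getattr(obj, part)
    return obj
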