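"""Endosomal FcRn binding, recycling and catabolism.

One endosomal pool (endothelial or APC) receives fluid-phase uptake of the
surrounding medium, where the acidic pH allows IgG-type species to bind
FcRn.  Receptor-bound material is recycled back to the cell surface at
``k_rc`` and survives; unbound material is committed to lysosomal
degradation at ``k_cat``.  All dosed and endogenous IgG species compete for
the same finite receptor pool, which is what makes the salvage saturable:
a transient spike in total endosomal IgG depresses the free receptor and
raises the catabolized fraction of *every* species.

Amounts are tracked in mg; receptor occupancy is evaluated in uM inside the
endosomal water volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EndosomePool", "EndosomeFluxes", "endosome_derivatives", "free_fcrn_percent"]


@dataclass(frozen=True)
class EndosomePool:
    """Precompiled constants of one endosomal pool shared by all species.

    Per-species rate arrays are aligned with the engine's species axis
    (dose-label drug, systemic-label drug, endogenous IgG).
    """

    volume: float  # L
    fcrn_total: float  # uM
    k_on: np.ndarray  # 1/(uM h), per species
    k_off: np.ndarray  # 1/h
    k_rc: np.ndarray  # 1/h
    k_cat: np.ndarray  # 1/h
    fr: np.ndarray  # dimensionless
    mg_to_um: np.ndarray  # conversion amount (mg) -> concentration (uM)
    # Fraction of the receptor-bound recycling traffic missorted to the
    # lysosomal branch instead of the cell surface.  Recycling is not
    # perfectly efficient; a nonzero missort puts a floor under the
    # catabolized fraction even when binding capacity is plentiful.
    missort: float = 0.0

    @staticmethod
    def build(volume: float, fcrn_total: float, kinetics, molecular_weights,
              missort: float = 0.0) -> "EndosomePool":
        """Assemble from per-species ``FcRnKinetics`` and molecular weights."""
        if volume <= 0:
            raise ValueError("endosomal volume must be positive")
        if fcrn_total < 0:
            raise ValueError("fcrn_total must be non-negative")
        if not 0 <= missort <= 1:
            raise ValueError("missort must lie in [0, 1]")
        mw = np.asarray(molecular_weights, dtype=float)
        return EndosomePool(
            volume=volume,
            fcrn_total=fcrn_total,
            k_on=np.array([k.k_on for k in kinetics]),
            k_off=np.array([k.k_off for k in kinetics]),
            k_rc=np.array([k.k_rc for k in kinetics]),
            k_cat=np.array([k.k_cat for k in kinetics]),
            fr=np.array([k.fr for k in kinetics]),
            mg_to_um=1e3 / (mw * volume),
            missort=missort,
        )

    def free_fcrn(self, complex_amounts: np.ndarray) -> float:
        """Free receptor concentration (uM) given bound amounts (mg)."""
        return self.fcrn_total - float(np.sum(complex_amounts * self.mg_to_um))


@dataclass(frozen=True)
class EndosomeFluxes:
    """Mass fluxes (mg/h, per species) leaving one endosomal pool."""

    recycled_to_vascular: np.ndarray
    recycled_to_interstitial: np.ndarray
    catabolized: np.ndarray


def endosome_derivatives(pool: EndosomePool, free_amounts: np.ndarray,
                         complex_amounts: np.ndarray, uptake_in: np.ndarray,
                         ) -> tuple[np.ndarray, np.ndarray, EndosomeFluxes]:
    """Time derivatives of the endosomal free/bound amounts (mg/h).

    ``uptake_in`` is the fluid-phase mass inflow per species.  Binding is
    bimolecular against the shared free receptor; the bound complex either
    dissociates or is recycled out (split ``fr`` vascular / ``1 - fr``
    interstitial), the free species is catabolized at ``k_cat``.
    """
    r_free = pool.free_fcrn(complex_amounts)
    binding = pool.k_on * r_free * free_amounts  # mg/h
    unbinding = pool.k_off * complex_amounts
    sorted_out = pool.k_rc * complex_amounts
    recycled = (1.0 - pool.missort) * sorted_out
    catabolized = pool.k_cat * free_amounts + pool.missort * sorted_out
    d_free = uptake_in - binding + unbinding - pool.k_cat * free_amounts
    d_complex = binding - unbinding - sorted_out
    fluxes = EndosomeFluxes(
        recycled_to_vascular=pool.fr * recycled,
        recycled_to_interstitial=(1.0 - pool.fr) * recycled,
        catabolized=catabolized,
    )
    return d_free, d_complex, fluxes


def _quadratic_refine(t: np.ndarray, v: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through three grid points around index ``i``."""
    if i == 0 or i == len(t) - 1:
        return float(t[i]), float(v[i])
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    v0, v1, v2 = v[i - 1], v[i], v[i + 1]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    a = (t2 * (v1 - v0) + t1 * (v0 - v2) + t0 * (v2 - v1)) / denom
    b = (t2**2 * (v0 - v1) + t1**2 * (v2 - v0) + t0**2 * (v1 - v2)) / denom
    if a == 0:
        return float(t1), float(v1)
    tv = -b / (2 * a)
    if not t0 <= tv <= t2:
        return float(t1), float(v1)
    c = v1 - a * t1**2 - b * t1
    return float(tv), float(a * tv**2 + b * tv + c)


@dataclass(frozen=True)
class FreeFcRnSeries:
    """Baseline-normalized free-receptor time course and its summary."""

    times: np.ndarray  # h
    percent: np.ndarray  # % of the pre-dose free receptor
    minimum_percent: float
    time_of_minimum: float  # h
    return_to_baseline: float | None  # h; first t after the minimum >= 99%


def free_fcrn_percent(times: np.ndarray, complex_traj: np.ndarray,
                      pool: EndosomePool, baseline_complexes: np.ndarray,
                      ) -> FreeFcRnSeries:
    """Free-FcRn time course as percent of the pre-dose steady state.

    ``complex_traj`` has shape ``(n_times, n_species)`` in mg;
    ``baseline_complexes`` is the pre-dose bound state.  The pre-dose
    baseline already carries endogenous-IgG occupancy, so 100% refers to the
    physiological, not the receptor-total, free level.
    """
    baseline_free = pool.free_fcrn(np.asarray(baseline_complexes))
    if baseline_free <= 0:
        raise ValueError("degenerate baseline: no free FcRn before dosing")
    occupancy = complex_traj @ pool.mg_to_um
    percent = 100.0 * (pool.fcrn_total - occupancy) / baseline_free
    i_min = int(np.argmin(percent))
    t_min, v_min = _quadratic_refine(np.asarray(times, float), percent, i_min)
    recovery = None
    after = np.flatnonzero((times > t_min) & (percent >= 99.0))
    if after.size:
        recovery = float(times[after[0]])
    return FreeFcRnSeries(
        times=np.asarray(times, float),
        percent=percent,
        minimum_percent=v_min,
        time_of_minimum=t_min,
        return_to_baseline=recovery,
    )
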