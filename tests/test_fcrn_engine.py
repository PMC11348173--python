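"""Endosomal FcRn salvage: equilibria, conservation, saturation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from scpbpk.fcrn_engine import (EndosomePool, endosome_derivatives,
                                free_fcrn_percent)
from scpbpk.physiology import FcRnKinetics

MW = 150_000.0


def make_pool(n_species=1, fcrn_total=10.0, volume=1e-4, missort=0.0, **kin):
    k = FcRnKinetics(**kin)
    return EndosomePool.build(volume, fcrn_total, [k] * n_species,
                              [MW] * n_species, missort=missort)


def integrate_pool(pool, uptake, t_end=400.0):
    n = len(uptake)

    def rhs(t, y):
        d_free, d_cplx, _ = endosome_derivatives(pool, y[:n], y[n:],
                                                 np.asarray(uptake))
        return np.concatenate([d_free, d_cplx])

    sol = solve_ivp(rhs, (0, t_end), np.zeros(2 * n), method="BDF",
                    rtol=1e-10, atol=1e-14)
    assert sol.success
    return sol.y[:n, -1], sol.y[n:, -1]


class TestDerivatives:
    def test_quiescence(self):
        pool = make_pool(2)
        d_free, d_cplx, fluxes = endosome_derivatives(
            pool, np.zeros(2), np.zeros(2), np.zeros(2)
        )
        assert not d_free.any() and not d_cplx.any()
        assert not fluxes.catabolized.any()

    def test_rapid_equilibrium_bound_fraction(self):
        """Stiff integration against the closed-form binding isotherm.

        With binding much faster than trafficking and receptor far from
        saturation, the steady-state bound fraction of the endosomal drug
        is R_free / (R_free + KD*) with KD* = (k_off + k_rc) / k_on.
        """
        pool = make_pool(fcrn_total=200.0, k_on=3.6e4, kd_ph6=0.728)
        free, cplx = integrate_pool(pool, [1e-4])
        r_free = pool.free_fcrn(cplx)
        kd_star = (pool.k_off[0] + pool.k_rc[0]) / pool.k_on[0]
        expected = r_free / (r_free + kd_star)
        bound_frac = cplx[0] / (cplx[0] + free[0])
        assert bound_frac == pytest.approx(expected, rel=1e-6)

    def test_label_symmetry(self):
        """Two species with identical kinetics and uptake are exchangeable."""
        pool = make_pool(2, fcrn_total=5.0)
        free, cplx = integrate_pool(pool, [1e-3, 1e-3])
        assert free[0] == pytest.approx(free[1], rel=1e-9)
        assert cplx[0] == pytest.approx(cplx[1], rel=1e-9)

    def test_mass_conservation_of_fluxes(self):
        """uptake = d/dt(endosomal mass) + recycled + catabolized."""
        pool = make_pool(2, fcrn_total=3.0, missort=0.1)
        rng = np.random.default_rng(7)
        free = rng.uniform(0, 1e-2, 2)
        cplx = rng.uniform(0, 1e-2, 2)
        uptake = rng.uniform(0, 1e-3, 2)
        d_free, d_cplx, fx = endosome_derivatives(pool, free, cplx, uptake)
        recycled = fx.recycled_to_vascular + fx.recycled_to_interstitial
        np.testing.assert_allclose(
            uptake, d_free + d_cplx + recycled + fx.catabolized,
            rtol=0, atol=1e-15,
        )

    def test_recycling_split_is_fr(self):
        pool = make_pool(fcrn_total=3.0)
        _, _, fx = endosome_derivatives(pool, np.array([1e-3]),
                                        np.array([1e-3]), np.array([0.0]))
        total = fx.recycled_to_vascular + fx.recycled_to_interstitial
        assert fx.recycled_to_vascular / total == pytest.approx(pool.fr[0])

    def test_missort_puts_floor_on_catabolism(self):
        pool = make_pool(fcrn_total=1e4, missort=0.2)  # receptor in vast excess
        free, cplx = integrate_pool(pool, [1e-3])
        _, _, fx = endosome_derivatives(pool, free, cplx, np.array([1e-3]))
        phi = fx.catabolized[0] / 1e-3
        assert phi > 0.19  # essentially everything bound, floor remains

    def test_saturation_monotonicity(self):
        """More uptake never leaves more receptor free."""
        pool = make_pool(fcrn_total=2.0)
        frees = []
        for uptake in (1e-4, 3e-4, 1e-3, 3e-3):
            _, cplx = integrate_pool(pool, [uptake])
            frees.append(pool.free_fcrn(cplx))
        assert all(a > b for a, b in zip(frees, frees[1:]))


class TestFreeFcRnSeries:
    def test_self_normalization_and_minimum(self):
        pool = make_pool(fcrn_total=10.0)
        t = np.linspace(0, 100, 201)
        occupancy = 4.0 * np.exp(-0.5 * ((t - 30.0) / 8.0) ** 2)  # uM dip
        cplx = (occupancy / pool.mg_to_um[0])[:, None]
        baseline = np.zeros(1)
        series = free_fcrn_percent(t, cplx, pool, baseline)
        assert series.percent[0] == pytest.approx(100.0, abs=0.05)
        assert series.time_of_minimum == pytest.approx(30.0, abs=0.2)
        assert series.minimum_percent == pytest.approx(60.0, abs=0.2)
        assert series.return_to_baseline is not None
        assert series.return_to_baseline > 30.0

    def test_degenerate_baseline_rejected(self):
        pool = make_pool(fcrn_total=1.0)
        full = np.array([1.0 / pool.mg_to_um[0]])  # all receptor occupied
        with pytest.raises(ValueError):
            free_fcrn_percent(np.array([0.0]), full[None, :], pool, full)
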