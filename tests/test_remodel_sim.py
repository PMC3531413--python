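"""Sector model: initialization, rupture rule, growth dynamics, sweep."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from cytoremodel.kinematics import fiber_strain
from cytoremodel.remodel_sim import (
    SWEEP_EPS,
    SWEEP_SIGMAS,
    CellShape,
    SimParams,
    apply_stretch,
    adhesion_stress,
    event_load_share,
    init_cell,
    simulate,
    step,
    sweep,
)


class TestInitCell:
    def test_degenerate_spread_gives_uniform_prestretch(self):
        p = SimParams(sigma_pre=0.0)
        cell = init_cell("circular", p)
        np.testing.assert_allclose(cell.lambda_pre, p.mu_pre)
        np.testing.assert_allclose(cell.lambda_total, cell.lambda_pre)

    def test_seed_determinism(self):
        p = SimParams(sigma_pre=0.1, seed=42)
        a, b = init_cell("circular", p), init_cell("circular", p)
        np.testing.assert_array_equal(a.lambda_pre, b.lambda_pre)
        c = init_cell("circular", replace(p, seed=43))
        assert not np.array_equal(a.lambda_pre, c.lambda_pre)

    def test_truncated_normal_moments(self):
        """Sample moments at n = 10^4 match the truncated-normal oracle to 1%."""
        p = SimParams(lambda_min=1.0, lambda_max=1.35, mu_pre=1.10,
                      sigma_pre=0.05, n_sectors=10_000, seed=7)
        cell = init_cell("circular", p)
        a = (p.lambda_min - p.mu_pre) / p.sigma_pre
        b = (p.lambda_max - p.mu_pre) / p.sigma_pre
        mean, var = stats.truncnorm.stats(a, b, loc=p.mu_pre,
                                          scale=p.sigma_pre, moments="mv")
        assert cell.lambda_pre.mean() == pytest.approx(float(mean), rel=0.01)
        assert cell.lambda_pre.std() == pytest.approx(float(np.sqrt(var)),
                                                      rel=0.01)
        assert cell.lambda_pre.min() >= p.lambda_min
        assert cell.lambda_pre.max() <= p.lambda_max

    def test_invalid_spread_rejected(self):
        with pytest.raises(ValueError):
            SimParams(sigma_pre=-0.1)

    def test_circular_sectors_span_half_turn(self):
        cell = init_cell("circular", SimParams(n_sectors=36))
        assert cell.theta.min() >= 0 and cell.theta.max() < np.pi
        assert cell.width.sum() == pytest.approx(np.pi)

    def test_spindle_orientations_concentrate_on_axis(self):
        p = SimParams(n_sectors=200, spindle_kappa=16.0, seed=1)
        cell = init_cell(CellShape.spindle, p)
        folded = np.minimum(cell.theta, np.pi - cell.theta)
        assert np.median(np.abs(folded)) < np.pi / 8


class TestApplyStretch:
    def test_window_rule_at_principal_orientations(self):
        """With deterministic pre-stretch 1.10, a 10% stretch at unit Poisson
        ratio ruptures the axial sector (1.21 > 1.20), buckles the transverse
        one (0.99 < 1.00), and spares the 45-degree sector (1.10)."""
        p = SimParams(lambda_min=1.00, lambda_max=1.20, mu_pre=1.10,
                      sigma_pre=0.0, n_sectors=4)
        cell = init_cell("circular", p)
        # sectors at 22.5, 67.5, 112.5, 157.5 deg; rebuild at exact angles
        cell.theta = np.array([0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4])
        out = apply_stretch(cell, 0.10, 1.0, p)
        assert out.lambda_total[0] == pytest.approx(1.21)
        assert out.lambda_total[2] == pytest.approx(0.99)
        assert not out.intact[0]          # tensile rupture
        assert not out.intact[2]          # compressive buckling
        assert out.intact[1] and out.intact[3]
        assert out.rho[0] == 0 and out.rho[2] == 0
        assert out.reservoir > 0

    def test_zero_strain_changes_nothing(self):
        p = SimParams(sigma_pre=0.1, seed=3)
        cell = init_cell("circular", p)
        out = apply_stretch(cell, 0.0, 1.0, p)
        assert out.intact.all()
        np.testing.assert_allclose(out.lambda_total, cell.lambda_total)

    def test_matches_brute_force_loop(self):
        """Vectorized rupture decisions equal a per-sector recomputation."""
        p = SimParams(sigma_pre=0.10, n_sectors=10_000, seed=11)
        cell = init_cell("circular", p)
        out = apply_stretch(cell, 0.10, 1.0, p)
        for i in range(0, p.n_sectors, 97):  # stride keeps the loop cheap
            lam = cell.lambda_pre[i] * (1 + fiber_strain(0.10, cell.theta[i], 1.0))
            expected = p.lambda_min <= lam <= p.lambda_max
            assert out.intact[i] == expected


class TestStressAndStep:
    def test_compressed_and_ruptured_sectors_bear_no_stress(self):
        p = SimParams(lambda_min=1.00, lambda_max=1.20, mu_pre=1.10,
                      sigma_pre=0.0, n_sectors=4)
        cell = init_cell("circular", p)
        cell.theta = np.array([0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4])
        out = apply_stretch(cell, 0.10, 1.0, p)
        s = adhesion_stress(out, p, load_share=1.0)
        assert s[0] == 0 and s[2] == 0          # depolymerized
        assert s[1] == pytest.approx(p.k_fiber * p.rho0 * 0.10)

    def test_full_share_identity(self):
        p = SimParams(sigma_pre=0.0)
        pre = init_cell("circular", p)
        post = apply_stretch(pre, 0.02, 1.0, p)  # mild: nothing ruptures
        assert post.intact.all()
        assert event_load_share(pre, post, p) == pytest.approx(1.0)

    def test_growth_matches_exponential_saturation(self):
        """Constant in-band stress: rho(t) follows the closed-form relaxation
        to rho_max within O(dt)."""
        p = SimParams(sigma_pre=0.0, dt=0.01, k_poly=0.2, rho_max=2.0)
        cell = init_cell("circular", p)
        cell.lambda_total = np.full_like(cell.lambda_total, 1.0 + p.s_low + 0.01)
        t_end, n = 10.0, 1000
        cur = cell
        for _ in range(n):
            cur = step(cur, p.dt, p, load_share=1.0)
        expected = p.rho_max - (p.rho_max - p.rho0) * np.exp(-p.k_poly * t_end)
        np.testing.assert_allclose(cur.rho, expected, rtol=2e-3)

    def test_rock_inhibition_freezes_densities(self):
        p = SimParams(sigma_pre=0.05, seed=2, rock_inhibited=True)
        out = simulate(p, eps_o=0.10)
        assert np.all(np.diff(out.per_sector_density, axis=0) <= 0 + 1e-15)
        assert out.model_fibrosity.max() <= 1.0 + 1e-12

    def test_finite_reservoir_caps_total_growth(self):
        cap = 0.05
        p = SimParams(sigma_pre=0.0, reservoir_finite=True,
                      reservoir_capacity=cap, seed=0)
        cell = init_cell("circular", p)
        pre_density = cell.total_weighted_density
        cell.reservoir = cap
        cur = apply_stretch(cell, 0.05, 1.0, p)
        share = 1.0
        for _ in range(300):
            cur = step(cur, p.dt, p, load_share=share)
        grown = cur.total_weighted_density - pre_density
        assert grown <= cap + 1e-9
        assert cur.reservoir >= -1e-9

    def test_invalid_timestep(self):
        p = SimParams()
        with pytest.raises(ValueError):
            step(init_cell("circular", p), -0.1, p)


class TestSimulate:
    def test_no_stretch_gives_flat_unit_trace(self):
        out = simulate(SimParams(sigma_pre=0.05, seed=9), eps_o=0.0)
        np.testing.assert_allclose(out.model_fibrosity, 1.0)
        assert out.response_class == "flat"

    def test_densities_bounded_all_times(self):
        for seed in range(5):
            p = SimParams(sigma_pre=0.2, seed=seed)
            out = simulate(p, eps_o=0.10)
            assert out.per_sector_density.min() >= 0
            assert out.per_sector_density.max() <= p.rho_max + 1e-12

    def test_depolymerization_is_irreversible(self):
        p = SimParams(sigma_pre=0.25, seed=13)
        out = simulate(p, eps_o=0.10)
        dead = out.depolymerized_mask
        assert dead.any()
        assert np.all(out.per_sector_density[1:, dead] == 0.0)

    def test_low_spread_reinforces_in_most_replicates(self):
        """Little pre-stretch variability: no tensile ruptures, growth along
        the stretch axis, monotonic reinforcement in >= 90% of runs."""
        p = SimParams(lambda_min=1.0, lambda_max=1.35, mu_pre=1.10,
                      sigma_pre=0.01)
        wins = sum(
            simulate(replace(p, seed=s), eps_o=0.05).response_class
            == "monotonic_reinforcement"
            for s in range(20)
        )
        assert wins >= 18

    def test_high_spread_retraction_is_modal_class(self):
        counts = {}
        for s in range(30):
            cls = simulate(replace(SimParams(), sigma_pre=0.25, seed=s),
                           eps_o=SWEEP_EPS).response_class
            counts[cls] = counts.get(cls, 0) + 1
        assert max(counts, key=counts.get) == "monotonic_retraction"

    def test_normalized_to_prestretch_state(self):
        out = simulate(SimParams(sigma_pre=0.1, seed=4), eps_o=0.10)
        assert out.model_fibrosity[0] == 1.0

    def test_chained_stretches_reuse_state(self):
        p = SimParams(sigma_pre=0.05, seed=21, duration=10.0)
        first = simulate(p, eps_o=0.05)
        cell = init_cell("circular", p)
        cell2 = apply_stretch(cell, 0.05, 1.0, p)
        # a second stretch applied to an already-stretched cell compounds
        cell3 = apply_stretch(cell2, 0.05, 1.0, p)
        assert np.all(cell3.lambda_total <= cell2.lambda_total * 1.11)
        assert first.model_fibrosity.shape == first.times.shape


class TestSweep:
    def test_depolymerized_fraction_monotone_in_spread(self):
        p = SimParams()
        fractions = []
        for sigma in [0.01, 0.05, 0.10, 0.20, 0.30]:
            masks = [
                simulate(replace(p, sigma_pre=sigma, seed=s),
                         eps_o=SWEEP_EPS).depolymerized_mask.mean()
                for s in range(10)
            ]
            fractions.append(np.mean(masks))
        assert all(a <= b + 1e-9 for a, b in zip(fractions, fractions[1:]))

    def test_class_ordering_over_sigma_grid(self):
        freq, angles, _ = sweep(SWEEP_SIGMAS, 15, SimParams(), eps_o=SWEEP_EPS)
        doms = [max(freq[s], key=freq[s].get) for s in SWEEP_SIGMAS]
        assert doms == ["monotonic_reinforcement",
                        "retraction_then_reinforcement",
                        "monotonic_retraction"]
        assert angles[SWEEP_SIGMAS[0]].size < angles[SWEEP_SIGMAS[2]].size

    def test_reverse_sequence_never_generated(self):
        """classify_trace raises on reinforcement-then-retraction; no sweep
        run triggers it (growth is monotone after the rupture event)."""
        sweep(SWEEP_SIGMAS, 10, SimParams(seed=500), eps_o=SWEEP_EPS)
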