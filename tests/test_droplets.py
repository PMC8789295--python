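"""Droplet seeding statistics, per-droplet growth, and selection direction."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import solve_ivp

from overflowsel import (
    DropletDesign,
    Genotype,
    ModelParameters,
    PopulationState,
    expected_emulsion_weights,
    grow_droplet,
    growth_rate_on_glucose,
    propagate_batch,
    propagate_emulsion,
    seed_droplets,
    simulate_biphasic,
)


def make_genotype(name="wt", phi=0.25, **overrides) -> Genotype:
    return Genotype(name, ModelParameters().with_overrides(**overrides), phi=phi)


class TestDropletDesign:
    def test_printed_protocol_arithmetic(self, design):
        # 50 um droplet = 6.545e-8 ml; 2e6 cells/ml -> lambda ~ 0.1309
        assert design.droplet_volume_ml == pytest.approx(6.545e-8, rel=1e-3)
        assert design.seeding_mean == pytest.approx(0.1309, abs=2e-4)
        assert design.glucose_per_droplet == pytest.approx(1.636e-13, rel=1e-3)

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            DropletDesign(diameter=-1.0)


class TestSeeding:
    def test_occupancy_moments_and_poisson_fit(self, rng):
        design = DropletDesign(n_droplets=100_000)
        state = PopulationState({"wt": 1.0})
        occ = seed_droplets(state, design, rng).sum(axis=1)
        lam = design.seeding_mean
        se = math.sqrt(lam / design.n_droplets)
        assert occ.mean() == pytest.approx(lam, abs=3 * se)
        # fraction with exactly one cell ~ lambda * exp(-lambda) ~ 0.115
        p1 = lam * math.exp(-lam)
        se1 = math.sqrt(p1 * (1 - p1) / design.n_droplets)
        assert (occ == 1).mean() == pytest.approx(p1, abs=3 * se1)
        # chi-square goodness of fit against Poisson(lambda), alpha = 0.01
        kmax = int(stats.poisson.ppf(1 - 1e-6, lam)) + 1
        observed = np.bincount(occ, minlength=kmax + 1)[: kmax + 1]
        expected = stats.poisson.pmf(np.arange(kmax + 1), lam)
        expected[-1] = 1.0 - expected[:-1].sum()
        expected *= design.n_droplets
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        pval = stats.chi2.sf(chi2, keep.sum() - 1)
        assert pval > 0.01

    def test_single_genotype_population(self, design, rng):
        state = PopulationState({"only": 42.0})
        occ = seed_droplets(state, design, rng)
        assert occ.shape[1] == 1 and occ.sum() > 0

    def test_two_genotypes_split_by_frequency(self, design, rng):
        state = PopulationState({"a": 3.0, "b": 1.0})
        occ = seed_droplets(state, design, rng)
        frac_a = occ[:, 0].sum() / occ.sum()
        assert frac_a == pytest.approx(0.75, abs=0.02)


class TestGrowDroplet:
    def test_empty_droplet(self, design):
        out = grow_droplet([0], [make_genotype()], design.glucose_per_droplet)
        assert out.tolist() == [0.0]

    def test_single_cell_yields_five_to_six_generations(self, design):
        for phi in (0.0, 0.25, 0.5):
            out = grow_droplet(
                [1], [make_genotype(phi=phi)], design.glucose_per_droplet
            )
            assert 5.0 <= math.log2(out[0]) <= 6.0

    def test_two_identical_cells_add_one_founder(self, design):
        gt = make_genotype()
        glc = design.glucose_per_droplet
        single = grow_droplet([1], [gt], glc)[0]
        double = grow_droplet([2], [gt], glc)[0]
        assert double == pytest.approx(single + 1.0, rel=1e-10)

    def test_matches_closed_form_for_single_lineage(self, design):
        gt = make_genotype(phi=0.3)
        glc = design.glucose_per_droplet
        out = grow_droplet([3], [gt], glc)[0]
        closed = simulate_biphasic(
            0.3, gt.params.with_overrides(glc0=glc, N0=3.0)
        ).N_final
        assert out == pytest.approx(closed, rel=1e-9)

    def test_equal_split_is_per_founder_closed_form(self, design):
        slow = make_genotype("slow", phi=0.1)
        fast = make_genotype("fast", phi=0.45)
        glc = design.glucose_per_droplet
        out = grow_droplet([2, 1], [slow, fast], glc, split="equal")
        per_founder = [
            simulate_biphasic(
                g.phi, g.params.with_overrides(glc0=glc / 3, N0=1.0)
            ).N_final
            for g in (slow, fast)
        ]
        assert out[0] == pytest.approx(2 * per_founder[0], rel=1e-12)
        assert out[1] == pytest.approx(per_founder[1], rel=1e-12)

    def test_competitive_split_against_ode_integration(self, design):
        """Two genotypes racing for one droplet, checked by forward integration."""
        slow = make_genotype("slow", phi=0.1)
        fast = make_genotype("fast", phi=0.45)
        glc = design.glucose_per_droplet
        ours = grow_droplet([1, 1], [slow, fast], glc, split="competitive")

        gts = [slow, fast]
        mu = np.array([growth_rate_on_glucose(g.phi, g.params) for g in gts])
        qg = np.array(
            [g.params.Y_xg * (1 - g.phi) / (g.params.rho * g.params.V_cg)
             for g in gts]
        )

        def rhs1(t, y):
            dn = mu * y[:2]
            return [*dn, -(dn / qg).sum()]

        def gone1(t, y):
            return y[2]

        gone1.terminal, gone1.direction = True, -1
        s1 = solve_ivp(rhs1, (0, 100), [1.0, 1.0, glc], events=gone1,
                       max_step=1e-3, rtol=1e-12, atol=1e-30)
        n_tg = s1.y_events[0][0][:2]
        consumed = (n_tg - 1.0) / qg
        ace = sum(g.params.Y_ag * g.phi * c for g, c in zip(gts, consumed))
        mua = np.array([g.params.mu_a for g in gts])
        qa = np.array([g.params.acetate_cell_yield for g in gts])

        def rhs2(t, y):
            dn = mua * y[:2]
            return [*dn, -(dn / qa).sum()]

        def gone2(t, y):
            return y[2]

        gone2.terminal, gone2.direction = True, -1
        s2 = solve_ivp(rhs2, (0, 100), [*n_tg, ace], events=gone2,
                       max_step=1e-3, rtol=1e-12, atol=1e-30)
        expected = s2.y_events[0][0][:2]
        assert np.allclose(ours, expected, rtol=1e-5)


class TestPropagateEmulsion:
    def test_single_genotype_frequency_stays_one(self, design):
        traj = propagate_emulsion([make_genotype()], design, 3, rng=7)
        assert np.allclose(traj["frequency"], 1.0)

    def test_frequencies_sum_to_one(self, design):
        gts = [make_genotype("a"), make_genotype("b", V_cg=0.9, V_ca=0.45)]
        traj = propagate_emulsion(gts, design, 4, rng=5)
        sums = traj.groupby("transfer")["frequency"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_seed_reproducibility(self, design):
        gts = [make_genotype("a"), make_genotype("b", V_cg=0.9, V_ca=0.45)]
        t1 = propagate_emulsion(gts, design, 3, rng=11)
        t2 = propagate_emulsion(gts, design, 3, rng=11)
        assert t1.equals(t2)

    def test_smaller_cells_rise_toward_deterministic_expectation(self, design):
        """Higher numerical yield wins in droplets; drift-averaged trajectory
        tracks the single-founder expectation recursion."""
        wt = make_genotype("wt")
        small = make_genotype("small", V_cg=1 / 1.23, V_ca=0.5 / 1.23)
        w = expected_emulsion_weights([wt, small], design)
        assert w[1] > w[0]
        n_transfers, n_seeds = 6, 8
        freqs = np.zeros((n_seeds, n_transfers + 1))
        for s in range(n_seeds):
            traj = propagate_emulsion([wt, small], design, n_transfers, rng=s)
            freqs[s] = traj[traj.genotype == "small"]["frequency"].to_numpy()
        mean = freqs.mean(axis=0)
        assert np.all(np.diff(mean) > 0)
        f = 0.5
        for t in range(1, n_transfers + 1):
            f = f * w[1] / (f * w[1] + (1 - f) * w[0])
            assert mean[t] == pytest.approx(f, abs=0.02)

    def test_rate_difference_is_yield_neutral(self, design):
        """A genotype that only grows faster on glucose has the same
        per-droplet offspring count and gains nothing in emulsion."""
        wt = make_genotype("wt")
        fast = make_genotype("fast", alpha=0.2 * 1.4, delta=2.0 * 1.4)
        w = expected_emulsion_weights([wt, fast], design)
        assert w[1] == pytest.approx(w[0], rel=1e-12)
        final = []
        for s in range(8):
            traj = propagate_emulsion([wt, fast], design, 6, rng=100 + s)
            final.append(
                traj[traj.genotype == "fast"]["frequency"].to_numpy()[-1]
            )
        assert np.mean(final) == pytest.approx(0.5, abs=0.03)


class TestPropagateBatch:
    def test_equal_genotypes_unchanged(self):
        gts = [make_genotype("a"), make_genotype("b")]
        traj = propagate_batch(gts, 2.5e-3, 5, dilution=50,
                               initial_counts={"a": 4e8, "b": 4e8})
        assert np.allclose(traj["frequency"], 0.5, atol=1e-12)

    def test_faster_genotype_wins(self):
        wt = make_genotype("wt")
        fast = make_genotype("fast", alpha=0.2 * 1.4, delta=2.0 * 1.4)
        traj = propagate_batch([wt, fast], 2.5e-3, 8, dilution=50,
                               initial_counts={"wt": 4e8, "fast": 4e8})
        f = traj[traj.genotype == "fast"]["frequency"].to_numpy()
        assert np.all(np.diff(f) > 0)
        assert f[-1] > 0.95

    def test_steady_state_fold_change_equals_dilution(self):
        gt = make_genotype()
        traj = propagate_batch([gt], 2.5e-3, 6, dilution=100,
                               initial_counts={"wt": 5e9})
        counts = traj["count"].to_numpy()
        # after a few transfers the pre-dilution population is glucose-set,
        # so each transfer returns to the same post-dilution count
        assert counts[-1] == pytest.approx(counts[-2], rel=1e-6)

    def test_dilution_must_exceed_one(self):
        with pytest.raises(ValueError):
            propagate_batch([make_genotype()], 1e-3, 2, dilution=1.0)
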