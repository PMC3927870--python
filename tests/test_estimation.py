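"""Estimation: chi-square, steady-state initialisation, fitting, profiles."""

import numpy as np
import pytest
from scipy.stats import norm

from grnlab.estimation import (
    Objective,
    chi2,
    fit_multistart,
    profile_likelihood,
    rank_experiments,
    solve_regulation,
    steady_state_init,
)
from grnlab.lab import (
    Dataset,
    MeasurementRequest,
    NoiseModel,
    Perturbation,
)
from grnlab.model import (
    GeneSpec,
    ModelInstance,
    NetworkSpec,
    ParameterSet,
    TimeGrid,
    protein_species,
    mrna_species,
    regulation_term,
    simulate,
)
from conftest import noisy_datasets


def _noise_free_dataset(model, grid=None, perturbations=()):
    from grnlab.lab import apply_perturbation

    grid = grid or TimeGrid(0.0, 20.0, 0.5)
    m = model
    for p in perturbations:
        m = apply_perturbation(m, p)
    traj = simulate(m, grid)
    return Dataset(tuple(perturbations), "massspec", grid, traj.species, traj.values)


class TestChi2:
    def test_zero_at_truth_on_noise_free_data(self, three_gene_po):
        ds = _noise_free_dataset(three_gene_po)
        assert chi2(three_gene_po, [ds]) == pytest.approx(0.0, abs=1e-8)

    def test_unit_residual_counts_one(self, three_gene_po):
        grid = TimeGrid(0.0, 1.0, 1.0)  # 2 points
        traj = simulate(three_gene_po, grid)
        nm = NoiseModel()
        values = traj.values.copy()
        # displace exactly one measurement by one model-predicted sigma
        values[0, 1] += np.sqrt(nm.variance(values[0, 1]))
        ds = Dataset((), "massspec", grid, traj.species, values)
        assert chi2(three_gene_po, [ds], nm) == pytest.approx(1.0, abs=1e-6)

    def test_additive_over_datasets(self, three_gene_po):
        rng = np.random.default_rng(0)
        ds = noisy_datasets(three_gene_po, [(), ()], rng)
        both = chi2(three_gene_po, ds)
        assert both == pytest.approx(
            chi2(three_gene_po, [ds[0]]) + chi2(three_gene_po, [ds[1]])
        )

    def test_matches_minus_two_log_likelihood(self, three_gene_po):
        rng = np.random.default_rng(1)
        nm = NoiseModel()
        (ds,) = noisy_datasets(three_gene_po, [()], rng, nm)
        traj = simulate(three_gene_po, ds.grid)
        sigma = np.sqrt(nm.variance(traj.values))
        loglik = norm.logpdf(ds.values, loc=traj.values, scale=sigma).sum()
        constant = np.sum(np.log(2 * np.pi * sigma**2))
        assert chi2(three_gene_po, [ds], nm) == pytest.approx(
            -2 * loglik - constant, rel=1e-6
        )


class TestSteadyStateInit:
    def test_recovers_rates_from_noise_free_steady_data(self, model1):
        # late-time wildtype course: the network is essentially steady by
        # the end of the horizon
        grid = TimeGrid(0.0, 100.0, 0.5)
        traj = simulate(model1, grid)
        ds = Dataset((), "microarray", grid, traj.species, traj.values)
        guess, warnings = steady_state_init([ds], model1.spec)
        assert not warnings
        delta = guess["protein_degradation_rate"]
        assert delta == pytest.approx(model1.params["protein_degradation_rate"], rel=0.01)
        # RBS strengths follow delta * P_ss / m_ss; exact for every gene
        for g in model1.spec.gene_ids:
            assert guess[f"{g}_rbs"] == pytest.approx(
                model1.params[f"{g}_rbs"], rel=0.01
            )
        # promoter strength exact for the unregulated gene g6
        assert guess["g6_promoter"] == pytest.approx(
            model1.params["g6_promoter"], rel=0.01
        )

    def test_all_zero_data_gives_empty_guess_with_warning(self, model1):
        grid = TimeGrid(0.0, 20.0, 1.0)
        species = model1.species
        ds = Dataset(
            (), "microarray", grid, species, np.zeros((len(species), grid.n_points))
        )
        guess, warnings = steady_state_init([ds], model1.spec)
        assert guess == {}
        assert warnings

    def test_guesses_are_positive(self, model1):
        rng = np.random.default_rng(3)
        grid = TimeGrid(0.0, 40.0, 0.5)
        (ds,) = noisy_datasets(model1, [()], rng, grid=grid)
        guess, _ = steady_state_init([ds], model1.spec)
        assert all(v > 0 for v in guess.values())


class TestSolveRegulation:
    def test_exact_recovery_from_three_points(self):
        Kd, h = 2.0, 3.0
        P = [1.0, 2.0, 4.0]
        pts = [(p, regulation_term(p, Kd, h, "-")) for p in P]
        fit = solve_regulation(pts, sign="-")
        assert fit.Kd == pytest.approx(Kd, rel=1e-9)
        assert fit.h == pytest.approx(h, rel=1e-9)
        assert fit.well_determined

    def test_activation_branch(self):
        pts = [(p, regulation_term(p, 1.5, 2.0, "+")) for p in (0.5, 1.5, 4.0)]
        fit = solve_regulation(pts, sign="+")
        assert (fit.Kd, fit.h) == pytest.approx((1.5, 2.0), rel=1e-9)

    def test_saturated_regulator_flagged(self):
        # regulator always far above Kd: the hard case needing a gel shift
        pts = [(p, regulation_term(p, 0.01, 2.0, "-")) for p in (5.0, 10.0, 20.0)]
        fit = solve_regulation(pts, sign="-")
        assert not fit.well_determined

    def test_order_invariance(self):
        pts = [(p, regulation_term(p, 2.0, 3.0, "-")) for p in (1.0, 2.0, 4.0)]
        a = solve_regulation(pts, sign="-")
        b = solve_regulation(pts[::-1], sign="-")
        assert (a.Kd, a.h) == pytest.approx((b.Kd, b.h))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            solve_regulation([(1.0, 0.5), (2.0, 0.3)])

    def test_saturated_terms_rejected(self):
        with pytest.raises(ValueError):
            solve_regulation([(1.0, 0.0), (2.0, 0.5), (3.0, 0.7)])


class TestFitMultistart:
    def test_start_from_truth_descends(self, three_gene_po, knockdown_conditions):
        rng = np.random.default_rng(0)
        ds = noisy_datasets(three_gene_po, knockdown_conditions[:2], rng)
        truth_chi2 = chi2(three_gene_po, ds, rtol=1e-6, atol=1e-8)
        fit = fit_multistart(
            three_gene_po,
            ds,
            n_starts=1,
            rng=np.random.default_rng(1),
            extra_starts=[dict(three_gene_po.params)],
            max_nfev=50,
        )
        assert fit.chi2 <= truth_chi2 + 1e-6

    def test_latin_hypercube_strata(self, three_gene_po, knockdown_conditions):
        """Each parameter's starts occupy distinct equal-probability strata."""
        rng = np.random.default_rng(2)
        ds = noisy_datasets(three_gene_po, knockdown_conditions[:1], rng)
        n = 8
        fit = fit_multistart(
            three_gene_po, ds, n_starts=n, rng=np.random.default_rng(3), max_nfev=1,
            refine_top=1, refine_max_nfev=1,
        )
        lo, hi = np.log10(fit.bounds[0]), np.log10(fit.bounds[1])
        x0s = np.stack([s.x0 for s in fit.starts[:n]])
        strata = np.floor((x0s - lo) / (hi - lo) * n).astype(int)
        for j in range(x0s.shape[1]):
            assert sorted(strata[:, j]) == list(range(n))

    def test_seeded_determinism(self, three_gene_po, knockdown_conditions):
        rng = np.random.default_rng(4)
        ds = noisy_datasets(three_gene_po, knockdown_conditions[:2], rng)
        fits = [
            fit_multistart(
                three_gene_po, ds, n_starts=5, rng=np.random.default_rng(9),
                max_nfev=5, refine_top=1, refine_max_nfev=20,
            )
            for _ in range(2)
        ]
        assert dict(fits[0].params) == pytest.approx(dict(fits[1].params))


class TestProfileLikelihood:
    def _product_nonidentifiable_fit(self, single_gene_model):
        """Only the protein is observed: promoter x rbs is constrained but
        the factors are not (classic structural non-identifiability)."""
        grid = TimeGrid(0.0, 20.0, 0.5)
        traj = simulate(single_gene_model, grid)
        ds = Dataset(
            (), "fluorescence", grid,
            (protein_species("g1"),),
            traj.subset([protein_species("g1")]).values,
        )
        fit = fit_multistart(
            single_gene_model,
            [ds],
            n_starts=1,
            rng=np.random.default_rng(0),
            extra_starts=[dict(single_gene_model.params)],
            max_nfev=30,
        )
        return fit, ds

    def test_flat_profile_flagged_nonidentifiable(self, single_gene_model):
        fit, ds = self._product_nonidentifiable_fit(single_gene_model)
        prof = profile_likelihood(
            single_gene_model, [ds], fit, "g1_promoter", n_points=7,
            span_decades=1.5, max_nfev=60,
        )
        assert not prof.identifiable
        assert np.all(prof.chi2_profile >= prof.chi2_min - 1e-6)

    def test_identifiable_parameter_gets_finite_ci(self, three_gene_po, knockdown_conditions):
        rng = np.random.default_rng(5)
        ds = noisy_datasets(three_gene_po, knockdown_conditions, rng)
        fit = fit_multistart(
            three_gene_po, ds, n_starts=1, rng=np.random.default_rng(6),
            extra_starts=[dict(three_gene_po.params)], max_nfev=80,
        )
        prof = profile_likelihood(
            three_gene_po, [*ds], fit, "g3_degradation", n_points=9,
            span_decades=1.0, max_nfev=40,
        )
        assert prof.identifiable
        lo, hi = prof.ci
        assert lo < three_gene_po.params["g3_degradation"] < hi

    def test_profile_minimum_at_fit(self, three_gene_po, knockdown_conditions):
        rng = np.random.default_rng(7)
        ds = noisy_datasets(three_gene_po, knockdown_conditions[:2], rng)
        fit = fit_multistart(
            three_gene_po, ds, n_starts=1, rng=np.random.default_rng(8),
            extra_starts=[dict(three_gene_po.params)], max_nfev=80,
        )
        prof = profile_likelihood(
            three_gene_po, ds, fit, "r1_Kd", n_points=5, span_decades=0.5,
            max_nfev=30,
        )
        center = np.argmin(np.abs(prof.values - fit.params["r1_Kd"]))
        assert prof.chi2_profile[center] == pytest.approx(fit.chi2, rel=1e-6)


class TestRankExperiments:
    def test_single_candidate_returned(self, three_gene_po):
        ensemble = [dict(three_gene_po.params)]
        cand = [((), MeasurementRequest("massspec", resolution="low"))]
        ranked = rank_experiments(three_gene_po, ensemble, cand)
        assert len(ranked) == 1 and ranked[0].spread == 0.0

    def test_zero_spread_candidate_ranks_last(self, three_gene_po):
        # ensemble disagrees only about r2 (affecting g3), not about g1/g2
        base = dict(three_gene_po.params)
        other = dict(base, r2_Kd=base["r2_Kd"] * 3.0)
        ensemble = [base, other]
        candidates = [
            ((), MeasurementRequest("fluorescence", targets=("g1", "g2"))),
            ((), MeasurementRequest("fluorescence", targets=("g2", "g3"))),
        ]
        ranked = rank_experiments(three_gene_po, ensemble, candidates)
        assert ranked[0].request.targets == ("g2", "g3")
        # only integrator-tolerance noise left on the uninformative candidate
        assert ranked[-1].spread < 1e-5
        assert ranked[0].spread > 100 * ranked[-1].spread
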