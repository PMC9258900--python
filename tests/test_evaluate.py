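import numpy as np
import pytest

from pairdistill import (
    ContactMap,
    contact_scores,
    coupling_scatter,
    extract_uniform_closed_form,
    mutational_spearman,
    nrmse,
    ppv_curve,
    random_pairwise_model,
    spearman,
    split_train_test,
    stratified_energy_report,
    synthetic_mutational_dataset,
    to_zero_sum_gauge,
)
from pairdistill.alignment import EncodedAlignment
from pairdistill.distill import extract_exact
from pairdistill.energy import PairwiseModel, n_pairs, pair_index


class TestNrmse:
    def test_identical_vectors_zero(self, rng):
        e = rng.normal(size=30)
        assert nrmse(e, e) == 0.0

    def test_hand_computed(self):
        assert nrmse(np.array([0.0, 2.0]), np.array([1.0, 1.0])) == pytest.approx(0.5)

    def test_zero_range_error(self):
        with pytest.raises(ValueError, match="range"):
            nrmse(np.ones(5), np.zeros(5))

    def test_shift_and_scale_invariance(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        base = nrmse(a, b)
        assert nrmse(a + 3.0, b + 3.0) == pytest.approx(base)
        assert nrmse(4.0 * a, 4.0 * b) == pytest.approx(base)


class TestSpearman:
    def test_monotone_transform_gives_one(self, rng):
        x = rng.normal(size=20)
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman(x, -np.exp(x)) == pytest.approx(-1.0)

    def test_hand_computed_with_rank_formula(self):
        # d^2 sum = 2 -> rho = 1 - 6*2/(3*8) = 0.5
        assert spearman(np.array([1.0, 2, 3]), np.array([2.0, 1, 3])) == pytest.approx(0.5)

    def test_invariant_under_monotone_transform_of_either_argument(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        base = spearman(x, y)
        assert spearman(np.tanh(x), y) == pytest.approx(base)
        assert spearman(x, y**3) == pytest.approx(base)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        with pytest.raises(ValueError):
            spearman(np.ones(5), np.arange(5.0))


class TestMutationalSpearman:
    def test_self_consistent_fitness_gives_high_rho(self):
        model = random_pairwise_model(8, 4, seed=1)
        wt = model.sample(1, seed=2).codes[0]
        data = synthetic_mutational_dataset(model, wt, 20, noise_sd=1e-6, seed=3)
        assert mutational_spearman(model, data) > 0.99

    def test_sign_convention_flipped_fitness(self):
        model = random_pairwise_model(8, 4, seed=4)
        wt = model.sample(1, seed=5).codes[0]
        data = synthetic_mutational_dataset(model, wt, 20, noise_sd=0.0, seed=6)
        flipped = type(data)(
            wildtype=data.wildtype,
            records=[(s, -f) for s, f in data.records],
            alphabet=data.alphabet,
        )
        assert mutational_spearman(model, flipped) == pytest.approx(-1.0)

    def test_too_few_records_error(self):
        model = random_pairwise_model(5, 3, seed=7)
        wt = np.zeros(5, dtype=int)
        data = synthetic_mutational_dataset(model, wt, 1, seed=8)
        with pytest.raises(ValueError):
            mutational_spearman(model, data)


class TestStratifiedReport:
    def _setup(self, seed=0):
        truth = random_pairwise_model(5, 3, coupling_scale=0.3, field_scale=0.5, seed=seed)
        aln = truth.sample(400, seed=seed + 1)
        from pairdistill import deduplicate

        split = split_train_test(deduplicate(aln), seed=seed + 2)
        return truth, split

    def test_identical_model_gives_zero_nrmse(self):
        truth, split = self._setup()
        report = stratified_energy_report(truth, {"self": truth}, split)
        for stratum, value in report.nrmse["self"].items():
            if value is not None:
                assert value <= 1e-12

    def test_shape_three_strata_per_model(self):
        truth, split = self._setup(3)
        wt = split.train.codes[0]
        mut = synthetic_mutational_dataset(truth, wt, 10, seed=9)
        models = {"a": truth, "b": to_zero_sum_gauge(truth)}
        report = stratified_energy_report(truth, models, split, mut)
        assert set(report.nrmse) == {"a", "b"}
        for label in models:
            assert set(report.nrmse[label]) == {"test_close", "test_distant", "mutational"}
        assert set(report.spearman) == {"original", "a", "b"}

    def test_independent_error_at_least_pairwise(self, tiny_ardca):
        aln = tiny_ardca.sample(300, seed=4)
        from pairdistill import deduplicate

        split = split_train_test(deduplicate(aln), seed=5)
        pw, _ = extract_exact(tiny_ardca, family="pairwise")
        ind, _ = extract_exact(tiny_ardca, family="independent")
        report = stratified_energy_report(tiny_ardca, {"pw": pw, "ind": ind}, split)
        # nesting holds for the overall weighted population; check the
        # combined test set rather than each tiny stratum
        E = tiny_ardca.energy(split.test.codes)
        assert nrmse(E, ind.energy(split.test.codes)) >= nrmse(
            E, pw.energy(split.test.codes)
        ) - 1e-9
        assert report.diagnostics["distance"].shape == (len(split.test),)

    def test_distance_diagnostics_track_construction(self):
        # energies with distance-dependent spread: further bins vary more
        truth, split = self._setup(7)
        report = stratified_energy_report(truth, {}, split)
        sd = report.diagnostics["energy_sd_per_bin"]
        assert len(sd) == len(report.diagnostics["bins"])
        assert np.all(np.isfinite(sd))


class TestContactScores:
    def test_zero_couplings_zero_scores(self):
        m = PairwiseModel(h=np.zeros((6, 3)), J=np.zeros((n_pairs(6), 3, 3)))
        assert np.all(contact_scores(m) == 0)

    def test_single_strong_pair_ranks_first(self, rng):
        N, q = 8, 4
        J = np.zeros((n_pairs(N), q, q))
        J[pair_index(1, 6, N)] = rng.normal(scale=2.0, size=(q, q))
        m = PairwiseModel(h=np.zeros((N, q)), J=J, alphabet="ACDE")
        raw = contact_scores(m, apc=False)
        i, j = np.unravel_index(np.argmax(raw), raw.shape)
        assert {i, j} == {1, 6}

    def test_constant_frobenius_apc_zeroes_everything(self):
        # every off-diagonal pair with the same coupling strength: the APC
        # background model explains all of it
        N, q = 5, 3
        J = np.zeros((n_pairs(N), q, q))
        g = np.random.default_rng(0)
        zs_block = g.normal(size=(q, q))
        zs_block -= zs_block.mean(axis=0)
        zs_block -= zs_block.mean(axis=1, keepdims=True)
        for p in range(n_pairs(N)):
            J[p] = zs_block
        m = PairwiseModel(h=np.zeros((N, q)), J=J, alphabet="ACD")
        assert np.max(np.abs(contact_scores(m))) < 1e-9

    def test_gap_symbol_excluded_when_alphabet_gapped(self):
        from pairdistill import AMINO_ACID_ALPHABET

        N, q = 4, 21
        J = np.zeros((n_pairs(N), q, q))
        # couple only through the gap symbol: should be invisible
        J[pair_index(0, 2, N), 20, 20] = 5.0
        m = PairwiseModel(h=np.zeros((N, q)), J=J, alphabet=AMINO_ACID_ALPHABET)
        raw = contact_scores(m, apc=False)
        # gauge fixing spreads a little mass into non-gap cells, but the
        # gap-only coupling must not dominate
        assert raw[0, 2] < 1.0


class TestPpvCurve:
    def test_perfect_ranking_gives_ones(self):
        N = 12
        truth = ContactMap(pairs={(0, 6), (1, 8), (2, 10)}, N=N)
        scores = np.zeros((N, N))
        for i, j in truth.pairs:
            scores[i, j] = scores[j, i] = 10.0
        curve = ppv_curve(scores, truth, top_n=3)
        assert np.allclose(curve, 1.0)

    def test_no_true_contacts_gives_zero(self, rng):
        N = 10
        truth = ContactMap(pairs=set(), N=N)
        s = rng.random((N, N))
        curve = ppv_curve(s + s.T, truth, top_n=5)
        assert np.all(curve == 0)

    def test_entries_are_fractions_and_truncation_warns(self, rng):
        N = 8
        truth = ContactMap(pairs={(0, 7)}, N=N)
        s = rng.random((N, N))
        with pytest.warns(UserWarning, match="truncated"):
            curve = ppv_curve(s + s.T, truth, top_n=100)
        assert np.all((curve >= 0) & (curve <= 1))
        assert curve[0] in (0.0, 1.0)

    def test_planted_couplings_recovered_from_extraction(self):
        # strong couplings on a known sparse pair set; the extracted model's
        # contact ranking should find them
        N, q = 10, 3
        rng = np.random.default_rng(11)
        true_pairs = {(0, 5), (1, 7), (2, 9), (3, 8)}
        J = np.zeros((n_pairs(N), q, q))
        for i, j in true_pairs:
            J[pair_index(i, j, N)] = rng.normal(scale=1.5, size=(q, q))
        truth_model = PairwiseModel(h=np.zeros((N, q)), J=J, alphabet="ACD")
        fitted, _ = extract_uniform_closed_form(truth_model, n_samples=50_000, seed=12)
        scores = contact_scores(fitted, exclude_last_symbol=False)
        cmap = ContactMap(pairs=true_pairs, N=N, min_separation=2)
        curve = ppv_curve(scores, cmap, top_n=4, min_separation=2)
        assert curve[-1] >= 0.9


class TestCouplingScatter:
    def test_identity_correlation_one(self):
        m = random_pairwise_model(6, 4, seed=1)
        x, y, r = coupling_scatter(m, m, n_points=500, seed=2)
        assert r == pytest.approx(1.0)
        assert np.array_equal(x, y)

    def test_independent_models_uncorrelated(self):
        a = random_pairwise_model(10, 5, seed=3)
        b = random_pairwise_model(10, 5, seed=4)
        _, _, r = coupling_scatter(a, b, n_points=5000, seed=5)
        assert abs(r) < 0.05

    def test_output_length_capped_by_total_entries(self):
        m = random_pairwise_model(3, 2, seed=6)
        x, y, _ = coupling_scatter(m, m, n_points=5000, seed=7)
        assert len(x) == len(y) == n_pairs(3) * 4

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            coupling_scatter(
                random_pairwise_model(4, 3, seed=0), random_pairwise_model(5, 3, seed=0)
            )
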