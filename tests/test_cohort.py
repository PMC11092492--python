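"""Score normalization, behavioral matching and the synthetic cohort."""

import numpy as np
import pytest

from pdnn.cohort_matching import (Cohort, Subject, behavioral_distance,
                                  generate_synthetic_cohort, match_cohort,
                                  normalize_scores, permutation_control,
                                  select_reference_iteration)
from pdnn.training import LearningCurve, SweepResult


def make_sweep(acc, gains=None, iterations=None):
    """SweepResult from a raw (n_gains, n_iters) accuracy array."""
    acc = np.asarray(acc, dtype=float)
    gains = np.arange(1, acc.shape[0] + 1) if gains is None else np.asarray(gains)
    iterations = (100 * np.arange(acc.shape[1])) if iterations is None else np.asarray(iterations)
    curves = [LearningCurve(g, iterations.copy(), acc[i]) for i, g in enumerate(gains)]
    return SweepResult(gains, curves, None, None)


class TestNormalize:
    def test_endpoints_and_midpoint(self):
        out = normalize_scores([2.0, 6.0, 10.0], 2.0, 10.0)
        np.testing.assert_allclose(out, [0, 0.5, 1])

    def test_affine_invariance(self):
        v = np.array([3.0, 5.0, 9.0])
        a = normalize_scores(v, v.min(), v.max())
        b = normalize_scores(v + 100, v.min() + 100, v.max() + 100)
        np.testing.assert_allclose(a, b)

    def test_degenerate_range_raises(self):
        with pytest.raises(ValueError):
            normalize_scores([1.0], 5.0, 5.0)


class TestDistance:
    def test_examples_and_symmetry(self):
        assert behavioral_distance(0.5, 0.5) == 0
        assert behavioral_distance(1.0, 0.0) == 1.0
        assert behavioral_distance(0.2, 0.7) == behavioral_distance(0.7, 0.2)


class TestMatching:
    def test_self_matching_recovers_generating_gain(self):
        # cohort built from the sweep's own normalized accuracies (with unit
        # normalization anchors): every subject matches its generating gain
        # with zero distance
        acc = np.array([[0.1, 0.9], [0.1, 0.6], [0.1, 0.3]])
        sweep = make_sweep(acc)
        norm = (acc - acc.min()) / (acc.max() - acc.min())
        subjects = [Subject(f"s{i}", norm[i, 1], "TD") for i in range(3)]
        match = match_cohort(sweep, Cohort(subjects, norm_bounds=(0.0, 1.0)))
        np.testing.assert_allclose(match.distance[1], 0, atol=1e-12)
        np.testing.assert_array_equal(match.best_gain[1], sweep.gains)

    def test_tie_breaks_toward_lower_gain(self):
        acc = np.array([[0.0, 0.5], [0.0, 0.5], [0.0, 1.0]])
        sweep = make_sweep(acc)
        match = match_cohort(sweep, Cohort([Subject("s", 50.0, "TD"),
                                            Subject("t", 0.0, "MLD")]))
        # subject "t" (normalized 0) is equidistant from the two 0.5-accuracy
        # models at the final iteration: the lower gain wins
        assert match.best_gain[1, 1] == sweep.gains[0]

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            match_cohort(make_sweep([[0.1, 0.5]]), Cohort([]))


class TestReferenceIteration:
    def test_argmin_with_earliest_tie(self):
        acc = np.array([[0.0, 0.4, 0.35, 0.8]])
        sweep = make_sweep(acc, iterations=np.array([0, 100, 200, 300]))
        cohort = Cohort([Subject("s", 35.0, "TD")])  # normalized 0.35... exactly?
        match = match_cohort(sweep, Cohort([Subject("a", 90.0, "TD"),
                                            Subject("b", 10.0, "MLD")]))
        it = select_reference_iteration(match)
        assert it in match.iterations

    def test_explicit_vector(self):
        # two gains, two subjects at normalized 1 and 0; accuracies chosen so
        # the cohort-mean best distance is [0.5, 0.0, 0.2] -> argmin at 200
        acc = np.array([[0.4, 1.0, 0.7], [0.4, 0.0, 0.1]])
        sweep = make_sweep(acc, iterations=np.array([100, 200, 300]))
        match = match_cohort(sweep, Cohort([Subject("hi", 100.0, "TD"),
                                            Subject("lo", 0.0, "MLD")]))
        np.testing.assert_allclose(match.mean_distance(), [0.5, 0.0, 0.2])
        assert select_reference_iteration(match) == 200


class TestPermutationControl:
    def test_seeded_reproducible(self):
        sweep = make_sweep(np.linspace(0, 1, 12).reshape(4, 3))
        cohort = Cohort([Subject(f"s{i}", float(10 * i), "TD") for i in range(4)])
        match = match_cohort(sweep, cohort)
        a = permutation_control(match, n_perm=5, seed=3)
        b = permutation_control(match, n_perm=5, seed=3)
        np.testing.assert_array_equal(a.per_permutation, b.per_permutation)

    def test_fitted_beats_null_for_separated_cohort(self):
        rng = np.random.default_rng(0)
        acc = np.concatenate([np.linspace(0.9, 0.1, 9)[:, None]] * 2, axis=1)
        sweep = make_sweep(acc)
        norm = (acc - acc.min()) / (acc.max() - acc.min())
        cohort = Cohort([Subject(f"s{i}", float(norm[i, 0] * 100), "TD") for i in range(9)])
        match = match_cohort(sweep, cohort)
        ctrl = permutation_control(match, n_perm=200, seed=1)
        assert ctrl.fitted_mean < ctrl.null_mean

    def test_degenerate_equal_accuracy_no_signal(self):
        acc = np.full((5, 2), 0.5)
        acc[0, 0] = 0.0  # keep the normalization range non-degenerate
        sweep = make_sweep(acc)
        cohort = Cohort([Subject("a", 50.0, "TD"), Subject("b", 60.0, "TD")])
        match = match_cohort(sweep, cohort)
        ctrl = permutation_control(match, n_perm=300, seed=0, iteration=100)
        # all gains identical at iteration 100 -> permuted equals fitted
        assert ctrl.null_mean == pytest.approx(ctrl.fitted_mean, abs=1e-12)


class TestSyntheticCohort:
    def _sweep(self):
        gains = 1 + 0.25 * np.arange(17)
        iters = np.array([0, 100, 200])
        rng = np.random.default_rng(5)
        acc = 0.05 + (0.9 - 0.8 * (gains[:, None] - 1) / 4) * (iters[None, :] / 200)
        return SweepResult(gains, [LearningCurve(g, iters.copy(), acc[i])
                                   for i, g in enumerate(gains)], None, None)

    def test_group_sizes_and_threshold(self):
        sweep = self._sweep()
        cohort = generate_synthetic_cohort(24, 21, sweep, 200, 0.0, seed=0)
        assert len(cohort.subjects) == 45
        groups = cohort.groups
        assert (groups == "MLD").sum() == 21
        scores = cohort.scores
        assert scores[groups == "MLD"].max() < scores[groups == "TD"].min()

    def test_noiseless_recovery_is_exact(self):
        sweep = self._sweep()
        cohort = generate_synthetic_cohort(10, 10, sweep, 200, 0.0, seed=2)
        match = match_cohort(sweep, cohort)
        i = np.nonzero(match.iterations == 200)[0][0]
        np.testing.assert_allclose(match.best_gain[i], cohort.true_gains)

    def test_seed_determinism(self):
        sweep = self._sweep()
        a = generate_synthetic_cohort(5, 5, sweep, 200, 0.05, seed=9)
        b = generate_synthetic_cohort(5, 5, sweep, 200, 0.05, seed=9)
        np.testing.assert_array_equal(a.scores, b.scores)
        np.testing.assert_array_equal(a.true_gains, b.true_gains)

    def test_rejects_empty_group(self):
        with pytest.raises(ValueError):
            generate_synthetic_cohort(0, 5, self._sweep(), 200, 0.0, seed=0)


class TestCohortCsv:
    def test_roundtrip_and_group_check(self, tmp_path):
        cohort = Cohort([Subject("a", 95.0, "TD"), Subject("b", 85.0, "MLD")])
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path)
        back = Cohort.from_csv(path)
        assert [s.group for s in back.subjects] == ["TD", "MLD"]

    def test_inconsistent_group_rejected(self, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text("subject_id,score,group\na,95.0,MLD\n")
        with pytest.raises(ValueError):
            Cohort.from_csv(path)
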