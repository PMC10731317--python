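import numpy as np
import pandas as pd
import pytest

from eyelab import psychometrics as psy
from eyelab import synthetic_data as synth
from eyelab._exceptions import (
    CoverageError,
    CrossLoadingError,
    DegenerateItemError,
)


def _noise_matrix(seed, n=456, p=10):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.standard_normal((n, p)))


class TestParallelAnalysis:
    def test_pure_noise_retains_zero_factors(self):
        # Horn's criterion with the 95th-percentile reference: noise data
        # clear the bar in ~5% of seeds by construction, so the zero-factor
        # rate over this frozen seed set must be ≥ 95%
        retained = [
            psy.parallel_analysis(
                _noise_matrix(s), n_random=300, criterion="p95", seed=2000 + s
            )
            for s in range(100, 140)
        ]
        assert np.mean(np.array(retained) == 0) >= 0.95

    def test_two_factor_data_retains_two(self, study2_ratings):
        items = study2_ratings[list(psy.PERSONALITY_ITEMS)]
        assert psy.parallel_analysis(items, seed=0) == 2

    def test_rank_one_data_retains_one(self):
        rng = np.random.default_rng(9)
        f = rng.standard_normal(456)
        data = pd.DataFrame(
            np.outer(f, np.full(10, 0.85)) + 0.3 * rng.standard_normal((456, 10))
        )
        assert psy.parallel_analysis(data, seed=1) == 1

    def test_column_permutation_invariance(self, study2_ratings):
        items = study2_ratings[list(psy.PERSONALITY_ITEMS)]
        shuffled = items[list(np.random.default_rng(2).permutation(items.columns))]
        assert psy.parallel_analysis(items, seed=3) == psy.parallel_analysis(
            shuffled, seed=3
        )

    def test_deterministic_given_seed(self, study2_ratings):
        items = study2_ratings[list(psy.PERSONALITY_ITEMS)]
        assert psy.parallel_analysis(items, seed=7) == psy.parallel_analysis(
            items, seed=7
        )

    def test_constant_column_raises(self):
        data = _noise_matrix(3)
        data[0] = 1.0
        with pytest.raises(DegenerateItemError):
            psy.parallel_analysis(data)

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError):
            psy.parallel_analysis(_noise_matrix(4, n=20, p=10))


def _align(recovered: pd.DataFrame, target: pd.DataFrame) -> np.ndarray:
    """Best column permutation/sign alignment of recovered onto target."""
    R, T = recovered.to_numpy(), target.to_numpy()
    best = None
    from itertools import permutations, product

    for perm in permutations(range(T.shape[1])):
        for signs in product([1, -1], repeat=T.shape[1]):
            cand = R[:, list(perm)] * np.array(signs)
            rmse = np.sqrt(((cand - T) ** 2).mean())
            if best is None or rmse < best[0]:
                best = (rmse, cand)
    return best


class TestMlFactorAnalysis:
    def test_recovers_generator_loadings(self, factor_solution):
        rmse, _ = _align(factor_solution.loadings, synth.DEFAULT_LOADINGS)
        assert rmse < 0.10

    def test_communality_identity(self, factor_solution):
        row_sums = (factor_solution.loadings**2).sum(axis=1)
        assert np.allclose(factor_solution.communalities, row_sums, atol=1e-8)
        assert (factor_solution.communalities <= 1.0).all()
        assert (factor_solution.communalities >= 0.0).all()

    def test_ss_loadings_are_column_sums(self, factor_solution):
        cols = (factor_solution.loadings**2).sum(axis=0)
        assert np.allclose(factor_solution.ss_loadings, cols)
        # ordered by descending explained variance
        assert factor_solution.ss_loadings.is_monotonic_decreasing

    def test_sign_convention(self, factor_solution):
        for col in factor_solution.loadings:
            column = factor_solution.loadings[col]
            assert column.loc[column.abs().idxmax()] > 0

    def test_near_zero_uniqueness_drives_communalities_to_one(self):
        # noise SD 0.1 is near the smallest uniqueness the ML optimizer
        # handles stably; communalities approach 1 from below
        rng = np.random.default_rng(10)
        f = rng.standard_normal((800, 2))
        L = np.array(
            [[0.9, 0], [0.8, 0], [0.85, 0], [0.7, 0.1], [0.75, 0],
             [0, 0.9], [0, 0.8], [0.1, 0.85], [0, 0.7], [0, 0.75]]
        )
        data = pd.DataFrame(f @ L.T + 0.1 * rng.standard_normal((800, 10)))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # Heywood flags are expected here
            solution = psy.ml_factor_analysis(data, 2)
        assert solution.communalities.min() > 0.9

    def test_variance_explained_identity(self, factor_solution):
        expected = factor_solution.ss_loadings.sum() / len(
            factor_solution.loadings
        )
        assert factor_solution.variance_explained == pytest.approx(expected)


def _solution_from_reference(reference_loadings, study=2):
    sub = reference_loadings[reference_loadings["study"] == study]
    loadings = sub.set_index("item")[["factor1", "factor2"]]
    communalities = (loadings**2).sum(axis=1)
    ss = (loadings**2).sum(axis=0)
    return psy.FactorSolution(
        n_factors=2,
        loadings=loadings,
        communalities=communalities,
        ss_loadings=ss,
        variance_explained=float(ss.sum() / len(loadings)),
    )


class TestAssignItems:
    def test_reference_pattern_assignment(self, reference_loadings):
        solution = _solution_from_reference(reference_loadings)
        mapping = psy.assign_items(solution)
        friendliness = {i for i, (s, _) in mapping.items() if s == "friendliness"}
        maturity = {i for i, (s, _) in mapping.items() if s == "maturity"}
        assert friendliness == {"sociable", "kind", "friendly", "easygoing",
                                "aggressive"}
        assert maturity == {"trustworthy", "confident", "independent",
                            "intelligent", "mature"}
        assert mapping["aggressive"][1] == -1
        assert all(mapping[i][1] == 1 for i in friendliness - {"aggressive"})

    def test_sign_flip_invariance(self, reference_loadings):
        solution = _solution_from_reference(reference_loadings)
        flipped = _solution_from_reference(reference_loadings)
        flipped.loadings = flipped.loadings.assign(
            factor1=-flipped.loadings["factor1"]
        )
        a = psy.assign_items(solution)
        b = psy.assign_items(flipped)
        assert {i: s for i, (s, _) in a.items()} == {
            i: s for i, (s, _) in b.items()
        }

    def test_all_below_threshold_raises(self, reference_loadings):
        solution = _solution_from_reference(reference_loadings)
        solution.loadings = solution.loadings * 0.1
        with pytest.raises(CoverageError):
            psy.assign_items(solution)

    def test_cross_loading_raises(self, reference_loadings):
        solution = _solution_from_reference(reference_loadings)
        solution.loadings.loc["mature", "factor1"] = 0.75
        with pytest.raises(CrossLoadingError) as err:
            psy.assign_items(solution)
        assert "mature" in err.value.items


def _single_rater_frame(values: dict[str, int], n_raters=1):
    rows = []
    for r in range(n_raters):
        for image_id in (1, 2):
            for colour in ("dark", "light"):
                rows.append(
                    {
                        "participant_id": f"p{r}",
                        "image_id": image_id,
                        "eye_colour": colour,
                        **values,
                    }
                )
    return pd.DataFrame(rows)


class TestScaleScores:
    def test_maximal_case_under_reversal(self):
        values = {item: 5 for item in psy.PERSONALITY_ITEMS}
        values["aggressive"] = 0  # reversed: contributes 5
        table = psy.scale_scores(
            _single_rater_frame(values), synth.DEFAULT_MAPPING
        )
        assert (table["friendliness"] == 5.0).all()

    def test_identical_raters_reduce_to_single_rater(self):
        values = {item: 3 for item in psy.PERSONALITY_ITEMS}
        one = psy.scale_scores(_single_rater_frame(values, 1), synth.DEFAULT_MAPPING)
        many = psy.scale_scores(_single_rater_frame(values, 7), synth.DEFAULT_MAPPING)
        pd.testing.assert_frame_equal(
            one.drop(columns="n_raters"), many.drop(columns="n_raters")
        )

    def test_rater_order_invariance(self, study2_ratings):
        shuffled = study2_ratings.sample(frac=1.0, random_state=0)
        a = psy.scale_scores(study2_ratings, synth.DEFAULT_MAPPING)
        b = psy.scale_scores(shuffled, synth.DEFAULT_MAPPING)
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True)
        )

    def test_incomplete_mapping_raises(self, study2_ratings):
        mapping = dict(synth.DEFAULT_MAPPING)
        mapping.pop("mature")
        with pytest.raises(CoverageError):
            psy.scale_scores(study2_ratings, mapping)

    def test_latent_gap_maps_to_score_gap(self):
        # generator truth: a latent dark-minus-light friendliness gap δ maps
        # to a score gap of ≈ mean|loading|·δ; observed within 0.15 at 76 raters
        delta = 0.5
        design = synth.generate_design(76, seed=21)
        ratings = synth.generate_ratings(
            design, synth.RatingModelSpec(seed=22, delta_f=delta, delta_m=0.0)
        )
        table = psy.scale_scores(ratings, synth.DEFAULT_MAPPING)
        gap = (
            table.pivot(index="image_id", columns="eye_colour",
                        values="friendliness")
            .eval("dark - light")
            .mean()
        )
        friendliness_loadings = synth.DEFAULT_LOADINGS["factor1"]
        expected = friendliness_loadings.abs()[
            friendliness_loadings != 0
        ].mean() * delta
        assert gap == pytest.approx(expected, abs=0.15)

    def test_full_design_has_24_rows(self, scale_table):
        assert len(scale_table) == 24
        assert scale_table["friendliness"].between(0, 5).all()
        assert scale_table["maturity"].between(0, 5).all()
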