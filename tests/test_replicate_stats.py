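"""Normalization, correlation and dispersion statistics for replicate sections."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest

import spotquant as sq
from spotquant.spatial_quant import SpotGeneCounts
from spotquant.replicate_stats import (
    bulk_sum,
    coefficient_of_variation,
    log2_pseudo,
    normalize_counts,
    pearson_matrix,
    region_average,
    size_factors,
)


def _counts(mat, design=None):
    return SpotGeneCounts(mat, design=design)


@pytest.fixture(scope="module")
def profiles():
    design = sq.make_array_design(n_spots=50, n_cols=10, seed=1)
    tx = sq.make_transcriptome(n_genes=100, seed=2)
    return sq.make_spot_profiles(design, tx, baseline_mean=10.0, seed=3)


class TestBulkSum:
    def test_single_spot_is_identity(self):
        mat = pd.DataFrame([[3, 0, 7]], index=["0_0"], columns=list("abc"))
        assert bulk_sum(_counts(mat)).tolist() == [3, 0, 7]

    def test_two_spots_add(self):
        mat = pd.DataFrame({"g": [1, 2]}, index=["0_0", "1_0"])
        assert bulk_sum(_counts(mat))["g"] == 3

    def test_equals_ground_truth_totals_when_noise_free(self, clean_run):
        totals = bulk_sum(clean_run.result.counts)
        truth_mat = clean_run.truth.true_matrix(
            clean_run.design, clean_run.transcriptome.polya_gene_ids
        )
        assert totals.equals(truth_mat.sum(axis=0))


class TestRegionAverage:
    def test_single_spot_region_is_that_spot(self):
        mat = pd.DataFrame({"g": [5, 9]}, index=["0_0", "1_0"])
        assert region_average(_counts(mat), [(0, 0)])["g"] == 5

    def test_two_spot_region_averages(self):
        mat = pd.DataFrame({"g": [2, 4]}, index=["0_0", "1_0"])
        assert region_average(_counts(mat), [(0, 0), (1, 0)])["g"] == 3

    def test_unknown_spot_named_in_error(self):
        mat = pd.DataFrame({"g": [2]}, index=["0_0"])
        with pytest.raises(ValueError, match="9_9"):
            region_average(_counts(mat), [(9, 9)])

    def test_empty_region_rejected(self):
        mat = pd.DataFrame({"g": [2]}, index=["0_0"])
        with pytest.raises(ValueError, match="empty"):
            region_average(_counts(mat), [])

    def test_region_effect_visible_in_averaged_counts(self, profiles):
        counts = _counts(sq.simulate_replicate_counts(profiles, seed=11))
        region = region_average(counts, profiles.region_spots)
        background_spots = [
            (x, y)
            for x, y in profiles.design.coordinates
            if (x, y) not in set(profiles.region_spots)
        ]
        background = region_average(counts, background_spots)
        ratios = region[list(profiles.region_genes)] / background[list(profiles.region_genes)]
        assert ratios.mean() == pytest.approx(4.0, rel=0.15)


def size_factor_oracle(df):
    """Direct per-definition median-of-ratios recomputation."""
    keep = [g for g in df.index if (df.loc[g] > 0).all()]
    out = {}
    for sample in df.columns:
        ratios = []
        for g in keep:
            geomean = math.exp(sum(math.log(v) for v in df.loc[g]) / df.shape[1])
            ratios.append(df.loc[g, sample] / geomean)
        out[sample] = statistics.median(ratios)
    return pd.Series(out)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        v = pd.Series([5, 1, 9, 3], name="a")
        df = pd.concat([v.rename("a"), v.rename("b"), v.rename("c")], axis=1)
        assert np.allclose(size_factors(df), 1.0)

    def test_global_doubling_doubles_the_factor(self):
        a = pd.Series([5, 1, 9, 3], name="a")
        df = pd.concat([a, (2 * a).rename("b")], axis=1)
        sf = size_factors(df)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_matches_per_definition_oracle_on_random_samples(self):
        rng = np.random.default_rng(23)
        df = pd.DataFrame(
            rng.poisson(15, size=(80, 3)),
            index=[f"g{i}" for i in range(80)],
            columns=["s1", "s2", "s3"],
        )
        ours = size_factors(df)
        oracle = size_factor_oracle(df)
        assert np.allclose(ours, oracle)

    def test_matches_reference_deseq2_implementation(self):
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(29)
        # odd gene count: the reference takes the median in log space, which
        # matches a ratio-space median exactly only when no averaging occurs
        df = pd.DataFrame(
            rng.poisson(20, size=(61, 4)), columns=[f"s{i}" for i in range(4)]
        )
        assert (df > 0).all().all()
        _, ref = pydeseq2.deseq2_norm(df.T)  # reference wants samples x genes
        assert np.allclose(size_factors(df), np.asarray(ref).ravel())

    def test_all_zero_rows_everywhere_rejected_with_advice(self):
        df = pd.DataFrame({"a": [0, 3], "b": [2, 0]})
        with pytest.raises(ValueError, match="nonzero"):
            size_factors(df)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="two samples"):
            size_factors(pd.DataFrame({"a": [1, 2]}))


class TestLog2Pseudo:
    @pytest.mark.parametrize("x, expected", [(0, 0), (1, 1), (7, 3)])
    def test_exact_values(self, x, expected):
        assert log2_pseudo(np.array([x]))[0] == expected

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            log2_pseudo(np.array([-1.0]))

    def test_preserves_pandas_containers(self):
        s = pd.Series([0.0, 3.0], index=["g1", "g2"], name="s")
        out = log2_pseudo(s)
        assert isinstance(out, pd.Series) and out.name == "s"
        assert out.tolist() == [0.0, 2.0]


class TestPearsonMatrix:
    def test_duplicate_sample_correlates_perfectly(self):
        v = pd.Series([1.0, 4.0, 2.0, 8.0], name="a")
        rep = pearson_matrix([v, v.rename("b")])
        assert rep.pair("a", "b") == pytest.approx(1.0)

    def test_reflected_sample_anticorrelates_perfectly(self):
        v = pd.Series([1.0, 4.0, 2.0, 8.0], name="a")
        rep = pearson_matrix([v, (v.max() - v).rename("b")])
        assert rep.pair("a", "b") == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(37)
        a = pd.Series(rng.poisson(30, 200).astype(float), name="a")
        b = pd.Series((a + rng.normal(0, 5, 200)).clip(0), name="b")
        r = pearson_matrix([a, b]).pair("a", "b")
        xa, xb = a - a.mean(), b - b.mean()
        textbook = (xa * xb).sum() / math.sqrt((xa**2).sum() * (xb**2).sum())
        assert r == pytest.approx(textbook, abs=1e-12)

    def test_affine_rescaling_leaves_r_unchanged(self):
        rng = np.random.default_rng(41)
        a = pd.Series(rng.normal(10, 3, 100), name="a")
        b = pd.Series(rng.normal(10, 3, 100), name="b")
        r0 = pearson_matrix([a, b]).pair("a", "b")
        r1 = pearson_matrix([(2.5 * a + 7).rename("a"), b]).pair("a", "b")
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_matrix_is_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(43)
        samples = [pd.Series(rng.poisson(9, 50).astype(float), name=f"s{i}") for i in range(4)]
        m = pearson_matrix(samples).matrix.to_numpy()
        assert np.allclose(m, m.T) and np.allclose(np.diag(m), 1.0)
        assert (np.abs(m) <= 1 + 1e-12).all()

    def test_zero_variance_sample_named(self):
        a = pd.Series([1.0, 2.0, 3.0], name="ok")
        b = pd.Series([4.0, 4.0, 4.0], name="flat")
        with pytest.raises(ValueError, match="flat"):
            pearson_matrix([a, b])


class TestCoefficientOfVariation:
    def test_constant_vector_has_zero_cv(self):
        assert coefficient_of_variation([4.2, 4.2, 4.2]) == 0.0

    def test_hand_computed_value(self):
        # sd([1,3]) = sqrt(2), mean = 2 -> 70.710...%
        assert coefficient_of_variation([1, 3]) == pytest.approx(100 * math.sqrt(2) / 2)

    def test_matches_independent_recomputation_at_library_scale(self):
        vals = [4.38e6, 4.02e6, 4.71e6]
        expected = 100 * statistics.stdev(vals) / statistics.mean(vals)
        assert coefficient_of_variation(vals) == pytest.approx(expected, abs=1e-9)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


def _bulk_r_pair(profiles, sigma, seed):
    a = bulk_sum(_counts(sq.simulate_replicate_counts(profiles, sigma, seed=seed)), "a")
    b = bulk_sum(_counts(sq.simulate_replicate_counts(profiles, sigma, seed=seed + 1)), "b")
    t = log2_pseudo(normalize_counts([a, b]))
    return pearson_matrix(t).pair("a", "b")


class TestConcordanceProperties:
    def test_pure_depth_difference_normalizes_away(self, profiles):
        counts = sq.simulate_replicate_counts(profiles, seed=51)
        a = bulk_sum(_counts(counts), "a")
        b = (3 * a).rename("b")
        sf = size_factors([a, b])
        assert sf["b"] / sf["a"] == pytest.approx(3.0, abs=1e-9)
        normed = normalize_counts([a, b])
        assert np.allclose(normed["a"], normed["b"])
        r = pearson_matrix(log2_pseudo(normed)).pair("a", "b")
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_increasing_technical_noise_decreases_mean_r(self, profiles):
        levels = [0.05, 0.3, 0.8]
        mean_rs = []
        for li, sigma in enumerate(levels):
            rs = [_bulk_r_pair(profiles, sigma, 100 * li + 2 * rep) for rep in range(5)]
            mean_rs.append(np.mean(rs))
        assert mean_rs[0] > mean_rs[1] > mean_rs[2]

    def test_region_correlations_more_variable_than_bulk(self, profiles):
        bulk_rs, region_rs = [], []
        for rep in range(20):
            ca = _counts(sq.simulate_replicate_counts(profiles, 0.1, seed=1000 + 2 * rep))
            cb = _counts(sq.simulate_replicate_counts(profiles, 0.1, seed=1001 + 2 * rep))
            for extractor, out in (
                (lambda c, n: bulk_sum(c, n), bulk_rs),
                (lambda c, n: region_average(c, profiles.region_spots, n), region_rs),
            ):
                t = log2_pseudo(normalize_counts([extractor(ca, "a"), extractor(cb, "b")]))
                out.append(pearson_matrix(t).pair("a", "b"))
        assert statistics.variance(region_rs) > statistics.variance(bulk_rs)
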