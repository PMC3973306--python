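import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from crossmeth import ValidationError
from crossmeth.core_io import IntensitySet, ProbeAnnotation
from crossmeth.preprocess import (
    PROFILE_27K,
    PROFILE_450K,
    ExtremeProbeFilter,
    QualityThresholds,
    align_typeII_to_typeI,
    compute_beta,
    drop_failed_samples,
    filter_extreme_probes,
    filter_snp_probes,
    mask_low_quality,
    quantile_normalize,
)

from conftest import make_beta


def intensity_set(m, u, p=None, beads=None):
    idx = [f"S{i + 1}" for i in range(np.shape(m)[0])]
    cols = [f"cg{j + 1}" for j in range(np.shape(m)[1])]
    wrap = lambda a: None if a is None else pd.DataFrame(np.asarray(a, float), index=idx, columns=cols)
    return IntensitySet(wrap(m), wrap(u), wrap(p), wrap(beads))


class TestComputeBeta:
    @pytest.mark.parametrize(
        "m,u,expected",
        [(0.0, 0.0, 0.0), (1000.0, 900.0, 0.5), (900.0, 0.0, 0.9)],
    )
    def test_beta_formula(self, m, u, expected):
        beta = compute_beta(intensity_set([[m]], [[u]]))
        assert beta.values[0, 0] == pytest.approx(expected)

    def test_strictly_below_one_with_positive_offset(self, rng):
        m = rng.uniform(0, 1e5, (3, 20))
        beta = compute_beta(intensity_set(m, np.zeros_like(m)), offset=100.0)
        assert (beta.values < 1.0).all()

    def test_negative_signal_rejected(self):
        with pytest.raises(ValidationError):
            compute_beta(intensity_set([[-1.0]], [[5.0]]))


class TestQualityMasking:
    def test_detection_p_threshold_is_strict(self):
        intens = intensity_set([[100, 100, 100]], [[100, 100, 100]], p=[[0.04, 0.05, 0.051]])
        beta = compute_beta(intens)
        out = mask_low_quality(beta, intens, QualityThresholds(detection_p_max=0.05, min_bead_count=0))
        np.testing.assert_array_equal(out.missing_mask.to_numpy()[0], [False, False, True])

    def test_bead_count_below_three_masks(self):
        intens = intensity_set(
            [[100] * 3], [[100] * 3], p=[[0.0] * 3], beads=[[2, 3, 30]]
        )
        beta = compute_beta(intens)
        out = mask_low_quality(beta, intens, PROFILE_450K)
        np.testing.assert_array_equal(out.missing_mask.to_numpy()[0], [True, False, False])

    def test_dimension_mismatch_is_an_error(self):
        beta = make_beta([[0.5, 0.5]])
        intens = intensity_set([[100]], [[100]])
        with pytest.raises(ValidationError):
            mask_low_quality(beta, intens, PROFILE_27K)


class TestSampleQc:
    def test_strictly_above_threshold_removes(self):
        vals = np.full((2, 100), 0.5)
        vals[0, :21] = np.nan  # 21% missing
        vals[1, :20] = np.nan  # exactly 20%: retained
        out = drop_failed_samples(make_beta(vals), PROFILE_450K)
        assert out.sample_ids == ["S2"]

    def test_complete_data_is_identity(self):
        m = make_beta([[0.1, 0.2], [0.3, 0.4]])
        assert drop_failed_samples(m, PROFILE_450K).equals(m)

    def test_all_samples_failing_is_an_error(self):
        vals = np.full((2, 10), np.nan)
        vals[:, 0] = 0.5
        with pytest.raises(ValidationError):
            drop_failed_samples(make_beta(vals), PROFILE_450K)


class TestQuantileNormalize:
    def test_two_sample_rank_mean(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        out = quantile_normalize(df)
        np.testing.assert_allclose(out.to_numpy(), [[2.5, 3.5, 4.5], [2.5, 3.5, 4.5]])

    def test_identical_samples_fixed_point(self):
        df = pd.DataFrame([[0.3, 0.9, 0.1], [0.3, 0.9, 0.1]])
        out = quantile_normalize(df)
        np.testing.assert_allclose(out.to_numpy(), df.to_numpy())

    def test_permuted_samples_become_same_multiset(self):
        df = pd.DataFrame([[5.0, 1.0, 3.0], [1.0, 3.0, 5.0]])
        out = quantile_normalize(df)
        np.testing.assert_allclose(np.sort(out.iloc[0]), np.sort(out.iloc[1]))
        # ranks preserved within each sample
        assert list(out.iloc[0].rank()) == list(df.iloc[0].rank())

    def test_single_usable_value_is_an_error(self):
        df = pd.DataFrame([[1.0, np.nan, np.nan], [1.0, 2.0, 3.0]])
        with pytest.raises(ValidationError):
            quantile_normalize(df)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        arrays(
            float,
            st.tuples(st.integers(2, 6), st.integers(2, 30)),
            elements=st.floats(0, 1, allow_nan=False, width=32).map(float),
        )
    )
    def test_complete_data_contract(self, vals):
        out = quantile_normalize(pd.DataFrame(vals)).to_numpy()
        sorted_rows = np.sort(out, axis=1)
        for i in range(1, out.shape[0]):
            np.testing.assert_allclose(sorted_rows[i], sorted_rows[0], atol=1e-12)
        assert np.sum(out) == pytest.approx(np.sum(vals), rel=1e-9, abs=1e-9)


def annotation(design, category, snp=None):
    probes = [f"cg{j + 1:05d}" for j in range(len(design))]
    table = pd.DataFrame(
        {
            "design_type": design,
            "category": category,
            "snp_flag": snp if snp is not None else [False] * len(design),
        },
        index=probes,
    )
    return ProbeAnnotation(table)


class TestTypeIIAlignment:
    def test_identical_distributions_unchanged(self):
        vals = [[0.1, 0.5, 0.9, 0.1, 0.5, 0.9]]
        ann = annotation(["I"] * 3 + ["II"] * 3, ["island"] * 6)
        out = align_typeII_to_typeI(make_beta(vals), ann)
        np.testing.assert_allclose(out.values, vals, atol=1e-12)

    def test_single_type2_probe_at_median_maps_to_type1_median(self):
        # type I values {0.2, 0.4, 0.8}: median 0.4; single type II value maps there
        vals = [[0.2, 0.4, 0.8, 0.55]]
        ann = annotation(["I", "I", "I", "II"], ["island"] * 4)
        out = align_typeII_to_typeI(make_beta(vals), ann)
        assert out.values[0, 3] == pytest.approx(0.4)

    def test_monotone_and_type1_untouched(self, rng):
        n2 = 10
        vals = np.concatenate([rng.uniform(0, 1, 6), np.sort(rng.uniform(0, 1, n2))])[None, :]
        ann = annotation(["I"] * 6 + ["II"] * n2, ["shore"] * 16)
        out = align_typeII_to_typeI(make_beta(vals), ann)
        np.testing.assert_array_equal(out.values[0, :6], vals[0, :6])
        mapped = out.values[0, 6:]
        assert (np.diff(mapped) >= -1e-12).all()
        assert (mapped >= 0).all() and (mapped <= 1).all()

    def test_category_without_type1_probes_is_an_error(self):
        ann = annotation(["II", "II"], ["shelf", "shelf"])
        with pytest.raises(ValidationError, match="shelf"):
            align_typeII_to_typeI(make_beta([[0.2, 0.4]]), ann)


class TestSnpFilter:
    def test_flagged_probes_removed(self):
        ann = annotation(["I"] * 3, ["island"] * 3, snp=[False, True, False])
        out = filter_snp_probes(make_beta([[0.1, 0.2, 0.3]]), ann)
        assert out.n_probes == 2 and "cg00002" not in out.probe_ids

    def test_no_flags_is_identity(self):
        m = make_beta([[0.1, 0.2]])
        ann = annotation(["I", "II"], ["island", "island"])
        assert filter_snp_probes(m, ann).equals(m)

    def test_all_flagged_leaves_empty_probe_set(self):
        ann = annotation(["I", "I"], ["island"] * 2, snp=[True, True])
        out = filter_snp_probes(make_beta([[0.1, 0.2]]), ann)
        assert out.n_probes == 0


class TestExtremeProbeFilter:
    def test_constitutively_high_probe_removed(self):
        m = make_beta([[0.92, 0.3], [0.95, 0.7], [0.99, 0.5]])
        kept = filter_extreme_probes([m], ExtremeProbeFilter(0.9, 0.1))
        assert kept == ["cg00002"]

    def test_constitutively_low_probe_removed(self):
        m = make_beta([[0.05, 0.3], [0.08, 0.7]])
        kept = filter_extreme_probes([m], ExtremeProbeFilter(0.9, 0.1))
        assert kept == ["cg00002"]

    def test_mid_range_probe_kept_under_both_levels(self):
        m = make_beta([[0.30], [0.70]])
        for f in (ExtremeProbeFilter(0.9, 0.1), ExtremeProbeFilter(0.8, 0.2)):
            assert filter_extreme_probes([m], f) == ["cg00001"]

    def test_vacuous_thresholds_retain_everything(self, small_pair):
        X, Y, _, _ = small_pair
        kept = filter_extreme_probes([X, Y], ExtremeProbeFilter(1.0, 0.0))
        assert kept == X.probe_ids

    def test_nestedness_of_filter_levels(self, small_pair):
        X, Y, _, _ = small_pair
        loose = set(filter_extreme_probes([X, Y], ExtremeProbeFilter(0.9, 0.1)))
        strict = set(filter_extreme_probes([X, Y], ExtremeProbeFilter(0.8, 0.2)))
        assert strict <= loose

    def test_pooling_spans_all_matrices(self):
        # probe is extreme in each matrix alone but not pooled
        a = make_beta([[0.95], [0.92]])
        b = make_beta([[0.50], [0.60]])
        assert filter_extreme_probes([a, b], ExtremeProbeFilter(0.9, 0.1)) == ["cg00001"]

    def test_invalid_threshold_order_rejected(self):
        with pytest.raises(ValidationError):
            ExtremeProbeFilter(0.1, 0.9)
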