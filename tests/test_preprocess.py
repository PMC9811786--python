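"""QC filters, normalization, scale transforms, batch and cell adjustment."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_detection_matrix
from snpmeth.preprocess import (
    SingletonBatchError,
    adjust_batch_location_scale,
    adjust_cell_composition,
    beta_to_m,
    estimate_cell_proportions,
    filter_probes_by_annotation,
    filter_probes_by_detection,
    filter_samples_by_detection,
    m_to_beta,
    quantile_normalize,
)
from snpmeth.types import MethylationMatrix


def _mat(values, detection=None, scale="beta"):
    return MethylationMatrix(values=values, scale=scale, detection_p=detection)


class TestDetectionFilters:
    def test_sample_above_threshold_retained_at_boundary_removed(self):
        det = make_detection_matrix([0.80, 0.75, 1.0])
        values = pd.DataFrame(
            np.full(det.shape, 0.5), index=det.index, columns=det.columns
        )
        out = filter_samples_by_detection(_mat(values, det))
        # 80% passing retained; exactly 75% removed (strict >); all-pass retained
        assert out.sample_ids == ["s0", "s2"]

    def test_all_pass_matrix_is_identity(self):
        det = make_detection_matrix([1.0, 1.0])
        values = pd.DataFrame(
            np.full(det.shape, 0.5), index=det.index, columns=det.columns
        )
        out = filter_samples_by_detection(_mat(values, det))
        assert out.sample_ids == ["s0", "s1"]
        assert out.probe_ids == list(det.index)

    def test_missing_detection_matrix_rejected(self):
        values = pd.DataFrame({"s1": [0.5]}, index=["p1"])
        with pytest.raises(ValueError):
            filter_samples_by_detection(_mat(values))

    def test_probe_filter_boundary_and_count(self):
        # probes pass in 76%, 75%, and varying fractions of 100 samples
        n_samples = 100
        fracs = [0.76, 0.75, 1.0, 0.5, 0.9, 1.0, 0.2, 1.0, 1.0, 1.0]
        rows = []
        for f in fracs:
            k = int(round(f * n_samples))
            rows.append([0.001] * k + [0.5] * (n_samples - k))
        det = pd.DataFrame(
            rows,
            index=[f"p{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
        values = pd.DataFrame(
            np.full(det.shape, 0.5), index=det.index, columns=det.columns
        )
        out = filter_probes_by_detection(_mat(values, det))
        assert "p0" in out.probe_ids  # 76% > 75%
        assert "p1" not in out.probe_ids  # exactly 75% -> removed
        assert len(out.probe_ids) == 7  # 3 probes fail (0.75, 0.5, 0.2)

    def test_filters_idempotent(self):
        det = make_detection_matrix([0.80, 0.70, 1.0])
        values = pd.DataFrame(
            np.full(det.shape, 0.5), index=det.index, columns=det.columns
        )
        once = filter_samples_by_detection(_mat(values, det))
        twice = filter_samples_by_detection(once)
        assert once.sample_ids == twice.sample_ids


class TestAnnotationFilter:
    @pytest.fixture
    def eight_probe_setup(self):
        probes = [f"p{i}" for i in range(8)]
        values = pd.DataFrame(
            np.full((8, 3), 0.5), index=probes, columns=["s1", "s2", "s3"]
        )
        ann = pd.DataFrame(
            {
                "chrom": ["chrX", "chr1", "chr1", "chr1", "chr1", "chr2", "chr2", "chr2"],
                "is_sex_chrom": [True] + [False] * 7,
                "is_cpg": [True, False] + [True] * 6,
                "snp_in_probe_maf": [0, 0, 0.06, 0, 0, 0, 0, 0],
                "snp_at_cpg_or_sbe": [False] * 8,
                "cross_reactive": [False] * 8,
            },
            index=probes,
        )
        return _mat(values), ann

    def test_enumerated_removals(self, eight_probe_setup):
        mat, ann = eight_probe_setup
        out, report = filter_probes_by_annotation(
            mat, ann, cross_reactive={"p3"}
        )
        assert set(out.probe_ids) == {"p4", "p5", "p6", "p7"}
        assert report["sex_chromosome"] == 1
        assert report["non_cpg"] == 1
        assert report["snp_in_probe"] == 1
        assert report["cross_reactive"] == 1

    def test_maf_exactly_at_threshold_retained(self, eight_probe_setup):
        mat, ann = eight_probe_setup
        ann.loc["p2", "snp_in_probe_maf"] = 0.05  # strict > 0.05 removes
        out, _ = filter_probes_by_annotation(mat, ann)
        assert "p2" in out.probe_ids

    def test_clean_annotation_is_identity(self, eight_probe_setup):
        mat, ann = eight_probe_setup
        ann["is_sex_chrom"] = False
        ann["is_cpg"] = True
        ann["snp_in_probe_maf"] = 0.0
        out, report = filter_probes_by_annotation(mat, ann)
        assert out.probe_ids == mat.probe_ids
        assert sum(report.values()) == 0

    def test_missing_value_rule_claims_probe(self, eight_probe_setup):
        mat, ann = eight_probe_setup
        ann["is_sex_chrom"] = False
        ann["is_cpg"] = True
        ann["snp_in_probe_maf"] = 0.0
        mat.values.loc["p5", "s2"] = np.nan
        out, report = filter_probes_by_annotation(mat, ann)
        assert "p5" not in out.probe_ids
        assert report["missing_values"] == 1

    def test_unannotated_probe_rejected(self, eight_probe_setup):
        mat, ann = eight_probe_setup
        with pytest.raises(ValueError):
            filter_probes_by_annotation(mat, ann.drop(index="p3"))


class TestQuantileNormalize:
    def test_two_sample_forced_result(self):
        values = pd.DataFrame(
            {"s1": [0.1, 0.2, 0.3], "s2": [0.4, 0.5, 0.6]}, index=["a", "b", "c"]
        )
        out = quantile_normalize(_mat(values))
        expected = [0.25, 0.35, 0.45]
        assert np.allclose(out.values["s1"], expected)
        assert np.allclose(out.values["s2"], expected)

    def test_identical_distributions_unchanged(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(0.1, 0.9, 50)
        values = pd.DataFrame(
            {"s1": col, "s2": rng.permutation(col)},
            index=[f"p{i}" for i in range(50)],
        )
        out = quantile_normalize(_mat(values))
        pd.testing.assert_frame_equal(out.values, values)

    def test_equalizes_sample_distributions_exactly(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(
            rng.uniform(0.05, 0.95, (100, 5)),
            index=[f"p{i}" for i in range(100)],
            columns=[f"s{j}" for j in range(5)],
        )
        out = quantile_normalize(_mat(values))
        sorted_cols = np.sort(out.values.to_numpy(), axis=0)
        assert np.ptp(sorted_cols, axis=1).max() == 0.0
        assert np.allclose(out.values.mean(axis=0), out.values.mean(axis=0).iloc[0])

    def test_ties_get_average_target_quantile(self):
        values = pd.DataFrame(
            {"s1": [0.2, 0.2, 0.8], "s2": [0.1, 0.5, 0.9]}, index=["a", "b", "c"]
        )
        out = quantile_normalize(_mat(values))
        target = np.sort(values.to_numpy(), axis=0).mean(axis=1)
        assert out.values.loc["a", "s1"] == pytest.approx((target[0] + target[1]) / 2)
        assert out.values.loc["b", "s1"] == pytest.approx((target[0] + target[1]) / 2)

    def test_nan_rejected(self):
        values = pd.DataFrame({"s1": [0.1, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError):
            quantile_normalize(_mat(values))


class TestScaleTransforms:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_known_values(self, beta, m):
        values = pd.DataFrame({"s": [beta]}, index=["p"])
        out = beta_to_m(_mat(values))
        assert out.values.iloc[0, 0] == pytest.approx(m, abs=1e-12)

    def test_round_trip_exact(self):
        grid = np.arange(0.1, 0.95, 0.1)
        values = pd.DataFrame({"s": grid}, index=[f"p{i}" for i in range(len(grid))])
        back = m_to_beta(beta_to_m(_mat(values)))
        assert np.allclose(back.values["s"], grid, atol=1e-9)

    def test_out_of_range_clipped_with_warning(self):
        values = pd.DataFrame({"s": [0.0, 1.0]}, index=["a", "b"])
        with pytest.warns(UserWarning):
            out = beta_to_m(_mat(values))
        assert np.isfinite(out.values.to_numpy()).all()


class TestBatchAdjustment:
    def _matrix(self, n_probes=30, n_samples=40, seed=0):
        rng = np.random.default_rng(seed)
        values = pd.DataFrame(
            rng.normal(0, 1, (n_probes, n_samples)),
            index=[f"p{i}" for i in range(n_probes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
        return values

    def test_single_batch_identity(self):
        values = self._matrix()
        out = adjust_batch_location_scale(
            _mat(values, scale="M"), np.zeros(values.shape[1], dtype=int)
        )
        pd.testing.assert_frame_equal(out.values, values)

    @pytest.mark.parametrize("shrink", [False, True])
    def test_planted_shift_removed_grand_mean_preserved(self, shrink):
        values = self._matrix()
        batch = np.array([0] * 20 + [1] * 20)
        shifted = values.copy()
        shifted.iloc[:, 20:] += 1.0
        out = adjust_batch_location_scale(_mat(shifted, scale="M"), batch, shrink=shrink)
        diff = (
            out.values.iloc[:, 20:].mean(axis=1) - out.values.iloc[:, :20].mean(axis=1)
        )
        assert np.abs(diff).max() < 0.01
        assert np.allclose(
            out.values.mean(axis=1), shifted.mean(axis=1), atol=1e-9
        )

    def test_singleton_batch_rejected(self):
        values = self._matrix(n_samples=5)
        with pytest.raises(SingletonBatchError):
            adjust_batch_location_scale(
                _mat(values, scale="M"), np.array([0, 0, 0, 0, 1])
            )


class TestCellDeconvolution:
    @pytest.fixture
    def reference(self):
        rng = np.random.default_rng(3)
        return pd.DataFrame(
            rng.normal(0, 2, (200, 3)),
            index=[f"p{i}" for i in range(200)],
            columns=["neuron", "glia", "other"],
        )

    def test_pure_column_recovered_as_unit_vector(self, reference):
        values = pd.DataFrame({"s1": reference["glia"]}, index=reference.index)
        w, resid = estimate_cell_proportions(_mat(values, scale="M"), reference)
        assert w.loc["s1", "glia"] == pytest.approx(1.0, abs=1e-6)
        assert w.loc["s1"].drop("glia").abs().max() < 1e-6

    def test_noiseless_mixture_recovered_exactly(self, reference):
        mix = 0.6 * reference.iloc[:, 0] + 0.4 * reference.iloc[:, 1]
        values = pd.DataFrame({"s1": mix}, index=reference.index)
        w, resid = estimate_cell_proportions(_mat(values, scale="M"), reference)
        assert w.loc["s1", "neuron"] == pytest.approx(0.6, abs=1e-6)
        assert w.loc["s1", "glia"] == pytest.approx(0.4, abs=1e-6)
        assert resid["s1"] < 1e-8

    def test_noisy_mixture_recovered_within_tolerance(self):
        rng = np.random.default_rng(4)
        ref = pd.DataFrame(
            rng.normal(0, 2, (500, 4)),
            index=[f"p{i}" for i in range(500)],
            columns=list("ABCD"),
        )
        w_true = rng.dirichlet((4, 4, 4, 4), size=10)
        m = ref.to_numpy() @ w_true.T + rng.normal(0, 0.02, (500, 10))
        values = pd.DataFrame(m, index=ref.index, columns=[f"s{j}" for j in range(10)])
        w, _ = estimate_cell_proportions(_mat(values, scale="M"), ref)
        assert np.abs(w.to_numpy() - w_true).max() < 0.05

    def test_too_few_shared_probes_rejected(self, reference):
        values = pd.DataFrame(
            {"s1": reference["glia"].iloc[:2]}, index=reference.index[:2]
        )
        with pytest.raises(ValueError):
            estimate_cell_proportions(_mat(values, scale="M"), reference)


class TestCellAdjustment:
    def test_planted_cell_effect_fully_removed(self):
        rng = np.random.default_rng(5)
        n, p = 60, 20
        props = rng.dirichlet((5, 3, 2), size=n)
        effect = rng.normal(0, 1, (p, 3))
        values = pd.DataFrame(
            rng.normal(0, 0.2, (p, n)) + effect @ props.T,
            index=[f"pr{i}" for i in range(p)],
            columns=[f"s{j}" for j in range(n)],
        )
        prop_df = pd.DataFrame(props, index=values.columns, columns=list("XYZ"))
        out = adjust_cell_composition(_mat(values, scale="M"), prop_df)
        # residual slope on the fitted (free) proportion columns is ~0
        pc = props[:, :2] - props[:, :2].mean(axis=0)
        for g in range(p):
            slope, *_ = np.linalg.lstsq(pc, out.values.iloc[g].to_numpy(), rcond=None)
            assert np.abs(slope).max() < 1e-8
        assert np.allclose(out.values.mean(axis=1), values.mean(axis=1), atol=1e-9)

    def test_constant_proportions_identity_up_to_centering(self):
        values = pd.DataFrame(
            np.random.default_rng(6).normal(0, 1, (5, 10)),
            index=[f"p{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(10)],
        )
        props = pd.DataFrame(
            np.tile([0.5, 0.3, 0.2], (10, 1)), index=values.columns, columns=list("XYZ")
        )
        with pytest.warns(UserWarning):
            out = adjust_cell_composition(_mat(values, scale="M"), props)
        pd.testing.assert_frame_equal(out.values, values)
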