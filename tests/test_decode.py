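"""ICP registration, supervised GMM classification, and cluster QC metrics."""

import numpy as np
import pandas as pd
import pytest

from spectralbeads.decode import (
    TargetCodeTable,
    _transform_cost,
    cluster_quality,
    confidence_ellipse,
    decode,
    gmm_classify,
    icp_align,
    initial_transform,
)


@pytest.fixture(scope="module")
def grid_targets():
    return TargetCodeTable.from_levels(
        {
            "Dy.Eu": [0.0, 0.3, 0.6, 0.9],
            "Sm.Eu": [0.0, 0.3, 0.6, 0.9],
            "Tm.Eu": [0.0, 0.45, 0.9],
        }
    )


def beads_at_targets(targets, per_code=10, noise_frac=0.0, seed=0):
    """Beads drawn around the target points; returns (ratios, true codes)."""
    rng = np.random.default_rng(seed)
    codes = np.repeat(np.arange(targets.n_codes), per_code)
    ratios = targets.ratios[codes]
    if noise_frac > 0:
        sd = noise_frac * targets.level_spacing()
        ratios = ratios + rng.normal(0, 1, ratios.shape) * sd
    return ratios, codes


class TestTargetCodeTable:
    def test_from_levels_is_full_factorial(self, grid_targets):
        assert grid_targets.n_codes == 4 * 4 * 3 == 48
        assert len(np.unique(grid_targets.ratios, axis=0)) == 48

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            TargetCodeTable(ratios=[[0.1, 0.2], [0.1, 0.2]], dimensions=["a", "b"])

    def test_csv_round_trip(self, grid_targets, tmp_path):
        path = grid_targets.to_csv(tmp_path / "targets.csv")
        loaded = TargetCodeTable.read_csv(path)
        np.testing.assert_allclose(loaded.ratios, grid_targets.ratios)
        assert loaded.dimensions == grid_targets.dimensions

    def test_level_spacing(self, grid_targets):
        np.testing.assert_allclose(grid_targets.level_spacing(), [0.3, 0.3, 0.45])


class TestInitialTransform:
    def test_identity_when_already_matched(self, grid_targets):
        ratios, _ = beads_at_targets(grid_targets)
        T0, o0 = initial_transform(ratios, grid_targets)
        np.testing.assert_allclose(T0, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(o0, 0.0, atol=1e-9)

    def test_doubled_ratios_give_half_scale(self, grid_targets):
        ratios, _ = beads_at_targets(grid_targets)
        T0, _ = initial_transform(2.0 * ratios, grid_targets)
        np.testing.assert_allclose(T0, 0.5 * np.eye(3), atol=1e-9)

    def test_sd_ratio_oracle_per_dimension(self, grid_targets):
        rng = np.random.default_rng(3)
        ratios = rng.random((200, 3))
        T0, _ = initial_transform(ratios, grid_targets)
        expected = grid_targets.ratios.std(axis=0) / ratios.std(axis=0)
        np.testing.assert_allclose(np.diag(T0), expected)

    def test_single_bead_errors(self, grid_targets):
        with pytest.raises(ValueError, match="2 beads"):
            initial_transform(np.array([[0.1, 0.2, 0.3]]), grid_targets)

    def test_zero_spread_errors_naming_dimension(self, grid_targets):
        ratios, _ = beads_at_targets(grid_targets)
        ratios[:, 1] = 0.5
        with pytest.raises(ValueError, match="Sm.Eu"):
            initial_transform(ratios, grid_targets)

    def test_reverse_direction_is_reciprocal(self, grid_targets):
        ratios, _ = beads_at_targets(grid_targets, noise_frac=0.05, seed=1)
        Tf, _ = initial_transform(ratios, grid_targets, "data_to_target")
        Tr, _ = initial_transform(ratios, grid_targets, "target_to_data")
        np.testing.assert_allclose(np.diag(Tf) * np.diag(Tr), 1.0)


class TestIcpAlign:
    def test_exact_match_converges_to_identity(self, grid_targets):
        ratios, _ = beads_at_targets(grid_targets)
        result = icp_align(ratios, grid_targets)
        assert result.converged
        assert result.n_iterations <= 3
        np.testing.assert_allclose(result.T, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(result.o, 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_affine_recovery(self, grid_targets, seed):
        """A known diagonal scaling + offset distortion is undone to within
        2% per entry (composition with the truth is the identity)."""
        T_true = np.diag([0.8, 1.2, 0.9])
        o_true = np.array([0.05, 0.0, -0.02])
        ratios, _ = beads_at_targets(grid_targets, per_code=20,
                                     noise_frac=0.01, seed=seed)
        observed = ratios @ T_true + o_true
        result = icp_align(observed, grid_targets)
        assert result.converged
        np.testing.assert_allclose(T_true @ result.T, np.eye(3), atol=0.02)
        # the full affine composition maps targets back onto themselves
        np.testing.assert_allclose(
            (grid_targets.ratios @ T_true + o_true) @ result.T + result.o,
            grid_targets.ratios,
            atol=0.01,
        )

    def test_trim_absorbs_extreme_outlier(self, grid_targets):
        ratios, _ = beads_at_targets(grid_targets, per_code=11,
                                     noise_frac=0.01, seed=5)
        ratios = ratios[:500]
        clean = icp_align(ratios, grid_targets, trim_pct=1.0)
        spoiled_input = ratios.copy()
        spoiled_input[0] = [50.0, -40.0, 30.0]
        spoiled = icp_align(spoiled_input, grid_targets, trim_pct=1.0)
        np.testing.assert_allclose(spoiled.T, clean.T, atol=0.01)
        np.testing.assert_allclose(spoiled.o, clean.o, atol=0.01)

    def test_self_consistency_of_stored_transform(self, grid_targets):
        ratios, _ = beads_at_targets(grid_targets, noise_frac=0.05, seed=2)
        result = icp_align(ratios, grid_targets)
        np.testing.assert_array_equal(
            result.transformed, ratios @ result.T + result.o
        )

    def test_cost_formula_direct_evaluation(self):
        rng = np.random.default_rng(4)
        T_old, T_new = rng.random((2, 3, 3))
        o_old, o_new = rng.random((2, 3))
        got = _transform_cost(T_new, T_old, o_new, o_old)
        num = ((T_new - T_old) ** 2).sum() + ((o_new - o_old) ** 2).sum()
        den = (T_new**2).sum() + (o_new**2).sum()
        assert abs(got - num / den) < 1e-12

    def test_bad_trim_pct_errors(self, grid_targets):
        ratios, _ = beads_at_targets(grid_targets)
        with pytest.raises(ValueError, match="trim_pct"):
            icp_align(ratios, grid_targets, trim_pct=100.0)


class TestGmmClassify:
    def test_exact_points_classified_with_certainty(self, grid_targets):
        ratios, codes = beads_at_targets(grid_targets, per_code=5)
        beads, _ = gmm_classify(ratios, grid_targets)
        np.testing.assert_array_equal(beads["code"], codes)
        assert (beads["prob"] > 1 - 1e-9).all()

    def test_accuracy_at_study_noise(self, grid_targets):
        """48 codes x 40 beads at 10% level-spacing noise: >= 99% accuracy."""
        ratios, codes = beads_at_targets(grid_targets, per_code=40,
                                         noise_frac=0.10, seed=11)
        beads, _ = gmm_classify(ratios, grid_targets)
        accuracy = (beads["code"].to_numpy() == codes).mean()
        assert accuracy >= 0.99

    def test_probabilities_normalized(self, grid_targets):
        ratios, _ = beads_at_targets(grid_targets, per_code=5,
                                     noise_frac=0.15, seed=6)
        _, gmm = gmm_classify(ratios, grid_targets)
        resp = gmm.predict_proba(ratios)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-9)

    def test_invalid_sigma0_errors(self, grid_targets):
        with pytest.raises(ValueError, match="sigma0"):
            gmm_classify(np.zeros((5, 3)), grid_targets, sigma0=0.0)


class TestConfidenceEllipse:
    def test_identity_covariance_axis_length(self):
        out = confidence_ellipse(np.eye(2), level=0.95)
        np.testing.assert_allclose(out["axis_lengths"], 3.92, atol=1e-3)

    def test_diagonal_covariance_eigenstructure(self):
        out = confidence_ellipse(np.diag([4.0, 1.0]))
        ratio = out["axis_lengths"][0] / out["axis_lengths"][1]
        assert abs(ratio - 2.0) < 1e-12  # sqrt(4/1)
        major = out["axes"][:, 0]
        assert abs(abs(major[0]) - 1.0) < 1e-12  # along dimension 0

    def test_rotation_similarity_transform(self):
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        cov = np.diag([4.0, 1.0])
        rotated = confidence_ellipse(R @ cov @ R.T)
        base = confidence_ellipse(cov)
        np.testing.assert_allclose(rotated["axis_lengths"], base["axis_lengths"])
        np.testing.assert_allclose(
            np.abs(rotated["axes"][:, 0]), np.abs(R @ base["axes"][:, 0]),
            atol=1e-9,
        )

    def test_non_symmetric_errors(self):
        with pytest.raises(ValueError, match="symmetric"):
            confidence_ellipse(np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestClusterQuality:
    def test_point_clusters_silhouette_exactly_one(self):
        targets = TargetCodeTable(
            ratios=[[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]],
            dimensions=["a", "b", "c"],
        )
        X = np.repeat(targets.ratios, 10, axis=0)
        labels = np.repeat([0, 1, 2], 10)
        found, missing, sil = cluster_quality(X, labels, targets)
        assert found == 3 and missing == []
        assert sil == 1.0

    def test_missing_code_listed(self, grid_targets):
        ratios, codes = beads_at_targets(grid_targets, per_code=3)
        keep = codes != 17
        found, missing, _ = cluster_quality(ratios[keep], codes[keep], grid_targets)
        assert found == 47
        assert missing == [17]

    def test_random_labels_silhouette_near_zero(self):
        targets = TargetCodeTable(ratios=[[0.0], [1.0]], dimensions=["a"])
        rng = np.random.default_rng(12)
        X = rng.random((2000, 3))
        labels = rng.integers(0, 2, 2000)
        _, _, sil = cluster_quality(X, labels, targets)
        assert abs(sil) < 0.1

    def test_single_cluster_undefined(self, grid_targets):
        ratios, _ = beads_at_targets(grid_targets, per_code=1)
        found, _, sil = cluster_quality(ratios[:5], np.zeros(5, int), grid_targets)
        assert found == 1 and sil is None


class TestDecodeEndToEnd:
    def test_full_decode_recovers_scaled_library(self, grid_targets):
        rng_seed = 21
        ratios, codes = beads_at_targets(grid_targets, per_code=20,
                                         noise_frac=0.08, seed=rng_seed)
        observed = ratios @ np.diag([0.85, 1.1, 0.95]) + [0.03, -0.01, 0.02]
        result = decode(observed, grid_targets, seed=0)
        assert result.clusters_found == 48
        assert result.missing_codes == []
        accuracy = (result.beads["code"].to_numpy() == codes).mean()
        assert accuracy >= 0.99
        assert result.silhouette > 0.5
        np.testing.assert_allclose(result.counts.sum(), len(codes))

    def test_low_probability_postfilter(self, grid_targets):
        ratios, _ = beads_at_targets(grid_targets, per_code=5,
                                     noise_frac=0.2, seed=8)
        result = decode(ratios, grid_targets, min_prob=0.999)
        assert (result.beads["code"] == -1).any()
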