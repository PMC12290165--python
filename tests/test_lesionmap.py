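"""Tests for density maps, voxel selection and the maxT permutation test."""

import math

import numpy as np
import pytest

from nihssnet._validate import ValidationError
from nihssnet.lesionmap import (
    LesionVolumeSet,
    density_map,
    lesion_volume_comparison,
    one_vs_rest_analysis,
    permutation_maxt,
    proportion_statistic,
    select_voxels,
    voxel_count_threshold,
)


def volumes_from_flat(flat, grid=(4, 4, 4), affine=None):
    flat = np.asarray(flat, dtype=np.uint8)
    masks = flat.reshape(flat.shape[0], *grid)
    if affine is None:
        affine = np.eye(4)
    return LesionVolumeSet(masks=masks, affine=affine)


def make_sphere_cohort(n=20, grid=(8, 8, 8), seed=0):
    rng = np.random.default_rng(seed)
    masks = np.zeros((n, *grid), dtype=np.uint8)
    center = np.array(grid) / 2
    idx = np.indices(grid)
    for a in range(n):
        c = center + rng.normal(0, 1, 3)
        r = rng.uniform(1.5, 3.0)
        masks[a] = (sum((idx[d] - c[d]) ** 2 for d in range(3)) <= r * r).astype(
            np.uint8
        )
    return LesionVolumeSet(masks=masks)


class TestDensityMap:
    def test_singleton_cluster_equals_mask(self):
        vols = make_sphere_cohort(4)
        labels = np.array([0, 1, 1, 1])
        dm = density_map(vols, labels, 0)
        assert np.array_equal(dm, vols.masks[0].astype(float))

    def test_shared_and_private_voxels(self):
        flat = np.zeros((2, 64))
        flat[0, [0, 1]] = 1
        flat[1, [1, 2]] = 1
        vols = volumes_from_flat(flat)
        dm = density_map(vols, np.array([0, 0]), 0).reshape(-1)
        assert dm[1] == 1.0 and dm[0] == 0.5 and dm[2] == 0.5

    def test_range_and_empty_cluster(self):
        vols = make_sphere_cohort(6)
        labels = np.array([0, 0, 1, 1, 1, 1])
        dm = density_map(vols, labels, 1)
        assert dm.min() >= 0.0 and dm.max() <= 1.0
        with pytest.raises(ValidationError):
            density_map(vols, labels, 3)


class TestSelectVoxels:
    def test_printed_threshold_from_five_percent_of_172(self):
        assert voxel_count_threshold(172, 0.05) == 8

    def test_threshold_applied_to_counts(self):
        flat = np.zeros((40, 64))
        flat[:, 0] = 1  # lesioned in everyone
        flat[:1, 1] = 1  # lesioned once: below floor(0.05*40)=2
        flat[:2, 2] = 1  # exactly at threshold
        vols = volumes_from_flat(flat)
        selected = select_voxels(vols, 0.05)
        assert set(selected) == {0, 2}

    def test_zero_threshold_promoted_to_one(self):
        flat = np.zeros((10, 64))
        flat[0, 5] = 1
        vols = volumes_from_flat(flat)
        selected = select_voxels(vols, 0.01)  # floor(0.1) = 0 -> 1
        assert set(selected) == {5}

    def test_empty_selection_warns(self):
        vols = volumes_from_flat(np.zeros((30, 64)))
        with pytest.warns(UserWarning, match="empty"):
            assert select_voxels(vols, 0.5).size == 0


class TestProportionStatistic:
    def test_equal_proportions_zero(self):
        assert proportion_statistic(5, 20, 25, 100) == pytest.approx(0.0)

    def test_hand_arithmetic_oracle(self):
        # n=100, n_i=20, v+=30, v_i+=12, written out digit by digit
        num = abs(12 / 20 - (30 - 12) / (100 - 20))
        den = math.sqrt((30 / 100) * (70 / 100) * (1 / 20 + 1 / 80))
        assert proportion_statistic(12, 20, 30, 100) == pytest.approx(num / den)
        assert proportion_statistic(12, 20, 30, 100) == pytest.approx(3.27326835, abs=1e-7)

    def test_cluster_rest_swap_symmetry(self):
        # swapping the roles of cluster and rest leaves |t| unchanged
        t1 = proportion_statistic(12, 20, 30, 100)
        t2 = proportion_statistic(30 - 12, 100 - 20, 30, 100)
        assert t1 == pytest.approx(t2)

    def test_degenerate_pooled_proportion(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert proportion_statistic(0, 20, 0, 100) == 0.0
        with pytest.warns(UserWarning, match="degenerate"):
            assert proportion_statistic(20, 20, 100, 100) == 0.0

    def test_preconditions(self):
        with pytest.raises(ValidationError):
            proportion_statistic(1, 0, 1, 10)
        with pytest.raises(ValidationError):
            proportion_statistic(30, 20, 30, 100)


class TestPermutationMaxT:
    def test_stepdown_monotonicity_and_dominance(self):
        vols = make_sphere_cohort(24, seed=3)
        labels = np.zeros(24, dtype=int)
        labels[:8] = 1
        selected = select_voxels(vols, 0.05)
        B = 300
        res = permutation_maxt(vols, labels, 1, selected, B=B, family_alpha=0.05, seed=9)
        order = np.lexsort((selected, -res.t_obs))
        assert np.all(np.diff(res.p_adjusted[order]) >= -1e-15)
        # maxT dominance: adjusted p >= raw per-voxel permutation p
        M = vols.flat()[:, selected].astype(float)
        rng = np.random.default_rng(9)
        perm = np.argsort(rng.random((B, 24)), axis=1)[:, :8]
        ind = np.zeros((B, 24))
        np.put_along_axis(ind, perm, 1.0, axis=1)
        totals = M.sum(axis=0)
        n_i, n = 8, 24
        pooled = totals / n
        den = np.sqrt(pooled * (1 - pooled) * (1 / n_i + 1 / (n - n_i)))
        t_perm = np.abs((ind @ M) / n_i - (totals - ind @ M) / (n - n_i)) / den
        p_raw = (1 + (t_perm >= res.t_obs[None, :] - 1e-12).sum(axis=0)) / (B + 1)
        assert np.all(res.p_adjusted >= p_raw - 1e-12)

    def test_perfectly_separating_voxel_attains_minimal_p(self):
        n, n_i = 20, 6
        flat = np.zeros((n, 64))
        flat[:n_i, 0] = 1  # voxel 0 lesioned in all of cluster 0, never elsewhere
        flat[:, 1] = np.arange(n) % 2  # label-free voxel to pad selection
        vols = volumes_from_flat(flat)
        labels = (np.arange(n) >= n_i).astype(int)
        B = 400
        res = permutation_maxt(
            vols, labels, 0, np.array([0, 1]), B=B, family_alpha=0.01, seed=4
        )
        assert res.p_adjusted[0] == pytest.approx(1.0 / (B + 1))
        assert bool(res.significant[0])

    def test_pure_function_of_seed(self):
        vols = make_sphere_cohort(16, seed=5)
        labels = (np.arange(16) < 5).astype(int)
        sel = select_voxels(vols, 0.05)
        r1 = permutation_maxt(vols, labels, 1, sel, B=100, family_alpha=0.05, seed=21)
        r2 = permutation_maxt(vols, labels, 1, sel, B=100, family_alpha=0.05, seed=21)
        assert np.array_equal(r1.p_adjusted, r2.p_adjusted)

    def test_degenerate_clusters_rejected(self):
        vols = make_sphere_cohort(10)
        with pytest.raises(ValidationError):
            permutation_maxt(vols, np.zeros(10, dtype=int), 0, np.array([0]), B=10)
        with pytest.raises(ValidationError):
            permutation_maxt(vols, np.zeros(10, dtype=int), 1, np.array([0]), B=10)


class TestOneVsRest:
    def test_family_alpha_is_bonferroni_share(self):
        vols = make_sphere_cohort(25, seed=8)
        labels = np.arange(25) % 5
        results = one_vs_rest_analysis(vols, labels, overall_alpha=0.05, B=50, seed=0)
        assert len(results) == 5
        for res in results:
            assert res.family_alpha == pytest.approx(0.01)

    def test_two_cluster_mirror_symmetry(self):
        vols = make_sphere_cohort(18, seed=2)
        labels = (np.arange(18) < 7).astype(int)
        r0, r1 = one_vs_rest_analysis(vols, labels, overall_alpha=0.05, B=80, seed=3)
        assert np.allclose(r0.t_obs, r1.t_obs)

    def test_selection_is_label_free(self):
        vols = make_sphere_cohort(30, seed=11)
        labels_a = (np.arange(30) < 10).astype(int)
        labels_b = (np.arange(30) % 3 == 0).astype(int)
        sel = select_voxels(vols, 0.05)
        res_a = one_vs_rest_analysis(vols, labels_a, B=20, seed=1)
        res_b = one_vs_rest_analysis(vols, labels_b, B=20, seed=1)
        for res in (*res_a, *res_b):
            assert np.array_equal(res.selected_voxels, sel)


class TestLesionVolumes:
    def test_voxel_volume_unit_conversion(self):
        flat = np.zeros((2, 64))
        flat[0, :10] = 1
        vols = volumes_from_flat(flat, affine=np.eye(4))  # 1 mm^3 voxels
        assert vols.volumes_ml()[0] == pytest.approx(0.01)

    def test_kruskal_matches_rank_formula(self):
        # volumes {1,2,3} vs {10,11,12} voxels; no ties
        flat = np.zeros((6, 64))
        for i, v in enumerate([1, 2, 3, 10, 11, 12]):
            flat[i, :v] = 1
        vols = volumes_from_flat(flat)
        labels = np.array([0, 0, 0, 1, 1, 1])
        H, p = lesion_volume_comparison(vols, labels, 0)
        # hand rank formula: H = 12/(N(N+1)) * sum R_g^2/n_g - 3(N+1)
        expected = 12.0 / (6 * 7) * ((1 + 2 + 3) ** 2 / 3 + (4 + 5 + 6) ** 2 / 3) - 3 * 7
        assert H == pytest.approx(expected)
        assert 0 < p < 0.1

    def test_identical_distributions_h_near_zero(self):
        flat = np.zeros((8, 64))
        for i in range(8):
            flat[i, : 5 + (i % 2)] = 1  # volumes alternate 5, 6 in both groups
        vols = volumes_from_flat(flat)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        H, _ = lesion_volume_comparison(vols, labels, 0)
        assert H == pytest.approx(0.0, abs=1e-9)

    def test_all_tied_warns(self):
        flat = np.zeros((4, 64))
        flat[:, :3] = 1
        vols = volumes_from_flat(flat)
        with pytest.warns(UserWarning, match="tied"):
            H, p = lesion_volume_comparison(vols, np.array([0, 0, 1, 1]), 0)
        assert H == 0.0


class TestLesionVolumeSetIO:
    def test_manifest_roundtrip_and_binarization_warning(self, tmp_path):
        import nibabel as nib
        import pandas as pd

        grid = (4, 4, 4)
        rng = np.random.default_rng(0)
        rows = []
        for sid in ("a", "b"):
            data = (rng.random(grid) > 0.5).astype(np.float32)
            if sid == "b":
                data *= 0.7  # non-binary values
            nib.Nifti1Image(data, np.eye(4)).to_filename(str(tmp_path / f"{sid}.nii"))
            rows.append({"subject_id": sid, "path": f"{sid}.nii"})
        pd.DataFrame(rows).to_csv(tmp_path / "manifest.csv", index=False)
        with pytest.warns(UserWarning, match="binariz"):
            vols = LesionVolumeSet.from_manifest(tmp_path / "manifest.csv")
        assert vols.n == 2 and vols.grid_shape == grid
        assert set(np.unique(vols.masks)) <= {0, 1}

    def test_missing_file_names_subject(self, tmp_path):
        import pandas as pd

        pd.DataFrame([{"subject_id": "ghost", "path": "nope.nii"}]).to_csv(
            tmp_path / "manifest.csv", index=False
        )
        with pytest.raises(ValidationError, match="ghost"):
            LesionVolumeSet.from_manifest(tmp_path / "manifest.csv")
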