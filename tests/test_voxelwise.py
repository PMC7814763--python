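"""Unit tests of the GLM / TFCE / permutation engine against oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from d50tracts.voxelwise import (
    DesignMatrix,
    PermutationTFCE,
    SkeletonDataset,
    StatMap,
    TFCEParams,
    build_design,
    glm_tstat,
    permutation_maxtfce,
    tbss_tfce_params,
    tfce_enhance,
    threshold_report,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def _neighbours(idx, shape, connectivity):
    """Neighbour offsets for 6/18/26-connectivity flood fill."""
    out = []
    for off in itertools.product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        order = sum(abs(o) for o in off)
        if (connectivity == 6 and order > 1) or (connectivity == 18 and order > 2):
            continue
        nb = tuple(i + o for i, o in zip(idx, off))
        if all(0 <= n < s for n, s in zip(nb, shape)):
            out.append(nb)
    return out


def brute_force_tfce(vol, E, H, dh, connectivity=26):
    """Per-threshold explicit flood-fill component labelling (slow, exact)."""
    vol = np.asarray(vol, dtype=float)
    pos = np.where(vol > 0, vol, 0.0)
    out = np.zeros_like(pos)
    vmax = pos.max()
    k = 1
    while k * dh <= vmax + 1e-9:
        h = k * dh
        sup = pos >= h
        seen = np.zeros_like(sup)
        for start in zip(*np.nonzero(sup)):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                cur = stack.pop()
                comp.append(cur)
                for nb in _neighbours(cur, vol.shape, connectivity):
                    if sup[nb] and not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
            contrib = len(comp) ** E * h**H * dh
            for v in comp:
                out[v] += contrib
        k += 1
    return out


def two_sample_t(a, b):
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


class TestBuildDesign:
    def _table(self, n=10):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "patient_id": [f"s{i}" for i in range(n)],
                "grp": ["case"] * (n // 2) + ["control"] * (n - n // 2),
                "age": rng.normal(60, 8, n),
                "sex": rng.choice(["male", "female"], n),
            }
        )

    def test_case_control_layout(self):
        tab = self._table()
        des = build_design(tab, group="grp", covariates=("age", "sex"))
        assert des.matrix.shape == (10, 4)
        c = next(iter(des.contrasts.values()))
        assert list(c) == [1.0, -1.0, 0.0, 0.0]
        assert des.matrix[:, 2].mean() == pytest.approx(0.0, abs=1e-12)  # demeaned age

    def test_extra_nuisance_columns(self):
        tab = self._table()
        tab["cfs"] = np.linspace(20, 45, 10)
        tab["onset_type"] = ["limb", "bulbar"] * 5
        des = build_design(tab, group="grp", covariates=("age", "sex", "cfs", "onset_type"))
        assert "cfs" in des.columns
        assert any(col.startswith("onset_type[") for col in des.columns)

    def test_duplicate_subjects_rejected(self):
        tab = self._table()
        tab.loc[1, "patient_id"] = tab.loc[0, "patient_id"]
        with pytest.raises(ValueError, match="duplicate"):
            build_design(tab, group="grp", covariates=("age",))

    def test_missing_values_named(self):
        tab = self._table()
        tab.loc[3, "age"] = np.nan
        with pytest.raises(ValueError, match="age.*s3"):
            build_design(tab, group="grp", covariates=("age",))

    def test_rank_deficiency_rejected(self):
        tab = self._table()
        tab["dup"] = tab["age"]
        with pytest.raises(ValueError, match="rank"):
            build_design(tab, group="grp", covariates=("age", "dup"))


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------


class TestGlm:
    def test_matches_closed_form_two_sample_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(1, 1, 8), rng.normal(0, 1, 7)
        tab = pd.DataFrame(
            {"patient_id": [f"s{i}" for i in range(15)], "grp": ["a"] * 8 + ["b"] * 7}
        )
        des = build_design(tab, group="grp")
        data = SkeletonDataset(
            mask=np.ones((1, 1, 1), bool), values=np.r_[a, b].reshape(-1, 1)
        )
        stat = glm_tstat(data, des, next(iter(des.contrasts.values())))
        assert stat.values[0] == pytest.approx(two_sample_t(a, b), abs=1e-10)
        assert stat.df == 13

    def test_orthogonal_noise_regressor_leaves_t_unchanged(self):
        rng = np.random.default_rng(2)
        n = 24
        x = rng.normal(0, 1, n)
        noise_reg = rng.normal(0, 1, n)
        # orthogonalise the extra regressor against interest + intercept
        basis = np.column_stack([np.ones(n), x])
        noise_reg -= basis @ np.linalg.lstsq(basis, noise_reg, rcond=None)[0]
        # data orthogonal to the noise regressor: residualise Y against it
        Y = rng.normal(0, 1, (n, 5)) + np.outer(x, np.ones(5))
        Y -= np.outer(noise_reg, noise_reg @ Y) / (noise_reg @ noise_reg)

        X1 = np.column_stack([np.ones(n), x])
        X2 = np.column_stack([np.ones(n), x, noise_reg])
        d1 = DesignMatrix(matrix=X1, columns=["i", "x"], contrasts={"c": np.array([0.0, 1.0])})
        d2 = DesignMatrix(
            matrix=X2, columns=["i", "x", "nz"], contrasts={"c": np.array([0.0, 1.0, 0.0])}
        )
        mask = np.ones((1, 5, 1), bool)
        t1 = glm_tstat(SkeletonDataset(mask=mask, values=Y), d1, "c").values
        t2 = glm_tstat(SkeletonDataset(mask=mask, values=Y), d2, "c").values
        # same numerator and residuals; only df differs
        assert np.allclose(t1 / np.sqrt(n - 2), t2 / np.sqrt(n - 3), atol=1e-10)

    def test_zero_contrast_gives_zero_map(self):
        rng = np.random.default_rng(3)
        tab = pd.DataFrame(
            {"patient_id": [f"s{i}" for i in range(10)], "grp": ["a"] * 5 + ["b"] * 5}
        )
        des = build_design(tab, group="grp")
        data = SkeletonDataset(mask=np.ones((1, 4, 1), bool), values=rng.normal(0, 1, (10, 4)))
        assert np.all(glm_tstat(data, des, np.zeros(2)).values == 0)

    def test_degenerate_voxel_set_to_zero(self):
        tab = pd.DataFrame(
            {"patient_id": [f"s{i}" for i in range(8)], "grp": ["a"] * 4 + ["b"] * 4}
        )
        des = build_design(tab, group="grp")
        vals = np.zeros((8, 2))
        vals[:, 0] = des.matrix[:, 0]  # exactly explained: zero residual variance
        vals[:, 1] = np.arange(8) % 3
        stat = glm_tstat(SkeletonDataset(mask=np.ones((1, 2, 1), bool), values=vals), des,
                         next(iter(des.contrasts.values())))
        assert stat.values[0] == 0.0
        assert np.isfinite(stat.values).all()


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------


class TestTfce:
    def test_all_zero_map(self):
        assert np.all(tfce_enhance(np.zeros((4, 4, 3))) == 0)

    def test_single_voxel_direct_summation(self):
        vol = np.zeros((5, 5, 3))
        vol[2, 2, 1] = 2.0
        out = tfce_enhance(vol, TFCEParams(E=0.5, H=2.0, dh=0.1))
        expected = sum(1**0.5 * (0.1 * k) ** 2 * 0.1 for k in range(1, 21))
        assert out[2, 2, 1] == pytest.approx(expected, abs=1e-12)
        assert np.count_nonzero(out) == 1

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_agrees_with_brute_force_on_random_maps(self, connectivity):
        rng = np.random.default_rng(7)
        for _ in range(5):
            vol = rng.normal(0, 1, (8, 8, 3))
            params = TFCEParams(E=0.5, H=2.0, dh=0.15, connectivity=connectivity)
            fast = tfce_enhance(vol, params)
            slow = brute_force_tfce(vol, 0.5, 2.0, 0.15, connectivity)
            assert np.allclose(fast, slow, atol=1e-9)

    def test_masked_input_roundtrip(self):
        rng = np.random.default_rng(8)
        mask = rng.random((6, 6, 4)) > 0.4
        vals = rng.normal(0, 1, int(mask.sum()))
        params = TFCEParams(dh=0.2)
        masked = tfce_enhance(vals, params, mask)
        vol = np.zeros(mask.shape)
        vol[mask] = vals
        assert np.allclose(masked, tfce_enhance(vol, params)[mask])

    def test_monotone_in_voxel_height(self):
        rng = np.random.default_rng(9)
        vol = np.abs(rng.normal(0, 1, (6, 6, 3)))
        params = TFCEParams(dh=0.1)
        base = tfce_enhance(vol, params)
        bumped = vol.copy()
        bumped[3, 3, 1] += 0.7
        assert np.all(tfce_enhance(bumped, params) >= base - 1e-12)

    def test_disjoint_clusters_independent(self):
        params = TFCEParams(dh=0.1)
        a = np.zeros((10, 4, 3))
        a[1:3, 1:3, 1] = 1.5
        b = np.zeros((10, 4, 3))
        b[7:9, 1:3, 1] = 2.5
        joint = tfce_enhance(a + b, params)
        assert np.allclose(joint, tfce_enhance(a, params) + tfce_enhance(b, params))

    def test_negative_values_contribute_nothing(self):
        vol = np.zeros((4, 4, 3))
        vol[1, 1, 1] = -3.0
        assert np.all(tfce_enhance(vol, TFCEParams(dh=0.1)) == 0)

    def test_tbss_preset(self):
        p = tbss_tfce_params()
        assert (p.E, p.H, p.connectivity) == (1.0, 2.0, 26)

    def test_nonfinite_rejected(self):
        vol = np.zeros((4, 4, 3))
        vol[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            tfce_enhance(vol)


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------


def _toy_two_group(seed=0, n_vox=6, shift=2.0):
    rng = np.random.default_rng(seed)
    Y = rng.normal(0, 1, (6, n_vox))
    Y[:3, : n_vox // 2] += shift
    tab = pd.DataFrame({"patient_id": [f"s{i}" for i in range(6)],
                        "grp": ["a"] * 3 + ["b"] * 3})
    des = build_design(tab, group="grp")
    data = SkeletonDataset(mask=np.ones((1, n_vox, 1), bool), values=Y)
    return data, des


class TestPermutation:
    def test_exhaustive_matches_all_relabelings_oracle(self):
        data, des = _toy_two_group(seed=4)
        c = next(iter(des.contrasts.values()))
        params = TFCEParams(dh=0.1)
        res = permutation_maxtfce(data, des, c, params=params, n_perm=1000, seed=0)
        assert res.exhaustive and res.n_perm == 19

        Y = data.values
        maxima = []
        for idx_a in itertools.combinations(range(6), 3):
            idx_b = [i for i in range(6) if i not in idx_a]
            t_map = np.array(
                [two_sample_t(Y[list(idx_a), v], Y[idx_b, v]) for v in range(Y.shape[1])]
            )
            tf = brute_force_tfce(t_map.reshape(1, -1, 1), 0.5, 2.0, 0.1)
            maxima.append(tf.max())
        maxima = np.array(maxima)
        obs_tf = brute_force_tfce(
            np.array([two_sample_t(Y[:3, v], Y[3:, v]) for v in range(Y.shape[1])]
                     ).reshape(1, -1, 1), 0.5, 2.0, 0.1,
        ).ravel()
        p_oracle = np.array([(maxima >= o).sum() / 20 for o in obs_tf])
        assert np.allclose(res.p_fwe, p_oracle, atol=1e-12)

    def test_determinism_same_seed(self):
        rng = np.random.default_rng(10)
        Y = rng.normal(0, 1, (14, 30))
        tab = pd.DataFrame({"patient_id": [f"s{i}" for i in range(14)],
                            "grp": ["a"] * 7 + ["b"] * 7,
                            "age": rng.normal(60, 5, 14)})
        des = build_design(tab, group="grp", covariates=("age",))
        data = SkeletonDataset(mask=np.ones((5, 6, 1), bool), values=Y)
        c = next(iter(des.contrasts.values()))
        r1 = permutation_maxtfce(data, des, c, n_perm=50, seed=42)
        r2 = permutation_maxtfce(data, des, c, n_perm=50, seed=42)
        assert np.array_equal(r1.p_fwe, r2.p_fwe)
        assert np.array_equal(r1.null_max, r2.null_max)

    def test_p_floor_and_monotonicity(self):
        data, des = _toy_two_group(seed=5, shift=5.0)
        c = next(iter(des.contrasts.values()))
        res = permutation_maxtfce(data, des, c, n_perm=1000, seed=1)
        assert res.p_fwe.min() >= 1.0 / (res.n_perm + 1) - 1e-12
        order = np.argsort(res.observed_tfce)
        assert np.all(np.diff(res.p_fwe[order]) <= 1e-12)

    def test_estimator_wrapper(self):
        data, des = _toy_two_group(seed=6)
        est = PermutationTFCE(design=des,
                              contrast=next(iter(des.contrasts.values())),
                              params=TFCEParams(dh=0.1), n_perm=100, seed=3)
        est.fit(data.values)
        assert est.p_fwe_.shape == (data.n_voxels,)
        assert est.null_max_.shape[0] == est.result_.n_perm


class TestThresholdReport:
    def test_empty_findings(self):
        data, des = _toy_two_group(seed=7, shift=0.0)
        c = next(iter(des.contrasts.values()))
        res = permutation_maxtfce(data, des, c, n_perm=100, seed=2)
        rep = threshold_report(res, alpha=0.01)
        assert rep["n_significant"] == 0 and rep["components"] == []

    def test_histogram_conserves_counts(self):
        data, des = _toy_two_group(seed=8, shift=4.0)
        c = next(iter(des.contrasts.values()))
        res = permutation_maxtfce(data, des, c, n_perm=200, seed=2)
        rep = threshold_report(res, alpha=0.05)
        assert rep["histogram"]["n_voxels"].sum() == rep["n_significant"]

    def test_planted_blob_single_component(self):
        rng = np.random.default_rng(11)
        mask = np.ones((6, 6, 3), bool)
        n_vox = mask.sum()
        Y = rng.normal(0, 0.5, (16, n_vox))
        blob = np.zeros(mask.shape, bool)
        blob[2:4, 2:4, 1] = True
        Y[:8, blob[mask]] += 4.0
        tab = pd.DataFrame({"patient_id": [f"s{i}" for i in range(16)],
                            "grp": ["a"] * 8 + ["b"] * 8})
        des = build_design(tab, group="grp")
        res = permutation_maxtfce(
            SkeletonDataset(mask=mask, values=Y), des,
            next(iter(des.contrasts.values())), n_perm=499, seed=5,
        )
        rep = threshold_report(res, alpha=0.05, mask=mask)
        assert len(rep["components"]) == 1
        sig_vol = np.zeros(mask.shape, bool)
        sig_vol[mask] = rep["significant"]
        assert np.array_equal(sig_vol, blob)

    def test_alpha_validated(self):
        data, des = _toy_two_group(seed=9)
        res = permutation_maxtfce(data, des, next(iter(des.contrasts.values())),
                                  n_perm=30, seed=1)
        with pytest.raises(ValueError):
            threshold_report(res, alpha=1.5)
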