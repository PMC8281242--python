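"""Task PLS: assembly, SVD, permutation, bootstrap, contrasts, maps."""

import numpy as np
import pandas as pd
import pytest

from tmteeg import task_pls as P
from tmteeg.synth.features import FeatureEffect, simulate_feature_cohort


@pytest.fixture
def cohort(rng):
    return simulate_feature_cohort(rng, n_participants=16)


@pytest.fixture
def effect_cohort(rng):
    effect = FeatureEffect(
        ("LinkA", "LinkB"), ("Fp1", "Fp2", "F3", "F4"), ("delta", "theta"), -3.0
    )
    return simulate_feature_cohort(rng, n_participants=16, effects=(effect,))


class TestAssembly:
    def test_omnibus_dimensions(self, cohort):
        design = P.assemble_matrices(cohort)
        assert design.X.shape == (64, 150)  # 16 x 4 rows, 30 x 5 columns
        assert design.Y.shape == (64, 4)
        np.testing.assert_allclose(design.Y.sum(axis=1), 1.0)

    def test_two_condition_design_has_32_rows(self, cohort):
        design = P.assemble_matrices(cohort, ("LinkA", "NonlinkA"))
        assert design.X.shape == (32, 150)

    def test_columns_are_electrode_major(self, cohort):
        design = P.assemble_matrices(cohort)
        electrodes = [e for e, _ in design.feature_index]
        assert electrodes[0] == electrodes[4]  # 5 bands per electrode block
        assert electrodes[0] != electrodes[5]

    def test_columns_are_mean_centered(self, cohort):
        design = P.assemble_matrices(cohort)
        np.testing.assert_allclose(design.X.mean(axis=0), 0.0, atol=1e-12)

    def test_missing_cell_is_assembly_error(self, cohort):
        broken = cohort.iloc[:-1]
        with pytest.raises(P.AssemblyError):
            P.assemble_matrices(broken)


class TestSVD:
    def test_identical_condition_means_give_null_singular_values(self):
        rows = []
        base = np.arange(10, dtype=float)
        for p in range(4):
            for cond in P.PLS_CONDITIONS:
                for f, v in enumerate(base):
                    rows.append((p, cond, f"e{f}", "delta", v + p))
        df = pd.DataFrame(rows, columns=["participant", "condition", "electrode", "band", "db"])
        result = P.pls_svd(P.assemble_matrices(df))
        assert np.all(result.singular_values < 1e-10)

    def test_variance_explained_sums_to_one(self, cohort):
        result = P.pls_svd(P.assemble_matrices(cohort))
        assert result.variance_explained.sum() == pytest.approx(1.0)

    def test_matches_dense_brute_force_on_toy_design(self, rng):
        X = rng.normal(size=(8, 6))
        X -= X.mean(axis=0)
        Y = np.kron(np.eye(4), np.ones((2, 1)))
        design = P.PLSDesign(X, Y, ("a", "b", "c", "d"), [0, 1], [("e", str(i)) for i in range(6)])
        result = P.pls_svd(design)
        E = np.zeros((6, 4))
        for i in range(6):
            for j in range(4):
                E[i, j] = sum(X[r, i] * Y[r, j] for r in range(8))
        s_expected = np.linalg.svd(E, compute_uv=False)
        np.testing.assert_allclose(result.singular_values, s_expected, atol=1e-10)

    def test_rank_one_construction_recovered(self):
        u = np.zeros(6)
        u[2] = 1.0
        v = np.array([1.0, -1.0]) / np.sqrt(2)
        rows = []
        for p in range(6):
            for ci, cond in enumerate(("LinkA", "NonlinkA")):
                for f in range(6):
                    rows.append((p, cond, f"e{f}", "delta", 5.0 * u[f] * v[ci]))
        df = pd.DataFrame(rows, columns=["participant", "condition", "electrode", "band", "db"])
        result = P.pls_svd(P.assemble_matrices(df, ("LinkA", "NonlinkA")))
        got_u = result.spatial_saliences[:, 0]
        sign = np.sign(got_u[2])
        np.testing.assert_allclose(sign * got_u, u, atol=1e-10)
        np.testing.assert_allclose(sign * result.task_saliences[:, 0], v, atol=1e-10)


class TestPermutation:
    def test_p_floor(self, effect_cohort):
        design = P.assemble_matrices(effect_cohort)
        p = P.permutation_test(design, n_perm=99, rng=np.random.default_rng(0))
        assert np.all(p >= 1.0 / 100.0)

    def test_strong_effect_significant(self, effect_cohort):
        design = P.assemble_matrices(effect_cohort)
        p = P.permutation_test(design, n_perm=400, rng=np.random.default_rng(0))
        assert p[0] <= 0.005

    def test_feature_permutation_equivariance(self, cohort, rng):
        design = P.assemble_matrices(cohort)
        perm = rng.permutation(design.X.shape[1])
        permuted = P.PLSDesign(
            design.X[:, perm], design.Y, design.conditions, design.participants,
            [design.feature_index[i] for i in perm],
        )
        r1 = P.pls_svd(design)
        r2 = P.pls_svd(permuted)
        np.testing.assert_allclose(r1.singular_values, r2.singular_values, atol=1e-10)
        np.testing.assert_allclose(
            np.abs(r2.spatial_saliences[:, 0]),
            np.abs(r1.spatial_saliences[perm, 0]),
            atol=1e-10,
        )

    def test_exhaustive_fallback_for_tiny_design(self):
        rows = []
        rng = np.random.default_rng(1)
        for p in range(3):  # (2!)^3 = 8 distinct permutations < n_perm
            for cond in ("LinkA", "NonlinkA"):
                for f in range(4):
                    rows.append((p, cond, f"e{f}", "delta", rng.normal()))
        df = pd.DataFrame(rows, columns=["participant", "condition", "electrode", "band", "db"])
        design = P.assemble_matrices(df, ("LinkA", "NonlinkA"))
        p = P.permutation_test(design, n_perm=1000, rng=np.random.default_rng(0))
        assert np.all(p >= 1.0 / 8.0)


class TestBootstrap:
    def test_global_sign_flip_preserves_abs_bsr(self, effect_cohort):
        design = P.assemble_matrices(effect_cohort)
        flipped = P.PLSDesign(
            -design.X, design.Y, design.conditions, design.participants, design.feature_index
        )
        b1 = P.bootstrap_bsr(design, n_boot=150, rng=np.random.default_rng(3))
        b2 = P.bootstrap_bsr(flipped, n_boot=150, rng=np.random.default_rng(3))
        np.testing.assert_allclose(
            np.abs(b1["spatial_bsr"][:, 0]), np.abs(b2["spatial_bsr"][:, 0]), rtol=1e-9
        )

    def test_injected_electrodes_have_large_bsr(self, effect_cohort):
        design = P.assemble_matrices(effect_cohort)
        boot = P.bootstrap_bsr(design, n_boot=300, rng=np.random.default_rng(4))
        idx = [
            i
            for i, (e, b) in enumerate(design.feature_index)
            if e in ("Fp1", "Fp2", "F3", "F4") and b in ("delta", "theta")
        ]
        assert np.all(np.abs(boot["spatial_bsr"][idx, 0]) > 2.0)


class TestContrasts:
    def test_identical_conditions_give_null_contrast(self, rng):
        samples = np.tile(rng.normal(size=(200, 1, 2)), (1, 3, 1))
        out = P.contrast_saliences(samples, ("a", "b", "c"))
        np.testing.assert_allclose(out["mean"], 0.0, atol=1e-12)

    def test_antisymmetry(self, rng):
        samples = rng.normal(size=(300, 4, 2))
        out = P.contrast_saliences(samples, ("a", "b", "c", "d"))
        ab = out[(out["cond_a"] == "a") & (out["cond_b"] == "b")].iloc[0]
        manual = samples[:, 1, 0] - samples[:, 0, 0]  # contrast(b, a)
        assert manual.mean() == pytest.approx(-ab["mean"])

    def test_link_contrasts_dominate_when_ordering_injected(self, rng):
        """With condition means ordered NonlinkA < NonlinkB < LinkA < LinkB,
        the Link-vs-Nonlink contrasts exceed the within-period part contrasts."""
        shifts = {"NonlinkA": -1.5, "NonlinkB": -0.9, "LinkA": 0.9, "LinkB": 1.5}
        effects = tuple(
            FeatureEffect((c,), ("Fp1", "Fp2", "F3", "F4", "Fz", "Cz"), ("delta", "theta", "alpha"), d)
            for c, d in shifts.items()
        )
        feats = simulate_feature_cohort(rng, n_participants=16, effects=effects)
        result = P.run_task_pls(feats, n_perm=50, n_boot=200, seed=0)
        c = result.contrasts.set_index(["cond_a", "cond_b"])["mean"].abs()
        link_vs_nonlink = min(c[("LinkA", "NonlinkA")], c[("LinkB", "NonlinkB")])
        part_contrast = max(c[("LinkA", "LinkB")], c[("NonlinkA", "NonlinkB")])
        assert link_vs_nonlink > part_contrast


class TestThresholdMap:
    def _result_with_bsr(self, bsr_values):
        n = len(bsr_values)
        feature_index = [(f"e{i}", "delta") for i in range(n)]
        r = P.PLSResult(
            conditions=("a", "b"),
            feature_index=feature_index,
            singular_values=np.ones(2),
            variance_explained=None,
            task_saliences=np.eye(2),
            spatial_saliences=np.zeros((n, 2)),
        )
        r.spatial_bsr = np.column_stack([np.asarray(bsr_values, float), np.zeros(n)])
        return r

    def test_stable_but_small_bsr_zeroed(self):
        # BSR 1.9 may clear FDR amid many large BSRs but fails |BSR| > 2
        values = [8.0] * 10 + [1.9] + [0.1] * 9
        result = self._result_with_bsr(values)
        out = P.threshold_map(result)
        assert out.loc["delta", "e10"] == 0.0
        assert out.loc["delta", "e0"] == 8.0

    def test_every_nonzero_entry_satisfies_both_criteria(self, effect_cohort):
        result = P.run_task_pls(effect_cohort, n_perm=50, n_boot=200, seed=1)
        amap = result.maps[0]
        nz = amap.to_numpy()[amap.to_numpy() != 0]
        assert np.all(np.abs(nz) > 2.0)


class TestSubtests:
    def test_combined_features_are_elementwise_sums(self, cohort):
        combined = P.combine_link_nonlink(cohort)
        one = combined[
            (combined["participant"] == 0)
            & (combined["condition"] == "Link")
            & (combined["electrode"] == "Fp1")
            & (combined["band"] == "delta")
        ]["db"].iloc[0]
        parts = cohort[
            (cohort["participant"] == 0)
            & (cohort["condition"].isin(["LinkA", "LinkB"]))
            & (cohort["electrode"] == "Fp1")
            & (cohort["band"] == "delta")
        ]["db"].sum()
        assert one == pytest.approx(parts)

    def test_subtest_suppresses_p_and_varexp(self, cohort):
        result = P.run_subtest(cohort, ("LinkB", "LinkA"), n_boot=100, seed=0)
        assert result.perm_p is None
        assert result.variance_explained is None
        assert result.task_saliences.shape == (2, 2)

    def test_identical_conditions_give_empty_map(self, rng):
        rows = []
        for p in range(8):
            vals = rng.normal(size=10)
            for cond in ("LinkA", "LinkB"):
                for f, v in enumerate(vals):
                    rows.append((p, cond, f"e{f}", "delta", v))
        df = pd.DataFrame(rows, columns=["participant", "condition", "electrode", "band", "db"])
        result = P.run_subtest(df, ("LinkB", "LinkA"), n_boot=100, seed=0)
        assert (result.maps[0].to_numpy() == 0).all()

    def test_unknown_condition_rejected(self, cohort):
        with pytest.raises(ValueError):
            P.run_subtest(cohort, ("LinkA", "Bogus"))
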