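"""Preprocessing steps and chains: parameter estimation on the reference
training subset, frozen application, back-projection, leakage safety."""

import numpy as np
import pandas as pd
import pytest

from symclass.preprocess import (
    CovariateRegress,
    NotFittedError,
    PCAEnergy,
    PreprocessChain,
    ReliabilityMask,
    ScaleWinsorize,
    SiteOffsetCorrect,
    build_chain,
)


def _meta(n, seed=0, sites=3):
    rng = np.random.default_rng(seed)
    m = pd.DataFrame(
        {
            "age": rng.uniform(18, 40, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "fd": rng.uniform(0.05, 0.4, n),
            "site": rng.integers(0, sites, n),
        }
    )
    for j in range(10):
        m[f"pc{j + 1}"] = rng.standard_normal(n)
    return m


class TestCovariateRegress:
    def test_residuals_uncorrelated_with_covariates(self):
        rng = np.random.default_rng(1)
        n, p = 400, 6
        meta = _meta(n, seed=1)
        X = (
            rng.standard_normal((n, p))
            + 0.08 * np.outer(meta["age"] - 30, rng.uniform(0.5, 1.5, p))
            + np.outer(meta["sex"], rng.uniform(-1, 1, p))
        )
        step = CovariateRegress(("age", "sex"))
        step.fit(X, meta, np.ones(n, dtype=bool))
        R = step.apply(X, meta)
        for c in ("age", "sex"):
            r = np.corrcoef(np.column_stack([meta[c], R]), rowvar=False)[0, 1:]
            assert np.abs(r).max() < 0.05

    def test_reference_subset_preserves_group_difference(self):
        """Slopes learned on the reference (control) rows do not absorb a
        genuine group effect that happens to align with a covariate."""
        rng = np.random.default_rng(2)
        n = 300
        meta = _meta(n, seed=2)
        ref = np.zeros(n, dtype=bool)
        ref[:150] = True
        X = rng.standard_normal((n, 3))
        X[~ref] += 1.0  # group effect only in non-reference rows
        step = CovariateRegress(("age",))
        step.fit(X, meta, ref)
        R = step.apply(X, meta)
        assert np.allclose(R[ref].mean(axis=0), 0.0, atol=0.05)
        assert np.all(R[~ref].mean(axis=0) > 0.8)

    def test_rank_deficiency_names_columns(self):
        n = 50
        meta = _meta(n, seed=3)
        meta["age2"] = meta["age"]  # exact duplicate
        X = np.random.default_rng(3).standard_normal((n, 2))
        step = CovariateRegress(("age", "age2"))
        with pytest.raises(ValueError, match="collinear"):
            step.fit(X, meta, np.ones(n, dtype=bool))

    def test_intercept_only_is_reference_centering(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 4)) + 5.0
        meta = _meta(60, seed=4)
        ref = np.arange(60) < 30
        step = CovariateRegress(())
        step.fit(X, meta, ref)
        R = step.apply(X, meta)
        assert np.allclose(R[ref].mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(R, X - X[ref].mean(axis=0))


class TestSiteOffsetCorrect:
    def test_removes_planted_offsets(self):
        rng = np.random.default_rng(5)
        n, p = 600, 4
        meta = _meta(n, seed=5, sites=3)
        X = rng.standard_normal((n, p))
        X[meta["site"].values == 1] += 2.0
        step = SiteOffsetCorrect()
        step.fit(X, meta, np.ones(n, dtype=bool))
        C = step.apply(X, meta)
        means = np.array(
            [C[meta["site"].values == s].mean(axis=0) for s in range(3)]
        )
        assert np.abs(means - means.mean(axis=0)).max() < 0.15

    def test_unseen_site_warns_and_passes_through(self):
        meta = _meta(40, seed=6, sites=2)
        X = np.random.default_rng(6).standard_normal((40, 3))
        step = SiteOffsetCorrect()
        step.fit(X, meta, np.ones(40, dtype=bool))
        meta2 = meta.copy()
        meta2.loc[meta2.index[:5], "site"] = 99
        with pytest.warns(RuntimeWarning, match="unseen"):
            out = step.apply(X, meta2)
        assert np.array_equal(out[:5], X[:5])

    def test_site_without_reference_warns(self):
        meta = _meta(40, seed=7, sites=2)
        X = np.random.default_rng(7).standard_normal((40, 3))
        ref = (meta["site"].values == 0)
        with pytest.warns(RuntimeWarning, match="no reference"):
            step = SiteOffsetCorrect()
            step.fit(X, meta, ref)
        assert np.allclose(step.offsets[1], 0.0)


class TestPCAEnergy:
    def test_component_counts_from_known_shares(self):
        """Variance shares (0.5, 0.3, 0.2) on orthogonal directions:
        energy 0.4 -> 1 comp, 0.6 -> 2, 0.9 -> 3."""
        rng = np.random.default_rng(8)
        n = 4000
        Z = rng.standard_normal((n, 3))
        Z -= Z.mean(axis=0)
        Z /= Z.std(axis=0)
        X = Z * np.sqrt(np.array([0.5, 0.3, 0.2]))
        # embed in 6 dims with a random rotation
        Q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        X6 = np.column_stack([X, np.zeros((n, 3))]) @ Q.T
        meta = _meta(n)
        for energy, expected in [(0.4, 1), (0.6, 2), (0.79, 2), (0.9, 3)]:
            step = PCAEnergy(energy)
            step.fit(X6, meta, np.ones(n, dtype=bool))
            assert step.n_components == expected

    def test_energy_one_reconstructs_exactly(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((50, 8))
        meta = _meta(50)
        step = PCAEnergy(1.0)
        step.fit(X, meta, np.ones(50, dtype=bool))
        Y = step.apply(X, meta)
        back = Y @ step.basis.T + step.center
        assert np.allclose(back, X, atol=1e-10)

    def test_flat_spectrum_component_count(self):
        """With an exactly flat eigenvalue spectrum, energy e keeps
        ceil(e*p) components."""
        rng = np.random.default_rng(10)
        n, p = 2000, 100
        Z = rng.standard_normal((n, p))
        Z -= Z.mean(axis=0)
        cov = (Z.T @ Z) / (n - 1)
        X = Z @ np.linalg.cholesky(np.linalg.inv(cov))  # exact whitening
        step = PCAEnergy(0.4)
        step.fit(X, _meta(n), np.ones(n, dtype=bool))
        assert step.n_components == 40

    def test_backprojection_roundtrip(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((100, 10))
        step = PCAEnergy(0.8)
        step.fit(X, _meta(100), np.ones(100, dtype=bool))
        w = rng.standard_normal(step.n_components)
        w_in = step.backproject(w)
        # scores along backprojected direction equal component-space scores
        Xc = X - step.center
        assert np.allclose(Xc @ w_in, step.apply(X, _meta(100)) @ w, atol=1e-10)

    def test_invalid_energy(self):
        with pytest.raises(ValueError, match="energy"):
            PCAEnergy(0.0)
        with pytest.raises(ValueError, match="energy"):
            PCAEnergy(1.2)


class TestScaleWinsorize:
    def test_bounds_and_training_moments(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((500, 5)) * 3 + 2
        X[0, 0] = 1e4  # gross outlier
        meta = _meta(500)
        step = ScaleWinsorize(center="mean", limit=4.0)
        step.fit(X, meta, np.ones(500, dtype=bool))
        Z = step.apply(X, meta)
        assert np.abs(Z).max() <= 4.0
        assert Z[0, 0] == 4.0

    def test_center_row_maps_to_zero(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((100, 3)) + 7
        step = ScaleWinsorize(center="median")
        step.fit(X, _meta(100), np.ones(100, dtype=bool))
        med = np.median(X, axis=0)
        assert np.allclose(step.apply(med[None, :], _meta(1)), 0.0, atol=1e-12)

    def test_apply_is_frozen_idempotent_on_params(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((80, 4))
        step = ScaleWinsorize()
        step.fit(X, _meta(80), np.ones(80, dtype=bool))
        p1 = step.params()
        step.apply(rng.standard_normal((10, 4)), _meta(10))
        assert step.params() == p1

    def test_zero_scale_dropped_with_warning(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((60, 3))
        X[:, 1] = 2.5
        step = ScaleWinsorize()
        with pytest.warns(RuntimeWarning, match="zero-scale"):
            step.fit(X, _meta(60), np.ones(60, dtype=bool))
        Z = step.apply(X, _meta(60))
        assert Z.shape[1] == 2
        assert step.dropped == [1]
        assert np.array_equal(step.backproject(np.array([1.0, 2.0])), [1.0, 0.0, 2.0])

    def test_invalid_center(self):
        with pytest.raises(ValueError, match="center"):
            ScaleWinsorize(center="mode")


class TestReliabilityMask:
    def test_identity_and_drop(self):
        X = np.arange(12.0).reshape(3, 4)
        meta = _meta(3)
        ident = ReliabilityMask()
        ident.fit(X, meta, np.ones(3, dtype=bool))
        assert np.array_equal(ident.apply(X, meta), X)
        drop = ReliabilityMask(np.array([1, 0, 1, 0]))
        drop.fit(X, meta, np.ones(3, dtype=bool))
        out = drop.apply(X, meta)
        assert np.array_equal(out, X[:, [0, 2]])
        assert np.array_equal(drop.backproject(np.array([5.0, 7.0])), [5, 0, 7, 0])

    def test_length_mismatch(self):
        X = np.zeros((3, 4))
        step = ReliabilityMask(np.array([1, 0]))
        with pytest.raises(ValueError, match="mask length"):
            step.fit(X, _meta(3), np.ones(3, dtype=bool))


class TestChain:
    def test_build_chain_step_names(self):
        assert build_chain("neurocognition").step_names == [
            "covariate_regress",
            "scale_winsorize",
        ]
        for m in ("falff5", "falff4", "fc", "gmv"):
            ch = build_chain(m)
            assert ch.step_names == [
                "site_offset_correct",
                "covariate_regress",
                "reliability_mask",
                "pca_energy",
                "scale_winsorize",
            ]
            assert ch.reference_group == "HC"
        prs = build_chain("prs")
        assert prs.step_names == ["covariate_regress", "scale_winsorize"]
        assert prs.steps[0].covariates == ("age", "sex", "ancestry")
        with pytest.raises(ValueError, match="unknown modality"):
            build_chain("bogus")

    def test_generic_presets(self):
        assert build_chain("m1", {"preset": "generic"}).step_names == [
            "scale_winsorize"
        ]
        assert build_chain("m1", {"preset": "generic_pca"}).step_names == [
            "pca_energy",
            "scale_winsorize",
        ]

    def test_not_fitted_and_missing_reference(self):
        ch = build_chain("neurocognition")
        with pytest.raises(NotFittedError):
            ch.apply(np.zeros((2, 3)), _meta(2))
        ch2 = PreprocessChain([ScaleWinsorize()], reference_group="HC")
        with pytest.raises(ValueError, match="reference group"):
            ch2.fit(np.zeros((4, 2)), _meta(4), np.array(["A"] * 4))

    def test_leakage_guard_parameters_ignore_nonfit_rows(self):
        """Fitted parameters depend only on the rows passed to fit: applying
        to arbitrary other data never re-estimates anything."""
        rng = np.random.default_rng(16)
        n = 120
        meta = _meta(n, seed=16)
        X = rng.standard_normal((n, 30)) + 0.05 * meta[["age"]].values
        labels = np.array(["HC"] * 60 + ["P"] * 60)
        ch = build_chain("gmv", {"pca_energy": 0.8})
        ch.fit(X, meta, labels)
        params_before = ch.to_dict()
        wild = rng.standard_normal((40, 30)) * 50 + 100
        out1 = ch.apply(wild, _meta(40, seed=99))
        out2 = ch.apply(wild, _meta(40, seed=99))
        assert np.array_equal(out1, out2)
        assert ch.to_dict() == params_before

    def test_fit_apply_equals_fit_then_apply(self):
        rng = np.random.default_rng(17)
        n = 80
        meta = _meta(n, seed=17)
        X = rng.standard_normal((n, 12))
        labels = np.array(["HC"] * 40 + ["P"] * 40)
        a = build_chain("fc", {"pca_energy": 0.6}).fit_apply(X, meta, labels)
        ch = build_chain("fc", {"pca_energy": 0.6}).fit(X, meta, labels)
        assert np.array_equal(a, ch.apply(X, meta))

    def test_chain_backprojection_dimension(self):
        rng = np.random.default_rng(18)
        n, p = 100, 25
        meta = _meta(n, seed=18)
        X = rng.standard_normal((n, p))
        labels = np.array(["HC"] * 50 + ["P"] * 50)
        mask = np.ones(p)
        mask[:5] = 0
        ch = build_chain("falff5", {"pca_energy": 0.6, "mask": mask})
        Z = ch.fit_apply(X, meta, labels)
        w = rng.standard_normal(Z.shape[1])
        w_in = ch.backproject(w)
        assert w_in.shape == (p,)
        assert np.allclose(w_in[:5], 0.0)

    def test_serialization_roundtrip_values(self):
        rng = np.random.default_rng(19)
        n = 60
        meta = _meta(n, seed=19)
        X = rng.standard_normal((n, 8))
        ch = build_chain("neurocognition")
        ch.fit(X, meta, np.array(["A"] * n))
        d = ch.to_dict()
        assert d["reference_group"] == "all"
        assert [s["name"] for s in d["steps"]] == ch.step_names
        assert all(s["fitted"] for s in d["steps"])
        import json

        json.dumps(d)  # plain-JSON serializable
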