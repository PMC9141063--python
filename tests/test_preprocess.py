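"""Preprocessing cascade: filters, size factors, VST, batch/covariate removal."""

import numpy as np
import pandas as pd
import pytest

import txclass as t
from txclass.preprocess import (DispersionTrend, PipelineError,
                                drop_blacklist, fit_dispersion_trend)


def toy_counts(arr, gene_ids=None, sample_ids=None):
    arr = np.asarray(arr)
    g = gene_ids or [f"g{i}" for i in range(arr.shape[0])]
    s = sample_ids or [f"s{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=pd.Index(g, name="gene_id"), columns=s)


class TestBiotypeFilter:
    def test_membership(self):
        counts = toy_counts(np.arange(10).reshape(5, 2))
        annot = pd.DataFrame({"biotype": ["pc", "pc", "lincRNA", "rRNA",
                                          "pseudogene"]}, index=counts.index)
        out = t.filter_biotypes(counts, annot, allowed=("pc", "lincRNA"))
        assert list(out.index) == ["g0", "g1", "g2"]

    def test_allow_all_identity(self):
        counts = toy_counts(np.ones((4, 2), dtype=int))
        annot = pd.DataFrame({"biotype": ["a", "b", "c", "d"]},
                             index=counts.index)
        pd.testing.assert_frame_equal(
            t.filter_biotypes(counts, annot, allowed=set("abcd")), counts)

    def test_missing_annotation_raises_with_id(self):
        counts = toy_counts(np.ones((2, 2), dtype=int))
        annot = pd.DataFrame({"biotype": ["pc"]}, index=["g0"])
        with pytest.raises(KeyError, match="g1"):
            t.filter_biotypes(counts, annot, allowed={"pc"})

    def test_published_biotype_census(self):
        # 18,727 protein coding + 7,444 lincRNA among extras -> 26,171 kept
        n_pc, n_linc, n_other = 18727, 7444, 1500
        biotypes = (["protein_coding"] * n_pc + ["lincRNA"] * n_linc
                    + ["rRNA"] * n_other)
        ids = [f"g{i}" for i in range(len(biotypes))]
        counts = toy_counts(np.zeros((len(ids), 1), dtype=int), gene_ids=ids)
        annot = pd.DataFrame({"biotype": biotypes}, index=counts.index)
        out = t.filter_biotypes(counts, annot)
        assert out.shape[0] == 26171


class TestBlacklist:
    def test_empty_identity(self):
        counts = toy_counts(np.ones((3, 2), dtype=int))
        pd.testing.assert_frame_equal(drop_blacklist(counts, set()), counts)

    def test_all_blacklisted_degenerate(self):
        counts = toy_counts(np.ones((3, 2), dtype=int))
        out = drop_blacklist(counts, set(counts.index))
        assert out.shape[0] == 0

    def test_set_difference_oracle(self):
        rng = np.random.default_rng(0)
        counts = toy_counts(rng.integers(0, 50, (500, 4)))
        present = rng.choice(counts.index, 60, replace=False)
        absent = [f"zz{i}" for i in range(40)]
        out = drop_blacklist(counts, set(present) | set(absent))
        assert out.shape[0] == 500 - 60
        assert set(out.index) == set(counts.index) - set(present)


class TestLowExpressionFilter:
    def test_threshold_arithmetic(self):
        row = [6, 6] + [0] * 8  # 2 samples above 5, need ceil(0.1*10)=1
        counts = toy_counts([row])
        assert t.filter_low_expression(counts).shape[0] == 1

    def test_strict_inequality_boundary(self):
        counts = toy_counts([[5] * 10])
        assert t.filter_low_expression(counts).shape[0] == 0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        counts = toy_counts(rng.poisson(4, (2000, 30)))
        out = t.filter_low_expression(counts, min_count=5, min_fraction=0.1)
        keep = [g for g in counts.index
                if (counts.loc[g] > 5).sum() >= np.ceil(0.1 * 30)]
        assert list(out.index) == keep

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        counts = toy_counts(rng.poisson(6, (300, 20)))
        kept = [t.filter_low_expression(counts, min_count=c).shape[0]
                for c in (2, 5, 10, 20)]
        assert kept == sorted(kept, reverse=True)


class TestSizeFactors:
    def test_scale_equivariance_two_samples(self):
        counts = toy_counts([[10, 20], [30, 60], [5, 10]])
        s = t.estimate_size_factors(counts)
        assert s.iloc[1] / s.iloc[0] == pytest.approx(2.0)
        assert s.iloc[0] == pytest.approx(1 / np.sqrt(2))
        assert s.iloc[1] == pytest.approx(np.sqrt(2))

    def test_hand_computed_median_of_ratios(self):
        counts = toy_counts([[10, 20], [100, 200], [4, 8]])
        s = t.estimate_size_factors(counts)
        assert s.iloc[1] / s.iloc[0] == pytest.approx(2.0)

    def test_identical_columns_unity(self):
        counts = toy_counts(np.tile([[7], [13], [29]], (1, 4)))
        assert np.allclose(t.estimate_size_factors(counts), 1.0)

    def test_geometric_mean_one(self, small_cohort):
        counts, *_ = small_cohort
        s = t.estimate_size_factors(counts)
        assert np.exp(np.mean(np.log(s))) == pytest.approx(1.0, abs=1e-6)

    def test_multiplying_sample_scales_its_factor(self, small_cohort):
        counts, *_ = small_cohort
        s0 = t.estimate_size_factors(counts)
        scaled = counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 3
        s1 = t.estimate_size_factors(scaled)
        # pre-rescaling equivariance shows up as ratio of ratios
        ratio = (s1.iloc[0] / s0.iloc[0]) / (s1.iloc[1] / s0.iloc[1])
        assert ratio == pytest.approx(3.0, rel=1e-6)

    def test_no_reference_gene_raises(self):
        counts = toy_counts([[0, 5], [5, 0]])
        with pytest.raises(PipelineError):
            t.estimate_size_factors(counts)


class TestIndependentFilter:
    def test_zero_quantile_identity(self, small_cohort):
        counts, *_ = small_cohort
        s = t.estimate_size_factors(counts)
        pd.testing.assert_frame_equal(
            t.independent_filter(counts, s, 0.0), counts)

    def test_median_cut_quantile_oracle(self):
        rng = np.random.default_rng(3)
        means = rng.permutation(np.arange(1, 101))
        counts = toy_counts(np.outer(means, [1, 1, 1, 1]))
        s = t.estimate_size_factors(counts)
        out = t.independent_filter(counts, s, 0.5)
        stat = (counts / s).mean(axis=1)
        expected = (stat >= np.quantile(stat, 0.5)).sum()
        assert out.shape[0] == expected == 50

    def test_ties_at_cutoff_retained(self):
        # median falls on a run of tied means: every tied gene is kept
        means = np.array([1, 2, 3, 4, 5, 5, 5, 8, 9, 10])
        counts = toy_counts(np.outer(means, [1, 1]))
        s = pd.Series([1.0, 1.0], index=counts.columns)
        out = t.independent_filter(counts, s, 0.5)
        assert out.shape[0] == 6  # the three tied 5s all survive

    def test_bad_quantile_raises(self, small_cohort):
        counts, *_ = small_cohort
        s = t.estimate_size_factors(counts)
        with pytest.raises(ValueError):
            t.independent_filter(counts, s, 1.0)


class TestVst:
    trend = DispersionTrend(a0=0.05, a1=1.0)

    def _v(self, n):
        a0, a1 = self.trend.a0, self.trend.a1
        return np.log2((1 + a1 + 2 * a0 * n
                        + 2 * np.sqrt(a0 * n * (1 + a1 + a0 * n))) / (4 * a0))

    def test_monotone(self):
        assert self._v(0) < self._v(1) < self._v(100)

    def test_large_n_asymptote_tracks_log2(self):
        d1 = self._v(1e5) - np.log2(1e5)
        d2 = self._v(1e6) - np.log2(1e6)
        assert abs(d1 - d2) < 0.01

    def test_matches_closed_form_on_matrix(self):
        counts = toy_counts([[0, 10], [100, 1000]])
        s = pd.Series([1.0, 1.0], index=counts.columns)
        out = t.vst(counts, s, self.trend)
        assert np.allclose(out.to_numpy(),
                           self._v(counts.to_numpy(dtype=float)))

    def test_fallback_when_a0_zero(self):
        counts = toy_counts([[1, 2], [3, 4]])
        s = pd.Series([1.0, 1.0], index=counts.columns)
        with pytest.warns(UserWarning, match="falling back"):
            out = t.vst(counts, s, DispersionTrend(a0=0.0, a1=1.0))
        assert np.allclose(out.to_numpy(),
                           np.log2(counts.to_numpy(dtype=float) + 1))

    def test_variance_flattening_on_simulated_trend(self):
        # NB data spanning a wide mean range: VST flattens the per-gene
        # variance across mean bins, raw log2 does not
        from txclass.simulate import _nb_draw

        rng = np.random.default_rng(8)
        n, g = 200, 600
        mu = np.exp(rng.uniform(np.log(2), np.log(5000), g))
        alpha = 1.0 / mu + 0.05
        x = _nb_draw(rng, np.tile(mu[:, None], (1, n)), alpha[:, None])
        counts = toy_counts(x)
        s = pd.Series(np.ones(n), index=counts.columns)
        vs = t.vst(counts, s, DispersionTrend(0.05, 1.0)).to_numpy()
        lg = np.log2(x + 1.0)

        def bin_ratio(mat):
            var = mat.var(axis=1, ddof=1)
            bins = pd.qcut(np.log(mu), 6, labels=False)
            bv = pd.Series(var).groupby(bins).mean()
            return bv.max() / bv.min()

        assert bin_ratio(vs) < 3
        assert bin_ratio(lg) > 5  # raw log2 leaves a strong mean-variance trend


class TestDispersionTrendFit:
    def test_recovers_known_trend(self):
        from txclass.simulate import _nb_draw

        rng = np.random.default_rng(9)
        n, g = 400, 800
        mu = np.exp(rng.uniform(np.log(10), np.log(2000), g))
        a0, a1 = 0.08, 1.5
        alpha = a1 / mu + a0
        x = _nb_draw(rng, np.tile(mu[:, None], (1, n)), alpha[:, None])
        counts = toy_counts(x)
        s = pd.Series(np.ones(n), index=counts.columns)
        trend = fit_dispersion_trend(counts, s)
        assert trend.a0 == pytest.approx(a0, rel=0.3)
        assert trend.a1 == pytest.approx(a1, rel=0.4)


class TestSmallSiteExclusion:
    @staticmethod
    def _meta(spec):
        """spec: list of (site, n_cases, n_controls)."""
        rows = []
        for site, nc, nh in spec:
            rows += [("case", site)] * nc + [("control", site)] * nh
        meta = pd.DataFrame(rows, columns=["label", "site"])
        meta.index = pd.Index([f"s{i}" for i in range(len(meta))],
                              name="sample_id")
        return meta

    def test_published_cohort_counts(self):
        # 579 samples; sites 14 (1 sample), 26 (16), 55 (4), 59 (10) carry
        # <=1 control each and are dropped, leaving 548 samples
        spec = [("14", 1, 0), ("26", 15, 1), ("55", 4, 0), ("59", 9, 1)]
        remaining = 579 - 31
        n_keep_sites = 21
        per = remaining // n_keep_sites
        extra = remaining - per * n_keep_sites
        for k in range(n_keep_sites):
            n = per + (1 if k < extra else 0)
            spec.append((f"ok{k}", n - 2, 2))
        meta = self._meta(spec)
        assert len(meta) == 579
        counts = toy_counts(np.ones((3, len(meta)), dtype=int),
                            sample_ids=list(meta.index))
        out_c, out_m, removed = t.exclude_small_sites(counts, meta)
        assert out_c.shape[1] == 548
        assert removed == {"14": 1, "26": 16, "55": 4, "59": 10}

    def test_identity_when_all_sites_have_controls(self):
        meta = self._meta([("a", 3, 2), ("b", 4, 3)])
        counts = toy_counts(np.ones((2, len(meta)), dtype=int),
                            sample_ids=list(meta.index))
        out_c, out_m, removed = t.exclude_small_sites(counts, meta)
        assert removed == {}
        assert out_c.shape[1] == len(meta)

    def test_brute_force_site_scan(self):
        rng = np.random.default_rng(10)
        n = 200
        meta = pd.DataFrame({
            "label": rng.choice(["case", "control"], n, p=[0.8, 0.2]),
            "site": rng.choice([f"x{i}" for i in range(12)], n),
        }, index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"))
        counts = toy_counts(np.ones((2, n), dtype=int),
                            sample_ids=list(meta.index))
        out_c, out_m, _ = t.exclude_small_sites(counts, meta)
        expected = set()
        for site, grp in meta.groupby("site"):
            if (grp["label"] == "control").sum() >= 2:
                expected |= set(grp.index)
        assert set(out_m.index) == expected

    def test_all_sites_removed_raises(self):
        meta = self._meta([("a", 3, 0), ("b", 4, 1)])
        counts = toy_counts(np.ones((2, len(meta)), dtype=int),
                            sample_ids=list(meta.index))
        with pytest.raises(PipelineError):
            t.exclude_small_sites(counts, meta)


class TestSiteBatchRemoval:
    @staticmethod
    def _noiseless(offsets_by_site, n_per_site=6, n_ctrl=3, n_genes=4):
        rng = np.random.default_rng(11)
        base = rng.normal(5, 1, n_genes)
        cols, rows_meta = [], []
        for site, off in offsets_by_site.items():
            for j in range(n_per_site):
                cols.append(base + off)
                rows_meta.append(("control" if j < n_ctrl else "case", site))
        meta = pd.DataFrame(rows_meta, columns=["label", "site"])
        meta.index = pd.Index([f"s{i}" for i in range(len(meta))],
                              name="sample_id")
        expr = pd.DataFrame(np.column_stack(cols),
                            index=[f"g{i}" for i in range(n_genes)],
                            columns=meta.index)
        return expr, meta, base

    def test_exact_recovery_noiseless(self):
        offs = {"a": 0.7, "b": -0.2, "c": -0.5}  # sum-to-zero truth
        expr, meta, base = self._noiseless(offs)
        corrected, est = t.remove_site_batch(expr, meta)
        for site, off in offs.items():
            assert np.allclose(est[site], off, atol=1e-8)
        assert np.allclose(corrected.to_numpy(),
                           np.tile(base[:, None], (1, expr.shape[1])),
                           atol=1e-8)

    def test_zero_offsets_identity(self):
        expr, meta, _ = self._noiseless({"a": 0.0, "b": 0.0})
        corrected, _ = t.remove_site_batch(expr, meta)
        assert np.allclose(corrected.to_numpy(), expr.to_numpy(), atol=1e-10)

    def test_control_means_equalized_and_variance_shrinks(self, small_cohort):
        counts, meta, annot, truth, cfg = small_cohort
        expr, meta2, _ = t.run_preprocess(counts, meta, annot,
                                          config=t.PreprocessConfig(
                                              covariates=()))
        # recompute pre-correction matrix for comparison
        from txclass.preprocess import (estimate_size_factors,
                                        fit_dispersion_trend, vst,
                                        filter_biotypes, drop_blacklist,
                                        filter_low_expression,
                                        independent_filter,
                                        exclude_small_sites,
                                        remove_site_batch)
        c = filter_biotypes(counts, annot)
        c = filter_low_expression(c)
        s = estimate_size_factors(c)
        c = independent_filter(c, s, 0.4)
        pre = vst(c, s, fit_dispersion_trend(c, s))
        pre, m, _ = exclude_small_sites(pre, meta)
        post, _ = remove_site_batch(pre, m)
        literal, _ = remove_site_batch(pre, m, cross_fit=False)
        ctrl = m["label"] == "control"

        def between_site_var(mat):
            cm = mat.loc[:, ctrl.to_numpy()].T.groupby(
                m.loc[ctrl, "site"].to_numpy()).mean()
            return cm.var(axis=0, ddof=1)

        v_pre = between_site_var(pre)
        assert (between_site_var(post) < v_pre).mean() >= 0.95
        # literal mode centers control site means exactly
        assert np.allclose(between_site_var(literal), 0.0, atol=1e-12)

    def test_cross_fit_equalizes_residual_variance(self):
        # pure-noise expression: the literal correction leaves controls
        # with systematically smaller residuals than cases, the
        # cross-fitted default does not
        rng = np.random.default_rng(15)
        n_sites, per_site = 6, 20
        n = n_sites * per_site
        meta = pd.DataFrame({
            "site": np.repeat([f"x{j}" for j in range(n_sites)], per_site),
            "label": np.tile(["control"] * 6 + ["case"] * 14, n_sites),
        }, index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"))
        expr = pd.DataFrame(rng.normal(size=(400, n)),
                            index=[f"g{i}" for i in range(400)],
                            columns=meta.index)
        ctrl = (meta["label"] == "control").to_numpy()

        def var_ratio(mat):
            x = mat.to_numpy()
            return (x[:, ctrl] ** 2).mean() / (x[:, ~ctrl] ** 2).mean()

        lit, _ = t.remove_site_batch(expr, meta, cross_fit=False)
        xf, _ = t.remove_site_batch(expr, meta, cross_fit=True)
        assert var_ratio(lit) < 0.92          # literal: controls shrunk
        assert abs(var_ratio(xf) - 1.0) < 0.05  # cross-fit: symmetric

    def test_site_without_controls_raises(self):
        expr, meta, _ = self._noiseless({"a": 0.1, "b": 0.2})
        meta.loc[meta["site"] == "b", "label"] = "case"
        with pytest.raises(PipelineError, match="exclude_small_sites"):
            t.remove_site_batch(expr, meta)


class TestCovariateRemoval:
    def test_planted_sex_effect_exactly_removed(self):
        rng = np.random.default_rng(12)
        n, g = 40, 5
        base = rng.normal(5, 1, g)
        sex = rng.choice(["M", "F"], n)
        beta = rng.normal(0, 1, g)
        expr = pd.DataFrame(base[:, None] + beta[:, None] * (sex == "M"),
                            index=[f"g{i}" for i in range(g)],
                            columns=[f"s{i}" for i in range(n)])
        meta = pd.DataFrame({"sex": sex, "rin": np.full(n, 8.0)},
                            index=expr.columns)
        with pytest.warns(UserWarning, match="constant"):
            out = t.remove_covariates(expr, meta)
        assert np.allclose(out.to_numpy().std(axis=1), 0.0, atol=1e-10)

    def test_no_effect_identity(self):
        rng = np.random.default_rng(13)
        expr = pd.DataFrame(np.tile(rng.normal(5, 1, 4)[:, None], (1, 30)),
                            columns=[f"s{i}" for i in range(30)])
        meta = pd.DataFrame({"sex": rng.choice(["M", "F"], 30),
                             "rin": rng.normal(8, 1, 30)}, index=expr.columns)
        out = t.remove_covariates(expr, meta)
        assert np.allclose(out.to_numpy(), expr.to_numpy(), atol=1e-10)

    def test_rin_correlation_reduced(self, small_cohort):
        counts, meta, annot, truth, cfg = small_cohort
        expr, meta2, _ = t.run_preprocess(
            counts, meta, annot, config=t.PreprocessConfig(covariates=()))
        post = t.remove_covariates(expr, meta2)
        rin = meta2["rin"].to_numpy()

        def mean_abs_r(mat):
            x = mat.to_numpy()
            xc = x - x.mean(axis=1, keepdims=True)
            rc = rin - rin.mean()
            num = xc @ rc
            den = np.sqrt((xc ** 2).sum(axis=1) * (rc ** 2).sum())
            return np.abs(num / den).mean()

        assert mean_abs_r(post) < mean_abs_r(expr)


class TestCascade:
    def test_stage_accounting_and_monotone_gene_counts(self, small_cohort):
        counts, meta, annot, truth, cfg = small_cohort
        expr, meta2, report = t.run_preprocess(counts, meta, annot)
        stages = {s["stage"]: s for s in report["stages"]}
        assert stages["input"]["n_genes"] == cfg.n_genes
        genes = [s["n_genes"] for s in report["stages"]]
        assert genes == sorted(genes, reverse=True)
        assert report["transform_tag"].startswith("vst")
        assert np.isfinite(expr.to_numpy()).all()

    def test_blacklist_respected_in_cascade(self, small_cohort):
        counts, meta, annot, *_ = small_cohort
        bl = set(counts.index[:50])
        expr, _, _ = t.run_preprocess(counts, meta, annot, blacklist=bl)
        assert not (set(expr.index) & bl)
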