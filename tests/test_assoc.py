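"""Filters, transforms, mixed models, TMM, NB differential expression,
ranking and FDR adjustment."""

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

from magpheno import assoc
from magpheno.errors import (
    DegenerateModelError,
    InvalidDesignError,
    InvalidInputError,
    RankDeficiencyError,
)


class TestTpmFilter:
    def test_hand_worked_rules(self):
        tpm = pd.DataFrame(
            {
                "s1": [6.0, 6.0, 5.0],
                "s2": [6.0, 0.0, 5.0],
                "s3": [0.0, 0.0, 5.0],
            },
            index=["kept", "low_prev", "at_threshold"],
        )
        # 2/3 > 0.40 -> kept; 1/3 < 0.40 -> dropped; exactly 5 TPM fails the
        # strict > rule everywhere
        assert assoc.filter_mags_tpm(tpm) == ["kept"]

    def test_empty_table(self):
        assert assoc.filter_mags_tpm(pd.DataFrame()) == []


class TestVarianceStabilize:
    def test_finite_on_zeros_and_monotone(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, size=(30, 6)))
        vst = assoc.variance_stabilize(counts)
        assert np.isfinite(vst.to_numpy()).all()
        for col in counts:
            order = counts[col].argsort().to_numpy()
            assert (np.diff(vst[col].to_numpy()[order]) >= -1e-12).all()

    def test_all_zero_sample_names_the_sample(self):
        counts = pd.DataFrame({"ok": [3, 5], "empty": [0, 0]})
        with pytest.raises(InvalidInputError, match="empty"):
            assoc.variance_stabilize(counts)

    def test_flattens_mean_variance_trend(self):
        """On NB counts with unequal sequencing depths, per-gene SD binned by
        mean is flatter and uniformly smaller than a plain log2(x+1)
        baseline (the size factors absorb the depth component)."""
        rng = np.random.default_rng(1)
        means = np.exp(rng.uniform(np.log(5), np.log(2000), 300))
        disp = 0.4
        depth = rng.uniform(0.3, 3.0, 20)
        lam = means[:, None] * depth[None, :]
        counts = pd.DataFrame(rng.poisson(rng.gamma(1 / disp, disp, lam.shape) * lam))

        def binned_sd(table):
            m = table.mean(axis=1).to_numpy()
            s = table.std(axis=1).to_numpy()
            bins = pd.qcut(m, 10, labels=False, duplicates="drop")
            bm = np.array([m[bins == b].mean() for b in np.unique(bins)])
            bs = np.array([s[bins == b].mean() for b in np.unique(bins)])
            return np.polyfit(np.log(bm), bs, 1)[0], bs

        vst_slope, vst_sd = binned_sd(assoc.variance_stabilize(counts))
        log_slope, log_sd = binned_sd(np.log2(counts + 1))
        assert vst_sd.mean() < log_sd.mean()
        assert abs(vst_slope) < abs(log_slope) + 0.05


class TestZeroLowDna:
    def _tables(self):
        counts = pd.DataFrame(
            {"s1": [10, 20, 5], "s2": [7, 3, 9]}, index=["g1", "g2", "g3"]
        )
        dna = pd.DataFrame({"s1": [0.4, 0.5], "s2": [2.0, 0.49]}, index=["m1", "m2"])
        mapping = pd.Series({"g1": "m1", "g2": "m1", "g3": "m2"})
        return counts, dna, mapping

    def test_zeroing_rule_strict_floor(self):
        counts, dna, mapping = self._tables()
        out = assoc.zero_low_dna_transcripts(counts, dna, mapping, floor=0.5)
        # m1 at 0.4 < 0.5 in s1 -> g1, g2 zeroed there; m2 at exactly 0.5 in
        # s1 untouched; m2 at 0.49 in s2 -> g3 zeroed
        assert out.loc["g1", "s1"] == 0 and out.loc["g2", "s1"] == 0
        assert out.loc["g3", "s1"] == 5
        assert out.loc["g1", "s2"] == 7 and out.loc["g3", "s2"] == 0

    def test_zero_floor_is_identity(self):
        counts, dna, mapping = self._tables()
        out = assoc.zero_low_dna_transcripts(counts, dna, mapping, floor=0.0)
        assert out.equals(counts)

    def test_unknown_mag_errors(self):
        counts, dna, _ = self._tables()
        with pytest.raises(InvalidInputError):
            assoc.zero_low_dna_transcripts(counts, dna, pd.Series({"g1": "m1"}))


class TestCpmFilter:
    def test_inclusive_boundary(self):
        # transcript at exactly 5 CPM in exactly 35% of 20 samples is kept
        n = 20
        lib = 1_000_000
        counts = pd.DataFrame(0, index=["t"], columns=[f"s{i}" for i in range(n)])
        counts.iloc[0, :7] = 5  # 5 / 1e6 * 1e6 = 5 CPM in 7/20 = 35%
        filler = pd.DataFrame(
            np.full((1, n), lib - 5), index=["filler"], columns=counts.columns
        )
        filler.iloc[0, 7:] = lib
        table = pd.concat([counts, filler])
        assert "t" in assoc.cpm_filter(table, min_cpm=5, min_prev=0.35)

    def test_just_below_dropped(self):
        counts = pd.DataFrame(
            {"s1": [49, 999_951], "s2": [49, 999_951]}, index=["t", "filler"]
        )  # 49 CPM < 50
        assert assoc.cpm_filter(counts, min_cpm=50) == ["filler"]

    def test_hand_worked_toy_table(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(
            rng.integers(0, 40, size=(10, 6)),
            index=[f"t{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(6)],
        )
        lib = counts.sum(axis=0)
        expected = []
        for t in counts.index:
            rate = counts.loc[t] / lib * 1e6
            if (rate >= 5).mean() >= 0.35:
                expected.append(t)
        assert assoc.cpm_filter(counts, 5, 0.35) == expected

    def test_zero_library_errors(self):
        counts = pd.DataFrame({"ok": [5], "empty": [0]}, index=["t"])
        with pytest.raises(InvalidInputError, match="empty"):
            assoc.cpm_filter(counts)


class TestTmm:
    def test_identical_libraries_unit_factors(self):
        rng = np.random.default_rng(2)
        col = rng.poisson(40, 200)
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        assert np.allclose(assoc.tmm_factors(counts), 1.0)

    def test_pure_depth_scaling_equalizes_expression(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(100, 300)
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        f = assoc.tmm_factors(counts)
        lib = counts.sum(axis=0) * f
        norm = counts / lib
        assert np.allclose(norm["a"], norm["b"], rtol=1e-10)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.negative_binomial(4, 0.02, size=(400, 5)))
        f = assoc.tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_edger_reference(self):
        """Cross-check against edgeR's calcNormFactors on a composition-shifted
        matrix."""
        rng = np.random.default_rng(42)
        counts = pd.DataFrame(rng.negative_binomial(5, 0.05, size=(300, 6)))
        counts.iloc[:30, 0] *= 4
        ours = assoc.tmm_factors(counts)
        with tempfile.TemporaryDirectory() as td:
            csv = Path(td) / "counts.csv"
            counts.to_csv(csv, index=False)
            script = (
                "suppressMessages(library(edgeR));"
                f"x <- as.matrix(read.csv('{csv}'));"
                "cat(sprintf('%.10f', calcNormFactors(x, method=\"TMM\")), sep='\\n')"
            )
            out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                                 text=True, check=True)
        theirs = np.array([float(x) for x in out.stdout.split()])
        assert np.allclose(ours.to_numpy(), theirs, rtol=1e-6)


class TestFitLmm:
    def test_zero_group_variance_matches_ols_exactly(self):
        rng = np.random.default_rng(5)
        n = 80
        x = rng.normal(size=n)
        y = 0.3 + 0.5 * x + rng.normal(0, 0.4, n)  # no participant effect
        groups = pd.Series([f"P{i % 20}" for i in range(n)])
        fixed = pd.DataFrame({"x": x})
        fit = assoc.fit_lmm(pd.Series(y), fixed, groups)
        ols = sm.OLS(y, sm.add_constant(fixed)).fit()
        assert abs(fit["x"]["estimate"] - ols.params["x"]) < 1e-6
        assert abs(fit["const"]["estimate"] - ols.params["const"]) < 1e-6

    def test_planted_effect_recovered(self):
        """beta1 = 0.5 with participant random intercepts: mean estimate over
        replicates within 10%."""
        estimates = []
        for rep in range(40):
            rng = np.random.default_rng(100 + rep)
            npart, nt = 40, 5
            pid = np.repeat(np.arange(npart), nt)
            week = np.tile([0.0, 4, 8, 12, 16], npart)
            x = rng.normal(size=npart * nt)
            u = rng.normal(0, 0.5, npart)
            y = u[pid] + 0.5 * x + 0.01 * week + rng.normal(0, 0.3, npart * nt)
            fit = assoc.fit_lmm(
                pd.Series(y), pd.DataFrame({"x": x, "week": week}),
                pd.Series(pid.astype(str)),
            )
            estimates.append(fit["x"]["estimate"])
        assert abs(np.mean(estimates) - 0.5) < 0.05

    def test_constant_response_errors(self):
        with pytest.raises(DegenerateModelError):
            assoc.fit_lmm(pd.Series([1.0] * 10), pd.DataFrame({"x": range(10)}),
                          pd.Series(["a"] * 5 + ["b"] * 5))

    def test_rank_deficient_design_errors(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=20)
        with pytest.raises(RankDeficiencyError):
            assoc.fit_lmm(pd.Series(rng.normal(size=20)),
                          pd.DataFrame({"x": x, "x2": 2 * x}),
                          pd.Series(["a", "b"] * 10))


class TestGroupTimeModel:
    def _simulate(self, rng, meta, slope_b=0.0):
        pid_codes = meta["PID"].astype("category").cat.codes.to_numpy()
        u = rng.normal(0, 0.6, pid_codes.max() + 1)
        g = (meta["arm"] == "RUSF").to_numpy(float)
        y = u[pid_codes] + 0.02 * meta["study_week"].to_numpy() \
            + slope_b * g * meta["study_week"].to_numpy() \
            + rng.normal(0, 0.5, len(meta))
        return pd.Series(y, index=meta.index)

    def test_label_swap_negates_interaction(self, longitudinal_meta):
        rng = np.random.default_rng(7)
        y = self._simulate(rng, longitudinal_meta, slope_b=0.1)
        fit = assoc.fit_group_time_model(y, longitudinal_meta)
        swapped = longitudinal_meta.copy()
        swapped["arm"] = swapped["arm"].map({"MDCF-2": "RUSF", "RUSF": "MDCF-2"})
        fit2 = assoc.fit_group_time_model(y, swapped)
        assert fit["interaction"]["estimate"] == pytest.approx(
            -fit2["interaction"]["estimate"], rel=1e-8
        )

    def test_null_interaction_calibrated(self, longitudinal_meta):
        """Identical group trajectories: |t3| stays below the null 97.5%
        quantile in >= 90% of simulations."""
        crit = stats.t.ppf(0.975, len(longitudinal_meta) - 4)
        inside = 0
        n_sims = 60
        for rep in range(n_sims):
            rng = np.random.default_rng(500 + rep)
            y = self._simulate(rng, longitudinal_meta, slope_b=0.0)
            fit = assoc.fit_group_time_model(y, longitudinal_meta)
            inside += int(abs(fit["interaction"]["t"]) < crit)
        assert inside >= 0.9 * n_sims

    def test_planted_slope_sign_recovered(self, longitudinal_meta):
        hits = 0
        n_sims = 40
        for rep in range(n_sims):
            rng = np.random.default_rng(900 + rep)
            y = self._simulate(rng, longitudinal_meta, slope_b=0.15)
            fit = assoc.fit_group_time_model(y, longitudinal_meta)
            hits += int(fit["interaction"]["estimate"] > 0)
        assert hits >= 0.95 * n_sims

    def test_single_level_group_rejected(self, longitudinal_meta):
        meta = longitudinal_meta.copy()
        meta["arm"] = "MDCF-2"
        with pytest.raises(InvalidDesignError):
            assoc.fit_group_time_model(
                pd.Series(np.arange(len(meta), dtype=float) % 7, index=meta.index), meta
            )


class TestNbDifferentialExpression:
    def test_planted_fold_change_recovered(self, longitudinal_meta):
        rng = np.random.default_rng(8)
        meta = longitudinal_meta
        g = (meta["arm"] == "RUSF").to_numpy(float)
        n_genes = 600
        lfc = np.zeros(n_genes)
        lfc[:120] = 2.0  # 4-fold, planted in a 20% subset
        base = rng.lognormal(3.0, 1.0, n_genes)
        lam = base[:, None] * np.power(2.0, lfc[:, None] * g[None, :])
        counts = pd.DataFrame(
            rng.poisson(rng.gamma(1 / 0.2, 0.2, lam.shape) * lam),
            index=[f"g{i}" for i in range(n_genes)], columns=meta.index,
        )
        de = assoc.nb_differential_expression(
            counts, meta, norm_factors=assoc.tmm_factors(counts), test="group",
        )
        planted = de.iloc[:120]
        assert 1.5 <= np.median(np.abs(planted["logFC"])) <= 2.5
        assert (planted["q"] < 0.05).mean() > 0.9

    def test_null_pvalues_uniform(self, longitudinal_meta):
        rng = np.random.default_rng(9)
        n_genes = 2000
        base = rng.lognormal(3.0, 1.0, n_genes)
        lam = np.tile(base[:, None], (1, len(longitudinal_meta)))
        counts = pd.DataFrame(
            rng.poisson(rng.gamma(1 / 0.2, 0.2, lam.shape) * lam),
            index=[f"g{i}" for i in range(n_genes)], columns=longitudinal_meta.index,
        )
        de = assoc.nb_differential_expression(counts, longitudinal_meta, test="group")
        assert stats.kstest(de["p"], "uniform").pvalue > 0.01


class TestRankingAndBh:
    @pytest.mark.parametrize(
        "logfc,p,expected",
        [(2.0, 0.001, 3.0), (-1.0, 0.01, -2.0), (5.0, 1.0, 0.0), (-3.0, 1.0, 0.0)],
    )
    def test_metric_values(self, logfc, p, expected):
        assert assoc.ranking_metric([logfc], [p])[0] == pytest.approx(expected)

    def test_zero_p_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            val = assoc.ranking_metric([1.0], [0.0])
        assert val[0] == pytest.approx(300.0)

    def test_ranked_list_strictly_ordered_deterministic_ties(self):
        table = pd.DataFrame({"logFC": [1, 1, -1], "p": [0.1, 0.1, 0.5]},
                             index=["b", "a", "c"])
        ranked = assoc.build_ranked_list(table)
        assert list(ranked.index) == ["a", "b", "c"]

    def test_bh_hand_worked(self):
        assert np.allclose(assoc.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert assoc.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_bh_out_of_range_errors(self):
        with pytest.raises(InvalidInputError):
            assoc.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_bh_dominates_p_and_is_order_invariant(self, pvals):
        p = np.array(pvals)
        q = assoc.bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0 + 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        q_perm = assoc.bh_adjust(p[perm])
        assert np.allclose(q[perm], q_perm)
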