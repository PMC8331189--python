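"""Tests for study-level statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from _oracles import groupby_mean_loop, trimmed_mean_sorted
from mitoquant.stats import (
    MitophagicThreshold,
    PowerParams,
    analytic_power_two_means,
    anova_tukey,
    classify_mitophagic_cells,
    iqr_fence_mean,
    mitophagic_threshold,
    sample_size_two_means,
    stars,
    summarize_by_subject,
    tem_scores,
    truncated_mean,
)


class TestTruncatedMean:
    def test_constant_values(self):
        assert truncated_mean([7.0] * 10, 0.2) == 7.0

    def test_zero_trim_is_mean(self):
        vals = [1.0, 2.0, 4.0, 9.0]
        assert truncated_mean(vals, 0.0) == pytest.approx(np.mean(vals))

    def test_worked_example(self):
        # n=5, trim 0.2 drops one from each end: mean(1, 2, 3) = 2
        assert truncated_mean([0, 1, 2, 3, 100], 0.2) == 2.0

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(1, 40))
            vals = rng.normal(0, 10, n)
            frac = float(rng.uniform(0, 0.49))
            assert truncated_mean(vals, frac) == pytest.approx(
                trimmed_mean_sorted(vals, frac)
            )

    @given(
        vals=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50),
        frac=st.floats(0, 0.49),
    )
    @settings(max_examples=100, deadline=None)
    def test_property_vs_oracle(self, vals, frac):
        assert truncated_mean(vals, frac) == pytest.approx(
            trimmed_mean_sorted(vals, frac)
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            truncated_mean([], 0.2)
        with pytest.raises(ValueError):
            truncated_mean([1.0], 0.5)

    def test_iqr_fence_drops_outlier(self):
        assert iqr_fence_mean([1, 2, 3, 4, 1000]) == pytest.approx(2.5)


class TestMitophagicClassification:
    def test_all_zero_counts(self):
        thr = MitophagicThreshold(value=1.0)
        assert classify_mitophagic_cells([0, 0, 0, 0], thr) == 0.0

    def test_all_above(self):
        thr = MitophagicThreshold(value=1.0)
        assert classify_mitophagic_cells([5, 9, 2], thr) == 100.0

    def test_strictly_above(self):
        thr = MitophagicThreshold(value=3.0)
        # ties go to non-mitophagic
        assert classify_mitophagic_cells([3, 3, 4], thr) == pytest.approx(100 / 3)

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3, 50).astype(float)
        thr = mitophagic_threshold(counts)
        pct = classify_mitophagic_cells(counts, thr)
        scaled_thr = MitophagicThreshold(value=thr.value * 10)
        assert classify_mitophagic_cells(counts * 10, scaled_thr) == pct

    def test_mixture_design_oracle(self):
        """Two-population mixture: recovered percentage tracks the designed
        mixing proportion."""
        design_fraction = 0.30
        n_cells = 200
        recovered = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            # reference condition: pure low-count population
            reference = np.ones(150)
            thr = mitophagic_threshold(reference, trim_fraction=0.2)
            high = rng.uniform(size=n_cells) < design_fraction
            counts = np.where(high, 1 + rng.poisson(10, n_cells), 1.0)
            recovered.append(classify_mitophagic_cells(counts, thr))
        assert abs(np.mean(recovered) - 100 * design_fraction) < 2.0

    def test_outliers_only_removed_for_threshold(self):
        # the outlier cell itself is still classified
        reference = [1, 1, 1, 1, 50]
        thr = mitophagic_threshold(reference, trim_fraction=0.2)
        assert thr.value == 1.0
        pct = classify_mitophagic_cells(reference, thr)
        assert pct == pytest.approx(20.0)


class TestSummarizeBySubject:
    def _records(self, rows):
        return pd.DataFrame(
            rows,
            columns=["subject_id", "genotype", "treatment", "cell_type",
                     "mitolysosomes_per_cell"],
        )

    def test_single_subject_mean(self):
        rec = self._records([
            ("m1", "WT", "none", "all", 2.0),
            ("m1", "WT", "none", "all", 4.0),
        ])
        out = summarize_by_subject(rec, "mitolysosomes_per_cell")
        assert len(out) == 1
        assert out["mean_mitolysosomes_per_cell"].iloc[0] == 3.0
        assert out["n_images"].iloc[0] == 2

    def test_single_image_identity(self):
        rec = self._records([("m1", "WT", "none", "all", 5.5)])
        out = summarize_by_subject(rec, "mitolysosomes_per_cell")
        assert out["mean_mitolysosomes_per_cell"].iloc[0] == 5.5

    def test_missing_subject_id_rejected(self):
        rec = self._records([("", "WT", "none", "all", 1.0)])
        with pytest.raises(ValueError):
            summarize_by_subject(rec, "mitolysosomes_per_cell")

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(17)
        rows = []
        for _ in range(200):
            rows.append((
                f"m{rng.integers(8)}",
                rng.choice(["WT", "KO"]),
                "none",
                "all",
                float(rng.normal()),
            ))
        rec = self._records(rows)
        out = summarize_by_subject(rec, "mitolysosomes_per_cell")
        oracle = groupby_mean_loop(
            rec.to_dict("records"),
            ("subject_id", "genotype", "treatment", "cell_type"),
            "mitolysosomes_per_cell",
        )
        assert len(out) == len(oracle)
        for _, row in out.iterrows():
            key = (row.subject_id, row.genotype, row.treatment, row.cell_type)
            assert row["mean_mitolysosomes_per_cell"] == pytest.approx(oracle[key])


class TestAnovaTukey:
    def _fixture(self, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, mu in (("WT", 3.0), ("G2019S", 1.5), ("KO", 5.0)):
            for s in range(6):
                rows.append({"genotype": g, "y": float(rng.normal(mu, 1.0))})
        return pd.DataFrame(rows)

    def test_identical_groups_f_zero_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        df = pd.DataFrame({
            "genotype": ["WT"] * 5 + ["KO"] * 5,
            "y": vals + vals,
        })
        anova, tukey = anova_tukey(df, "y", ["genotype"])
        f = float(anova.table.loc[anova.table.term == "C(genotype)", "F"].iloc[0])
        assert f == pytest.approx(0.0, abs=1e-10)
        assert tukey.table["p_adj"].iloc[0] == pytest.approx(1.0, abs=1e-8)

    def test_label_invariance(self):
        df = self._fixture()
        renamed = df.replace({"WT": "aaa", "G2019S": "bbb", "KO": "ccc"})
        a1, t1 = anova_tukey(df, "y", ["genotype"])
        a2, t2 = anova_tukey(renamed, "y", ["genotype"])
        assert float(a1.table["F"].iloc[0]) == pytest.approx(
            float(a2.table["F"].iloc[0])
        )
        assert sorted(t1.table["p_adj"]) == pytest.approx(sorted(t2.table["p_adj"]))

    def test_reference_implementation_oracle(self):
        """F, df and Tukey adjusted p match scipy to 1e-8."""
        df = self._fixture(seed=42)
        anova, tukey = anova_tukey(df, "y", ["genotype"])
        groups = [g["y"].to_numpy() for _, g in df.groupby("genotype")]
        f_ref, p_ref = sps.f_oneway(*groups)
        row = anova.table.loc[anova.table.term == "C(genotype)"].iloc[0]
        assert float(row["F"]) == pytest.approx(f_ref, abs=1e-8)
        assert float(row["p"]) == pytest.approx(p_ref, abs=1e-8)
        assert float(row["df"]) == 2.0
        resid = anova.table.loc[anova.table.term == "Residual"].iloc[0]
        assert float(resid["df"]) == 15.0
        hsd = sps.tukey_hsd(*groups)
        names = sorted(df["genotype"].unique())
        ref_p = {}
        for i in range(3):
            for j in range(i + 1, 3):
                ref_p[frozenset((names[i], names[j]))] = hsd.pvalue[i, j]
        for _, row in tukey.table.iterrows():
            key = frozenset((row.group1, row.group2))
            assert row.p_adj == pytest.approx(ref_p[key], abs=1e-8)

    def test_two_way_interaction_terms_present(self):
        rng = np.random.default_rng(3)
        rows = []
        for g in ("WT", "KO"):
            for t in ("vehicle", "inhibitor"):
                n = 5 if (g, t) == ("KO", "inhibitor") else 4  # unbalanced
                for _ in range(n):
                    rows.append({
                        "genotype": g, "treatment": t,
                        "y": float(rng.normal(1 + (g == "KO") * 2, 1)),
                    })
        df = pd.DataFrame(rows)
        anova, tukey = anova_tukey(df, "y", ["genotype", "treatment"])
        terms = set(anova.table["term"])
        assert "C(genotype)" in terms
        assert "C(treatment)" in terms
        assert "C(genotype):C(treatment)" in terms
        assert len(tukey.table) == 6  # 4 cells -> 6 pairs

    def test_empty_cell_reported(self):
        rows = [
            {"genotype": g, "treatment": t, "y": float(i)}
            for i, (g, t) in enumerate([
                ("WT", "vehicle"), ("WT", "vehicle"),
                ("WT", "inhibitor"), ("WT", "inhibitor"),
                ("KO", "vehicle"), ("KO", "vehicle"),
            ])
        ]
        anova, _tukey = anova_tukey(pd.DataFrame(rows), "y",
                                    ["genotype", "treatment"])
        assert any("empty design cell" in w for w in anova.warnings)

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"genotype": ["WT"] * 4, "y": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError):
            anova_tukey(df, "y", ["genotype"])


class TestStars:
    @pytest.mark.parametrize("p,code", [
        (0.2, "ns"), (0.049, "*"), (0.009, "**"),
        (0.0009, "***"), (0.00009, "****"), (0.05, "ns"),
    ])
    def test_star_codes(self, p, code):
        assert stars(p) == code


class TestSampleSize:
    def test_in_paper_worked_example(self):
        p = PowerParams(mu=60.6, sd=19.8, effect_fraction=0.4)
        n_unrounded, n = sample_size_two_means(p)
        assert n == 10
        assert 10 < n_unrounded < 11

    def test_huge_effect_floors_at_one(self):
        p = PowerParams(mu=60.6, sd=19.8, effect_fraction=10.0)
        _, n = sample_size_two_means(p)
        assert n == 1

    def test_half_power_closed_form(self):
        # power 0.5 makes z_power = 0: n = 2 sd^2 z_{1-a/2}^2 / delta^2
        p = PowerParams(mu=10.0, sd=4.0, effect_fraction=0.5, power=0.5)
        n_unrounded, _ = sample_size_two_means(p)
        z = sps.norm.ppf(0.975)
        assert n_unrounded == pytest.approx(2 * 16 * z**2 / 25)

    def test_monotonicities(self):
        base = PowerParams(mu=60.6, sd=19.8, effect_fraction=0.4)
        n_base, _ = sample_size_two_means(base)
        bigger_effect, _ = sample_size_two_means(
            PowerParams(mu=60.6, sd=19.8, effect_fraction=0.6)
        )
        assert bigger_effect < n_base
        more_sd, _ = sample_size_two_means(
            PowerParams(mu=60.6, sd=30.0, effect_fraction=0.4)
        )
        assert more_sd > n_base
        more_power, _ = sample_size_two_means(
            PowerParams(mu=60.6, sd=19.8, effect_fraction=0.4, power=0.9)
        )
        assert more_power > n_base

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            PowerParams(mu=1.0, sd=0.0, effect_fraction=0.4)
        with pytest.raises(ValueError):
            PowerParams(mu=1.0, sd=1.0, effect_fraction=0.4, alpha=1.5)
        with pytest.raises(ValueError):
            sample_size_two_means(
                PowerParams(mu=0.0, sd=1.0, effect_fraction=0.4)
            )


class TestEmpiricalPower:
    def test_simulation_matches_analytic_power(self):
        """Two-group design at n=10: simulated rejection rate tracks the
        analytic power within 10 points."""
        p = PowerParams(mu=60.6, sd=19.8, effect_fraction=0.4)
        _, n = sample_size_two_means(p)
        analytic = analytic_power_two_means(p, n)
        rng = np.random.default_rng(2024)
        n_sims = 500
        rejections = 0
        for _ in range(n_sims):
            a = rng.normal(p.mu, p.sd, n)
            b = rng.normal(p.mu * (1 - p.effect_fraction), p.sd, n)
            _t, pval = sps.ttest_ind(a, b)
            rejections += pval < p.alpha
        assert abs(rejections / n_sims - analytic) < 0.10


class TestTemScores:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["experiment", "arm", "n_with_mito", "n_total"]
        )

    def test_equal_arms_fold_one(self):
        t = self._table([
            ("e1", "control", 3, 10), ("e1", "treated", 6, 20),
        ])
        out = tem_scores(t)
        assert out["fold_vs_control"].tolist() == pytest.approx([1.0, 1.0])

    def test_double_percentage_fold_two(self):
        t = self._table([
            ("e1", "control", 2, 10), ("e1", "treated", 4, 10),
        ])
        out = tem_scores(t)
        treated = out[out.arm == "treated"]["fold_vs_control"].iloc[0]
        assert treated == pytest.approx(2.0)

    def test_zero_control_flagged_missing(self):
        t = self._table([
            ("e1", "control", 0, 10), ("e1", "treated", 4, 10),
        ])
        out = tem_scores(t)
        assert out["fold_vs_control"].isna().all()

    def test_missing_control_arm_rejected(self):
        t = self._table([("e1", "treated", 4, 10)])
        with pytest.raises(ValueError):
            tem_scores(t)

    def test_designed_enrichment_recovered(self):
        """Three simulated experiments with 1.3x designed enrichment."""
        rng = np.random.default_rng(7)
        p_control, enrichment = 0.30, 1.3
        rows = []
        for e in range(3):
            for arm, prob in (("control", p_control),
                              ("treated", p_control * enrichment)):
                for _ in range(80):
                    total = int(rng.integers(1, 5))
                    rows.append((f"e{e}", arm, int(rng.binomial(total, prob)),
                                 total))
        out = tem_scores(self._table(rows))
        folds = out[out.arm == "treated"]["fold_vs_control"]
        assert np.mean(folds) == pytest.approx(enrichment, abs=0.15)
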