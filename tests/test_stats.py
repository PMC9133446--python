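"""Statistical battery: t-tests, noncentral-t power machinery,
equivalence, mixed ANOVA, Wilcoxon, chi-square, Pearson — each checked
against an independent oracle (enumeration, direct formula, cell-means
GLM, bootstrap) where the computation is non-trivial."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vigileeg.stats import (
    PowerSpec,
    chi_square_crosstab,
    cohens_d_ci,
    cohens_d_paired,
    cohens_d_two_sample,
    equivalence_check,
    equivalence_verdict,
    mde_t,
    mixed_anova_2x2,
    paired_t,
    pearson_r,
    power_t,
    t_from_summary,
    two_sample_t,
    wilcoxon_signed_rank,
)

# printed summary rows of the study's paired tests: group, measure,
# (difference mean, difference SD, t, dz), n = 9 pairs
TABLE_ROWS = [
    ("BLT", "A1", -0.069, 0.128, -1.621, -0.540),
    ("BLT", "B23", 0.090, 0.079, 3.430, 1.143),
    ("BLT", "mean_vigilance", -0.489, 0.498, -2.944, -0.981),
    ("TAU", "A1", -0.043, 0.212, -0.602, -0.201),
    ("TAU", "B23", 0.046, 0.298, 0.460, 0.153),
    ("TAU", "mean_vigilance", -0.237, 1.067, -0.667, -0.222),
]


class TestPairedT:
    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            paired_t([0.3, 0.3, 0.3])

    def test_antisymmetric_sample_is_null(self):
        res = paired_t([0.5, -0.5, 1.2, -1.2])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_sign_flip_negates_statistic(self, rng):
        d = rng.normal(0.3, 1.0, size=12)
        assert paired_t(-d).statistic == pytest.approx(-paired_t(d).statistic)

    def test_dz_scale_invariant(self, rng):
        d = rng.normal(0.4, 0.8, size=10)
        assert cohens_d_paired(3.7 * d) == pytest.approx(cohens_d_paired(d))

    @pytest.mark.parametrize("group,measure,mean,sd,t_printed,dz_printed", TABLE_ROWS)
    def test_printed_rows_recovered_within_rounding(
        self, group, measure, mean, sd, t_printed, dz_printed
    ):
        """t and dz recomputed from the printed difference mean/SD (3
        decimals, n=9) bracket the printed statistics."""
        n = 9
        corners_t = []
        corners_dz = []
        for dm in (mean - 5e-4, mean + 5e-4):
            for ds in (sd - 5e-4, sd + 5e-4):
                t, dz = t_from_summary(dm, ds, n)
                corners_t.append(t)
                corners_dz.append(dz)
        assert min(corners_t) - 5e-4 <= t_printed <= max(corners_t) + 5e-4
        assert min(corners_dz) - 5e-4 <= dz_printed <= max(corners_dz) + 5e-4


class TestTwoSampleT:
    def test_identical_groups_are_null(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = two_sample_t(x, x)
        assert res.statistic == pytest.approx(0.0)

    def test_effect_size_matches_direct_formula(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, size=rng.integers(3, 20))
            b = rng.normal(0.5, 1.5, size=rng.integers(3, 20))
            sp = np.sqrt(
                ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1))
                / (len(a) + len(b) - 2)
            )
            assert cohens_d_two_sample(a, b) == pytest.approx(
                (a.mean() - b.mean()) / sp
            )

    def test_printed_baseline_b23_t_from_descriptives(self):
        """Pooled t from the printed pre descriptives (0.435/0.359 n=9 vs
        0.664/0.244 n=10) brackets the printed −1.639."""
        corners = []
        for m1 in (0.4345, 0.4355):
            for s1 in (0.3585, 0.3595):
                for m2 in (0.6635, 0.6645):
                    for s2 in (0.2435, 0.2445):
                        sp = np.sqrt((8 * s1**2 + 9 * s2**2) / 17)
                        corners.append((m1 - m2) / (sp * np.sqrt(1 / 9 + 1 / 10)))
        assert min(corners) - 5e-4 <= -1.639 <= max(corners) + 5e-4


class TestMde:
    def test_monotone_in_design_parameters(self):
        base = mde_t(PowerSpec("paired", n=15))
        assert mde_t(PowerSpec("paired", n=25)) < base
        assert mde_t(PowerSpec("paired", n=15, alpha=0.10)) < base
        assert mde_t(PowerSpec("paired", n=15, power=0.9)) > base

    def test_vanishes_as_power_approaches_alpha(self):
        tiny = mde_t(PowerSpec("paired", n=20, alpha=0.05, power=0.051))
        assert tiny < 0.05

    def test_power_at_mde_hits_target(self):
        spec = PowerSpec("two-sample", n1=9, n2=10)
        d = mde_t(spec)
        assert power_t(spec, d) == pytest.approx(0.8, abs=1e-5)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec("paired", n=1).validate()
        with pytest.raises(ValueError):
            PowerSpec("anova").validate()


class TestEquivalence:
    def test_identical_large_samples_equivalent(self, rng):
        x = rng.normal(0, 1, size=200)
        res = equivalence_check(x, x + rng.normal(0, 1e-3, size=200), sesoi=1.366)
        assert res.extra["equivalent"]

    def test_printed_ci_verdict_not_equivalent(self):
        # the study's mean-vigilance CI reaches beyond the SESOI
        assert not equivalence_verdict((-0.16, 1.72), sesoi=1.366)
        assert equivalence_verdict((-0.16, 1.30), sesoi=1.366)

    def test_verdict_monotone_in_sesoi(self, rng):
        a = rng.normal(0, 1, size=12)
        b = rng.normal(0.3, 1, size=12)
        ci = cohens_d_ci(a, b)
        verdicts = [equivalence_verdict(ci, s) for s in (0.5, 1.0, 2.0, 4.0)]
        # enlarging the SESOI never flips equivalent -> not equivalent
        assert verdicts == sorted(verdicts)

    def test_pivot_ci_matches_bootstrap(self, rng):
        """Noncentral-t pivot CI agrees with a percentile bootstrap within
        0.05 on a fixed moderate-size dataset."""
        a = rng.normal(0.0, 1.0, size=40)
        b = rng.normal(0.4, 1.0, size=40)
        lo, hi = cohens_d_ci(a, b)
        n_boot = 100_000
        ia = rng.integers(0, len(a), size=(n_boot, len(a)))
        ib = rng.integers(0, len(b), size=(n_boot, len(b)))
        ra, rb = a[ia], b[ib]
        va = ra.var(axis=1, ddof=1)
        vb = rb.var(axis=1, ddof=1)
        sp = np.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2))
        ds = (ra.mean(axis=1) - rb.mean(axis=1)) / sp
        blo, bhi = np.quantile(ds, [0.025, 0.975])
        assert lo == pytest.approx(blo, abs=0.05)
        assert hi == pytest.approx(bhi, abs=0.05)


def _cell_means_mixed_anova(data: pd.DataFrame):
    """Classical sums-of-squares oracle for the balanced 2×2 mixed design.

    F(time) and F(time×group) from cell means, with the subject×time
    residual as the within error term.
    """
    wide = data.pivot_table(index=["id", "group"], columns="time", values="value")
    groups = wide.index.get_level_values("group")
    times = ["pre", "post"]
    n_subj = len(wide)
    cell = {
        (g, t): wide.loc[groups == g, t].mean()
        for g in sorted(set(groups))
        for t in times
    }
    time_mean = {t: wide[t].mean() for t in times}
    group_mean = {g: wide.loc[groups == g].to_numpy().mean()
                  for g in sorted(set(groups))}
    grand = wide.to_numpy().mean()

    ss_time = n_subj * sum((time_mean[t] - grand) ** 2 for t in times)
    n_per = {g: (groups == g).sum() for g in sorted(set(groups))}
    ss_int = sum(
        n_per[g] * (cell[(g, t)] - group_mean[g] - time_mean[t] + grand) ** 2
        for g in sorted(set(groups))
        for t in times
    )
    # subject×time residual
    subj_mean = wide.mean(axis=1)
    sse = 0.0
    for (pid, g), row in wide.iterrows():
        for t in times:
            pred = subj_mean[(pid, g)] + cell[(g, t)] - group_mean[g]
            sse += (row[t] - pred) ** 2
    df_err = n_subj - len(set(groups))
    ms_err = sse / df_err
    return ss_time / ms_err, ss_int / ms_err


class TestMixedAnova:
    @staticmethod
    def toy(rng, n_per_group=4, effect=0.0, interaction=0.0):
        rows = []
        for gi, g in enumerate(("BLT", "TAU")):
            for i in range(n_per_group):
                base = rng.normal()
                for ti, t in enumerate(("pre", "post")):
                    val = base + rng.normal(0, 0.5)
                    val += effect * ti + interaction * ti * gi
                    rows.append(
                        {"id": f"{g}{i}", "group": g, "time": t, "value": val}
                    )
        return pd.DataFrame(rows)

    @staticmethod
    def from_wide(wide):
        rows = []
        for (pid, g), row in wide.iterrows():
            for t in ("pre", "post"):
                rows.append({"id": pid, "group": g, "time": t, "value": row[t]})
        return pd.DataFrame(rows)

    def test_no_change_gives_zero_time_effect(self, rng):
        wide = self.toy(rng).pivot_table(
            index=["id", "group"], columns="time", values="value"
        )
        wide["post"] = wide["pre"]
        res = mixed_anova_2x2(self.from_wide(wide), dv="value", subject="id",
                              between="group", within="time")
        assert res["time"].statistic == pytest.approx(0.0, abs=1e-10)

    def test_parallel_shift_gives_zero_interaction(self, rng):
        wide = self.toy(rng).pivot_table(
            index=["id", "group"], columns="time", values="value"
        )
        wide["post"] = wide["pre"] + 1.5  # identical shift in both groups
        res = mixed_anova_2x2(self.from_wide(wide), dv="value", subject="id",
                              between="group", within="time")
        assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-10)

    def test_matches_cell_means_glm_on_balanced_toy(self, rng):
        """F(time) and F(interaction) agree with the classical cell-means
        sums-of-squares computation on a balanced 4-per-group design."""
        data = self.toy(rng, effect=0.8, interaction=0.5)
        res = mixed_anova_2x2(data, dv="value", subject="id",
                              between="group", within="time")
        f_time, f_int = _cell_means_mixed_anova(data)
        assert res["time"].statistic == pytest.approx(f_time, rel=1e-6)
        assert res["interaction"].statistic == pytest.approx(f_int, rel=1e-6)

    def test_missing_timepoint_lists_subject(self, rng):
        data = self.toy(rng).iloc[:-1]
        with pytest.raises(ValueError, match="TAU3"):
            mixed_anova_2x2(data, dv="value", subject="id",
                            between="group", within="time")


class TestWilcoxon:
    def test_symmetric_differences_are_null(self):
        res = wilcoxon_signed_rank([1.0, -1.0, 2.0, -2.0, 3.0, -3.0, 4.0, -4.0])
        assert abs(res.statistic) < 1e-9
        assert res.p_value == pytest.approx(1.0)

    def test_exact_p_matches_sign_enumeration(self, rng):
        """Exact two-tailed p equals full enumeration of the 2^8 sign
        patterns under the null."""
        d = rng.normal(0.5, 1.0, size=8)
        while len(np.unique(np.abs(d))) < 8 or (d == 0).any():
            d = rng.normal(0.5, 1.0, size=8)
        res = wilcoxon_signed_rank(d, method="exact")
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        mu = 8 * 9 / 4
        count = 0
        for signs in itertools.product([0, 1], repeat=8):
            w = sum(r for r, s in zip(ranks, signs) if s)
            if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
                count += 1
        assert res.p_value == pytest.approx(count / 2**8)

    def test_all_positive_differences_minimal_p(self):
        d = np.arange(1, 11, dtype=float)
        res = wilcoxon_signed_rank(d, method="exact")
        assert res.p_value == pytest.approx(2 / 2**10)

    def test_effect_size_r_definition(self, rng):
        d = rng.normal(0.8, 1.0, size=20)
        res = wilcoxon_signed_rank(d, method="approx")
        assert res.effect_size == pytest.approx(abs(res.statistic) / np.sqrt(20))


class TestChiSquare:
    def test_independence_gives_zero(self):
        margins_r = np.array([0.2, 0.3, 0.5])
        margins_c = np.array([0.4, 0.6])
        table = 1000 * np.outer(margins_r, margins_c)
        res = chi_square_crosstab(table)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.df == 2

    def test_perfect_association_w_is_one(self):
        res = chi_square_crosstab([[10, 0], [0, 10]])
        assert res.effect_size == pytest.approx(1.0)

    def test_matches_direct_formula_on_random_tables(self, rng):
        for _ in range(50):
            obs = rng.integers(1, 30, size=(rng.integers(2, 5), rng.integers(2, 4)))
            res = chi_square_crosstab(obs)
            expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            chi2 = ((obs - expected) ** 2 / expected).sum()
            assert res.statistic == pytest.approx(chi2)
            assert res.effect_size == pytest.approx(np.sqrt(chi2 / obs.sum()))


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        assert pearson_r(x, x).statistic == pytest.approx(1.0)

    def test_independent_samples_near_zero(self, rng):
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        assert abs(pearson_r(x, y).statistic) < 0.05

    def test_affine_invariance(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r1 = pearson_r(x, y).statistic
        r2 = pearson_r(3 * x - 7, 0.5 * y + 2).statistic
        assert r2 == pytest.approx(r1)
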