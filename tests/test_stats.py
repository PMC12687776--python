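"""Factorial statistics layer against hand computations and independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from bonescore.errors import ContractError, InestimableDesignError, InputError
from bonescore.stats import (
    AnovaSpec,
    apply_welch_rule,
    bonferroni_adjust,
    bonferroni_contrasts,
    chi_square_gof,
    factorial_anova,
    gate_assumptions,
    groupmean_correlation,
    sidak_adjust,
    sidak_pairwise,
    welch_f,
)


def _table_2x2(cells, factors=("model", "genotype")):
    rows = []
    for (a, b), values in cells.items():
        for v in values:
            rows.append({factors[0]: a, factors[1]: b, "y": float(v)})
    return pd.DataFrame(rows)


def _type3_ss_oracle(table, factors, response="y"):
    """Independent Type III oracle: model comparison on an explicitly built
    sum-to-zero design matrix (full vs. full-minus-term), via lstsq."""
    def codes(levels, val):
        # sum coding: last level = -1 on all columns
        k = len(levels)
        row = np.zeros(k - 1)
        i = levels.index(val)
        if i < k - 1:
            row[i] = 1.0
        else:
            row[:] = -1.0
        return row

    level_sets = {f: sorted(table[f].unique().tolist()) for f in factors}
    blocks, names = [], []
    for order in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, order):
            cols = []
            for _, r in table.iterrows():
                mats = [codes(level_sets[f], r[f]) for f in combo]
                v = mats[0]
                for m in mats[1:]:
                    v = np.outer(v, m).ravel()
                cols.append(v)
            blocks.append(np.array(cols))
            names.append(":".join(combo))
    y = table[response].to_numpy(dtype=float)

    def sse(mat):
        _, res, *_ = np.linalg.lstsq(mat, y, rcond=None)
        fitted = mat @ np.linalg.lstsq(mat, y, rcond=None)[0]
        return float(np.sum((y - fitted) ** 2))

    intercept = np.ones((len(y), 1))
    full = np.hstack([intercept] + blocks)
    out = {}
    for i, name in enumerate(names):
        reduced = np.hstack([intercept] + [b for j, b in enumerate(blocks) if j != i])
        out[name] = sse(reduced) - sse(full)
    out["_residual"] = sse(full)
    return out


class TestFactorialAnova:
    def test_hand_computed_2x2(self):
        """Balanced 2x2, n=2/cell: genotype F = 16 on (1, 4) df."""
        t = _table_2x2({("A", "eup"): (1, 2), ("A", "tri"): (3, 4),
                        ("B", "eup"): (1, 2), ("B", "tri"): (3, 4)})
        res = factorial_anova(t, AnovaSpec("y", ("model", "genotype")))
        row = res.table.set_index("term").loc["genotype"]
        assert row["F"] == pytest.approx(16.0, abs=1e-10)
        assert row["df"] == 1 and res.residual_df == 4
        assert res.table.set_index("term").loc["model", "F"] == pytest.approx(0.0, abs=1e-10)

    def test_equal_cell_means_give_zero_f(self):
        t = _table_2x2({("A", "eup"): (1, 3), ("A", "tri"): (2, 2),
                        ("B", "eup"): (3, 1), ("B", "tri"): (1, 3)})
        res = factorial_anova(t, AnovaSpec("y", ("model", "genotype")))
        assert np.allclose(res.table["F"], 0.0, atol=1e-10)
        assert np.allclose(res.table["p"], 1.0, atol=1e-10)

    def test_type3_matches_contrast_oracle_unbalanced(self, rng):
        """Unbalanced 2x2: Type III SS agree with the cell-means oracle to 1e-8."""
        cells = {("A", "eup"): rng.normal(0, 1, 5), ("A", "tri"): rng.normal(1, 1, 9),
                 ("B", "eup"): rng.normal(0.5, 1, 7), ("B", "tri"): rng.normal(2, 1, 12)}
        t = _table_2x2({k: list(v) for k, v in cells.items()})
        res = factorial_anova(t, AnovaSpec("y", ("model", "genotype")))
        oracle = _type3_ss_oracle(t, ("model", "genotype"))
        got = dict(zip(res.table["term"], res.table["sum_sq"]))
        for term in ("model", "genotype", "model:genotype"):
            assert got[term] == pytest.approx(oracle[term], abs=1e-8)
        assert res.residual_ss == pytest.approx(oracle["_residual"], abs=1e-8)

    def test_three_way_type3_matches_oracle(self, rng):
        factors = ("genotype", "sex", "age")
        rows = []
        for g in ("eup", "tri"):
            for s in ("M", "F"):
                for a in ("6wk", "16wk"):
                    n = rng.integers(3, 7)
                    for v in rng.normal(0, 1, n):
                        rows.append({"genotype": g, "sex": s, "age": a, "y": v})
        t = pd.DataFrame(rows)
        res = factorial_anova(t, AnovaSpec("y", factors))
        oracle = _type3_ss_oracle(t, factors)
        got = dict(zip(res.table["term"], res.table["sum_sq"]))
        for term, ss in oracle.items():
            if term != "_residual":
                assert got[term] == pytest.approx(ss, abs=1e-8)

    def test_empty_cell_named_in_error(self):
        t = _table_2x2({("A", "eup"): (1, 2), ("A", "tri"): (3, 4),
                        ("B", "eup"): (1, 2)})
        with pytest.raises(InestimableDesignError, match="tri"):
            factorial_anova(t, AnovaSpec("y", ("model", "genotype")))


class TestGateAssumptions:
    SPEC = AnovaSpec("y", ("model", "genotype"))

    def _cohort(self, values):
        n = len(values) // 4
        rows = []
        for i, v in enumerate(values):
            rows.append({"model": "AB"[(i // n) % 2], "genotype": "et"[(i // (2 * n)) % 2],
                         "y": v})
        return pd.DataFrame(rows)

    def test_normal_residuals_rarely_flagged(self):
        """Under H0 normality, the gate passes in >= 90% of replicates."""
        rng = np.random.default_rng(11)
        passes = 0
        reps = 200
        for _ in range(reps):
            t = self._cohort(rng.normal(size=48))
            _, rec = gate_assumptions(t, self.SPEC)
            passes += not rec.log_applied and not rec.untransformable
        assert passes >= 0.90 * reps

    def test_skewed_data_triggers_log_transform(self):
        rng = np.random.default_rng(12)
        flagged = 0
        reps = 200
        for _ in range(reps):
            t = self._cohort(rng.lognormal(0.0, 1.0, size=48))
            _, rec = gate_assumptions(t, self.SPEC)
            flagged += rec.log_applied
        assert flagged >= 0.90 * reps

    def test_nonpositive_untransformable(self):
        rng = np.random.default_rng(13)
        vals = np.concatenate([-np.abs(rng.lognormal(0, 1.5, 24)),
                               np.abs(rng.lognormal(0, 1.5, 24))])
        t = self._cohort(vals)
        _, rec = gate_assumptions(t, self.SPEC)
        if rec.shapiro_p < 0.05:
            assert rec.untransformable and not rec.log_applied

    def test_identical_values_give_zero_levene(self):
        t = self._cohort([5.0] * 48)
        _, rec = gate_assumptions(t, self.SPEC)
        assert rec.levene_stat == 0.0


class TestWelch:
    def test_matches_pingouin_oracle(self, rng):
        import pingouin as pg
        values = np.concatenate([rng.normal(0, 1, 8), rng.normal(1, 3, 12),
                                 rng.normal(0.5, 0.5, 10)])
        groups = np.repeat(["a", "b", "c"], [8, 12, 10])
        res = welch_f(values, groups)
        oracle = pg.welch_anova(dv="y", between="g",
                                data=pd.DataFrame({"y": values, "g": groups}))
        assert res.f == pytest.approx(float(oracle["F"].iloc[0]), rel=1e-9)
        assert res.df_den == pytest.approx(float(oracle["ddof2"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(oracle["p_unc"].iloc[0]), rel=1e-9)

    def test_close_to_classical_f_under_equal_variance(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.8, 1, 30)
        res = welch_f(np.concatenate([a, b]), np.repeat(["a", "b"], 30))
        f_classic = sps.f_oneway(a, b).statistic
        assert res.f == pytest.approx(f_classic, rel=0.05)

    def test_type1_error_calibrated_under_unequal_variance(self):
        """Equal means, 10x variance ratio: rejection rate 0.05 +/- 0.03."""
        rng = np.random.default_rng(21)
        rejections = 0
        reps = 500
        for _ in range(reps):
            v = np.concatenate([rng.normal(0, 0.5, 10), rng.normal(0, 5.0, 15)])
            g = np.repeat(["a", "b"], [10, 15])
            rejections += welch_f(v, g).p < 0.05
        assert 0.02 <= rejections / reps <= 0.08

    def test_separated_groups_decisively_rejected(self):
        base = np.linspace(0.0, 1.0, 8)
        v = np.concatenate([base, base + 10.0])
        g = np.repeat(["a", "b"], 8)
        assert welch_f(v, g).p < 1e-6

    def test_zero_variance_group_rejected(self):
        with pytest.raises(InputError, match="zero variance"):
            welch_f(np.array([1.0, 1, 1, 2, 3, 4]), np.repeat(["a", "b"], 3))

    def test_welch_rule(self):
        assert apply_welch_rule(0.01, 0.01)
        assert not apply_welch_rule(0.01, 0.30)   # Welch disagrees: not reported
        assert not apply_welch_rule(0.30, 0.01)


class TestAdjustments:
    def test_sidak_closed_form(self):
        assert sidak_adjust([0.01], m=3)[0] == pytest.approx(0.029701, abs=1e-9)
        assert sidak_adjust([0.5], m=1)[0] == 0.5
        assert sidak_adjust([0.9], m=10)[0] == pytest.approx(1.0, abs=1e-9)

    def test_bonferroni_closed_form(self):
        assert bonferroni_adjust([0.03], m=2)[0] == pytest.approx(0.06)
        assert bonferroni_adjust([0.4], m=5)[0] == 1.0

    @given(p=st.floats(1e-6, 1.0), m=st.integers(1, 50))
    @settings(max_examples=50, deadline=None)
    def test_bonferroni_dominates_sidak_and_raw(self, p, m):
        s = sidak_adjust([p], m=m)[0]
        b = bonferroni_adjust([p], m=m)[0]
        assert p <= s * (1 + 1e-9) + 1e-15
        assert s <= b * (1 + 1e-9) and b <= 1.0

    def test_empty_family_rejected(self):
        with pytest.raises(ContractError):
            sidak_adjust([0.5], m=0)


class TestPairwiseAndContrasts:
    def _fitted(self):
        t = _table_2x2({("A", "eup"): (1.0, 2.0), ("A", "tri"): (5.0, 6.0),
                        ("B", "eup"): (1.5, 2.5), ("B", "tri"): (2.0, 3.0)})
        res = factorial_anova(t, AnovaSpec("y", ("model", "genotype")))
        return t, res

    def test_pairwise_estimates_are_cell_mean_differences(self):
        t, res = self._fitted()
        pw = sidak_pairwise(t, res, compare="genotype", within=("model",))
        est = {r["model"]: r["estimate"] for _, r in pw.iterrows()}
        assert est["A"] == pytest.approx(1.5 - 5.5)
        assert est["B"] == pytest.approx(2.0 - 2.5)
        assert (pw["p_adj"] >= pw["p_raw"] - 1e-15).all()
        assert pw["m"].iloc[0] == 2

    def test_contrast_estimate_equals_cell_difference(self):
        t, res = self._fitted()
        ct = bonferroni_contrasts(t, res, {
            "tri_vs_eup_in_A": {("A", "tri"): 1.0, ("A", "eup"): -1.0},
            "tri_vs_eup_in_B": {("B", "tri"): 1.0, ("B", "eup"): -1.0},
        })
        est = dict(zip(ct["contrast"], ct["estimate"]))
        assert est["tri_vs_eup_in_A"] == pytest.approx(4.0)
        assert est["tri_vs_eup_in_B"] == pytest.approx(0.5)
        assert np.allclose(ct["p_adj"], np.minimum(1.0, 2 * ct["p_raw"]))

    def test_contrast_on_missing_cell_rejected(self):
        t, res = self._fitted()
        with pytest.raises(InestimableDesignError):
            bonferroni_contrasts(t, res, {"bad": {("C", "tri"): 1.0}})


class TestChiSquare:
    def test_closed_form_60_40(self):
        chi2, df, p = chi_square_gof([60, 40], [1, 1])
        assert chi2 == pytest.approx(4.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(sps.chi2.sf(4.0, 1), abs=1e-12)

    def test_perfect_fit(self):
        chi2, df, p = chi_square_gof([25, 25, 25, 25], [1, 1, 1, 1])
        assert chi2 == 0.0 and p == pytest.approx(1.0)
        assert df == 3

    @pytest.mark.parametrize("obs,ratios", [
        ([10, -1], [1, 1]),
        ([10, 10], [1, 0]),
        ([0, 0], [1, 1]),
    ])
    def test_invalid_inputs_rejected(self, obs, ratios):
        with pytest.raises(InputError):
            chi_square_gof(obs, ratios)


class TestGroupMeanCorrelation:
    def test_hand_pearson(self):
        res = groupmean_correlation([1, 2, 3], [1, 3, 2])
        assert res.r == pytest.approx(0.5, abs=1e-12)
        assert res.df == 1

    def test_collinear_means(self):
        res = groupmean_correlation([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r == pytest.approx(1.0)
        assert res.p == 0.0

    def test_sign_flip_antisymmetry(self):
        a = groupmean_correlation([1, 2, 3, 5], [1, 3, 2, 4], ns=[5, 9, 7, 12])
        b = groupmean_correlation([1, 2, 3, 5], [-1, -3, -2, -4], ns=[5, 9, 7, 12])
        assert a.r == pytest.approx(-b.r)
        assert abs(a.t) == pytest.approx(abs(b.t))
        assert a.p == pytest.approx(b.p)

    def test_weights_change_r(self):
        unw = groupmean_correlation([1, 2, 3], [1, 3, 2])
        wt = groupmean_correlation([1, 2, 3], [1, 3, 2], ns=[100, 1, 1])
        assert unw.r != pytest.approx(wt.r)

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError, match="undefined"):
            groupmean_correlation([1, 1, 1], [1, 2, 3])
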