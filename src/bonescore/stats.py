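"""Factorial statistics: assumption gating, Type III ANOVA, Welch fallback,
Sidak pairwise comparisons, Bonferroni contrasts, chi-square goodness of fit
and group-mean correlation.

The analysis plan mirrors common practice for unbalanced factorial cohort
designs: Shapiro-Wilk on model residuals with a natural-log re-test for
non-normal responses, Levene's test (mean-centered) for variance homogeneity,
full-interaction linear models with sum-to-zero coding and Type III
(each-term-last) sums of squares, and a one-way Welch F side-check when both
Levene and a term are significant — a term is only *reported* significant if
Welch agrees. Pairwise genotype comparisons inside significant interactions
use the model residual MS with a Sidak family correction; planned contrasts
use Bonferroni.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import ContractError, InestimableDesignError, InputError

__all__ = [
    "AnovaSpec",
    "AssumptionRecord",
    "FactorialResult",
    "WelchResult",
    "gate_assumptions",
    "factorial_anova",
    "welch_f",
    "welch_reassess",
    "apply_welch_rule",
    "sidak_adjust",
    "bonferroni_adjust",
    "sidak_pairwise",
    "bonferroni_contrasts",
    "chi_square_gof",
    "groupmean_correlation",
]

ALPHA = 0.05


@dataclass(frozen=True)
class AnovaSpec:
    """A between-subjects factorial design on one response."""

    response: str
    factors: tuple
    alpha: float = ALPHA

    def __post_init__(self):
        if not 2 <= len(self.factors) <= 3:
            raise ContractError("factorial designs here have 2 or 3 between factors")


@dataclass
class AssumptionRecord:
    shapiro_p: float
    shapiro_p_after_log: float | None
    log_applied: bool
    untransformable: bool
    levene_stat: float
    levene_p: float

    @property
    def heteroscedastic(self) -> bool:
        return self.levene_p < ALPHA


@dataclass
class WelchResult:
    f: float
    df_num: float
    df_den: float
    p: float


@dataclass
class FactorialResult:
    spec: AnovaSpec
    table: pd.DataFrame                 # term, df, sum_sq, F, p
    residual_df: float
    residual_ss: float
    assumptions: AssumptionRecord | None = None
    welch: dict = field(default_factory=dict)      # term -> WelchResult
    pairwise: pd.DataFrame | None = None
    contrasts: pd.DataFrame | None = None
    model = None                        # fitted statsmodels results (set in fit)

    @property
    def residual_ms(self) -> float:
        return self.residual_ss / self.residual_df

    def p_value(self, term: str) -> float:
        row = self.table[self.table["term"] == term]
        if row.empty:
            raise ContractError(f"no term {term!r} in ANOVA table")
        return float(row["p"].iloc[0])


# ---------------------------------------------------------------------------
# formula plumbing
# ---------------------------------------------------------------------------

def _formula(response: str, factors) -> str:
    terms = " * ".join(f"C(Q('{f}'), Sum)" for f in factors)
    return f"Q('{response}') ~ {terms}"


def _term_name(raw: str, factors) -> str:
    """Map patsy's C(Q('a'), Sum):C(Q('b'), Sum) to a:b."""
    out = raw
    for f in factors:
        out = out.replace(f"C(Q('{f}'), Sum)", f)
    return out


def _check_cells(table: pd.DataFrame, spec: AnovaSpec) -> None:
    levels = [sorted(table[f].dropna().unique().tolist()) for f in spec.factors]
    counts = table.groupby(list(spec.factors), observed=False).size()
    for combo in itertools.product(*levels):
        key = combo if len(combo) > 1 else combo[0]
        n = counts.get(key, 0)
        if n == 0:
            cell = dict(zip(spec.factors, combo))
            raise InestimableDesignError(f"empty factorial cell {cell!r}")


def _fit_ols(table: pd.DataFrame, spec: AnovaSpec):
    return smf.ols(_formula(spec.response, spec.factors), data=table).fit()


# ---------------------------------------------------------------------------
# assumption gating
# ---------------------------------------------------------------------------

def gate_assumptions(
    table: pd.DataFrame,
    spec: AnovaSpec,
    on: str = "residuals",
    alpha: float = ALPHA,
) -> tuple[pd.DataFrame, AssumptionRecord]:
    """Shapiro-Wilk (with natural-log fallback) and Levene's test.

    Normality is assessed on the residuals of the full-interaction model
    (``on="cells"`` switches to per-cell testing, using the smallest cell p).
    If normality fails and all responses are positive, the response is
    replaced by its natural log and re-tested; non-positive responses are
    recorded as untransformable and analysis proceeds on the raw scale.
    Levene's test (center = mean) runs across the full factorial cells on the
    possibly-transformed response and drives the Welch fallback downstream.

    Returns ``(table, record)`` where ``table`` has the (possibly
    transformed) response column.
    """
    values = table[spec.response].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise InputError("response contains non-finite values")

    def _normality_p(t):
        if on == "residuals":
            return float(sps.shapiro(_fit_ols(t, spec).resid).pvalue)
        groups = [g[spec.response].to_numpy(dtype=float)
                  for _, g in t.groupby(list(spec.factors), observed=True)]
        return float(min(sps.shapiro(g).pvalue for g in groups if len(g) >= 3))

    p_raw = _normality_p(table)
    p_log = None
    log_applied = False
    untransformable = False
    out = table
    if p_raw < alpha:
        if np.all(values > 0):
            out = table.copy()
            out[spec.response] = np.log(values)
            p_log = _normality_p(out)
            log_applied = True
        else:
            untransformable = True

    groups = [g[spec.response].to_numpy(dtype=float)
              for _, g in out.groupby(list(spec.factors), observed=True)]
    if all(np.ptp(g) == 0 for g in groups):
        lev_stat, lev_p = 0.0, 1.0      # zero spread everywhere
    else:
        lev_stat, lev_p = sps.levene(*groups, center="mean")
    record = AssumptionRecord(
        shapiro_p=p_raw, shapiro_p_after_log=p_log, log_applied=log_applied,
        untransformable=untransformable,
        levene_stat=float(lev_stat), levene_p=float(lev_p))
    return out, record


# ---------------------------------------------------------------------------
# Type III factorial ANOVA
# ---------------------------------------------------------------------------

def factorial_anova(
    table: pd.DataFrame,
    spec: AnovaSpec,
    gate: bool = False,
) -> FactorialResult:
    """Full-interaction linear model, sum-to-zero coding, Type III SS.

    Type III (each-term-last) sums of squares are marginal to all other
    terms, which is what makes unequal cell sizes comparable; on balanced
    designs they coincide with sequential (Type I) SS. F statistics test each
    term against the residual mean square.
    """
    for col in (spec.response, *spec.factors):
        if col not in table.columns:
            raise ContractError(f"column {col!r} not in table")
    table = table.dropna(subset=[spec.response]).copy()
    if len(table) == 0:
        raise InputError("no non-missing responses")
    _check_cells(table, spec)
    assumptions = None
    if gate:
        table, assumptions = gate_assumptions(table, spec)
    fit = _fit_ols(table, spec)
    aov = anova_lm(fit, typ=3)
    rows = []
    for raw, r in aov.iterrows():
        if raw in ("Intercept", "Residual"):
            continue
        rows.append({
            "term": _term_name(raw, spec.factors),
            "df": float(r["df"]),
            "sum_sq": float(r["sum_sq"]),
            "F": float(r["F"]),
            "p": float(r["PR(>F)"]),
        })
    resid = aov.loc["Residual"]
    result = FactorialResult(
        spec=spec,
        table=pd.DataFrame(rows),
        residual_df=float(resid["df"]),
        residual_ss=float(resid["sum_sq"]),
        assumptions=assumptions,
    )
    result.model = fit
    if gate and assumptions is not None and assumptions.heteroscedastic:
        for f in spec.factors:
            if result.p_value(f) < spec.alpha:
                vals = table[spec.response].to_numpy(dtype=float)
                result.welch[f] = welch_f(vals, table[f].to_numpy())
    return result


# ---------------------------------------------------------------------------
# Welch's heteroscedastic one-way F
# ---------------------------------------------------------------------------

def welch_f(values, groups) -> WelchResult:
    """Welch's one-way F across a factor's marginal groups.

    Weights each group by n/s^2 and uses Satterthwaite denominator degrees of
    freedom; appropriate when Levene's test rejects variance homogeneity.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise InputError("Welch's F needs at least 2 groups")
    ns, means, variances = [], [], []
    for lv in levels:
        g = values[groups == lv]
        if g.size < 2:
            raise InputError(f"group {lv!r} has n < 2")
        v = g.var(ddof=1)
        if v == 0:
            raise InputError(f"group {lv!r} has zero variance")
        ns.append(g.size)
        means.append(g.mean())
        variances.append(v)
    n = np.array(ns, dtype=float)
    m = np.array(means)
    v = np.array(variances)
    k = len(levels)
    w = n / v
    sw = w.sum()
    grand = (w * m).sum() / sw
    num = ((w * (m - grand) ** 2).sum()) / (k - 1)
    h = ((1 - w / sw) ** 2 / (n - 1)).sum()
    den = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * h
    f = num / den
    df2 = (k**2 - 1) / (3.0 * h)
    p = float(sps.f.sf(f, k - 1, df2))
    return WelchResult(f=float(f), df_num=float(k - 1), df_den=float(df2), p=p)


def welch_reassess(values, groups) -> WelchResult:
    """Alias for :func:`welch_f`, named for its role as the re-assessment step."""
    return welch_f(values, groups)


def apply_welch_rule(anova_p: float, welch_p: float, alpha: float = ALPHA) -> bool:
    """Final significance call: the ANOVA term stands only if Welch agrees."""
    return anova_p < alpha and welch_p < alpha


# ---------------------------------------------------------------------------
# multiplicity corrections
# ---------------------------------------------------------------------------

def sidak_adjust(p_raw, m: int | None = None) -> np.ndarray:
    """Sidak familywise adjustment: ``p_adj = 1 - (1 - p)^m``, capped at 1."""
    p = np.atleast_1d(np.asarray(p_raw, dtype=float))
    m = len(p) if m is None else int(m)
    if m < 1:
        raise ContractError("comparison family must have m >= 1")
    return np.minimum(1.0, 1.0 - (1.0 - p) ** m)


def bonferroni_adjust(p_raw, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``p_adj = min(1, m * p)``."""
    p = np.atleast_1d(np.asarray(p_raw, dtype=float))
    m = len(p) if m is None else int(m)
    if m < 1:
        raise ContractError("comparison family must have m >= 1")
    return np.minimum(1.0, m * p)


def _cell_stats(table: pd.DataFrame, response: str, factors) -> pd.DataFrame:
    g = table.groupby(list(factors), observed=True)[response]
    out = g.agg(["mean", "count"]).reset_index()
    return out


def sidak_pairwise(
    table: pd.DataFrame,
    result: FactorialResult,
    compare: str,
    within: tuple = (),
) -> pd.DataFrame:
    """Pairwise comparisons of ``compare`` levels inside each ``within`` slice.

    Used after a significant interaction: e.g. genotype comparisons within
    each sex x age cell. Each comparison is a t test on cell means using the
    full model's residual MS and the two cell ns; the family for the Sidak
    correction is every comparison actually performed across the slices.
    """
    spec = result.spec
    if compare not in spec.factors:
        raise ContractError(f"{compare!r} is not a design factor")
    for w in within:
        if w not in spec.factors or w == compare:
            raise ContractError(f"invalid slicing factor {w!r}")
    cells = _cell_stats(table.dropna(subset=[spec.response]), spec.response, spec.factors)
    mse, df = result.residual_ms, result.residual_df
    slices = (cells.groupby(list(within), observed=True) if within
              else [((), cells)])
    rows = []
    for key, sub in slices:
        key = key if isinstance(key, tuple) else (key,)
        g = sub.groupby(compare, observed=True)
        # n-weighted collapse over any non-slice factors remaining in the cell table
        means = g.apply(lambda gg: np.average(gg["mean"], weights=gg["count"]),
                        include_groups=False)
        ns = g["count"].sum()
        for a, b_ in itertools.combinations(list(means.index), 2):
            m1, n1 = means[a], ns[a]
            m2, n2 = means[b_], ns[b_]
            se = np.sqrt(mse * (1.0 / n1 + 1.0 / n2))
            t = (m1 - m2) / se
            p = 2.0 * float(sps.t.sf(abs(t), df))
            rows.append({**dict(zip(within, key)), "comparison": f"{a} - {b_}",
                         "estimate": m1 - m2, "se": se, "t": t, "df": df, "p_raw": p})
    if not rows:
        raise ContractError("comparison family is empty")
    out = pd.DataFrame(rows)
    out["m"] = len(out)
    out["p_adj"] = sidak_adjust(out["p_raw"].to_numpy(), m=len(out))
    return out


def bonferroni_contrasts(
    table: pd.DataFrame,
    result: FactorialResult,
    contrasts: dict,
) -> pd.DataFrame:
    """Planned cell-mean contrasts with Bonferroni correction.

    ``contrasts`` maps a contrast name to ``{cell_tuple: weight}`` where the
    cell tuple holds factor levels in design order. Estimate = sum of
    weighted cell means; SE uses the model residual MS and cell ns.
    """
    if not contrasts:
        raise ContractError("contrast set is empty")
    spec = result.spec
    cells = _cell_stats(table.dropna(subset=[spec.response]), spec.response, spec.factors)
    cells = cells.set_index(list(spec.factors))
    mse, df = result.residual_ms, result.residual_df
    rows = []
    for name, weights in contrasts.items():
        est, var = 0.0, 0.0
        for cell, w in weights.items():
            cell = cell if isinstance(cell, tuple) else (cell,)
            key = cell if len(cell) > 1 else cell[0]
            try:
                m = float(cells.loc[key, "mean"])
                n = float(cells.loc[key, "count"])
            except KeyError:
                raise InestimableDesignError(
                    f"contrast {name!r} references empty cell {cell!r}") from None
            est += w * m
            var += w * w * mse / n
        se = np.sqrt(var)
        t = est / se
        p = 2.0 * float(sps.t.sf(abs(t), df))
        rows.append({"contrast": name, "estimate": est, "se": se,
                     "t": t, "df": df, "p_raw": p})
    out = pd.DataFrame(rows)
    out["m"] = len(out)
    out["p_adj"] = bonferroni_adjust(out["p_raw"].to_numpy(), m=len(out))
    return out


# ---------------------------------------------------------------------------
# chi-square goodness of fit and group-mean correlation
# ---------------------------------------------------------------------------

def chi_square_gof(observed, expected_ratios):
    """Chi-square goodness of fit of observed counts against expected ratios.

    Used for transmission-ratio tests (observed genotype counts vs the
    expected Mendelian ratio). Returns ``(chi2, df, p)``.
    """
    obs = np.asarray(observed, dtype=float)
    ratios = np.asarray(expected_ratios, dtype=float)
    if obs.shape != ratios.shape or obs.ndim != 1:
        raise InputError("observed and expected ratios must be 1-D and equal length")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise InputError("observed counts must be non-negative integers")
    if np.any(ratios <= 0):
        raise InputError("expected ratios must be positive")
    total = obs.sum()
    if total == 0:
        raise InputError("total observed count is zero")
    expected = ratios / ratios.sum() * total
    chi2, p = sps.chisquare(obs, f_exp=expected)
    return float(chi2), int(obs.size - 1), float(p)


@dataclass
class CorrelationResult:
    r: float
    t: float
    df: int
    p: float


def groupmean_correlation(x, y, ns=None) -> CorrelationResult:
    """Pearson correlation over group means, optionally weighted by group n.

    Significance uses the two-tailed t distribution with k - 2 degrees of
    freedom, k = number of groups (the group, not the animal, is the unit).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    k = x.size
    if y.size != k or k < 3:
        raise InputError("need >= 3 groups with matching x and y means")
    w = np.ones(k) if ns is None else np.asarray(ns, dtype=float)
    if np.any(w <= 0):
        raise InputError("group sizes must be positive")
    w = w / w.sum()
    mx, my = (w * x).sum(), (w * y).sum()
    cov = (w * (x - mx) * (y - my)).sum()
    vx = (w * (x - mx) ** 2).sum()
    vy = (w * (y - my) ** 2).sum()
    if vx == 0 or vy == 0:
        raise InputError("zero variance in group means: correlation undefined")
    r = cov / np.sqrt(vx * vy)
    r = float(np.clip(r, -1.0, 1.0))
    df = k - 2
    if abs(r) == 1.0:
        return CorrelationResult(r=r, t=np.inf if r > 0 else -np.inf, df=df, p=0.0)
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return CorrelationResult(r=r, t=float(t), df=df, p=p)
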