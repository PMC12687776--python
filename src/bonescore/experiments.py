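"""Replicated simulation experiments over the full analysis pipeline.

Each experiment runs simulate -> standardize -> composite -> test over many
seeded replicate cohorts and reports an operating characteristic of the
method: the type-I error of the genotype test under null effects, the
probability of recovering the expected PC1 sign structure, and the power
advantage of the composite score over the best Sidak-corrected univariate
test for a diffuse subclinical deficit.

Replicate seeds are spawned from the top-level seed via
:class:`numpy.random.SeedSequence`, so one integer reproduces the whole
experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .cohort import CohortConfig, EffectTerm, default_config, generate_cohort
from .composite import PC1CompositeScorer
from .standardize import standardize_within_model
from .stats import AnovaSpec, factorial_anova, sidak_adjust
from .variables import TRABECULAR, TRABECULAR_VARIABLES

__all__ = [
    "null_genotype_rejection_rate",
    "model_effect_ss_balanced",
    "sign_pattern_rate",
    "subclinical_power",
    "PowerComparison",
]

_TRAB = list(TRABECULAR_VARIABLES)


def _replicate_seeds(seed: int, n: int) -> list:
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def _two_model_config(n_per_group, effects) -> CohortConfig:
    return default_config(
        n_per_group=n_per_group,
        factors={"model": ("Ts65Dn", "Ts66Yah"),
                 "genotype": ("euploid", "trisomic")},
        effects=effects,
        compartments=(TRABECULAR,),
    )


def _composite_scores(table, group_cols=("model",)):
    z, _ = standardize_within_model(table, variables=_TRAB, stratify_by=group_cols)
    scorer = PC1CompositeScorer(variables=_TRAB, anchor="BVTV").fit(z)
    return z, scorer, scorer.transform(z)[:, 0]


def null_genotype_rejection_rate(n_reps: int = 1000, n_per_group: int = 10,
                                 seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I error of the genotype main effect on composite scores.

    Simulates two-model, two-genotype trabecular cohorts with *zero* effects,
    runs the full pipeline (within-model standardization, pooled PC1
    composite, model x genotype Type III ANOVA) and counts how often the
    genotype term is significant at ``alpha``. Under a correct pipeline this
    converges to ``alpha``.
    """
    spec = AnovaSpec(response="score", factors=("model", "genotype"))
    rejections = 0
    for s in _replicate_seeds(seed, n_reps):
        cfg = _two_model_config(n_per_group, effects=[])
        table = generate_cohort(cfg, seed=s)
        z, _, scores = _composite_scores(table)
        z = z.assign(score=scores)
        res = factorial_anova(z, spec)
        if res.p_value("genotype") < alpha:
            rejections += 1
    return {"rate": rejections / n_reps, "rejections": rejections, "n_reps": n_reps}


def model_effect_ss_balanced(seed: int = 0, n_per_group: int = 12) -> float:
    """Mouse-model main-effect sum of squares on composite scores, balanced design.

    Standardization forces each model's pooled z-mean (hence composite mean)
    to zero, so with balanced cells the between-model Type III SS is exactly
    zero — the mechanism behind null model effects after harmonization.
    """
    cfg = _two_model_config(n_per_group, effects=[
        EffectTerm({"genotype": "trisomic"},
                   {"BMD": -0.6, "BVTV": -0.8, "Tb.Th": -0.4, "Tb.Sp": 0.7,
                    "Tb.N": -0.8})])
    table = generate_cohort(cfg, seed=seed)
    z, _, scores = _composite_scores(table)
    z = z.assign(score=scores)
    res = factorial_anova(z, AnovaSpec(response="score", factors=("model", "genotype")))
    row = res.table[res.table["term"] == "model"]
    return float(row["sum_sq"].iloc[0])


def sign_pattern_rate(n_reps: int = 200, n_per_group: int = 12, seed: int = 0) -> dict:
    """How often oriented PC1 recovers the expected trabecular sign structure.

    On cohorts whose Tb.Sp is anticorrelated with the other four trabecular
    variables, the oriented first component (anchor BV/TV positive) should
    load positively on BMD, BV/TV, Tb.Th and Tb.N and negatively on Tb.Sp.
    """
    hits = 0
    for s in _replicate_seeds(seed, n_reps):
        cfg = _two_model_config(n_per_group, effects=[])
        table = generate_cohort(cfg, seed=s)
        _, scorer, _ = _composite_scores(table)
        load = dict(zip(scorer.variables_, scorer.loadings_))
        ok = (load["Tb.Sp"] < 0 and all(load[v] > 0 for v in
                                        ("BMD", "BVTV", "Tb.Th", "Tb.N")))
        hits += bool(ok)
    return {"rate": hits / n_reps, "hits": hits, "n_reps": n_reps}


@dataclass
class PowerComparison:
    composite_power: float
    best_univariate_power: float
    n_reps: int

    @property
    def advantage(self) -> float:
        return self.composite_power - self.best_univariate_power


def subclinical_power(n_reps: int = 500, n_per_group: int = 12,
                      deficit_sd: float = 0.4, seed: int = 0,
                      alpha: float = 0.05) -> PowerComparison:
    """Composite vs best Sidak-corrected univariate test under a diffuse deficit.

    Each replicate simulates one model with euploid and trisomic groups of
    ``n_per_group`` where every trabecular variable is shifted by
    ``deficit_sd`` SD in its deficit direction (down for BMD/BV/TV/Tb.Th/Tb.N,
    up for Tb.Sp). The composite test is a two-sample t test on PC1 composite
    scores; the univariate competitor tests each of the five variables and
    takes the best Sidak-adjusted p. Powers are rejection rates at ``alpha``.
    """
    shift = {v: -deficit_sd for v in _TRAB}
    shift["Tb.Sp"] = deficit_sd
    comp_hits = uni_hits = 0
    for s in _replicate_seeds(seed, n_reps):
        cfg = default_config(
            n_per_group=n_per_group,
            factors={"genotype": ("euploid", "trisomic")},
            effects=[EffectTerm({"genotype": "trisomic"}, shift)],
            compartments=(TRABECULAR,),
        )
        table = generate_cohort(cfg, seed=s)
        table["model"] = "Ts66Yah"
        _, _, scores = _composite_scores(table)
        eup = table["genotype"] == "euploid"
        _, p_comp = sps.ttest_ind(scores[eup.to_numpy()], scores[~eup.to_numpy()])
        comp_hits += p_comp < alpha
        p_raw = np.array([
            sps.ttest_ind(table.loc[eup, v], table.loc[~eup, v]).pvalue
            for v in _TRAB])
        uni_hits += sidak_adjust(p_raw, m=len(p_raw)).min() < alpha
    return PowerComparison(composite_power=comp_hits / n_reps,
                           best_univariate_power=uni_hits / n_reps,
                           n_reps=n_reps)
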