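"""End-to-end orchestration: simulate/ingest -> validate -> standardize ->
composite -> stats -> report, with a reproducible run manifest.

The run configuration is declarative (YAML/JSON mapping); unknown keys are
errors. One top-level seed drives all randomness. All intermediate tables are
persisted as CSV in the output directory, and the manifest records the config
hash, seed, input digests and per-stage row counts so a rerun with the same
inputs reproduces byte-identical score and stats CSVs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import CohortConfig, generate_cohort
from .composite import PC1CompositeScorer
from .errors import ConfigurationError, InestimableDesignError
from .standardize import standardize_within_model, validate_panels
from .stats import AnovaSpec, apply_welch_rule, factorial_anova, sidak_pairwise
from .variables import COMPARTMENT_VARIABLES, DEFAULT_ANCHORS, ID_COLUMN

__all__ = ["run_pipeline", "render_report"]

_KNOWN_KEYS = {"cohort", "compartments", "stratify", "design", "anchors",
               "standardize_by", "exclude_variables", "gate_assumptions"}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_cohort(cohort_cfg: dict, seed: int):
    source = cohort_cfg.get("source", "synthetic")
    if source == "synthetic":
        cfg = CohortConfig.from_dict(cohort_cfg.get("config", {"factors": {
            "model": ["Ts65Dn", "Ts66Yah"], "genotype": ["euploid", "trisomic"],
            "sex": ["M", "F"]}}))
        return generate_cohort(cfg, seed=seed), None
    if source == "csv":
        path = Path(cohort_cfg["path"])
        return pd.read_csv(path), path
    raise ConfigurationError(f"unknown cohort source {source!r}")


def run_pipeline(config: dict, seed: int, outdir) -> Path:
    """Execute all stages; returns the output directory.

    Raises with the stage name and offending identifiers on schema
    mismatches, degenerate strata or inestimable designs.
    """
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": _config_hash(config), "seed": int(seed),
                "version": __version__, "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
                "stages": [], "input_digests": {}}
    exclusion_log = []

    # --- stage 1: cohort -------------------------------------------------
    table, src_path = _load_cohort(config.get("cohort", {}), seed)
    if src_path is not None:
        manifest["input_digests"][str(src_path)] = _file_digest(src_path)
    table.to_csv(outdir / "cohort.csv", index=False)
    manifest["stages"].append({"stage": "cohort", "rows": len(table)})

    # --- stage 2: validation ---------------------------------------------
    exclude_vars = set(config.get("exclude_variables", []))
    compartments = config.get("compartments", ["trabecular", "cortical"])
    compartments = [c for c in compartments
                    if any(v in table.columns for v in COMPARTMENT_VARIABLES[c])]
    report = validate_panels(table)
    for _, r in report.exclusions.iterrows():
        exclusion_log.append({ID_COLUMN: r[ID_COLUMN], "stage": "validate",
                              "reason": r["reason"]})
    clean = report.clean
    manifest["stages"].append({"stage": "validate", "rows": len(clean),
                               "excluded": int(report.n_excluded)})

    # --- stages 3-5 per compartment ---------------------------------------
    stratify = [c for c in config.get("stratify", []) if c in clean.columns]
    standardize_by = [c for c in config.get("standardize_by", ["model", "sex", "age"])
                      if c in clean.columns]
    anchors = {**DEFAULT_ANCHORS, **config.get("anchors", {})}
    design = config.get("design", {})
    design_factors = tuple(design.get("factors", ("model", "genotype")))
    pairwise_factor = design.get("pairwise")
    gate = bool(config.get("gate_assumptions", False))

    all_scores, all_loadings, all_stats, all_pairwise, provenances = [], [], [], [], []
    for compartment in compartments:
        variables = [v for v in COMPARTMENT_VARIABLES[compartment]
                     if v in clean.columns and v not in exclude_vars]
        complete = clean.dropna(subset=variables)
        for aid in sorted(set(clean[ID_COLUMN]) - set(complete[ID_COLUMN])):
            exclusion_log.append({ID_COLUMN: aid, "stage": f"standardize/{compartment}",
                                  "reason": f"missing {compartment} variable(s)"})
        z, prov = standardize_within_model(complete, variables=variables,
                                           stratify_by=standardize_by)
        prov.insert(0, "compartment", compartment)
        provenances.append(prov)

        strata = ([(None, z)] if not stratify
                  else [(k if isinstance(k, tuple) else (k,), g)
                        for k, g in z.groupby(stratify, observed=True)])
        for key, sub in strata:
            label = dict(zip(stratify, key)) if key else {}
            scorer = PC1CompositeScorer(variables=variables,
                                        anchor=anchors.get(compartment)).fit(sub)
            lt = scorer.loadings_table()
            lt.insert(0, "compartment", compartment)
            lt.insert(1, "anchor", scorer.anchor_)
            for c, v in label.items():
                lt.insert(1, c, v)
            all_loadings.append(lt)

            scored = sub.copy()
            scored["score"] = scorer.transform(sub)[:, 0]
            keep = [ID_COLUMN, *[c for c in clean.columns
                                 if c in ("model", "genotype", "sex", "age",
                                          "dyrk1a_copies", "treatment")], "score"]
            st = scored[[c for c in keep if c in scored.columns]].copy()
            st.insert(1, "compartment", compartment)
            all_scores.append(st)

            # --- stats on composite scores ---
            missing = [f for f in design_factors if f not in scored.columns]
            if missing:
                raise ConfigurationError(
                    f"design factor(s) {missing!r} absent from cohort (stats stage)")
            spec = AnovaSpec(response="score", factors=design_factors)
            res = factorial_anova(scored, spec, gate=gate)
            tab = res.table.copy()
            tab.insert(0, "compartment", compartment)
            for c, v in label.items():
                tab.insert(1, c, v)
            if res.welch:
                tab["welch_p"] = [res.welch[t].p if t in res.welch else float("nan")
                                  for t in tab["term"]]
                tab["reported_significant"] = [
                    apply_welch_rule(p, res.welch[t].p) if t in res.welch else p < spec.alpha
                    for t, p in zip(tab["term"], tab["p"])]
            all_stats.append(tab)
            if pairwise_factor and len(design_factors) >= 2:
                interaction = ":".join(design_factors)
                if res.p_value(interaction) < spec.alpha:
                    within = tuple(f for f in design_factors if f != pairwise_factor)
                    pw = sidak_pairwise(scored, res, compare=pairwise_factor,
                                        within=within)
                    pw.insert(0, "compartment", compartment)
                    for c, v in label.items():
                        pw.insert(1, c, v)
                    all_pairwise.append(pw)

    pd.concat(provenances).to_csv(outdir / "standardization_provenance.csv", index=False)
    pd.concat(all_loadings).to_csv(outdir / "loadings.csv", index=False)
    scores = pd.concat(all_scores)
    scores.to_csv(outdir / "scores.csv", index=False)
    pd.concat(all_stats).to_csv(outdir / "stats.csv", index=False)
    if all_pairwise:
        pd.concat(all_pairwise).to_csv(outdir / "pairwise.csv", index=False)
    pd.DataFrame(exclusion_log, columns=[ID_COLUMN, "stage", "reason"]).to_csv(
        outdir / "exclusions.csv", index=False)
    manifest["stages"].append({"stage": "composite", "rows": len(scores)})
    manifest["stages"].append({"stage": "stats",
                               "rows": sum(len(t) for t in all_stats)})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    render_report(outdir)
    return outdir


def render_report(outdir) -> Path:
    """Human-readable text summary assembled from the persisted CSVs."""
    outdir = Path(outdir)
    for name in ("loadings.csv", "stats.csv", "scores.csv"):
        if not (outdir / name).exists():
            raise ConfigurationError(f"missing pipeline output {name}")
    loadings = pd.read_csv(outdir / "loadings.csv")
    stats = pd.read_csv(outdir / "stats.csv")
    lines = ["Composite-score skeletal phenotyping report", "=" * 44, ""]
    group_cols = [c for c in loadings.columns
                  if c not in ("variable", "loading", "pc1_variance_explained")]
    for key, sub in loadings.groupby([c for c in group_cols if c != "anchor"],
                                     dropna=False):
        lines.append(f"PCA stratum {dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))}")
        lines.append(f"  anchor: {sub['anchor'].iloc[0]}   "
                     f"PC1 variance explained: {100 * sub['pc1_variance_explained'].iloc[0]:.2f}%")
        for _, r in sub.iterrows():
            lines.append(f"    {r['variable']:<12} loading {r['loading']:+.4f}")
        lines.append("")
    lines.append("Factorial ANOVA (Type III) on composite scores")
    lines.append(stats.to_string(index=False))
    lines.append("")
    if (outdir / "pairwise.csv").exists():
        lines.append("Sidak pairwise comparisons (significant interactions)")
        lines.append(pd.read_csv(outdir / "pairwise.csv").to_string(index=False))
        lines.append("")
    excl = pd.read_csv(outdir / "exclusions.csv")
    lines.append(f"Exclusions: {len(excl)}")
    if len(excl):
        lines.append(excl.to_string(index=False))
    path = outdir / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
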