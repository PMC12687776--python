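"""Synthetic cohorts, bend curves and cross-section masks.

This module generates data with the statistical structure the downstream
analysis assumes, at configurable size and noise:

* :func:`generate_cohort` draws per-animal bone-variable panels from a
  multivariate normal whose mean is a model-specific baseline plus additive
  factorial effects expressed in within-model SD units, and whose correlation
  structure makes Tb.Sp run opposite to the other trabecular variables.
* :func:`generate_bend_curve` builds piecewise-linear three-point-bend
  force-displacement traces with known ground truth for every mechanical
  property the analysis extracts.
* :func:`generate_annulus_mask` rasterizes circular/offset annuli with known
  closed-form areas, perimeters and second moments of area.

All randomness flows through :func:`numpy.random.default_rng` (PCG64); the
seed is part of the configuration, and identical configuration + seed give
identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .geometry import CrossSectionMask
from .mechanics import ForceDisplacementCurve
from .variables import (
    COMPARTMENT_VARIABLES,
    CORTICAL,
    CORTICAL_VARIABLES,
    FACTOR_LEVELS,
    TRABECULAR,
    TRABECULAR_VARIABLES,
)

__all__ = [
    "EffectTerm",
    "CohortConfig",
    "default_config",
    "factor_model_correlation",
    "generate_cohort",
    "generate_bend_curve",
    "generate_annulus_mask",
]


def factor_model_correlation(loadings) -> np.ndarray:
    """Correlation matrix of a single-factor model, ``R = ll' + diag(1 - l^2)``.

    Guaranteed symmetric positive-definite for |loading| < 1, with unit
    diagonal; the sign pattern of ``loadings`` sets the sign pattern of the
    pairwise correlations.
    """
    lam = np.asarray(loadings, dtype=float)
    if np.any(np.abs(lam) >= 1.0):
        raise ConfigurationError("factor loadings must have absolute value < 1")
    r = np.outer(lam, lam)
    np.fill_diagonal(r, 1.0)
    return r


# Default single-factor correlation structures. The study data do not report
# correlation magnitudes, so these are assumptions chosen to place PC1
# variance-explained in the regime seen for real trabecular (~85-90%) and
# cortical (~60-70%) panels; Tb.Sp loads negatively.
_TRAB_FACTOR_LOADINGS = (0.93, 0.97, 0.88, -0.93, 0.95)
_CORT_FACTOR_LOADINGS = (0.92, 0.85, 0.88, 0.35, 0.45, 0.90, 0.85, 0.88, 0.86, 0.15)

# Plausible murine femur baselines (means, SDs) per mouse model; the small
# between-model offsets emulate background-strain differences that the
# within-model standardization is designed to remove.
_BASELINES = {
    "Ts65Dn": {
        "BMD": (0.100, 0.018), "BVTV": (12.0, 3.0), "Tb.Th": (0.045, 0.006),
        "Tb.Sp": (0.30, 0.05), "Tb.N": (2.6, 0.5),
        "Tt.Ar": (1.80, 0.20), "Ma.Ar": (0.95, 0.14), "Ct.Ar": (0.85, 0.10),
        "Ct.Ar_Tt.Ar": (47.0, 3.5), "Ct.Th": (0.175, 0.02), "Ps.Pm": (5.3, 0.35),
        "Ec.Pm": (3.8, 0.30), "Imax": (0.33, 0.07), "Imin": (0.16, 0.035),
        "Ct.TMD": (1.10, 0.05),
    },
    "Ts66Yah": {
        "BMD": (0.112, 0.016), "BVTV": (13.5, 2.8), "Tb.Th": (0.047, 0.006),
        "Tb.Sp": (0.28, 0.045), "Tb.N": (2.9, 0.5),
        "Tt.Ar": (1.92, 0.21), "Ma.Ar": (1.02, 0.15), "Ct.Ar": (0.90, 0.11),
        "Ct.Ar_Tt.Ar": (46.5, 3.5), "Ct.Th": (0.180, 0.02), "Ps.Pm": (5.5, 0.36),
        "Ec.Pm": (3.9, 0.31), "Imax": (0.37, 0.08), "Imin": (0.18, 0.04),
        "Ct.TMD": (1.13, 0.05),
    },
}

# Default trisomic deficit, in within-model SD units per variable. Deficit
# direction: less bone, thinner/ fewer trabeculae, larger separation, smaller
# cortical section.
_DEFAULT_TRISOMIC_SHIFT = {
    "BMD": -0.6, "BVTV": -0.8, "Tb.Th": -0.4, "Tb.Sp": 0.7, "Tb.N": -0.8,
    "Tt.Ar": -0.6, "Ma.Ar": -0.3, "Ct.Ar": -0.6, "Ct.Ar_Tt.Ar": -0.2,
    "Ct.Th": -0.3, "Ps.Pm": -0.6, "Ec.Pm": -0.3, "Imax": -0.5, "Imin": -0.5,
    "Ct.TMD": -0.1,
}

# Sex- and age-scaling of gross measures (body weight g, femur length mm).
_GROSS_BASE = {"M": (22.0, 2.0, 14.6, 0.55), "F": (18.0, 1.8, 14.2, 0.55)}
_AGE_SCALE = {"P36": 0.70, "6wk": 1.00, "9wk": 1.10, "16wk": 1.25}


@dataclass(frozen=True)
class EffectTerm:
    """Additive shift applied to every animal matching ``when``.

    ``when`` maps factor name -> level; an animal matches when all listed
    factors take the listed level, so a single-factor ``when`` is a main
    effect and a multi-factor ``when`` is an interaction cell. ``shifts``
    are in units of the variable's within-model baseline SD.
    """

    when: dict
    shifts: dict

    def matches(self, cell: dict) -> bool:
        return all(cell.get(f) == lv for f, lv in self.when.items())


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort.

    Attributes
    ----------
    factors:
        Ordered mapping factor name -> tuple of levels; cells are the
        cartesian product. Factor names and levels must come from the
        recognized sets in :mod:`bonescore.variables`.
    n_per_group:
        Integer (same n in every cell) or mapping from cell tuple (levels in
        factor order) to n; supports the unbalanced designs the Type III
        analysis exists for.
    baseline_means, baseline_sds:
        Per mouse model, per variable.
    correlations:
        Compartment -> correlation matrix over that compartment's variables.
    effects:
        List of :class:`EffectTerm`.
    missing_fraction:
        Probability that an individual panel cell is set missing, to exercise
        downstream complete-case handling.
    """

    factors: dict
    n_per_group: object = 12
    baseline_means: dict = field(default_factory=dict)
    baseline_sds: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)
    effects: list = field(default_factory=list)
    compartments: tuple = (TRABECULAR, CORTICAL)
    missing_fraction: float = 0.0

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if not self.factors:
            raise ConfigurationError("at least one factor is required")
        for name, levels in self.factors.items():
            if name not in FACTOR_LEVELS:
                raise ConfigurationError(f"unknown factor: {name!r}")
            bad = [lv for lv in levels if lv not in FACTOR_LEVELS[name]]
            if bad:
                raise ConfigurationError(f"unknown level(s) {bad!r} for factor {name!r}")
            if len(levels) < 1:
                raise ConfigurationError(f"factor {name!r} has no levels")
        for compartment in self.compartments:
            if compartment not in COMPARTMENT_VARIABLES:
                raise ConfigurationError(f"unknown compartment: {compartment!r}")
            r = np.asarray(self.correlations.get(compartment))
            k = len(COMPARTMENT_VARIABLES[compartment])
            if r.shape != (k, k):
                raise ConfigurationError(
                    f"correlation matrix for {compartment!r} must be {k}x{k}")
            if not np.allclose(r, r.T, atol=1e-12):
                raise ConfigurationError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(r), 1.0, atol=1e-12):
                raise ConfigurationError("correlation matrix must have unit diagonal")
            try:
                np.linalg.cholesky(r)
            except np.linalg.LinAlgError:
                raise ConfigurationError(
                    f"correlation matrix for {compartment!r} is not positive-definite"
                ) from None
        for model in self._models():
            for var in self._variables():
                sd = self.baseline_sds.get(model, {}).get(var)
                mu = self.baseline_means.get(model, {}).get(var)
                if sd is None or mu is None:
                    raise ConfigurationError(f"missing baseline for {model!r}/{var!r}")
                if not np.isfinite(mu):
                    raise ConfigurationError(f"non-finite baseline mean {model!r}/{var!r}")
                if not (np.isfinite(sd) and sd > 0):
                    raise ConfigurationError(f"baseline SD must be > 0: {model!r}/{var!r}")
        for term in self.effects:
            for f, lv in term.when.items():
                if f not in self.factors or lv not in self.factors[f]:
                    raise ConfigurationError(
                        f"effect term references unknown cell {f!r}={lv!r}")
            if not all(np.isfinite(v) for v in term.shifts.values()):
                raise ConfigurationError("effect shifts must be finite")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ConfigurationError("missing_fraction must be in [0, 1)")
        for cell in self.cells():
            if self.cell_n(cell) < 1:
                raise ConfigurationError(f"cell {cell!r} has n < 1")

    # -- helpers ----------------------------------------------------------
    def _models(self):
        return self.factors.get("model", ("Ts66Yah",))

    def _variables(self):
        out = []
        for compartment in self.compartments:
            out.extend(COMPARTMENT_VARIABLES[compartment])
        return out

    def cells(self):
        """Cartesian product of factor levels, in declaration order."""
        names = list(self.factors)
        for combo in itertools.product(*(self.factors[n] for n in names)):
            yield dict(zip(names, combo))

    def cell_n(self, cell: dict) -> int:
        if isinstance(self.n_per_group, int):
            return self.n_per_group
        key = tuple(cell[n] for n in self.factors)
        try:
            return int(self.n_per_group[key])
        except KeyError:
            raise ConfigurationError(f"no group size configured for cell {key!r}") from None

    def total_shift(self, cell: dict, variable: str) -> float:
        return float(sum(t.shifts.get(variable, 0.0)
                         for t in self.effects if t.matches(cell)))

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "factors": {k: list(v) for k, v in self.factors.items()},
            "n_per_group": (self.n_per_group if isinstance(self.n_per_group, int)
                            else {"|".join(map(str, k)): int(v)
                                  for k, v in self.n_per_group.items()}),
            "baseline_means": self.baseline_means,
            "baseline_sds": self.baseline_sds,
            "correlations": {k: np.asarray(v).tolist()
                             for k, v in self.correlations.items()},
            "effects": [{"when": t.when, "shifts": t.shifts} for t in self.effects],
            "compartments": list(self.compartments),
            "missing_fraction": self.missing_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        n = d.get("n_per_group", 12)
        if isinstance(n, dict):
            n = {tuple(k.split("|")): int(v) for k, v in n.items()}
        cfg = cls(
            factors={k: tuple(v) for k, v in d["factors"].items()},
            n_per_group=n,
            baseline_means=d.get("baseline_means", {}),
            baseline_sds=d.get("baseline_sds", {}),
            correlations={k: np.asarray(v, dtype=float)
                          for k, v in d.get("correlations", {}).items()},
            effects=[EffectTerm(dict(t["when"]), dict(t["shifts"]))
                     for t in d.get("effects", [])],
            compartments=tuple(d.get("compartments", (TRABECULAR, CORTICAL))),
            missing_fraction=float(d.get("missing_fraction", 0.0)),
        )
        if not cfg.baseline_means:
            base = default_config(factors=cfg.factors, n_per_group=2,
                                  compartments=cfg.compartments)
            cfg.baseline_means = base.baseline_means
            cfg.baseline_sds = base.baseline_sds
        if not cfg.correlations:
            cfg.correlations = {
                TRABECULAR: factor_model_correlation(_TRAB_FACTOR_LOADINGS),
                CORTICAL: factor_model_correlation(_CORT_FACTOR_LOADINGS),
            }
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(
    n_per_group: object = 12,
    factors: dict | None = None,
    effects: list | None = None,
    compartments: tuple = (TRABECULAR, CORTICAL),
    missing_fraction: float = 0.0,
) -> CohortConfig:
    """A ready-to-run configuration mirroring the study design.

    Defaults: two mouse models x two genotypes x two sexes at n = 12/group
    (study groups ranged 9-21), an additive trisomic deficit, and
    single-factor correlation structure with Tb.Sp anticorrelated.
    """
    if factors is None:
        factors = {
            "model": ("Ts65Dn", "Ts66Yah"),
            "genotype": ("euploid", "trisomic"),
            "sex": ("M", "F"),
        }
    if effects is None:
        effects = []
        if "genotype" in factors and "trisomic" in factors["genotype"]:
            effects.append(EffectTerm({"genotype": "trisomic"},
                                      dict(_DEFAULT_TRISOMIC_SHIFT)))
    means = {m: {v: _BASELINES[m][v][0] for v in _BASELINES[m]} for m in _BASELINES}
    sds = {m: {v: _BASELINES[m][v][1] for v in _BASELINES[m]} for m in _BASELINES}
    return CohortConfig(
        factors=dict(factors),
        n_per_group=n_per_group,
        baseline_means=means,
        baseline_sds=sds,
        correlations={
            TRABECULAR: factor_model_correlation(_TRAB_FACTOR_LOADINGS),
            CORTICAL: factor_model_correlation(_CORT_FACTOR_LOADINGS),
        },
        effects=effects,
        compartments=compartments,
        missing_fraction=missing_fraction,
    )


def generate_cohort(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Draw a cohort as one row per animal.

    Within each factorial cell, the variable vector of each compartment is
    drawn from a multivariate normal with mean ``baseline + SD * summed
    effect shifts`` and covariance ``D R D`` (D diagonal of baseline SDs,
    R the configured correlation matrix). Group sizes are exactly as
    configured and output is deterministic given ``seed``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    rows = []
    counter = itertools.count(1)
    for cell in config.cells():
        n = config.cell_n(cell)
        model = cell.get("model", "Ts66Yah")
        sex = cell.get("sex", "M")
        age = cell.get("age", "6wk")
        panels = {}
        for compartment in config.compartments:
            variables = COMPARTMENT_VARIABLES[compartment]
            mu = np.array([
                config.baseline_means[model][v]
                + config.baseline_sds[model][v] * config.total_shift(cell, v)
                for v in variables
            ])
            d = np.diag([config.baseline_sds[model][v] for v in variables])
            cov = d @ np.asarray(config.correlations[compartment]) @ d
            panels[compartment] = rng.multivariate_normal(
                mu, cov, size=n, method="cholesky")
        bw_mu, bw_sd, fl_mu, fl_sd = _GROSS_BASE[sex]
        scale = _AGE_SCALE[age]
        body_weight = np.abs(rng.normal(bw_mu * scale, bw_sd * scale, size=n))
        femur_length = np.abs(rng.normal(fl_mu * scale, fl_sd * scale, size=n))
        for i in range(n):
            row = {"animal_id": f"A{next(counter):05d}", **cell,
                   "body_weight": body_weight[i], "femur_length": femur_length[i]}
            for compartment in config.compartments:
                for j, v in enumerate(COMPARTMENT_VARIABLES[compartment]):
                    row[v] = panels[compartment][i, j]
            rows.append(row)
    table = pd.DataFrame(rows)
    if config.missing_fraction > 0:
        variables = config._variables()
        mask = rng.random((len(table), len(variables))) < config.missing_fraction
        vals = table[variables].to_numpy(dtype=float)
        vals[mask] = np.nan
        table[variables] = vals
    return table


# ---------------------------------------------------------------------------
# Three-point-bend curve fixtures
# ---------------------------------------------------------------------------

def generate_bend_curve(
    stiffness: float,
    yield_force: float,
    postyield_slope: float = 0.0,
    failure_displacement: float = 800.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    toe_displacement: float = 0.0,
    step_um: float = 5.0,
    span_mm: float = 6.0,
    c_mm: float = 1.0,
    i_mm4: float = 0.7363,
    preload_n: float = 0.2,
    offset_strain: float = 0.002,
) -> tuple[ForceDisplacementCurve, dict]:
    """Piecewise-linear bend curve plus ground truth for recovery tests.

    The ideal trace is: optional toe rising to the preload force, an elastic
    segment of slope ``stiffness`` (N/mm), a post-yield segment of slope
    ``postyield_slope`` starting at ``yield_force``, and a terminal cliff
    sample at 5% of the ultimate force. Kink displacements are inserted into
    the sample grid so that trapezoidal integration downstream is exact, and
    Gaussian force noise (``noise_sd``) is added last.

    Returns ``(curve, truth)`` where ``truth`` holds the analytic value of
    every extracted property under the analysis definitions (0.2%-offset
    yield, first-maximum ultimate, 10%-drop failure), in the analysis units.

    ``failure_displacement`` (um) is measured from the preload crossing, i.e.
    on the re-zeroed axis the preprocessing step establishes.
    """
    k, s = float(stiffness), float(postyield_slope)
    if k <= 0:
        raise ConfigurationError("stiffness must be positive")
    if s >= k:
        raise ConfigurationError("postyield slope must be below stiffness (no detectable yield)")
    if s < 0:
        raise ConfigurationError("postyield slope must be non-negative")
    p = float(preload_n)
    fy = float(yield_force)
    if fy <= p:
        raise ConfigurationError("yield force must exceed the preload")
    d_kink = (fy - p) / k                      # mm past the preload crossing
    d_fail = failure_displacement / 1000.0     # mm
    if d_fail <= d_kink:
        raise ConfigurationError("failure displacement must lie beyond the yield displacement")

    # --- analytic landmarks on the re-zeroed axis (mm, N) ---
    a = span_mm * c_mm / (4.0 * i_mm4)         # stress per force, MPa/N
    b = 6.0 * c_mm / span_mm**2                # strain per displacement, 1/mm
    d_off = offset_strain / b                  # offset in displacement terms
    f_ult = fy + s * (d_fail - d_kink)
    d_ult = d_fail if s > 0 else d_kink        # first maximum on a plateau is the kink
    step_mm = step_um / 1000.0
    d_cliff = d_fail + step_mm
    f_cliff = 0.05 * f_ult
    # 0.2%-offset line in force-displacement terms: F = k (d - d_off); it can
    # only intersect the post-yield branch (the elastic branch is parallel
    # shifted up by the preload).
    d_yield = (fy - s * d_kink + k * d_off) / (k - s)
    no_yield = d_yield > d_fail
    if no_yield:
        d_yield, f_yield = d_ult, f_ult
    else:
        f_yield = k * (d_yield - d_off)

    def _area(d0, d1):
        """Exact area under the ideal trace between re-zeroed displacements (N*mm)."""
        def f_at(d):
            return p + k * d if d <= d_kink else fy + s * (d - d_kink)
        pieces = sorted({d0, d1, min(max(d_kink, d0), d1)})
        total = 0.0
        for lo, hi in zip(pieces[:-1], pieces[1:]):
            total += 0.5 * (f_at(lo) + f_at(hi)) * (hi - lo)
        return total

    work_to_yield = _area(0.0, d_yield)
    f_at_fail = fy + s * (d_fail - d_kink)
    # total work runs to the failure landmark, which is the cliff sample
    work_to_fail = _area(0.0, d_fail) + 0.5 * (f_at_fail + f_cliff) * step_mm
    truth = {
        "stiffness_n_mm": k,
        "yield_force_n": f_yield,
        "ultimate_force_n": f_ult,
        "displacement_to_yield_um": d_yield * 1000.0,
        "total_displacement_um": d_cliff * 1000.0,
        "postyield_displacement_um": (d_cliff - d_yield) * 1000.0,
        "work_to_yield_mj": work_to_yield,
        "total_work_mj": work_to_fail,
        "postyield_work_mj": work_to_fail - work_to_yield,
        "modulus_gpa": k * span_mm**3 / (48.0 * i_mm4) / 1000.0,
        "yield_stress_mpa": a * f_yield,
        "ultimate_stress_mpa": a * f_ult,
        "strain_to_yield_ue": b * d_yield * 1e6,
        "total_strain_ue": b * d_cliff * 1e6,
        "resilience_mpa": a * b * work_to_yield,
        "toughness_mpa": a * b * work_to_fail,
        "no_yield": no_yield,
        "kink_force_n": fy,
        "ultimate_displacement_um": d_ult * 1000.0,
    }

    # --- sample grid (raw axis: toe occupies [0, toe_displacement]) ---
    d_toe = toe_displacement / 1000.0
    raw_end = d_toe + d_cliff
    n_steps = int(np.floor(raw_end / step_mm + 1e-9))
    grid = np.arange(n_steps + 1) * step_mm
    kinks = np.array([d_toe, d_toe + d_kink, d_toe + d_fail, raw_end])
    kinks = np.unique(kinks[kinks <= raw_end + 1e-12])
    # insert kink displacements exactly, dropping grid points that collide
    clear = np.all(np.abs(grid[:, None] - kinks[None, :]) > step_mm * 1e-6, axis=1)
    grid = np.sort(np.concatenate([grid[clear], kinks]))
    force = np.empty_like(grid)
    tol = step_mm * 1e-6
    for i, d in enumerate(grid):
        if d < d_toe - tol:
            frac = d / d_toe if d_toe > 0 else 0.0
            force[i] = 0.05 + (p - 0.05) * frac
        else:
            dz = d - d_toe
            if dz <= d_kink + tol:
                force[i] = p + k * min(dz, d_kink)
            elif dz <= d_fail + tol:
                force[i] = fy + s * (min(dz, d_fail) - d_kink)
            else:
                force[i] = f_cliff
    if noise_sd > 0:
        force = force + np.random.default_rng(seed).normal(0.0, noise_sd, size=force.size)
    curve = ForceDisplacementCurve(grid * 1000.0, force, span_mm, c_mm, i_mm4)
    return curve, truth


# ---------------------------------------------------------------------------
# Cross-section mask fixtures
# ---------------------------------------------------------------------------

def generate_annulus_mask(
    outer_radius_mm: float,
    inner_radius_mm: float = 0.0,
    pixel_size_um: float = 10.0,
    center_offset_px: tuple = (0.0, 0.0),
    pad_px: int = 3,
    axis_ratio: float = 1.0,
) -> CrossSectionMask:
    """Rasterize a (possibly elliptical) annulus.

    A pixel belongs to cortex iff its center lies between the inner and outer
    boundary. ``axis_ratio`` scales the y-semiaxis relative to x (1 = circle);
    ``center_offset_px`` shifts the center off the grid midpoint. The grid is
    padded at least ``pad_px`` pixels beyond the outer boundary.
    """
    if not outer_radius_mm > inner_radius_mm >= 0:
        raise ConfigurationError("need outer_radius > inner_radius >= 0")
    px_mm = pixel_size_um / 1000.0
    if outer_radius_mm < px_mm or (0 < inner_radius_mm < px_mm):
        raise ConfigurationError("radii must span at least one pixel")
    if axis_ratio <= 0:
        raise ConfigurationError("axis_ratio must be positive")
    r_out_px = outer_radius_mm / px_mm
    r_in_px = inner_radius_mm / px_mm
    half = int(np.ceil(r_out_px * max(1.0, axis_ratio))) + max(int(pad_px), 2)
    n = 2 * half + 1
    cy = half + float(center_offset_px[0])
    cx = half + float(center_offset_px[1])
    yy, xx = np.mgrid[0:n, 0:n]
    rho = np.hypot(xx - cx, (yy - cy) / axis_ratio)
    grid = ((rho <= r_out_px) & (rho >= r_in_px)).astype(np.uint8)
    return CrossSectionMask(grid, pixel_size_um)
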