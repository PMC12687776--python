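"""Three-point-bend mechanical property extraction.

From a force-displacement trace and the specimen's cortical geometry this
module extracts the nine whole-bone (extrinsic) and seven tissue-estimate
(intrinsic) properties: preload trimming and re-zeroing, stiffness from the
most linear window, beam-theory stress-strain normalization, 0.2%-offset
yield, first-maximum ultimate and force-drop failure detection, and
trapezoidal work/energy integrals split at yield.

Beam equations (standard three-point-bend practice, span L, centroid-to-
surface distance c, second moment of area I):

    sigma = F L c / (4 I)        [MPa]
    eps   = 6 c d / L^2          [reported in microstrain]
    E     = k L^3 / (48 I)       [from deflection; reported in GPa]

The 0.2% offset construction uses the measured slope of the linear portion
of the stress-strain curve itself (the exact image of the fitted stiffness
window under the equations above), so the offset line is parallel to the
elastic branch of the curve it intersects.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, UnusableCurveError

__all__ = [
    "ForceDisplacementCurve",
    "StressStrainCurve",
    "StiffnessFit",
    "YieldPoint",
    "Landmarks",
    "MechanicalSummary",
    "preprocess_curve",
    "to_stress_strain",
    "fit_stiffness",
    "find_yield",
    "find_ultimate_failure",
    "summarize_mechanics",
    "analyze_curve",
    "analyze_directory",
    "TABLE_COLUMNS",
]

PRELOAD_N = 0.2          # lower bound of the preload window (N)
OFFSET_UE = 2000.0       # 0.2% offset on the strain axis, in microstrain
FAILURE_DROP = 0.10      # failure = force below this fraction of ultimate
MIN_WINDOW_FRAC = 0.15   # linear window spans >= this fraction of pre-ultimate samples
MIN_R2 = 0.90            # below this best R^2, flag low linearity


@dataclass
class ForceDisplacementCurve:
    """Ordered (displacement um, force N) samples with span and section geometry.

    ``c_mm`` is the distance from the section centroid to the bone surface
    along the loading (anterior-posterior) direction; ``i_mm4`` the second
    moment of area about the bending axis (I_min for anterior-posterior
    loading).
    """

    displacement_um: np.ndarray
    force_n: np.ndarray
    span_mm: float
    c_mm: float
    i_mm4: float
    specimen_id: str = ""

    def __post_init__(self):
        self.displacement_um = np.asarray(self.displacement_um, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        if self.displacement_um.ndim != 1 or self.force_n.shape != self.displacement_um.shape:
            raise ConfigurationError("displacement and force must be 1-D and equal length")
        if np.any(np.diff(self.displacement_um) <= 0):
            raise ConfigurationError("displacement must be strictly increasing")
        if not np.all(np.isfinite(self.force_n)):
            raise ConfigurationError("forces must be finite")
        if min(self.span_mm, self.c_mm, self.i_mm4) <= 0:
            raise ConfigurationError("span, c and I must be positive")

    def __len__(self):
        return self.displacement_um.size


@dataclass
class StressStrainCurve:
    strain_ue: np.ndarray
    stress_mpa: np.ndarray


@dataclass
class StiffnessFit:
    stiffness_n_mm: float
    window: tuple          # (first, last) sample indices of the chosen window
    r_squared: float
    low_linearity: bool


@dataclass
class YieldPoint:
    index_before: int      # sample index preceding the interpolated yield
    frac: float            # interpolation fraction in [0, 1]
    no_yield: bool


@dataclass
class Landmarks:
    ultimate_index: int
    failure_index: int
    no_failure: bool
    yield_point: YieldPoint | None = None


@dataclass
class MechanicalSummary:
    """Extrinsic (force-displacement) and intrinsic (stress-strain) properties."""

    specimen_id: str = ""
    # extrinsic
    yield_force_n: float = np.nan
    ultimate_force_n: float = np.nan
    displacement_to_yield_um: float = np.nan
    postyield_displacement_um: float = np.nan
    total_displacement_um: float = np.nan
    stiffness_n_mm: float = np.nan
    work_to_yield_mj: float = np.nan
    postyield_work_mj: float = np.nan
    total_work_mj: float = np.nan
    # intrinsic
    yield_stress_mpa: float = np.nan
    ultimate_stress_mpa: float = np.nan
    strain_to_yield_ue: float = np.nan
    total_strain_ue: float = np.nan
    modulus_gpa: float = np.nan
    resilience_mpa: float = np.nan
    toughness_mpa: float = np.nan
    # flags
    no_yield: bool = False
    no_failure: bool = False
    low_linearity: bool = False

    @property
    def excluded(self) -> bool:
        """Specimens that never reach failure are excluded from group analysis."""
        return self.no_failure


#: Output CSV headers in the conventional reporting form.
TABLE_COLUMNS = {
    "specimen_id": "Specimen",
    "yield_force_n": "Yield Force (N)",
    "ultimate_force_n": "Ultimate Force (N)",
    "displacement_to_yield_um": "Displacement to Yield (um)",
    "postyield_displacement_um": "Postyield Displacement (um)",
    "total_displacement_um": "Total Displacement (um)",
    "stiffness_n_mm": "Stiffness (N/mm)",
    "work_to_yield_mj": "Work to Yield (mJ)",
    "postyield_work_mj": "Postyield Work (mJ)",
    "total_work_mj": "Total Work (mJ)",
    "yield_stress_mpa": "Yield Stress (MPa)",
    "ultimate_stress_mpa": "Ultimate Stress (MPa)",
    "strain_to_yield_ue": "Strain to Yield (ue)",
    "total_strain_ue": "Total Strain (ue)",
    "modulus_gpa": "Modulus (GPa)",
    "resilience_mpa": "Resilience (MPa)",
    "toughness_mpa": "Toughness (MPa)",
    "no_yield": "No Yield Flag",
    "no_failure": "Excluded (No Failure)",
    "low_linearity": "Low Linearity Flag",
}


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_curve(curve: ForceDisplacementCurve,
                     preload_n: float = PRELOAD_N) -> ForceDisplacementCurve:
    """Trim the toe below the preload and re-zero displacement at the crossing.

    Samples before force first reaches ``preload_n`` are discarded; the
    crossing is located by linear interpolation and becomes displacement
    zero. Everything after (including post-failure samples) is retained.
    """
    d, f = curve.displacement_um, curve.force_n
    above = np.nonzero(f >= preload_n)[0]
    if above.size == 0:
        raise UnusableCurveError(
            f"force never reaches the {preload_n} N preload"
            + (f" (specimen {curve.specimen_id})" if curve.specimen_id else ""))
    i = int(above[0])
    if i == 0 or f[i] == preload_n:
        d_new, f_new = d[i:] - d[i], f[i:]
    else:
        frac = (preload_n - f[i - 1]) / (f[i] - f[i - 1])
        d0 = d[i - 1] + frac * (d[i] - d[i - 1])
        d_new = np.concatenate([[0.0], d[i:] - d0])
        f_new = np.concatenate([[preload_n], f[i:]])
    return ForceDisplacementCurve(d_new, f_new, curve.span_mm, curve.c_mm,
                                  curve.i_mm4, curve.specimen_id)


# ---------------------------------------------------------------------------
# stress-strain normalization
# ---------------------------------------------------------------------------

def stress_per_force(curve: ForceDisplacementCurve) -> float:
    """sigma/F = L c / (4 I), in MPa per newton."""
    return curve.span_mm * curve.c_mm / (4.0 * curve.i_mm4)


def strain_per_displacement(curve: ForceDisplacementCurve) -> float:
    """eps/d = 6 c / L^2, dimensionless strain per millimetre of displacement."""
    return 6.0 * curve.c_mm / curve.span_mm**2


def to_stress_strain(curve: ForceDisplacementCurve) -> StressStrainCurve:
    """Pointwise beam-theory transform; preserves sample count and ordering."""
    stress = stress_per_force(curve) * curve.force_n
    strain_ue = strain_per_displacement(curve) * (curve.displacement_um / 1000.0) * 1e6
    return StressStrainCurve(strain_ue=strain_ue, stress_mpa=stress)


# ---------------------------------------------------------------------------
# stiffness: deterministic most-linear-window search
# ---------------------------------------------------------------------------

def fit_stiffness(curve: ForceDisplacementCurve,
                  ultimate_index: int | None = None) -> StiffnessFit:
    """Slope of the most linear portion of the pre-ultimate curve.

    Among contiguous windows that (a) lie between 10% and 90% of the ultimate
    force, (b) end at or before the ultimate point and (c) span at least 15%
    of the pre-ultimate samples, the window maximizing the regression R^2 is
    chosen; ties go to the larger window, then the earlier start. Stiffness
    is that window's least-squares slope in N/mm. If no window reaches
    R^2 >= 0.9 the best one is still used and flagged.
    """
    d_mm = curve.displacement_um / 1000.0
    f = curve.force_n
    if ultimate_index is None:
        ultimate_index = int(np.argmax(f))
    n_pre = ultimate_index + 1
    if n_pre < 20:
        raise UnusableCurveError(
            f"only {n_pre} samples before the ultimate point; need >= 20")
    f_ult = f[ultimate_index]
    qual = np.nonzero((f[:n_pre] >= 0.1 * f_ult) & (f[:n_pre] <= 0.9 * f_ult))[0]
    if qual.size < 2:
        raise UnusableCurveError("no usable samples between 10% and 90% of ultimate force")
    lo, hi = int(qual[0]), int(qual[-1])
    x = d_mm[lo:hi + 1]
    y = f[lo:hi + 1]
    m = x.size
    min_len = max(2, int(np.ceil(MIN_WINDOW_FRAC * n_pre)))
    min_len = min(min_len, m)

    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])

    best = (-np.inf, None, None)  # (r2, start, length)
    for length in range(m, min_len - 1, -1):
        s = np.arange(0, m - length + 1)
        e = s + length
        sx = cx[e] - cx[s]
        sy = cy[e] - cy[s]
        sxx = cxx[e] - cxx[s]
        syy = cyy[e] - cyy[s]
        sxy = cxy[e] - cxy[s]
        num = length * sxy - sx * sy
        den_x = length * sxx - sx * sx
        den_y = length * syy - sy * sy
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(den_y <= 0, 1.0, num * num / (den_x * den_y))
        j = int(np.argmax(r2))
        if r2[j] > best[0] + 1e-12:
            best = (float(r2[j]), int(s[j]), length)
    r2_best, s_best, len_best = best
    e_best = s_best + len_best
    sx = x[s_best:e_best]
    sy = y[s_best:e_best]
    slope = float(np.polyfit(sx, sy, 1)[0])
    return StiffnessFit(
        stiffness_n_mm=slope,
        window=(lo + s_best, lo + e_best - 1),
        r_squared=r2_best,
        low_linearity=r2_best < MIN_R2,
    )


def modulus_gpa(stiffness_n_mm: float, span_mm: float, i_mm4: float) -> float:
    """Elastic modulus from beam deflection: E = k L^3 / (48 I), in GPa."""
    return stiffness_n_mm * span_mm**3 / (48.0 * i_mm4) / 1000.0


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def find_ultimate_failure(curve: ForceDisplacementCurve,
                          drop_frac: float = FAILURE_DROP) -> Landmarks:
    """Ultimate = first force maximum; failure = first post-ultimate sample
    below ``drop_frac`` of ultimate, else the last sample with a no-failure
    flag (the specimen is excluded downstream)."""
    f = curve.force_n
    i_ult = int(np.argmax(f))
    post = np.nonzero(f[i_ult + 1:] < drop_frac * f[i_ult])[0]
    if post.size:
        return Landmarks(i_ult, i_ult + 1 + int(post[0]), no_failure=False)
    return Landmarks(i_ult, len(f) - 1, no_failure=True)


def find_yield(ss: StressStrainCurve, elastic_slope_mpa: float,
               failure_index: int | None = None,
               ultimate_index: int | None = None,
               offset_ue: float = OFFSET_UE) -> YieldPoint:
    """First intersection of the stress-strain curve with the offset line
    ``sigma = E (eps - offset)``, located by linear interpolation between the
    bracketing samples. ``elastic_slope_mpa`` is the slope of the linear
    portion of the stress-strain curve (MPa per unit strain). If there is no
    intersection before the failure point the curve never yields and the
    yield landmark collapses onto the ultimate point (flagged)."""
    eps, sig = ss.strain_ue, ss.stress_mpa
    stop = len(eps) if failure_index is None else failure_index + 1
    line = elastic_slope_mpa * (eps[:stop] - offset_ue) * 1e-6
    g = sig[:stop] - line
    below = np.nonzero(g <= 0.0)[0]
    below = below[below > 0]
    if below.size == 0:
        # no intersection before failure: yield collapses onto the ultimate point
        at = ultimate_index if ultimate_index is not None else stop - 1
        return YieldPoint(index_before=at, frac=0.0, no_yield=True)
    i = int(below[0])
    denom = g[i - 1] - g[i]
    frac = 0.0 if denom == 0 else float(g[i - 1] / denom)
    return YieldPoint(index_before=i - 1, frac=frac, no_yield=False)


def _interp(arr: np.ndarray, yp: YieldPoint) -> float:
    i = yp.index_before
    if i + 1 >= arr.size:
        return float(arr[i])
    return float(arr[i] + yp.frac * (arr[i + 1] - arr[i]))


def _area_to(x: np.ndarray, y: np.ndarray, yp: YieldPoint | None, index: int | None) -> float:
    """Trapezoidal area under (x, y) up to an interpolated point or an index."""
    if yp is not None:
        i = yp.index_before
        xi, yi = _interp(x, yp), _interp(y, yp)
        base = np.trapezoid(y[:i + 1], x[:i + 1]) if i >= 1 else 0.0
        return float(base + 0.5 * (y[i] + yi) * (xi - x[i]))
    return float(np.trapezoid(y[:index + 1], x[:index + 1]))


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def summarize_mechanics(curve: ForceDisplacementCurve,
                        ss: StressStrainCurve,
                        stiffness: StiffnessFit,
                        landmarks: Landmarks) -> MechanicalSummary:
    """Assemble all extrinsic and intrinsic properties from the landmarks.

    Works are trapezoidal areas under force-displacement (N*mm = mJ) split at
    yield; resilience and toughness are areas under stress-strain (MPa, with
    strain dimensionless) to yield and to failure.
    """
    yp = landmarks.yield_point
    if yp is None:
        raise InputError("landmarks lack a yield point; run find_yield first")
    d_mm = curve.displacement_um / 1000.0
    f = curve.force_n
    eps = ss.strain_ue * 1e-6
    sig = ss.stress_mpa
    i_ult, i_fail = landmarks.ultimate_index, landmarks.failure_index

    d_yield = _interp(curve.displacement_um, yp)
    d_total = float(curve.displacement_um[i_fail])
    work_yield = _area_to(d_mm, f, yp, None)
    work_total = _area_to(d_mm, f, None, i_fail)
    return MechanicalSummary(
        specimen_id=curve.specimen_id,
        yield_force_n=_interp(f, yp),
        ultimate_force_n=float(f[i_ult]),
        displacement_to_yield_um=d_yield,
        postyield_displacement_um=d_total - d_yield,
        total_displacement_um=d_total,
        stiffness_n_mm=stiffness.stiffness_n_mm,
        work_to_yield_mj=work_yield,
        postyield_work_mj=work_total - work_yield,
        total_work_mj=work_total,
        yield_stress_mpa=_interp(sig, yp),
        ultimate_stress_mpa=float(sig[i_ult]),
        strain_to_yield_ue=_interp(ss.strain_ue, yp),
        total_strain_ue=float(ss.strain_ue[i_fail]),
        modulus_gpa=modulus_gpa(stiffness.stiffness_n_mm, curve.span_mm, curve.i_mm4),
        resilience_mpa=_area_to(eps, sig, yp, None),
        toughness_mpa=_area_to(eps, sig, None, i_fail),
        no_yield=yp.no_yield,
        no_failure=landmarks.no_failure,
        low_linearity=stiffness.low_linearity,
    )


def analyze_curve(curve: ForceDisplacementCurve,
                  preload_n: float = PRELOAD_N,
                  drop_frac: float = FAILURE_DROP) -> MechanicalSummary:
    """Full per-specimen pipeline: preprocess, landmarks, stiffness, summary."""
    pre = preprocess_curve(curve, preload_n=preload_n)
    landmarks = find_ultimate_failure(pre, drop_frac=drop_frac)
    stiff = fit_stiffness(pre, ultimate_index=landmarks.ultimate_index)
    ss = to_stress_strain(pre)
    # exact image of the fitted stiffness under the beam transform
    slope_ss = stiff.stiffness_n_mm * stress_per_force(pre) / strain_per_displacement(pre)
    landmarks.yield_point = find_yield(ss, slope_ss,
                                       failure_index=landmarks.failure_index,
                                       ultimate_index=landmarks.ultimate_index)
    return summarize_mechanics(pre, ss, stiff, landmarks)


# ---------------------------------------------------------------------------
# batch I/O
# ---------------------------------------------------------------------------

def read_curve_csv(path, span_mm, c_mm, i_mm4, specimen_id="") -> ForceDisplacementCurve:
    """Two-column numeric CSV: displacement (um), force (N)."""
    arr = pd.read_csv(path).to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise InputError(f"{path}: expected two numeric columns")
    return ForceDisplacementCurve(arr[:, 0], arr[:, 1], span_mm, c_mm, i_mm4,
                                  specimen_id or Path(path).stem)


def analyze_directory(curves_dir, geometry_csv) -> pd.DataFrame:
    """Analyze every ``<specimen>.csv`` listed in the geometry sidecar.

    The sidecar has columns specimen_id, span_mm, c_mm, i_mm4. Output: one
    row per specimen with conventional reporting column names.
    """
    geom = pd.read_csv(geometry_csv)
    need = {"specimen_id", "span_mm", "c_mm", "i_mm4"}
    if not need.issubset(geom.columns):
        raise InputError(f"geometry sidecar must have columns {sorted(need)}")
    rows = []
    for _, g in geom.iterrows():
        path = Path(curves_dir) / f"{g['specimen_id']}.csv"
        curve = read_curve_csv(path, g["span_mm"], g["c_mm"], g["i_mm4"],
                               specimen_id=str(g["specimen_id"]))
        rows.append(asdict(analyze_curve(curve)))
    out = pd.DataFrame(rows)
    return out.rename(columns=TABLE_COLUMNS)
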