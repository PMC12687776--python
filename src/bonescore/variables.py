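"""Variable panels and factor level sets used throughout the package.

Column headers follow ASBMR micro-CT nomenclature, with ``/`` replaced by ``_``
(and ``BV/TV`` shortened to ``BVTV``) so the names survive round-trips through
CSV headers and formula interfaces.
"""

from __future__ import annotations

TRABECULAR = "trabecular"
CORTICAL = "cortical"

#: Trabecular compartment panel: density, volume fraction, thickness,
#: separation and number. Tb.Sp runs opposite to the rest (more separation =
#: less bone).
TRABECULAR_VARIABLES: tuple[str, ...] = ("BMD", "BVTV", "Tb.Th", "Tb.Sp", "Tb.N")

#: Cortical compartment panel: cross-sectional areas, area fraction, mean
#: thickness, perimeters, principal second moments of area, tissue density.
CORTICAL_VARIABLES: tuple[str, ...] = (
    "Tt.Ar",
    "Ma.Ar",
    "Ct.Ar",
    "Ct.Ar_Tt.Ar",
    "Ct.Th",
    "Ps.Pm",
    "Ec.Pm",
    "Imax",
    "Imin",
    "Ct.TMD",
)

COMPARTMENT_VARIABLES: dict[str, tuple[str, ...]] = {
    TRABECULAR: TRABECULAR_VARIABLES,
    CORTICAL: CORTICAL_VARIABLES,
}

#: Default orientation anchors: the variable whose PC1 loading is forced
#: positive, so a higher composite score always reads as "more/denser bone".
DEFAULT_ANCHORS: dict[str, str] = {TRABECULAR: "BVTV", CORTICAL: "Ct.Ar"}

#: Recognized factor columns and their level sets.
FACTOR_LEVELS: dict[str, tuple] = {
    "model": ("Ts65Dn", "Ts66Yah"),
    "genotype": ("euploid", "trisomic"),
    "sex": ("M", "F"),
    "age": ("P36", "6wk", "9wk", "16wk"),
    "dyrk1a_copies": (1, 2, 3),
    "treatment": ("none", "vehicle", "L21"),
}

FACTOR_COLUMNS: tuple[str, ...] = tuple(FACTOR_LEVELS)

ID_COLUMN = "animal_id"
GROSS_COLUMNS: tuple[str, ...] = ("body_weight", "femur_length")


def compartment_of(variable: str) -> str:
    """Return which compartment a panel variable belongs to."""
    for compartment, names in COMPARTMENT_VARIABLES.items():
        if variable in names:
            return compartment
    raise KeyError(f"unknown panel variable: {variable!r}")
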