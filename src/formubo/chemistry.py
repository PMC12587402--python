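"""Acid-base speciation, pH solving, osmolality and design-space decoding.

The formulation design space has six independent variables: sorbitol (mM),
arginine (mM), pH, and the relative fractions of aspartic acid, glutamic
acid and HCl used for pH adjustment (the acetic-acid fraction is the
remainder of the simplex).  Histidine buffer is fixed at 10 mM.  The total
acid concentration is not a free variable: it is whatever amount titrates
the histidine/arginine base mixture to the target pH.

Speciation uses classical alpha-fraction chemistry: each component is a
polyprotic acid/base described by the charge of its fully protonated form
and a ladder of pKa values.  Charge balance (including water
autoionization, Kw = 1e-14) closes the system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

KW = 1e-14

__all__ = [
    "AcidBase",
    "SPECIES_DB",
    "DesignSpace",
    "Formulation",
    "FeasibilityReport",
    "SpeciesTable",
    "InfeasibleTargetError",
    "UnknownComponentError",
    "average_charge",
    "alpha_fractions",
    "solve_mixture_pH",
    "speciate",
    "acid_totals_for_target_pH",
    "estimate_osmolality",
    "decode_point",
    "check_feasibility",
]


class InfeasibleTargetError(ValueError):
    """Target pH cannot be reached with the given acids/bases."""


class UnknownComponentError(KeyError):
    """Composition contains a component absent from the species database."""


@dataclass(frozen=True)
class AcidBase:
    """A (poly)protic component: charge of the fully protonated form and
    its pKa ladder in ascending order.  A strong electrolyte (e.g. the
    chloride delivered by HCl) has an empty ladder."""

    name: str
    z_max: int
    pkas: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if any(b < a for a, b in zip(self.pkas, self.pkas[1:])):
            raise ValueError(f"pKa ladder of {self.name} must be ascending")


# Standard CRC/biochemistry values.  Editable: pass a modified mapping to
# the solver functions to swap conventions.
SPECIES_DB: dict[str, AcidBase] = {
    "histidine": AcidBase("histidine", 2, (1.82, 6.04, 9.17)),
    "arginine": AcidBase("arginine", 2, (2.03, 9.00, 12.10)),
    "aspartic": AcidBase("aspartic", 1, (1.99, 3.90, 9.90)),
    "glutamic": AcidBase("glutamic", 1, (2.10, 4.07, 9.47)),
    "acetic": AcidBase("acetic", 0, (4.76,)),
    "chloride": AcidBase("chloride", -1, ()),
    "sorbitol": AcidBase("sorbitol", 0, ()),
}

#: Map from a formulation's acid label to the species name of what the acid
#: delivers into solution ("hcl" dissociates fully to chloride).
ACID_SPECIES = {"asp": "aspartic", "glu": "glutamic", "acetic": "acetic", "hcl": "chloride"}

OBJECTIVE_COLUMNS = ("Tm_C", "kD_mL_per_g", "RM_pct")

FORMULATION_COLUMNS = (
    "sorbitol_mM",
    "arginine_mM",
    "pH",
    "f_asp",
    "f_glu",
    "f_hcl",
    "f_acetic",
    "asp_mM",
    "glu_mM",
    "acetic_mM",
    "hcl_mM",
    "histidine_mM",
    "osmolality_mOsm_kg",
    "feasible",
)


def alpha_fractions(species: AcidBase, pH: float) -> np.ndarray:
    """Fractions of each protonation state (from fully protonated down) at
    the given pH, computed in log10 space for stability."""
    n = len(species.pkas)
    if n == 0:
        return np.array([1.0])
    j = np.arange(n + 1)
    # log10 weight of state j relative to fully protonated
    logw = np.concatenate(([0.0], -np.cumsum(species.pkas))) + j * pH
    logw -= logw.max()
    w = 10.0 ** logw
    return w / w.sum()


def average_charge(species: AcidBase, pH: float) -> float:
    """Concentration-weighted mean charge of the component at this pH."""
    alphas = alpha_fractions(species, pH)
    charges = species.z_max - np.arange(len(alphas))
    return float(alphas @ charges)


def _charge_residual(pH: float, composition: dict[str, float], db: dict[str, AcidBase]) -> float:
    """Charge-balance residual in molar: sum(z_i * c_i) + [H+] - [OH-]."""
    h = 10.0 ** (-pH)
    resid = h - KW / h
    for name, conc_mM in composition.items():
        if name not in db:
            raise UnknownComponentError(name)
        resid += (conc_mM * 1e-3) * average_charge(db[name], pH)
    return resid


def solve_mixture_pH(
    composition: dict[str, float],
    db: dict[str, AcidBase] | None = None,
    residual_tol: float = 1e-10,
) -> float:
    """pH at which the mixture is electroneutral.

    Parameters
    ----------
    composition
        Analytical concentrations in mM, keyed by species-database name.
    residual_tol
        Maximum allowed |charge residual| in molar at the returned pH.
    """
    db = SPECIES_DB if db is None else db
    for name, conc in composition.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {name}")
        if name not in db:
            raise UnknownComponentError(name)
    f = lambda ph: _charge_residual(ph, composition, db)
    pH = brentq(f, 0.0, 14.0, xtol=1e-12, rtol=8.9e-16)
    if abs(f(pH)) > residual_tol:
        raise RuntimeError(f"pH solver residual {f(pH):.3e} M above tolerance")
    return float(pH)


@dataclass
class SpeciesTable:
    """Per-component speciation at a solved pH: list of (charge, mM)."""

    pH: float
    species: dict[str, list[tuple[int, float]]]

    def charge_residual(self) -> float:
        """Charge-balance residual in molar, including H+/OH-."""
        h = 10.0 ** (-self.pH)
        total = h - KW / h
        for rows in self.species.values():
            for z, conc_mM in rows:
                total += z * conc_mM * 1e-3
        return total


def speciate(
    composition: dict[str, float],
    pH: float | None = None,
    db: dict[str, AcidBase] | None = None,
) -> SpeciesTable:
    """Full speciation table; solves the mixture pH unless one is given."""
    db = SPECIES_DB if db is None else db
    if pH is None:
        pH = solve_mixture_pH(composition, db)
    table: dict[str, list[tuple[int, float]]] = {}
    for name, conc_mM in composition.items():
        sp = db[name]
        alphas = alpha_fractions(sp, pH)
        table[name] = [
            (sp.z_max - j, float(conc_mM * a)) for j, a in enumerate(alphas)
        ]
    return SpeciesTable(pH=pH, species=table)


def acid_totals_for_target_pH(
    target_pH: float,
    fractions: tuple[float, float, float, float],
    histidine_mM: float = 10.0,
    arginine_mM: float = 0.0,
    cap_mM: float = 2000.0,
    db: dict[str, AcidBase] | None = None,
) -> dict[str, float]:
    """Per-acid totals (mM) that titrate the base mixture to ``target_pH``.

    ``fractions`` is (f_asp, f_glu, f_hcl, f_acetic), non-negative and
    summing to one.  At fixed pH every speciation fraction is a constant,
    so the charge balance is linear in the total acid concentration C and
    the inverse problem is solved in closed form; C outside [0, cap] (the
    target above the acid-free pH, or needing more acid than the cap)
    raises :class:`InfeasibleTargetError`.
    """
    db = SPECIES_DB if db is None else db
    f_asp, f_glu, f_hcl, f_acetic = fractions
    if min(fractions) < -1e-12:
        raise ValueError("acid fractions must be non-negative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("acid fractions must sum to 1")

    h = 10.0 ** (-target_pH)
    base_charge = h - KW / h
    base_charge += histidine_mM * 1e-3 * average_charge(db["histidine"], target_pH)
    base_charge += arginine_mM * 1e-3 * average_charge(db["arginine"], target_pH)

    per_acid_charge = (
        f_asp * average_charge(db["aspartic"], target_pH)
        + f_glu * average_charge(db["glutamic"], target_pH)
        + f_hcl * average_charge(db["chloride"], target_pH)
        + f_acetic * average_charge(db["acetic"], target_pH)
    )
    if per_acid_charge >= -1e-15:
        raise InfeasibleTargetError(
            "acid mixture carries no negative charge at the target pH"
        )
    C = -base_charge / per_acid_charge * 1e3  # mM
    if C < -1e-9:
        raise InfeasibleTargetError(
            f"target pH {target_pH} is above the acid-free mixture pH"
        )
    C = max(C, 0.0)
    if C > cap_mM:
        raise InfeasibleTargetError(
            f"required total acid {C:.1f} mM exceeds cap {cap_mM} mM"
        )
    return {
        "asp": C * f_asp,
        "glu": C * f_glu,
        "hcl": C * f_hcl,
        "acetic": C * f_acetic,
    }


@dataclass(frozen=True)
class DesignSpace:
    """Bounds of the six independent variables plus fixed quantities and
    the osmolality constraint window."""

    sorbitol_range: tuple[float, float] = (0.0, 550.0)
    arginine_range: tuple[float, float] = (0.0, 250.0)
    pH_range: tuple[float, float] = (4.5, 7.5)
    f_asp_range: tuple[float, float] = (0.0, 1.0)
    f_glu_range: tuple[float, float] = (0.0, 1.0)
    f_hcl_range: tuple[float, float] = (0.0, 1.0)
    histidine_fixed: float = 10.0
    osmolality_range: tuple[float, float] = (100.0, 600.0)
    acid_cap_mM: float = 2000.0

    def __post_init__(self) -> None:
        for lo, hi in (
            self.sorbitol_range,
            self.arginine_range,
            self.pH_range,
            self.f_asp_range,
            self.f_glu_range,
            self.f_hcl_range,
            self.osmolality_range,
        ):
            if lo > hi:
                raise ValueError("range lower bound exceeds upper bound")
        for lo, hi in (self.f_asp_range, self.f_glu_range, self.f_hcl_range):
            if lo < 0 or hi > 1:
                raise ValueError("fraction ranges must lie within [0, 1]")
        if self.histidine_fixed <= 0:
            raise ValueError("histidine concentration must be positive")

    @property
    def bounds(self) -> np.ndarray:
        """(6, 2) array of variable bounds in decode order."""
        return np.array(
            [
                self.sorbitol_range,
                self.arginine_range,
                self.pH_range,
                self.f_asp_range,
                self.f_glu_range,
                self.f_hcl_range,
            ]
        )


@dataclass(frozen=True)
class Formulation:
    """A concrete point of the design space with its derived chemistry."""

    sorbitol: float
    arginine: float
    pH: float
    f_asp: float
    f_glu: float
    f_hcl: float
    f_acetic: float
    acid_totals: dict[str, float] = field(default_factory=dict)
    histidine: float = 10.0
    osmolality: float = float("nan")
    feasible: bool = False
    reason: str = ""

    def composition(self) -> dict[str, float]:
        """Analytical composition (mM) keyed by species-database name."""
        comp = {
            "histidine": self.histidine,
            "arginine": self.arginine,
            "sorbitol": self.sorbitol,
        }
        for acid, total in self.acid_totals.items():
            comp[ACID_SPECIES[acid]] = comp.get(ACID_SPECIES[acid], 0.0) + total
        return comp

    def to_row(self) -> dict[str, float | bool]:
        t = self.acid_totals
        return {
            "sorbitol_mM": self.sorbitol,
            "arginine_mM": self.arginine,
            "pH": self.pH,
            "f_asp": self.f_asp,
            "f_glu": self.f_glu,
            "f_hcl": self.f_hcl,
            "f_acetic": self.f_acetic,
            "asp_mM": t.get("asp", float("nan")),
            "glu_mM": t.get("glu", float("nan")),
            "acetic_mM": t.get("acetic", float("nan")),
            "hcl_mM": t.get("hcl", float("nan")),
            "histidine_mM": self.histidine,
            "osmolality_mOsm_kg": self.osmolality,
            "feasible": self.feasible,
        }


def estimate_osmolality(formulation: Formulation) -> float:
    """Ideal osmolality (mOsm/kg): one particle per analytical solute.

    Sorbitol, histidine and arginine count once each; every weak acid
    counts once per analytical particle (its conjugate pairs are one
    particle); HCl contributes its chloride.  Molar is taken as molal and
    no osmotic coefficients are applied.
    """
    if not formulation.acid_totals:
        raise ValueError("acid_totals not populated")
    return (
        formulation.sorbitol
        + formulation.histidine
        + formulation.arginine
        + sum(formulation.acid_totals.values())
    )


@dataclass(frozen=True)
class FeasibilityReport:
    feasible: bool
    violations: tuple[str, ...] = ()


def decode_point(u: np.ndarray, space: DesignSpace | None = None) -> Formulation:
    """Map a unit-hypercube 6-vector to a constraint-checked Formulation.

    Coordinates map affinely to (sorbitol, arginine, pH, f_asp, f_glu,
    f_hcl); the acetic fraction is the simplex remainder.  An unreachable
    pH target or an out-of-window osmolality marks the formulation
    infeasible rather than raising.
    """
    space = DesignSpace() if space is None else space
    u = np.asarray(u, dtype=float)
    if u.shape != (6,):
        raise ValueError("expected a 6-vector")
    if np.any(u < -1e-12) or np.any(u > 1 + 1e-12):
        raise ValueError("unit-cube coordinates must lie in [0, 1]")
    b = space.bounds
    s, a, pH, f_asp, f_glu, f_hcl = b[:, 0] + u * (b[:, 1] - b[:, 0])
    f_acetic = 1.0 - (f_asp + f_glu + f_hcl)

    base = Formulation(
        sorbitol=s,
        arginine=a,
        pH=pH,
        f_asp=f_asp,
        f_glu=f_glu,
        f_hcl=f_hcl,
        f_acetic=f_acetic,
        histidine=space.histidine_fixed,
    )
    if f_acetic < -1e-12:
        return replace(base, feasible=False, reason="fraction simplex violated")
    f_acetic = max(f_acetic, 0.0)
    try:
        totals = acid_totals_for_target_pH(
            pH,
            (f_asp, f_glu, f_hcl, f_acetic),
            histidine_mM=space.histidine_fixed,
            arginine_mM=a,
            cap_mM=space.acid_cap_mM,
        )
    except InfeasibleTargetError as exc:
        return replace(base, feasible=False, reason=f"pH target unreachable: {exc}")
    form = replace(base, f_acetic=f_acetic, acid_totals=totals)
    osmo = estimate_osmolality(form)
    lo, hi = space.osmolality_range
    if not (lo <= osmo <= hi):
        return replace(form, osmolality=osmo, feasible=False, reason="osmolality out of range")
    return replace(form, osmolality=osmo, feasible=True, reason="")


def check_feasibility(formulation: Formulation, space: DesignSpace | None = None) -> FeasibilityReport:
    """Re-evaluate the constraint set on a decoded formulation."""
    space = DesignSpace() if space is None else space
    violations: list[str] = []
    fsum = formulation.f_asp + formulation.f_glu + formulation.f_hcl
    if fsum > 1 + 1e-12:
        violations.append("fraction simplex violated")
    if not formulation.acid_totals:
        violations.append("pH target unreachable")
    else:
        lo, hi = space.osmolality_range
        if not (lo <= formulation.osmolality <= hi):
            violations.append("osmolality out of range")
    return FeasibilityReport(feasible=not violations, violations=tuple(violations))


def feasible_predicate(space: DesignSpace | None = None):
    """Unit-cube feasibility predicate used by the search modules."""
    space = DesignSpace() if space is None else space

    def is_feasible(u: np.ndarray) -> bool:
        u = np.asarray(u, dtype=float)
        if np.any(u < 0) or np.any(u > 1):
            return False
        return decode_point(u, space).feasible

    return is_feasible
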