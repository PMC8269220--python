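"""Catabolic reaction energetics at 25 °C, 1 bar.

Computes standard (ΔG_r°) and overall (ΔG_r) Gibbs energies of dissolved-phase
redox reactions,

    ΔG_r = ΔG_r° + R·T·ln Q_r,          Q_r = Π_i a_i^ν_i,

with species activities a_i = γ_i·(C_i/C_iθ) (C_iθ = 1 molal referenced to
infinite dilution), individual activity coefficients γ_i from the B-dot
extended Debye-Hückel equation, unit activity for pure liquids, and the H⁺
activity set directly by pH.  Also provides the nominal oxidation state of
carbon (NOSC) of organic compounds, carbon-weighted composite NOSC of medium
recipes, and construction of the aerobic oxidation reaction of composite
dissolved organic carbon to bicarbonate from its NOSC.

Sign convention: negative ΔG_r is exergonic.  Per-electron energies are
kJ·(mol e⁻)⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .refdata import (
    DEFAULT_ION_SIZE,
    DH_A,
    DH_B,
    DH_BDOT,
    NOSC_GIBBS_INTERCEPT,
    NOSC_GIBBS_SLOPE,
    R_KJ,
    T_REF,
    ChemicalSpecies,
    load_species_table,
    parse_formula,
)

__all__ = [
    "Reaction",
    "SolutionConditions",
    "EnergyResult",
    "MediumRecipe",
    "BalanceError",
    "nosc",
    "medium_nosc",
    "activity_coefficient",
    "reaction_quotient",
    "standard_gibbs",
    "overall_gibbs",
    "doc_oxidation_reaction",
]

_BALANCE_TOL = 1e-9

# Counter-ions whose contribution is removed when assigning oxidation states
# to the CHNOPS moiety of a salt given as a neutral formula (e.g. sodium
# acetate C2H3NaO2 is scored as the acetate anion).
_COUNTER_ION_VALENCE = {"Na": 1, "K": 1, "Li": 1, "Mg": 2, "Ca": 2}
_NOSC_ELEMENTS = {"C", "H", "N", "O", "P", "S"}


class BalanceError(ValueError):
    """Raised when a reaction fails element or charge balance."""


def nosc(formula, charge: int = 0) -> float:
    """Nominal oxidation state of carbon of an organic compound.

    For C_a H_b N_c O_d P_e S_f with net charge Z,

        NOSC = −(−Z + 4a + b − 3c − 2d + 5e − 2f)/a + 4.

    ``formula`` may be a Hill-notation string or an element→count mapping.
    Alkali/alkaline-earth counter-ions (Na, K, Li, Mg, Ca) in salt formulas
    are stripped and their valence charged to Z.  Raises ``ValueError`` when
    the compound contains no carbon (NOSC undefined).
    """
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    z = float(charge)
    for elem, n in counts.items():
        if n == 0 or elem in _NOSC_ELEMENTS:
            continue
        if elem in _COUNTER_ION_VALENCE:
            z -= _COUNTER_ION_VALENCE[elem] * n
        else:
            raise ValueError(f"NOSC undefined for element {elem!r} in formula")
    a = counts.get("C", 0.0)
    if a <= 0:
        raise ValueError("NOSC undefined: compound contains no carbon")
    b = counts.get("H", 0.0)
    c = counts.get("N", 0.0)
    d = counts.get("O", 0.0)
    e = counts.get("P", 0.0)
    f = counts.get("S", 0.0)
    return -(-z + 4 * a + b - 3 * c - 2 * d + 5 * e - 2 * f) / a + 4


@dataclass
class MediumRecipe:
    """Organic composition of a growth medium.

    ``entries`` is a list of ``(formula, charge, concentration)`` tuples with
    concentrations in mol·kg⁻¹.  Compounds without carbon are carried but
    ignored by the NOSC composite.
    """

    entries: list

    def __post_init__(self):
        if not self.entries:
            raise ValueError("empty medium recipe")
        for formula, _charge, conc in self.entries:
            if conc < 0:
                raise ValueError(f"negative concentration for {formula!r}")

    def carbon_concentration(self) -> float:
        """Total organic carbon, mol C·kg⁻¹ (Σ concentration × carbon atoms)."""
        total = 0.0
        for formula, _charge, conc in self.entries:
            counts = parse_formula(formula) if isinstance(formula, str) else formula
            total += conc * counts.get("C", 0.0)
        return total


def medium_nosc(recipe: MediumRecipe) -> float:
    """Carbon-atom-weighted mean NOSC of a medium recipe.

    Each compound contributes its NOSC weighted by its molar carbon delivery
    (concentration × carbon atoms): Σ(C_i·a_i·NOSC_i) / Σ(C_i·a_i).
    """
    num = 0.0
    den = 0.0
    for formula, charge, conc in recipe.entries:
        counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
        a = counts.get("C", 0.0)
        if a <= 0:
            continue
        num += conc * a * nosc(counts, charge)
        den += conc * a
    if den <= 0:
        raise ValueError("recipe contains no carbon-bearing compound")
    return num / den


def activity_coefficient(
    charge: int,
    ionic_strength: float,
    ion_size: float | None = None,
    temperature: float = T_REF,
) -> float:
    """Individual activity coefficient γ from the B-dot equation.

    log₁₀ γ = −A·z²·√I / (1 + å·B·√I) + Ḃ·I with the pinned 25 °C constants
    (A = 0.5092, B = 0.3283 Å⁻¹, Ḃ = 0.041; Helgeson 1969).  Neutral species
    return γ = 1 by convention, as does the infinite-dilution limit I = 0.
    The constants are valid at 25 °C; ``temperature`` is accepted for
    interface symmetry and validated positive only.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be nonnegative")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if charge == 0 or ionic_strength == 0:
        return 1.0
    a = DEFAULT_ION_SIZE if ion_size is None else ion_size
    sqrt_i = math.sqrt(ionic_strength)
    log10_gamma = (
        -DH_A * charge**2 * sqrt_i / (1.0 + a * DH_B * sqrt_i)
        + DH_BDOT * ionic_strength
    )
    return 10.0**log10_gamma


@dataclass
class SolutionConditions:
    """Temperature, composition, and pH of the solution.

    Concentrations are molalities (mol·kg⁻¹) keyed by species name.  The
    ionic strength may be supplied directly (e.g. 0.7 mol·kg⁻¹ for a
    seawater-like matrix whose full major-ion composition is not itemized);
    otherwise it is computed as ½ Σ C_i z_i² over the charged species present.
    """

    temperature: float = T_REF
    concentrations: dict = field(default_factory=dict)
    pH: float = 8.0
    ionic_strength: float | None = None

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for name, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name!r}")
        if self.ionic_strength is not None and self.ionic_strength < 0:
            raise ValueError("ionic strength must be nonnegative")

    def effective_ionic_strength(self, species_table: dict) -> float:
        if self.ionic_strength is not None:
            return self.ionic_strength
        i = 0.0
        for name, c in self.concentrations.items():
            sp = species_table.get(name)
            if sp is not None and sp.charge != 0:
                i += c * sp.charge**2
        return 0.5 * i

    def activity(self, species: ChemicalSpecies, species_table: dict) -> float:
        """Thermodynamic activity of one species under these conditions."""
        if species.phase == "liquid":
            return 1.0
        if species.name == "H+":
            return 10.0 ** (-self.pH)
        if species.name not in self.concentrations:
            raise KeyError(
                f"no concentration given for species {species.name!r}"
            )
        c = self.concentrations[species.name]
        gamma = activity_coefficient(
            species.charge,
            self.effective_ionic_strength(species_table),
            species.ion_size,
            self.temperature,
        )
        return gamma * c  # C_i / C_i_theta with C_i_theta = 1 molal


@dataclass
class Reaction:
    """Signed stoichiometry over named species (products > 0, reactants < 0).

    ``n_electrons`` is the number of electrons transferred per formula
    reaction.  ``dG0`` optionally pins a precomputed standard Gibbs energy
    (kJ·mol⁻¹); composite-carbon reactions built from a NOSC relation carry
    one because their pseudo-species has no tabulated formation energy.
    ``local_species`` holds reaction-private species not in the shared table.
    """

    stoichiometry: dict
    n_electrons: float | None = None
    dG0: float | None = None
    local_species: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.stoichiometry:
            raise ValueError("empty reaction")
        if self.n_electrons is not None and self.n_electrons <= 0:
            raise ValueError("n_electrons must be positive for redox reactions")

    def resolve(self, name: str, species_table: dict) -> ChemicalSpecies:
        if name in self.local_species:
            return self.local_species[name]
        try:
            return species_table[name]
        except KeyError:
            raise KeyError(f"unknown species {name!r}") from None

    def scaled(self, k: float) -> "Reaction":
        """The same reaction with all coefficients (and electrons) × k."""
        return Reaction(
            {s: k * v for s, v in self.stoichiometry.items()},
            n_electrons=None if self.n_electrons is None else k * self.n_electrons,
            dG0=None if self.dG0 is None else k * self.dG0,
            local_species=dict(self.local_species),
        )

    def validate_balance(self, species_table: dict) -> None:
        """Check element and charge balance; raise BalanceError with residuals."""
        residuals: dict[str, float] = {}
        charge = 0.0
        for name, coef in self.stoichiometry.items():
            sp = self.resolve(name, species_table)
            charge += coef * sp.charge
            for elem, n in sp.formula.items():
                residuals[elem] = residuals.get(elem, 0.0) + coef * n
        bad = {e: r for e, r in residuals.items() if abs(r) > _BALANCE_TOL}
        if abs(charge) > _BALANCE_TOL:
            bad["charge"] = charge
        if bad:
            detail = ", ".join(f"{e}: {r:+g}" for e, r in sorted(bad.items()))
            raise BalanceError(f"reaction is unbalanced ({detail})")


@dataclass(frozen=True)
class EnergyResult:
    """Gibbs-energy bookkeeping for one reaction under given conditions."""

    dG0: float                      # kJ/mol reaction
    lnQ: float                      # dimensionless
    dGr: float                      # kJ/mol reaction; negative = exergonic
    dGr_per_electron: float | None  # kJ/(mol e-)
    temperature: float = T_REF


def standard_gibbs(reaction: Reaction, species_table: dict | None = None) -> float:
    """Standard Gibbs energy of reaction, ΔG_r° = Σ ν_i·ΔG_f,i° (kJ·mol⁻¹).

    Balance (element and charge) is validated before any energy is computed.
    Reactions carrying a pinned ``dG0`` (composite-carbon oxidations) return
    it directly after validation.
    """
    if species_table is None:
        species_table = load_species_table()
    reaction.validate_balance(species_table)
    if reaction.dG0 is not None:
        return reaction.dG0
    total = 0.0
    for name, coef in reaction.stoichiometry.items():
        sp = reaction.resolve(name, species_table)
        if sp.dGf0 is None:
            raise ValueError(f"species {sp.name!r} has no tabulated dGf0")
        total += coef * sp.dGf0
    return total


def reaction_quotient(
    reaction: Reaction,
    conditions: SolutionConditions,
    species_table: dict | None = None,
) -> float:
    """Natural log of the reaction quotient, ln Q = Σ ν_i·ln a_i."""
    if species_table is None:
        species_table = load_species_table()
    lnq = 0.0
    for name, coef in reaction.stoichiometry.items():
        sp = reaction.resolve(name, species_table)
        a = conditions.activity(sp, species_table)
        if a <= 0:
            raise ValueError(f"species {name!r} has nonpositive activity")
        lnq += coef * math.log(a)
    return lnq


def overall_gibbs(
    reaction: Reaction,
    conditions: SolutionConditions,
    species_table: dict | None = None,
) -> EnergyResult:
    """Overall Gibbs energy ΔG_r = ΔG_r° + R·T·ln Q and per-electron value."""
    if species_table is None:
        species_table = load_species_table()
    dg0 = standard_gibbs(reaction, species_table)
    lnq = reaction_quotient(reaction, conditions, species_table)
    dgr = dg0 + R_KJ * conditions.temperature * lnq
    per_e = None if reaction.n_electrons is None else dgr / reaction.n_electrons
    return EnergyResult(
        dG0=dg0,
        lnQ=lnq,
        dGr=dgr,
        dGr_per_electron=per_e,
        temperature=conditions.temperature,
    )


def doc_oxidation_reaction(
    nosc_value: float,
    species_table: dict | None = None,
    carbon_name: str = "C_org",
) -> Reaction:
    """Aerobic oxidation of composite organic carbon to bicarbonate, per mol C.

    The composite carbon is represented as the per-carbon pseudo-species
    CH_hO_o whose H/O content reproduces the given NOSC (h = 2 − NOSC, o = 1
    for NOSC ≤ 2; h = 0, o = NOSC/2 above).  Electrons transferred per mol C:
    n_e = 4 − NOSC.  The standard Gibbs energy couples the linear
    NOSC→energy relation for the carbon oxidation half reaction (to HCO₃⁻)
    with the O₂(aq)/H₂O half reaction:

        C_org + (n_e/4) O₂ → HCO₃⁻ + H⁺ + ((h−2)/2) H₂O.

    Raises for NOSC outside [−4, 4] and for the degenerate NOSC = 4 case
    (carbon already fully oxidized: no electrons to transfer).
    """
    if not -4.0 <= nosc_value <= 4.0:
        raise ValueError("NOSC must lie in [-4, 4]")
    n_e = 4.0 - nosc_value
    if n_e <= 0:
        raise ValueError(
            "NOSC = +4: carbon is already fully oxidized; "
            "oxidation reaction is degenerate"
        )
    if species_table is None:
        species_table = load_species_table()
    if nosc_value <= 2.0:
        h, o = 2.0 - nosc_value, 1.0
    else:
        h, o = 0.0, nosc_value / 2.0
    composite = ChemicalSpecies(
        name=carbon_name,
        formula={"C": 1.0, "H": h, "O": o},
        charge=0,
        dGf0=None,
        ion_size=None,
        phase="aqueous",
    )
    x = n_e / 4.0                      # mol O2 per mol C
    y = (h - 2.0) / 2.0                # mol H2O produced per mol C
    dg0_cox = NOSC_GIBBS_INTERCEPT + NOSC_GIBBS_SLOPE * nosc_value
    # O2(aq) + 4 H+ + 4 e- -> 2 H2O, from the pinned table:
    dg0_o2_half = 2 * species_table["H2O"].dGf0 - species_table["O2"].dGf0
    dg0 = dg0_cox + x * dg0_o2_half
    return Reaction(
        stoichiometry={
            carbon_name: -1.0,
            "O2": -x,
            "HCO3-": 1.0,
            "H+": 1.0,
            "H2O": y,
        },
        n_electrons=n_e,
        dG0=dg0,
        local_species={carbon_name: composite},
    )


def thiosulfate_oxidation() -> Reaction:
    """Aerobic thiosulfate oxidation: S₂O₃²⁻ + 2 O₂ + H₂O → 2 SO₄²⁻ + 2 H⁺ (8 e⁻)."""
    return Reaction(
        {"S2O3-2": -1.0, "O2": -2.0, "H2O": -1.0, "SO4-2": 2.0, "H+": 2.0},
        n_electrons=8.0,
    )
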