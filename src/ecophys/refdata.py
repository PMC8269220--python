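"""Pinned reference data: formation energies, Debye-Hückel constants, and the
NOSC→Gibbs-energy relation.

All thermodynamic quantities are fixed at 25 °C and 1 bar.  The species table
(``data/species.tsv``) carries SUPCRT92-consistent standard molal Gibbs
energies of formation and Kielland (1937) ion-size parameters; the B-dot
extended Debye-Hückel constants follow Helgeson (1969); the linear relation
between the nominal oxidation state of carbon (NOSC) and the standard Gibbs
energy of the organic-carbon oxidation half reaction is that of LaRowe &
Van Cappellen (2011).
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass

import pandas as pd

#: Gas constant, kJ mol^-1 K^-1.
R_KJ = 8.314462618e-3

#: Reference temperature (K) at which the pinned data are valid.
T_REF = 298.15

# B-dot extended Debye-Hückel constants at 25 C (Helgeson 1969):
# log10(gamma_i) = -A z_i^2 sqrt(I) / (1 + a_i B sqrt(I)) + Bdot I
DH_A = 0.5092       # kg^1/2 mol^-1/2
DH_B = 0.3283       # 1/(Angstrom kg^-1/2 mol^1/2)
DH_BDOT = 0.041     # kg mol^-1
DEFAULT_ION_SIZE = 4.0  # Angstrom, used when a charged species lacks a value

# Standard Gibbs energy of the organic-carbon oxidation half reaction
# (organic C -> bicarbonate), kJ per mol C, as a linear function of NOSC:
#   dG0_Cox = NOSC_GIBBS_INTERCEPT + NOSC_GIBBS_SLOPE * NOSC
# (LaRowe & Van Cappellen 2011).
NOSC_GIBBS_INTERCEPT = 60.3
NOSC_GIBBS_SLOPE = -28.5

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str) -> dict[str, float]:
    """Parse a Hill-notation formula string into an element→count mapping.

    Counts may be fractional (composite pseudo-species); plain formulas give
    integer-valued floats.
    """
    if not formula or not formula.strip():
        raise ValueError("empty formula")
    counts: dict[str, float] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula.strip()):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        element = m.group(1)
        n = float(m.group(2)) if m.group(2) else 1.0
        if n < 0:
            raise ValueError(f"negative count in {formula!r}")
        counts[element] = counts.get(element, 0.0) + n
    if pos != len(formula.strip()):
        raise ValueError(f"cannot parse formula {formula!r}")
    if not any(v > 0 for v in counts.values()):
        raise ValueError(f"formula {formula!r} has no atoms")
    return counts


@dataclass(frozen=True)
class ChemicalSpecies:
    """A dissolved or pure-phase species with pinned 25 °C properties.

    Parameters
    ----------
    name : str
        Identifier used in reactions and concentration tables.
    formula : dict
        Element → atom count (nonnegative; fractional only for composites).
    charge : int
        Net charge in elementary units.
    dGf0 : float or None
        Standard molal Gibbs energy of formation at 25 °C, 1 bar (kJ/mol);
        None when unavailable.
    ion_size : float or None
        Debye-Hückel å parameter (Å); None for neutral/pure-phase species.
    phase : str
        One of ``aqueous``, ``liquid``, ``gas``. Pure liquids (water) have
        unit activity under the standard-state convention.
    """

    name: str
    formula: dict
    charge: int
    dGf0: float | None = None
    ion_size: float | None = None
    phase: str = "aqueous"

    def __post_init__(self):
        if any(v < 0 for v in self.formula.values()):
            raise ValueError(f"{self.name}: negative element count")
        if not any(v > 0 for v in self.formula.values()):
            raise ValueError(f"{self.name}: empty formula")
        if self.phase not in ("aqueous", "liquid", "gas"):
            raise ValueError(f"{self.name}: unknown phase {self.phase!r}")


def load_species_table(path=None) -> dict[str, ChemicalSpecies]:
    """Load a species table (TSV) into a name→ChemicalSpecies mapping.

    With no argument, returns the packaged 25 °C reference compilation.
    """
    if path is None:
        ref = importlib.resources.files("ecophys").joinpath("data/species.tsv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    table: dict[str, ChemicalSpecies] = {}
    for row in df.itertuples(index=False):
        dgf = None if pd.isna(row.dGf0_kJ_mol) else float(row.dGf0_kJ_mol)
        a = None if pd.isna(row.ion_size_A) else float(row.ion_size_A)
        table[row.name] = ChemicalSpecies(
            name=row.name,
            formula=parse_formula(row.formula),
            charge=int(row.charge),
            dGf0=dgf,
            ion_size=a,
            phase=row.phase,
        )
    return table
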