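"""Salinity arithmetic for artificial-seawater media design.

Practical salinity is tied to chlorinity by S‰ = 1.80655 Cl‰.  Two
experimental salinity-manipulation schemes are supported: adding NaCl only
(salinity rises affinely with the % w/v of added NaCl through its chloride
mass) and diluting all major ions proportionally (salinity scales linearly
with the dilution factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CHLORINITY_TO_SALINITY",
    "IonComposition",
    "salinity_from_chlorinity",
    "nacl_series",
    "proportional_series",
]

CHLORINITY_TO_SALINITY = 1.80655

# standard atomic weights
_M_CL = 35.453
_M_NACL = 58.443
#: chloride mass fraction of NaCl
CL_MASS_FRACTION_NACL = _M_CL / _M_NACL


def salinity_from_chlorinity(chlorinity: float) -> float:
    """Practical salinity (‰) from chlorinity (g·kg⁻¹): S = 1.80655 × Cl."""
    if chlorinity < 0:
        raise ValueError("chlorinity must be nonnegative")
    return CHLORINITY_TO_SALINITY * chlorinity


def nacl_series(base_salinity: float, nacl_percent_wv: float) -> float:
    """Salinity (‰) of a medium amended with NaCl at the given % w/v.

    % w/v is g per 100 ml; with solution density taken as 1 kg·l⁻¹, the
    added chlorinity is 10 × percent × 35.453/58.443 g·kg⁻¹, converted with
    the chlorinity–salinity constant and added to the base salinity.
    """
    if base_salinity < 0:
        raise ValueError("base salinity must be nonnegative")
    if nacl_percent_wv < 0:
        raise ValueError("NaCl percent must be nonnegative")
    added_chlorinity = 10.0 * nacl_percent_wv * CL_MASS_FRACTION_NACL  # g/kg
    return base_salinity + salinity_from_chlorinity(added_chlorinity)


@dataclass
class IonComposition:
    """Major-ion composition of a medium (masses in g·kg⁻¹ per ion).

    ``base_salinity`` may be given directly (‰); otherwise it is derived
    from the chloride entry via the chlorinity–salinity relation.  Salinity
    scales linearly under proportional dilution of all entries.
    """

    entries: dict = field(default_factory=dict)
    base_salinity: float | None = None

    def __post_init__(self):
        if any(m < 0 for m in self.entries.values()):
            raise ValueError("ion masses must be nonnegative")
        if self.base_salinity is not None and self.base_salinity < 0:
            raise ValueError("salinity must be nonnegative")

    @property
    def salinity(self) -> float:
        if self.base_salinity is not None:
            return self.base_salinity
        if "Cl" not in self.entries:
            raise ValueError("no chloride entry and no base_salinity given")
        return salinity_from_chlorinity(self.entries["Cl"])

    def diluted(self, factor: float) -> "IonComposition":
        if factor <= 0:
            raise ValueError("dilution factor must be positive")
        return IonComposition(
            entries={k: factor * v for k, v in self.entries.items()},
            base_salinity=None
            if self.base_salinity is None
            else factor * self.base_salinity,
        )


def proportional_series(full_strength, dilution_factors) -> list[float]:
    """Salinities (‰) from proportional dilution of all major ions.

    ``full_strength`` is an :class:`IonComposition` (or a plain salinity in
    ‰); each factor must lie in (0, 1].  Salinity is exactly linear in the
    factor.
    """
    if isinstance(full_strength, IonComposition):
        s0 = full_strength.salinity
    else:
        s0 = float(full_strength)
        if s0 < 0:
            raise ValueError("salinity must be nonnegative")
    out = []
    for f in dilution_factors:
        if f <= 0:
            raise ValueError("dilution factor must be positive")
        if f > 1:
            raise ValueError("dilution factor must not exceed 1")
        out.append(f * s0)
    return out
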