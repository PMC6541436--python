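"""Recovery and co-complex stoichiometry arithmetic.

Purifying the surface population of the bait via an irreversibly bound
extracellular probe recovers ``e_purif * f_s`` of total cellular bait.
Comparing that to the fraction of a candidate partner recovered in the
same purification, weighted by their relative cellular abundance, gives
the partner:bait molar ratio in the purified complex.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RecoveryInput", "StoichiometryResult", "bait_recovery_fraction",
           "partner_stoichiometry"]

#: Molar-ratio band treated as "comparable abundance" in the complex.
COMPARABLE_BAND = (0.5, 2.0)


@dataclass(frozen=True)
class RecoveryInput:
    """Inputs of the recovery/stoichiometry arithmetic.

    ``e_purif``: purification efficiency; ``f_s``: surface fraction of
    the bait; ``frac_partner``: fraction of total cellular partner
    recovered; ``abundance_ratio``: cellular partner:bait molar
    abundance (no printed value exists; an explicit input).
    """

    e_purif: float
    f_s: float
    frac_partner: float
    abundance_ratio: float

    def __post_init__(self) -> None:
        for name in ("e_purif", "f_s", "frac_partner"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.abundance_ratio <= 0:
            raise ValueError("abundance_ratio must be positive")

    def evaluate(self) -> "StoichiometryResult":
        frac_bait = bait_recovery_fraction(self.e_purif, self.f_s)
        return partner_stoichiometry(self.frac_partner, frac_bait,
                                     self.abundance_ratio)


@dataclass(frozen=True)
class StoichiometryResult:
    """Partner:bait molar ratio in the purified material."""

    ratio: float
    comparable: bool

    def to_dict(self) -> dict:
        return {"partner_bait_ratio": self.ratio, "comparable": self.comparable}


def bait_recovery_fraction(e_purif: float, f_s: float) -> float:
    """Fraction of total cellular bait recovered in a surface purification.

    The probe marks the surface fraction ``f_s``; purification recovers a
    fraction ``e_purif`` of marked molecules — the product of the two.
    """
    for name, v in (("e_purif", e_purif), ("f_s", f_s)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    return e_purif * f_s


def partner_stoichiometry(frac_partner: float, frac_bait: float,
                          abundance_ratio: float) -> StoichiometryResult:
    """Partner:bait molar ratio in the purified complex.

    ``frac_partner`` and ``frac_bait`` are fractions of the *total
    cellular* pool of each protein recovered; ``abundance_ratio`` is the
    cellular partner:bait molar abundance.  The ratio is scale-invariant
    in the recovered fractions.  ``comparable`` is True when the molar
    ratio falls within a factor of two of 1:1.
    """
    if frac_bait <= 0:
        raise ValueError("frac_bait must be positive")
    if frac_partner < 0:
        raise ValueError("frac_partner must be >= 0")
    if abundance_ratio <= 0:
        raise ValueError("abundance_ratio must be positive")
    ratio = (frac_partner / frac_bait) * abundance_ratio
    lo, hi = COMPARABLE_BAND
    return StoichiometryResult(ratio=ratio, comparable=lo <= ratio <= hi)
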