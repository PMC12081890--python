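"""Weak-acid trans-membrane partitioning of intracellular metabolites.

A weak acid whose neutral (protonated) species equilibrates freely
across the plasma membrane while the anion is membrane-impermeable
accumulates in the more alkaline compartment. At equilibrium the
intracellular-to-extracellular anion ratio is fixed by the two pH
values and the acid's pKa:

    A_in / A_out = (1 + 10**(pH_in - pKa)) / (1 + 10**(pH_out - pKa))

equivalently, solving for the intracellular pH,

    pH_in = pKa + log10( A_in/A_out * (1 + 10**(pH_out - pKa)) - 1 ).

For pyruvate (pKa 2.5) in a bioreactor held at extracellular pH 5, an
intracellular pH of 6 (glucose-starved yeast) gives an accumulation
factor of roughly 10, and pH 7 (glucose growth) roughly 100 — so a few
mM of extracellular pyruvate implies tens of mM inside the cell, enough
to product-inhibit an amine transaminase that releases pyruvate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Molecular weight of pyruvic acid (C3H4O3), g/mol, free-acid scale.
PYRUVATE_MW = 88.06

#: pKa of pyruvic acid.
PYRUVATE_PKA = 2.5


@dataclass(frozen=True)
class WeakAcidParams:
    """Partitioning parameters for one metabolite.

    Parameters
    ----------
    pka
        Acid dissociation exponent (pyruvate: 2.5).
    ph_in, ph_out
        Intracellular and extracellular pH. For yeast, pH_in is about
        6 when glucose-starved and about 7 during glucose growth; the
        bioreactor controls pH_out (here 5).
    mw
        Molecular weight in g/mol, for g/L ↔ mM conversion.
    """

    pka: float
    ph_in: float
    ph_out: float
    mw: float = PYRUVATE_MW

    def __post_init__(self) -> None:
        for name in ("pka", "ph_in", "ph_out"):
            v = getattr(self, name)
            if not 0 < v < 14:
                raise ValueError(f"{name} must lie in (0, 14), got {v}")
        if self.mw <= 0:
            raise ValueError("mw must be positive")


def accumulation_ratio(params: WeakAcidParams) -> float:
    """Equilibrium anion ratio A_in/A_out across the plasma membrane.

    Strictly increasing in pH_in, strictly decreasing in pH_out, and
    exactly 1 when the gradient vanishes.
    """
    return (1 + 10 ** (params.ph_in - params.pka)) / (
        1 + 10 ** (params.ph_out - params.pka)
    )


def ph_in_from_ratio(ratio: float, pka: float, ph_out: float) -> float:
    """Invert :func:`accumulation_ratio` for the intracellular pH.

    Raises
    ------
    ValueError
        If ``ratio * (1 + 10**(ph_out - pka)) <= 1``: such a ratio is
        too small to be produced by any intracellular pH under this
        model (log argument non-positive).
    """
    arg = ratio * (1 + 10 ** (ph_out - pka)) - 1
    if arg <= 0:
        raise ValueError(
            f"ratio {ratio} is too small for pKa {pka}, pH_out {ph_out}: "
            "log10 argument non-positive"
        )
    return pka + math.log10(arg)


def gl_to_mm(concentration_gl: float, mw: float) -> float:
    """Convert a concentration from g/L to mM given a molecular weight."""
    if mw <= 0:
        raise ValueError("mw must be positive")
    if concentration_gl < 0:
        raise ValueError("concentration must be non-negative")
    return concentration_gl / mw * 1000.0


def intracellular_mm(
    extracellular: float, params: WeakAcidParams, unit: str
) -> float:
    """Intracellular concentration (mM) from an extracellular measurement.

    ``unit`` must state the extracellular unit explicitly: ``"g/L"``
    (converted with ``params.mw``) or ``"mM"``. No unit is ever inferred.
    """
    if unit == "g/L":
        extracellular_mm = gl_to_mm(extracellular, params.mw)
    elif unit == "mM":
        if extracellular < 0:
            raise ValueError("concentration must be non-negative")
        extracellular_mm = extracellular
    else:
        raise ValueError(f"unit must be 'g/L' or 'mM', got {unit!r}")
    return extracellular_mm * accumulation_ratio(params)


def round_to_1sf(x: float) -> float:
    """Round to one significant figure (e.g. 9.97 → 10, 99.7 → 100)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent)
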