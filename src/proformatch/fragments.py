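"""Theoretical backbone fragment generation.

Generates neutral monoisotopic masses for the six classical backbone
series. b/y arise from amide-bond cleavage, c/z from N-Calpha cleavage
(the ETD/EThcD channel), a/x from Calpha-carbonyl cleavage. The z series
is emitted as the z-radical (z-dot) species standard for ETD data:
z = y - NH3 + H. All series offsets are derived from elemental
compositions at import time — no floating-point literals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .chem import ElementComposition, WATER_MASS, mass_of_composition, residue_mass
from .errors import InvalidConfigError, NoCleavageSitesError
from .proforma import Proteoform

__all__ = [
    "TheoreticalFragment",
    "generate_fragments",
    "ION_SERIES",
    "N_TERMINAL_SERIES",
    "C_TERMINAL_SERIES",
    "series_offset",
]

ION_SERIES = ("a", "b", "c", "x", "y", "z")
N_TERMINAL_SERIES = frozenset("abc")
C_TERMINAL_SERIES = frozenset("xyz")

_CO = mass_of_composition(ElementComposition.parse("CO"))
_NH3 = mass_of_composition(ElementComposition.parse("NH3"))
_H = mass_of_composition(ElementComposition.parse("H"))
_H2 = mass_of_composition(ElementComposition.parse("H2"))

# Neutral-mass offsets relative to the plain prefix (b) or suffix+water (y)
# residue sums. z is the z-radical: y - NH3 + H.
_SERIES_OFFSET = {
    "a": -_CO,
    "b": 0.0,
    "c": +_NH3,
    "x": +_CO - _H2,
    "y": 0.0,
    "z": -_NH3 + _H,
}


def series_offset(series: str) -> float:
    """Offset of a series from its parent b (N-terminal) or y (C-terminal)."""
    return _SERIES_OFFSET[series]


@dataclass(frozen=True, order=True)
class TheoreticalFragment:
    """One (series, cleavage-index) fragment with its neutral mass.

    ``index`` counts residues in the fragment (1..n-1); ``terminus`` is
    'N' for a/b/c and 'C' for x/y/z.
    """

    series: str
    index: int
    neutral_mass: float

    @property
    def terminus(self) -> str:
        return "N" if self.series in N_TERMINAL_SERIES else "C"


def generate_fragments(
    p: Proteoform, series: Iterable[str]
) -> list[TheoreticalFragment]:
    """All fragments of the selected series, sorted by (series, index).

    Fragment masses include every modification in range: terminal mods,
    localized mods on fragment residues, and fixed mods applied to every
    target residue before summation. For an n-residue proteoform each
    series yields exactly n-1 fragments, and complementary pairs obey
    b_i + y_{n-i} = intact mass exactly.
    """
    series = sorted(set(series))
    if not series:
        raise InvalidConfigError("ion series set must be non-empty")
    unknown = [s for s in series if s not in ION_SERIES]
    if unknown:
        raise InvalidConfigError(
            f"unknown ion series {unknown}; supported: {', '.join(ION_SERIES)}"
        )
    n = len(p)
    if n < 2:
        raise NoCleavageSitesError(
            f"proteoform of length {n} has no cleavage sites"
        )

    per_residue = [
        residue_mass(code) + p.residue_extra_mass(i)
        for i, code in enumerate(p.residues)
    ]
    # prefix[i] = mass of residues 0..i-1 with their mods
    prefix = [0.0]
    for m in per_residue:
        prefix.append(prefix[-1] + m)
    total = prefix[-1]

    n_term = p.n_term_total_mass
    c_term = p.c_term_total_mass

    out: list[TheoreticalFragment] = []
    for s in series:
        off = _SERIES_OFFSET[s]
        if s in N_TERMINAL_SERIES:
            for i in range(1, n):
                out.append(TheoreticalFragment(s, i, prefix[i] + n_term + off))
        else:
            for j in range(1, n):
                suffix = total - prefix[n - j]
                out.append(
                    TheoreticalFragment(s, j, suffix + WATER_MASS + c_term + off)
                )
    return out
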