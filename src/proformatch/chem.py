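"""Elemental compositions, monoisotopic masses and the modification model.

All mass arithmetic in the package bottoms out here. The atomic-mass
table, amino-acid residue compositions, monosaccharide (glycan token)
compositions and the starter PTM catalogue are bundled as plain TSV data
files and loaded once; residue and glycan masses are *derived* from
compositions at load time so there is a single source of truth.

Masses are neutral monoisotopic Da throughout — this library never deals
in charged m/z.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterator, Mapping

from .errors import (
    InvalidModificationError,
    UnknownElementError,
    UnknownGlycanTokenError,
    UnsupportedResidueError,
)

__all__ = [
    "ElementComposition",
    "GlycanComposition",
    "Modification",
    "atomic_mass",
    "mass_of_composition",
    "residue_composition",
    "residue_mass",
    "resolve_modification_mass",
    "load_catalogue",
    "WATER",
    "WATER_MASS",
]

_FORMULA_TOKEN = re.compile(r"(\d*)([A-Z][a-z]?)(-?\d*)")

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

GLYCAN_TOKENS = ("HexNAc", "Hex", "Fuc", "NeuAc", "NeuGc", "Pent")


def _read_table(name: str) -> Iterator[list[str]]:
    text = resources.files("proformatch.data").joinpath(name).read_text("utf-8")
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        yield line.split("\t")


@lru_cache(maxsize=1)
def _atomic_masses() -> dict[str, float]:
    return {sym: float(m) for sym, m in _read_table("atomic_masses.tsv")}


def atomic_mass(symbol: str) -> float:
    """Monoisotopic mass of one atom; isotopes as ``13C`` etc."""
    try:
        return _atomic_masses()[symbol]
    except KeyError:
        raise UnknownElementError(
            f"unknown element symbol {symbol!r}; known symbols: "
            f"{', '.join(sorted(_atomic_masses()))}"
        ) from None


@dataclass(frozen=True)
class ElementComposition:
    """A signed multiset of atoms, e.g. ``{'C': 2, 'H': 3, 'N': 1, 'O': 1}``.

    Zero-count entries are dropped on construction, so two compositions
    describing the same molecule compare equal. Addition and subtraction
    are supported; they are associative and commutative by construction.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for sym, n in self.counts.items():
            if not isinstance(n, int):
                raise TypeError(f"count for {sym!r} must be an integer, got {n!r}")
            if n != 0:
                clean[sym] = n
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, formula: str) -> "ElementComposition":
        """Parse a Hill-style formula such as ``C2H3NO`` or ``H-1NO2``.

        An element token is an optional isotope mass-number prefix, an
        element symbol, and an optional signed count (default 1).
        """
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise UnknownElementError(
                    f"cannot parse formula {formula!r} at {formula[pos:]!r}"
                )
            pos = m.end()
            isotope, sym, count = m.groups()
            key = (isotope + sym) if isotope else sym
            atomic_mass(key)  # validate symbol early
            counts[key] = counts.get(key, 0) + (int(count) if count else 1)
        if pos != len(formula) or not formula:
            raise UnknownElementError(
                f"cannot parse formula {formula!r} at {formula[pos:]!r}"
            )
        return cls(counts)

    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        counts = dict(self.counts)
        for sym, n in other.counts.items():
            counts[sym] = counts.get(sym, 0) + n
        return ElementComposition(counts)

    def __sub__(self, other: "ElementComposition") -> "ElementComposition":
        counts = dict(self.counts)
        for sym, n in other.counts.items():
            counts[sym] = counts.get(sym, 0) - n
        return ElementComposition(counts)

    def __mul__(self, k: int) -> "ElementComposition":
        return ElementComposition({s: n * k for s, n in self.counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementComposition):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    @property
    def mass(self) -> float:
        return mass_of_composition(self)

    def to_formula(self) -> str:
        """Canonical Hill-order formula string (C, H, then alphabetical)."""

        def key(sym: str) -> tuple[int, str]:
            base = sym.lstrip("0123456789")
            order = {"C": 0, "H": 1}.get(base, 2)
            return (order, base, sym)

        parts = []
        for sym in sorted(self.counts, key=key):
            n = self.counts[sym]
            parts.append(f"{sym}{n}" if n != 1 else sym)
        return "".join(parts)


def mass_of_composition(comp: ElementComposition) -> float:
    """Sum of count x monoisotopic atomic mass over the composition."""
    return sum(n * atomic_mass(sym) for sym, n in comp.counts.items())


WATER = ElementComposition({"H": 2, "O": 1})
WATER_MASS = mass_of_composition(WATER)


@lru_cache(maxsize=1)
def _residue_compositions() -> dict[str, ElementComposition]:
    table = {
        code: ElementComposition.parse(formula)
        for code, formula in _read_table("residues.tsv")
    }
    assert set(table) == set(CANONICAL_RESIDUES)
    return table


def residue_composition(code: str) -> ElementComposition:
    try:
        return _residue_compositions()[code]
    except KeyError:
        raise UnsupportedResidueError(
            f"unsupported residue {code!r}; the canonical 20-letter alphabet "
            f"({CANONICAL_RESIDUES}) is supported"
        ) from None


@lru_cache(maxsize=None)
def residue_mass(code: str) -> float:
    """Residue (dehydrated amino-acid) monoisotopic mass."""
    return mass_of_composition(residue_composition(code))


@lru_cache(maxsize=1)
def _glycan_token_masses() -> dict[str, float]:
    return {
        token: mass_of_composition(ElementComposition.parse(formula))
        for token, formula in _read_table("glycan_tokens.tsv")
    }


_GLYCAN_TOKEN_RE = re.compile(r"([A-Z][A-Za-z]*?)(\d+)")


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide counts, e.g. G1F = HexNAc4 Hex4 Fuc1.

    Each token contributes its residue (dehydrated) mass: glycans attach
    and extend through glycosidic bonds, so the water loss per bond is
    already accounted for in the token masses.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        known = _glycan_token_masses()
        for token, n in self.counts.items():
            if token not in known:
                raise UnknownGlycanTokenError(
                    f"unknown monosaccharide token {token!r}; known tokens: "
                    f"{', '.join(GLYCAN_TOKENS)}"
                )
            if not isinstance(n, int) or n < 0:
                raise InvalidModificationError(
                    f"glycan count for {token!r} must be a non-negative integer"
                )
            if n:
                clean[token] = n
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "GlycanComposition":
        """Parse ``HexNAc4Hex4Fuc1``-style composition text.

        Tokens are matched longest-first so ``HexNAc`` is never read as
        ``Hex`` + junk; every token must carry an explicit count.
        """
        counts: dict[str, int] = {}
        pos = 0
        tokens = sorted(_glycan_token_masses(), key=len, reverse=True)
        while pos < len(text):
            for token in tokens:
                if text.startswith(token, pos):
                    m = re.match(r"\d+", text[pos + len(token):])
                    if not m:
                        raise UnknownGlycanTokenError(
                            f"glycan token {token!r} in {text!r} lacks a count"
                        )
                    counts[token] = counts.get(token, 0) + int(m.group(0))
                    pos += len(token) + m.end()
                    break
            else:
                raise UnknownGlycanTokenError(
                    f"cannot parse glycan composition {text!r} at {text[pos:]!r}"
                )
        return cls(counts)

    @property
    def mass(self) -> float:
        table = _glycan_token_masses()
        return sum(n * table[token] for token, n in self.counts.items())

    def to_text(self) -> str:
        """Canonical composition string, fixed token order (HexNAc first)."""
        return "".join(
            f"{t}{self.counts[t]}" for t in GLYCAN_TOKENS if t in self.counts
        )


N_TERM = "N-term"
C_TERM = "C-term"

_CATEGORIES = ("PTM", "fixed", "N-glycan", "custom")


@dataclass(frozen=True)
class Modification:
    """A mass-shifting modification with exactly one mass source.

    The source is a literal Da shift, an elemental formula, or a glycan
    composition. ``targets`` lists residue codes and/or terminus markers
    the modification may sit on; fixed-category modifications are applied
    to *every* target residue of a proteoform and therefore must carry a
    non-empty target set.
    """

    name: str
    category: str = "custom"
    targets: frozenset[str] = frozenset()
    mass_shift: float | None = None
    formula: ElementComposition | None = None
    glycan: GlycanComposition | None = None

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise InvalidModificationError(
                f"category {self.category!r} not one of {_CATEGORIES}"
            )
        sources = [
            s for s in (self.mass_shift, self.formula, self.glycan) if s is not None
        ]
        if len(sources) != 1:
            raise InvalidModificationError(
                f"modification {self.name!r} must have exactly one mass source "
                f"(mass_shift, formula or glycan); got {len(sources)}"
            )
        object.__setattr__(self, "targets", frozenset(self.targets))
        if self.category == "fixed" and not self.targets:
            raise InvalidModificationError(
                f"fixed modification {self.name!r} requires a non-empty target set"
            )
        for t in self.targets:
            if t not in (N_TERM, C_TERM) and t not in CANONICAL_RESIDUES:
                raise InvalidModificationError(
                    f"modification {self.name!r} targets unknown residue {t!r}"
                )

    @property
    def mass(self) -> float:
        return resolve_modification_mass(self)


def resolve_modification_mass(mod: Modification) -> float:
    """Resolved monoisotopic shift in Da; deterministic and repeatable."""
    if mod.mass_shift is not None:
        return mod.mass_shift
    if mod.formula is not None:
        return mass_of_composition(mod.formula)
    assert mod.glycan is not None
    return mod.glycan.mass


@lru_cache(maxsize=1)
def load_catalogue() -> dict[str, Modification]:
    """The starter modification catalogue, keyed by name.

    Users extend it by merging their own :class:`Modification` entries
    into a copy and passing the result to the ProForma parser.
    """
    catalogue: dict[str, Modification] = {}
    for name, category, targets, source_type, source_value in _read_table(
        "ptm_catalogue.tsv"
    ):
        kwargs: dict = {}
        if source_type == "formula":
            kwargs["formula"] = ElementComposition.parse(source_value)
        elif source_type == "glycan":
            kwargs["glycan"] = GlycanComposition.parse(source_value)
        else:
            kwargs["mass_shift"] = float(source_value)
        catalogue[name] = Modification(
            name=name,
            category=category,
            targets=frozenset(targets.split(",")) if targets else frozenset(),
            **kwargs,
        )
    return catalogue
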