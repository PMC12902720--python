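"""ProForma parsing and writing for the supported subset.

Supported: a bare sequence over the canonical 20-letter alphabet;
localized bracketed tags carrying a signed mass delta (``[+79.966331]``),
an elemental formula (``[Formula:HPO3]``), a glycan composition
(``[Glycan:HexNAc4Hex4Fuc1]``) or a catalogue name (``[Phospho]``);
N-/C-terminal tags with the standard ``-`` delimiters; and global fixed
modifications in ``<[tag]@C,M>`` prefix notation.

Unlocalized (``[tag]?SEQ``), labile (``{tag}``) and range
(``(SEQ)[tag]``) modifications are recognized and rejected with an
explicit error naming the feature — never mis-parsed or dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .chem import (
    CANONICAL_RESIDUES,
    C_TERM,
    ElementComposition,
    GlycanComposition,
    Modification,
    N_TERM,
    WATER_MASS,
    load_catalogue,
    residue_mass,
)
from .errors import (
    ProFormaSyntaxError,
    UnknownModificationError,
    UnsupportedProFormaFeatureError,
    UnsupportedResidueError,
)

__all__ = ["Proteoform", "parse_proforma", "write_proforma"]

# 6-decimal printing keeps round-trips stable well below any matching
# tolerance; inputs quantized to 6 decimals round-trip bit-exactly.
_MASS_FMT = "{:+.6f}"

_DELTA_RE = re.compile(r"[+-]\d+(\.\d+)?$")


@dataclass(frozen=True)
class Proteoform:
    """A proteoform: sequence plus terminal, localized and fixed mods.

    ``localized_mods`` is keyed by 0-based residue index internally; all
    user-facing text (ProForma output, .pcml, reports, SVG legend) uses
    1-based positions.
    """

    residues: str
    n_term_mod: Modification | None = None
    c_term_mod: Modification | None = None
    localized_mods: Mapping[int, tuple[Modification, ...]] = field(
        default_factory=dict
    )
    fixed_mods: tuple[Modification, ...] = ()

    def __post_init__(self) -> None:
        for code in self.residues:
            if code not in CANONICAL_RESIDUES:
                raise UnsupportedResidueError(
                    f"unsupported residue {code!r} in sequence"
                )
        clean = {}
        for idx, mods in dict(self.localized_mods).items():
            if not 0 <= idx < len(self.residues):
                raise ProFormaSyntaxError(
                    f"localized modification index {idx} outside sequence of "
                    f"length {len(self.residues)}"
                )
            if mods:
                clean[idx] = tuple(mods)
        object.__setattr__(self, "localized_mods", clean)
        object.__setattr__(self, "fixed_mods", tuple(self.fixed_mods))

    def __len__(self) -> int:
        return len(self.residues)

    def fixed_mod_mass_at(self, index: int) -> float:
        """Summed fixed-modification mass applying to residue ``index``."""
        code = self.residues[index]
        return sum(m.mass for m in self.fixed_mods if code in m.targets)

    def residue_extra_mass(self, index: int) -> float:
        """Localized + fixed modification mass carried by one residue."""
        extra = self.fixed_mod_mass_at(index)
        for m in self.localized_mods.get(index, ()):
            extra += m.mass
        return extra

    @property
    def n_term_total_mass(self) -> float:
        total = self.n_term_mod.mass if self.n_term_mod else 0.0
        total += sum(m.mass for m in self.fixed_mods if N_TERM in m.targets)
        return total

    @property
    def c_term_total_mass(self) -> float:
        total = self.c_term_mod.mass if self.c_term_mod else 0.0
        total += sum(m.mass for m in self.fixed_mods if C_TERM in m.targets)
        return total

    @property
    def intact_mass(self) -> float:
        """Theoretical intact neutral monoisotopic mass.

        Sum of residue masses + one water + every resolved modification
        (fixed mods counted once per matching residue/terminus).
        """
        total = WATER_MASS + self.n_term_total_mass + self.c_term_total_mass
        for i, code in enumerate(self.residues):
            total += residue_mass(code) + self.residue_extra_mass(i)
        return total


def _resolve_tag(tag: str, catalogue: Mapping[str, Modification]) -> Modification:
    """Turn one bracketed tag body into a Modification."""
    if not tag:
        raise ProFormaSyntaxError("empty modification tag '[]'")
    if _DELTA_RE.match(tag):
        return Modification(name=tag, category="custom", mass_shift=float(tag))
    lowered = tag.lower()
    if lowered.startswith("formula:"):
        comp = ElementComposition.parse(tag[len("formula:"):].replace(" ", ""))
        return Modification(
            name=f"Formula:{comp.to_formula()}", category="custom", formula=comp
        )
    if lowered.startswith("glycan:"):
        gly = GlycanComposition.parse(tag[len("glycan:"):].replace(" ", ""))
        return Modification(
            name=f"Glycan:{gly.to_text()}", category="custom", glycan=gly
        )
    for prefix in ("info:", "gno:", "resid:", "xlmod:", "mod:", "unimod:", "u:"):
        if lowered.startswith(prefix):
            raise UnsupportedProFormaFeatureError(
                f"tag prefix {tag.split(':', 1)[0] + ':'!r} is not supported; "
                "use a catalogue name, a signed mass delta, Formula: or Glycan:"
            )
    if tag in catalogue:
        return catalogue[tag]
    # case-insensitive fallback so [phospho] resolves
    for name, mod in catalogue.items():
        if name.lower() == lowered:
            return mod
    raise UnknownModificationError(
        f"modification name {tag!r} not found in the catalogue"
    )


def _read_bracketed(text: str, pos: int) -> tuple[str, int]:
    """Return the tag body starting at ``text[pos] == '['`` and the end."""
    depth = 0
    for i in range(pos, len(text)):
        if text[i] == "[":
            depth += 1
        elif text[i] == "]":
            depth -= 1
            if depth == 0:
                return text[pos + 1 : i], i + 1
    raise ProFormaSyntaxError(f"unbalanced '[' at position {pos} in {text!r}")


def parse_proforma(
    text: str, catalogue: Mapping[str, Modification] | None = None
) -> Proteoform:
    """Parse a ProForma string into a :class:`Proteoform`.

    ``catalogue`` defaults to the bundled starter catalogue; pass a merged
    mapping to resolve user-defined modification names.
    """
    if not text or not text.strip():
        raise ProFormaSyntaxError("empty ProForma string")
    text = text.strip()
    catalogue = load_catalogue() if catalogue is None else catalogue

    fixed_mods: list[Modification] = []
    pos = 0
    # global fixed-modification prefix: <[tag]@T1,T2> (repeatable)
    while pos < len(text) and text[pos] == "<":
        end = text.find(">", pos)
        if end < 0:
            raise ProFormaSyntaxError(f"unbalanced '<' at position {pos}")
        body = text[pos + 1 : end]
        m = re.fullmatch(r"\[(?P<tag>[^\]]+)\]@(?P<targets>[A-Za-z,\- ]+)", body)
        if not m:
            raise UnsupportedProFormaFeatureError(
                f"unsupported global notation <{body}>; expected <[tag]@T1,T2>"
            )
        base = _resolve_tag(m.group("tag"), catalogue)
        targets = frozenset(t.strip() for t in m.group("targets").split(","))
        for t in targets:
            if t not in CANONICAL_RESIDUES and t not in (N_TERM, C_TERM):
                raise UnsupportedResidueError(
                    f"fixed modification target {t!r} is not a canonical residue"
                )
        fixed_mods.append(
            Modification(
                name=base.name,
                category="fixed",
                targets=targets,
                mass_shift=base.mass_shift,
                formula=base.formula,
                glycan=base.glycan,
            )
        )
        pos = end + 1

    if pos < len(text) and text[pos] == "{":
        raise UnsupportedProFormaFeatureError(
            "labile modifications '{...}' are not supported"
        )

    n_term_mod: Modification | None = None
    if pos < len(text) and text[pos] == "[":
        tag, after = _read_bracketed(text, pos)
        if after < len(text) and text[after] == "-":
            n_term_mod = _resolve_tag(tag, catalogue)
            pos = after + 1
        elif after < len(text) and text[after] == "?":
            raise UnsupportedProFormaFeatureError(
                f"unlocalized modifications '[{tag}]?' are not supported"
            )
        elif after < len(text) and text[after] == "^":
            raise UnsupportedProFormaFeatureError(
                f"unlocalized modification multipliers '[{tag}]^n' are not supported"
            )
        else:
            raise ProFormaSyntaxError(
                f"leading tag '[{tag}]' must be terminal ('[{tag}]-') — a tag "
                "before the first residue cannot be localized"
            )

    residues: list[str] = []
    localized: dict[int, list[Modification]] = {}
    c_term_mod: Modification | None = None
    while pos < len(text):
        ch = text[pos]
        if ch == "(":
            raise UnsupportedProFormaFeatureError(
                "range modifications '(...)' are not supported"
            )
        if ch == "{":
            raise UnsupportedProFormaFeatureError(
                "labile modifications '{...}' are not supported"
            )
        if ch == "-":
            # C-terminal tag: -[tag] at end of string
            if pos + 1 >= len(text) or text[pos + 1] != "[":
                raise ProFormaSyntaxError(
                    f"unexpected '-' at position {pos}; expected '-[tag]' at "
                    "the C terminus"
                )
            tag, after = _read_bracketed(text, pos + 1)
            if after != len(text):
                raise ProFormaSyntaxError(
                    "C-terminal tag must end the ProForma string"
                )
            c_term_mod = _resolve_tag(tag, catalogue)
            pos = after
            continue
        if ch == "[":
            if not residues:
                raise ProFormaSyntaxError(
                    f"tag at position {pos} precedes any residue"
                )
            tag, after = _read_bracketed(text, pos)
            if after < len(text) and text[after] in "?^":
                raise UnsupportedProFormaFeatureError(
                    f"unlocalized modifications '[{tag}]{text[after]}' are not "
                    "supported"
                )
            localized.setdefault(len(residues) - 1, []).append(
                _resolve_tag(tag, catalogue)
            )
            pos = after
            continue
        if ch == "?":
            raise UnsupportedProFormaFeatureError(
                "unlocalized modifications ('?') are not supported"
            )
        if ch not in CANONICAL_RESIDUES:
            raise UnsupportedResidueError(
                f"unsupported residue {ch!r} at position {pos}"
            )
        residues.append(ch)
        pos += 1

    if not residues:
        raise ProFormaSyntaxError(f"no residues found in {text!r}")
    return Proteoform(
        residues="".join(residues),
        n_term_mod=n_term_mod,
        c_term_mod=c_term_mod,
        localized_mods={i: tuple(ms) for i, ms in localized.items()},
        fixed_mods=tuple(fixed_mods),
    )


def _write_tag(mod: Modification, catalogue: Mapping[str, Modification]) -> str:
    """Canonical tag text for one modification.

    Catalogue-named mods are emitted by name; formula/glycan customs keep
    their structured notation; anything else becomes a signed mass delta
    printed with 6 decimals.
    """
    entry = catalogue.get(mod.name)
    if entry is not None and entry.mass == mod.mass:
        return mod.name
    if mod.formula is not None:
        return f"Formula:{mod.formula.to_formula()}"
    if mod.glycan is not None:
        return f"Glycan:{mod.glycan.to_text()}"
    return _MASS_FMT.format(mod.mass)


def write_proforma(
    p: Proteoform, catalogue: Mapping[str, Modification] | None = None
) -> str:
    """Write the canonical ProForma string for ``p``.

    ``parse_proforma(write_proforma(p))`` reproduces every resolved mass
    exactly (custom deltas are printed at 6 decimals, so custom masses
    quantized to 6 decimals — as all package inputs are — round-trip
    bit-identically).
    """
    catalogue = load_catalogue() if catalogue is None else catalogue
    parts: list[str] = []
    for mod in p.fixed_mods:
        targets = ",".join(
            sorted(mod.targets, key=lambda t: (len(t), t))
        )
        parts.append(f"<[{_write_tag(mod, catalogue)}]@{targets}>")
    if p.n_term_mod is not None:
        parts.append(f"[{_write_tag(p.n_term_mod, catalogue)}]-")
    for i, code in enumerate(p.residues):
        parts.append(code)
        for mod in p.localized_mods.get(i, ()):
            parts.append(f"[{_write_tag(mod, catalogue)}]")
    if p.c_term_mod is not None:
        parts.append(f"-[{_write_tag(p.c_term_mod, catalogue)}]")
    return "".join(parts)
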