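"""Session persistence: the .pcml dialect and the portable share blob.

A Session bundles everything needed to reproduce a characterization:
the proteoform, the observed mass list, an optional observed intact
mass, the match settings and the render settings. It is persisted as a
versioned XML dialect (.pcml, proteoform characterization markup
language) defined by this package, and as a single-line URL-safe share
blob (canonical XML + CRC32 checksum, base64url-encoded) that replaces
cloud-hosted share links with a portable piece of text.

Writing is canonical: fixed element and attribute order, masses printed
with 6 decimals, so identical Sessions produce byte-identical files and
write -> read -> write is a fixed point. Unknown elements found under
``<extensions>`` are preserved opaquely and re-emitted on write.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .chem import (
    ElementComposition,
    GlycanComposition,
    Modification,
)
from .errors import (
    PcmlParseError,
    PcmlSchemaError,
    PcmlVersionError,
    ShareIntegrityError,
)
from .matching import MatchConfig, ObservedMass
from .proforma import Proteoform
from .svgmap import RenderConfig

__all__ = [
    "Session",
    "read_pcml",
    "write_pcml",
    "session_to_bytes",
    "session_from_bytes",
    "export_share_state",
    "import_share_state",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1.0"

_MASS_FMT = "{:.6f}"


@dataclass(frozen=True)
class Session:
    proteoform: Proteoform
    observed: tuple[ObservedMass, ...] = ()
    observed_intact: float | None = None
    config: MatchConfig = field(default_factory=MatchConfig)
    render: RenderConfig = field(default_factory=RenderConfig)
    schema_version: str = SCHEMA_VERSION
    extensions: tuple[str, ...] = ()  # opaque XML snippets, preserved

    def __post_init__(self) -> None:
        object.__setattr__(self, "observed", tuple(self.observed))
        object.__setattr__(self, "extensions", tuple(self.extensions))

    @property
    def theoretical_mode(self) -> bool:
        return not self.observed


def _mod_element(tag: str, mod: Modification) -> etree._Element:
    el = etree.Element(tag)
    el.set("name", mod.name)
    el.set("category", mod.category)
    if mod.targets:
        el.set("targets", ",".join(sorted(mod.targets, key=lambda t: (len(t), t))))
    if mod.mass_shift is not None:
        el.set("massShift", _MASS_FMT.format(mod.mass_shift))
    elif mod.formula is not None:
        el.set("formula", mod.formula.to_formula())
    else:
        assert mod.glycan is not None
        el.set("glycan", mod.glycan.to_text())
    return el


def _mod_from_element(el: etree._Element) -> Modification:
    name = el.get("name")
    if name is None:
        raise PcmlSchemaError(f"<{el.tag}> missing required attribute 'name'")
    targets = frozenset(
        t for t in (el.get("targets") or "").split(",") if t
    )
    kwargs: dict = {}
    if el.get("massShift") is not None:
        kwargs["mass_shift"] = float(el.get("massShift"))
    elif el.get("formula") is not None:
        kwargs["formula"] = ElementComposition.parse(el.get("formula"))
    elif el.get("glycan") is not None:
        kwargs["glycan"] = GlycanComposition.parse(el.get("glycan"))
    else:
        raise PcmlSchemaError(
            f"<{el.tag} name={name!r}> carries none of massShift/formula/glycan"
        )
    return Modification(
        name=name,
        category=el.get("category", "custom"),
        targets=targets,
        **kwargs,
    )


def session_to_bytes(s: Session) -> bytes:
    """Canonical UTF-8 .pcml serialization of a Session."""
    root = etree.Element("pcml")
    root.set("schemaVersion", s.schema_version)

    proteo = etree.SubElement(root, "proteoform")
    seq = etree.SubElement(proteo, "sequence")
    seq.text = s.proteoform.residues
    if s.proteoform.fixed_mods:
        fixed = etree.SubElement(proteo, "fixedModifications")
        for mod in s.proteoform.fixed_mods:
            fixed.append(_mod_element("modification", mod))
    if s.proteoform.n_term_mod is not None:
        proteo.append(
            _mod_element("nTerminalModification", s.proteoform.n_term_mod)
        )
    if s.proteoform.c_term_mod is not None:
        proteo.append(
            _mod_element("cTerminalModification", s.proteoform.c_term_mod)
        )
    if s.proteoform.localized_mods:
        loc = etree.SubElement(proteo, "localizedModifications")
        for idx in sorted(s.proteoform.localized_mods):
            for mod in s.proteoform.localized_mods[idx]:
                el = _mod_element("modification", mod)
                # .pcml positions are 1-based, matching all reports
                el.attrib["position"] = str(idx + 1)
                loc.append(el)

    obs = etree.SubElement(root, "observedMasses")
    if s.observed_intact is not None:
        obs.set("intactMass", _MASS_FMT.format(s.observed_intact))
    for o in s.observed:
        el = etree.SubElement(obs, "mass")
        el.set("value", _MASS_FMT.format(o.neutral_mass))
        if o.intensity is not None:
            el.set("intensity", "{:.4f}".format(o.intensity))

    cfg = etree.SubElement(root, "matchSettings")
    cfg.set("tolPpm", _MASS_FMT.format(s.config.tol_ppm))
    cfg.set("series", ",".join(sorted(s.config.series)))
    cfg.set("isotopeShifts", str(s.config.n_isotope_shifts))
    cfg.set("isotopeSpacing", _MASS_FMT.format(s.config.isotope_spacing))

    render = etree.SubElement(root, "renderSettings")
    render.set("residuesPerLine", str(s.render.residues_per_line))
    render.set("theme", s.render.theme)
    render.set("targetWidthPx", str(s.render.target_width_px))

    if s.extensions:
        ext = etree.SubElement(root, "extensions")
        for snippet in s.extensions:
            ext.append(etree.fromstring(snippet))

    return etree.tostring(
        root,
        xml_declaration=True,
        encoding="UTF-8",
        pretty_print=True,
    )


def _require(parent: etree._Element, tag: str) -> etree._Element:
    el = parent.find(tag)
    if el is None:
        raise PcmlSchemaError(f"required element '{tag}' is missing")
    return el


def session_from_bytes(data: bytes) -> Session:
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise PcmlParseError(f"malformed .pcml XML: {exc}") from None
    if root.tag != "pcml":
        raise PcmlSchemaError(f"root element must be 'pcml', got {root.tag!r}")
    version = root.get("schemaVersion")
    if version is None:
        raise PcmlSchemaError("required attribute 'schemaVersion' is missing")
    if version.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
        raise PcmlVersionError(
            f"unsupported .pcml schema version {version!r}; this library "
            f"reads {SCHEMA_VERSION.split('.')[0]}.x"
        )

    proteo = _require(root, "proteoform")
    seq_el = _require(proteo, "sequence")
    sequence = (seq_el.text or "").strip()
    if not sequence:
        raise PcmlSchemaError("required element 'sequence' is empty")

    fixed_mods = []
    fixed_el = proteo.find("fixedModifications")
    if fixed_el is not None:
        fixed_mods = [_mod_from_element(el) for el in fixed_el.findall("modification")]
    n_term = proteo.find("nTerminalModification")
    c_term = proteo.find("cTerminalModification")
    localized: dict[int, list[Modification]] = {}
    loc_el = proteo.find("localizedModifications")
    if loc_el is not None:
        for el in loc_el.findall("modification"):
            pos = el.get("position")
            if pos is None:
                raise PcmlSchemaError(
                    "localized <modification> missing required attribute "
                    "'position'"
                )
            localized.setdefault(int(pos) - 1, []).append(_mod_from_element(el))

    proteoform = Proteoform(
        residues=sequence,
        n_term_mod=None if n_term is None else _mod_from_element(n_term),
        c_term_mod=None if c_term is None else _mod_from_element(c_term),
        localized_mods={i: tuple(ms) for i, ms in localized.items()},
        fixed_mods=tuple(fixed_mods),
    )

    obs_el = _require(root, "observedMasses")
    intact = obs_el.get("intactMass")
    observed = tuple(
        ObservedMass(
            neutral_mass=float(el.get("value")),
            intensity=None if el.get("intensity") is None else float(el.get("intensity")),
            id=i,
        )
        for i, el in enumerate(obs_el.findall("mass"))
    )

    cfg_el = _require(root, "matchSettings")
    config = MatchConfig(
        tol_ppm=float(cfg_el.get("tolPpm", "10")),
        series=frozenset((cfg_el.get("series") or "b,c,y,z").split(",")),
        n_isotope_shifts=int(cfg_el.get("isotopeShifts", "0")),
        isotope_spacing=float(cfg_el.get("isotopeSpacing", "1.00235")),
    )

    render_el = root.find("renderSettings")
    if render_el is None:
        render = RenderConfig()
    else:
        rpl_raw = render_el.get("residuesPerLine", "auto")
        render = RenderConfig(
            residues_per_line="auto" if rpl_raw == "auto" else int(rpl_raw),
            theme=render_el.get("theme", "light"),
            target_width_px=int(render_el.get("targetWidthPx", "900")),
        )

    extensions: tuple[str, ...] = ()
    ext_el = root.find("extensions")
    if ext_el is not None:
        extensions = tuple(
            etree.tostring(child, encoding="unicode").strip()
            for child in ext_el
        )

    return Session(
        proteoform=proteoform,
        observed=observed,
        observed_intact=None if intact is None else float(intact),
        config=config,
        render=render,
        schema_version=version,
        extensions=extensions,
    )


def write_pcml(s: Session, path: str | Path) -> None:
    Path(path).write_bytes(session_to_bytes(s))


def read_pcml(path: str | Path) -> Session:
    return session_from_bytes(Path(path).read_bytes())


_SHARE_PREFIX = "PCML1"


def export_share_state(s: Session) -> str:
    """Single-line, URL-safe blob: prefix.crc32.base64url(canonical pcml)."""
    payload = session_to_bytes(s)
    checksum = zlib.crc32(payload) & 0xFFFFFFFF
    b64 = base64.urlsafe_b64encode(payload).decode("ascii")
    return f"{_SHARE_PREFIX}.{checksum:08x}.{b64}"


def import_share_state(blob: str) -> Session:
    blob = blob.strip()
    parts = blob.split(".")
    if len(parts) != 3 or parts[0] != _SHARE_PREFIX:
        raise ShareIntegrityError(
            "not a share blob: expected 'PCML1.<crc32>.<base64>'"
        )
    try:
        payload = base64.urlsafe_b64decode(parts[2].encode("ascii"))
    except Exception:
        raise ShareIntegrityError("share blob payload is not valid base64") from None
    checksum = zlib.crc32(payload) & 0xFFFFFFFF
    try:
        stated = int(parts[1], 16)
    except ValueError:
        raise ShareIntegrityError("share blob checksum is not hexadecimal") from None
    if checksum != stated:
        raise ShareIntegrityError(
            f"share blob checksum mismatch: stated {parts[1]}, computed "
            f"{checksum:08x}"
        )
    return session_from_bytes(payload)
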