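"""Exception hierarchy.

Every error raised by the library derives from :class:`ProformatchError`
so callers (and the CLI) can catch one type. Subclasses are granular
enough that tests can assert on the *kind* of failure, and messages always
name the offending token (element symbol, residue code, tag text, ...).
"""


class ProformatchError(Exception):
    """Base class for all library errors."""


class UnknownElementError(ProformatchError):
    """An element symbol absent from the bundled atomic-mass table."""


class UnsupportedResidueError(ProformatchError):
    """A residue code outside the 20-letter canonical alphabet."""


class InvalidModificationError(ProformatchError):
    """A modification with zero or more than one mass source."""


class UnknownModificationError(ProformatchError):
    """A named modification tag not present in the catalogue."""


class UnknownGlycanTokenError(ProformatchError):
    """A monosaccharide token absent from the glycan table."""


class ProFormaSyntaxError(ProformatchError):
    """Malformed ProForma text (unbalanced brackets, empty tag, ...)."""


class UnsupportedProFormaFeatureError(ProformatchError):
    """A ProForma feature outside the supported subset.

    Unlocalized, labile and range modifications are recognized and
    rejected explicitly rather than mis-parsed.
    """


class InvalidConfigError(ProformatchError):
    """Out-of-range or inconsistent settings."""


class NoCleavageSitesError(ProformatchError):
    """A proteoform shorter than two residues has no backbone to cleave."""


class MassListFormatError(ProformatchError):
    """A mass-list line that is neither a comment nor mass[<TAB>intensity]."""


class PcmlParseError(ProformatchError):
    """Malformed XML in a .pcml file (carries the reported line number)."""


class PcmlSchemaError(ProformatchError):
    """Well-formed XML missing a required .pcml element or attribute."""


class PcmlVersionError(ProformatchError):
    """A .pcml schema version this library does not read."""


class ShareIntegrityError(ProformatchError):
    """A share blob whose checksum does not match its payload."""
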