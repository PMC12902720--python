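"""Matching observed neutral masses to theoretical fragments.

An observed deconvoluted mass m matches fragment f at isotope shift
s (an integer in [-k, +k]) iff

    |m - s * spacing - f.neutral| / f.neutral * 1e6 <= tol_ppm

Shift recovery addresses off-by-n isotoping errors: deconvolution
mis-assigning the monoisotopic peak by n isotopologue positions moves
the reported mass by ~ n x 1.00235 Da. Each enabled shift step adds two
effective ion types (+s and -s) per selected series, a penalty the
scorer charges so shift recovery cannot inflate scores.

Per observed mass one winning match is kept, chosen by smallest |s|,
then smallest |ppm error|, then lowest (series, index); every candidate
is retained in a diagnostic list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isfinite
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidConfigError, MassListFormatError
from .fragments import ION_SERIES, TheoreticalFragment

__all__ = [
    "ObservedMass",
    "MatchConfig",
    "FragmentMatch",
    "MatchSet",
    "match",
    "read_mass_list",
    "parse_mass_list",
    "write_mass_list",
    "DEFAULT_ISOTOPE_SPACING",
]

# Averagine inter-isotopologue spacing (Da), the step by which THRASH-style
# deconvolution errors displace a neutral monoisotopic mass.
DEFAULT_ISOTOPE_SPACING = 1.00235

DEFAULT_SERIES = frozenset("bycz")


@dataclass(frozen=True)
class ObservedMass:
    """One deconvoluted neutral monoisotopic mass from the instrument side."""

    neutral_mass: float
    intensity: float | None = None
    id: int = 0

    def __post_init__(self) -> None:
        if not (isfinite(self.neutral_mass) and self.neutral_mass > 0):
            raise InvalidConfigError(
                f"observed mass must be finite and positive, got "
                f"{self.neutral_mass!r}"
            )
        if self.intensity is not None and self.intensity < 0:
            raise InvalidConfigError("intensity must be non-negative")


@dataclass(frozen=True)
class MatchConfig:
    tol_ppm: float = 10.0
    series: frozenset[str] = DEFAULT_SERIES
    n_isotope_shifts: int = 0
    isotope_spacing: float = DEFAULT_ISOTOPE_SPACING

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise InvalidConfigError("tol_ppm must be positive")
        object.__setattr__(self, "series", frozenset(self.series))
        unknown = self.series - set(ION_SERIES)
        if not self.series or unknown:
            raise InvalidConfigError(
                f"series must be a non-empty subset of {ION_SERIES}, got "
                f"{sorted(self.series)}"
            )
        if self.n_isotope_shifts < 0:
            raise InvalidConfigError("n_isotope_shifts must be >= 0")
        if self.isotope_spacing <= 0:
            raise InvalidConfigError("isotope_spacing must be positive")

    @property
    def effective_ion_types(self) -> int:
        """|series| x (1 + 2k): each shift step adds 2 ion types per series."""
        return len(self.series) * (1 + 2 * self.n_isotope_shifts)


@dataclass(frozen=True)
class FragmentMatch:
    observed_id: int
    observed_mass: float
    fragment: TheoreticalFragment
    shift_steps: int
    ppm_error: float


@dataclass(frozen=True)
class MatchSet:
    """Winning matches plus the full candidate list and the run context."""

    matches: tuple[FragmentMatch, ...]
    candidates: tuple[FragmentMatch, ...]
    config: MatchConfig
    observed: tuple[ObservedMass, ...]
    n_theoretical: int

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    @property
    def n_matched_observed(self) -> int:
        return len(self.matches)


def match(
    observed: Sequence[ObservedMass],
    fragments: Sequence[TheoreticalFragment],
    cfg: MatchConfig,
) -> MatchSet:
    """Match every observed mass against every fragment at every shift.

    Candidate lists keep, per (observed, fragment) pair, the best shift
    (smallest |s|, then |ppm|); the per-observed winner additionally
    minimizes over fragments by (|s|, |ppm|, series, index). Results do
    not depend on input order beyond the observed ids themselves.
    """
    frags = sorted(fragments)
    frag_masses = np.array([f.neutral_mass for f in frags], dtype=float)
    k = cfg.n_isotope_shifts
    shifts = sorted(range(-k, k + 1), key=lambda s: (abs(s), s))
    shift_arr = np.array(shifts, dtype=float)
    winners: list[FragmentMatch] = []
    candidates: list[FragmentMatch] = []
    for obs in observed:
        if not len(frags):
            break
        # ppm[s, f] for every shift x fragment pair at once
        adj = obs.neutral_mass - shift_arr[:, None] * cfg.isotope_spacing
        ppm = (adj - frag_masses[None, :]) / frag_masses[None, :] * 1e6
        hit_s, hit_f = np.nonzero(np.abs(ppm) <= cfg.tol_ppm)
        per_pair: dict[int, FragmentMatch] = {}
        for si, fi in zip(hit_s.tolist(), hit_f.tolist()):
            cand = FragmentMatch(
                observed_id=obs.id,
                observed_mass=obs.neutral_mass,
                fragment=frags[fi],
                shift_steps=shifts[si],
                ppm_error=float(ppm[si, fi]),
            )
            best = per_pair.get(fi)
            if best is None or (abs(cand.shift_steps), abs(cand.ppm_error)) < (
                abs(best.shift_steps),
                abs(best.ppm_error),
            ):
                per_pair[fi] = cand
        if per_pair:
            pair_matches = sorted(
                per_pair.values(),
                key=lambda m: (
                    abs(m.shift_steps),
                    abs(m.ppm_error),
                    m.fragment.series,
                    m.fragment.index,
                ),
            )
            candidates.extend(
                sorted(pair_matches, key=lambda m: (m.fragment.series, m.fragment.index))
            )
            winners.append(pair_matches[0])
    return MatchSet(
        matches=tuple(winners),
        candidates=tuple(candidates),
        config=cfg,
        observed=tuple(observed),
        n_theoretical=len(frags),
    )


def parse_mass_list(text: str) -> list[ObservedMass]:
    """Parse the mass-list text format.

    UTF-8 text, one neutral mass per line, optional tab-separated
    intensity; blank lines and lines starting with '#' are ignored. The
    parse is bit-exact: values are read with float() untouched.
    """
    out: list[ObservedMass] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) > 2:
            raise MassListFormatError(
                f"line {lineno}: expected mass[<TAB>intensity], got "
                f"{len(fields)} fields"
            )
        try:
            mass = float(fields[0])
            intensity = float(fields[1]) if len(fields) == 2 else None
        except ValueError as exc:
            raise MassListFormatError(f"line {lineno}: {exc}") from None
        out.append(ObservedMass(neutral_mass=mass, intensity=intensity, id=len(out)))
    return out


def read_mass_list(path: str | Path) -> list[ObservedMass]:
    return parse_mass_list(Path(path).read_text("utf-8"))


def write_mass_list(path: str | Path, observed: Iterable[ObservedMass]) -> None:
    """Write masses with 6 decimals, one per line, intensity tab-separated."""
    lines = ["# neutral_mass\tintensity"]
    for obs in observed:
        if obs.intensity is None:
            lines.append(f"{obs.neutral_mass:.6f}")
        else:
            lines.append(f"{obs.neutral_mass:.6f}\t{obs.intensity:.4f}")
    Path(path).write_text("\n".join(lines) + "\n", "utf-8")
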