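"""Shared fixtures, hypothesis strategies and independent test oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, strategies as st

from proformatch.chem import CANONICAL_RESIDUES, Modification, load_catalogue
from proformatch.fragments import TheoreticalFragment
from proformatch.matching import MatchConfig, ObservedMass
from proformatch.proforma import Proteoform

settings.register_profile("det", derandomize=True, max_examples=50)
settings.load_profile("det")


# --- strategies -----------------------------------------------------------

sequences = st.text(alphabet=CANONICAL_RESIDUES, min_size=2, max_size=30)

# custom mass deltas quantized to 6 decimals: the package's text formats
# print 6 decimals, so these round-trip exactly
custom_masses = st.floats(
    min_value=-200.0, max_value=2000.0, allow_nan=False, allow_infinity=False
).map(lambda x: round(x, 6)).filter(lambda x: x != 0.0)


def _custom_mod(mass: float, tag: str = "custom") -> Modification:
    return Modification(name=f"{mass:+.6f}", category="custom", mass_shift=mass)


@st.composite
def proteoforms(draw) -> Proteoform:
    """Random proteoforms with catalogue, custom and fixed modifications."""
    seq = draw(sequences)
    catalogue = load_catalogue()
    localized: dict[int, tuple[Modification, ...]] = {}
    n_mods = draw(st.integers(0, min(3, len(seq))))
    indices = draw(
        st.lists(
            st.integers(0, len(seq) - 1),
            min_size=n_mods,
            max_size=n_mods,
            unique=True,
        )
    )
    for idx in indices:
        named = [
            m for m in catalogue.values()
            if seq[idx] in m.targets and m.category in ("PTM", "N-glycan")
        ]
        if named and draw(st.booleans()):
            localized[idx] = (draw(st.sampled_from(sorted(named, key=lambda m: m.name))),)
        else:
            localized[idx] = (_custom_mod(draw(custom_masses)),)
    n_term = _custom_mod(draw(custom_masses)) if draw(st.booleans()) else None
    c_term = _custom_mod(draw(custom_masses)) if draw(st.booleans()) else None
    fixed: tuple[Modification, ...] = ()
    if "C" in seq and draw(st.booleans()):
        base = catalogue["Carbamidomethyl"]
        fixed = (base,)
    return Proteoform(
        residues=seq,
        n_term_mod=n_term,
        c_term_mod=c_term,
        localized_mods=localized,
        fixed_mods=fixed,
    )


# --- independent matcher oracle ------------------------------------------


def brute_force_match(
    observed: list[ObservedMass],
    fragments: list[TheoreticalFragment],
    cfg: MatchConfig,
) -> tuple[set, set]:
    """Exhaustive all-pairs, all-shifts reference matcher.

    Returns (winner triples, candidate triples) as sets of
    (observed_id, series, index, shift_steps). Deliberately written as
    plain nested loops with no shared code with the implementation.
    """
    k = cfg.n_isotope_shifts
    winners = set()
    candidates = set()
    for obs in observed:
        scored = []
        for frag in fragments:
            for s in range(-k, k + 1):
                adjusted = obs.neutral_mass - s * cfg.isotope_spacing
                ppm = (adjusted - frag.neutral_mass) / frag.neutral_mass * 1e6
                if abs(ppm) <= cfg.tol_ppm:
                    scored.append(
                        (abs(s), abs(ppm), frag.series, frag.index, s, frag)
                    )
        # per (observed, fragment) pair keep the best shift only
        best_per_pair = {}
        for item in scored:
            key = (item[5].series, item[5].index)
            if key not in best_per_pair or item[:2] < best_per_pair[key][:2]:
                best_per_pair[key] = item
        for item in best_per_pair.values():
            candidates.add((obs.id, item[2], item[3], item[4]))
        if best_per_pair:
            win = min(best_per_pair.values())
            winners.add((obs.id, win[2], win[3], win[4]))
    return winners, candidates


def match_triples(ms) -> tuple[set, set]:
    """The implementation's matches in the oracle's triple form."""
    return (
        {
            (m.observed_id, m.fragment.series, m.fragment.index, m.shift_steps)
            for m in ms.matches
        },
        {
            (m.observed_id, m.fragment.series, m.fragment.index, m.shift_steps)
            for m in ms.candidates
        },
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
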