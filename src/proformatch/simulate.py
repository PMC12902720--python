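"""Synthetic observed-mass generation with ground truth.

Emulates the flat neutral-mass lists a deconvolution engine (THRASH and
kin) emits for a top-down fragmentation experiment: a subset of the true
theoretical fragments perturbed by ppm-scale mass error, a fraction of
them displaced by one isotopologue spacing in either direction (the
classic off-by-one monoisotopic mis-assignment), plus uniform decoy
masses. Every generated mass is tagged in a ground-truth table so
recovery rates can be measured exactly.

What this generator does NOT emulate: isotope envelopes, intensity
structure, correlated/systematic mass error, overlapping fragment
species, or decoys clustered near real fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidConfigError
from .fragments import TheoreticalFragment, generate_fragments
from .matching import DEFAULT_ISOTOPE_SPACING, ObservedMass
from .proforma import Proteoform

__all__ = ["GroundTruth", "simulate_observed", "write_ground_truth", "DEMO_PROFORMA"]

# Synthetic demo proteoform: an Fc-like 119-residue glycoprotein subunit
# (invented sequence, not any database entry) carrying a biantennary G1F
# N-glycan at N61, in the spirit of antibody Fc/2 characterization runs.
DEMO_PROFORMA = (
    "GPSVFLFPPKPKDTLMISRTPEVTCVVVDVSHEDPEVKFNWYVDGVEVHNAKTKPREEQY"
    "N[G1F]STYRVVSVLTVLHQDWLNGKEYKCKVSNKALPAPIEKTISKAKGQPREPQVYTLPPSR"
)


@dataclass(frozen=True)
class GroundTruth:
    """Provenance of one observed mass: planted fragment or decoy."""

    observed_id: int
    kind: str  # "fragment" | "decoy"
    series: str | None
    index: int | None
    shift_steps: int  # isotope displacement applied at generation


def simulate_observed(
    p: Proteoform,
    series: Iterable[str] = frozenset("bycz"),
    frac_matched: float = 0.5,
    ppm_sigma: float = 1.0,
    n_decoys: int = 0,
    n_isotope_corrupted: int = 0,
    spacing: float = DEFAULT_ISOTOPE_SPACING,
    seed: int = 0,
) -> tuple[list[ObservedMass], list[GroundTruth]]:
    """Generate a seeded observed-mass list with known provenance.

    Samples ``round(frac_matched * n_fragments)`` theoretical fragments
    without replacement, perturbs each by Gaussian ppm noise of width
    ``ppm_sigma``, displaces ``n_isotope_corrupted`` of them by one
    isotopologue spacing with random sign, adds ``n_decoys`` uniform
    masses in (100, intact mass), shuffles, and rounds every mass to 6
    decimals (deconvolution report precision — also what makes sessions
    built from simulated data round-trip exactly through .pcml).
    """
    if not 0.0 <= frac_matched <= 1.0:
        raise InvalidConfigError(
            f"frac_matched must be in [0, 1], got {frac_matched}"
        )
    if ppm_sigma < 0 or n_decoys < 0 or n_isotope_corrupted < 0:
        raise InvalidConfigError("noise/decoy parameters must be non-negative")
    rng = np.random.default_rng(seed)
    fragments = generate_fragments(p, series)
    n_pick = round(frac_matched * len(fragments))
    if n_isotope_corrupted > n_pick:
        raise InvalidConfigError(
            f"n_isotope_corrupted={n_isotope_corrupted} exceeds the "
            f"{n_pick} sampled fragments"
        )
    picked_idx = rng.choice(len(fragments), size=n_pick, replace=False)
    corrupt_pos = set(
        rng.choice(n_pick, size=n_isotope_corrupted, replace=False).tolist()
    ) if n_pick else set()

    entries: list[tuple[float, str, str | None, int | None, int]] = []
    for pos, fi in enumerate(picked_idx.tolist()):
        frag: TheoreticalFragment = fragments[fi]
        mass = frag.neutral_mass * (1.0 + rng.normal(0.0, ppm_sigma) * 1e-6)
        shift = 0
        if pos in corrupt_pos:
            shift = int(rng.choice([-1, 1]))
            mass += shift * spacing
        entries.append((mass, "fragment", frag.series, frag.index, shift))

    intact = p.intact_mass
    for _ in range(n_decoys):
        entries.append(
            (float(rng.uniform(100.0, intact)), "decoy", None, None, 0)
        )

    order = rng.permutation(len(entries))
    observed: list[ObservedMass] = []
    truth: list[GroundTruth] = []
    for new_id, old in enumerate(order.tolist()):
        mass, kind, ser, idx, shift = entries[old]
        observed.append(ObservedMass(neutral_mass=round(mass, 6), id=new_id))
        truth.append(
            GroundTruth(
                observed_id=new_id, kind=kind, series=ser, index=idx,
                shift_steps=shift,
            )
        )
    return observed, truth


def write_ground_truth(path: str | Path, truth: Sequence[GroundTruth]) -> None:
    """TSV: observed_id, kind, series, index, shift_steps."""
    lines = ["observed_id\tkind\tseries\tindex\tshift_steps"]
    for t in truth:
        lines.append(
            f"{t.observed_id}\t{t.kind}\t{t.series or ''}\t"
            f"{'' if t.index is None else t.index}\t{t.shift_steps}"
        )
    Path(path).write_text("\n".join(lines) + "\n", "utf-8")
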