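"""Report metrics: coverage, Poisson P-score, PCS, intact-mass deltas.

The P-score asks: how probable is it to see at least this many fragment
matches by chance alone? Each observed mass i opens a ppm half-window
delta_i = m_i * tol_ppm * 1e-6 around every theoretical mass; under a
null in which observed masses fall uniformly in (0, intact_mass), its
single-mass random-match probability is

    q_i = min(1, F_eff * 2 * delta_i / intact_mass)

with F_eff = (n - 1) * |series| * (1 + 2k) the effective number of
theoretical targets: n - 1 cleavage sites, |series| ion types, and the
(1 + 2k) inflation charged for k enabled isotope-shift steps (each step
adds two ion types per series — a +shift and a -shift channel). The
expected chance-match count is lambda = sum_i q_i, and

    P-score = P(X >= n_matched),  X ~ Poisson(lambda)

computed through the regularized incomplete gamma function (survival
form) for stability at large lambda. Lower is better; zero matches give
exactly 1.0.

PCS (proteoform characterization score) rewards each matched fragment
by its information content:

    PCS = sum over matched observed masses of -log10(q_i)

so more matches and tighter windows raise PCS, while enabling isotope
shifts inflates every q_i by (1 + 2k) and lowers it — shift recovery can
never improve either score for free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import log, log10
from pathlib import Path

import numpy as np

from scipy.special import gammainc, gammaln, logsumexp

from .fragments import N_TERMINAL_SERIES
from .matching import MatchSet
from .proforma import Proteoform

__all__ = [
    "ScoreReport",
    "sequence_coverage",
    "covered_sites",
    "p_score",
    "p_score_log10",
    "pcs",
    "intact_mass_difference",
    "build_report",
    "write_report_json",
    "write_report_tsv",
]


def covered_sites(ms: MatchSet, n_residues: int) -> tuple[set[int], set[int]]:
    """Cleavage sites evidenced from each terminus, as two sets of 1..n-1.

    Site i lies between residues i and i+1 (1-based). A matched
    N-terminal-series fragment of index i covers site i; a matched
    C-terminal-series fragment of index j covers site n - j.
    """
    n_sites: set[int] = set()
    c_sites: set[int] = set()
    for m in ms.matches:
        if m.fragment.series in N_TERMINAL_SERIES:
            site = m.fragment.index
        else:
            site = n_residues - m.fragment.index
        if 1 <= site <= n_residues - 1:
            (n_sites if m.fragment.series in N_TERMINAL_SERIES else c_sites).add(site)
    return n_sites, c_sites


def sequence_coverage(ms: MatchSet, n_residues: int) -> tuple[int, float]:
    """(number of covered cleavage sites, fraction of the n-1 sites)."""
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    n_sites, c_sites = covered_sites(ms, n_residues)
    covered = n_sites | c_sites
    return len(covered), len(covered) / (n_residues - 1)


def _match_probabilities(ms: MatchSet, intact_mass: float) -> list[float]:
    """q_i for every observed mass under the uniform-null model."""
    cfg = ms.config
    # F_eff = (n-1) * |series| * (1+2k); n_theoretical is already (n-1)*|series|
    f_eff = ms.n_theoretical * (1 + 2 * cfg.n_isotope_shifts)
    qs = []
    for obs in ms.observed:
        delta = obs.neutral_mass * cfg.tol_ppm * 1e-6
        qs.append(min(1.0, f_eff * 2.0 * delta / intact_mass))
    return qs


def p_score(ms: MatchSet, intact_mass: float) -> float:
    """Poisson upper-tail probability of >= n_matched chance matches.

    Clamped to the smallest positive float when the tail underflows
    (hundreds of matches give P-scores far below 1e-308); use
    :func:`p_score_log10` for the exact magnitude.
    """
    value = 10.0 ** p_score_log10(ms, intact_mass)
    return max(value, 5e-324) if value < 1.0 else 1.0


def p_score_log10(ms: MatchSet, intact_mass: float) -> float:
    """log10 of the P-score, computed stably for extreme tails."""
    if intact_mass <= 0:
        raise ValueError("intact_mass must be positive")
    n_matched = ms.n_matched_observed
    if n_matched == 0:
        return 0.0
    lam = sum(_match_probabilities(ms, intact_mass))
    if lam == 0.0:
        return float("-inf")
    # P(X >= n) for X ~ Poisson(lam) is the regularized lower incomplete
    # gamma function P(n, lam) — the survival-form contract.
    tail = float(gammainc(n_matched, lam))
    if tail > 1e-280:
        return log10(tail)
    # deep tail: sum Poisson log-pmfs n..n+w in log space; terms decay
    # geometrically by lam/(n+1) < 1 here, so a short window suffices
    i = n_matched + np.arange(0, 64)
    log_pmf = -lam + i * log(lam) - gammaln(i + 1)
    return float(logsumexp(log_pmf)) / log(10.0)


def pcs(ms: MatchSet, intact_mass: float) -> float:
    """Sum of -log10(q_i) over matched observed masses; 0 with no matches."""
    if intact_mass <= 0:
        raise ValueError("intact_mass must be positive")
    if not ms.matches:
        return 0.0
    qs = _match_probabilities(ms, intact_mass)
    by_id = {obs.id: q for obs, q in zip(ms.observed, qs)}
    return sum(-log10(by_id[m.observed_id]) for m in ms.matches)


def intact_mass_difference(
    theoretical: float, observed: float | None
) -> tuple[float, float] | None:
    """(Da difference, ppm difference), or None in theoretical mode."""
    if theoretical <= 0:
        raise ValueError("theoretical intact mass must be positive")
    if observed is None:
        return None
    da = observed - theoretical
    return da, da / theoretical * 1e6


@dataclass(frozen=True)
class ScoreReport:
    n_matched_observed: int
    n_covered_sites: int
    coverage_fraction: float
    p_score: float
    p_score_log10: float
    pcs: float
    intact_mass_theoretical: float
    intact_mass_observed: float | None
    mass_difference_da: float | None
    mass_difference_ppm: float | None
    effective_ion_types: int


def build_report(
    p: Proteoform, ms: MatchSet, observed_intact: float | None = None
) -> ScoreReport:
    """Assemble every report metric for one proteoform/match-set pair."""
    theo = p.intact_mass
    n_cov, frac = sequence_coverage(ms, len(p))
    diff = intact_mass_difference(theo, observed_intact)
    return ScoreReport(
        n_matched_observed=ms.n_matched_observed,
        n_covered_sites=n_cov,
        coverage_fraction=frac,
        p_score=p_score(ms, theo),
        p_score_log10=p_score_log10(ms, theo),
        pcs=pcs(ms, theo),
        intact_mass_theoretical=theo,
        intact_mass_observed=observed_intact,
        mass_difference_da=None if diff is None else diff[0],
        mass_difference_ppm=None if diff is None else diff[1],
        effective_ion_types=ms.config.effective_ion_types,
    )


def _report_dict(report: ScoreReport, ms: MatchSet) -> dict:
    cfg = ms.config
    return {
        "settings": {
            "tol_ppm": cfg.tol_ppm,
            "series": "".join(sorted(cfg.series)),
            "n_isotope_shifts": cfg.n_isotope_shifts,
            "isotope_spacing": cfg.isotope_spacing,
        },
        "scores": {
            "n_observed": ms.n_observed,
            "n_theoretical": ms.n_theoretical,
            "n_matched_observed": report.n_matched_observed,
            "n_covered_sites": report.n_covered_sites,
            "coverage_fraction": report.coverage_fraction,
            "p_score": report.p_score,
            "p_score_log10": report.p_score_log10,
            "pcs": report.pcs,
            "intact_mass_theoretical": report.intact_mass_theoretical,
            "intact_mass_observed": report.intact_mass_observed,
            "mass_difference_da": report.mass_difference_da,
            "mass_difference_ppm": report.mass_difference_ppm,
            "effective_ion_types": report.effective_ion_types,
        },
        "matches": [
            {
                "series": m.fragment.series,
                "index": m.fragment.index,
                "theoretical_mass": m.fragment.neutral_mass,
                "observed_mass": m.observed_mass,
                "shift_steps": m.shift_steps,
                "ppm_error": m.ppm_error,
            }
            for m in ms.matches
        ],
    }


def write_report_json(
    path: str | Path, report: ScoreReport, ms: MatchSet
) -> None:
    Path(path).write_text(
        json.dumps(_report_dict(report, ms), indent=2) + "\n", "utf-8"
    )


def write_report_tsv(path: str | Path, report: ScoreReport, ms: MatchSet) -> None:
    """Key/value header block followed by one row per winning match."""
    d = _report_dict(report, ms)
    lines = []
    for section in ("settings", "scores"):
        for key, value in d[section].items():
            lines.append(f"# {key}\t{value}")
    lines.append("series\tindex\ttheoretical_mass\tobserved_mass\tshift_steps\tppm_error")
    for m in d["matches"]:
        lines.append(
            f"{m['series']}\t{m['index']}\t{m['theoretical_mass']:.6f}\t"
            f"{m['observed_mass']:.6f}\t{m['shift_steps']}\t{m['ppm_error']:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n", "utf-8")
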