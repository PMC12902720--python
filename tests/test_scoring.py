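"""Coverage, Poisson P-score, PCS and intact-mass difference metrics."""

import dataclasses
import math

import numpy as np
import pytest

import proformatch as pf
from proformatch.matching import FragmentMatch, MatchConfig, MatchSet, ObservedMass
from proformatch.fragments import TheoreticalFragment, generate_fragments
from proformatch.scoring import (
    build_report,
    intact_mass_difference,
    p_score,
    pcs,
    sequence_coverage,
)
from proformatch.simulate import DEMO_PROFORMA


def make_matchset(matches, observed, cfg, n_theoretical):
    return MatchSet(
        matches=tuple(matches),
        candidates=tuple(matches),
        config=cfg,
        observed=tuple(observed),
        n_theoretical=n_theoretical,
    )


def one_match(series="b", index=3, mass=331.2, obs_id=0):
    frag = TheoreticalFragment(series, index, mass)
    return FragmentMatch(
        observed_id=obs_id,
        observed_mass=mass,
        fragment=frag,
        shift_steps=0,
        ppm_error=0.0,
    )


EMPTY = make_matchset([], [], MatchConfig(series=frozenset("by")), 12)


class TestCoverage:
    def test_empty_matchset_covers_nothing(self):
        assert sequence_coverage(EMPTY, 7) == (0, 0.0)

    def test_single_b3_covers_site_3(self):
        ms = make_matchset(
            [one_match("b", 3)],
            [ObservedMass(331.2, id=0)],
            MatchConfig(series=frozenset("by")),
            12,
        )
        assert sequence_coverage(ms, 7) == (1, pytest.approx(1 / 6))

    def test_b3_and_y4_cover_the_same_site_once(self):
        # on n=7, y4 evidences site 7-4 = 3, same as b3: no double count
        ms = make_matchset(
            [one_match("b", 3), one_match("y", 4, mass=480.0, obs_id=1)],
            [ObservedMass(331.2, id=0), ObservedMass(480.0, id=1)],
            MatchConfig(series=frozenset("by")),
            12,
        )
        assert sequence_coverage(ms, 7) == (1, pytest.approx(1 / 6))


class TestEffectiveIonTypes:
    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    @pytest.mark.parametrize("nseries", [1, 2, 3, 4, 5, 6])
    def test_ion_type_accounting(self, k, nseries):
        """Each off-by-one step adds 2 ion types per selected series."""
        cfg = MatchConfig(
            series=frozenset("abcxyz"[:nseries]), n_isotope_shifts=k
        )
        assert cfg.effective_ion_types == nseries * (1 + 2 * k)


class TestPScore:
    def test_zero_matches_give_exactly_one(self):
        assert p_score(EMPTY, 10000.0) == 1.0

    def test_poisson_tail_against_closed_form(self):
        # with n_matched = 1, P(X >= 1) = 1 - exp(-lambda)
        obs = [ObservedMass(500.0, id=0)]
        cfg = MatchConfig(tol_ppm=10, series=frozenset("by"))
        ms = make_matchset([one_match(mass=500.0)], obs, cfg, n_theoretical=12)
        q = min(1.0, 12 * 2 * (500.0 * 10e-6) / 10000.0)
        assert p_score(ms, 10000.0) == pytest.approx(1 - math.exp(-q), rel=1e-12)

    def test_enabling_shifts_worsens_p_score_with_unchanged_matches(self):
        obs = [ObservedMass(500.0, id=0), ObservedMass(900.0, id=1)]
        matches = [one_match(mass=500.0)]
        cfg0 = MatchConfig(tol_ppm=10, series=frozenset("by"))
        cfg1 = dataclasses.replace(cfg0, n_isotope_shifts=1)
        ms0 = make_matchset(matches, obs, cfg0, 12)
        ms1 = make_matchset(matches, obs, cfg1, 12)
        # lambda scales by exactly (1+2k) = 3
        assert p_score(ms1, 10000.0) > p_score(ms0, 10000.0)
        lam0 = -math.log(1 - p_score(ms0, 10000.0))
        lam1 = -math.log(1 - p_score(ms1, 10000.0))
        assert lam1 == pytest.approx(3 * lam0, rel=1e-9)

    def test_bounds_hold_across_configs(self, rng):
        p = pf.parse_proforma("PEPTIDESPEPTIDES")
        frags = generate_fragments(p, {"b", "y"})
        for _ in range(20):
            obs = [
                ObservedMass(float(m), id=i)
                for i, m in enumerate(rng.uniform(100, p.intact_mass, 30))
            ]
            cfg = MatchConfig(
                tol_ppm=float(rng.choice([5, 50, 500])),
                series=frozenset("by"),
                n_isotope_shifts=int(rng.integers(0, 3)),
            )
            ms = pf.match(obs, frags, cfg)
            ps = p_score(ms, p.intact_mass)
            assert 0.0 < ps <= 1.0
            assert pcs(ms, p.intact_mass) >= 0.0


class TestPcs:
    def test_zero_matches_give_zero(self):
        assert pcs(EMPTY, 10000.0) == 0.0

    def test_single_match_information_content(self):
        # engineer q_i = 0.1: q = F_eff * 2 * m*tol*1e-6 / M
        # choose M so q = 0.1 with F_eff = 12, m = 500, tol = 10 ppm
        m, tol, f_eff = 500.0, 10.0, 12
        M = f_eff * 2 * (m * tol * 1e-6) / 0.1
        obs = [ObservedMass(m, id=0)]
        cfg = MatchConfig(tol_ppm=tol, series=frozenset("by"))
        ms = make_matchset([one_match(mass=m)], obs, cfg, n_theoretical=12)
        assert pcs(ms, M) == pytest.approx(1.0, rel=1e-9)

    def test_enabling_shifts_strictly_lowers_pcs(self):
        obs = [ObservedMass(500.0, id=0)]
        matches = [one_match(mass=500.0)]
        cfg0 = MatchConfig(tol_ppm=10, series=frozenset("by"))
        cfg1 = dataclasses.replace(cfg0, n_isotope_shifts=1)
        v0 = pcs(make_matchset(matches, obs, cfg0, 12), 10000.0)
        v1 = pcs(make_matchset(matches, obs, cfg1, 12), 10000.0)
        assert v1 < v0
        assert v0 - v1 == pytest.approx(math.log10(3), rel=1e-9)


class TestIntactMassDifference:
    def test_equal_masses_give_zero(self):
        assert intact_mass_difference(10000.0, 10000.0) == (0.0, 0.0)

    def test_theoretical_mode_reports_no_difference(self):
        assert intact_mass_difference(10000.0, None) is None
        p = pf.parse_proforma("PEPTIDE")
        report = build_report(p, EMPTY, observed_intact=None)
        assert report.mass_difference_da is None
        assert report.mass_difference_ppm is None
        assert report.intact_mass_theoretical > 0

    def test_ppm_uses_theoretical_denominator(self):
        da, ppm = intact_mass_difference(10000.0, 10000.01)
        assert da == pytest.approx(0.01, abs=1e-9)
        assert ppm == pytest.approx(1.0, abs=1e-6)


class TestCalibration:
    def test_mc_frequency_matches_poisson_tail(self, rng):
        """On uniform-random (decoy-only) masses the empirical frequency of
        >= n_matched matches agrees with the Poisson tail probability."""
        p = pf.parse_proforma(DEMO_PROFORMA)
        M = p.intact_mass
        series = frozenset("by")
        frags = generate_fragments(p, series)
        tol, n_obs, reps = 2.0, 4000, 2000
        obs = [
            ObservedMass(float(m), id=i)
            for i, m in enumerate(rng.uniform(0.0, M, n_obs).round(6))
        ]
        cfg = MatchConfig(tol_ppm=tol, series=series)
        ms = pf.match(obs, frags, cfg)
        n_matched = max(ms.n_matched_observed, 1)
        ps = p_score(ms, M) if ms.n_matched_observed else None

        fm = np.sort([f.neutral_mass for f in frags])
        lo, hi = fm * (1 - tol * 1e-6), fm * (1 + tol * 1e-6)
        merged = [[lo[0], hi[0]]]
        for l, h in zip(lo[1:], hi[1:]):
            if l <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], h)
            else:
                merged.append([l, h])
        edges = np.array(merged).ravel()
        counts = np.empty(reps)
        for start in range(0, reps, 500):
            m = rng.uniform(0.0, M, (500, n_obs))
            counts[start : start + 500] = (
                (np.searchsorted(edges, m) % 2) == 1
            ).sum(axis=1)
        freq = float((counts >= n_matched).mean())
        if ps is None:
            ps = p_score(
                make_matchset([one_match(mass=float(obs[0].neutral_mass))],
                              obs, cfg, len(frags)),
                M,
            )
        se = math.sqrt(max(freq * (1 - freq), 1e-9) / reps)
        assert abs(freq - ps) <= 3 * se + 0.005
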