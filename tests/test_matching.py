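"""Matcher semantics against an exhaustive brute-force oracle."""

import numpy as np
import pytest

from proformatch.errors import InvalidConfigError, MassListFormatError
from proformatch.fragments import TheoreticalFragment, generate_fragments
from proformatch.matching import (
    MatchConfig,
    ObservedMass,
    match,
    parse_mass_list,
    write_mass_list,
    read_mass_list,
)
from proformatch.proforma import parse_proforma

from conftest import brute_force_match, match_triples


def random_instance(rng, n_obs=50, n_frag=200):
    """A random fragment table plus observed masses that hover near it."""
    series = rng.choice(list("abcxyz"), size=n_frag)
    frags = [
        TheoreticalFragment(str(s), int(i % 80 + 1), float(m))
        for i, (s, m) in enumerate(
            zip(series, rng.uniform(200.0, 20000.0, size=n_frag))
        )
    ]
    observed = []
    for j in range(n_obs):
        base = float(rng.choice([f.neutral_mass for f in frags]))
        kind = rng.integers(0, 3)
        if kind == 0:  # near-hit with ppm jitter
            m = base * (1 + rng.normal(0, 3) * 1e-6)
        elif kind == 1:  # isotope-displaced
            m = base + float(rng.choice([-2, -1, 1, 2])) * 1.00235
        else:  # anywhere
            m = float(rng.uniform(200.0, 20000.0))
        observed.append(ObservedMass(neutral_mass=max(m, 1.0), id=j))
    return observed, frags


class TestMatchDefinition:
    def setup_method(self):
        self.p = parse_proforma("PEPTIDES")
        self.frags = generate_fragments(self.p, {"b", "y"})
        self.b3 = next(
            f for f in self.frags if (f.series, f.index) == ("b", 3)
        )

    def test_exact_hit_matches_with_zero_ppm(self):
        ms = match(
            [ObservedMass(self.b3.neutral_mass, id=0)],
            self.frags,
            MatchConfig(tol_ppm=10, series=frozenset("by")),
        )
        assert len(ms.matches) == 1
        m = ms.matches[0]
        assert (m.fragment.series, m.fragment.index) == ("b", 3)
        assert m.ppm_error == 0.0 and m.shift_steps == 0

    def test_isotope_displaced_hit_needs_shift_recovery(self):
        obs = [ObservedMass(self.b3.neutral_mass + 1.00235, id=0)]
        cfg0 = MatchConfig(tol_ppm=10, series=frozenset("by"))
        assert not match(obs, self.frags, cfg0).matches
        cfg1 = MatchConfig(
            tol_ppm=10, series=frozenset("by"), n_isotope_shifts=1
        )
        ms = match(obs, self.frags, cfg1)
        assert len(ms.matches) == 1
        assert ms.matches[0].shift_steps == 1
        assert abs(ms.matches[0].ppm_error) < 1e-6

    def test_empty_observed_yields_empty_matchset(self):
        ms = match([], self.frags, MatchConfig())
        assert ms.matches == () and ms.n_observed == 0

    def test_ppm_error_uses_theoretical_denominator(self):
        target = self.b3.neutral_mass
        obs = ObservedMass(target * (1 + 5e-6), id=0)
        ms = match([obs], self.frags, MatchConfig(tol_ppm=10, series=frozenset("by")))
        assert ms.matches[0].ppm_error == pytest.approx(5.0, abs=1e-6)


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_instances(self, rng):
        """Implementation reproduces the exhaustive all-pairs/all-shifts
        oracle on randomized instances across tolerances and shift depths."""
        for trial in range(25):
            observed, frags = random_instance(rng)
            cfg = MatchConfig(
                tol_ppm=float(rng.choice([1.0, 5.0, 10.0, 50.0])),
                series=frozenset("abcxyz"),
                n_isotope_shifts=int(rng.integers(0, 3)),
            )
            ms = match(observed, frags, cfg)
            got_w, got_c = match_triples(ms)
            exp_w, exp_c = brute_force_match(observed, frags, cfg)
            assert got_w == exp_w
            assert got_c == exp_c


class TestInvariants:
    def test_monotone_in_tolerance_and_shifts(self, rng):
        observed, frags = random_instance(rng, n_obs=40, n_frag=120)
        counts = []
        for tol, k in [(1, 0), (5, 0), (5, 1), (10, 1), (10, 2), (50, 2)]:
            cfg = MatchConfig(
                tol_ppm=tol, series=frozenset("abcxyz"), n_isotope_shifts=k
            )
            counts.append(len(match(observed, frags, cfg).matches))
        assert counts == sorted(counts)

    def test_zero_shift_preferred_when_available(self, rng):
        observed, frags = random_instance(rng, n_obs=60, n_frag=150)
        cfg = MatchConfig(
            tol_ppm=20, series=frozenset("abcxyz"), n_isotope_shifts=2
        )
        ms = match(observed, frags, cfg)
        zero_pairs = {
            (c.observed_id, c.fragment.series, c.fragment.index)
            for c in ms.candidates
            if c.shift_steps == 0
        }
        for c in ms.candidates:
            if c.shift_steps != 0:
                assert (
                    c.observed_id,
                    c.fragment.series,
                    c.fragment.index,
                ) not in zero_pairs

    def test_input_order_does_not_change_match_content(self, rng):
        observed, frags = random_instance(rng, n_obs=30, n_frag=100)
        cfg = MatchConfig(tol_ppm=10, series=frozenset("abcxyz"), n_isotope_shifts=1)
        fwd = match(observed, frags, cfg)
        perm = list(reversed(observed))
        renumbered = [
            ObservedMass(o.neutral_mass, o.intensity, id=i)
            for i, o in enumerate(perm)
        ]
        bwd = match(renumbered, frags, cfg)
        strip = lambda ms: {
            (m.observed_mass, m.fragment.series, m.fragment.index, m.shift_steps)
            for m in ms.matches
        }
        assert strip(fwd) == strip(bwd)

    def test_at_most_one_winner_per_observed(self, rng):
        observed, frags = random_instance(rng)
        ms = match(observed, frags, MatchConfig(tol_ppm=50, series=frozenset("abcxyz")))
        ids = [m.observed_id for m in ms.matches]
        assert len(ids) == len(set(ids))


class TestMassListFormat:
    def test_parse_masses_with_comments_and_intensities(self):
        text = "# header\n1234.5678\n\n2345.678901\t1500.0\n"
        obs = parse_mass_list(text)
        assert [o.neutral_mass for o in obs] == [1234.5678, 2345.678901]
        assert obs[1].intensity == 1500.0
        assert [o.id for o in obs] == [0, 1]

    @pytest.mark.parametrize("bad", ["abc\n", "1\t2\t3\n", "-5.0\n"])
    def test_bad_lines_rejected(self, bad):
        with pytest.raises((MassListFormatError, InvalidConfigError)):
            parse_mass_list(bad)

    def test_write_read_round_trip_is_bit_exact(self, tmp_path):
        obs = [
            ObservedMass(1234.567891, id=0),
            ObservedMass(999.000001, intensity=3.5, id=1),
        ]
        path = tmp_path / "masses.txt"
        write_mass_list(path, obs)
        again = read_mass_list(path)
        assert [o.neutral_mass for o in again] == [
            o.neutral_mass for o in obs
        ]
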