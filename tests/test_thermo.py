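import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromopaint.candidates import CandidateOligo
from chromopaint.genome_io import GenomicInterval
from chromopaint.thermo import (
    NO_HAIRPIN,
    ThermoModel,
    ThermoProfile,
    dtm_filter,
    hairpin_tm,
    melting_temperature,
    thermo_profile,
)

from conftest import brute_stems, random_dna, rc

DNA = st.text(alphabet="ACGT", min_size=8, max_size=45)


class TestMeltingTemperature:
    def test_hand_summed_worked_example(self):
        """Independent hand evaluation of AGGCTTGACA from literal unified
        parameters (dH kcal/mol, dS cal/mol/K), frozen before the build."""
        DH = {"AG": -7.8, "GG": -8.0, "GC": -9.8, "CT": -7.8, "TT": -7.9,
              "TG": -8.5, "GA": -8.2, "AC": -8.4, "CA": -8.5}
        DS = {"AG": -21.0, "GG": -19.9, "GC": -24.4, "CT": -21.0, "TT": -22.2,
              "TG": -22.7, "GA": -22.2, "AC": -22.4, "CA": -22.7}
        seq = "AGGCTTGACA"
        dh = 2.3 + 2.3  # A/T initiation at both ends
        ds = 4.1 + 4.1
        for i in range(len(seq) - 1):
            dh += DH[seq[i : i + 2]]
            ds += DS[seq[i : i + 2]]
        ds += 0.368 * (len(seq) - 1) * math.log(0.05)
        expected = 1000.0 * dh / (ds + 1.9872 * math.log(0.25e-6 / 4)) - 273.15
        assert expected == pytest.approx(28.3264, abs=1e-3)  # frozen hand value
        assert melting_temperature(seq) == pytest.approx(expected, abs=0.01)

    @settings(max_examples=100, deadline=None)
    @given(DNA)
    def test_revcomp_symmetry(self, seq):
        assert melting_temperature(seq) == pytest.approx(
            melting_temperature(rc(seq)), abs=1e-9
        )

    def test_gc_melts_higher_than_at(self):
        assert melting_temperature("G" * 45) > melting_temperature("A" * 45)

    def test_deterministic(self):
        seq = random_dna(1, 45)
        assert melting_temperature(seq) == melting_temperature(seq)

    def test_self_complementary_symmetry_correction(self):
        pal = "GCATATGC"
        assert pal == rc(pal)
        model_on = ThermoModel(symmetry_correction=True)
        model_off = ThermoModel(symmetry_correction=False)
        # symmetry dS penalty and x=1 both shift Tm; they must differ
        assert melting_temperature(pal, model_on) != melting_temperature(pal, model_off)

    def test_rejects_n_and_short(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTN")
        with pytest.raises(ValueError):
            melting_temperature("A")


class TestHairpinTm:
    def test_no_stem_returns_sentinel(self):
        assert hairpin_tm("A" * 45) is NO_HAIRPIN

    def test_designed_stem_equals_stem_duplex_tm(self):
        stem = "CCGCCCCCCG"  # 10 bp; full-length stem is the strongest sub-stem
        seq = stem + "AATAA" + rc(stem)
        # oracle: brute-force enumeration confirms the 10 bp stem is maximal
        stems = brute_stems(seq, min_stem=4, min_loop=3)
        assert (0, 15, 10) in stems
        expected = max(
            melting_temperature(seq[i : i + k], unimolecular=True)
            for i, _, k in stems
        )
        assert hairpin_tm(seq) == pytest.approx(expected, abs=1e-9)
        assert hairpin_tm(seq) == pytest.approx(
            melting_temperature(stem, unimolecular=True), abs=1e-9
        )

    @settings(max_examples=40, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=12, max_size=40))
    def test_matches_brute_force_enumeration(self, seq):
        stems = brute_stems(seq)
        got = hairpin_tm(seq)
        if not stems:
            assert got is NO_HAIRPIN
        else:
            expected = max(
                melting_temperature(seq[i : i + k], unimolecular=True)
                for i, _, k in stems
            )
            assert got == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=12, max_size=45))
    def test_revcomp_invariance(self, seq):
        a, b = hairpin_tm(seq), hairpin_tm(rc(seq))
        if a is NO_HAIRPIN or b is NO_HAIRPIN:
            assert a is b
        else:
            assert a == pytest.approx(b, abs=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=12, max_size=40),
           st.text(alphabet="ACGT", min_size=1, max_size=8))
    def test_monotone_under_extension(self, seq, tail):
        before = hairpin_tm(seq)
        after = hairpin_tm(seq + tail)
        if before is not NO_HAIRPIN:
            assert after is not NO_HAIRPIN
            assert after >= before - 1e-12

    def test_wobble_not_counted(self):
        # G.T pairs would make a stem here; Watson-Crick-only must not
        seq = "GGGG" + "AAA" + "TTTT"  # G:T wobble stem candidate only
        assert hairpin_tm(seq) is NO_HAIRPIN


def _cand(i, tm, hairpin):
    c = CandidateOligo(
        interval=GenomicInterval("c1", i * 50, i * 50 + 45), sequence="A" * 45
    )
    c.profile = ThermoProfile.build(tm, hairpin)
    return c


class TestDtmFilter:
    def test_kept_and_dropped_boundaries(self):
        cands = [
            _cand(0, 75.0, 60.0),   # dtm 15 -> kept
            _cand(1, 70.0, 60.0),   # dtm 10 exactly -> dropped (strict >)
            _cand(2, 70.0, 59.999), # just above -> kept
            _cand(3, 60.0, 60.0),   # dtm 0 -> dropped
            _cand(4, 70.0, NO_HAIRPIN),  # +inf -> kept
        ]
        kept = dtm_filter(cands, 10.0)
        assert [c.start // 50 for c in kept] == [0, 2, 4]

    def test_profile_required(self):
        c = _cand(0, 70.0, 60.0)
        c.profile = None
        with pytest.raises(ValueError):
            dtm_filter([c], 10.0)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.floats(40, 90), st.floats(0, 90)), max_size=20))
    def test_subset_preserving_order(self, pairs):
        cands = [_cand(i, tm, hp) for i, (tm, hp) in enumerate(pairs)]
        kept = dtm_filter(cands, 10.0)
        ids = [id(c) for c in cands]
        assert [id(c) for c in kept] == [i for i in ids if i in {id(k) for k in kept}]
        assert all(c.profile.dtm > 10.0 for c in kept)


class TestThermoProfile:
    def test_dtm_identity(self):
        p = ThermoProfile.build(72.5, 60.25)
        assert p.dtm == pytest.approx(12.25)
        assert ThermoProfile.build(72.5, NO_HAIRPIN).dtm == math.inf

    def test_profile_consistency(self):
        seq = random_dna(9, 45)
        p = thermo_profile(seq)
        assert p.tm == melting_temperature(seq)
        hp = hairpin_tm(seq)
        assert p.hairpin_tm == hp
        if hp is not NO_HAIRPIN:
            assert p.dtm == pytest.approx(p.tm - hp)
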