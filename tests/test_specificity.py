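import numpy as np
import pytest

from chromopaint.candidates import mask_filter, tile
from chromopaint.fixtures import plant_duplication, random_fixture
from chromopaint.genome_io import GenomicInterval
from chromopaint.specificity import (
    InternalConsistencyError,
    brute_force_homology,
    build_kmer_index,
    find_homologous_loci,
    matches_required,
    uniqueness_filter,
)

from conftest import ms, random_dna, rc, window_matches


class TestMatchesRequired:
    def test_published_threshold(self):
        # 75% of 45 nt: >= 34 matching bases qualifies (33.75 rounded up)
        assert matches_required(0.75, 45) == 34

    def test_integer_boundary_inclusive(self):
        assert matches_required(0.8, 45) == 36  # exactly 36.0
        assert matches_required(1.0, 45) == 45


class TestKmerIndex:
    def test_repeated_kmer_positions(self):
        idx = build_kmer_index([ms("c1", "ACGTACGT")], 4)
        assert idx.occurrences("ACGT") == [("c1", 0), ("c1", 4)]

    def test_minus_strand_lookup(self):
        idx = build_kmer_index([ms("c1", "ACGTACGT")], 4)
        # minus strand of [0,4) reads rc("ACGT") == "ACGT" (palindrome)
        assert idx.occurrences("ACGT", strand="-") == [("c1", 0), ("c1", 4)]
        assert idx.occurrences("AAAA") == []

    def test_n_kmers_never_indexed(self):
        idx = build_kmer_index([ms("c1", "ACGTNACGT")], 4)
        # positions 1..4 all contain the N; only 0 and 5 survive
        total = idx.n_positions
        assert total == 2

    def test_position_count_identity(self):
        L, k = 10_000, 9
        idx = build_kmer_index([ms("c1", random_dna(9, L))], k)
        assert idx.n_positions == L - k + 1

    def test_k_larger_than_all_sequences_errors(self):
        with pytest.raises(ValueError):
            build_kmer_index([ms("c1", "ACGT")], 9)


class TestBruteForce:
    def test_planted_verbatim_two_loci(self):
        oligo = random_dna(20, 45)
        text = random_dna(21, 100) + oligo + random_dna(22, 60) + oligo + random_dna(23, 50)
        hits = brute_force_homology(oligo, [ms("c1", text)], 0.75)
        perfect = [h for h in hits if h.identity == 1.0 and h.interval.strand == "+"]
        assert {h.interval.start for h in perfect} == {100, 205}

    def test_11_substitutions_detected_12_not(self):
        oligo = random_dna(30, 45)
        for n_sub, expect_second in [(11, True), (12, False)]:
            mutated = list(oligo)
            rng = np.random.default_rng(n_sub)
            for pos in rng.choice(45, size=n_sub, replace=False):
                mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
            text = oligo + random_dna(31, 50) + "".join(mutated)
            hits = brute_force_homology(oligo, [ms("c1", text)], 0.75)
            starts = {h.interval.start for h in hits if h.interval.strand == "+"}
            assert 0 in starts
            assert (95 in starts) == expect_second

    def test_minus_strand_hit(self):
        oligo = random_dna(32, 45)
        text = random_dna(33, 50) + rc(oligo) + random_dna(34, 50)
        hits = brute_force_homology(oligo, [ms("c1", text)], 0.9)
        assert any(
            h.interval.strand == "-" and h.interval.start == 50 and h.identity == 1.0
            for h in hits
        )

    def test_n_scores_as_mismatch(self):
        oligo = "A" * 45
        text = "A" * 33 + "N" * 12
        hits = brute_force_homology(oligo, [ms("c1", text)], 0.75)
        assert hits == []  # 33/45 < 0.75


class TestFindHomologousLoci:
    def test_exact_duplicate_always_found(self, two_chrom_genome):
        genome = two_chrom_genome
        oligo = genome[0].residues[100:145]
        genome = plant_duplication(
            genome,
            GenomicInterval("chrA", 100, 145),
            GenomicInterval("chrB", 200, 245),
            0,
            seed=0,
        )
        idx = build_kmer_index(genome, 9)
        hits = find_homologous_loci(
            oligo, genome, idx, 0.75, source=GenomicInterval("chrA", 100, 145)
        )
        others = [h for h in hits if not h.is_source]
        assert any(
            h.interval.chrom == "chrB" and h.interval.start == 200 and h.identity == 1.0
            for h in others
        )

    def test_subset_of_brute_force(self):
        genome, _ = random_fixture(5, length=2000, n_duplications=2,
                                   substitution_choices=(0, 6, 9))
        idx = build_kmer_index(genome, 9)
        chrom = genome[0]
        for start in range(0, 400, 45):
            oligo = chrom.residues[start : start + 45]
            if "N" in oligo:
                continue
            heur = find_homologous_loci(oligo, genome, idx, 0.75)
            brute = brute_force_homology(oligo, genome, 0.75)
            brute_starts = {(h.interval.chrom, h.interval.strand, h.interval.start)
                            for h in brute}
            for h in heur:
                key = (h.interval.chrom, h.interval.strand, h.interval.start)
                assert key in brute_starts
                assert h.identity >= 0.75

    def test_below_threshold_never_emitted(self):
        genome, _ = random_fixture(6, length=3000, n_duplications=3,
                                   substitution_choices=(9, 12))
        idx = build_kmer_index(genome, 9)
        chrom = genome[0]
        for start in range(0, 2900, 100):
            oligo = chrom.residues[start : start + 45]
            if "N" in oligo:
                continue
            for h in find_homologous_loci(oligo, genome, idx, 0.75):
                assert h.identity >= 0.75


class TestUniquenessFilter:
    @pytest.mark.parametrize("exact", [False, True])
    def test_single_copy_kept_duplicate_eliminated(self, exact):
        genome = [ms("chrA", random_dna(40, 400)), ms("chrB", random_dna(41, 400))]
        src = GenomicInterval("chrA", 100, 145)
        genome = plant_duplication(genome, src, GenomicInterval("chrB", 60, 105), 0, 1)
        chrom = genome[0]
        cands = mask_filter(tile(chrom, 45, 5), chrom)
        kept = uniqueness_filter(cands, genome, 0.75, exact=exact)
        kept_starts = {c.start for c in kept}
        assert 100 not in kept_starts  # exact copy on chrB
        assert 0 in kept_starts

    def test_manifest_ground_truth_exact_mode(self):
        genome, manifest = random_fixture(7, length=4000, n_duplications=2,
                                          substitution_choices=(0, 6))
        chrom = genome[0]
        cands = mask_filter(tile(chrom, 45, 5), chrom)
        kept = uniqueness_filter([c for c in cands], genome, 0.75, exact=True)
        # independent expectation by direct window comparison
        from chromopaint.fixtures import predicted_nonunique_starts

        bad = predicted_nonunique_starts(genome, manifest, chrom.name, 45, 5, 0.75)
        expected = [c.start for c in cands if c.start not in bad]
        assert [c.start for c in kept] == expected

    def test_corrupted_candidate_raises(self, two_chrom_genome):
        genome = two_chrom_genome
        cands = tile(genome[0], 45, 5)
        cands[0].sequence = "A" * 45
        if genome[0].residues[0:45] != "A" * 45:
            with pytest.raises(InternalConsistencyError):
                uniqueness_filter(cands, genome, 0.75)

    def test_revcomp_genome_invariance(self):
        genome, _ = random_fixture(8, length=3000, n_chroms=2, n_duplications=2,
                                   substitution_choices=(0, 9))
        survivors = {}
        for flip in (False, True):
            g = genome
            if flip:
                g = [ms(s.name, rc(s.residues)) for s in genome]
                # carry the mask over (mirrored)
                for orig, new in zip(genome, g):
                    new.mask[:] = orig.mask[::-1]
            chrom = g[0]
            cands = mask_filter(tile(chrom, 45, 5), chrom)
            kept = uniqueness_filter(cands, g, 0.75)
            L = len(chrom)
            if flip:
                survivors[flip] = {L - c.end for c in kept}
            else:
                # forward windows only exist on the tiling grid of the flipped
                # genome if (L - end) is on the grid; compare as locus sets
                survivors[flip] = {c.start for c in kept}
        # a forward window [s, s+45) is the flipped window [L-s-45, L-s);
        # restrict to loci present on both tiling grids
        L = len(genome[0])
        common = {
            s for s in survivors[False] if (L - s - 45) % 5 == 0
        }
        flipped_common = {s for s in survivors[True] if s % 5 == 0 and (L - s - 45) % 5 == 0}
        assert common == flipped_common

    def test_minus_strand_palindrome_counts_as_second_locus(self):
        # build an oligo whose window matches its own minus strand: a long
        # palindromic stretch (34 of 45 positions self-complementary)
        arm = random_dna(50, 22)
        pal = arm + "T" + rc(arm)  # 45 nt, rc(pal) == pal except centre
        genome = [ms("chrA", random_dna(51, 100) + pal + random_dna(52, 100))]
        cands = [c for c in tile(genome[0], 45, 5) if c.start == 100]
        assert cands[0].sequence == pal
        kept = uniqueness_filter(cands, genome, 0.75, exact=True)
        assert kept == []  # self minus-strand hit at >= 44/45 identity
        kept_h = uniqueness_filter(
            [c for c in tile(genome[0], 45, 5) if c.start == 100], genome, 0.75
        )
        assert kept_h == []
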