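"""Satellite monomer characterization and in-silico mapping."""

import numpy as np
import pandas as pd
import pytest

from vitiscape import simdata
from vitiscape.satellites import (
    at_content,
    build_consensus,
    call_tandem_loci,
    compare_haplotypes,
    estimate_period,
    find_palindrome,
    map_monomer,
    site_counts,
)
from vitiscape.simdata import ReferenceGenome, make_tandem_array, reverse_complement


class TestEstimatePeriod:
    @pytest.mark.parametrize("period", [107, 187])
    def test_monomer_length_recovered(self, period, rng):
        _, arr = make_tandem_array(rng, period, 50, divergence=0.02)
        assert estimate_period(arr) == period

    def test_random_sequence_has_no_period(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 5000))
        assert estimate_period(seq) is None

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_period("ACGTACGTACGT")

    def test_fundamental_not_harmonic(self, rng):
        """The smallest significant period wins over its multiples."""
        _, arr = make_tandem_array(rng, 50, 60, divergence=0.01)
        assert estimate_period(arr) == 50


class TestBuildConsensus:
    def test_identical_frames_reproduce_monomer(self):
        monomer = "ACGGTTACCA" * 4  # 40 nt
        assert build_consensus(monomer * 5, 40) == monomer

    def test_diverged_copies_majority_vote(self, rng):
        monomer, arr = make_tandem_array(rng, 107, 50, divergence=0.02)
        assert build_consensus(arr, 107) == monomer

    def test_tie_breaks_lexicographically(self):
        # two frames, column 0 split A/T -> A (lexicographic); need >= 3 frames
        seqs = "ACG" + "TCG" + "ACG" + "TCG"
        with_majority = build_consensus(seqs, 3)
        assert with_majority == "ACG"  # A vs T tie at column 0 -> A

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            build_consensus("ACGTACGT", 8)


class TestAtContent:
    @pytest.mark.parametrize(
        "seq,expected", [("ATAT", 1.0), ("GCGC", 0.0), ("ATGC", 0.5)]
    )
    def test_basic_fractions(self, seq, expected):
        assert at_content(seq) == expected

    def test_n_excluded(self):
        assert at_content("ATNN") == 1.0

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            at_content("NNNN")

    def test_generated_composition_matches_target(self, rng):
        monomer, _ = make_tandem_array(rng, 500, 3, at_fraction=0.65)
        assert at_content(monomer) == pytest.approx(0.65, abs=0.03)


class TestFindPalindrome:
    def _monomer_with_palindrome(self, arm, mid="A"):
        pal = arm + mid + reverse_complement(arm)
        # flanks of C on both sides never extend a palindrome (C pairs G)
        return "GGATCACGA" + "C" * 20 + pal + "C" * 20 + "TGACTGATC", pal

    def test_implanted_43nt_palindrome_found_exactly(self):
        arm = "ACGTTGCAGGTACCTAGGATC"  # 21 nt arm + centre = 43 nt
        monomer, pal = self._monomer_with_palindrome(arm)
        assert len(pal) == 43
        offset, length, mism = find_palindrome(monomer)
        assert length == 43
        assert monomer[offset : offset + 43] == pal

    def test_random_monomers_have_none_at_min40(self, rng):
        found = 0
        for _ in range(100):
            monomer = "".join(rng.choice(list("ACGT"), 100))
            if find_palindrome(monomer, min_length=40, max_mismatch=2):
                found += 1
        assert found == 0

    def test_mismatch_budget_threshold(self):
        arm = "ACGTTGCAGGTACCTAGGATCAG"  # 23-nt arm, even palindrome (46 nt)
        pal = arm + reverse_complement(arm)
        pal = pal[:10] + "A" + pal[11:]  # one internal mismatch (position 10 was C)
        monomer = "C" * 25 + pal + "C" * 25
        hit1 = find_palindrome(monomer, min_length=40, max_mismatch=1)
        assert hit1 is not None and hit1[1] >= 40
        assert find_palindrome(monomer, min_length=40, max_mismatch=0) is None

    def test_short_monomer_rejected(self):
        with pytest.raises(ValueError):
            find_palindrome("ACGT", min_length=20)


def _assembly_with_array(rng, monomer_length=107, n_copies=30, chrom_len=200_000,
                         at=50_000, divergence=0.02, name="chr1"):
    monomer, arr = make_tandem_array(rng, monomer_length, n_copies, divergence)
    bg = "".join(rng.choice(list("ACGT"), chrom_len))
    seq = bg[:at] + arr + bg[at:]
    return monomer, ReferenceGenome(chromosomes=[(name, seq)])


class TestMapMonomer:
    def test_array_yields_one_hit_per_copy(self, rng):
        monomer, genome = _assembly_with_array(rng)
        hits = map_monomer(monomer, genome)
        assert abs(len(hits) - 30) <= 2
        assert (hits.identity >= 0.8).all()

    def test_absent_monomer_no_hits(self, rng):
        _, genome = _assembly_with_array(rng)
        other = "".join(rng.choice(list("ACGT"), 107))
        assert map_monomer(other, genome).empty

    def test_strand_symmetry(self, rng):
        monomer, genome = _assembly_with_array(rng)
        rc_genome = ReferenceGenome(
            chromosomes=[(n, reverse_complement(s)) for n, s in genome.chromosomes]
        )
        fwd = map_monomer(monomer, genome)
        rev = map_monomer(monomer, rc_genome)
        assert len(fwd) == len(rev)
        assert set(fwd.strand) == {"+"} and set(rev.strand) == {"-"}

    def test_monomer_longer_than_chromosome_skipped(self, rng):
        genome = ReferenceGenome(chromosomes=[("tiny", "ACGTACGTAA")])
        hits = map_monomer("A" * 50, genome)
        assert hits.empty


class TestCallTandemLoci:
    def _hits(self, starts, m=107, chrom="chr1"):
        return pd.DataFrame(
            [(chrom, s, s + m, "+", 0.95) for s in starts],
            columns=["chrom", "start", "end", "strand", "identity"],
        )

    def test_contiguous_hits_single_locus(self):
        loci = call_tandem_loci(self._hits(range(0, 30 * 107, 107)), 107)
        assert len(loci) == 1
        assert loci.iloc[0].n_hits == 30

    def test_distant_arrays_two_loci(self):
        starts = list(range(0, 10 * 107, 107)) + list(range(50_000, 50_000 + 10 * 107, 107))
        loci = call_tandem_loci(self._hits(starts), 107)
        assert len(loci) == 2
        assert site_counts(loci)["chr1"] == 2

    def test_below_min_hits_no_locus(self):
        assert call_tandem_loci(self._hits(range(0, 4 * 107, 107)), 107).empty

    def test_recovers_implanted_arrays_across_chromosomes(self, rng):
        monomer, _ = make_tandem_array(rng, 107, 1, 0)
        chroms = []
        expected = {}
        for i in range(4):
            name = f"chr{i+1}"
            bg = "".join(rng.choice(list("ACGT"), 100_000))
            if i % 2 == 0:
                _, arr = make_tandem_array(rng, 107, 20, 0.02)
                # re-use one monomer so hits match: implant monomer-based array
                arr = "".join(
                    simdata._mutate(rng, np.frombuffer(monomer.encode(), np.uint8), 0.02)
                    .tobytes().decode() for _ in range(20)
                )
                chroms.append((name, bg[:40_000] + arr + bg[40_000:]))
                expected[name] = 1
            else:
                chroms.append((name, bg))
        genome = ReferenceGenome(chromosomes=chroms)
        hits = map_monomer(monomer, genome)
        loci = call_tandem_loci(hits, 107)
        assert site_counts(loci).to_dict() == expected


class TestCompareHaplotypes:
    def _loci(self, rows):
        return pd.DataFrame(
            [(c, s, e, 10, 0.95, 1.0) for c, s, e in rows],
            columns=["chrom", "start", "end", "n_hits", "mean_identity", "fwd_fraction"],
        )

    HOM = {"h1_chr15": "h2_chr15", "h1_chr10": "h2_chr10"}

    def test_identical_sets_all_shared(self):
        loci = self._loci([("h1_chr15", 100, 5000)])
        loci2 = self._loci([("h2_chr15", 100, 5000)])
        res = compare_haplotypes(loci, loci2, self.HOM)
        assert (res.status == "shared").all()

    def test_missing_partner_is_hemizygous(self):
        loci1 = self._loci([("h1_chr15", 100, 5000)])
        loci2 = self._loci([])
        res = compare_haplotypes(loci1, loci2, self.HOM)
        assert list(res.status) == ["hemizygous"]
        assert res.iloc[0].haplotype == "h1"

    def test_shared_plus_h2_only_counts(self):
        loci1 = self._loci([("h1_chr10", 0, 3000)])
        loci2 = self._loci([("h2_chr10", 100, 2900), ("h2_chr15", 0, 4000)])
        res = compare_haplotypes(loci1, loci2, self.HOM)
        assert (res.status == "shared").sum() == 2  # both sides of one pair
        hemi = res[res.status == "hemizygous"]
        assert len(hemi) == 1 and hemi.iloc[0].chrom == "h2_chr15"

    def test_unknown_chromosome_rejected(self):
        loci1 = self._loci([("weird", 0, 100)])
        with pytest.raises(KeyError):
            compare_haplotypes(loci1, self._loci([]), self.HOM)
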