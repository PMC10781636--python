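"""Upstream windows, IUPAC word scanning, PWM building and comparison."""

import re

import numpy as np
import pytest

from genefam_bd import fixture as fx
from genefam_bd.motif import (PWM, UpstreamWindow, build_pwm, compare_pwm,
                              conservation_call, extract_upstream,
                              reverse_complement, scan_word)
from genefam_bd.simulate import simulate_upstream
from genefam_bd.trees import GeneModel


def window(seq, species="sp", gene="g"):
    return UpstreamWindow(species=species, gene=gene, sequence=seq)


def brute_force_offsets(seq, word):
    """Oracle: regex scan of both strands for exact (non-IUPAC) words."""
    fwd = [m.start() - len(seq) for m in re.finditer(f"(?={word})", seq)]
    rc = reverse_complement(word)
    rev = [m.start() - len(seq) for m in re.finditer(f"(?={rc})", seq)]
    return sorted(fwd), sorted(rev)


class TestExtractUpstream:
    def test_plus_strand_coordinates(self):
        genome = {"scf": "A" * 700 + "C" * 300 + "ATG" + "A" * 100}
        model = GeneModel("g", "sp", "scf", "+", [(1000, 1103)])
        win = extract_upstream(genome, model, L=300)
        assert win.length == 300
        assert win.sequence == "C" * 300

    def test_truncated_at_scaffold_start(self):
        genome = {"scf": "C" * 50 + "ATG" + "A" * 100}
        model = GeneModel("g", "sp", "scf", "+", [(50, 153)])
        win = extract_upstream(genome, model, L=300)
        assert win.length == 50

    def test_minus_strand_reads_coding_orientation(self):
        word = "ATGCAAAT"
        upstream_coding = "G" * 100 + word + "G" * 92   # 200 bp window
        genome_insert = reverse_complement(upstream_coding)
        # gene body (minus strand): CAT at genomic [100,103), upstream after it
        genome = {"scf": "T" * 100 + "CAT" + genome_insert + "T" * 50}
        model = GeneModel("g", "sp", "scf", "-", [(100, 103)])
        win = extract_upstream(genome, model, L=200)
        assert win.sequence == upstream_coding
        hits = scan_word([win], word=word, strands="+")
        assert [h.offset for h in hits] == [100 - 200]

    def test_start_codon_outside_scaffold(self):
        genome = {"scf": "ACGT"}
        model = GeneModel("g", "sp", "scf", "+", [(100, 200)])
        with pytest.raises(ValueError):
            extract_upstream(genome, model)


class TestScanWord:
    def test_word_free_window_gives_no_hits(self):
        assert scan_word([window("ACGT" * 25)]) == []

    def test_offset_arithmetic(self):
        seq = "C" * 10 + "ATGCAAAT" + "C" * 5   # length 23, word at index 10
        hits = scan_word([window(seq)])
        assert len(hits) == 1
        assert hits[0].offset == 10 - 23 and hits[0].strand == "+"

    def test_fixture_hits_exactly_the_conserved_lineages(self):
        windows = [window(seq, species=sp)
                   for sp, seq in sorted(fx.upstream_windows().items())]
        hits = scan_word(windows, word=fx.OCT_WORD)
        assert sorted({h.species for h in hits}) == sorted(fx.OCT_CARRIERS)

    def test_iupac_degenerate_positions(self):
        hits = scan_word([window("AAATGCAAATAA")], word="ATGCARAT")
        assert [h.offset for h in hits if h.strand == "+"] == [2 - 12]

    def test_invalid_iupac_character(self):
        with pytest.raises(ValueError):
            scan_word([window("ACGT" * 10)], word="ATGZ")

    def test_matches_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(13)
        word = "ATGCAAAT"
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=80))
            hits = scan_word([window(seq)], word=word)
            fwd = sorted(h.offset for h in hits if h.strand == "+")
            rev = sorted(h.offset for h in hits if h.strand == "-")
            exp_fwd, exp_rev = brute_force_offsets(seq, word)
            assert fwd == exp_fwd and rev == exp_rev

    def test_reverse_complement_mirrors_offsets(self):
        rng = np.random.default_rng(29)
        word = "ATGCAAAT"
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            hits = scan_word([window(seq)], word=word)
            mirrored = scan_word([window(reverse_complement(seq))], word=word)
            L, w = len(seq), len(word)
            # a + hit at index i = offset i-L appears in the mirrored window
            # as a - hit at index L-w-i, i.e. offset -w-i = -w-L-offset
            expected = sorted(-w - L - h.offset
                              for h in hits if h.strand == "+")
            got = sorted(h.offset for h in mirrored if h.strand == "-")
            assert got == expected


class TestConservationCall:
    def test_no_hits_not_conserved(self, species_tree):
        call = conservation_call([], species_tree, min_species=1)
        assert not call.conserved and call.supporting_species == []

    def test_fixture_conserved_across_four_lineages(self, species_tree):
        windows = [window(seq, species=sp)
                   for sp, seq in sorted(fx.upstream_windows().items())]
        hits = scan_word(windows, word=fx.OCT_WORD)
        call = conservation_call(hits, species_tree, min_species=4,
                                 band=(-300, -1))
        assert call.conserved
        assert call.spanning_node == "jawed_vertebrate_ancestor"
        assert sorted(call.supporting_species) == sorted(fx.OCT_CARRIERS)

    def test_threshold_rule_on_planted_carriers(self, species_tree):
        species = sorted(species_tree.leaf_ids())
        for k, min_species in [(2, 4), (4, 4), (6, 4)]:
            windows_map, _truth = simulate_upstream(
                species, fx.OCT_WORD, carrier_species=species[:k],
                L=300, gc=0.5, seed=k)
            hits = scan_word([window(s, species=sp)
                              for sp, s in windows_map.items()],
                             word=fx.OCT_WORD)
            call = conservation_call(hits, species_tree,
                                     min_species=min_species)
            assert call.conserved == (k >= min_species)


class TestBuildPwm:
    def test_identical_sites_without_pseudocount(self):
        pwm = build_pwm(["ATGCAAAT"] * 5, pseudocount=0.0)
        assert pwm.consensus() == "ATGCAAAT"
        assert np.allclose(pwm.probabilities.max(axis=0), 1.0)

    def test_single_site_pseudocount_arithmetic(self):
        pwm = build_pwm(["ACGT"], pseudocount=0.5)
        # matched base: (1 + 0.5) / (1 + 2) = 0.5
        assert pwm.probabilities[0, 0] == pytest.approx(0.5)
        assert pwm.probabilities[1, 0] == pytest.approx(0.5 / 3)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(37)
        bases = "ACGT"
        for _ in range(30):
            n, width = int(rng.integers(1, 12)), int(rng.integers(1, 10))
            sites = ["".join(rng.choice(list(bases), size=width))
                     for _ in range(n)]
            pc = float(rng.choice([0.0, 0.5, 1.0]))
            pwm = build_pwm(sites, pseudocount=pc)
            for j in range(width):
                for i, base in enumerate(bases):
                    count = sum(site[j] == base for site in sites)
                    assert pwm.probabilities[i, j] == pytest.approx(
                        (count + pc) / (n + 4 * pc))

    def test_ragged_sites_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["ACGT", "ACG"])

    def test_jaspar_round_trip(self):
        pwm = build_pwm(["ATGCAAAT", "ATGCAAAT", "ATACAAAT"])
        again = PWM.from_jaspar(pwm.to_jaspar("oct"))
        assert np.allclose(again.probabilities, pwm.probabilities)


class TestComparePwm:
    def test_identical_pwms_score_one_at_zero_offset(self):
        pwm = build_pwm(["ATGCAAAT", "ATGCATAT", "CTGCAAAT"])
        result = compare_pwm(pwm, pwm)
        assert result.score == pytest.approx(1.0)
        assert result.offset == 0 and result.strand == "+"

    def test_reverse_complement_scores_one_on_minus_strand(self):
        pwm = build_pwm(["ATGCAAAT", "ATGCATAT", "CTGCAAAT"])
        result = compare_pwm(pwm, pwm.reverse_complement())
        assert result.score == pytest.approx(1.0)
        assert result.strand == "-"

    def test_symmetric_scores(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            a = build_pwm(["".join(rng.choice(list("ACGT"), size=8))
                           for _ in range(4)])
            b = build_pwm(["".join(rng.choice(list("ACGT"), size=10))
                           for _ in range(4)])
            assert compare_pwm(a, b).score == pytest.approx(
                compare_pwm(b, a).score)

    def test_planted_sub_motif_found_at_constructed_offset(self):
        core = ["ATGCAAAT", "ATGCATAT", "CTGCAAAT", "ATGAAAAT"]
        padded = ["GC" + s + "T" for s in core]
        pwm_core = build_pwm(core)
        pwm_padded = build_pwm(padded)
        result = compare_pwm(pwm_padded, pwm_core)
        assert result.offset == 2 and result.strand == "+"
        assert result.score == pytest.approx(1.0)

    def test_too_short_overlap_rejected(self):
        short = build_pwm(["ACGTA"])
        with pytest.raises(ValueError):
            compare_pwm(short, short)

    def test_oct_fixture_word_matches_itself_under_perturbation(self):
        rng = np.random.default_rng(43)
        base = build_pwm([fx.OCT_WORD] * 10, pseudocount=0.5)
        noisy_sites = [fx.OCT_WORD] * 8 + ["ATACAAAT", "ATGCAGAT"]
        noisy = build_pwm(noisy_sites, pseudocount=0.5)
        result = compare_pwm(base, noisy)
        assert result.offset == 0 and result.strand == "+"
        assert result.score > 0.8


class TestSimulatedRecovery:
    def test_planted_words_recovered_at_exact_offsets(self, species_tree):
        species = sorted(species_tree.leaf_ids())
        for seed in range(10):
            windows_map, truth = simulate_upstream(
                species, fx.OCT_WORD, carrier_species=species,
                L=300, gc=0.42, seed=seed)
            hits = scan_word([window(s, species=sp)
                              for sp, s in windows_map.items()],
                             word=fx.OCT_WORD, strands="+")
            found = {h.species: h.offset for h in hits}
            planted = {sp: off for sp, (off, _strand) in truth.planted.items()}
            assert found == planted

    def test_background_hit_rate_matches_analytic_expectation(self):
        # 10,000 i.i.d. uniform windows scanned on both strands; vectorised
        # scan (independent of scan_word) compared with the analytic rate
        rng = np.random.default_rng(59)
        n, L, w = 10_000, 300, 8
        word = fx.OCT_WORD
        codes = np.frombuffer(word.encode(), dtype=np.uint8)
        rc = np.frombuffer(reverse_complement(word).encode(), dtype=np.uint8)
        seqs = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=(n, L))
        windows_view = np.lib.stride_tricks.sliding_window_view(seqs, w, axis=1)
        count = int((windows_view == codes).all(axis=2).sum()
                    + (windows_view == rc).all(axis=2).sum())
        expected = n * 2 * (L - w + 1) * 0.25 ** w
        # position/strand slots are nearly independent Bernoullis, so the
        # total count is ~Poisson(expected); 4 sigma guard
        sd = np.sqrt(expected)
        assert abs(count - expected) <= 4 * sd
        # cross-check the package scanner on a subset of the same windows
        subset = ["".join(chr(c) for c in row) for row in seqs[:100]]
        hits = scan_word([window(s, gene=f"w{i}")
                          for i, s in enumerate(subset)], word=word)
        sub_view = np.lib.stride_tricks.sliding_window_view(seqs[:100], w, axis=1)
        sub_count = int((sub_view == codes).all(axis=2).sum()
                        + (sub_view == rc).all(axis=2).sum())
        assert len(hits) == sub_count
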