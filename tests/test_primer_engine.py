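"""Thermodynamics, primer enumeration, in-silico PCR, marker classification."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from introseeker._seq import mutate, random_seq, revcomp
from introseeker.primer_engine import (
    PrimerConstraints,
    PrimerPair,
    audit_primer_pair,
    classify_marker,
    design_primers,
    gc_content,
    in_silico_pcr,
    melting_temperature,
)

from _oracles import nn_melting_temperature

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestGC:
    def test_hand_cases(self):
        assert gc_content("ATGC") == 50.0
        assert gc_content("GGCC") == 100.0
        assert gc_content("ATAT") == 0.0

    @given(dna)
    def test_matches_counting_oracle(self, seq):
        expected = 100.0 * sum(b in "GC" for b in seq) / len(seq)
        assert gc_content(seq) == pytest.approx(expected)

    def test_ambiguous_base_is_an_error(self):
        with pytest.raises(ValueError):
            gc_content("ACGN")


class TestMeltingTemperature:
    def test_duplex_symmetry(self, rng):
        for _ in range(20):
            seq = random_seq(rng, int(rng.integers(12, 30)))
            assert melting_temperature(seq) == pytest.approx(
                melting_temperature(revcomp(seq)), abs=1e-9
            )

    def test_matches_independent_table_lookup_oracle(self, rng):
        assert melting_temperature("AGCGTCGACCTGAAGGCTAT") == pytest.approx(
            nn_melting_temperature("AGCGTCGACCTGAAGGCTAT"), abs=0.05
        )
        for _ in range(50):
            seq = random_seq(rng, int(rng.integers(8, 41)))
            assert melting_temperature(seq) == pytest.approx(
                nn_melting_temperature(seq), abs=0.05
            )

    def test_cross_check_against_biopython(self, rng):
        from Bio.SeqUtils import MeltingTemp as mt

        for _ in range(20):
            seq = random_seq(rng, 22)
            if seq == revcomp(seq):
                continue
            ours = melting_temperature(seq)
            ref = mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50, dnac1=250, dnac2=250, saltcorr=1)
            assert ours == pytest.approx(ref, abs=0.5)

    def test_appending_gc_never_lowers_tm(self, rng):
        for _ in range(100):
            seq = random_seq(rng, 18)
            assert melting_temperature(seq + "GC") >= melting_temperature(seq) - 1e-9

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTACG")  # 7-mer
        with pytest.raises(ValueError):
            melting_temperature("ACGT" * 11)  # 44-mer


def brute_force_pairs(template, cons, na_mM=50.0, oligo_nM=500.0):
    """O(n^2) exhaustive enumeration with scalar thermodynamics."""
    windows = []
    n = len(template)
    for length in range(cons.length_min, cons.length_max + 1):
        for start in range(n - length + 1):
            w = template[start : start + length]
            tm = melting_temperature(w, na_mM, oligo_nM)
            gc = gc_content(w)
            if cons.tm_min <= tm <= cons.tm_max and cons.gc_min <= gc <= cons.gc_max:
                windows.append((start, length, tm))
    keys = []
    for fs, fl, ftm in windows:
        for rs, rl, rtm in windows:
            rend = rs + rl - 1
            product = rend - fs + 1
            if not cons.product_min <= product <= cons.product_max:
                continue
            if abs(ftm - rtm) > cons.max_tm_diff:
                continue
            keys.append(
                (
                    abs(ftm - 60.0) + abs(rtm - 60.0),
                    abs(product - 450.0),
                    fs,
                    rend,
                    fl,
                    rl,
                )
            )
    keys.sort()
    return keys


class TestDesign:
    def test_template_below_product_min_yields_empty_list(self, rng):
        assert design_primers(random_seq(rng, 150)) == []

    def test_every_emitted_pair_passes_the_independent_audit(self, rng):
        cons = PrimerConstraints()
        template = random_seq(rng, 700)
        pairs = design_primers(template, cons, max_pairs=5)
        assert pairs, "no pairs designed on a 700 bp template"
        for p in pairs:
            assert audit_primer_pair(p, cons)
            assert p.forward == template[p.fwd_start - 1 : p.fwd_start - 1 + len(p.forward)]
            assert p.reverse == revcomp(
                template[p.rev_end - len(p.reverse) : p.rev_end]
            )

    def test_matches_exhaustive_enumeration_on_small_template(self, rng):
        """The emitted top-5 must coincide with the brute-force O(n^2)
        enumeration's best keys (ties allowed at the cutoff)."""
        cons = PrimerConstraints()
        for attempt in range(10):
            template = random_seq(rng, 250)
            oracle = brute_force_pairs(template, cons)
            pairs = design_primers(template, cons, max_pairs=5)
            assert len(pairs) == min(5, len(oracle))
            if not oracle:
                continue
            cutoff = oracle[min(4, len(oracle) - 1)][:2]
            for p in pairs:
                key = (
                    abs(p.tm_forward - 60.0) + abs(p.tm_reverse - 60.0),
                    abs(p.product_size - 450.0),
                )
                assert key <= (cutoff[0] + 1e-9, cutoff[1] + 1e-9)

    def test_deterministic_output(self, rng):
        template = random_seq(rng, 600)
        assert design_primers(template) == design_primers(template)


def perfect_pair(template, tid="t"):
    pairs = design_primers(template, template_id=tid, max_pairs=1)
    assert pairs
    return pairs[0]


class TestInSilicoPCR:
    def test_amplicon_found_on_the_source_genome(self, rng):
        chrom = random_seq(rng, 5000)
        template = chrom[1000:1700]
        pair = perfect_pair(template)
        amps = in_silico_pcr(pair, {"4Ns": chrom}, "donor")
        assert len(amps) >= 1
        a = amps[0]
        assert a.chrom == "4Ns"
        assert a.size == pair.product_size
        assert 1000 < a.start and a.end <= 1700 + 1000
        assert a.mismatch_forward == 0 and a.mismatch_reverse == 0

    def test_forward_site_without_convergent_reverse_gives_nothing(self, rng):
        chrom = random_seq(rng, 3000)
        template = chrom[500:1200]
        pair = perfect_pair(template)
        # genome containing only the forward-primer site
        fsite = template[pair.fwd_start - 1 : pair.fwd_start - 1 + len(pair.forward)]
        genome = {"1A": random_seq(rng, 1000) + fsite + random_seq(rng, 1000)}
        assert in_silico_pcr(pair, genome, "g") == []

    def test_mismatch_tolerance_and_clamp(self, rng):
        chrom = random_seq(rng, 4000)
        template = chrom[800:1500]
        pair = perfect_pair(template)
        # mutate one internal base of the forward site (outside the 3' clamp)
        pos = 800 + pair.fwd_start - 1
        mutated = list(chrom)
        base = mutated[pos]
        mutated[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
        amps = in_silico_pcr(pair, {"1Ns": "".join(mutated)}, "donor")
        assert amps and amps[0].mismatch_forward == 1
        # break the clamp: mutate the forward primer's 3'-terminal base
        pos3 = 800 + pair.fwd_start - 1 + len(pair.forward) - 1
        mutated[pos3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[pos3]]
        assert in_silico_pcr(pair, {"1Ns": "".join(mutated)}, "donor") == []

    def test_heavily_diverged_genome_yields_no_amplicon(self, rng):
        chrom = random_seq(rng, 4000)
        template = chrom[800:1500]
        pair = perfect_pair(template)
        diverged = mutate(chrom, 0.6, rng)
        assert in_silico_pcr(pair, {"4D": diverged}, "recipient") == []


class TestClassify:
    ROLES = {
        "cv1": "recipient",
        "cv2": "recipient",
        "donor": "donor",
        "line": "donor_derived",
        "amph": "donor_derived",
        "rel1": "relative",
        "rel2": "relative",
    }

    def _pattern(self, banded):
        return {m: m in banded for m in self.ROLES}

    def test_bands_only_in_donor_lineage_is_donor_specific(self):
        mc = classify_marker("m", self._pattern({"donor", "line", "amph"}), self.ROLES)
        assert mc.marker_class == "donor_specific"

    def test_band_in_a_relative_makes_it_transferable(self):
        mc = classify_marker("m", self._pattern({"donor", "line", "rel1"}), self.ROLES)
        assert mc.marker_class == "transferable"

    def test_band_in_a_recipient_cultivar_is_non_specific(self):
        mc = classify_marker("m", self._pattern({"donor", "line", "cv1"}), self.ROLES)
        assert mc.marker_class == "non_specific"

    def test_no_band_anywhere_is_failed(self):
        mc = classify_marker("m", self._pattern(set()), self.ROLES)
        assert mc.marker_class == "failed"

    def test_missing_panel_member_is_an_error(self):
        pattern = self._pattern({"donor"})
        del pattern["rel2"]
        with pytest.raises(ValueError):
            classify_marker("m", pattern, self.ROLES)
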