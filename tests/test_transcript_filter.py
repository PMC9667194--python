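"""Expression filtering, differential expression, and homology criteria."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from introseeker._seq import mutate, random_seq
from introseeker.alien_transcript_filter import (
    GenomePanel,
    benjamini_hochberg,
    best_hit_per_genome,
    compute_fpkm,
    cross_species_distribution,
    deg_chromosome_distribution,
    differential_expression,
    presence_absence_filter,
    select_candidates,
    HomologyHit,
)

from _oracles import bh_step_up


class TestFPKM:
    def test_closed_form_example(self):
        counts = pd.DataFrame({"s1": [10]}, index=["t1"])
        lengths = pd.Series({"t1": 1000})
        lib = pd.Series({"s1": 1_000_000})
        fpkm = compute_fpkm(counts, lengths, lib)
        assert fpkm.loc["t1", "s1"] == pytest.approx(10.0)

    def test_zero_count_gives_zero_fpkm(self):
        counts = pd.DataFrame({"s1": [0, 5]}, index=["t1", "t2"])
        lengths = pd.Series({"t1": 500, "t2": 500})
        fpkm = compute_fpkm(counts, lengths)
        assert fpkm.loc["t1", "s1"] == 0.0

    def test_matches_scalar_loop_oracle(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(30, 4)),
            index=[f"t{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(4)],
        )
        lengths = pd.Series(rng.integers(200, 2000, 30), index=counts.index)
        fpkm = compute_fpkm(counts, lengths)
        libs = counts.sum(axis=0)
        for t in counts.index:
            for s in counts.columns:
                expected = counts.loc[t, s] * 1e9 / (lengths[t] * libs[s])
                assert fpkm.loc[t, s] == pytest.approx(expected)

    def test_zero_library_size_is_an_error(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["t1", "t2"])
        lengths = pd.Series({"t1": 500, "t2": 500})
        with pytest.raises(ValueError):
            compute_fpkm(counts, lengths)


class TestPresenceAbsence:
    def _fpkm(self, rows):
        return pd.DataFrame(
            rows,
            columns=["line_r1", "line_r2", "line_r3", "parent_r1", "parent_r2", "parent_r3"],
            index=[f"t{i}" for i in range(len(rows))],
        )

    def test_expressed_in_line_silent_in_parent_is_retained(self):
        fpkm = self._fpkm([[2, 3, 2, 0, 0, 0]])
        kept = presence_absence_filter(fpkm, ["line_r1", "line_r2", "line_r3"],
                                       ["parent_r1", "parent_r2", "parent_r3"])
        assert list(kept) == ["t0"]

    def test_one_low_line_replicate_drops_the_transcript(self):
        fpkm = self._fpkm([[2, 0.5, 2, 0, 0, 0]])
        kept = presence_absence_filter(fpkm, ["line_r1", "line_r2", "line_r3"],
                                       ["parent_r1", "parent_r2", "parent_r3"])
        assert len(kept) == 0

    def test_any_mode_relaxes_the_line_side(self):
        fpkm = self._fpkm([[2, 0.5, 2, 0, 0, 0]])
        kept = presence_absence_filter(fpkm, ["line_r1", "line_r2", "line_r3"],
                                       ["parent_r1", "parent_r2", "parent_r3"], mode="any")
        assert list(kept) == ["t0"]

    def test_matches_row_scan_oracle(self, rng):
        vals = rng.random(size=(50, 6)) * 3
        fpkm = self._fpkm(vals.tolist())
        line = ["line_r1", "line_r2", "line_r3"]
        parent = ["parent_r1", "parent_r2", "parent_r3"]
        kept = set(presence_absence_filter(fpkm, line, parent))
        for tid, row in fpkm.iterrows():
            expected = all(row[c] >= 1.0 for c in line) and all(row[c] < 1.0 for c in parent)
            assert (tid in kept) is expected

    def test_unknown_sample_column(self):
        fpkm = self._fpkm([[1, 1, 1, 0, 0, 0]])
        with pytest.raises(KeyError):
            presence_absence_filter(fpkm, ["nope"], ["parent_r1"])


class TestBenjaminiHochberg:
    def test_four_value_hand_case(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_ten_value_hand_case(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216]
        expected = [0.01, 0.04, 0.084, 0.084, 0.084, 0.1, 0.074 * 10 / 7,
                    0.216, 0.216, 0.216]
        assert benjamini_hochberg(p) == pytest.approx(expected)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_matches_textbook_step_up_and_dominates_raw_p(self, pvals):
        adj = benjamini_hochberg(pvals)
        assert adj == pytest.approx(bh_step_up(pvals))
        assert all(a >= p - 1e-12 for a, p in zip(adj, pvals))

    def test_monotone_when_sorted_by_raw_p(self, rng):
        p = np.sort(rng.random(40))
        adj = benjamini_hochberg(p)
        assert (np.diff(adj) >= -1e-12).all()


class TestDifferentialExpression:
    def test_identical_groups_yield_no_degs(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 500, size=(40, 3))
        counts = pd.DataFrame(
            np.hstack([base, base]),
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
            index=[f"t{i}" for i in range(40)],
        )
        de = differential_expression(counts, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert (de["log2fc"] == 0).all()
        assert (de["status"] == "unchanged").all()

    def test_all_zero_transcript_is_unchanged_with_undefined_p(self):
        counts = pd.DataFrame(
            {"a1": [0, 10], "a2": [0, 12], "b1": [0, 11], "b2": [0, 9]},
            index=["t0", "t1"],
        )
        de = differential_expression(counts, ["a1", "a2"], ["b1", "b2"])
        assert de.loc["t0", "status"] == "unchanged"
        assert np.isnan(de.loc["t0", "pvalue"])

    def test_adjusted_p_dominates_raw_p(self, dataset):
        tx = dataset.transcripts
        de = differential_expression(
            tx.counts, tx.sample_groups["parent"], tx.sample_groups["line"]
        )
        ok = de.dropna(subset=["pvalue"])
        assert (ok["padj"] >= ok["pvalue"] - 1e-12).all()

    def test_recovers_donor_transcripts_as_upregulated(self, ten_seed_runs):
        """Transcripts expressed only in the line should be flagged up in at
        least 90% of cases across seeds."""
        total = flagged = 0
        for run in ten_seed_runs:
            tx = run["dataset"].transcripts
            de = differential_expression(
                tx.counts, tx.sample_groups["parent"], tx.sample_groups["line"],
                lengths=tx.lengths, chrom_of=tx.chrom_of,
            )
            total += len(run["truth"])
            flagged += int((de.loc[sorted(run["truth"]), "status"] == "up").sum())
        assert flagged / total >= 0.90

    def test_single_replicate_is_an_error(self):
        counts = pd.DataFrame({"a1": [1], "b1": [2], "b2": [3]}, index=["t0"])
        with pytest.raises(ValueError):
            differential_expression(counts, ["a1"], ["b1", "b2"])


class TestDegDistribution:
    def test_matches_tally_oracle(self, rng):
        n = 300
        chroms = [f"{rng.integers(1, 8)}A" for _ in range(n)]
        status = rng.choice(["up", "down", "unchanged"], size=n)
        de = pd.DataFrame({"status": status, "chrom": chroms})
        dist = deg_chromosome_distribution(de)
        for chrom in set(chroms):
            n_up = sum(1 for c, s in zip(chroms, status) if c == chrom and s == "up")
            n_down = sum(1 for c, s in zip(chroms, status) if c == chrom and s == "down")
            assert dist.loc[chrom, "n_up"] == n_up
            assert dist.loc[chrom, "n_down"] == n_down
        assert dist["frac_up"].sum() == pytest.approx(1.0)
        assert dist["frac_down"].sum() == pytest.approx(1.0)

    def test_no_degs_gives_empty_distribution(self):
        de = pd.DataFrame({"status": ["unchanged"] * 5, "chrom": ["1A"] * 5})
        assert deg_chromosome_distribution(de).empty

    def test_missing_chromosome_annotation_is_an_error(self):
        with pytest.raises(ValueError):
            deg_chromosome_distribution(pd.DataFrame({"status": ["up"]}))


def tiny_panel(rng):
    """A miniature panel with known homology structure (exact DP scale).

    Recipient W carries 4A/4D; proxy Ns carries 4Ns derived from nothing the
    recipient shares; related genome H carries 4H derived from 4Ns.
    """
    w4d = random_seq(rng, 600)
    ns4 = random_seq(rng, 600)
    genomes = {
        "W": {"4A": random_seq(rng, 600), "4D": w4d},
        "Ns": {"4Ns": ns4},
        "H": {"4H": mutate(ns4, 0.1, rng), "1H": random_seq(rng, 600)},
    }
    return GenomePanel(genomes=genomes, recipient="W", donor_proxy="Ns"), ns4, w4d


class TestBestHit:
    def test_donor_fragment_hits_the_homoeologous_group_in_related_genome(self, rng):
        panel, ns4, _ = tiny_panel(rng)
        hits = best_hit_per_genome("q", ns4[100:400], panel)
        assert hits["Ns"].chrom == "4Ns" and hits["Ns"].identity == 100.0
        assert hits["H"].chrom == "4H" and hits["H"].group == 4

    def test_all_n_transcript_has_no_hit_anywhere(self, rng):
        panel, _, _ = tiny_panel(rng)
        hits = best_hit_per_genome("q", "N" * 60, panel)
        assert all(h.chrom is None and h.identity == 0.0 for h in hits.values())

    def test_equal_hits_break_ties_lexicographically(self, rng):
        seq = random_seq(rng, 500)
        panel = GenomePanel(
            genomes={"W": {"5W": seq, "4W": seq}, "Ns": {"1Ns": random_seq(rng, 200)}},
            recipient="W",
            donor_proxy="Ns",
        )
        hits = best_hit_per_genome("q", seq[100:300], panel)
        assert hits["W"].chrom == "4W"


class TestSelectCandidates:
    def test_donor_fragment_is_a_candidate_and_recipient_fragment_is_not(self, rng):
        panel, ns4, w4d = tiny_panel(rng)
        seqs = {"donor_tx": ns4[100:400], "wheat_tx": w4d[100:400]}
        records, _ = select_candidates(seqs, {"donor_tx", "wheat_tx"}, panel, target_group=4)
        assert records.loc["donor_tx", "candidate"]
        assert records.loc["donor_tx", "assigned_group"] == 4
        # the wheat fragment fails criterion II (identity ~100% to recipient)
        assert not records.loc["wheat_tx", "passes_II"]
        assert not records.loc["wheat_tx", "candidate"]

    def test_criteria_thresholds_are_strict_inequalities(self, rng):
        panel, ns4, _ = tiny_panel(rng)
        seqs = {"tx": ns4[100:400]}
        # identity to the proxy is exactly 100: III requires strictly more
        records, _ = select_candidates(seqs, {"tx"}, panel, id_min_donor=100.0)
        assert not records.loc["tx", "passes_III"]
        # identity to the recipient is some value v: II requires strictly less
        _, hits = select_candidates(seqs, {"tx"}, panel)
        v = hits["tx"][panel.recipient].identity
        records2, _ = select_candidates(seqs, {"tx"}, panel, id_max_recipient=v)
        assert not records2.loc["tx", "passes_II"]

    def test_threshold_monotonicity(self, rng):
        """Raising id_max_recipient never shrinks the candidate set; raising
        id_min_donor never grows it."""
        panel, ns4, w4d = tiny_panel(rng)
        seqs = {
            "a": ns4[0:300],
            "b": ns4[250:550],
            "c": w4d[0:300],
            "d": mutate(ns4[300:600], 0.2, rng),
        }
        expressed = set(seqs)
        sizes_ii = []
        for thr in (10.0, 50.0, 99.0):
            rec, _ = select_candidates(seqs, expressed, panel, id_max_recipient=thr)
            sizes_ii.append(set(rec.index[rec["candidate"]]))
        assert sizes_ii[0] <= sizes_ii[1] <= sizes_ii[2]
        sizes_iii = []
        for thr in (10.0, 50.0, 99.0):
            rec, _ = select_candidates(seqs, expressed, panel, id_min_donor=thr)
            sizes_iii.append(set(rec.index[rec["candidate"]]))
        assert sizes_iii[0] >= sizes_iii[1] >= sizes_iii[2]

    def test_unexpressed_transcripts_cannot_be_candidates(self, rng):
        panel, ns4, _ = tiny_panel(rng)
        records, _ = select_candidates({"tx": ns4[100:400]}, set(), panel)
        assert not records.loc["tx", "candidate"]
        assert not records.loc["tx", "passes_expression"]

    def test_invalid_target_group(self, rng):
        panel, ns4, _ = tiny_panel(rng)
        with pytest.raises(ValueError):
            select_candidates({"tx": ns4[:200]}, {"tx"}, panel, target_group=9)


class TestCrossSpecies:
    def test_matches_tally_oracle(self, rng):
        related = ["H", "R"]
        hits = {}
        expected_any = 0
        for i in range(200):
            per = {}
            any_g4 = False
            for g in related:
                group = int(rng.integers(1, 8))
                per[g] = HomologyHit(f"t{i}", g, f"{group}{g}", 80.0, 100, 90.0, 50)
                any_g4 |= group == 4
            hits[f"t{i}"] = per
            expected_any += any_g4
        table, overall = cross_species_distribution(hits, related, target_group=4)
        assert overall == pytest.approx(expected_any / 200)
        for g in related:
            n = sum(1 for per in hits.values() if per[g].group == 4)
            assert table.loc[g, "n_on_target_group"] == n

    def test_all_on_target_group_gives_fraction_one(self):
        hits = {
            f"t{i}": {"H": HomologyHit(f"t{i}", "H", "4H", 90.0, 50, 80.0, 40)}
            for i in range(5)
        }
        table, overall = cross_species_distribution(hits, ["H"], 4)
        assert overall == 1.0 and table.loc["H", "fraction"] == 1.0
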