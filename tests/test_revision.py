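"""Consolidation rules: overlap joins, homology joins, splice duplicates."""

import numpy as np
import pandas as pd
import pytest

from sporoseq import revision as rev
from sporoseq.io import BLAST6_COLUMNS
from sporoseq.records import MergeCandidate, TranscriptRecord

from conftest import random_dna


def lcs_oracle(a: str, b: str) -> int:
    """O(n*m) dynamic-programming longest-common-substring length."""
    prev = np.zeros(len(b) + 1, dtype=np.int32)
    best = 0
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    for ca in a.encode():
        cur = np.zeros(len(b) + 1, dtype=np.int32)
        match = bb == ca
        cur[1:][match] = prev[:-1][match] + 1
        m = cur.max()
        if m > best:
            best = int(m)
        prev = cur
    return best


def make_pair(seq_a, seq_b, scaffold="sc1", strand="+", ranks=(0, 1)):
    return [
        TranscriptRecord("A", seq_a, scaffold, strand, ranks[0]),
        TranscriptRecord("B", seq_b, scaffold, strand, ranks[1]),
    ]


class TestOverlapJoins:
    def test_planted_overlap_detected_with_exact_length(self):
        rng = np.random.default_rng(0)
        gene = random_dna(rng, 500)
        up, down = gene[:300], gene[240:]  # 60 nt exact overlap
        recs = make_pair(up, down)
        # brute-force check of the planted overlap
        assert max(
            (k for k in range(1, 301) if up[-k:] == down[:k]), default=0
        ) == 60
        cands = rev.find_overlap_joins(recs, min_overlap=50)
        assert len(cands) == 1
        assert cands[0].rule == "overlap"
        assert cands[0].evidence["overlap_length"] == 60

    def test_threshold_is_inclusive_boundary(self):
        rng = np.random.default_rng(1)
        gene = random_dna(rng, 500)
        recs = make_pair(gene[:300], gene[240:])
        assert rev.find_overlap_joins(recs, min_overlap=60)
        assert not rev.find_overlap_joins(recs, min_overlap=61)

    def test_different_scaffolds_are_not_neighbours(self):
        rng = np.random.default_rng(2)
        gene = random_dna(rng, 500)
        recs = [
            TranscriptRecord("A", gene[:300], "sc1", "+", 0),
            TranscriptRecord("B", gene[240:], "sc2", "+", 0),
        ]
        assert rev.find_overlap_joins(recs, min_overlap=50) == []

    def test_non_adjacent_ranks_are_not_neighbours(self):
        rng = np.random.default_rng(3)
        gene = random_dna(rng, 500)
        recs = make_pair(gene[:300], gene[240:], ranks=(0, 2))
        assert rev.find_overlap_joins(recs, min_overlap=50) == []

    def test_missing_locus_metadata_skips_rule(self, caplog):
        rng = np.random.default_rng(4)
        gene = random_dna(rng, 400)
        recs = [
            TranscriptRecord("A", gene[:250]),
            TranscriptRecord("B", gene[200:]),
        ]
        with caplog.at_level("WARNING"):
            assert rev.find_overlap_joins(recs, min_overlap=50) == []
        assert "locus metadata" in caplog.text

    def test_minus_strand_orientation(self):
        """On '-', the upstream (5') fragment sits at the higher rank."""
        rng = np.random.default_rng(5)
        gene = random_dna(rng, 500)
        up, down = gene[:300], gene[240:]
        recs = [
            TranscriptRecord("D", down, "sc1", "-", 0),
            TranscriptRecord("U", up, "sc1", "-", 1),
        ]
        (cand,) = rev.find_overlap_joins(recs, min_overlap=50)
        assert (cand.id_a, cand.id_b) == ("U", "D")


def hits_frame(rows):
    df = pd.DataFrame(rows, columns=BLAST6_COLUMNS)
    return df


def hit(q, s, sstart, send, bit=200.0):
    return dict(
        qseqid=q, sseqid=s, pident=90.0, length=send - sstart + 1, mismatch=0,
        gapopen=0, qstart=1, qend=3 * (send - sstart + 1), sstart=sstart,
        send=send, evalue=1e-30, bitscore=bit,
    )


class TestHomologyJoins:
    def setup_method(self):
        rng = np.random.default_rng(10)
        self.recs = make_pair(random_dna(rng, 400), random_dna(rng, 400))

    def test_disjoint_subject_intervals_join(self):
        hits = hits_frame([hit("A", "S", 1, 80), hit("B", "S", 95, 200)])
        (cand,) = rev.find_homology_joins(self.recs, hits)
        assert cand.rule == "homology_join"
        assert cand.evidence["subject"] == "S"

    def test_heavily_overlapping_intervals_rejected(self):
        hits = hits_frame([hit("A", "S", 1, 80), hit("B", "S", 40, 120)])
        assert rev.find_homology_joins(self.recs, hits, 0.1) == []

    def test_different_subjects_do_not_join(self):
        hits = hits_frame([hit("A", "S1", 1, 80), hit("B", "S2", 95, 200)])
        assert rev.find_homology_joins(self.recs, hits) == []

    def test_subject_order_must_match_genomic_order(self):
        # downstream fragment covering the earlier subject part: inconsistent
        hits = hits_frame([hit("A", "S", 95, 200), hit("B", "S", 1, 80)])
        assert rev.find_homology_joins(self.recs, hits) == []


class TestSpliceDuplicates:
    def test_planted_block_matches_oracle_exactly(self):
        rng = np.random.default_rng(20)
        block = random_dna(rng, 150)
        # force mismatching boundary characters so the block cannot extend
        flank = lambda n: random_dna(rng, n)
        a = flank(180) + "A" + block + "A" + flank(168)
        b = flank(120) + "C" + block + "C" + flank(228)
        recs = [TranscriptRecord("A", a), TranscriptRecord("B", b)]
        (cand,) = rev.find_splice_duplicates(recs, min_shared_block=100)
        assert cand.evidence["shared_block_length"] == lcs_oracle(a, b) == 150

    def test_random_pairs_share_nothing_long(self):
        rng = np.random.default_rng(21)
        a, b = random_dna(rng, 500), random_dna(rng, 500)
        assert lcs_oracle(a, b) < 100
        recs = [TranscriptRecord("A", a), TranscriptRecord("B", b)]
        assert rev.find_splice_duplicates(recs, min_shared_block=100) == []

    def test_agrees_with_oracle_on_many_random_instances(self):
        """Exact agreement (pairs and block lengths) with the DP oracle."""
        rng = np.random.default_rng(22)
        recs = []
        for i in range(30):
            seq = random_dna(rng, int(rng.integers(200, 1000)))
            recs.append(TranscriptRecord(f"t{i:02d}", seq))
        # plant some duplicates at varying block lengths around the threshold
        for i, blk in enumerate((90, 100, 101, 140, 300)):
            donor = recs[i].sequence
            start = int(rng.integers(0, len(donor) - blk))
            piece = donor[start : start + blk]
            recs.append(
                TranscriptRecord(
                    f"d{i:02d}", random_dna(rng, 50) + piece + random_dna(rng, 50)
                )
            )
        found = {
            c.pair: c.evidence["shared_block_length"]
            for c in rev.find_splice_duplicates(recs, min_shared_block=100)
        }
        expected = {}
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                L = lcs_oracle(recs[i].sequence, recs[j].sequence)
                if L > 100:
                    expected[frozenset((recs[i].id, recs[j].id))] = L
        assert found == expected
        assert expected  # the planted >100 blocks were actually present

    def test_threshold_strictly_greater(self):
        rng = np.random.default_rng(23)
        block = random_dna(rng, 100)
        a = "A" + block + "A" + random_dna(rng, 100)
        b = "C" + block + "C" + random_dna(rng, 100)
        recs = [TranscriptRecord("A", a), TranscriptRecord("B", b)]
        assert lcs_oracle(a, b) == 100
        assert rev.find_splice_duplicates(recs, min_shared_block=100) == []
        assert rev.find_splice_duplicates(recs, min_shared_block=99)

    def test_opposite_strands_not_compared(self):
        rng = np.random.default_rng(24)
        seq = random_dna(rng, 400)
        recs = [
            TranscriptRecord("A", seq, "sc1", "+", 0),
            TranscriptRecord("B", seq, "sc1", "-", 1),
        ]
        assert rev.find_splice_duplicates(recs) == []

    def test_self_pairing_rejected_by_contract(self):
        with pytest.raises(ValueError):
            MergeCandidate("X", "X", "splice_dup")


class TestApplyRevision:
    def test_zero_candidates_is_identity(self, reference_scenario):
        _, records, _ = reference_scenario
        revised, rmap = rev.apply_revision(records, [])
        assert [r.id for r in revised] == sorted(r.id for r in records)
        assert all(rmap.revised_id[r.id] == r.id for r in records)

    def test_overlap_pairs_merge_and_splice_correctly(self):
        rng = np.random.default_rng(30)
        gene = random_dna(rng, 600)
        recs = make_pair(gene[:350], gene[290:])
        cands = rev.find_overlap_joins(recs, min_overlap=50)
        revised, rmap = rev.apply_revision(recs, cands)
        assert len(revised) == 1
        assert revised[0].sequence == gene  # overlap counted once
        assert rmap.revised_id == {"A": "A", "B": "A"}

    def test_homology_join_inserts_n_spacer(self):
        rng = np.random.default_rng(31)
        a, b = random_dna(rng, 300), random_dna(rng, 300)
        recs = make_pair(a, b)
        cand = MergeCandidate("A", "B", "homology_join", {"subject": "S"})
        revised, _ = rev.apply_revision(recs, [cand], spacer_length=10)
        assert revised[0].sequence == a + "N" * 10 + b

    def test_splice_dup_keeps_longest_member(self):
        rng = np.random.default_rng(32)
        block = random_dna(rng, 150)
        long = random_dna(rng, 200) + block + random_dna(rng, 200)
        short = random_dna(rng, 20) + block + random_dna(rng, 20)
        recs = [TranscriptRecord("L", long), TranscriptRecord("S", short)]
        cands = rev.find_splice_duplicates(recs)
        revised, rmap = rev.apply_revision(recs, cands)
        assert [r.id for r in revised] == ["L"]
        assert revised[0].sequence == long
        assert rmap.rule_chain["S"] == ("splice_dup",)

    def test_unknown_candidate_ids_raise(self):
        recs = [TranscriptRecord("A", "ACGT" * 30)]
        cand = MergeCandidate("A", "Z", "splice_dup")
        with pytest.raises(KeyError):
            rev.apply_revision(recs, [cand])

    def test_branched_component_left_unmerged_and_flagged(self):
        rng = np.random.default_rng(33)
        recs = [TranscriptRecord(i, random_dna(rng, 200)) for i in "ABCD"]
        cands = [
            MergeCandidate("A", "B", "homology_join"),
            MergeCandidate("A", "C", "homology_join"),
            MergeCandidate("A", "D", "homology_join"),
        ]
        revised, rmap = rev.apply_revision(recs, cands)
        assert len(revised) == 4
        assert rmap.flagged_components == [("A", "B", "C", "D")]


class TestFullRevision:
    def test_synthetic_truth_counts(self):
        from sporoseq import simulate as sim

        params = sim.RevisionScenarioParams(
            n_genes=100, frac_split_overlap=0.2, frac_split_homology=0.0,
            frac_splice_dup=0.0, seed=41,
        )
        records, truth = sim.generate_reference(params)
        assert len(records) == 120  # 20 genes split into pairs
        revised, _ = rev.revise_transcriptome(records)
        assert len(revised) == 100

    def test_truth_grouping_recovered(self, reference_scenario):
        _, records, truth = reference_scenario
        revised, rmap = rev.revise_transcriptome(
            records, protein_hits=truth.homology_join_hits
        )
        pred_groups = set()
        by_rid = {}
        for tid, rid in rmap.revised_id.items():
            by_rid.setdefault(rid, set()).add(tid)
        pred_groups = {frozenset(v) for v in by_rid.values()}
        true_groups = {frozenset(v) for v in truth.members().values()}
        frac = len(pred_groups & true_groups) / len(true_groups)
        assert frac >= 0.99

    def test_idempotence_at_fixpoint(self, reference_scenario):
        _, records, truth = reference_scenario
        revised, _ = rev.revise_transcriptome(
            records, protein_hits=truth.homology_join_hits
        )
        assert rev.find_overlap_joins(revised) == []
        assert rev.find_splice_duplicates(revised) == []
        revised2, rmap2 = rev.revise_transcriptome(
            revised, protein_hits=truth.homology_join_hits
        )
        assert len(revised2) == len(revised)
        assert all(rmap2.revised_id[r.id] == r.id for r in revised)

    def test_conservation_invariant(self, reference_scenario):
        _, records, truth = reference_scenario
        revised, rmap = rev.revise_transcriptome(
            records, protein_hits=truth.homology_join_hits
        )
        assert set(rmap.revised_id) == {r.id for r in records}
        assert sum(len(m) for m in rmap.members.values()) == len(records)
        assert len(revised) <= len(records)
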