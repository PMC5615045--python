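"""Rule-based consolidation of a fragmented reference transcriptome.

Assembled reference transcriptomes are typically redundant and fragmented:
one gene may be represented by two abutting fragments, by two pieces whose
protein homology shows they belong together, or by several alternatively
spliced variants.  This module detects all three situations and collapses
them, producing a revised transcript set plus a map from every input ID to
its revised ID.

Rules
-----
``overlap``
    Rank-adjacent transcripts on the same scaffold and strand whose
    upstream 3' end exactly matches the downstream 5' start over at least
    ``min_overlap`` nt are spliced into one sequence (overlap counted once).
``homology_join``
    Rank-adjacent transcripts that hit the same database subject on
    essentially disjoint subject intervals, in an order consistent with
    their genomic order, are concatenated with a short N-spacer.  The
    N-spacer marks the unsequenced gap without fabricating nucleotides.
``splice_dup``
    Any two transcripts sharing an exact identical block longer than
    ``min_shared_block`` nt (default: strictly more than 100) are treated as
    splice variants of one gene; only the longest variant is retained.

Candidates from all three rules are merged in a single union-find pass;
sequence construction within each connected component applies the rule
priority overlap > homology_join > splice_dup.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .records import MergeCandidate, TranscriptRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 50
DEFAULT_MIN_SHARED_BLOCK = 100
DEFAULT_MAX_SUBJECT_OVERLAP_FRAC = 0.1
DEFAULT_SPACER_LENGTH = 10

_RULE_PRIORITY = {"overlap": 0, "homology_join": 1, "splice_dup": 2}


@dataclass
class RevisionMap:
    """Accounting of a revision run: every input ID maps to one revised ID."""

    revised_id: dict[str, str] = field(default_factory=dict)
    rule_chain: dict[str, tuple[str, ...]] = field(default_factory=dict)
    members: dict[str, tuple[str, ...]] = field(default_factory=dict)
    flagged_components: list[tuple[str, ...]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "input_id": tid,
                "revised_id": rid,
                "rule_chain": ",".join(self.rule_chain.get(tid, ())) or "identity",
            }
            for tid, rid in sorted(self.revised_id.items())
        ]
        return pd.DataFrame(rows, columns=["input_id", "revised_id", "rule_chain"])

    def summary(self) -> dict:
        n_in = len(self.revised_id)
        n_out = len(self.members)
        per_rule: dict[str, int] = defaultdict(int)
        for chain in self.rule_chain.values():
            for rule in set(chain):
                per_rule[rule] += 1
        return {
            "n_input": n_in,
            "n_revised": n_out,
            "n_merged_away": n_in - n_out,
            "inputs_touched_per_rule": dict(sorted(per_rule.items())),
            "n_flagged_components": len(self.flagged_components),
        }


# ---------------------------------------------------------------------------
# candidate detection


def _adjacent_pairs(
    transcripts: Sequence[TranscriptRecord],
) -> list[tuple[TranscriptRecord, TranscriptRecord]]:
    """Pairs of rank-adjacent transcripts on the same scaffold and strand.

    The first element of each pair is the upstream transcript in
    transcription order (lower rank on '+', higher rank on '-')."""
    by_locus: dict[tuple[str, str], list[TranscriptRecord]] = defaultdict(list)
    for rec in transcripts:
        if rec.has_locus:
            by_locus[(rec.scaffold, rec.strand)].append(rec)
    pairs = []
    for (scaffold, strand), recs in sorted(by_locus.items()):
        recs = sorted(recs, key=lambda r: r.rank)
        for a, b in zip(recs, recs[1:]):
            if b.rank - a.rank == 1:
                pairs.append((a, b) if strand == "+" else (b, a))
    return pairs


def _longest_suffix_prefix(a: str, b: str) -> int:
    """Length of the longest suffix of ``a`` equal to a prefix of ``b``."""
    for k in range(min(len(a), len(b)), 0, -1):
        if a[-k:] == b[:k]:
            return k
    return 0


def find_overlap_joins(
    transcripts: Sequence[TranscriptRecord], min_overlap: int = DEFAULT_MIN_OVERLAP
) -> list[MergeCandidate]:
    """Detect rank-adjacent fragments with an exact suffix-prefix overlap.

    Only exact matches count; the candidate stores the longest overlap of at
    least ``min_overlap`` nt.  Transcripts without locus metadata are skipped
    with a warning (the rule is undefined without genomic neighbourhood).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    n_skipped = sum(1 for t in transcripts if not t.has_locus)
    if n_skipped:
        logger.warning(
            "overlap rule: %d transcripts lack locus metadata and were skipped",
            n_skipped,
        )
    out = []
    for up, down in _adjacent_pairs(transcripts):
        k = _longest_suffix_prefix(up.sequence, down.sequence)
        if k >= min_overlap:
            out.append(
                MergeCandidate(
                    id_a=up.id,
                    id_b=down.id,
                    rule="overlap",
                    evidence={"overlap_length": k},
                )
            )
    return out


def _best_hits_by_subject(hits: pd.DataFrame) -> dict[str, dict[str, tuple[int, int]]]:
    """query -> subject -> best (by bitscore) subject interval, normalised."""
    out: dict[str, dict[str, tuple[int, int]]] = defaultdict(dict)
    best_score: dict[tuple[str, str], float] = {}
    for row in hits.itertuples(index=False):
        key = (row.qseqid, row.sseqid)
        if best_score.get(key, -1.0) < row.bitscore:
            best_score[key] = row.bitscore
            lo, hi = sorted((int(row.sstart), int(row.send)))
            out[row.qseqid][row.sseqid] = (lo, hi)
    return out


def find_homology_joins(
    transcripts: Sequence[TranscriptRecord],
    protein_hits: pd.DataFrame,
    max_subject_overlap_frac: float = DEFAULT_MAX_SUBJECT_OVERLAP_FRAC,
) -> list[MergeCandidate]:
    """Detect adjacent fragments jointly representing one database subject.

    A candidate is reported when two rank-adjacent transcripts hit the same
    subject on intervals whose overlap is at most ``max_subject_overlap_frac``
    of the shorter interval, and the subject-coordinate order of the two
    intervals matches the transcripts' order in transcription direction.
    """
    if not 0 <= max_subject_overlap_frac < 1:
        raise ValueError("max_subject_overlap_frac must be in [0, 1)")
    intervals = _best_hits_by_subject(protein_hits)
    out = []
    for up, down in _adjacent_pairs(transcripts):
        subjects = set(intervals.get(up.id, {})) & set(intervals.get(down.id, {}))
        for subj in sorted(subjects):
            lo_u, hi_u = intervals[up.id][subj]
            lo_d, hi_d = intervals[down.id][subj]
            if lo_u > lo_d:  # upstream fragment must cover the earlier part
                continue
            ov = min(hi_u, hi_d) - max(lo_u, lo_d) + 1
            shorter = min(hi_u - lo_u, hi_d - lo_d) + 1
            if ov > max_subject_overlap_frac * shorter:
                continue
            out.append(
                MergeCandidate(
                    id_a=up.id,
                    id_b=down.id,
                    rule="homology_join",
                    evidence={
                        "subject": subj,
                        "subject_interval_a": (lo_u, hi_u),
                        "subject_interval_b": (lo_d, hi_d),
                    },
                )
            )
            break  # one shared subject suffices
    return out


def longest_common_substring(a: str, b: str, min_len: int = 1) -> int:
    """Length of the longest exact common substring of ``a`` and ``b``.

    Uses k-mer seeding with ``k = min_len`` followed by seed extension; the
    answer is exact whenever it is >= ``min_len`` (any common substring of
    length >= k contains a shared k-mer), else 0 is returned.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    k = min_len
    if len(a) < k or len(b) < k:
        return 0
    seeds: dict[str, list[int]] = defaultdict(list)
    for i in range(len(a) - k + 1):
        seeds[a[i : i + k]].append(i)
    best = 0
    # visited left-anchored diagonals to avoid re-extending the same match
    seen: set[tuple[int, int]] = set()
    for j in range(len(b) - k + 1):
        kmer = b[j : j + k]
        for i in seeds.get(kmer, ()):
            # extend left to the maximal match anchor on this diagonal
            li, lj = i, j
            while li > 0 and lj > 0 and a[li - 1] == b[lj - 1]:
                li -= 1
                lj -= 1
            if (li, lj) in seen:
                continue
            seen.add((li, lj))
            ri, rj = i + k, j + k
            while ri < len(a) and rj < len(b) and a[ri] == b[rj]:
                ri += 1
                rj += 1
            best = max(best, ri - li)
    return best


def find_splice_duplicates(
    transcripts: Sequence[TranscriptRecord],
    min_shared_block: int = DEFAULT_MIN_SHARED_BLOCK,
) -> list[MergeCandidate]:
    """Detect pairs sharing an identical block of more than ``min_shared_block`` nt.

    Every unordered pair on the same strand (or with unknown strand) is
    tested; the threshold is strict (block length must exceed
    ``min_shared_block``), matching the convention "identical sequences of
    more than N bases".  Runs of the ambiguity base N (spacers introduced by
    homology joins) never seed or extend a match.
    """
    if min_shared_block < 1:
        raise ValueError("min_shared_block must be >= 1")
    recs = list(transcripts)
    k = min_shared_block + 1
    # shortlist pairs by a shared k-mer: any common substring of length >= k
    # contains one, so the shortlist is an exact superset of true candidates
    # (hash collisions only add pairs, which the exact LCS check then rejects)
    index: dict[int, list[int]] = defaultdict(list)
    for i, rec in enumerate(recs):
        seq = rec.sequence
        seen_local: set[int] = set()
        for segment in seq.split("N"):
            for p in range(len(segment) - k + 1):
                h = hash(segment[p : p + k])
                if h not in seen_local:
                    seen_local.add(h)
                    index[h].append(i)
    pairs: set[tuple[int, int]] = set()
    for ids_at_kmer in index.values():
        if len(ids_at_kmer) > 1:
            for x in range(len(ids_at_kmer)):
                for y in range(x + 1, len(ids_at_kmer)):
                    pairs.add((ids_at_kmer[x], ids_at_kmer[y]))
    out = []
    for i, j in sorted(pairs):
        a, b = recs[i], recs[j]
        if a.strand is not None and b.strand is not None and a.strand != b.strand:
            continue
        block = _lcs_ignoring_n(a.sequence, b.sequence, k)
        if block > min_shared_block:
            out.append(
                MergeCandidate(
                    id_a=a.id,
                    id_b=b.id,
                    rule="splice_dup",
                    evidence={"shared_block_length": block},
                )
            )
    return out


# ---------------------------------------------------------------------------
# applying candidates


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: str, y: str) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[max(rx, ry)] = min(rx, ry)


def _stitch_chain(
    chain: list[TranscriptRecord],
    edges: dict[frozenset, MergeCandidate],
    spacer_length: int,
) -> TranscriptRecord:
    """Splice a transcription-ordered chain of fragments into one record."""
    head = chain[0]
    seq = head.sequence
    for prev, nxt in zip(chain, chain[1:]):
        cand = edges[frozenset((prev.id, nxt.id))]
        if cand.rule == "overlap":
            k = cand.evidence["overlap_length"]
            seq = seq + nxt.sequence[k:]
        else:  # homology_join: gap of unknown sequence
            seq = seq + "N" * spacer_length + nxt.sequence
        # N spacers violate the ACGT contract of TranscriptRecord on purpose:
        # the joined record is constructed directly below.
    ranks = [r.rank for r in chain if r.rank is not None]
    starts = [r.start for r in chain if r.start is not None]
    ends = [r.end for r in chain if r.end is not None]
    rec = TranscriptRecord.__new__(TranscriptRecord)
    rec.id = head.id
    rec.sequence = seq
    rec.scaffold = head.scaffold
    rec.strand = head.strand
    rec.rank = min(ranks) if ranks else None
    rec.start = min(starts) if starts else None
    rec.end = max(ends) if ends else None
    return rec


def apply_revision(
    transcripts: Sequence[TranscriptRecord],
    candidates: Sequence[MergeCandidate],
    spacer_length: int = DEFAULT_SPACER_LENGTH,
) -> tuple[list[TranscriptRecord], RevisionMap]:
    """Merge transcripts according to candidate edges.

    Connected components are formed over all candidate edges.  Within a
    component, adjacency edges (overlap / homology_join) are stitched along
    the transcription-ordered chain; splice-duplicate edges then select the
    longest resulting sequence (ties broken lexicographically by ID) as the
    component representative.  A component whose adjacency edges do not form
    simple chains (a branch or a cycle) is left unmerged and flagged.
    """
    by_id = {t.id: t for t in transcripts}
    unknown = [
        c for c in candidates if c.id_a not in by_id or c.id_b not in by_id
    ]
    if unknown:
        offenders = ({c.id_a for c in unknown} | {c.id_b for c in unknown}) - set(by_id)
        raise KeyError(
            f"candidates reference unknown transcript IDs: {sorted(offenders)[:5]}"
        )

    uf = _UnionFind(by_id)
    # one edge per pair, highest-priority rule wins
    edges: dict[frozenset, MergeCandidate] = {}
    for cand in candidates:
        prev = edges.get(cand.pair)
        if prev is None or _RULE_PRIORITY[cand.rule] < _RULE_PRIORITY[prev.rule]:
            edges[cand.pair] = cand
        uf.union(cand.id_a, cand.id_b)

    components: dict[str, list[str]] = defaultdict(list)
    for tid in by_id:
        components[uf.find(tid)].append(tid)

    revision = RevisionMap()
    revised: list[TranscriptRecord] = []

    for root in sorted(components):
        member_ids = sorted(components[root])
        members = [by_id[t] for t in member_ids]
        comp_edges = {
            pair: cand
            for pair, cand in edges.items()
            if next(iter(pair)) in components[root]
        }
        if len(members) == 1:
            rec = members[0]
            revised.append(rec)
            revision.revised_id[rec.id] = rec.id
            revision.rule_chain[rec.id] = ()
            revision.members[rec.id] = (rec.id,)
            continue

        adjacency = {p: c for p, c in comp_edges.items() if c.rule != "splice_dup"}
        degree: dict[str, int] = defaultdict(int)
        for pair in adjacency:
            for tid in pair:
                degree[tid] += 1
        if any(d > 2 for d in degree.values()):
            # branched join order is ambiguous: leave the component as-is
            logger.warning(
                "component %s has conflicting join orders; left unmerged", member_ids
            )
            revision.flagged_components.append(tuple(member_ids))
            for rec in members:
                revised.append(rec)
                revision.revised_id[rec.id] = rec.id
                revision.rule_chain[rec.id] = ()
                revision.members[rec.id] = (rec.id,)
            continue

        # stitch adjacency chains in transcription order
        chain_uf = _UnionFind(member_ids)
        for pair in adjacency:
            a, b = tuple(pair)
            chain_uf.union(a, b)
        chains: dict[str, list[TranscriptRecord]] = defaultdict(list)
        for tid in member_ids:
            chains[chain_uf.find(tid)].append(by_id[tid])

        pieces: list[tuple[TranscriptRecord, tuple[str, ...], tuple[str, ...]]] = []
        for croot in sorted(chains):
            chain = chains[croot]
            if len(chain) == 1:
                pieces.append((chain[0], (chain[0].id,), ()))
                continue
            strand = chain[0].strand
            chain = sorted(
                chain, key=lambda r: r.rank, reverse=(strand == "-")
            )
            rules = tuple(
                adjacency[frozenset((p.id, n.id))].rule
                for p, n in zip(chain, chain[1:])
            )
            stitched = _stitch_chain(chain, adjacency, spacer_length)
            pieces.append((stitched, tuple(r.id for r in chain), rules))

        # splice-duplicate selection among the stitched pieces: longest
        # sequence wins, ties broken by lexicographically smallest ID
        dup_edges_used = len(pieces) > 1
        rep_rec, _, _ = min(pieces, key=lambda p: (-len(p[0].sequence), p[0].id))
        revised.append(rep_rec)
        for piece_rec, piece_members, piece_rules in pieces:
            chain_rules = tuple(dict.fromkeys(piece_rules))
            extra = ("splice_dup",) if dup_edges_used else ()
            for tid in piece_members:
                revision.revised_id[tid] = rep_rec.id
                revision.rule_chain[tid] = chain_rules + extra
        revision.members[rep_rec.id] = tuple(member_ids)

    # conservation invariant
    assert len(revision.revised_id) == len(by_id)
    assert sum(len(m) for m in revision.members.values()) == len(by_id)
    return revised, revision


def revise_transcriptome(
    transcripts: Sequence[TranscriptRecord],
    protein_hits: Optional[pd.DataFrame] = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_shared_block: int = DEFAULT_MIN_SHARED_BLOCK,
    max_subject_overlap_frac: float = DEFAULT_MAX_SUBJECT_OVERLAP_FRAC,
    spacer_length: int = DEFAULT_SPACER_LENGTH,
    max_rounds: int = 10,
) -> tuple[list[TranscriptRecord], RevisionMap]:
    """Run candidate detection and merging to a fixpoint.

    Detection and merging alternate until a round produces no candidates
    (merged sequences could in principle expose new overlaps).  The returned
    RevisionMap composes the rounds, mapping every original ID to its final
    revised ID.
    """
    current = list(transcripts)
    total_map = RevisionMap(
        revised_id={t.id: t.id for t in current},
        rule_chain={t.id: () for t in current},
        members={t.id: (t.id,) for t in current},
    )
    for _ in range(max_rounds):
        candidates = list(find_overlap_joins(current, min_overlap))
        if protein_hits is not None and len(protein_hits):
            candidates += find_homology_joins(
                current, protein_hits, max_subject_overlap_frac
            )
        candidates += find_splice_duplicates(current, min_shared_block)
        if not candidates:
            break
        current, step = apply_revision(current, candidates, spacer_length)
        # compose step into total_map
        new_map = RevisionMap(flagged_components=total_map.flagged_components)
        for orig, mid in total_map.revised_id.items():
            new_map.revised_id[orig] = step.revised_id[mid]
            new_map.rule_chain[orig] = tuple(
                dict.fromkeys(total_map.rule_chain[orig] + step.rule_chain[mid])
            )
        for rid in step.members:
            new_map.members[rid] = tuple(
                orig
                for orig, final in sorted(new_map.revised_id.items())
                if final == rid
            )
        new_map.flagged_components.extend(step.flagged_components)
        total_map = new_map
    return current, total_map


def _lcs_ignoring_n(a: str, b: str, min_len: int) -> int:
    if "N" not in a and "N" not in b:
        return longest_common_substring(a, b, min_len=min_len)
    best = 0
    for seg_a in a.split("N"):
        if len(seg_a) < min_len:
            continue
        for seg_b in b.split("N"):
            if len(seg_b) < min_len:
                continue
            best = max(best, longest_common_substring(seg_a, seg_b, min_len=min_len))
    return best
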