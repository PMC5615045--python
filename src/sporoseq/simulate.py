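"""Synthetic study generator with planted ground truth.

Every input the pipeline consumes can be generated here: a fragmented
reference transcriptome whose redundancy events (suffix-prefix overlaps,
homology-joinable fragment pairs, splice-variant duplicates) are planted and
recorded; a negative-binomial count matrix over a 0/6/10 h design with
planted log2 fold changes; and homology hit tables (protein database,
developmental core gene set, protein domains) with a known ortholog
fraction.  The truth tables let every downstream stage be scored against
what was planted.

All randomness flows from a single integer seed; each generator derives one
``numpy.random.Generator`` stream per output so runs are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import BLAST6_COLUMNS
from .records import TranscriptRecord

_NT = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NT, size=length))


# ---------------------------------------------------------------------------
# reference transcriptome with planted fragmentation


@dataclass
class RevisionScenarioParams:
    """Parameters of the fragmented-reference scenario.

    Fractions give the share of genes corrupted by each event class; they
    must sum to at most 1 and the classes are disjoint.  ``shared_block_min``
    is the minimum identical block planted between splice-variant pairs
    (must satisfy the > 100 nt detection convention, so >= 100).
    """

    n_genes: int = 100
    n_scaffolds: int = 5
    frac_split_overlap: float = 0.2
    frac_split_homology: float = 0.2
    frac_splice_dup: float = 0.2
    gene_length_range: tuple[int, int] = (400, 1200)
    overlap_length_range: tuple[int, int] = (55, 90)
    shared_block_min: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_scaffolds < 1:
            raise ValueError("n_genes and n_scaffolds must be positive")
        fr = (self.frac_split_overlap, self.frac_split_homology, self.frac_splice_dup)
        if any(not 0 <= f <= 1 for f in fr) or sum(fr) > 1 + 1e-12:
            raise ValueError("event fractions must be in [0,1] and sum to <= 1")
        if self.shared_block_min < 100:
            raise ValueError("shared_block_min must be >= 100")
        for lo, hi in (self.gene_length_range, self.overlap_length_range):
            if lo > hi or lo < 1:
                raise ValueError("ranges must satisfy 1 <= low <= high")
        min_gene = self.gene_length_range[0]
        if self.overlap_length_range[1] >= min_gene // 2:
            raise ValueError(
                "overlap_length_range exceeds what the shortest gene can host"
            )
        if self.shared_block_min + 20 >= min_gene:
            raise ValueError("shared_block_min too large for gene_length_range")


@dataclass
class ReferenceTruth:
    """Planted truth for a generated reference: grouping plus join evidence."""

    group_of: dict[str, str]  # transcript id -> true gene/group id
    event_of: dict[str, str]  # group id -> {none, split_overlap, split_homology, splice_dup}
    homology_join_hits: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_groups(self) -> int:
        return len(set(self.group_of.values()))

    def members(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {}
        for tid, gid in self.group_of.items():
            out.setdefault(gid, []).append(tid)
        return {g: tuple(sorted(ms)) for g, ms in out.items()}


def _blast_row(
    q: str, s: str, qstart: int, qend: int, sstart: int, send: int,
    pident: float, evalue: float, bitscore: float,
) -> dict:
    return {
        "qseqid": q,
        "sseqid": s,
        "pident": round(pident, 1),
        "length": abs(qend - qstart) + 1,
        "mismatch": 0,
        "gapopen": 0,
        "qstart": qstart,
        "qend": qend,
        "sstart": sstart,
        "send": send,
        "evalue": evalue,
        "bitscore": round(bitscore, 1),
    }


def generate_reference(
    params: RevisionScenarioParams,
) -> tuple[list[TranscriptRecord], ReferenceTruth]:
    """Emit a fragmented reference transcriptome with planted events.

    Genes are laid out consecutively on scaffolds (alternating strands per
    gene) and a planted fraction is corrupted into (a) overlapping fragment
    pairs, (b) non-overlapping fragment pairs with hits to one synthetic
    subject protein, or (c) splice-variant pairs sharing one identical
    block.  Fragments of one gene occupy consecutive ranks so they are
    genomic neighbours.  The returned truth records the intended grouping
    and, for (b), the supporting protein hit rows.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    n_ov = int(round(params.frac_split_overlap * n))
    n_hj = int(round(params.frac_split_homology * n))
    n_sd = int(round(params.frac_splice_dup * n))
    perm = rng.permutation(n)
    ov_set = set(perm[:n_ov])
    hj_set = set(perm[n_ov : n_ov + n_hj])
    sd_set = set(perm[n_ov + n_hj : n_ov + n_hj + n_sd])

    records: list[TranscriptRecord] = []
    group_of: dict[str, str] = {}
    event_of: dict[str, str] = {}
    hit_rows: list[dict] = []

    scaffold_of = np.sort(rng.integers(0, params.n_scaffolds, size=n))
    rank_counter: dict[str, int] = {}
    pos_counter: dict[str, int] = {}

    def place(seq: str, tid: str, scaffold: str, strand: str) -> TranscriptRecord:
        rank = rank_counter.get(scaffold, 0)
        rank_counter[scaffold] = rank + 1
        start = pos_counter.get(scaffold, 1)
        end = start + len(seq) - 1
        pos_counter[scaffold] = end + 1 + int(rng.integers(50, 500))
        return TranscriptRecord(
            id=tid, sequence=seq, scaffold=scaffold, strand=strand,
            rank=rank, start=start, end=end,
        )

    for g in range(n):
        gid = f"gene{g:05d}"
        scaffold = f"scaffold_{scaffold_of[g]:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        lo, hi = params.gene_length_range
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)

        if g in ov_set:
            event_of[gid] = "split_overlap"
            ov = int(rng.integers(*params.overlap_length_range))
            ov = min(ov, params.overlap_length_range[1])
            cut = int(rng.integers(ov + 20, length - 20))
            up = seq[:cut]
            down = seq[cut - ov :]
            ids = (f"{gid}.f1", f"{gid}.f2")
            frags = (up, down) if strand == "+" else (down, up)
            # on '-' the downstream-in-transcription fragment has lower rank
            for tid, fseq in zip(ids if strand == "+" else ids[::-1], frags):
                records.append(place(fseq, tid, scaffold, strand))
                group_of[tid] = gid
        elif g in hj_set:
            event_of[gid] = "split_homology"
            cut = int(rng.integers(length // 3, 2 * length // 3))
            up, down = seq[:cut], seq[cut:]
            subj = f"SUBJ_{gid}"
            prot_len = length // 3
            mid = prot_len // 2
            ids = (f"{gid}.f1", f"{gid}.f2")
            for tid, fseq in zip(ids if strand == "+" else ids[::-1],
                                 (up, down) if strand == "+" else (down, up)):
                records.append(place(fseq, tid, scaffold, strand))
                group_of[tid] = gid
            hit_rows.append(
                _blast_row(ids[0], subj, 1, cut, 1, mid, 92.0, 1e-40, 180.0)
            )
            hit_rows.append(
                _blast_row(
                    ids[1], subj, 1, length - cut, mid + 3, prot_len, 91.0, 1e-38, 170.0
                )
            )
        elif g in sd_set:
            event_of[gid] = "splice_dup"
            block_len = params.shared_block_min + int(rng.integers(1, 101))
            block_len = min(block_len, length - 10)
            bstart = int(rng.integers(0, length - block_len + 1))
            block = seq[bstart : bstart + block_len]
            flank_a = int(rng.integers(30, 200))
            flank_b = int(rng.integers(30, 200))
            variant = _random_seq(rng, flank_a) + block + _random_seq(rng, flank_b)
            for tid, vseq in ((f"{gid}.v1", seq), (f"{gid}.v2", variant)):
                records.append(place(vseq, tid, scaffold, strand))
                group_of[tid] = gid
        else:
            event_of[gid] = "none"
            tid = f"{gid}.t1"
            records.append(place(seq, tid, scaffold, strand))
            group_of[tid] = gid

    hits = pd.DataFrame(hit_rows, columns=BLAST6_COLUMNS)
    truth = ReferenceTruth(group_of=group_of, event_of=event_of, homology_join_hits=hits)
    return records, truth


# ---------------------------------------------------------------------------
# counts with planted fold changes


@dataclass
class CountScenarioParams:
    """Parameters of the NB count scenario over the 0/6/10 h design.

    ``design`` mirrors the study layout: one entry per (experiment, strain,
    timepoint, replicate count).  ``frac_de`` transcripts receive a planted
    |log2FC| drawn from Normal(lfc_mean, lfc_sd) (truncated at 0.5), with
    probability ``prob_up`` of being up-regulated, assigned to one of three
    monotone trajectory classes (step at 6 h, step at 10 h, gradual).
    Dispersion follows alpha(mu) = disp_intercept + disp_slope / mu.
    """

    n_transcripts: int = 2000
    design: tuple[tuple[str, str, int, int], ...] = (
        # experiment, strain, timepoint_h, replicates; the default mirrors
        # the study layout (5 / 4 / 3 pooled replicates at 0 / 6 / 10 h,
        # with 8 h and 10.5 h samplings mapped to the 10 h class)
        ("exp1", "LU897xLU898", 0, 1),
        ("exp1", "LU897xLU898", 6, 1),
        ("exp2", "LU897xLU898", 0, 1),
        ("exp2", "LU897xLU898", 10, 2),
        ("exp3", "WT31", 0, 2),
        ("exp3", "WT31", 6, 2),
        ("exp3", "WT31xMA25", 0, 1),
        ("exp3", "WT31xMA25", 6, 1),
        ("exp3", "WT31xMA25", 10, 1),
    )
    frac_de: float = 0.2
    lfc_mean: float = 2.0
    lfc_sd: float = 1.0
    prob_up: float = 0.5
    disp_intercept: float = 0.02
    disp_slope: float = 2.0
    library_size_range: tuple[float, float] = (0.5e6, 2e6)
    baseline_mean_range: tuple[float, float] = (5.0, 2000.0)
    strain_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be positive")
        if not 0 <= self.frac_de <= 1:
            raise ValueError("frac_de must be in [0,1]")
        tps = {d[2] for d in self.design}
        if not tps <= {0, 6, 10}:
            raise ValueError("design time points must be in {0, 6, 10}")
        if tps != {0, 6, 10}:
            raise ValueError("design must cover all of 0, 6 and 10 h")
        per_tp: dict[int, int] = {}
        for _, _, tp, nrep in self.design:
            if nrep < 1:
                raise ValueError("replicate counts must be >= 1")
            per_tp[tp] = per_tp.get(tp, 0) + nrep
        if any(v < 2 for v in per_tp.values()):
            raise ValueError("tests need >= 2 pooled replicates per time point")
        if self.library_size_range[0] > self.library_size_range[1]:
            raise ValueError("library_size_range must be ordered")


@dataclass
class CountTruth:
    """Planted per-transcript truth of the count scenario."""

    table: pd.DataFrame  # is_de, lfc_0_6, lfc_6_10, lfc_0_10, baseline_mean, trajectory

    def lfc(self, contrast: tuple[int, int]) -> pd.Series:
        return self.table[f"lfc_{contrast[0]}_{contrast[1]}"]


def generate_counts(
    transcript_ids: Sequence[str], params: CountScenarioParams
) -> tuple[pd.DataFrame, pd.DataFrame, CountTruth]:
    """Draw an NB count matrix with planted log2 fold changes.

    Returns (counts, sample sheet, truth).  Counts for transcript i in
    sample j are NB with mean = library factor_j * baseline_i *
    2**(planted log2FC of i at the sample's time point relative to 0 h) and
    dispersion alpha(mu) = disp_intercept + disp_slope / mu.  Truth log2FCs
    satisfy lfc(0-10) = lfc(0-6) + lfc(6-10) exactly by construction.
    """
    ids = list(transcript_ids)
    if not ids:
        raise ValueError("transcript set must be non-empty")
    n = len(ids)
    rng = np.random.default_rng(params.seed)

    # planted trajectories
    n_de = int(round(params.frac_de * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True
    magnitude = np.maximum(rng.normal(params.lfc_mean, params.lfc_sd, size=n), 0.5)
    sign = np.where(rng.random(n) < params.prob_up, 1.0, -1.0)
    trajectory = rng.choice(["step6", "step10", "gradual"], size=n)
    d06 = np.zeros(n)
    d610 = np.zeros(n)
    eff = magnitude * sign
    step6 = is_de & (trajectory == "step6")
    step10 = is_de & (trajectory == "step10")
    gradual = is_de & (trajectory == "gradual")
    d06[step6] = eff[step6]
    d610[step10] = eff[step10]
    d06[gradual] = eff[gradual] / 2
    d610[gradual] = eff[gradual] / 2
    trajectory = np.where(is_de, trajectory, "flat")

    baseline = np.exp(
        rng.uniform(*np.log(params.baseline_mean_range), size=n)
    )

    # sample layout
    sample_rows = []
    for exp, strain, tp, nrep in params.design:
        for r in range(nrep):
            sample_rows.append(
                {
                    "sample_id": f"{exp}_{strain}_{tp}h_r{r + 1}",
                    "experiment": exp,
                    "strain": strain,
                    "timepoint_h": tp,
                }
            )
    samples = pd.DataFrame(sample_rows)
    m = len(samples)
    lib_lo, lib_hi = params.library_size_range
    lib_raw = np.exp(rng.uniform(np.log(lib_lo), np.log(lib_hi), size=m))
    # express as relative depth factors; mean normalised count == baseline
    lib_factor = lib_raw / np.exp(np.mean(np.log(lib_raw)))

    strains = sorted(samples["strain"].unique())
    strain_shift = {
        s: rng.normal(0.0, params.strain_effect_sd, size=n) for s in strains
    }

    tp_arr = samples["timepoint_h"].to_numpy()
    lfc_at_tp = np.zeros((n, m))
    lfc_at_tp[:, tp_arr == 6] = d06[:, None]
    lfc_at_tp[:, tp_arr == 10] = (d06 + d610)[:, None]
    for j, s in enumerate(samples["strain"]):
        lfc_at_tp[:, j] += strain_shift[s]

    mu = lib_factor[None, :] * baseline[:, None] * 2.0**lfc_at_tp
    alpha = params.disp_intercept + params.disp_slope / np.maximum(mu, 1e-8)
    # NB as Gamma-Poisson: shape r = 1/alpha, scale mu*alpha
    r_shape = 1.0 / np.maximum(alpha, 1e-12)
    lam = rng.gamma(shape=r_shape, scale=mu / r_shape)
    counts = rng.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=ids, columns=samples["sample_id"])
    counts_df.index.name = "transcript_id"

    truth_table = pd.DataFrame(
        {
            "is_de": is_de,
            "lfc_0_6": d06,
            "lfc_6_10": d610,
            "lfc_0_10": d06 + d610,
            "baseline_mean": baseline,
            "trajectory": trajectory,
        },
        index=ids,
    )
    truth_table.index.name = "transcript_id"
    return counts_df, samples, CountTruth(table=truth_table)


# ---------------------------------------------------------------------------
# homology hit tables


def generate_homology(
    transcript_ids: Sequence[str],
    core_set_size: int = 1167,
    frac_ortholog: float = 0.1,
    frac_uniprot: float = 0.47,
    frac_domain: float = 0.54,
    seed: int = 0,
    multi_hit_frac: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str]]:
    """Generate protein, core-set and domain hit tables plus the core ID list.

    A fraction ``frac_uniprot`` of transcripts receives a protein-database
    best hit, ``frac_ortholog`` a hit into the developmental core gene set,
    and ``frac_domain`` one to three domain hits.  ``multi_hit_frac`` of the
    core-hit transcripts receive a second, weaker hit to another core gene,
    and a matching share of core genes is deliberately hit by two
    transcripts, exercising duplicate elimination downstream.
    """
    if core_set_size < 1:
        raise ValueError("core_set_size must be >= 1")
    for name, f in (
        ("frac_ortholog", frac_ortholog),
        ("frac_uniprot", frac_uniprot),
        ("frac_domain", frac_domain),
        ("multi_hit_frac", multi_hit_frac),
    ):
        if not 0 <= f <= 1:
            raise ValueError(f"{name} must be in [0,1]")
    ids = list(transcript_ids)
    n = len(ids)
    rng = np.random.default_rng(seed)
    core_genes = [f"DDB_G{200000 + i}" for i in range(core_set_size)]

    descriptions = [
        "GATA-type zinc finger transcription factor",
        "basic leucine zipper transcription factor",
        "myb-like DNA-binding protein",
        "serine/threonine-protein kinase",
        "histidine kinase hybrid signal transduction protein",
        "protein tyrosine phosphatase",
        "E3 ubiquitin-protein ligase",
        "pumilio homolog RNA-binding protein",
        "ELAV-like RNA-binding protein",
        "cyclin-dependent kinase",
        "DNA repair protein RAD51 homolog",
        "meiotic recombination protein DMC1",
        "glycogen phosphorylase",
        "actin-related protein",
        "ras-related protein Ral-A",
        "phosphatidylinositol 3-kinase",
        "homeobox protein",
        "argonaute protein",
        "uncharacterized protein",
    ]

    # protein (UniProt-style) hits
    n_up = int(round(frac_uniprot * n))
    up_idx = rng.choice(n, size=n_up, replace=False)
    prot_rows = []
    for i in up_idx:
        subj = f"UP{rng.integers(10000, 99999)}_{rng.integers(0, 1000):03d}"
        bit = float(rng.uniform(60, 400))
        qlen = int(rng.integers(150, 900))
        prot_rows.append(
            _blast_row(
                ids[i], subj, 1, qlen, 1, qlen // 3,
                float(rng.uniform(35, 95)), float(10.0 ** rng.uniform(-80, -6)), bit,
            )
        )
    protein_hits = pd.DataFrame(prot_rows, columns=BLAST6_COLUMNS)
    protein_hits["description"] = [
        descriptions[int(k)] for k in rng.integers(0, len(descriptions), size=len(prot_rows))
    ]

    # core-set hits
    n_core_hit = int(round(frac_ortholog * n))
    core_hit_idx = rng.choice(n, size=n_core_hit, replace=False)
    assigned_genes = rng.choice(core_set_size, size=n_core_hit, replace=True)
    core_rows = []
    for i, gidx in zip(core_hit_idx, assigned_genes):
        bit = float(rng.uniform(80, 500))
        core_rows.append(
            _blast_row(
                ids[i], core_genes[gidx], 1, int(rng.integers(150, 900)),
                1, int(rng.integers(50, 300)),
                float(rng.uniform(30, 90)), float(10.0 ** rng.uniform(-60, -6)), bit,
            )
        )
        if rng.random() < multi_hit_frac:  # secondary, weaker hit
            other = int((gidx + 1 + rng.integers(0, core_set_size - 1)) % core_set_size)
            core_rows.append(
                _blast_row(
                    ids[i], core_genes[other], 1, int(rng.integers(100, 600)),
                    1, int(rng.integers(50, 300)),
                    float(rng.uniform(25, 60)), float(10.0 ** rng.uniform(-20, -6)),
                    bit - float(rng.uniform(10, 40)),
                )
            )
    core_hits = pd.DataFrame(core_rows, columns=BLAST6_COLUMNS)

    # domain hits (1-3 per annotated transcript)
    n_dom = int(round(frac_domain * n))
    dom_idx = rng.choice(n, size=n_dom, replace=False)
    dom_rows = []
    for i in dom_idx:
        for _ in range(int(rng.integers(1, 4))):
            db = "pfam" if rng.random() < 0.7 else "prosite"
            dom_id = f"PF{rng.integers(1, 20000):05d}" if db == "pfam" else f"PS{rng.integers(1, 60000):05d}"
            dom_rows.append(
                {
                    "qseqid": ids[i],
                    "db": db,
                    "domain_id": dom_id,
                    "description": descriptions[int(rng.integers(0, len(descriptions)))]
                    + " domain",
                    "evalue": float(10.0 ** rng.uniform(-40, -3)),
                }
            )
    domain_hits = pd.DataFrame(
        dom_rows, columns=["qseqid", "db", "domain_id", "description", "evalue"]
    )
    return protein_hits, core_hits, domain_hits, core_genes
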