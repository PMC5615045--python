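"""Cross-species comparison against a core set of developmental genes.

Social amoebae (Dictyostelia) define a set of 1167 genes whose developmental
up-regulation is evolutionarily conserved.  Here, differentially expressed
transcripts of the distantly related myxomycete are mapped onto that set by
best sequence-similarity hit, and the result is summarised as a
direction x time-interval table: transcript counts, split by presence of a
protein-database annotation, the number of distinct core-set genes hit
(duplicate gene identifiers collapsed), and the ortholog percentage among
annotated transcripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_E_CUTOFF = 1e-5

INTERVALS = ["0-6h", "6-10h", "0-10h"]

SUMMARY_COLUMNS = [
    "regulation",
    "max_change_at",
    "all",
    "hits_without_uniprot",
    "hits_with_uniprot",
    "unique_ortholog_genes",
    "pct_ortholog_of_uniprot",
]


@dataclass
class CoreSetMapping:
    """Best core-set hit per transcript plus the reverse index."""

    best_gene: dict[str, str] = field(default_factory=dict)
    transcripts_of: dict[str, tuple[str, ...]] = field(default_factory=dict)
    n_rejected_rows: int = 0


def map_coreset(
    core_hits: pd.DataFrame, e_cutoff: float = DEFAULT_E_CUTOFF
) -> CoreSetMapping:
    """Assign each transcript its best core-set gene.

    Hits above the e-value cutoff are discarded; among the rest the best hit
    per transcript is chosen by highest bit score, ties broken by lower
    e-value and then lexicographic subject ID.  The reverse index lists, per
    core gene, every transcript whose best hit it is.
    """
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive")
    mapping = CoreSetMapping(n_rejected_rows=core_hits.attrs.get("n_rejected", 0))
    if core_hits.empty:
        return mapping
    kept = core_hits[core_hits["evalue"] <= e_cutoff]
    if kept.empty:
        return mapping
    ranked = kept.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = ranked.drop_duplicates(subset="qseqid", keep="first")
    mapping.best_gene = dict(zip(best["qseqid"], best["sseqid"]))
    reverse: dict[str, list[str]] = {}
    for tid, gene in mapping.best_gene.items():
        reverse.setdefault(gene, []).append(tid)
    mapping.transcripts_of = {g: tuple(sorted(ts)) for g, ts in reverse.items()}
    return mapping


def summarize(
    assignments: pd.DataFrame,
    has_uniprot: pd.Series,
    mapping: CoreSetMapping,
) -> pd.DataFrame:
    """Direction x interval summary of the DE set against the core set.

    ``assignments`` is the max-change table (index: transcript, columns
    including ``best_contrast`` and ``direction``); ``has_uniprot`` flags
    transcripts with a protein-database annotation.  Output rows are
    down/up x (0-6 h, 6-10 h, 0-10 h, total) plus a grand-total row.  Per
    row: ``all`` transcripts, split into with/without annotation;
    ``unique_ortholog_genes`` counts distinct core genes hit by the row's
    transcripts (duplicates collapsed); the percentage column is
    100 * unique_ortholog_genes / hits_with_uniprot to one decimal.

    The published form of this table reports ortholog percentages for
    up-regulated rows only; here they are computed for both directions (the
    down-direction values are an extension, flagged in ``attrs``).
    """
    required = {"best_contrast", "direction"}
    if not required <= set(assignments.columns):
        raise ValueError(f"assignments must carry columns {sorted(required)}")
    bad = assignments["best_contrast"].isna() | ~assignments["best_contrast"].isin(
        INTERVALS
    )
    if bad.any():
        raise ValueError(
            f"transcripts with direction but invalid contrast: "
            f"{list(assignments.index[bad])[:5]}"
        )
    flags = has_uniprot.reindex(assignments.index).fillna(False).astype(bool)

    def row_stats(sub: pd.DataFrame) -> dict:
        n_all = len(sub)
        with_up = int(flags.loc[sub.index].sum())
        genes = {
            mapping.best_gene[t] for t in sub.index if t in mapping.best_gene
        }
        n_genes = len(genes)
        pct = round(100.0 * n_genes / with_up, 1) if with_up else None
        return {
            "all": n_all,
            "hits_without_uniprot": n_all - with_up,
            "hits_with_uniprot": with_up,
            "unique_ortholog_genes": n_genes,
            "pct_ortholog_of_uniprot": pct,
        }

    rows = []
    for direction in ("down", "up"):
        sub_dir = assignments[assignments["direction"] == direction]
        for interval in INTERVALS:
            sub = sub_dir[sub_dir["best_contrast"] == interval]
            rows.append(
                {"regulation": direction, "max_change_at": interval, **row_stats(sub)}
            )
        rows.append(
            {"regulation": direction, "max_change_at": "total", **row_stats(sub_dir)}
        )
    rows.append(
        {"regulation": "up & down", "max_change_at": "total", **row_stats(assignments)}
    )
    out = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    out.attrs["extension_down_percentages"] = True
    return out


def coverage_stats(
    mapping: CoreSetMapping,
    core_gene_ids: Sequence[str],
    core_hits: Optional[pd.DataFrame] = None,
    e_cutoff: float = DEFAULT_E_CUTOFF,
) -> dict:
    """Core-set coverage: how much of the core set has any transcript hit.

    Percent covered is rounded to a whole percent.  ``n_hits`` counts
    retained hit rows when the raw hit table is supplied, else the number of
    best-hit assignments.
    """
    core = list(core_gene_ids)
    if not core:
        raise ValueError("core gene list must be non-empty")
    if core_hits is not None and not core_hits.empty:
        kept = core_hits[core_hits["evalue"] <= e_cutoff]
        genes_hit = set(kept["sseqid"]) & set(core)
        n_hits = len(kept)
        n_transcripts = kept["qseqid"].nunique()
    else:
        genes_hit = set(mapping.transcripts_of) & set(core)
        n_hits = len(mapping.best_gene)
        n_transcripts = len(mapping.best_gene)
    return {
        "n_core_genes_hit": len(genes_hit),
        "core_set_size": len(core),
        "pct_core_set_hit": round(100.0 * len(genes_hit) / len(core)),
        "n_hits": n_hits,
        "n_distinct_transcripts": n_transcripts,
    }
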