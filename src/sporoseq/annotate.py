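"""Master annotation table and keyword-based functional grouping.

The comprehensive table combines, for every transcript of the (revised)
reference, its protein-database similarity hit, its protein-domain hits and
its differential-expression classification.  A transcript with k >= 1
domain hits contributes k rows; a transcript without domain hits
contributes a single row.  On top of the table, configurable keyword rules
reproduce the functional grouping of differentially regulated transcripts
(transcription factors, kinases, RNA-binding proteins, ...) as an auditable
case-insensitive substring match over annotation descriptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

MASTER_COLUMNS = [
    "transcript_id",
    "revised_id",
    "uniprot_subject",
    "uniprot_description",
    "uniprot_evalue",
    "domain_db",
    "domain_id",
    "domain_description",
    "domain_evalue",
    "best_contrast",
    "log2fc",
    "direction",
    "pvalue",
]


@dataclass
class GroupingRule:
    """One functional group: matched by substrings, vetoed by exclusions."""

    label: str
    match_terms: tuple[str, ...]
    exclude_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.match_terms:
            raise ValueError(f"rule {self.label!r} has no match terms")

    def matches(self, description: str) -> bool:
        d = description.lower()
        if any(t.lower() in d for t in self.exclude_terms):
            return False
        return any(t.lower() in d for t in self.match_terms)


def default_rules() -> list[GroupingRule]:
    """Functional groups used for the standard panels."""
    return [
        GroupingRule("transcription factor", ("transcription factor", "zinc finger", "homeobox", "myb-like", "transcriptional regulator", "transcriptional corepressor")),
        GroupingRule("kinase", ("kinase",), ("phosphatase",)),
        GroupingRule("phosphatase", ("phosphatase",)),
        GroupingRule("RNA-binding", ("rna-binding", "pumilio", "elav", "argonaute", "piwi")),
        GroupingRule("cell cycle", ("cyclin", "cell cycle", "cell division", "mitotic", "checkpoint")),
        GroupingRule("DNA repair / meiotic recombination", ("dna repair", "recombination", "rad51", "dmc1", "meiotic")),
        GroupingRule("ubiquitin ligase", ("ubiquitin-protein ligase", "ubiquitin ligase", "e3 ubiquitin")),
    ]


def load_rules(path: str | Path) -> list[GroupingRule]:
    """Load grouping rules from a YAML file.

    Format: a list of mappings with keys ``label``, ``match`` (list of
    substrings) and optional ``exclude``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = [
        GroupingRule(
            label=item["label"],
            match_terms=tuple(item["match"]),
            exclude_terms=tuple(item.get("exclude", ())),
        )
        for item in raw
    ]
    labels = [r.label for r in rules]
    if len(set(labels)) != len(labels):
        raise ValueError("rule labels must be unique")
    return rules


def write_rules(rules: Sequence[GroupingRule], path: str | Path) -> None:
    raw = [
        {
            "label": r.label,
            "match": list(r.match_terms),
            **({"exclude": list(r.exclude_terms)} if r.exclude_terms else {}),
        }
        for r in rules
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def build_master_table(
    transcript_ids: Sequence[str],
    uniprot_hits: pd.DataFrame,
    domain_hits: pd.DataFrame,
    de_table: Optional[pd.DataFrame] = None,
    revision_map: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Assemble the comprehensive per-transcript annotation table.

    Left-join semantics anchored on ``transcript_ids``: every transcript
    appears, in max(1, number of domain hits) rows; similarity and DE fields
    repeat across a transcript's rows.  Row order is deterministic
    (transcript ID, then domain ID).  DE rows referencing transcripts
    outside the reference are an error.
    """
    ids = list(transcript_ids)
    id_set = set(ids)
    if de_table is not None and len(de_table):
        unknown = sorted(set(de_table.index) - id_set)
        if unknown:
            raise ValueError(f"DE table references unknown transcripts: {unknown[:5]}")

    base = pd.DataFrame({"transcript_id": sorted(ids)})

    if revision_map is not None and len(revision_map):
        rev = revision_map.rename(columns={"input_id": "transcript_id"})[
            ["transcript_id", "revised_id"]
        ]
        base = base.merge(rev, on="transcript_id", how="left")
        base["revised_id"] = base["revised_id"].fillna(base["transcript_id"])
    else:
        base["revised_id"] = base["transcript_id"]

    if len(uniprot_hits):
        up = uniprot_hits.rename(columns={"qseqid": "transcript_id"})
        cols = {"sseqid": "uniprot_subject", "evalue": "uniprot_evalue"}
        if "description" in up.columns:
            cols["description"] = "uniprot_description"
        # best row per transcript by bit score when several are present
        if "bitscore" in up.columns:
            up = up.sort_values(
                ["transcript_id", "bitscore"], ascending=[True, False], kind="mergesort"
            )
        up = up.drop_duplicates("transcript_id").rename(columns=cols)
        keep = ["transcript_id"] + [c for c in cols.values()]
        base = base.merge(up[keep], on="transcript_id", how="left")
    for col in ("uniprot_subject", "uniprot_description", "uniprot_evalue"):
        if col not in base.columns:
            base[col] = pd.NA

    if len(domain_hits):
        dom = domain_hits.rename(
            columns={
                "qseqid": "transcript_id",
                "db": "domain_db",
                "description": "domain_description",
                "evalue": "domain_evalue",
            }
        )[["transcript_id", "domain_db", "domain_id", "domain_description", "domain_evalue"]]
        dom = dom.sort_values(["transcript_id", "domain_id"], kind="mergesort")
        table = base.merge(dom, on="transcript_id", how="left")
    else:
        table = base.copy()
    for col in ("domain_db", "domain_id", "domain_description", "domain_evalue"):
        if col not in table.columns:
            table[col] = pd.NA

    if de_table is not None and len(de_table):
        de = de_table[["best_contrast", "log2fc", "direction", "pvalue"]].copy()
        de.index.name = "transcript_id"
        table = table.merge(de.reset_index(), on="transcript_id", how="left")
    for col in ("best_contrast", "log2fc", "direction", "pvalue"):
        if col not in table.columns:
            table[col] = pd.NA

    table = table.sort_values(
        ["transcript_id", "domain_id"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    return table[MASTER_COLUMNS]


def summary_stats(table: pd.DataFrame) -> dict:
    """Coverage report over the master table.

    Percentages count transcripts (not rows).  ``n_domain_no_uniprot`` is
    the number of transcripts carrying a domain hit but no similarity hit.
    """
    per_tx = table.groupby("transcript_id").agg(
        has_uniprot=("uniprot_subject", lambda s: s.notna().any()),
        has_domain=("domain_id", lambda s: s.notna().any()),
        is_de=("direction", lambda s: s.notna().any()),
    )
    n = len(per_tx)
    n_up = int(per_tx["has_uniprot"].sum())
    n_dom = int(per_tx["has_domain"].sum())
    n_dom_no_up = int((per_tx["has_domain"] & ~per_tx["has_uniprot"]).sum())
    n_de = int(per_tx["is_de"].sum())
    n_de_annot = int((per_tx["is_de"] & (per_tx["has_uniprot"] | per_tx["has_domain"])).sum())
    return {
        "n_transcripts": n,
        "n_rows": len(table),
        "n_with_uniprot": n_up,
        "pct_with_uniprot": round(100.0 * n_up / n, 1) if n else 0.0,
        "n_with_domain": n_dom,
        "n_domain_no_uniprot": n_dom_no_up,
        "n_de": n_de,
        "n_de_annotated": n_de_annot,
        "n_de_unannotated": n_de - n_de_annot,
    }


def apply_grouping(
    table: pd.DataFrame, rules: Sequence[GroupingRule]
) -> dict[str, pd.DataFrame]:
    """Group differentially regulated transcripts by annotation description.

    A transcript joins every group whose match terms hit its similarity or
    domain description (case-insensitive substring) with no exclusion term
    hitting; a transcript may belong to several groups.  Within each group
    the listing is one row per transcript, sorted by |log2FC| descending
    (ties by transcript ID), carrying direction, log2FC and p-value.
    """
    labels = [r.label for r in rules]
    if len(set(labels)) != len(labels):
        raise ValueError("rule labels must be unique")
    de_rows = table[table["direction"].notna()].copy()
    de_rows["uniprot_description"] = de_rows["uniprot_description"].fillna("")
    de_rows["domain_description"] = de_rows["domain_description"].fillna("")

    out: dict[str, pd.DataFrame] = {}
    for rule in rules:
        hit_mask = de_rows.apply(
            lambda r: rule.matches(r["uniprot_description"])
            or rule.matches(r["domain_description"]),
            axis=1,
        ) if len(de_rows) else pd.Series(dtype=bool)
        sub = de_rows[hit_mask] if len(de_rows) else de_rows
        per_tx = (
            sub.drop_duplicates("transcript_id")[
                [
                    "transcript_id",
                    "uniprot_subject",
                    "uniprot_description",
                    "best_contrast",
                    "log2fc",
                    "direction",
                    "pvalue",
                ]
            ].copy()
            if len(sub)
            else pd.DataFrame(
                columns=[
                    "transcript_id",
                    "uniprot_subject",
                    "uniprot_description",
                    "best_contrast",
                    "log2fc",
                    "direction",
                    "pvalue",
                ]
            )
        )
        if len(per_tx):
            per_tx["abs_lfc"] = per_tx["log2fc"].abs()
            per_tx = per_tx.sort_values(
                ["abs_lfc", "transcript_id"], ascending=[False, True], kind="mergesort"
            ).drop(columns="abs_lfc")
        out[rule.label] = per_tx.reset_index(drop=True)
    return out
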