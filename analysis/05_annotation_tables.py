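#!/usr/bin/env python
"""Assemble the master annotation table and functional groupings.

Combines similarity hits, domain hits and DE status into the comprehensive
per-transcript table (one row per domain hit, at least one per transcript),
reports annotation coverage, and lists differentially regulated transcripts
per functional group (transcription factors, kinases, RNA-binding, ...).
"""

from pathlib import Path

import pandas as pd

from sporoseq import annotate as ann
from sporoseq import io as io_mod

OUT = Path("results/analysis")


def main() -> None:
    revised_ids = list(io_mod.read_fasta(OUT / "reference_revised.fasta"))
    protein_hits = pd.read_csv(OUT / "protein_hits.tsv", sep="\t")
    domain_hits = pd.read_csv(OUT / "domain_hits.tsv", sep="\t")
    de_table = pd.read_csv(OUT / "de_table.tsv", sep="\t", index_col=0)
    revision_map = pd.read_csv(OUT / "revision_map.tsv", sep="\t")

    master = ann.build_master_table(
        revised_ids, protein_hits, domain_hits, de_table, revision_map
    )
    master.round(6).to_csv(OUT / "master_table.tsv", sep="\t", index=False)
    stats = ann.summary_stats(master)
    io_mod.write_json(stats, OUT / "annotation_coverage.json")

    rules = ann.default_rules()
    ann.write_rules(rules, OUT / "grouping_rules.yaml")
    groups = ann.apply_grouping(master, rules)
    gdir = OUT / "groups"
    gdir.mkdir(exist_ok=True)
    for label, frame in sorted(groups.items()):
        slug = label.replace(" ", "_").replace("/", "-")
        frame.round(6).to_csv(gdir / f"{slug}.tsv", sep="\t", index=False)

    print(
        f"master table: {stats['n_rows']} rows over {stats['n_transcripts']} "
        f"transcripts; {stats['pct_with_uniprot']}% with similarity annotation, "
        f"{stats['n_with_domain']} with >=1 domain "
        f"({stats['n_domain_no_uniprot']} of them without similarity hit)"
    )
    print(
        f"DE transcripts: {stats['n_de']} "
        f"({stats['n_de_annotated']} annotated, {stats['n_de_unannotated']} not)"
    )
    print("functional groups (DE transcripts per group):")
    for label, frame in sorted(groups.items()):
        print(f"  {label}: {len(frame)}")


if __name__ == "__main__":
    main()
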