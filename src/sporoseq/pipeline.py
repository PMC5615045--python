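"""End-to-end orchestration: simulate -> revise -> de -> compare -> annotate.

Each stage is a thin wrapper over the library modules that reads and writes
the plain-text interchange formats, so a whole synthetic study can be run
with one call and reproduced byte-for-byte from one seed.  The run manifest
records a SHA-256 hash of every produced file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import coreset as coreset_mod
from . import diffexpr as de_mod
from . import io as io_mod
from . import revision as rev_mod
from . import simulate as sim_mod

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full run; see ``load_config`` for the YAML layout."""

    outdir: Path
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    revision: dict = field(default_factory=dict)
    de: dict = field(default_factory=dict)
    coreset: dict = field(default_factory=dict)
    annotate: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # paths when not simulating

    @property
    def do_simulate(self) -> bool:
        return not self.inputs


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "outdir" not in raw:
        raise ValueError("config is missing required field 'outdir'")
    cfg = PipelineConfig(
        outdir=Path(raw["outdir"]),
        seed=int(raw.get("seed", 0)),
        simulate=raw.get("simulate", {}) or {},
        revision=raw.get("revision", {}) or {},
        de=raw.get("de", {}) or {},
        coreset=raw.get("coreset", {}) or {},
        annotate=raw.get("annotate", {}) or {},
        inputs=raw.get("inputs", {}) or {},
    )
    for key, p in cfg.inputs.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"config field inputs.{key}: no such file: {p}")
    return cfg


def _write_counts(counts: pd.DataFrame, path: Path) -> None:
    counts.to_csv(path, sep="\t")


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to disk).

    With no external inputs configured, a complete synthetic study is
    generated: a fragmented reference (revised by the consolidation rules),
    NB counts over the revised transcript set, and homology tables.  Any
    stage failure propagates; the manifest is written only on success.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []

    def save(path: Path) -> Path:
        produced.append(path)
        return path

    seed = config.seed

    # ---- stage 1: reference (simulated or loaded) --------------------------
    if config.do_simulate:
        ref_params = sim_mod.RevisionScenarioParams(
            **{"seed": seed, **config.simulate.get("reference", {})}
        )
        raw_records, ref_truth = sim_mod.generate_reference(ref_params)
        io_mod.write_fasta(raw_records, save(out / "reference_raw.fasta"))
        io_mod.write_loci(raw_records, save(out / "reference_loci.tsv"))
        io_mod.write_blast6(
            ref_truth.homology_join_hits, save(out / "join_evidence_hits.tsv")
        )
        truth_groups = pd.DataFrame(
            sorted(ref_truth.group_of.items()), columns=["transcript_id", "true_group"]
        )
        truth_groups.to_csv(save(out / "truth_groups.tsv"), sep="\t", index=False)
        join_hits = ref_truth.homology_join_hits
    else:
        raw_records = io_mod.read_transcripts(
            config.inputs["fasta"], config.inputs.get("loci")
        )
        join_hits = (
            io_mod.read_blast6(config.inputs["protein_hits"])
            if "protein_hits" in config.inputs
            else pd.DataFrame(columns=io_mod.BLAST6_COLUMNS)
        )

    # ---- stage 2: revision -------------------------------------------------
    revised, revision_map = rev_mod.revise_transcriptome(
        raw_records,
        protein_hits=join_hits,
        min_overlap=config.revision.get("min_overlap", rev_mod.DEFAULT_MIN_OVERLAP),
        min_shared_block=config.revision.get(
            "min_shared_block", rev_mod.DEFAULT_MIN_SHARED_BLOCK
        ),
    )
    io_mod.write_fasta(revised, save(out / "reference_revised.fasta"))
    revision_map.to_frame().to_csv(
        save(out / "revision_map.tsv"), sep="\t", index=False
    )
    io_mod.write_json(revision_map.summary(), save(out / "revision_summary.json"))
    revised_ids = [r.id for r in revised]

    # ---- stage 3: counts and homology (simulated or loaded) ----------------
    if config.do_simulate:
        count_params = sim_mod.CountScenarioParams(
            **{"seed": seed + 1, **config.simulate.get("counts", {})}
        )
        counts, samples, count_truth = sim_mod.generate_counts(
            revised_ids, count_params
        )
        _write_counts(counts, save(out / "counts.tsv"))
        samples.to_csv(save(out / "samples.tsv"), sep="\t", index=False)
        count_truth.table.to_csv(save(out / "truth_expression.tsv"), sep="\t")
        hom_kwargs = {"seed": seed + 2, **config.simulate.get("homology", {})}
        protein_hits, core_hits, domain_hits, core_genes = sim_mod.generate_homology(
            revised_ids, **hom_kwargs
        )
        protein_hits.to_csv(save(out / "protein_hits.tsv"), sep="\t", index=False)
        io_mod.write_blast6(core_hits, save(out / "core_hits.tsv"))
        domain_hits.to_csv(save(out / "domain_hits.tsv"), sep="\t", index=False)
        (out / "core_genes.txt").write_text("".join(g + "\n" for g in core_genes))
        save(out / "core_genes.txt")
    else:
        counts = io_mod.read_counts(config.inputs["counts"])
        samples = io_mod.read_sample_sheet(config.inputs["samples"])
        protein_hits = pd.read_csv(config.inputs["similarity_hits"], sep="\t")
        core_hits = io_mod.read_blast6(config.inputs["core_hits"])
        domain_hits = pd.read_csv(config.inputs["domain_hits"], sep="\t")
        core_genes = [
            line.strip()
            for line in Path(config.inputs["core_list"]).read_text().splitlines()
            if line.strip()
        ]

    # ---- stage 4: differential expression ----------------------------------
    de_params = de_mod.DEParams(**config.de)
    cm = de_mod.CountMatrix(counts=counts, samples=samples)
    results = de_mod.run_contrasts(cm, de_params)
    results.round(6).to_csv(save(out / "contrast_results.tsv"), sep="\t")
    de_table = de_mod.max_interval_assignment(results, de_params)
    de_table.round(6).to_csv(save(out / "de_table.tsv"), sep="\t")
    pca_coords, var_frac = de_mod.pca_samples(cm)
    pca_out = pca_coords.round(6)
    pca_out.to_csv(save(out / "pca_samples.tsv"), sep="\t")

    # ---- stage 5: core-set comparison --------------------------------------
    e_cutoff = config.coreset.get("e_cutoff", coreset_mod.DEFAULT_E_CUTOFF)
    mapping = coreset_mod.map_coreset(core_hits, e_cutoff)
    has_uniprot = pd.Series(
        {tid: tid in set(protein_hits["qseqid"]) for tid in counts.index}
    )
    summary = coreset_mod.summarize(de_table, has_uniprot, mapping)
    summary.to_csv(save(out / "coreset_summary.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(mapping.best_gene.items()), columns=["transcript_id", "core_gene"]
    ).to_csv(save(out / "coreset_mapping.tsv"), sep="\t", index=False)
    coverage = coreset_mod.coverage_stats(mapping, core_genes, core_hits, e_cutoff)
    io_mod.write_json(coverage, save(out / "coreset_coverage.json"))

    # ---- stage 6: master annotation table ----------------------------------
    rules_path = config.annotate.get("rules")
    rules = annotate_mod.load_rules(rules_path) if rules_path else annotate_mod.default_rules()
    master = annotate_mod.build_master_table(
        list(counts.index),
        protein_hits,
        domain_hits,
        de_table,
        revision_map.to_frame(),
    )
    master.round(6).to_csv(save(out / "master_table.tsv"), sep="\t", index=False)
    io_mod.write_json(
        annotate_mod.summary_stats(master), save(out / "annotation_coverage.json")
    )
    annotate_mod.write_rules(rules, save(out / "grouping_rules.yaml"))
    groups = annotate_mod.apply_grouping(master, rules)
    groups_dir = out / "groups"
    groups_dir.mkdir(exist_ok=True)
    for label, frame in sorted(groups.items()):
        slug = label.replace(" ", "_").replace("/", "-")
        frame.round(6).to_csv(save(groups_dir / f"{slug}.tsv"), sep="\t", index=False)

    # ---- manifest ----------------------------------------------------------
    manifest = {
        "seed": seed,
        "n_revised_transcripts": len(revised_ids),
        "n_de_transcripts": int(len(de_table)),
        "pc_variance_fractions": [round(float(v), 6) for v in var_frac],
        "files": {
            str(p.relative_to(out)): io_mod.sha256_file(p) for p in sorted(produced)
        },
    }
    io_mod.write_json(manifest, out / "manifest.json")
    return manifest
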