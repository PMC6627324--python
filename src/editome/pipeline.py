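"""End-to-end orchestration: predict -> stats -> matrix -> trees -> verify.

Every stage writes plain TSV / NEXUS / Newick so each can be re-run or
inspected independently, and a JSON manifest records the seed, versions and
per-stage record counts. Outputs are deterministic under a fixed seed and
fixed inputs.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .edit_matrix import build_binary_matrix, build_gene_template, concatenate_templates, write_nexus
from .edit_predict import EditingProfile, EditingSite, PredictionConfig, predict_editome
from .edit_stats import build_frequency_table, compare_groups_per_gene
from .phylo_binary import (
    bootstrap_trees,
    hamming_distances,
    majority_consensus,
    neighbor_joining,
    to_newick,
)
from .seqio import SpeciesGeneSet, read_gene_fasta
from .transcript_verify import align_transcript, classify_mismatches, verify_predictions

logger = logging.getLogger(__name__)

SITE_COLUMNS = [
    "species", "gene", "position", "direction", "codon_index", "codon_pos",
    "aa_from", "aa_to", "ambiguous",
]


def write_sites_tsv(profile: EditingProfile, path: str | Path) -> int:
    n = 0
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SITE_COLUMNS)
        for s in profile.all_sites():
            w.writerow(
                [s.species_id, s.gene, s.position, s.direction, s.codon_index,
                 s.codon_pos, s.aa_from, s.aa_to, int(s.ambiguous)]
            )
            n += 1
    return n


def read_sites_tsv(path: str | Path) -> EditingProfile:
    profile = EditingProfile()
    df = pd.read_csv(path, sep="\t")
    from_to = {"C2U": ("C", "T"), "U2C": ("T", "C")}
    for (sp, gene), rows in df.groupby(["species", "gene"], sort=True):
        sites = [
            EditingSite(
                species_id=str(sp), gene=str(gene), position=int(r.position),
                direction=str(r.direction), codon_index=int(r.codon_index),
                codon_pos=int(r.codon_pos),
                from_base=from_to[str(r.direction)][0],
                to_base=from_to[str(r.direction)][1],
                aa_from=str(r.aa_from), aa_to=str(r.aa_to),
                ambiguous=bool(r.ambiguous),
            )
            for r in rows.itertuples()
        ]
        profile.add(str(sp), str(gene), sites)
    return profile


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    groups = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "species":
                continue
            groups[row[0]] = row[1]
    return groups


@dataclass
class RunConfig:
    """Inputs and options of one full pipeline run."""

    query_dir: Path
    reference_path: Path
    out_dir: Path
    groups_path: Optional[Path] = None
    transcripts_dir: Optional[Path] = None
    directions: tuple[str, ...] = ("C2U", "U2C")
    gene_order: Optional[Sequence[str]] = None
    prediction: PredictionConfig = field(default_factory=PredictionConfig)
    tree_method: str = "mp"
    bootstrap_replicates: int = 1000
    consensus_cutoff: float = 0.5
    outgroup: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        for p, required in [
            (self.query_dir, True),
            (self.reference_path, True),
            (self.groups_path, False),
            (self.transcripts_dir, False),
        ]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
        if not 0 < self.consensus_cutoff < 1:
            raise ValueError("consensus cutoff must be in (0, 1)")


def _load_species_sets(
    query_dir: Path, groups: Mapping[str, str]
) -> list[SpeciesGeneSet]:
    sets = []
    for path in sorted(Path(query_dir).glob("*.fasta")):
        ss = read_gene_fasta(path, species_id=path.stem)
        ss.group = groups.get(path.stem)
        sets.append(ss)
    if not sets:
        raise FileNotFoundError(f"no *.fasta files in {query_dir}")
    return sets


def run_full(config: RunConfig) -> dict:
    """Run every stage and return the output manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "editome_version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    def stage(name: str):
        logger.info("stage %s starting", name)
        return time.perf_counter()

    # --- prediction -------------------------------------------------------
    t0 = stage("predict")
    groups = read_groups_tsv(config.groups_path) if config.groups_path else {}
    species_sets = _load_species_sets(config.query_dir, groups)
    reference = read_gene_fasta(config.reference_path, species_id=Path(config.reference_path).stem)
    pred_config = config.prediction
    if tuple(pred_config.directions) != tuple(config.directions):
        pred_config = PredictionConfig(
            **{**pred_config.__dict__, "directions": tuple(config.directions)}
        )
    profile = predict_editome(species_sets, reference, pred_config)
    n_sites = write_sites_tsv(profile, out / "sites.tsv")
    manifest["stages"]["predict"] = {
        "species": len(species_sets),
        "sites": n_sites,
    }
    logger.info("stage predict done in %.2fs", time.perf_counter() - t0)

    # --- frequencies and group statistics ---------------------------------
    t0 = stage("stats")
    lengths = {
        (ss.species_id, g): ss[g].length for ss in species_sets for g in ss.records
    }
    stats_counts = {}
    for direction in config.directions:
        table = build_frequency_table(profile, lengths, direction, groups)
        table.values.to_csv(out / f"frequency_{direction}.tsv", sep="\t", na_rep="NA")
        stats_counts[direction] = int(table.values.notna().sum().sum())
        if len(set(groups.values())) >= 2:
            rows = []
            for comp in compare_groups_per_gene(table):
                row = {"gene": comp.gene, "H": comp.h, "p": comp.p}
                for g, m in comp.group_means.items():
                    row[f"mean_{g}"] = m
                    row[f"se_{g}"] = comp.group_se[g]
                for r in comp.dunn.itertuples():
                    row[f"p_adj_{r.group_a}_vs_{r.group_b}"] = r.p_adj
                rows.append(row)
            pd.DataFrame(rows).to_csv(
                out / f"group_comparison_{direction}.tsv", sep="\t", index=False
            )
    manifest["stages"]["stats"] = {"cells": stats_counts}
    logger.info("stage stats done in %.2fs", time.perf_counter() - t0)

    # --- binary matrix ----------------------------------------------------
    t0 = stage("matrix")
    gene_order = list(config.gene_order) if config.gene_order else sorted(
        {g for ss in species_sets for g in ss.records}
    )
    templates = {g: build_gene_template(profile, g) for g in gene_order}
    global_template = concatenate_templates(templates, gene_order)
    matrix = build_binary_matrix(
        profile, global_template, exclude={reference.species_id}
    )
    (out / "matrix.nex").write_text(write_nexus(matrix))
    with open(out / "characters.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["index", "gene", "position"])
        for j, (gene, pos) in enumerate(matrix.characters, start=1):
            w.writerow([j, gene, pos])
    manifest["stages"]["matrix"] = {"taxa": len(matrix.taxa), "characters": matrix.width}
    logger.info("stage matrix done in %.2fs", time.perf_counter() - t0)

    # --- trees ------------------------------------------------------------
    t0 = stage("trees")
    if len(matrix.taxa) >= 4 and matrix.width >= 1:
        nj = neighbor_joining(hamming_distances(matrix))
        (out / "nj.nwk").write_text(to_newick(nj, outgroup=config.outgroup, with_lengths=True) + "\n")
        boots = bootstrap_trees(
            matrix,
            method=config.tree_method,
            replicates=config.bootstrap_replicates,
            seed=config.seed,
        )
        consensus = majority_consensus(boots, cutoff=config.consensus_cutoff)
        (out / f"{config.tree_method}_consensus.nwk").write_text(
            to_newick(consensus, outgroup=config.outgroup, with_supports=True) + "\n"
        )
        with open(out / "splits.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["split", "support_percent"])
            for split in sorted(consensus.supports, key=sorted):
                w.writerow(["|".join(sorted(split)), f"{consensus.supports[split]:g}"])
        manifest["stages"]["trees"] = {
            "method": config.tree_method,
            "bootstrap_replicates": config.bootstrap_replicates,
            "consensus_splits": len(consensus.supports),
        }
    else:
        logger.warning("fewer than 4 matrix taxa; tree stage skipped")
        manifest["stages"]["trees"] = {"skipped": True}
    logger.info("stage trees done in %.2fs", time.perf_counter() - t0)

    # --- transcript verification ------------------------------------------
    if config.transcripts_dir is not None:
        t0 = stage("verify")
        rows = []
        for ss in species_sets:
            tpath = Path(config.transcripts_dir) / f"{ss.species_id}.fasta"
            if not tpath.exists():
                continue
            transcripts = read_gene_fasta(tpath, species_id=ss.species_id)
            for gene in transcripts.genes():
                if gene not in ss:
                    continue
                cds = ss[gene].seq
                aln = align_transcript(cds, transcripts[gene].seq)
                mm = classify_mismatches(aln, cds, transcripts[gene].seq)
                sites = profile.sites_for(ss.species_id, gene)
                summary = verify_predictions(sites, mm, cds_length=len(cds))
                for direction in config.directions:
                    rows.append(
                        {
                            "species": ss.species_id,
                            "gene": gene,
                            "direction": direction,
                            "predicted": summary.predicted[direction],
                            "confirmed": summary.confirmed[direction],
                            "observed_not_predicted": summary.observed_not_predicted[direction],
                        }
                    )
        pd.DataFrame(rows).to_csv(out / "verification.tsv", sep="\t", index=False)
        manifest["stages"]["verify"] = {"records": len(rows)}
        logger.info("stage verify done in %.2fs", time.perf_counter() - t0)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
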