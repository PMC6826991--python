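"""End-to-end orchestration: simulate → fit → score → cluster → enrich/GTA →
integrate, with per-stage logging and a content-hash manifest for
reproducibility checks."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import enrichment, integration, io, remc, simulate
from .config import PipelineConfig
from .growth import fit_cpp_table
from .interaction import score_all

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_config(config: PipelineConfig) -> list[str]:
    """Structured pre-flight validation; returns an error list (empty = ok)."""
    return config.validate()


def run_all(config: PipelineConfig, outdir) -> dict:
    """Run every stage on a fully synthetic experiment; returns the manifest.

    Outputs (all TSV under ``outdir``): timeseries, ground_truth, cpps,
    interactions, clusters, enrichment, gta, associations, hits,
    conservation — plus ``manifest.json`` with a sha256 per artifact.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid pipeline config: " + "; ".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    sim = config.simulation

    logger.info("stage simulate: %d mutants, %d reference cultures",
                sim.n_mutant_strains, sim.n_reference_cultures)
    ts, truth = simulate.generate_plate_experiment(sim)
    paths["timeseries"] = io.write_tsv(ts, outdir / "timeseries.tsv")
    paths["ground_truth"] = io.write_tsv(truth, outdir / "ground_truth.tsv")

    logger.info("stage fit: %d cultures", ts.groupby(["plate", "row", "col"]).ngroups)
    cpps = fit_cpp_table(ts)
    logger.info("  no-growth cultures: %d", int(cpps["no_growth"].sum()))
    paths["cpps"] = io.write_tsv(cpps, outdir / "cpps.tsv")

    tables = []
    for drug in sim.doses_by_drug:
        tbl = score_all(
            cpps, drug, ref_strain=sim.ref_strain,
            kd_strains=sim.knockdown_strains, threshold=config.z_threshold,
        )
        n_classified = (
            tbl[tbl["cpp"] == "K"]["class"].isin(["enhancer", "suppressor"]).sum()
        )
        logger.info("stage score (%s): %d enhancer/suppressor calls", drug, n_classified)
        tables.append(tbl)
    interactions = pd.concat(tables, ignore_index=True)
    paths["interactions"] = io.write_tsv(interactions, outdir / "interactions.tsv")

    matrix = remc.build_profile_matrix(tables)
    tree = remc.remc(
        matrix,
        k_max=config.remc_k_max,
        n_init=config.remc_n_init,
        min_size=config.remc_min_size,
        max_depth=config.remc_max_depth,
        seed=config.seed,
    )
    clusters = tree.to_table()
    logger.info("stage remc: %d leaves", clusters["cluster_name"].nunique())
    paths["clusters"] = io.write_tsv(clusters, outdir / "clusters.tsv")

    genes = list(matrix.index)
    annotations = simulate.generate_go_annotations(
        len(genes), config.n_go_terms, config.go_term_size_range,
        seed=config.seed + 1, gene_names=genes,
    )
    paths["annotations"] = io.write_tsv(annotations, outdir / "annotations.tsv")
    enr_rows = []
    for name, members in clusters.groupby("cluster_name")["gene"].agg(list).items():
        enr_rows.extend(
            enrichment.hypergeom_enrichment(members, genes, annotations, cluster_name=name)
        )
    enr = enrichment.enrichment_table(enr_rows)
    paths["enrichment"] = io.write_tsv(enr, outdir / "enrichment.tsv")

    gta_rows = []
    for tbl in tables:
        drug = tbl["drug"].iloc[0]
        for cpp in ("K", "L"):
            scores = enrichment.scores_by_gene(tbl, drug, cpp)
            for res in enrichment.gta_all(annotations, scores, threshold=config.gta_threshold):
                gta_rows.append(vars(res) | {"drug": drug, "cpp": cpp})
    gta_df = pd.DataFrame(gta_rows)
    logger.info("stage gta: %d term×drug×cpp rows, %d passing filter",
                len(gta_df), int(gta_df["passes_filter"].sum()) if len(gta_df) else 0)
    paths["gta"] = io.write_tsv(gta_df, outdir / "gta.tsv")

    yeast = integration.yeast_class_table(tables)
    homologs = simulate.generate_homology_map(
        genes, config.n_human_genes, config.homology_class_mix, seed=config.seed + 2
    )
    paths["homologs"] = io.write_tsv(homologs, outdir / "homologs.tsv")

    # plant pharmacogenomic structure consistent with the yeast truth: human
    # homologs of enhancers are UES, of suppressors OES
    direction_by_yeast = {}
    for _, row in yeast[yeast["drug"] == list(sim.doses_by_drug)[0]].iterrows():
        if row["class"] == "enhancer":
            direction_by_yeast[row["yeast_gene"]] = "UES"
        elif row["class"] == "suppressor":
            direction_by_yeast[row["yeast_gene"]] = "OES"
    planted = {}
    for _, row in homologs.iterrows():
        d = direction_by_yeast.get(row["yeast_gene"])
        if d:
            planted[row["human_gene"]] = (d, config.pharmaco_effect_size)
    expr, sens, tissues = simulate.generate_pharmaco_dataset(
        config.n_cell_lines, list(homologs["human_gene"].unique()),
        config.tissues, planted, seed=config.seed + 3,
    )
    paths["expression"] = io.write_tsv(expr, outdir / "expression.tsv", index=True)
    paths["sensitivity"] = io.write_tsv(
        sens.rename_axis("cell_line").reset_index(), outdir / "sensitivity.tsv"
    )
    paths["tissues"] = io.write_tsv(
        tissues.rename_axis("cell_line").reset_index(), outdir / "tissues.tsv"
    )

    assoc_frames = []
    for stratum in ("all",) + tuple(config.tissues):
        try:
            assoc_frames.append(associate_with_drugs(
                expr, sens, tissues, stratum, list(sim.doses_by_drug)
            ))
        except ValueError as exc:  # stratum too small
            logger.info("stage integrate: skipping stratum %s (%s)", stratum, exc)
    associations = pd.concat(assoc_frames, ignore_index=True)
    paths["associations"] = io.write_tsv(associations, outdir / "associations.tsv")

    hits = integration.call_hits(
        yeast, homologs, associations, alpha=config.alpha, clusters=clusters
    )
    logger.info("stage integrate: %d UES/OES hits", len(hits))
    paths["hits"] = io.write_tsv(hits, outdir / "hits.tsv")
    conservation = integration.summarize_conservation(hits, yeast)
    paths["conservation"] = io.write_tsv(conservation, outdir / "conservation.tsv")

    manifest = {name: _sha256(p) for name, p in sorted(paths.items())}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def associate_with_drugs(expr, sens, tissues, stratum, drugs) -> pd.DataFrame:
    """Associations for one stratum, replicated per drug (the synthetic world
    carries one sensitivity vector; real data would have one per drug)."""
    assoc = integration.associate(expr, sens, tissues, stratum=stratum)
    frames = []
    for drug in drugs:
        f = assoc.copy()
        f.insert(1, "drug", drug)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
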