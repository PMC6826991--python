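#!/usr/bin/env python
"""Homology-based integration with cell-line pharmacogenomics.

Maps the yeast interaction classes onto human homologs, simulates a
cell-line expression/sensitivity dataset in which homologs of planted
enhancers are underexpression-sensitive (UES) and homologs of planted
suppressors overexpression-sensitive (OES), recomputes the per-gene
standardized association within tissue strata, and calls UES/OES hits at
alpha = 0.05."""

import argparse
from pathlib import Path

import pandas as pd

from phenomiq import io
from phenomiq.integration import call_hits, summarize_conservation, yeast_class_table
from phenomiq.pipeline import associate_with_drugs
from phenomiq.simulate import generate_homology_map, generate_pharmaco_dataset

DRUGS = ("gemcitabine", "cytarabine")
TISSUES = ("HaL", "lung", "breast")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    interactions = io.read_tsv(args.outdir / "interactions.tsv")
    yeast = yeast_class_table([interactions[interactions["drug"] == d] for d in DRUGS])
    genes = sorted(yeast["yeast_gene"].unique())

    homologs = generate_homology_map(genes, 500, (0.5, 0.3, 0.2), seed=args.seed + 1)
    io.write_tsv(homologs, args.outdir / "homologs.tsv")

    direction = {}
    gem = yeast[yeast["drug"] == "gemcitabine"].set_index("yeast_gene")["class"]
    for _, row in homologs.iterrows():
        cls = gem.get(row["yeast_gene"], "none")
        if cls == "enhancer":
            direction[row["human_gene"]] = ("UES", 1.0)
        elif cls == "suppressor":
            direction[row["human_gene"]] = ("OES", 1.0)
    expr, sens, tissues = generate_pharmaco_dataset(
        200, sorted(homologs["human_gene"].unique()), TISSUES, direction,
        seed=args.seed + 2,
    )

    assoc = pd.concat(
        [associate_with_drugs(expr, sens, tissues, s, list(DRUGS))
         for s in ("all",) + TISSUES],
        ignore_index=True,
    )
    io.write_tsv(assoc, args.outdir / "associations.tsv")

    clusters = io.read_tsv(args.outdir / "clusters.tsv")
    hits = call_hits(yeast, homologs, assoc, alpha=0.05, clusters=clusters)
    io.write_tsv(hits, args.outdir / "hits.tsv")
    conservation = summarize_conservation(hits, yeast)
    io.write_tsv(conservation, args.outdir / "conservation.tsv")

    print(f"{len(hits)} UES/OES hits across {hits['tissue'].nunique()} strata")
    print(hits["direction"].value_counts().to_string())
    hal = conservation[(conservation["tissue"] == "HaL")]
    for _, r in hal.iterrows():
        print(f"conserved buffering ({r['drug']}, HaL): "
              f"{r['n_with_ues_homolog']}/{r['n_enhancers']} enhancers with a "
              f"UES homolog ({r['fraction']:.0%})")


if __name__ == "__main__":
    main()
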