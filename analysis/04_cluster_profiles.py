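#!/usr/bin/env python
"""Recursive EM clustering of the interaction z-score profiles.

Builds the gene x (drug x CPP) z-score matrix (shift columns carried for
display only, 0.0001 sentinel for strains that grew in no condition without
drug), runs REMc and writes leaf memberships with lineage-encoded names."""

import argparse
from pathlib import Path

from phenomiq import io
from phenomiq.remc import build_profile_matrix, order_for_display, remc

DRUGS = ("gemcitabine", "cytarabine")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    interactions = io.read_tsv(args.outdir / "interactions.tsv")
    tables = [interactions[interactions["drug"] == d] for d in DRUGS]
    matrix = build_profile_matrix(tables)
    io.write_tsv(matrix.reset_index(), args.outdir / "profile_matrix.tsv")

    root = remc(matrix, seed=args.seed)
    clusters = root.to_table()
    io.write_tsv(clusters, args.outdir / "clusters.tsv")

    leaves = list(root.leaves())
    print(f"REMc: {len(leaves)} leaf clusters over {len(matrix)} genes")
    for leaf in sorted(leaves, key=lambda n: -len(n.members))[:5]:
        ordered = order_for_display(leaf, matrix)
        preview = ", ".join(ordered[:6]) + ("..." if len(ordered) > 6 else "")
        print(f"  {leaf.name}: {len(leaf.members)} genes [{preview}]")


if __name__ == "__main__":
    main()
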