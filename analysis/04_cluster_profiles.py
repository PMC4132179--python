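#!/usr/bin/env python
"""Two-way hierarchical clustering of the interaction profiles.

Reverse-weights the simulated score matrix, clusters alleles and genes
with uncentered Pearson similarity and average linkage, writes
TreeView-compatible CDT/GTR/ATR files, cuts the allele tree at nine
clusters, and scores the cut against the planted truth (adjusted Rand
index).  Outputs under results/clustering/.
"""

import argparse
import json
import warnings
from pathlib import Path

from sklearn.metrics import adjusted_rand_score

from chiscreen.cluster import cut_clusters, drop_empty_profiles, two_way_cluster
from chiscreen.matrix import read_matrix, reverse_weights
from chiscreen.treeview import write_cdt_gtr_atr


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--k-clusters", type=int, default=9)
    args = parser.parse_args()
    out = args.outdir / "clustering"
    out.mkdir(parents=True, exist_ok=True)

    matrix_path = args.outdir / "synthetic_screen" / "matrix.tsv"
    if not matrix_path.exists():
        raise SystemExit("no synthetic matrix found; run 01_simulate_screen.py first")
    matrix = read_matrix(matrix_path)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        weighted = drop_empty_profiles(reverse_weights(matrix))
        row_dend, col_dend = two_way_cluster(weighted)
    for w in caught:
        print(f"note: {w.message}")

    write_cdt_gtr_atr(
        weighted, row_dend, col_dend,
        out / "clustered.cdt", out / "clustered.gtr", out / "clustered.atr",
    )
    labels = cut_clusters(row_dend, args.k_clusters)
    with (out / "allele_clusters.tsv").open("w") as fh:
        fh.write("allele\tcluster\n")
        for allele in row_dend.leaf_order():
            fh.write(f"{allele}\t{labels[allele]}\n")

    print(f"clustered {len(weighted.allele_ids)} alleles x "
          f"{len(weighted.gene_ids)} genes; TreeView files in {out}")

    truth_path = args.outdir / "synthetic_screen" / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())["allele_cluster"]
        alleles = sorted(truth)
        ari = adjusted_rand_score(
            [truth[a] for a in alleles], [labels[a] for a in alleles]
        )
        print(f"k={args.k_clusters} cut vs planted clusters: "
              f"adjusted Rand index {ari:.3f}")


if __name__ == "__main__":
    main()
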