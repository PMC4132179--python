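#!/usr/bin/env python
"""Degree statistics of the screen network.

Reports the interaction-count statistics of the packaged 32-allele table
(mean degree, phenotype-class means) and of the simulated screen (degree
tables, gene-degree histogram), plus the digenic combination count for a
genome carrying 150 loss-of-function alleles.  Tables land in
results/screen_statistics/.
"""

import argparse
from pathlib import Path

from chiscreen.datasets import load_alanine_scan_table
from chiscreen.matrix import read_matrix
from chiscreen.stats import (
    allele_degrees,
    digenic_combinations,
    gene_degree_histogram,
    phenotype_class_summary,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    out = args.outdir / "screen_statistics"
    out.mkdir(parents=True, exist_ok=True)

    print(f"150 loss-of-function loci -> {digenic_combinations(150):,} "
          "possibly deleterious digenic combinations")

    annotations, degrees = load_alanine_scan_table()
    summary = phenotype_class_summary(degrees, annotations)
    summary.to_csv(out / "phenotype_class_summary.tsv", sep="\t")
    print(f"\nalanine-scan panel: {len(degrees)} alleles, "
          f"{degrees.sum()} interactions, mean degree {degrees.mean():.1f}")
    print("phenotype-class mean degrees (severity tracks connectivity):")
    for cls, row in summary.sort_values("mean_degree").iterrows():
        print(f"  {cls:<28} n={int(row.n_alleles):>2}  mean {row.mean_degree:.1f}")

    matrix_path = args.outdir / "synthetic_screen" / "matrix.tsv"
    if matrix_path.exists():
        matrix = read_matrix(matrix_path)
        adeg = allele_degrees(matrix)
        adeg.to_csv(out / "synthetic_allele_degrees.tsv", sep="\t",
                    index_label="allele")
        hist = gene_degree_histogram(matrix)
        with (out / "synthetic_gene_degree_histogram.tsv").open("w") as fh:
            fh.write("degree\tn_genes\n")
            for degree in sorted(hist):
                fh.write(f"{degree}\t{hist[degree]}\n")
        print(f"\nsynthetic screen: mean allele degree {adeg.mean():.1f}; "
              f"{hist.get(0, 0)} of {len(matrix.gene_ids)} genes never interact")
    else:
        print("\n(no synthetic matrix found; run 01_simulate_screen.py first)")


if __name__ == "__main__":
    main()
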