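"""Cluster-3.0 / Java TreeView compatible output (CDT + GTR + ATR).

The CDT holds the weighted matrix reordered to dendrogram leaf order, with
``GENEnX`` leaf ids on rows and ``ARRYnX`` on columns (numbered by the
original matrix order, as Cluster 3.0 does).  The GTR and ATR files list
one merge per line — node id, the two children joined, and the join
similarity (1 - merge distance) — in merge order, so the similarity column
is non-increasing down the file.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cluster import Dendrogram
from .matrix import FormatError, WeightedMatrix


def _node_names(ids: tuple[str, ...], prefix: str) -> dict[int, str]:
    return {i: f"{prefix}{i}X" for i in range(len(ids))}


def _tree_lines(dend: Dendrogram, leaf_prefix: str) -> list[str]:
    n = dend.n_leaves
    names = {i: f"{leaf_prefix}{i}X" for i in range(n)}
    lines = []
    for t, (a, b, sim) in enumerate(dend.merges):
        node = f"NODE{t + 1}X"
        names[n + t] = node
        lines.append(f"{node}\t{names[a]}\t{names[b]}\t{sim:.6f}")
    return lines


def write_cdt_gtr_atr(
    m: WeightedMatrix,
    row_dend: Dendrogram,
    col_dend: Dendrogram,
    cdt_path: str | Path,
    gtr_path: str | Path,
    atr_path: str | Path,
) -> None:
    """Write the clustered matrix and both merge trees.

    `m` must carry exactly the leaves of the two dendrograms (typically the
    matrix after all-zero profiles were dropped).
    """
    if set(m.allele_ids) != set(row_dend.ids):
        raise FormatError("row dendrogram leaves do not match matrix alleles")
    if set(m.gene_ids) != set(col_dend.ids):
        raise FormatError("column dendrogram leaves do not match matrix genes")

    row_order = row_dend.leaf_order()
    col_order = col_dend.leaf_order()
    w = m.weights.loc[list(row_order), list(col_order)]

    row_index = {allele: i for i, allele in enumerate(m.allele_ids)}
    col_index = {gene: j for j, gene in enumerate(m.gene_ids)}

    with Path(cdt_path).open("w") as fh:
        fh.write("GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(col_order) + "\n")
        fh.write(
            "AID\t\t\t\t"
            + "\t".join(f"ARRY{col_index[g]}X" for g in col_order)
            + "\n"
        )
        fh.write("EWEIGHT\t\t\t\t" + "\t".join("1.000000" for _ in col_order) + "\n")
        for allele in row_order:
            values = "\t".join(str(int(v)) for v in w.loc[allele])
            fh.write(f"GENE{row_index[allele]}X\t{allele}\t{allele}\t1.000000\t{values}\n")

    Path(gtr_path).write_text("\n".join(_tree_lines(row_dend, "GENE")) + "\n")
    Path(atr_path).write_text("\n".join(_tree_lines(col_dend, "ARRY")) + "\n")


def read_cdt(path: str | Path) -> WeightedMatrix:
    """Read back the reordered weighted matrix from a CDT file."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df[~df["GID"].isin(["AID", "EWEIGHT"])]
    genes = [c for c in df.columns if c not in ("GID", "UNIQID", "NAME", "GWEIGHT")]
    out = df.set_index("UNIQID")[genes].astype(int)
    out.index.name = None
    return WeightedMatrix(weights=out)
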