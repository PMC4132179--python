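"""Write a synthetic dataset in the same formats the pipeline reads."""

from __future__ import annotations

import json
from pathlib import Path

from .matrix import write_annotations, write_matrix
from .pipeline import write_topology
from .structure import write_calpha_pdb
from .synthetic import (
    SyntheticConfig,
    generate_filament,
    generate_replicates,
    plant_alleles_and_matrix,
)
from .validation import write_replicate_edges


def write_synthetic_dataset(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write matrix, annotations, PDB, topology, replicates and
    the ground-truth file; returns the paths keyed by role."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    model, topo = generate_filament(cfg)
    matrix, annotations, truth = plant_alleles_and_matrix(cfg, model)
    reps = generate_replicates(truth, cfg)

    paths = {
        "matrix": out / "matrix.tsv",
        "annotations": out / "annotations.tsv",
        "pdb_filament": out / "filament.pdb",
        "topology": out / "topology.yaml",
        "truth": out / "truth.json",
    }
    write_matrix(matrix, paths["matrix"])
    write_annotations(annotations, paths["annotations"])
    write_calpha_pdb(model, paths["pdb_filament"])
    write_topology(topo, paths["topology"])

    rep_dir = out / "replicates"
    rep_dir.mkdir(exist_ok=True)
    rep_paths = []
    for i, rep in enumerate(reps.replicates, start=1):
        p = rep_dir / f"replicate_{i}.tsv"
        write_replicate_edges(rep, p)
        rep_paths.append(p)
    paths["replicates"] = rep_paths

    truth_doc = {
        "allele_cluster": dict(sorted(truth.allele_cluster.items())),
        "cluster_genes": {
            str(c): sorted(g) for c, g in sorted(truth.cluster_genes.items())
        },
        "allele_positions": {
            a: list(p) for a, p in sorted(truth.allele_positions.items())
        },
        "n_true_interactions": len(truth.true_interactions),
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=2, sort_keys=True) + "\n")
    return paths
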