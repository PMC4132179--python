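"""End-to-end pipeline: from screen files to tables, trees and tests.

Every stage is a library call; this module only sequences them, logs the
parameters, and writes deterministic text outputs so that identical
configuration and seed give byte-identical results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import cluster as clu
from . import correlate as corr
from . import stats, structure, treeview, validation
from .matrix import (
    InteractionMatrix,
    read_annotations,
    read_matrix,
    reverse_weights,
)

log = logging.getLogger("chiscreen")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    matrix: Path
    annotations: Path
    pdb_filament: Path
    topology: Path
    outdir: Path
    seed: int
    pdb_monomer: Path | None = None
    replicates: tuple[Path, ...] = ()
    monomer_chain: str | None = None
    k_clusters: int = 9
    n_perm: int = 10_000
    min_support: int = 2
    confidence: float = 0.95

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        base = Path(path).parent

        def _p(key):
            return (base / raw[key]) if key in raw and raw[key] is not None else None

        return cls(
            matrix=_p("matrix"),
            annotations=_p("annotations"),
            pdb_filament=_p("pdb_filament"),
            topology=_p("topology"),
            pdb_monomer=_p("pdb_monomer"),
            replicates=tuple(base / r for r in raw.get("replicates", ())),
            outdir=Path(raw["outdir"]),
            seed=int(raw["seed"]),
            monomer_chain=raw.get("monomer_chain"),
            k_clusters=int(raw.get("k_clusters", 9)),
            n_perm=int(raw.get("n_perm", 10_000)),
            min_support=int(raw.get("min_support", 2)),
            confidence=float(raw.get("confidence", 0.95)),
        )


def read_topology(path: str | Path) -> structure.FilamentTopology:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return structure.FilamentTopology(
        stacked_pairs=tuple(tuple(p) for p in raw.get("stacked", ())),
        backed_pairs=tuple(tuple(p) for p in raw.get("backed", ())),
    )


def write_topology(topo: structure.FilamentTopology, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "stacked": [list(p) for p in topo.stacked_pairs],
                "backed": [list(p) for p in topo.backed_pairs],
            },
            sort_keys=True,
        )
    )


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc

        return inner

    return wrap


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every analysis stage and return the machine-readable summary."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run config: %s", cfg)
    summary: dict = {"seed": cfg.seed, "k_clusters": cfg.k_clusters, "n_perm": cfg.n_perm}

    matrix, annotations, topo, model, mono_model = _load(cfg)
    summary["n_alleles"] = len(matrix.allele_ids)
    summary["n_genes"] = len(matrix.gene_ids)

    summary["degrees"] = _degrees(cfg, out, matrix, annotations)
    if cfg.replicates:
        summary["validation"] = _validate(cfg, out)
    weighted, assignment = _cluster(cfg, out, matrix)
    summary["clusters"] = {
        "k": cfg.k_clusters,
        "sizes": sorted(
            len(v) for v in clu.cluster_sets(assignment).values()
        ),
    }
    table = _distances(cfg, out, annotations, weighted, model, topo, mono_model)
    summary["correlation"] = _correlate(cfg, out, table)
    summary["regions"] = _regions(cfg, out, matrix, annotations)
    _attributes(cfg, out, matrix, annotations)

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary


@_stage("load")
def _load(cfg: RunConfig):
    matrix = read_matrix(cfg.matrix)
    annotations = read_annotations(cfg.annotations)
    topo = read_topology(cfg.topology)
    model = structure.read_pdb_calpha(cfg.pdb_filament)
    topo.validate_against(model)
    if not topo.stacked_pairs or not topo.backed_pairs:
        raise structure.StructureError(
            "topology must declare both stacked and backed subunit pairs"
        )
    mono_model = (
        structure.read_pdb_calpha(cfg.pdb_monomer) if cfg.pdb_monomer else None
    )
    return matrix, annotations, topo, model, mono_model


@_stage("degrees")
def _degrees(cfg, out, matrix, annotations):
    adeg = stats.allele_degrees(matrix)
    adeg.to_csv(out / "allele_degrees.tsv", sep="\t", index_label="allele")
    hist = stats.gene_degree_histogram(matrix)
    with (out / "gene_degree_histogram.tsv").open("w") as fh:
        fh.write("degree\tn_genes\n")
        for degree in sorted(hist):
            fh.write(f"{degree}\t{hist[degree]}\n")
    pheno = stats.phenotype_class_summary(adeg, annotations)
    pheno.to_csv(out / "phenotype_summary.tsv", sep="\t", index_label="phenotype_class")
    return {
        "mean_allele_degree": round(float(adeg.mean()), 4),
        "n_interactions": int(adeg.sum()),
        "n_interacting_genes": int((stats.gene_degrees(matrix) > 0).sum()),
    }


@_stage("validation")
def _validate(cfg, out):
    reps = [validation.read_replicate_edges(p) for p in cfg.replicates]
    if len(reps) < 3:
        raise ValueError("need >= 3 replicate files (>=2 for the standard + 1 held out)")
    held_out, rest = reps[-1], reps[:-1]
    standard = validation.build_standard(
        validation.ScreenReplicateSet(tuple(rest), min_support=cfg.min_support)
    )
    report = validation.precision_recall(held_out, standard)
    validation.write_replicate_edges(standard, out / "standard.tsv")
    with (out / "validation.txt").open("w") as fh:
        for key in ("n_called", "n_standard", "n_overlap"):
            fh.write(f"{key}\t{getattr(report, key)}\n")
        fh.write(f"precision\t{report.precision:.4f}\n")
        fh.write(f"recall\t{report.recall:.4f}\n")
    return {
        "precision": round(report.precision, 4),
        "recall": round(report.recall, 4),
        "n_standard": report.n_standard,
    }


@_stage("cluster")
def _cluster(cfg, out, matrix: InteractionMatrix):
    weighted = clu.drop_empty_profiles(reverse_weights(matrix))
    row_dend, col_dend = clu.two_way_cluster(weighted)
    treeview.write_cdt_gtr_atr(
        weighted,
        row_dend,
        col_dend,
        out / "clustered.cdt",
        out / "clustered.gtr",
        out / "clustered.atr",
    )
    assignment = clu.cut_clusters(row_dend, min(cfg.k_clusters, row_dend.n_leaves))
    with (out / "allele_clusters.tsv").open("w") as fh:
        fh.write("allele\tcluster\n")
        for allele in row_dend.leaf_order():
            fh.write(f"{allele}\t{assignment[allele]}\n")
    return weighted, assignment


@_stage("distances")
def _distances(cfg, out, annotations, weighted, model, topo, mono_model):
    result = structure.distance_table(
        annotations,
        weighted,
        model,
        topo,
        monomer_model=mono_model,
        monomer_subunit=cfg.monomer_chain,
    )
    result.table.to_csv(
        out / "pairwise_distances.tsv", sep="\t", index=False, float_format="%.4f"
    )
    if result.excluded:
        log.info("alleles excluded from distance analysis: %s", result.excluded)
    return result.table


@_stage("correlate")
def _correlate(cfg, out, table):
    rows = {}
    with (out / "correlation.tsv").open("w") as fh:
        fh.write("configuration\tn_pairs\tr\tp_analytic\tp_permutation\n")
        for config in structure.CONFIGURATIONS:
            res = corr.similarity_distance_correlation(
                table, config, n_perm=cfg.n_perm, seed=cfg.seed
            )
            fh.write(
                f"{config}\t{res.n_pairs}\t{res.r:.4f}\t"
                f"{res.p_analytic:.4g}\t{res.p_permutation:.4g}\n"
            )
            rows[config] = {
                "r": round(res.r, 4),
                "p_permutation": round(res.p_permutation, 6),
            }
    return rows


@_stage("regions")
def _regions(cfg, out, matrix, annotations):
    groups = corr.region_groups(annotations)
    degrees = stats.allele_degrees(matrix)
    a = [int(degrees[x]) for x in groups.front_top_bottom if x in degrees]
    b = [int(degrees[x]) for x in groups.back_side if x in degrees]
    res = corr.rank_sum_test(a, b) if a and b else None
    with (out / "regions.txt").open("w") as fh:
        fh.write(f"front_top_bottom\t{','.join(groups.front_top_bottom)}\n")
        fh.write(f"back_side\t{','.join(groups.back_side)}\n")
        fh.write(f"excluded\t{','.join(groups.excluded)}\n")
        if res is None:
            fh.write("rank_sum_test\tskipped: one group empty\n")
        else:
            fh.write(f"median_front_top_bottom\t{res.median_a}\n")
            fh.write(f"median_back_side\t{res.median_b}\n")
            fh.write(f"rank_sum_statistic\t{res.statistic}\n")
            fh.write(f"p_two_sided\t{res.p:.4g}\n")
            fh.write(f"method\t{res.method}\n")
    if res is None:
        return {"n_front_top_bottom": len(a), "n_back_side": len(b), "p": None}
    return {
        "median_front_top_bottom": res.median_a,
        "median_back_side": res.median_b,
        "p": round(res.p, 6),
    }


@_stage("attributes")
def _attributes(cfg, out, matrix, annotations):
    degrees = stats.allele_degrees(matrix).to_dict()
    structure.export_residue_attributes(
        degrees, annotations, out / "residue_attributes.txt"
    )
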