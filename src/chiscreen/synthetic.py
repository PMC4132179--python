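"""Synthetic screen data with planted clusters and a parametric filament.

The generator emulates the structure of a complex-heterozygosity screen so
every pipeline stage is testable without the original data:

* an idealised two-start helical filament — subunit k sits at angle
  k*twist and height k*rise on a helix, with an identical (seeded) residue
  layout on a sphere around each subunit centre; intrastrand "stacked"
  neighbours are (k, k+2), interstrand "backed" neighbours (k, k+1);
* planted allele clusters: each cluster owns a dedicated gene set and a
  pair of surface patches — an anchor patch and its *stacked image*, the
  patch on the long-pitch neighbour subunit that comes closest to the
  anchor across the stacked interface.  Cluster members alternate between
  the two patches, so same-cluster alleles are near each other across
  stacked subunits (and often far apart on a single monomer), the
  geometric motif the distance analysis is designed to detect;
* allele x gene scores drawn with cluster-specific hit probability
  `p_signal`, off-cluster `p_background`, and severities sampled from
  `severity_weights`;
* replicate screens that detect each true pair independently with
  `detection_prob` and add false positives at `p_background`.

Every generator is a pure function of (config, seed): identical inputs give
bitwise-identical outputs.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import (
    AlleleAnnotation,
    InteractionMatrix,
    PHENOTYPE_CLASSES,
    Substitution,
)
from .structure import FilamentTopology, StructureModel
from .validation import ScreenReplicateSet

_CHARGED = "DEKR"
# phenotype class frequencies roughly matching a charged-cluster scan panel
_PHENOTYPE_PROBS = (8 / 32, 7 / 32, 7 / 32, 1 / 32, 3 / 32, 5 / 32, 1 / 32, 0.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic screen.

    Defaults mirror the real screen's shape (32 alleles x 238 genes, nine
    clusters) and actin-filament geometry (rise 27.5 A and twist -166.7
    degrees per subunit along the genetic helix, ~25 A subunit radius).
    """

    n_alleles: int = 32
    n_genes: int = 238
    k_clusters: int = 9
    genes_per_cluster: int = 20
    p_signal: float = 0.8
    p_background: float = 0.02
    severity_weights: tuple[float, float, float] = (0.2, 0.3, 0.5)
    n_subunits: int = 5
    rise_per_subunit: float = 27.5
    twist_per_subunit: float = -166.7
    helix_radius: float = 15.0
    residues_per_subunit: int = 375
    subunit_radius: float = 25.0
    patch_radius: float = 12.0
    detection_prob: float = 0.7
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_signal", "p_background", "detection_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if abs(sum(self.severity_weights) - 1.0) > 1e-9 or min(self.severity_weights) < 0:
            raise ValueError("severity_weights must be a probability vector over 1,2,3")
        if self.k_clusters > self.n_alleles:
            raise ValueError("more clusters than alleles")
        if self.k_clusters * self.genes_per_cluster > self.n_genes:
            raise ValueError("cluster gene sets exceed the gene panel")
        if self.rise_per_subunit <= 0:
            raise ValueError("rise must be positive")
        if self.n_subunits < 3:
            raise ValueError("need at least 3 subunits for a filament")
        if self.n_subunits > 26:
            raise ValueError("at most 26 subunits (single-letter chain ids)")
        if self.residues_per_subunit < 10:
            raise ValueError("need at least 10 residues per subunit")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a generated dataset."""

    allele_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    allele_cluster: Mapping[str, int]
    cluster_genes: Mapping[int, frozenset[str]]
    allele_positions: Mapping[str, tuple[int, ...]]
    true_interactions: frozenset[tuple[str, str]]


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


def _rot_z(degrees: float) -> np.ndarray:
    t = math.radians(degrees)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def subunit_center(cfg: SyntheticConfig, k: int) -> np.ndarray:
    t = math.radians(cfg.twist_per_subunit) * k
    return np.array(
        [
            cfg.helix_radius * math.cos(t),
            cfg.helix_radius * math.sin(t),
            cfg.rise_per_subunit * k,
        ]
    )


def generate_filament(cfg: SyntheticConfig) -> tuple[StructureModel, FilamentTopology]:
    """Build the helical model and its stacked/backed topology."""
    rng = _rng(cfg, 1)
    dirs = rng.normal(size=(cfg.residues_per_subunit, 3))
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    local = dirs * cfg.subunit_radius

    chains = string.ascii_uppercase[: cfg.n_subunits]
    subunits: dict[str, dict[int, np.ndarray]] = {}
    for k, chain in enumerate(chains):
        rot = _rot_z(cfg.twist_per_subunit * k)
        coords = subunit_center(cfg, k) + local @ rot.T
        subunits[chain] = {i + 1: coords[i] for i in range(cfg.residues_per_subunit)}

    stacked = tuple((chains[k], chains[k + 2]) for k in range(cfg.n_subunits - 2))
    backed = tuple((chains[k], chains[k + 1]) for k in range(cfg.n_subunits - 1))
    return StructureModel(subunits=subunits), FilamentTopology(
        stacked_pairs=stacked, backed_pairs=backed
    )


def _local_layout(cfg: SyntheticConfig, model: StructureModel) -> np.ndarray:
    """Recover the shared local residue layout from the first subunit."""
    chain = model.subunit_ids[0]
    coords = np.array([model.subunits[chain][i + 1] for i in range(len(model.subunits[chain]))])
    return coords - subunit_center(cfg, 0)


def _stacked_partner(
    model: StructureModel, anchor_idx: int
) -> tuple[int, float]:
    """Residue index whose patch, on a stacked neighbour, is nearest the anchor.

    Both directions across the first stacked pair are examined (the anchor
    may face its upper or its lower long-pitch neighbour).
    """
    a, c = model.subunit_ids[0], model.subunit_ids[2]
    coords_a = np.array([model.subunits[a][i] for i in sorted(model.subunits[a])])
    coords_c = np.array([model.subunits[c][i] for i in sorted(model.subunits[c])])
    d_up = np.linalg.norm(coords_c - coords_a[anchor_idx], axis=1)
    d_dn = np.linalg.norm(coords_a - coords_c[anchor_idx], axis=1)
    if d_up.min() <= d_dn.min():
        return int(np.argmin(d_up)), float(d_up.min())
    return int(np.argmin(d_dn)), float(d_dn.min())


def _patch_backed_distance(
    model: StructureModel,
    topo: FilamentTopology,
    patch_p: np.ndarray,
    patch_q: np.ndarray,
) -> float:
    """Minimum C-alpha distance between the two patches across any declared
    interstrand (backed) subunit pair, in either orientation."""
    best = math.inf
    coords = {
        c: np.array([model.subunits[c][i] for i in sorted(model.subunits[c])])
        for c in model.subunit_ids
    }
    for u, v in topo.backed_pairs:
        for first, second in ((patch_p, patch_q), (patch_q, patch_p)):
            a = coords[u][first]
            b = coords[v][second]
            d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1).min()
            best = min(best, float(d))
    return best


def _cluster_sizes(n: int, k: int) -> list[int]:
    base, extra = divmod(n, k)
    return [base + (1 if c < extra else 0) for c in range(k)]


def _location_class(centroid: np.ndarray, radius: float) -> str:
    # z extremes face the long-pitch neighbours; +x is the outward radial
    # direction of the subunit in its local frame
    if abs(centroid[2]) > 0.6 * radius:
        return "top/bottom"
    if centroid[0] > 0.4 * radius:
        return "front"
    if centroid[0] < -0.4 * radius:
        return "back"
    return "side"


def plant_alleles_and_matrix(
    cfg: SyntheticConfig, model: StructureModel, max_retries: int = 500
) -> tuple[InteractionMatrix, list[AlleleAnnotation], SyntheticTruth]:
    """Plant clustered alleles on the filament and draw their score matrix.

    A cluster's patch pair must span a *stacked-specific* contact: the
    anchor faces a long-pitch neighbour (contact within `patch_radius`)
    while the patch pair stays clear of every interstrand interface
    (backed patch-to-patch distance > 20 A), so the planted spatial signal
    lives in the stacked configuration only.
    """
    rng = _rng(cfg, 2)
    local = _local_layout(cfg, model)
    nres = local.shape[0]

    allele_ids = tuple(f"mut{i + 1:03d}" for i in range(cfg.n_alleles))
    gene_ids = tuple(f"gene{j + 1:03d}" for j in range(cfg.n_genes))

    cluster_genes = {
        c: frozenset(gene_ids[c * cfg.genes_per_cluster : (c + 1) * cfg.genes_per_cluster])
        for c in range(cfg.k_clusters)
    }

    # anchor + stacked-image patch per cluster
    chains = model.subunit_ids
    backed_topo = FilamentTopology(
        backed_pairs=tuple((chains[k], chains[k + 1]) for k in range(len(chains) - 1))
    )
    allele_cluster: dict[str, int] = {}
    allele_positions: dict[str, tuple[int, ...]] = {}
    annotations: list[AlleleAnnotation] = []
    i = 0
    used: set[int] = set()  # alanine-scan alleles never share residues
    for c, size in enumerate(_cluster_sizes(cfg.n_alleles, cfg.k_clusters)):
        n_on_p = (size + 1) // 2
        n_on_q = size // 2
        for _attempt in range(max_retries):
            anchor = int(rng.integers(nres))
            partner, contact_dist = _stacked_partner(model, anchor)
            if contact_dist > 1.25 * cfg.patch_radius:
                continue  # anchor does not face a stacked interface
            patch_p = np.nonzero(
                np.linalg.norm(local - local[anchor], axis=1) <= cfg.patch_radius
            )[0]
            patch_q = np.nonzero(
                np.linalg.norm(local - local[partner], axis=1) <= cfg.patch_radius
            )[0]
            overlap = set(patch_p.tolist()) & set(patch_q.tolist())
            if len(patch_p) < 2 or len(patch_q) < 2 or overlap:
                continue
            # at least one fresh residue per allele this cluster will place
            fresh_p = [r for r in patch_p if r not in used]
            fresh_q = [r for r in patch_q if r not in used]
            if len(fresh_p) < n_on_p or len(fresh_q) < n_on_q:
                continue
            if _patch_backed_distance(model, backed_topo, patch_p, patch_q) <= 20.0:
                continue  # patch pair doubles as an interstrand contact
            break
        else:
            raise RuntimeError(
                f"could not place a cluster patch within {max_retries} retries"
            )
        left_p, left_q = n_on_p, n_on_q
        for t in range(size):
            allele = allele_ids[i]
            on_p = t % 2 == 0
            patch = patch_p if on_p else patch_q
            anchor_point = local[anchor if on_p else partner]
            # prefer the core of the patch so the planted contact stays sharp
            inner = patch[
                np.linalg.norm(local[patch] - anchor_point, axis=1)
                <= 0.7 * cfg.patch_radius
            ]
            pool = np.array([r for r in inner if r not in used])
            if len(pool) < 2:
                pool = np.array([r for r in patch if r not in used])
            if on_p:
                left_p -= 1
                reserve = left_p
            else:
                left_q -= 1
                reserve = left_q
            # leave a fresh residue for each later allele on this patch
            n_subs = max(1, min(int(rng.integers(2, 4)), len(pool) - reserve))
            picked = rng.choice(pool, size=n_subs, replace=False)
            used.update(int(p) for p in picked)
            positions = tuple(sorted(int(p) + 1 for p in picked))
            allele_cluster[allele] = c + 1
            allele_positions[allele] = positions
            substitutions = tuple(
                Substitution(str(rng.choice(list(_CHARGED))), pos, "A")
                for pos in positions
            )
            centroid = local[[p - 1 for p in positions]].mean(axis=0)
            annotations.append(
                AlleleAnnotation(
                    allele_id=allele,
                    substitutions=substitutions,
                    phenotype_class=str(rng.choice(PHENOTYPE_CLASSES, p=_PHENOTYPE_PROBS)),
                    location_class=_location_class(centroid, cfg.subunit_radius),
                )
            )
            i += 1

    # score matrix: cluster genes hit with p_signal, the rest with p_background
    probs = np.full((cfg.n_alleles, cfg.n_genes), cfg.p_background)
    gene_index = {g: j for j, g in enumerate(gene_ids)}
    for i, allele in enumerate(allele_ids):
        cols = [gene_index[g] for g in cluster_genes[allele_cluster[allele] - 1]]
        probs[i, cols] = cfg.p_signal
    hits = rng.random(probs.shape) < probs
    severities = rng.choice([1, 2, 3], size=probs.shape, p=cfg.severity_weights)
    scores = np.where(hits, severities, 0)

    matrix = InteractionMatrix(
        scores=pd.DataFrame(scores, index=list(allele_ids), columns=list(gene_ids))
    )
    truth = SyntheticTruth(
        allele_ids=allele_ids,
        gene_ids=gene_ids,
        allele_cluster=allele_cluster,
        cluster_genes={c + 1: genes for c, genes in cluster_genes.items()},
        allele_positions=allele_positions,
        true_interactions=frozenset(
            (allele_ids[i], gene_ids[j]) for i, j in zip(*np.nonzero(scores))
        ),
    )
    return matrix, annotations, truth


def generate_replicates(truth: SyntheticTruth, cfg: SyntheticConfig) -> ScreenReplicateSet:
    """Replicate screens: true pairs detected with `detection_prob`, false
    positives drawn from the non-interacting pairs at `p_background`."""
    rng = _rng(cfg, 3)
    true_pairs = sorted(truth.true_interactions)
    non_pairs = sorted(
        (a, g)
        for a in truth.allele_ids
        for g in truth.gene_ids
        if (a, g) not in truth.true_interactions
    )
    replicates = []
    for _ in range(cfg.n_replicates):
        detected = rng.random(len(true_pairs)) < cfg.detection_prob
        fps = rng.random(len(non_pairs)) < cfg.p_background
        called = {p for p, keep in zip(true_pairs, detected) if keep}
        called.update(p for p, keep in zip(non_pairs, fps) if keep)
        replicates.append(frozenset(called))
    return ScreenReplicateSet(replicates=tuple(replicates), min_support=2)
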