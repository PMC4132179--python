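"""Protein-structure geometry for allele pairs.

An allele marks a handful of mutated surface residues; for every pair of
alleles we measure the shortest straight-line distance between the alpha
carbons of their nearest mutated residues, in three configurations:

* ``monomer`` — both residue sets on a single subunit;
* ``stacked`` — the two sets on intrastrand (long-pitch helix) neighbour
  subunits of a filament model, minimised over both orientations and all
  declared stacked pairs;
* ``backed`` — likewise for interstrand neighbours.

Which subunit pairs of a filament model count as stacked vs backed is
explicit configuration (:class:`FilamentTopology`), never inferred from
coordinates.  Residue numbering in allele annotations is used unchanged as
the PDB residue sequence number.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .cluster import uncentered_pearson
from .matrix import AlleleAnnotation, WeightedMatrix

CONFIGURATIONS = ("monomer", "stacked", "backed")


class StructureError(ValueError):
    """A structure file or topology declaration is unusable."""


class UnresolvedAlleleError(StructureError):
    """None of an allele's mutated residues are resolved in the model."""


@dataclass(frozen=True, eq=False)
class StructureModel:
    """Per-subunit residue -> C-alpha coordinate map (Angstroms)."""

    subunits: Mapping[str, Mapping[int, np.ndarray]]

    def __post_init__(self) -> None:
        for chain, residues in self.subunits.items():
            for resnum, xyz in residues.items():
                if not np.all(np.isfinite(xyz)):
                    raise StructureError(
                        f"non-finite coordinate at {chain}:{resnum}"
                    )

    @property
    def subunit_ids(self) -> tuple[str, ...]:
        return tuple(self.subunits)

    def coords(self, subunit: str, positions: Sequence[int]) -> np.ndarray:
        """Coordinates of the given residue numbers present in `subunit`."""
        residues = self.subunits[subunit]
        found = [residues[p] for p in positions if p in residues]
        return np.array(found, dtype=float).reshape(-1, 3)


@dataclass(frozen=True)
class FilamentTopology:
    """Declared intrastrand (stacked) and interstrand (backed) subunit pairs."""

    stacked_pairs: tuple[tuple[str, str], ...] = ()
    backed_pairs: tuple[tuple[str, str], ...] = ()

    def pairs(self, kind: str) -> tuple[tuple[str, str], ...]:
        if kind == "stacked":
            return self.stacked_pairs
        if kind == "backed":
            return self.backed_pairs
        raise ValueError(f"unknown pair kind {kind!r}")

    def validate_against(self, model: StructureModel) -> None:
        known = set(model.subunit_ids)
        for u, v in self.stacked_pairs + self.backed_pairs:
            if u not in known or v not in known:
                raise StructureError(f"topology references unknown subunit ({u}, {v})")


def read_pdb_calpha(
    path: str | Path, chains: set[str] | None = None
) -> StructureModel:
    """Parse C-alpha coordinates from a PDB file.

    Only ATOM records with atom name CA are retained (first altloc wins);
    hetero residues are skipped and insertion codes rejected.  `chains`
    optionally restricts which chain ids are kept.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        pdb = parser.get_structure("model", str(path))
    except PDBConstructionException as exc:
        raise StructureError(f"{path}: {exc}") from exc
    try:
        model = next(pdb.get_models())
    except StopIteration:
        raise StructureError(f"{path}: no models in file") from None

    subunits: dict[str, dict[int, np.ndarray]] = {}
    for chain in model:
        if chains is not None and chain.id not in chains:
            continue
        residues: dict[int, np.ndarray] = {}
        for residue in chain:
            hetflag, resseq, icode = residue.id
            if hetflag != " ":
                continue
            if icode != " ":
                raise StructureError(
                    f"{path}: insertion code at {chain.id}:{resseq}{icode} not supported"
                )
            if "CA" not in residue:
                continue
            atom = residue["CA"]
            if atom.is_disordered():
                atom = atom.disordered_get_list()[0]  # first altloc wins
            if resseq in residues:
                raise StructureError(
                    f"{path}: duplicate CA for residue {chain.id}:{resseq}"
                )
            residues[resseq] = np.asarray(atom.coord, dtype=float)
        if residues:
            subunits[chain.id] = residues
    if not subunits:
        raise StructureError(f"{path}: no CA atoms found")
    return StructureModel(subunits=subunits)


def write_calpha_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a C-alpha-only model as PDB (one ALA CA per residue)."""
    from Bio.PDB import PDBIO, StructureBuilder

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("model")
    builder.init_model(0)
    serial = 1
    for chain_id, residues in model.subunits.items():
        builder.init_chain(chain_id)
        builder.init_seg("    ")
        for resnum in sorted(residues):
            builder.init_residue("ALA", " ", resnum, " ")
            builder.init_atom(
                "CA",
                np.asarray(residues[resnum], dtype=float),
                0.0,
                1.0,
                " ",
                " CA ",
                serial,
                element="C",
            )
            serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def map_allele_residues(
    ann: AlleleAnnotation, model: StructureModel, subunit: str
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Coordinates of an allele's mutated residues on one subunit.

    Returns (coordinates, unresolved positions).  Raises
    :class:`UnresolvedAlleleError` when *no* position is resolved — such an
    allele cannot enter the distance analysis at all.
    """
    residues = model.subunits[subunit]
    resolved = [p for p in ann.positions if p in residues]
    unresolved = tuple(p for p in ann.positions if p not in residues)
    if not resolved:
        raise UnresolvedAlleleError(
            f"allele {ann.allele_id}: no mutated residue resolved on subunit {subunit}"
        )
    if unresolved:
        warnings.warn(
            f"allele {ann.allele_id}: positions {unresolved} unresolved on {subunit}"
        )
    return model.coords(subunit, resolved), unresolved


def min_ca_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum Euclidean distance over all cross pairs of two point sets."""
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty coordinate set")
    return float(cdist(a, b).min())


def pair_distance(
    a1: AlleleAnnotation,
    a2: AlleleAnnotation,
    config: str,
    model: StructureModel,
    topo: FilamentTopology | None = None,
    monomer_subunit: str | None = None,
) -> float:
    """Shortest C-alpha distance between two alleles' residue sets.

    monomer: both sets on one subunit (`monomer_subunit`, default the first
    subunit of the model).  stacked/backed: for every declared subunit pair
    (u, v) of that kind, the minimum is taken over both assignments (a1 on
    u with a2 on v, and the swap); the overall minimum is returned.
    """
    if config not in CONFIGURATIONS:
        raise ValueError(f"unknown configuration {config!r}")
    if config == "monomer":
        subunit = monomer_subunit or model.subunit_ids[0]
        c1, _ = map_allele_residues(a1, model, subunit)
        c2, _ = map_allele_residues(a2, model, subunit)
        return min_ca_distance(c1, c2)

    if topo is None:
        raise StructureError(f"{config} distance requested without a topology")
    pairs = topo.pairs(config)
    if not pairs:
        raise StructureError(f"no declared {config} subunit pairs")
    best = math.inf
    for u, v in pairs:
        for first, second in ((a1, a2), (a2, a1)):
            try:
                cu, _ = map_allele_residues(first, model, u)
                cv, _ = map_allele_residues(second, model, v)
            except UnresolvedAlleleError:
                continue
            best = min(best, min_ca_distance(cu, cv))
    if not math.isfinite(best):
        raise UnresolvedAlleleError(
            f"pair ({a1.allele_id}, {a2.allele_id}): unresolved on all {config} pairs"
        )
    return best


@dataclass(frozen=True)
class DistanceTableResult:
    table: pd.DataFrame
    excluded: tuple[str, ...]


def distance_table(
    annotations: Sequence[AlleleAnnotation],
    m: WeightedMatrix,
    model: StructureModel,
    topo: FilamentTopology,
    monomer_model: StructureModel | None = None,
    monomer_subunit: str | None = None,
) -> DistanceTableResult:
    """Profile similarity plus monomer/stacked/backed distances per allele pair.

    Alleles are excluded (and listed) when no mutated residue is resolved,
    when they are absent from the weighted matrix, or when their weight
    profile is all-zero (undefined similarity).  Needs >= 3 usable alleles.
    Monomer distances may come from a separate single-subunit model.
    """
    mono_model = monomer_model if monomer_model is not None else model
    mono_subunit = monomer_subunit or mono_model.subunit_ids[0]

    usable: list[AlleleAnnotation] = []
    excluded: list[str] = []
    w = m.weights
    for ann in annotations:
        if ann.allele_id not in w.index:
            excluded.append(ann.allele_id)
            continue
        if not (w.loc[ann.allele_id] > 0).any():
            excluded.append(ann.allele_id)
            continue
        try:
            map_allele_residues(ann, mono_model, mono_subunit)
        except UnresolvedAlleleError:
            excluded.append(ann.allele_id)
            continue
        usable.append(ann)
    if len(usable) < 3:
        raise StructureError(f"need >= 3 usable alleles, got {len(usable)}")

    rows = []
    for i, a1 in enumerate(usable):
        p1 = w.loc[a1.allele_id].to_numpy(dtype=float)
        for a2 in usable[i + 1 :]:
            p2 = w.loc[a2.allele_id].to_numpy(dtype=float)
            row = {
                "allele_a": a1.allele_id,
                "allele_b": a2.allele_id,
                "similarity": uncentered_pearson(p1, p2),
            }
            for config in CONFIGURATIONS:
                try:
                    if config == "monomer":
                        d = pair_distance(
                            a1, a2, "monomer", mono_model,
                            monomer_subunit=mono_subunit,
                        )
                    else:
                        d = pair_distance(a1, a2, config, model, topo)
                except (UnresolvedAlleleError, StructureError):
                    d = math.nan
                row[f"d_{config}"] = d
            rows.append(row)
    return DistanceTableResult(table=pd.DataFrame(rows), excluded=tuple(excluded))


def export_residue_attributes(
    degrees: Mapping[str, int],
    annotations: Sequence[AlleleAnnotation],
    path: str | Path,
    attribute: str = "chi_interactions",
) -> None:
    """Write a molecular-viewer attribute file mapping residues to degrees.

    Each mutated residue of each annotated allele gets one line carrying
    that allele's interaction count, suitable for heat-map colouring of the
    protein surface.  A residue claimed by two alleles is an error.
    """
    claimed: dict[int, str] = {}
    lines = [f"attribute: {attribute}"]
    for ann in annotations:
        if ann.allele_id not in degrees:
            continue
        degree = degrees[ann.allele_id]
        for pos in ann.positions:
            if pos in claimed and claimed[pos] != ann.allele_id:
                raise ValueError(
                    f"residue {pos} claimed by both {claimed[pos]} and {ann.allele_id}"
                )
            claimed[pos] = ann.allele_id
            lines.append(f"\t:{pos}\t{degree}")
    Path(path).write_text("\n".join(lines) + "\n")
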