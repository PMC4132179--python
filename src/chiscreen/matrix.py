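"""Interaction-matrix data model and I/O.

A complex-heterozygosity screen records, for every (query allele, deletion
gene) pair, a growth-defect score on a 1-3 scale: 1 = lethal, 2 = severe
growth defect, 3 = colony size perceptibly smaller than the control; 0 (or a
blank cell) means no interaction.  Clustering operates on the *reversed*
scale ("weights"), where 3 marks the strongest interaction and 1 the
weakest, so that weak hits sit next to non-interactions.

Alleles carry annotations: the cluster of point substitutions they encode
(e.g. ``D363A,E364A``), a phenotype class, and the surface region of the
protein the mutated residues occupy.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_SCORES = frozenset({0, 1, 2, 3})
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Closed phenotype vocabulary (normalised, ASCII hyphens).
PHENOTYPE_CLASSES = (
    "wild type",
    "Ts-",
    "Cs- Ts-",
    "weak Ts-",
    "lethal recessive",
    "lethal partial dominant",
    "Ts- weakly dominant",
    "other",
)

#: Closed surface-location vocabulary.
LOCATION_CLASSES = ("front", "back", "side", "top/bottom", "ATP cleft", "ND")


class FormatError(ValueError):
    """A file does not conform to the expected tab-delimited layout."""


class MutationSpecError(ValueError):
    """A mutation string such as ``D363A,E364A`` could not be parsed."""


# ---------------------------------------------------------------------------
# allele annotations
# ---------------------------------------------------------------------------

_SUBSTITUTION_RE = re.compile(r"([A-Za-z])(\d+)([A-Za-z])")


@dataclass(frozen=True, order=True)
class Substitution:
    """A single point substitution in mature-protein residue numbering."""

    wild_type: str
    position: int
    mutant: str

    def __post_init__(self) -> None:
        if self.wild_type not in AMINO_ACIDS:
            raise MutationSpecError(f"unknown wild-type residue {self.wild_type!r}")
        if self.mutant not in AMINO_ACIDS:
            raise MutationSpecError(f"unknown mutant residue {self.mutant!r}")
        if self.position < 1:
            raise MutationSpecError(f"residue position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.wild_type}{self.position}{self.mutant}"


def parse_mutation_spec(text: str) -> list[Substitution]:
    """Parse a comma-separated substitution string, e.g. ``"D363A,E364A"``.

    Whitespace around tokens is tolerated; token order is preserved.
    Raises :class:`MutationSpecError` naming the offending token.
    """
    if not text or not text.strip():
        raise MutationSpecError("empty mutation specification")
    out: list[Substitution] = []
    for token in text.split(","):
        token = token.strip()
        m = _SUBSTITUTION_RE.fullmatch(token)
        if m is None:
            raise MutationSpecError(f"malformed substitution token {token!r}")
        out.append(Substitution(m.group(1).upper(), int(m.group(2)), m.group(3).upper()))
    return out


def format_mutation_spec(substitutions: Iterable[Substitution]) -> str:
    return ",".join(str(s) for s in substitutions)


def _canon(text: str) -> str:
    # unify unicode minus / dashes, case, comma and whitespace runs
    text = text.replace("−", "-").replace("–", "-").replace("—", "-")
    text = text.lower().replace(",", " ")
    return " ".join(text.split())


_PHENOTYPE_MAP = {
    "wild type": "wild type",
    "ts-": "Ts-",
    "ts- recessive": "Ts-",
    "cs- ts-": "Cs- Ts-",
    "cs- ts- recessive": "Cs- Ts-",
    "weak ts-": "weak Ts-",
    "weak ts- recessive": "weak Ts-",
    "lethal recessive": "lethal recessive",
    "lethal partial dominant": "lethal partial dominant",
    "ts- weakly dominant": "Ts- weakly dominant",
    "ts- weak dominant": "Ts- weakly dominant",
}

_LOCATION_MAP = {
    "front": "front",
    "back": "back",
    "side": "side",
    "top/bottom": "top/bottom",
    "top bottom": "top/bottom",
    "atp cleft": "ATP cleft",
    "nd": "ND",
}


def normalize_phenotype(text: str) -> str:
    """Map a printed phenotype string onto the closed vocabulary.

    Normalisation is case-insensitive and tolerant of commas and unicode
    minus signs; strings that match no known class collapse to ``"other"``.
    """
    return _PHENOTYPE_MAP.get(_canon(text), "other")


def normalize_location(text: str) -> str:
    key = _canon(text)
    if key not in _LOCATION_MAP:
        raise FormatError(f"unknown surface location label {text!r}")
    return _LOCATION_MAP[key]


@dataclass(frozen=True)
class AlleleAnnotation:
    """Per-allele annotation: substitutions, phenotype and surface region."""

    allele_id: str
    substitutions: tuple[Substitution, ...]
    phenotype_class: str
    location_class: str

    def __post_init__(self) -> None:
        if not self.substitutions:
            raise ValueError(f"allele {self.allele_id}: no substitutions")
        if self.phenotype_class not in PHENOTYPE_CLASSES:
            raise ValueError(
                f"allele {self.allele_id}: phenotype class {self.phenotype_class!r} "
                f"not in {PHENOTYPE_CLASSES}"
            )
        if self.location_class not in LOCATION_CLASSES:
            raise ValueError(
                f"allele {self.allele_id}: location class {self.location_class!r} "
                f"not in {LOCATION_CLASSES}"
            )

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.position for s in self.substitutions)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def _validate_axes(df: pd.DataFrame, what: str) -> None:
    if not df.index.is_unique:
        dupes = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"{what}: duplicate allele ids {dupes}")
    if not df.columns.is_unique:
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise FormatError(f"{what}: duplicate gene ids {dupes}")


@dataclass(frozen=True, eq=False)
class InteractionMatrix:
    """Allele x gene score matrix; 0 = no interaction, 1-3 = severity."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_axes(self.scores, "interaction matrix")
        values = self.scores.to_numpy()
        if values.size and not np.isin(values, list(VALID_SCORES)).all():
            bad = sorted(set(values.ravel()) - VALID_SCORES)
            raise FormatError(f"scores outside {{0,1,2,3}}: {bad}")
        object.__setattr__(self, "scores", self.scores.astype(int))

    @property
    def allele_ids(self) -> tuple[str, ...]:
        return tuple(self.scores.index)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.scores.columns)

    def equals(self, other: "InteractionMatrix") -> bool:
        return self.scores.equals(other.scores)


@dataclass(frozen=True, eq=False)
class WeightedMatrix:
    """Reverse-weighted matrix: 3 = strongest interaction, 0 = none."""

    weights: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_axes(self.weights, "weighted matrix")
        values = self.weights.to_numpy()
        if values.size and not np.isin(values, list(VALID_SCORES)).all():
            bad = sorted(set(values.ravel()) - VALID_SCORES)
            raise FormatError(f"weights outside {{0,1,2,3}}: {bad}")
        object.__setattr__(self, "weights", self.weights.astype(int))

    @property
    def allele_ids(self) -> tuple[str, ...]:
        return tuple(self.weights.index)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.weights.columns)

    def to_scores(self) -> InteractionMatrix:
        """Invert the weight reversal (4 - w on nonzero cells)."""
        w = self.weights
        return InteractionMatrix(scores=(4 - w).where(w > 0, 0))

    def equals(self, other: "WeightedMatrix") -> bool:
        return self.weights.equals(other.weights)


def reverse_weights(m: InteractionMatrix) -> WeightedMatrix:
    """Reverse score weights for clustering: {0->0, 1->3, 2->2, 3->1}.

    Score 1 (lethality) is the *strongest* interaction and must carry the
    largest weight; non-interactions stay at zero so weak hits sit next to
    them in similarity space.
    """
    s = m.scores
    return WeightedMatrix(weights=(4 - s).where(s > 0, 0))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path) -> InteractionMatrix:
    """Read a tab-delimited score matrix.

    Layout: first row = gene ids (first cell is a corner label), first
    column = allele ids.  Cells may be blank (treated as 0) or an integer
    score in {0,1,2,3}.  Structural problems raise :class:`FormatError`
    naming the offending line.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        genes = [g.strip() for g in header[1:]]
        if len(set(genes)) != len(genes):
            raise FormatError(f"{path}: duplicate gene id on line 1")
        alleles: list[str] = []
        rows: list[list[int]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # trailing blank line
            if len(row) != len(genes) + 1:
                raise FormatError(
                    f"{path}: line {lineno}: expected {len(genes) + 1} fields, got {len(row)}"
                )
            allele = row[0].strip()
            if allele in alleles:
                raise FormatError(f"{path}: line {lineno}: duplicate allele id {allele!r}")
            alleles.append(allele)
            values: list[int] = []
            for cell in row[1:]:
                cell = cell.strip()
                if cell == "":
                    values.append(0)
                    continue
                try:
                    value = int(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}: line {lineno}: non-integer cell {cell!r}"
                    ) from None
                if value not in VALID_SCORES:
                    raise FormatError(f"{path}: line {lineno}: score {value} outside 0-3")
                values.append(value)
            rows.append(values)
    df = pd.DataFrame(rows, index=alleles, columns=genes, dtype=int)
    return InteractionMatrix(scores=df)


def write_matrix(m: InteractionMatrix, path: str | Path) -> None:
    m.scores.to_csv(path, sep="\t", index_label="allele")


def to_edge_list(m: InteractionMatrix) -> list[tuple[str, str, int]]:
    """All (allele, gene, score) triples with score > 0, row-major order."""
    values = m.scores.to_numpy()
    rows, cols = np.nonzero(values)
    alleles, genes = m.allele_ids, m.gene_ids
    return [(alleles[i], genes[j], int(values[i, j])) for i, j in zip(rows, cols)]


def matrix_from_edges(
    edges: Iterable[tuple[str, str, int]],
    allele_ids: Sequence[str],
    gene_ids: Sequence[str],
) -> InteractionMatrix:
    """Rebuild a matrix from an edge list over declared axes."""
    df = pd.DataFrame(0, index=list(allele_ids), columns=list(gene_ids), dtype=int)
    for allele, gene, score in edges:
        df.loc[allele, gene] = score
    return InteractionMatrix(scores=df)


def read_annotations(path: str | Path) -> list[AlleleAnnotation]:
    """Read a tab-delimited annotation table.

    Expected columns: allele, mutation, phenotype, location (a trailing
    ``interactions`` column, if present, is ignored here; see
    :func:`chiscreen.datasets.load_alanine_scan_table`).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"allele", "mutation", "phenotype", "location"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            AlleleAnnotation(
                allele_id=row["allele"],
                substitutions=tuple(parse_mutation_spec(row["mutation"])),
                phenotype_class=normalize_phenotype(row["phenotype"]),
                location_class=normalize_location(row["location"]),
            )
        )
    return out


def write_annotations(annotations: Sequence[AlleleAnnotation], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("allele\tmutation\tphenotype\tlocation\n")
        for ann in annotations:
            fh.write(
                f"{ann.allele_id}\t{format_mutation_spec(ann.substitutions)}\t"
                f"{ann.phenotype_class}\t{ann.location_class}\n"
            )
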