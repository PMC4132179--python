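"""Packaged reference tables.

The alanine-scan allele table ships with the package: 32 actin alleles with
their substitution clusters, phenotype class, surface location, and the
number of complex-heterozygous interactions each allele showed against the
238-gene deletion panel.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .matrix import (
    AlleleAnnotation,
    normalize_location,
    normalize_phenotype,
    parse_mutation_spec,
)


def _table_path():
    return resources.files("chiscreen").joinpath("data/alanine_scan_alleles.tsv")


def load_alanine_scan_table() -> tuple[list[AlleleAnnotation], pd.Series]:
    """Return (annotations, per-allele interaction counts) for the 32 alleles."""
    with resources.as_file(_table_path()) as path:
        df = pd.read_csv(path, sep="\t", dtype={"interactions": int})
    annotations = [
        AlleleAnnotation(
            allele_id=row.allele,
            substitutions=tuple(parse_mutation_spec(row.mutation)),
            phenotype_class=normalize_phenotype(row.phenotype),
            location_class=normalize_location(row.location),
        )
        for row in df.itertuples()
    ]
    degrees = pd.Series(
        df["interactions"].to_numpy(), index=df["allele"], name="degree"
    )
    return annotations, degrees
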