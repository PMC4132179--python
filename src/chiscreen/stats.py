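"""Degree statistics and feature correlations for the screen network.

Degree counts ignore severity: any nonzero score counts as one interaction,
matching how the allele table reports interaction numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import AlleleAnnotation, InteractionMatrix


def allele_degrees(m: InteractionMatrix) -> pd.Series:
    """Number of interacting genes (score > 0) per allele."""
    return (m.scores > 0).sum(axis=1).rename("degree")


def gene_degrees(m: InteractionMatrix) -> pd.Series:
    """Number of interacting alleles (score > 0) per gene."""
    return (m.scores > 0).sum(axis=0).rename("degree")


def gene_degree_histogram(m: InteractionMatrix) -> dict[int, int]:
    """Histogram degree -> number of genes; the 0 bin counts non-interactors."""
    counts = gene_degrees(m).value_counts().sort_index()
    return {int(k): int(v) for k, v in counts.items()}


def phenotype_class_summary(
    degrees: Mapping[str, int] | pd.Series,
    annotations: Sequence[AlleleAnnotation],
) -> pd.DataFrame:
    """Mean interaction degree and membership per phenotype class.

    Every allele in `degrees` must be annotated; unannotated alleles raise
    a ``KeyError`` listing them.
    """
    degrees = pd.Series(degrees)
    by_allele = {a.allele_id: a.phenotype_class for a in annotations}
    missing = [a for a in degrees.index if a not in by_allele]
    if missing:
        raise KeyError(f"unannotated alleles: {missing}")
    classes = degrees.index.map(by_allele)
    df = pd.DataFrame({"degree": degrees.to_numpy(), "phenotype_class": classes})
    grouped = df.groupby("phenotype_class")["degree"].agg(["count", "mean"])
    grouped.columns = ["n_alleles", "mean_degree"]
    return grouped.sort_index()


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    ci_low: float
    ci_high: float
    n: int


def pearson_with_ci(
    x: Sequence[float], y: Sequence[float], confidence: float = 0.95
) -> CorrelationResult:
    """Pearson r with a two-sided t-based p and a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 4:
        raise ValueError(f"need at least 4 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = sps.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=confidence)
    return CorrelationResult(
        r=float(res.statistic),
        p=float(res.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n=int(x.size),
    )


def digenic_combinations(n_loci: int) -> int:
    """Number of unordered digenic combinations among n loci: n(n-1)/2."""
    if n_loci < 2:
        raise ValueError(f"need at least 2 loci, got {n_loci}")
    return math.comb(n_loci, 2)
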