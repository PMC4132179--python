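"""Profile-similarity vs structural-distance correlation and region tests.

The working hypothesis is directional: the closer two alleles' mutated
residues lie in a given configuration, the more similar their genetic
interaction profiles should be (a negative similarity-distance
correlation).  Because the pairwise observations share alleles and are not
independent, the p-value of record is a Mantel-style permutation p: allele
identities are permuted jointly on the distance relation (never the
flattened pair vector), and by default the test is one-sided in the
hypothesised negative direction.  A two-sided analytic p from the
t-transform is reported alongside for reference, with the usual caveat
that it overstates the effective sample size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import AlleleAnnotation
from .structure import CONFIGURATIONS

ALTERNATIVES = ("less", "greater", "two-sided")


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_analytic: float
    p_permutation: float
    n_pairs: int
    n_permutations: int
    seed: int
    configuration: str
    alternative: str


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def similarity_distance_correlation(
    table: pd.DataFrame,
    config: str,
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: str = "less",
) -> MantelResult:
    """Mantel-style correlation between profile similarity and distance.

    `table` is a pairwise allele table with columns allele_a, allele_b,
    similarity and d_<config>.  Alleles with any missing distance for the
    chosen configuration are dropped so the pair set stays complete.
    Allele order is canonicalised (sorted) so the permutation p does not
    depend on input order.
    """
    if config not in CONFIGURATIONS:
        raise ValueError(f"unknown configuration {config!r}")
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    col = f"d_{config}"
    if col not in table.columns:
        raise ValueError(f"table lacks column {col}")

    # greedily remove the alleles carrying missing distances so the
    # surviving pair set stays complete
    drop: set[str] = set()
    while True:
        bad = table.loc[
            table[col].isna()
            & ~table["allele_a"].isin(drop)
            & ~table["allele_b"].isin(drop)
        ]
        if bad.empty:
            break
        counts = pd.concat([bad["allele_a"], bad["allele_b"]]).value_counts()
        drop.add(counts.index[0])
    kept = table.loc[~table["allele_a"].isin(drop) & ~table["allele_b"].isin(drop)]
    alleles = sorted(set(kept["allele_a"]) | set(kept["allele_b"]))
    n = len(alleles)
    n_pairs = n * (n - 1) // 2
    if len(kept) != n_pairs:
        raise ValueError("pairwise table incomplete after dropping missing distances")
    if n_pairs < 10:
        raise ValueError(f"need >= 10 complete pairs, got {n_pairs}")

    index = {a: i for i, a in enumerate(alleles)}
    s_mat = np.zeros((n, n))
    d_mat = np.zeros((n, n))
    for row in kept.itertuples():
        i, j = index[row.allele_a], index[row.allele_b]
        s = row.similarity
        d = getattr(row, col)
        s_mat[i, j] = s_mat[j, i] = s
        d_mat[i, j] = d_mat[j, i] = d

    iu = np.triu_indices(n, k=1)
    s_vec = s_mat[iu]
    d_vec = d_mat[iu]
    if np.ptp(d_vec) == 0:
        raise ValueError("constant distance vector: correlation undefined")
    if np.ptp(s_vec) == 0:
        raise ValueError("constant similarity vector: correlation undefined")

    r = _corr(s_vec, d_vec)
    df = n_pairs - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df) / np.sqrt(max(1.0 - r * r, np.finfo(float).tiny))
    p_analytic = float(2.0 * sps.t.sf(abs(t), df))

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = _corr(s_vec, d_mat[np.ix_(perm, perm)][iu])
        if alternative == "less":
            exceed += r_perm <= r
        elif alternative == "greater":
            exceed += r_perm >= r
        else:
            exceed += abs(r_perm) >= abs(r)
    p_perm = (exceed + 1) / (n_perm + 1)

    return MantelResult(
        r=r,
        p_analytic=p_analytic,
        p_permutation=float(p_perm),
        n_pairs=n_pairs,
        n_permutations=n_perm,
        seed=-1 if seed is None else int(seed),
        configuration=config,
        alternative=alternative,
    )


@dataclass(frozen=True)
class RegionGroups:
    front_top_bottom: tuple[str, ...]
    back_side: tuple[str, ...]
    excluded: tuple[str, ...]


def region_groups(annotations: Sequence[AlleleAnnotation]) -> RegionGroups:
    """Split alleles into exposed (front + top/bottom) vs tucked (back + side).

    Alleles located in the ATP cleft or with undetermined (ND) locations are
    excluded and listed — they are not on the accessible surface.
    """
    import warnings

    a: list[str] = []
    b: list[str] = []
    excluded: list[str] = []
    for ann in annotations:
        loc = ann.location_class
        if loc in ("front", "top/bottom"):
            a.append(ann.allele_id)
        elif loc in ("back", "side"):
            b.append(ann.allele_id)
        elif loc in ("ATP cleft", "ND"):
            excluded.append(ann.allele_id)
        else:  # unreachable for vocabulary-validated annotations
            raise ValueError(f"unknown location label {loc!r}")
    if not b:
        warnings.warn("back/side group is empty")
    if not a:
        warnings.warn("front/top-bottom group is empty")
    return RegionGroups(tuple(a), tuple(b), tuple(excluded))


@dataclass(frozen=True)
class RankSumResult:
    median_a: float
    median_b: float
    statistic: float
    p: float
    n_a: int
    n_b: int
    method: str


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    Uses the exact null distribution when both groups have <= 12
    observations and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.  The statistic reported is the
    rank sum of group A.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    if a.size <= 12 and b.size <= 12 and not ties:
        method = "exact"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    rank_sum_a = float(res.statistic) + a.size * (a.size + 1) / 2.0
    return RankSumResult(
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        statistic=rank_sum_a,
        p=float(min(res.pvalue, 1.0)),
        n_a=int(a.size),
        n_b=int(b.size),
        method=method,
    )
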