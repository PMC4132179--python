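# Methods

## Score semantics and weight reversal

A screen cell holds 0 (no interaction) or a growth-defect score in 1–3:
1 = lethal, 2 = severe growth defect, 3 = colony size perceptibly smaller
than control. Severity is *inversely* ordered, so clustering operates on
reversed weights, `w = 4 − s` on nonzero cells and 0 elsewhere: the
strongest interactions get weight 3 and weak hits sit next to
non-interactions in similarity space. Degree counts ignore severity — any
nonzero score counts once, matching how interaction numbers are tabulated
per allele. Blank cells and explicit zeros are both accepted on read and
written back as 0.

## Clustering

Similarity between two weight profiles is the **uncentered Pearson
correlation** — the cosine `Σxy / (‖x‖‖y‖)` with no mean subtraction — the
similarity Cluster 3.0 uses. It is undefined for all-zero profiles, so
rows/columns that never interact are dropped with a warning before
clustering (in a real screen these are the genes that interact with the
null allele but with no point allele). Distance is `d = 1 − s`, and both
axes are clustered independently by **average linkage (UPGMA)**: the
distance between clusters is the unweighted mean of all cross-pair leaf
distances, implemented with the Lance–Williams update. Ties in the minimum
distance are broken by the smallest (row, column) slot index, making merge
order deterministic across platforms; the test suite checks the merge
heights and partitions against both a brute-force O(n³) re-averaging
oracle and scipy's average-linkage implementation. Merge records carry the
join *similarity* (1 − height), which is what the GTR/ATR files expose;
because UPGMA heights never invert, these similarities are non-increasing
down the file. The number of allele clusters *k* is a parameter (default
9); no automatic selection is attempted, and `cut_clusters` simply undoes
the last k−1 merges, labelling clusters 1..k in leaf order.

CDT/GTR/ATR output follows Cluster-3.0 conventions (GENEnX/ARRYnX leaf
ids numbered by the original matrix order, NODEnX internal nodes, matrix
rows/columns reordered to leaf order) so Java TreeView renders the result
directly; no image rendering is done in-package.

## Replicate validation

A pair is "called" in a replicate if it scored nonzero; the gold standard
is the set of pairs supported by at least `min_support` (default 2)
replicates, and the screen being evaluated is *excluded* from standard
construction. Precision is the confirmed fraction of calls, recall the
recovered fraction of the standard. Under independent per-replicate
detection with probability *q*, a held-out replicate's expected recall is
*q* and a called true pair enters a ≥2-of-4 standard with probability
`P(Binom(4, q) ≥ 2)`; the tests hold observed counts to exact 99% binomial
intervals around these closed forms.

## Structure distances

Only Cα atoms are used (strict PDB parsing; first altloc wins; insertion
codes rejected). An allele maps to the Cα coordinates of its substituted
residues, keyed directly by mature-sequence residue number; alleles with
*no* resolved residue are excluded from distance analysis and listed
(partial resolution only warns). The distance between two alleles is the
minimum Cα–Cα distance over all cross pairs of their residue sets, in
three configurations:

- **monomer** — both sets on one subunit;
- **stacked** — sets on intrastrand (long-pitch) neighbour subunits,
  minimised over both orientations and every declared stacked pair;
- **backed** — likewise for interstrand neighbours.

Which subunit pairs count as stacked vs backed is explicit configuration
(`FilamentTopology`), never inferred from coordinates: for a five-subunit
long-pitch model, stacked pairs are (k, k+2) in helical numbering and
backed pairs (k, k+1). Residue numbering is applied to filament models
without alignment offsetting; a per-position offset map can be layered on
by editing the annotations when numbering schemes differ.

## Profile–structure correlation

For the allele pairs with defined distances, the Pearson correlation *r*
between the similarity vector and the distance vector is tested two ways:
an analytic two-sided p from the t-transform with (n_pairs − 2) degrees of
freedom, and a **Mantel-style permutation p** obtained by permuting allele
identities jointly on the distance relation (never the flattened pair
vector) with the +1 correction. The permutation p is the value of record:
pairs sharing an allele are not independent, which the t-reference
ignores. The permutation test defaults to the directional alternative
(`less`: negative correlation, closer ⇒ more similar), because the
scientific hypothesis is directional and because filament geometry couples
the configurations — residue pairs that meet across the stacked interface
necessarily sit near opposite poles of the monomer, so a non-directional
test would flag that induced *positive* monomer association as signal.
`alternative="two-sided"` and `"greater"` are available. Allele order is
canonicalised before permutation so the p-value does not depend on input
order; the seed is a required input in the CLI.

The surface-region contrast groups alleles into exposed (front +
top/bottom) versus tucked (back + side) classes, excluding ATP-cleft and
unresolved alleles, and compares interaction degrees with a **two-sided
Wilcoxon rank-sum test** — exact when both groups have ≤12 observations
and no ties (verified against full enumeration for sizes ≤7), otherwise
the normal approximation with tie and continuity corrections.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *structure* of the study, not its biology.
An idealised filament puts subunit k at angle k·twist and height k·rise on
a helix (defaults: rise 27.5 Å, twist −166.7°, helix radius 15 Å — the
genetic-helix parameters of an actin-like filament), with 375 residues per
subunit placed on a 25 Å sphere in an identical seeded layout. Each of the
k = 9 planted clusters owns a private set of 20 genes and a pair of
surface patches: an anchor facing a stacked contact (nearest cross-subunit
residue within 1.25 × the 12 Å patch radius) and that contact's partner
patch on the neighbouring subunit, with the pair required to stay > 20 Å
from every backed interface so the planted spatial signal is
stacked-specific. Cluster alleles alternate between the two patches — the
motif of mutations far apart on the monomer yet adjacent across the
long-pitch interface — and draw 1–3 residues each, globally disjoint
(alanine-scan alleles never share residues) and preferentially from the
inner 70 % of the patch. Scores arrive per cell: cluster genes hit with
p_signal = 0.8, everything else with p_background = 0.02, severities drawn
from (0.2, 0.3, 0.5) over scores 1/2/3 (lethal rarest). Replicates detect
each true pair independently with probability 0.7 (matching a ~70 %
replicate recall) and add false positives at the background rate. All
generators are pure functions of (config, seed); two calls with the same
seed are bitwise identical.

What passing tests on these data show: the pipeline recovers planted
cluster structure (ARI ≥ 0.9 at k = 9), detects planted stacked-contact
geometry (Mantel r < 0, permutation p < 0.05) and stays null where nothing
was planted (monomer/backed p > 0.05 in ≥ 90 % of seeded replicates).
What they do not show: robustness to plate/batch effects, severity-score
miscalibration between replicates, non-spherical subunit shapes, or
correlated gene panels — none of which the generator models.

## Numerical choices and degenerate inputs

- Similarities are clipped to [−1, 1] against floating-point drift;
  distance matrices must be symmetric with zero diagonal (1e-8 tolerance),
  and NaN distances are rejected outright.
- Constant similarity or distance vectors make the correlation undefined
  and raise, as do all-zero profiles in the cosine.
- `pearson_with_ci` requires n ≥ 4 (the Fisher-z interval needs n − 3 > 0)
  and non-constant inputs.
- Pipeline outputs are deterministic text (sorted JSON keys, fixed float
  formats); identical configuration and seed reproduce every output file
  byte for byte.
- Permutation count defaults to 10,000 in the library; the analysis
  drivers use 4,999 and the test suite 499–999, keeping the full suite and
  the acceptance script to a few minutes on one CPU while leaving p-value
  resolution far below the 0.05 decision threshold. The synthetic-recovery
  property is evaluated over 100 seeded runs.

## Known limitations

- The published headline correlation of the real screen is not
  reproducible here: it requires the unpublished full interaction matrix
  and the authors' (unstated) choice of filament subunit pairing. The
  package instead proves each primitive against an independent oracle and
  the whole chain against planted synthetic truth.
- The two printed class averages that disagree with arithmetic over the
  packaged table (wild-type mean, region-group sizes) are reported as
  computed from the table; no attempt is made to reverse-engineer the
  original class memberships.
- Surface-location classes are taken from the annotation table, not
  computed from solvent accessibility.
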