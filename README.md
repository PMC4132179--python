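# chiscreen

Analysis of **complex-heterozygosity screens**: diploid genetics in which a
point-mutant allele of one gene (here, alanine-scan alleles of yeast actin,
*ACT1*) is combined with heterozygous deletions of other genes, and the
double heterozygote is scored for growth defects. Screens of this kind
produce an allele × gene interaction matrix whose row profiles can be
clustered and mapped onto protein structure: alleles with similar genetic
interaction profiles tend to alter residues that are close in space —
sometimes on one monomer, sometimes only across subunit interfaces of the
actin filament.

The package covers the full analysis chain:

- **Interaction matrices** — scores 1–3 (1 = lethal, 3 = mildly reduced
  colony size; 0/blank = no interaction), with the weight reversal used for
  clustering (weight = 4 − score, so lethal interactions are strongest).
- **Degree statistics** — per-allele and per-gene interaction counts,
  phenotype-class summaries, Pearson correlation with Fisher-z confidence
  intervals, and the digenic combinatorics `n(n−1)/2`.
- **Replicate validation** — a gold standard from pairs supported by ≥2
  replicate screens, and precision/recall of an independent screen against
  it.
- **Two-way hierarchical clustering** — uncentered Pearson similarity
  (cosine; no mean-centering) with average linkage (UPGMA) on both the
  allele and gene axes, cluster extraction at a chosen *k*, and
  Cluster-3.0/Java-TreeView-compatible CDT/GTR/ATR output.
- **Structure geometry** — Cα coordinates from PDB files, minimum
  inter-residue-set distances in three configurations (monomer, intrastrand
  "stacked" dimer, interstrand "backed" dimer, with the subunit pairing
  declared explicitly), and per-residue attribute export for molecular
  viewers.
- **Profile–structure correlation** — a Mantel-style permutation test for
  the correlation between profile similarity and structural distance, and a
  Wilcoxon rank-sum contrast of interaction degrees between surface-region
  groups.
- **Synthetic data** — a parametric helical filament and an interaction
  matrix with planted allele clusters whose mutated residues straddle the
  stacked inter-subunit contact, so every stage of the pipeline is testable
  end to end without the original screen data.

The 32-allele annotation table (mutations, phenotypes, surface locations,
interaction counts) ships with the package
(`chiscreen.datasets.load_alanine_scan_table`).

## Worked example

Simulate a screen, cluster it, and test the structural correlation:

```sh
python analysis/01_simulate_screen.py --seed 1
python analysis/04_cluster_profiles.py
python analysis/05_structure_correlation.py --seed 1
```

which prints (seed 1):

```
k=9 cut vs planted clusters: adjusted Rand index 1.000
496 allele pairs; similarity-distance correlation:
  monomer  r +0.0111  permutation p 0.5604  (null)
  stacked  r -0.1298  permutation p 0.0002  (signal)
  backed   r +0.0367  permutation p 0.936  (null)
```

The adjusted Rand index of 1.0 says the nine-cluster cut of the allele
dendrogram recovered the planted clusters exactly. The Mantel-style test
finds a negative correlation between profile similarity and Cα distance
*only* in the stacked configuration — allele pairs with similar interaction
profiles sit close together across the long-pitch subunit interface, which
is exactly the geometry the generator planted. On the packaged allele
table, `analysis/05_structure_correlation.py` also reports that the 13
front/top/bottom alleles have a median of 40 interactions versus 13 for the
17 back/side alleles (two-sided rank-sum p = 0.0238): exposed surfaces
carry more genetic interactions.

The same pipeline runs from the shell on any dataset in the supported
formats:

```sh
chiscreen simulate --seed 1 --outdir screen/
chiscreen run --config run.yaml --seed 1
chiscreen combinations 150        # -> 11175
```

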