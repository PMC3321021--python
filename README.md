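# radiascan

A tested, reusable pipeline for dominant-marker (AFLP) population genomics,
built around the analysis stack of island-radiation studies:

- **Marker QC** — peak-profile scoring (relative noise threshold, fixed-width
  binning, detection threshold), replicate-based repeatability, the four
  marker-exclusion rules (low repeatability, null-allele-only bins,
  unconfirmed bins, monomorphic markers) and the per-marker mismatch
  genotyping-error rate.
- **Distances & trees** — Nei–Li (Dice) distances on band presences,
  Saitou–Nei neighbor joining with locus bootstrap, uncorrected p-distances
  for sequences.
- **MOTU clustering** — single-linkage transitive closure at a p-distance
  threshold (default 3%).
- **AMOVA** — one- and two-level variance decomposition of binary band
  phenotypes with permutation tests (Φ_ST / Φ_SC / Φ_CT) and pairwise Φ_ST
  matrices.
- **Isolation by distance** — great-circle distance matrices and simple
  Mantel tests (exact enumeration for small n, sampled permutations
  otherwise).
- **Cluster-number selection** — product-Bernoulli mixture fitted by EM
  (a desk-scale stand-in for Bayesian admixture clustering) feeding the ΔK
  second-order statistic.
- **F_ST-outlier scan** — Bayesian F-model for dominant data on population
  pairs (Balding–Nichols hierarchy, HWE dominance likelihood, spike-and-slab
  selection indicator, Metropolis-within-Gibbs), with consistent-outlier
  aggregation across MOTU pairs.
- **Population graphs** — conditional genetic covariance networks with
  edge-exclusion-deviance pruning against χ²₁.
- **Geometric morphometrics** — generalized Procrustes alignment, centroid
  size, shape PCA, leave-one-out CVA assignment with typicality
  probabilities, Goodall's F.
- **Synthetic data** — a Balding–Nichols metapopulation generator (locus- and
  population-specific F, optional selected loci, genotyping error, replicate
  re-scores, 1-D stepping-stone spatial mode producing isolation by
  distance), peak-profile, sequence-cluster and landmark simulators. Every
  downstream stage is testable offline with known ground truth.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the pipeline-level calibration suite
(estimator bias, permutation-p uniformity, NJ exactness against generating
trees, MCMC vs. grid-integration oracle, ΔK recovery, …). It is the slowest
part of the suite (~15 min single-core).

## Command line

```sh
radiascan simulate --seed 1 --outdir sim            # synthetic data + truth
radiascan qc sim/markers.tsv --out qc.tsv           # marker selection + error rate
radiascan dist qc.tsv --out neili.tsv               # Nei–Li distances
radiascan tree qc.tsv --bootstrap 1000 --out nj.nwk # NJ + bootstrap supports
radiascan motu coi.fasta --threshold 0.03           # MOTU clusters
radiascan amova qc.tsv --hierarchy samples.tsv --perms 20022 --seed 1
radiascan ibd qc.tsv --coords samples.tsv --perms 1000000 --seed 1
radiascan clusterk qc.tsv --kmin 1 --kmax 6 --restarts 10 --seed 1
radiascan outliers qc.tsv --hierarchy samples.tsv --prior-odds 10 --seed 1
radiascan popgraph qc.tsv --hierarchy samples.tsv --alpha 0.05
radiascan morpho gpa shells.tps
radiascan run config.yaml                           # whole pipeline + manifest
```

`radiascan run` executes the configured stages in dependency order, hashes
every output into `manifest.json`, and re-runs only stages whose outputs are
missing or whose upstream stages changed.

## Notes on scope

Model-based admixture clustering (MCMC over ancestry with a recessive-allele
model) is deliberately out of scope; the Bernoulli-mixture EM supplies the
per-K log-likelihoods that the ΔK machinery needs, and externally produced
L(K) tables can be imported (`radiascan clusterk --runs-table`). Likewise the
outlier scan replaces reversible-jump moves with an equivalent spike-and-slab
indicator, which is validated against a brute-force grid-integration oracle
in the test suite.
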