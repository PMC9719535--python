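# Methods

## The model

`lncoop` implements a multi-step procedure for discovering functionally
cooperative lncRNA pairs from matched tumor multi-omics profiles, and for
carrying the resulting immune cooperative networks into downstream
immunogenomic analyses.

### Cancer-context lncRNA targets

For each (lncRNA, mRNA) candidate within one cancer type, mRNA expression
*y* (log2) is modelled by ordinary least squares as

    y = b0 + b_CN * x_CN + b_Me * x_Me + b_lnc * x_lnc + eps,

where *x_CN* is the gene-level copy number and *x_Me* the promoter
methylation beta value of the mRNA, and *x_lnc* the lncRNA's log2
expression. Significance attaches only to *b_lnc* (two-sided t test with
n − 4 degrees of freedom); copy number and methylation are confounder
covariates, not screened. Multiplicity is controlled per cancer over all
tested pairs: a regulation is retained when its Benjamini–Hochberg FDR is
below 0.01 **and** its Bonferroni-adjusted p is below 0.1. Bonferroni is
computed on the full tested universe (not the FDR survivors), which is the
stricter, order-independent reading. A pre-filter (default on) drops
features expressed (> 0) in fewer than 20% of samples to bound the pair
universe. Features with more than 20% missing cells are dropped on
ingest; remaining missing cells are excluded pairwise per fit.

The screen uses a Frisch–Waugh–Lovell factorisation — response and all
lncRNAs are residualised once per mRNA on [1, CNV, methylation] — which
gives the identical coefficient, t statistic and p-value as the explicit
four-parameter fit at a fraction of the cost; retained pairs are refit
with the explicit model so reported coefficients come from the canonical
path, and a unit test pins the two routes to each other.

### Cooperative pairs

Two lncRNAs are cooperative in a cancer when they co-regulate at least
one *functional module*:

1. **Shared targets.** Pairs sharing ≥ 3 targets whose overlap is
   hypergeometrically significant (upper tail, universe = mRNAs tested in
   that cancer) are candidates. Both the count threshold and the
   significance test are applied and each is independently switchable,
   since either reading of the procedure is defensible.
2. **GO coherence.** The shared set is tested per GO BP term
   (hypergeometric upper tail against the same universe); a candidate
   module is the intersection of shared targets with an enriched term and
   must keep ≥ 3 genes. Enrichment is not multiplicity-adjusted across
   terms by default (a plain hypergeometric test); a BH flag exists.
3. **Interaction-network compactness.** (i) every module gene must have
   another module gene within shortest-path distance ≤ 2 in the full
   protein-interaction network — the per-gene-minimum reading of the
   criterion; a stricter all-pairs variant is behind a flag. Genes absent
   from the network fail the criterion, since silently excluding them
   would shrink modules below the size floor unpredictably. (ii) the
   module's characteristic path length (CPL: mean shortest-path distance
   over connected module pairs) must be significantly shorter than in
   degree-preserving random networks.

The null ensemble is generated by the edge-switch (double-edge swap)
method: each attempt picks two edges and crosses their endpoints,
rejecting moves that would create a self-loop or multi-edge, so the
degree sequence is preserved exactly. Attempts per network default to
10 × |E|, a standard mixing heuristic. The permutation p is the fraction
of random networks in which the same gene subset attains a *strictly*
shorter CPL (ties count as not-shorter; a network where the module CPL is
undefined also counts as not-shorter). One ensemble is generated per
detection run and shared by all candidate modules, mirroring the
"fixed set of random networks" design. All three significance levels
default to 0.05 and are configuration-exposed.

### Networks, hubs, summaries

The pan-cancer cooperation network is the union over cancers; each edge
carries its cancer-label set and GO-term set. LICNs (lncRNA immune
cooperative networks) keep exactly the edges backed by ≥ 1 immune-flagged
module; their nodes are the IC-lncRNAs. Immune flags come from an
explicit term list or a keyword fallback (immune, T cell, interferon,
inflammat, ...). Hubs are the top 10% of nodes by degree, with ties at
the cut included (deterministic and order-free); pan-cancer hubs are
*common* when they are hubs of ≥ 2 per-cancer LICNs, *specific* at
exactly 1, *other* at 0. Topology reports include a descriptive discrete
maximum-likelihood power-law exponent (no goodness-of-fit gate) and a
clustering-coefficient comparison against edge-switch nulls. Catalog
percentages round to 2 decimals.

### Infiltration, similarity, subtyping, survival

- **Infiltration.** Spearman rho per (lncRNA, cell type) with pass
  cutoffs |R| > 0.3 and raw p < 0.05 (no multiplicity adjustment, as the
  cutoff is quoted raw). Median-split differential expression: groups
  above vs at-or-below the median infiltration (ties to the low group,
  deterministic), fold change 2^(Δ mean log2) (geometric-mean ratio),
  Welch t test (safer than pooled when variances differ), BH FDR; DE iff
  FC > 2 or < 0.5 and FDR < 0.05. Fisher's exact overlap reports the
  sample odds ratio with a Woolf-logit 95% CI; zero cells take a Haldane
  0.5 correction for the estimate/CI (flagged) while the p stays exact.
- **Cross-cancer similarity.** R1 = Jaccard of IC-lncRNA membership,
  R2 = Pearson of per-lncRNA mean log2 expression over the pan-cancer
  IC-lncRNA union restricted to lncRNAs quantified in both cancers
  (summary vectors, since samples are unpaired across cancers); combined
  = (R1 + R2)/2, falling back to R1 where R2 is undefined (< 3 shared
  features). Hierarchical clustering uses average linkage on
  1 − combined; negative combined entries are flagged, not clipped.
- **Subtyping.** Ordered feature filters: expressed (> 0) in > 50% of
  samples, top 10% by expression variance (ceil count, ties included),
  intersect with hubs. Consensus clustering is the Monti resampling
  procedure: 80% sample draws without replacement, inner hierarchical
  clustering with 1 − Pearson distance and average linkage (the
  ConsensusClusterPlus default family), consensus = co-cluster count /
  co-sample count, final labels by clustering 1 − consensus. k is fixed
  at 2; no automatic k selection. CYT is the geometric mean of linear
  cytolytic-gene expression (+1 offset; defaults GZMA, PRF1), MHC the
  mean log2 expression of the MHC list, and the immune score a mean
  per-gene z-score over a supplied list (an ESTIMATE-style surrogate;
  the ESTIMATE algorithm itself is out of scope). Subtype comparisons
  use two-sided Wilcoxon–Mann–Whitney except for the subtype-defining
  lncRNAs (Welch t) and lncRNA–checkpoint relations (Pearson).
- **Survival.** Cox fits use Efron tie handling (lifelines default).
  Candidates pass a raw univariate p < 0.05 screen (unadjusted, as
  quoted); the signature is selected by bidirectional stepwise AIC from
  the full candidate model (the add/drop move that lowers AIC most, until
  none improves) — AIC rather than p-value stepping, since the
  elimination criterion is not stated; a tiny ridge (1e-6) stabilises
  near-collinear multivariate fits. The risk score is the linear
  combination Σ βj·expr_j; patients split at the median score (ties to
  low risk) and are compared by the log-rank test. The optimal cutpoint
  scans every observed expression value between the 10% and 90% quantiles
  and returns the threshold maximising the standardised log-rank
  statistic; its p-value is selection-biased (a maximum over many tests)
  and the function says so in a warning — no maxstat correction is
  implemented.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes,
with planted ground truth so every stage is testable without external
data:

- mRNA expression follows the regression model exactly: baseline 5.0 +
  1.0 × CNV − 1.0 × methylation (+ 2.0 × each regulating lncRNA) +
  N(0, 1) noise. The positive CNV default reflects the expectation that
  targets are positively dosage-regulated. CNV is Gaussian centred at 2
  (sd 0.5); methylation is logit-normal in [0, 1]. Defaults: 300
  samples, 30 lncRNAs, 300 mRNAs.
- 5 planted cooperative pairs of disjoint lncRNAs, each with a 4-gene
  shared module plus 3 private targets per lncRNA (so overlap tests see
  realistic margins). Each module gets its own GO term (padded to 10
  genes) and forms a clique overlaid on an Erdős–Rényi background PPI at
  mean degree 4 — the simplest null that still exercises shortest-path
  code while guaranteeing the distance criterion by construction. Half
  the planted modules are immune-flagged by default so LICNs are proper
  subgraphs.
- Infiltration fractions are rank transforms of a noisy linear function
  of the linked lncRNA; the Pearson mixing weight is set to
  2·sin(π·rho/6) so the requested strength is a Spearman target.
  Unlinked cell types are pure-noise ranks; fractions are marginal scores
  in (0, 1) and deliberately do not sum to 1 per sample.
- Survival times are exponential with log-hazard linear in standardised
  linked-lncRNA expression (baseline rate 0.1) under independent uniform
  censoring on [0, 30], yielding ≈ 30% censoring.
- Latent subtypes shift designated lncRNAs (the first 6, reserved and
  excluded from planted pairs so regulatory ground truth stays orthogonal
  to subtype structure) by ± sep/2 with alternating sign across features:
  subtypes differ in profile *shape*, which is what correlation-distance
  clustering detects — a uniform level shift would be invisible to it.
  Default separation 3 sd; the separable-case analyses pass 6 sd.
- Everything derives from one integer seed through order-independent
  substreams, so annotation can be regenerated without replaying the
  omics draw; identical config + seed gives bit-identical output.

What the generator does **not** model: read-level sequencing, batch
effects, copy-number segmentation, probe-level methylation, correlated
lncRNA co-expression beyond the subtype pattern, non-linear or
cell-type-specific regulation. Passing tests therefore demonstrate that
the procedures recover the planted linear/graph structure under Gaussian
noise at TCGA-like sample sizes — not that they would perform identically
on real tumor compendia, where effect sizes, confounding and annotation
error are harsher.

## Numerical and scale choices

- Hypergeometric tails come from `scipy.stats.hypergeom.sf` and are
  pinned to an exact enumeration oracle (≤ 1e-12 over all universes
  ≤ 25).
- Degenerate inputs raise typed errors rather than returning NaNs:
  constant covariates, rank-deficient designs, < 5 complete samples,
  empty sample intersections, zero events, all-equal expression.
- Analysis and recovery suites use 200 edge-switch networks per ensemble
  and 100–500 consensus resamples; the module-level defaults remain 1000
  for both, matching the procedure's published scale. Recovery statistics
  average 10 generator seeds; the planted effects are strong enough that
  the permutation p-values sit far from the 0.05 boundary, so the
  ensemble size does not bind.
- Ratios printed by `summary_counts`/`pct` round half-even at 2 decimals
  (1 for hub-category percentages), matching the catalog convention.

## Known limitations

- The immune GO-term list and immune-category mapping are user inputs;
  the keyword fallback is a heuristic, not a curated ontology slice.
- The overlap test's universe is the tested-mRNA set of one cancer;
  cross-cancer universes are not harmonised.
- The consensus-clustering inner metric (1 − Pearson) assumes ≥ 2
  informative features and no missing values.
- `optimal_cutpoint` reports no corrected p-value; treat its p as
  descriptive.
- Gene identifiers are matched exactly; no alias resolution.
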