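# Methods

## Model and procedure

`txoverlap` treats every input dataset as an already-normalized log2
expression matrix (probes × samples) with a case/control design. The
analysis chain is:

1. **Per-probe testing.** Welch's two-sample *t*-test (unequal variances,
   Welch–Satterthwaite degrees of freedom, two-sided p). The degenerate case
   of zero variance in both groups is defined explicitly: equal means give
   t = 0, p = 1; unequal means give |t| = ∞, p = 0. The vectorized path is
   `scipy.stats.ttest_ind(equal_var=False)` with these limits patched in.
2. **Multiplicity.** Benjamini–Hochberg step-up adjustment
   (`statsmodels.multipletests(method="fdr_bh")`), always *within* one
   dataset — datasets differ in platform and power, so pooling q-values
   across them would let a well-powered study dictate another's threshold.
3. **Fold change.** log2FC = median(case) − median(control) on the log2
   scale; the linear ratio is 2^log2FC. Medians (not means) follow the
   convention of presenting fold changes against the control median, and the
   probe's direction comes from the sign of this quantity, not from the
   t-statistic.
4. **Signature selection.** A probe passes with (q if FDR mode else p) ≤
   0.05 and linear fold change ≥ 2 or ≤ 1/2. Probes collapse to genes by the
   minimum-p representative (ties by probe id); unannotated probes are
   dropped and counted. Signatures can be truncated to a common size
   (smallest-p genes kept, ties by symbol) so lists from studies of very
   different power are comparable; FDR mode and the fold-change cutoff are
   per-dataset configuration because adequately powered human-tissue studies
   support FDR control while small in-vitro/model studies may only support
   raw p thresholds.
5. **Cross-species translation.** Gene symbols are upper-cased at parse time
   (human upper-case and mouse title-case conventions meet on one spelling)
   and joined to homolog groups. All target-taxon symbols of a group are
   kept, with multiplicity reported — conservative for overlap detection and
   auditable. When two source genes of opposite direction land on one target
   symbol, the smaller source p wins and the conflict is counted, mirroring
   the probe-collapse rule.
6. **Overlap.** Membership is direction-blind; direction enters only the
   decomposition into concordant-up / concordant-down / discordant.
   Percentages are computed against both list sizes, kept to one decimal in
   tables and rounded to integers in the JSON summary.
7. **Overlap-difference test.** Pearson chi-square without continuity
   correction on [[k₁, n₁−k₁], [k₂, n₂−k₂]]; any observed cell < 10 routes
   to the two-sided Fisher exact test (the threshold is an argument). No
   Yates correction: the Fisher fallback already covers small tables. A zero
   column margin yields p = 1 with a warning rather than an error.
8. **Over-representation.** Hypergeometric upper tail P[X ≥ k] via the
   survival function, BH across tested sets. The background universe
   defaults to all annotated genes of the platform and is an explicit
   argument because it materially changes every p-value.

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical structure the testing chain assumes:
independent Gaussian noise on the log2 scale around a per-gene baseline
(baseline ~ N(7, 1.5), noise SD 0.4 by default — typical post-normalization
array values), planted DE genes with case means shifted by ±effect_size
(default 1.5 log2 units, 70% up — the asymmetry seen in inflamed-tissue
signatures), and exact planted sharing between studies. Defaults for
study size are configurable rather than fixed, since real multi-cohort
designs vary; tests use 8–10 samples per group, the scale at which the Welch
test is well calibrated (at n = 6/6 its null rejection rate is ≈0.043 — the
mild conservatism of the Satterthwaite approximation, not a defect).

Construction guarantees worth relying on:

- Planted counts are exact, never approximate: round(frac_up · n) genes up;
  pairwise shared cores contain the triple core; pair-exclusive cores get
  round(concordance_frac · n) concordant genes, the concordant up/down split
  using the *first* label's frac_up so a 106-up/42-down core of 148 is
  representable exactly.
- All planted DE sets are disjoint across studies except the configured
  sharing, so at high effect size the recovered overlap equals the planted
  count exactly (the 2-fold filter suppresses the BH false positives that
  would otherwise blur it).
- Per-gene baselines are drawn once per species and shared across that
  species' studies, isolating overlap signal from baseline drift.
- Gene index *i* is the same biological gene in every study; symbols are
  species-prefixed (GENE#### / MGENE####) so cross-species overlap genuinely
  requires the homolog join. The homolog table covers exactly
  round(ortholog_fraction · n) positions, one gene per species per group.
- All studies in one multi-disease design share n_genes (the positional
  correspondence requires it); the generator rejects configs whose shared
  cores exceed any study's DE budget or the universe.

Not emulated: probe-level (pre-normalization) intensities, batch effects,
correlated genes, heavy-tailed noise, array-specific artifacts, many-to-many
homolog groups (the generator emits 1:1 groups; the translator handles
many-to-many tables from other sources). Passing recovery tests therefore
shows the chain is correct under its own assumptions, not that those
assumptions hold for any particular real dataset.

## Numerical and design choices

- **Fold-change cutoff 2.0 by default, configurable** — a fold-change filter
  is part of the selection contract but no universal constant exists; 2 is
  the field's customary screen.
- **"Events below 10" = any observed 2×2 cell < 10.** The standard
  small-sample trigger; exposed as `small_cell_threshold`.
- **Chi-square vs Fisher agreement.** The two tests converge as counts grow;
  at signature-scale tables (every cell ≥ 500) they agree within |Δp| ≤ 0.01
  (property-tested). At moderate counts the exact test is conservative
  relative to the uncorrected chi-square and the gap can exceed 0.05 — one
  reason the fallback threshold matters.
- **Null calibration of the overlap test** is checked on random signature
  pairs from a 54,000-feature universe (the scale of a full-genome array).
  Overlap counts of fixed-size random sets are hypergeometric, whose
  variance is (N−n)/(N−1) of binomial; at small universes this attenuation
  makes the chi-square visibly conservative, at platform scale it is
  negligible.
- **Determinism.** Every generator consumes a `numpy` Generator seeded from
  one config seed; reruns are byte-identical including written files (float
  round-trip via shortest-repr formatting).
- **Problem sizes in tests and the acceptance script** (hundreds of genes,
  8–10 samples per group, 200-replicate simulations) are chosen so each
  property is decided by construction or by ≥3-sigma margins while the whole
  suite stays interactive.

## Known limitations

- The pipeline consumes normalized matrices only; normalization of raw
  probe-level data is out of scope.
- The over-representation step is a plain hypergeometric test, not an
  ontology-aware method: no GO-graph propagation, no term redundancy
  clustering, no EASE-style score adjustment.
- Direction conflicts and many-to-many homolog expansions are resolved by
  documented deterministic rules (min-p, keep-all) rather than by biological
  evidence; the translation report makes their frequency visible.
- Equal-size truncation keeps the most significant genes, which biases
  truncated signatures toward large effects; that is the intended trade-off
  of comparing "lists of similar sizes".
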