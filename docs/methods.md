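# Methods

## Problem and model

`pathvote` classifies two-class gene-expression cohorts (e.g. pathologic
complete response vs. residual disease after chemotherapy) by combining many
weak, biologically scoped classifiers instead of one classifier on all
genes. Each pathway of a gene-set collection contributes one *base
classifier*: a soft-margin SVM restricted to the pathway's differentially
expressed member genes. Base classifiers are ranked by balanced
cross-validated accuracy, and a majority-vote ensemble is assembled from the
top of that ranking by a two-stage selection that trades accuracy against
*diversity* — the idea that an ensemble only outvotes its members when those
members err on different samples.

## Pipeline

1. **DE screen.** On the full (possibly imbalanced) training set, each gene
   gets a two-sample moderated t-statistic: pooled per-gene variances are
   shrunk toward a prior fitted by empirical Bayes. The prior
   (d0, s0²) is moment-matched on log sample variances, solving
   trigamma(d0/2) = Var[log s²] − trigamma(d/2) by Newton iteration; the
   posterior variance is (d0·s0² + d·s²)/(d0 + d) with d = n₁+n₂−2, and
   p-values use a t reference with d + d0 degrees of freedom. This is the
   standard two-group microarray analysis; the implementation reproduces
   the reference R implementation (limma) to ~1e-10 on a frozen
   heteroscedastic fixture (see `tests/test_de.py`). Genes with p < α
   (default α = 0.05, raw p-values; Benjamini–Hochberg optional and off by
   default) form the DE list. A Welch t-test is available via
   `de_method="welch"`. Genes with zero variance in both classes get p = 1
   and are excluded from the prior fit.
2. **DE pathways.** Each pathway is intersected (exact, case-sensitive ID
   match) with the DE list; non-empty intersections become the feature sets
   of the base classifiers. No minimum size beyond one gene.
3. **Base classifiers.** One SVM per DE pathway: RBF kernel, C = 1,
   γ = 1/p (p = number of features) — the classical library defaults —
   on features standardised with training-fold statistics. Standardisation
   is applied because SVMs on raw expression scales are dominated by
   high-variance genes.
4. **Balanced repeated CV.** Each of `n_runs` runs (default 100) draws a
   class-balanced subsample (all minority samples plus an equal-size uniform
   draw from the majority), splits it into `n_folds` stratified folds
   (default 5) and pools held-out predictions; a learner's score is the mean
   pooled accuracy over runs. Subsample and folds are derived from the run
   index only, so every learner is evaluated on identical resamples.
5. **Diversity.** Per run, each learner's held-out predictions yield a
   binary correctness vector over that run's subsample; the pairwise
   disagreement D_{i,k} = (N10 + N01)/n (the fraction of samples on which
   exactly one of the two was correct) is averaged over runs into a
   symmetric matrix D for the top-N learners. Overall diversity is the
   double sum OD[i] = Σ_j (D[i,j] + D[j,i]) = 2 · row sum.
6. **Preliminary optimisation.** The top-N set S is reordered by OD
   descending into S* (ties keep accuracy rank). Prefixes of S* of size
   1..N (configurable `min_prefix`) are scored by the same CV with
   majority-vote predictions; m is the smallest prefix size achieving the
   maximum, and S′ = S*[:m].
7. **Second optimisation (θ-pruning).** While some unresolved surviving
   pair has D < θ (default θ = 0.15): take the pair with minimal D
   (lexicographic tie-break), score four candidates — S1 keep both, S2 drop
   the later member, S3 drop the earlier, S4 drop both — under the identical
   seed stream, and keep the best; accuracy ties within 1e-6 resolve by the
   priority S4 > S3 > S2 > S1 (prefer smaller ensembles). Each pair is
   resolved at most once, which guarantees termination; the ensemble never
   shrinks below one member. Every decision is recorded in the selection
   trace.
8. **Vote and evaluation.** Survivors S″ are refitted once on a seeded
   balanced subsample of the full training set and vote by simple majority;
   an exact even-split tie follows the member with the highest base CV
   accuracy (deterministic and seed-free). Held-out performance is reported
   as accuracy, precision, sensitivity, specificity and F-score
   (F = 2TP/(2TP+FP+FN)) over repeated balanced subsamples of the test set;
   a metric with a zero denominator in a run is flagged undefined and
   excluded from the mean rather than coerced to zero, which would bias
   small-run summaries. The fitted model is never refitted on test data:
   repeated balanced resampling of the test set is the only coherent reading
   of a per-run mean ± SD for a fixed model.

## Design choices where the protocol was open

- **"Bootstrap" CV** is read as the repeated random balanced resampling
  around an ordinary stratified k-fold, not within-fold resampling with
  replacement; this matches drawing a fresh majority-class subsample in
  every run.
- **Correctness vectors** are out-of-fold: each sample's correctness comes
  from the fold in which it was held out, avoiding resubstitution optimism.
  The aggregate per-learner vector marks a sample correct when it was
  correct in a strict majority of the runs that held it out (never-drawn
  samples count as incorrect). Pairwise diversity, however, is computed per
  run and averaged, which needs no such convention.
- **Shared resampling streams.** Balanced subsamples and fold partitions
  depend only on (protocol seed, run index). This makes per-run correctness
  vectors of different learners aligned sample-for-sample (required for the
  disagreement averaging), makes CV means of identical ensembles
  bit-identical (so the 1e-6 tie tolerance only absorbs genuine float
  noise), and keeps every stage reproducible from one master seed.
- **Prediction cache.** Ensemble CV reuses the per-learner held-out fold
  predictions computed during base-learner evaluation and recomputes only
  the vote. Because fold plans are shared and one member's fold fit never
  depends on other members, this equals naive re-evaluation exactly; the
  test suite asserts the equality against a refitting path.
- **Even-T vote ties** follow the highest-accuracy member. An alternative
  fixed-label fallback was rejected as it biases toward one class.

## Synthetic cohorts

The generator emulates a normalised (log-intensity-like) expression matrix:
per-gene baselines ~ N(6, 1), Gaussian noise with SD `noise_sd`, and a
configurable pathway collection. Genes of one pathway share an
equicorrelated latent factor with loading √ρ (pairwise correlation ρ,
default 0.3) — the simplest structure that makes a pathway a unit rather
than a bag of independent genes. Every gene of an *informative* pathway
gains `effect_size`·`noise_sd` (default 2) in positive-class samples.
Informative pathways may overlap each other; background pathways draw only
from genes untouched by any informative pathway, so ground truth is
well-defined and background sets carry no class separation by construction.
Class labels default to `pCR`/`RD` with a configurable imbalance
(`n_pos`/`n_neg`).

Default study conditions — 2000 genes, 50 pathways of 10–40 genes, 5
informative, δ = 2, ρ = 0.3, 60/60 samples — are the desk-scale regime used
across the test suite and by `scripts/acceptance.py`. At this scale the
selection cut `top_n` is set to 10 in those studies, preserving roughly the
ratio a 35-of-298 cut implies at full KEGG scale; a cut of 35 on a
50-pathway pool would keep essentially everything and exercise no
selection. The package default remains `top_n=35`.

What the generator does *not* emulate: heavy-tailed or count noise, batch
effects, probe-level artefacts, missing values, realistic pathway size
distributions, or correlation between pathways beyond shared genes. Passing
tests therefore demonstrate correctness of the algorithms and calibration
under Gaussian assumptions, not performance on any real cohort.

## Numerical notes and limitations

- All randomness flows from one master seed through named
  `numpy.random.SeedSequence` spawn keys; reruns are bit-identical
  (byte-identical selection-trace JSON).
- CV problem sizes in tests (3–10 runs, cohorts of a few hundred genes) are
  the package's chosen desk scale; the algorithms are O(N²) in the top-N
  count during pruning and linear in runs, folds and pathways elsewhere.
- With very small balanced subsamples, stratified folds can fail to keep
  both classes in every training split; folds are re-drawn (up to 100
  attempts) before erroring.
- The DE screen, being run on the same training set later resampled by CV,
  lets chance-DE genes of background pathways carry a little overfit signal;
  background learners therefore score slightly above 0.5, which is the
  realistic behaviour of the protocol, not a bug.
- Only two-class problems are supported; weighted or soft voting and other
  diversity statistics (Q-statistic, kappa, double-fault) are out of scope.
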