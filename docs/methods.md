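# Methods

This note documents the models, numerical choices and limitations behind
`trscout`.  It covers what the code computes and why the defaults are what
they are; all empirical statements here are recomputed by the test suite or
`scripts/acceptance.py`.

## Similarity graph

Pairwise BLASTP hits (12-column tabular layout) become an undirected weighted
graph.  Hits with e-value above the cutoff (default 1e-5) and self-hits are
dropped; multiple HSPs per directed pair keep the lowest e-value.  The BLAST
literature gives no canonical e-value→weight map for MCL input; we use the
standard −log₁₀(e) transform, capped at 180 so that e = 0 does not produce an
infinite weight, and merge reciprocal hits by the mean of the two directed
weights (a symmetric, order-independent rule).  A `unit` weight scheme (every
retained edge weight 1) is available for sensitivity checks.  Collapsing
multiple HSPs to the best hit before merging is a modelling choice; pipelines
that sum HSP scores may produce slightly different graphs.

## Markov clustering

`mcl_cluster` implements dense MCL: self-loops are added (by default each
node receives its maximum incident edge weight, the mcl binary's behaviour;
a unit rule is available), columns are normalized to a stochastic matrix,
and the iteration alternates expansion (matrix squaring) with inflation
(entrywise power r followed by column renormalization), zeroing entries
below 1e-7 and renormalizing after each step.  Convergence is declared when
the maximum absolute column change falls below 1e-6 (at most 200
iterations; non-convergence interprets the current matrix and warns).
Families are read off the attractor structure: rows with positive diagonal
mass are attractors, each node joins every attractor it flows to, and
attractor sets sharing a node are merged so the output is always a
partition; nodes attracted by nothing (possible only pre-convergence)
follow their strongest outflow.  These defaults converge on desk-scale
graphs (hundreds to a few thousand nodes); the implementation does not
reproduce the mcl binary's sparse pruning heuristics and is not intended
for millions of nodes.

Inflation selection scores each candidate r by the mean best-match Jaccard
index of gold families against the clustering and returns the argmax, with
ties broken toward the smaller (coarser) inflation — a deliberate
preference, since equal quality at lower r means larger, more inclusive
families.

## Disorder features and the long-protein rule

The per-protein disorder ratio is simply (#disordered residues)/length.
Per-residue predictors typically fail above 2500 residues, so proteins
strictly longer than the cap are split two ways: into n contiguous
near-equal pieces, n minimal such that every piece is strictly shorter than
2500, and into n+1 pieces; the protein's ratio is the *unweighted* mean of
the per-piece ratios over all n+(n+1) pieces.  Averaging the two schemes
dampens edge artefacts at the cut sites.  Within a scheme piece lengths
differ by at most one, longer pieces first (deterministic).  A
length-weighted mean is exposed behind a flag for sensitivity analysis; for
near-equal pieces the two differ negligibly.  Exactly-2500-residue proteins
are not split (the cap is strict).

The disorder threshold is derived from the TF distribution as its 5th
percentile (linear interpolation between closest ranks, inclusive); the
Arabidopsis constant 0.341 is shipped as the documented default for callers
without a TF reference set.  Deriving the cutoff from fewer than 20 TF
ratios triggers a warning.

## Family summaries and the filters

Family-level aggregation is conservative with missing data: a missing
nuclear call counts as non-nuclear (it can never help a family across the
>50 % filter), while missing disorder ratios are excluded from the family
mean rather than imputed, with coverage reported so callers can enforce
their own minimum.  A family with no member disorder prediction fails the
disorder filter outright.  All three thresholds are strict inequalities:
exactly 50 % nuclear or a mean disorder of exactly the cutoff fails.
"Unknown family" is a universal quantifier — one member with a non-root MF
annotation removes the family from the screen.  Families with no
autoactivation-tested member fail the third filter but remain in the
universe; the tested/untested distinction matters only for enrichment
denominators.  A singleton mode admits 1–2-member families under the same
family-level rules.

## Evaluation statistics

*Precision/recall* are computed at the protein level (every member of a
predicted family counts as predicted), the stricter convention given that
prediction happens at the family level; recall is taken against the gold
proteins inside the eligible universe (families of at least the minimum
size).

*Fold enrichment* of a criterion is (k/n)/(K/N) with an upper-tail
hypergeometric p-value P[X ≥ k]; for the autoactivation criterion and the
final candidate set, the universe (and criterion set) are first restricted
to families with ≥ 1 tested member, since untested families cannot
contribute evidence either way.  Depletion (lower-tail) reporting is out of
scope.

*Yates χ²* uses the clamped continuity correction
N·(max(0, |ad−bc| − N/2))²/((a+b)(c+d)(a+c)(b+d)) with 1 df; zero margins
leave the statistic undefined (flagged NaN rather than 0).

*t-tests* default to Welch (Satterthwaite df) — the safer choice when only
"t-test" is specified — with a pooled-variance flag; two zero-variance
samples with equal means report (0, 1).  Bonferroni adjustment is
min(1, m·p).

*Fisher exact test* is two-sided by the point-mass rule (summing all tables
with the observed margins whose probability does not exceed the observed
one, with the customary 1+1e-7 relative slack for ties).  It is implemented
over the margin support with vectorized hypergeometric masses, which keeps
exhaustive sweeps cheap, and is verified against both
`scipy.stats.fisher_exact` and an exact-integer enumeration oracle in the
tests.  The TF/TR-interaction analysis defines its universe as proteins with
≥ 1 interaction; the background rate includes the candidates (the
proteome-wide denominator convention), while the Fisher table contrasts
candidates with the rest.

*Composition analysis* records, per protein, the maximum count of a residue
set in 20-residue windows at step 1 (overlap 19); sequences shorter than
the window are a single whole-sequence window rather than being dropped.
Seven residue sets are tested (D, E, N, Q, S, P, and acidic D+E), and the
Bonferroni family size is 7.  Non-standard letters (X, *) never match.

*Taxon specificity* aggregates (a) distinct-species counts per family into
categories 1/2/3/4+, and (b) a precomputed ortholog-presence table into a
deepest-conserved-scope assignment per family (ranks ordered from most to
least inclusive; no presence anywhere means own-species-only).  The summary
enforces that scope percentages total 100 and that sub-scope percentages sum
to their enclosing total.  Ortholog presence is an input, not a computation;
meta-genome clustering through this package's MCL is an approximation of
orthogroup inference (OrthoMCL-style reciprocal-best-hit normalization is
not implemented), and precomputed family input is the faithful path.

## Synthetic data

The generator builds a complete input bundle from one seed (per-stage
substreams, so adding a stage does not reshuffle earlier ones; the seed is
recorded in the manifest).  Families are drawn first (size distribution
defaulting to 5 % singletons, 10 % pairs, 35/25/15/10 % of sizes 3–6); a
configurable fraction (default 15 %) is planted as regulator families.
Half of the background families are "known" (members annotated with terms
from a small fixed MF vocabulary; no ontology reasoning); the rest, and all
planted families, carry only root-term or no MF annotation.  Sequences are
random residues (lengths ~ lognormal, median ≈ 300), with the planted class
biased 1.8× toward D/E/N/Q/S/P.  Within-family similarity hits have
e-values 10⁻³⁰–10⁻⁸⁰; sparse between-family hits (2 % of family pairs) sit
just inside the cutoff (10⁻⁵–10⁻⁶·⁵, roughly a 1:10 weight ratio), and an
additional 1 % of pairs produce sub-cutoff noise hits that the reader must
discard.

Class feature models: planted — nuclear probability 0.95, disorder ~
Beta(4, 4) (mean 0.5), autoactivation positivity 0.9; background — 0.25,
Beta(2, 8) (mean 0.2), 0.02; testing coverage 0.5 for both (the published
screens covered roughly a quarter to a third of a proteome; 0.5 keeps
size-3 families detectable).  `expected_feature_gap` returns the closed
forms (Beta mean a/(a+b); P(≥1 detected positive | size s) =
1 − (1 − coverage·positivity)^s), which the calibration tests compare with
observed rates at n = 2000 families within three standard errors.

Ground truth distinguishes *planted families* from *planted candidates*:
the latter are the planted families whose realized feature draws actually
satisfy the three criteria, so the manifest is always consistent with the
generated tables.  Recovery is scored two ways: `recovery_scores` against
the planted candidates (exact member-set matching; measures the pipeline
end to end including clustering) and `detection_scores` against all
eligible planted families (measures the feature separation itself and
degrades as the `hard` preset's separation parameter shrinks toward 0).

What the simulator does **not** emulate: real BLAST score distributions,
protein evolution, shared domains between families, hub proteins in the
interactome, isoforms, or annotation errors.  Passing the planted-recovery
tests therefore demonstrates correctness of the pipeline mechanics under
the stated statistical assumptions, not expected performance on a real
proteome, where family structure is far less clean and feature coverage is
lower and biased.

## Problem sizes

Default test and acceptance runs use bundles of 60–300 families (a few
hundred to ~1100 proteins), exhaustive sweeps over all 2×2 margin
configurations with N ≤ 60, all protein lengths to 100 000 for the split
rule, 200 random ≤ 12-node graphs × 4 inflations for the MCL oracle
battery, 1000 random sequences for the window scan, and 2000 families for
simulator calibration — sizes chosen so the complete suite exercises every
exhaustive check while remaining a desk-scale run.

## Known limitations

- The dense MCL is O(n³) per iteration; large proteomes need the sparse mcl
  binary upstream, with families supplied via `--families`.
- The 0.341 Arabidopsis cutoff is shipped as a constant; recalibrating it
  requires a real TF reference set with disorder predictions.
- Published organism-level counts and precision/recall figures depend on
  external proteomes and predictor outputs and are not reproduced here.
- Between-family similarity noise can merge weakly separated families
  (clustering, not filtering, is then the error source); the recoverable
  preset keeps this rare but not impossible at every seed.
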