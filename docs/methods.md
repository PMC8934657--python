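# Methods

## The selection ratio and its local neutral model

`selratio` quantifies selection on the primary sequence of a genomic
feature (typically a conserved RNA structure) by comparing its human–mouse
divergence to that of neutrally evolving DNA *in its immediate
neighbourhood*. Neutral substitution rates are not uniform along a genome —
they vary on a mega-base scale and track local covariates such as G+C
content — so a global neutral rate would mislabel features that merely sit
in fast or slow regions. The local proxy for neutrality is the set of
ancestral repeats (ARs): transposable-element copies that were already
present in the human/mouse common ancestor and have since evolved
essentially without constraint.

For a feature *X* with de-gapped pairwise distance d_F(X), and a local
neutral model with distance d_LN(X), the selection ratio is

    SR(X) = d_F(X) / d_LN(X)

with SR ≈ 1 for neutral sequence, SR < 0.5 taken as negative selection and
SR > 2 (1.5 for curated Rfam families) as rapid sequence evolution. The
local neutral model concatenates the 1000 gap-free AR positions nearest to
X — 500 walking outward from its 5′ boundary and 500 from its 3′ boundary,
never using positions inside X. Fixing the denominator at a moderately
large constant keeps the variance of SR low while preserving locality.

### AR selection

Repeats qualify as ancestral when they (i) are not primate-specific,
(ii) are not rodent-specific, (iii) are not Alu elements, and (iv) have
diverged more than 25% from their reconstructed ancestral consensus (more
than 20% for L1 elements), and additionally are aligned in all three
analysis species. Divergence-from-consensus is taken from the input repeat
annotation; it is never recomputed here. All thresholds are strict
inequalities.

### Shortfall policy

When one side of a feature cannot supply its 500 positions (chromosome
end, AR desert), the default **borrow** policy tops the model up with the
other side's next-nearest positions so the denominator stays at 1000;
a strict mode caps each side at 500 instead and marks the model
incomplete. Features that cannot reach 1000 positions even with borrowing
are excluded. "Nearest" is measured in reference bp from the feature
boundary (a midpoint mode is available). A legacy variant instead takes
*all* AR positions within 1 kb of the feature, giving a variable-length
denominator; it is retained for comparison.

## Distance estimation

Distances are maximum-likelihood branch lengths under the general
time-reversible (GTR/REV) model: Q = R·diag(π) with symmetric
exchangeabilities R and stationary frequencies π, normalized so
−Σ π_i Q_ii = 1 (distances in expected substitutions per site). For a
sequence pair the likelihood is Π (π_i P_ij(d))^{N_ij} over the 4×4
site-pattern counts N, which under reversibility depends only on the
symmetrized counts. Choices:

- π is the empirical average composition of the two sequences (standard
  practice; leaves 5 free exchangeabilities, GT fixed at 1, plus d).
- Optimization is two-start Nelder–Mead over log-parameters (equal-rates
  and transition-biased starts), followed by a Brent polish of the branch
  length at the fitted exchangeabilities; the polish drives the
  log-likelihood tolerance to 1e-8. On exact Jukes–Cantor pattern counts
  the fitted distance reproduces the closed form −(3/4)ln(1 − 4p/3) to
  better than 1e-6.
- P(d) = exp(Qd) is computed through the symmetric eigendecomposition of
  diag(√π) Q diag(√π)^{-1}, which is stable for any reversible Q.
- Degenerate inputs — an unobserved base in π or fewer than 50 sites
  (configurable) — fall back to Jukes–Cantor, recorded in
  `GtrFit.method`; 6-parameter ML is unstable on tiny counts, and the
  1000-site neutral denominators never trigger the fallback. p ≥ 0.75
  under the fallback raises a saturation error.
- Distances are capped at 10 substitutions/site (flagged `capped`).
- All distances are computed on de-gapped alignments only: every column
  with a gap in any included species is removed first. `N` bases are kept
  by de-gapping (N is not a gap) but excluded from substitution counts, so
  ambiguity never inflates divergence.

GTR parameters are estimated per pair; nothing is shared across features.

## Empirical FDR of extreme selection ratios

SR depends systematically on the feature's G+C content and de-gapped
length, so the false discovery rate of an extreme SR is estimated inside
covariate cells. Features and randomly sampled ARs — each sampled AR scored
exactly like a feature, with its own flanking neutral model that excludes
the AR itself — are binned by:

- G+C: [0–0.25], seven width-0.05 half-open bins (0.25–0.30] … (0.55–0.60],
  (0.60–1.00] (9 bins);
- de-gapped length: (0–100], (100–150], (150–200], (200–300], (300–500]
  (5 bins); lengths above 500 overflow into the last bin and are flagged;
- SR: [0–0.1], 39 width-0.1 half-open bins to (3.9–4.0], (4.0–∞) (41 bins).

For feature X, with n features in its G+C × length cell, t of them sharing
X's SR bin (t includes X, so t ≥ 1), and m / s the analogous counts among
sampled ARs, one sampling estimates FDR(SR) = min((s/m)/(t/n), 1); the
reported value is the mean over independent samplings (defaults: 120 000
ARs of de-gapped length > 80, 10 samplings, sampling i seeded with
master seed + i). Cells with no sampled ARs leave the FDR absent
(`null_sparse`). Features are classified `negative` (SR < 0.5),
`rapid` (SR > 2, or > 1.5 in Rfam mode) only when FDR(SR) ≤ 0.2;
everything else, including features with an undefined SR (d_LN = 0) or
absent FDR, stays `unclassified`.

A theoretical counterpart (`theoretical_fdr`) treats both the feature and
its null as acquiring substitutions independently with fixed per-site
probability P, so both counts are binomial, and computes the exact null
exceedance P(SR > threshold) by summation over the joint count
distribution, with distances either raw count fractions or their
Jukes–Cantor transforms. Conventions: a zero (or JC-saturated) null count
leaves SR undefined and never exceeds; a zero feature count gives SR = 0;
a saturated feature count exceeds any threshold. Converting the exceedance
into a full FDR needs a prior mixture of truly-neutral vs truly-rapid
features, which is an explicit argument and never defaulted.

## Synthetic genomes

The generator emits the exact input shape the pipeline reads (MAF + feature
BED + attributed repeat BED) plus a ground-truth table, at desk scale. A
chromosome is a left-to-right sequence of loci: upstream AR, spacer,
occasionally a decoy repeat that the Yang criteria must reject (an Alu, a
lineage-specific repeat, or an under-diverged element), the feature, spacer,
downstream AR. Sequences evolve under GTR with human-like composition
(π = 0.295/0.205/0.205/0.295, 4:1 transition bias): an ancestor is drawn
from π and descendants evolved along a star tree (reference 0.2 d, partner
0.8 d, third species 0.25 d, so the reference–partner path is exactly the
nominal distance d). Per locus, ARs and spacers evolve at the local neutral
rate — 0.4 substitutions/site by default, matching genome-wide human–mouse
neutral divergence, optionally modulated sinusoidally along the chromosome
to emulate mega-base rate linkage — and the feature at that rate times its
multiplier. AR lengths are drawn from 120–800 bp (a RepeatMasker-like
fragment spread, which also makes the sampled-AR covariate cells overlap
the features'); repeat divergence annotations are drawn consistent with
ancestral age (26–45%, 21–40% for L1) so rule (iv) is exercised.

Indels are deletions in the non-reference lineages (per-site start
probability 0.005, geometric mean length 3); they exist to exercise
de-gapping, and ground-truth distances refer to the substitution process
only. What the generator does **not** emulate: selection on RNA structure
(compensatory changes), realistic repeat family evolution, alignment
error, and reference-lineage indels. Passing tests therefore demonstrate
correct recovery of planted substitution-rate signals under the model's
own assumptions, not robustness to real-genome alignment artifacts.

## Problem sizes in the test and acceptance runs

Calibration and recovery checks run at desk scale, chosen to keep binomial
sampling error well inside the asserted tolerances: 200 neutral loci with
200-bp features for median-SR calibration (median SR asserted within
[0.9, 1.1]); 250 sampled ARs and 1–2 samplings for the empirical FDR
(config defaults keep 120 000 × 10); 100 replicate 10-kb pairs per true
distance for GTR recovery; 2×10⁶ sites for the Jukes–Cantor
simulation-bisection oracle; 10⁶ draws for the Monte-Carlo exceedance
oracle; 24-locus genomes over 10 seeds for planted-signal rank recovery.

## Known limitations

- Pairwise distances only; no Γ rate heterogeneity, codon structure or
  indel model.
- The empirical FDR inherits the binning's resolution: sparse
  G+C × length cells yield absent or coarse estimates (flagged rather than
  smoothed; the binned estimator is deliberate, not regression-smoothed).
- The 3-way extraction assumes reference-forward MAF blocks with a
  gap-free reference inside each retained column window; exotic
  rearrangements are out of scope.
- Repeat divergence, lineage and class annotations are trusted as given.
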