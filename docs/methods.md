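# Methods

## Quantities and conventions

All statistics are pooled ratios over a proteome, not means of per-protein
ratios. For genome *G* with coding genes *g*, proteome *P(G)*, amino acid
*aa* and structure state *ss* ∈ {H, E, C}:

* GC_G = Σ_g GC(g) / Σ_g |g| over protein-coding genes only. `N` bases are
  excluded from numerator and denominator. Stop codons are part of the CDS
  as supplied and therefore contribute to gene GC (they encode no amino
  acid; the effect is below 1% of gene length for typical gene sizes).
* aa_G = Σ_p |p(aa)| / |P(G)|; aa_ss^G = Σ_p |ss(p,aa)| / Σ_p |ss(p)|.
* F_ss^aa = Σ_p |ss(p,aa)| / Σ_p |p(aa)|, F_ss = Σ_p |ss(p)| / |P(G)|,
  CP(aa,ss) = F_ss^aa / F_ss (Chou–Fasman conformational parameter).
* `X` residues and their annotation positions are dropped from every count,
  including |p| and |ss(p)|. This keeps the identities Σ_ss F_ss^aa = 1,
  Σ_ss F_ss = 1 and Σ_aa aa_G·CP(aa,ss) = 1 exact; the test suite asserts
  them at 1e-9 on random synthetic proteomes.
* An amino acid absent from a proteome has *missing* CP (with its zero
  count), never 0 — "absent" is distinct from "present but never in the
  state" (CP = 0). Downstream regressions skip missing cells.
* Selenocysteine/pyrrolysine (`U`/`O`) are out of alphabet and rejected at
  parse time; the analysis covers the 20 standard amino acids.

Codon-GC classification uses the unweighted mean over synonymous codons of
(G+C)/3, not a usage-weighted mean: the classification is a property of the
code itself. Means are exact multiples of 1/36, computed as rationals, so
the neutral boundary (= ½) is crisp; comparison tolerance is 1e-9. CP
values can mathematically exceed 2 even though classical tables describe
the 0–2 range; no cap is imposed. The five-label CP categorization
(strong breaker … strong former) uses configurable cut points with
defaults (0.6, 0.9, 1.1, 1.4); these defaults are this package's own
convention, as published category assignments vary between sources.

Three-state annotations are consumed as FASTA-like records over {H, E, C};
any other letter in a predictor's output is remapped to C on import (with a
logged count), since only helix and strand are positively defined in most
three-state reductions.

## Regression and the biased-COG rule

Fits are ordinary least squares with GC as a fraction (0–1) internally;
output tables report slopes per GC percentage point. Degree 1 uses the
closed-form simple regression (slope p-value from the two-sided t-test);
degree 2 adds a quadratic term and tests its coefficient; `auto` keeps the
quadratic only when an F-test at 0.05 prefers it. A zero-variance response
returns slope 0, p-value 1, flagged. No multiple-testing correction is
applied across the per-amino-acid regressions: raw p-values are reported,
mirroring standard practice for these descriptive scans.

Significance codes follow the R convention with breakpoints
0.001 / 0.01 / 0.05 / 0.1 and right-closed intervals: p = 0.001 maps to
`***`, p = 0.01 to `**`, and so on.

A COG is called *GC-biased* when at least two of the three per-structure
regressions (member helix/sheet/coil fraction vs member gene GC, unweighted
over all retained members, default floor 10 members) have p < 0.001. Under
independence the two-of-three rule at α = 0.001 has a per-COG false-positive
probability of about 3α² = 3×10⁻⁶; the acceptance suite checks the
empirical rate on 1,000 null COGs stays below 0.005.

## COG representative selection

Both filters are computed once on the unfiltered group and applied in a
single pass: retain members with |length − mean| ≤ 1 sample SD (ddof = 1)
**and** domain span ≥ 80% of the mean domain length. Boundaries are
inclusive ("no more than", "at least"). Domain spans are 1-based inclusive,
length = end − start + 1. The first criterion excludes multidomain
outliers, the second partial domains. Iterative re-estimation after the
first filter was deliberately not implemented; the selection is defined as
a one-shot criterion on the observed group.

## Secondary-structure alignment

The H/E/C strings of a COG are aligned progressively: all pairwise global
Gotoh (affine-gap Needleman–Wunsch) alignments give distances (negated
scores), average-linkage joining fixes the merge order with ties broken
toward the lowest cluster index, and profiles are merged by
profile-to-profile dynamic programming (column score = mean cross-profile
substitution score, gaps inside existing columns scoring 0; new gaps pay
the full open/extend penalties). Default scoring: match +2, H/E mismatch
−2, any mismatch against C −1, gap open −4, gap extend −1 (a length-k gap
costs 4 + (k − 1)). The rationale: confusing helix with strand is a
structural error, while coil boundaries are genuinely fuzzy in three-state
reductions, so C mismatches are penalized less. This scoring is a declared
convention of this package — there is no community standard for aligning
three-letter structure strings — and externally produced alignments can be
imported from gapped FASTA instead for exact reproduction of upstream
tools. Traceback preferences (diagonal, then gap-in-second, then
gap-in-first) make results deterministic given input order. Pairwise
scores are verified against exhaustive enumeration of all alignments for
short strings and against an independent affine-gap aligner.

## Synthetic generator

The generator emulates what the pipeline needs from real data — a GC
gradient across organisms, proteomes coupled to codon composition, and
annotations with known per-amino-acid state propensities:

* **Codon model.** Sense codons (table 11; its sense-codon set matches the
  standard code) are drawn i.i.d. with weight ∝ exp(λ·gc(c)). λ is solved
  by bisection (tolerance 1e-4 on expected GC, cap 200 iterations) so the
  expected GC of the generated codon stream equals the target. The stream
  expectation includes the deterministic ATG start and the tilted stop
  codon at their expected share 2/(n̄ + 2) of codons, with n̄ the mean of
  the truncated length distribution: leaving them out would bias realized
  GC by up to ~0.002 at extreme targets, a detectable offset at genome
  scale. With the correction the realized GC is an unbiased binomial
  estimate; the generator meets a 3σ bound at ~270 kb of coding sequence.
* **Gene lengths.** Negative binomial, default mean 300 codons and shape 8
  (coefficient of variation ≈ 0.37, prokaryote-like), truncated below at
  50 codons so CP estimation never sees degenerate proteins.
* **Structure states.** Per residue from P(state | aa); with probability
  `persistence` the residue copies its predecessor instead, creating
  helix/strand runs. The default propensity matrix is built from the
  classic Chou–Fasman helix/sheet/turn propensity table, converted to
  conditionals via a (0.35, 0.22, 0.43) H/E/C background and row-
  normalized. It is ground truth for recovery tests, not a claim about any
  organism.
* **Closed-form oracle.** With persistence 0, CP(aa,ss) =
  P(ss|aa) / Σ_aa' f(aa')·P(ss|aa') for any amino-acid frequency vector f;
  the suite checks estimator agreement within ±0.05 on every cell with
  ≥ 200 occurrences in a ~6×10⁵-residue proteome.
* **GC-coupled panels.** For the coil-up/helix-down pattern, each
  organism's coil propensity is shifted by `strength·(gc − 0.475)` (H and E
  rescaled proportionally), with GC targets linearly spaced over the
  gradient; 0.475 is the midpoint of the default 0.25–0.70 panel so the
  average organism keeps the background composition. Panels default to 100
  genes per organism; the regression-pattern test uses 30 organisms of 60
  genes × 150 codons, ample power at the default effect size.

What the generator does **not** emulate: phylogenetic correlation between
organisms, organism-specific codon-usage bias beyond the single GC tilt,
any intrinsic coupling of amino-acid propensities to GC (beyond the
explicit coil tilt), or length/composition covariance. Passing tests
therefore demonstrate correctness of the estimators and detection
machinery under the stated model, not biological conclusions about real
proteomes.

## Determinism and problem sizes

Every stochastic component takes a single seed; one `numpy` PCG64 stream
per generated genome, with panel sub-seeds spawned via `SeedSequence`.
Pipeline reruns with identical configuration produce byte-identical
outputs, recorded as SHA-256 hashes in the run manifest. Test problem
sizes (50 proteomes for the identity suite, 2,000 genes for CP recovery,
1,000 null COGs, 200 alignment round-trip groups) were chosen as the
smallest panels at which the checked bounds are comfortably away from
their noise floors.

## Known limitations

* The aligner is a stand-in for general-purpose sequence aligners run on
  letter-coded structure strings; its guide tree is average-linkage on
  alignment scores, not a phylogeny.
* Three-state reduction conventions differ between predictors; only the
  H/E-positive remap rule is applied on import.
* Degree-2 fits test only the top coefficient; model selection beyond the
  single F-test (`auto`) is out of scope.
* Regressions treat organisms as independent points; no phylogenetic
  correction is offered.
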