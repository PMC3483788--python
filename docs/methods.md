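# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer should know about.

## Seed-matching sites

A mature miRNA of length ≥ 8 yields exactly two 7-nt site words: the
reverse complement of bases 2–8 (7(2), the 7mer-m8 of the canonical
site taxonomy) and the reverse complement of bases 2–7 with a 3′ A
appended (7(1A) / 7mer-A1; the A pairs no miRNA base but is read by the
silencing complex). Longer (8mer) and shorter (6mer, offset-6mer) site
classes, seed-pairing thermodynamics and conservation filters are
deliberately out of scope: the package follows the experiment-driven
philosophy in which targets are defined by observed repression plus the
minimal site requirement, not by prediction scores.

Words are deduplicated across miRNAs with merged provenance. Three
words — CAAUAAA, UAUUUAU, UCAAUAA — are excluded by default because
they are one edit away from the AAUAAA polyadenylation signal; any
distribution bias they show in 3′UTR rankings is confounded with
polyadenylation biology and cannot be attributed to miRNA action. The
exclusion list is a plain parameter (the set is defined by enumeration,
not by an edit-distance rule, so no similarity detection is attempted);
both the pre- and post-exclusion word counts are reported.

Internally all sequence is DNA (U→T on ingestion, uppercased); words
are rendered back as RNA for display. Coordinates are 0-based
half-open.

## Masking and word counting

Counting operates on *word positions*: a 7-mer window is countable iff
it contains no masked and no ambiguous (N) base; overlapping
occurrences all count. This makes per-gene totals additive over bins,
which the landscape's urn model requires.

Low-complexity masking is a DUST-style triplet score: over windows of
64 nt, score = 10·Σ_t c_t(c_t−1)/2 / (n_triplets−1) with c_t the count
of triplet t; windows scoring above 20 (the conventional DUST level)
are masked. A homopolymer scores ≈ 10·(n−2)/2 and random sequence ≈ 5,
so the threshold separates them by an order of magnitude. Redundant
sequence shared across UTRs (repeat remnants that per-sequence
complexity misses) is approximated by masking every exact 30-mer that
occurs in more than 5 distinct UTRs; both the k-mer length and the
recurrence cutoff are parameters. The original masking pipeline this
emulates is unpublished, so these are this package's own concrete
choices tuned to the same intent: removing composition-driven word
biases before enrichment testing. Totals are always computed on the
masked sequence, uniformly for all words.

## Markov background

An order-m model stores exhaustive m-mer and (m+1)-mer counts over
countable windows. A word's per-position probability is the standard
chain factorisation

    P(w) = C_m(w[0:m])/T · Π_i C_{m+1}(w[i:i+m+1]) / C_m(w[i:i+m])

(T = total m-mer positions), which is algebraically the ratio of
(m+1)-mer count products to inner m-mer count products normalised per
position. Conditional next-base probabilities sum to 1 up to edge
effects only (an m-mer at a sequence end has no successor); the test
suite checks normalisation with that tolerance. A zero count for any
required sub-word raises rather than silently flooring — with order 4
over realistic UTR universes this only happens on degenerate inputs.

## Enrichment landscape

Genes are ranked most-downregulated first by the moderated t. For bin
sizes b = step, 2·step, …(step defaults to 100 genes; the final
partial bin is always evaluated so the landscape ends at the full
list), each word w is tested with X ~ Hypergeometric(N, K, n):

* N = total countable word positions in the whole ranked list,
* K = positions spelling w in the whole list,
* n = positions in the leading bin, k = positions spelling w in it.

Both tails are evaluated; the reported value is +|log₁₀ P(X ≥ k)| when
the enrichment tail is the more extreme, −|log₁₀ P(X ≤ k)| otherwise
(ties report +). Bins with zero total positions record 0. No multiple
testing correction is applied inside the landscape (raw signed log-P is
what is plotted); a Bonferroni line over words × bins is provided for
annotating peak significance.

Tails are computed in log space by summing the gammaln-based log-pmf
over the support with logsumexp. This is exact to floating precision
and fast at word-position universes in the millions, where generic
discrete survival functions are impractically slow; the test suite
pins it to an integer-arithmetic enumeration oracle on the complete
parameter grid N ≤ 12.

With Markov correction enabled (order 4 by default; 0 disables), the
empirical K is replaced by the background-expected count
K* = clip(round(p_w·N), 1, N). This recentres each word's urn on its
composition-expected frequency: a word globally over-represented
relative to the order-4 background becomes uniformly easier to call
enriched, and vice versa. The correction shifts the baseline per word;
it does not model composition gradients *along* the ranking. When an
adjusted K* places the observed k outside the hypergeometric support,
k is clamped to the support boundary so values stay finite; this only
occurs when the background deviates grossly from the empirical counts.
The uncorrected mode is the reference behaviour for all oracle tests.

## Differential expression

The two-group moderated t follows the standard empirical-Bayes
treatment of gene-wise variances: gene residual variance s²_g on
d_g = n_A + n_B − 2 df is shrunk to s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g)
and t_g = Δmean / (s̃_g √(1/n_A + 1/n_B)) is referred to a t
distribution on d₀ + d_g df. The prior (d₀, s₀²) is estimated by
moment-matching the log sample variances against scaled-F theory
(digamma/trigamma identities; trigamma inverted by Newton iteration).
Under-dispersed variance sets yield d₀ = ∞ (all genes share s₀², normal
reference); d₀ = 0 recovers the classical pooled t exactly, which is
the oracle limit used in tests, and the full estimator is cross-checked
against the Bioconductor reference implementation in one test. Only
two-group contrasts are supported — multi-factor designs, batch terms
and array QC are out of scope, and matrices are assumed normalised
(log2) upstream.

BH adjustment is the plain step-up q_(i) = min_{j≥i}(p_(j)·m/j) capped
at 1, evaluated in the same floating-point order as the statsmodels
reference so the two agree bit-for-bit.

Detection filtering keeps genes with detection P < 0.01 (strict) in at
least one contrasted condition; the surviving set is the universe for
all downstream overlap tests. Probe-level results collapse to one row
per gene by smallest adjusted P, ties broken by probe id.

Ranking ties (equal t) break alphabetically by gene id so orderings are
reproducible regardless of input order.

## Probe mapping

Probes are scored against each transcript by the longest run of
consecutive perfect matches — the longest exact common substring,
found by binary search over the run length with a hashed window set.
Since probes are ~50 nt and the acceptance rule is a perfect ≥ 30-nt
run, exact substring scoring is equivalent to the original seeded
aligner for this purpose and needs no gapped alignment. Both probe
strands are scored (platform orientation varies) and the better kept.
Ties resolve by: source (curated/Vega first), then biotype
(protein-coding > pseudogene > other > nonsense-mediated decay — the
placement of "other" between pseudogene and NMD is this package's
decision where no rule was stated), then longest 3′UTR, longest cDNA,
and finally transcript id, which makes the cascade a total order.

## Target calling and set overlap

Putative direct targets of a transfected miRNA: adjusted P < α
(default 0.05) *and* logFC < 0 in its mimic-vs-inhibitor (or
mimic-vs-mock) contrast *and* ≥ 1 seed site of either type in the
3′UTR. "Downregulated" is the two-sided adjusted P combined with the
sign condition. α = 0.05 is the default because that cutoff tends to
coincide with the landscape peak of seed-site enrichment in transfection
experiments; it is a plain parameter. Lowering α never adds targets.

Set overlap restricts both sets to the declared universe first, then
reports k, fold enrichment k/(|A||B|/N) (also as log2), the enrichment
tail P(X ≥ k) and the depletion tail P(X ≤ k). Panels of tests get BH
adjustment across all testable cells; cells empty after universe
restriction are recorded as untestable rather than erroring.

## Synthetic studies

The generator emulates the structure of a transfection experiment in
primary neurons, with these defaults chosen once as the study
conditions:

| parameter | default | rationale |
| --- | --- | --- |
| genes | 2,000 | enough for 20 landscape bins at step 100 while keeping a full study ~1 s |
| miRNAs | 25 (1 planted, 2 controls, 22 decoys) | ~50-word lexicon, comparable multiplicity to a focused panel |
| UTR length | Normal(800, 400) nt, min 60 | mouse 3′UTR-like scale |
| GC | 0.42 | mammalian 3′UTR composition |
| baseline expression | Normal(8, 1.5) log2 | typical normalised microarray range |
| planted targets | 100, 1 site each | "dozens to hundreds" of targets per miRNA |
| target effect | −1.5 log2 in mimic | strong but realistic knockdown (3× the noise SD) |
| inhibitor effect | +0.75 log2 | de-repression is weaker than repression |
| stress effect | +1.5 log2 on the stress-up set | clear induction |
| noise | SD 0.5 log2, i.i.d. Gaussian | effects additive on log2 scale — the simplest model consistent with normalised arrays; heavier tails are a config option, not a default |
| replicates | 4 per arm | matches 3–4 biological replicates per condition |
| stress coupling ρ | 0.8 | fraction of the 100-gene stress-up set drawn from planted targets; ρ dials the headline phenomenon from chance to strong |

Each transfected miRNA gets its own mimic/inhibitor arm pair (controls'
arms are pure null), mirroring a panel in which every miRNA is assayed
in its own cultures; calling a control's targets on the planted miRNA's
contrast would instead measure chance word co-occurrence inside the
planted target set. Detection P is 0 for all genes unless a dropout
fraction is configured (those genes get 0.5). All generators are pure
functions of configuration + seed.

What the simulation does **not** emulate: probe-level intensities and
normalisation artefacts, correlated noise across genes, length/GC
dependence of expression, multiple sites with cooperative repression,
isoform-level UTR variation, and real phylogenetic word structure.
Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the stated generative model, not that any
particular biological dataset will show the phenomenon.

## Validation surface

* Hypergeometric tails and overlap P-values match integer-arithmetic
  enumeration over the complete grid N ≤ 12 (max |Δ| ~ 4e-15).
* BH equals the statsmodels reference exactly on 1,000 random vectors.
* Moderated t equals the classical pooled t at d₀ = 0 and the
  Bioconductor reference at estimated (d₀, s₀²); null type-I error sits
  in the binomial band.
* Under permuted (null) rankings, landscape cells with enrichment
  P < 0.05 occur at ≤ nominal rate and the peak clears the Bonferroni
  line in ≤ 5% of 1,000 simulations (the hypergeometric is discrete,
  hence super-uniform: observed rates run ~0.03–0.04).
* At the study conditions, target calling reaches precision/recall
  ≥ 0.9 and the planted miRNA's seed word tops the landscape on the
  correct end of both the mimic and the stress contrast in ≥ 95% of 20
  independent studies; with ρ = 0.8 its target set is enriched in the
  stress-up set at P < 0.001 while the control miRNAs are not.

Problem sizes used by the test-bench (2,000-gene studies, 1,000 null
permutations, 20 replicate studies) are the package's chosen study
conditions; all are recomputed from scratch by `scripts/acceptance.py`.

## Known limitations

* The Markov correction adjusts per-word baselines, not within-ranking
  composition gradients; a ranking correlated with GC content can still
  produce composition-driven peaks (inspect the grey word cloud, not
  just the top word).
* Landscape totals are computed on masked sequence uniformly; if masks
  are word-specific in some upstream pipeline, totals will differ.
* The moderated t assumes equal group variances and independence across
  samples; no array weights or duplicate-correlation structure.
* Probe mapping is exact-match only: a probe whose best alignment needs
  gaps or mismatches within a 30-nt run is dropped rather than scored.
* Fold enrichment is undefined (reported 0 with log2 = −inf) when a set
  is empty after universe restriction; such cells are flagged
  untestable instead of contributing to the BH batch.
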