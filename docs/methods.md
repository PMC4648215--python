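# Methods

## Analysis model

Each sample is a collapsed clone table: one row per clonotype with its
CDR3 nucleotide and amino-acid sequence, gene-level V/D/J calls, a
count (template counts preferred over read counts when a `templates`
column is present), and a frequency defined as count over the sample
total. All statistics operate on productive clones by default
(in-frame, stop-free junctions), with frequencies renormalised after
filtering; a flag retains all frames.

Diversity follows the entropy family: Shannon entropy
`H = −Σ P_i log2 P_i` in bits, `H_max = log2 N`, evenness
`H_N = H/H_max`, clonality `C = 1 − H_N`. Entropy is computed on
observed frequencies with no coverage correction. Boundary
conventions: a single-entry vector has `H = 0` exactly; a singleton
repertoire (`N = 1`, where `H_N` is 0/0) is assigned `C = 1`, the
maximal-concentration limit consistent with the statistic's upper
boundary. Floating-point round-off is clamped so `C` stays in [0, 1].

Clone identity is deliberately dual. `nt_vj` = (CDR3 nucleotide, V
gene, J gene) is the default for collapsing, counting and
within-patient paired comparison; the D call is excluded because it is
frequently unresolved and absent for the γ-chain. `aa_only` = CDR3
amino acid is the default for cross-patient analyses (pooled overlap,
public clones), since convergent recombination produces identical
amino-acid junctions from different nucleotide rearrangements. Allele
suffixes (`*01`) are stripped and the first gene of an ambiguous
comma-separated call is kept, giving gene-level comparisons
throughout.

Overlap between two repertoires is the Jaccard index on unique clone
keys. The wording "normalized to total number of sequences" admits
several readings; Jaccard was chosen as the symmetric, [0, 1]-bounded
one, with shared-over-smaller (`min`) and abundance-weighted
Morisita–Horn (`morisita`) exposed as options. Overlap is
presence-based by design: pooled comparisons ask whether clonotypes
recur across people, not how abundant they are. When pooling all
pairwise scores into the six comparison groups, within-patient NL-LS
pairs are flagged and excluded from the pooled NL-LS group — a
patient's own non-lesional/lesional sharing would otherwise inflate
the between-patient signal.

Inference mirrors a standard small-cohort analysis: two-tailed
pooled-variance Student's t-tests ("unpaired t-test" read literally;
Welch is an option), one-way ANOVA for the pooled overlap groups
followed by pairwise t-tests, SEM as sd(ddof=1)/√n, significance at
raw p < 0.05 with no multiple-testing correction; the report records
the number of tests performed. Degenerate inputs (zero variance
everywhere) return p = 1 with a `degenerate` flag instead of raising,
so simulated edge cases cannot abort a pipeline run. When the group
means differ but every within-group variance is zero, the statistic is
reported as ±inf with p = 0 and the same flag.

## Synthetic cohort generator

The generator emulates the statistical structure of a three-group skin
study so every downstream stage has a deterministic, download-free
test surface. Study defaults (`study_config`): 7 normal / 5
non-lesional / 8 lesional samples, the first five psoriatic patients
contributing a paired NL+LS biopsy; group richness means 2700 / 3200 /
10900 unique clones for the β-chain and 397 / 558 / 1570 for the
γ-chain; three public amino-acid clones injected into every psoriatic
γ sample (none for β).

Mechanics, per sample:

1. latent richness drawn from a gamma distribution around the group
   mean with coefficient of variation `richness_dispersion`
   (default 0.25 — chosen for plausible between-patient spread; the
   study reports no within-group variance, so this is a stability
   choice, not a fit);
2. latent clone frequencies are normalised i.i.d. Pareto weights with
   tail exponent `freq_shape` (one-parameter heavy tail spanning
   polyclonal → oligoclonal; shape → ∞ approaches uniformity);
3. observed counts are one multinomial draw of `depth` templates
   (default 20× the richness mean) from the latent frequencies;
   zero-count clones are dropped, so observed richness is
   depth-dependent, mirroring the sensitivity of repertoire richness
   to sampling depth;
4. clone skeletons are random in-frame CDR3s of 27–54 nt (uniform over
   multiples of 3, codons uniform over the 61 sense codons, translated
   with the standard genetic code), with V/J labels sampled from
   fixed, arbitrary-but-logged usage weights per chain; key uniqueness
   within a sample is enforced by a bounded regeneration loop.

Clonality calibration. For normalised i.i.d. Pareto(a) weights the
expected entropy is asymptotically `log2 n − D(a)` with
`D(a) = [1/(a−1) − ln(a/(a−1))]/ln 2`, so expected clonality
`≈ D(a)/log2 n` falls as richness grows at fixed shape. A cohort with
one shared shape therefore cannot show equal clonality across a 3-fold
richness gap in expectation. Because comparable clonality across
groups is part of the structure being emulated, `study_config` solves
`D(a_g) = C* · log2(n_g)` per group (Brent's method on the closed
form) for a common target clonality `C* = 0.08`, a low, polyclonal,
skin-like value. The calibration is asymptotic and ignores the small
concentration added by multinomial subsampling; realised group mean
clonality lands near 0.06–0.08 at study scale. Passing an explicit
shared `freq_shape` disables calibration, and the resulting group
clonality means still differ by well under 0.05 at study-like scales.

Paired samples share a latent clone pool covering
`paired_sharing_rate` of the lesional latent richness (default 0.1,
i.e. ~30% of the non-lesional repertoire at the default 3-fold
richness gap; rates demanding more shared clones than the smaller
repertoire holds raise a parameter error). Shared-pool frequencies in
the two tissues are coupled by a Gaussian copula with correlation
`paired_freq_correlation` (default 0.8) over Pareto marginals, giving
rank-correlated abundances — abundant lesional clones tend to be
abundant non-lesionally. Private clones are drawn independently per
tissue; both samples are then subsampled independently.

Public clones are `n_public_clones` amino-acid sequences appended to
every psoriatic (non-lesional and lesional) observed sample — never to
normal samples — each with a freshly drawn synonymous nucleotide
sequence per sample, so `aa_only` sharing is high while `nt_vj`
sharing stays low. Injection happens after subsampling at
`public_clone_freq` (default 0.002) of the sample total, with counts
floored at 1 and frequencies renormalised, so presence in every
psoriatic sample is guaranteed rather than probabilistic.

All randomness flows through one `numpy.random.Generator` seeded from
the config; whole-cohort generation is bit-reproducible given the
seed.

What the generator does not model: non-productive rearrangements
(every simulated clone is in-frame; frame handling is exercised by
hand-built fixtures), biophysical V(D)J recombination (insertions,
deletions, thymic selection), PCR/sequencing error structure, real
gene-usage distributions, and any clinical covariates. Passing tests
on synthetic cohorts therefore demonstrate the pipeline's estimators
and bookkeeping under a controlled abundance model, not fidelity to
any real repertoire.

## Problem sizes and numerical choices

Study-scale property checks run on the γ-chain configuration (the
chain carrying the public-clone and overlap findings, and the smaller
one): 100 seeded cohorts of 20 samples for power, clonality-null and
public-clone recovery checks, the first 50 for richness-ratio
recovery; type-I calibration uses 2000 replicates of three-group null
draws at the study group sizes. The β-chain is exercised by smoke
tests at reduced richness. Frequency-closure tolerance is 1e−6;
entropy oracle agreement is asserted at 1e−12. TSV round-trips
preserve (key, count) multisets exactly; frequencies are always
recomputed from counts on read, so serialisation precision of the
frequency column is irrelevant.

## Known limitations

- The overlap score definition and the clone-identity definition are
  package choices among defensible readings; both are options, and
  defaults are documented above rather than asserted as canonical.
- Pareto-tail shapes below 2 have infinite variance; per-sample
  clonality is correspondingly volatile at small richness. This is
  intentional (heavy tails are the realistic regime) but means
  single-seed clonality values should not be over-interpreted.
- No rarefaction, Hill numbers beyond Shannon, coverage estimators, or
  post-hoc multiple-comparison procedures; the inference layer matches
  the simple t-test/ANOVA design it reimplements.
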