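# Methods

## Band typing and summary statistics

Each MSAP locus is observed as a presence pair (EH, EM) across the
EcoRI+HpaII and EcoRI+MspI digests. The four-entry lookup to band types
I–IV is total over {0,1}²; any non-binary call raises an error naming the
locus rather than being coerced. Observations with either digest unscored
are flagged missing and excluded listwise from all counts and denominators
(gel scoring only admits clear, reproducible fragments; a partial pair
carries no usable state), with the exclusion count carried on the result.

The three percentages are computed at full precision; `msap_pct` is stored
as `full_pct + hemi_pct` so the additivity identity holds exactly in
floating point (the direct formula agrees to one ulp). Display rounding is
one decimal, half away from zero, applied only at the presentation layer —
all internal comparisons use full precision.

Type IV (absence in both digests) is counted as fully methylated by
default, matching the standard MSAP reading; `include_type_iv=False` drops
it from numerator and denominator for the alternative reading that double
absence may reflect sequence change rather than methylation.

The bundled count tables reproduce their own printed percentages to one
decimal in most cells; a minority of printed cells (e.g. Nipponbare shoot
control total methylation 46.4 vs recomputed 46.33, IR29 root control 21.9
vs 21.96) are off their own counts by up to ~0.09 under any single rounding
rule. The toolkit computes from counts and documents the discrepancy; tests
assert those cells within ±0.15 and all others at printed precision.

## Transition patterns

The 16-row quad lookup (control EH, control EM, stress EH, stress EM →
class A–P) is exhaustive and unambiguous: 4 classes are no-change (the
digest pair is preserved), 6 demethylation (a band is gained under
stress), 6 methylation (a band is lost). Group percentages divide by the
grand total over all sixteen classes — including the doubly-absent class
D — not by the per-condition amplified-band total; the two differ when
loci are excluded. Loci with any NA in the quad, or mismatched locus ids
between conditions, are skipped with a logged count rather than an error.

## Independence testing

Pearson χ² and the likelihood-ratio G statistic are computed through
`scipy.stats.chi2_contingency` with no continuity correction by default
(a Yates flag exists for 2×2 tables); p-values come from the asymptotic χ²
upper tail with df=(r−1)(c−1), with no exact test and no multiple-testing
correction across genotype×tissue combinations. Adjusted standardized
residuals are implemented directly from the closed form
(O−E)/√(E(1−row/n)(1−col/n)) and cross-checked against
`statsmodels.stats.Table.standardized_resids` in the test suite. Zero row
or column margins raise a degenerate-table error before any statistic is
computed.

The level-by-treatment builder defaults to a 3×2 table pooling band types
III and IV into one "fully methylated" level — the contrast of interest is
unmethylated vs hemi vs full — with a 4×2 variant (`pool_full=False`)
keeping III and IV separate, since either row structure is defensible for
this family of designs.

## Bisulfite calling

Only the top strand is modelled, as amplicon bisulfite sequencing with a
forward primer reads that strand; the context classifier takes the
reference and a position, so a bottom-strand (G→A) mode can be added
without changing call semantics. Context is CG if the next base is G, CHG
if base+2 is G with an intervening H, CHH if both following bases are H;
a C whose needed neighbours fall off the 3′ end or are N is "undefined"
and excluded from percentages. Context is a function of the reference
only — conversion in the read never changes a site's context.

Alignment is global (Needleman–Wunsch via Biopython's `PairwiseAligner`)
with an asymmetric substitution matrix scoring reference-C/read-T as a
match (+1), other identities +1, mismatches −2, gap open −5, gap extend
−1; N scores 0 against everything. The highest-scoring alignment is taken
(Biopython's enumeration order makes this deterministic). Alignments whose
identity over matchable columns falls below 0.70 are rejected as
low-quality rather than silently producing garbage calls.

Calls are strictly three-valued: read C → methylated, read T →
unmethylated, anything else (gap, mismatch, N) → ambiguous; ambiguous
calls enter no numerator or denominator. Sanger consensus traces with
heterogeneous peaks are therefore not resolved into partial methylation —
the input convention is one consensus sequence per sample, and multiple
reads are combined by per-position majority vote with ties ambiguous.
Incomplete conversion is reported as a QC estimate (1 − the CHH
"methylated" fraction, since CHH methylation is rare) and never used to
adjust calls. Positions are 1-based on the reference throughout.

## ddCt expression

Technical replicates are averaged in Ct space **before** the ΔCt
subtraction (the common convention; the alternative — averaging per-tech
folds — is biased upward because 2^x is convex, and a test pins the
implemented choice). The fold is computed per biological replicate and
summarised by mean and sample SD (ddof=1; with two replicates this equals
half the range times √2). Amplification efficiency is fixed at 2 per
cycle, as the ddCt model assumes; no efficiency correction is applied. The
reference gene is a parameter (eEF1α in the motivating experiments), never
hard-coded. Non-finite or non-positive Ct values ("Undetermined" wells)
are dropped with a warning; a biological replicate missing any of its four
condition×gene means is skipped, and a result requires at least one
complete replicate.

## Synthetic data

The band-matrix generator draws a latent control state per locus
(unmethylated / hemimethylated / full-internal-CG / full-both), a stress
state from a 4×4 row-stochastic transition matrix, emits the (EH, EM) pair
of each state deterministically (the inverse of band typing), and flips
each of the four digest calls independently with the scoring-noise
probability — per call, not per locus, because gel-scoring errors are
digest-specific. The default regime is derived programmatically from the
bundled IR29 shoot pattern counts: each class A–P fixes both latent
states, so the empirical 4×4 joint yields the control state probabilities
(margins) and transition matrix (row-normalised). This gives a realistic
shoot-like demonstration regime (control MSAP ≈ 59%, about half the loci
unchanged under stress) and is clearly a simulation, not deposited data.
Default sizes are 5000 loci and 2% scoring noise. States never observed in
control get identity transition rows (their probability is zero, so the
row is inert but keeps the matrix stochastic).

`expected_class_probs` computes the exact class distribution implied by a
config by enumerating the 16-cell joint over state pairs and pushing it
through the per-call flip channel; recovery tests compare simulated
frequencies against it at 3 binomial SDs.

The bisulfite generator methylates each reference C independently with its
context probability (undefined contexts use the CHH rate), emits
methylated C as C and unmethylated C as T with the conversion rate (else C,
modelling non-conversion), and records per-read, per-position truth. It
does not model sequencing error, chimeric reads or PCR bias, so passing
recovery tests demonstrate calibration of the caller under clean
conversion chemistry, not robustness to base-calling noise.

The Ct generator holds the reference gene at a constant baseline and
offsets each target's stress Ct by −log₂(fold), with independent Gaussian
noise per technical replicate (default SD 0.2 cycles, a typical SYBR
plateau-method spread; defaults of two biological × three technical
replicates match the motivating experimental design). Gaussian Ct noise
makes the recovered fold slightly log-normal-biased upward (≈1% at SD
0.2); the recovery test allows for this known convexity bias.

All generators use a single `numpy.random.default_rng(seed)` stream;
identical seeds reproduce outputs bit-for-bit.

## Problem sizes

Monte-Carlo checks use 1000 replicates at n=1000 for the type-I error
calibration, 50 reads × 300 bp for bisulfite recovery, 100 simulated
experiments for ddCt recovery, and 5000 loci for end-to-end pattern
recovery — sizes at which binomial error bands are tight enough to be
informative while the whole suite runs in seconds.

## Known limitations

- No bottom-strand or genome-scale bisulfite mode; this is amplicon-scale.
- No partial-methylation calls from heterogeneous Sanger peaks.
- Percent summaries assume the Type IV = fully methylated reading unless
  opted out; neither reading can distinguish methylation from indel loss
  at a locus without sequencing.
- The χ² machinery offers no exact test; very sparse tables should be
  pooled before testing.
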