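# Methods

## Design and data model

The pipeline targets a factorial small RNA-seq design: genotype ∈
{tolerant, sensitive} × condition ∈ {NT, HT} × stage ∈ {SCP, MP, MRP, PM},
one library per cell by default (16 libraries; H1–H4/T1–T4 are the
tolerant/sensitive HT libraries, HC/TC their NT controls). Counts are
miRNA × library integers; the per-library normalization denominator is the
library's total mapped reads, which may exceed the miRNA column sum because
totals include non-miRNA small RNAs.

"TPM" throughout is counts-per-million of total mapped reads
(`count / total × 1e6`). No transcript length enters the computation; the
label follows the convention of the small RNA literature this pipeline
serves. Columns sum to 1e6 exactly when totals equal column sums, a property
the tests enforce at 1e-9 relative tolerance.

## The replicate-free exact test

With one library per design cell there is no within-group variance to
estimate, so the default test conditions on what is observed: for a miRNA
with counts (a, b) in libraries with totals (t_a, t_b), conditional on
n = a + b, the null distribution of a is hypergeometric (choosing n reads
from t_a + t_b). The two-sided p-value sums P(k) over all k in the support
with P(k) ≤ P(a) — the minimum-likelihood ordering also used by Fisher's
exact test.

Implementation: tables with t_a + t_b ≤ 4000 are evaluated in exact integer
arithmetic (the p-value is a ratio of big-integer sums, so it matches
enumeration bit for bit); larger tables use vectorized log-pmf via
`gammaln` with a 1e-7 relative tie tolerance. The tests cross-check the
float path against `scipy.stats.fisher_exact` (agreement ~5e-8 relative)
and the integer path against exhaustive enumeration of **all** 2×2 tables
with totals ≤ 60. The in-package implementation exists because the screen
runs ~6×10⁵ tests in the calibration studies and the scipy routine is an
order of magnitude slower per large-margin table.

Assumption and caveat: conditioning is exact for Poisson sampling noise.
Biological overdispersion between unreplicated libraries is *not*
distinguishable from signal — the classic limitation of replicate-free
designs — so the measured Type-I error is nominal (~4–5% at α = 0.05) only
in the Poisson regime. The null-calibration study therefore runs at
dispersion 0; with the default dispersion 0.05 the screen's raw p-values
are anti-conservative, which the fold-change filter only partly offsets.
With ≥ 2 replicates per side the pipeline switches to a Welch t-test on
log₂(TPM + pseudocount); mixed designs pool counts within a side and use
the exact test.

Screening thresholds are inclusive as printed: p ≤ 0.05, FC ≥ 2 or ≤ 0.5 on
(mean TPM + 1)/(mean TPM + 1). The pseudocount (default 1 TPM) guards
against zero denominators and is configurable. No multiple-testing
correction is applied by default — the screen is a per-contrast filter, not
a discovery set with FDR semantics — but Benjamini–Hochberg is available
(`adjust="bh"`).

## Family classification

The seed (nucleotides 2–8 from the 5′ end) defines membership for entries
without a name token. A parseable token ("miR" + number, ignoring species
prefix, "-novel-" infix, member letter, arm suffix) always wins, because
known and novel members of a numbered family belong together regardless of
seed drift. Unnamed records cluster single-linkage on seed identity (exact
by default; one mismatch opt-in). Identical-sequence records share a
group_id, are reported joined with " > " (ordered by descending mean
abundance — the ordering inside joined names is a reporting convention,
recorded in the run summary), and can never split across families; a
group spanning two name tokens is a validation error rather than a silent
override.

## Genotype adjustment and family rates

"Responsive" at a stage means: HT-DE in the tolerant-vs-sensitive contrast,
minus genotype-specific changes. The default removal mode excludes an HT-DE
miRNA only when it is NT-DE in the *same* direction, on the reasoning that
an HT-induced reversal of a genotype difference is itself a response; the
stricter `any_de` mode (exclude on any NT call) is first-class because the
underlying definition is genuinely ambiguous, and `any_de` output is
provably contained in `same_direction` output.

A family's abundance rate at a stage is its responsive members' mean TPM
over that stage's HT libraries, divided by the same sum over all responsive
miRNAs, × 100. HT libraries anchor the rates because the response is
defined under HT; the NT+HT mean is configurable. Families without a
responsive member are absent from the table, not 0%. Main regulators are
families with rate strictly > 10% ("more than 10%" is a strict inequality,
verified at the boundary in the tests).

## Synthetic data

The generator emulates the study conditions: 16 unreplicated libraries,
5×10⁶ reads each (configurable mean and CV), per-miRNA baseline TPM
lognormal with log₂-mean 5 and log₂-sd 2, gamma-Poisson (negative binomial)
counts with dispersion α so that var = μ + αμ² (default α = 0.05, a mild
technical-plus-biological overdispersion; α = 0 gives the Poisson limit
used in closed-form checks). Planted HT effects multiply the tolerant
line's expectation by 2^(±log₂FC) under HT at one stage for every member of
a seed-sharing family; planted genotype effects do the same for a single
miRNA under both conditions. Read-length histograms are multinomial over
16–30 nt with 42% mass at 24 nt and 15% at 21 nt (24/21 ratio 2.8, inside
the 2.6–7.5 range reported for cotton anther libraries), the remainder
uniform. All randomness derives from one integer seed via per-operation
`default_rng([seed, stream])` streams, so outputs are reproducible and
independent of call order.

What the generator does **not** emulate: correlated dispersion across
miRNAs, GC/length sequencing bias, adapter artifacts, mapping ambiguity
between paralogous loci, compositional coupling between miRNAs, or
developmental autocorrelation between stages. Passing recovery tests
therefore demonstrates the correctness of the screen's logic under its own
statistical assumptions, not robustness to real-data artifacts.

Study sizes used by the calibration/recovery studies: 2,000 null contrasts
× 300 miRNAs for Type-I error; 200 runs of a 24-miRNA catalog with five
planted (family, stage) effects at |log₂FC| = 3 and 512 TPM baseline plus
four genotype-specific miRNAs for sensitivity/specificity. These sizes give
Monte-Carlo standard errors well below the acceptance margins while keeping
a full run to a few minutes on one CPU.

## qPCR quantification

2^(−ΔΔCt) with ΔCt = Ct(target) − Ct(reference) per sample and ΔΔCt the
difference of group means (treatment − control; aggregation order — mean of
per-sample ΔCt — is a choice, as is the single-reference design; the
multi-reference geometric-mean variant is out of scope). The spread
reported is the propagated standard error of ΔΔCt over replicates
(default 3). Amplification-efficiency correction is deliberately absent:
the method is the plain comparative one. Swapping groups inverts the result
exactly.

## Numerical and degenerate-input choices

* Exact-test ties compare pmf values with a 1e-7 relative tolerance in the
  float path (exact comparison in the integer path); p-values are clipped
  at 1.0.
* n = 0 (both counts zero) and single-point supports return p = 1.
* Welch t on two identical constant groups returns p = 1 (the statistic is
  0/0; "no evidence" is the only sensible reading).
* The expression floor keeps a miRNA at exactly TPM = 10 ("removed if < 10
  in all samples"); abundance bands use ≥ at both thresholds.
* An empty responsive set yields an empty rate table, never a 0/0.
* Library IDs are free-form strings; the H/T/HC/TC dialect appears only in
  generated data and examples.

## Known limitations

* Per-stage responsive counts from any real dataset depend on the DE test
  chosen; the exact conditional test is a defensible default, not a
  reconstruction of any particular study's unstated machinery.
* Name-token precedence over seed evidence is an assumption; a catalog
  whose naming disagrees with its sequences will follow the names.
* The unreplicated test's calibration degrades with overdispersion (see
  above); for designs with replicates, use them.
* Between-library normalization is library-size scaling only; no TMM or
  quantile normalization.
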