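# Methods

## Scope and data model

The package operates entirely at the summary level: each trait is a table of
per-variant association records (variant, alleles, effect-allele frequency,
beta, SE, p, sample sizes), and every analysis consumes a *harmonised set* —
exposure and outcome effects for the shared instruments, aligned to a common
effect allele. Exposure effects are per SD of the exposure; binary-outcome
effects are log-odds ratios, so a causal estimate exponentiates to an OR per
SD (OR_SD).

## Instrument QC

Instruments must pass `p < 5e-8` (strict) and minor-allele frequency
`> 0.01` (strict). LD pruning is greedy: variants are visited by ascending
p-value (ties broken lexicographically on variant ID, for determinism) and a
variant is kept only if its squared correlation with every previously kept
variant is at most 0.01. The LD matrix is a required input — there is no
reference-panel lookup; the synthetic module generates matching matrices.
Instruments with exposure F-statistics below 10 are removed before
estimation.

Harmonisation resolves label swaps (outcome beta negated, frequency
complemented), strand flips (alleles complemented before matching), and
combinations of the two. Palindromic variants (A/T, C/G) cannot be resolved
by strand, only by frequency: they are dropped when the minor-allele
frequency is ≥ 0.42 on either side (orientation indeterminate) and otherwise
oriented by frequency agreement. Unresolvable allele pairs are dropped and
counted, never silently kept. Harmonisation is idempotent, and relabelling
alleles in an input (with the corresponding sign/frequency flip) cannot
change the harmonised output.

## Estimators

All multi-instrument estimators weight by the outcome-side precision
1/s²_Yj, ignoring exposure-side uncertainty (the standard first-order
convention; the Wald-ratio SE is likewise first order, s_Yj/|b_Xj|).

* **IVW-RE.** Weighted regression through the origin. The random-effects
  dialect is multiplicative: the fixed-effect SE is scaled by
  `max(1, sqrt(Q/(J-1)))`, so balanced heterogeneity widens intervals but
  under-dispersion never narrows them. This floor makes the test slightly
  conservative in calibrated simulations (type-I ≈ 4–4.5% at nominal 5%),
  which is the accepted trade-off of the dialect.
* **Weighted median.** Ratio estimates sorted with standardised cumulative
  weights `s_j = (Σ_{k≤j} w_k − w_j/2)/Σw`, linearly interpolated at 0.5.
* **Mode-based estimate.** Arg-max of the inverse-variance-weighted normal
  kernel density over ratio estimates evaluated on a 2,048-point grid
  spanning the ratio range ± 3 bandwidths; the bandwidth is a modified
  Silverman rule `0.9·min(sd, MAD/0.6745)·J^(−1/5)` times a tuning factor φ
  (default 1). If all ratios coincide the bandwidth degenerates and that
  common value is returned.
* **Bootstrap SEs** (median and mode): parametric — instrument effects
  resampled from normals centred at the observed values with their SEs —
  1,000 replicates by default, seed mandatory, bit-reproducible.
* **MR-Egger.** Weighted regression with intercept after orienting every
  instrument to positive exposure effect; the same multiplicative SE floor
  on J−2 df; inference uses a t distribution with J−2 df (the intercept
  consumes a parameter), while all other estimators use normal inference.
* **Steiger.** Per-variant variance explained is `2p(1−p)b²` on continuous
  traits; binary traits are put on the observed scale by multiplying by
  `K(1−K)`, with K the outcome's lifetime risk supplied in configuration
  (default 0.05, the order of common-cancer lifetime risks). The p-value
  compares the implied multiple correlations through Fisher's z with the two
  sample sizes.
* **Power.** Two-sided normal approximation for a binary outcome: the MR
  SE is ≈ `1/sqrt(N φ(1−φ) R²)` (φ = case fraction, R² = exposure variance
  explained), giving non-centrality `|β|·sqrt(N φ(1−φ) R²)`. Power equals α
  exactly at β = 0 and is monotone in N, R² and |β|.

Dispatch: 1 instrument → Wald ratio; ≥ 2 → IVW-RE plus Cochran's Q; ≥ 3 adds
weighted median, mode, Egger and leave-one-out IVW diagnostics.

## Multivariable MR

`mv_ivw` solves the weighted normal equations for the outcome effects
against the J×K exposure-association matrix, no intercept, weights 1/s²_Y,
with the same multiplicative SE floor on J−K df. Rank deficiency raises an
error naming the dependent exposures. Instruments are merged across
exposures by intersection (complete-case; documented limitation — no
imputation of missing exposure associations). Conditional F for exposure k
is the weighted residual sum of squares of its associations regressed on the
other exposures' associations (precision-weighted by 1/s²_Xk, whitened by
the instrument correlation matrix when one is supplied), divided by J−K+1;
an exact linear combination scores ~0, and with K=1 it reduces to the mean
marginal F. Conditional F < 3 flags the exposure as weak at report level
rather than raising.

## Colocalisation

Wakefield log approximate Bayes factors
`0.5(log(1−r) + r z²)`, `r = W/(V+W)`, with prior effect SD √W defaulting to
0.20 for quantitative and 0.15 for binary traits. Hypothesis evidence is
accumulated entirely in log space (logsumexp; H3's product-minus-shared term
via a stable log-difference), so regions with |z| up to 50 and 10⁴ variants
cannot overflow. Priors default to p₁ = p₂ = 10⁻⁴, p₁₂ = 10⁻⁵; a posterior
≥ 0.80 classifies a region as shared (H4) or distinct (H3), otherwise
indeterminate. Colocalisation is gated on the cis instrument reaching
p < 10⁻⁶ in the outcome; the cis window is the gene body ± 1 Mb, 1-based
inclusive.

## Evidence grading

The four-tier rule for continuous exposures is applied exactly as stated in
the README, with strict inequalities everywhere (a p-value of exactly 0.05
fails). The Bonferroni denominator defaults to 3,500 tests (configurable),
giving the robust cutoff 1.4×10⁻⁵. The Steiger direction requirement applies
to robust and probable only; single-instrument significant results are
always suggestive. The Egger intercept is reported but is not a gate. Every
grade carries an ordered rule trace sufficient to re-derive it. Binary
exposures: supported iff p < 0.05; effects reported on the beta/SE scale
with ORs for consistency only.

The phenome-wide driver grades one row per exposure–outcome pair, exports a
Z-statistic (beta/SE) matrix for external clustering/heatmaps, counts grades,
and records per-pair drop reasons; unreadable manifest entries are skipped
and counted, not fatal.

## Synthetic data

The generator emulates a two-sample design directly at the summary level.
Per instrument: frequency p_j ~ U(0.05, 0.5); true exposure effect
γ_j ~ N(0, γ_sd²) with γ_sd = 0.05; exposure sampling SE
`1/sqrt(2p(1−p)·n_exp)` with n_exp = 300,000; outcome (binary) SE
`1/sqrt(2p(1−p)·N·φ(1−φ))` with 60,000 cases and 60,000 controls. True
outcome effects are `Γ_j = β·γ_j + sign(γ_j)·a_j` with
a_j ~ N(μ_α, σ_α²): the pleiotropic term acts in the
exposure-increasing-allele frame (the frame MR-Egger regresses in), because
a "directional" mean defined against arbitrary allele labels would cancel
under re-orientation and be unrecoverable by construction. Exposure and
outcome draws are independent (no sample overlap). Defaults give mean
instrument F in the hundreds and ~35–40 instruments surviving genome-wide
selection from J = 50, comparable to a well-powered anthropometric trait.

What the generator does **not** emulate: real allele-frequency spectra,
winner's curse in instrument discovery, sample overlap, population
stratification, or LD between instruments and outcome causal variants
beyond the AR(1) toy structure. Passing calibration tests therefore
demonstrates internal statistical correctness of the estimators and the
decision procedure, not robustness to those real-data pathologies.

Colocalisation regions plant one causal variant per trait (same index when
shared, indices J/2 apart when distinct) with causal |z| = 8, propagate
marginal z-scores through AR(1) LD (ρ = 0.5, J = 200 by default), and draw
observed z ~ MVN(Rz_true, R).

## Replicate-study problem sizes

The calibration harnesses use 500 replicates for bias/coverage and Egger
recovery, 2,000 for type-I error, 100 regions per colocalisation scenario,
and 100 traits for the null sweep (bootstrap reduced to 200 replicates
there, since only the IVW/WME/MBE p-value gates matter at scale). These
sizes put Monte-Carlo error well inside the decision margins while keeping
any single study under a minute on one core. Replicate seeds are spawned
from one master seed via `numpy.random.SeedSequence`, so every number is
reproducible from a single integer.

## Known limitations

* No MR-PRESSO, SIMEX-Egger, contamination-mixture or correlated-instrument
  (generalised) IVW estimators; no MVMR-Egger.
* Single-causal-variant colocalisation only (no SuSiE-style multi-signal
  decomposition, no LD-aware fine-mapping).
* Triple matching is exact string match after case-folding — no concept
  normalisation, so synonyms are distinct terms.
* The binary-trait Steiger conversion is a linear-probability approximation;
  liability-scale alternatives would shift r² by a scale factor but rarely
  the direction verdict.
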