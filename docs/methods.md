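# Methods

## Estimands and estimators

The package estimates the causal effect $\theta$ of an exposure on an
outcome from two-sample GWAS summary statistics. Per instrument $j$ the
observed pair is $(\hat\gamma_j, \hat\Gamma_j)$ with standard errors
$(\sigma_{Xj}, \sigma_{Yj})$; the working model is
$\Gamma_j = \theta\gamma_j + \alpha_j$, where $\alpha_j$ is a direct
(pleiotropic) effect that is zero for a valid instrument.

**IVW.** Weighted least squares of $\hat\Gamma$ on $\hat\gamma$ through
the origin, weights $1/\sigma_{Yj}^2$ (first-order: exposure-side noise
is ignored in the weights). Two variance models:

* *fixed*: $\mathrm{SE}^2 = 1/\sum_j \hat\gamma_j^2/\sigma_{Yj}^2$;
* *multiplicative random effects* (default): the fixed SE multiplied by
  $\max(1, \sqrt{Q/(J-1)})$, so heterogeneity widens but never narrows
  the interval.

The default matches common two-sample MR practice when the published
analysis does not state a variant. P-values use the standard normal
reference. A single usable instrument degrades to the Wald ratio.

**MR-Egger.** Each pair is recoded so $\hat\gamma_j > 0$ (both effects
flipped when negative) — the orientation convention that makes the
intercept identifiable — then weighted linear regression with intercept,
weights $1/\sigma_{Yj}^2$ (computed via statsmodels WLS; the normal
equations are unit-tested against an independent solver). SEs are the
unscaled WLS SEs times $\max(1, s)$ where $s$ is the residual SD, and
both slope and intercept are tested against $t_{J-2}$ — conservative for
the small instrument counts typical of protein exposures. The intercept
estimates the average directional pleiotropy on the
exposure-increasing-allele orientation; intercept $P > 0.05$ is read as
no detectable directional pleiotropy.

**Weighted median.** Ratio estimates $\hat\theta_j$ sorted ascending with
normalized weights $w_j \propto \hat\gamma_j^2/\sigma_{Yj}^2$
(first-order; second-order weights including the exposure SE are
available behind a flag). The estimate is the linear interpolation of the
50% crossing of the midpoint cumulative weights $\sum_{i\le j} w_i - w_j/2$.
The SE is a parametric bootstrap: both effects of every pair resampled
from $\mathcal N(\text{observed}, \text{SE})$, 1,000 replicates by
default, seeded (default seed 0) so runs are reproducible. The point
estimate is exactly equivariant under sign flips of the outcome; the
bootstrap SE is equivariant only in distribution, since finite replicates
reuse one noise stream.

**Sensitivity.** Cochran's $Q$ with first-order weights around the IVW
estimate ($\chi^2_{J-1}$ upper tail); leave-one-out IVW with an outlier
flag raised when any exclusion flips the estimate's sign or moves its
p-value across 0.05; for binary outcomes, estimates are exponentiated to
odds ratios with symmetric 95% Wald bounds ($\pm1.96\,\mathrm{SE}$ on
the log scale — the multiplier is fixed at 1.96 throughout).

## Instrument selection

Genome-wide threshold $P < 5\times10^{-8}$; when fewer than `min_count`
(default 3, the smallest count admitting MR-Egger) variants pass, the
threshold relaxes to $5\times10^{-6}$. Greedy clumping: repeatedly take
the smallest-p remaining variant as index (ties by lexicographic variant
id, for determinism) and remove same-chromosome variants within
10,000 kb with $r^2 \ge 0.001$ against it. The LD matrix is an explicit
input (file or simulator); pairs absent from it count as unlinked with a
warning, and no reference-panel computation is attempted. Variance
explained is $2\,\mathrm{MAF}(1-\mathrm{MAF})\beta^2$ with the supplied
beta (assumed SD-standardized for molecular exposures; no internal
re-standardization). The $F<10$ exclusion is applied per variant with
$k=1$; the aggregate $F$ (summed $R^2$, $k$ = instrument count, median
$n$) is reported but not used for filtering, since the weak-instrument
exclusion is defined per SNP while the formula's $k$ covers the
aggregate reading — both are surfaced.

## Harmonization

Non-palindromic pairs are resolved from allele letters alone, before or
after complementing the outcome's alleles; a swapped orientation flips
the outcome beta's sign and replaces its frequency with one minus it.
Palindromic variants are oriented by allele frequency: after letter
alignment, effect-allele frequencies on opposite sides of 0.5 imply a
hidden strand flip and one more sign flip. Palindromes are dropped as
ambiguous when either frequency is missing (no guessing) or both lie in
$[0.42, 0.58]$ — the window (`ambiguity_window=0.08`) is the conventional
default in two-sample MR tooling and is configurable. Irreconcilable
allele pairs are excluded. Attrition counts
(missing/incompatible/ambiguous/analyzed) always sum to the instrument
count. Only biallelic SNVs are handled; indels and multi-allelics are
rejected at I/O.

## Pipeline decisions

* Bonferroni denominator = number of exposures tested in a direction;
  display rounding to two significant figures (0.05/91 prints 5.5e-4,
  0.05/3 prints 0.017).
* Reverse-direction selection uses the same primary threshold and
  fallback rule; disease GWAS are large so the fallback rarely triggers.
* Robustness is the conjunction of the three criteria; a criterion that
  cannot be evaluated (fewer than three instruments) is recorded as
  not-evaluable and fails the conjunction — robustness is never claimed
  on missing evidence. On direction disagreement the IVW estimate stays
  primary. All three methods are always reported; no winner is selected
  silently.
* Cells with no usable instruments produce explicit null calls with a
  reason rather than disappearing from the grid.
* Zero p-values in input are rejected by default; a dialect flag clamps
  them to the smallest positive double instead (avoids silent
  $-\log_{10}$ infinities). Matching across studies is by variant id
  only; no positional or proxy matching.

## The synthetic-data generator

Summary statistics are generated directly on the summary scale:
$\hat\gamma_j \sim \mathcal N(\gamma_j, \sigma_{Xj}^2)$,
$\hat\Gamma_j \sim \mathcal N(\theta\gamma_j + \alpha_j, \sigma_{Yj}^2)$,
with the analytic GWAS standard error
$\sigma^2 = 1/(2\,\mathrm{maf}(1-\mathrm{maf})\,n)$. Binary outcomes are
generated on the log-odds scale with effective sample size
$4n\phi(1-\phi)$ for case fraction $\phi$, rather than via
individual-level logistic sampling — closed-form and fast, at the price
of ignoring rare-disease asymptotics. Defaults emulate a plasma-protein
exposure GWAS (n = 14,824) with ~18 instruments against a large binary
outcome (n = 115,803), effect sizes in SD units (`gamma_sd` = 0.15,
giving per-variant F in the tens-to-thousands range typical of pQTLs);
true effects are redrawn until the expected per-variant F exceeds 10, so
generated instruments are valid under the pipeline's own filter.

Directional pleiotropy is parameterized on the exposure-increasing-allele
orientation: the contribution to the reported-allele outcome effect is
$\mathrm{sign}(\gamma_j)\,\alpha_j$ with
$\alpha_j \sim \mathcal N(\mu_\alpha, \sigma_\alpha^2)$. With
allele-symmetric $\gamma$ signs, attaching $\alpha$ directly to the
reported allele would average directional pleiotropy to zero and no
estimator could (or should) recover it; the oriented convention is the
quantity the Egger intercept actually estimates. InSIDE violation adds
$\lambda|\gamma_j|$ to the oriented $\alpha$.

LD is block-constant $r^2$ with blocks spaced beyond the clumping window,
so greedy clumping is fully determined by block membership and p-value
order. Outcome-file corruptions (allele swaps: roles exchanged, beta
negated, frequency complemented; strand flips: letters complemented) are
applied per variant with configured probabilities and logged in the truth
table; harmonization inverts them exactly for non-ambiguous variants,
which the invariance tests exploit at tolerance 1e-12. Corruption flags
are drawn after all effect draws, so changing corruption probabilities
never changes the simulated effects — clean and corrupted runs are
comparable at machine precision under a shared seed. Grids reuse one
exposure draw per row with independently-seeded outcome noise per cell,
as a real exposures-by-outcomes design would.

What the generator does **not** emulate: realistic human LD maps,
winner's-curse selection of discovery-stage instruments, sample overlap
between the two studies, population stratification, or infinitesimal
polygenic background. Passing calibration tests therefore demonstrate
correctness of the estimators and plumbing under the stated model, not
robustness of MR itself to those real-data pathologies.

## Calibration results verified by the test suite

Under $\theta=0.1$, 30 instruments, $n$ = 50,000/100,000, 2,000
replicates: IVW absolute bias below 0.01 and 95% CI coverage within
[92%, 97%] (measured ≈ 95.5–96%; the $\max(1,\cdot)$ truncation makes the
default SE mildly conservative). Under $\theta=0$ with balanced
pleiotropy at $\sigma_\alpha = 0.002$ — a level at which Cochran's Q
stays non-significant in the bulk of replicates, matching the
no-detectable-heterogeneity regime the robustness rule targets — the IVW
type-I error at 0.05 lies within [3.5%, 6.5%] (measured ≈ 5–6%). As
balanced-pleiotropy variance grows to dominate the sampling variance
(e.g. $\sigma_\alpha = 0.01$, $I^2 \approx 80\%$), the multiplicative
variance model is increasingly mis-specified for additive heterogeneity
with unequal SEs and the IVW test over-rejects (≈ 8% observed) — a known
limitation, demonstrated but not asserted. Under directional pleiotropy
$\mu_\alpha = 0.02$ the mean Egger intercept recovers 0.02 within two
Monte-Carlo SEs (300 replicates).

Replicate counts (2,000 / 2,000 / 300) were set so the Monte-Carlo SE is
small against each band's width (≈0.5% on a coverage percentage). The
acceptance script re-runs all of the above from scratch at the caller's
seed.

## Known limitations

* No proxy-SNP lookup, Steiger filtering, MR-PRESSO, multivariable MR or
  contamination-mixture models; the robustness rule is the three-criterion
  conjunction only.
* First-order ratio weights throughout by default; precise exposures with
  noisy instruments may prefer the second-order weighted-median flag.
* LD handling requires a user-supplied matrix; with none supplied,
  clumping reduces to the distance window with all pairs treated as
  unlinked (warned).
* Reproducing published odds ratios for real exposure-outcome pairs
  requires the corresponding external GWAS downloads; the repository
  verifies the identical pipeline path on synthetic stand-ins with known
  truth at the published sample sizes instead.
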