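# Methods notes

This note records the modelling choices behind each stage, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the known limitations. No empirical claim here goes beyond
what the test suite and `scripts/acceptance.py` themselves compute.

## Growth-rate extraction

μ_max is the maximum of the first derivative of a cubic smoothing spline
fitted to ln(abundance) vs time, maximized on a 200-point grid over the
observed interval. The smoothing penalty is chosen by generalized
cross-validation (scipy's `make_smoothing_spline`); series with fewer than
five points fall back to an interpolating cubic spline, which is exact for
noiseless data. The full series is used as recorded — cultures are ended
at the onset of stationary phase, so no additional truncation rule is
applied. Blank correction subtracts the medium blank and drops points at
or below it (no biomass signal on the log scale); a series with fewer than
three surviving points is rejected.

Degenerate inputs: a constant series gives μ_max = 0; log-transforming
makes the estimate invariant to rescaling the abundance unit (cells vs
fluorescence).

## Thermal performance curves

The curve μ(T) = a·e^{bT}·[1 − ((T−z)/(w/2))²] has four parameters: rate
scale a (d⁻¹), exponential sensitivity b (°C⁻¹), quadratic location z
(°C), and niche width w (°C). Fitting is nonlinear least squares with
multi-start initialization — z₀ at the empirically best temperature, a₀
from the maximum observed rate, w₀ from the observed span (×1 and ×1.5),
b₀ ∈ {0, 0.05, 0.1} — keeping the best-SSR converged start. Flat rate
tables drive w toward infinity; a fitted w above 20× the data span is
reported as unidentifiable rather than returned. At least five distinct
temperatures are required (four parameters).

Derived traits are computed strictly inside the tested range (no
extrapolation): T_opt by grid + bounded refinement (the closed-form root
of dμ/dT = 0 is kept as a cross-check); the Tb₈₀ crossings by bisection,
clipped and flagged at a range edge when 0.8·μ_max is not crossed inside
it; E_A as the regression slope of ln μ on −1/(k_B·T_K) over temperatures
below T_opt with μ > 0 (k_B = 8.617×10⁻⁵ eV K⁻¹), evaluated at the
observed gradient temperatures. The definition of E_A from a fitted TPC is
not unique; the Arrhenius-limb regression used here is exposed as its own
function (`activation_energy`) so an alternative convention can be
plugged in, and reproduced E_A values may differ from analyses using a
different convention.

**Bootstrap.** Confidence intervals come from a nonparametric residual
bootstrap: centered residuals, inflated by √(n/(n−p)) for the degrees of
freedom absorbed by the curve, are resampled onto the fitted values with
the temperature design held fixed; each resample is refit from the point
estimate. Case resampling (plain or stratified by temperature) is
available as an option, but on designs of this size (7 levels × 4
replicates) its per-resample perturbation of the design makes the
intervals run systematically short: in a simulation at the synthetic study
conditions, the true T_opt fell inside the stratified-case 95% interval in
86 of 100 runs versus 96 of 100 for the residual scheme. The reported 95%
interval is the basic (pivot) construction 2·θ̂ − q₍₉₇.₅, ₂.₅₎, which
orients skew in the bootstrap distribution correctly (93 vs 96 of 100 for
plain percentile quantiles in the same simulation); `ci_method`
switches back to percentile. Resamples that fail to fit are dropped and
counted; more than 50% failures aborts.

Origin comparisons use Welch's unequal-variance *t*-test on strain-level
trait means, with Welch–Satterthwaite degrees of freedom; p-values are
reported at machine precision.

## Photoperiod reaction norms

Rates are normalized within each origin by that origin's highest achieved
rate (so each origin's maximum is exactly 1), and the two origins' curves
are compared with a reference + difference-smooth additive model. Both
terms are clamped cubic regression splines; the basis dimension defaults
to 5 and may not exceed the number of distinct photoperiods — with the
canonical 5-level design (1, 4, 8, 16, 24 h) the basis saturates the
design, a smoothing penalty has no support, and unpenalized regression
splines with an exact F-test replace the penalized-spline/Wald machinery
that a denser design would call for.

Two structural facts shape the test. First, replicate noise in growth
rates is multiplicative, so the model is fitted on the log scale whenever
all responses are positive (`family='lognormal'`, the default; lognormal
errors are then exactly Gaussian). Second, dividing by the origin's
maximum — a noisy statistic — rescales every observation in that origin
by a common random factor; on the log scale this is a pure origin-level
intercept shift. The deviation smooth is therefore centered (sum-to-zero
over the data) and the origin intercept is excluded from the tested
block, so the F-test covers only genuine shape differences: the log-ratio
of the two reaction norms varying with photoperiod. An identity-scale
Gaussian variant is available for data with nonpositive rates.

Fitted curves, their pointwise difference and its SE are evaluated on a
0.01 h grid; each origin's optimum photoperiod is the grid argmax, with an
uncertainty available from resampling replicates within design cells
(`bootstrap_optimum`). With only five design levels the argmax of the
interpolating smooth between widely spaced levels (16 and 24 h) is
smoother-dependent; optimum estimates are sharp only under denser designs.

## Nitrate uptake

δ¹⁵N (‰ vs atmospheric N₂, R = 0.0036764) converts to atom% via
R_sample = R_ref·(δ/1000 + 1), atom% = 100·R/(1+R); the baseline A₀
defaults to natural abundance (0.3663 atom%) unless a measured t₀ sample
is supplied. The mixing model V_abs = [(A_PN − A₀)/(A_src − A₀)]·PN/Δt
uses the end-of-incubation particulate nitrogen; the incubation (40 min
default) is treated as short enough that A_src stays constant (no isotope
dilution). Source-pool atom% per substrate level follows the label recipe
— 1:1 ¹⁴N:¹⁵N for additions ≤ 2 µmol L⁻¹, 9:1 above, 98% label purity —
diluted by a configurable residual of unlabelled nitrate (default
0.1 µmol L⁻¹) carried over from the washing steps.

Michaelis–Menten fitting runs on cell-normalized rates with uniform
weights, initialized at V_max = max(V) and K_s at the half-maximum
substrate by interpolation; rates are internally rescaled to O(1) so the
optimizer's relative tolerances bite at the ~10⁻⁷ magnitudes of per-cell
uptake. Confidence intervals by case bootstrap of the (S, V) rows.

## CAAS screen

Clustering: single-linkage (transitive) grouping at ≥75% pairwise
identity, computed from Biopython global alignments (match 1, mismatch −1,
gap open −2, extend −0.5) as identities over alignment length — exact
pairwise alignment is affordable at the scale this package targets.

Trimming: a simplified gap-distribution rule — per-column gap fractions
are sorted, the cutoff is placed at the largest jump in the sorted unique
values, and columns above it are removed (a fixed fallback cutoff applies
when the distribution has no usable jump). A trimmed→original column map
is kept so every reported position is also available in original
alignment coordinates; human-facing output is 1-based.

Scan rule: a column (ungapped in all members by default; gap-tolerant
scanning is an option) is a candidate when the arctic and temperate
residue sets are disjoint and at least one side is fixed on a single
residue. Specificity is arctic or temperate by which side is fixed, and
"both" when both are. Taxa absent from a cluster contribute nothing and
never veto a record — coverage varies across clusters. An ID with several
positions counts once in summaries: its specificity is the shared call if
all positions agree and "both" otherwise.

Filters (each a recorded flag; the default screen requires all):

* *additional species* — each fixed residue must have a non-focal carrier
  and the opposite habitat must be represented beyond the focal pair at
  the site;
* *expression* — the cluster contains metatranscriptome members from both
  habitats;
* *conserved context* — all columns within ±5 of the site are gap-free
  and their mean residue diversity (distinct residues / members),
  focal site excluded, is ≤ 0.3. The window and threshold are
  configurable; the values automate a judgment that would otherwise be a
  manual inspection, and a window running past the alignment edge fails
  with an edge flag rather than raising;
* *phylogenetic independence* — the fixed residue must show ≥2
  independent origins on the species tree. Origins are counted by binary
  parsimony treating the derived residue as irreversible (origins are
  charged on 0→1 branches, once for ancestral presence at the root, and
  1→0 reversals are disallowed), which equals the number of maximal
  clades whose tips all carry the residue. A free-reversal count would
  let any scattered pattern collapse to a single ancestral origin plus
  losses, voiding the independence notion the filter exists to capture.
  The filter can be relaxed to a reported-only flag via configuration.

Functional tallies parse category letters from bracketed annotations;
J/K/L are grouped as central-dogma processes and G/I/Q as metabolic
functions, with unannotated IDs under the unknown-function bucket.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic given (seed, parameters), asserted
byte-wise on serialized output. Noise models follow data support:
multiplicative lognormal (unit mean) for abundances and δ¹⁵N, additive
Gaussian for growth rates.

Defaults are fixed study conditions, chosen once: the thermal truth
(a = 0.45, b = 0.05, z = 7, w = 26; T_opt ≈ 10.9 °C, μ_max ≈ 0.7 d⁻¹ on
the −0.5…15 °C gradient with 4 replicates and rate noise SD 0.03 d⁻¹)
mirrors an arctic-adapted strain; the photoperiod stage uses a saturating
arctic curve and a temperate curve peaking at 17 h over the 5-level
gradient with 5% multiplicative noise; the uptake stage uses
V_max = 2×10⁻⁷ µmol N cell⁻¹ h⁻¹ and K_s = 1.5 µmol L⁻¹ on the
7-level substrate gradient with 2% noise on δ¹⁵N. Replicate-level noise
magnitudes are calibration choices of this package, not measured values.

The CAAS generator evolves clusters on a 10-taxon species tree in which
every arctic tip is sister to a temperate tip, so planted substitutions
are phylogenetically independent by construction. Background columns
mutate with per-branch per-site probability 0.02 under a uniform
20-residue kernel — a presence/absence discrimination rule does not need
a realistic exchangeability matrix. Planted columns fix one residue
across arctic tips and draw temperate residues from a disjoint 4-residue
pool; their ±window flanks are held invariant and gap-free, so the
conserved-context check is exercised away from edge effects, and gap runs
are inserted elsewhere to exercise trimming. Consequences: passing
recovery tests show the scan-and-filter chain is correct under its own
assumptions; they say nothing about alignment error, assembly chimeras,
incomplete taxon sampling, or rate heterogeneity in real
metatranscriptomes, none of which are simulated.

## Problem sizes

Simulation-based checks use 10 clusters × 300 columns × 5 planted sites
over 20 seeds (CAAS recovery), 50 experiments × 300 bootstrap resamples
(thermal CI coverage), 200 null + 50 alternative simulations
(difference-smooth calibration and power), and 50 noisy assays
(Michaelis–Menten recovery) — sizes at which the Monte-Carlo error of
each rate is a few percent.

## Known limitations

* The whole pipeline treats replicates as independent; shared-strain or
  batch effects are not modelled anywhere.
* Tb₈₀ at a clipped range edge is a lower bound, flagged but still
  reported.
* The difference-smooth comparison assumes a common residual variance
  across origins (after the log transform).
* Fitch-style origin counting ignores branch lengths and, on unrooted
  input, depends on the supplied rooting; midpoint rooting is available.
* The screen's discrimination rule implements the fixed-vs-disjoint
  patterns (singleton against multiple, singleton against singleton);
  other foreground/background discrimination patterns are out of scope.
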