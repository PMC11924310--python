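# polartrait

Comparative trait analysis for Arctic- and temperate-adapted diatoms
(*Thalassiosira gravida* vs *T. rotula* and relatives): thermal performance
curves, photoperiod reaction norms, ¹⁵N-tracer nitrate uptake kinetics, and
a screen for convergent amino-acid substitutions (CAAS) in habitat-labelled
protein families. Every stage runs on real data tables or on synthetic data
with known ground truth, so estimator recovery can be scored exactly.

## What it computes

**Growth rates.** For each strain × condition × replicate, the maximum
specific growth rate μ_max (d⁻¹) is the steepest slope of a smoothing
spline fitted to ln(abundance) vs time, with the smoothing penalty chosen
by generalized cross-validation.

**Thermal performance curves.** Per-temperature growth rates are fitted
with the exponential-times-quadratic curve

    μ(T) = a·e^{bT} · [1 − ((T − z)/(w/2))²]

which allows negative rates (mortality) beyond the thermal limits
z ± w/2. Derived traits: the optimum temperature T_opt, the maximum rate
μ_max = μ(T_opt), the thermal breadth Tb₈₀ (width of the interval where
μ ≥ 0.8·μ_max, never extrapolated beyond the tested gradient), and the
activation energy E_A (eV), the Arrhenius slope of ln μ against
−1/(k_B·T) on the rising limb. Uncertainty comes from a nonparametric
residual bootstrap; origins are compared with Welch *t*-tests on
strain-level trait means.

**Photoperiod reaction norms.** Growth rates along a photoperiod gradient
(h of light per 24 h) are normalized per origin by the highest achieved
rate, and shape differences between origins are tested with a
reference + difference-smooth additive model

    log μ* ~ f(photoperiod) + origin + d(photoperiod)·[origin = temperate]

where the centered deviation smooth *d* is tested with an exact F-test.
Fitting on the log scale makes the multiplicative replicate noise Gaussian
and absorbs the normalization constant into the untested origin term, so
the test is correctly sized.

**Nitrate uptake.** δ¹⁵N readings from short tracer incubations are
converted to absolute uptake via the isotope mixing model

    V_abs = (A_PN − A₀)/(A_src − A₀) · PN/Δt    [µmol N L⁻¹ h⁻¹]

cell-normalized, and fitted with the Michaelis–Menten function
V = V_max·S/(K_s + S).

**CAAS screen.** Aligned, habitat-labelled homolog clusters (culture
transcriptomes + environmental metatranscriptomes) are trimmed
(gap-distribution breakpoint rule), scanned column-by-column for positions
where arctic and temperate members carry disjoint residue sets with at
least one side fixed on a single residue, and filtered: the substitution
must extend beyond the focal species pair, the cluster must be expressed in
both habitats' metatranscriptomes, the site must sit in a gapless conserved
region, and the convergent residue must have arisen on ≥2 independent
branches of the species tree (binary parsimony origin count). Candidates
are tallied per alignment ID, origin-specificity class, and functional
category letter.

## Worked example

Run the full synthetic pipeline (simulate → analyse each stage) with one
seed:

```bash
polartrait run --seed 1 --out out/
```

which prints (abridged):

```json
{
  "stages": {
    "tpc":   {"t_opt": 10.63, "mu_max": 0.700, "tb80": 10.32, "e_a": 0.534},
    "photoperiod": {"p_difference": 1.2e-213,
                    "optimum_h": {"arctic": 20.95, "temperate": 17.11}},
    "uptake": {"v_max": 1.999e-07, "k_s": 1.499},
    "caas":  {"n_candidates": 10, "sensitivity": 1.0, "precision": 1.0}
  }
}
```

Reading the numbers: the thermal stage simulated an arctic-like curve
(true T_opt 10.85 °C) on the −0.5…15 °C gradient and recovered
T_opt = 10.63 °C with μ_max = 0.70 d⁻¹; the photoperiod stage rejects
shape equality between the saturating arctic and 17 h-peaked temperate
reaction norms (p ≪ 0.001) and places the temperate optimum at 17.1 h; the
uptake stage recovers the planted kinetics (V_max = 2×10⁻⁷ µmol N cell⁻¹
h⁻¹, K_s = 1.5 µmol L⁻¹) almost exactly; and the CAAS stage finds every
planted convergent site in all 10 clusters with no false positives.

Each stage also has its own subcommand for real data tables
(`polartrait growth|tpc|photoperiod|uptake|caas --help`), reading the TSV
layouts described in the module docstrings, and `polartrait simulate`
writes synthetic inputs plus ground truth for any stage.

The packaged reference candidate table ships with the package:

```python
from polartrait import summarize_candidates
from polartrait.io import load_reference_candidates

records, annotations = load_reference_candidates()
print(summarize_candidates(records, annotations))
# CandidateSummary(n_candidates=26, n_annotated=12,
#   by_specificity={'arctic': 22, 'temperate': 3, 'both': 1}, ...,
#   n_central_dogma=6, n_metabolic=5)
```

## Layout

```
src/polartrait/
  growth.py       growth-rate extraction (smoothing splines)
  thermal.py      TPC fit, derived traits, bootstrap, Welch tests
  photoperiod.py  normalization + difference-smooth comparison
  nitrogen.py     isotope mixing model + Michaelis-Menten kinetics
  caas.py         clustering, trimming, scan, filters, parsimony, summary
  synthetic.py    generators with ground truth for every stage
  io.py           FASTA / newick / TSV readers and writers
  config.py       strict YAML pipeline configuration
  pipeline.py     stage orchestration
  cli.py          polartrait command-line interface
docs/methods.md   modelling choices, defaults, and limitations
```
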