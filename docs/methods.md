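# Methods

## The fitness model

Fitness is modelled as a benefit–cost balance over three phenotypes:
FlhA level `E_A`, FghA level `E_G` (both in mU of enzyme activity, or
equivalently on a relative scale with the ancestor at 100), and
plasmid copy number `P`:

```
W(E_A, E_G, P) = max(0, Vmax * E_A/(Eh + E_A) - Ft)
                 - cA*E_A - cG*E_G - cP*P
```

Assumptions built into this form:

* **Only FlhA is catalytically limiting.**  Over the perturbation
  range, reducing FghA monotonically increases fitness, i.e. FghA
  behaves as a low-control enzyme whose only first-order effect is
  its expression cost.  The model therefore has no benefit term in
  `E_G`; a second catalytic cliff at extremely low FghA is real but
  outside the modelled range, and `fitscape` makes no claims there.
* **Hyperbolic benefit.**  Steady-state pathway flux saturates in the
  level of a single limiting enzyme, giving the Michaelis–Menten-like
  `Vmax·E_A/(Eh+E_A)` with a pathway-level `Vmax` (fitness units) and
  half-maximal level `Eh` (expression units).
* **Flux threshold `Ft`.**  Empirically the fitness–FlhA relation is
  right-shifted: fitness approaches zero while enzyme is still
  measurable, plausibly because low dehydrogenase levels let
  formaldehyde accumulate to toxic steady states.  `Ft` subtracts
  from the benefit before costs.  The default reading clamps the net
  benefit at zero (`max(0, ·)`); an unclamped variant is available via
  `clamp=False` everywhere, and both are tested.  In the clamped
  region the benefit gradient is zero and the geometry functions flag
  this.
* **Linear costs.**  Expression cost per molecule is linear for each
  enzyme (`cA`, `cG`), plus a per-plasmid maintenance cost (`cP`).

Consequences used by the analysis: `W` is concave in `E_A` wherever
unclamped; the FlhA optimum has the closed form
`E_A* = sqrt(Vmax*Eh/cA) − Eh` (requires `cA > 0` and
`Vmax*Eh/cA ≥ Eh²`, otherwise the optimum is a domain boundary and
`NoInteriorOptimum` is raised); the FghA and copy-number directions
are pure costs, so the global optimum always pins them to the lower
domain bound — reported explicitly as a boundary hit, never hidden.

## Fitting

The six parameters are estimated by nonlinear least squares on the
fitness scale (unweighted; no measurement-CI weighting is attempted)
over the training partition only: ancestor, single mutants, and the
inducible-promoter series.  Combination strains are never used in
fitting; they are scored out of sample as
`R² = 1 − SS_res/SS_tot` on observed vs predicted fitness.
Optimization is `scipy.optimize.least_squares` (trust-region
reflective) in log10-parameter space, which enforces positivity and
makes steps scale-free; the box bounds (`DEFAULT_BOUNDS`) are wide
enough for both the mU and relative scales.  Multistart uses
log-uniform draws inside the box, 200 starts by default (40 suffice
for the simulation studies; both are deterministic given a seed).
The best converged start is kept; if none converges an error reports
the failure.  Parameters convert between the mU and relative scales
by rescaling `Eh`, `cA`, `cG` (see `pipeline._rescale_params`).

## Epistasis statistics

All fitness values are normalized by the ancestor before any
epistasis arithmetic, so the ancestor is exactly 1.  Epistasis is the
difference on the multiplicative-fitness scale,
`ε = W_ig − W_i·W_g` (not log-scale; a log variant would change the
null but the difference scale is used throughout, matching how the
combination data are summarized).  Sign epistasis is flagged when the
focal mutation reverses direction: beneficial alone but deleterious
in the background, or vice versa.  The multiplicative fitness null is
scored as the squared Pearson correlation of observed on expected
combination fitness; the adjusted variant penalizes with the number
of single-mutant parameters.  The s–ε trend averages ε over
backgrounds per mutation and regresses the means on s by OLS, with
the two-group comparison done by Welch's t-test by default
(equal-variance is an option).

## The synthetic study generator

The generator emulates the study design: one ancestor (100 mU FlhA,
100 mU FghA, 9 plasmid copies), three Class A mutations, Class B
variants B2, B3, B5 and the co-occurring B2B3 pair, the 12 A×B
combination plasmids, and a 12-level inducible-promoter dilution
series that scales both enzymes by a common factor (one promoter
drives the cassette) at ancestral copy number.  Mutation effects are
multiplicative: total expression = ancestor level × per-copy
multipliers × copy-number ratio.  Class A leaves copy number
untouched; idealized Class B acts purely through dosage, but B2 and
B5 carry an additional per-copy FghA reduction (0.8 and 0.7),
representing copy-number variants that depress FghA beyond dosage
through unknown mechanisms — this "asymmetric B" case exercises the
geometry code with off-diagonal jumps.

Ground-truth landscape parameters (`default_true_params`):
`Vmax=2.8, Eh=10, Ft=0.30, cA=0.009, cG=0.0025, cP=0.01`.  These were
chosen so that, jointly: the ancestor sits on the costly flank with
`W = 1.0055 ≈ 1`; the FlhA optimum (45.8 mU) lies inside the
simulated range; the strongest single mutants gain `s ≈ 0.4–0.5`; the
flux threshold is a prominent feature of the low-expression flank;
and the ancestor's local gradient is dominated by the FlhA cost
(ratio ≈ 2.7:1), so the steepest-ascent direction differs markedly
from the direction to the global optimum — the topographic situation
the geometry analysis is about.

Noise model: observed values are means of `n_replicates = 3`
independent measurements (assays in this field are typically run in
triplicate).  Expression noise is mean-preserving lognormal
(positivity; default CV 5% per replicate), fitness noise is additive
Gaussian (fitness ≈ 1; default sd 0.02 per replicate), and
copy-number noise enters as Gaussian ΔCt error (default sd 0.05 per
Ct read, two reads per ΔCt).  What the generator does **not**
emulate: day/batch effects, correlated errors between the two enzyme
assays, cytometer gating bias, plate-position effects, or any real
biological deviation from exact multiplicativity of expression
effects.  Passing tests therefore demonstrate correctness of the
estimators under the stated design and noise, not robustness to every
failure mode of real data.

The simulated competition assay inverts the fitness equation: given
true `W` and total expansion `X`, the reference growth factor solves
`f0·g^W + (1−f0)·g = X`, and pre/post counts are binomial draws at
the implied fractions (`exact=True` skips sampling for identity
tests).  The simulated qPCR emits the four-point standards ladder at
1, 0.1, 0.01, 0.001 ng (molecule counts from the 650 g/mol/bp dsDNA
conversion at a 10.19 kb plasmid length, chosen to make 1 ng ≈
9.09×10⁷ molecules) and a sample ΔCt; at zero Ct noise the
fit-then-interpolate chain recovers copies per genome exactly for any
amplification efficiency encoded in the slope.

## Null simulation (regression to the mean)

Each locus i has a background-independent log-fitness main effect
`m_i ~ N(0, 0.2²)` and an independent idiosyncratic deviation
`η_{i,b} ~ N(0, 0.15²)` for every background b it is placed in;
genotype fitness is `exp(Σ m_i + Σ η)`.  By construction
`E[ε] = 0` for every pair (both `W_ig` and `W_i·W_g` contain two
independent η draws).  Conditioning on `W_i > 1` in the ancestor
biases the ancestral deviation upward, so single-mutant fitness
overstates the locus's typical effect and ε turns negative, most
strongly for the largest observed s.  Records within a replicate
share draws, so all Monte-Carlo error estimates (and the calibration
check that the 95% CI of mean ε covers 0 in ≥90% of unconditioned
batches) are computed on independent per-replicate means, not raw
records.  Only qualitative sign claims are tested — the quantitative
slope depends on the distributional choices, which are the simplest
consistent with "random effects and no epistatic tendency".

## Numerical choices and degenerate inputs

* Competition fitness requires all four counts positive and a growing
  reference population; fractions of exactly 0 or 1 are errors, and
  totals under 50 000 counts log a warning (a data-quality floor, not
  a validity bound).
* The standard curve requires ≥2 distinct molecule counts and a
  negative slope (more template ⇒ earlier Ct).
* The expression fit excludes non-positive expression values with a
  warning and reports rank deficiency by naming the confounded
  mutation columns (e.g. two mutations that only ever co-occur).
  Inducible-promoter rows are excluded from the expression model
  because their levels are set by the inducer, not by mutations.
  The natural log is used throughout; coefficients are reported both
  as logs and as multipliers.  Adjusted R² uses the standard
  `(n−1)/(n−p−1)` penalty.  Combination rows are included in the fit
  by default; `mode="singles_only"` scores them purely out of sample.
* Geometry is computed on the linear relative-expression plane
  (ancestor at (100, 100)), matching how the surfaces are drawn; a
  uniform rescaling of both axes leaves the diagonal and optimum
  angles invariant while the gradient direction is scale-covariant —
  the convention is documented and asserted in tests.  The global
  optimum needs a bounded domain (default [1, 150]² relative) because
  FghA is a pure cost dimension.
* `flank_analysis` defines the margin as the expression drop a strain
  tolerates before predicted fitness falls below 1 on the
  low-expression side of its axis profile; strains whose whole
  profile sits below 1 get margin −∞, strains already below 1 on the
  low flank get a negative margin.
* Tie-break in `direction_report`: the nearest reference is the
  argmin of the three angles; exact ties resolve in the fixed order
  gradient, optimum, diagonal.

## Problem sizes

Defaults used by the test suite and the acceptance script: 32-record
studies (1 + 7 + 12 + 12); 100-point gradient oracle checks; 20-seed
noisy recovery studies at 40 multistarts each; null simulations of
1500 replicates × 6 loci (~45 000 records).  These sizes give stable
statistics while keeping a full run in tens of seconds on one CPU.

## Known limitations

* The landscape's FghA cliff at extreme depletion is not modelled.
* `Eh` and `Ft` are partially confounded when the inducible series is
  short or does not reach low FlhA levels; the default 12-level
  series reaches 3% of ancestral expression for this reason.
* The multiplicative fitness null's adjusted R² can be strongly
  negative for small combination sets (n = 12, p = 7); it is reported
  but the unadjusted squared correlation is the primary summary.
* Real copy-number mutations may have per-copy expression side
  effects of unknown structure; the generator represents them only as
  fixed per-copy multipliers.
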