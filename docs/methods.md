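# Methods

## The model

A disordered protein is represented as a weighted conformational
ensemble: conformers j = 1..n with weights w_j on the probability
simplex. Measured observables are grouped into blocks by type k (CD
intensities, SAXS intensities, backbone-carbon chemical shifts), and
every predicted observable is linear in the weights,

    Obar_ki(w) = sum_j w_j * O_kij ,

where O_kij is the prediction for conformer j (produced by external
predictors; this package never computes observables from coordinates).

### Refinement objective

Given a prior w0 (uniform in practice), the refined weights minimise

    L(w) = sum_k (M_k / 2) * chi2_k(w)  -  theta * S_rel(w, w0)

    chi2_k(w) = (1 / M_k) * sum_i ( (O_ki - alpha_k * Obar_ki(w)) / sigma_ki )^2

    S_rel(w, w0) = - sum_j w_j * ln(w_j / w0_j)     (nats, <= 0)

M_k is the number of fitted observables of type k and theta > 0 sets
the price of moving away from the prior. S_rel uses the natural
logarithm (the standard maximum-entropy convention; any other base only
rescales theta) with 0·ln 0 = 0 so refined weights may reach the
simplex boundary.

The scaling factor alpha_k compensates machine-dependent beam intensity
for SAXS and is a free positive parameter with the closed-form optimum

    alpha_k* = [ sum_i O_ki Obar_ki / sigma_ki^2 ] / [ sum_i Obar_ki^2 / sigma_ki^2 ] ,

clipped to (0, inf). CD intensities and chemical shifts are on absolute
scales, so alpha_k = 1 for those blocks.

### Uncertainty models

| observable | sigma | default |
|---|---|---|
| CD | delta·\|O\| + sigma0 | delta = 0.2, sigma0 = 0.75 kMRE |
| chemical shift | fixed per atom type | 0.95 (CA), 1.03 (CB), 1.13 (CO) ppm |
| SAXS | per-point sigma from the measured curve | — |

The CD model combines a fractional normalisation uncertainty
(concentration and path-length determination) with a machine-error
floor; the magnitude |O| is used because CD intensities are signed.
The shift sigmas reflect predictor accuracy rather than measurement
error, which is typically several times smaller.

### Optimisation

The simplex constraint is removed by the softmax parameterisation
w = exp(z)/sum exp(z), initialised at z = ln w0, and L is minimised by
L-BFGS with an analytic gradient. For free-scale blocks alpha_k is
*profiled*: its closed-form optimum is recomputed inside every
loss/gradient evaluation, and by the envelope theorem the gradient in w
needs no alpha term. This has the same stationary points as updating
alpha between quasi-Newton sweeps but avoids an outer loop and is fully
deterministic. Convergence: relative loss change below 1e-9 or gradient
infinity-norm below 1e-7, capped at 5000 iterations (exceeding the cap
raises an error carrying the best iterate). The optimiser was checked
against a stationarity oracle on two-conformer problems and a dense
(1e-3 step) simplex grid search on three-conformer problems; agreement
is within 2e-3 per weight.

### Theta scan and selection

Refinements run independently (each from the prior) over the grid
theta ∈ {0.1, 1, 2, 5, 10, 20, 50, 100, 200}. Lower theta always fits
at least as well and spends at least as much entropy (verified as a
property test). "Largest theta with significant improvement" is made
quantitative as: the largest theta whose total chi2 reduction from the
prior, Delta(theta) = sum_k M_k [chi2_k(w0) - chi2_k(theta)], reaches
at least a fraction `frac` (default 0.5) of the maximum reduction on
the grid. Significance is judged jointly over blocks (the M_k-weighted
total), matching the weighting of the loss itself; `frac` is a config
knob because no principled universal threshold exists. If no theta
improves the fit, the largest theta is returned with a warning.

### Sub-ensembles

Final compact models are multisets of conformers drawn with replacement
from the refined weights (sizes 5, 10, 20, 50, 100, 200; 5 replicas per
size). Categorical draws are used directly; they are equal in law to
rejection sampling (propose uniformly, accept with probability
w_j/max(w)) and cheaper. Per size, replica chi2 values are averaged
with standard errors (n-1 variance over replicas), and the replicas are
concatenated into a pooled model. The selected size is the smallest one
where (i) the relative mean-chi2 improvement to the next size is below
`improve_tol` (default 0.05) for every block and (ii) replica means
agree with the concatenated model within `agree_tol` (default 1.0)
standard errors; with no qualifying size the largest is returned with a
warning. Both tolerances are configuration because "considerably" and
"within uncertainty" admit no unique quantification. All replicas of
the chosen size are emitted; the first replica is marked as the
representative single-draw model.

## Assessment metrics

* **CD accuracy**: RMSD (kMRE) over the overlapping wavelengths after
  linear regridding of the predicted spectrum onto the measured grid.
  The optional scaling factor multiplies the *experimental* spectrum
  (alpha_j = sum I_exp I_calc / sum I_exp^2, the least-squares
  minimiser) — deliberately asymmetric to the refinement chi2, which
  scales the calculated curve; both conventions are in active use and
  the assessment layer follows the spectrum-comparison one.
* **SS accuracy**: RMSD over the M class fractions of a scheme, plus a
  scale-free chi2 when per-class uncertainties are available.
  Compositions from different classification schemes are made
  comparable by surjective class groupings (`ClassMap`), which conserve
  total fraction mass; an optional completion rule recomputes one class
  as the remainder (the three-class estimator that only reports helix
  and sheet). The shipped member tables follow the standard scheme
  definitions but are plain configuration data and editable.
* **SAXS quality**: chi = sqrt(chi2) at the optimal alpha, invariant
  under any positive rescaling of the predicted curve (and of the
  measured curve jointly with its sigmas).
* **Group statistics**: mean ± SEM (sample SD over sqrt(n)), NA cells
  dropped; printed reports round half-up at the displayed precision.
  The package also exposes the SD for transparency. Note that group
  statistics recomputed from already-rounded per-ensemble table cells
  can differ from pre-rounding values by up to one unit in the last
  printed decimal; one SEM in the shipped tables (Group B SAXS) sits
  exactly on a rounding tie.

## Synthetic data

`gen_problem` draws truth weights from a Dirichlet distribution
(concentration 1.0 = uniform over the simplex; 0.1 emulates ensembles
dominated by a few conformers) and builds three linear observable
blocks: CD spectra from a smooth random three-class basis (178–260 nm)
times random per-conformer compositions; SAXS curves as Debye-chain
intensities with radii of gyration of 10–30 Å on q ∈ [0.01, 0.25] 1/Å
and per-point relative uncertainties of 2–20% (mean ≈ 12%, the typical
spread of beamline error estimates); chemical shifts as per-residue
backbone-carbon base values with ~1 ppm conformer-dependent offsets.
Measured data are the truth-weighted averages plus Gaussian noise of
standard deviation `noise_scale` times the model sigma; the blocks
always carry the *model* sigmas, so at noise_scale = 1 the truth
weights give E[chi2] ≈ 1 (verified over 20 seeds within ±0.3) and at 0
the data are exact. An optional beam-scale factor multiplies the
measured SAXS curve and its sigmas to exercise the free alpha.
Gaussian noise is the maximum-entropy choice given that only scales are
specified. All generators take explicit seeds; no global RNG state.

What the generator does **not** emulate: real SAXS physics beyond a
smooth decaying curve, correlated noise, systematic predictor bias, or
conformer geometries. Passing tests therefore demonstrate correctness
of the inference machinery under its own assumptions, not accuracy on
real ensembles.

`recovery_check` compares refined against truth observable averages
per block (weights themselves are identifiable only up to the
observable null space, so averages are the meaningful target). For
free-scale blocks both averages are first put on their optimally scaled
footing, since a free alpha means the data constrain the ensemble only
up to that factor. On noiseless problems at theta = 0.1 the relative
average error is below 0.5% (measured ≈ 0.02%).

## Numerical choices and degenerate inputs

* Weight/simplex comparisons use absolute tolerance 1e-9.
* alpha* is clipped at 1e-12 when the closed form goes nonpositive;
  all-zero predictions raise a degenerate-scale error.
* Observables with an NA prediction in any conformer are dropped from
  M_k at load time (logged).
* Theta-scan ties: the grid is scanned from largest to smallest theta
  and the first qualifying theta wins.
* Descending wavelength files are sorted with a warning; duplicate
  wavelengths or conformer ids are errors.

## Problem sizes

The shipped tests and the acceptance script run the pipeline at 15–500
conformers with 30–100 observables, sizes chosen so the whole suite
completes in well under a minute while still exercising every stage at
realistic dimensionality (refined IDP ensembles in the hundreds of
conformers). Scan grids, replica counts and sub-ensemble sizes are the
study defaults throughout.

## Known limitations

* No error bars on refined weights (no replica or bootstrap scheme).
* The theta-selection and size-selection thresholds are heuristics with
  documented defaults, not statistical tests.
* The CD forward model is strictly linear in composition; side-chain
  correction channels are carried through but the package does not
  derive basis spectra.
* Chemical-shift handling assumes the three backbone carbon types;
  other nuclei require explicit sigmas.
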