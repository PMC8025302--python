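# Methods

`smalex` analyses µs-ALEX single-molecule FRET measurements of freely
diffusing, double-labelled proteins — here the tandem substrate-binding
domains SBD1 and SBD2 of the amino-acid ABC importer GlnPQ — together with
the ITC binding isotherms of the same constructs. Because no raw photon data
are available for this system, the package pairs every analysis stage with a
synthetic generator whose ground truth is known exactly; all quantitative
claims about the code are statements about what the pipeline recovers from
those simulations.

## The measurement model

A molecule diffusing through the confocal volume emits a **burst** of
photons. With alternating laser excitation (period 50 µs; donor excitation
in the half-open window [0, 25) µs, acceptor excitation in [25, 50) µs) each
photon is classified by detector and excitation period into three streams:
F(DD) (donor excitation, donor emission), F(DA) (donor excitation, acceptor
emission) and F(AA) (acceptor excitation, acceptor emission). Two
uncorrected ("apparent") quantities summarize each burst:

    E* = F(DA) / (F(DD) + F(DA))
    S  = (F(DD) + F(DA)) / (F(DD) + F(DA) + F(AA))

E* reports donor–acceptor proximity (conformational state), S the
donor/acceptor brightness ratio. No γ, leakage or direct-excitation
corrections are applied anywhere: the analysis operates on apparent
quantities throughout, and the synthetic states are parameterized directly
by their apparent values.

## Synthetic photon data

Per burst the generator draws a state from the mixture, a base
donor-excitation brightness `B` from the burst-size model, then

* `N_Dexc ~ Poisson(alpha * B)`, split binomially into F(DA) with
  probability E* and F(DD) otherwise;
* `F(AA) ~ Poisson(B * (1 - S)/S)`, coupled to the same `B` so that
  per-burst stoichiometry is tight around the state value (as it is for real
  transits, where all streams scale with the transit time);
* per-stream background `~ Poisson(rate * burst duration)`.

PIFE (protein-induced fluorescence enhancement of Cy3 by a nearby protein
surface) is modelled as the multiplicative factor `alpha >= 1` on the
donor-excitation intensity only. This leaves E* unchanged and moves the
expected stoichiometry by an odds scaling,
`S_alpha = alpha*odds / (1 + alpha*odds)` with `odds = S/(1-S)`, which
`derive_pife_factor` inverts. The ensemble is treated as a single effective
alpha; sub-populations from stochastic labelling are not resolved.

Timetrace mode places bursts as a Poisson process (default 20 bursts/s, the
regime of ~50 pM samples) with rectangular 1 ms envelopes; photon timestamps
are integer microseconds folded into the excitation window matching their
stream, and background photons are uniform in time.

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| alternation period | 50 µs | the instrument setting of the assay |
| burst-size model | shifted exponential, min 20 photons | diffusing-molecule burst sizes are heavy-tailed; the minimum keeps every generated burst above trivial size |
| mean N_Dexc | 120 photons (200 for titration traces) | 120 matches the single-population recovery studies; titrations use 200 so a realistic fraction of bursts survives the 150-photon selection |
| background (DD, DA, AA) | 1000 / 500 / 1000 counts/s | typical confocal background; not reported for this dataset, so a stand-in |
| burst rate, duration | 20 /s, 1 ms | picomolar sample, ~ms transits; rectangular envelope is the simplest defensible transit model |

The `constant` burst-size family (all bursts share one intensity; counts are
then Poisson about it) exists because the shot-noise law below is a fixed-N
statement: under a heavy-tailed N mixture the population E* width is
inflated by E[1/N]·E[N] ≈ 1.4 relative to the law evaluated at the mean N,
which is a property of the burst-size distribution, not of conformational
heterogeneity. BVA studies therefore use the constant family.

## Burst search and selection

The all-photon burst search marks photon *i* as high-rate when photons
*i..i+M−1* (forward window over all streams) span at most *T* µs; maximal
runs of marked photons, extended by the M−1 look-ahead photons of the last
marked index, are merged where they share photons and kept when they contain
at least *L* photons. Defaults M = 15, T = 500 µs, L = 25. The forward
anchoring and overlap-merge rule are stated explicitly so results are
reproducible bit for bit; output bursts are disjoint and ordered.

Intensity selection ("all channels greater than 150 photons") is read as
*both excitation sums* above the threshold — F(DD)+F(DA) > 150 **and**
F(AA) > 150 — a double-labelled-molecule selection; the literal per-stream
reading would bias against low-FRET states (F(DA) alone rarely exceeds 150
at E* ≈ 0.3). Both alternatives remain available through `channel_rule`.
The BVA selection (threshold 250) is applied to the *total* photon count
plus S in [0.3, 0.6]: a per-excitation-sum reading at 250 would contradict
the reported mean of ~162 donor-excitation photons per selected burst.

## Population fitting and titrations

Sub-populations in the (E*, S) plane are covariant bivariate Gaussians
(amplitude, means µ_E/µ_S, widths w_E/w_S, correlation ρ). The default
backend fits them by expectation–maximization on the unbinned points
(scikit-learn Gaussian mixture: k-means initialization, seeded, relative
log-likelihood tolerance 1e-8, at most 500 iterations, width floor 1e-3 via
covariance regularization) because EM avoids bin-size sensitivity; the
binned 2D-histogram least-squares fit is available as the `histogram`
backend and agrees on well-separated populations. Fits that do not converge
or see degenerate input raise; they are never silent. Burst membership
probabilities are density ratios `p_i = f_i(E,S) / Σ_j f_j(E,S)`.

Titrations anchor the open and closed states on the endpoint datasets (apo
and saturating ligand), freeze those parameters, and refit only the closed
amplitude at each concentration by 1-D maximum likelihood; the closed
fraction is the closed area over total area, with the mean closed-assignment
probability reported alongside (the two agree within 0.02 on well-separated
states). Fractions are fitted with the one-site model
`f(L) = B_max L / (K_D + L)` by weighted least squares (binomial weights
`sqrt(f(1-f)/n)` per point); the Hill exponent is fixed at 1, with a free-h
fit available as a diagnostic only. Because the two states overlap at about
2.7 widths, pure-state datasets return fractions of ~0.99/0.01 rather than
exactly 1/0 — an estimator resolution of roughly two percentage points that
propagates into B_max more than into K_D.

Simulated titrations use 12 log-spaced concentrations spanning 0.03–30 times
K_D with 3000 bursts per point, matching the sub-K_D-to-saturating span of
the titration figures.

## Burst variance analysis

For a static state emitting N donor-excitation photons per burst, binomial
partitioning fixes the per-burst E* standard deviation at

    sigma_E* = sqrt( E*(1 - E*) / N_DD+DA ).

`bva_compare` reports the observed std of per-burst E* against this limit
evaluated at the mean E* and the arithmetic mean N_DD+DA of the selected
bursts. The package's primary mode is this population-level comparison (the
form used to argue the inter-domain population is static); classic sub-burst
BVA (windowed E* along each burst, default 100-photon windows) is included
as an optional extension. The reference width of 0.037 at E* = 0.33
corresponds to N_DD+DA = 162, obtained by inverting the law; that count is a
derived quantity, not a printed one.

## ITC

Independent-site binding isotherms with standard perfusion bookkeeping: each
injection of volume v displaces a fraction v/V0 of the cell contents, so
total concentrations update as `M_i = M_{i-1}(1 - v/V0)` and
`X_i = X_{i-1}(1 - v/V0) + X_syringe v/V0`. One site uses the closed-form
quadratic root of the mass balance; two independent sites solve the monotone
scalar equation `X = L + M Σ n_k K_k L/(1 + K_k L)` for free ligand with a
bracketed root (Brent). The heat of injection i is
`V0 Σ_k ΔH_k ([ML]_{k,i} − [ML]_{k,i-1}(1 − v/V0))`, reported per mole of
injectant. Fitting is nonlinear least squares over (n, log10 K_A, ΔH) per
site with a small multistart grid over log10 K_A (c-values 1–1000 for the
tight site, 0.1–10 for the weak site) to avoid local minima; the sequential
fixed-parameter mode holds one site's values constant, as done when one site
has been characterized in a separate titration. Derived thermodynamics:
K_D = 1/K_A, ΔG = −RT ln K_A, ΔS from ΔG = ΔH − TΔS, with
R = 8.314462618 J/(mol·K) and T defaulting to 298.15 K. Units are kJ/mol
and µM internally; calories are converted on input (4.184 J/cal). First
injections can be excluded (syringe-leak convention), off by default.
The synthetic-isotherm noise model offers a constant-sd term and a
per-injection proportional term; the fixed-site recovery study uses 1%
proportional noise and reports the median over 20 seeds, since a single
weakly saturated low-affinity site (c ≈ 0.3–3) is not identifiable to 5%
from every noise realization.

## Anisotropy

Pure arithmetic on already-extracted polarized intensities:
`G = I_HV/I_HH` and `r = (I_VV − G·I_VH)/(I_VV + 2G·I_VH)`; no spectral
integration or time-resolved analysis.

## What the simulations do and do not show

The generator reproduces the statistics the analysis relies on — Poisson
streams, mixture populations, one-site occupancy along a titration,
donor-brightness scaling, uniform background — but contains no photophysics
(blinking, bleaching, triplets), no 3-D diffusion through a Gaussian focus
(transits are rectangular), no lifetime information and no γ-type
instrumental asymmetries beyond the S baseline. Passing recovery tests
therefore demonstrates the correctness and calibration of the analysis
chain, not robustness to every artefact of real traces. Two visible
consequences of the modelled imperfections: uniform background shifts
thresholded fitted means by a few 10⁻³ (apparent, exactly as in the real
measurement), and intensity selection near the burst-size mode slightly
favours upward donor fluctuations, raising fitted µ_S by about +0.003 at
the PIFE baseline. Both effects are inside every tolerance used.

## Problem sizes

Defaults throughout were chosen as the smallest sizes at which the recovery
statements are comfortably stable: 10^4 bursts for single-population fits
and BVA, 12 concentrations × 3000 bursts for titrations, 20-seed replicate
studies for bias statements, 20–30 injections per isotherm. The full test
suite and the acceptance study each run in a few minutes on one CPU.
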