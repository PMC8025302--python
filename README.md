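# smalex

Single-molecule ALEX/FRET/PIFE burst analysis and ITC isotherm fitting for
tandem substrate-binding domains.

## What this package is for

Type I ABC importers such as GlnPQ capture amino acids with extracytoplasmic
substrate-binding domains (SBDs) that close around their ligand. GlnPQ is
unusual in carrying two different SBDs in tandem — SBD1 (asparagine,
high affinity; glutamine, low affinity) and SBD2 (glutamine only) — raising
the question of whether the adjoining domain changes ligand binding or
conformation. Answering it requires, on the computational side:

* **µs-ALEX burst analysis** — locating single-molecule photon bursts in
  alternating-laser-excitation traces, computing per-burst apparent FRET
  efficiency `E* = F(DA)/(F(DD)+F(DA))` and stoichiometry
  `S = (F(DD)+F(DA))/(F(DD)+F(DA)+F(AA))`, and fitting covariant bivariate
  Gaussian populations in the (E*, S) plane;
* **titration analysis** — converting population amplitudes along a ligand
  series into closed-state fractions and fitting
  `f(L) = B_max·L/(K_D + L)` for the dissociation constant;
* **burst variance analysis (BVA)** — comparing the observed spread of
  per-burst E* with the shot-noise limit
  `σ_E* = sqrt(E*(1−E*)/N_DD+DA)` to detect conformational dynamics;
* **PIFE–FRET** — reading protein-induced fluorescence enhancement of the
  Cy3 donor as a stoichiometry shift ΔS*, with the brightness factor α
  recovered from the odds transform `S/(1−S) → α·S/(1−S)`;
* **ITC isotherm fitting** — one- and two-independent-site binding models
  with per-injection displacement dilution, sequential fixed-parameter fits,
  and the derived thermodynamics `K_D = 1/K_A`, `ΔG = −RT ln K_A`,
  `ΔS` from `ΔG = ΔH − TΔS`.

This package implements all of those stages as a tested library
(`src/smalex/`), a command-line interface (`smalex`), and a set of analysis
drivers (`analysis/`), together with a synthetic µs-ALEX photon generator
and ITC isotherm simulator so that every stage is verifiable against known
ground truth without any experimental download. `docs/methods.md` describes
the models and numerical choices in detail.

## Worked example

Recover a glutamine-binding constant through the complete photon-level
pipeline — simulate traces at 12 concentrations with ground-truth
K_D = 0.9 µM, burst-search them (M=15, T=500 µs, L=25, 150-photon
selection), anchor the open/closed states on the endpoint datasets, extract
closed fractions and fit the binding curve:

```python
import numpy as np
from smalex import FluorophoreState
from smalex.pipeline import titration_photon_pipeline

open_state = FluorophoreState("open", e_app=0.58, s_app=0.5)
closed_state = FluorophoreState("closed", e_app=0.74, s_app=0.5)

res = titration_photon_pipeline(
    kd_true=0.9,
    concentrations=np.geomspace(0.03, 30, 12),   # µM
    open_state=open_state, closed_state=closed_state,
    seed=1, n_bursts_per_point=3000,
)
fit = res["binding_fit"]
print(f"K_D = {fit.kd:.3f} ± {fit.kd_err:.3f} µM, Bmax = {fit.bmax:.3f}")
```

which prints

```
K_D = 0.896 ± 0.024 µM, Bmax = 1.000
```

i.e. the pipeline returns the generating dissociation constant to within its
standard error; the per-point closed fractions (`res["points"]`) rise from
0.03 at 0.03 µM to 0.97 at 30 µM along the one-site curve. The same chain is
available from the shell:

```bash
smalex simulate-alex --config examples/alex.yaml --seed 1 --out photons.h5
smalex burst-search --in photons.h5 --out bursts.csv
smalex fit-populations --in bursts.csv --n 2 --out populations.json
```

The numbered drivers reproduce the full set of analyses and write tables
under `results/`:

```bash
python analysis/01_fret_states.py      # apo/holo/inter-domain state recovery
python analysis/02_titration_kd.py     # smFRET K_D's (0.9 µM, 75 nM, 140 nM)
python analysis/03_bva.py              # shot-noise test of the inter-domain state
python analysis/04_pife_series.py      # PIFE stoichiometry series + null control
python analysis/05_itc.py              # ITC one-/two-site and fixed-site fits
```

## Layout

```
src/smalex/        library: synthetic, bursts, populations, titration,
                   bva, pife, itc, anisotropy, io, pipeline, cli
analysis/          numbered narrative drivers writing results/ tables
tests/             pytest suite (unit, property and end-to-end recovery)
scripts/           acceptance script
docs/methods.md    models, parameters, numerical choices, limitations
```
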