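# trichodiel

A diel physiological model of a marine *Trichodesmium* trichome, built to
ask one question quantitatively: what does a cell gain by dynamically
regulating the O₂ permeability of its membrane instead of keeping it
fixed?

*Trichodesmium* fixes N₂ with nitrogenase — an enzyme destroyed by O₂ —
while photosynthesizing O₂ in the same cells during the same light period.
It copes by temporal segregation: strong photosynthesis in the morning,
then an afternoon "low-O₂ window" created by deliberately wasteful
respiration of carbohydrate ("respiratory protection"), inside which
nitrogenase operates.  High intracellular O₂ also drives photorespiration,
an energy-wasting RuBisCO oxygenation flux.  A membrane whose relative O₂
diffusivity ε rises with intracellular O₂,

    ε(O₂) = ε_max · O₂/(O₂ + k),      ε_max = 2×10⁻⁴, k = 0.213 mol m⁻³,

vents O₂ in the morning (less photorespiration) and seals the cell during
the window (less O₂ influx, hence less respiratory protection), compared
with a fixed ε = 1×10⁻⁴.  The model couples photosynthetic electron
transport (linear + alternative pathways with an exact per-step ATP/NADPH
closure), carbon fixation, photorespiration, respiratory protection, N₂
fixation, diurnal Fe allocation among photosystems/nitrogenase/storage
pools, and physical O₂ exchange through the membrane and boundary layer of
a cylindrical trichome.  Four rate caps (respiratory protection,
photosystem synthesis/decomposition, nitrogenase synthesis) are calibrated
by maximizing growth per scenario.  See `docs/methods.md` for the full
model description.

Intended users: microbial ecophysiologists and biogeochemical modelers who
want a transparent, testable single-cell diel flux model of a diazotroph.

## Worked example

```python
from trichodiel import ModelParams, Environment, Scenario, run_diel
from trichodiel.calibration_fit import calibrated_for

params = ModelParams()
for mode in ("fixed", "dynamic"):
    sc = Scenario(mode=mode, environment=Environment(Fe_diss=40.0))
    out = run_diel(sc, params, calibrated=calibrated_for(mode, 40.0))
    d = out.daily
    print(f"{mode:8s} growth {d['growth_rate_d']:.3f} /d   "
          f"N2 fixation {d['n2_fixation']:.4f} molN/molC/d   "
          f"RP share {d['frac_resp_protection']:.0%}   "
          f"window NF {d['nf_in_window_frac']:.0%}")
```

prints (low-Fe, 40 pM dissolved Fe):

```
fixed    growth 0.105 /d   N2 fixation 0.0195 molN/molC/d   RP share 63%   window NF 99%
dynamic  growth 0.209 /d   N2 fixation 0.0376 molN/molC/d   RP share 34%   window NF 100%
```

Read: under Fe scarcity the dynamically permeable cell grows roughly twice
as fast.  The fixed-permeability cell spends 63% of its gross fixed carbon
on respiratory protection to hold the low-O₂ window open against O₂
leaking in; the dynamic membrane seals during the window, halving that
carbon tax, and essentially all N₂ fixation happens inside the window in
both cases.

The same comparison across ten dissolved-Fe levels (20–1,800 pM), external
O₂ scans, ε_max sensitivity, and the photorespiration-substitution
experiment are available from the CLI:

```bash
trichodiel simulate --mode dynamic --fe 40        # one scenario -> CSV + JSON
trichodiel compare-permeability                   # budget table, 2 modes x 2 Fe
trichodiel scan-fe                                # growth promotion vs Fe
trichodiel substitute-pr                          # force fixed-case photorespiration
trichodiel calibrate --mode fixed --fe 40         # re-derive the calibration
trichodiel fixtures --noise-cv 0.1                # synthetic diel observations
```

All outputs are CSV/JSON with a config hash, package version, and seed.

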