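# qramanomics

Calibrated, quantitative chemometric phenotyping of 3D confocal Raman
hyperspectral image stacks.

Confocal Raman spectral imaging records a full vibrational spectrum at
every voxel of a 3D scan, giving label-free access to proteins, lipid
classes, nucleic acids, glycogen, cytochrome c and xenobiotics in intact
specimens such as liver organoids. Raw counts, however, are arbitrary
units. This package implements the calibration and unmixing pipeline that
turns them into absolute concentrations:

1. **Preprocessing** (per voxel): cosmic-ray removal (filter size 4,
   dynamic factor 4.1), dark-current zeroing on the Rayleigh region
   (−150–50 cm⁻¹), normalization of the water OH-stretch band mean
   (3220–3420 cm⁻¹) to 1 — liquid water in the constant ~5 fL confocal
   volume is the internal intensity standard — matrix-blank subtraction,
   rolling-circle baseline correction (shape size 300), and cropping to
   400–3100 cm⁻¹ with the biologically silent region (1800–2700 cm⁻¹)
   excluded. A 785-nm branch (detector range 400–2300 cm⁻¹, no water band)
   substitutes standard-normal-variate scaling.
2. **Calibration**: per-channel ordinary least squares of preprocessed
   tissue-phantom spectra against known concentrations (protein
   10–300 mg/mL, DPPC 5–80, POPC 5–50, nucleic acids 10–60, glycogen
   10–100 mg/mL, cytochrome c in µg/mL) yields unit-scaled endmember
   spectra — the columns of the calibration matrix **X** (a.u. per
   1 mg/mL). Depth-profiling of homogeneous phantoms fits the attenuation
   SNR(z) = A·e^(−z/τ).
3. **Unmixing**: per voxel, y = Xβ + e is solved by least squares with a
   non-negativity constraint on β (Lawson–Hanson NNLS; internally
   column-normalized against the ~1000× resonance-enhanced cytochrome c
   column). Because X is unit-scaled, β̂ reads directly in concentration
   units. Voxels failing the SNR rule (CH-stretch maximum < 10× the
   silent-region SD) are masked.
4. **Chemotyping**: Pearson co-localization matrices, treated-vs-control
   |Δr| difference maps, joint frequency-distribution (waterfall)
   histograms, and per-specimen summary tables.
5. **Deposits / qVRI**: xenobiotic deposit detection (library-augmented or
   residual-anomaly), biomolecule-signal subtraction to recover pure
   deposit spectra, cosine comparison against parent-drug references,
   kernel-density drug–biomolecule context, 3D connected-component
   particle sizing, and arbitrary-unit relative-abundance maps for the
   785-nm branch.

No public datasets exist for this modality, so `qramanomics.synthetic`
generates every input with full ground truth — component peak spectra,
water band, matrix blank, phantom series, depth-attenuated organoid-like
stacks, deposits, cosmic-ray spikes — and the test suite measures the
pipeline against that truth.

## Worked example

```python
import numpy as np
from qramanomics import PreprocessConfig, preprocess_stack, unmix_stack
from qramanomics import synthetic as syn
from qramanomics.calibration import (build_reference_library,
                                     fit_concentration_series, preprocess_series)
from qramanomics.chemotyping import pearson_colocalization, specimen_summary

config = PreprocessConfig()
axis = syn.make_axis()                      # 0-3600 cm^-1 instrument grid
models = syn.default_peak_models()          # six endmember peak models
blank = syn.simulate_blank(axis)            # agarose/PBS matrix blank

# 1. calibrate a unit-scaled library from simulated tissue-phantom series
fits = []
for model in models:
    series = syn.simulate_phantom_series(model, seed=0)
    fits.append(fit_concentration_series(preprocess_series(series, blank, config)))
library = build_reference_library(fits)

# 2. simulate a noisy organoid-like stack with known concentration fields
truth = syn.make_organoid_truth(shape=(5, 20, 20), seed=42)
quiet = syn.simulate_organoid_stack(truth, models)
truth.noise_sd = syn.noise_sd_for_snr(quiet, target_snr=20.0)
stack = syn.simulate_organoid_stack(truth, models)

# 3. preprocess (532-nm branch) and unmix into absolute concentrations
pre = preprocess_stack(stack, blank, config, branch=532)
cmap = unmix_stack(pre, library)

print(specimen_summary(cmap).round(1)[["unit", "mean", "median", "p95"]])
r = pearson_colocalization(cmap)
i, j = r.component_names.index("protein"), r.component_names.index("total lipid")
print(f"\nprotein/total-lipid Pearson r = {r.r[i, j]:+.3f} over {r.n_voxels} voxels")
err = np.abs(cmap.component_values("protein") - truth.fields["protein"])
rel = err[cmap.valid_mask] / truth.fields["protein"][cmap.valid_mask]
print(f"median |relative error| on protein vs ground truth = {np.median(rel):.1%}")
```

Output:

```
                unit  mean  median    p95
component
protein        mg/mL  99.8    99.9  148.6
DPPC           mg/mL  29.9    29.6   45.8
POPC           mg/mL  20.5    20.3   31.6
nucleic acids  mg/mL  30.1    30.3   43.1
glycogen       mg/mL  40.6    40.9   58.8
cytochrome c   ug/mL  50.1    49.4   76.5
total lipid    mg/mL  50.3    48.9   71.2

protein/total-lipid Pearson r = -0.189 over 2000 voxels
median |relative error| on protein vs ground truth = 1.4%
```

The summary rows are per-voxel concentration statistics over the 2000
valid voxels (the simulated fields were drawn around 100 mg/mL protein,
30/20 mg/mL DPPC/POPC, and so on — the unmixed means land on top of
them); "total lipid" is the derived DPPC + POPC channel. At a mean voxel
SNR of 20, the unmixed protein map deviates from the generating field by
1.4% (median).

A `qramanomics` console script exposes the same pipeline
(`simulate`, `preprocess`, `calibrate`, `unmix`, `chemotype`,
`deposits`); each subcommand's `--help` lists its options.

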