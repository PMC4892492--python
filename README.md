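# aladdin-acbv

Quantification of **arterial cerebral blood volume (aCBV)** from multiphase,
inter-slice-labeled balanced-SSFP ASL — the ALADDIN (alternate
ascending/descending directional navigation) acquisition scheme.

In sequential 2D bSSFP imaging, every slice's RF train saturates blood
flowing toward subsequent slices, so ascending and descending slice orders
act as label and control without any dedicated labeling pulses.  A long
bSSFP pulse train also drives slow (capillary/tissue) blood into its steady
state while fast arterial blood escapes after few pulses — the signal
difference between orders is therefore dominated by the *arterial*
compartment.  Fitting the nine-phase time course of that difference yields
the arterial flow parameter F, the arterial-compartment transit time δ, and
the labeling-plane→slice travel time ATT, from which

    aCBV = F · δ   (mL blood per 100 mL tissue, with δ in minutes)

The package is aimed at ASL methodologists: it contains the full model
stack plus the simulation machinery needed to validate it without scanner
data.

## What's inside

| module | contents |
| --- | --- |
| `signal_models` | bSSFP decay factor ρ, steady state, transient response |
| `kinetic_models` | arterial input function, residue function, T1 model, bSSFP model, aCBV |
| `sss_model` | venous (superior sagittal sinus) labeling model, labeling-efficiency estimation |
| `bloch_sim` | isochromat Bloch simulator of flowing labeled spins; Monte Carlo accuracy study |
| `recon` | 8-type ALADDIN image combination, phase timing, S0 estimation |
| `fitting` | voxel-wise bounded NLLS (`KineticModelFitter`, scikit-learn style), maps, ROI stats, region growing |
| `synthetic_data` | digital phantom generator (full 8-type datasets + ground truth) |
| `cli` / `config` / `io` | `aladdin-acbv` command line, validated YAML config, NIfTI+JSON I/O |

The model curves are

* **T1 model** — delivery `2αF'e^(−ATT/T1b)` ending at ATT, convolved with
  the residue function `e^(−t/δ)` and T1 recovery `e^(−t/T1b)`;
* **bSSFP model** — the same delivery, but signal acquired during the
  readout decays with the continuous bSSFP envelope `ρ^(t/TR)`,
  `ρ = E2 sin²(FA/2) + E1 cos²(FA/2)`, instead of T1 alone.

See `docs/methods.md` for the full derivations, conventions and numerical
choices.

## Worked example

Simulate a small noiseless phantom, estimate the labeling efficiency from
its sinus voxels, and fit every gray-matter voxel:

```bash
$ printf 'phantom:\n  shape: [24, 24]\n' > cfg.yaml
$ aladdin-acbv simulate --config cfg.yaml --seed 7 --out run
INFO aladdin_acbv: phantom written to run

$ aladdin-acbv sss --data run --out sss.json
INFO aladdin_acbv: labeling efficiency: 0.10516163083133206

$ aladdin-acbv fit --config cfg.yaml --data run --out fit
INFO aladdin_acbv: fitting 145 voxels (model=bssfp, alpha=0.208, S0=0.5)
INFO aladdin_acbv: GM aCBV = 2.170 +- 0.000 mL/100 mL over 141 voxels

$ cat fit/roi_summary.csv
quantity,mean,sd,n_voxels
F,196.99999999998548,2.842170943040401e-14,141
delta,661.00000000006,1.1368683772161603e-13,141
ATT,627.9999999999909,1.1368683772161603e-13,141
aCBV,2.170283333333371,0.0,141
```

The phantom's gray matter was generated with F = 197 mL/100 mL/min,
δ = 661 ms, ATT = 628 ms, so the fit recovers the generating kinetics to
machine precision and the aCBV (197·661/60000 = 2.17 mL/100 mL) lands in
the physiological gray-matter range.  The SSS estimate is the mean of the
first two phases — the interval during which vein-labeled blood is still
traversing the 36-mm inter-slice gap (ε ≈ 277 ms at 13 cm/s).  The same
library calls are available programmatically
(`make_phantom → combine_aladdin → KineticModelFitter.fit`), and
`aladdin-acbv montecarlo` runs the simulation study below.

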