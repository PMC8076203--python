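# pmri — variable-density sampling and GRAPPA/NL-GRAPPA reconstruction for Cartesian parallel MRI

`pmri` is a toolkit for studying how the *distribution* of phase-encode
lines in an undersampled Cartesian acquisition affects auto-calibrated
parallel-MRI reconstruction. It implements

* **line-based undersampling masks**: the traditional single-ORF pattern
  (full ACS block + one line in every *R*), **VDS** (variable-density
  sampling, which trades ACS lines for a low-ORF band near the centre), and
  **MVDS** (multiple-variable-density sampling, which keeps the ACS block
  intact and instead trades outermost density for a low-ORF band — several
  outer reduction factors increasing from the centre outwards);
* **GRAPPA**: missing line `S_j(k_y + rΔk_y, k_x)` synthesized per target
  coil *j* as a linear combination of acquired neighbours
  `S_l(k_y + bRΔk_y, k_x + hΔk_x)` over all coils *l*, blocks *b* and
  columns *h*, with weights fitted on the ACS block by least squares
  (`b = A x`);
* **NL-GRAPPA**: the same fit after an explicit second-order polynomial
  feature lift (constant, first-order terms, squares, adjacent- and gap-2
  column products; `N_k = 1 + 4·L·N_b·N_h` features), the truncated feature
  space of the polynomial kernel `(aᵢᵀaⱼ + 1)²`;
* **metrics**: root-sum-of-squares coil combination
  `I_sos = sqrt(Σ_l |I_l|²)`, artifact power
  `AP = Σ_ROI(|I_ref| − |I_rec|)² / Σ_ROI |I_ref|²`, SNR in dB, difference
  maps, and the net acceleration `R_net = N_full / N_sampled`;
* **a simulator** for multi-coil phantom acquisitions (analytic
  Shepp-Logan, smooth Gaussian blobs, or generic "speckle" images; smooth
  Gaussian or pure-spatial-harmonic coil sensitivities; seeded complex
  Gaussian noise) — including the SMASH-exactness fixture in which
  harmonic coils make every missing line an exact linear combination of
  acquired ones, a numerical correctness oracle for GRAPPA-type methods.

The central experimental question it reproduces: at a **fixed total line
budget and fixed ACS size**, sampling the near-centre k-space more densely
(and the periphery more sparsely) lowers reconstruction error, especially
when ACS lines are scarce, whereas shrinking the ACS block (VDS) backfires.

## Worked example

Compare the three schemes at a matched budget of 38 of 128 phase-encode
lines (8 coils, smooth phantom, noise σ = 0.02, GRAPPA, 15×2 kernel):

```python
from pmri.experiment import RunConfig, run_experiment

cfg = RunConfig.model_validate({
    "simulation": {"matrix": 128, "coils": 8, "phantom": "blobs",
                   "sensitivities": "smooth-gaussian",
                   "noise_sigma": 0.02, "seed": 0},
    "schemes": [
        {"name": "tradition", "kind": "uniform", "acs": 8, "r_nom": 4},
        {"name": "vds", "kind": "vds", "acs": 6, "r_nom": 4,
         "low_orf": 2, "low_orf_lines": 3},
        {"name": "mvds", "kind": "mvds", "acs": 8,
         "bands": [[2, 10], [4, 10], [6, 10]]},
    ],
    "recon": {"method": "grappa"},
})
print(run_experiment(cfg).to_string(index=False))
```

prints

```
   scheme method  lines_ACS  lines_R4  total_lines  r_net  ap_percent  snr_db  lines_R2  lines_R6
tradition grappa          8        30           38   3.37        2.56   16.17       NaN       NaN
      vds grappa          6        29           38   3.37        5.05   13.75       3.0       NaN
     mvds grappa          8        10           38   3.37        0.67   21.81      10.0      10.0
```

All three schemes sample 38 lines (`R_net = 128/38 = 3.37`), but MVDS —
which keeps all 8 ACS lines and redistributes the outer budget into bands
at ORF 2/4/6 — cuts the artifact power from 2.56 % to 0.67 % and raises
SNR by 5.6 dB, while VDS (which gave up two ACS lines) is worse than the
traditional pattern. That is the qualitative behaviour reported for this
family of sampling schemes.

The same pipeline is scriptable from a shell:

```
pmri simulate --coils 8 --matrix 128 --phantom blobs --noise 0.02 -o k.h5
pmri mask --scheme mvds --ny 128 --acs 8 --bands 2:10,4:10,6:10 -o mask.json
pmri recon --method grappa -i k.h5 -m mask.json -o recon.h5
pmri eval -i recon.h5 -r k.h5 -o metrics.json
```

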