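# fa-relax

Quantitative analysis of focal-adhesion (FA) disassembly after actomyosin
relaxation, for cell biologists and biophysicists studying adhesome
mechanosensitivity.

When Rho-kinase is inhibited (e.g., with Y-27632), the tension on focal
adhesions collapses and their component proteins dissociate — each at its
own characteristic rate.  This package links two independent measurements
of that process:

* **FRAP**: a reaction–diffusion exchange model of fluorescence recovery
  after photobleaching a Gaussian spot on an FA, fit to extract each
  protein's apparent on-rate k_on and off-rate k_off (with the cytoplasmic
  diffusion coefficient D_C and pool sizes N_FA, N_C entered as fixed
  inputs);
* **Live-cell imaging**: segmentation (top-hat + robust threshold +
  marker-controlled watershed), tracking, photobleach correction, and
  survival / normalized intensity-decay curves of individual adhesions in
  time-lapse movies, with single-exponential time constants τ.

The bridge is the disassembly statistic

```
K_dis = k_off − k_on          y(t) = exp(−K_dis · t)
```

which predicts a mono-exponential disassembly curve reaching 1/e (≈37%) of
its initial value at t = 1/K_dis.  The package compares this FRAP-derived
prediction against the curve measured directly from movies.  A synthetic
data module generates FRAP traces and FA movies with known ground truth,
so the entire chain is verifiable without external data.

## Worked example

Run the full synthetic experiment — three proteins whose FRAP rates and
movie decay constants derive from one shared ground truth:

```python
from fa_relax.workflow import demo_config, run_pipeline

report = run_pipeline(demo_config(seed=1))
for name, e in report["proteins"].items():
    print(f"{name:15s} K_dis={e['k_dis_per_min']:.4f}/min "
          f"tau_meas={e['tau_measured_min']:.1f} min "
          f"RMS={e['rms']:.3f} ratio={e['rate_ratio']:.2f}")
```

prints

```
zyxin-like      K_dis=0.1359/min tau_meas=7.7 min RMS=0.028 ratio=1.05
paxillin-like   K_dis=0.0654/min tau_meas=16.5 min RMS=0.041 ratio=1.08
vinculin-like   K_dis=0.0397/min tau_meas=27.4 min RMS=0.053 ratio=1.16
```

Reading this: the fast (zyxin-like) protein's fitted FRAP rates give
K_dis = 0.136 min⁻¹, predicting a disassembly time constant
1/K_dis ≈ 7.4 min; the movie-measured intensity-decay τ is 7.7 min.  The
predicted and measured curves differ by an RMS of 0.03 on the [0, 60] min
window and their implied rates by 5%; across proteins the rate ranking is
fully concordant (report["ranking_concordance"] == 1.0).  The slight
excess of the rate ratio above 1 reflects that the prediction neglects
diffusion and so runs a little fast — the expected direction.

The same stages are exposed on the command line:

```
fa-relax simulate-movie --seed 3 --out demo/
fa-relax segment --movie demo/movie.tif --pixel-size 0.16 --out demo/records.csv
fa-relax track --records demo/records.csv --pixel-size 0.16 --out demo/lifespans.csv
fa-relax run --seed 1 --out demo-run/
```

## Library layout

| module | contents |
|---|---|
| `fa_relax.frap_model` | reaction–diffusion FRAP solver, pure-diffusion closed form, normalization/averaging, D_C fit, exchange fit, R_f / T_1/2 |
| `fa_relax.synthetic_data` | FRAP-curve and FA-movie generators with ground-truth tables |
| `fa_relax.adhesion_imaging` | background subtraction, watershed segmentation, 30+ features, bleach correction, ratio images |
| `fa_relax.adhesion_tracking` | greedy nearest-neighbor linking, lifespans, peripheral/central classification |
| `fa_relax.kinetics_analysis` | survival & intensity-decay curves, exponential fits, K_dis, predicted-vs-measured comparison |
| `fa_relax.workflow` | configuration, seeding, the end-to-end pipeline, report output |

See `docs/methods.md` for the model, its assumptions, numerical choices
and limitations.

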