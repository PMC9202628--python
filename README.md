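# aquaforecast

Denoising and one-step-ahead forecasting of aquaculture water-quality sensor
series — dissolved oxygen, water temperature, salinity — sampled at fixed
(typically 10-minute) intervals.

Sensor records from sea-farming sites are noisy and non-stationary: a slow
seasonal drift, a strong diurnal cycle, weather-driven disturbances and
instrument noise are superimposed. Forecasting the next reading accurately
matters for husbandry (e.g. keeping dissolved oxygen above safe levels), and
works much better after the noise is stripped out and the forecaster's
hyperparameters are tuned rather than guessed.

## Method

The package chains four pieces:

1. **Variational mode decomposition (VMD).** The series x(t) is split into k
   band-limited intrinsic mode functions u_k with center frequencies w_k by
   minimizing the summed mode bandwidths subject to Σ_k u_k = x, solved with
   ADMM in the frequency domain. The pair (k, α) — mode count and bandwidth
   penalty — is chosen by **relative entropy**: an EMD sift bounds k from
   above, then k = 2..k_max (at α = 1000) and α = 1000..2000 (step 50) are
   scored by D(p‖q) = Σ p log(p/q) between amplitude histograms of the
   original series (p) and the mode-sum reconstruction (q); the minimum wins.
2. **Correlation-gated wavelet-packet denoising.** Modes whose |Pearson
   correlation| with the original series is below 0.5 are treated as
   noise-dominant and cleaned by wavelet-packet thresholding (sym8, 3
   levels) with the universal threshold
   λ = (median|W₁ⱼ|/0.6745)·√(2 ln N), using a soft/hard compromise rule;
   the cleaned series is the sum of kept and denoised modes.
3. **Improved whale optimization algorithm (IWOA).** A whale-style
   metaheuristic (encircling, spiral bubble-net, random search) minimizes
   validation MSE over six GRU hyperparameters: learning rate, epochs, two
   hidden-layer widths, batch size, window length. The improvement replaces
   the linear decay of the convergence factor with a cubic one,
   a(t) = (a_init − a_final)·((T_max − t)/T_max)³, which accelerates early
   convergence while preserving late local search.
4. **GRU forecaster.** A two-layer gated recurrent unit network (update gate
   z, reset gate r, candidate state h̃, h_t = z⊙h̃ + (1−z)⊙h_prev) with a
   linear head, written in numpy with full backpropagation through time,
   Adam, and gradient clipping; trained on sliding windows for one-step-ahead
   prediction. Test performance is reported as MAE, MSE and R² on the
   original physical scale.

A synthetic-data module generates both multi-tone test signals and simulated
sensor series (trend + diurnal cycle + AR(1) disturbance + white noise), so
everything is testable without external data.

## Worked example

```python
import numpy as np
from aquaforecast import (WaterSimSpec, gen_water_series, VMDConfig,
                          PipelineConfig, IWOAConfig, run_pipeline,
                          small_search_space)

noisy, clean = gen_water_series(WaterSimSpec(n_days=6, seed=0))  # 864 samples
cfg = PipelineConfig(vmd=VMDConfig(k=3, alpha=1350),
                     iwoa=IWOAConfig(pop_size=6, t_max=10),
                     space=small_search_space(), seed=0)
res = run_pipeline(noisy, cfg)
print(f"MAE {res.metrics.mae:.4f}  MSE {res.metrics.mse:.5f}  R2 {res.metrics.r2:.4f}")
print("mode correlations:", np.round(res.correlations, 3),
      "denoised:", res.denoised_indices)
```

prints (about a minute on one core):

```
MAE 0.0304  MSE 0.00153  R2 0.9954
mode correlations: [0.967 0.271 0.089] denoised: [1, 2]
```

The first mode (trend + daily cycle) correlates 0.967 with the raw series
and is kept; the two noise-dominant modes fall below the 0.5 cutoff and are
wavelet-denoised. The tuned GRU then predicts the held-out last 20% of the
series with R² ≈ 0.995 on the original mg/L scale — versus MSE 0.00190 for
the same model with default hyperparameters.

There is also a CLI:

```bash
aquaforecast simulate --out water.csv --n-days 6 --seed 1
aquaforecast denoise --input water.csv --column temp --k 3 --alpha 1350 --out clean.csv
aquaforecast run-all --input water.csv --column rjy_con --small-space \
                     --pop-size 6 --t-max 10 --seed 0 --out-dir results/
```

Real sensor CSVs with columns `rjy_con` (dissolved oxygen), `temp`, `salt`
and an optional ISO-8601 timestamp column are read the same way.

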