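# respmotion

Respiratory-motion modelling for image-guided radiotherapy research:
synthetic breathing-signal simulation, wavelet denoising, and a
latency-compensating multi-task neural network that jointly

1. classifies each signal's motion range into four clinical amplitude bins
   (0–4, 4–6, 6–8, ≥8 mm peak-to-trough),
2. predicts future tumor-surrogate position across 50–500 ms latency
   horizons (the reaction delay of gating/tracking delivery systems),
3. reconstructs a physiologically coherent clean breathing curve from a
   16-dimensional latent code, and
4. flags excessive motion (≥ 9 mm), the level at which common planning
   margins and gating tolerances are exceeded.

It is aimed at researchers prototyping motion-management algorithms who need
a fully reproducible, label-complete stand-in for clinical surrogate data,
together with the standard evaluation protocol (confusion matrix, per-class
precision/recall/F1, one-vs-rest AUC, per-axis and per-latency RMSE,
reconstruction MAE).

## Model

Signals are three-axis (SI/AP/LR) displacement traces. The generator uses
the standard breathing model *z(t) = z₀ − b·cos²ⁿ(πt/τ − φ)* with per-cycle
amplitude modulation, period jitter, baseline drift, cough-like transients
and sensor noise; every record carries its noise-free component, from which
the motion label (mean per-cycle EROM) is measured.

After per-axis DWT denoising (db4, level 4, soft universal threshold) and
per-record min-max normalization, 6 s windows feed a hybrid network:

    dilated causal convolutions (32 ch, k=3, d=1/2/4/8, layer norm,
    spatial dropout)
      → bidirectional LSTM (H=64, outputs concatenated)
      → trunk summary → encoder → z ∈ R¹⁶ → decoder → reconstruction x̂
      → softmax motion-range head, per-horizon regression head
        (persistence-anchored offsets), sigmoid excessive head

trained by minimizing
λ_cls·CE + λ_reg·MSE + λ_rec·MAE(x, x̂) + λ_exc·BCE with adaptive-moment
gradient descent. The implementation is a compact NumPy deep-learning core
with explicit backpropagation — single CPU, fully deterministic per seed.
See `docs/methods.md` for the full model description and design rationale.

## Worked example

```bash
python examples/latency_baselines.py
```

prints the latency sweep of the persistence baseline on a pure 4 s sine next
to its closed form `0.5·√(1 − cos ωhΔt)`:

```
bin (ms)    persistence   closed form   linear extrapolation
40-50       0.0277        0.0278        0.0022
100-150     0.0831        0.0831        0.0131
200-300     0.1649        0.1651        0.0455
400-500     0.2703        0.2706        0.1178
```

Errors are in normalized amplitude units (fractions of the record's motion
range): a persistence controller at a 400–500 ms latency is off by ~27 % of
the breathing amplitude, which is why learned prediction is needed.
`examples/simulate_cohort.py`, `examples/denoise_and_segment.py` and
`examples/train_and_predict.py` walk through cohort generation, denoising /
cycle segmentation, and a desk-scale training run with its evaluation
report.

A command-line surface covers the same pipeline for shell use:

```bash
respmotion simulate   --config run.json --out runs/sim
respmotion preprocess --config run.json --manifest runs/sim/manifest.json --out runs/w.npz
respmotion train      --config run.json --data runs/w.npz --out runs/model.npz
respmotion evaluate   --config run.json --data runs/w.npz \
                      --checkpoint runs/model.npz --out runs/report.json
respmotion predict    --config run.json --checkpoint runs/model.npz \
                      --signal runs/sim/P00000S00.csv --out runs/pred.json
```

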