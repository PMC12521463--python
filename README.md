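# tvbold

Total-variation denoising of multi-echo BOLD fMRI time series and
dynamic T2\* mapping.

## What it is for

Multi-echo fMRI records several gradient-echo images per repetition
time.  Under the monoexponential decay model

    e = S0 · exp(−TE / T2*)

the echoes at each frame determine the voxel's effective transverse
relaxation time T2\* — a quantitative, time-unit-valued alternative to
arbitrary-unit BOLD signals.  The catch is that the log-linear fit
amplifies echo noise, so T2\* time courses from raw echoes oscillate
wildly even though the underlying physiological BOLD signal is smooth.

`tvbold` restores each voxel × echo time course `b` by minimising the
1D TV–l2 (Rudin–Osher–Fatemi) objective

    G(u) = ‖D u‖₁ + (μ/2) ‖u − b‖₂²

with a partially inexact ADMM (steepest-descent inner steps with exact
line search, soft-threshold difference update, multiplier ascent).
Penalising total variation removes isolated spikes and broadband noise —
disturbances no frequency filter or component-removal method can take
out — while the fidelity term preserves local signal means, which is
exactly what unbiased T2\* fitting needs.  Dynamic T2\* maps are then
fitted frame by frame with an amplitude²-weighted log-linear fit, and
signal quality is quantified with tSNR, CNR, hemodynamic-response
similarity, Wilcoxon rank-sum comparisons and FDR-controlled ROIs.

Intended users: fMRI methods researchers working with multi-echo
(e.g. three-echo) BOLD acquisitions who want smooth, quantitative
dynamic T2\* maps and reproducible quality metrics.

## Worked example

```python
import numpy as np
import tvbold as tb

design = tb.TaskDesign()                      # 30.025 s OFF / 21.35 s ON, 7 cycles
spec = tb.PhantomSpec(dims=(8, 8, 2), design=design, seed=0)
series, truth = tb.generate_phantom(spec)     # 3 echoes, 210 frames, SNR 50, spikes

denoised = tb.denoise_multi_echo(series)
t2_raw = tb.dynamic_t2star_map(series)
t2_den = tb.dynamic_t2star_map(denoised)

err_raw = np.sqrt(np.nanmean((np.where(t2_raw.valid, t2_raw.t2star, np.nan)
                              - truth.t2star_series) ** 2))
err_den = np.sqrt(np.nanmean((np.where(t2_den.valid, t2_den.t2star, np.nan)
                              - truth.t2star_series) ** 2))
print(f"T2* RMSE vs truth: raw fit {err_raw:.2f} ms, TV-denoised fit {err_den:.2f} ms")

snr_raw, _ = tb.tsnr_map(series.echo(1))
snr_den, _ = tb.tsnr_map(denoised.echo(1))
print(f"median echo-2 tSNR: raw {np.nanmedian(snr_raw):.1f}, "
      f"TV-denoised {np.nanmedian(snr_den):.1f}")
```

prints

```
T2* RMSE vs truth: raw fit 3.43 ms, TV-denoised fit 1.89 ms
median echo-2 tSNR: raw 20.9, TV-denoised 40.3
```

The phantom's ground-truth T2\* is 40 ms (active voxels add a 2 ms
task-locked excursion): the raw frame-by-frame fit is off by ~3.4 ms RMS,
TV denoising roughly halves that error, and the temporal SNR of the
restored echo doubles.  The classic two-echo sanity check is one call:

```python
>>> tb.t2star_two_echo(20200, 12100, 15.00, 32.64)
34.42104674889114        # ms
```

## Command line

```bash
tvbold simulate --dims 16,16,4 --task --seed 0 --out-dir sim/
tvbold denoise  --echo-files sim/echo1.nii.gz --echo-files sim/echo2.nii.gz \
                --echo-files sim/echo3.nii.gz --te 15.00,32.64,50.28 --out-dir den/
tvbold t2map    --echo-files den/denoised_echo1.nii.gz ... --te 15.00,32.64,50.28 \
                --out-dir t2/
tvbold qc       --series den/denoised_echo2.nii.gz --metric tsnr --out qc/
tvbold roi      --echo2 sim/echo2.nii.gz --design design.json --out roi/
```

All inputs and outputs are NIfTI-1 (one 4D file per echo); every output
directory gets a provenance JSON.

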