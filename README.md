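# qmrisim

Scanner-free validation of open-source MRI pulse sequences: build
inversion-recovery spin-echo (IRSE) and turbo spin-echo (TSE) protocols in
a Pulseq-dialect `.seq` text format, execute them with an isochromat Bloch
simulator on numerical phantoms, reconstruct the Cartesian raw data, and
fit quantitative T1/T2 maps — the full acquisition-to-quantification chain
that cross-site repeatability studies run on real scanners, reproduced
end-to-end in software.

It is written for MR physicists and students who want to prototype,
audit, or teach spin-echo protocols without scanner time: every nominal
parameter (TR, TE, TI, echo spacing, slice count) is realized as an
explicit event timeline and can be *measured back* from that timeline by
the built-in timing auditor, and every image is traceable to closed-form
Bloch physics.

## Core models

**Bloch simulation.** Each nonzero voxel of a phantom becomes an
isochromat with proton density, T1, T2 and position. RF pulses are
hard-pulse rotations at the pulse center; between pulses the state evolves
in closed form,

    Mxy(t+dt) = Mxy(t) · exp(−dt/T2) · exp(−i·2π·∫ g(τ)·r dτ)
    Mz(t+dt)  = M0 + (Mz(t) − M0) · exp(−dt/T1),

with gradient phase integrated analytically over trapezoids (no
time-stepping error). The raw signal is the proton-density-weighted sum of
transverse magnetization at each ADC sample, stored in the
(samples × channels × readouts) layout.

**Quantitative mapping.** Voxel-wise bounded least squares of the standard
magnitude signal equations

    T1:  S(TI) = | A·(1 − 2·e^(−TI/T1) + e^(−TR/T1)) + B |
    T2:  S(TE) =   A·e^(−TE/T2) + B

with per-sphere ROI statistics, via a statsmodels-style
`RelaxometryModel(...).fit()` front end.

**Reconstruction.** Acquisition-order correction → optional n-point 2D
Hamming apodization → centered 2D inverse FFT → sum-of-squares channel
combination → joint [0, 1] normalization across slices/contrasts.

## Worked example

Simulate the 23-echo multi-echo TSE T2-mapping protocol (TE = 7…161 ms in
7 ms steps, TR 4.5 s) at a 32×32 desk scale on a synthetic T2 sphere
plane, reconstruct one image per echo, and fit the T2 map from echoes
5–23:

```python
from qmrisim import ExperimentConfig, run_experiment

summary = run_experiment(ExperimentConfig(
    preset="tse_t2map", outdir="out/t2demo", scale=4, seed=0))
for row in summary["roi_table"][:4]:
    print(f"sphere {row['roi']}: true T2 {row['truth_s']*1e3:5.1f} ms, "
          f"fitted median {row['median_s']*1e3:6.2f} ms (n={row['n']})")
```

prints

```
sphere 0: true T2  20.0 ms, fitted median  20.00 ms (n=4)
sphere 1: true T2  30.0 ms, fitted median  30.07 ms (n=8)
sphere 2: true T2  45.0 ms, fitted median  45.02 ms (n=8)
sphere 3: true T2  60.0 ms, fitted median  60.02 ms (n=8)
```

i.e. the pipeline recovers the phantom's transverse relaxation times to a
fraction of a percent from fully simulated raw data. `out/t2demo/`
additionally holds the generated `.seq` file, raw k-space and images
(HDF5), a PNG montage of the 23 echo images, the fitted T2 map and a
reproducible JSON summary.

The same presets are available from the shell:

```bash
qmri seqgen --preset irse_acr --out out/seq        # write .seq + timing audit
qmri run --preset irse_t1map --scale 4 --out out/t1demo
qmri rfpower --seq out/seq/irse_acr.seq            # relative RF power
```

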