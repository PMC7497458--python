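# petsr — anatomy-prior super-resolution for gated cardiac PET

Cardiac PET of small animals is degraded by two coupled effects: the
heart beats several times per second, smearing activity over the
cardiac cycle, and the scanner point-spread function (~1.5 mm FWHM) is
comparable to the thickness of the rodent left-ventricle wall, so the
partial-volume effect depresses the apparent wall uptake. ECG gating
removes the motion blur but leaves each gate starved of counts.

`petsr` implements an image-domain super-resolution (SR) method that
fuses the gated low-resolution PET frames with motion fields estimated
from a simultaneously acquired high-resolution anatomical cine
(B-mode-ultrasound-like), restoring a single high-resolution,
motion-frozen activity map. It is aimed at researchers working on
preclinical cardiac PET motion correction and partial-volume recovery
who want a desk-scale, fully synthetic, ground-truthed testbed for the
whole chain.

## Model

Each gated frame is a degraded view of the high-resolution reference
activity `H`:

    Γ_i = B D M_i H + Ψ_i,   i = 1 … N_f

with `M_i` the cardiac motion at gate *i*, `D` linear decimation by an
integer factor, `B` a Gaussian PSF (FWHM in mm) and `Ψ_i` count noise.
The maximum-a-posteriori estimate with a total-variation prior,

    Ĥ = argmin_H  ½ Σ_i |Γ_i − B D M_i H|² + λ TV(H),

is computed by steepest descent

    H^{n+1} = H^n + (1/N_f) Σ_i M_i⁻¹ D⁻¹ (Γ_i − L_i^n) + λ ∇·(∇H^n/|∇H^n|),

where `L_i^n` is the frame simulated from `H^n`, the back-projector
replaces `B⁻¹` by a one-pixel delta, and `M_i⁻¹ ≈ −M_i`. The iteration
starts from the motion-corrected (MoCo) average and stops when the
data RMSE changes by less than 5 % between consecutive iterations.

The motion fields are estimated on the anatomical cine by a
demons-like variational registration combining an intensity term with
a monogenic **local-phase** term (log-Gabor even filter + Riesz odd
pair), with fluid (Gaussian) regularization of each additive update
and a 3-level coarse-to-fine pyramid — robust to the contrast
variability of ultrasound speckle.

Because no public gated PET/ultrasound pairs exist at this scale, the
`phantom` module generates a beating annular left ventricle (wall
activity 4, cavity/background 1, SUV-like) with *analytic* motion
fields, a tissue-attached speckle rendering, and the full
warp → decimate → blur → Poisson degradation, so every stage can be
validated against exact truth.

## Worked example

```sh
petsr all --seed 1 --out results/demo
```

runs phantom simulation → registration → static/MoCo/SR reconstruction
→ quality metrics and prints (abridged):

```
              wall_mean  wall_std  cavity_mean  contrast     snr_db  resolution_mm
gated_frame1   3.176694  0.200629     1.447268  1.194960  11.995814       0.958240
static         3.122840  0.128595     1.491667  1.093523  13.853251       0.966168
moco           3.148469  0.093177     1.453253  1.166497  15.287901       1.026380
sr             3.987936  0.248210     0.911735  3.374009  12.059296       0.566066
```

Reading the rows: the static average and the MoCo image under-read the
true wall activity of 4 by ~21 % (partial-volume loss), while the SR
estimate recovers it to 0.3 %; Weber contrast between wall and cavity
triples over the static baseline; and the wall line-spread resolution
(mean FWHM of Gaussian fits to the mirrored outer-edge profiles at
five sites) drops from ~0.97 mm to ~0.57 mm. Each stage is also
available separately (`petsr simulate`, `register`, `sr`, `evaluate`)
on multi-page TIFF or NIfTI-1 stacks carrying mm pixel spacing.

The same chain is available as a library:

```python
import petsr

res = petsr.run_pipeline(petsr.PipelineConfig(seed=1))
print(res.report.to_frame())
```

## Layout

- `petsr.phantom` — synthetic beating-heart generator with analytic truth
- `petsr.registration` — log-Gabor/Riesz local phase, demons registration
- `petsr.srcore` — forward operators, MoCo/static baselines, MAP/TV SR
- `petsr.metrics` — ROI statistics, SNR, Weber contrast, LSF resolution
- `petsr.io`, `petsr.pipeline`, `petsr.cli` — stacks on disk, orchestration

See `docs/methods.md` for the modelling assumptions, parameter
defaults and known limitations.
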