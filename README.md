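# speckleflow

Blood speckle imaging (BSI) is an ultrasound mode that tracks the
interference pattern of blood echoes across ultra-high-frame-rate frames to
produce 2D velocity vector fields of intracardiac flow — for example in the
left ventricular outflow tract before and after surgical relief of a
subaortic obstruction. The scanner's output is a multichannel cine: a tissue
brightness channel, a two-component velocity field, and a per-pixel
confidence level in [0, 1]. Clinical cine data of this kind is generally
restricted, which makes the quantification chain hard to validate.

`speckleflow` re-implements that chain end to end, and pairs it with a
synthetic speckle phantom whose flow field is known analytically, so every
stage can be validated against exact ground truth:

* **phantom** — point-scatterer speckle cine loops advected by analytic,
  pulsatile flow models (uniform, Poiseuille channel, symmetric top-hat jet,
  and an anteriorly deflected stenotic jet with posterior flow reversal),
  rendered through a Gaussian point-spread function at a clinical geometry
  (0.0825 mm/pixel, PRF 6 kHz);
* **tracking** — block-matching velocimetry: normalized cross-correlation
  over an integer-lag search restricted to the tracker's velocity limit
  (2 m/s by default), three-point sub-pixel peak refinement, and a
  confidence channel equal to the clamped NCC peak;
* **fields** — the validated `CineLoop` container, bilinear profile
  extraction along user-drawn lines, and cardiac-phase bookkeeping;
* **hemodynamics** — shear stress profiles τ = μ∂V/∂y, signed wall shear
  stress (WSS) series, and their cycle summaries

  TAWSS = (1/T) ∫₀ᵀ |WSS| dt,  OSI = ½ (1 − |∫₀ᵀ WSS dt| / ∫₀ᵀ |WSS| dt),

  plus peak-velocity traces and the simplified Bernoulli gradient
  ΔP = 4 v² mmHg;
* **cli / io** — an HDF5 cine container and a
  `simulate → track → quantify → report` command chain.

## Worked example

Run the default pre-operative-style scenario — a 1.5 m/s stenotic jet with
posterior recirculation, 50 frames over one compressed cardiac cycle:

```bash
speckleflow run --out run1 --seed 3
```

which simulates, tracks, quantifies and renders figures, printing

```json
{
  "bernoulli_mmhg": 8.122659138028453,
  "mean_confidence": 0.9877969977140427,
  "osi_anterior": 0.01871622949956131,
  "osi_posterior": 0.3502676915286466,
  "tawss_anterior": 0.12757284098750626,
  "tawss_posterior": 0.2381022141410834,
  "v_peak_mps": 1.4250139594078064
}
```

Reading the numbers: the tracked peak velocity along the mid-tract probe
line is 1.43 m/s (true phantom peak 1.5 m/s), giving a simplified Bernoulli
gradient of 8.1 mmHg. The posterior wall sees an oscillatory shear index of
0.35 — its WSS changes sign during systole as the jet detaches and a
retrograde recirculation develops — while the anterior wall stays
essentially unidirectional (OSI 0.02). Time-averaged wall shear stress is a
few tenths of a pascal at both walls. Running the same command with a
top-hat (post-operative-style) flow model instead drives the posterior OSI
to ≈ 0, reproducing the qualitative pre/post contrast reported for this
kind of repair.

The library surface mirrors the CLI:

```python
import speckleflow as sf

cine, truth = sf.generate_cine(sf.preop_like_flow(), sf.ImagingConfig(), seed=1)
tracked = sf.track_cine(cine, sf.TrackerConfig())
line = sf.LineProfile((5.24, 1.24), (5.24, 9.16))
series = sf.wall_series(tracked, line, "posterior")
print(sf.indicators(series))   # WSSIndicators(tawss=..., osi=...)
```

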