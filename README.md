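# beamgait

Posture and gait analysis for mice traversing a balance beam, from
markerless 2D tracking to quantitative walk-cycle statistics.

Balance-beam assays probe vestibular and motor function, but the usual
readouts (traversal time, stop counts) miss most of what the video
contains.  `beamgait` turns per-frame tracked feature points — 18 named
landmarks on the head (3), torso (4), tail (7) and feet (4), in the
DeepLabCut table convention — into:

- merged 2D coordinates from opposed 90° camera pairs, or full 3D
  postures from 45° stereo pairs, autocalibrated from three traced pairs
  of parallel scene lines (no calibration hardware), scaled to
  centimetres with the beam along x;
- per-frame speed vectors **V**(t) = **X**(t) − **X**(t − Δt) over all
  coordinates (36 components for 2D tracking, 54 for 3D);
- the **standard walk cycle (SWC)**: the speed waveform of one typical
  stride, obtained by segmenting the speed series into contiguous cycles
  (t_{i+1} = t_i + τ_i, periods searched from half to double a template
  cycle) that best correlate with a rescaled template, then averaging
  the cycles weighted by their correlation Cmax — with a file format
  that carries Σ Cmax so further videos refine the SWC as a running
  weighted mean;
- drift-free **synthetic walk animations**: the SWC is normalised so
  every point advances the same distance per period and integrated by
  Forward Euler from any starting posture;
- the **variance of correlation (VoC)**: per body-part group and per
  cycle, the population variance of the normalised cycle-to-SWC
  correlations (0 = no movement, 1 = match, >1 = faster, negative =
  opposite).  VoC is near zero during typical walking and spikes on
  slips, jumps, stops and head movements — a one-line-per-group anomaly
  trace over the run.

A fully ground-truthed gait simulator (2-3-3 support pattern, stance and
swing phases, period jitter, tracking noise, injectable stop / slip /
jump / phase-shift anomalies, stereo projection) ships as a first-class
module, so the entire pipeline is testable without animal data.

## Worked example

Everything below is reproducible from the command line (the library API
mirrors it one-to-one).  Simulate a noisy, period-jittered walk and
analyse it:

```
$ beamgait simulate --out fix --seed 1 --noise 0.05 --jitter 2
$ beamgait speed --table fix/pose3d_true.csv --config fix/config.yaml -o speed.csv
wrote speed.csv (201 frames x 54 components)

$ beamgait swc extract --speed speed.csv --config fix/config.yaml --auto \
      -o walk.swc --seg-out seg.csv
wrote walk.swc (tau=20, 10 cycles, weight=8.439)
```

The 54 components are x/y/z speeds of all 18 points.  The auto-detected
template has the true 20-frame stride period; 10 cycles were matched and
averaged with total correlation weight 8.44 (a weight of 1 means a cycle
that matches the template exactly; jitter and noise lower it).  The
segmentation CSV lists each cycle's start, period and weight:

```
$ head -5 seg.csv
t,tau,cmax
0,12,0.5097591607018289
12,22,0.9075932352170154
34,20,0.8331162705522553
54,22,0.8323103537526759
```

(the first 12-frame fragment is the partial cycle before the first full
stride boundary — the auto template's phase is arbitrary).  Comparing
every cycle back against the SWC gives the VoC per group and cycle:

```
$ beamgait voc --swc walk.swc --speed speed.csv --config fix/config.yaml \
      --out-prefix voc
wrote voc_corr.csv, _voc.csv, _events.csv (2 event(s) above 0.05)
$ head -3 voc_voc.csv
cycle,head,body,tail,feet
0,0.030594200557417812,0.007317430349377057,0.07719322309414492,0.21442779394743797
1,0.0006862513251776949,0.0016020055492085529,0.0017840828672308448,0.003003954921347943
```

Cycles of typical walking sit near zero (~0.001–0.003 here, the tracking-
noise floor); the partial first cycle deviates from the SWC and is
flagged.  An injected slip or jump raises the feet-group VoC by one to
two orders of magnitude at exactly the affected cycle (see
`tests/test_acceptance.py`).

3D reconstruction from the simulated 45° stereo pair, calibrated only
from the traced beam/box lines and the measured beam length:

```
$ beamgait reconstruct45 --left fix/tracking_left.csv --right fix/tracking_right.csv \
      --lines fix/calibration_lines.yaml --config fix/config.yaml -o rec3d.csv
wrote rec3d.csv (reprojection rms 0.000 px)
```

On noiseless projections the reconstruction is exact to machine
precision; with 0.5 px tracking noise the RMS 3D error stays below 2% of
the 60 cm beam length.

See `docs/methods.md` for the underlying models, parameter defaults and
their rationale, and known limitations.

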