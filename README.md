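# gema — real-time brightfield cell-culture segmentation

`gema` measures how much of a microfluidic culture chamber is covered by
adherent cells (e.g. MCF7) from label-free brightfield time-lapse images,
frame by frame, fast enough to run while the experiment is still going.
The percent-area trace it produces is the quantity an experimenter (or an
automated pump controller) watches to detect confluence during growth or
the decline of coverage during drug-induced apoptosis.

It is aimed at labs doing image-based lab-on-a-chip experiments who need a
headless, parameter-free-in-operation segmenter — no GUI, no per-frame
manual threshold fiddling.

## Method

Brightfield cells are hard to segment by intensity: they are nearly
transparent. What distinguishes them from the chamber background is
fine-grained **texture**. The adaptive engine exploits this:

1. **Preprocess** — grayscale `I = (R+G+B)/3`, CLAHE contrast enhancement,
   light Gaussian smoothing.
2. **Gabor filter bank** — the real part of

   `g(x, y) = (f²/πγη) · exp(−(x′²f²/γ² + y′²f²/η²)) · cos(2πf x′)`,

   with `x′ = x cosθ + y sinθ`, `y′ = −x sinθ + y cosθ`, evaluated at four
   orientations θ ∈ {0°, 45°, 90°, 135°} on a 21×21 grid spanning [−1, 1]
   (`f = 3`, `γ = 10`, `η = 0.5`). Kernels are mean-subtracted; the fused
   response is the pixel-wise max of the absolute orientation responses,
   normalized to [0, 255] with a gain cap so empty frames are not
   amplified into false texture.
3. **Online threshold scheduling** — each frame contributes its
   coefficient of variation `CV = σ/μ`. A running least-squares line
   `CV = m·x + b` over frame index x models the series and is refit
   whenever its mean absolute relative error over recent frames exceeds
   5%. The predicted CV is mapped linearly between the observed CV
   extremes onto an integer offset `C ∈ [5, 11]` — near confluence the
   image binarizes best with C close to 5, during apoptosis close to 11.
4. **Adaptive binarization + morphology** — a pixel is foreground iff its
   Gabor response exceeds its Gaussian-weighted local mean by more than
   `C`; binary closing then consolidates the texture ridges into solid
   cell regions.

A classical **morphological-gradient baseline** (dilation − erosion under
a 5×5 structuring element, fixed global threshold 25) is included for
comparison, along with pixel **accuracy** `(TP+TN)/n` and **Dice**
`2TP/(2TP+FP+FN)` evaluation against gold-standard masks, VIA polygon
annotation parsing with shoelace areas, and a seeded synthetic time-lapse
generator with exact ground truth.

## Worked example

`examples/segment_growth_sequence.py` generates an 8-frame synthetic
growth sequence (coverage ramping 15% → 70%) and runs both engines:

```
frame  true%  est%   CV      thr  dice(gema)  dice(gradient)
    0   15.8   23.0  0.1277   11       0.791           0.679
    1   17.3   25.1  0.1312   11       0.806           0.682
...
    4   48.7   48.1  0.1915   11       0.869           0.830
...
    7   70.1   60.3  0.1798   10       0.868           0.878

mean Dice: adaptive engine 0.832, gradient baseline 0.794
```

`true%` is the exact generated coverage, `est%` the engine's estimate,
`thr` the scheduled offset. The estimate tracks truth closely and the
adaptive engine outscores the fixed-threshold baseline on average.

The other examples show the controller refitting across a CV level shift
(`schedule_threshold_from_cv.py`), VIA polygons becoming masks and areas
(`annotations_to_masks.py`), and the evaluation report
(`evaluate_against_gold.py`).

## Command line

```bash
gema --dump-config > run.toml          # all defaults, editable
gema generate --output-dir fixture --seed 1     # synthetic sequence + truth
gema segment  --input-dir fixture/frames --output-dir run --engine gema
gema evaluate --output-dir run --gold-dir fixture/masks
gema watch    --input-dir incoming --output-dir run   # online polling mode
```

`segment` writes `masks/*.png` ({0,255}) and `trace.csv`
(`frame,filename,cv,threshold,percent_cells`); `watch` appends to the
trace after every frame, survives restarts without reprocessing, and stops
when a `STOP` file appears in the input directory.

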