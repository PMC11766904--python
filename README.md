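# eegdem

Screening for dementia from resting-state EEG, using spectrogram-image
representations and a convolutional classifier, evaluated without subject
leakage.

## The problem

Clinical EEG shows reproducible spectral signatures of neurodegeneration:
Alzheimer's disease (AD) slows the rhythm — theta power rises while the
posterior alpha rhythm and beta activity fade — and frontotemporal dementia
(FTD) shows theta elevation concentrated over frontal and temporal
electrodes.  `eegdem` turns a 19-channel 10–20 recording into a compact
*channel × frequency* image per 30 s epoch and lets a small CNN separate
AD / FTD / cognitively normal (CN) classes from those images.  It is aimed
at methods work in EEG-based dementia screening: every stage is an
inspectable, seeded, pure-Python implementation, and a synthetic cohort
generator with class-conditional spectra makes the whole pipeline testable
end to end on a laptop.

The critical methodological point the package enforces is **subject-disjoint
validation**: epochs of one subject are highly correlated, so k-fold
splitting over epochs lets a model recognize subjects rather than disease.
All evaluation here is leave-N-subjects-out (LNSO) — each diagnostic group
is split into K = 5 subject subsets, and every epoch stays on its subject's
side of every fold, which the code asserts per fold.

## Pipeline

1. **Preprocess** — re-reference to the linked-ear (A1+A2)/2 mean; zero-phase
   Butterworth 0.5–45 Hz; windowed burst rejection (a window is dropped when
   any channel's SD exceeds 17× its calibrated baseline on 0.5 s windows).
2. **Spectrogram images** — non-overlapping 30 s epochs (15,000 samples at
   500 Hz); an exact-length Cooley–Tukey FFT per channel, X_k = Σ_m x_m
   e^(−i2πkm/N), with the radix-2 split X_k = E_k + e^(−i2πk/N)·O_k for
   power-of-two N and a mixed-radix/Bluestein path otherwise (bin spacing
   1/30 ≈ 0.033 Hz); single-sided amplitudes over [0.5, 40) Hz give a raw
   19 × 1185 image, colormapped and bilinearly resized to 150 × 150 × 3.
3. **Classify** — a CNN of three conv/LeakyReLU(0.1)/maxpool/dropout blocks
   (32/64/128 filters of 3×3) and a 128-unit dense head with softmax output,
   trained with Adam on categorical cross-entropy (default 100 passes);
   implemented in plain numpy with hand-written backprop, so training is
   bit-exactly reproducible from its seed.
4. **Evaluate** — per-fold confusion matrices, pooled metrics, and fold
   accuracy summarized as mean ± sample SD with a Student-t 95 % interval
   (t₀.₉₇₅,K₋₁ · sd/√K).
5. **Baselines** — Welch relative band power on 2 s epochs (19 channels ×
   5 bands, rows sum to 1 per channel) feeding gradient-boosted trees,
   PCA+SVM, PCA+kNN, or a 96-unit MLP, through the same split machinery.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a small cohort, run the CNN pipeline on the AD-vs-CN problem:

```sh
eegdem simulate --out cohort --seed 5 --n-ad 2 --n-ftd 1 --n-cn 2 --duration 120
eegdem run --config small.cfg --out results/
```

or, from Python (this is the acceptance run; scaled-down sizes):

```python
from eegdem.config import RunConfig
from eegdem.pipeline import run_cnn_experiment

cfg = RunConfig(n_ad=8, n_cn=8, duration_s=300.0, seed=1, image_size=32,
                train_epochs=20, folds=4, problem="ad_cn")
report = run_cnn_experiment(cfg)
mean, sd, ci, lo, hi = report.summary()
```

which prints, via `scripts/acceptance.py --seed 1`:

```
LNSO CNN (ad_cn, K=4, seed=1) in 74 s
  mean accuracy 95.83%  sd 6.61%  95% CI ±10.52%  bounds [85.31, 106.36]
  pooled confusion (AD/CN):
      66     6
       0    72
```

Reading this: 16 synthetic subjects (8 AD, 8 CN, 300 s each) yield 144
30-second spectrogram images after preprocessing; across 4 subject-disjoint
folds the CNN classifies 138/144 held-out images correctly (6 AD epochs
were called CN).  The wide t-interval reflects K = 4 folds — with so few
folds the upper bound can exceed 100 %, which is a property of the t
approximation, not of the accuracy.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline's headline run from scratch — synthesizes the seeded
cohort, preprocesses, builds images, trains the CNN per fold under LNSO and
prints the summary above — then writes the acceptance JSON to `--out`.

## Layout

```
src/eegdem/
  io.py          EDF + fixture formats, Recording/SubjectMeta, participants
  synth.py       synthetic cohorts with class-conditional spectra
  preprocess.py  re-reference, band-pass, burst rejection, projection hook
  fourier.py     direct DFT oracle + Cooley–Tukey/Bluestein FFT
  spectrogram.py epoching and channel×frequency images
  cnn.py         the numpy CNN (build/train/predict/save)
  baselines.py   Welch band power + classical learners
  evaluate.py    LNSO splits, confusion aggregation, summaries
  pipeline.py    end-to-end orchestration
  cli.py         `eegdem simulate | run | baseline`
```
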