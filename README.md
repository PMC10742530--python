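# fishcut

Automatic identification of the head-cut position for whole fish on a
processing line, from line-laser surface scans.

In industrial fish pre-processing the head must be removed at the trailing
edge of the gill cover.  Cutting too far back wastes meat; cutting too far
forward hits the gill bones and damages the blade.  `fishcut` implements a
contactless pipeline for finding that position: a line-laser sensor above a
conveyor sweeps the fish and yields one radial height profile per frame;
the profiles are cleaned and condensed into the **ventral–dorsal
demarcation line** (the curve of per-frame maximum heights along the body);
that curve is reduced to a few principal components, which a trained
regressor maps to the head length in millimetres — the ideal cut position.

Because no raw scan data of this kind is openly deposited, the package
ships a first-class synthetic-scan simulator: parametric spindle-shaped
fish bodies, with size statistics matched to a measured crucian-carp
sample, scanned by a virtual line laser with Gaussian, impulse and
vibration noise.  Every downstream stage is developed and tested against
this generator's ground truth.

## Pipeline

1. **Threshold segmentation** — within each frame the fish body rises tens
   of millimetres above the conveyor, so the belt points are removed by
   scanning the absolute height differences of adjacent points: the fish
   run is bounded by the first and last jump exceeding a threshold *T*
   (default 5 mm).
2. **Denoising** — a scalar constant-position Kalman filter
   (process covariance 10⁻⁴ mm², measurement covariance 0.1 mm²) followed
   by an asymmetric sliding-window median filter (offsets −2…+1).
3. **Feature extraction** — per-frame maxima above the belt form the
   demarcation line, which is linearly resampled to *p* = 60 equally
   spaced positions.
4. **PCA** — Z-scored features, eigendecomposition of the correlation
   matrix *D* = ZᵀZ/(n−1); components kept up to 95% cumulative explained
   variance (three on this data); scores Fᵢ = Z Pᵢ/√λᵢ.
5. **Regression** — three identifiers trained on a 154/50 split of 204
   fish:
   * **LS-SVM**: RBF-kernel least-squares SVM, `[[0, 1ᵀ],[1, K + I/γ]]
     [b; α] = [0; y]` solved exactly; (γ, σ²) found by particle-swarm
     search over 5-fold cross-validated RMSE;
   * **PSO-BP**: a 3–10–1 sigmoid network whose 51 weights are first
     located by PSO (swarm 20, positions [−2,2], velocities [−1,1]), then
     refined by full-batch gradient descent (rate 0.09, goal MSE 10⁻⁵);
   * **LSTM**: a single-layer LSTM consuming the three scores as a 3-step
     sequence, trained by backpropagation through time with gradient-norm
     clipping at 1, learning rate 0.005, dropout 0.2 on the output path,
     200 epochs.
6. **Evaluation** — R², RMSE, MAE and the residual predictive deviation
   RPD = SD(y)/RMSE, with the usual reading: R² > 0.82 practically usable,
   R² > 0.9 excellent, RPD > 2.5 accurate and reliable.

## Worked example

```bash
fishcut run --seed 1 --out report/
```

simulates 204 fish, runs the full pipeline and prints:

```
fishcut 0.1.0 pipeline report
config_hash=3eb973caf8f5b321 seed=1
samples=204 (train=154, test=50)
feature_length=60 components=3 cumulative_variance=0.951837

model   split           R2   RMSE/mm    MAE/mm       RPD
lssvm   train       0.9641    0.3570    0.2879    5.2984
lssvm   test        0.9181    0.4887    0.3838    3.5307
psobp   train       0.9620    0.3677    0.3027    5.1442
psobp   test        0.9049    0.5268    0.3967    3.2754
lstm    train       0.9597    0.3785    0.3059    4.9980
lstm    test        0.9058    0.5243    0.4207    3.2911

lssvm: accurate_and_reliable, practical, excellent
psobp: accurate_and_reliable, practical, excellent
lstm: accurate_and_reliable, practical, excellent
```

Reading: the first three principal components carry 95.2% of the
demarcation-line variance; on the 50 held-out fish every identifier
predicts the head-cut position with an R² above 0.9 and an RMSE around
0.5 mm, and all three clear the RPD > 2.5 reliability band.

The same stages are available piecewise (`fishcut simulate`, `preprocess`,
`extract`, `pca`, `train`, `predict`, `evaluate`) and as library calls:

```python
import fishcut as fc

ds = fc.generate_dataset(204, fc.ScanConfig(), seed=1)
clean = fc.preprocess_cloud(ds.clouds[0])
line = fc.extract_demarcation_line(clean)
```

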