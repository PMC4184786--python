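# erclust

Quantitative analysis of protein-aggregate dynamics in the early secretory
pathway. When aggregation-prone proteins (e.g. Ig-µ chains lacking their first
constant domain) condense inside the endoplasmic reticulum, they form roundish
deposits — Russell bodies — that grow by apposition of newly made molecules
and move subdiffusively within the ER. `erclust` provides the two analyses
needed to quantify that behaviour from fluorescence microscopy, plus a
synthetic-data generator with known ground truth so the whole pipeline is
testable without raw movies:

1. **Cluster growth by two-color pulse-chase.** Old protein is labelled red,
   new protein green; each cluster's diameter per channel is the full width at
   half maximum (FWHM) of an intensity profile through its center, and growth
   is the relative size increase

   ```
   rel_increase = (d_g − d_r) / d_r
   ```

   summarised as mean ± SEM over clusters.

2. **Cluster mobility by single-particle tracking.** Clusters are detected
   per frame (Laplacian-of-Gaussian, sub-pixel refinement), linked by optimal
   bipartite assignment with a displacement gate, and each track's
   time-averaged mean-square displacement is fit over its first 20 lags with
   the anomalous-diffusion model

   ```
   MSD(t) = 4 D t^α
   ```

   giving a short-term diffusion coefficient `D` (µm²/s) and anomalous
   exponent `α` (α < 1 subdiffusive, 1 Brownian, ≈ 2 directed). Populations
   are summarised as mean ± SEM over tracks; arms (e.g. untreated vs
   nocodazole) are compared per parameter with two-sided Mann–Whitney U tests.

The generator simulates 2D fractional Brownian motion (Davies–Harte circulant
embedding with an exact Cholesky fallback) realising `MSD = 4Dt^α` exactly,
with optional drift and static localization error, and renders PSF-blurred
cluster images and movies with Poisson noise and full ground-truth tables.

## Worked example

```python
from erclust import msd, synth

cfg = synth.TrackSimConfig(D=0.0045, alpha=0.74, n_frames=300, frame_interval=0.5)
tracks = synth.simulate_population(cfg, n_tracks=115, seed=1)
fits = [msd.fit_anomalous(msd.compute_msd(t), n_points=20) for t in tracks]
print(msd.summarize_population(fits))
```

prints

```
PopulationSummary(mean_D=0.004511..., sem_D=2.797e-05..., mean_alpha=0.74949...,
                  sem_alpha=0.006476..., n_tracks=115, condition='untreated')
```

i.e. from 115 simulated tracks of 300 frames at 0.5 s the fits recover the
generating parameters — α ≈ 0.75 vs truth 0.74 and D ≈ 0.0045 µm²/s — with the
SEMs quantifying the track-to-track spread of the 20-point fits.

The `examples/` directory has one short script per capability:

| script | what it shows |
|---|---|
| `simulate_and_fit_msd.py` | population simulation → MSD → (D, α) recovery |
| `measure_cluster_growth.py` | rendered pulse-chase pairs → FWHM growth ≈ 16%, null control ≈ 0 |
| `track_rendered_movie.py` | movie rendering → detection → linking fidelity |
| `compare_conditions.py` | untreated vs treated arms: only D responds |
| `full_pipeline_report.py` | orchestrated end-to-end run with a reconciled report |

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computations from scratch at the study's sampling
scale — 99 rendered cluster pairs for the growth statistic, and two 115-track
populations (treated arm with D halved) for the MSD fits and the condition
comparison — printing the recovered growth percentage, α, D and the D ratio,
and writing the JSON result file.

See `docs/methods.md` for the models, assumptions, parameter defaults and
known limitations.
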