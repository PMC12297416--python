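# spt — diffusional HMM analysis of single-particle tracking in bacteria

`spt` turns single-molecule trajectories of intracellular proteins and tRNAs
— e.g. translation initiation factors tracked in live *E. coli* at
millisecond frame rates — into binding kinetics. A molecule that alternates
between a ribosome-bound and a freely diffusing population shows up in
tracking data as switching between slow and fast Brownian motion. This
package:

* **simulates** such data realistically: K-state Brownian motion confined to
  a spherocylindrical cell, Markov state switching, stroboscopic motion
  blur, localization noise, photobleaching-limited trajectory lengths, and
  detection gaps, with ground truth for validation;
* **fits** all trajectories jointly with a K-state diffusional hidden Markov
  model by maximum likelihood (Baum–Welch EM), with AIC comparison across
  model sizes. The per-step displacement of state k over n frames is
  Gaussian with per-dimension variance
  `v_k(n) = 2 D_k nΔt (1 − 2R/n) + 2σ²`, correcting for motion blur
  (R = t_E/6Δt) and localization error σ; gaps are handled exactly through
  matrix powers of the transition matrix;
* **coarse-grains** fitted states into labeled classes by thresholds on D
  (e.g. 1 and 8 µm²/s: bound / free / cleavage artifact) and computes class
  occupancies, stationary fluxes, and flux-based mean dwell times
  `τ_G = occ_G / outflux_G` — unbiased even when binding events outlast
  trajectories;
* **summarizes kinetics** across replicate experiments (means and
  between-experiment SDs, two-sided unpaired t-tests) and computes factor
  cycle times `T_cycle = τ_bound / occ_bound` against concentration-scaled
  thresholds to ask whether a factor binds ribosomes more than once per
  translation cycle;
* **maps** class-resolved spatial distributions into normalized cell
  coordinates (posterior-weighted occupancy heatmaps, e.g. nucleoid
  enrichment of transcription-associated states).

It is written for single-molecule biophysicists analyzing (or planning)
live-cell tracking experiments, and for method validation against synthetic
data with known truth.

## Worked example

```python
import spt

# simulate a 2-state experiment: D = (0.1, 3.0) µm²/s, dwells (0.3, 0.7) s,
# 3 ms pulses in 5 ms frames, 30 nm localization error, gaps, 3 replicates
cfg = spt.SimulationConfig(seed=7, n_traj=400)
ds, truth = spt.simulate_dataset(cfg)
ds = spt.filter_trajectories(ds)          # keep trajectories > 5 frames

print(f"{ds.n_trajectories} trajectories, {ds.n_cells} cells, {ds.n_steps} steps")

model = spt.fit(ds, K=2, n_starts=4, seed=0, sigma_loc=0.03)
print("D =", model.D.round(3), "um^2/s")
print("occupancy =", model.pi.round(3))

cm = spt.coarse_grain(model, thresholds=(1.0,), labels=("bound", "free"))
print(f"bound: occ={cm.occ[0]:.2f} dwell={cm.dwell[0]:.2f} s")
print(f"free:  occ={cm.occ[1]:.2f} dwell={cm.dwell[1]:.2f} s")

cycle = spt.cycle_time(cm.occ[0], cm.dwell[0])
thr = spt.cycle_threshold(spt.ThresholdInputs(0.20))
print(f"cycle time = {cycle:.2f} s (threshold {thr:.1f} s -> "
      f"{'multiple bindings per translation cycle' if cycle < thr else 'single binding'})")
```

which prints:

```
342 trajectories, 400 cells, 10809 steps
D = [0.094 2.447] um^2/s
occupancy = [0.287 0.713]
bound: occ=0.29 dwell=0.31 s
free:  occ=0.71 dwell=0.78 s
cycle time = 1.09 s (threshold 2.0 s -> multiple bindings per translation cycle)
```

The slow state's D and the bound occupancy/dwell recover the simulation
truth (0.1 µm²/s, 0.3, 0.3 s); the fast state's apparent D (2.45 vs the
true 3.0 µm²/s) is depressed by confinement in the 0.8 µm-wide cell, which
the likelihood deliberately does not model — fitted states are apparent
diffusion states (see `docs/methods.md`). The cycle time of 1.09 s against
the 2.0 s threshold (a factor present at 20% of ribosome concentration,
ribosome translation cycle ≥ 10 s) would indicate multiple ribosome
bindings per translation cycle.

The same pipeline is available from the shell:

```sh
spt simulate --config sim.yaml --out traj.csv --cells cells.csv
spt fit traj.csv cells.csv -K 1..9 --seeds 10 --out models.json
spt coarse models.json --thresholds 1,8 --labels bound,free,artifact --out cm.json
spt kinetics cm_exp*.json --out summary.json
spt run --config pipeline.yaml     # end-to-end with provenance
```

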