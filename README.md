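# dynparc

Dynamic states of seed-based parcellation for resting-state fMRI.

Functional brain parcellations are usually treated as static: one labeling
of voxels per subject, averaged over a whole scan. `dynparc` instead asks
how the parcel containing a given seed voxel *reconfigures over time*. It
cuts the BOLD time series into sliding windows, parcellates each window
with replicated k-means, binarizes every parcellation at the seed, and
clusters the resulting seed-parcel maps into a small number of recurring
**dynamic states of parcellation**, each summarized by a voxelwise
**stability map** and a **dwell time**. The package also ships the full
evaluation battery for such states — split-half reproducibility with
Hungarian state matching, subject fingerprinting with a chance baseline,
dwell-time comparison — and a synthetic-data generator with planted ground
truth so the entire pipeline can be validated without any scanner data.

It is intended for researchers studying dynamic functional connectivity
who want subject-level, seed-centric state decompositions with an
explicit, testable processing chain.

## Method

For one subject and one seed voxel (MNI mm coordinates mapped to the
acquisition grid):

1. **Windows.** Sessions are concatenated and cut into sliding windows of
   W = 100 frames with O = 10 frames of overlap, starting at the first
   frame (windows may span session boundaries).
2. **Window parcellations.** Each window is clustered into k = 12 parcels
   by k-means on voxels (features = the W frames), k-means++
   initialization, replicated R = 5 times with distinct seeds, giving
   N = n_windows x R parcellations.
3. **Seed binarization.** Each parcellation is reduced to the binary map
   of the seed's parcel: b_v = 1 iff voxel v shares the seed's label.
4. **State clustering.** The N x N Dice matrix
   D_ij = 2|b_i ∩ b_j| / (|b_i| + |b_j|) feeds average-linkage
   hierarchical clustering on distance 1 − D, cut at 1 − 0.3. Clusters
   holding more than 10% of the N instances are retained as dynamic
   states; the rest are reported unassigned.
5. **Stability maps.** Each state's maps are averaged voxelwise into a
   stability map in [0, 1] (the probability a voxel joins the seed's
   parcel while the state is active), ranked primary/secondary/... by
   decreasing dwell fraction. Maps can be split into contiguous regions
   (threshold 0.5, 6-connectivity, minimum 50 voxels).

Evaluation across two independent replication sets pairs states by the
Hungarian method maximizing total Pearson correlation; unmatched states
score 0. Deterministic fingerprinting matches each pooled stability map to
its nearest neighbor (Pearson r, excluding itself) and scores success when
the subjects agree; the chance baseline draws random map pairs and has
closed-form accuracy (m − 1)/(S·m − 1) for S subjects with m maps each.

## Worked example

Simulate one subject with two planted states (60/40 dwell) on a 12^3 grid
and recover them:

```python
import numpy as np
from dynparc import (SyntheticSpec, RunConfig, SeedSpec, make_ground_truth,
                     simulate_bold, fit_states, evaluate_recovery)

spec = SyntheticSpec(rng_seed=7)          # 12x12x12 grid, 2 states, 60/40 dwell
rng = np.random.default_rng(7)
truth = make_ground_truth(spec, rng=rng)
run = simulate_bold(spec, truth, rng=rng)

seed = SeedSpec(mni_mm=(18.0, 18.0, 18.0), voxel_index=spec.seed_row)
config = RunConfig(smoothing_fwhm_mm=0.0)  # simulated signals are already smooth
result = fit_states([run], seed, config)

for m in result.state_maps:
    print(f"state {m.state_rank}: dwell = {m.dwell_fraction:.3f}, "
          f"mean within-state Dice = {m.mean_within_dice:.3f}")

recovery = evaluate_recovery(result.state_maps, result.assignment, truth,
                             window_length=config.window_length)
print("matched Dice vs planted parcels:", recovery["matched_dice"])
print("window-assignment accuracy:", round(recovery["assignment_accuracy"], 3))
```

Output:

```
state 1: dwell = 0.605, mean within-state Dice = 0.906
state 2: dwell = 0.395, mean within-state Dice = 0.833
matched Dice vs planted parcels: [1.0, 1.0]
window-assignment accuracy: 0.968
```

Both planted states are found, ranked by dwell time (0.605/0.395 against
the planted 60/40), their thresholded stability maps coincide exactly with
the planted seed parcels (Dice 1.0), and 96.8% of window instances are
assigned to the state that was actually active for the majority of the
window.

The same pipeline runs from the shell on NIfTI files:

```bash
dynparc simulate spec.json --out data/
dynparc fit data/sub-01/set-1/bold.nii.gz --mask data/mask.nii.gz \
    --seed-mni 18 18 18 --subject sub-01 --set-name set-1 --out fits/ --n-reps 1
dynparc eval fits/sub-01/seed/set-1/rep-1 fits/sub-01/seed/set-2/rep-1 --out eval/
dynparc fingerprint fits/*/seed/*/rep-1 --out fingerprint.json
```

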