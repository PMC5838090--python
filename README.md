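# spraymode

Spray-mode analysis of electrospray droplet delivery from high-speed
video.

Electrospray (electrohydrodynamic atomization) disperses a conducting
liquid into charged microdroplets that are accelerated toward a target
acting as counter electrode — for gene delivery, a cell monolayer or
tissue.  Which droplets actually do the delivering is characterised by
the **spray mode**: the joint distribution of droplet volume and impact
velocity.  This package implements that characterisation for grayscale
high-speed recordings (e.g. 992 × 600 px at 10 kHz over a 5.565 mm ×
3.366 mm field of view, i.e. 5.6 µm/pixel):

1. **Detection** — per-frame background subtraction (temporal median),
   adaptive thresholding at *k*·σ of the robust noise level, 8-connected
   components, and a 10-pixel size cutoff separating droplets from noise
   (equivalent to a 4.2 pl spherical droplet of r = 10 µm at 5.6 µm/px).
2. **Trajectory linking** — greedy nearest-neighbour association frame
   to frame inside a gating radius set by the maximum trackable velocity
   (20 m/s), with motion-coherence gating and explicit handling of
   in-flight droplet **splitting** (child trajectories carry a parent
   link).
3. **Qualification** — only droplets that traverse the region of
   interest (the axial band from 25% to 87.5% of the working distance
   beyond the capillary tip) and stay within the ~0.5 mm focal range
   are evaluated.
4. **Volumetry** — droplet volume `V_d` at first appearance from the
   projected area A and axial diameter d, assuming rotational symmetry
   around the propagation axis: with a = d/2 and b = A/(πa),
   `V = (4/3)·π·a·b²`.
5. **Impact velocity** — `v_d` from the centroid displacement between
   the last two tracked frames.
6. **Grouping** — replicate record sets are merged and clustered with
   k-means (Lloyd's algorithm, best of 10 restarts) on standardized
   (equivalent diameter, velocity) features; the cluster count k is
   chosen by the mean silhouette over k = 2…6, falling back to a single
   group when the best silhouette is below 0.5.  Each group is reported
   as ⟨V_d⟩ ± sd, ⟨v_d⟩ ± sd, the group volume `V_g` and its fractional
   contribution `V_% = 100·V_g/ΣV_g`.

A synthetic spray-video generator (`spraymode.synthetic`) renders
droplet ensembles with known ground truth — log-normal volumes,
truncated-normal velocities, defocus blur, sensor noise and splitting
events — so every stage is testable without raw recordings.

## Worked example

Simulate a two-population spray (the 3.0 kV reference condition:
~1.4 nl droplets at ~2.9 m/s carrying 95% of the volume, plus ~0.2 nl
satellites at ~14.3 m/s) and analyse it end to end:

```python
from spraymode import (AcquisitionGeometry, EnsembleSettings, RenderSettings,
                       REFERENCE_CONDITIONS, RunConfig, render_frames,
                       run_pipeline, sample_ensemble)

geo = AcquisitionGeometry(fov_width_mm=5.565, fov_height_mm=3.366,
                          image_width=992, image_height=600,
                          frame_rate_hz=10_000, working_distance_mm=4.0,
                          tip_position_px=50.0)
ens = sample_ensemble(REFERENCE_CONDITIONS["3.0kV"], duration_s=0.2,
                      total_volume_nl=350.0, geometry=geo, seed=1,
                      settings=EnsembleSettings(lateral_sd_mm=0.7,
                                                split_fraction=0.0),
                      fractions_basis="evaluable")
frames, truth = render_frames(ens, geo, RenderSettings(rng_seed=1),
                              duration_s=0.2)
res = run_pipeline(RunConfig(geometry=geo, seed=1, output_dir="out"),
                   stacks=[frames])
print(f"k = {res.result.k}")
for i, g in enumerate(res.result.groups, 1):
    print(f"group {i}: <V_d> = {g.volume_mean_nl:.2f} nl, "
          f"<v_d> = {g.velocity_mean_m_s:.1f} m/s, "
          f"V_g = {g.group_volume_nl:.0f} nl ({g.volume_fraction_pct:.0f}%)")
```

Output (seed 1):

```
k = 2
group 1: <V_d> = 1.22 nl, <v_d> = 3.0 m/s, V_g = 285 nl (95%)
group 2: <V_d> = 0.29 nl, <v_d> = 13.8 m/s, V_g = 15 nl (5%)
```

The silhouette selection finds the two generated populations; the
dominant group's centroid (1.22 nl at 3.0 m/s) and fractional volume
(95%) recover the generating specification (1.4 nl at 2.9 m/s, 95%),
with the slow group's centroid volume a few percent low because of the
heavy right skew of the log-normal volume distribution at finite sample
size.  `out/` receives per-stage CSV tables (blobs, trajectories,
records, group table, scatter data) and a JSON summary with stage
counts, the seed and a configuration hash.

## Command line

```sh
spraymode simulate --condition 3.0kV --duration 0.2 --out spray.tif
spraymode detect spray.tif --out blobs.csv
spraymode track spray.tif --out trajectories.csv
spraymode analyze --config run.yaml
spraymode calc delivery-time 25 20      # -> 75 s
spraymode calc detection-limit 10 5.6 sphere   # -> 4.18 pl
spraymode calc osmolarity 12.67         # -> 370.1 mOsm
```

`run.yaml` keys: a `geometry` block (`fov_width_mm`, `fov_height_mm`,
`image_width`, `image_height`, `frame_rate_hz`, `working_distance_mm`,
`tip_position_px`, `propagation_axis`), an optional `spray` metadata
block (`voltage_kv`, `flow_rate_ul_min`, `delivered_volume_ul`,
`plasmid_concentration_ug_ml`, `medium_osmolarity_mosm`), `inputs` (a
list of TIFF stacks or frame directories, one per replicate), and
analysis settings (`threshold_k`, `pixel_cutoff`, `max_velocity_m_s`,
`area_tol`, `max_gap`, `focus_mode`, `sharpness_band`,
`volume_floor_pl`, `k`, `k_min`, `k_max`, `n_restarts`, `volume_scale`,
`seed`, `output_dir`).  Lengths are in mm, rates in µl/min, voltage in
kV.

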