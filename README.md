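# craniodot

Scalp-to-cortex correspondence from diffuse optical tomography (DOT)
sensitivity, on synthetic age-scaled head phantoms.

NIRS/fNIRS and DOT measure cortical hemodynamics through optodes on the
scalp, so every anatomical interpretation rests on two questions: *how far*
is the cortex beneath each standard scalp location, and *which* cortical
regions does a measurement at that location actually sample? Both answers
change substantially as the head grows from infancy to adulthood.
`craniodot` implements the full analysis chain that answers them:

* **Head phantoms** — nested-ellipsoid segmented head volumes (scalp,
  skull, CSF, grey/white matter) with age-scaled size and thicknesses,
  optional anterior CSF gradient, vertex-to-base gap gradient and
  hemispheric asymmetry, cranial fiducials, and a two-level
  (lobar/sublobar) sector atlas. Real NIfTI head segmentations are
  accepted in place of phantoms.
* **Virtual montages** — the 81 standard 10-10 electrode positions
  constructed from the fiducials by plane-curve tracing and arc-length
  subdivision; the 358-location 10-5 superset; 251 source–detector
  channels at each level, centred on 10-10 electrodes.
* **Three scalp-to-cortex distance estimators** —

  | method | definition |
  |---|---|
  | scalp projection | distance to the first cortical intersection of the ray toward the brain centre |
  | direct DOT | distance to the brain voxel with maximum single-optode Monte Carlo fluence (2-point Green's function) in a 15 mm search sphere |
  | S-D channel DOT | distance to the voxel with maximum channel PMDF — the voxelwise product of source and detector fluence (3-point Green's function) — in the sphere |

* **Monte Carlo photon transport** — a deterministic, counter-seeded voxel
  random walk (exponential step lengths, albedo survival weighting,
  Henyey–Greenstein scattering, track-length fluence tally, Russian
  roulette), validated against the infinite-medium diffusion closed form
  `exp(-mu_eff r) / (4 pi D r)`.
* **Scalp-location-to-ROI look-up tables** — per location, method and age:
  the percentage of brain voxels in the search sphere falling in each atlas
  region; 25%-thresholded cross-age consistency classes
  (consistent / partial / discrepant); PMDF-weighted channel-to-region
  specificity.

See `docs/methods.md` for the models, parameter tables and numerical
choices.

## Worked example

```python
from craniodot import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    profiles=("2wk", "adult"),          # packaged age profiles
    photons=3000,                        # per optode
    master_seed=1,
    channel_centers=("Fz", "Cz", "Pz", "Oz", "C3", "C4"),
)
res = run_pipeline(cfg)
print(res.distance_table.groupby(["profile", "method"])["distance_mm"].mean())
```

prints

```
profile  method
2wk      direct_dot           8.544823
         scalp_projection     7.463542
         sd_channel_dot      13.806196
adult    direct_dot          19.034515
         scalp_projection    17.041667
         sd_channel_dot      21.136877
Name: distance_mm, dtype: float64
```

Read: on the newborn-scale phantom the cortex lies about 7.5 mm under these
scalp locations, and about 17 mm in the adult — the developmental increase
the analysis is designed to expose. The S-D channel DOT distance is the
largest of the three at both ages (the channel's sensitivity peak lies
deeper than the cortical surface), while direct DOT tracks the geometric
projection within about a millimetre. `res.orderings` reports these
orderings with margins, `res.summary` the cell means by age, method and
electrode group, and `res.consistency` the cross-age ROI consistency
classes per scalp location.

A command-line interface wraps the same pipeline:

```bash
craniodot phantom  --profile 3mo --out out/        # NIfTI head + atlas + fiducials
craniodot montage  --profile 3mo --out out/        # electrode/channel tables
craniodot simulate --profile 3mo --electrode Cz --out out/
craniodot all --config cfg.json --seed 1 --out out/
```

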