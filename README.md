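# chambergrow

Strain-driven voxel design of healing chambers for additively
manufactured dental implants.

## The problem

A *healing chamber* is the recessed region between the threads of a
dental implant (here: a rectangular circumferential trough) that is not
in bone contact at placement. It fills with blood clot and woven bone
and largely determines the biological (secondary) stability of the
implant. Which chamber shape is best depends on how the surrounding
bone is strained under function — something a fixed machined profile
cannot adapt to, but a 3D-printed implant can.

`chambergrow` *grows* the chamber instead of prescribing it. It couples
a voxel finite-element model of an implant in bone to a Mechanostat-style
bone-remodeling rule: for every chamber bone voxel in contact with the
implant, the signed action probability is

    f*(Γ, ε) =  -1                        ε < ε_du         (disuse: resorb)
                blend(-1 → f(Γ))          ε_du ≤ ε < ε_pl
                f(Γ)                      ε_pl ≤ ε < ε_pu   (physiological)
                blend(f(Γ) → +1)          ε_pu ≤ ε < ε_ol
                +1                        ε_ol ≤ ε          (overload: form)

where ε is the element's equivalent (von Mises-type) strain,
Γ = (σ_c − ⟨σ⟩_w)/⟨σ⟩_w is the relative deviation of its equivalent
stress from the inverse-distance-weighted neighborhood mean, and
f(Γ) = clamp(Γ/Γ_u, −1, 1). Resorbed bone voxels are back-filled with
implant material; deposited bone reclaims adjacent implant voxels.
Every iteration is a candidate chamber geometry; candidates are ranked
by the volume fraction of *healthy* bone (400–1500 µε) in a cylindrical
region of interest around the implant, with the bone–implant contact
area as a secondary readout. See `docs/methods.md` for the full model
description and all defaults.

The package is aimed at computational-biomechanics work on implant
design: it ships a parameterized synthetic implant-in-bone model
(axisymmetric threaded titanium implant, cortical crest over cancellous
body), a self-contained hex8 FE solver, the remodeling law, the design
loop, candidate metrics, and VTK/STL export for inspection and
printing.

## Worked example

```python
from chambergrow import (
    ImplantModelParams, RemodelingParams, build_synthetic_model,
    default_materials, run_design, select_best,
)

grid = build_synthetic_model(ImplantModelParams())   # 48 x 48 x 72 voxels, 50 um
history = run_design(
    grid, default_materials(), total_force=3.0,
    params=RemodelingParams(seed=1), max_iter=12, verbose=True,
)
best = select_best(history)
```

prints one line per candidate:

```
iter   0  changes     0  healthy 0.4006  BIC 12.4000 mm^2
iter   1  changes   987  healthy 0.4224  BIC 14.5400 mm^2
iter   2  changes  1042  healthy 0.4385  BIC 14.4250 mm^2
iter   3  changes   825  healthy 0.4487  BIC 13.2550 mm^2
iter   4  changes   292  healthy 0.4539  BIC 11.7400 mm^2
iter   5  changes    22  healthy 0.4542  BIC 11.5600 mm^2
```

Reading the output: iteration 0 is the as-placed design (rectangular
troughs full of bone) — 40.1 % of the ROI bone is in the healthy
400–1500 µε band, and 12.4 mm² of bone–implant interface exists. The
stress-shielded chamber bone then resorbs and is back-filled by implant
(`changes` counts voxel conversions); the contact area transiently
rises as the interface roughens, and the healthy fraction climbs as the
low-strain chamber bone disappears and load transfer to the surrounding
bone improves, until the design region is entirely implant and the loop
stops. `select_best(history)` returns the candidate with the highest
healthy fraction; `history[i].grid` can be exported with
`export_stl` / `export_vtk`.

The same run from the shell, with artifacts (per-candidate grid
containers, `metrics.csv`, `summary.json` provenance):

```bash
chambergrow run --out results/run1 --seed 1
chambergrow export --history results/run1 --iteration 2 --stl candidate2.stl
```

`chambergrow build` writes just the voxel model; custom geometries,
materials, loads and remodeling parameters go in a YAML config
(`--config`), with the defaults documented in `docs/methods.md`.

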