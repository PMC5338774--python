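# cranioplan

Headless, scriptable planning of patient-specific cranial implants
(cranioplasty). After a craniectomy, the missing piece of skull must be
replaced by an implant whose curvature continues the surrounding bone.
`cranioplan` reproduces the classic mirror-template workflow as a library +
CLI: no GUI, no commercial CAD package, every step reproducible from a seed.

**Who it is for:** researchers prototyping implant-planning methods,
and anyone who needs a deterministic, testable reference pipeline for
mirror-based cranioplasty planning on STL surface models (CT-derived, mm).

## Method

1. **Mirror template.** The defect skull is reflected across the midsagittal
   plane (Householder map `v ↦ v − 2((v−p)·n)n`; for the default plane
   `x = 0` this is `diag(−1, 1, 1)`), so the intact side covers the defect
   and provides the initial curvature.
2. **Typed markers.** The implant is described by landmarks of four types:
   outer/inner *edge* markers (types 0/1) on the defect rim, and
   outer/inner *surface* markers (types 2/3) on the mirrored template.
   Types group into an outer layer {0, 2} and an inner layer {1, 3}.
3. **Constrained Laplacian smoothing.** Each surface marker moves to the
   weighted mean of its same-layer neighbors within radius *x*:

   `x_i = Σ_j w_j x_j / Σ_j w_j`,  `w_j = y` for edge markers, else 1,

   which reduces to the plain Laplacian mean `x_i = (1/N) Σ_j x_j` at
   `y = 1`. Edge markers never move — they pin the implant to the bone and
   bound the shrinkage smoothing otherwise causes. Updates are simultaneous
   (Jacobi), so marker order is irrelevant.
4. **Delaunay + alpha meshing.** The marker cloud is tetrahedralized
   (empty-circumsphere Delaunay); tetrahedra with circumradius > α are
   discarded, carving the concave inner side out of the convex hull; the
   boundary triangles of the surviving solid are exported as a watertight
   STL ready for 3D printing.
5. **Evaluation.** Implants are compared volumetrically on a shared voxel
   grid: Dice similarity `DSC = 2|A∩B|/(|A|+|B|)` (percent), Hausdorff
   distance (voxel units) and volumes in voxels / mm³.

A synthetic phantom (ellipsoidal two-table shell, ~adult-cranium semiaxes,
4 mm thick, with an open-rimmed defect wedge and its ground-truth patch)
makes the whole pipeline testable without clinical data. The package also
reproduces a published usability-questionnaire summary (six-point Likert
scale) from its raw ratings.

## Worked example

```bash
cranioplan phantom --out-dir ph                # defect.stl, intact.stl, truth.stl
cranioplan mirror --in ph/defect.stl --out template.stl
cranioplan markers --defect ph/defect.stl --template template.stl \
                   --out m.csv --seed 3        # 24+24 edge, 40+40 surface markers
cranioplan smooth --radius 6 --border-weight 2 --in m.csv --out m_s.csv
cranioplan triangulate --alpha 20 --markers m_s.csv --out implant.stl
cranioplan metrics --a implant.stl --b ph/truth.stl
```

prints

```
mirrored template written to template.stl
128 markers written to m.csv
smoothed markers written to m_s.csv
implant (232 faces) written to implant.stl
{
  "dsc_percent": 90.98,
  "hd_voxels": 5.39,
  ...
}
```

i.e. the planned implant overlaps the ground-truth patch with a Dice
coefficient of 90.98 % and a worst-case surface disagreement of 5.39 voxels
(2.7 mm at the default 0.5 mm spacing). `cranioplan plan --config plan.json`
runs the same steps as one deterministic pipeline with a JSON report, and
`cranioplan stats` prints the bundled questionnaire summary (per-item mean
and standard error on the 1–6 scale).

Library use mirrors the CLI:

```python
import cranioplan as cp

result = cp.generate_phantom(cp.PhantomSpec())
cp.write_stl(result.defect_mesh, "defect.stl")
implant, report = cp.plan_implant(cp.PlanConfig(input_path="defect.stl", seed=0))
```

## Layout

- `src/cranioplan/mesh_io.py` — STL read/write (binary + ASCII), vertex welding
- `src/cranioplan/geometry.py` — centering, mirroring, clipping, Procrustes
  registration, defect-rim detection
- `src/cranioplan/markers.py` — typed markers, CSV/JSON format, placement
- `src/cranioplan/smoother.py` — constrained Laplacian smoothing
- `src/cranioplan/implant_mesh.py` — Delaunay, alpha filter, surface extraction
- `src/cranioplan/metrics.py` — voxelization, Dice, Hausdorff, volumes
- `src/cranioplan/phantom.py` — synthetic defect-skull generator
- `src/cranioplan/pipeline.py` — end-to-end orchestration
- `src/cranioplan/study_stats.py` — Likert questionnaire summaries
- `docs/methods.md` — models, parameters, numerical choices, limitations
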