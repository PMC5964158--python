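# repe

Shape a transcranial electrical stimulation (tES) electrode from the scalp
projection of an individual cortical sulcus, compute the scalp-landmark
distances needed to (re)position it without neuronavigation, quantify
positioning error, and compare electrode montages with a quasi-static
volume-conductor field solver. Everything runs on synthetic head phantoms
with known ground truth, so the whole workflow is testable offline.

## What's inside

| module | role |
|---|---|
| `repe.phantom` | synthetic "template" and "individual" heads: nested ellipsoidal tissue shells, neck stub, a parametric curved sulcus carved as a CSF cleft, known linking affine, fiducials |
| `repe.segreg` | brain/scalp extraction (threshold + morphology) and 12-dof affine normalisation (moment matching + signed-distance least squares); exact point mapping of the 123-point template sulcus |
| `repe.shaping` | marching-cubes scalp surface, exact minimal-distance projection of the sulcus onto it, arc-length flattening, 20 mm-wide electrode polygon, true-scale SVG export (1 unit = 1 mm, with a 100 mm ruler) |
| `repe.positioning` | on-surface (Dijkstra) nasion-referenced placement distances, 27 marker points at 5 mm, seeded repositioning simulation, error reports |
| `repe.evaluation` | nearest-point trace agreement with ICC(2,1), one-way repeated-measures ANOVA (F = paired-t² on two conditions) |
| `repe.fields` | voxel finite-volume solver for div(sigma grad V) = 0 with harmonic-mean face conductivities, conjugate gradients (rtol 1e-6), gel-capped electrode patches, S1/M1 strip ROIs, montage study tables |
| `repe.cli` / `repe.pipeline` | `repe` command-line tool and a deterministic end-to-end pipeline with a checksummed manifest |

Conventions: RAS world frame in millimetres, 0-based voxel indices,
`world = affine @ (i, j, k, 1)`. The normalisation matrix `TM` maps
individual world-mm to template world-mm; the template sulcus is brought
into individual space with `TM⁻¹`. `TM` is saved as a plain-text 4×4 matrix.

## CLI

Every stage is available individually; `repe all` chains them:

```sh
repe all --seed 1 --out run/                 # full pipeline, default config
repe phantom --seed 1 --out run/phantom/
repe segreg  --t1 t1.nii.gz --template-labels tpl.nii.gz \
             --template-sulcus mni_cs.json --out run/segreg/
repe shape   --ics ics.json --scalp iscalp.nii.gz --width-mm 20 --out electrode.svg
repe place   --scalp iscalp.nii.gz --footprint icss.json --truth truth.json \
             --out placement_sheet.json
repe evaluate --auto icss.json --manual manual_icss.json --out agreement.json
repe fields  --labels head.nii.gz --trace icss.json --truth truth.json \
             --references oz,ring --out dose_table.csv
```

A YAML config (`--config`) can set grid size, sulcus curvature, electrode
width, montage list, solver tolerance, etc.; a seed is mandatory and is
expanded into per-stage seeds (`seed*1000 + stage index`). Identical configs
produce byte-identical artifacts (the manifest records sha256 checksums).

## Known approximations

- Geodesics run on the surface edge graph and can overestimate true
  geodesics by up to ~10% (documented per-test); fine for tape-measure
  placement distances.
- The "shoulders" return electrode is realised as a ring at the neck-stub
  base (the phantom has no shoulders); 10-10 landmarks (Oz etc.) are defined
  by arc fractions of the nasion-inion midline.
- The field solver is a voxel finite-volume discretisation, not tetrahedral
  FEM; validation is against the analytic layered-sphere solution.
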