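# pairmorph

Quantifying bilateral bony symmetry of paired knee surface models.

Side-to-side comparison of knee joints is routine in orthopaedic research and
surgery: the contralateral knee is assumed to be a healthy anatomical
baseline. `pairmorph` implements a 3D morphometric pipeline that tests this
assumption on pairs of CT-derived triangle-mesh surface models of the distal
femur, patella, and proximal tibia, quantifying left-right asymmetry as dense
per-correspondence-point (CP) distances — usable both for single pairs and
for cohorts grouped by trochlear dysplasia severity.

## Method

For one bone pair (left mesh *L*, right mesh *R*, coordinates in mm):

1. **Preprocess** — keep the largest connected component (loose bone
   fragments are excluded, as in segmentation practice) and remesh both
   surfaces isotropically to 2.0 mm elements.
2. **Mirror + rigid registration** — mirror *L* in the sagittal plane and
   rigidly register it to *R* with Coherent Point Drift (CPD): EM over a
   Gaussian mixture whose centroids are the transformed moving points, with
   posterior P(m|xₙ) ∝ exp(−‖xₙ − (Ryₘ + t)‖²/2σ²), rotation solved by SVD of
   the P-weighted cross-covariance. No scale factor: size differences count
   as asymmetry.
3. **Align + trim** (femur/tibia only) — align to a global frame
   (proximal-distal = +Z, medial-lateral = +X) via area-weighted principal
   axes (or registration to a pre-aligned reference for compact bones), then
   run two iterations of trim-and-register: cut both meshes at a shared plane
   so the kept joint-end height equals the bone's medial-lateral range (or
   the available height minus 5 mm for short models), re-registering after
   each cut. The patella is analysed whole.
4. **Nonrigid correspondence** — deform *R* onto the aligned mirrored *L*
   with nonrigid CPD, T(Y) = Y + GW, G(i,j) = exp(−‖yᵢ − yⱼ‖²/2β²),
   regularized by the motion-coherence penalty (λ/2)·tr(WᵀGW). The CP
   distance at each right-mesh vertex is the Euclidean norm of its
   displacement.
5. **Statistics** — CPs within 2.0 mm of a cutting plane are excluded; the
   rest are summarized as median, IQR, and 1st-99th percentiles, pooled per
   dysplasia group (no / low-grade / high-grade). No hypothesis testing: with
   10⁴-10⁵ CPs per bone, even irrelevant differences would reach
   significance. Heatmaps render CP distances on the right mesh with values
   ≤ 1.0 mm (the measurement-accuracy floor) in grey.

A synthetic-data module generates parametric femur/patella/tibia surrogates
(implicit-solid unions surfaced by marching cubes) and left/right pairs with
known injected asymmetry, so the whole pipeline is testable without any
patient data.

## Worked example

```python
import pairmorph as pm
from pairmorph.synthetic_data import (
    AsymmetrySpec, BoneSurrogateSpec, Bump, make_pair, make_surrogate,
)

base = make_surrogate(BoneSurrogateSpec(kind="femur", scale=70.0))
anchor = base.vertices[base.vertices[:, 2].argmin()]     # on a condyle
left, right, truth = make_pair(
    base,
    AsymmetrySpec(bumps=[Bump(anchor=anchor, amplitude=2.5, radius=8.0)],
                  misalign_rot_deg=10.0, misalign_trans_mm=5.0,
                  noise_sigma=0.0),
    seed=11,
)
cs, artifacts = pm.run_pair(left, right, "femur", pm.PipelineConfig(seed=3))
s = pm.summarize(cs)
print(f"n_cps={s.n_cps} median={s.median:.2f} mm "
      f"IQR=({s.q1:.2f}-{s.q3:.2f}) max={cs.included_distances().max():.2f}")
```

Output:

```
n_cps=1189 median=0.14 mm IQR=(0.11-0.30) max=2.41
```

Away from the injected bump the pair is perfectly symmetric, and the rigid
step has absorbed the 10°/5 mm misalignment: the median CP distance (0.14 mm)
sits far below the 1.0 mm measurement-accuracy threshold, while the maximum
CP distance recovers the 2.5 mm bump within 4%. The same analysis runs from the shell:

```bash
pairmorph simulate --kind cohort --n-per-group 1 --seed 0 --out cohort/
pairmorph run-cohort --manifest cohort/manifest.csv --seed 9 --out results/
pairmorph run-pair --left L.stl --right R.stl --bone femur --out out/
```

`run-cohort` writes per-pair summaries (CSV), a pooled cohort report (JSON),
per-pair heatmaps (PLY with a `cp_distance` vertex property, plus PNG
renders), and the resolved configuration for reproducibility.

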