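# pigairway

Synthetic pig airway-tree morphometry: a parametric generator of monopodial
bronchial trees with measured domestic-pig geometry, a CT-like rasterizer,
a skeleton-based extraction stage, and the morphometric analyses that
produce the tree's headline statistics.

Pig airways are not scaled-down human airways: a **tracheal bronchus**
feeds the right upper lobe before the main carina, the mainstem bronchi are
**monopodial** (the major daughter continues the parent's direction while
minor daughters leave laterally at ~41°), the minor-daughter/parent
diameter ratio is **bimodal** (d2/D ≈ 0.57 for bifurcations in the
trachea–mainstem plane, ≈ 0.35 for bifurcations rotated out of it), and the
bifurcating plane rotates in a repeating **0, +90, −90°** pattern along
each pathway. Anyone building physical or computational models of the pig
chest (airflow, sound transmission, deposition) needs this geometry rather
than a human-tree approximation; this package generates it, degrades it to
a binary CT-like mask, and verifies that the measurement pipeline recovers
it.

## The model in brief

* Diameter vs generation follows three log-linear segments,
  `log10 D = a·g + b` with (a, b) = (−0.0438, 1.3094) for generations 0–11,
  (−0.0228, 1.0979) for 12–20, (−0.0418, 1.488) for 21–24
  (trachea = generation 0, D in mm).
* Bifurcations draw class-conditional geometry: angle 1 ~ 14.34° (in-plane)
  / ~0° (out-of-plane); angle 2 ~ 41.4° both classes; d1/D 0.88/0.86;
  d2/D 0.57/0.35.
* Generation assignment groups diameters in descending order with a 0.3 mm
  tolerance (the measurement uncertainty), so asymmetric daughters
  indistinguishable from their parent share its generation.
* Extraction measures diameters as 2× the Euclidean distance transform
  along the skeleton centerline, validated against tube phantoms of
  20/12/7/3 mm to better than 0.3 mm at 0.4 mm voxels.

See `docs/methods.md` for the full model, numerical choices and limits.

## Worked example

```python
from pigairway import (GeneratorParams, generate_tree, compute_bifurcations,
                       summarize_morphometry, mainstem_pathway_series)

records = []
for seed in range(1, 7):                      # one tree per animal
    tree = generate_tree(GeneratorParams(), seed=seed)
    records += compute_bifurcations(tree, planarity_threshold_deg=45.0)

summary = summarize_morphometry(records)
inp = summary.per_class["in_plane"]
out = summary.per_class["out_of_plane"]
print(f"angle1 in-plane  {inp['angle1_deg']['mean']:.2f} deg")
print(f"d2/D   in/out    {inp['d2_over_D']['mean']:.2f} / "
      f"{out['d2_over_D']['mean']:.2f}")
print(f"pooled d1/D      {summary.pooled_d1_over_D['mean']:.3f}")

nf = generate_tree(GeneratorParams().noise_free(), seed=1)
print([round(r) for _, r in mainstem_pathway_series(nf, "right")[:6]])
```

prints (5 062 bifurcations pooled):

```
angle1 in-plane  14.43 deg
d2/D   in/out    0.57 / 0.35
pooled d1/D      0.869
[0, 90, -90, 0, 90, -90]
```

— the in-plane major daughter deviates ~14° from its parent, the
minor-daughter ratio is bimodal at 0.57/0.35 by planarity class, the
overall major-daughter ratio is ≈0.87, and the noise-free bifurcating plane
cycles 0/+90/−90 along the mainstem.

The analysis drivers under `analysis/` run the four studies end to end and
write their tables to `results/`:

```sh
python analysis/01_diameter_regression.py    # piecewise log-linear refits
python analysis/02_morphometry_ensemble.py   # pooled bifurcation statistics
python analysis/03_phantom_validation.py     # tube-phantom accuracy
python analysis/04_pipeline_recovery.py      # generate->voxelize->extract
```

A CLI wraps the same library (`pigairway generate|voxelize|extract|analyze|
fit|phantom|reproduce`); trees are schema-versioned JSON, masks NIfTI,
meshes binary STL, tables CSV.

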