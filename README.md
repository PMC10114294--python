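# fibmorph

Morphometrics and spatial statistics for FIB-SEM label volumes of 3D cell
cultures (organoids and spheroids).

Volume electron microscopy of whole organoids produces semantic
segmentations of nuclei, mitochondria, cell junctions, microvillar actin
bundles, lumina and cell bodies. `fibmorph` is the quantitative layer on top
of those segmentations:

* **instance extraction** — split a semantic volume into single 3D objects by
  connected components ("multi-ROI"), on anisotropic voxel grids;
* **per-object morphometrics** — exact volume `V_p`, centroid, surface area
  `A_p` (configuration-weight estimator accurate on anisotropic grids), and
  Wadell sphericity `Ψ = (6√π V_p)^{2/3} / A_p`; volume-outlier flagging
  (e.g. 100×-median "giant" mitochondria) and per-cell nuclear/mitochondrial
  volume fractions;
* **nearest-neighbour statistics** — exact centroid NN distances after
  excluding same-class objects whose boundary gap is below 50 nm
  (segmentations sliced at ~40 nm in z cannot reliably separate them), with
  percentile and threshold-fraction summaries per acquisition;
* **local density maps** — volume fraction of a structure inside a spherical
  kernel (default radius 1.0 μm ≈ 4.19 μm³) scanned at 0.25-μm steps, plus a
  co-occurrence score between two maps (junctions vs actin bundles);
* **preservation statistics** — per-organoid preserved-tile fractions from
  manual TEM tile scores, packing density (μm² per cell), box summaries and
  the packing–preservation Pearson correlation;
* **a seeded synthetic organoid generator** — monolayer / compact / mixed
  packing morphologies with controllable lumen fraction, nuclear sphericity
  and volume fraction, junction point processes with a programmable
  nearest-neighbour scale, lumen-lining actin fibers, and heavy-tailed
  mitochondrial volumes — so every statistic has a ground-truth recovery
  test without any raw microscopy data.

I/O covers multipage TIFF (spacing in a JSON sidecar), HDF5 and integer-mode
MRC, and CSV tile-score tables. A thin CLI (`fibmorph generate | measure |
nn | density | preservation | run | demo`) wraps the library for shell use;
`examples/` contains one short narrative script per capability.

## Worked example

`python examples/02_junction_nearest_neighbors.py` generates a 10-cell
synthetic monolayer organoid (96³ voxels, 80-nm spacing) with 150 cell
junctions on its cell–cell interfaces and runs the full measurement chain:

```
junction objects: 150 (0 close pairs excluded)
median NN distance: 0.473 um
25-75% interval:    0.416 - 0.525 um
90th percentile:    0.600 um
fraction within 0.5 um: 63.3%
fraction within 1 um: 100.0%
```

The summary reads: after proximity exclusion, the typical junction has its
nearest neighbour ~0.47 μm away, and every junction in this small dense
scene has one within 1 μm — the threshold-fraction statistic used to compare
packing morphologies. `python examples/01_measure_morphometrics.py` shows
the morphometrics against closed forms (digitized ball: Ψ = 1.0016 vs 1;
cube: Ψ = 0.7706 vs (π/6)^{1/3} ≈ 0.806, within the 5% estimator
tolerance), and `python examples/05_full_pipeline.py` (equivalent to
`fibmorph demo`) produces a complete, bit-reproducible run directory with a
manifest of all 22 outputs.

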