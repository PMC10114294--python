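"""Local density maps and junction/actin co-occurrence.

Two synthetic scenes differing in one respect: junctions seeded near the
lumen-lining interfaces ('apical', where the actin bundles live) vs spread
uniformly over all interfaces. The density-map correlation separates them.
"""

import fibmorph as fm

for placement in ("apical", "uniform"):
    spec = fm.SyntheticSpec(
        morphology="mixed",
        shape=(72, 72, 72),
        spacing_nm=(100.0, 100.0, 100.0),
        n_cells=12,
        lumen_fraction_target=0.08,
        nucleus_axes_um=None,
        n_junctions=100,
        junction_placement=placement,
        apical_band_um=0.6,
        fiber_density_per_um2=1.5,
        seed=1,
    )
    scene = fm.generate_organoid(spec)
    maps = {
        name: fm.compute_density_map(scene.volumes[name], kernel_radius_um=0.5, step_um=0.4)
        for name in ("junctions", "actin_bundles")
    }
    r = fm.overlap_score(maps["junctions"], maps["actin_bundles"])
    co = fm.co_occupancy(maps["junctions"], maps["actin_bundles"], quantile=0.75)
    print(f"{placement:8s}: density-map Pearson r = {r:+.3f}, high-density co-occupancy = {co:.3f}")
print(
    "A higher score for the apical scene shows the maps detect spatial "
    "co-enrichment of junctions and microvillar actin around lumina."
)
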