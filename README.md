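# tetromap

Monte Carlo simulation of cardiac optical-mapping signals on unstructured
tetrahedral meshes.

Optical mapping images cardiac electrical activity by illuminating tissue
stained with a voltage-sensitive dye and recording the fluorescence at the
surface.  Light scatters strongly in myocardium, so each detector pixel
actually integrates transmembrane voltage V_m over a three-dimensional
*scattering volume* beneath it — distorting action-potential upstrokes and
shock responses.  Saline-filled intramural cavities (blood vessels) are
*non-scattering*, which breaks photon-diffusion models; `tetromap` instead
tracks photon packets stochastically, tetrahedron by tetrahedron, through
scattering tissue and transparent cavities alike, and is aimed at
researchers who combine cardiac electrophysiology simulation with optical
mapping experiments.

The pipeline:

1. **build-mesh** — cuboid wedge phantoms (4 x 4 x 2 mm default) with an
   optional sub-epicardial cylindrical vessel cavity and a saline bath
   shell, or externally supplied `.vtu` / CARP `.pts/.elem` meshes;
2. **illuminate** — broad-field epicardial illumination
   (mu_a = 0.52 mm^-1, mu_s = 23.0 mm^-1, g = 0.94): photon-density field;
3. **emit** — voltage-sensitive-dye fluorescence (mu_a = 0.1,
   mu_s = 21.8, g = 0.96), sources proportional to excitation density,
   detection at square surface pixels (160/320/640 um): per-pixel
   scattering volumes;
4. **signal** — V_opt(t) = sum_e w_e Vbar_e(t) / sum_e w_e, the
   scattering-volume-weighted average of V_m, plus upstroke-duration and
   shock-polarization metrics;
5. **make-vm / validate** — synthetic V_m generators (plane-wave pacing,
   parametric shock-polarization snapshots) and diffusion-theory
   cross-checks (`delta = sqrt(D/mu_a)`, `D = 1/(3(mu_a+mu_s(1-g)))`).

The physics (weighted packets, Henyey-Greenstein scattering,
Fresnel/Snell boundaries, Russian roulette) follows the standard MCML
scheme, extended with face-adjacency ray walking on tetrahedra and
free-flight transport through non-scattering bath regions.  See
`docs/methods.md` for the model, parameters and numerical choices.

## Worked example

```python
import tetromap as tm

spec = tm.SlabSpec(dims=(4, 4, 2), spacing=0.1,
                   vessel=tm.VesselSpec(diameter=0.8, depth=0.2),
                   bath_width=0.1)
mesh = tm.build_slab_mesh(spec)
adj = tm.build_face_adjacency(mesh)

field = tm.run_illumination(mesh, adj, [tm.ILLUMINATION_488, tm.SALINE_BATH],
                            tm.IlluminationConfig(total_packets=1_000_000),
                            tm.TransportConfig(seed=1))
pixel = tm.DetectorPixel(center=(2.0, 2.0), edge=0.64)
svs, _ = tm.run_emission(mesh, adj, field,
                         [tm.EMISSION_669, tm.SALINE_BATH], [pixel],
                         total_packets=5_000_000,
                         transport=tm.TransportConfig(seed=2))
prof = tm.scattering_volume_depth_profile(svs[0], mesh)
print(f"normalized scattering volume at 1000 um: {prof.value_at(1.0):.3f}")

delta = tm.theoretical_delta(0.52, 23.0, 0.94)
print(f"diffusion-theory penetration depth: {delta:.2f} mm")
```

prints (the first value carries a few percent of Monte Carlo scatter):

```
normalized scattering volume at 1000 um: 0.066
diffusion-theory penetration depth: 0.58 mm
```

i.e. the 640 um pixel above an 800 um vessel still draws ~6-7% of its
peak signal from tissue a full millimetre deep — the distal cavity
edge — roughly 3-fold more than over compact tissue at the same depth,
and illuminating light decays with a ~0.6 mm length constant.

The same run from the shell:

```sh
tetromap build-mesh --dims 4,4,2 --spacing 0.1 \
    --vessel-diameter 0.8 --vessel-depth 0.2 --bath 0.1 -o mesh.vtu
tetromap illuminate --mesh mesh.vtu --packets 1000000 --seed 1 -o illum.vtu
tetromap emit --mesh mesh.vtu --illum illum.vtu --packets 5000000 -o sv.h5
tetromap make-vm --mesh mesh.vtu --mode plane -o vm.csv
tetromap signal --mesh mesh.vtu --sv sv.h5 --vm vm.csv -o traces.csv
```

`tetromap run --config cfg.yaml` drives the whole pipeline with stage
caching and per-stage seeds derived from one global seed.

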