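# nichemech

Muscle stem cells (MuSCs, satellite cells) live flattened between a myofiber
and its basement membrane.  Culturing them without that niche lets them dome
up and differentiate; pressing them back to a niche-like height restores
quiescence.  `nichemech` packages the quantitative analysis behind that
observation for reuse on new data and for simulation studies:

* **Cell-shape mechanics** — a constant-volume force-balance solver for an
  adherent cell compressed to a fixed height, predicting how cortical
  tension redistributes with compressive strain.
* **AFM tension estimation** — a small-indentation model whose universal
  strain–F/P′ curve turns a measured indentation strain–stress curve into an
  effective pressure P′ and an overall-tension estimate P′·r₀.
* **Quantitative imaging** — per-cell antigen levels with local-background
  annulus correction, negative-control positivity cutoffs, edge/center and
  nuclear/cytoplasmic ratios, and confocal z-stack volume estimation.
* **Fate statistics** — Pax7/MyoD fate classification, repeat-stratified
  Cochran–Mantel–Haenszel tests on population fractions, and Fisher-exact
  gene-list overlap.
* **Synthetic data** — seeded generators with exact ground truth for every
  stage, so the whole pipeline is testable without any downloads.

## The model at the core

The uncompressed cell is a hemisphere of radius r₀ on its substrate.  Under
a plate at height H < r₀ the cortex, at uniform Laplace tension, takes the
squeezed-droplet shape: a flat contact disc plus a free surface of constant
mean curvature c_m + c_h = ΔP/T, leaving the plate tangentially and meeting
the substrate at 90°, at fixed volume V₀ = (2/3)πr₀³.  Directional tensions
are read off the free surface through the curvature closure T ∼ k/c: the
azimuthal (overall) tension is k/c_m (meridional curvature) and the axial
tension k/c_h (hoop curvature), each summarised by its area-weighted
geometric mean and normalised by the uncompressed value k·r₀.

## Worked example

```bash
$ python examples/tension_vs_strain.py
 strain  height um  T_overall/T0  T_axial/T0
   0.00       8.70         1.000       1.000
   0.10       7.83         0.889       1.110
   0.20       6.96         0.783       1.238
   0.30       6.09         0.682       1.395
   0.40       5.22         0.583       1.592
   0.50       4.35         0.485       1.843
   0.54       4.00         0.447       1.965

At 54% compression (4 um height) the overall tension drops by 55% and the
axial tension rises 2.0-fold.
```

The two columns are the overall and axial cortical tension relative to the
uncompressed hemisphere.  Flattening a cell to niche height roughly halves
its overall tension while doubling the axial component — lower overall
tension tracks the return to quiescence, higher axial tension the flattened,
axially stretched cortex.  Other entry points are in `examples/`
(AFM fitting, scene quantification, fate statistics, confocal volume, and
the YAML-configured pipeline, also available as the `nichemech` command).

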