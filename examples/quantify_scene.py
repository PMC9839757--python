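"""Quantify per-cell antigen levels and spatial ratios in a synthetic scene.

Builds a multichannel image of isolated cells whose 'pmlc' channel carries a
2x cortical (edge) enrichment, segments the cells from bright-field/DAPI,
and prints background-corrected levels with edge/center and nuclear/
cytoplasmic ratios next to the generator's ground truth.
"""

from nichemech import imaging, synth

spec = synth.SceneSpec(
    n_cells=4, seed=2,
    channels={"pmlc": synth.ChannelModel(cell_contrast=100.0, edge_multiplier=2.0)})
channels, truth = synth.gen_cell_scene(spec)

records = imaging.quantify_scene(channels)
print(f"segmented {len(records)} of {truth.labels.max()} cells")
print(f"{'cell':>5} {'area um^2':>10} {'level':>7} {'edge/center':>12} {'nuc/cyt':>8}")
for rec in records:
    print(f"{rec.cell_id:>5} {rec.area_um2:10.1f} {rec.levels['pmlc']:7.1f} "
          f"{rec.edge_center['pmlc']:12.2f} {rec.nuc_cyt['pmlc']:8.2f}")

print("\nGround truth: edge/center 2.0, nuc/cyt 1.0; the level exceeds the "
      "100 a.u. interior contrast because the cell mean includes the 2x "
      "edge band.  All values are local-background corrected.")
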