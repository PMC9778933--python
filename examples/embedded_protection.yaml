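# Demo experiment: an embedded, phage-protected cell group beside a loose
# mixed cluster in one 16 x 16 x 8 um chamber.
# Run:  packfrac run --config examples/embedded_protection.yaml --seed 1 --out out/
mode: synthetic
seed: 1
domain_size: [16.0, 16.0, 8.0]
species_ratio: {vibrio: 2.0, ecoli: 1.0}
regions:
  - name: embedded
    lo: [0.0, 0.0, 0.0]
    hi: [8.0, 16.0, 8.0]
    target_packing: 0.9
    architecture: embedded_basal_layer
    species: [vibrio, ecoli]   # (overlay, basal)
    basal_height_um: 2.0
  - name: loose
    lo: [8.0, 0.0, 0.0]
    hi: [16.0, 16.0, 6.0]
    target_packing: 0.45
    architecture: loose_cluster
phage_mode: excluded_from_dense
phage_density: 0.02
# analysis parameters (standard defaults, stated here for visibility)
voxel_size: [0.2, 0.2, 0.5]
cube_edge_um: 0.8
neighborhood_radius_um: 6.0
shell_um: 2.0
focal_species: ecoli
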