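# Demo run: simulate a small two-type tissue subvolume with painted pores,
# then quantify interfaces, map pores and test open-pore spacing.
# The TC fraction is set to 0.5 so all three interface classes carry
# enough wall area to be exercised in a volume this small.
tissue:
  shape: [176, 176, 176]        # 22 um cube at 0.125 um voxels
  spacing: [0.125, 0.125, 0.125]
  n_cells: 12
  tc_fraction: 0.5
  tc_clustering: 0.5
  seed: 0
seed: 0
group: demo
pd_op_threshold: 0.2            # um equivalent diameter
max_assign_distance: 2.0        # um
alpha: 0.05
nn_unit: per-pore
outdir: results/demo
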