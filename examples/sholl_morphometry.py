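"""Sholl analysis of a simulated dendritic tree and an axon arbor.

Dendrites are analyzed in 2-D about the soma; axon terminal arbors in
3-D about the first branching point, following how each is imaged
(maximum projections vs. volumetric stacks).
"""

from cerebquant import morpho, synth

dendrite = synth.generate_tree(
    synth.TreeSimParams(branch_prob=0.45, segment_len_mean=15.0, max_depth=8, planar=True, seed=2)
)
profile = morpho.sholl(dendrite, radius_step=5.0, mode="2d")
summary = morpho.summarize(dendrite, radius_step=5.0, mode="2d")
print("dendritic tree (2-D, soma-centered)")
print(f"  nodes               : {dendrite.n_nodes}")
print(f"  total intersections : {summary.total_intersections}")
print(f"  longest dendrite    : {summary.max_length:.1f} um")
print(f"  projected hull area : {summary.area:.0f} um^2")

axon = synth.generate_tree(
    synth.TreeSimParams(branch_prob=0.5, segment_len_mean=12.0, max_depth=7, planar=False, seed=5)
)
bp = morpho.first_branch_point(axon)
profile3d = morpho.sholl(axon, radius_step=5.0, mode="3d")
print("axon arbor (3-D, centered on first branch point)")
print(f"  first branch point  : node {bp.node_id} at {bp.path_distance:.1f} um from soma")
print(f"  total intersections : {profile3d.total_intersections}")
print(f"  peak crossings      : {profile3d.crossings.max()} at "
      f"r = {profile3d.radii[profile3d.crossings.argmax()]:.0f} um")
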