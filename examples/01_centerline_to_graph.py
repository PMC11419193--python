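"""Build a 1D vascular graph from a centerline volume.

Generates a synthetic bifurcating arterial tree (voxel values carry the
local vessel radius in mm, as a centerline NIfTI would), rebuilds the graph
from the voxels alone, and reports its composition. The root is the
thickest open end — anatomically the catheterized feeding artery.
"""

from emboflow.graph import build_graph
from emboflow.synthetic import TreeSpec, make_tree

vol, truth = make_tree(TreeSpec(depth=4, seed=0))
print(f"rasterized tree: {vol.values.shape} voxels, "
      f"{vol.n_centerline} on the centerline, spacing {vol.spacing} mm")

vg = build_graph(vol)
roles = [vg.g.nodes[n]["role"] for n in vg.nodes]
print(f"graph: {vg.n_nodes} nodes / {vg.g.number_of_edges()} edges")
print(f"roles: 1 root, {roles.count('interior')} interior, "
      f"{roles.count('terminal')} terminals "
      f"(ground truth has {truth.n_terminals} tips)")
print(f"root radius {vg.radius(vg.root):.2f} mm; "
      f"terminal radii ~{vg.radius(vg.terminals[0]):.2f} mm (Murray taper)")
# every centerline voxel is a pressure node; terminals = the open ends that
# drain into the unsegmented downstream vasculature
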