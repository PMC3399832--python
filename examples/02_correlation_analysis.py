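"""Recover planted correlated motions with DCCM and chained correlations.

Draws a 10,000-frame Gaussian ensemble in which residues 2 and 15 carry a
planted displacement correlation of 0.8, computes the dynamical
cross-correlation matrix, and runs the chained-correlation search from a
root residue. The printed matrix entry should be ~0.8 and the chain graph
shows which residues communicate with the root through intermediate
correlations (depth 1 = direct partner, deeper = relayed).
"""

import numpy as np

import loopdyn as ld
from loopdyn.synthetic_data import make_planted_covariance_ensemble

ensemble, planted = make_planted_covariance_ensemble(
    20, [(2, 15, 0.8), (15, 18, 0.7)], n_frames=10_000, seed=2)
mat = ld.dccm(ensemble, window_frames=2000, fit=False)
print(f"DCCM averaged over {len(mat.window_matrices)} windows")
print(f"C(2,15) = {mat.averaged[2, 15]:.3f}   (planted 0.80)")
print(f"C(15,18) = {mat.averaged[15, 18]:.3f}  (planted 0.70)")

mask = mat.significant_long_range()
print(f"significant long-range pairs (|C|>0.35, |i-j|>10): "
      f"{int(mask.sum() // 2)}")

graph = ld.chained_correlations(mat, roots=[2], threshold=0.5, max_depth=5)
print("\nchained correlations from root residue 2:")
for edge in graph.edges:
    print(f"  depth {edge.depth}: {edge.parent} -> {edge.child} "
          f"(C = {edge.correlation:+.2f})")
print("residue 18 is reached only through residue 15: a relayed, "
      "long-range communication path.")
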