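"""B-spline grids: the univariate basis behind every KAN edge function.

Builds a cubic grid, shows the partition-of-unity property, and prints how
the number of trainable parameters of a KAN layer grows with grid size G.
"""

import numpy as np

from gkan import build_grid, bspline_basis
from gkan.kan_layers import linear_kan_param_count

grid = build_grid(-1.0, 1.0, num_intervals=5, degree=3)
print(f"grid: G=5, k=3 -> {len(grid.knots)} knots, {grid.basis_dim} basis functions")

x = np.linspace(-1, 1, 7)
rows = bspline_basis(x, grid)
print("max |row sum - 1| on the domain:", float(np.abs(rows.sum(1) - 1).max()))
# each row is one evaluation point; columns are the G+k basis functions

print("\nparameters of a 4->8 linear KAN layer vs grid size (slope = 4*8):")
for G in (2, 5, 10, 20):
    print(f"  G={G:3d}: {linear_kan_param_count(4, 8, G, 3, use_scaler=True)}")
# the linear growth in G is what makes large grids expensive — the trade-off
# probed by the grid-size ablation
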