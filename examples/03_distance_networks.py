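"""Split decomposition and Neighbor-Net from a distance matrix.

On an additive (tree-like) matrix both methods return exactly the
tree's splits; on the conflicting 'box' metric below they behave
differently: split decomposition and Neighbor-Net both report the two
incompatible splits the data support equally.
"""

import numpy as np

from gonet import (
    DistanceMatrix,
    is_circular,
    is_weakly_compatible,
    neighbor_net,
    split_decomposition,
    write_splits_nexus,
)

# d(A,B)=d(C,D)=2, d(A,C)=d(B,D)=2, d(A,D)=d(B,C)=4: equal support for
# the splits AB|CD and AC|BD -- no tree fits this matrix.
box = DistanceMatrix(
    ("A", "B", "C", "D"),
    np.array([[0, 2, 2, 4], [2, 0, 4, 2], [2, 4, 0, 2], [4, 2, 2, 0]], float),
)

sd = split_decomposition(box)
print("split decomposition (weight = isolation index):")
for s in sorted(sd.nontrivial(), key=str):
    print(f"  {s}  alpha={sd.weight(s):.3f}")
print(f"  weakly compatible: {is_weakly_compatible(sd)}")

nn = neighbor_net(box)
print("neighbor-net (weight = NNLS edge length):")
for s in sorted(nn.nontrivial(), key=str):
    print(f"  {s}  w={nn.weight(s):.3f}")
print(f"  circular ordering: {' '.join(nn.circular_ordering)}")
print(f"  circular: {is_circular(nn)}")

write_splits_nexus(nn, "example_box.nex", comment="box metric, neighbor-net")
print("wrote example_box.nex (open in SplitsTree4 to draw the network)")
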