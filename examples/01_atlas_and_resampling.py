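"""Build the nested two-hemisphere atlas and move a field across resolutions.

Constructs the icosphere hierarchy the model runs on, builds receptive fields
between two consecutive resolutions, and pools a smooth test field down and
back up.  The printed numbers show the atlas sizes, that every fine vertex is
covered by some receptive field, and that averaging pools preserve constants.
"""

import numpy as np

from cortexage import build_hierarchy, build_receptive_fields, pool_down, pool_up

hierarchy = build_hierarchy((0, 1, 2))
print("joint vertex counts per level:", hierarchy.vertex_counts)
print("medial-wall vertices at finest level:", int(hierarchy.medial_wall[-1].sum()))

coarse, fine = hierarchy.levels[1], hierarchy.levels[2]
rf = build_receptive_fields(coarse, fine)
print(f"receptive fields: {rf.n_coarse} coarse -> {rf.n_fine} fine, "
      f"coverage {rf.coverage:.2f}, field sizes "
      f"{min(len(f) for f in rf.fields)}-{max(len(f) for f in rf.fields)}")

# a smooth field: the z coordinate of each vertex
field = fine.vertices[:, 2:3]
down = pool_down(field, rf)
back = pool_up(down, rf)
print(f"field range fine {field.min():+.3f}..{field.max():+.3f}, "
      f"after down+up {back.min():+.3f}..{back.max():+.3f} (contraction of range "
      "is the expected averaging effect)")
const = np.full((coarse.n_vertices, 1), 4.2)
print("constant field is a fixed point:", bool(np.allclose(pool_up(const, rf), 4.2)))
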