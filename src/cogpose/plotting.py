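"""Quick 3D skeleton visualization (matplotlib, imported lazily)."""
from __future__ import annotations

import numpy as np

from .skeleton import make_bone_tree

__all__ = ["plot_pose3d"]


def plot_pose3d(pose, ax=None, color="tab:red", label=None):
    """Draw the bone segments of a 3D pose; returns the axes."""
    import matplotlib.pyplot as plt  # lazy: plotting is optional

    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    coords = np.asarray(pose.coords if hasattr(pose, "coords") else pose)
    tree = make_bone_tree()
    first = True
    for p, c in tree.edges:
        seg = coords[[p, c]]
        ax.plot(seg[:, 0], seg[:, 2], -seg[:, 1], color=color,
                label=label if first else None, lw=1)
        first = False
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("z (mm)")
    ax.set_zlabel("-y (mm)")
    return ax
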