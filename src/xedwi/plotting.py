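"""Minimal map plotting (matplotlib)."""
from __future__ import annotations

import numpy as np

from .data import ParameterMap

__all__ = ["plot_map"]


def plot_map(pmap: ParameterMap, slice_index: int | None = None, axis: int = 2,
             ax=None, **imshow_kw):
    """Show one slice of a parameter map with its units in the title.

    Defaults to the middle slice along the cranio-caudal (third) axis.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if slice_index is None:
        slice_index = pmap.data.shape[axis] // 2
    sl = [slice(None)] * 3
    sl[axis] = slice_index
    img = pmap.data[tuple(sl)]
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(np.asarray(img).T, origin="lower", **imshow_kw)
    label = f"{pmap.name} [{pmap.units}]" if pmap.units else pmap.name
    ax.set_title(f"{label}  slice {slice_index}")
    ax.figure.colorbar(im, ax=ax)
    return ax
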