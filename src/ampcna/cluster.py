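"""Hierarchical ordering and heatmap rendering of CN levels and CNA calls.

Clustering uses Manhattan (L1) distance with average linkage (the
distance between clusters is the unweighted mean of all cross-pair
distances).  Agglomeration is fully deterministic: among equal-distance
merge candidates the pair whose (lexicographically sorted) representative
ids compare smallest is merged first, and at each merge the subtree
containing the smaller original index is placed on the left.  This makes
dendrograms and leaf orders bit-reproducible without an optimal
leaf-ordering dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import AmpcnaError


@dataclass
class AxisOrdering:
    axis: str  # "genes" or "samples"
    order: list[str]  # permutation of the axis ids
    clustered: bool
    #: list of merges (left_node, right_node, height, size); leaves are 0..n-1,
    #: internal nodes n, n+1, ... in merge order (same convention as a linkage
    #: matrix row list)
    merge_tree: Optional[list[tuple[int, int, float, int]]] = None


def identity_order(ids, axis: str) -> AxisOrdering:
    return AxisOrdering(axis=axis, order=list(ids), clustered=False)


def hierarchical_order(
    matrix: pd.DataFrame,
    axis: str = "samples",
    metric: str = "manhattan",
    linkage: str = "average",
) -> AxisOrdering:
    """Order the rows of ``matrix`` (pass the transpose to order samples).

    Returns the dendrogram leaf order; a single-element axis yields the
    trivial ordering with ``clustered=False``.
    """
    if metric != "manhattan" or linkage != "average":
        raise AmpcnaError("only manhattan distance with average linkage is supported")
    ids = list(matrix.index)
    if len(ids) == 0:
        raise AmpcnaError("cannot order an empty axis")
    if len(ids) == 1:
        return identity_order(ids, axis)
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise AmpcnaError("matrix contains non-finite entries")
    dist = squareform(pdist(values, metric="cityblock"))

    n = len(ids)
    # active cluster state; node numbering follows the linkage convention
    members: dict[int, list[int]] = {i: [i] for i in range(n)}  # original indices
    leaf_order: dict[int, list[int]] = {i: [i] for i in range(n)}
    rep: dict[int, str] = {i: ids[i] for i in range(n)}  # lexicographically smallest id
    d = {(min(i, j), max(i, j)): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int, float, int]] = []
    next_node = n
    active = set(range(n))
    while len(active) > 1:
        best = None
        for key, val in d.items():
            pair_ids = tuple(sorted((rep[key[0]], rep[key[1]])))
            cand = (val, pair_ids, key)
            if best is None or cand < best:
                best = cand
        height, _, (a, b) = best
        # left subtree: the one holding the smaller original index
        left, right = (a, b) if min(members[a]) < min(members[b]) else (b, a)
        new = next_node
        next_node += 1
        members[new] = members[a] + members[b]
        leaf_order[new] = leaf_order[left] + leaf_order[right]
        rep[new] = min(rep[a], rep[b])
        size_a, size_b = len(members[a]), len(members[b])
        merges.append((left, right, height, size_a + size_b))
        active.discard(a)
        active.discard(b)
        # average linkage: size-weighted mean of the two old distances
        for c in active:
            ka = (min(a, c), max(a, c))
            kb = (min(b, c), max(b, c))
            d[(c, new) if c < new else (new, c)] = (
                size_a * d[ka] + size_b * d[kb]
            ) / (size_a + size_b)
            del d[ka], d[kb]
        del d[(min(a, b), max(a, b))]
        active.add(new)

    root = next(iter(active))
    order = [ids[i] for i in leaf_order[root]]
    return AxisOrdering(axis=axis, order=order, clustered=True, merge_tree=merges)


def write_ordering(ordering: AxisOrdering, path) -> None:
    """Export the computed id order as one id per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for x in ordering.order:
            fh.write(f"{x}\n")


_CALL_CODES = {"loss": -1, "none": 0, "gain": 1}


def render_heatmap(
    matrix: pd.DataFrame,
    row_order: AxisOrdering,
    col_order: AxisOrdering,
    kind: str = "cn",
    path=None,
    title: Optional[str] = None,
):
    """Render a CN-level or call-status heatmap to an image file.

    ``kind="cn"`` expects numeric copy numbers and uses a diverging
    colour scale centred at the diploid CN = 2; ``kind="calls"`` expects
    gain/loss/none strings and uses a three-state categorical scale.
    Row/column order follows the supplied orderings exactly, so the
    unclustered mode preserves the input order (useful for spotting batch
    effects along the natural sample order).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap, TwoSlopeNorm

    if set(row_order.order) != set(matrix.index) or set(col_order.order) != set(
        matrix.columns
    ):
        raise AmpcnaError("orderings do not cover the matrix axes")
    data = matrix.loc[row_order.order, col_order.order]

    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.06 * data.shape[1] + 2), max(3.0, 0.12 * data.shape[0] + 2))
    )
    if kind == "cn":
        arr = data.to_numpy(dtype=float)
        vmax = max(4.0, float(np.nanmax(arr)))
        norm = TwoSlopeNorm(vmin=0.0, vcenter=2.0, vmax=vmax)
        im = ax.imshow(arr, aspect="auto", cmap="RdBu_r", norm=norm, interpolation="nearest")
        fig.colorbar(im, ax=ax, label="copy number")
    elif kind == "calls":
        arr = data.map(lambda v: _CALL_CODES[v]).to_numpy(dtype=float)
        cmap = ListedColormap(["#2166ac", "#f7f7f7", "#b2182b"])
        norm = BoundaryNorm([-1.5, -0.5, 0.5, 1.5], cmap.N)
        im = ax.imshow(arr, aspect="auto", cmap=cmap, norm=norm, interpolation="nearest")
        cbar = fig.colorbar(im, ax=ax, ticks=[-1, 0, 1])
        cbar.ax.set_yticklabels(["loss", "none", "gain"])
    else:
        plt.close(fig)
        raise AmpcnaError(f"unknown heatmap kind {kind!r}")

    if data.shape[0] <= 60:
        ax.set_yticks(range(data.shape[0]))
        ax.set_yticklabels(data.index, fontsize=6)
    else:
        ax.set_yticks([])
    if data.shape[1] <= 60:
        ax.set_xticks(range(data.shape[1]))
        ax.set_xticklabels(data.columns, fontsize=6, rotation=90)
    else:
        ax.set_xticks([])
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
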