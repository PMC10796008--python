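"""Rank-rank hypergeometric overlap (RRHO) grids.

Two datasets' full gene rankings (most-upregulated first, restricted to the
shared universe) are compared at a lattice of rank cutoffs. At cutoff pair
(i, j) the overlap x of the top-i genes of one ranking with the top-j of the
other is tested against the hypergeometric null (expected overlap i*j/N):

    x >= expected:  value = -log10 P(X >= x)   (positive, over-enrichment)
    x <  expected:  value = +log10 P(X <= x)   (negative, under-enrichment)

The signed grid renders as the familiar RRHO heatmap: a hot upper-left /
lower-right diagonal for concordant datasets, a hot anti-diagonal for
datasets that mirror each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .congruence import P_LOG_FLOOR
from .signature import RankVector

__all__ = ["RRHOGrid", "rrho_grid", "export_grid"]

_MAX_MAG = -np.log10(P_LOG_FLOOR)
_LN10 = np.log(10.0)


@dataclass
class RRHOGrid:
    """Signed -log10 overlap p-values on a lattice of rank cutoffs.

    ``values`` has shape (len(thresholds_y), len(thresholds_x)), y ascending
    down the rows; both threshold axes are increasing rank cutoffs on the
    shared universe of size ``N``.
    """

    step: int
    thresholds_x: np.ndarray
    thresholds_y: np.ndarray
    values: np.ndarray
    N: int
    dataset_x: str = ""
    dataset_y: str = ""

    def __post_init__(self) -> None:
        assert self.values.shape == (len(self.thresholds_y), len(self.thresholds_x))
        assert np.isfinite(self.values).all()


def default_step(N: int) -> int:
    """~100x100 grid: figure-scale resolution at desk cost."""
    return max(1, N // 100)


def rrho_grid(rx: RankVector, ry: RankVector, step: int | None = None) -> RRHOGrid:
    """Full RRHO grid between two rank vectors.

    Both rankings are restricted to their shared universe (each keeping its
    own order). Thresholds run step, 2*step, ... with N always included, so
    the (N, N) corner — complete overlap, p = 1, value 0 — exists for any
    step.
    """
    shared = frozenset(rx.genes) & frozenset(ry.genes)
    if not shared:
        raise ValueError("empty shared universe")
    gx = rx.restrict(shared).genes
    gy = ry.restrict(shared).genes
    N = len(shared)
    if step is None:
        step = default_step(N)
    if not (1 <= step <= N):
        raise ValueError(f"step must be in [1, {N}], got {step}")

    thresholds = list(range(step, N + 1, step))
    if thresholds[-1] != N:
        thresholds.append(N)
    tx = np.asarray(thresholds, dtype=np.int64)
    ty = tx.copy()

    # position (1-based) of each shared gene in each ranking
    pos_y = {g: b for b, g in enumerate(gy, start=1)}
    a = np.arange(1, N + 1)  # positions along gx
    b = np.asarray([pos_y[g] for g in gx])

    # 2-D histogram of (a, b) over threshold bins, then cumulative sums:
    # overlap[jy, ix] = #{genes with a <= tx[ix] and b <= ty[jy]}
    ax = np.searchsorted(tx, a, side="left")
    by = np.searchsorted(ty, b, side="left")
    hist = np.zeros((len(ty), len(tx)), dtype=np.int64)
    np.add.at(hist, (by, ax), 1)
    overlap = hist.cumsum(axis=0).cumsum(axis=1)

    I = tx[np.newaxis, :].astype(float)  # draws
    J = ty[:, np.newaxis].astype(float)  # successes
    expected = I * J / N
    with np.errstate(divide="ignore"):
        log_sf = hypergeom.logsf(overlap - 1, N, J, I)
        log_cdf = hypergeom.logcdf(overlap, N, J, I)
    over_mag = np.minimum(-log_sf / _LN10, _MAX_MAG)
    under_mag = np.minimum(-log_cdf / _LN10, _MAX_MAG)
    values = np.where(overlap >= expected, over_mag, -under_mag)

    return RRHOGrid(
        step=step,
        thresholds_x=tx,
        thresholds_y=ty,
        values=values,
        N=N,
        dataset_x=rx.dataset_id,
        dataset_y=ry.dataset_id,
    )


def export_grid(g: RRHOGrid, path: str | Path) -> None:
    """Write the grid as TSV: x thresholds as columns, y thresholds as the
    first column, one row per y cutoff."""
    if g.values.size == 0:
        raise ValueError("empty grid")
    df = pd.DataFrame(g.values, index=g.thresholds_y, columns=g.thresholds_x)
    df.index.name = "rank_y"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_grid(path: str | Path) -> pd.DataFrame:
    """Re-read an exported grid (values only, thresholds on the axes)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.columns.astype(int)
    return df


def plot_grid(g: RRHOGrid, ax=None, cmap: str = "RdBu_r", **imshow_kwargs):
    """Thin rendering layer over the computed grid (matplotlib heatmap)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    vmax = np.abs(g.values).max() or 1.0
    im = ax.imshow(
        g.values,
        origin="lower",
        aspect="auto",
        cmap=cmap,
        vmin=-vmax,
        vmax=vmax,
        extent=(0, g.N, 0, g.N),
        **imshow_kwargs,
    )
    ax.set_xlabel(f"rank in {g.dataset_x or 'x'}")
    ax.set_ylabel(f"rank in {g.dataset_y or 'y'}")
    return im
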