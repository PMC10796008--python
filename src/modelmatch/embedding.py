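"""2-D neighborhood embedding of dataset signature vectors.

Each dataset becomes a row vector of signed significances over a chosen gene
subset (typically the reference portrait's top differentially expressed
genes, kept only where most datasets measured them). Pairwise correlation
distances between rows drive a UMAP layout; datasets whose expression
changes track the reference land near it. All quantitative contracts live on
the distance matrix — the 2-D coordinates are for visual assessment only.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .de_io import DETable

__all__ = ["signature_matrix", "correlation_distances", "embed_2d"]


def signature_matrix(
    tables: Sequence[DETable],
    gene_subset: Sequence[str],
    min_fraction_present: float = 0.5,
) -> pd.DataFrame:
    """Datasets x genes matrix of signed significances.

    Columns are restricted to ``gene_subset`` genes measured in at least
    ``min_fraction_present`` of the tables; entries for genes a dataset did
    not measure are filled with 0 (neutral on the signed scale). Row order
    follows the input order.
    """
    if len(gene_subset) == 0:
        raise ValueError("gene_subset is empty")
    subset = pd.Index(pd.unique(pd.Series(list(gene_subset))))
    presence = pd.DataFrame(0.0, index=[t.dataset_id for t in tables], columns=subset)
    mat = presence.copy()
    for t in tables:
        s = t.signed_sig_by_gene()
        hit = subset.intersection(s.index)
        mat.loc[t.dataset_id, hit] = s[hit].to_numpy()
        presence.loc[t.dataset_id, hit] = 1.0
    keep = presence.mean(axis=0) >= min_fraction_present
    if not keep.any():
        raise ValueError("no gene of the subset is present in enough datasets")
    return mat.loc[:, keep]


def correlation_distances(m: pd.DataFrame) -> pd.DataFrame:
    """Pairwise correlation distance (1 - Pearson r) between rows.

    Constant rows have undefined correlation; they are assigned distance 1
    (the null value) to every other row and 0 to themselves.
    """
    X = m.to_numpy(dtype=float)
    sd = X.std(axis=1)
    constant = sd == 0
    Xs = X.copy()
    if constant.any():
        # placeholder rows keep pdist finite; overwritten below
        Xs[constant] = np.random.default_rng(0).normal(size=(int(constant.sum()), X.shape[1]))
    D = squareform(pdist(Xs, metric="correlation"))
    if constant.any():
        D[constant, :] = 1.0
        D[:, constant] = 1.0
        np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=m.index, columns=m.index)


def embed_2d(
    m: pd.DataFrame,
    metric: str = "correlation",
    seed: int = 0,
    n_neighbors: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """UMAP embedding of the signature matrix rows.

    Returns (coords, distances): a rows x 2 coordinate frame, deterministic
    for a given seed, and the pairwise correlation-distance matrix the
    quantitative checks should use instead of the layout geometry.
    """
    if len(m) < 3:
        raise ValueError("need at least 3 rows to embed")
    import umap  # deferred: numba compilation is slow at import

    distances = correlation_distances(m) if metric == "correlation" else None
    if n_neighbors is None:
        n_neighbors = min(15, len(m) - 1)
    reducer = umap.UMAP(
        n_components=2,
        metric="precomputed" if distances is not None else metric,
        n_neighbors=n_neighbors,
        random_state=seed,
        min_dist=0.1,
    )
    X = distances.to_numpy() if distances is not None else m.to_numpy(dtype=float)
    coords = reducer.fit_transform(X)
    if distances is None:
        distances = pd.DataFrame(
            squareform(pdist(m.to_numpy(dtype=float), metric=metric)), index=m.index, columns=m.index
        )
    return pd.DataFrame(coords, index=m.index, columns=["umap1", "umap2"]), distances
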