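"""Ranked gene signatures: top-K up/down sets and full signed rankings.

A signature is the top K upregulated genes (largest positive signed
significance) and top K downregulated genes (most negative). K defaults to
1000 — a fixed cutoff keeps comparisons between datasets on equal footing
and is large enough to reflect reproducible biology rather than only the
extreme tail. The full rank vector (every measured gene ordered by signed
significance) feeds the rank-rank overlap grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de_io import DETable, EmptyInputError

DEFAULT_K = 1000


def _ordered(t: DETable) -> pd.DataFrame:
    # descending signed_sig; ties broken by ascending gene symbol
    return t.data.sort_values(["signed_sig", "gene"], ascending=[False, True], kind="mergesort")


@dataclass
class Signature:
    """Top-K up and down gene lists over a dataset's measured universe.

    ``up`` is ordered by descending signed_sig (positives only), ``down`` by
    ascending signed_sig (negatives only); either may be shorter than K when
    the table has fewer genes of that sign. Genes with signed_sig exactly 0
    carry no direction evidence and appear in neither list.
    """

    dataset_id: str
    universe: frozenset[str]
    up: list[str]
    down: list[str]
    K: int

    def __post_init__(self) -> None:
        assert not (set(self.up) & set(self.down))

    @property
    def sizes(self) -> tuple[int, int]:
        return len(self.up), len(self.down)

    def restrict(self, shared: frozenset[str]) -> "Signature":
        """Drop genes outside ``shared`` while keeping each list's own order."""
        return Signature(
            dataset_id=self.dataset_id,
            universe=self.universe & shared,
            up=[g for g in self.up if g in shared],
            down=[g for g in self.down if g in shared],
            K=self.K,
        )

    def flipped(self) -> "Signature":
        """Sign-reversed signature (up and down exchanged)."""
        return Signature(self.dataset_id + ":flipped", self.universe, list(self.down), list(self.up), self.K)


@dataclass
class RankVector:
    """Full ordering of a dataset's universe, most-upregulated first."""

    dataset_id: str
    genes: list[str] = field(repr=False)

    def __len__(self) -> int:
        return len(self.genes)

    def restrict(self, shared: frozenset[str]) -> "RankVector":
        return RankVector(self.dataset_id, [g for g in self.genes if g in shared])


def extract_signature(t: DETable, K: int = DEFAULT_K) -> Signature:
    """Top-K up and top-K down genes of ``t`` by signed significance.

    Shorter lists are returned when fewer than K genes carry the sign; the
    actual sizes are available as ``Signature.sizes``.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if len(t) == 0:
        raise EmptyInputError("empty DE table")
    df = _ordered(t)
    pos = df[df["signed_sig"] > 0]
    neg = df[df["signed_sig"] < 0]
    up = pos["gene"].head(K).tolist()
    # most negative first: reverse of the descending order, re-tie-broken
    down = (
        neg.sort_values(["signed_sig", "gene"], ascending=[True, True], kind="mergesort")["gene"].head(K).tolist()
    )
    return Signature(
        dataset_id=t.dataset_id,
        universe=frozenset(t.data["gene"]),
        up=up,
        down=down,
        K=K,
    )


def rank_vector(t: DETable) -> RankVector:
    """Full descending ordering by signed_sig, ties by gene symbol."""
    if len(t) == 0:
        raise EmptyInputError("empty DE table")
    return RankVector(t.dataset_id, _ordered(t)["gene"].tolist())


def export_signature(sig: Signature, path) -> None:
    """Two-column TSV (gene, side) for downstream enrichment tools."""
    rows = [(g, "up") for g in sig.up] + [(g, "down") for g in sig.down]
    pd.DataFrame(rows, columns=["gene", "side"]).to_csv(path, sep="\t", index=False)
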