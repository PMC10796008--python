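"""Consensus disease portraits built by directional consistency across datasets.

Each input dataset gets an equal vote per gene: the consensus sign is the
majority direction among the datasets that measured the gene, and the
consensus score weights that vote margin by the gene's mean significance
magnitude::

    consensus_score = (support_up - support_down) / n_present
                      * mean(|signed_sig| where present)

Genes measured by too few datasets are excluded (``min_present``, default a
majority). A portrait can be converted back to a DE table so it can be
scored, ranked against, or embedded like any single dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de_io import DETable

__all__ = ["Portrait", "build_portrait", "portrait_to_detable"]


@dataclass
class Portrait:
    """Per-gene consensus over a collection of DE tables.

    ``data`` columns: gene, support_up, support_down, n_present,
    consensus_sign, consensus_score.
    """

    data: pd.DataFrame
    n_datasets: int
    dataset_id: str = "portrait"

    def __len__(self) -> int:
        return len(self.data)

    def to_detable(self) -> DETable:
        return portrait_to_detable(self)

    def to_tsv(self, path) -> None:
        cols = ["gene", "support_up", "support_down", "n_present", "consensus_sign", "consensus_score"]
        self.data[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def build_portrait(
    tables: list[DETable],
    min_present: int | None = None,
    dataset_id: str = "portrait",
) -> Portrait:
    """Vote-based consensus portrait over ``tables``.

    ``min_present`` defaults to a strict majority of the inputs. The result
    is invariant to the order of the input tables. Raises if no gene clears
    the presence threshold.
    """
    if len(tables) < 1:
        raise ValueError("need at least one table")
    n = len(tables)
    if min_present is None:
        min_present = n // 2 + 1
    if not (1 <= min_present <= n):
        raise ValueError(f"min_present must be in [1, {n}], got {min_present}")

    frames = []
    for t in tables:
        df = t.data[["gene", "direction", "signed_sig"]].copy()
        df["abs_sig"] = df["signed_sig"].abs()
        frames.append(df[["gene", "direction", "abs_sig"]])
    stacked = pd.concat(frames, ignore_index=True)

    grouped = stacked.groupby("gene", sort=True)
    agg = grouped.agg(
        n_present=("direction", "size"),
        support_up=("direction", lambda d: int((d > 0).sum())),
        mean_abs=("abs_sig", "mean"),
    ).reset_index()
    agg["support_down"] = agg["n_present"] - agg["support_up"]
    agg = agg[agg["n_present"] >= min_present].reset_index(drop=True)
    if len(agg) == 0:
        raise ValueError(f"no gene present in >= {min_present} of {n} tables")

    margin = agg["support_up"] - agg["support_down"]
    agg["consensus_sign"] = np.sign(margin).astype(int)
    agg["consensus_score"] = margin / agg["n_present"] * agg["mean_abs"]
    cols = ["gene", "support_up", "support_down", "n_present", "consensus_sign", "consensus_score"]
    return Portrait(data=agg[cols], n_datasets=n, dataset_id=dataset_id)


def portrait_to_detable(p: Portrait) -> DETable:
    """Re-express a portrait as a DE table with signed_sig = consensus_score.

    Genes with a tied vote (consensus_sign 0) are dropped; the p column is
    materialized as 10**(-|consensus_score|) so the signed significance
    round-trips exactly.
    """
    if len(p) == 0:
        raise ValueError("empty portrait")
    df = p.data[p.data["consensus_sign"] != 0]
    if len(df) == 0:
        raise ValueError("portrait has no directional genes")
    out = pd.DataFrame(
        {
            "gene": df["gene"].to_numpy(),
            "direction": df["consensus_sign"].to_numpy(dtype=int),
            "p": np.power(10.0, -df["consensus_score"].abs().to_numpy()),
            "signed_sig": df["consensus_score"].to_numpy(dtype=float),
        }
    )
    return DETable(dataset_id=p.dataset_id, data=out)
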