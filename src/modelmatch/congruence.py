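"""Four-quadrant hypergeometric congruence scoring and model ranking.

Given a model signature and a reference signature restricted to their shared
gene universe, the four overlap quadrants are

    A: up in model and up in reference      (concordant)
    B: up in model, down in reference       (discordant)
    C: down in model, up in reference       (discordant)
    D: down in model and down in reference  (concordant)

Each overlap gets an exact one-sided hypergeometric enrichment p-value
(upper tail: the probability of an overlap at least as large under random
draws from the shared universe). The congruence score is

    score = (-log10 pA - log10 pD) - (-log10 pB - log10 pC)

so concordant enrichment raises the score and discordant enrichment lowers
it. A strongly negative score flags a model whose expression changes mirror
the reference in reverse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de_io import DETable
from .signature import DEFAULT_K, Signature, extract_signature

logger = logging.getLogger(__name__)

#: floor applied to tail p-values before -log10; keeps scores finite
P_LOG_FLOOR = 1e-320


def hypergeom_upper_tail(N: int, k1: int, k2: int, x: int) -> float:
    """Exact upper-tail hypergeometric p-value P(X >= x).

    X counts the overlap when ``k1`` items are drawn without replacement from
    a population of ``N`` containing ``k2`` marked items. Evaluated through
    the survival function in log space, floored at ``P_LOG_FLOOR`` so the
    result is never 0; returns exactly 1 when x == 0.
    """
    if not (0 <= x <= min(k1, k2) <= max(k1, k2) <= N):
        raise ValueError(f"require 0 <= x <= min(k1, k2) <= N, got N={N}, k1={k1}, k2={k2}, x={x}")
    if x == 0:
        return 1.0
    logp = hypergeom.logsf(x - 1, N, k2, k1)
    return float(max(np.exp(logp), P_LOG_FLOOR))


@dataclass(frozen=True)
class QuadrantCounts:
    """Overlap counts of the four direction quadrants on the shared universe.

    ``up_m``/``down_m``/``up_h``/``down_h`` are the signature sizes after
    restriction to the shared universe — the effective draw/success counts
    used in the tail tests — not the nominal K.
    """

    N: int
    up_m: int
    down_m: int
    up_h: int
    down_h: int
    A: int
    B: int
    C: int
    D: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.A <= min(self.up_m, self.up_h)
            and 0 <= self.B <= min(self.up_m, self.down_h)
            and 0 <= self.C <= min(self.down_m, self.up_h)
            and 0 <= self.D <= min(self.down_m, self.down_h)
            and self.A + self.B <= self.up_m
            and self.C + self.D <= self.down_m
        )
        if not ok:
            raise ValueError(f"inconsistent quadrant counts: {self}")


@dataclass(frozen=True)
class CongruenceResult:
    counts: QuadrantCounts
    pA: float
    pB: float
    pC: float
    pD: float

    @property
    def logs(self) -> tuple[float, float, float, float]:
        return tuple(-np.log10(max(p, P_LOG_FLOOR)) for p in (self.pA, self.pB, self.pC, self.pD))

    @property
    def score(self) -> float:
        lA, lB, lC, lD = self.logs
        return (lA + lD) - (lB + lC)


def quadrant_counts(sig_m: Signature, sig_h: Signature) -> QuadrantCounts:
    """Count the four quadrant overlaps on the shared universe.

    Both signatures are restricted to the intersection of the two measured
    universes before counting; no re-ranking refills the lists, so each
    dataset's own ordering stays authoritative.
    """
    shared = sig_m.universe & sig_h.universe
    if not shared:
        raise ValueError(f"empty shared universe between {sig_m.dataset_id} and {sig_h.dataset_id}")
    m = sig_m.restrict(shared)
    h = sig_h.restrict(shared)
    up_m, down_m = set(m.up), set(m.down)
    up_h, down_h = set(h.up), set(h.down)
    return QuadrantCounts(
        N=len(shared),
        up_m=len(up_m),
        down_m=len(down_m),
        up_h=len(up_h),
        down_h=len(down_h),
        A=len(up_m & up_h),
        B=len(up_m & down_h),
        C=len(down_m & up_h),
        D=len(down_m & down_h),
    )


def congruence_score(c: QuadrantCounts) -> CongruenceResult:
    """Per-quadrant upper-tail p-values and the signed congruence score."""
    return CongruenceResult(
        counts=c,
        pA=hypergeom_upper_tail(c.N, c.up_m, c.up_h, c.A),
        pB=hypergeom_upper_tail(c.N, c.up_m, c.down_h, c.B),
        pC=hypergeom_upper_tail(c.N, c.down_m, c.up_h, c.C),
        pD=hypergeom_upper_tail(c.N, c.down_m, c.down_h, c.D),
    )


def score_signatures(sig_m: Signature, sig_h: Signature) -> CongruenceResult:
    """Convenience: quadrant counts then score in one call."""
    return congruence_score(quadrant_counts(sig_m, sig_h))


def congruent_gene_lists(
    sig_m: Signature, sig_h: Signature
) -> tuple[list[str], list[str], list[str]]:
    """Genes behind the quadrant counts: (up_up, down_down, opposite).

    up_up has length A, down_down length D, opposite length B + C; all three
    lists are drawn from the shared universe and sorted by gene symbol.
    """
    shared = sig_m.universe & sig_h.universe
    if not shared:
        raise ValueError("empty shared universe")
    m = sig_m.restrict(shared)
    h = sig_h.restrict(shared)
    up_m, down_m = set(m.up), set(m.down)
    up_h, down_h = set(h.up), set(h.down)
    up_up = sorted(up_m & up_h)
    down_down = sorted(down_m & down_h)
    opposite = sorted((up_m & down_h) | (down_m & up_h))
    return up_up, down_down, opposite


Reference = Union[DETable, "Portrait"]  # noqa: F821  (Portrait duck-types via portrait_to_detable)


def _as_detable(reference) -> DETable:
    if isinstance(reference, DETable):
        return reference
    to_detable = getattr(reference, "to_detable", None)
    if to_detable is not None:
        return to_detable()
    raise TypeError(f"reference must be a DETable or Portrait, got {type(reference)!r}")


def rank_models(
    library: Iterable[DETable],
    reference,
    K: int = DEFAULT_K,
) -> pd.DataFrame:
    """Score every model table against the reference and rank by score.

    Returns a DataFrame with one row per model — dataset_id, quadrant counts,
    per-quadrant p-values and -log10 values, score, and rank 1..n — sorted by
    descending score with ties broken by dataset_id. Models sharing no genes
    with the reference are reported in the ``skipped`` attribute of the
    returned frame (``df.attrs["skipped"]``), never silently dropped. The
    most negative scores identify discordant models.
    """
    ref_table = _as_detable(reference)
    sig_h = extract_signature(ref_table, K)
    rows = []
    skipped: list[str] = []
    for t in library:
        sig_m = extract_signature(t, K)
        try:
            res = congruence_score(quadrant_counts(sig_m, sig_h))
        except ValueError:
            skipped.append(t.dataset_id)
            logger.warning("skipping %s: no shared genes with %s", t.dataset_id, ref_table.dataset_id)
            continue
        c = res.counts
        lA, lB, lC, lD = res.logs
        rows.append(
            {
                "dataset_id": t.dataset_id,
                "reference": ref_table.dataset_id,
                "N": c.N,
                "A": c.A,
                "B": c.B,
                "C": c.C,
                "D": c.D,
                "pA": res.pA,
                "pB": res.pB,
                "pC": res.pC,
                "pD": res.pD,
                "lA": lA,
                "lB": lB,
                "lC": lC,
                "lD": lD,
                "score": res.score,
            }
        )
    if not rows:
        raise ValueError("no scoreable models in library")
    df = pd.DataFrame(rows).sort_values(
        ["score", "dataset_id"], ascending=[False, True], kind="mergesort"
    )
    df["rank"] = np.arange(1, len(df) + 1)
    df = df.reset_index(drop=True)
    df.attrs["skipped"] = skipped
    return df
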