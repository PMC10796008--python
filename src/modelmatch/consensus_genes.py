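"""Cross-model consensus genes and direction-aware Venn overlaps.

After ranking a library of models against a reference, each model contributes
its congruent gene lists (up-up and down-down with the reference). Genes that
recur in the same direction across at least m of the n models form the
cross-model consensus — the shared core of the disease pattern that many
models reproduce.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations
from typing import Mapping, Sequence

__all__ = ["common_direction_genes", "venn_counts"]


def common_direction_genes(
    lists: Sequence[tuple[Sequence[str], Sequence[str]]],
    m: int,
) -> tuple[list[str], list[str], list[str]]:
    """Genes congruent with the reference in >= m of the models, per side.

    ``lists`` holds one (up_up, down_down) pair per model. Returns
    (common_up, common_down, conflicts): each side is counted independently,
    and a gene qualifying on both sides (up in >= m models and down in >= m
    others) appears in both lists and is flagged in ``conflicts``. Outputs
    are sorted by symbol. Monotone: raising m never adds genes.
    """
    n = len(lists)
    if not (1 <= m <= n):
        raise ValueError(f"need 1 <= m <= {n}, got m={m}")
    up_counts: Counter[str] = Counter()
    down_counts: Counter[str] = Counter()
    for up_up, down_down in lists:
        up_counts.update(set(up_up))
        down_counts.update(set(down_down))
    common_up = sorted(g for g, c in up_counts.items() if c >= m)
    common_down = sorted(g for g, c in down_counts.items() if c >= m)
    conflicts = sorted(set(common_up) & set(common_down))
    return common_up, common_down, conflicts


def venn_counts(sets: Mapping[str, Mapping[str, int]]) -> dict[frozenset[str], int]:
    """Region counts of a 2- or 3-set Venn partition, direction-aware.

    Each named set maps gene -> sign (+1/-1). Membership is by signed gene:
    a gene counts as shared between sets only where it appears with the same
    sign, and a gene present with conflicting signs contributes one signed
    element per sign group. Keys of the result are frozensets of set names
    (the region's membership pattern); values sum to the size of the union
    of the signed elements.
    """
    names = list(sets)
    if not (2 <= len(names) <= 3):
        raise ValueError(f"venn_counts supports 2 or 3 sets, got {len(names)}")
    for name in names:
        if not sets[name]:
            raise ValueError(f"set {name!r} is empty")

    all_genes = set()
    for s in sets.values():
        all_genes.update(s)

    regions: dict[frozenset[str], int] = {
        frozenset(combo): 0 for r in range(1, len(names) + 1) for combo in combinations(names, r)
    }
    for gene in all_genes:
        present = {name: sets[name][gene] for name in names if gene in sets[name]}
        # group by sign: members agreeing in sign share a region
        by_sign: dict[int, list[str]] = {}
        for name, sign in present.items():
            by_sign.setdefault(sign, []).append(name)
        for members in by_sign.values():
            regions[frozenset(members)] += 1
    return regions
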