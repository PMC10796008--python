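"""Synthetic DE-table libraries with planted shared structure.

The generator emulates the statistical situation the scoring pipeline
assumes: a set of "human" datasets and a set of "model" datasets that share
(to a tunable degree) one underlying signed effect vector. Each dataset is
simulated at the level the pipeline consumes — a per-gene direction and
p-value from a two-group comparison:

* a planted truth assigns +effect_size / -effect_size (in noise-SD units)
  to a fraction of genes, signs balanced;
* per dataset, each planted gene keeps its effect with probability rho
  (congruence), flips sign with probability delta (discordance), or goes
  silent otherwise; unplanted genes are always null;
* two groups of ``n_per_group`` observations are drawn from
  normal(+-effect/2, noise_sd) and compared by Welch's t-test; the direction
  is the sign of the group-mean difference.

One master seed drives everything; per-dataset seeds are derived at fixed
offsets so streams are independent but reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .de_io import DEFAULT_P_FLOOR, DETable, signed_significance

__all__ = ["SynthConfig", "simulate_truth", "simulate_de_table", "simulate_library"]

_HUMAN_SEED_OFFSET = 100_003
_MODEL_SEED_OFFSET = 200_003


@dataclass
class SynthConfig:
    """Parameters of a synthetic library.

    model_specs lists one (rho, delta) pair per model dataset: rho is the
    probability a planted gene keeps its true effect, delta the probability
    it is sign-flipped; rho + delta <= 1 and the remainder goes silent.
    Human datasets are always drawn at rho = 1, delta = 0 with independent
    noise. effect_size is the group-mean shift in units of noise_sd.
    """

    n_genes: int = 20000  # ~ protein-coding transcriptome
    effect_fraction: float = 0.1
    effect_size: float = 1.0
    n_per_group: int = 6
    n_human_datasets: int = 5
    model_specs: list[tuple[float, float]] = field(default_factory=lambda: [(0.9, 0.0), (0.5, 0.0), (0.1, 0.0)])
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_per_group < 2 or self.n_human_datasets < 0:
            raise ValueError("counts must be positive (n_per_group >= 2)")
        if not (0 <= self.effect_fraction < 1):
            raise ValueError(f"effect_fraction must be in [0, 1), got {self.effect_fraction}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for rho, delta in self.model_specs:
            if not (0 <= rho <= 1 and 0 <= delta <= 1 and rho + delta <= 1):
                raise ValueError(f"invalid model spec (rho={rho}, delta={delta})")

    def gene_names(self) -> np.ndarray:
        width = len(str(self.n_genes))
        return np.array([f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)], dtype=object)


def simulate_truth(c: SynthConfig) -> np.ndarray:
    """Planted signed effect vector: 0, +effect_size or -effect_size per gene.

    Exactly round(effect_fraction * n_genes) genes carry an effect, with up
    and down counts balanced to within one. Deterministic given c.seed.
    """
    rng = np.random.default_rng(c.seed)
    n_effect = int(round(c.effect_fraction * c.n_genes))
    truth = np.zeros(c.n_genes)
    if n_effect:
        idx = rng.choice(c.n_genes, size=n_effect, replace=False)
        half = n_effect // 2
        signs = np.concatenate([np.ones(n_effect - half), -np.ones(half)])
        rng.shuffle(signs)
        truth[idx] = signs * c.effect_size
    return truth


def simulate_de_table(
    truth: np.ndarray,
    rho: float,
    delta: float,
    c: SynthConfig,
    dataset_seed: int,
    dataset_id: str = "synthetic",
    p_floor: float = DEFAULT_P_FLOOR,
) -> DETable:
    """One DE table sharing the planted truth with congruence rho / discordance delta.

    Per planted gene the dataset-specific effect is the planted one with
    probability rho, the sign-flipped one with probability delta, and zero
    otherwise. Two groups of n_per_group samples are drawn from
    normal(-effect/2, noise_sd) and normal(+effect/2, noise_sd); p comes from
    Welch's t-test and the direction from the sign of the observed group-mean
    difference.
    """
    if c.n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(dataset_seed)
    truth = np.asarray(truth, dtype=float)
    n = truth.size

    effect = np.zeros(n)
    planted = truth != 0
    if planted.any():
        u = rng.random(n)
        keep = planted & (u < rho)
        flip = planted & (u >= rho) & (u < rho + delta)
        effect[keep] = truth[keep]
        effect[flip] = -truth[flip]
    effect_sd = effect * c.noise_sd  # effect_size is in SD units

    g1 = rng.normal(-effect_sd[:, None] / 2, c.noise_sd, size=(n, c.n_per_group))
    g2 = rng.normal(+effect_sd[:, None] / 2, c.noise_sd, size=(n, c.n_per_group))
    res = ttest_ind(g2, g1, axis=1, equal_var=False)
    diff = g2.mean(axis=1) - g1.mean(axis=1)
    direction = np.where(diff >= 0, 1, -1)
    p = np.clip(np.nan_to_num(res.pvalue, nan=1.0), p_floor, 1.0)

    df = pd.DataFrame(
        {
            "gene": c.gene_names()[:n],
            "direction": direction,
            "p": p,
            "signed_sig": signed_significance(p, direction, p_floor),
        }
    )
    return DETable(dataset_id=dataset_id, data=df)


def simulate_library(c: SynthConfig) -> tuple[list[DETable], list[DETable], np.ndarray]:
    """Full synthetic study: human tables, model tables, and the truth.

    Human tables are perfectly congruent with the truth (rho = 1, delta = 0)
    up to sampling noise; model tables follow ``c.model_specs``. The returned
    truth vector supports recovery scoring.
    """
    truth = simulate_truth(c)
    humans = [
        simulate_de_table(truth, 1.0, 0.0, c, dataset_seed=c.seed + _HUMAN_SEED_OFFSET + i, dataset_id=f"human{i + 1}")
        for i in range(c.n_human_datasets)
    ]
    models = [
        simulate_de_table(
            truth,
            rho,
            delta,
            c,
            dataset_seed=c.seed + _MODEL_SEED_OFFSET + j,
            dataset_id=f"model{j + 1}_rho{rho:g}_delta{delta:g}",
        )
        for j, (rho, delta) in enumerate(c.model_specs)
    ]
    return humans, models, truth
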