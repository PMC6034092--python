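"""Synthetic linear group-structured classification benchmark.

Generates datasets in which the truly relevant feature groups are known,
so selection procedures can be scored exactly.  p features are split into
g contiguous groups of random sizes (g - 1 distinct cut-offs drawn from
{1..p-1}).  R groups are relevant: group k carries a latent driver
``z_k ~ N(0,1)`` per sample, and each of its features is an independent
noisy copy ``z_k + N(0,1)`` (within-group correlation 0.5).  Features of
irrelevant groups are i.i.d. N(0,1).  The label is

    y = 1  if  sum_k w_k z_k > 0  else 0,

with weights ``w_k ~ U[0,1]``, after which a fixed fraction of labels
(default 1%) is flipped, chosen uniformly without replacement.

``R = 0`` is accepted as an explicit null model: every feature is pure
noise and labels are i.i.d. fair coin flips, independent of all features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .partition import FeaturePartition


@dataclass
class SyntheticSpec:
    """Generator parameters.

    Defaults follow the benchmark's central setting: 500 features in 50
    groups, 5 relevant groups, 100 samples, 1% label noise.
    """

    p: int = 500
    g: int = 50
    R: int = 5
    n: int = 100
    flip_fraction: float = 0.01
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.R <= self.g <= self.p:
            raise ValueError("need 0 <= R <= g <= p")
        if not 0 <= self.flip_fraction < 0.5:
            raise ValueError("flip_fraction must be in [0, 0.5)")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass
class SyntheticGroundTruth:
    """Everything needed to score a selection against the generator."""

    spec: SyntheticSpec
    partition: FeaturePartition
    relevant_groups: list[str]
    weights: np.ndarray  # shape (R,)
    latents: np.ndarray  # shape (n, R)
    flipped_samples: np.ndarray  # indices of label-noise samples

    @property
    def irrelevant_groups(self) -> list[str]:
        rel = set(self.relevant_groups)
        return [g for g in self.partition.group_ids if g not in rel]


def sample_partition_sizes(p: int, g: int, rng: np.random.Generator) -> np.ndarray:
    """Random group sizes: g - 1 distinct cut-offs from {1..p-1}.

    With cut-offs c_1 < ... < c_{g-1}, c_0 = 0 and c_g = p, the i-th size
    is c_i - c_{i-1}; all sizes are >= 1 and sum to p.  (Drawing from
    {1..p-1} rather than {1..p} guarantees no empty final group.)
    """
    if g > p:
        raise ValueError("cannot split p features into more than p groups")
    if g == 1:
        return np.array([p])
    cuts = np.sort(rng.choice(np.arange(1, p), size=g - 1, replace=False))
    bounds = np.concatenate(([0], cuts, [p]))
    return np.diff(bounds)


def generate(spec: SyntheticSpec):
    """Generate one dataset.

    Returns
    -------
    X : ndarray, shape (n, p)
    y : ndarray of {0,1}, shape (n,)
    truth : SyntheticGroundTruth
    """
    rng = np.random.default_rng(spec.seed)
    sizes = sample_partition_sizes(spec.p, spec.g, rng)
    group_ids = [f"G{i + 1}" for i in range(spec.g)]
    assignment = np.repeat(np.arange(spec.g), sizes)
    partition = FeaturePartition(group_ids, assignment)

    relevant_idx = np.sort(rng.choice(spec.g, size=spec.R, replace=False))
    weights = rng.uniform(0.0, 1.0, size=spec.R)
    latents = rng.standard_normal((spec.n, spec.R))

    if spec.R > 0:
        y = (latents @ weights > 0).astype(np.int64)  # sgn(0) -> class 0
    else:
        y = rng.integers(0, 2, size=spec.n).astype(np.int64)

    rel_pos = {int(gi): k for k, gi in enumerate(relevant_idx)}
    X = np.empty((spec.n, spec.p))
    start = 0
    for gi, size in enumerate(sizes):
        block = slice(start, start + size)
        if gi in rel_pos:
            z = latents[:, rel_pos[gi]][:, None]
            X[:, block] = z + rng.standard_normal((spec.n, size))
        else:
            X[:, block] = rng.standard_normal((spec.n, size))
        start += size

    n_flip = round(spec.flip_fraction * spec.n)
    flipped = np.sort(rng.choice(spec.n, size=n_flip, replace=False))
    y[flipped] = 1 - y[flipped]

    truth = SyntheticGroundTruth(
        spec=spec,
        partition=partition,
        relevant_groups=[group_ids[i] for i in relevant_idx],
        weights=weights,
        latents=latents,
        flipped_samples=flipped,
    )
    return X, y, truth
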