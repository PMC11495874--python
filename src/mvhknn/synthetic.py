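"""Synthetic benchmark data.

The generator emulates the statistical setting the classifier is built
for — two balanced classes of high-dimensional, roughly isotropic feature
vectors (in the intended application, fixed-length sequence embeddings) —
plus the controlled violations the robust loss is supposed to absorb:
feature-space outliers (samples displaced far along random directions)
and label noise. It makes no attempt to mimic the geometry of any real
embedding space; it only provides separable-by-construction problems on
which every solver property can be exercised without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import FeatureDataset
from .exceptions import ConfigurationError

__all__ = ["BlobConfig", "generate_blobs", "contaminate", "random_peptides",
           "AMINO_ACIDS"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class BlobConfig:
    """Two-class Gaussian-mixture design.

    n_per_class : samples per class (balanced by construction).
    d           : feature dimension.
    separation  : distance between the class means, in units of the
                  within-class standard deviation, along a random
                  direction.
    within_sd   : isotropic within-class standard deviation.
    outlier_fraction / outlier_scale : fraction of samples displaced by
                  ``outlier_scale * within_sd`` along random directions.
    label_flip_fraction : fraction of labels flipped (disjoint from the
                  displaced set).
    seed        : drives every random draw.

    The defaults (100 per class, d = 50, separation 6) give a clean,
    easily separable problem that is still high-dimensional enough for
    K-neighbourhoods up to K = 10 with d > K.
    """

    n_per_class: int = 100
    d: int = 50
    separation: float = 6.0
    within_sd: float = 1.0
    outlier_fraction: float = 0.0
    outlier_scale: float = 10.0
    label_flip_fraction: float = 0.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.d < 1:
            raise ConfigurationError("n_per_class and d must be >= 1")
        if self.within_sd <= 0:
            raise ConfigurationError("within_sd must be > 0")
        if not 0 <= self.outlier_fraction < 1:
            raise ConfigurationError("outlier_fraction must be in [0, 1)")
        if not 0 <= self.label_flip_fraction < 1:
            raise ConfigurationError("label_flip_fraction must be in [0, 1)")
        if self.outlier_scale < 1:
            raise ConfigurationError("outlier_scale must be >= 1")


def _unit_vector(rng: np.random.Generator, d: int) -> np.ndarray:
    v = rng.standard_normal(d)
    n = np.linalg.norm(v)
    while n == 0.0:  # pragma: no cover - probability zero
        v = rng.standard_normal(d)
        n = np.linalg.norm(v)
    return v / n


def generate_blobs(cfg: BlobConfig) -> FeatureDataset:
    """Two isotropic Gaussian classes, means ``separation * within_sd``
    apart along a random unit direction; deterministic given seed."""
    rng = np.random.default_rng(cfg.seed)
    u = _unit_vector(rng, cfg.d)
    offset = 0.5 * cfg.separation * cfg.within_sd * u
    n = cfg.n_per_class
    X0 = -offset + cfg.within_sd * rng.standard_normal((n, cfg.d))
    X1 = offset + cfg.within_sd * rng.standard_normal((n, cfg.d))
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    ids = [f"s{i:04d}" for i in range(2 * n)]
    return FeatureDataset(ids=ids, X=X, y=y,
                          metadata={"config": cfg, "class_means_axis": u})


def contaminate(data: FeatureDataset, cfg: BlobConfig) -> FeatureDataset:
    """Displace and/or label-flip seeded, disjoint subsets of samples.

    Exactly ``round(outlier_fraction * n)`` rows are moved by
    ``outlier_scale * within_sd`` along fresh random directions and
    exactly ``round(label_flip_fraction * n)`` labels are flipped; the
    affected indices are recorded in ``metadata``. All-zero fractions
    return an identical copy.
    """
    n = data.n
    n_out = _round_half_up(cfg.outlier_fraction * n)
    n_flip = _round_half_up(cfg.label_flip_fraction * n)
    if n_out + n_flip > n:
        raise ConfigurationError(
            f"outlier ({n_out}) plus flipped ({n_flip}) samples exceed n={n}"
        )
    rng = np.random.default_rng([cfg.seed, 1])  # independent of generation
    perm = rng.permutation(n)
    out_idx = np.sort(perm[:n_out])
    flip_idx = np.sort(perm[n_out:n_out + n_flip])

    X = data.X.copy()
    y = data.y.copy()
    for i in out_idx:
        X[i] += cfg.outlier_scale * cfg.within_sd * _unit_vector(rng, data.d)
    y[flip_idx] = 1 - y[flip_idx]  # binary by construction

    meta = dict(data.metadata)
    meta["displaced_indices"] = out_idx.tolist()
    meta["flipped_indices"] = flip_idx.tolist()
    return FeatureDataset(ids=list(data.ids), X=X, y=y, metadata=meta)


def random_peptides(ids, seed: int = 0, min_len: int = 8,
                    max_len: int = 30) -> list[tuple[str, str]]:
    """Random amino-acid sequences keyed by the given IDs.

    Pure bookkeeping: lets synthetic feature tables travel with a FASTA
    file whose record IDs match the table rows, as real embedding tables
    would. The sequences carry no signal.
    """
    rng = np.random.default_rng(seed)
    out = []
    for sid in ids:
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        out.append((str(sid), seq))
    return out
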