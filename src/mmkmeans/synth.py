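"""Seeded synthetic datasets with known cluster structure.

Two generators are provided.  ``generate_mixture`` draws spherical
Gaussian components around deterministically placed means — the geometry
(component separation in units of the within-component standard
deviation) is the single knob that controls problem difficulty, and it
emulates the large dense benchmark matrices (up to 50,000 x 50) used to
stress-test k-means variants.  ``generate_periodic_profiles`` produces
sinusoidal rows over equally spaced timepoints with k distinct phases —
a microarray-like stand-in for periodic expression programs sampled
across a developmental cycle.

Both are pure functions of their spec (one named RNG per call, no global
state): the same seed always yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice, product
from typing import Optional, Sequence

import numpy as np

from .io import DataMatrix, PartitionLabels


@dataclass
class MixtureSpec:
    """Parameters of a spherical Gaussian mixture.

    ``separation`` is the distance between adjacent component means;
    ``noise_sd`` the within-component standard deviation (both unitless,
    so separation/noise_sd is the signal-to-noise ratio).  Defaults give
    well-separated clusters (separation = 8 x noise_sd), the regime in
    which whole-cluster stability is expected to emerge early.
    """

    n: int
    d: int
    k_true: int
    separation: float = 8.0
    noise_sd: float = 1.0
    seed: int = 0
    weights: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if not (self.n >= self.k_true >= 1):
            raise ValueError("need n >= k_true >= 1")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (self.k_true,) or (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError("weights must be k_true non-negative values summing to 1")


def component_means(k: int, d: int, separation: float) -> np.ndarray:
    """Deterministic placement of k component means in d dimensions.

    For k <= d the means sit on scaled canonical basis vectors (a regular
    simplex: every pair exactly ``separation`` apart).  For k > d they
    occupy the first k sites of an integer lattice scaled so adjacent
    sites are ``separation`` apart.
    """
    if k <= d:
        means = np.zeros((k, d))
        np.fill_diagonal(means[:, :k], separation / np.sqrt(2.0))
        return means
    side = max(2, int(np.ceil(k ** (1.0 / d))))
    while side**d < k:
        side += 1
    pts = np.array(list(islice(product(range(side), repeat=d), k)), dtype=float)
    return pts * separation


def generate_mixture(spec: MixtureSpec) -> tuple[DataMatrix, PartitionLabels]:
    """Draw n points from a spherical Gaussian mixture with known labels."""
    rng = np.random.default_rng(spec.seed)
    means = component_means(spec.k_true, spec.d, spec.separation)
    weights = None if spec.weights is None else np.asarray(spec.weights, dtype=float)
    labels = rng.choice(spec.k_true, size=spec.n, p=weights)
    X = means[labels] + rng.normal(0.0, spec.noise_sd, size=(spec.n, spec.d))
    ids = [f"pt{i}" for i in range(spec.n)]
    return (
        DataMatrix(ids=ids, values=X),
        PartitionLabels(ids=list(ids), labels=labels),
    )


def generate_periodic_profiles(
    n: int,
    d: int,
    k_true: int,
    phase_jitter: float = 0.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[DataMatrix, PartitionLabels]:
    """Sinusoidal rows over d equally spaced timepoints, k distinct phases.

    Row i of class c is ``sin(t + 2*pi*c/k_true + jitter_i) + noise`` over
    ``t = 0 .. 2*pi`` (exclusive).  With ``phase_jitter = noise_sd = 0``
    all rows of a class are identical; with k_true = 2 the two class mean
    profiles are in antiphase (Pearson r = -1).
    """
    if d < 4:
        raise ValueError("d must be >= 4 for periodic profiles")
    if not (n >= k_true >= 1):
        raise ValueError("need n >= k_true >= 1")
    if phase_jitter < 0 or noise_sd < 0:
        raise ValueError("phase_jitter and noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 2.0 * np.pi, d, endpoint=False)
    labels = rng.choice(k_true, size=n)
    phases = 2.0 * np.pi * labels / k_true
    if phase_jitter > 0:
        phases = phases + rng.normal(0.0, phase_jitter, size=n)
    X = np.sin(t[None, :] + phases[:, None])
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=(n, d))
    ids = [f"g{i}" for i in range(n)]
    return (
        DataMatrix(ids=ids, values=X),
        PartitionLabels(ids=list(ids), labels=labels),
    )
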