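"""Stochastic augmentations for tri-axial windows and their composition.

The contrastive views t(x), t'(x) are two independent draws of the composed
transformation. Composition order is fixed (jitter → scale → rotate →
permute) so a run is fully determined by one RNG stream. Magnitudes are
deliberately config-exposed, never hard-coded, since sensible values depend
on the sensor and units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "AugmentationConfig",
    "jitter",
    "scale",
    "rotate",
    "permute",
    "permute_with_plan",
    "compose",
    "PRESETS",
]


@dataclass(frozen=True)
class AugmentationConfig:
    """Which augmentations are enabled and how strong they are.

    ``jitter_sigma``: additive white-noise std (signal units).
    ``scaling_sigma``: per-channel multiplicative factor ~ N(1, sigma^2) —
    channel-wise gain mimics device orientation/sensitivity differences.
    ``use_rotation``: one uniform random 3-D rotation applied to all samples.
    ``use_permutation``: cut into ``n_perm_segments`` chunks (each at least
    ``min_perm_segment_len`` samples) and reorder them.
    """

    jitter_sigma: float = 0.05
    scaling_sigma: float = 0.1
    use_rotation: bool = False
    use_permutation: bool = False
    n_perm_segments: int = 4
    min_perm_segment_len: int = 10

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0 or self.scaling_sigma < 0:
            raise ValueError("sigmas must be non-negative")
        if self.n_perm_segments < 1 or self.min_perm_segment_len < 1:
            raise ValueError("permutation parameters must be positive")


#: Per-dataset-style recipes: permutation-based vs rotation-based view pairs.
PRESETS: dict[str, AugmentationConfig] = {
    "uci_like": AugmentationConfig(use_permutation=True),
    "hasc_like": AugmentationConfig(use_rotation=True),
}


def jitter(window: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Add element-wise Gaussian noise N(0, sigma^2)."""
    if sigma == 0:
        return window.copy()
    return window + rng.normal(0.0, sigma, size=window.shape)


def scale(window: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Multiply each channel by its own factor drawn from N(1, sigma^2)."""
    if sigma == 0:
        return window.copy()
    factors = rng.normal(1.0, sigma, size=window.shape[1])
    return window * factors


def rotate(window: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply one uniformly random proper 3-D rotation to every time sample."""
    if window.shape[1] != 3:
        raise ValueError(f"rotation needs 3 channels, got {window.shape[1]}")
    R = Rotation.random(rng=rng).as_matrix()
    return window @ R.T


def _cut_lengths(
    length: int, n_segments: int, min_len: int, rng: np.random.Generator
) -> np.ndarray:
    extra = length - n_segments * min_len
    if extra < 0:
        raise ValueError(
            f"cannot cut {length} samples into {n_segments} chunks of >= {min_len}"
        )
    if n_segments == 1:
        return np.array([length])
    bars = np.sort(rng.integers(0, extra + 1, size=n_segments - 1))
    return min_len + np.diff(np.concatenate(([0], bars, [extra])))


def permute(
    window: np.ndarray,
    n_segments: int,
    min_len: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cut into contiguous chunks at random points and shuffle their order.

    The multiset of time samples is preserved exactly; only their order
    changes. ``n_segments=1`` is the identity.
    """
    if n_segments == 1:
        return window.copy()
    lengths = _cut_lengths(window.shape[0], n_segments, min_len, rng)
    order = rng.permutation(n_segments)
    return permute_with_plan(window, lengths, order)


def permute_with_plan(
    window: np.ndarray, lengths: np.ndarray, order: np.ndarray
) -> np.ndarray:
    """Deterministic core of :func:`permute`: explicit chunk lengths + order."""
    if int(np.sum(lengths)) != window.shape[0]:
        raise ValueError("chunk lengths must sum to the window length")
    bounds = np.concatenate(([0], np.cumsum(lengths)))
    chunks = [window[bounds[i] : bounds[i + 1]] for i in range(len(lengths))]
    return np.concatenate([chunks[i] for i in order], axis=0)


def compose(
    config: AugmentationConfig,
) -> Callable[[np.ndarray, np.random.Generator], np.ndarray]:
    """Build the view transformation t(·) from a config.

    Returns ``transform(window, rng) -> window`` applying the enabled
    augmentations in the fixed order jitter → scale → rotate → permute.
    With all magnitudes zero and both flags off it is the identity.
    """

    def transform(window: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = jitter(window, config.jitter_sigma, rng)
        out = scale(out, config.scaling_sigma, rng)
        if config.use_rotation:
            out = rotate(out, rng)
        if config.use_permutation:
            out = permute(
                out, config.n_perm_segments, config.min_perm_segment_len, rng
            )
        return out

    return transform
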