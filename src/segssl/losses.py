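"""The segment-based loss family for unsupervised activity representation.

Four pieces:

- **Segment discrimination (SD)**: a non-parametric softmax classifying each
  window's normalized feature against a memory bank holding one unit-norm
  row per *segment* (instance discrimination uses one row per window; SD is
  the same machinery with segment pseudo-labels, so M ≤ N output classes).
- **Feature-independent softmax (FIS)**: a soft orthogonality penalty on the
  per-dimension column vectors of the batch feature matrix, decorrelating
  feature dimensions.
- **NT-Xent**: the normalized temperature-scaled cross entropy over cosine
  similarities; each anchor's positive is its paired view, every other view
  in the 2b-batch is a negative.
- Their weighted combination ``λ1·Ls + λ2·Lsd + λ3·Lfd``.

All losses accept either plain numpy arrays or autodiff tensors; gradients
flow to the features (the memory bank is a buffer updated by momentum, not
by backprop).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, as_tensor, concatenate

__all__ = [
    "LossConfig",
    "MemoryBank",
    "sd_probability",
    "sd_loss",
    "update_bank",
    "fis_loss",
    "nt_xent_loss",
    "combined_loss",
]


@dataclass
class LossConfig:
    """Temperatures and component weights.

    ``tau`` is the NT-Xent temperature (1 gives plain cross-entropy on
    cosine similarities); ``sd_tau`` the SD softmax temperature (1 matches
    the printed non-parametric softmax). ``lambda1..3`` weight NT-Xent, SD
    and FIS respectively. ``bank_momentum`` is the memory-bank update inertia.
    """

    tau: float = 1.0
    sd_tau: float = 1.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 1.0
    bank_momentum: float = 0.5
    batch_size: int = 64

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.sd_tau <= 0:
            raise ValueError("temperatures must be positive")
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("loss weights must be non-negative")
        if not 0 <= self.bank_momentum <= 1:
            raise ValueError("bank_momentum must lie in [0, 1]")


class MemoryBank:
    """M unit-norm d-dimensional rows, one stored feature per segment."""

    def __init__(self, bank: np.ndarray, momentum: float = 0.5):
        bank = np.asarray(bank, dtype=np.float64)
        if bank.ndim != 2:
            raise ValueError("bank must be an M x d matrix")
        self.bank = bank / np.linalg.norm(bank, axis=1, keepdims=True)
        self.momentum = float(momentum)

    @classmethod
    def random_init(
        cls, n_slots: int, dim: int, rng: np.random.Generator, momentum: float = 0.5
    ) -> "MemoryBank":
        return cls(rng.normal(size=(n_slots, dim)), momentum=momentum)

    @property
    def n_slots(self) -> int:
        return self.bank.shape[0]

    @property
    def dim(self) -> int:
        return self.bank.shape[1]


def sd_probability(bank: MemoryBank, f: np.ndarray, s: int, sd_tau: float = 1.0) -> float:
    """P(s | f): softmax over all bank rows of the stored-feature dot products."""
    if not 0 <= s < bank.n_slots:
        raise IndexError(f"segment label {s} outside [0, {bank.n_slots})")
    logits = bank.bank @ np.asarray(f, dtype=np.float64) / sd_tau
    logits -= logits.max()
    p = np.exp(logits)
    return float(p[s] / p.sum())


def sd_loss(
    bank: MemoryBank,
    features,
    segment_labels: np.ndarray,
    sd_tau: float = 1.0,
) -> Tensor:
    """Mean over the batch of −log P(s_i | f_i).

    ``features`` are row-normalized (b, d); the bank enters as a constant so
    gradients reach only the features. With a single bank slot the softmax
    is degenerate and the loss is exactly zero.
    """
    F = as_tensor(features)
    labels = np.asarray(segment_labels, dtype=np.int64)
    if F.shape[0] != labels.shape[0]:
        raise ValueError("one segment label per feature row required")
    if labels.min() < 0 or labels.max() >= bank.n_slots:
        raise ValueError(
            f"segment labels must lie in [0, {bank.n_slots}); "
            f"got range [{labels.min()}, {labels.max()}]"
        )
    logits = F @ bank.bank.T * (1.0 / sd_tau)  # (b, M)
    lse = logits.logsumexp(axis=1)
    hit = logits.take_rows(np.arange(labels.size), labels)
    return (lse - hit).mean()


def update_bank(
    bank: MemoryBank, features, segment_labels: np.ndarray
) -> MemoryBank:
    """Momentum-update the rows of segments present in the batch, in place.

    ``row ← normalize(m·row + (1−m)·mean(batch features of that segment))``;
    rows of absent segments are untouched. Returns the same bank object.
    """
    F = features.value if isinstance(features, Tensor) else np.asarray(features)
    labels = np.asarray(segment_labels, dtype=np.int64)
    m = bank.momentum
    if m == 1.0:
        return bank
    for s in np.unique(labels):
        mean_f = F[labels == s].mean(axis=0)
        row = m * bank.bank[s] + (1 - m) * mean_f
        bank.bank[s] = row / np.linalg.norm(row)
    return bank


def fis_loss(features) -> Tensor:
    """Soft orthogonality penalty on feature dimensions.

    With V = Fᵀ and columns v_i (one per feature dimension), returns
    −Σ_i log[ exp(v_i·v_i) / Σ_j exp(v_j·v_i) ] — a sum over the d
    dimensions, exactly as the softmax form is printed (no averaging, no
    column normalization).
    """
    F = as_tensor(features)
    G = F.T @ F  # (d, d), G[i, j] = v_i · v_j
    d = G.shape[0]
    lse = G.logsumexp(axis=0)  # over j for each column i
    diag = G.take_rows(np.arange(d), np.arange(d))
    return (lse - diag).sum()


def nt_xent_loss(z_a, z_b, tau: float = 1.0) -> Tensor:
    """Normalized temperature-scaled cross entropy over a batch of pairs.

    The 2b views are stacked; for anchor i with positive partner j the term
    is −log[ exp(sim(z_i,z_j)/τ) / Σ_{k≠i} exp(sim(z_i,z_k)/τ) ] with
    cosine similarity; the mean over all 2b anchors is returned. With b=1
    the positive is the only non-self term, making the loss exactly zero.
    """
    z_a, z_b = as_tensor(z_a), as_tensor(z_b)
    if z_a.shape != z_b.shape:
        raise ValueError(f"paired batches must match: {z_a.shape} vs {z_b.shape}")
    b = z_a.shape[0]
    z = concatenate([z_a, z_b], axis=0).normalize(axis=-1)
    sim = z @ z.T * (1.0 / tau)  # (2b, 2b) cosine similarities
    mask = np.zeros((2 * b, 2 * b))
    np.fill_diagonal(mask, -1e12)  # exclude self-similarity from the denominator
    masked = sim + mask
    lse = masked.logsumexp(axis=1)
    partner = np.concatenate([np.arange(b, 2 * b), np.arange(b)])
    pos = sim.take_rows(np.arange(2 * b), partner)
    return (lse - pos).mean()


def combined_loss(
    z_a,
    z_b,
    sd_features,
    segment_labels: np.ndarray,
    bank: MemoryBank,
    config: LossConfig,
) -> tuple[Tensor, dict[str, float]]:
    """λ1·Ls + λ2·Lsd + λ3·Lfd, plus the component values.

    The contrastive term consumes the paired fp1 projections; SD and FIS
    consume the concatenated 2b batch of fp2 projections (the pair is merged
    into one batch for the discrimination losses). A component with zero
    weight is skipped entirely, so e.g. λ=(1,0,0) is exactly NT-Xent.
    """
    total: Tensor = as_tensor(0.0)
    parts: dict[str, float] = {"ls": 0.0, "lsd": 0.0, "lfd": 0.0}
    if config.lambda1 > 0:
        ls = nt_xent_loss(z_a, z_b, tau=config.tau)
        parts["ls"] = ls.item()
        total = total + config.lambda1 * ls
    if config.lambda2 > 0:
        lsd = sd_loss(bank, sd_features, segment_labels, sd_tau=config.sd_tau)
        parts["lsd"] = lsd.item()
        total = total + config.lambda2 * lsd
    if config.lambda3 > 0:
        lfd = fis_loss(sd_features)
        parts["lfd"] = lfd.item()
        total = total + config.lambda3 * lfd
    return total, parts
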