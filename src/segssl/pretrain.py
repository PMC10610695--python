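"""Pair sampling and the unsupervised pretraining loop.

Seven method variants share one loop:

===================  =============================================
method               losses / pairing
===================  =============================================
id                   instance-label discrimination, bank size N
idfd                 id + feature decorrelation (FIS)
sd                   segment-label discrimination, bank size M
sdfd                 sd + FIS
simclr               NT-Xent on instance pairs (two views, one window)
simclr_seg           NT-Xent on segment pairs (two windows, one segment)
simclr_seg_sdfd      segment pairs: NT-Xent on fp1 of the pair plus
                     SD + FIS on fp2 of the concatenated 2b batch
===================  =============================================

Discrimination methods (id/idfd/sd/sdfd) are literally the same code path
with different pseudo-labels, so making every window its own segment
reproduces instance discrimination bit for bit. The checkpoint kept is the
one with the lowest epoch-mean training loss, not the last epoch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import augment as aug
from .losses import LossConfig, MemoryBank, combined_loss, fis_loss, nt_xent_loss, sd_loss, update_bank
from .model import HarModel, ModelSpec
from .nn import Adam
from .segments import DatasetIndex

__all__ = [
    "METHODS",
    "PairBatch",
    "PretrainConfig",
    "PretrainResult",
    "sample_segment_pairs",
    "sample_instance_pairs",
    "pretrain",
    "named_streams",
]

METHODS = ("id", "idfd", "sd", "sdfd", "simclr", "simclr_seg", "simclr_seg_sdfd")

_PAIR_METHODS = ("simclr", "simclr_seg", "simclr_seg_sdfd")


def named_streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    """Split one root seed into independent named RNG streams."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class PairBatch:
    """Two augmented views per row; both views of row i share an identity.

    For segment-based sampling that identity is the segment label (the
    source windows may differ); for instance-based sampling it is the
    window itself.
    """

    view_a: np.ndarray  # (b, L, 3)
    view_b: np.ndarray
    segment_labels: np.ndarray
    instance_labels: np.ndarray  # source of view_a
    source_instance_b: np.ndarray  # source of view_b


@dataclass
class PretrainConfig:
    """Training hyperparameters for the pretext task.

    Defaults follow the reference protocol: Adam at learning rate 0.01 for
    150 epochs; one epoch is ⌈N/b⌉ batches. The augmentation preset names a
    view recipe in :mod:`segssl.augment`.
    """

    method: str = "simclr_seg_sdfd"
    epochs: int = 150
    batch_size: int = 64
    learning_rate: float = 0.01
    seed: int = 0
    augmentation: aug.AugmentationConfig = field(
        default_factory=lambda: aug.PRESETS["hasc_like"]
    )
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; one of {METHODS}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class PretrainResult:
    model: HarModel
    steps: list[dict]  # per-step loss components
    epoch_loss: list[float]  # epoch-mean total loss
    best_epoch: int  # index of the checkpointed epoch

    def write_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for row in self.steps:
                fh.write(json.dumps(row) + "\n")


def _draw_pair_sources(
    index: DatasetIndex, batch_size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pick b segments and two source windows per segment."""
    M = index.n_segments
    segs = (
        rng.choice(M, size=batch_size, replace=False)
        if M >= batch_size
        else rng.choice(M, size=batch_size, replace=True)
    )
    src_a = np.empty(batch_size, dtype=np.int64)
    src_b = np.empty(batch_size, dtype=np.int64)
    for row, s in enumerate(segs):
        members = index.segment_to_instances[int(s)]
        if len(members) >= 2:
            pick = rng.choice(len(members), size=2, replace=False)
            src_a[row], src_b[row] = members[pick[0]], members[pick[1]]
        else:
            # singleton segment: both views augment the same window
            src_a[row] = src_b[row] = members[0]
    return segs.astype(np.int64), src_a, src_b


def _augment_batch(
    windows: np.ndarray,
    transform,
    rng: np.random.Generator,
) -> np.ndarray:
    return np.stack([transform(w, rng) for w in windows])


def sample_segment_pairs(
    index: DatasetIndex,
    batch_size: int,
    rng: np.random.Generator,
    transform=None,
) -> PairBatch:
    """Positive pairs drawn from segments: two windows of the same segment.

    Segments are drawn without replacement within a batch when M ≥ b (so a
    segment never serves as its own negative), otherwise with replacement.
    The two windows are distinct whenever the segment has at least two;
    each view receives an independent augmentation draw.
    """
    if index.n_instances == 0:
        raise ValueError("empty dataset index")
    transform = transform or (lambda w, r: w)
    segs, src_a, src_b = _draw_pair_sources(index, batch_size, rng)
    wins = index.windows_array()
    return PairBatch(
        view_a=_augment_batch(wins[src_a], transform, rng),
        view_b=_augment_batch(wins[src_b], transform, rng),
        segment_labels=segs,
        instance_labels=src_a,
        source_instance_b=src_b,
    )


def sample_instance_pairs(
    index: DatasetIndex,
    batch_size: int,
    rng: np.random.Generator,
    transform=None,
) -> PairBatch:
    """Positive pairs drawn from instances: two augmentations of one window."""
    if index.n_instances == 0:
        raise ValueError("empty dataset index")
    transform = transform or (lambda w, r: w)
    N = index.n_instances
    src = (
        rng.choice(N, size=batch_size, replace=False)
        if N >= batch_size
        else rng.choice(N, size=batch_size, replace=True)
    )
    src = src.astype(np.int64)
    wins = index.windows_array()
    seg_of = index.segment_labels()
    return PairBatch(
        view_a=_augment_batch(wins[src], transform, rng),
        view_b=_augment_batch(wins[src], transform, rng),
        segment_labels=seg_of[src],
        instance_labels=src,
        source_instance_b=src.copy(),
    )


def pretrain(
    index: DatasetIndex,
    model_spec: ModelSpec,
    config: PretrainConfig,
) -> PretrainResult:
    """Run unsupervised pretraining and return the best-loss snapshot.

    All randomness (parameter init, bank init, sampling, augmentation) is
    derived from ``config.seed`` through named streams, so identical
    (index, spec, config) reproduce identical loss traces single-threaded.
    """
    streams = named_streams(
        config.seed, ("model", "bank", "data", "augment")
    )
    model = HarModel(model_spec, rng=streams["model"])
    transform = aug.compose(config.augmentation)
    method = config.method
    d = model_spec.feature_dim
    lc = config.loss

    uses_pairs = method in _PAIR_METHODS
    uses_bank = method in ("id", "idfd", "sd", "sdfd", "simclr_seg_sdfd")
    uses_fis = method in ("idfd", "sdfd", "simclr_seg_sdfd")

    if method in ("id", "idfd"):
        disc_labels = index.instance_labels()
        n_slots = index.n_instances
    else:
        disc_labels = index.segment_labels()
        n_slots = index.n_segments
    bank = (
        MemoryBank.random_init(n_slots, d, streams["bank"], momentum=lc.bank_momentum)
        if uses_bank
        else None
    )

    if uses_pairs:
        param_groups: tuple[str, ...] = (
            ("enc", "fp1", "fp2") if method == "simclr_seg_sdfd" else ("enc", "fp1")
        )
    else:
        param_groups = ("enc", "fp2")
    optimizer = Adam(model.params(param_groups), lr=config.learning_rate)

    N, b = index.n_instances, config.batch_size
    steps_per_epoch = math.ceil(N / b)
    wins = index.windows_array()

    steps: list[dict] = []
    epoch_loss: list[float] = []
    best: tuple[float, int, dict] | None = None  # (loss, epoch, state)

    for epoch in range(config.epochs):
        totals: list[float] = []
        order = streams["data"].permutation(N) if not uses_pairs else None
        for step in range(steps_per_epoch):
            parts = {"ls": 0.0, "lsd": 0.0, "lfd": 0.0}
            if uses_pairs:
                sampler = (
                    sample_instance_pairs if method == "simclr" else sample_segment_pairs
                )
                batch = sampler(index, b, streams["data"], transform=None)
                va = _augment_batch(batch.view_a, transform, streams["augment"])
                vb = _augment_batch(batch.view_b, transform, streams["augment"])
                feat = model.encode(np.concatenate([va, vb]), train=True)
                nb = va.shape[0]
                z = model.project_contrastive(feat)
                z_a, z_b = z[:nb], z[nb:]
                if method == "simclr_seg_sdfd":
                    f2 = model.project_sd(feat)
                    labels2 = np.concatenate(
                        [batch.segment_labels, batch.segment_labels]
                    )
                    loss, parts = combined_loss(
                        z_a, z_b, f2, labels2, bank, lc
                    )
                    update_bank(bank, f2, labels2)
                else:
                    loss = nt_xent_loss(z_a, z_b, tau=lc.tau)
                    parts["ls"] = loss.item()
            else:
                rows = order[step * b : (step + 1) * b]
                x = _augment_batch(wins[rows], transform, streams["augment"])
                labels = disc_labels[rows]
                feat = model.encode(x, train=True)
                f2 = model.project_sd(feat)
                lsd = sd_loss(bank, f2, labels, sd_tau=lc.sd_tau)
                parts["lsd"] = lsd.item()
                loss = lc.lambda2 * lsd
                if uses_fis:
                    lfd = fis_loss(f2)
                    parts["lfd"] = lfd.item()
                    loss = loss + lc.lambda3 * lfd
                update_bank(bank, f2, labels)

            total = loss.item()
            if not np.isfinite(total):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"step {step} (method {method})"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            totals.append(total)
            steps.append(
                {
                    "epoch": epoch,
                    "step": step,
                    "ls": parts["ls"],
                    "lsd": parts["lsd"],
                    "lfd": parts["lfd"],
                    "total": total,
                }
            )
        mean_loss = float(np.mean(totals))
        epoch_loss.append(mean_loss)
        if best is None or mean_loss < best[0]:
            best = (mean_loss, epoch, model.state_arrays())

    model.load_state_arrays(best[2])
    return PretrainResult(
        model=model, steps=steps, epoch_loss=epoch_loss, best_epoch=best[1]
    )
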