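"""Frozen-encoder few-shot evaluation: linear probes, macro F1, sweeps.

Representation quality is measured by transfer: k labeled windows per class
train a single affine head on top of the frozen encoder (Adam, no
augmentation, weights taken at the lowest validation loss), and macro F1 on
a held-out test split is reported, averaged over independently seeded
trials. A ``finetune`` mode trains the whole model from its current
initialization instead (the no-pretraining baseline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .model import HarModel, ModelSpec
from .nn import Adam, Tensor
from .segments import SegmentRecord, WindowingConfig, assign_pseudo_labels

__all__ = [
    "EvalConfig",
    "ProbeResult",
    "TrialSummary",
    "select_few_shot",
    "linear_probe",
    "macro_f1",
    "run_trials",
    "shot_sweep",
    "cross_domain_eval",
    "segment_split",
    "windows_xy",
]


@dataclass(frozen=True)
class EvalConfig:
    """Few-shot transfer-learning protocol parameters.

    Defaults mirror the reference protocol: 10 shots per class, five
    trials, the head trained for 300 epochs with Adam at 0.001 and no
    augmentation, selecting the weights with the lowest validation loss.
    """

    n_shots: int = 10
    n_trials: int = 5
    epochs: int = 300
    learning_rate: float = 0.001
    batch_size: int = 256
    seed: int = 0
    mode: str = "probe"  # "probe" (frozen encoder) or "finetune" (non-pre)

    def __post_init__(self) -> None:
        if self.n_shots < 1 or self.n_trials < 1:
            raise ValueError("n_shots and n_trials must be >= 1")
        if self.mode not in ("probe", "finetune"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ProbeResult:
    confusion: np.ndarray  # (C, C) counts, rows = true class
    per_class_f1: np.ndarray
    macro_f1: float
    n_shots: int
    trial_seed: int


@dataclass
class TrialSummary:
    trials: list[ProbeResult]
    mean_macro_f1: float
    std_macro_f1: float
    mean_per_class_f1: np.ndarray

    @classmethod
    def from_trials(cls, trials: list[ProbeResult]) -> "TrialSummary":
        macros = np.array([t.macro_f1 for t in trials])
        per_class = np.stack([t.per_class_f1 for t in trials])
        return cls(
            trials=trials,
            mean_macro_f1=float(macros.mean()),
            std_macro_f1=float(macros.std()),
            mean_per_class_f1=per_class.mean(axis=0),
        )


# ------------------------------------------------------------------ helpers


def windows_xy(
    segments: list[SegmentRecord],
    config: WindowingConfig,
    classes: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Window labeled segments into (X, y, class_names).

    Only the evaluation stage calls this — it is the one place activity
    labels are read.
    """
    index = assign_pseudo_labels(segments, config)
    acts = index.activities()
    if any(a is None for a in acts):
        raise ValueError("evaluation requires activity labels on every segment")
    if classes is None:
        classes = sorted(set(acts))
    lut = {c: i for i, c in enumerate(classes)}
    y = np.array([lut[a] for a in acts], dtype=np.int64)
    return index.windows_array(), y, classes


def segment_split(
    segments: list[SegmentRecord],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    rng: np.random.Generator | int = 0,
) -> tuple[list[SegmentRecord], list[SegmentRecord], list[SegmentRecord]]:
    """Split segments into train/validation/test, stratified by activity.

    Splitting at segment level keeps windows of one recording on one side
    of the split (the stand-in for subject-wise splits on synthetic data).
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    f_train, f_val, _ = fractions
    by_class: dict[str | None, list[SegmentRecord]] = {}
    for seg in segments:
        by_class.setdefault(seg.activity, []).append(seg)
    train, val, test = [], [], []
    for members in by_class.values():
        order = rng.permutation(len(members))
        n = len(members)
        n_train = max(1, int(round(f_train * n)))
        n_val = max(1, int(round(f_val * n)))
        for pos, j in enumerate(order):
            if pos < n_train:
                train.append(members[j])
            elif pos < n_train + n_val:
                val.append(members[j])
            else:
                test.append(members[j])
    return train, val, test


def select_few_shot(
    labels: np.ndarray, n_per_class: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly draw ``n_per_class`` window indices per class.

    Classes with fewer windows contribute all of them (with a warning);
    a class with zero windows is an error upstream (it cannot appear in an
    integer label array, so the check lives in :func:`linear_probe`).
    """
    labels = np.asarray(labels)
    picked: list[np.ndarray] = []
    for c in np.unique(labels):
        pool = np.flatnonzero(labels == c)
        if len(pool) < n_per_class:
            warnings.warn(
                f"class {c} has only {len(pool)} windows < {n_per_class} shots; "
                "taking all",
                stacklevel=2,
            )
            picked.append(pool)
        else:
            picked.append(rng.choice(pool, size=n_per_class, replace=False))
    return np.sort(np.concatenate(picked))


def macro_f1(confusion: np.ndarray) -> float:
    """Unweighted mean of per-class F1 from a square count matrix."""
    return float(np.mean(per_class_f1(confusion)))


def per_class_f1(confusion: np.ndarray) -> np.ndarray:
    """Per-class F1 = 2PR/(P+R); 0 when precision+recall is undefined/zero."""
    confusion = np.asarray(confusion, dtype=np.float64)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    tp = np.diag(confusion)
    pred = confusion.sum(axis=0)
    true = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred > 0, tp / pred, 0.0)
        recall = np.where(true > 0, tp / true, 0.0)
        f1 = np.where(
            precision + recall > 0,
            2 * precision * recall / (precision + recall),
            0.0,
        )
    return f1


def _softmax_xent(logits: Tensor, y: np.ndarray) -> Tensor:
    lse = logits.logsumexp(axis=1)
    hit = logits.take_rows(np.arange(len(y)), y)
    return (lse - hit).mean()


def _encode_all(model: HarModel, X: np.ndarray, batch: int = 512) -> np.ndarray:
    parts = [
        model.encode(X[i : i + batch], train=False).value
        for i in range(0, len(X), batch)
    ]
    return np.concatenate(parts)


def linear_probe(
    model: HarModel,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    test: tuple[np.ndarray, np.ndarray],
    config: EvalConfig,
    n_classes: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> ProbeResult:
    """Train an affine head on frozen encoder features; score the test set.

    Head weights are taken at the epoch with the lowest validation loss.
    In ``finetune`` mode the whole model (from its current initialization)
    is trained instead — the no-pretraining baseline.
    """
    X_tr, y_tr = train
    X_va, y_va = val
    X_te, y_te = test
    C = n_classes or int(max(y_tr.max(), y_va.max(), y_te.max())) + 1
    missing = set(range(C)) - set(np.unique(y_tr).tolist())
    if missing:
        raise ValueError(f"classes {sorted(missing)} absent from the training subset")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, int):
        rng = np.random.default_rng(rng)

    d = model.spec.feature_dim
    if config.mode == "probe":
        F_tr = _encode_all(model, X_tr)
        F_va = _encode_all(model, X_va)
        W = Tensor(rng.normal(0, np.sqrt(1.0 / d), size=(d, C)), requires_grad=True)
        bias = Tensor(np.zeros(C), requires_grad=True)
        params = {"W": W, "b": bias}
        forward = lambda F: Tensor(F) @ W + bias
    else:
        head_model = HarModel(
            replace(model.spec, n_classes=C)
            if model.spec.n_classes != C
            else model.spec,
            rng=rng,
        )
        params = head_model.params(("enc", "head"))

    opt = Adam(params, lr=config.learning_rate)
    best_val = np.inf
    best_state = {k: p.value.copy() for k, p in params.items()}
    n = len(y_tr)
    bsz = min(config.batch_size, n)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, bsz):
            rows = order[lo : lo + bsz]
            if config.mode == "probe":
                logits = forward(F_tr[rows])
            else:
                feats = head_model.encode(X_tr[rows], train=True)
                logits = head_model.classify(feats)
            loss = _softmax_xent(logits, y_tr[rows])
            opt.zero_grad()
            loss.backward()
            opt.step()
        if config.mode == "probe":
            val_loss = _softmax_xent(forward(F_va), y_va).item()
        else:
            feats = head_model.encode(X_va, train=False)
            val_loss = _softmax_xent(head_model.classify(feats), y_va).item()
        if val_loss < best_val:
            best_val = val_loss
            best_state = {k: p.value.copy() for k, p in params.items()}
    for k, p in params.items():
        p.value = best_state[k]

    if config.mode == "probe":
        y_hat = np.argmax(_encode_all(model, X_te) @ W.value + bias.value, axis=1)
    else:
        feats = head_model.encode(X_te, train=False)
        y_hat = np.argmax(head_model.classify(feats).value, axis=1)
    confusion = _sk_confusion(y_te, y_hat, labels=np.arange(C))
    f1 = per_class_f1(confusion)
    return ProbeResult(
        confusion=confusion,
        per_class_f1=f1,
        macro_f1=float(f1.mean()),
        n_shots=config.n_shots,
        trial_seed=int(config.seed),
    )


def run_trials(
    model: HarModel,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    test: tuple[np.ndarray, np.ndarray],
    config: EvalConfig,
) -> TrialSummary:
    """Repeat few-shot selection + probing over independently seeded trials.

    Each trial reseeds both the shot draw and the head initialization
    (seeds are the spawn children of ``config.seed``, logged in the
    per-trial results).
    """
    X_tr, y_tr = train
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_trials)
    results = []
    for t, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        idx = select_few_shot(y_tr, config.n_shots, rng)
        trial_cfg = replace(config, seed=config.seed + t)
        res = linear_probe(
            model,
            (X_tr[idx], y_tr[idx]),
            val,
            test,
            trial_cfg,
            n_classes=int(max(y_tr.max(), val[1].max(), test[1].max())) + 1,
            rng=rng,
        )
        results.append(res)
    return TrialSummary.from_trials(results)


def shot_sweep(
    model: HarModel,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    test: tuple[np.ndarray, np.ndarray],
    shots: list[int],
    config: EvalConfig,
) -> pd.DataFrame:
    """Run the trial protocol at each shot count; tidy table of macro F1."""
    rows = []
    for k in shots:
        summary = run_trials(model, train, val, test, replace(config, n_shots=k))
        for t, res in enumerate(summary.trials):
            rows.append(
                {"shots": k, "trial": t, "macro_f1": res.macro_f1}
            )
    return pd.DataFrame(rows)


def cross_domain_eval(
    pretext_segments: list[SegmentRecord],
    target_segments: list[SegmentRecord],
    method: str,
    windowing: WindowingConfig,
    model_spec: ModelSpec,
    pretrain_config,
    eval_config: EvalConfig,
) -> TrialSummary:
    """Pretrain on one domain, probe on another.

    Signals are not resampled across sampling rates: the pretext window
    length is kept, target segments shorter than one window are dropped by
    the windowing stage.
    """
    from .pretrain import pretrain  # local import: cycle

    index = assign_pseudo_labels(pretext_segments, windowing)
    cfg = (
        pretrain_config
        if pretrain_config.method == method
        else replace(pretrain_config, method=method)
    )
    result = pretrain(index, model_spec, cfg)
    tr_seg, va_seg, te_seg = segment_split(
        target_segments, rng=np.random.default_rng(eval_config.seed)
    )
    X_tr, y_tr, classes = windows_xy(tr_seg, windowing)
    X_va, y_va, _ = windows_xy(va_seg, windowing, classes)
    X_te, y_te, _ = windows_xy(te_seg, windowing, classes)
    return run_trials(
        result.model, (X_tr, y_tr), (X_va, y_va), (X_te, y_te), eval_config
    )
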