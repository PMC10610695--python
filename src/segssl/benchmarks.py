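"""Scaled-down benchmark experiments on the bundled synthetic data.

These reproduce, at desk scale, the two qualitative findings the method is
built on: (i) pretraining with the combined segment-based objective yields
features a 10-shot linear probe classifies far better than a random-init
encoder, and (ii) segment-based positive pairs do not underperform
instance-based pairs when windows of one segment differ in phase.

Problem sizes (default4: 60 segments at 50 Hz, 128-sample windows with
stride 64, a 16/32/64-channel encoder, 50 / 30 pretext epochs) are chosen so
each experiment runs in minutes on one CPU; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from .evaluate import EvalConfig, run_trials, segment_split, windows_xy
from .model import HarModel, ModelSpec
from .pretrain import PretrainConfig, pretrain
from .segments import WindowingConfig, assign_pseudo_labels
from .synthetic import generate_segments, load_preset

__all__ = ["recovery_benchmark", "pairing_benchmark", "BENCH_SPEC", "BENCH_WINDOWING"]

BENCH_SPEC = ModelSpec(channels=(16, 32, 64))
BENCH_WINDOWING = WindowingConfig(window_length=128, stride=64)


def _derive_seeds(seed: int, n: int) -> list[int]:
    return [
        int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)
    ]


def _prepared_splits(ds_seed: int):
    segs = generate_segments(load_preset("default4", seed=ds_seed))
    tr, va, te = segment_split(segs, rng=np.random.default_rng(ds_seed))
    X_tr, y_tr, classes = windows_xy(tr, BENCH_WINDOWING)
    X_va, y_va, _ = windows_xy(va, BENCH_WINDOWING, classes)
    X_te, y_te, _ = windows_xy(te, BENCH_WINDOWING, classes)
    index = assign_pseudo_labels(tr, BENCH_WINDOWING)
    return index, (X_tr, y_tr), (X_va, y_va), (X_te, y_te)


def recovery_benchmark(
    seed: int = 0,
    n_seeds: int = 3,
    epochs: int = 50,
    method: str = "simclr_seg_sdfd",
) -> dict:
    """Pretrained vs random-init 10-shot probe on default4, paired by seed.

    Per replicate: generate default4, split by segment, pretrain on the
    training split only, probe with 10 shots per class over 3 trials; the
    baseline probes a freshly initialized frozen encoder the same way.
    """
    pre_scores, rand_scores = [], []
    for ds_seed in _derive_seeds(seed, n_seeds):
        index, tr, va, te = _prepared_splits(ds_seed)
        cfg = PretrainConfig(method=method, epochs=epochs, batch_size=64, seed=ds_seed)
        result = pretrain(index, BENCH_SPEC, cfg)
        ec = EvalConfig(n_shots=10, n_trials=3, seed=ds_seed)
        pre_scores.append(run_trials(result.model, tr, va, te, ec).mean_macro_f1)
        random_model = HarModel(BENCH_SPEC, rng=np.random.default_rng(ds_seed + 1))
        rand_scores.append(run_trials(random_model, tr, va, te, ec).mean_macro_f1)
    return {
        "pretrained": pre_scores,
        "random": rand_scores,
        "mean_pretrained": float(np.mean(pre_scores)),
        "mean_random": float(np.mean(rand_scores)),
        "margin": float(np.mean(pre_scores) - np.mean(rand_scores)),
        "n_seeds": n_seeds,
    }


def pairing_benchmark(
    seed: int = 0, n_seeds: int = 5, epochs: int = 30
) -> dict:
    """Paired segment-pair vs instance-pair contrastive comparison.

    Same dataset, same seeds, same budget; only the positive-pair
    definition differs. Reports the per-seed 10-shot macro-F1 difference
    (segment minus instance) and its mean.
    """
    diffs, seg_scores, inst_scores = [], [], []
    for ds_seed in _derive_seeds(seed, n_seeds):
        index, tr, va, te = _prepared_splits(ds_seed)
        ec = EvalConfig(n_shots=10, n_trials=3, seed=ds_seed)
        scores = {}
        for method in ("simclr_seg", "simclr"):
            cfg = PretrainConfig(
                method=method, epochs=epochs, batch_size=64, seed=ds_seed
            )
            result = pretrain(index, BENCH_SPEC, cfg)
            scores[method] = run_trials(result.model, tr, va, te, ec).mean_macro_f1
        seg_scores.append(scores["simclr_seg"])
        inst_scores.append(scores["simclr"])
        diffs.append(scores["simclr_seg"] - scores["simclr"])
    return {
        "segment_pairs": seg_scores,
        "instance_pairs": inst_scores,
        "diffs": diffs,
        "mean_diff": float(np.mean(diffs)),
        "n_seeds": n_seeds,
    }
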