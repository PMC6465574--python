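"""Per-participant binary SVM decoding with permutation chance levels.

Each binary contrast (a positive-emotion cluster vs the negative
condition, or one cluster vs another) uses 6 film clips per class and 3
spatial feature samples per clip: 18 + 18 = 36 samples of 24 channel
means.  A linear-kernel SVM is evaluated by sixfold cross-validation with
clip-grouped folds — one clip per class per fold, so each fold tests 6
samples and the three windows of a clip never straddle the train/test
split.  Chance levels come from refitting the whole cross-validation
under 100 random label shuffles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .preprocessing import FeatureSample

logger = logging.getLogger(__name__)

__all__ = [
    "DecodeProblem",
    "DecodeResult",
    "assemble_problem",
    "crossval_accuracy",
    "permutation_chance",
    "decode_contrast",
    "summarize_group",
    "group_stats",
]

N_FOLDS = 6
SAMPLES_PER_CLIP = 3


@dataclass
class DecodeProblem:
    """A balanced 18-vs-18 classification task for one participant."""

    x: np.ndarray          # (36, n_channels)
    y: np.ndarray          # (36,) 0/1
    clip_ids: np.ndarray   # (36,)
    folds: np.ndarray      # (36,) in 0..5
    participant_id: object
    chromophore: str
    contrast: tuple        # (class0 name, class1 name)

    def __post_init__(self) -> None:
        n = len(self.y)
        if n != 2 * SAMPLES_PER_CLIP * N_FOLDS:
            raise ValueError(f"expected 36 samples, got {n}")
        if np.bincount(self.y, minlength=2)[0] != n // 2:
            raise ValueError("classes must be balanced 18/18")
        counts = np.bincount(self.folds, minlength=N_FOLDS)
        if not np.all(counts == n // N_FOLDS):
            raise ValueError("each fold must hold exactly 6 samples")
        for cid in np.unique(self.clip_ids):
            if len(np.unique(self.folds[self.clip_ids == cid])) != 1:
                raise ValueError(f"windows of clip {cid} split across folds")


@dataclass
class DecodeResult:
    """Cross-validated accuracy and (optionally) its permutation null."""

    participant_id: object
    chromophore: str
    contrast: tuple
    accuracy: float                   # percent, pooled over held-out samples
    fold_accuracies: np.ndarray       # percent, per fold
    chance_mean: float | None = None  # percent over shuffles
    chance_sd: float | None = None
    chance_accuracies: np.ndarray | None = None
    seed: int | None = None


def assemble_problem(
    features: list[FeatureSample],
    class_a_clips: list,
    class_b_clips: list,
    chromophore: str,
    contrast: tuple = ("A", "B"),
    seed: int = 0,
) -> DecodeProblem:
    """Collect the 36 samples of a contrast and assign clip-grouped folds.

    Class A is label 0, class B label 1.  Clips within each class are
    shuffled with ``seed`` and paired off so that fold k holds one clip
    from each class (6 test samples).  The fold assignment is logged.
    """
    if len(class_a_clips) != N_FOLDS or len(class_b_clips) != N_FOLDS:
        raise ValueError(
            f"need exactly {N_FOLDS} clips per class, got "
            f"{len(class_a_clips)} and {len(class_b_clips)}"
        )
    if set(class_a_clips) & set(class_b_clips):
        raise ValueError(
            f"classes share clips: {sorted(set(class_a_clips) & set(class_b_clips))}"
        )
    pool = {
        (f.clip_id, f.sample_index): f
        for f in features
        if f.chromophore == chromophore
    }
    rows, labels, clips = [], [], []
    for label, clip_list in ((0, class_a_clips), (1, class_b_clips)):
        for cid in clip_list:
            for s in range(1, SAMPLES_PER_CLIP + 1):
                if (cid, s) not in pool:
                    raise ValueError(
                        f"missing {chromophore} sample {s} for clip {cid}"
                    )
                rows.append(pool[(cid, s)].vector)
                labels.append(label)
                clips.append(cid)
    participant = next(iter(pool.values())).participant_id

    rng = np.random.default_rng(seed)
    order_a = rng.permutation(N_FOLDS)
    order_b = rng.permutation(N_FOLDS)
    fold_of = {}
    for k in range(N_FOLDS):
        fold_of[class_a_clips[order_a[k]]] = k
        fold_of[class_b_clips[order_b[k]]] = k
    folds = np.array([fold_of[c] for c in clips])
    logger.debug(
        "participant %s %s %s: fold map %s", participant, chromophore, contrast, fold_of
    )
    return DecodeProblem(
        x=np.asarray(rows, dtype=float),
        y=np.asarray(labels, dtype=int),
        clip_ids=np.asarray(clips, dtype=object),
        folds=folds,
        participant_id=participant,
        chromophore=chromophore,
        contrast=tuple(contrast),
    )


def _cv_accuracy(x: np.ndarray, y: np.ndarray, folds: np.ndarray, c: float):
    """Pooled held-out accuracy (%) of a linear SVM over the given folds."""
    correct = np.zeros(len(y), dtype=bool)
    fold_acc = np.empty(N_FOLDS)
    for k in range(N_FOLDS):
        test = folds == k
        if len(np.unique(y[~test])) < 2:
            # a shuffle may strand a fold's training set in one class
            pred = np.full(test.sum(), y[~test][0])
        else:
            clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=c))
            clf.fit(x[~test], y[~test])
            pred = clf.predict(x[test])
        correct[test] = pred == y[test]
        fold_acc[k] = 100.0 * np.mean(pred == y[test])
    return 100.0 * correct.mean(), fold_acc


def crossval_accuracy(problem: DecodeProblem, c: float = 1.0) -> DecodeResult:
    """Sixfold cross-validated linear-SVM accuracy, in percent.

    Per fold the classifier is fit on 30 samples (z-scored with training
    statistics only) and tested on 6; accuracy pools all 36 held-out
    predictions — with equal-sized folds this equals the mean of the
    per-fold accuracies.
    """
    if np.ptp(problem.x) == 0:
        raise ValueError("degenerate problem: constant features")
    acc, fold_acc = _cv_accuracy(problem.x, problem.y, problem.folds, c)
    return DecodeResult(
        participant_id=problem.participant_id,
        chromophore=problem.chromophore,
        contrast=problem.contrast,
        accuracy=acc,
        fold_accuracies=fold_acc,
    )


def permutation_chance(
    problem: DecodeProblem, n_shuffles: int = 100, seed: int = 0, c: float = 1.0
):
    """Null accuracy distribution from random label shuffles.

    The 36 labels are permuted uniformly at random before each full
    cross-validation (folds unchanged); the mean of the shuffle
    accuracies estimates the chance level.  Returns
    (mean, sd, accuracies) in percent; sd uses ddof=1.
    """
    rng = np.random.default_rng(seed)
    accs = np.empty(n_shuffles)
    for i in range(n_shuffles):
        y_perm = rng.permutation(problem.y)
        accs[i], _ = _cv_accuracy(problem.x, y_perm, problem.folds, c)
    return float(accs.mean()), float(accs.std(ddof=1)), accs


def decode_contrast(
    features: list[FeatureSample],
    class_a_clips: list,
    class_b_clips: list,
    chromophore: str,
    contrast: tuple,
    seed: int = 0,
    n_shuffles: int = 100,
    c: float = 1.0,
    with_permutation: bool = True,
) -> DecodeResult:
    """Assemble, cross-validate and (optionally) permutation-test a contrast."""
    problem = assemble_problem(
        features, class_a_clips, class_b_clips, chromophore, contrast, seed=seed
    )
    result = crossval_accuracy(problem, c=c)
    if with_permutation:
        mean, sd, accs = permutation_chance(
            problem, n_shuffles=n_shuffles, seed=seed + 1, c=c
        )
        result.chance_mean = mean
        result.chance_sd = sd
        result.chance_accuracies = accs
    result.seed = seed
    return result


def group_stats(values) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) of per-participant accuracies."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty accuracy list")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return float(v.mean()), sd


def summarize_group(results: list[DecodeResult]) -> pd.DataFrame:
    """Participants x contrasts accuracy table with a mean ± SD footer.

    One table per chromophore is conventional; pass the results of one
    chromophore to mirror the published layout (rows = participants,
    columns = contrasts, final row = group mean ± SD).
    """
    if not results:
        raise ValueError("no decoding results to summarize")
    rows = [
        {
            "participant": r.participant_id,
            "contrast": " vs ".join(map(str, r.contrast)),
            "accuracy": r.accuracy,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    table = df.pivot(index="participant", columns="contrast", values="accuracy")
    footer = {}
    for col in table.columns:
        m, s = group_stats(table[col].dropna())
        footer[col] = f"{m:.2f} ± {s:.2f}"
    table = table.round(2).astype(object)
    table.loc["Mean"] = pd.Series(footer)
    return table
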