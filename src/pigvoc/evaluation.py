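"""Leakage-aware partitioning and measurement machinery.

All data splitting follows a grouped mutual-exclusion principle: correlated
recordings share a group token (pen x date x session for routine clips, a
pig token for close-range coughs) and a token never straddles two
partitions or folds. On top of the splits this module provides macro
metrics, out-of-fold confusion matrices, leave-one-session-out evaluation
with the noon-shift statistic

    dNoon = (Morning + Evening) / 2 - Noon   (Macro-F1, %)

an additive-noise robustness sweep with group-exclusive noise selection,
an exact fold-paired Wilcoxon signed-rank test, and a linear background
separability probe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    balanced_accuracy_score, precision_recall_fscore_support, roc_auc_score,
)
from sklearn.model_selection import GroupKFold

from .errors import (
    CoverageError, InvalidInputError, LeakageError, ManifestError,
    SplitInfeasibleError,
)
from .synthetic import CLASSES, SESSIONS, DatasetManifest, mix_at_snr

__all__ = [
    "SplitAssignment", "ConfusionMatrix", "MetricsReport",
    "SessionGeneralizationReport", "NoiseRobustnessCurve", "assign_groups",
    "grouped_holdout_split", "grouped_kfold", "loso_by_session",
    "verify_no_leakage", "compute_metrics", "oof_confusion", "delta_noon",
    "session_summary", "noise_robustness_sweep", "wilcoxon_fold_test",
    "background_probe",
]

PARTITIONS = ("train", "val", "test")


# ---------------------------------------------------------------------------
# Group tokens and splits
# ---------------------------------------------------------------------------

def assign_groups(manifest: DatasetManifest) -> np.ndarray:
    """One group token per sample.

    Routine samples share a (pen, date, session) token; all close-range
    cough clips from one pig share a single pig token regardless of date,
    so individual-specific traits can never straddle a split.
    """
    rec = manifest.records
    required = {"pen_id", "date", "session", "close_range"}
    if rec[list(required)].isna().any().any():
        raise ManifestError("incomplete group metadata")
    tokens = []
    for r in rec.itertuples():
        if r.close_range:
            if r.pig_id is None or (isinstance(r.pig_id, float) and np.isnan(r.pig_id)):
                raise ManifestError("close-range sample without pig_id")
            tokens.append(f"pig|{r.pig_id}")
        else:
            tokens.append(f"{r.pen_id}|{r.date}|{r.session}")
    return np.asarray(tokens)


@dataclass
class SplitAssignment:
    """Sample -> partition name (train/val/test) or fold index."""

    assignment: pd.Series  # index: sample position; values: str or int
    kind: str = "holdout"

    def indices(self, part) -> np.ndarray:
        return np.asarray(self.assignment.index[self.assignment == part])

    def parts(self) -> list:
        return sorted(self.assignment.unique(), key=str)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.assignment.index, "partition": self.assignment.values}
        )


def _greedy_allocate(
    groups: list[str],
    group_class_counts: dict[str, np.ndarray],
    targets: np.ndarray,  # (n_parts, n_classes) target sample counts
    rng: np.random.Generator,
) -> dict[str, int]:
    """Assign each group to the partition with the largest remaining
    per-class deficit along the group's class composition."""
    order = list(groups)
    rng.shuffle(order)
    order.sort(key=lambda g: -group_class_counts[g].sum())  # big groups first
    counts = np.zeros_like(targets, dtype=float)
    out = {}
    class_tot = np.maximum(targets.sum(axis=0), 1.0)
    for g in order:
        gc = group_class_counts[g]
        deficits = ((targets - counts) / class_tot * gc).sum(axis=1)
        p = int(np.argmax(deficits))
        out[g] = p
        counts[p] += gc
    return out


def _class_counts_by_group(labels: np.ndarray, tokens: np.ndarray):
    classes = list(CLASSES)
    lut = {c: i for i, c in enumerate(classes)}
    out: dict[str, np.ndarray] = {}
    for lab, tok in zip(labels, tokens):
        vec = out.setdefault(tok, np.zeros(len(classes)))
        vec[lut.get(lab, 0)] += 1
    return out


def grouped_holdout_split(
    manifest: DatasetManifest,
    ratios: tuple[float, float, float] = (8, 1, 1),
    seed: int = 0,
) -> SplitAssignment:
    """Group-wise train/val/test split approaching per-class 8:1:1.

    Allocation is at group level, so sample ratios are approximate.
    """
    tokens = assign_groups(manifest)
    labels = manifest.records["label"].to_numpy()
    for c in np.unique(labels):
        if len(np.unique(tokens[labels == c])) < 3:
            raise SplitInfeasibleError(f"class {c!r} has fewer than 3 groups")
    gcc = _class_counts_by_group(labels, tokens)
    class_totals = np.sum(list(gcc.values()), axis=0)
    frac = np.asarray(ratios, dtype=float) / np.sum(ratios)
    targets = frac[:, None] * class_totals[None, :]
    alloc = _greedy_allocate(
        list(gcc), gcc, targets, np.random.default_rng(seed)
    )
    part_names = np.array(PARTITIONS)
    assignment = pd.Series(
        part_names[[alloc[t] for t in tokens]], index=np.arange(len(tokens))
    )
    split = SplitAssignment(assignment, kind="holdout")
    verify_no_leakage(manifest, split)
    return split


def grouped_kfold(manifest: DatasetManifest, k: int = 5, seed: int = 0) -> SplitAssignment:
    """Partition groups into k folds balancing per-fold sample counts."""
    tokens = assign_groups(manifest)
    uniq = list(dict.fromkeys(tokens))
    if len(uniq) < k:
        raise SplitInfeasibleError(f"{len(uniq)} groups < k={k}")
    rng = np.random.default_rng(seed)
    order = list(uniq)
    rng.shuffle(order)
    sizes = {t: int(np.sum(tokens == t)) for t in uniq}
    order.sort(key=lambda t: -sizes[t])
    fold_totals = np.zeros(k)
    alloc = {}
    for t in order:
        f = int(np.argmin(fold_totals))
        alloc[t] = f
        fold_totals[f] += sizes[t]
    assignment = pd.Series(
        [alloc[t] for t in tokens], index=np.arange(len(tokens)), dtype=int
    )
    split = SplitAssignment(assignment, kind="kfold")
    verify_no_leakage(manifest, split)
    return split


def loso_by_session(
    manifest: DatasetManifest, val_fraction: float = 0.1, seed: int = 0
) -> list[tuple[str, SplitAssignment]]:
    """Leave-one-session-out: one split per session in (morning, noon,
    evening); the held-out session is test, and the grouped train/val
    subdivision is performed only within the remaining sessions."""
    rec = manifest.records
    present = set(rec["session"].unique())
    missing = set(SESSIONS) - present
    if missing:
        raise SplitInfeasibleError(f"missing sessions: {sorted(missing)}")
    tokens = assign_groups(manifest)
    labels = rec["label"].to_numpy()
    out = []
    for si, session in enumerate(SESSIONS):
        is_test = (rec["session"] == session).to_numpy()
        dev_idx = np.where(~is_test)[0]
        dev_tokens = tokens[dev_idx]
        gcc = _class_counts_by_group(labels[dev_idx], dev_tokens)
        totals = np.sum(list(gcc.values()), axis=0)
        frac = np.array([1 - val_fraction, val_fraction])
        targets = frac[:, None] * totals[None, :]
        alloc = _greedy_allocate(
            list(gcc), gcc, targets, np.random.default_rng((seed, si))
        )
        names = np.array(["train", "val"])
        values = np.empty(len(rec), dtype=object)
        values[is_test] = "test"
        values[dev_idx] = names[[alloc[t] for t in dev_tokens]]
        split = SplitAssignment(
            pd.Series(values, index=np.arange(len(rec))), kind="loso"
        )
        verify_no_leakage(manifest, split, check_parts=("train", "val"))
        out.append((session, split))
    return out


def verify_no_leakage(
    manifest: DatasetManifest,
    split: SplitAssignment,
    check_parts: tuple | None = None,
) -> None:
    """Assert group and pig-wise mutual exclusion across partitions/folds.

    For leave-one-session-out splits the test partition is defined by the
    session itself, so exclusivity is asserted within the development
    partitions (pass ``check_parts``).
    """
    tokens = assign_groups(manifest)
    pigs = manifest.records["pig_id"].to_numpy()
    parts = check_parts if check_parts is not None else split.parts()
    seen_tokens: dict[str, object] = {}
    seen_pigs: dict[str, object] = {}
    for p in parts:
        for i in split.indices(p):
            tok = tokens[i]
            if tok in seen_tokens and seen_tokens[tok] != p:
                raise LeakageError(f"group {tok!r} spans {seen_tokens[tok]} and {p}")
            seen_tokens[tok] = p
            pig = pigs[i]
            if isinstance(pig, str):
                if pig in seen_pigs and seen_pigs[pig] != p:
                    raise LeakageError(f"pig {pig!r} spans {seen_pigs[pig]} and {p}")
                seen_pigs[pig] = p


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class PerClassMetrics:
    label: str
    precision: float
    recall: float
    f1: float
    auroc: float | None


@dataclass
class MetricsReport:
    accuracy: float  # %
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_auroc: float  # [0, 1]
    per_class: list[PerClassMetrics] = field(default_factory=list)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    labels: tuple = CLASSES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise InvalidInputError("negative confusion counts")

    def row_normalized(self, decimals: int = 1) -> np.ndarray:
        """Row percentages, rounded for reporting."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(sums > 0, self.counts / sums * 100.0, 0.0)
        return np.round(pct, decimals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def compute_metrics(
    y_true, y_pred, y_score=None, labels: tuple = CLASSES
) -> MetricsReport:
    """Accuracy and macro precision/recall/F1 (+ one-vs-rest macro AUROC).

    A class absent from ``y_true`` has undefined recall/AUROC; it is
    excluded from the macro averages with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise InvalidInputError("length mismatch")
    accuracy = float(np.mean(y_true == y_pred)) * 100.0
    prfs = precision_recall_fscore_support(
        y_true, y_pred, labels=list(labels), zero_division=0.0
    )
    per_class: list[PerClassMetrics] = []
    macro_p, macro_r, macro_f, macro_a = [], [], [], []
    for ci, lab in enumerate(labels):
        prec, rec, f1, support = (float(m[ci]) for m in prfs)
        if support == 0:
            warnings.warn(
                f"class {lab!r} absent from y_true; excluded from macro averages"
            )
            per_class.append(PerClassMetrics(lab, np.nan, np.nan, np.nan, None))
            continue
        auroc = None
        if y_score is not None:
            scores = np.asarray(y_score)[:, ci]
            binary = (y_true == lab).astype(int)
            if binary.min() != binary.max():
                auroc = float(roc_auc_score(binary, scores))
                macro_a.append(auroc)
        per_class.append(
            PerClassMetrics(lab, prec * 100, rec * 100, f1 * 100, auroc)
        )
        macro_p.append(prec)
        macro_r.append(rec)
        macro_f.append(f1)
    if not macro_p:
        raise InvalidInputError("no class present in y_true")
    return MetricsReport(
        accuracy=accuracy,
        macro_precision=float(np.mean(macro_p)) * 100,
        macro_recall=float(np.mean(macro_r)) * 100,
        macro_f1=float(np.mean(macro_f)) * 100,
        macro_auroc=float(np.mean(macro_a)) if macro_a else float("nan"),
        per_class=per_class,
    )


def oof_confusion(
    fold_predictions: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    n_samples: int | None = None,
    labels: tuple = CLASSES,
) -> ConfusionMatrix:
    """Tally out-of-fold predictions: each entry is (sample indices,
    y_true, y_pred) for one fold; every sample must appear exactly once."""
    seen: set[int] = set()
    lut = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for idx, y_true, y_pred in fold_predictions:
        for i, t, p in zip(np.asarray(idx), np.asarray(y_true), np.asarray(y_pred)):
            i = int(i)
            if i in seen:
                raise CoverageError(f"sample {i} predicted more than once")
            seen.add(i)
            counts[lut[t], lut[p]] += 1
    if n_samples is not None and len(seen) != n_samples:
        raise CoverageError(f"covered {len(seen)} of {n_samples} samples")
    return ConfusionMatrix(counts, labels=labels)


# ---------------------------------------------------------------------------
# Cross-session generalization
# ---------------------------------------------------------------------------

@dataclass
class SessionGeneralizationReport:
    per_session_macro_f1: dict[str, float]  # session -> Macro-F1 %
    mean: float
    sd: float  # sample SD (n - 1)
    delta_noon: float


def delta_noon(report: SessionGeneralizationReport | dict[str, float]) -> float:
    """(Morning + Evening) / 2 - Noon, on Macro-F1 in %."""
    per = (
        report.per_session_macro_f1
        if isinstance(report, SessionGeneralizationReport)
        else report
    )
    missing = set(SESSIONS) - set(per)
    if missing:
        raise InvalidInputError(f"missing sessions: {sorted(missing)}")
    return (per["morning"] + per["evening"]) / 2.0 - per["noon"]


def session_summary(per_session_macro_f1: dict[str, float]) -> SessionGeneralizationReport:
    """Mean, sample SD (divisor n - 1) and the noon-shift statistic."""
    missing = set(SESSIONS) - set(per_session_macro_f1)
    if missing:
        raise InvalidInputError(f"missing sessions: {sorted(missing)}")
    vals = np.array([per_session_macro_f1[s] for s in SESSIONS], dtype=float)
    return SessionGeneralizationReport(
        per_session_macro_f1=dict(per_session_macro_f1),
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
        delta_noon=delta_noon(per_session_macro_f1),
    )


# ---------------------------------------------------------------------------
# Additive-noise robustness
# ---------------------------------------------------------------------------

@dataclass
class NoiseRobustnessCurve:
    points: list[tuple[float, float]]  # (snr_db, macro_f1 %)

    def __post_init__(self):
        snrs = [p[0] for p in self.points]
        if len(set(snrs)) != len(snrs):
            raise InvalidInputError("SNR bins must be distinct")


def noise_robustness_sweep(
    classify,
    samples: list[tuple],  # (Waveform, label, group token)
    noise_pool: list[tuple],  # (Waveform, GroupKey)
    snr_bins: tuple[float, ...] = (10.0, 5.0, 0.0, -5.0),
    seed: int = 0,
) -> NoiseRobustnessCurve:
    """Macro-F1 after mixing group-exclusive noise into every test clip.

    ``classify`` maps a Waveform to a predicted label using the shared
    feature pipeline and a trained model (no retraining or threshold
    recalibration). For each clip a noise segment with a different group
    token is drawn; sharing a token raises an exclusivity error.
    """
    rng = np.random.default_rng(seed)
    noise_tokens = [
        f"{k.pen_id}|{k.date}|{k.session}" for _, k in noise_pool
    ]
    points = []
    for snr in snr_bins:
        y_true, y_pred = [], []
        for w, label, token in samples:
            admissible = [i for i, nt in enumerate(noise_tokens) if nt != token]
            if not admissible:
                raise LeakageError("no group-exclusive noise segment available")
            ni = int(rng.choice(admissible))
            mixed = mix_at_snr(w, noise_pool[ni][0], snr)
            y_true.append(label)
            y_pred.append(classify(mixed))
        rep = compute_metrics(np.array(y_true), np.array(y_pred))
        points.append((float(snr), rep.macro_f1))
    return NoiseRobustnessCurve(points)


# ---------------------------------------------------------------------------
# Fold-paired significance test
# ---------------------------------------------------------------------------

def wilcoxon_fold_test(scores_a, scores_b) -> float:
    """Exact two-sided Wilcoxon signed-rank p on paired fold scores.

    Zero differences are dropped with a warning; if every difference is
    zero the test is uninformative and p = 1 is returned.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError("paired score lists must have equal length")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    if np.any(d == 0):
        warnings.warn("zero differences dropped from the signed-rank test")
        d = d[d != 0]
    res = sstats.wilcoxon(d, zero_method="wilcox", method="exact",
                          alternative="two-sided")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Background separability probe
# ---------------------------------------------------------------------------

def background_probe(
    background_specs: list,
    region_labels,
    groups,
    n_splits: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Linear separability of two recording environments from their
    non-event background, under grouped CV (guards against a model
    exploiting location-specific background cues).

    Features are time-averaged log-Mel vectors; returns out-of-fold
    (balanced accuracy, AUROC).
    """
    y = np.asarray(region_labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise InvalidInputError("background probe needs exactly two region labels")
    x = np.stack([s.values.mean(axis=1) for s in background_specs])
    groups = np.asarray(groups)
    n_splits = min(n_splits, len(np.unique(groups)))
    if n_splits < 2:
        raise SplitInfeasibleError("need at least two groups")
    ybin = (y == classes[1]).astype(int)
    oof_score = np.zeros(len(y))
    oof_pred = np.zeros(len(y), dtype=int)
    for tr, te in GroupKFold(n_splits=n_splits).split(x, ybin, groups):
        assert not set(groups[tr]) & set(groups[te])
        clf = LogisticRegression(max_iter=2000, random_state=seed)
        clf.fit(x[tr], ybin[tr])
        oof_score[te] = clf.predict_proba(x[te])[:, 1]
        oof_pred[te] = clf.predict(x[te])
    bal_acc = float(balanced_accuracy_score(ybin, oof_pred))
    auroc = float(roc_auc_score(ybin, oof_score))
    return bal_acc, auroc
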