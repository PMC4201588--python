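"""Validation engines: leave-one-study-out ISV and stratified ten-fold RCV.

Inter-study validation (ISV) excludes one whole study per iteration: a
classifier is trained on the samples of every other study and evaluated on
the excluded one, so training and test sets are *not* identically
distributed whenever study-effects exist.  Randomized cross-validation
(RCV) instead deals the pooled samples of each phenotype into ten disjoint
folds, which mixes studies and is therefore blind to study-effects.

Both engines share the stratified training loop: each repeat subsamples
every phenotype (without replacement) down to the smallest phenotype's
training count, reruns feature selection, and trains a model on the
balanced subsample; the ensemble predicts by per-sample majority vote.
This mitigates sample-number bias between phenotypes without reweighting
the classifiers themselves.

Performance is reported as per-phenotype *sensitivity* — the fraction of a
phenotype's test samples assigned that phenotype's label — tallied per
evaluation unit (held-out study for ISV, fold for RCV).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classifiers import (
    LabelledExpression,
    SignatureModel,
    predict,
    select_features,
    train_margin,
    train_rank_pairs,
)
from .dataset_io import MultiStudyDataset

__all__ = [
    "Split",
    "SplitPlan",
    "PipelineConfig",
    "SensitivityEntry",
    "SensitivityReport",
    "make_isv_splits",
    "make_rcv_folds",
    "stratified_train",
    "predict_ensemble",
    "split_models",
    "run_validation",
]

# a phenotype needs this many training samples to be learnable at all
_MIN_TRAIN = 2


@dataclass(frozen=True)
class Split:
    """One train/test partition.  ``untrainable`` lists phenotypes with too
    few training samples in this split; they are recorded, never silently
    dropped."""

    unit_label: str
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    untrainable: tuple[str, ...] = ()


@dataclass(frozen=True)
class SplitPlan:
    mode: str  # "ISV" | "RCV"
    splits: tuple[Split, ...]

    def __post_init__(self) -> None:
        if self.mode not in ("ISV", "RCV"):
            raise ValueError(f"mode must be ISV or RCV, got {self.mode!r}")
        for s in self.splits:
            if set(s.train_ids) & set(s.test_ids):
                raise ValueError(f"split '{s.unit_label}': train/test overlap")


@dataclass(frozen=True)
class PipelineConfig:
    """Classifier pipeline settings shared by every validation iteration.

    ``n_features`` genes are selected by one-vs-rest F-score inside each
    training repeat; the ``margin`` scheme then fits one-versus-one linear
    SVMs with cost ``cost``, while ``rank_pair`` selects
    ``pairs_per_phenotype`` gene-disjoint pairs per phenotype among the
    selected genes.  ``n_repeats`` balanced subsamples form the ensemble.
    """

    scheme: str = "margin"
    n_features: int = 100
    pairs_per_phenotype: int = 10
    cost: float = 1.0
    n_repeats: int = 11

    def __post_init__(self) -> None:
        if self.scheme not in ("margin", "rank_pair"):
            raise ValueError(f"scheme must be margin or rank_pair, got {self.scheme!r}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.pairs_per_phenotype < 1:
            raise ValueError("pairs_per_phenotype must be >= 1")

    def fingerprint(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _untrainable(ds: MultiStudyDataset, train_ids: Sequence[str]) -> tuple[str, ...]:
    counts: dict[str, int] = {}
    for s in train_ids:
        p = ds.phenotype_of[s]
        counts[p] = counts.get(p, 0) + 1
    return tuple(p for p in ds.phenotypes if counts.get(p, 0) < _MIN_TRAIN)


def make_isv_splits(ds: MultiStudyDataset) -> SplitPlan:
    """One split per study, ordered by study id; the held-out study is the
    whole test set."""
    splits = []
    for study in ds.studies:
        test = ds.samples_of_study(study)
        train = tuple(s for s in ds.sample_ids if ds.study_of[s] != study)
        splits.append(Split(study, train, test, _untrainable(ds, train)))
    return SplitPlan("ISV", tuple(splits))


def make_rcv_folds(
    ds: MultiStudyDataset, n_folds: int = 10, seed: int = 0
) -> SplitPlan:
    """Phenotype-stratified folds over the pooled samples of all studies.

    Each phenotype's samples are shuffled (seeded) and dealt round-robin, so
    per-phenotype fold sizes differ by at most one; folds are disjoint and
    cover every sample.  Stratification is by phenotype only, never by
    study — pooling across studies is precisely what makes RCV blind to
    study-effects.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng([seed, 202])
    fold_members: list[list[str]] = [[] for _ in range(n_folds)]
    for p in ds.phenotypes:
        ids = list(ds.samples_of_phenotype(p))
        if len(ids) < n_folds:
            raise ValueError(
                f"phenotype '{p}' has {len(ids)} samples, fewer than "
                f"{n_folds} folds"
            )
        perm = rng.permutation(len(ids))
        for r, i in enumerate(perm):
            fold_members[r % n_folds].append(ids[i])
    all_ids = set(ds.sample_ids)
    width = len(str(n_folds - 1))
    splits = []
    for f, members in enumerate(fold_members):
        test = tuple(s for s in ds.sample_ids if s in set(members))
        train = tuple(s for s in ds.sample_ids if s in (all_ids - set(members)))
        splits.append(
            Split(f"fold{f:0{width}d}", train, test, _untrainable(ds, train))
        )
    return SplitPlan("RCV", tuple(splits))


# -- stratified training loop --------------------------------------------


def _train_one(data: LabelledExpression, pipeline: PipelineConfig) -> SignatureModel:
    k = min(pipeline.n_features, len(data.gene_ids))
    features = select_features(data, k)
    if pipeline.scheme == "margin":
        return train_margin(data, features, cost=pipeline.cost)
    return train_rank_pairs(
        data.restrict_genes(features), pipeline.pairs_per_phenotype
    )


def stratified_train(
    train: LabelledExpression | MultiStudyDataset,
    pipeline: PipelineConfig,
    seed: int = 0,
    trainer=None,
) -> list[SignatureModel]:
    """Class-balanced subsampling with ensemble training.

    For each of ``pipeline.n_repeats`` repeats, every phenotype is
    subsampled without replacement down to the smallest phenotype's count
    (a distinct seeded draw per repeat); feature selection and training run
    on the balanced subsample.  If the training set is already balanced the
    subsample is the full training set in every repeat.

    ``trainer`` overrides the pipeline-derived training function (a callable
    :class:`LabelledExpression` -> model); used mainly for testing the
    subsampling behaviour in isolation.
    """
    data = train if isinstance(train, LabelledExpression) else LabelledExpression.from_dataset(train)
    classes = data.classes
    if len(classes) < 2:
        raise ValueError("need >=2 phenotypes in training data")
    by_class = {c: np.flatnonzero(data.labels == c) for c in classes}
    n_min = min(len(v) for v in by_class.values())
    if n_min < _MIN_TRAIN:
        small = min(classes, key=lambda c: len(by_class[c]))
        raise ValueError(f"phenotype '{small}' has <{_MIN_TRAIN} training samples")
    models: list[SignatureModel] = []
    for r in range(pipeline.n_repeats):
        rng = np.random.default_rng([seed, 303, r])
        cols: list[int] = []
        for c in classes:  # sorted order -> deterministic stream use
            idx = by_class[c]
            if len(idx) == n_min:
                cols.extend(int(i) for i in idx)
            else:
                cols.extend(int(i) for i in np.sort(rng.choice(idx, n_min, replace=False)))
        balanced = data.take_samples(sorted(cols))
        models.append(trainer(balanced) if trainer else _train_one(balanced, pipeline))
    return models


def predict_ensemble(models: Sequence[SignatureModel], samples) -> np.ndarray:
    """Per-sample majority vote over the ensemble, ties broken by
    lexicographic label order."""
    if not models:
        raise ValueError("empty ensemble")
    preds = np.stack([predict(m, samples) for m in models])
    out = []
    for j in range(preds.shape[1]):
        labels, counts = np.unique(preds[:, j].astype(str), return_counts=True)
        best = counts.max()
        out.append(min(l for l, c in zip(labels, counts) if c == best))
    return np.array(out, dtype=object)


# -- running a plan -------------------------------------------------------


@dataclass(frozen=True)
class SensitivityEntry:
    phenotype: str
    unit_label: str
    n_correct: int
    n_total: int

    @property
    def sensitivity(self) -> float:
        return self.n_correct / self.n_total


@dataclass(frozen=True)
class SensitivityReport:
    """Per-phenotype, per-evaluation-unit sensitivities with counts.

    ``skipped`` records (phenotype, unit) cells where the phenotype was
    untrainable in that split; sensitivities are reported only over units
    where training was possible.
    """

    mode: str
    entries: tuple[SensitivityEntry, ...]
    skipped: tuple[tuple[str, str], ...]
    seed: int
    config_hash: str

    def phenotypes(self) -> tuple[str, ...]:
        return tuple(sorted({e.phenotype for e in self.entries}))

    def unit_sensitivities(self, phenotype: str) -> dict[str, float]:
        return {
            e.unit_label: e.sensitivity for e in self.entries if e.phenotype == phenotype
        }

    def mean_sensitivity(self, phenotype: str) -> float:
        """Unweighted mean over evaluation units (each unit one vote)."""
        vals = [e.sensitivity for e in self.entries if e.phenotype == phenotype]
        if not vals:
            raise ValueError(f"no entries for phenotype '{phenotype}'")
        return float(np.mean(vals))

    def pooled_sensitivity(self, phenotype: str) -> float:
        """Pooled-count ratio over all units (sample-weighted)."""
        sel = [e for e in self.entries if e.phenotype == phenotype]
        if not sel:
            raise ValueError(f"no entries for phenotype '{phenotype}'")
        return sum(e.n_correct for e in sel) / sum(e.n_total for e in sel)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mode": self.mode,
                "phenotype": [e.phenotype for e in self.entries],
                "unit_label": [e.unit_label for e in self.entries],
                "n_correct": [e.n_correct for e in self.entries],
                "n_total": [e.n_total for e in self.entries],
                "sensitivity": [e.sensitivity for e in self.entries],
                "seed": self.seed,
                "config_hash": self.config_hash,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def split_models(
    ds: MultiStudyDataset,
    split: Split,
    pipeline: PipelineConfig,
    split_seed: int,
) -> list[SignatureModel]:
    """Train the ensemble for one split from its training side only.

    The result depends on the split's training samples, the pipeline and
    the seed — never on the test samples, which is what makes the
    validation leakage-free and lets it be audited by recomputation.
    """
    trainable_ids = [
        s for s in split.train_ids if ds.phenotype_of[s] not in split.untrainable
    ]
    sub = ds.matrix.restrict_samples(trainable_ids)
    labels = np.array([ds.phenotype_of[s] for s in trainable_ids], dtype=object)
    data = LabelledExpression(ds.gene_ids, sub.values, labels)
    return stratified_train(data, pipeline, seed=split_seed)


def _split_seed(seed: int, split_index: int) -> int:
    return int(np.random.default_rng([seed, 404, split_index]).integers(2**31))


def run_validation(
    ds: MultiStudyDataset,
    plan: SplitPlan,
    pipeline: PipelineConfig | None = None,
    seed: int = 0,
) -> SensitivityReport:
    """Execute a split plan: per split, select features and train on the
    training side only, predict the test side, and tally per-phenotype
    correct/total counts per evaluation unit.

    Feature selection happens inside each training repeat, so no test
    sample ever influences the trained models (no leakage).
    """
    pipeline = pipeline or PipelineConfig()
    entries: list[SensitivityEntry] = []
    skipped: list[tuple[str, str]] = []
    for si, split in enumerate(plan.splits):
        models = split_models(ds, split, pipeline, _split_seed(seed, si))
        test_matrix = ds.matrix.restrict_samples(split.test_ids)
        preds = predict_ensemble(models, test_matrix)
        truth = np.array([ds.phenotype_of[s] for s in split.test_ids], dtype=object)
        for p in sorted(set(truth)):
            if p in split.untrainable:
                skipped.append((p, split.unit_label))
                continue
            mask = truth == p
            entries.append(
                SensitivityEntry(
                    p,
                    split.unit_label,
                    int((preds[mask] == p).sum()),
                    int(mask.sum()),
                )
            )
    return SensitivityReport(
        plan.mode,
        tuple(entries),
        tuple(skipped),
        seed,
        pipeline.fingerprint(),
    )
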