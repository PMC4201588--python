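"""Feature selection and the two classification schemes under comparison.

* ``margin`` — a maximal-margin linear discriminant (linear SVM) trained
  one-versus-one on F-score-selected genes, predicting by pairwise majority
  vote.
* ``rank_pair`` — a rank-pair classifier in the top-scoring-pairs family:
  each phenotype owns a list of gene-disjoint ordered gene pairs, and a
  sample votes for the phenotype whose expected within-pair orderings it
  satisfies most often.  Decisions depend only on within-sample orderings,
  so they are invariant under any strictly increasing per-sample transform.

Feature selection and pair selection are recomputed from the training data
of every validation iteration; nothing here ever sees test samples.
All tie-breaks are lexicographic so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence, Union

import numpy as np
from sklearn.svm import SVC

from .dataset_io import ExpressionMatrix, MultiStudyDataset

__all__ = [
    "LabelledExpression",
    "SignatureModel",
    "MarginModel",
    "RankPairModel",
    "fscore",
    "fscore_vector",
    "select_features",
    "train_margin",
    "train_rank_pairs",
    "predict",
    "models_equal",
]


@dataclass(frozen=True, eq=False)
class LabelledExpression:
    """A genes x samples value block with one phenotype label per sample.

    The minimal training input: unlike :class:`MultiStudyDataset` it carries
    no study structure and no multi-study invariants, so class-balanced
    subsamples (which may come from a single study) are representable.
    """

    gene_ids: tuple[str, ...]
    values: np.ndarray  # genes x samples
    labels: np.ndarray  # phenotype per sample

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        vals = np.asarray(self.values, dtype=np.float64)
        labs = np.asarray(self.labels, dtype=object)
        if vals.shape != (len(self.gene_ids), labs.shape[0]):
            raise ValueError("values shape does not match gene_ids x labels")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", labs)

    @classmethod
    def from_dataset(cls, ds: MultiStudyDataset) -> "LabelledExpression":
        return cls(ds.gene_ids, ds.matrix.values, ds.phenotype_labels())

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels)))

    def restrict_genes(self, gene_ids: Sequence[str]) -> "LabelledExpression":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return LabelledExpression(tuple(gene_ids), self.values[rows, :], self.labels)

    def take_samples(self, cols: Sequence[int]) -> "LabelledExpression":
        cols = list(cols)
        return LabelledExpression(self.gene_ids, self.values[:, cols], self.labels[cols])


TrainInput = Union[MultiStudyDataset, LabelledExpression]


def _as_labelled(train: TrainInput) -> LabelledExpression:
    if isinstance(train, MultiStudyDataset):
        return LabelledExpression.from_dataset(train)
    return train


# -- F-score feature selection -------------------------------------------


def fscore(pos: Sequence[float], neg: Sequence[float]) -> float:
    """Fisher-style F-score of one feature between two groups.

    F = [(m+ - m)^2 + (m- - m)^2] / (s2+ + s2-), with m+/m- the group
    means, m the pooled mean and s2+/- the unbiased within-group variances.
    A zero denominator yields +inf, which ranks above every finite score.
    """
    pos = np.asarray(pos, dtype=np.float64)
    neg = np.asarray(neg, dtype=np.float64)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each group needs >=2 values")
    m_pos, m_neg = pos.mean(), neg.mean()
    m_all = np.concatenate([pos, neg]).mean()
    denom = pos.var(ddof=1) + neg.var(ddof=1)
    num = (m_pos - m_all) ** 2 + (m_neg - m_all) ** 2
    if denom == 0.0:
        return float("inf")
    return float(num / denom)


def fscore_vector(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise F-scores for a genes x samples split into two groups."""
    if pos.shape[1] < 2 or neg.shape[1] < 2:
        raise ValueError("each group needs >=2 samples")
    m_pos = pos.mean(axis=1)
    m_neg = neg.mean(axis=1)
    n_p, n_n = pos.shape[1], neg.shape[1]
    m_all = (m_pos * n_p + m_neg * n_n) / (n_p + n_n)
    num = (m_pos - m_all) ** 2 + (m_neg - m_all) ** 2
    denom = pos.var(axis=1, ddof=1) + neg.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom == 0.0, np.inf, num / denom)
    return out


def select_features(train: TrainInput, k: int) -> list[str]:
    """Top-k genes by the maximum one-vs-rest F-score over phenotypes.

    For every phenotype the one-vs-rest F-score of each gene is computed on
    the training samples; a gene's overall score is its maximum across
    phenotypes, so each phenotype contributes its most discriminative genes.
    Ties are broken by lexicographic gene id; the result is deterministic.
    """
    data = _as_labelled(train)
    n_genes = len(data.gene_ids)
    if not (1 <= k <= n_genes):
        raise ValueError(f"k must be in [1, {n_genes}], got {k}")
    classes = data.classes
    if len(classes) < 2:
        raise ValueError("need >=2 phenotypes for feature selection")
    best = np.full(n_genes, -np.inf)
    for p in classes:
        mask = data.labels == p
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(
                f"phenotype '{p}' needs >=2 samples on each side of the "
                "one-vs-rest split"
            )
        best = np.maximum(best, fscore_vector(data.values[:, mask], data.values[:, ~mask]))
    order = sorted(range(n_genes), key=lambda i: (-best[i], data.gene_ids[i]))
    return [data.gene_ids[i] for i in order[:k]]


# -- models ---------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseDiscriminant:
    """One linear decision boundary between two phenotypes.

    ``weights @ x + offset > 0`` votes for ``class_b`` (the lexicographically
    larger label), otherwise for ``class_a``.
    """

    class_a: str
    class_b: str
    weights: tuple[float, ...]
    offset: float


class SignatureModel:
    """A trained classifier artifact; see :class:`MarginModel` and
    :class:`RankPairModel`."""

    scheme: str
    classes: tuple[str, ...]

    def genes_used(self) -> tuple[str, ...]:
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError


@dataclass(frozen=True)
class MarginModel(SignatureModel):
    features: tuple[str, ...]
    discriminants: tuple[PairwiseDiscriminant, ...]
    classes: tuple[str, ...]
    scheme = "margin"

    def genes_used(self) -> tuple[str, ...]:
        return self.features

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "features": list(self.features),
            "classes": list(self.classes),
            "discriminants": [
                {
                    "class_a": d.class_a,
                    "class_b": d.class_b,
                    "weights": list(d.weights),
                    "offset": d.offset,
                }
                for d in self.discriminants
            ],
        }


@dataclass(frozen=True)
class RankPairModel(SignatureModel):
    # phenotype -> ordered gene pairs (gene_i, gene_j, delta); orientation
    # means "expression of gene_i below gene_j is typical of this phenotype"
    pairs: Mapping[str, tuple[tuple[str, str, float], ...]]
    classes: tuple[str, ...]
    scheme = "rank_pair"

    def genes_used(self) -> tuple[str, ...]:
        genes: list[str] = []
        for plist in self.pairs.values():
            for gi, gj, _ in plist:
                genes.extend((gi, gj))
        return tuple(dict.fromkeys(genes))

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "classes": list(self.classes),
            "pairs": {
                p: [[gi, gj, d] for gi, gj, d in plist]
                for p, plist in self.pairs.items()
            },
        }


def models_equal(a: SignatureModel, b: SignatureModel) -> bool:
    return a.to_dict() == b.to_dict()


def save_model(model: SignatureModel, path) -> None:
    """Serialize a trained model to JSON (weights table or pairs table)."""
    import json
    from pathlib import Path

    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n", encoding="utf-8")


def load_model(path) -> SignatureModel:
    import json
    from pathlib import Path

    d = json.loads(Path(path).read_text(encoding="utf-8"))
    if d["scheme"] == "margin":
        return MarginModel(
            tuple(d["features"]),
            tuple(
                PairwiseDiscriminant(
                    x["class_a"], x["class_b"], tuple(x["weights"]), x["offset"]
                )
                for x in d["discriminants"]
            ),
            tuple(d["classes"]),
        )
    if d["scheme"] == "rank_pair":
        return RankPairModel(
            {
                p: tuple((gi, gj, float(dl)) for gi, gj, dl in plist)
                for p, plist in d["pairs"].items()
            },
            tuple(d["classes"]),
        )
    raise ValueError(f"unknown model scheme {d.get('scheme')!r}")


# -- training -------------------------------------------------------------


def train_margin(
    train: TrainInput, features: Sequence[str], cost: float = 1.0
) -> MarginModel:
    """Fit one maximal-margin linear discriminant per unordered phenotype
    pair (one-versus-one) on the selected features only."""
    data = _as_labelled(train).restrict_genes(features)
    classes = data.classes
    for p in classes:
        if (data.labels == p).sum() < 2:
            raise ValueError(f"phenotype '{p}' has <2 training samples")
    discs = []
    for a, b in combinations(classes, 2):
        mask = (data.labels == a) | (data.labels == b)
        X = data.values[:, mask].T
        y = data.labels[mask].astype(str)
        clf = SVC(kernel="linear", C=cost)
        clf.fit(X, y)
        # sklearn sorts classes, so decision_function > 0 means the larger
        # label; (a, b) are already in lexicographic order
        w = np.asarray(clf.coef_).ravel()
        discs.append(
            PairwiseDiscriminant(a, b, tuple(float(v) for v in w), float(clf.intercept_[0]))
        )
    return MarginModel(tuple(features), tuple(discs), classes)


def _less_than_fractions(X: np.ndarray) -> np.ndarray:
    """M[i, j] = fraction of samples (columns) with X[i] < X[j]."""
    return (X[:, None, :] < X[None, :, :]).mean(axis=2)


def train_rank_pairs(train: TrainInput, pairs_per_phenotype: int) -> RankPairModel:
    """Greedy gene-disjoint rank-pair selection per phenotype.

    Every ordered gene pair (i, j) is scored by
    ``delta_c(i, j) = P(x_i < x_j | c) - P(x_i < x_j | not c)`` with the
    empirical fractions over training samples.  Pairs are accepted in
    decreasing delta (orientation with delta > 0; ties by lexicographic
    (gene_i, gene_j)), skipping any pair sharing a gene with an accepted
    pair of the same phenotype, until the quota is filled.
    """
    if pairs_per_phenotype < 1:
        raise ValueError("pairs_per_phenotype must be >= 1")
    data = _as_labelled(train)
    classes = data.classes
    for p in classes:
        if (data.labels == p).sum() < 2:
            raise ValueError(f"phenotype '{p}' has <2 training samples")
    genes = data.gene_ids
    if 2 * pairs_per_phenotype > len(genes):
        raise ValueError(
            f"{pairs_per_phenotype} gene-disjoint pairs need "
            f">= {2 * pairs_per_phenotype} genes, have {len(genes)}"
        )
    pairs: dict[str, tuple[tuple[str, str, float], ...]] = {}
    for c in classes:
        mask = data.labels == c
        delta = _less_than_fractions(data.values[:, mask]) - _less_than_fractions(
            data.values[:, ~mask]
        )
        n = len(genes)
        ii, jj = np.nonzero(~np.eye(n, dtype=bool))
        order = sorted(
            range(len(ii)),
            key=lambda t: (-delta[ii[t], jj[t]], genes[ii[t]], genes[jj[t]]),
        )
        used: set[str] = set()
        accepted: list[tuple[str, str, float]] = []
        for t in order:
            gi, gj = genes[ii[t]], genes[jj[t]]
            if gi in used or gj in used:
                continue
            accepted.append((gi, gj, float(delta[ii[t], jj[t]])))
            used.update((gi, gj))
            if len(accepted) == pairs_per_phenotype:
                break
        if len(accepted) < pairs_per_phenotype:
            raise ValueError(
                f"phenotype '{c}': only {len(accepted)} gene-disjoint pairs "
                f"available, {pairs_per_phenotype} requested"
            )
        pairs[c] = tuple(accepted)
    return RankPairModel(pairs, classes)


# -- prediction -----------------------------------------------------------


def _gene_rows(matrix: ExpressionMatrix, genes: Sequence[str]) -> np.ndarray:
    idx = matrix.gene_index()
    rows = []
    for g in genes:
        if g not in idx:
            raise ValueError(f"model gene '{g}' missing from input samples")
        rows.append(idx[g])
    return matrix.values[rows, :]


def predict(model: SignatureModel, samples: ExpressionMatrix) -> np.ndarray:
    """Phenotype label per sample (aligned with ``samples.sample_ids``).

    margin: each pairwise discriminant votes; the majority label wins, ties
    broken by lexicographic label order.  rank_pair: each phenotype is
    scored by the fraction of its pairs whose orientation holds strictly in
    the sample; argmax, ties lexicographic.
    """
    if isinstance(model, MarginModel):
        X = _gene_rows(samples, model.features)
        votes = {c: np.zeros(samples.n_samples, dtype=int) for c in model.classes}
        for d in model.discriminants:
            score = np.asarray(d.weights) @ X + d.offset
            votes[d.class_b] += score > 0
            votes[d.class_a] += score <= 0
        labels = []
        for j in range(samples.n_samples):
            best = max(votes[c][j] for c in model.classes)
            labels.append(min(c for c in model.classes if votes[c][j] == best))
        return np.array(labels, dtype=object)
    if isinstance(model, RankPairModel):
        genes = model.genes_used()
        X = _gene_rows(samples, genes)
        row = {g: i for i, g in enumerate(genes)}
        scores = np.zeros((len(model.classes), samples.n_samples))
        for ci, c in enumerate(model.classes):
            plist = model.pairs[c]
            hold = np.zeros(samples.n_samples)
            for gi, gj, _ in plist:
                hold += X[row[gi], :] < X[row[gj], :]
            scores[ci] = hold / len(plist)
        labels = []
        for j in range(samples.n_samples):
            best = scores[:, j].max()
            labels.append(
                min(c for ci, c in enumerate(model.classes) if scores[ci, j] == best)
            )
        return np.array(labels, dtype=object)
    raise TypeError(f"unknown model type: {type(model).__name__}")
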