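"""The comparative layer: RCV - ISV gaps, consistency, cumulative curves.

For each phenotype the analysis contrasts the *unweighted* mean of its
per-study ISV sensitivities (each study one vote) with the sensitivity
from ten-fold RCV.  The gap ``rcv - mean_isv`` measures how much
study-effects degrade transfer to unseen studies; the coefficient of
variation (CoVar) of the per-study ISV sensitivities measures how
consistent cross-study performance is.

The cumulative analysis repeats this on datasets that contain only ``n`` of
the ``N`` available studies of a phenotype (plus all studies lacking it),
tracing how ISV converges toward RCV as study diversity grows.

The nonparametric statistics used to describe these trends — Spearman rank
correlation and the two-sided Wilcoxon rank-sum test — are evaluated by
exact enumeration at small sample sizes and by large-sample approximations
otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import MultiStudyDataset
from .validation import (
    PipelineConfig,
    SensitivityReport,
    make_isv_splits,
    make_rcv_folds,
    run_validation,
)

__all__ = [
    "CCVAResult",
    "CurvePoint",
    "CumulativeCurve",
    "compare",
    "results_to_frame",
    "cumulative_ccva",
    "TrendStats",
    "trend_stats",
    "difference_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CCVAResult:
    """Per-phenotype comparison of mean ISV sensitivity against RCV.

    ``covar`` is sd/mean of the per-study ISV sensitivities; it is undefined
    (None) when the mean is zero or fewer than two studies contributed.
    """

    phenotype: str
    mean_isv: float
    rcv: float
    n_studies: int
    covar: float | None

    @property
    def gap(self) -> float:
        return self.rcv - self.mean_isv


def _covar(values: Sequence[float]) -> float | None:
    vals = np.asarray(values, dtype=float)
    if vals.size < 2 or vals.mean() <= 0:
        return None
    return float(vals.std(ddof=1) / vals.mean())


def compare(
    isv: SensitivityReport,
    rcv: SensitivityReport,
    rcv_aggregate: str = "mean_folds",
) -> dict[str, CCVAResult]:
    """Per-phenotype CCVA summary from an ISV and an RCV report.

    ``rcv_aggregate`` selects the RCV summary: ``mean_folds`` (the average
    sensitivity across folds, the default used throughout) or ``pooled``
    (pooled-count ratio over all folds).  Phenotypes present in only one
    report are excluded with a warning.
    """
    if rcv_aggregate not in ("mean_folds", "pooled"):
        raise ValueError("rcv_aggregate must be 'mean_folds' or 'pooled'")
    out: dict[str, CCVAResult] = {}
    isv_ph, rcv_ph = set(isv.phenotypes()), set(rcv.phenotypes())
    for p in sorted(isv_ph ^ rcv_ph):
        logger.warning("phenotype '%s' present in only one report; excluded", p)
    for p in sorted(isv_ph & rcv_ph):
        per_study = list(isv.unit_sensitivities(p).values())
        rcv_val = (
            rcv.mean_sensitivity(p)
            if rcv_aggregate == "mean_folds"
            else rcv.pooled_sensitivity(p)
        )
        out[p] = CCVAResult(
            phenotype=p,
            mean_isv=float(np.mean(per_study)),
            rcv=float(rcv_val),
            n_studies=len(per_study),
            covar=_covar(per_study),
        )
    return out


def results_to_frame(results: dict[str, CCVAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "phenotype": list(results),
            "mean_isv": [r.mean_isv for r in results.values()],
            "rcv": [r.rcv for r in results.values()],
            "gap": [r.gap for r in results.values()],
            "covar": [r.covar if r.covar is not None else float("nan") for r in results.values()],
            "n_studies": [r.n_studies for r in results.values()],
        }
    )


# -- cumulative CCVA ------------------------------------------------------


@dataclass(frozen=True)
class CurvePoint:
    """One point of a cumulative curve.

    ``covar`` is the coefficient of variation of the per-study ISV
    sensitivities pooled over all resamples at this ``n`` (5 resamples of
    n studies give 5n values), which keeps the consistency estimate
    meaningful even at n = 2 where a single resample holds only two
    studies.
    """

    n: int
    mean_isv: float
    sd_isv: float
    mean_rcv: float
    sd_rcv: float
    covar: float
    n_resamples: int


@dataclass(frozen=True)
class CumulativeCurve:
    phenotype: str
    points: tuple[CurvePoint, ...]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phenotype": self.phenotype,
                "n": [p.n for p in self.points],
                "mean_isv": [p.mean_isv for p in self.points],
                "sd_isv": [p.sd_isv for p in self.points],
                "mean_rcv": [p.mean_rcv for p in self.points],
                "sd_rcv": [p.sd_rcv for p in self.points],
                "covar": [p.covar for p in self.points],
                "n_resamples": [p.n_resamples for p in self.points],
                "seed": self.seed,
            }
        )


def _draw_subsets(
    studies: Sequence[str], n: int, n_resamples: int, rng: np.random.Generator
) -> list[tuple[str, ...]]:
    """Distinct study subsets of size n, uniform over subsets; all of them
    when fewer than n_resamples exist."""
    total = math.comb(len(studies), n)
    if total <= n_resamples:
        return [tuple(c) for c in combinations(sorted(studies), n)]
    chosen: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    while len(chosen) < n_resamples:
        pick = tuple(sorted(rng.choice(len(studies), n, replace=False)))
        subset = tuple(sorted(studies[i] for i in pick))
        if subset not in seen:
            seen.add(subset)
            chosen.append(subset)
    return chosen


def cumulative_ccva(
    ds: MultiStudyDataset,
    phenotype: str,
    n_values: Sequence[int],
    pipeline: PipelineConfig | None = None,
    n_resamples: int = 5,
    n_folds: int = 10,
    seed: int = 0,
) -> CumulativeCurve:
    """ISV and RCV sensitivity of one phenotype versus the number of its
    studies included.

    For each ``n``, ``n_resamples`` distinct subsets of ``n`` studies
    carrying the phenotype are drawn; each subset is combined with every
    study lacking the phenotype, full ISV and RCV run on that reduced
    dataset, and the phenotype's mean ISV and RCV sensitivities are
    recorded.  Points report mean and sd over the resamples.  ``n == N``
    reduces to standard CCVA on the full dataset; ``n == 1`` degenerates to
    train-on-one-study / test-on-the-rest.
    """
    pipeline = pipeline or PipelineConfig()
    if phenotype not in ds.phenotypes:
        raise ValueError(
            f"phenotype '{phenotype}' not in dataset (have {list(ds.phenotypes)})"
        )
    with_ph = list(ds.studies_with_phenotype(phenotype))
    lacking = [s for s in ds.studies if s not in with_ph]
    N = len(with_ph)
    n_values = sorted(set(int(n) for n in n_values))
    for n in n_values:
        if not (1 <= n <= N):
            raise ValueError(f"n={n} outside [1, {N}] (phenotype has {N} studies)")
    points = []
    for ni, n in enumerate(n_values):
        rng = np.random.default_rng([seed, 505, n])
        subsets = _draw_subsets(with_ph, n, n_resamples, rng)
        isv_vals, rcv_vals, pooled_per_study = [], [], []
        for ri, subset in enumerate(subsets):
            sub = ds.subset(set(subset) | set(lacking))
            run_seed = int(np.random.default_rng([seed, 606, n, ri]).integers(2**31))
            isv = run_validation(sub, make_isv_splits(sub), pipeline, seed=run_seed)
            rcv = run_validation(
                sub, make_rcv_folds(sub, n_folds, seed=run_seed), pipeline, seed=run_seed
            )
            per_study = list(isv.unit_sensitivities(phenotype).values())
            isv_vals.append(float(np.mean(per_study)))
            rcv_vals.append(rcv.mean_sensitivity(phenotype))
            pooled_per_study.extend(per_study)
        sd = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        cv = _covar(pooled_per_study)
        points.append(
            CurvePoint(
                n=n,
                mean_isv=float(np.mean(isv_vals)),
                sd_isv=sd(isv_vals),
                mean_rcv=float(np.mean(rcv_vals)),
                sd_rcv=sd(rcv_vals),
                covar=cv if cv is not None else float("nan"),
                n_resamples=len(subsets),
            )
        )
    return CumulativeCurve(phenotype, tuple(points), seed)


# -- nonparametric statistics --------------------------------------------


@dataclass(frozen=True)
class TrendStats:
    """Spearman correlation result; ``rho is None`` marks the undefined
    case (a constant input vector), which is never silently NaN."""

    rho: float | None
    p_value: float | None

    @property
    def defined(self) -> bool:
        return self.rho is not None


def _rank_corr(xr: np.ndarray, yr: np.ndarray) -> float:
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    return float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))


def trend_stats(xs: Sequence[float], ys: Sequence[float]) -> TrendStats:
    """Spearman rank correlation with average ranks for ties.

    The p-value is computed by exact permutation enumeration for n <= 9 and
    by the large-sample t approximation otherwise.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.size < 3:
        raise ValueError("need two equal-length vectors with >=3 entries")
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return TrendStats(None, None)
    xr = stats.rankdata(xs)
    yr = stats.rankdata(ys)
    rho = _rank_corr(xr, yr)
    n = xs.size
    if n <= 9:
        perms = np.array(list(permutations(yr)))
        xc = xr - xr.mean()
        pc = perms - yr.mean()
        rhos = pc @ xc / math.sqrt((xc @ xc) * float(((yr - yr.mean()) ** 2).sum()))
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(xs, ys).pvalue)
    return TrendStats(rho, p)


def difference_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value for a location difference.

    Exact enumeration of all rank assignments (with average ranks for ties)
    when the combined sample size is <= 20; otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    N = n1 + n2
    ranks = stats.rankdata(np.concatenate([a, b]))
    w = float(ranks[:n1].sum())
    if N <= 20:
        combs = np.array(list(combinations(range(N), n1)))
        sums = ranks[combs].sum(axis=1)
        p_le = float(np.mean(sums <= w + 1e-9))
        p_ge = float(np.mean(sums >= w - 1e-9))
        return min(1.0, 2.0 * min(p_le, p_ge))
    mean_w = n1 * (N + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / (N * (N - 1))
    var_w = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var_w == 0:
        return 1.0
    z = (w - mean_w) / math.sqrt(var_w)
    return float(2.0 * stats.norm.sf(abs(z)))
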