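"""Synthetic multi-study expression data with explicit study-effects.

The generator emulates the structure of a multi-study transcriptomic
compendium: several phenotypes, several studies per phenotype, studies that
lack some phenotypes, unequal per-study sample sizes, and per-study
expression shifts.  All components are additive Gaussians on the log scale:

    x[g, j] = mu_g + beta_{g,p} * [g in S_p] + b_{g,s}
              + eta_{g,s,p} * [g in S_p] + eps

for sample ``j`` belonging to study ``s`` with phenotype ``p``, where

* ``mu_g ~ N(m0, sigma_mu^2)`` is the per-gene baseline (drawn once per gene);
* ``S_p`` is the phenotype's signature gene set, ``k`` genes drawn uniformly
  without replacement (signatures of different phenotypes may overlap);
* ``beta_{g,p} = sign_g * (delta + N(0, sigma_beta^2))`` is the phenotype
  effect; ``sign_g`` is +-1 equiprobable per gene, so a gene's direction of
  effect is the same in every study — only the study components below break
  transferability;
* ``b_{g,s} ~ N(0, sigma_study^2)`` is the study-effect (batch shift),
  drawn once per (gene, study) and shared by all of the study's samples;
* ``eta_{g,s,p} ~ N(0, sigma_het^2)`` is study x phenotype heterogeneity on
  the signature genes, modelling subpopulation differences between cohorts;
* ``eps ~ N(0, sigma_eps^2)`` is i.i.d. measurement noise per cell.

One root seed drives a single named stream; the draw order is fixed
(baselines, signs, per-phenotype signatures and effect deviations, study
effects, heterogeneity, noise), so identical configs give bit-identical
datasets across runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .dataset_io import ExpressionMatrix, MultiStudyDataset, SampleAnnotation

__all__ = [
    "SimulationConfig",
    "balanced_design",
    "simulate",
    "simulate_dataset",
    "ground_truth",
    "load_config",
    "config_from_mapping",
    "config_to_mapping",
]

StudyDesign = tuple[tuple[str, dict[str, int]], ...]


def balanced_design(
    n_studies: int,
    phenotypes: Sequence[str] = ("A", "B"),
    samples_per_phenotype: int = 20,
    prefix: str = "st",
) -> StudyDesign:
    """A fully crossed design: every study holds every phenotype at equal n."""
    return tuple(
        (f"{prefix}{i + 1:02d}", {p: samples_per_phenotype for p in phenotypes})
        for i in range(n_studies)
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model (log-expression units throughout).

    Defaults describe a balanced two-phenotype compendium: 6 studies of
    20 + 20 samples, 500 genes, 30-gene signatures, effect size 1.5 x the
    noise sd, and study-effect sd equal to the noise sd.
    """

    n_genes: int = 500
    phenotypes: tuple[str, ...] = ("A", "B")
    study_design: StudyDesign = field(
        default_factory=lambda: balanced_design(6, ("A", "B"), 20)
    )
    signature_size: int = 30
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    effect_size: float = 1.5
    effect_sd: float = 0.3
    study_effect_sd: float = 1.0
    heterogeneity_sd: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "phenotypes", tuple(self.phenotypes))
        object.__setattr__(
            self,
            "study_design",
            tuple((str(s), dict(d)) for s, d in self.study_design),
        )
        self._validate()

    def _validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.phenotypes) < 2:
            raise ValueError("need >=2 phenotypes")
        if len(set(self.phenotypes)) != len(self.phenotypes):
            raise ValueError("duplicate phenotype labels")
        if len(self.study_design) < 2:
            raise ValueError("need >=2 studies")
        study_ids = [s for s, _ in self.study_design]
        if len(set(study_ids)) != len(study_ids):
            raise ValueError("duplicate study ids in study_design")
        if not (1 <= self.signature_size <= self.n_genes):
            raise ValueError("signature_size must be in [1, n_genes]")
        seen: set[str] = set()
        for study_id, counts in self.study_design:
            total = 0
            for p, c in counts.items():
                if p not in self.phenotypes:
                    raise ValueError(
                        f"study '{study_id}' references unknown phenotype '{p}'"
                    )
                if not isinstance(c, int) or c < 0:
                    raise ValueError(
                        f"sample count for ('{study_id}', '{p}') must be a "
                        "non-negative integer"
                    )
                if c > 0:
                    seen.add(p)
                total += c
            if total == 0:
                raise ValueError(f"study '{study_id}' has no samples")
        missing = [p for p in self.phenotypes if p not in seen]
        if missing:
            raise ValueError(f"phenotype(s) with no samples: {', '.join(missing)}")
        for name in ("baseline_sd", "effect_sd", "study_effect_sd", "heterogeneity_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def _gene_ids(n_genes: int) -> tuple[str, ...]:
    width = max(4, len(str(n_genes)))
    return tuple(f"g{i + 1:0{width}d}" for i in range(n_genes))


def simulate(
    config: SimulationConfig,
) -> tuple[MultiStudyDataset, dict[str, frozenset[str]]]:
    """Draw one dataset and its ground-truth signatures from the same seed."""
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    genes = _gene_ids(G)
    phenos = config.phenotypes
    studies = [s for s, _ in config.study_design]

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=G)
    sign = rng.choice([-1.0, 1.0], size=G)

    # per-phenotype signature sets and effect vectors, in config order
    beta = np.zeros((G, len(phenos)))
    signatures: dict[str, frozenset[str]] = {}
    for pi, p in enumerate(phenos):
        members = np.sort(rng.choice(G, size=config.signature_size, replace=False))
        dev = rng.normal(0.0, config.effect_sd, size=config.signature_size)
        beta[members, pi] = sign[members] * (config.effect_size + dev)
        signatures[p] = frozenset(genes[g] for g in members)

    b_study = rng.normal(0.0, config.study_effect_sd, size=(G, len(studies)))
    eta = rng.normal(0.0, config.heterogeneity_sd, size=(G, len(studies), len(phenos)))
    # heterogeneity acts only on signature genes
    sig_mask = np.zeros((G, len(phenos)), dtype=bool)
    for pi, p in enumerate(phenos):
        idx = [i for i, g in enumerate(genes) if g in signatures[p]]
        sig_mask[idx, pi] = True

    sample_ids: list[str] = []
    annotations: list[SampleAnnotation] = []
    columns: list[np.ndarray] = []
    for si, (study_id, design) in enumerate(config.study_design):
        for pi, p in enumerate(phenos):
            count = design.get(p, 0)
            base = (
                mu
                + beta[:, pi]
                + b_study[:, si]
                + np.where(sig_mask[:, pi], eta[:, si, pi], 0.0)
            )
            for r in range(count):
                sid = f"{study_id}_{p}_s{r + 1:03d}"
                sample_ids.append(sid)
                annotations.append(SampleAnnotation(sid, study_id, p))
                columns.append(base + rng.normal(0.0, config.noise_sd, size=G))

    values = np.column_stack(columns)
    matrix = ExpressionMatrix(genes, tuple(sample_ids), values)
    return MultiStudyDataset(matrix, annotations), signatures


def simulate_dataset(config: SimulationConfig) -> MultiStudyDataset:
    """The dataset alone (see :func:`simulate`)."""
    return simulate(config)[0]


def ground_truth(config: SimulationConfig) -> dict[str, frozenset[str]]:
    """Per-phenotype signature gene sets realized for this config's seed.

    Signatures of different phenotypes are drawn independently, so they may
    overlap; disjointness is not guaranteed.
    """
    return simulate(config)[1]


# -- config file handling -------------------------------------------------

_FIELD_NAMES = tuple(f.name for f in dataclasses.fields(SimulationConfig))


def config_from_mapping(mapping: Mapping) -> SimulationConfig:
    """Build a config from a plain key-value mapping (e.g. parsed YAML).

    ``study_design`` is accepted as ``{study_id: {phenotype: count}}`` or as
    a list of ``[study_id, {phenotype: count}]`` pairs.
    """
    unknown = [k for k in mapping if k not in _FIELD_NAMES]
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    kwargs = dict(mapping)
    if "phenotypes" in kwargs:
        kwargs["phenotypes"] = tuple(kwargs["phenotypes"])
    if "study_design" in kwargs:
        sd = kwargs["study_design"]
        if isinstance(sd, Mapping):
            kwargs["study_design"] = tuple(
                (str(s), dict(d)) for s, d in sd.items()
            )
        else:
            kwargs["study_design"] = tuple((str(s), dict(d)) for s, d in sd)
    return SimulationConfig(**kwargs)


def config_to_mapping(config: SimulationConfig) -> dict:
    """Plain-data form of a config (JSON/YAML serializable)."""
    out = dataclasses.asdict(config)
    out["phenotypes"] = list(config.phenotypes)
    out["study_design"] = {s: dict(d) for s, d in config.study_design}
    return out


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML (or JSON, a YAML subset) simulation config file."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: config must be a key-value mapping")
    return config_from_mapping(data)
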