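import numpy as np
import pytest
from hypothesis import settings

from ccva import (
    ExpressionMatrix,
    MultiStudyDataset,
    SampleAnnotation,
    SimulationConfig,
    balanced_design,
    simulate_dataset,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def build_dataset(design, n_genes=20, seed=0, scale=1.0):
    """Small dataset with arbitrary study/phenotype layout and pure-noise
    values; design = {study: {phenotype: count}}."""
    rng = np.random.default_rng(seed)
    genes = tuple(f"g{i:03d}" for i in range(n_genes))
    sample_ids, anns = [], []
    for st, counts in design.items():
        for ph, c in counts.items():
            for r in range(c):
                sid = f"{st}_{ph}_{r}"
                sample_ids.append(sid)
                anns.append(SampleAnnotation(sid, st, ph))
    values = rng.normal(0, scale, size=(n_genes, len(sample_ids)))
    return MultiStudyDataset(ExpressionMatrix(genes, tuple(sample_ids), values), anns)


@pytest.fixture
def toy_dataset():
    """3 studies x 2 phenotypes, 20 genes, noise only."""
    return build_dataset(
        {
            "stA": {"ADC": 4, "NORM": 4},
            "stB": {"ADC": 3, "NORM": 5},
            "stC": {"ADC": 4, "NORM": 4},
        }
    )


@pytest.fixture
def signal_dataset():
    """Separable dataset: strong phenotype signal, no study-effects."""
    cfg = SimulationConfig(
        n_genes=60,
        phenotypes=("ADC", "NORM"),
        study_design=balanced_design(3, ("ADC", "NORM"), 6),
        signature_size=10,
        effect_size=3.0,
        study_effect_sd=0.0,
        heterogeneity_sd=0.0,
        noise_sd=0.5,
        seed=11,
    )
    return simulate_dataset(cfg)
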