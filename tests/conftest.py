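import numpy as np
import pandas as pd
import pytest

from sdmnstates import EffectSpec, StudyDesign, simulate_study
from sdmnstates.synthdata import make_fish_table, simulate_truth


@pytest.fixture(scope="session")
def design() -> StudyDesign:
    return StudyDesign()


@pytest.fixture(scope="session")
def null_effects(design) -> EffectSpec:
    return EffectSpec.null(design)


@pytest.fixture(scope="session")
def dataset(design):
    """One default simulated study (with curves), shared across tests."""
    return simulate_study(design=design, seed=11)


@pytest.fixture(scope="session")
def expression_from_truth(dataset):
    """Expression table taken directly from the latent truth (no qPCR noise)."""
    t = dataset.truth
    t = t.loc[t["gene"] != dataset.design.reference_gene].copy()
    t["relative_expression"] = np.exp(t["log_expression"])
    return t[
        ["fish_id", "dyad_id", "treatment", "nucleus", "gene", "relative_expression"]
    ].reset_index(drop=True)


def truth_expression_table(design, effects, seed) -> pd.DataFrame:
    """Fast path used by calibration studies: latent truth -> expression."""
    fish = make_fish_table(design, seed)
    truth = simulate_truth(design, effects, seed, fish)
    t = truth.loc[truth["gene"] != design.reference_gene].copy()
    t["relative_expression"] = np.exp(t["log_expression"])
    return t[
        ["fish_id", "dyad_id", "treatment", "nucleus", "gene", "relative_expression"]
    ].reset_index(drop=True)
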