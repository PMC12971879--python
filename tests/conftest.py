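import numpy as np
import pandas as pd
import pytest

from diet2gut import (
    CohortConfig,
    clr_transform,
    core_taxa,
    generate_cohort,
    to_relative,
)


@pytest.fixture(scope="session")
def cohort():
    """Default-sized synthetic cohort with the planted mediation chain."""
    cfg = CohortConfig(seed=7)
    metadata, intake, groups, maternal, infant, truth = generate_cohort(cfg)
    return {
        "config": cfg,
        "metadata": metadata,
        "intake": intake,
        "groups": groups,
        "maternal": maternal,
        "infant": infant,
        "truth": truth,
    }


def prep_clr(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts -> relative -> core filter -> CLR, as the pipeline does."""
    rel = to_relative(counts)
    return clr_transform(rel, core_taxa(rel))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
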