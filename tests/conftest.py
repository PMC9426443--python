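import numpy as np
import pytest

from dielflux.curves import fit_transcriptome
from dielflux.expression import (SyntheticTranscriptomeSpec,
                                 generate_synthetic_transcriptome)
from dielflux.toy import run_scenario, scenario

PHENOTYPE_SCENARIOS = ("wt_minimal", "wt_acetate", "sta6_minimal",
                       "sta6_acetate")


@pytest.fixture(scope="session")
def phenotype_runs():
    """48-h diel runs of the four genotype/medium scenario bundles."""
    return {name: run_scenario(scenario(name, hours=48.0))
            for name in PHENOTYPE_SCENARIOS}


@pytest.fixture(scope="session")
def small_fitted_transcriptome():
    """20 synthetic genes (mild noise) fitted against all families."""
    spec = SyntheticTranscriptomeSpec(n_genes=20, noise_cv=0.02, seed=11)
    series, truth = generate_synthetic_transcriptome(spec)
    ensembles = fit_transcriptome(series, n_restarts=8, seed=0)
    return series, truth, ensembles


@pytest.fixture(scope="session")
def wt_bundle():
    return scenario("wt_minimal", hours=24.0)
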