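import warnings

import numpy as np
import pytest

from fcstrat.config import PipelineConfig
from fcstrat.connectome import residualize, standardize_dataset
from fcstrat.pipeline import _covariates
from fcstrat.simulate import SimParams, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Planted-structure cohort at a small edge scale (20 ROIs, 190 edges)."""
    params = SimParams(
        n_roi=20, n_discovery=80, n_control=60, n_validation=10,
        n_sites=4, n_signal_edges=24, n_severe_marker_edges=12,
        n_mild_marker_edges=8, seed=11,
    )
    return generate_cohort(params)


@pytest.fixture(scope="session")
def discovery_matrix(small_cohort):
    """Standardized+residualized discovery-group edge matrix with subscales."""
    c = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = standardize_dataset(c.fc)
        data = residualize(data, _covariates(c.phenotypes).loc[data.subject_ids])
    disc_ids = c.phenotypes.loc[
        c.phenotypes["group_assignment"] == "discovery", "subject_id"
    ].tolist()
    disc = data.subset(disc_ids)
    pi = c.phenotypes.set_index("subject_id")
    sub = pi.loc[disc_ids, ["ados_comm", "ados_social", "ados_rrb"]].to_numpy(float)
    totals = pi.loc[disc_ids, "ados_total"].to_numpy(float)
    return disc, sub, totals


@pytest.fixture()
def cfg():
    return PipelineConfig(n_permutations=49, rng_seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
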