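"""Shared study conditions for the numbered analyses.

The cohort is regenerated deterministically from these parameters in each
script (generation takes well under a second), so no bulky connectivity
table needs to be stored; 01 additionally writes a file fixture for
inspection.
"""

import warnings
from pathlib import Path

from fcstrat.connectome import residualize, standardize_dataset
from fcstrat.pipeline import _covariates
from fcstrat.simulate import SimParams, generate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
SEED = 20260926

PARAMS = SimParams(n_roi=30, n_discovery=260, n_control=574,
                   n_validation=29, seed=SEED)


def cohort():
    return generate_cohort(PARAMS)


def prepared_data(c):
    """Standardized + covariate-residualized edge matrix for all subjects."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = standardize_dataset(c.fc)
        return residualize(data, _covariates(c.phenotypes).loc[data.subject_ids])
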