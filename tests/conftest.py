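import warnings

import pytest

from dehpkids import indices, quant, synth


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized synthetic cohort (41 obese + 31 controls), fixed seed."""
    return synth.generate_cohort(synth.SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def merged_cohort(default_cohort):
    """Cohort with normalized metabolites and insulin indices merged in."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        q = quant.process_cohort(default_cohort)
    idx = indices.indices_table(default_cohort)
    return q.merge(idx.drop(columns=["group"]), on="subject_id")
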