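"""Shared fixtures: phantom cohorts and co-aligned shape databases.

Everything is generated programmatically with fixed seeds; the expensive
cohort-level objects are session-scoped so the suite builds them once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from renalseg import metrics, phantom, preprocess
from renalseg import shape_prior as sp

warnings.filterwarnings("ignore", message="LCDG fit hit the subordinate budget")


@pytest.fixture(scope="session")
def small_cohort():
    """Six 48-cube phantom subjects at the default study conditions."""
    spec = phantom.PhantomSpec(seed=11, n_subjects=6)
    return phantom.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_db(small_cohort):
    """Shape database from the small cohort's preprocessed b0 scans."""
    train = [
        (preprocess.preprocess_volume(s.volumes[0]), t) for s, t in small_cohort
    ]
    return train, sp.build_shape_database(train, reference_id=0)


@pytest.fixture(scope="session")
def held_out_subject():
    """A phantom subject generated outside the small cohort's index range."""
    spec = phantom.PhantomSpec(seed=11, n_subjects=8)
    series, truth = phantom.generate_subject(spec, 7)
    b0 = preprocess.preprocess_volume(series.volumes[0])
    return series, truth, b0


@pytest.fixture(scope="session")
def adapted_prior(small_db, held_out_subject):
    train, db = small_db
    _, truth, b0 = held_out_subject
    field = sp.align_test(b0, db)
    prior = sp.adapt_shape_prior(b0, db, field=field)
    return prior, field, db


def pairwise_mean_dsc(maps) -> float:
    import itertools

    vals = [metrics.dsc(a, b) for a, b in itertools.combinations(maps, 2)]
    return float(np.mean(vals))
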