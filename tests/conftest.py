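import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from dmscape.ingest import StudyConfig, combine_studies, process_study
from dmscape.synthetic import StudySpec, SyntheticSpec, generate_landscape


def run_pipeline(spec):
    """Raw synthetic studies -> normalized -> combined ProfileSet (+ truth)."""
    tables, truth = generate_landscape(spec)
    normalized = [
        process_study(tab, StudyConfig(study_id=sid, gene=tab["gene"].iloc[0]))
        for sid, tab in tables.items()
    ]
    filtered, profiles = combine_studies(normalized)
    return filtered, profiles, truth


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def small_landscape(small_spec):
    """Default three-study synthetic landscape (600 positions before filtering)."""
    return run_pipeline(small_spec)


@pytest.fixture(scope="session")
def planted_landscape():
    """A 2,000-position landscape with planted archetypes (recovery tests)."""
    spec = SyntheticSpec(
        studies=(
            StudySpec("study_A", "geneA", scale=1.0, n_positions=700),
            StudySpec("study_B", "geneB", scale=2.5, n_positions=700),
            StudySpec("study_C", "geneC", scale=0.7, n_positions=600),
        ),
        seed=1,
    )
    return run_pipeline(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def truth_for(profiles, truth):
    """Planted archetype per retained position, aligned to the profile index."""
    t = truth.set_index(["study", "gene", "position", "wt_aa"])
    return t.loc[profiles.index]
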