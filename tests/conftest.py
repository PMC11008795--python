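import numpy as np
import pytest

from wormclock import synthetic as syn
from wormclock.behavior import ActivityTrace


@pytest.fixture(scope="session")
def small_cohort_config():
    return syn.CohortConfig(n_individuals=6, days_ld=4, days_dd=4, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    return syn.simulate_locomotor_cohort(small_cohort_config)


@pytest.fixture(scope="session")
def small_count_sim():
    cfg = syn.CountSimConfig(
        n_transcripts_per_category={
            "rhythmic_only": 20, "arrhythmic_only": 20, "both": 20,
            "none": 60, "desync_A": 25,
        },
        seed=29,
    )
    counts, lengths, design, truth = syn.simulate_count_matrix(cfg)
    return cfg, counts, lengths, design, truth


def make_trace(activity, dt_s=60.0, days_ld=1, days_dd=0, light_h=16,
               individual_id="w1"):
    """Build a trace with standard LD->DD annotation from an activity array."""
    activity = np.asarray(activity, float)
    time_s = np.arange(activity.size) * dt_s
    hod = (time_s / 3600.0) % 24.0
    in_ld = time_s < days_ld * 86400
    light = np.where(in_ld & (hod < light_h), "L", "D").astype(object)
    phase = np.where(in_ld, "LD", "DD").astype(object)
    return ActivityTrace(individual_id, time_s, activity, light, phase)


@pytest.fixture
def trace_factory():
    return make_trace


TOY_OBO = """format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: neuronal signaling
namespace: biological_process
is_a: GO:0000001 ! root process

[Term]
id: GO:0000003
name: synaptic transmission
namespace: biological_process
is_a: GO:0000002 ! neuronal signaling

[Term]
id: GO:0000004
name: metabolic process
namespace: biological_process
is_a: GO:0000001 ! root process

[Term]
id: GO:0000008
name: molecular widget
namespace: molecular_function

[Term]
id: GO:0000009
name: outdated process
namespace: biological_process
is_obsolete: true
"""


@pytest.fixture
def toy_obo_path(tmp_path):
    p = tmp_path / "toy.obo"
    p.write_text(TOY_OBO)
    return p
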