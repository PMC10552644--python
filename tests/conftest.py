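import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from psorqsp import activity, vpop

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_patients():
    spec = vpop.reference_trial_spec(30)
    patients = vpop.generate_population(spec, seed=42)
    return vpop.assign_comorbidities(
        patients, vpop.default_comorbidities(), seed=43
    )


@pytest.fixture(scope="session")
def grouped_activity():
    """Activity matrix with 3 planted mechanistic groups, two arms."""
    spec = vpop.reference_trial_spec(60)
    patients = vpop.generate_population(spec, seed=7)
    scenario = activity.MechanisticScenario(n_groups=3, effect_shift=0.5,
                                            noise_sd=0.1)
    definition = activity.synthetic_definition(30, seed=1)
    exposures = pd.DataFrame(
        [{"patient_id": p.id, "arm": arm, "exposure": expo}
         for p in patients for arm, expo in (("czp200", 20.0), ("czp400", 40.0))]
    )
    groups = activity.assign_groups(patients, scenario, seed=11)
    matrix = activity.generate_activity(patients, exposures, definition,
                                        scenario, seed=13, groups=groups)
    truth = np.array([groups[m.rsplit("_", 1)[0]] for m in matrix.values.index])
    return matrix, truth, patients
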