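import numpy as np
import pytest

from beenose import (
    DecisionTable,
    FeatureVector,
    GeneratorConfig,
    build_decision_table,
    generate_study,
)


@pytest.fixture(scope="session")
def default_study():
    """Full synthetic study under the default stated world (160 objects)."""
    return generate_study(GeneratorConfig.default(seed=11))


@pytest.fixture(scope="session")
def table_m1_wooden(default_study):
    """Option-I analogue: M1 device, wooden insert, no baseline correction."""
    return build_decision_table(default_study, "M1", "wooden", baseline_correct=False)


@pytest.fixture
def noiseless_config():
    return GeneratorConfig.default(seed=0, noise_sd=0.0)


def random_table(rng, n_rows=12, classes=(1, 5, 6, 7)):
    """Small random decision table for oracle-equivalence tests."""
    rows = []
    for i in range(n_rows):
        rows.append(
            FeatureVector(
                descriptors=rng.normal(0.0, 3.0, 6),
                class_label=int(rng.choice(classes)),
                object_id=f"r{i}",
                device="M1",
                insert="wooden",
            )
        )
    return DecisionTable(rows=rows)
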