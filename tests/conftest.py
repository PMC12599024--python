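import pytest
from hypothesis import settings

from glymal import apply_edits, builtin_m4_edits, builtin_table1_scenarios, load_ecoli_core

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def core_model():
    return load_ecoli_core()


@pytest.fixture(scope="session")
def m4_model(core_model):
    return apply_edits(core_model, builtin_m4_edits())


@pytest.fixture(scope="session")
def table1_scenarios():
    return builtin_table1_scenarios()


@pytest.fixture(scope="session")
def scenario_by_label(table1_scenarios):
    def get(label, grade, scale):
        for sc in table1_scenarios:
            if (sc.label, sc.glycerol_grade, sc.scale) == (label, grade, scale):
                return sc
        raise KeyError((label, grade, scale))

    return get
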