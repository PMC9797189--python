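import numpy as np
import pytest

from pappus import synthetic as syn
from pappus import survival as sv
from pappus import weather as w


@pytest.fixture(scope="session")
def gen_cfg():
    return syn.GeneratorConfig(seed=101)


@pytest.fixture(scope="session")
def weather_ds(gen_cfg):
    return w.filter_records(syn.gen_weather(gen_cfg), provenance="synthetic")


@pytest.fixture(scope="session")
def wind_split(weather_ds):
    dry, wet = w.split(weather_ds)
    return {"dry": dry, "wet": wet}


@pytest.fixture(scope="session")
def assays(gen_cfg):
    return syn.gen_detachment_assays(gen_cfg)


@pytest.fixture(scope="session")
def assays_by_condition(assays):
    return {
        cond: [a for a in assays if a.condition == cond] for cond in ("dry", "wet")
    }


@pytest.fixture(scope="session")
def detach_fits(assays_by_condition):
    return {
        cond: sv.fit_parametric(group)
        for cond, group in assays_by_condition.items()
    }
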