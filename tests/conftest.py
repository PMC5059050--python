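from datetime import date, timedelta

import pytest
from hypothesis import HealthCheck, settings

import rxpersist as rx
from rxpersist.pipeline import tables_from_simulation

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

BASE = date(2006, 1, 1)


def mk_fill(day, tablets, text="1 tablet daily", atc="C03AA03", pid="p1",
            strength=25.0, unit_bag=False):
    return rx.DispensingRecord(
        patient_id=pid,
        fill_date=BASE + timedelta(days=day),
        atc_code=atc,
        tablets=tablets,
        strength_mg=strength,
        dosage_text=text,
        unit_bag=unit_bag,
    )


def schedule_for(fills):
    parses = [rx.parse_dosage(f.dosage_text) for f in fills]
    return rx.build_supply_schedule(fills, parses)


@pytest.fixture(scope="session")
def small_sim():
    cfg = rx.SimulationConfig(n_patients=400, seed=7)
    return rx.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_result(small_sim):
    return rx.analyze(tables_from_simulation(small_sim), rx.StudyConfig())
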