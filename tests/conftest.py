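import pytest

from efrailch.records_io import Hospitalization, IndicatorPanel


def make_panel(
    cognition=(0, 0, 0, 0),
    functional=(0, 0, 0, 0),
    continence=(0, 0),
    performance=(0, 0, 0, 0, 0),
    exhaustion=0,
    mood_disorder_code=0,
):
    return IndicatorPanel(
        cognition=tuple(cognition),
        functional=tuple(functional),
        continence=tuple(continence),
        performance=tuple(performance),
        exhaustion=exhaustion,
        mood_disorder_code=mood_disorder_code,
    )


def make_record(
    episode_id="E1",
    age=72.0,
    gender="woman",
    admitted_from="home",
    discharged_to="home",
    length_of_stay=5,
    marital_status="married",
    residence="home",
    n_codes=1,
    n_medications_admission=2,
    n_medications_discharge=2,
    admission_panel=None,
    discharge_panel="same",
    fim_total=None,
    **kw,
):
    adm = admission_panel if admission_panel is not None else make_panel()
    dis = adm if discharge_panel == "same" else discharge_panel
    if discharged_to == "died":
        dis = None
    return Hospitalization(
        episode_id=episode_id,
        age=age,
        gender=gender,
        admitted_from=admitted_from,
        discharged_to=discharged_to,
        length_of_stay=length_of_stay,
        marital_status=marital_status,
        residence=residence,
        n_codes=n_codes,
        n_medications_admission=n_medications_admission,
        n_medications_discharge=n_medications_discharge,
        admission_panel=adm,
        discharge_panel=dis,
        fim_total=fim_total,
        **kw,
    )


@pytest.fixture
def small_cohort():
    """Deterministic 200-episode cohort shared across tests."""
    from efrailch.cohortgen import CohortGenParams, generate_cohort

    return generate_cohort(CohortGenParams(n_episodes=200, seed=42))
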