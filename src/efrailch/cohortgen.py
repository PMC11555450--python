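"""Synthetic hospital-register cohorts for exercising the frailty pipeline.

The real registry behind the instrument (a Swiss multisite acute-care
hospital, 2015-2017) is private, so this module generates cohorts with the
statistical structure the analysis assumes and ships the published score
distributions and demographic marginals as fixtures for desk-scale checks.

Generative model. Each episode carries a single continuous latent frailty
factor on the instrument's own 0-12 scale,

    f_adm ~ Normal(latent_mean_admission, latent_sd),
    f_dis = f_adm + DRIFT_GAIN * discharge_drift + Normal(0, drift_noise_sd),

and every dimension's indicators are ordinal cuts of a per-dimension
propensity p_d = clip(f_phase / 12 + eps_d, 0, 1) with independent noise
eps_d ~ Normal(0, dimension_noise_sd) shared across phases. Binary
dimensions are parameterized so that P(dimension scores 1) = p_d exactly;
the two 3-level clustered dimensions cut p_d at 1/3 and 2/3. The FIM total
at discharge is a decreasing affine function of the discharge latent plus
Gaussian noise, clipped to [18, 126]. Nutrition fields are set missing at
the configured (very high) rates; died episodes lack discharge panels and
FIM. All draws come from one seed via named substreams, so regenerating a
cohort with the same parameters is byte-identical.

``discharge_drift`` is expressed in score points: DRIFT_GAIN converts it to
the latent scale and was calibrated once by simulation at the default
parameters so that the scored mean admission->discharge difference equals
the configured drift (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional

import numpy as np

from .records_io import Hospitalization, IndicatorPanel
from .validate import ScoreDistribution

__all__ = [
    "CohortGenParams",
    "generate_cohort",
    "table3_fixture",
    "table1_marginals",
    "DRIFT_GAIN",
]

#: latent-scale units per score point of configured drift; frozen one-time
#: calibration at the default parameters (see docs/methods.md).
DRIFT_GAIN = 1.33

_SUBSTREAMS = {
    "latent": 0,
    "death": 1,
    "demographics": 2,
    "cognition": 3,
    "functional": 4,
    "medication": 5,
    "mood": 6,
    "continence": 7,
    "performance": 8,
    "general_health": 9,
    "social": 10,
    "fim": 11,
    "nutrition": 12,
    "los": 13,
}


@dataclass(frozen=True)
class CohortGenParams:
    """Generator configuration; defaults are the study conditions.

    ``discharge_drift`` is in e-Frail-CH score points; age, proportions and
    nutrition missingness default to the published cohort marginals.
    ``death_latent_coupling`` (log-odds of death per latent point above the
    mean) is 0 by default: death is sampled independently of frailty.
    ``dimension_noise_sd`` controls how tightly the dimensions share the
    single latent factor (0 = perfectly one-dimensional).
    """

    n_episodes: int
    seed: int = 0
    latent_mean_admission: float = 4.55
    latent_sd: float = 2.0
    discharge_drift: float = 0.45
    death_rate: float = 0.0492
    death_latent_coupling: float = 0.0
    nutrition_missing_admission: float = 0.927
    nutrition_missing_discharge: float = 0.838
    age_mean: float = 78.4
    age_sd: float = 7.9
    prop_women: float = 0.5218
    prop_home_admission: float = 0.6852
    fim_noise_sd: float = 6.0
    dimension_noise_sd: float = 0.15
    drift_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.n_episodes < 1:
            raise ValueError("n_episodes must be >= 1")
        if self.latent_sd <= 0 or self.fim_noise_sd <= 0:
            raise ValueError("scale parameters must be positive")
        for name in (
            "death_rate",
            "nutrition_missing_admission",
            "nutrition_missing_discharge",
            "prop_women",
            "prop_home_admission",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @classmethod
    def from_file(cls, path, n_episodes: Optional[int] = None) -> "CohortGenParams":
        """Read parameters from a flat ``key = value`` file (# comments)."""
        kv = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        typed = {}
        for f in fields(cls):
            if f.name in kv:
                typed[f.name] = (int if f.type == "int" else float)(kv[f.name])
        if n_episodes is not None:
            typed["n_episodes"] = n_episodes
        unknown = set(kv) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**typed)


def _rng(params: CohortGenParams, name: str) -> np.random.Generator:
    return np.random.default_rng([int(params.seed) % (2**31), _SUBSTREAMS[name]])


def _propensity(latent: np.ndarray, eps: np.ndarray) -> np.ndarray:
    return np.clip(latent / 12.0 + eps, 0.0, 1.0)


def _cut3(p: np.ndarray) -> np.ndarray:
    return (p > 1.0 / 3.0).astype(int) + (p > 2.0 / 3.0).astype(int)


# Representative indicator combinations per score category and phase for the
# two clustered 3-level dimensions; every listed combination maps back to
# its category under the built-in scoring conditions.
_COG_COMBOS = {
    "admission": {
        0: [(0, 0, 0, 0)],
        1: [(0, 0, 1, 1)],
        2: [(1, 0, 0, 0), (0, 1, 0, 0), (1, 1, 1, 1), (2, 1, 1, 1), (2, 2, 2, 2)],
    },
    "discharge": {
        0: [(0, 0, 0, 0)],
        1: [(0, 1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1)],
        2: [(1, 0, 0, 0), (0, 1, 1, 0), (0, 0, 2, 0), (1, 1, 1, 1), (2, 2, 1, 1)],
    },
}
_FUN_COMBOS = {
    "admission": {
        0: [(0, 0, 0, 0)],
        1: [(0, 1, 0, 0), (1, 1, 0, 0)],
        2: [(2, 1, 0, 0), (0, 0, 1, 1), (1, 1, 1, 1), (2, 2, 2, 2), (1, 2, 1, 0)],
    },
    "discharge": {
        0: [(0, 0, 0, 0)],
        1: [(1, 0, 0, 0), (2, 0, 0, 0), (0, 1, 0, 0), (0, 2, 0, 0)],
        2: [(1, 1, 0, 0), (1, 0, 1, 0), (0, 1, 0, 1), (2, 2, 2, 1), (1, 1, 1, 1)],
    },
}


def _pick_combos(cat: np.ndarray, table: dict, rng: np.random.Generator) -> np.ndarray:
    """Map score categories to indicator rows, sampling within-category variety."""
    out = np.zeros((len(cat), len(table[0][0])), dtype=int)
    for level, combos in table.items():
        idx = np.flatnonzero(cat == level)
        if len(idx) == 0:
            continue
        choice = rng.integers(0, len(combos), size=len(idx))
        arr = np.asarray(combos, dtype=int)
        out[idx] = arr[choice]
    return out


def generate_cohort(params: CohortGenParams) -> list[Hospitalization]:
    """Generate ``params.n_episodes`` synthetic hospitalization episodes."""
    n = params.n_episodes
    f_adm = _rng(params, "latent").normal(
        params.latent_mean_admission, params.latent_sd, size=n
    )
    drift_rng = np.random.default_rng(
        [int(params.seed) % (2**31), 100]
    )
    f_dis = (
        f_adm
        + DRIFT_GAIN * params.discharge_drift
        + drift_rng.normal(0.0, params.drift_noise_sd, size=n)
    )

    death_rng = _rng(params, "death")
    if params.death_latent_coupling == 0.0:
        died = death_rng.random(n) < params.death_rate
    else:
        base = np.log(params.death_rate / (1.0 - params.death_rate))
        logit = base + params.death_latent_coupling * (
            f_adm - params.latent_mean_admission
        )
        died = death_rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    # demographics
    demo = _rng(params, "demographics")
    age = demo.normal(params.age_mean, params.age_sd, size=n)
    for _ in range(100):  # resample below the >=65 inclusion bound
        under = age < 65
        if not under.any():
            break
        age[under] = demo.normal(params.age_mean, params.age_sd, size=int(under.sum()))
    age = np.maximum(age, 65.0)
    woman = demo.random(n) < params.prop_women
    from_home = demo.random(n) < params.prop_home_admission
    to_home = demo.random(n) < 0.661  # home share among surviving discharges
    los_rng = _rng(params, "los")
    los = np.maximum(
        1, np.rint(los_rng.lognormal(np.log(8.0), 0.92, size=n)).astype(int)
    )

    def dim(name: str):
        rng = _rng(params, name)
        eps = rng.normal(0.0, params.dimension_noise_sd, size=n)
        return rng, _propensity(f_adm, eps), _propensity(f_dis, eps)

    cog_rng, p_cog_a, p_cog_d = dim("cognition")
    cog_adm = _pick_combos(_cut3(p_cog_a), _COG_COMBOS["admission"], cog_rng)
    cog_dis = _pick_combos(_cut3(p_cog_d), _COG_COMBOS["discharge"], cog_rng)

    fun_rng, p_fun_a, p_fun_d = dim("functional")
    fun_adm = _pick_combos(_cut3(p_fun_a), _FUN_COMBOS["admission"], fun_rng)
    fun_dis = _pick_combos(_cut3(p_fun_d), _FUN_COMBOS["discharge"], fun_rng)

    con_rng, p_con_a, p_con_d = dim("continence")
    q_a = 1.0 - np.sqrt(1.0 - p_con_a)  # P(any of 2 flags) = p
    q_d = 1.0 - np.sqrt(1.0 - p_con_d)
    con_adm = (con_rng.random((n, 2)) < q_a[:, None]).astype(int)
    con_dis = (con_rng.random((n, 2)) < q_d[:, None]).astype(int)

    per_rng, p_per_a, p_per_d = dim("performance")
    q_a = 1.0 - (1.0 - p_per_a) ** 0.2  # P(any of 5 flags) = p
    q_d = 1.0 - (1.0 - p_per_d) ** 0.2
    per_adm = (per_rng.random((n, 5)) < q_a[:, None]).astype(int)
    per_dis = (per_rng.random((n, 5)) < q_d[:, None]).astype(int)

    mood_rng, p_mood_a, p_mood_d = dim("mood")
    q_a = 1.0 - np.sqrt(1.0 - p_mood_a)
    q_d = 1.0 - np.sqrt(1.0 - p_mood_d)
    mood_adm = (mood_rng.random((n, 2)) < q_a[:, None]).astype(int)
    mood_dis = (mood_rng.random((n, 2)) < q_d[:, None]).astype(int)

    med_rng, p_med_a, p_med_d = dim("medication")
    poly_a = med_rng.random(n) < p_med_a
    poly_d = med_rng.random(n) < p_med_d
    meds_a = np.where(
        poly_a, 5 + med_rng.poisson(3.0, size=n), med_rng.integers(0, 5, size=n)
    )
    meds_d = np.where(
        poly_d, 5 + med_rng.poisson(3.0, size=n), med_rng.integers(0, 5, size=n)
    )

    # static dimensions: derived from the admission latent, identical at
    # both phases (code counts are fixed at discharge; marital status and
    # residence do not change within a stay)
    gh_rng = _rng(params, "general_health")
    r = _propensity(f_adm, gh_rng.normal(0.0, params.dimension_noise_sd, size=n))
    gh_cat = (r > 0.08).astype(int) + (r > 0.22).astype(int)
    n_codes = np.where(
        gh_cat == 0, 1, np.where(gh_cat == 1, 2, 3 + gh_rng.poisson(4.0, size=n))
    )

    soc_rng = _rng(params, "social")
    v = _propensity(f_adm, soc_rng.normal(0.0, 0.2, size=n))
    soc_cat = (v > 0.30).astype(int) + (v > 0.62).astype(int)
    soc_pick = soc_rng.integers(0, 2, size=n)
    _SOC = {
        0: [("married", "home"), ("married", "home")],
        1: [("divorced", "home"), ("single", "home")],
        2: [("widowed", "nursing_home"), ("widowed", "home")],
    }

    fim_rng = _rng(params, "fim")
    fim = np.rint(
        126.0 - 8.0 * f_dis + fim_rng.normal(0.0, params.fim_noise_sd, size=n)
    )
    fim = np.clip(fim, 18, 126).astype(int)

    nut_rng = _rng(params, "nutrition")
    nut_obs_a = nut_rng.random(n) >= params.nutrition_missing_admission
    nut_obs_d = nut_rng.random(n) >= params.nutrition_missing_discharge
    nut_a = (nut_rng.random(n) < 0.3 * p_per_a).astype(int)
    nut_d = (nut_rng.random(n) < 0.3 * p_per_d).astype(int)

    records = []
    for i in range(n):
        adm_panel = IndicatorPanel(
            cognition=tuple(int(x) for x in cog_adm[i]),
            functional=tuple(int(x) for x in fun_adm[i]),
            continence=tuple(int(x) for x in con_adm[i]),
            performance=tuple(int(x) for x in per_adm[i]),
            exhaustion=int(mood_adm[i, 0]),
            mood_disorder_code=int(mood_adm[i, 1]),
        )
        if died[i]:
            dis_panel = None
        else:
            dis_panel = IndicatorPanel(
                cognition=tuple(int(x) for x in cog_dis[i]),
                functional=tuple(int(x) for x in fun_dis[i]),
                continence=tuple(int(x) for x in con_dis[i]),
                performance=tuple(int(x) for x in per_dis[i]),
                exhaustion=int(mood_dis[i, 0]),
                mood_disorder_code=int(mood_dis[i, 1]),
            )
        marital, residence = _SOC[int(soc_cat[i])][int(soc_pick[i])]
        records.append(
            Hospitalization(
                episode_id=f"E{i:06d}",
                age=round(float(age[i]), 1),
                gender="woman" if woman[i] else "man",
                admitted_from="home" if from_home[i] else "health_care_setting",
                discharged_to=(
                    "died"
                    if died[i]
                    else ("home" if to_home[i] else "health_care_setting")
                ),
                length_of_stay=int(los[i]),
                marital_status=marital,
                residence=residence,
                n_codes=int(n_codes[i]),
                n_medications_admission=int(meds_a[i]),
                n_medications_discharge=None if died[i] else int(meds_d[i]),
                admission_panel=adm_panel,
                discharge_panel=dis_panel,
                fim_total=None if died[i] else int(fim[i]),
                nutrition_weight_loss_admission=(
                    int(nut_a[i]) if nut_obs_a[i] else None
                ),
                nutrition_weight_loss_discharge=(
                    int(nut_d[i]) if (nut_obs_d[i] and not died[i]) else None
                ),
            )
        )
    return records


# -------------------------------------------------------------- fixtures --

_TABLE3_ADMISSION = (268, 1040, 5078, 6871, 7297, 6546, 5438, 4373, 3436, 2670, 1878, 1488, 360)
_TABLE3_DISCHARGE = (226, 782, 2784, 6710, 7350, 6664, 5766, 5249, 3900, 2677, 2008, 2511, 734)


def table3_fixture() -> tuple[ScoreDistribution, ScoreDistribution]:
    """The published score distributions: counts over scores 0-12 at
    admission (n=46,743) and discharge (n=47,361)."""
    return (
        ScoreDistribution(counts=_TABLE3_ADMISSION, phase="admission"),
        ScoreDistribution(counts=_TABLE3_DISCHARGE, phase="discharge"),
    )


def table1_marginals() -> dict:
    """Published sociodemographic marginals of the source register
    (N=53,690 hospitalizations), for generator calibration and report
    comparison."""
    return {
        "n_hospitalizations": 53_690,
        "men": 25_672,
        "women": 28_018,
        "age_mean": 78.37,
        "age_sd": 7.91,
        "age_median": 78,
        "age_iqr": (72, 84),
        "age_range": (65, 106),
        "admitted_from_home": 36_792,
        "admitted_from_health_care_setting": 16_898,
        "discharged_home": 33_738,
        "discharged_health_care_setting": 17_306,
        "died_in_hospital": 2_646,
        "length_of_stay_mean": 12.26,
        "length_of_stay_sd": 16.5,
        "length_of_stay_median": 8,
        "length_of_stay_iqr": (4, 15),
        "length_of_stay_range": (1, 1316),
    }
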