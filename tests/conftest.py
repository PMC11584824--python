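import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import epitraj as et

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def toy_codes() -> et.CodeListConfig:
    return et.CodeListConfig(
        exposure_codes={"F32", "F41", "F43"},
        outcome_groups={c: {c} for c in ("I10", "I20", "I21", "I48", "I50", "I63")},
        acute_event_codes={"I21", "I63"},
    )


def codes_for(cfg: et.SimulationConfig) -> et.CodeListConfig:
    return et.CodeListConfig(exposure_codes=set(cfg.exposure_codes),
                             outcome_groups={c: {c} for c in cfg.codes})


def run_cohort(cfg: et.SimulationConfig, outcome: str, seed: int | None = None,
               reuse: bool = True):
    """Simulate -> ascertain -> exclude -> match -> follow-up for one outcome."""
    seed = cfg.seed if seed is None else seed
    parts, diags = et.generate_cohort(cfg)
    codes = codes_for(cfg)
    emap = et.ascertain_exposure(diags, codes)
    exposed, _ = et.apply_exclusions(emap, diags, parts, codes)
    fcvd = et.first_event_date(diags, codes.cvd_any_codes)
    matched, _ = et.incidence_density_match(exposed, parts, emap, fcvd,
                                            ratio=5, seed=seed,
                                            reuse_across_sets=reuse)
    fu = et.build_followup(matched, diags, parts, codes, outcome, emap)
    return parts, diags, codes, emap, exposed, matched, fu


@pytest.fixture(scope="session")
def small_cohort():
    """One modest simulated cohort with a real exposure effect, shared."""
    cfg = et.SimulationConfig(n_individuals=8000, exposure_log_hr=np.log(1.6),
                              seed=11)
    parts, diags = et.generate_cohort(cfg)
    return cfg, parts, diags


@pytest.fixture()
def toy_events():
    rows = [
        # person, code, vocabulary, date, source
        ("p01", "F32", "ICD10", "2001-05-01", "primary_care"),
        ("p01", "F32", "ICD10", "2003-02-01", "inpatient_primary"),
        ("p02", "F41", "ICD10", "2005-07-20", "self_report"),
        ("p03", "I10", "ICD10", "2002-03-03", "inpatient_primary"),
        ("p04", "F43", "ICD10", "2010-01-01", "inpatient_secondary"),
        ("p05", "I21", "ICD10", "2004-04-04", "inpatient_primary"),
        ("p06", "F32", "ICD10", "2007-09-09", "primary_care"),
        ("p06", "I10", "ICD10", "2006-01-01", "inpatient_primary"),
        ("p07", "I50", "ICD10", "2001-01-01", "inpatient_secondary"),
        ("p08", "XYZ", "SNOMED", "2001-01-01", "primary_care"),
    ]
    df = pd.DataFrame(rows, columns=["person_id", "code", "vocabulary",
                                     "date", "source"])
    df["date"] = pd.to_datetime(df["date"])
    return df
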