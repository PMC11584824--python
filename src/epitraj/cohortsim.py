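"""Synthetic registry-style cohort simulation.

Generates the two tables the analysis pipeline consumes — a participant table
and a long diagnosis-event table — from an event-driven multistate model.
Each person carries piecewise-constant competing exponential hazards for:
onset of the psychiatric exposure, first occurrence of each cardiovascular
disease group, death, and loss to follow-up.  The hazard of disease ``d`` at
time ``t`` is

    baseline_rate(d) * exp( exposure_log_hr(d) * I[psych onset <= t]
                            + sum_i progression_log_or(i, d) * I[disease i <= t]
                            + covariate, family-history and PRS terms
                            + modification term * I[exposed] * modifier )

so exposure effects, planted disease-progression chains and effect
modification are all generative quantities that downstream estimators can be
checked against.  Time runs in days inside a fixed calendar window; only the
first occurrence of each disease is recorded, and death/loss truncate the
record.  Output is reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

DEFAULT_WINDOW = ("1997-01-01", "2019-12-31")
DEFAULT_EXPOSURE_CODES = ("F32", "F41", "F43")
# psychiatric diagnoses are ascertained from all sources; disease outcomes
# are hospitalizations, so their records carry inpatient sources only
DEFAULT_EXPOSURE_SOURCE_PROBS = {
    "inpatient_primary": 0.10,
    "inpatient_secondary": 0.05,
    "primary_care": 0.60,
    "self_report": 0.25,
}
DEFAULT_DISEASE_SOURCE_PROBS = {
    "inpatient_primary": 0.65,
    "inpatient_secondary": 0.35,
}


@dataclass(frozen=True)
class DiseaseDef:
    """One grouped disease outcome (3-digit ICD-10-like label)."""

    code: str
    baseline_rate: float  # first-occurrence events per person-year

    def __post_init__(self):
        if self.baseline_rate <= 0:
            raise ValueError(f"baseline_rate must be > 0 for {self.code}")


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic cohort.

    Rates are events per person-year; log effects are natural-log hazard
    ratios.  ``progression_log_or_matrix[i, j]`` is the log effect of having
    had disease ``i`` on the hazard of disease ``j`` (zero diagonal).
    ``modification_log_hr`` is the per-disease interaction of exposure with
    the modifier (family history by default); zero means no effect
    modification.
    """

    n_individuals: int = 50_000
    calendar_window: tuple[str, str] = DEFAULT_WINDOW
    psych_onset_rate: float = 0.008
    disease_defs: list[DiseaseDef] = field(
        default_factory=lambda: [DiseaseDef("I10", 0.015), DiseaseDef("I20", 0.004),
                                 DiseaseDef("I21", 0.003), DiseaseDef("I48", 0.004),
                                 DiseaseDef("I50", 0.002), DiseaseDef("I63", 0.002)]
    )
    exposure_log_hr: dict[str, float] | float = 0.0
    progression_log_or_matrix: np.ndarray | None = None
    covariate_effects: dict[str, dict[str, float] | float] = field(default_factory=dict)
    family_history_prevalence: float = 0.556
    family_history_log_hr: float = np.log(1.3)
    prs_log_hr_per_sd: dict[str, float] | float = np.log(1.3)
    modification_log_hr: dict[str, float] | float = 0.0
    modifier: str = "family_history"  # or "prs"
    death_rate: float = 0.005
    loss_rate: float = 0.002
    prs_missing_rate: float = 0.2719
    female_fraction: float = 0.65
    birth_year_range: tuple[int, int] = (1937, 1970)
    exposure_codes: tuple[str, ...] = DEFAULT_EXPOSURE_CODES
    exposure_source_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPOSURE_SOURCE_PROBS))
    disease_source_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISEASE_SOURCE_PROBS))
    seed: int = 0

    # -- derived helpers ----------------------------------------------------

    @property
    def codes(self) -> list[str]:
        return [d.code for d in self.disease_defs]

    def _per_disease(self, value) -> np.ndarray:
        codes = self.codes
        if isinstance(value, dict):
            return np.array([float(value.get(c, 0.0)) for c in codes])
        return np.full(len(codes), float(value))

    def progression_matrix(self) -> np.ndarray:
        d = len(self.disease_defs)
        if self.progression_log_or_matrix is None:
            return np.zeros((d, d))
        m = np.asarray(self.progression_log_or_matrix, dtype=float)
        if m.shape != (d, d):
            raise ValueError(f"progression matrix must be {d}x{d}")
        if np.any(np.diag(m) != 0):
            raise ValueError("progression matrix must have a zero diagonal")
        return m

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        start, end = pd.Timestamp(self.calendar_window[0]), pd.Timestamp(self.calendar_window[1])
        if end <= start:
            raise ValueError("calendar window is empty")
        for name, r in (("psych_onset_rate", self.psych_onset_rate),
                        ("death_rate", self.death_rate),
                        ("loss_rate", self.loss_rate)):
            if r < 0:
                raise ValueError(f"{name} must be >= 0")
        codes = self.codes
        if len(set(codes)) != len(codes):
            raise ValueError("disease codes must be unique")
        self.progression_matrix()
        if self.modifier not in ("family_history", "prs"):
            raise ValueError("modifier must be 'family_history' or 'prs'")

    def to_dict(self) -> dict:
        m = self.progression_matrix()
        return {
            "n_individuals": self.n_individuals,
            "calendar_window": list(self.calendar_window),
            "psych_onset_rate": self.psych_onset_rate,
            "disease_defs": [[d.code, d.baseline_rate] for d in self.disease_defs],
            "exposure_log_hr": self._per_disease(self.exposure_log_hr).tolist(),
            "progression_log_or_matrix": m.tolist(),
            "family_history_prevalence": self.family_history_prevalence,
            "family_history_log_hr": self.family_history_log_hr,
            "prs_log_hr_per_sd": self._per_disease(self.prs_log_hr_per_sd).tolist(),
            "modification_log_hr": self._per_disease(self.modification_log_hr).tolist(),
            "modifier": self.modifier,
            "death_rate": self.death_rate,
            "loss_rate": self.loss_rate,
            "prs_missing_rate": self.prs_missing_rate,
            "female_fraction": self.female_fraction,
            "birth_year_range": list(self.birth_year_range),
            "seed": self.seed,
        }


def planted_trajectory_config(
    chain: list[str],
    strength: float,
    *,
    baseline_rate: float = 0.0018,
    exposure_log_hr: float = np.log(2.0),
    extra_diseases: list[DiseaseDef] | None = None,
    **overrides,
) -> SimulationConfig:
    """Config whose progression matrix plants a directed disease chain.

    Consecutive chain pairs get log-odds ``strength``; every other entry is
    zero.  Chain diseases also receive a positive exposure effect so that the
    chain is discoverable downstream of the exposure.
    """
    if len(chain) < 2:
        raise ValueError("chain needs at least 2 diseases")
    if len(set(chain)) != len(chain):
        raise ValueError("duplicate diseases in chain")
    defs = [DiseaseDef(c, baseline_rate) for c in chain] + list(extra_diseases or [])
    codes = [d.code for d in defs]
    m = np.zeros((len(codes), len(codes)))
    for a, b in zip(chain[:-1], chain[1:]):
        m[codes.index(a), codes.index(b)] = strength
    cfg = SimulationConfig(
        disease_defs=defs,
        exposure_log_hr={c: exposure_log_hr for c in chain},
        progression_log_or_matrix=m,
        **overrides,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

_EDU = (["university", "high_school", "middle_school", "unknown"], [0.44, 0.12, 0.28, 0.16])
_ETH = (["white", "other", "unknown"], [0.894, 0.100, 0.006])
_SMK = (["never", "previous", "current", "unknown"], [0.567, 0.316, 0.111, 0.006])
_BMI = (["<18.5", "18.5-25", "25-30", ">30", "unknown"], [0.006, 0.353, 0.402, 0.233, 0.006])


def _categorical(rng, n, spec):
    cats, p = spec
    return np.asarray(cats, dtype=object)[rng.choice(len(cats), size=n, p=p)]


def generate_cohort(config: SimulationConfig):
    """Simulate the cohort; returns ``(participants, diagnoses)`` DataFrames.

    Participant columns: person_id, sex, birth_year, tdi, education,
    ethnicity, smoking, bmi_category, cci, history_other_psych,
    family_history_cvd, prs_<code> per disease, death_date, loss_date.
    Diagnosis columns: person_id, code, vocabulary, date, source.
    """
    config.validate()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))
    n = config.n_individuals
    codes = config.codes
    D = len(codes)
    start = pd.Timestamp(config.calendar_window[0])
    end = pd.Timestamp(config.calendar_window[1])
    horizon = float((end - start).days)

    # --- fixed covariates --------------------------------------------------
    female = rng.random(n) < config.female_fraction
    birth_year = rng.integers(config.birth_year_range[0],
                              config.birth_year_range[1] + 1, size=n)
    tdi = rng.standard_normal(n)
    fh = rng.random(n) < config.family_history_prevalence
    prs = rng.standard_normal((n, D))
    history_other_psych = rng.random(n) < 0.05
    cci = rng.choice([0, 1, 2], size=n, p=[0.995, 0.003, 0.002])

    # --- linear predictors (per person x disease, time-invariant part) -----
    beta_prs = config._per_disease(config.prs_log_hr_per_sd)
    base_lp = np.zeros((n, D))
    base_lp += np.log([d.baseline_rate for d in config.disease_defs])[None, :]
    base_lp += fh[:, None] * config.family_history_log_hr
    base_lp += prs * beta_prs[None, :]
    cov_values = {
        "sex_female": female.astype(float),
        "tdi": tdi,
        "birth_year_c": (birth_year - 1950) / 10.0,
    }
    for cov, eff in config.covariate_effects.items():
        if cov not in cov_values:
            raise ValueError(f"unknown covariate {cov!r} in covariate_effects")
        base_lp += cov_values[cov][:, None] * config._per_disease(eff)[None, :]

    exp_lhr = config._per_disease(config.exposure_log_hr)
    mod_lhr = config._per_disease(config.modification_log_hr)
    modifier = fh.astype(float) if config.modifier == "family_history" else prs
    if config.modifier == "family_history":
        exposure_mult = np.exp(exp_lhr[None, :] + mod_lhr[None, :] * modifier[:, None])
    else:  # per-disease PRS modifies its own disease's exposure effect
        exposure_mult = np.exp(exp_lhr[None, :] + mod_lhr[None, :] * modifier)
    prog = np.exp(config.progression_matrix())

    rate_dis = np.exp(base_lp) / DAYS_PER_YEAR  # per-day first-occurrence hazards
    for name, arr in (("baseline hazards", rate_dis), ("exposure multipliers", exposure_mult)):
        if not np.all(np.isfinite(arr)):
            bad = codes[int(np.argmax(~np.isfinite(arr).all(axis=0)))]
            raise ValueError(f"non-finite {name} (overflow) for disease {bad!r}")

    # --- event-driven simulation in vectorized rounds ----------------------
    t = np.zeros(n)
    active = np.ones(n, dtype=bool)
    exposed = np.zeros(n, dtype=bool)
    exposure_day = np.full(n, np.nan)
    disease_day = np.full((n, D), np.nan)
    death_day = np.full(n, np.nan)
    loss_day = np.full(n, np.nan)
    psych_rate = config.psych_onset_rate / DAYS_PER_YEAR
    death_rate = config.death_rate / DAYS_PER_YEAR
    loss_rate = config.loss_rate / DAYS_PER_YEAR

    while np.any(active):
        idx = np.flatnonzero(active)
        r_dis = rate_dis[idx]
        r_psych = np.where(exposed[idx], 0.0, psych_rate)
        cols = np.column_stack([
            r_dis,
            r_psych,
            np.full(idx.size, death_rate),
            np.full(idx.size, loss_rate),
        ])
        total = cols.sum(axis=1)
        # with zero total hazard nothing can happen: censor administratively
        zero = total <= 0
        if np.any(zero):
            z = idx[zero]
            active[z] = False
            idx = idx[~zero]
            if idx.size == 0:
                continue
            cols = cols[~zero]
            total = total[~zero]
        dt = rng.exponential(1.0, size=idx.size) / total
        t_new = t[idx] + dt
        over = t_new > horizon
        censored = idx[over]
        active[censored] = False
        idx = idx[~over]
        if idx.size == 0:
            continue
        t_new = t_new[~over]
        cols = cols[~over]
        total = total[~over]
        t[idx] = t_new

        u = rng.random(idx.size) * total
        choice = (u[:, None] >= np.cumsum(cols, axis=1)).sum(axis=1)
        choice = np.minimum(choice, D + 2)

        for d in range(D):
            who = idx[choice == d]
            if who.size:
                disease_day[who, d] = t[who]
                rate_dis[who, d] = 0.0
                rate_dis[who] *= prog[d][None, :]
        who = idx[choice == D]  # psychiatric onset
        if who.size:
            exposed[who] = True
            exposure_day[who] = t[who]
            rate_dis[who] *= exposure_mult[who]
        who = idx[choice == D + 1]
        if who.size:
            death_day[who] = t[who]
            active[who] = False
        who = idx[choice == D + 2]
        if who.size:
            loss_day[who] = t[who]
            active[who] = False

    # --- assemble tables ----------------------------------------------------
    width = len(str(n))
    person_id = np.array([f"P{i:0{width}d}" for i in range(1, n + 1)], dtype=object)

    def _dates(days):
        out = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
        ok = ~np.isnan(days)
        out[ok] = start + pd.to_timedelta(np.floor(days[ok]).astype(int), unit="D")
        return out

    participants = pd.DataFrame({
        "person_id": person_id,
        "sex": np.where(female, "female", "male"),
        "birth_year": birth_year,
        "tdi": tdi,
        "education": _categorical(rng, n, _EDU),
        "ethnicity": _categorical(rng, n, _ETH),
        "smoking": _categorical(rng, n, _SMK),
        "bmi_category": _categorical(rng, n, _BMI),
        "cci": cci,
        "history_other_psych": history_other_psych,
        "family_history_cvd": fh,
        "death_date": _dates(death_day),
        "loss_date": _dates(loss_day),
    })
    miss = rng.random(n) < config.prs_missing_rate
    for j, c in enumerate(codes):
        col = prs[:, j].copy()
        col[miss] = np.nan
        participants[f"prs_{c}"] = col

    def _sources(probs: dict[str, float], size: int) -> np.ndarray:
        names = list(probs)
        p = np.array([probs[s] for s in names], dtype=float)
        return np.asarray(names, dtype=object)[rng.choice(len(names), size=size,
                                                          p=p / p.sum())]

    recs = []
    pi, di = np.nonzero(~np.isnan(disease_day))
    for i, d in zip(pi, di):
        recs.append((person_id[i], codes[d], disease_day[i, d]))
    n_dis = len(recs)
    exp_idx = np.flatnonzero(~np.isnan(exposure_day))
    exp_codes = rng.choice(len(config.exposure_codes), size=exp_idx.size)
    for k, i in enumerate(exp_idx):
        recs.append((person_id[i], config.exposure_codes[exp_codes[k]], exposure_day[i]))
    diagnoses = pd.DataFrame(recs, columns=["person_id", "code", "day"])
    diagnoses["vocabulary"] = "ICD10"
    diagnoses["date"] = start + pd.to_timedelta(
        np.floor(diagnoses["day"].to_numpy()).astype(int), unit="D")
    diagnoses["source"] = np.concatenate([
        _sources(config.disease_source_probs, n_dis),
        _sources(config.exposure_source_probs, len(diagnoses) - n_dis),
    ])
    diagnoses = (diagnoses.drop(columns="day")
                 [["person_id", "code", "vocabulary", "date", "source"]]
                 .sort_values(["person_id", "date", "code"], kind="mergesort")
                 .reset_index(drop=True))
    return participants, diagnoses


def crude_incidence(participants: pd.DataFrame, diagnoses: pd.DataFrame,
                    code: str, calendar_window=DEFAULT_WINDOW) -> float:
    """First-occurrence incidence of ``code`` per person-year at risk."""
    start = pd.Timestamp(calendar_window[0])
    end = pd.Timestamp(calendar_window[1])
    first = (diagnoses[diagnoses["code"] == code]
             .groupby("person_id")["date"].min())
    p = participants.set_index("person_id")
    stop = pd.Series(end, index=p.index)
    for c in ("death_date", "loss_date"):
        stop = stop.where(~(p[c].notna() & (p[c] < stop)), p[c])
    stop = stop.where(~(first.reindex(p.index).notna()
                        & (first.reindex(p.index) < stop)),
                      first.reindex(p.index))
    days = (stop - start).dt.days.clip(lower=0).sum()
    return float(len(first) / (days / DAYS_PER_YEAR))


def write_cohort(participants: pd.DataFrame, diagnoses: pd.DataFrame,
                 outdir, config: SimulationConfig | None = None,
                 sep: str = "\t") -> None:
    """Write the two tables plus a provenance sidecar recording the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    participants.to_csv(outdir / "participants.tsv", sep=sep, index=False)
    diagnoses.to_csv(outdir / "diagnoses.tsv", sep=sep, index=False)
    if config is not None:
        (outdir / "provenance.json").write_text(
            json.dumps({"seed": config.seed, "config": config.to_dict()}, indent=2)
            + "\n")
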