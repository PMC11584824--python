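"""Cohort construction: ascertainment, exclusions, matching, follow-up.

Implements an incidence-density matched cohort design on long-format
participant and diagnosis tables.  Each person first diagnosed with an
exposure condition (anxiety/depression/stress-related codes) becomes an index
patient at that diagnosis date; up to ``m`` unexposed comparators are sampled
at the index date from people matched on sex, deprivation quartile and birth
year (+/- 2 years) who are alive, in follow-up, exposure-free and free of any
studied outcome at that date.  A person may serve as a comparator before
later becoming exposed; comparator follow-up is additionally censored at
their own first exposure diagnosis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

KNOWN_VOCABULARIES = {"ICD10", "ICD9", "Read", "self_report"}
ADMIN_END = pd.Timestamp("2019-12-31")
_FAR = 10**9  # sentinel day meaning "never"


def _norm3(code: str) -> str:
    """Normalize a diagnosis code to its 3-character (ICD-10 chapter) form."""
    return str(code).strip().upper().replace(".", "")[:3]


@dataclass
class CodeListConfig:
    """Code lists mapping diagnosis codes to exposure / outcome groups."""

    exposure_codes: set[str]
    outcome_groups: dict[str, set[str]]
    acute_event_codes: set[str] = field(default_factory=set)
    cvd_any_codes: set[str] | None = None
    primary_only: bool = False

    def __post_init__(self):
        self.exposure_codes = {_norm3(c) for c in self.exposure_codes}
        self.outcome_groups = {g: {_norm3(c) for c in cs}
                               for g, cs in self.outcome_groups.items()}
        self.acute_event_codes = {_norm3(c) for c in self.acute_event_codes}
        seen: dict[str, str] = {}
        for g, cs in self.outcome_groups.items():
            for c in cs:
                if c in seen:
                    raise ValueError(
                        f"code {c} appears in outcome groups {seen[c]!r} and {g!r}")
                seen[c] = g
        if self.cvd_any_codes is None:
            self.cvd_any_codes = set(seen)
        else:
            self.cvd_any_codes = {_norm3(c) for c in self.cvd_any_codes}

    @classmethod
    def from_yaml(cls, path) -> "CodeListConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            exposure_codes=set(raw["exposure_codes"]),
            outcome_groups={g: set(cs) for g, cs in raw["outcome_groups"].items()},
            acute_event_codes=set(raw.get("acute_event_codes", [])),
            cvd_any_codes=set(raw["cvd_any_codes"]) if "cvd_any_codes" in raw else None,
            primary_only=bool(raw.get("primary_only", False)),
        )


@dataclass
class FlowCounts:
    """Participant-flow bookkeeping: identified - sum(excluded) = final."""

    identified: int
    excluded: dict[str, int] = field(default_factory=dict)
    pre_exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def final(self) -> int:
        return self.identified - sum(self.excluded.values())

    def to_dict(self) -> dict:
        return {"identified": self.identified, "excluded": dict(self.excluded),
                "pre_exclusions": dict(self.pre_exclusions), "final": self.final}


@dataclass
class MatchStats:
    """Bookkeeping for an incidence-density matching run."""

    n_exposed_sets: int
    ratio: int
    n_controls: int = 0
    n_full_sets: int = 0
    n_short_sets: int = 0
    n_empty_sets: int = 0

    @property
    def requested_controls(self) -> int:
        return self.n_exposed_sets * self.ratio


# ---------------------------------------------------------------------------
# ascertainment
# ---------------------------------------------------------------------------


def _filter_known_vocab(events: pd.DataFrame) -> pd.DataFrame:
    known = events["vocabulary"].isin(KNOWN_VOCABULARIES)
    n_bad = int((~known).sum())
    if n_bad:
        warnings.warn(f"skipping {n_bad} records with unknown vocabulary",
                      stacklevel=3)
        log.warning("skipped %d diagnosis records with unknown vocabulary", n_bad)
    return events[known]


def ascertain_exposure(events: pd.DataFrame, codes: CodeListConfig) -> pd.Series:
    """Earliest qualifying exposure diagnosis date per person (all sources)."""
    ev = _filter_known_vocab(events)
    hit = ev["code"].map(_norm3).isin(codes.exposure_codes)
    return ev[hit].groupby("person_id")["date"].min()


def first_event_date(events: pd.DataFrame, codeset: set[str],
                     primary_only: bool = False) -> pd.Series:
    """First date per person with a code in ``codeset`` (inpatient outcomes).

    Outcome ascertainment uses hospital inpatient records; when
    ``primary_only`` is set only primary inpatient diagnoses count
    (the sensitivity definition).
    """
    ev = events
    if primary_only:
        ev = ev[ev["source"] == "inpatient_primary"]
    else:
        ev = ev[ev["source"].isin(["inpatient_primary", "inpatient_secondary"])]
    hit = ev["code"].map(_norm3).isin(codeset)
    return ev[hit].groupby("person_id")["date"].min()


def compute_tdi_quartiles(tdi: pd.Series, cut_points=None) -> pd.Series:
    """Ordinal deprivation quartile (1..4) from empirical or pinned cuts."""
    if cut_points is None:
        cut_points = tdi.quantile([0.25, 0.5, 0.75]).to_numpy()
    cuts = np.asarray(cut_points, dtype=float)
    q = np.searchsorted(cuts, tdi.to_numpy(dtype=float), side="left") + 1
    return pd.Series(np.where(tdi.isna(), np.nan, q), index=tdi.index)


def apply_exclusions(
    exposure_map: pd.Series,
    events: pd.DataFrame,
    participants: pd.DataFrame,
    codes: CodeListConfig,
) -> tuple[pd.DataFrame, FlowCounts]:
    """Exclusions before matching; emits the participant-flow record.

    Persons with missing deprivation score are dropped before the exposed
    cohort is counted as "identified"; persons with any studied outcome code
    strictly before their index date are then excluded.  Returns
    ``(exposed_cohort, flow)`` where the cohort has person_id + index_date.
    """
    p = participants.set_index("person_id")
    n_candidates = len(exposure_map)
    has_tdi = exposure_map.index.isin(p.index[p["tdi"].notna()])
    identified = exposure_map[has_tdi]
    first_cvd = first_event_date(events, codes.cvd_any_codes, codes.primary_only)
    fc = first_cvd.reindex(identified.index)
    prior = fc.notna() & (fc < identified)
    final = identified[~prior]
    flow = FlowCounts(
        identified=len(identified),
        excluded={"prior_cvd": int(prior.sum())},
        pre_exclusions={"candidates": n_candidates,
                        "missing_tdi": int((~has_tdi).sum())},
    )
    if len(final) == 0:
        warnings.warn("exposed cohort is empty after exclusions", stacklevel=2)
    out = final.rename("index_date").rename_axis("person_id").reset_index()
    return out.sort_values("person_id").reset_index(drop=True), flow


# ---------------------------------------------------------------------------
# incidence-density matching
# ---------------------------------------------------------------------------


def _days(dates: pd.Series, index) -> np.ndarray:
    d = dates.reindex(index)
    out = np.full(len(index), _FAR, dtype=np.int64)
    ok = d.notna().to_numpy()
    out[ok] = d[ok].to_numpy().astype("datetime64[D]").astype(np.int64)
    return out


def incidence_density_match(
    exposed_cohort: pd.DataFrame,
    participants: pd.DataFrame,
    exposure_map: pd.Series,
    first_cvd: pd.Series,
    ratio: int = 5,
    seed: int = 0,
    tdi_cut_points=None,
    reuse_across_sets: bool = True,
) -> tuple[pd.DataFrame, MatchStats]:
    """Sample up to ``ratio`` matched comparators per exposed person.

    Matching: same sex, same deprivation quartile, birth year within +/- 2.
    Eligibility at the index date: exposure-free, outcome-free, alive and
    uncensored.  Sampling is uniform without replacement within a set; by
    default a person may be reused across sets and may later become exposed.
    With ``reuse_across_sets=False`` each person serves as comparator at most
    once (matched sets are then disjoint, so Wald inference treats strata as
    independent exactly); either way a past comparator may still become an
    exposed index patient later.
    Returns a long table (set_id, person_id, exposed, index_date) plus stats;
    sets with no eligible comparator are emitted empty and logged.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    p = participants.reset_index(drop=True)
    pid = p["person_id"].to_numpy()
    pos_of = pd.Series(np.arange(len(p)), index=pid)

    sex = pd.factorize(p["sex"])[0]
    quart = compute_tdi_quartiles(p["tdi"], tdi_cut_points).to_numpy()
    by = p["birth_year"].to_numpy(dtype=np.int64)
    exp_day = _days(exposure_map, pid)
    cvd_day = _days(first_cvd, pid)
    death_day = _days(p.set_index("person_id")["death_date"], pid)
    loss_day = _days(p.set_index("person_id")["loss_date"], pid)

    # composite bucket key: (sex, quartile, birth year) packed into one int
    ok_pool = ~np.isnan(quart)
    comp = np.full(len(p), -1, dtype=np.int64)
    comp[ok_pool] = ((sex[ok_pool].astype(np.int64) * 8
                      + quart[ok_pool].astype(np.int64)) * 100_000
                     + by[ok_pool])
    order = np.argsort(comp, kind="stable")
    comp_sorted = comp[order]
    uniq, starts = np.unique(comp_sorted, return_index=True)
    ends = np.append(starts[1:], len(comp_sorted))
    buckets = {int(k): order[a:b] for k, a, b in zip(uniq, starts, ends) if k >= 0}

    ex = exposed_cohort.sort_values("person_id").reset_index(drop=True)
    rows_set, rows_pid, rows_exp = [], [], []
    index_dates = []
    used = np.zeros(len(p), dtype=bool)
    stats = MatchStats(n_exposed_sets=len(ex), ratio=ratio)
    for set_id, (person, idx_date) in enumerate(
            zip(ex["person_id"], ex["index_date"]), start=1):
        i = int(pos_of[person])
        t = np.int64(pd.Timestamp(idx_date).to_datetime64().astype("datetime64[D]").astype(np.int64))
        base = (int(sex[i]) * 8 + int(quart[i])) * 100_000 + int(by[i])
        cand_list = [buckets.get(base + db) for db in range(-2, 3)]
        cand = np.concatenate([c for c in cand_list if c is not None]) \
            if any(c is not None for c in cand_list) else np.empty(0, dtype=int)
        if cand.size:
            ok = ((exp_day[cand] > t) & (cvd_day[cand] > t)
                  & (death_day[cand] > t) & (loss_day[cand] > t)
                  & (cand != i))
            if not reuse_across_sets:
                ok &= ~used[cand]
            elig = cand[ok]
        else:
            elig = cand
        if elig.size > ratio:
            chosen = np.sort(rng.choice(elig, size=ratio, replace=False))
        else:
            chosen = np.sort(elig)
        if chosen.size == 0:
            stats.n_empty_sets += 1
            log.info("set %d (%s): no eligible comparators", set_id, person)
        elif chosen.size < ratio:
            stats.n_short_sets += 1
        else:
            stats.n_full_sets += 1
        stats.n_controls += int(chosen.size)
        if not reuse_across_sets:
            used[chosen] = True
        members = np.concatenate([[i], chosen])
        rows_set.extend([set_id] * len(members))
        rows_pid.extend(pid[members])
        rows_exp.extend([True] + [False] * len(chosen))
        index_dates.extend([idx_date] * len(members))

    matched = pd.DataFrame({
        "set_id": np.asarray(rows_set, dtype=np.int64),
        "person_id": rows_pid,
        "exposed": np.asarray(rows_exp, dtype=bool),
        "index_date": pd.to_datetime(index_dates),
    })
    return matched, stats


def validate_matched_sets(matched: pd.DataFrame, participants: pd.DataFrame,
                          exposure_map: pd.Series, first_cvd: pd.Series,
                          tdi_cut_points=None) -> None:
    """Assert every emitted set satisfies the matching invariants."""
    p = participants.set_index("person_id")
    quart = compute_tdi_quartiles(p["tdi"], tdi_cut_points)
    m = matched.merge(
        pd.DataFrame({"sex": p["sex"], "quart": quart, "by": p["birth_year"],
                      "death": p["death_date"], "loss": p["loss_date"]}),
        left_on="person_id", right_index=True)
    m["exp_date"] = m["person_id"].map(exposure_map)
    m["cvd_date"] = m["person_id"].map(first_cvd)
    for _, g in m.groupby("set_id"):
        e = g[g["exposed"]].iloc[0]
        c = g[~g["exposed"]]
        assert (c["sex"] == e["sex"]).all()
        assert (c["quart"] == e["quart"]).all()
        assert (c["by"] - e["by"]).abs().le(2).all()
        t = e["index_date"]
        assert (c["exp_date"].isna() | (c["exp_date"] > t)).all()
        assert (c["cvd_date"].isna() | (c["cvd_date"] > t)).all()
        assert (c["death"].isna() | (c["death"] > t)).all()
        assert (c["loss"].isna() | (c["loss"] > t)).all()


# ---------------------------------------------------------------------------
# follow-up intervals
# ---------------------------------------------------------------------------


def build_followup(
    matched: pd.DataFrame,
    events: pd.DataFrame,
    participants: pd.DataFrame,
    codes: CodeListConfig,
    outcome_group: str,
    exposure_map: pd.Series | None = None,
    admin_end: pd.Timestamp = ADMIN_END,
) -> pd.DataFrame:
    """One at-risk interval per set member for one outcome group.

    Follow-up runs from the index date to the earliest of: first outcome
    diagnosis (event), death, loss to follow-up, administrative end, and —
    for unexposed comparators only — their own first exposure diagnosis.
    Members with the outcome strictly before index leave that outcome's risk
    set; if the exposed member leaves, the whole set is dropped.  A same-day
    outcome (or censoring) is kept as a half-day interval so stop > start.
    """
    if outcome_group == "any_cvd":
        codeset = codes.cvd_any_codes
    elif outcome_group == "acute_events":
        codeset = codes.acute_event_codes
    else:
        codeset = codes.outcome_groups[outcome_group]
    if exposure_map is None:
        exposure_map = ascertain_exposure(events, codes)
    first_out = first_event_date(events, codeset, codes.primary_only)

    m = matched.reset_index(drop=True)
    pid = m["person_id"]
    t0 = m["index_date"].to_numpy().astype("datetime64[D]").astype(np.int64)
    out_day = _days(first_out, pid)
    exp_day = _days(exposure_map, pid)
    p = participants.set_index("person_id")
    death_day = _days(p["death_date"], pid)
    loss_day = _days(p["loss_date"], pid)
    end_day = np.int64(admin_end.to_datetime64().astype("datetime64[D]").astype(np.int64))
    exposed = m["exposed"].to_numpy(dtype=bool)

    prior = out_day < t0
    censor = np.minimum.reduce([death_day, loss_day,
                                np.full(len(m), end_day)])
    censor = np.where(exposed, censor, np.minimum(censor, exp_day))
    event = (~prior) & (out_day != _FAR) & (out_day <= censor)
    stop_day = np.where(event, out_day, censor)

    keep = ~prior
    # drop whole sets whose exposed member has a prior outcome
    bad_sets = set(m.loc[prior & exposed, "set_id"])
    if bad_sets:
        keep &= ~m["set_id"].isin(bad_sets).to_numpy()
    # drop sets that end up without any comparator
    df = pd.DataFrame({
        "set_id": m["set_id"], "person_id": pid, "exposed": exposed,
        "start": 0.0, "stop": np.maximum((stop_day - t0).astype(float), 0.5),
        "event": event, "outcome_group": outcome_group,
    })[keep]
    sizes = df.groupby("set_id")["exposed"].agg(["size", "sum"])
    good = sizes.index[(sizes["size"] > 1) & (sizes["sum"] == 1)]
    dropped = len(sizes) - len(good)
    if dropped:
        log.info("build_followup(%s): dropped %d singleton/invalid sets",
                 outcome_group, dropped)
    return df[df["set_id"].isin(good)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# covariate design
# ---------------------------------------------------------------------------


@dataclass
class AdjustmentSet:
    """Named covariate adjustment cascade entry."""

    label: str
    covariates: list[str]


CATEGORICAL = {"education": "university", "ethnicity": "white",
               "smoking": "never", "bmi_category": "18.5-25", "sex": "female"}

ADJUSTMENT_CASCADE = [
    AdjustmentSet("model1", ["sex", "birth_year", "tdi", "ethnicity", "education"]),
    AdjustmentSet("model2", ["sex", "birth_year", "tdi", "ethnicity", "education",
                             "bmi_category", "smoking", "history_other_psych", "cci"]),
    AdjustmentSet("model3", ["sex", "birth_year", "tdi", "ethnicity", "education",
                             "bmi_category", "smoking", "history_other_psych", "cci",
                             "family_history_cvd"]),
]


def build_design(intervals: pd.DataFrame, participants: pd.DataFrame,
                 adjustment: AdjustmentSet | None) -> tuple[pd.DataFrame, list[str]]:
    """Attach numerically-coded covariate columns to interval rows.

    Categorical covariates are dummy-coded against a fixed reference level
    with 'unknown' kept as its own level; booleans become 0/1; birth_year is
    centered.  Returns the augmented frame and the model column names
    (exposure first).
    """
    cols = ["exposed"]
    df = intervals.copy()
    df["exposed"] = df["exposed"].astype(float)
    if adjustment is None:
        return df, cols
    p = participants.set_index("person_id")
    for cov in adjustment.covariates:
        v = df["person_id"].map(p[cov])
        if cov in CATEGORICAL:
            ref = CATEGORICAL[cov]
            for level in sorted(set(p[cov].dropna().unique()) - {ref}):
                name = f"{cov}[{level}]"
                df[name] = (v == level).astype(float)
                cols.append(name)
        elif cov == "birth_year":
            df[cov] = (v - 1950.0) / 10.0
            cols.append(cov)
        else:
            df[cov] = v.astype(float)
            cols.append(cov)
    return df, cols
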