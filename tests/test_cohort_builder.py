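"""Ascertainment, exclusions, incidence-density matching and follow-up."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import epitraj as et
from conftest import codes_for, run_cohort, toy_codes


class TestAscertainExposure:
    def test_earliest_date_across_sources(self, toy_events):
        emap = et.ascertain_exposure(toy_events, toy_codes())
        assert emap["p01"] == pd.Timestamp("2001-05-01")

    def test_person_with_only_outcome_codes_absent(self, toy_events):
        emap = et.ascertain_exposure(toy_events, toy_codes())
        assert "p03" not in emap.index and "p05" not in emap.index

    def test_toy_map_matches_exhaustive_scan(self, toy_events):
        emap = et.ascertain_exposure(toy_events, toy_codes())
        # independent oracle: scan every row by hand
        expected = {}
        for _, r in toy_events.iterrows():
            if r.vocabulary in ("ICD10", "ICD9", "Read", "self_report") \
                    and r.code[:3] in {"F32", "F41", "F43"}:
                cur = expected.get(r.person_id)
                expected[r.person_id] = min(cur, r.date) if cur is not None else r.date
        assert dict(emap) == expected
        assert len(emap) == 4

    def test_unknown_vocabulary_warned_and_skipped(self, toy_events):
        bad = toy_events.copy()
        bad.loc[bad.person_id == "p02", "vocabulary"] = "OPCS"
        with pytest.warns(UserWarning, match="unknown vocabulary"):
            emap = et.ascertain_exposure(bad, toy_codes())
        assert "p02" not in emap.index


def _participants(ids, **overrides):
    n = len(ids)
    base = dict(
        person_id=ids, sex=["female"] * n, birth_year=[1950] * n,
        tdi=np.zeros(n), education=["university"] * n, ethnicity=["white"] * n,
        smoking=["never"] * n, bmi_category=["18.5-25"] * n, cci=[0] * n,
        history_other_psych=[False] * n, family_history_cvd=[False] * n,
        death_date=[pd.NaT] * n, loss_date=[pd.NaT] * n)
    base.update(overrides)
    df = pd.DataFrame(base)
    for c in ("death_date", "loss_date"):
        df[c] = pd.to_datetime(df[c])
    return df


class TestApplyExclusions:
    def test_flow_identity_and_prior_cvd_exclusion(self, toy_events):
        parts = _participants([f"p{i:02d}" for i in range(1, 9)])
        emap = et.ascertain_exposure(toy_events, toy_codes())
        cohort, flow = et.apply_exclusions(emap, toy_events, parts, toy_codes())
        # p06 has I10 (2006) strictly before exposure (2007) -> excluded
        assert flow.identified - sum(flow.excluded.values()) == flow.final
        assert flow.excluded["prior_cvd"] == 1
        assert set(cohort.person_id) == {"p01", "p02", "p04"}

    def test_same_day_outcome_retained(self):
        events = pd.DataFrame({
            "person_id": ["a", "a"], "code": ["F32", "I10"],
            "vocabulary": ["ICD10", "ICD10"],
            "date": pd.to_datetime(["2005-06-01", "2005-06-01"]),
            "source": ["primary_care", "inpatient_primary"]})
        parts = _participants(["a"])
        emap = et.ascertain_exposure(events, toy_codes())
        cohort, flow = et.apply_exclusions(emap, events, parts, toy_codes())
        assert list(cohort.person_id) == ["a"]
        assert flow.excluded["prior_cvd"] == 0

    def test_missing_tdi_dropped_before_identification(self, toy_events):
        parts = _participants([f"p{i:02d}" for i in range(1, 9)],
                              tdi=[np.nan] + [0.0] * 7)
        emap = et.ascertain_exposure(toy_events, toy_codes())
        cohort, flow = et.apply_exclusions(emap, toy_events, parts, toy_codes())
        assert flow.pre_exclusions["missing_tdi"] == 1
        assert "p01" not in set(cohort.person_id)

    def test_all_prior_cvd_yields_empty_cohort_with_warning(self):
        events = pd.DataFrame({
            "person_id": ["a", "a"], "code": ["I10", "F32"],
            "vocabulary": ["ICD10"] * 2,
            "date": pd.to_datetime(["2001-01-01", "2005-01-01"]),
            "source": ["inpatient_primary", "primary_care"]})
        parts = _participants(["a"])
        emap = et.ascertain_exposure(events, toy_codes())
        with pytest.warns(UserWarning, match="empty"):
            cohort, flow = et.apply_exclusions(emap, events, parts, toy_codes())
        assert cohort.empty and flow.final == 0


class TestIncidenceDensityMatch:
    def _pool(self):
        # 20 unexposed candidates + 1 exposed; 6 candidates eligible by
        # sex/quartile/birth-year; others fail one criterion each
        ids = [f"c{i:02d}" for i in range(20)] + ["x"]
        sex = ["female"] * 7 + ["male"] * 13 + ["female"]
        by = [1950, 1951, 1952, 1949, 1948, 1950, 1960] + [1950] * 13 + [1950]
        tdi = [0.0] * 6 + [9.0] + [0.0] * 13 + [0.0]
        parts = _participants(ids, sex=sex, birth_year=by, tdi=tdi)
        return parts

    def test_eligible_set_matches_brute_force(self):
        parts = self._pool()
        exposed = pd.DataFrame({"person_id": ["x"],
                                "index_date": [pd.Timestamp("2005-01-01")]})
        emap = pd.Series({"x": pd.Timestamp("2005-01-01")})
        fcvd = pd.Series(dtype="datetime64[ns]")
        matched, stats = et.incidence_density_match(
            exposed, parts, emap, fcvd, ratio=5, seed=0)
        controls = set(matched.loc[~matched.exposed, "person_id"])
        # brute-force eligibility: female, same empirical TDI quartile as x,
        # |birth year - 1950| <= 2, unexposed/alive/uncensored/outcome-free
        quart = et.compute_tdi_quartiles(parts.set_index("person_id")["tdi"])
        qx = quart["x"]
        eligible = {
            r.person_id for r in parts.itertuples()
            if r.person_id != "x" and r.sex == "female"
            and abs(r.birth_year - 1950) <= 2 and quart[r.person_id] == qx
        }
        assert len(eligible) == 6
        assert len(controls) == 5 and controls <= eligible
        assert stats.n_short_sets == 0 and stats.n_full_sets == 1

    def test_no_same_sex_candidates_gives_empty_set(self):
        parts = _participants(["x", "m1", "m2"], sex=["female", "male", "male"])
        exposed = pd.DataFrame({"person_id": ["x"],
                                "index_date": [pd.Timestamp("2005-01-01")]})
        emap = pd.Series({"x": pd.Timestamp("2005-01-01")})
        matched, stats = et.incidence_density_match(
            exposed, parts, emap, pd.Series(dtype="datetime64[ns]"), 5, seed=0)
        assert stats.n_empty_sets == 1
        assert (~matched.exposed).sum() == 0

    def test_deterministic_under_seed(self, small_cohort):
        cfg, parts, diags = small_cohort
        codes = codes_for(cfg)
        emap = et.ascertain_exposure(diags, codes)
        exposed, _ = et.apply_exclusions(emap, diags, parts, codes)
        fcvd = et.first_event_date(diags, codes.cvd_any_codes)
        m1, _ = et.incidence_density_match(exposed, parts, emap, fcvd, 5, seed=4)
        m2, _ = et.incidence_density_match(exposed, parts, emap, fcvd, 5, seed=4)
        pd.testing.assert_frame_equal(m1, m2)

    def test_all_emitted_sets_satisfy_matching_invariants(self, small_cohort):
        cfg, parts, diags = small_cohort
        codes = codes_for(cfg)
        emap = et.ascertain_exposure(diags, codes)
        exposed, _ = et.apply_exclusions(emap, diags, parts, codes)
        fcvd = et.first_event_date(diags, codes.cvd_any_codes)
        matched, _ = et.incidence_density_match(exposed, parts, emap, fcvd, 5, seed=4)
        from epitraj.cohort import validate_matched_sets
        validate_matched_sets(matched, parts, emap, fcvd)

    def test_control_may_later_become_exposed(self, small_cohort):
        """Incidence-density principle: control service before own exposure."""
        cfg, parts, diags = small_cohort
        codes = codes_for(cfg)
        emap = et.ascertain_exposure(diags, codes)
        exposed, _ = et.apply_exclusions(emap, diags, parts, codes)
        fcvd = et.first_event_date(diags, codes.cvd_any_codes)
        matched, _ = et.incidence_density_match(exposed, parts, emap, fcvd, 5, seed=4)
        ctrl = matched[~matched.exposed].copy()
        ctrl["exp_date"] = ctrl.person_id.map(emap)
        later_exposed = ctrl[ctrl.exp_date.notna()]
        assert len(later_exposed) > 0
        assert (later_exposed.exp_date > later_exposed.index_date).all()


class TestBuildFollowup:
    def _toy(self):
        parts = _participants(
            ["e1", "c1", "c2", "e2", "c3", "c4"],
            death_date=[pd.NaT, pd.NaT, "2010-06-15", pd.NaT, pd.NaT, pd.NaT],
            loss_date=[pd.NaT] * 5 + ["2012-01-01"])
        events = pd.DataFrame({
            "person_id": ["e1", "c1", "c1", "e2", "c4"],
            "code": ["F32", "F41", "I10", "F43", "I10"],
            "vocabulary": ["ICD10"] * 5,
            "date": pd.to_datetime(["2005-01-01", "2006-02-05", "2006-08-23",
                                    "2008-01-01", "2008-01-01"]),
            "source": ["primary_care", "primary_care", "inpatient_primary",
                       "self_report", "inpatient_primary"]})
        matched = pd.DataFrame({
            "set_id": [1, 1, 1, 2, 2, 2],
            "person_id": ["e1", "c1", "c2", "e2", "c3", "c4"],
            "exposed": [True, False, False, True, False, False],
            "index_date": pd.to_datetime(["2005-01-01"] * 3 + ["2008-01-01"] * 3)})
        return parts, events, matched

    def test_intervals_match_hand_computation(self):
        parts, events, matched = self._toy()
        codes = toy_codes()
        emap = et.ascertain_exposure(events, codes)
        fu = et.build_followup(matched, events, parts, codes, "any_cvd", emap)
        got = fu.set_index("person_id")
        # c1: censored at own psychiatric diagnosis 2006-02-05 (400 days)
        # even though CVD follows 2006-08-23 -> no event
        assert got.loc["c1", "stop"] == 400 and not got.loc["c1", "event"]
        # c2: dies 2010-06-15 -> 1991 days, no event
        assert got.loc["c2", "stop"] == (pd.Timestamp("2010-06-15")
                                         - pd.Timestamp("2005-01-01")).days
        assert not got.loc["c2", "event"]
        # e1: no events -> administrative end 2019-12-31
        assert got.loc["e1", "stop"] == (pd.Timestamp("2019-12-31")
                                         - pd.Timestamp("2005-01-01")).days
        # c4: outcome on index date -> half-day event interval
        assert got.loc["c4", "stop"] == 0.5 and got.loc["c4", "event"]
        # c3: clean until administrative end
        assert got.loc["c3", "stop"] == (pd.Timestamp("2019-12-31")
                                         - pd.Timestamp("2008-01-01")).days
        assert (fu.start == 0).all() and (fu.stop > fu.start).all()

    def test_prior_outcome_excludes_member_from_risk_set(self):
        parts, events, matched = self._toy()
        extra = pd.DataFrame({
            "person_id": ["c3"], "code": ["I10"], "vocabulary": ["ICD10"],
            "date": [pd.Timestamp("2007-01-01")], "source": ["inpatient_primary"]})
        events = pd.concat([events, extra], ignore_index=True)
        codes = toy_codes()
        emap = et.ascertain_exposure(events, codes)
        fu = et.build_followup(matched, events, parts, codes, "I10", emap)
        assert "c3" not in set(fu.person_id)

    def test_at_most_one_event_interval_per_person_per_outcome(self, small_cohort):
        cfg, parts, diags = small_cohort
        *_, fu = run_cohort(cfg, "any_cvd")
        per = fu.groupby("person_id")["event"].sum()
        assert (fu.groupby(["set_id", "person_id"]).size() == 1).all()
        assert (per <= fu.groupby("person_id").size()).all()


@given(st.integers(1000, 10**6), st.integers(0, 1000))
def test_flow_counts_identity(identified, excluded):
    fc = et.FlowCounts(identified=identified, excluded={"prior": excluded})
    assert fc.final == identified - excluded


def test_tdi_quartiles_empirical_and_pinned():
    s = pd.Series(np.arange(100, dtype=float))
    q = et.compute_tdi_quartiles(s)
    assert sorted(q.unique()) == [1, 2, 3, 4]
    assert (q.value_counts().sort_index() >= 24).all()
    pinned = et.compute_tdi_quartiles(s, cut_points=[10, 20, 30])
    assert pinned.iloc[5] == 1 and pinned.iloc[15] == 2 and pinned.iloc[99] == 4


def test_codelist_rejects_overlapping_groups():
    with pytest.raises(ValueError, match="appears in outcome groups"):
        et.CodeListConfig(exposure_codes={"F32"},
                          outcome_groups={"a": {"I10"}, "b": {"I10", "I21"}})
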