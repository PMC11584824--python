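"""End-to-end pipeline orchestration.

Runs simulate/ingest -> ascertain + exclude -> incidence-density match ->
follow-up -> hazard-ratio tables (whole period, within/beyond 6 months, fine
windows, adjustment cascade) -> effect-modification analyses (family history,
polygenic-score tertiles) -> subgroup analyses (diagnosis source, age at
diagnosis) -> disease-trajectory network -> exports, with a participant-flow
report and a run manifest recording every threshold and seed.

One user-facing seed governs all random stages through independent derived
streams, so a stage can be rerun on its own yet reproduce the full run.
"""

from __future__ import annotations

import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (ADJUSTMENT_CASCADE, ADMIN_END, CodeListConfig,
                     apply_exclusions, ascertain_exposure, build_design,
                     build_followup, first_event_date, incidence_density_match)
from .cohortsim import DiseaseDef, SimulationConfig, generate_cohort, write_cohort
from .survival import (NoInformativeStrataError, fit_stratified_cox,
                       hazard_ratio_result, interaction_test, prs_tertiles,
                       split_followup, subgroup_analysis)
from .trajectory import (assemble_network, confirm_edges, directionality_filter,
                         enumerate_pairs, export_network, exposed_first_dates,
                         pair_stats_table, screen_diseases, step1_disease_cox)

log = logging.getLogger(__name__)

FINE_WINDOWS = [3, 6, 12, 18, 24, 60, 120, 240]
SIX_MONTHS = [6]


def stage_seed(seed: int, stage: str) -> int:
    """Independent, reproducible sub-seed for a named pipeline stage."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything a pipeline run needs; loadable from YAML."""

    codelist: str
    outdir: str
    participants: str | None = None
    diagnoses: str | None = None
    simulate: dict | None = None
    matching_ratio: int = 5
    matching_reuse: bool = True
    followup_cutpoints_months: list[float] = field(default_factory=lambda: list(FINE_WINDOWS))
    trajectory: dict = field(default_factory=lambda: {
        "min_cases": 200, "min_co": 100, "alpha": 0.05,
        "m_controls": 5, "prevalence_first": True})
    primary_only: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        missing = [f for f in (cfg.codelist, cfg.participants, cfg.diagnoses)
                   if f and not Path(f).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        if cfg.simulate is None and not (cfg.participants and cfg.diagnoses):
            raise ValueError("config needs either input tables or a simulate block")
        return cfg

    def to_dict(self) -> dict:
        return {
            "codelist": self.codelist, "outdir": self.outdir,
            "participants": self.participants, "diagnoses": self.diagnoses,
            "simulate": self.simulate, "matching_ratio": self.matching_ratio,
            "matching_reuse": self.matching_reuse,
            "followup_cutpoints_months": list(self.followup_cutpoints_months),
            "trajectory": dict(self.trajectory),
            "primary_only": self.primary_only, "seed": self.seed,
        }


def simulation_config_from_dict(d: dict, seed: int) -> SimulationConfig:
    d = dict(d)
    diseases = d.pop("diseases", None)
    kwargs = {}
    if diseases:
        kwargs["disease_defs"] = [DiseaseDef(c, float(r)) for c, r in diseases.items()]
    for key in ("n_individuals", "psych_onset_rate", "exposure_log_hr",
                "progression_log_or_matrix", "family_history_prevalence",
                "family_history_log_hr", "prs_log_hr_per_sd",
                "modification_log_hr", "modifier", "death_rate", "loss_rate",
                "prs_missing_rate", "female_fraction", "calendar_window",
                "exposure_source_probs", "disease_source_probs"):
        if key in d:
            kwargs[key] = d[key]
    if "progression_log_or_matrix" in kwargs:
        kwargs["progression_log_or_matrix"] = np.asarray(
            kwargs["progression_log_or_matrix"], dtype=float)
    if "calendar_window" in kwargs:
        kwargs["calendar_window"] = tuple(kwargs["calendar_window"])
    return SimulationConfig(seed=seed, **kwargs)


class PipelineRun:
    """Stateful pipeline over one output directory.

    Stages persist their outputs as delimited text under ``outdir`` so that
    later stages (or CLI subcommands) can resume from disk.  Any stage
    failure propagates with the stage name; already-written outputs remain.
    """

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.codes = CodeListConfig.from_yaml(config.codelist)
        if config.primary_only:
            self.codes.primary_only = True
        self.manifest: dict = {
            "epitraj_version": __version__,
            "versions": {m.__name__: m.__version__
                         for m in (np, pd, __import__("scipy"), __import__("networkx"))},
            "config": config.to_dict(),
            "seed": config.seed,
            "stage_seeds": {},
            "stage_records": {},
        }
        self.participants: pd.DataFrame | None = None
        self.diagnoses: pd.DataFrame | None = None

    # -- stages -------------------------------------------------------------

    def _record(self, stage: str, **counts):
        self.manifest["stage_records"][stage] = counts
        log.info("stage %s: %s", stage, counts)

    def load_inputs(self):
        if self.cfg.simulate is not None:
            seed = stage_seed(self.cfg.seed, "simulate")
            self.manifest["stage_seeds"]["simulate"] = seed
            sim = simulation_config_from_dict(self.cfg.simulate, seed)
            self.participants, self.diagnoses = generate_cohort(sim)
            write_cohort(self.participants, self.diagnoses, self.outdir, sim)
        else:
            self.participants = pd.read_csv(self.cfg.participants, sep="\t",
                                            parse_dates=["death_date", "loss_date"])
            self.diagnoses = pd.read_csv(self.cfg.diagnoses, sep="\t",
                                         parse_dates=["date"])
        self._record("inputs", participants=len(self.participants),
                     diagnoses=len(self.diagnoses))
        return self

    def match(self):
        seed = stage_seed(self.cfg.seed, "match")
        self.manifest["stage_seeds"]["match"] = seed
        self.exposure_map = ascertain_exposure(self.diagnoses, self.codes)
        self.exposed, self.flow = apply_exclusions(
            self.exposure_map, self.diagnoses, self.participants, self.codes)
        self.first_cvd = first_event_date(self.diagnoses, self.codes.cvd_any_codes,
                                          self.codes.primary_only)
        self.matched, self.match_stats = incidence_density_match(
            self.exposed, self.participants, self.exposure_map, self.first_cvd,
            ratio=self.cfg.matching_ratio, seed=seed,
            reuse_across_sets=self.cfg.matching_reuse)
        (self.outdir / "flow.json").write_text(
            json.dumps(self.flow.to_dict(), indent=2) + "\n")
        self.matched.to_csv(self.outdir / "matched_sets.tsv", sep="\t",
                            index=False, date_format="%Y-%m-%d")
        self._record("match", exposed=self.flow.final,
                     controls=self.match_stats.n_controls,
                     empty_sets=self.match_stats.n_empty_sets)
        return self

    def _followup(self, outcome_group: str) -> pd.DataFrame:
        return build_followup(self.matched, self.diagnoses, self.participants,
                              self.codes, outcome_group, self.exposure_map)

    def _fit_row(self, fu: pd.DataFrame, outcome: str, window: str,
                 adjustment) -> dict:
        base = {"outcome": outcome, "window": window,
                "model": adjustment.label if adjustment else "crude"}
        try:
            df, cols = build_design(fu, self.participants, adjustment)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = fit_stratified_cox(df, cols)
            self._log_fit(f"{outcome}/{window}/{base['model']}", fit)
            if not fit.coef_ok("exposed"):
                return base | {"estimable": False}
            r = hazard_ratio_result(fit, fu, "exposed", model_label=base["model"])
            return base | {
                "n_cases_exposed": r.n_cases_exposed,
                "n_cases_unexposed": r.n_cases_unexposed,
                "py_exposed": r.person_years_exposed,
                "py_unexposed": r.person_years_unexposed,
                "incidence_exposed": r.incidence_exposed,
                "incidence_unexposed": r.incidence_unexposed,
                "hr": r.hr, "ci_low": r.ci95[0], "ci_high": r.ci95[1],
                "p": r.wald_p, "estimable": True,
            }
        except NoInformativeStrataError:
            return base | {"estimable": False}

    def _log_fit(self, label: str, fit) -> None:
        """Append the full coefficient vector and diagnostics to the fit log."""
        with open(self.outdir / "cox_fits.log", "a") as fh:
            fh.write(f"== {label} ==\n")
            fh.write(f"converged={fit.converged} iterations={fit.n_iter} "
                     f"loglik={fit.loglik:.6f} events={fit.n_events} "
                     f"strata={fit.n_strata} "
                     f"informative={fit.n_informative_strata} "
                     f"monotone={fit.monotone_likelihood}\n")
            fh.write(fit.summary().to_string(float_format="%.6g") + "\n\n")

    def cox(self):
        (self.outdir / "cox_fits.log").write_text("")  # fresh log per run
        rows = []
        outcomes = ["any_cvd"] + sorted(self.codes.outcome_groups) + (
            ["acute_events"] if self.codes.acute_event_codes else [])
        cascade = ADJUSTMENT_CASCADE
        for outcome in outcomes:
            fu = self._followup(outcome)
            if fu.empty:
                continue
            if outcome == "any_cvd":
                fu.to_csv(self.outdir / "followup_any_cvd.tsv", sep="\t",
                          index=False)
            models = cascade if outcome == "any_cvd" else cascade[-1:]
            for adj in models:
                rows.append(self._fit_row(fu, outcome, "whole", adj))
                split6 = split_followup(fu, SIX_MONTHS)
                for win, g in split6.groupby("window", observed=True):
                    rows.append(self._fit_row(g, outcome, str(win), adj))
            if outcome == "any_cvd":
                fine = split_followup(fu, self.cfg.followup_cutpoints_months)
                for win, g in fine.groupby("window", observed=True):
                    rows.append(self._fit_row(g, outcome, str(win), cascade[-1]))
        self.hr_table = pd.DataFrame(rows)
        self.hr_table.to_csv(self.outdir / "hr_results.tsv", sep="\t", index=False)
        self._record("cox", rows=len(self.hr_table))
        return self

    def modify(self):
        """Family-history and PRS-tertile stratified analyses + interactions."""
        p = self.participants.set_index("person_id")
        fu_any = self._followup("any_cvd")
        exposed_of_set = (self.matched[self.matched["exposed"]]
                          .set_index("set_id")["person_id"])
        rows = []
        diffs = []

        def run_block(fu, outcome, groups, extremes, modifier_col_values, label):
            table, diff_p = subgroup_analysis(fu, groups, extremes=extremes,
                                              windows=SIX_MONTHS, model_label=label)
            table.insert(0, "grouping", label)
            table.insert(1, "outcome", outcome)
            rows.append(table)
            inter = {}
            df = fu.merge(modifier_col_values.rename("modifier"),
                          left_on="person_id", right_index=True, how="inner")
            for win, g in split_followup(df, SIX_MONTHS).groupby("window", observed=True):
                try:
                    pval, _ = interaction_test(g, "modifier")
                except (NoInformativeStrataError, ValueError):
                    pval = float("nan")
                inter[str(win)] = pval
            for win in diff_p:
                diffs.append({"grouping": label, "outcome": outcome, "window": win,
                              "difference_p": diff_p[win],
                              "interaction_p": inter.get(win, float("nan"))})

        fh = p["family_history_cvd"].astype(bool)
        groups = exposed_of_set.map(fh.map({True: "yes", False: "no"}))
        run_block(fu_any, "any_cvd", groups, ("yes", "no"),
                  fh.astype(float), "family_history")

        for disease in sorted(self.codes.outcome_groups):
            col = f"prs_{disease}"
            if col not in p.columns:
                continue
            tert = prs_tertiles(p[col])
            fu = self._followup(disease)
            if fu.empty:
                continue
            groups = exposed_of_set.map(tert)
            extreme = tert.map({"low": 0.0, "high": 1.0}).astype(float)
            run_block(fu, disease, groups, ("low", "high"), extreme.dropna(),
                      "prs_tertile")

        self.modification_table = (pd.concat(rows, ignore_index=True)
                                   if rows else pd.DataFrame())
        self.modification_diffs = pd.DataFrame(diffs)
        self.modification_table.to_csv(self.outdir / "modification_results.tsv",
                                       sep="\t", index=False)
        self.modification_diffs.to_csv(self.outdir / "modification_tests.tsv",
                                       sep="\t", index=False)
        self._record("modify", rows=len(self.modification_table))
        return self

    def subgroups(self):
        """Diagnosis-source and age-at-diagnosis subgroup analyses."""
        fu_any = self._followup("any_cvd")
        exposed_of_set = (self.matched[self.matched["exposed"]]
                          .set_index("set_id")["person_id"])
        ev = self.diagnoses
        hit = ev["code"].map(lambda c: str(c).strip().upper()[:3]).isin(
            self.codes.exposure_codes)
        first_rows = (ev[hit].sort_values(["person_id", "date", "source"])
                      .groupby("person_id").first())
        source = first_rows["source"].map(
            lambda s: "inpatient" if str(s).startswith("inpatient")
            else "self_report_or_primary_care")
        p = self.participants.set_index("person_id")
        idx_year = self.matched[self.matched["exposed"]].set_index("person_id")[
            "index_date"].dt.year
        age = idx_year - p["birth_year"].reindex(idx_year.index)
        band = pd.cut(age, [-np.inf, 47, 55, np.inf],
                      labels=["<47", "47-55", ">55"]).astype(object)

        rows, diffs = [], []
        for label, mapping, extremes in (
                ("diagnosis_source", source, ("inpatient", "self_report_or_primary_care")),
                ("age_at_diagnosis", band, ("<47", ">55"))):
            groups = exposed_of_set.map(mapping)
            table, diff_p = subgroup_analysis(fu_any, groups, extremes=extremes,
                                              windows=SIX_MONTHS, model_label=label)
            table.insert(0, "grouping", label)
            rows.append(table)
            for win, dp in diff_p.items():
                diffs.append({"grouping": label, "window": win, "difference_p": dp})
        self.subgroup_table = pd.concat(rows, ignore_index=True)
        self.subgroup_diffs = pd.DataFrame(diffs)
        self.subgroup_table.to_csv(self.outdir / "subgroup_results.tsv",
                                   sep="\t", index=False)
        self.subgroup_diffs.to_csv(self.outdir / "subgroup_tests.tsv",
                                   sep="\t", index=False)
        self._record("subgroups", rows=len(self.subgroup_table))
        return self

    def run_trajectory(self):
        tcfg = self.cfg.trajectory
        seed = stage_seed(self.cfg.seed, "trajectory")
        self.manifest["stage_seeds"]["trajectory"] = seed
        diseases = sorted(self.codes.outcome_groups)
        fu_by = {d: self._followup(d) for d in diseases}
        eligible = screen_diseases(fu_by, min_cases=tcfg.get("min_cases", 200))
        step1 = step1_disease_cox(fu_by, eligible, self.participants,
                                  ADJUSTMENT_CASCADE[-1],
                                  alpha=tcfg.get("alpha", 0.05))
        sig = step1.loc[step1["significant"], "disease"].tolist()
        pairs = enumerate_pairs(sig)
        first_dates = exposed_first_dates(self.exposed, self.diagnoses, self.codes,
                                          sig, self.participants, self.exposure_map)
        stats = directionality_filter(
            pairs, first_dates, min_co=tcfg.get("min_co", 100),
            alpha=tcfg.get("alpha", 0.05),
            prevalence_first=tcfg.get("prevalence_first", True))
        passed = [s for s in stats if s.passed]
        edges = confirm_edges(passed, first_dates, self.participants,
                              m_controls=tcfg.get("m_controls", 5),
                              alpha=tcfg.get("alpha", 0.05), seed=seed)
        net = assemble_network(edges, step1)

        tdir = self.outdir / "trajectory"
        tdir.mkdir(exist_ok=True)
        step1.to_csv(tdir / "step1_disease_hr.tsv", sep="\t", index=False)
        pair_stats_table(stats).to_csv(tdir / "pair_stats.tsv", sep="\t", index=False)
        edges.to_csv(tdir / "edges.tsv", sep="\t", index=False)
        export_network(net, tdir)
        (tdir / "run-manifest.json").write_text(json.dumps({
            "thresholds": {k: tcfg.get(k) for k in
                           ("min_cases", "min_co", "alpha", "m_controls",
                            "prevalence_first")},
            "seed": seed, "n_eligible": len(eligible), "n_significant": len(sig),
            "n_pairs": len(pairs),
            "n_pass_prevalence": sum(s.passed_prevalence for s in stats),
            "n_pass_direction": len(passed),
            "n_confirmed": int(edges["confirmed"].sum()) if len(edges) else 0,
        }, indent=2) + "\n")
        self.step1, self.pair_stats, self.edges, self.network = step1, stats, edges, net
        self._record("trajectory", eligible=len(eligible), significant=len(sig),
                     confirmed=int(edges["confirmed"].sum()) if len(edges) else 0)
        return self

    def finish(self):
        (self.outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")
        return self


def run_pipeline(config: RunConfig, stages=("match", "cox", "modify",
                                            "subgroups", "trajectory")) -> PipelineRun:
    """Execute the pipeline; any stage failure aborts naming the stage."""
    run = PipelineRun(config)
    todo = ["inputs"] + list(stages) + ["reports"]
    dispatch = {
        "inputs": run.load_inputs, "match": run.match, "cox": run.cox,
        "modify": run.modify, "subgroups": run.subgroups,
        "trajectory": run.run_trajectory,
    }
    for stage in todo:
        if stage == "reports":
            from .reports import render_reports
            try:
                render_reports(run)
            except Exception as exc:
                run.finish()
                raise RuntimeError(f"pipeline stage 'reports' failed: {exc}") from exc
            continue
        try:
            dispatch[stage]()
        except Exception as exc:
            run.finish()
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    run.finish()
    return run
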