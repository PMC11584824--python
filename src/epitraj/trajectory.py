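"""Three-step disease-trajectory inference and network assembly.

Step 1 screens grouped disease outcomes by case count among exposed persons
and fits one stratified Cox model per disease to find outcomes positively
associated with the exposure (HR > 1, Bonferroni-corrected).  Step 2 forms
all ordered pairs of the significant diseases, applies a co-occurrence
prevalence filter, and runs an exact binomial test of temporal order (is one
disease diagnosed before the other more often than chance?).  Step 3
confirms each directed pair with a nested case-control design: for every D2
case, outcome-free persons still at risk at the case's follow-up time are
sampled as controls and the odds of a prior D1 diagnosis are contrasted with
conditional logistic regression.  Confirmed edges (OR > 1, Bonferroni) are
assembled into a layered directed network describing disease progression
downstream of the exposure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .cohort import AdjustmentSet, CodeListConfig, _days, _norm3, build_design
from .survival import (NoInformativeStrataError, Z975, fit_conditional_logistic,
                       fit_stratified_cox, hazard_ratio_result)

log = logging.getLogger(__name__)
_FAR = 10**9


@dataclass
class DiseasePairStats:
    """Temporal-order evidence for one unordered disease pair."""

    d1: str  # majority-first disease
    d2: str
    n_both: int
    n_d1_first: int
    n_d2_first: int
    n_same_day: int
    binomial_p: float
    passed_prevalence: bool
    passed: bool = False

    def __post_init__(self):
        assert self.n_d1_first + self.n_d2_first + self.n_same_day == self.n_both


# ---------------------------------------------------------------------------
# step 1: disease-level screening + Cox
# ---------------------------------------------------------------------------


def screen_diseases(followup_by_disease: dict[str, pd.DataFrame],
                    min_cases: int = 200) -> list[str]:
    """Diseases with strictly more than ``min_cases`` exposed events."""
    eligible = []
    for disease, fu in followup_by_disease.items():
        n = int((fu["event"] & fu["exposed"]).sum())
        if n > min_cases:
            eligible.append(disease)
    if not eligible:
        raise RuntimeError("no disease passed the exposed-case screen; "
                           "trajectory analysis halted")
    return sorted(eligible)


def step1_disease_cox(
    followup_by_disease: dict[str, pd.DataFrame],
    eligible: list[str],
    participants: pd.DataFrame,
    adjustment: AdjustmentSet | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-disease exposure hazard ratios with Bonferroni significance.

    Significant iff HR > 1 and p < alpha / k, where k counts all diseases
    tested (non-estimable ones included in the denominator and reported).
    """
    k = len(eligible)
    rows = []
    for disease in eligible:
        fu = followup_by_disease[disease]
        try:
            df, cols = build_design(fu, participants, adjustment)
            fit = fit_stratified_cox(df, cols)
            res = hazard_ratio_result(fit, fu, "exposed",
                                      model_label=adjustment.label if adjustment else "crude")
            rows.append({"disease": disease, "hr": res.hr, "ci_low": res.ci95[0],
                         "ci_high": res.ci95[1], "p": res.wald_p,
                         "n_cases_exposed": res.n_cases_exposed,
                         "n_cases_unexposed": res.n_cases_unexposed,
                         "estimable": True})
        except NoInformativeStrataError:
            rows.append({"disease": disease, "hr": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan, "n_cases_exposed": 0,
                         "n_cases_unexposed": 0, "estimable": False})
    out = pd.DataFrame(rows)
    out["bonferroni_threshold"] = alpha / k
    out["significant"] = (out["hr"] > 1.0) & (out["p"] < alpha / k)
    out["significant"] = out["significant"].fillna(False)
    return out


def enumerate_pairs(diseases: list[str]) -> list[tuple[str, str]]:
    """All ordered pairs (d1, d2), d1 != d2; count = k(k-1)."""
    ds = list(diseases)
    if len(ds) < 2:
        if len(ds) < 2:
            log.warning("fewer than 2 significant diseases: no pairs to test")
        return []
    return [(a, b) for a in ds for b in ds if a != b]


# ---------------------------------------------------------------------------
# step 2: temporal directionality
# ---------------------------------------------------------------------------


def exposed_first_dates(
    exposed_cohort: pd.DataFrame,
    events: pd.DataFrame,
    codes: CodeListConfig,
    diseases: list[str],
    participants: pd.DataFrame,
    exposure_map: pd.Series | None = None,
    admin_end=pd.Timestamp("2019-12-31"),
) -> pd.DataFrame:
    """Per exposed person: index/censor days and first day of each disease.

    Days are integers on a common calendar scale; censoring is death, loss or
    administrative end (whichever first).  Disease dates outside
    ``(index, censor]`` follow-up are set far in the future (ignored).
    Returned columns: ``index_day``, ``end_day`` and one ``day_<disease>``
    per disease, indexed by person_id.
    """
    ex = exposed_cohort.set_index("person_id")
    pid = ex.index
    out = pd.DataFrame(index=pid)
    t0 = ex["index_date"].to_numpy().astype("datetime64[D]").astype(np.int64)
    p = participants.set_index("person_id")
    death = _days(p["death_date"], pid)
    loss = _days(p["loss_date"], pid)
    end = np.int64(pd.Timestamp(admin_end).to_datetime64()
                   .astype("datetime64[D]").astype(np.int64))
    out["index_day"] = t0
    out["end_day"] = np.minimum.reduce([death, loss, np.full(len(pid), end)])
    ev = events
    if codes.primary_only:
        ev = ev[ev["source"] == "inpatient_primary"]
    else:
        ev = ev[ev["source"].isin(["inpatient_primary", "inpatient_secondary"])]
    norm = ev["code"].map(_norm3)
    for disease in diseases:
        codeset = codes.outcome_groups[disease]
        first = ev[norm.isin(codeset)].groupby("person_id")["date"].min()
        day = _days(first, pid)
        in_fu = (day >= t0) & (day <= out["end_day"].to_numpy())
        out[f"day_{disease}"] = np.where(in_fu, day, _FAR)
    return out


def directionality_filter(
    pairs: list[tuple[str, str]],
    first_dates: pd.DataFrame,
    min_co: int = 100,
    alpha: float = 0.05,
    prevalence_first: bool = True,
) -> list[DiseasePairStats]:
    """Exact binomial test of temporal order for each co-occurring pair.

    For each unordered pair, persons with both diagnoses during follow-up are
    counted; same-day pairs are uninformative for order and excluded from the
    binomial n.  The test is one-sided on the observed-majority direction
    against P = 0.5.  A directed pair passes iff it clears the prevalence
    filter (n_both >= min_co) and its p-value beats alpha / n_tested, where
    n_tested counts pairs passing prevalence when ``prevalence_first`` (the
    default) and all testable pairs otherwise.
    """
    unordered = sorted({tuple(sorted(p)) for p in pairs})
    stats: list[DiseasePairStats] = []
    for a, b in unordered:
        da = first_dates[f"day_{a}"].to_numpy()
        db = first_dates[f"day_{b}"].to_numpy()
        both = (da != _FAR) & (db != _FAR)
        n_both = int(both.sum())
        n_a_first = int((da[both] < db[both]).sum())
        n_b_first = int((db[both] < da[both]).sum())
        n_same = n_both - n_a_first - n_b_first
        n_inf = n_a_first + n_b_first
        if n_a_first >= n_b_first:
            d1, d2, k = a, b, n_a_first
        else:
            d1, d2, k = b, a, n_b_first
        if n_inf == 0:
            if n_both > 0:
                log.info("pair %s-%s untestable: all co-occurrences same-day", a, b)
            p = np.nan
        else:
            p = binomtest(k, n_inf, 0.5, alternative="greater").pvalue
        stats.append(DiseasePairStats(
            d1=d1, d2=d2, n_both=n_both, n_d1_first=k,
            n_d2_first=n_inf - k, n_same_day=n_same,
            binomial_p=float(p), passed_prevalence=n_both >= min_co))
    testable = [s for s in stats if np.isfinite(s.binomial_p)]
    if prevalence_first:
        denom = sum(1 for s in testable if s.passed_prevalence)
    else:
        denom = len(testable)
    thr = alpha / denom if denom else 0.0
    for s in stats:
        s.passed = bool(s.passed_prevalence and np.isfinite(s.binomial_p)
                        and s.binomial_p < thr)
    return stats


def pair_stats_table(stats: list[DiseasePairStats]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in stats])


# ---------------------------------------------------------------------------
# step 3: nested case-control confirmation
# ---------------------------------------------------------------------------


def nested_case_control(
    first_dates: pd.DataFrame,
    participants: pd.DataFrame,
    d1: str,
    d2: str,
    m_controls: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Risk-set sampled case-control sets for D1 -> D2 within exposed persons.

    For each D2 case, controls are drawn at the case's follow-up time (days
    since own index) from exposed persons still at risk and D2-free at that
    time, matched on sex and birth year +/- 2; a control may develop D2 later
    and may be reused across sets.  The predictor is a prior D1 diagnosis
    strictly before the same follow-up time (same-day D1 does not count).
    Cases with no eligible control are dropped and logged.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    pid = first_dates.index
    p = participants.set_index("person_id").reindex(pid)
    sex = pd.factorize(p["sex"])[0]
    by = p["birth_year"].to_numpy(dtype=np.int64)
    t0 = first_dates["index_day"].to_numpy()
    end_t = first_dates["end_day"].to_numpy() - t0
    d1_t = np.where(first_dates[f"day_{d1}"].to_numpy() == _FAR, np.inf,
                    first_dates[f"day_{d1}"].to_numpy() - t0)
    d2_t = np.where(first_dates[f"day_{d2}"].to_numpy() == _FAR, np.inf,
                    first_dates[f"day_{d2}"].to_numpy() - t0)

    comp = sex.astype(np.int64) * 100_000 + by
    order = np.argsort(comp, kind="stable")
    uniq, starts = np.unique(comp[order], return_index=True)
    ends = np.append(starts[1:], len(order))
    buckets = {int(k): order[a:b] for k, a, b in zip(uniq, starts, ends)}

    cases = np.flatnonzero(np.isfinite(d2_t))
    rows = []
    n_dropped = 0
    for set_id, i in enumerate(np.sort(cases), start=1):
        t = d2_t[i]
        base = int(sex[i]) * 100_000 + int(by[i])
        cand_list = [buckets.get(base + db) for db in range(-2, 3)]
        cand = np.concatenate([c for c in cand_list if c is not None])
        ok = (d2_t[cand] > t) & (end_t[cand] >= t) & (cand != i)
        elig = cand[ok]
        if elig.size == 0:
            n_dropped += 1
            continue
        if elig.size > m_controls:
            chosen = np.sort(rng.choice(elig, size=m_controls, replace=False))
        else:
            chosen = np.sort(elig)
        members = np.concatenate([[i], chosen])
        for j, who in enumerate(members):
            rows.append((set_id, pid[who], j == 0, float(d1_t[who] < t)))
    if n_dropped:
        log.info("nested case-control %s->%s: %d cases had no eligible control",
                 d1, d2, n_dropped)
    return pd.DataFrame(rows, columns=["set_id", "person_id", "case", "prior_d1"])


def confirm_edges(
    passed_pairs: list[DiseasePairStats],
    first_dates: pd.DataFrame,
    participants: pd.DataFrame,
    m_controls: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Conditional-logistic confirmation of every directed pair.

    An edge is confirmed iff OR > 1 and p < alpha / (number of directed pairs
    tested in this step).
    """
    rows = []
    for j, s in enumerate(passed_pairs):
        sets = nested_case_control(first_dates, participants, s.d1, s.d2,
                                   m_controls=m_controls, seed=seed + j)
        try:
            fit = fit_conditional_logistic(sets, ["prior_d1"])
            b, se = fit.coef("prior_d1")
            rows.append({"d1": s.d1, "d2": s.d2, "or": float(np.exp(b)),
                         "ci_low": float(np.exp(b - Z975 * se)),
                         "ci_high": float(np.exp(b + Z975 * se)),
                         "p": fit.wald_p("prior_d1"),
                         "n_sets": int(sets["case"].sum()),
                         "estimable": True})
        except NoInformativeStrataError:
            rows.append({"d1": s.d1, "d2": s.d2, "or": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan,
                         "n_sets": int(sets["case"].sum()) if len(sets) else 0,
                         "estimable": False})
    out = pd.DataFrame(rows, columns=["d1", "d2", "or", "ci_low", "ci_high",
                                      "p", "n_sets", "estimable"])
    k = len(out)
    out["bonferroni_threshold"] = alpha / k if k else np.nan
    out["confirmed"] = (out["or"] > 1.0) & (out["p"] < alpha / k) if k else False
    if k:
        out["confirmed"] = out["confirmed"].fillna(False)
    return out


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------


def assemble_network(edges: pd.DataFrame, step1: pd.DataFrame | None = None) -> nx.DiGraph:
    """Layered directed network from confirmed edges.

    Cycles are resolved by repeatedly deleting, within a detected cycle, the
    edge with the largest p (ties: smaller OR) until the graph is acyclic;
    deletions are logged and recorded on the graph.  Layers: nodes with no
    incoming edge sit at layer 1; otherwise layer = 1 + max(predecessor
    layers), so every retained edge goes to a strictly later layer.  Nodes
    are annotated with the step-1 hazard ratio, edges with the conditional-
    logistic odds ratio.
    """
    g = nx.DiGraph()
    confirmed = edges[edges.get("confirmed", pd.Series(True, index=edges.index))]
    for _, r in confirmed.iterrows():
        g.add_edge(r["d1"], r["d2"], odds_ratio=float(r["or"]),
                   ci_low=float(r["ci_low"]), ci_high=float(r["ci_high"]),
                   p=float(r["p"]))
    deleted = []
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        worst = max(cycle, key=lambda e: (g.edges[e[:2]]["p"],
                                          -g.edges[e[:2]]["odds_ratio"]))
        deleted.append(worst[:2])
        log.info("cycle resolution: removing edge %s->%s", *worst[:2])
        g.remove_edge(*worst[:2])
    g.graph["deleted_edges"] = [list(e) for e in deleted]

    layer: dict[str, int] = {}
    for node in nx.topological_sort(g):
        preds = list(g.predecessors(node))
        layer[node] = 1 if not preds else 1 + max(layer[u] for u in preds)
    nx.set_node_attributes(g, layer, "layer")
    if step1 is not None:
        hrs = step1.set_index("disease")["hr"].to_dict()
        nx.set_node_attributes(
            g, {n: float(hrs.get(n, np.nan)) for n in g.nodes}, "step1_hr")
    return g


def export_network(g: nx.DiGraph, outdir, stem: str = "trajectory_network") -> None:
    """Write the network as GraphML and as a JSON node/edge document."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clean = g.copy()
    clean.graph["deleted_edges"] = json.dumps(g.graph.get("deleted_edges", []))
    for _, d in clean.nodes(data=True):
        for k, v in list(d.items()):
            if isinstance(v, float) and np.isnan(v):
                d[k] = "NA"
    nx.write_graphml(clean, outdir / f"{stem}.graphml")
    doc = {
        "nodes": [{"id": n, **{k: (None if isinstance(v, float) and np.isnan(v) else v)
                               for k, v in d.items()}}
                  for n, d in sorted(g.nodes(data=True))],
        "edges": [{"source": u, "target": v, **d}
                  for u, v, d in sorted(g.edges(data=True))],
        "deleted_edges": g.graph.get("deleted_edges", []),
    }
    (outdir / f"{stem}.json").write_text(json.dumps(doc, indent=2) + "\n")
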