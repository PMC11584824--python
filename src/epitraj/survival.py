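"""Stratified Cox partial-likelihood estimation and matched-set inference.

The central estimator is a Cox proportional-hazards model whose partial
likelihood is computed *within strata* (here, matched sets), so that each
stratum keeps its own unspecified baseline hazard.  Rows are counting-process
intervals ``(start, stop]`` with an event flag; a row is at risk at event time
``t`` iff ``start < t <= stop``.  Ties are handled with the Breslow
approximation by default (Efron available).  Estimation is Newton-Raphson on
the analytic score and observed information, with step-halving.

Conditional logistic regression for matched case-control sets is fitted by
the same engine: every member of a set is placed at a common event time and
the case is the event, which makes the conditional likelihood of the
case-control set identical to the stratified Cox partial likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

Z975 = norm.ppf(0.975)  # 1.959964...

DEFAULT_WINDOWS_MONTHS = [3, 6, 12, 18, 24, 60, 120, 240]
DAYS_PER_MONTH = 365.25 / 12.0
DAYS_PER_YEAR = 365.25


class NoInformativeStrataError(ValueError):
    """Raised when no stratum carries information about any coefficient."""


@dataclass
class CoxFit:
    """Full output of a stratified Cox (or conditional logistic) fit."""

    params: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    names: list[str]
    loglik: float
    score_norm: float
    n_iter: int
    converged: bool
    monotone_likelihood: bool
    n_rows: int
    n_events: int
    n_strata: int
    n_informative_strata: int
    ties: str = "breslow"
    diverged: np.ndarray | None = None

    def coef_ok(self, name: str) -> bool:
        """True when the named coefficient is finite and well-identified."""
        i = self.names.index(name)
        if self.diverged is not None and self.diverged[i]:
            return False
        return bool(np.isfinite(self.se[i]) and 0 < self.se[i] <= 10)

    def coef(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.params[i]), float(self.se[i])

    def wald_p(self, name: str) -> float:
        b, s = self.coef(name)
        return float(2.0 * norm.sf(abs(b) / s))

    def summary(self) -> pd.DataFrame:
        # a covariate matched exactly within strata has ~zero information:
        # its huge/zero SE overflows harmlessly here
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            return self._summary_frame()

    def _summary_frame(self) -> pd.DataFrame:
        z = self.params / self.se
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.se,
                "hr": np.exp(self.params),
                "ci_low": np.exp(self.params - Z975 * self.se),
                "ci_high": np.exp(self.params + Z975 * self.se),
                "z": z,
                "p": 2.0 * norm.sf(np.abs(z)),
            },
            index=self.names,
        )


@dataclass
class HazardRatioResult:
    """Hazard ratio for one contrast, with the bookkeeping a report row needs.

    ``ci95 = exp(log_hr -/+ 1.959964 * se_log_hr)``; incidence rates are per
    1000 person-years, ``1000 * cases / person_years``.
    """

    hr: float
    log_hr: float
    se_log_hr: float
    ci95: tuple[float, float]
    wald_p: float
    n_cases_exposed: int = 0
    n_cases_unexposed: int = 0
    person_years_exposed: float = float("nan")
    person_years_unexposed: float = float("nan")
    model_label: str = ""
    estimable: bool = True
    flags: dict = field(default_factory=dict)

    @property
    def incidence_exposed(self) -> float:
        return 1000.0 * self.n_cases_exposed / self.person_years_exposed

    @property
    def incidence_unexposed(self) -> float:
        return 1000.0 * self.n_cases_unexposed / self.person_years_unexposed

    @classmethod
    def not_estimable(cls, model_label: str = "", **flags) -> "HazardRatioResult":
        nan = float("nan")
        return cls(nan, nan, nan, (nan, nan), nan, model_label=model_label,
                   estimable=False, flags=flags)


# ---------------------------------------------------------------------------
# engine internals
# ---------------------------------------------------------------------------


class _RiskSetIndex:
    """Precomputed sorted indices for suffix-sum risk-set evaluation.

    For an event at time t in stratum s the Breslow denominator is
    ``sum_{i in s: stop_i >= t} v_i  -  sum_{i in s: start_i >= t} v_i``
    for any per-row quantity v.  Both sums are suffix sums over rows sorted
    by (stratum, time); positions depend only on the data, not on beta, so
    they are computed once and reused every Newton iteration.
    """

    def __init__(self, strata: np.ndarray, start: np.ndarray, stop: np.ndarray,
                 event: np.ndarray):
        n = strata.shape[0]
        ut = np.unique(np.concatenate([start, stop]))
        m = ut.shape[0] + 1
        r_start = np.searchsorted(ut, start)
        r_stop = np.searchsorted(ut, stop)
        key_stop = strata.astype(np.int64) * m + r_stop
        key_start = strata.astype(np.int64) * m + r_start

        self.ord_stop = np.argsort(key_stop, kind="stable")
        self.ord_start = np.argsort(key_start, kind="stable")
        ks_sorted = key_stop[self.ord_stop]
        ka_sorted = key_start[self.ord_start]

        eidx = np.flatnonzero(event)
        self.event_rows = eidx
        key_e = key_stop[eidx]
        # suffix-sum start positions for each event
        self.i_stop = np.searchsorted(ks_sorted, key_e, side="left")
        self.i_start = np.searchsorted(ka_sorted, key_e, side="left")
        # end-of-stratum positions (exclusive) to cut suffix sums at
        key_end = (strata[eidx].astype(np.int64) + 1) * m
        self.e_stop = np.searchsorted(ks_sorted, key_end, side="left")
        self.e_start = np.searchsorted(ka_sorted, key_end, side="left")
        # tie groups: events sharing (stratum, time)
        grp_key = key_e
        order = np.argsort(grp_key, kind="stable")
        self.tie_order = order
        sorted_keys = grp_key[order]
        boundaries = np.flatnonzero(np.diff(sorted_keys)) + 1
        self.tie_starts = np.concatenate([[0], boundaries])
        self.tie_ends = np.concatenate([boundaries, [len(grp_key)]])
        self.n = n

    def sums(self, v: np.ndarray) -> np.ndarray:
        """Risk-set sum of v for each event row (Breslow denominator)."""
        cs_stop = np.zeros(self.n + 1)
        cs_stop[:-1] = np.cumsum(v[self.ord_stop][::-1])[::-1]
        cs_start = np.zeros(self.n + 1)
        cs_start[:-1] = np.cumsum(v[self.ord_start][::-1])[::-1]
        return (cs_stop[self.i_stop] - cs_stop[self.e_stop]) - (
            cs_start[self.i_start] - cs_start[self.e_start]
        )


def _loglik_grad_hess(beta: np.ndarray, X: np.ndarray, idx: _RiskSetIndex,
                      ties: str):
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    ev = idx.event_rows
    ne = ev.shape[0]

    S0 = idx.sums(w)
    S1 = np.empty((ne, p))
    for j in range(p):
        S1[:, j] = idx.sums(w * X[:, j])
    S2 = np.empty((ne, p, p))
    for j in range(p):
        for k in range(j, p):
            s = idx.sums(w * X[:, j] * X[:, k])
            S2[:, j, k] = s
            S2[:, k, j] = s

    if ties == "efron":
        # within each tie group, downweight the tied events' own hazard mass
        T0 = np.zeros(ne)
        T1 = np.zeros((ne, p))
        T2 = np.zeros((ne, p, p))
        order = idx.tie_order
        for a, b in zip(idx.tie_starts, idx.tie_ends):
            g = order[a:b]
            K = len(g)
            if K == 1:
                continue
            rows = ev[g]
            t0 = w[rows].sum()
            t1 = (w[rows, None] * X[rows]).sum(axis=0)
            t2 = np.einsum("i,ij,ik->jk", w[rows], X[rows], X[rows])
            frac = np.arange(K) / K
            T0[g] = frac * t0
            T1[g] = frac[:, None] * t1
            T2[g] = frac[:, None, None] * t2
        S0 = S0 - T0
        S1 = S1 - T1
        S2 = S2 - T2

    if np.any(S0 <= 0) or not np.all(np.isfinite(S0)):
        return -np.inf, np.zeros(p), np.eye(p)

    ll = float(np.sum(eta[ev]) - np.sum(np.log(S0)))
    xbar = S1 / S0[:, None]
    grad = X[ev].sum(axis=0) - xbar.sum(axis=0)
    H = -(np.einsum("e,ejk->jk", 1.0 / S0, S2)
          - np.einsum("ej,ek->jk", xbar, xbar))
    return ll, grad, H


def _informative_strata(strata: np.ndarray, event: np.ndarray,
                        X: np.ndarray) -> int:
    df = pd.DataFrame({"s": strata, "e": event.astype(int)})
    has_event = df.groupby("s")["e"].max()
    varies = pd.Series(False, index=has_event.index)
    for j in range(X.shape[1]):
        g = pd.Series(X[:, j]).groupby(strata)
        varies |= (g.max() - g.min()) > 0
    return int((has_event.astype(bool) & varies).sum())


def fit_stratified_cox(
    intervals: pd.DataFrame,
    covariates: list[str] | None = None,
    *,
    strata_col: str = "set_id",
    start_col: str = "start",
    stop_col: str = "stop",
    event_col: str = "event",
    ties: str = "breslow",
    max_iter: int = 100,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
) -> CoxFit:
    """Fit a stratified Cox model on counting-process intervals.

    Parameters
    ----------
    intervals
        One row per at-risk interval with columns ``strata_col``,
        ``start_col``, ``stop_col``, ``event_col`` and the covariates.
    covariates
        Columns entering the linear predictor (already numerically coded);
        defaults to ``["exposed"]``.

    Raises
    ------
    NoInformativeStrataError
        If no stratum has both an event and within-stratum covariate
        variation (the conditional likelihood is flat).
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie handling {ties!r}")
    if covariates is None:
        covariates = ["exposed"]
    df = intervals
    strata, _ = pd.factorize(df[strata_col].to_numpy(), sort=True)
    start = df[start_col].to_numpy(dtype=float)
    stop = df[stop_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy(dtype=bool)
    if np.any(stop <= start):
        raise ValueError("intervals require stop > start")
    X = df[covariates].to_numpy(dtype=float)
    n, p = X.shape

    if event.sum() == 0:
        raise NoInformativeStrataError("no events in any stratum")
    n_informative = _informative_strata(strata, event, X)
    if n_informative == 0:
        raise NoInformativeStrataError(
            "no informative strata: every stratum lacks events or "
            "within-stratum covariate variation"
        )

    # center columns for numerical stability (affine shift cancels in the
    # partial likelihood)
    mu = X.mean(axis=0)
    Xc = X - mu

    idx = _RiskSetIndex(strata, start, stop, event)
    beta = np.zeros(p)
    ll, grad, H = _loglik_grad_hess(beta, Xc, idx, ties)
    converged = False
    it = 0
    ridge = 1e-10 * np.eye(p)
    for it in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(-H + ridge, grad)
        except np.linalg.LinAlgError as exc:
            raise NoInformativeStrataError(
                "singular information matrix: a covariate carries no "
                "within-stratum information"
            ) from exc
        step = 1.0
        for _ in range(40):
            # clip keeps a separated coefficient on its likelihood plateau
            cand = np.clip(beta + step * delta, -30.0, 30.0)
            ll_new, grad_new, H_new = _loglik_grad_hess(cand, Xc, idx, ties)
            if ll_new >= ll - 1e-14:
                break
            step *= 0.5
        rel = abs(ll_new - ll) / (abs(ll) + 1e-300)
        beta, grad, H = cand, grad_new, H_new
        ll = ll_new
        if np.max(np.abs(grad)) < score_tol or rel < ll_tol:
            converged = True
            break
    diverged = np.abs(beta) > 10.0
    monotone = bool(diverged.any())
    if monotone:
        warnings.warn(
            "monotone partial likelihood: estimate diverging for "
            f"{[covariates[j] for j in np.flatnonzero(diverged)]}; result flagged",
            RuntimeWarning,
            stacklevel=2,
        )

    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    return CoxFit(
        params=beta,
        se=se,
        cov=cov,
        names=list(covariates),
        loglik=ll,
        score_norm=float(np.max(np.abs(grad))),
        n_iter=it,
        converged=converged,
        monotone_likelihood=monotone,
        n_rows=n,
        n_events=int(event.sum()),
        n_strata=int(strata.max()) + 1,
        n_informative_strata=n_informative,
        ties=ties,
        diverged=diverged,
    )


def hazard_ratio_result(
    fit: CoxFit,
    intervals: pd.DataFrame,
    coef: str = "exposed",
    model_label: str = "",
    exposed_col: str = "exposed",
    event_col: str = "event",
) -> HazardRatioResult:
    """Summarise one coefficient of a fit together with arm-level counts."""
    b, s = fit.coef(coef)
    exp_mask = intervals[exposed_col].to_numpy(dtype=bool)
    ev = intervals[event_col].to_numpy(dtype=bool)
    days = (intervals["stop"] - intervals["start"]).to_numpy(dtype=float)
    return HazardRatioResult(
        hr=float(np.exp(b)),
        log_hr=b,
        se_log_hr=s,
        ci95=(float(np.exp(b - Z975 * s)), float(np.exp(b + Z975 * s))),
        wald_p=fit.wald_p(coef),
        n_cases_exposed=int(ev[exp_mask].sum()),
        n_cases_unexposed=int(ev[~exp_mask].sum()),
        person_years_exposed=float(days[exp_mask].sum() / DAYS_PER_YEAR),
        person_years_unexposed=float(days[~exp_mask].sum() / DAYS_PER_YEAR),
        model_label=model_label,
        flags={"monotone_likelihood": fit.monotone_likelihood,
               "converged": fit.converged},
    )


# ---------------------------------------------------------------------------
# conditional logistic regression
# ---------------------------------------------------------------------------


def fit_conditional_logistic(
    sets: pd.DataFrame,
    predictors: list[str] | None = None,
    *,
    set_col: str = "set_id",
    case_col: str = "case",
    ties: str = "breslow",
) -> CoxFit:
    """Conditional logistic regression on 1:m matched case-control sets.

    Each set must contain exactly one case.  The conditional likelihood of a
    set (probability that the case, rather than a control, is the one with
    the outcome given the set's covariates) equals a stratified Cox partial
    likelihood in which all members share one event time and the case is the
    event; the fit is therefore delegated to the Cox engine.

    For 1:1 sets with a single binary predictor the estimate is the classic
    discordant-pair ratio: OR = (# case-exposed-only sets)/(# control-exposed-only).
    """
    if predictors is None:
        predictors = ["prior_d1"]
    per_set = sets.groupby(set_col)[case_col].sum()
    if not (per_set == 1).all():
        bad = per_set.index[per_set != 1][:5].tolist()
        raise ValueError(f"each set needs exactly one case; offending sets: {bad}")
    df = sets.copy()
    df["_start"] = 0.0
    df["_stop"] = 1.0
    try:
        return fit_stratified_cox(
            df,
            predictors,
            strata_col=set_col,
            start_col="_start",
            stop_col="_stop",
            event_col=case_col,
            ties=ties,
        )
    except NoInformativeStrataError as exc:
        raise NoInformativeStrataError(
            "predictor constant within every set (all sets concordant)"
        ) from exc


# ---------------------------------------------------------------------------
# follow-up window splitting
# ---------------------------------------------------------------------------


def split_followup(
    intervals: pd.DataFrame,
    cutpoints_months: list[float] = DEFAULT_WINDOWS_MONTHS,
    *,
    start_col: str = "start",
    stop_col: str = "stop",
    event_col: str = "event",
) -> pd.DataFrame:
    """Partition intervals at follow-up cutpoints (months since index).

    Each ``(start, stop]`` row is split at the cutpoints; the event flag is
    kept only on the sub-interval whose half-open window contains the event
    time (= the original stop).  Person-time is conserved exactly: shared
    boundary values make the sub-interval lengths telescope.

    Adds a ``window`` column labelling each sub-interval, e.g. ``"(3,6]"`` or
    ``">240"`` months.
    """
    cuts = np.asarray(list(cutpoints_months), dtype=float)
    if len(cuts) == 0 or cuts[0] <= 0 or np.any(np.diff(cuts) <= 0):
        raise ValueError("cutpoints must be positive, strictly increasing and "
                         "non-empty")
    cut_days = cuts * DAYS_PER_MONTH
    lo = np.concatenate([[0.0], cut_days])
    hi = np.concatenate([cut_days, [np.inf]])
    labels = []
    prev = 0.0
    for c in cuts:
        labels.append(f"(0,{c:g}]" if prev == 0 else f"({prev:g},{c:g}]")
        prev = c
    labels.append(f">{cuts[-1]:g}")

    start = intervals[start_col].to_numpy(dtype=float)
    stop = intervals[stop_col].to_numpy(dtype=float)
    event = intervals[event_col].to_numpy(dtype=bool)
    n = len(intervals)
    k = len(lo)

    s = np.maximum(start[:, None], lo[None, :])
    e = np.minimum(stop[:, None], hi[None, :])
    keep = e > s
    # event belongs to the window with lo < stop <= hi
    ev = (event[:, None]
          & (stop[:, None] > lo[None, :])
          & (stop[:, None] <= hi[None, :]))

    rows, wins = np.nonzero(keep)
    out = intervals.iloc[rows].reset_index(drop=True)
    out[start_col] = s[rows, wins]
    out[stop_col] = e[rows, wins]
    out[event_col] = ev[rows, wins]
    out["window"] = pd.Categorical.from_codes(wins, categories=labels)
    return out


# ---------------------------------------------------------------------------
# Wald tests
# ---------------------------------------------------------------------------


def wald_difference(
    hr1: float,
    ci1: tuple[float, float],
    hr2: float,
    ci2: tuple[float, float],
    se1: float | None = None,
    se2: float | None = None,
) -> tuple[float, float]:
    """Wald z-test for equality of two independent hazard ratios.

    SEs are recovered from the 95% CIs as ``(ln hi - ln lo) / (2 * 1.959964)``
    unless given directly (e.g. from fitted models).  Returns ``(z, p)`` with
    ``p = 2 * (1 - Phi(|z|))``.
    """
    for hr, (lo, hi) in ((hr1, ci1), (hr2, ci2)):
        if not (0 < lo <= hr <= hi):
            raise ValueError(f"CI [{lo}, {hi}] does not bracket HR {hr}")
    if se1 is None:
        se1 = (np.log(ci1[1]) - np.log(ci1[0])) / (2.0 * Z975)
    if se2 is None:
        se2 = (np.log(ci2[1]) - np.log(ci2[0])) / (2.0 * Z975)
    z = (np.log(hr1) - np.log(hr2)) / np.hypot(se1, se2)
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


def interaction_test(
    intervals: pd.DataFrame,
    modifier_col: str,
    *,
    exposed_col: str = "exposed",
    covariates: list[str] | None = None,
    **fit_kwargs,
) -> tuple[float, CoxFit]:
    """Wald p-value for an exposure x modifier product term.

    Fits the stratified Cox model with exposure, the modifier main effect and
    their product, plus any extra covariates; returns the two-sided Wald p for
    the product coefficient together with the full fit.
    """
    mod = intervals[modifier_col].to_numpy(dtype=float)
    if np.nanmin(mod) == np.nanmax(mod):
        raise ValueError(f"modifier {modifier_col!r} is constant")
    df = intervals.copy()
    prod = f"{exposed_col}:{modifier_col}"
    df[prod] = df[exposed_col].astype(float) * mod
    cols = [exposed_col, modifier_col, prod] + list(covariates or [])
    fit = fit_stratified_cox(df, cols, **fit_kwargs)
    return fit.wald_p(prod), fit


# ---------------------------------------------------------------------------
# subgroup analysis
# ---------------------------------------------------------------------------


def prs_tertiles(values: pd.Series) -> pd.Series:
    """Tertile labels (low/moderate/high) among non-missing scores.

    Missing scores stay missing and are excluded from stratified fits,
    mirroring how unknown polygenic scores are handled.
    """
    v = values.astype(float)
    ok = v.notna()
    q = v[ok].quantile([1 / 3, 2 / 3]).to_numpy()
    out = pd.Series(pd.NA, index=values.index, dtype="object")
    out[ok] = np.select(
        [v[ok] <= q[0], v[ok] <= q[1]], ["low", "moderate"], default="high"
    )
    return out


def subgroup_analysis(
    intervals: pd.DataFrame,
    set_groups: pd.Series,
    *,
    covariates: list[str] | None = None,
    extremes: tuple[str, str] | None = None,
    windows: list[float] | None = None,
    model_label: str = "",
) -> tuple[pd.DataFrame, dict]:
    """Per-subgroup hazard ratios with a Wald test between extreme groups.

    ``set_groups`` maps set_id -> subgroup label of the set's exposed member
    (missing labels drop the set).  If ``windows`` is given, intervals are
    split and each window analysed separately.  Subgroups where the model is
    not estimable (no events, no informative strata) yield a not-estimable
    row rather than an error.

    Returns (table, difference_p) where difference_p maps window -> Wald p
    between the two ``extremes`` labels (NaN when either is not estimable).
    """
    covariates = covariates or ["exposed"]
    df = intervals[intervals["set_id"].isin(set_groups.dropna().index)].copy()
    df["_grp"] = df["set_id"].map(set_groups)
    if windows is not None:
        df = split_followup(df, windows)
        window_values = list(df["window"].cat.categories)
    else:
        df["window"] = "all"
        window_values = ["all"]

    rows = []
    results: dict[tuple[str, str], HazardRatioResult] = {}
    for win in window_values:
        dwin = df[df["window"] == win]
        for grp, dsub in dwin.groupby("_grp", observed=True, sort=True):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    fit = fit_stratified_cox(dsub, covariates)
                if not fit.coef_ok(covariates[0]):
                    res = HazardRatioResult.not_estimable(
                        model_label, reason="monotone likelihood")
                else:
                    res = hazard_ratio_result(fit, dsub, covariates[0],
                                              model_label=model_label)
            except NoInformativeStrataError:
                res = HazardRatioResult.not_estimable(model_label,
                                                      reason="no informative strata")
            results[(str(win), str(grp))] = res
            rows.append(
                {
                    "window": win,
                    "subgroup": grp,
                    "hr": res.hr,
                    "ci_low": res.ci95[0],
                    "ci_high": res.ci95[1],
                    "p": res.wald_p,
                    "n_cases_exposed": res.n_cases_exposed,
                    "n_cases_unexposed": res.n_cases_unexposed,
                    "incidence_exposed": res.incidence_exposed if res.estimable else np.nan,
                    "incidence_unexposed": res.incidence_unexposed if res.estimable else np.nan,
                    "estimable": res.estimable,
                }
            )

    diff_p: dict[str, float] = {}
    if extremes is not None:
        a, b = extremes
        for win in window_values:
            ra = results.get((str(win), a))
            rb = results.get((str(win), b))
            if ra is None or rb is None or not (ra.estimable and rb.estimable):
                diff_p[str(win)] = float("nan")
            else:
                try:
                    _, p = wald_difference(ra.hr, ra.ci95, rb.hr, rb.ci95,
                                           se1=ra.se_log_hr, se2=rb.se_log_hr)
                except ValueError:
                    p = float("nan")
                diff_p[str(win)] = p
    return pd.DataFrame(rows), diff_p
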