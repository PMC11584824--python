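"""Human-readable report tables from the numeric output bundle.

Formats hazard/odds ratios as ``"1.21 (1.18-1.23)"`` cells; the formatting is
round-trippable (`parse_ratio_cell`) so rendered tables can be checked
against the numeric bundle.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

BASELINE_VARIABLES = ["sex", "education", "ethnicity", "smoking",
                      "bmi_category", "history_other_psych",
                      "family_history_cvd", "cci"]


def format_ratio_cell(est: float, lo: float, hi: float, digits: int = 2) -> str:
    if not np.isfinite(est):
        return "NA"
    return f"{est:.{digits}f} ({lo:.{digits}f}-{hi:.{digits}f})"


_CELL_RE = re.compile(r"^([\d.]+) \(([\d.]+)-([\d.]+)\)$")


def parse_ratio_cell(cell: str) -> tuple[float, float, float]:
    """Inverse of `format_ratio_cell` (to the printed precision)."""
    m = _CELL_RE.match(cell.strip())
    if not m:
        raise ValueError(f"unparseable ratio cell: {cell!r}")
    return tuple(float(g) for g in m.groups())


def baseline_table(participants: pd.DataFrame, matched: pd.DataFrame,
                   variables: list[str] = BASELINE_VARIABLES) -> pd.DataFrame:
    """Counts and percentages of baseline characteristics by arm.

    One row per variable level; within each variable the percentages of each
    arm sum to 100.  Members are counted once per matched-set appearance
    (a reused comparator contributes to each of its sets), matching how the
    analysis weights them.
    """
    m = matched.merge(participants, on="person_id", how="left")
    rows = []
    for var in variables:
        v = m[var].astype(str)
        for level in sorted(v.unique()):
            sel = v == level
            n_exp = int((sel & m["exposed"]).sum())
            n_un = int((sel & ~m["exposed"]).sum())
            rows.append({
                "variable": var, "level": level,
                "exposed_n": n_exp,
                "exposed_pct": 100.0 * n_exp / max(int(m["exposed"].sum()), 1),
                "unexposed_n": n_un,
                "unexposed_pct": 100.0 * n_un / max(int((~m["exposed"]).sum()), 1),
            })
    return pd.DataFrame(rows)


def render_hr_table(hr_results: pd.DataFrame) -> pd.DataFrame:
    out = hr_results.copy()
    est = out.get("hr")
    out["hr_ci"] = [
        format_ratio_cell(e, lo, hi) if est.notna().iloc[i] else "NA"
        for i, (e, lo, hi) in enumerate(zip(out["hr"], out["ci_low"], out["ci_high"]))
    ]
    keep = [c for c in ("outcome", "window", "model", "n_cases_exposed",
                        "n_cases_unexposed", "incidence_exposed",
                        "incidence_unexposed", "hr_ci", "p") if c in out.columns]
    return out[keep]


def render_reports(run) -> None:
    """Write rendered report tables for a completed `PipelineRun`."""
    rdir = Path(run.outdir) / "reports"
    rdir.mkdir(exist_ok=True)
    baseline = baseline_table(run.participants, run.matched)
    baseline.to_csv(rdir / "baseline_characteristics.tsv", sep="\t",
                    index=False, float_format="%.2f")
    if getattr(run, "hr_table", None) is not None:
        render_hr_table(run.hr_table).to_csv(
            rdir / "hazard_ratios.tsv", sep="\t", index=False, float_format="%.4g")
    for attr, name in (("modification_table", "modification.tsv"),
                       ("subgroup_table", "subgroups.tsv")):
        tab = getattr(run, attr, None)
        if tab is not None and len(tab):
            tab = tab.copy()
            tab["hr_ci"] = [format_ratio_cell(e, lo, hi)
                            for e, lo, hi in zip(tab["hr"], tab["ci_low"],
                                                 tab["ci_high"])]
            tab.to_csv(rdir / name, sep="\t", index=False, float_format="%.4g")
    edges = getattr(run, "edges", None)
    if edges is not None and len(edges):
        tab = edges.copy()
        tab["or_ci"] = [format_ratio_cell(e, lo, hi)
                        for e, lo, hi in zip(tab["or"], tab["ci_low"],
                                             tab["ci_high"])]
        tab.to_csv(rdir / "trajectory_edges.tsv", sep="\t", index=False,
                   float_format="%.4g")
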