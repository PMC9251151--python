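"""The gp96-immune cell (GI) composite score and its survival stratification.

The GI score sums three binary high/low indicators — gp96 staining
extent, CD4+ cell density and PD-1+ cell density — giving an integer
0–3 per patient. Patients are stratified into the four score groups for
Kaplan–Meier display and log-rank testing; prognostic strength is
summarized by a Cox model treating the score as a per-unit covariate,
and by a multivariate model of the score-3 indicator adjusted for WHO
grade and IDH status.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd

from . import survival
from .quantify import dichotomize

INDICATORS = ("gp96_high", "cd4_high", "pd1_high")

# quantification column feeding each indicator
_SOURCE = {"gp96_high": "gp96_extent", "cd4_high": "cd4_density",
           "pd1_high": "pd1_density"}


def compute_gi(gp96_high, cd4_high, pd1_high) -> int:
    """Sum of the three binary indicators; missing values are an error."""
    total = 0
    for name, v in (("gp96_high", gp96_high), ("cd4_high", cd4_high),
                    ("pd1_high", pd1_high)):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing indicator {name}: GI score is not imputed")
        if v not in (0, 1, False, True):
            raise ValueError(f"indicator {name} must be binary, got {v!r}")
        total += int(v)
    return total


def build_gi_table(
    quant: pd.DataFrame,
    clinical: pd.DataFrame,
    mode: Literal["maxstat", "median"] = "maxstat",
    epsilon: float = 0.1,
) -> pd.DataFrame:
    """Per-patient GI records from a quantification table.

    ``quant`` is indexed by core/patient id with gp96_extent,
    cd4_density and pd1_density columns; ``clinical`` (patient_id,
    os_months, event) supplies the survival data that the maxstat
    dichotomization mode needs. Patients lacking follow-up are kept in
    the table (the score needs no survival) but excluded from cutpoint
    derivation.
    """
    clin = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    merged = quant.join(clin[["os_months", "event"]], how="left")
    complete = merged["os_months"].notna()
    out = pd.DataFrame(index=merged.index)
    for ind, col in _SOURCE.items():
        if mode == "maxstat":
            sub = merged.loc[complete]
            _, cutoff = dichotomize(
                sub[col], rule="maxstat",
                times=sub["os_months"].to_numpy(),
                events=sub["event"].to_numpy(int), epsilon=epsilon)
        else:
            _, cutoff = dichotomize(merged[col], rule="median")
        out[ind] = (merged[col] > cutoff).astype(int)
        out[ind.replace("_high", "_cutoff")] = cutoff
    out["score"] = out[list(INDICATORS)].sum(axis=1)
    return out


def _stratum_mask(clinical: pd.DataFrame, stratum: str) -> pd.Series:
    grade = clinical["grade"].astype(int)
    idh = clinical["idh"].astype(int)
    if stratum == "all":
        return pd.Series(True, index=clinical.index)
    if stratum == "IDHmut-LGG":
        return (idh == 1) & grade.isin([2, 3])
    if stratum == "IDHwt-GBM":
        return (idh == 0) & (grade == 4)
    raise ValueError(f"unknown stratum {stratum!r}")


def gi_stratification(
    gi: pd.DataFrame,
    clinical: pd.DataFrame,
    stratum: Literal["all", "IDHmut-LGG", "IDHwt-GBM"] = "all",
) -> dict:
    """Survival report for the four GI score groups within a stratum.

    Returns per-group sizes and KM median OS, the k-group log-rank test
    over the non-empty score groups, a per-unit Cox fit (score as a
    numeric 0-3 covariate), and a multivariate Cox fit of the score-3
    indicator adjusted for grade (per step above II) and IDH status.
    """
    clin = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    df = gi.join(clin, how="inner")
    df = df.loc[_stratum_mask(df, stratum) & df["os_months"].notna()]
    if df.empty:
        raise ValueError(f"stratum {stratum!r} is empty after follow-up filtering")
    times = df["os_months"].to_numpy(float)
    events = df["event"].to_numpy(int)
    scores = df["score"].to_numpy(int)

    warnings: list[str] = []
    groups = {}
    for s in range(4):
        m = scores == s
        if m.sum() == 0:
            groups[s] = {"n": 0, "n_events": 0, "median_os": None}
            continue
        km = survival.km_estimate(times[m], events[m])
        groups[s] = {
            "n": int(m.sum()), "n_events": int(events[m].sum()),
            "median_os": None if np.isinf(km.median_os) else km.median_os,
        }
    present = sorted({int(s) for s in scores})
    if len(present) < 2:
        raise ValueError(
            f"stratum {stratum!r} has a single GI group "
            f"(counts: { {s: groups[s]['n'] for s in range(4)} })")
    if len(present) < 4:
        warnings.append(
            f"only score groups {present} present; log-rank runs on "
            f"{len(present)} groups instead of 4")
    lr = survival.logrank_test(times, events, scores)

    per_unit = survival.cox_fit(times, events,
                                pd.DataFrame({"gi_score": scores}))
    covs = pd.DataFrame({
        "gi_score3": (scores == 3).astype(int),
        "grade_step": df["grade"].astype(int).to_numpy() - 2,
        "idh_mutant": df["idh"].astype(int).to_numpy(),
    })
    multivariate = survival.cox_fit(times, events, covs)

    def _cox_rows(res: survival.CoxResult) -> dict:
        return {c: {k: (None if not np.isfinite(v) else float(v))
                    for k, v in row.items()}
                for c, row in res.summary.iterrows()}

    return {
        "stratum": stratum,
        "n": int(len(df)),
        "n_events": int(events.sum()),
        "groups": groups,
        "logrank": {"chi2": lr.statistic, "df": lr.df, "p": lr.p_value},
        "cox_per_unit": _cox_rows(per_unit),
        "cox_multivariate": _cox_rows(multivariate),
        "warnings": warnings,
    }
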