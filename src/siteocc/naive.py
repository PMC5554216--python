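"""The naive (per-run ratio-of-sums) approach, kept for comparison.

The naive approach quantifies site occupancy within each single LC-MS run:
sum the feature intensities of a form at the site and divide by the summed
intensities of all forms at that site in that run.  Features that were not
detected in a run simply do not appear in either sum — so a form entirely
missing from a run scores occupancy 0 there, which is the bias mechanism the
model-based approach avoids.  Across replicate runs, the per-run occupancies
are averaged; the implicit model assumes i.i.d. normal residuals around that
mean, giving ``se = sd/sqrt(n)`` and a t interval on n-1 df.  Differential
occupancy is a two-sample Welch t-test on the per-run values.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError
from .differential import DifferentialResult, _direction
from .io import PeptideMapDataset
from .occupancy import OccupancyEstimate

log = logging.getLogger(__name__)

RUN_OCCUPANCY_COLUMNS = ["scope", "form_id", "run_id", "condition_id", "p"]


def _per_run_occupancy(totals: pd.DataFrame, scope: str) -> pd.DataFrame:
    """Occupancies from a table with columns form_id, run_id, condition_id, total."""
    out = []
    for (run, cond), grp in totals.groupby(["run_id", "condition_id"]):
        run_total = float(grp["total"].sum())
        if run_total <= 0:
            log.warning("run %s has zero total intensity at %s: skipped", run, scope)
            continue
        by_form = dict(zip(grp["form_id"], grp["total"]))
        for form in sorted(totals["form_id"].unique()):
            out.append({"scope": scope, "form_id": form, "run_id": run,
                        "condition_id": cond,
                        "p": by_form.get(form, 0.0) / run_total})
    return pd.DataFrame(out, columns=RUN_OCCUPANCY_COLUMNS)


def naive_occupancy(ds: PeptideMapDataset, site_id: str) -> pd.DataFrame:
    """Per-run occupancy of every form at one site (ratio of summed areas).

    A form with no observed feature in a run contributes zero to the
    numerator (it is absent from both sums), so its occupancy in that run
    is 0.  Runs with zero total intensity at the site yield no rows.
    """
    m = ds.measurements
    sub = m[m["site_id"] == site_id]
    if sub.empty:
        raise DataError(f"site {site_id} not present in the dataset")
    totals = (sub.groupby(["form_id", "run_id", "condition_id"], as_index=False)
              ["intensity"].sum().rename(columns={"intensity": "total"}))
    return _per_run_occupancy(totals, site_id)


def naive_estimate(run_occ: pd.DataFrame, level: float = 0.95,
                   ) -> List[OccupancyEstimate]:
    """Average per-run occupancies into one estimate per form × condition.

    ``p_hat`` is the mean over runs, ``se = sd/sqrt(n)``, and the CI uses the
    t distribution on n-1 df, clipped to [0, 1].  A condition with a single
    run yields an estimate without SE or CI.
    """
    if run_occ.empty:
        raise DataError("no per-run occupancies to average")
    out = []
    for (scope, form, cond), grp in run_occ.groupby(
            ["scope", "form_id", "condition_id"], sort=True):
        vals = grp["p"].to_numpy(dtype=float)
        n = len(vals)
        p_hat = float(vals.mean())
        if n >= 2:
            se = float(vals.std(ddof=1)) / math.sqrt(n)
            half = float(stats.t.ppf((1 + level) / 2, n - 1)) * se
            lo, hi = max(0.0, p_hat - half), min(1.0, p_hat + half)
            df = float(n - 1)
        else:
            se, lo, hi, df = math.nan, math.nan, math.nan, 0.0
        out.append(OccupancyEstimate(scope, form, cond, p_hat, se, lo, hi,
                                     df, method="naive"))
    return out


def naive_ttest(occ_a: pd.DataFrame, occ_b: pd.DataFrame) -> DifferentialResult:
    """Welch two-sample t-test on per-run occupancies of one form.

    Each input holds the per-run occupancies of the same form and scope in
    one condition; at least two runs per condition are required.
    """
    keys_a = occ_a[["scope", "form_id"]].drop_duplicates()
    keys_b = occ_b[["scope", "form_id"]].drop_duplicates()
    if (len(keys_a) != 1 or len(keys_b) != 1
            or tuple(keys_a.iloc[0]) != tuple(keys_b.iloc[0])):
        raise DataError("naive_ttest expects one identical (scope, form) per side")
    scope, form = keys_a.iloc[0]
    a = occ_a["p"].to_numpy(dtype=float)
    b = occ_b["p"].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError(f"{scope}/{form}: Welch t-test needs >= 2 runs per condition")
    delta = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    se = math.sqrt(va + vb)
    if se == 0.0:
        t_stat, df, p = (0.0, math.inf, 1.0) if delta == 0.0 else \
            (math.copysign(math.inf, delta), math.inf, 0.0)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t_stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return DifferentialResult(scope, form, "H1", delta, se, t_stat, df, p,
                              direction=_direction(delta), method="naive")


def naive_combined(ds: PeptideMapDataset, target_forms: Dict[str, Set[str]],
                   level: float = 0.95,
                   ) -> Tuple[pd.DataFrame, List[OccupancyEstimate]]:
    """Per-run combined occupancy over a site set, plus its naive estimate.

    Numerator: summed intensities of the target forms over all listed sites;
    denominator: summed intensities of all forms at those sites, per run.
    """
    if not target_forms or all(not v for v in target_forms.values()):
        raise DataError("empty target form set")
    sites = sorted(target_forms)
    m = ds.measurements
    sub = m[m["site_id"].isin(sites)]
    missing = set(sites) - set(sub["site_id"])
    if missing:
        raise DataError(f"site(s) {sorted(missing)} not present in the dataset")
    scope = "+".join(sites)
    label = "+".join(sorted({f for forms in target_forms.values() for f in forms}))

    in_target = [form in target_forms.get(site, set())
                 for site, form in zip(sub["site_id"], sub["form_id"])]
    sub = sub.assign(group=np.where(in_target, label, "__other__"))
    totals = (sub.groupby(["group", "run_id", "condition_id"], as_index=False)
              ["intensity"].sum().rename(columns={"intensity": "total",
                                                  "group": "form_id"}))
    per_run = _per_run_occupancy(totals, scope)
    per_run = per_run[per_run["form_id"] == label].reset_index(drop=True)
    estimates = naive_estimate(per_run, level) if not per_run.empty else []
    return per_run, estimates
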