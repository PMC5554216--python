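"""Whole-plot inference: per-condition log2 abundance of each form.

Run-level summaries are treated as independent whole-plot observations.  For
one form, the estimate for condition *k* is the mean of its run summaries;
the residual variance is pooled across all conditions of that form,

    s^2 = sum_k sum_r (s_kr - mu_k)^2 / df,   df = sum_k (n_k - 1),

and ``se_k = s / sqrt(n_k)``.  A condition observed in a single run still
gets a standard error from the pooled ``s``.  Variance is pooled within a
form only — different forms have different feature sets and noise levels.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .exceptions import DataError

ABUNDANCE_COLUMNS = ["site_id", "form_id", "condition_id",
                     "mu_hat", "se", "df", "n_runs"]


@dataclasses.dataclass(frozen=True)
class FormAbundance:
    """Model-based log2 abundance of one form in one condition."""

    site_id: str
    form_id: str
    condition_id: str
    mu_hat: float
    se: float      # NaN when no residual df is available
    df: float      # pooled residual df of the form's fit (0 if unavailable)
    n_runs: int


def fit_form(summaries: pd.DataFrame) -> Tuple[List[FormAbundance], pd.DataFrame]:
    """Fit the one-way whole-plot model for a single form.

    ``summaries`` must hold the run-level summaries of exactly one
    (site, form), with columns ``run_id, condition_id, log2_summary`` (and
    ``site_id, form_id``).  Returns one :class:`FormAbundance` per condition
    plus a residual table for model-assumption checks.
    """
    if summaries.empty:
        raise DataError("fit_form received no summaries")
    keys = summaries[["site_id", "form_id"]].drop_duplicates()
    if len(keys) != 1:
        raise DataError("fit_form expects summaries of exactly one form")
    site_id, form_id = keys.iloc[0]

    y = summaries["log2_summary"].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise DataError(f"non-finite summaries for {site_id}/{form_id}")

    means: Dict[str, float] = {}
    counts: Dict[str, int] = {}
    ss = 0.0
    df = 0
    fitted = np.empty_like(y)
    for cond, idx in summaries.groupby("condition_id").groups.items():
        vals = summaries.loc[idx, "log2_summary"].to_numpy(dtype=float)
        means[cond] = float(vals.mean())
        counts[cond] = len(vals)
        ss += float(((vals - means[cond]) ** 2).sum())
        df += len(vals) - 1
        fitted[summaries.index.get_indexer(idx)] = means[cond]

    s2 = ss / df if df > 0 else math.nan
    abundances = [
        FormAbundance(site_id, form_id, cond, means[cond],
                      math.sqrt(s2 / counts[cond]) if df > 0 else math.nan,
                      float(df), counts[cond])
        for cond in sorted(means)
    ]
    residuals = pd.DataFrame({
        "site_id": site_id,
        "form_id": form_id,
        "run_id": summaries["run_id"].to_numpy(),
        "condition_id": summaries["condition_id"].to_numpy(),
        "fitted": fitted,
        "residual": y - fitted,
    })
    return abundances, residuals


def fit_all_forms(summaries: pd.DataFrame) -> Tuple[List[FormAbundance], pd.DataFrame]:
    """Apply :func:`fit_form` to every (site, form) in a summary table."""
    abundances: List[FormAbundance] = []
    resid_parts = []
    for _, group in summaries.groupby(["site_id", "form_id"], sort=True):
        ab, resid = fit_form(group.reset_index(drop=True))
        abundances.extend(ab)
        resid_parts.append(resid)
    residuals = (pd.concat(resid_parts, ignore_index=True)
                 if resid_parts else pd.DataFrame())
    return abundances, residuals


def abundance_table(abundances: List[FormAbundance]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(a) for a in abundances],
                        columns=ABUNDANCE_COLUMNS)
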