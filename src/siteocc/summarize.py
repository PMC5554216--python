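"""Sub-plot summarization: one log2 abundance per (site, form, run).

Each modification form of a site is quantified by several spectral features
(charge states × isotopes of one or more peptides).  Before any whole-plot
inference, the per-run feature intensities are summarized in three steps:

1. **feature selection** — retain features with consistent coverage across
   runs, to avoid confounding by features with different ionization
   efficiency and sporadic detection;
2. **censored imputation** — unobserved cells are assumed censored below the
   detection limit and filled by an accelerated-failure-time-style censored
   normal regression (run + feature effects) truncated at a per-feature limit;
3. **Tukey median polish** — a robust additive decomposition
   ``log2 y = overall + run + feature + residual``; the run-level summary is
   ``overall + run effect``.

A simpler LogOfSum summary (log2 of the summed raw intensities of the
retained features per run) is available as an alternative.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DataError
from .io import PeptideMapDataset

log = logging.getLogger(__name__)

SUMMARY_COLUMNS = ["site_id", "form_id", "run_id", "condition_id", "log2_summary"]

#: censoring limit = LIMIT_FACTOR × minimum observed log2 intensity of a feature
LIMIT_FACTOR = 0.99


@dataclasses.dataclass
class FeatureMatrix:
    """Runs × features table of log2 intensities for one (site, form).

    ``values`` is indexed by run_id with feature labels as columns; missing
    cells are NaN and are interpreted as censored (below detection limit).
    ``conditions`` maps each run to its condition.
    """

    site_id: str
    form_id: str
    values: pd.DataFrame
    conditions: Dict[str, str]

    def __post_init__(self) -> None:
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise DataError(
                f"empty feature matrix for {self.site_id}/{self.form_id}")

    def _replace(self, values: pd.DataFrame) -> "FeatureMatrix":
        return FeatureMatrix(self.site_id, self.form_id, values, dict(self.conditions))


def feature_label(peptide_seq: str, charge: int, isotope: int) -> str:
    return f"{peptide_seq}.{int(charge)}.{int(isotope)}"


def build_feature_matrix(ds: PeptideMapDataset, site_id: str, form_id: str) -> FeatureMatrix:
    """Pivot the measurements of one form into a runs × features log2 matrix.

    Rows cover *all* runs of the design (a run with no observed feature is an
    all-NaN row, i.e. fully censored).
    """
    m = ds.measurements
    sub = m[(m["site_id"] == site_id) & (m["form_id"] == form_id)]
    if sub.empty:
        raise DataError(f"no measurements for {site_id}/{form_id}")
    sub = sub.assign(
        feature=[feature_label(p, z, i) for p, z, i in
                 zip(sub["peptide_seq"], sub["charge"], sub["isotope"])],
        log2=np.log2(sub["intensity"].to_numpy(dtype=float)),
    )
    mat = sub.pivot(index="run_id", columns="feature", values="log2")
    mat = mat.reindex(index=ds.runs, columns=sorted(mat.columns))
    return FeatureMatrix(site_id, form_id, mat, dict(ds.design))


# ---------------------------------------------------------------------------
# step 1: feature selection
# ---------------------------------------------------------------------------

def select_features(fm: FeatureMatrix, min_coverage: float = 0.5) -> FeatureMatrix:
    """Retain features observed in at least ``ceil(min_coverage × R)`` runs.

    If no feature qualifies, the single best-covered feature is retained
    (ties broken by higher total raw intensity, then lexicographic label), so
    the result is deterministic under permutation of the input columns.
    """
    if not 0.0 < min_coverage <= 1.0:
        raise DataError("min_coverage must lie in (0, 1]")
    vals = fm.values
    observed = vals.notna().sum(axis=0)
    if int(observed.sum()) == 0:
        raise DataError(f"no observed features for {fm.site_id}/{fm.form_id}")
    needed = math.ceil(min_coverage * vals.shape[0])
    keep = observed[observed >= needed].index
    if len(keep) == 0:
        total = np.exp2(vals).sum(axis=0)  # raw-intensity totals
        ranked = sorted(vals.columns,
                        key=lambda c: (-observed[c], -total[c], c))
        keep = ranked[:1]
    return fm._replace(vals[sorted(keep)])


# ---------------------------------------------------------------------------
# step 2: censored imputation
# ---------------------------------------------------------------------------

def _censored_additive_nll(params: np.ndarray, y: np.ndarray,
                           obs_mask: np.ndarray, limits: np.ndarray,
                           nrow: int, ncol: int) -> float:
    mu0 = params[0]
    row_eff = np.concatenate([[0.0], params[1:nrow]])
    col_eff = np.concatenate([[0.0], params[nrow:nrow + ncol - 1]])
    sigma = math.exp(min(max(params[-1], -10.0), 5.0))
    pred = mu0 + row_eff[:, None] + col_eff[None, :]
    ll = stats.norm.logpdf(y[obs_mask], loc=pred[obs_mask], scale=sigma).sum()
    cens = ~obs_mask
    if cens.any():
        lim = np.broadcast_to(limits[None, :], y.shape)[cens]
        ll += stats.norm.logcdf((lim - pred[cens]) / sigma).sum()
    return -ll


def impute_matrix(values: pd.DataFrame,
                  limit_factor: float = LIMIT_FACTOR,
                  ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Fill censored (NaN) cells of a runs × columns log2 matrix.

    Fits a censored normal linear model with additive row (run) and column
    effects by maximum likelihood, treating each NaN cell as left-censored at
    its column's limit (``limit_factor`` × the column's minimum observed
    value).  Imputed value = model prediction truncated at the limit, so an
    imputed cell never exceeds the limit.  Observed cells are unchanged.

    Returns ``(imputed matrix, censored-cell mask)``.  All-NaN rows are kept
    as NaN (a fully unobserved run yields no summary); all-NaN columns are
    dropped (a never-observed feature cannot be imputed).
    """
    vals = values.copy()
    dead_cols = vals.columns[vals.isna().all(axis=0)]
    if len(dead_cols):
        log.info("dropping %d never-observed feature column(s)", len(dead_cols))
        vals = vals.drop(columns=dead_cols)
    if vals.shape[1] == 0:
        raise DataError("no observed features to impute from")
    live_rows = ~vals.isna().all(axis=1)
    work = vals.loc[live_rows]
    cens_mask = work.isna()
    if not cens_mask.to_numpy().any():
        return vals, vals.isna() & False
    if int(work.notna().to_numpy().sum()) < 2:
        raise DataError("censored imputation needs >= 2 observed values")

    y = work.to_numpy(dtype=float)
    obs = ~np.isnan(y)
    nrow, ncol = y.shape
    limits = limit_factor * np.nanmin(y, axis=0)

    grand = float(np.nanmean(y))
    row_start = np.nan_to_num(np.nanmean(y, axis=1) - grand)
    col_start = np.nan_to_num(np.nanmean(y, axis=0) - grand)
    resid_sd = float(np.nanstd(y - (grand + row_start[:, None] + col_start[None, :])))
    x0 = np.concatenate([
        [grand + row_start[0] + col_start[0]],
        (row_start[1:] - row_start[0]) if nrow > 1 else [],
        (col_start[1:] - col_start[0]) if ncol > 1 else [],
        [math.log(max(resid_sd, 1e-2))],
    ])
    res = optimize.minimize(
        _censored_additive_nll, x0, args=(y, obs, limits, nrow, ncol),
        method="BFGS", options={"maxiter": 500})
    params = res.x
    mu0 = params[0]
    row_eff = np.concatenate([[0.0], params[1:nrow]])
    col_eff = np.concatenate([[0.0], params[nrow:nrow + ncol - 1]])
    pred = mu0 + row_eff[:, None] + col_eff[None, :]
    filled = np.where(obs, y, np.minimum(pred, limits[None, :]))

    out = vals.copy()
    out.loc[live_rows, :] = filled
    mask = out.isna() & False
    mask.loc[live_rows, :] = cens_mask
    return out, mask


def impute_censored(fm: FeatureMatrix, limit_factor: float = LIMIT_FACTOR) -> FeatureMatrix:
    """Censored imputation on a :class:`FeatureMatrix` (see :func:`impute_matrix`)."""
    filled, _ = impute_matrix(fm.values, limit_factor)
    return fm._replace(filled)


# ---------------------------------------------------------------------------
# step 3: Tukey median polish
# ---------------------------------------------------------------------------

def median_polish(x: np.ndarray, tol: float = 1e-6, max_iter: int = 100,
                  ) -> Tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Additive decomposition ``x = overall + row + col + residual``.

    Alternating row/column median sweeps, starting with rows; stops when the
    largest absolute change of any effect is below ``tol`` or after
    ``max_iter`` sweeps.  Even-length medians are midpoints of the two
    central order statistics (numpy's convention).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise DataError("median polish expects a 2-d matrix")
    overall = 0.0
    row = np.zeros(x.shape[0])
    col = np.zeros(x.shape[1])
    resid = x.copy()
    for _ in range(max_iter):
        prev = (overall, row.copy(), col.copy())
        rowmed = np.median(resid, axis=1)
        resid -= rowmed[:, None]
        row += rowmed
        d = float(np.median(col))
        col -= d
        overall += d
        colmed = np.median(resid, axis=0)
        resid -= colmed[None, :]
        col += colmed
        d = float(np.median(row))
        row -= d
        overall += d
        delta = max(abs(overall - prev[0]),
                    float(np.max(np.abs(row - prev[1]))),
                    float(np.max(np.abs(col - prev[2]))))
        if delta < tol:
            break
    return overall, row, col, resid


def tmp_summarize(fm: FeatureMatrix, tol: float = 1e-6, max_iter: int = 100) -> pd.DataFrame:
    """Run-level summaries ``overall + run effect`` from a complete matrix.

    Rows that are entirely NaN (fully censored runs) yield no summary; any
    other NaN indicates the matrix was not imputed and raises.
    """
    vals = fm.values
    live = ~vals.isna().all(axis=1)
    work = vals.loc[live]
    if work.isna().to_numpy().any():
        raise DataError("median polish needs a complete (imputed) matrix")
    overall, row_eff, _, _ = median_polish(work.to_numpy(dtype=float), tol, max_iter)
    return pd.DataFrame({
        "site_id": fm.site_id,
        "form_id": fm.form_id,
        "run_id": work.index,
        "condition_id": [fm.conditions[r] for r in work.index],
        "log2_summary": overall + row_eff,
    }).reset_index(drop=True)


def log_of_sum(fm: FeatureMatrix) -> pd.DataFrame:
    """Per-run log2 of the summed raw intensities of observed features."""
    sums = np.exp2(fm.values).sum(axis=1, min_count=1)
    out = sums.dropna()
    return pd.DataFrame({
        "site_id": fm.site_id,
        "form_id": fm.form_id,
        "run_id": out.index,
        "condition_id": [fm.conditions[r] for r in out.index],
        "log2_summary": np.log2(out.to_numpy(dtype=float)),
    }).reset_index(drop=True)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def summarize_form(ds: PeptideMapDataset, site_id: str, form_id: str,
                   method: str = "tmp", min_coverage: float = 0.5,
                   features: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Select → impute → summarize one form; returns run-level summaries.

    ``features`` overrides the selection step with an explicit label list
    (used for cross-form harmonization at a site).
    """
    fm = build_feature_matrix(ds, site_id, form_id)
    if features is not None:
        cols = [c for c in sorted(features) if c in fm.values.columns]
        if not cols:
            raise DataError(f"none of the requested features exist for "
                            f"{site_id}/{form_id}")
        fm = fm._replace(fm.values[cols])
    else:
        fm = select_features(fm, min_coverage)
    if method == "tmp":
        if fm.values.isna().to_numpy().any():
            fm = impute_censored(fm)
        return tmp_summarize(fm)
    if method == "logofsum":
        return log_of_sum(fm)
    raise DataError(f"unknown summarization method: {method!r}")


def harmonized_features(ds: PeptideMapDataset, site_id: str,
                        min_coverage: float = 0.5) -> Dict[str, List[str]]:
    """Per-form feature lists with charge states harmonized across forms.

    A charge state qualifies for the site if, in at least one form, a feature
    of that charge passes the coverage rule.  Each form then retains all of
    its observed features whose charge is in the site's qualified set.  This
    keeps forms comparable when, e.g., a charge state drops out of one form
    in a single run but is well covered elsewhere at the site.
    """
    qualified: set = set()
    selected: Dict[str, List[str]] = {}
    matrices: Dict[str, FeatureMatrix] = {}
    for form in ds.forms_at(site_id):
        fm = build_feature_matrix(ds, site_id, form)
        matrices[form] = fm
        picked = select_features(fm, min_coverage)
        qualified.update(int(c.rsplit(".", 2)[1]) for c in picked.values.columns)
    for form, fm in matrices.items():
        observed = fm.values.columns[fm.values.notna().any(axis=0)]
        cols = [c for c in observed if int(c.rsplit(".", 2)[1]) in qualified]
        selected[form] = sorted(cols) or list(select_features(fm, min_coverage).values.columns)
    return selected


def summarize_site(ds: PeptideMapDataset, site_id: str, method: str = "tmp",
                   min_coverage: float = 0.5, harmonize: bool = True) -> pd.DataFrame:
    """Run-level summaries for every form at one site."""
    chosen = (harmonized_features(ds, site_id, min_coverage)
              if harmonize else {f: None for f in ds.forms_at(site_id)})
    parts = []
    for form, feats in chosen.items():
        try:
            parts.append(summarize_form(ds, site_id, form, method,
                                        min_coverage, features=feats))
        except DataError as exc:
            log.warning("no summaries for %s/%s: %s", site_id, form, exc)
    if not parts:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def summarize_dataset(ds: PeptideMapDataset, method: str = "tmp",
                      min_coverage: float = 0.5, harmonize: bool = True) -> pd.DataFrame:
    """Run-level summaries for every (site, form) in the dataset."""
    parts = [summarize_site(ds, site, method, min_coverage, harmonize)
             for site in ds.sites()]
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=SUMMARY_COLUMNS)
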