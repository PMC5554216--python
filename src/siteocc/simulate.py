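"""Simulation framework: calibration and power of both analysis routes.

Datasets are simulated at the *summarized* level (the sub-plot summarization
is bypassed): for a single site with K forms at true occupancies p_1..p_K,
each run-level summary of form j is drawn independently as

    s_jr ~ Normal(mu_j, sd_log2),
    mu_j = mean_log2 + log2 p_j - (1/K) sum_l log2 p_l,

so that the occupancy implied by the mu's is exactly p and the mean of the
mu's equals ``mean_log2``.  The default configuration is three forms at
occupancies 5/20/75%, mean 25 and sd 0.2 on the log2 scale, with 1000
simulated datasets per setting.

The missing-data pattern removes the summary of one named form from one
replicate.  The model-based ("proposed") route treats the removed cell as
censored and imputes it within its condition's runs × forms summary matrix;
the naive route scores that form 0 in the affected run.  Power settings move
one form's occupancy in condition B by an absolute amount, rescaling the
remaining forms proportionally.

Run resampling draws (or enumerates) subsets of runs per condition, for
studying differential-analysis behaviour at small sample sizes.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Dict, Iterator, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, DataError
from . import summarize
from .differential import DifferentialResult, adjust_bh, result_table, test_h1
from .inference import FormAbundance, fit_form
from .io import PeptideMapDataset
from .naive import naive_estimate, naive_ttest
from .occupancy import OccupancyEstimate, occupancy_from_abundances

log = logging.getLogger(__name__)

SIM_SITE = "SIM"


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for the simulation experiments.

    ``occupancies`` must sum to 1.  ``effect`` is an absolute occupancy shift
    applied to ``effect_form`` in condition B during testing runs (0 = null).
    ``missing_form`` (optional) names the form whose summary is removed from
    replicate ``missing_replicate`` of condition ``missing_condition``.
    """

    occupancies: Tuple[float, ...] = (0.05, 0.20, 0.75)
    form_ids: Optional[Tuple[str, ...]] = None
    mean_log2: float = 25.0
    sd_log2: float = 0.2
    n_replicates: int = 3
    n_sims: int = 1000
    alpha: float = 0.05
    effect: float = 0.0
    effect_form: Optional[str] = None
    missing_form: Optional[str] = None
    missing_replicate: int = 1
    missing_condition: str = "A"
    level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        occ = tuple(float(p) for p in self.occupancies)
        if abs(sum(occ) - 1.0) > 1e-9:
            raise ConfigurationError("occupancies must sum to 1")
        if any(not 0.0 < p < 1.0 for p in occ):
            raise ConfigurationError("occupancies must lie in (0, 1)")
        self.occupancies = occ
        if self.form_ids is None:
            self.form_ids = tuple(f"form{i + 1}" for i in range(len(occ)))
        else:
            self.form_ids = tuple(self.form_ids)
        if len(self.form_ids) != len(occ):
            raise ConfigurationError("form_ids and occupancies differ in length")
        if self.effect_form is None:
            # default target: the form closest to 20% occupancy
            self.effect_form = self.form_ids[int(np.argmin(
                [abs(p - 0.20) for p in occ]))]
        if self.effect_form not in self.form_ids:
            raise ConfigurationError(f"unknown effect_form {self.effect_form!r}")
        if self.missing_form is not None and self.missing_form not in self.form_ids:
            raise ConfigurationError(f"unknown missing_form {self.missing_form!r}")
        if self.sd_log2 < 0:
            raise ConfigurationError("sd_log2 must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.effect:
            effect_occupancies(self.occupancies, self.effect,
                               self.form_ids.index(self.effect_form))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(f"bad simulation config {path}: {exc}") from exc


def mu_from_occupancies(occupancies: Sequence[float], mean_log2: float) -> np.ndarray:
    """Form means mu_j with occupancy(mu) = p and mean_j mu_j = mean_log2."""
    logs = np.log2(np.asarray(occupancies, dtype=float))
    return mean_log2 + logs - logs.mean()


def effect_occupancies(occupancies: Sequence[float], effect: float,
                       form_index: int) -> Tuple[float, ...]:
    """Shift one form's occupancy by ``effect`` (absolute), rescale the rest."""
    p = np.asarray(occupancies, dtype=float)
    target = p[form_index] + effect
    if not 0.0 < target < 1.0:
        raise ConfigurationError(
            f"effect {effect} pushes occupancy {p[form_index]} outside (0, 1)")
    out = p * (1.0 - target) / (1.0 - p[form_index])
    out[form_index] = target
    return tuple(float(v) for v in out)


def simulate_run_summaries(cfg: SimulationConfig,
                           rng: Optional[np.random.Generator] = None,
                           occupancies: Optional[Sequence[float]] = None,
                           condition_id: str = "A") -> pd.DataFrame:
    """One simulated dataset of run-level summaries for a single condition."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    occ = cfg.occupancies if occupancies is None else tuple(occupancies)
    mus = mu_from_occupancies(occ, cfg.mean_log2)
    draws = rng.normal(loc=mus[:, None], scale=cfg.sd_log2,
                       size=(len(occ), cfg.n_replicates))
    rows = []
    for j, form in enumerate(cfg.form_ids):
        for r in range(cfg.n_replicates):
            rows.append({"site_id": SIM_SITE, "form_id": form,
                         "run_id": f"{condition_id}_r{r + 1}",
                         "condition_id": condition_id,
                         "log2_summary": draws[j, r]})
    return pd.DataFrame(rows, columns=summarize.SUMMARY_COLUMNS)


def inject_missing(summaries: pd.DataFrame, form_id: str,
                   replicate_index: int, condition_id: str = "A") -> pd.DataFrame:
    """Remove the summary of one form in one replicate (1-based index)."""
    run_id = f"{condition_id}_r{replicate_index}"
    mask = (summaries["form_id"] == form_id) & (summaries["run_id"] == run_id)
    if not mask.any():
        raise DataError(f"no summary for form {form_id!r} in run {run_id!r}")
    return summaries[~mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# the two analysis routes, at the summarized level
# ---------------------------------------------------------------------------

def _design_of(summaries: pd.DataFrame,
               full_runs: Optional[Dict[str, str]] = None) -> Dict[str, str]:
    if full_runs is not None:
        return dict(full_runs)
    return dict(summaries[["run_id", "condition_id"]]
                .drop_duplicates().itertuples(index=False))


def proposed_site_estimates(summaries: pd.DataFrame,
                            design: Optional[Dict[str, str]] = None,
                            level: float = 0.95,
                            ) -> Tuple[Dict[str, List[OccupancyEstimate]],
                                       Dict[Tuple[str, str], FormAbundance]]:
    """Model-based occupancies per condition from run-level summaries.

    ``design`` lists *all* runs (run -> condition); a (form, run) cell with
    no summary is treated as censored and imputed within its condition's
    runs × forms matrix before the whole-plot fit.
    """
    design = _design_of(summaries, design)
    pivot = (summaries.pivot(index="run_id", columns="form_id",
                             values="log2_summary")
             .reindex(index=sorted(design), columns=sorted(summaries["form_id"].unique())))
    conditions = sorted(set(design.values()))
    blocks = []
    for cond in conditions:
        runs = sorted(r for r, c in design.items() if c == cond)
        block = pivot.loc[runs]
        if block.isna().to_numpy().any():
            block, _ = summarize.impute_matrix(block)
        blocks.append(block)
    completed = pd.concat(blocks)

    abundances: Dict[Tuple[str, str], FormAbundance] = {}
    for form in completed.columns:
        col = completed[form].dropna()
        form_summaries = pd.DataFrame({
            "site_id": SIM_SITE, "form_id": form,
            "run_id": col.index,
            "condition_id": [design[r] for r in col.index],
            "log2_summary": col.to_numpy(dtype=float),
        })
        for ab in fit_form(form_summaries)[0]:
            abundances[(form, ab.condition_id)] = ab

    estimates: Dict[str, List[OccupancyEstimate]] = {}
    for cond in conditions:
        per_cond = [abundances[(form, cond)] for form in completed.columns
                    if (form, cond) in abundances]
        estimates[cond] = occupancy_from_abundances(per_cond, level=level)
    return estimates, abundances


def naive_site_estimates(summaries: pd.DataFrame,
                         design: Optional[Dict[str, str]] = None,
                         level: float = 0.95,
                         ) -> Tuple[Dict[str, List[OccupancyEstimate]], pd.DataFrame]:
    """Naive per-run occupancies and their averages, from run summaries.

    Intensities are recovered as ``2^summary``; a form with no summary in a
    run contributes zero there (absent from both sums).
    """
    design = _design_of(summaries, design)
    forms = sorted(summaries["form_id"].unique())
    rows = []
    for run in sorted(design):
        sub = summaries[summaries["run_id"] == run]
        vals = dict(zip(sub["form_id"], sub["log2_summary"]))
        if not vals:
            log.warning("run %s has no summaries: skipped", run)
            continue
        shift = max(vals.values())     # numerical safety; ratios unchanged
        weights = {f: 2.0 ** (v - shift) for f, v in vals.items()}
        total = sum(weights.values())
        for form in forms:
            rows.append({"scope": SIM_SITE, "form_id": form, "run_id": run,
                         "condition_id": design[run],
                         "p": weights.get(form, 0.0) / total})
    run_occ = pd.DataFrame(rows, columns=["scope", "form_id", "run_id",
                                          "condition_id", "p"])
    estimates: Dict[str, List[OccupancyEstimate]] = {}
    for cond in sorted(set(design.values())):
        per_cond = naive_estimate(run_occ[run_occ["condition_id"] == cond], level)
        estimates[cond] = per_cond
    return estimates, run_occ


# ---------------------------------------------------------------------------
# evaluation experiments
# ---------------------------------------------------------------------------

def _simulate_condition(cfg: SimulationConfig, rng: np.random.Generator,
                        condition_id: str, occupancies: Sequence[float],
                        ) -> Tuple[pd.DataFrame, Dict[str, str]]:
    full = simulate_run_summaries(cfg, rng, occupancies, condition_id)
    design = dict(full[["run_id", "condition_id"]]
                  .drop_duplicates().itertuples(index=False))
    if cfg.missing_form is not None and condition_id == cfg.missing_condition:
        full = inject_missing(full, cfg.missing_form, cfg.missing_replicate,
                              condition_id)
    return full, design


def evaluate_estimation(cfg: SimulationConfig) -> pd.DataFrame:
    """Estimation accuracy/efficiency of both methods under the null.

    For each simulated single-condition dataset, both routes estimate the
    occupancies; reported per method × form: mean relative error
    ``(p_hat - p)/p`` and mean 95% CI width.
    """
    if cfg.effect:
        raise ConfigurationError("evaluate_estimation expects effect = 0")
    rng = np.random.default_rng(cfg.seed)
    idx = {f: j for j, f in enumerate(cfg.form_ids)}
    rel_err: Dict[Tuple[str, str], List[float]] = {}
    width: Dict[Tuple[str, str], List[float]] = {}
    for _ in range(cfg.n_sims):
        summaries, design = _simulate_condition(cfg, rng, "A", cfg.occupancies)
        prop, _ = proposed_site_estimates(summaries, design, cfg.level)
        naiv, _ = naive_site_estimates(summaries, design, cfg.level)
        for method, ests in (("proposed", prop["A"]), ("naive", naiv["A"])):
            for e in ests:
                p_true = cfg.occupancies[idx[e.form_id]]
                rel_err.setdefault((method, e.form_id), []).append(
                    (e.p_hat - p_true) / p_true)
                if math.isfinite(e.ci_low) and math.isfinite(e.ci_high):
                    width.setdefault((method, e.form_id), []).append(
                        e.ci_high - e.ci_low)
    rows = []
    for (method, form), errs in sorted(rel_err.items()):
        rows.append({
            "method": method, "form_id": form,
            "true_p": cfg.occupancies[idx[form]],
            "n_replicates": cfg.n_replicates,
            "missing_form": cfg.missing_form or "none",
            "mean_rel_error": float(np.mean(errs)),
            "mean_ci_width": float(np.mean(width.get((method, form), [math.nan]))),
            "n_sims": cfg.n_sims, "seed": cfg.seed,
        })
    return pd.DataFrame(rows)


def evaluate_testing(cfg: SimulationConfig) -> pd.DataFrame:
    """Type I error (effect = 0) or power (effect > 0) of both H1 routes.

    Two conditions are generated; condition B's occupancies carry the effect.
    Per simulated dataset, the proposed H1 test and the naive Welch t-test
    are applied to every form; rejection is at raw ``alpha`` (per-test
    calibration, no multiplicity adjustment inside the simulation).
    """
    rng = np.random.default_rng(cfg.seed)
    occ_b = cfg.occupancies
    if cfg.effect:
        occ_b = effect_occupancies(cfg.occupancies, cfg.effect,
                                   cfg.form_ids.index(cfg.effect_form))
    reject: Dict[Tuple[str, str], int] = {
        (m, f): 0 for m in ("proposed", "naive") for f in cfg.form_ids}
    for _ in range(cfg.n_sims):
        sum_a, des_a = _simulate_condition(cfg, rng, "A", cfg.occupancies)
        sum_b, des_b = _simulate_condition(cfg, rng, "B", occ_b)
        summaries = pd.concat([sum_a, sum_b], ignore_index=True)
        design = {**des_a, **des_b}

        prop, _ = proposed_site_estimates(summaries, design, cfg.level)
        occ_by_form = {c: {e.form_id: e for e in prop[c]} for c in ("A", "B")}
        for form in cfg.form_ids:
            res = test_h1(occ_by_form["A"][form], occ_by_form["B"][form])
            if res.p_value < cfg.alpha:
                reject[("proposed", form)] += 1

        _, run_occ = naive_site_estimates(summaries, design, cfg.level)
        for form in cfg.form_ids:
            sub = run_occ[run_occ["form_id"] == form]
            res = naive_ttest(sub[sub["condition_id"] == "A"],
                              sub[sub["condition_id"] == "B"])
            if res.p_value < cfg.alpha:
                reject[("naive", form)] += 1

    rows = [{
        "method": method, "form_id": form, "effect": cfg.effect,
        "effect_form": cfg.effect_form,
        "n_replicates": cfg.n_replicates,
        "missing_form": cfg.missing_form or "none",
        "rejection_rate": count / cfg.n_sims,
        "n_sims": cfg.n_sims, "alpha": cfg.alpha, "seed": cfg.seed,
    } for (method, form), count in sorted(reject.items())]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run resampling (small-sample behaviour)
# ---------------------------------------------------------------------------

def resample_runs(ds: PeptideMapDataset, per_condition_size: int,
                  seed: Optional[int] = None,
                  rng: Optional[np.random.Generator] = None) -> PeptideMapDataset:
    """Uniform subsample of runs, without replacement, per condition."""
    rng = np.random.default_rng(seed) if rng is None else rng
    keep: List[str] = []
    for cond in ds.conditions:
        runs = list(ds.runs_of(cond))
        if len(runs) < per_condition_size:
            raise DataError(f"condition {cond} has {len(runs)} runs "
                            f"< requested {per_condition_size}")
        keep.extend(rng.choice(runs, size=per_condition_size, replace=False))
    design = {r: ds.design[r] for r in keep}
    m = ds.measurements
    return PeptideMapDataset(
        m[m["run_id"].isin(keep)].reset_index(drop=True), design)


def enumerate_resamples(ds: PeptideMapDataset,
                        per_condition_size: int) -> Iterator[PeptideMapDataset]:
    """All run subsets of the given per-condition size, in deterministic order."""
    per_cond = []
    for cond in ds.conditions:
        runs = list(ds.runs_of(cond))
        if len(runs) < per_condition_size:
            raise DataError(f"condition {cond} has {len(runs)} runs "
                            f"< requested {per_condition_size}")
        per_cond.append(list(itertools.combinations(runs, per_condition_size)))
    m = ds.measurements
    for combo in itertools.product(*per_cond):
        keep = [r for subset in combo for r in subset]
        design = {r: ds.design[r] for r in keep}
        yield PeptideMapDataset(
            m[m["run_id"].isin(keep)].reset_index(drop=True), design)


def resampling_significance(ds: PeptideMapDataset, cond_a: str, cond_b: str,
                            per_condition_size: int,
                            min_coverage: float = 0.5,
                            max_subsets: Optional[int] = None,
                            seed: int = 0) -> pd.DataFrame:
    """Differential H1 significance across resampled run subsets.

    Runs the full proposed pipeline (summarize → fit → occupancy → H1 → BH)
    on every enumerated subset (optionally capped at ``max_subsets`` randomly
    chosen ones) and reports, per form, the max / median / min
    ``-log10 p_adj`` across subsets.
    """
    from .pipeline import proposed_differential  # local import: avoid cycle

    subsets = list(enumerate_resamples(
        _restrict_conditions(ds, [cond_a, cond_b]), per_condition_size))
    if max_subsets is not None and len(subsets) > max_subsets:
        rng = np.random.default_rng(seed)
        subsets = [subsets[i] for i in
                   rng.choice(len(subsets), size=max_subsets, replace=False)]
    sig: Dict[Tuple[str, str], List[float]] = {}
    for sub in subsets:
        results = proposed_differential(sub, cond_a, cond_b,
                                        min_coverage=min_coverage)
        for r in adjust_bh(results):
            val = -math.log10(r.p_adj) if r.p_adj > 0 else math.inf
            sig.setdefault((r.site_id, r.form_id), []).append(val)
    rows = [{
        "site_id": site, "form_id": form,
        "per_condition_size": per_condition_size,
        "n_subsets": len(vals),
        "max_neg_log10_p_adj": float(np.max(vals)),
        "median_neg_log10_p_adj": float(np.median(vals)),
        "min_neg_log10_p_adj": float(np.min(vals)),
    } for (site, form), vals in sorted(sig.items())]
    return pd.DataFrame(rows)


def _restrict_conditions(ds: PeptideMapDataset,
                         conditions: Sequence[str]) -> PeptideMapDataset:
    design = {r: c for r, c in ds.design.items() if c in conditions}
    if not design:
        raise DataError(f"no runs in conditions {list(conditions)}")
    m = ds.measurements
    return PeptideMapDataset(
        m[m["run_id"].isin(design)].reset_index(drop=True), design)
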