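"""End-to-end drivers: dataset → summaries → abundances → occupancy/tests.

These glue the pipeline stages together for a :class:`PeptideMapDataset`;
the CLI and the run-resampling analysis are thin wrappers over them.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .exceptions import DataError
from . import summarize
from .differential import DifferentialResult, test_h1, test_h2, test_h3
from .inference import FormAbundance, fit_all_forms
from .io import PeptideMapDataset
from .naive import naive_estimate, naive_occupancy, naive_ttest
from .occupancy import OccupancyEstimate, combined_occupancy, occupancy_from_abundances

log = logging.getLogger(__name__)


def proposed_abundances(ds: PeptideMapDataset, summary: str = "tmp",
                        min_coverage: float = 0.5, harmonize: bool = True,
                        ) -> Tuple[List[FormAbundance], pd.DataFrame, pd.DataFrame]:
    """Summarize every form and fit the whole-plot model.

    Returns (abundances, run-level summaries, residual table).
    """
    summaries = summarize.summarize_dataset(ds, summary, min_coverage, harmonize)
    if summaries.empty:
        raise DataError("no forms could be summarized")
    abundances, residuals = fit_all_forms(summaries)
    return abundances, summaries, residuals


def proposed_occupancies(ds: PeptideMapDataset, level: float = 0.95,
                         summary: str = "tmp", min_coverage: float = 0.5,
                         harmonize: bool = True) -> List[OccupancyEstimate]:
    """Model-based site occupancies for every site × condition."""
    abundances, _, _ = proposed_abundances(ds, summary, min_coverage, harmonize)
    return occupancies_from_fits(abundances, level)


def occupancies_from_fits(abundances: Sequence[FormAbundance],
                          level: float = 0.95) -> List[OccupancyEstimate]:
    by_site_cond: Dict[Tuple[str, str], List[FormAbundance]] = {}
    for ab in abundances:
        by_site_cond.setdefault((ab.site_id, ab.condition_id), []).append(ab)
    out: List[OccupancyEstimate] = []
    for (site, cond), group in sorted(by_site_cond.items()):
        try:
            out.extend(occupancy_from_abundances(group, level))
        except DataError as exc:
            log.warning("occupancy skipped for %s/%s: %s", site, cond, exc)
    return out


def naive_occupancies(ds: PeptideMapDataset,
                      level: float = 0.95) -> List[OccupancyEstimate]:
    """Naive per-run-averaged occupancies for every site × condition."""
    out: List[OccupancyEstimate] = []
    for site in ds.sites():
        out.extend(naive_estimate(naive_occupancy(ds, site), level))
    return out


def _reference_abundances(ds: PeptideMapDataset, reference_peptide: str,
                          summary: str, min_coverage: float,
                          ) -> Dict[str, FormAbundance]:
    """Whole-plot fit of the unmodified reference peptide, per condition."""
    m = ds.measurements
    sub = m[(m["peptide_seq"] == reference_peptide)
            & (m["form_id"] == "unmodified")]
    if sub.empty:
        raise DataError(f"reference peptide {reference_peptide!r} has no "
                        "unmodified measurements")
    site = sub["site_id"].iloc[0]
    ref_ds = PeptideMapDataset(sub.reset_index(drop=True), dict(ds.design))
    summaries = summarize.summarize_form(ref_ds, site, "unmodified",
                                         summary, min_coverage)
    abundances, _ = fit_all_forms(summaries)
    return {ab.condition_id: ab for ab in abundances}


def proposed_differential(ds: PeptideMapDataset, cond_a: str, cond_b: str,
                          hypothesis: str = "h1",
                          reference_peptide: Optional[str] = None,
                          level: float = 0.95, summary: str = "tmp",
                          min_coverage: float = 0.5, harmonize: bool = True,
                          ) -> List[DifferentialResult]:
    """Per-form differential tests between two conditions (proposed route).

    Forms lacking an estimate or SE in either condition are skipped with a
    warning — they cannot be tested, not an error of the comparison.
    """
    hypothesis = hypothesis.lower()
    if hypothesis not in ("h1", "h2", "h3"):
        raise DataError(f"unknown hypothesis {hypothesis!r}")
    if hypothesis == "h3" and not reference_peptide:
        raise DataError("H3 requires a reference peptide")
    for cond in (cond_a, cond_b):
        if cond not in ds.conditions:
            raise DataError(f"condition {cond!r} not in the design")

    abundances, _, _ = proposed_abundances(ds, summary, min_coverage, harmonize)
    results: List[DifferentialResult] = []

    if hypothesis == "h1":
        ests = occupancies_from_fits(abundances, level)
        by_key = {(e.scope, e.form_id, e.condition_id): e for e in ests}
        pairs = sorted({(e.scope, e.form_id) for e in ests})
        for site, form in pairs:
            ea = by_key.get((site, form, cond_a))
            eb = by_key.get((site, form, cond_b))
            if ea is None or eb is None:
                log.warning("H1 skipped for %s/%s: absent in a condition", site, form)
                continue
            try:
                results.append(test_h1(ea, eb))
            except DataError as exc:
                log.warning("H1 skipped for %s/%s: %s", site, form, exc)
        return results

    refs = (_reference_abundances(ds, reference_peptide, summary, min_coverage)
            if hypothesis == "h3" else {})
    if hypothesis == "h3":
        for cond in (cond_a, cond_b):
            if cond not in refs:
                raise DataError(f"reference abundance missing in condition {cond!r}")
    by_key = {(ab.site_id, ab.form_id, ab.condition_id): ab for ab in abundances}
    pairs = sorted({(ab.site_id, ab.form_id) for ab in abundances})
    for site, form in pairs:
        aa = by_key.get((site, form, cond_a))
        ab_ = by_key.get((site, form, cond_b))
        if aa is None or ab_ is None:
            log.warning("%s skipped for %s/%s: absent in a condition",
                        hypothesis.upper(), site, form)
            continue
        try:
            if hypothesis == "h2":
                results.append(test_h2(aa, ab_))
            else:
                results.append(test_h3(aa, ab_, refs[cond_a], refs[cond_b]))
        except DataError as exc:
            log.warning("%s skipped for %s/%s: %s", hypothesis.upper(),
                        site, form, exc)
    return results


def naive_differential(ds: PeptideMapDataset, cond_a: str, cond_b: str,
                       ) -> List[DifferentialResult]:
    """Naive Welch t-tests on per-run occupancies, per form."""
    results: List[DifferentialResult] = []
    for site in ds.sites():
        run_occ = naive_occupancy(ds, site)
        for form in sorted(run_occ["form_id"].unique()):
            sub = run_occ[run_occ["form_id"] == form]
            a = sub[sub["condition_id"] == cond_a]
            b = sub[sub["condition_id"] == cond_b]
            try:
                results.append(naive_ttest(a, b))
            except DataError as exc:
                log.warning("naive test skipped for %s/%s: %s", site, form, exc)
    return results


def proposed_combined(ds: PeptideMapDataset, target_forms: Dict[str, Set[str]],
                      level: float = 0.95, summary: str = "tmp",
                      min_coverage: float = 0.5, harmonize: bool = True,
                      ) -> List[OccupancyEstimate]:
    """Combined occupancy over a site set, one estimate per condition."""
    abundances, _, _ = proposed_abundances(ds, summary, min_coverage, harmonize)
    pool = [ab for ab in abundances if ab.site_id in target_forms]
    out = []
    for cond in ds.conditions:
        per_cond = [ab for ab in pool if ab.condition_id == cond]
        if per_cond:
            out.append(combined_occupancy(per_cond, target_forms, level))
    return out
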