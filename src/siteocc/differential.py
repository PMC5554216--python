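"""Differential site occupancy: tests of three null hypotheses.

For one form compared between conditions A and B, the tests differ in the
scale of the contrast (the "normalizing factor in the denominator"):

* **H1** — no difference in site occupancy: ``delta = p_A - p_B``, where p is
  the form's occupancy (its abundance normalized by the sum over all forms at
  the site).  This addresses the quantity of interest directly.
* **H2** — no difference in log2 abundance: ``delta = mu_A - mu_B``; identical
  to ordinary relative label-free quantification of the form alone.
* **H3** — as H2 but normalized by a reference peptide measured in the same
  runs: ``delta = (mu_A - rho_A) - (mu_B - rho_B)``; identical to label-free
  quantification against a global reference standard, and immune to global
  run-level intensity shifts.

In every case the statistic is the difference estimate divided by its
standard error, referred to a t distribution with Satterthwaite df.  Raw
p-values within one comparison family are adjusted by Benjamini-Hochberg
step-up to control the FDR.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError
from .inference import FormAbundance
from .occupancy import OccupancyEstimate, satterthwaite_df

log = logging.getLogger(__name__)

RESULT_COLUMNS = ["site_id", "form_id", "hypothesis", "delta_hat", "se",
                  "t_stat", "df", "p_value", "p_adj", "direction", "method"]


@dataclasses.dataclass(frozen=True)
class DifferentialResult:
    """One form's two-sided test of one null hypothesis (condition A vs B).

    ``delta_hat`` is on occupancy scale for H1 and log2 scale for H2/H3;
    positive values mean the form increased in condition A relative to B.
    """

    site_id: str
    form_id: str
    hypothesis: str        # "H1" | "H2" | "H3"
    delta_hat: float
    se: float
    t_stat: float
    df: float
    p_value: float
    p_adj: Optional[float] = None
    direction: str = "none"   # increased | decreased | none
    method: str = "proposed"


def _two_sided(delta: float, components: Sequence[Tuple[float, float]],
               ) -> Tuple[float, float, float, float]:
    """(se, t, df, p) for a difference with independent (se, df) components."""
    variances = [se * se for se, _ in components]
    dfs = [df for _, df in components]
    se = math.sqrt(sum(variances))
    if se == 0.0:
        if delta == 0.0:
            return 0.0, 0.0, math.inf, 1.0
        log.warning("zero SE with nonzero difference: p-value degenerates to 0")
        return 0.0, math.copysign(math.inf, delta), math.inf, 0.0
    df = satterthwaite_df(variances, dfs)
    t = delta / se
    if math.isinf(df):
        p = 2.0 * float(stats.norm.sf(abs(t)))
    else:
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return se, t, df, p


def _direction(delta: float) -> str:
    if delta > 0:
        return "increased"
    if delta < 0:
        return "decreased"
    return "none"


def _check_se(label: str, *ses: float) -> None:
    if any(not math.isfinite(se) for se in ses):
        raise DataError(f"{label}: standard error unavailable (needs >= 2 "
                        "runs in some condition of the fit)")


def _grouped_df(occ_a: OccupancyEstimate,
                occ_b: OccupancyEstimate) -> Optional[float]:
    """Satterthwaite df with per-form variance terms recombined across
    conditions.

    Both conditions' occupancy variances draw on the *same* pooled per-form
    residual variances, so each form contributes one chi-square — summing
    its two condition terms — rather than two independent ones.  Requires
    both estimates to carry matching component breakdowns.
    """
    if occ_a.components is None or occ_b.components is None:
        return None
    a = {f: (t, d) for f, t, d in occ_a.components}
    b = {f: (t, d) for f, t, d in occ_b.components}
    if set(a) != set(b) or any(a[f][1] != b[f][1] for f in a):
        return None
    terms = [a[f][0] + b[f][0] for f in a]
    dfs = [a[f][1] for f in a]
    return satterthwaite_df(terms, dfs)


def test_h1(occ_a: OccupancyEstimate, occ_b: OccupancyEstimate,
            method: str = "proposed") -> DifferentialResult:
    """H1: no difference in site occupancy of the form between conditions."""
    if (occ_a.form_id != occ_b.form_id) or (occ_a.scope != occ_b.scope):
        raise DataError("H1 test needs the same form and scope in both conditions")
    _check_se(f"{occ_a.scope}/{occ_a.form_id}", occ_a.se, occ_b.se)
    delta = occ_a.p_hat - occ_b.p_hat
    se, t, df, p = _two_sided(delta, [(occ_a.se, occ_a.df_eff),
                                      (occ_b.se, occ_b.df_eff)])
    grouped = _grouped_df(occ_a, occ_b)
    if grouped is not None and se > 0.0:
        df = grouped
        p = (2.0 * float(stats.norm.sf(abs(t))) if math.isinf(df)
             else 2.0 * float(stats.t.sf(abs(t), df)))
    return DifferentialResult(occ_a.scope, occ_a.form_id, "H1", delta, se, t,
                              df, p, direction=_direction(delta), method=method)


def test_h2(ab_a: FormAbundance, ab_b: FormAbundance,
            method: str = "proposed") -> DifferentialResult:
    """H2: no difference in log2 abundance of the form between conditions."""
    if (ab_a.form_id != ab_b.form_id) or (ab_a.site_id != ab_b.site_id):
        raise DataError("H2 test needs the same form in both conditions")
    _check_se(f"{ab_a.site_id}/{ab_a.form_id}", ab_a.se, ab_b.se)
    delta = ab_a.mu_hat - ab_b.mu_hat
    se, t, df, p = _two_sided(delta, [(ab_a.se, ab_a.df), (ab_b.se, ab_b.df)])
    return DifferentialResult(ab_a.site_id, ab_a.form_id, "H2", delta, se, t,
                              df, p, direction=_direction(delta), method=method)


def test_h3(ab_a: FormAbundance, ab_b: FormAbundance,
            ref_a: Optional[FormAbundance], ref_b: Optional[FormAbundance],
            method: str = "proposed") -> DifferentialResult:
    """H3: no difference in reference-normalized log2 abundance."""
    if (ab_a.form_id != ab_b.form_id) or (ab_a.site_id != ab_b.site_id):
        raise DataError("H3 test needs the same form in both conditions")
    for ref, ab in ((ref_a, ab_a), (ref_b, ab_b)):
        if ref is None:
            raise DataError(f"reference abundance missing in condition "
                            f"{ab.condition_id}")
    _check_se(f"{ab_a.site_id}/{ab_a.form_id}", ab_a.se, ab_b.se,
              ref_a.se, ref_b.se)
    delta = (ab_a.mu_hat - ref_a.mu_hat) - (ab_b.mu_hat - ref_b.mu_hat)
    se, t, df, p = _two_sided(delta, [(ab_a.se, ab_a.df), (ab_b.se, ab_b.df),
                                      (ref_a.se, ref_a.df), (ref_b.se, ref_b.df)])
    return DifferentialResult(ab_a.site_id, ab_a.form_id, "H3", delta, se, t,
                              df, p, direction=_direction(delta), method=method)


def adjust_bh(results: Sequence[DifferentialResult]) -> List[DifferentialResult]:
    """Benjamini-Hochberg step-up adjustment over one comparison family.

    The family is exactly the list passed in (all forms of one comparison
    under one hypothesis); callers decide the grouping.
    """
    if not results:
        return []
    pvals = [r.p_value for r in results]
    if any(not 0.0 <= p <= 1.0 for p in pvals):
        raise DataError("raw p-values must lie in [0, 1]")
    adj = multipletests(pvals, method="fdr_bh")[1]
    return [dataclasses.replace(r, p_adj=float(a)) for r, a in zip(results, adj)]


@dataclasses.dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts of differential calls against control labels."""

    TP: int
    FN: int
    FP: int
    TN: int

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) else math.nan

    @property
    def specificity(self) -> float:
        return self.TN / (self.FP + self.TN) if (self.FP + self.TN) else math.nan

    @property
    def ppv(self) -> float:
        return self.TP / (self.TP + self.FP) if (self.TP + self.FP) else math.nan

    def to_dict(self) -> Dict[str, Optional[float]]:
        def _num(x: float) -> Optional[float]:
            return None if math.isnan(x) else x   # undefined ratio -> JSON null
        return {"TP": self.TP, "FN": self.FN, "FP": self.FP, "TN": self.TN,
                "sensitivity": _num(self.sensitivity),
                "specificity": _num(self.specificity), "ppv": _num(self.ppv)}


def confusion(results: Sequence[DifferentialResult],
              truth: Mapping, fdr_cutoff: float = 0.05) -> ConfusionSummary:
    """Score adjusted calls (``p_adj < fdr_cutoff``) against expected-change flags.

    ``truth`` maps ``(site_id, form_id)`` (or bare ``form_id``) to a boolean:
    True when the form is expected to change (positive control).
    """
    tp = fn = fp = tn = 0
    for r in results:
        if r.p_adj is None:
            raise DataError(f"{r.site_id}/{r.form_id}: p_adj missing — run "
                            "adjust_bh before confusion")
        key = (r.site_id, r.form_id)
        if key in truth:
            expected = truth[key]
        elif r.form_id in truth:
            expected = truth[r.form_id]
        else:
            raise DataError(f"no truth label for {r.site_id}/{r.form_id}")
        called = r.p_adj < fdr_cutoff
        if expected and called:
            tp += 1
        elif expected:
            fn += 1
        elif called:
            fp += 1
        else:
            tn += 1
    return ConfusionSummary(tp, fn, fp, tn)


def result_table(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    """Volcano-plot table: one row per form with delta and -log10 p_adj."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in results],
                      columns=RESULT_COLUMNS)
    df["neg_log10_p_adj"] = [
        -math.log10(p) if p is not None and p > 0 else math.inf
        for p in df["p_adj"]]
    return df
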