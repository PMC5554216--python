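"""Site occupancy and combined occupancy with delta-method uncertainty.

Site occupancy of form *j* at a site is the relative abundance

    p_j = 2^{mu_j} / sum_l 2^{mu_l}

over all forms *l* at that site in one condition.  The standard error of the
plug-in estimate is obtained by the delta method: with forms treated as
independent,

    Var(p_j) ~= (ln 2)^2 * sum_l [p_j (delta_jl - p_l)]^2 Var(mu_l)

where ``delta_jl`` is the Kronecker delta.  Because the contributing
variances carry different degrees of freedom, an effective df is formed by
Satterthwaite's approximation and the confidence interval uses the t
distribution on that df, clipped to [0, 1].

Combined occupancy pools a set of target forms across several sites,

    P = sum_{i in S} sum_{j in target_i} 2^{mu_ij} / sum_{i in S} sum_j 2^{mu_ij},

which weights each site by its raw summed abundance — equivalent to assuming
identical ionization efficiency of the peptide features across sites.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError
from .inference import FormAbundance

log = logging.getLogger(__name__)

LN2 = math.log(2.0)

OCCUPANCY_COLUMNS = ["scope", "form_id", "condition_id", "p_hat", "se",
                     "ci_low", "ci_high", "df_eff", "method"]


@dataclasses.dataclass(frozen=True)
class OccupancyEstimate:
    """Occupancy of one form (or target set) in one condition, on [0, 1].

    ``components`` (optional) breaks Var(p_hat) into per-form variance terms
    ``(form_id, term, df)``.  Because each form's residual variance is pooled
    across conditions, a between-condition contrast must recombine these
    per form rather than treat the two condition SEs as independent; the
    differential tests use them when present.
    """

    scope: str              # site id, or '+'-joined site set for combined
    form_id: str
    condition_id: str
    p_hat: float
    se: float
    ci_low: float
    ci_high: float
    df_eff: float
    method: str = "proposed"
    components: Optional[Tuple[Tuple[str, float, float], ...]] = None


def satterthwaite_df(variance_terms: Sequence[float], dfs: Sequence[float]) -> float:
    """Effective df of a sum of independent variance components.

    ``df_eff = (sum v_l)^2 / sum v_l^2 / df_l`` over terms with positive
    variance; infinite when every term is zero (a degenerate, noiseless fit).
    """
    total = float(sum(variance_terms))
    if total <= 0.0:
        return math.inf
    denom = 0.0
    for v, df in zip(variance_terms, dfs):
        if v > 0.0:
            if not (df > 0.0):
                raise DataError("variance component with nonpositive df")
            denom += v * v / df
    return total * total / denom if denom > 0.0 else math.inf


def _t_quantile(level: float, df: float) -> float:
    q = (1.0 + level) / 2.0
    if math.isinf(df):
        return float(stats.norm.ppf(q))
    return float(stats.t.ppf(q, df))


def _weights(mus: np.ndarray) -> np.ndarray:
    # shift by max before exponentiating: occupancy is invariant to a common
    # shift of the mu's, and 2^25-scale values would otherwise lose precision
    w = np.exp2(mus - mus.max())
    return w / w.sum()


def occupancy_from_abundances(abundances: Sequence[FormAbundance],
                              level: float = 0.95,
                              method: str = "proposed",
                              ) -> List[OccupancyEstimate]:
    """Delta-method occupancy of every form at one site in one condition.

    ``abundances`` must contain all forms of a single site and condition.
    Occupancies sum to exactly 1 across the returned estimates.
    """
    if not abundances:
        raise DataError("no abundances given")
    sites = {a.site_id for a in abundances}
    conds = {a.condition_id for a in abundances}
    if len(sites) != 1 or len(conds) != 1:
        raise DataError("occupancy_from_abundances expects one site and one condition")
    site, cond = sites.pop(), conds.pop()
    abundances = sorted(abundances, key=lambda a: a.form_id)

    if len(abundances) == 1:
        log.warning("single form at %s/%s: occupancy degenerate at 1", site, cond)
        a = abundances[0]
        return [OccupancyEstimate(site, a.form_id, cond, 1.0, 0.0, 1.0, 1.0,
                                  math.inf, method)]

    mus = np.array([a.mu_hat for a in abundances], dtype=float)
    if not np.isfinite(mus).all():
        bad = [a.form_id for a in abundances if not math.isfinite(a.mu_hat)]
        raise DataError(f"non-finite abundance estimate for form(s) {bad}")
    ses = np.array([a.se for a in abundances], dtype=float)
    if not np.isfinite(ses).all():
        bad = [a.form_id for a in abundances if not math.isfinite(a.se)]
        raise DataError(f"missing SE for form(s) {bad}: need >= 2 runs in "
                        "some condition of their fit")
    dfs = np.array([a.df for a in abundances], dtype=float)

    p = _weights(mus)
    variances = ses ** 2
    out: List[OccupancyEstimate] = []
    for j, a in enumerate(abundances):
        grad = LN2 * p[j] * ((np.arange(len(p)) == j).astype(float) - p)
        terms = grad ** 2 * variances
        var_p = float(terms.sum())
        se_p = math.sqrt(var_p)
        df_eff = satterthwaite_df(terms, dfs)
        half = _t_quantile(level, df_eff) * se_p if se_p > 0 else 0.0
        comps = tuple((b.form_id, float(t), float(d))
                      for b, t, d in zip(abundances, terms, dfs))
        out.append(OccupancyEstimate(
            site, a.form_id, cond, float(p[j]), se_p,
            max(0.0, float(p[j]) - half), min(1.0, float(p[j]) + half),
            df_eff, method, comps))
    return out


def combined_occupancy(abundances: Sequence[FormAbundance],
                       target_forms: Dict[str, Set[str]],
                       level: float = 0.95,
                       method: str = "proposed",
                       ) -> OccupancyEstimate:
    """Occupancy of a modification class pooled over several sites.

    ``abundances`` must contain, for one condition, *all* forms of every site
    named in ``target_forms`` (site -> set of its target form ids).  The
    estimate pools raw abundances, i.e. assumes identical ionization
    efficiency across sites.
    """
    if not target_forms or all(not v for v in target_forms.values()):
        raise DataError("empty target form set")
    conds = {a.condition_id for a in abundances}
    if len(conds) != 1:
        raise DataError("combined_occupancy expects a single condition")
    cond = conds.pop()
    sites = sorted(target_forms)
    pool = [a for a in abundances if a.site_id in target_forms]
    missing_sites = set(sites) - {a.site_id for a in pool}
    if missing_sites:
        raise DataError(f"no abundances for site(s) {sorted(missing_sites)}")
    for site, forms in target_forms.items():
        present = {a.form_id for a in pool if a.site_id == site}
        absent = set(forms) - present
        if absent:
            raise DataError(f"target form(s) {sorted(absent)} absent at {site}")

    pool = sorted(pool, key=lambda a: (a.site_id, a.form_id))
    mus = np.array([a.mu_hat for a in pool], dtype=float)
    ses = np.array([a.se for a in pool], dtype=float)
    if not (np.isfinite(mus).all() and np.isfinite(ses).all()):
        bad = [(a.site_id, a.form_id) for a in pool
               if not (math.isfinite(a.mu_hat) and math.isfinite(a.se))]
        raise DataError(f"missing estimate or SE for {bad}")
    dfs = np.array([a.df for a in pool], dtype=float)
    in_target = np.array([a.form_id in target_forms[a.site_id] for a in pool])

    q = _weights(mus)
    P = float(q[in_target].sum())
    grad = LN2 * q * (in_target.astype(float) - P)
    terms = grad ** 2 * ses ** 2
    var_p = float(terms.sum())
    se_p = math.sqrt(var_p)
    df_eff = satterthwaite_df(terms, dfs)
    half = _t_quantile(level, df_eff) * se_p if se_p > 0 else 0.0
    label = "+".join(sorted({f for forms in target_forms.values() for f in forms}))
    comps = tuple((f"{a.site_id}/{a.form_id}", float(t), float(d))
                  for a, t, d in zip(pool, terms, dfs))
    return OccupancyEstimate(
        "+".join(sites), label, cond, P, se_p,
        max(0.0, P - half), min(1.0, P + half), df_eff, method, comps)


def occupancy_table(estimates: Sequence[OccupancyEstimate]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(e) for e in estimates],
                        columns=OCCUPANCY_COLUMNS)
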