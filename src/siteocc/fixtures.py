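"""Synthetic Skyline-like fixture generator.

Builds a feature-level report (sites × forms × charges × isotopes × runs), a
run→condition design table and a truth table of the occupancies used, for
end-to-end exercises and parameter-recovery checks.  All values are
synthetic: intensities follow the same generative scheme as the simulation
module (log2-normal noise around form means implied by the occupancies),
partitioned over features with fixed charge/isotope envelope weights.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .simulate import mu_from_occupancies

log = logging.getLogger(__name__)

DEFAULT_SPEC: Dict = {
    "sites": {
        "M251": {
            "peptide": "DTLMISR",
            "forms": {"unmodified": 0.75, "M251[+16]": 0.20, "M251[+32]": 0.05},
        },
        "M428": {
            "peptide": "WQQGNVFSCSVMHEALHNHYTQK",
            "forms": {"unmodified": 0.90, "M428[+16]": 0.10},
        },
    },
    "charges": [2, 3],
    "n_isotopes": 3,
    "conditions": {"A": 3, "B": 6},
    "mean_log2": 25.0,
    "sd_log2": 0.2,
    "missing": [],      # entries: {site, form, run} or {site, form, run, charge}
    "low_idotp": [],    # same selectors; stamps idotp 0.5 on matching rows
}

#: relative ionization of successive charge states / isotope peaks
CHARGE_WEIGHTS = (0.6, 0.3, 0.1)
ISOTOPE_WEIGHTS = (0.5, 0.3, 0.15, 0.05, 0.02)


def _weights(values, n):
    w = np.asarray(values[:n], dtype=float)
    return w / w.sum()


def _form_occupancy(spec_forms: Dict, condition: str) -> Dict[str, float]:
    """Form → occupancy for one condition (scalar or per-condition dict)."""
    occ = {}
    for form, val in spec_forms.items():
        occ[form] = float(val[condition]) if isinstance(val, dict) else float(val)
    total = sum(occ.values())
    if abs(total - 1.0) > 1e-6:
        raise ConfigurationError(
            f"form occupancies sum to {total:.6f}, expected 1")
    return occ


def generate_fixture_frames(spec: Optional[Dict] = None, seed: int = 0,
                            ) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Return (report, design, truth) DataFrames for a fixture spec."""
    spec = {**DEFAULT_SPEC, **(spec or {})}
    rng = np.random.default_rng(seed)
    charges = list(spec["charges"])
    n_iso = int(spec["n_isotopes"])
    cw = _weights(CHARGE_WEIGHTS, len(charges))
    iw = _weights(ISOTOPE_WEIGHTS, n_iso)

    design_rows = []
    runs: Dict[str, str] = {}
    for cond, n_rep in spec["conditions"].items():
        for r in range(int(n_rep)):
            run = f"{cond}_r{r + 1}"
            runs[run] = cond
            design_rows.append({"run_id": run, "condition_id": cond})

    def _matches(sel: Dict, site, form, run, charge) -> bool:
        return (sel.get("site", site) == site and sel.get("form", form) == form
                and sel.get("run", run) == run
                and sel.get("charge", charge) == charge)

    report_rows = []
    truth_rows = []
    for site, site_spec in spec["sites"].items():
        peptide = site_spec["peptide"]
        for cond in spec["conditions"]:
            occ = _form_occupancy(site_spec["forms"], cond)
            forms = sorted(occ)
            mus = mu_from_occupancies([occ[f] for f in forms], spec["mean_log2"])
            for form, mu in zip(forms, mus):
                truth_rows.append({"site_id": site, "form_id": form,
                                   "condition_id": cond, "occupancy": occ[form]})
                for run, run_cond in runs.items():
                    if run_cond != cond:
                        continue
                    form_total = 2.0 ** (mu + rng.normal(0.0, spec["sd_log2"]))
                    for ci, charge in enumerate(charges):
                        if any(_matches(s, site, form, run, charge)
                               for s in spec.get("missing", [])):
                            continue
                        for ii in range(n_iso):
                            idotp = 0.99
                            if any(_matches(s, site, form, run, charge)
                                   for s in spec.get("low_idotp", [])):
                                idotp = 0.5
                            noise = 2.0 ** rng.normal(0.0, spec["sd_log2"] / 2)
                            report_rows.append({
                                "site_id": site, "peptide_seq": peptide,
                                "form_id": form, "charge": charge,
                                "isotope": ii, "run_id": run,
                                "intensity": form_total * cw[ci] * iw[ii] * noise,
                                "idotp": idotp,
                                "rt_min": 30.0 + 5.0 * ci,
                            })
    report = pd.DataFrame(report_rows)
    design = pd.DataFrame(design_rows)
    # truth: one row per (site, form, condition) plus a changed flag
    truth = pd.DataFrame(truth_rows)
    changed = (truth.groupby(["site_id", "form_id"])["occupancy"]
               .transform(lambda s: s.nunique() > 1))
    truth["changed"] = changed
    return report, design, truth


def make_fixture(spec: Optional[Dict] = None, seed: int = 0,
                 out_dir: str | Path = ".") -> Dict[str, Path]:
    """Write report.csv, design.csv and truth.csv; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report, design, truth = generate_fixture_frames(spec, seed)
    paths = {
        "report": out_dir / "report.csv",
        "design": out_dir / "design.csv",
        "truth": out_dir / "truth.csv",
    }
    report.to_csv(paths["report"], index=False)
    design.to_csv(paths["design"], index=False)
    truth.to_csv(paths["truth"], index=False)
    log.info("fixture written to %s (%d report rows)", out_dir, len(report))
    return paths


def load_fixture_spec(path: str | Path) -> Dict:
    with open(path) as fh:
        spec = yaml.safe_load(fh) or {}
    if not isinstance(spec, dict):
        raise ConfigurationError(f"fixture spec {path} must be a mapping")
    return spec
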