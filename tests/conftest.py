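"""Shared fixtures: tiny programmatically built datasets."""

import numpy as np
import pandas as pd
import pytest

from siteocc.io import CANONICAL_COLUMNS, PeptideMapDataset


def make_dataset(rows, design):
    """Build a PeptideMapDataset from compact measurement tuples.

    Each row: (site, peptide, form, charge, isotope, run, intensity[, idotp]).
    """
    recs = []
    for row in rows:
        site, pep, form, z, iso, run, inten = row[:7]
        idotp = row[7] if len(row) > 7 else np.nan
        recs.append({"site_id": site, "peptide_seq": pep, "form_id": form,
                     "charge": z, "isotope": iso, "run_id": run,
                     "condition_id": design[run], "intensity": float(inten),
                     "idotp": idotp, "rt_min": np.nan})
    return PeptideMapDataset(pd.DataFrame(recs, columns=CANONICAL_COLUMNS),
                             dict(design))


@pytest.fixture
def two_form_one_run():
    """One site, one run: oxidized area 1 vs unmodified area 19."""
    design = {"r1": "C1"}
    return make_dataset([
        ("M1", "PEPM", "M1[+16]", 2, 0, "r1", 1.0),
        ("M1", "PEPM", "unmodified", 2, 0, "r1", 19.0),
    ], design)


@pytest.fixture
def small_fixture(tmp_path):
    """Synthetic Skyline-like report/design/truth files on disk."""
    from siteocc.fixtures import make_fixture
    spec = {
        "sites": {
            "M251": {"peptide": "DTLMISR",
                     "forms": {"unmodified": 0.75, "M251[+16]": 0.20,
                               "M251[+32]": 0.05}},
        },
        "charges": [2, 3],
        "n_isotopes": 2,
        "conditions": {"A": 3, "B": 6},
        "sd_log2": 0.15,
    }
    return make_fixture(spec, seed=42, out_dir=tmp_path), spec
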