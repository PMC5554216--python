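"""Reading feature-level peptide-mapping reports and study designs.

The input is a Skyline-style "custom report": a CSV with one row per quantified
peptide feature per LC-MS/MS run, where a *feature* is a combination of peptide
sequence, modification form, charge state and isotope index, quantified by the
integrated chromatographic peak area.  Column names in such reports are
user-defined, so a :class:`SchemaConfig` maps report columns onto the canonical
fields.  A separate two-column design table maps each run to its condition.

The canonical in-memory container is :class:`PeptideMapDataset`: a long-format
:class:`pandas.DataFrame` of measurements plus the run→condition design.  Two
data-quality filters from the peptide-mapping workflow are provided:

* :func:`filter_idotp` removes features whose isotopic dot product (the match
  between observed and theoretical isotope envelopes) falls strictly below a
  threshold (default 0.7);
* :func:`restrict_single_site` removes peptide forms modified at more than one
  site, so that every retained feature is attributable to exactly one site.
  Carboxymethylated cysteine (+58 Da, introduced during sample preparation) is
  not counted as a modification.

Zero or blank peak areas are treated as *unobserved* (below the detection
limit), not as measured zeros: such rows are dropped here and reappear
downstream as censored missing cells.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, DataError

log = logging.getLogger(__name__)

#: canonical long-format columns of a dataset
CANONICAL_COLUMNS = [
    "site_id", "peptide_seq", "form_id", "charge", "isotope",
    "run_id", "condition_id", "intensity", "idotp", "rt_min",
]

#: columns identifying one feature (a quantifiable ion)
FEATURE_KEY = ["peptide_seq", "form_id", "charge", "isotope"]

REQUIRED_FIELDS = ["site_id", "peptide_seq", "form_id", "charge",
                   "isotope", "run_id", "intensity"]
OPTIONAL_FIELDS = ["idotp", "rt_min"]


def _default_columns() -> Dict[str, str]:
    return {f: f for f in REQUIRED_FIELDS + OPTIONAL_FIELDS}


@dataclasses.dataclass
class SchemaConfig:
    """Mapping from a report's header onto canonical fields, plus parse rules.

    Parameters
    ----------
    columns
        ``canonical field -> report column name``.  All of
        ``site_id, peptide_seq, form_id, charge, isotope, run_id, intensity``
        must be mapped; ``idotp`` and ``rt_min`` are optional.
    idotp_threshold
        Features with idotp strictly below this are dropped by
        :func:`filter_idotp`.
    form_token
        Regex for one modification token inside a form label, with named
        groups ``site`` and ``mass`` (e.g. matching ``M251[+16]``).
    noncounting_masses
        Mass deltas (Da, rounded) that do not count as modifications when
        deciding whether a form is multi-site (default: +58 carboxymethyl).
    unmodified_labels
        Form labels denoting the unmodified peptide.
    """

    columns: Dict[str, str] = dataclasses.field(default_factory=_default_columns)
    idotp_threshold: float = 0.7
    log_base: float = 2.0
    delimiter: str = ","
    form_token: str = r"(?P<site>[A-Z]\d+)\[(?P<mass>[+-]?\d+(?:\.\d+)?)\]"
    noncounting_masses: Tuple[float, ...] = (58.0,)
    unmodified_labels: Tuple[str, ...] = ("unmodified",)

    def __post_init__(self) -> None:
        missing = [f for f in REQUIRED_FIELDS if f not in self.columns]
        if missing:
            raise ConfigurationError(
                f"schema is missing mandatory column mapping(s): {missing}")
        if not 0.0 <= self.idotp_threshold <= 1.0:
            raise ConfigurationError("idotp_threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SchemaConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "columns" in raw:
            base = _default_columns()
            base.update(raw["columns"])
            raw["columns"] = base
        for key in ("noncounting_masses", "unmodified_labels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(f"bad schema file {path}: {exc}") from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noncounting_masses"] = list(self.noncounting_masses)
        d["unmodified_labels"] = list(self.unmodified_labels)
        return d


@dataclasses.dataclass
class PeptideMapDataset:
    """Long-format feature measurements plus the run→condition design.

    ``measurements`` has the :data:`CANONICAL_COLUMNS`; every ``run_id``
    appears in ``design``.
    """

    measurements: pd.DataFrame
    design: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.design:
            raise DataError("design table is empty")
        unknown = set(self.measurements["run_id"]) - set(self.design)
        if unknown:
            raise DataError(f"runs missing from design table: {sorted(unknown)}")

    @property
    def conditions(self) -> Sequence[str]:
        return sorted(set(self.design.values()))

    @property
    def runs(self) -> Sequence[str]:
        return sorted(self.design)

    def replicate_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for cond in self.design.values():
            counts[cond] = counts.get(cond, 0) + 1
        return counts

    def runs_of(self, condition_id: str) -> Sequence[str]:
        return sorted(r for r, c in self.design.items() if c == condition_id)

    def sites(self) -> Sequence[str]:
        return sorted(self.measurements["site_id"].unique())

    def forms_at(self, site_id: str) -> Sequence[str]:
        sub = self.measurements[self.measurements["site_id"] == site_id]
        return sorted(sub["form_id"].unique())

    def summary(self, unmodified_labels: Sequence[str] = ("unmodified",)) -> Dict[str, int]:
        """Accounting of the dataset: sites, peptides, forms and features."""
        m = self.measurements
        peptide_forms = m[["peptide_seq", "form_id"]].drop_duplicates()
        modified = peptide_forms[~peptide_forms["form_id"].isin(unmodified_labels)]
        return {
            "n_sites": m["site_id"].nunique(),
            "n_peptides": m["peptide_seq"].nunique(),
            "n_modified_peptides": len(modified),
            "n_forms": len(m[["site_id", "form_id"]].drop_duplicates()),
            "n_features": len(m[FEATURE_KEY].drop_duplicates()),
            "n_runs": len(self.design),
            "n_rows": len(m),
        }

    def _replace(self, measurements: pd.DataFrame) -> "PeptideMapDataset":
        return PeptideMapDataset(measurements.reset_index(drop=True), dict(self.design))


def read_design(path: str | Path) -> Dict[str, str]:
    """Read a two-column (run_id, condition_id) CSV into a mapping."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ConfigurationError(f"design table {path} needs two columns")
    runs, conds = df.iloc[:, 0], df.iloc[:, 1]
    if runs.duplicated().any():
        dups = sorted(runs[runs.duplicated()].unique())
        raise DataError(f"duplicate run ids in design table: {dups}")
    return dict(zip(runs, conds))


def read_report(path: str | Path,
                schema: Optional[SchemaConfig] = None,
                design: Optional[Mapping[str, str] | str | Path] = None,
                ) -> PeptideMapDataset:
    """Read an exported feature-quantification report into a dataset.

    Rows whose intensity cannot be parsed as a number are rejected (and
    reported via logging); rows with blank, zero or negative intensity are
    treated as unobserved and dropped.  Duplicate (feature, run) keys raise
    :class:`DataError`.
    """
    schema = schema or SchemaConfig()
    if design is None:
        raise ConfigurationError("a run→condition design is required")
    if not isinstance(design, Mapping):
        design = read_design(design)

    raw = pd.read_csv(path, sep=schema.delimiter, dtype=str)
    missing = [col for field, col in schema.columns.items()
               if field in REQUIRED_FIELDS and col not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"report {path} lacks mapped column(s): {missing}")

    df = pd.DataFrame()
    for field in REQUIRED_FIELDS + OPTIONAL_FIELDS:
        col = schema.columns.get(field)
        df[field] = raw[col] if col in raw.columns else np.nan

    # numeric coercions
    intensity = pd.to_numeric(df["intensity"], errors="coerce")
    unparseable = intensity.isna() & df["intensity"].notna() & (df["intensity"].str.strip() != "")
    if unparseable.any():
        bad = df.loc[unparseable, "intensity"].head(5).tolist()
        log.warning("rejected %d row(s) with unparseable intensity (e.g. %s)",
                    int(unparseable.sum()), bad)
    unobserved = (~unparseable) & (intensity.isna() | (intensity <= 0))
    if unobserved.any():
        log.info("dropped %d row(s) with blank/zero intensity (treated as "
                 "below detection limit)", int(unobserved.sum()))
    df["intensity"] = intensity
    df = df[~(unparseable | unobserved)].copy()

    for field in ("charge", "isotope"):
        vals = pd.to_numeric(df[field], errors="coerce")
        if vals.isna().any():
            rows = df.index[vals.isna()].tolist()[:5]
            raise DataError(f"unparseable {field} values at rows {rows}")
        df[field] = vals.astype(int)
    if (df["charge"] <= 0).any():
        raise DataError("charge states must be positive")
    for field in ("idotp", "rt_min"):
        df[field] = pd.to_numeric(df[field], errors="coerce")

    unknown_runs = set(df["run_id"]) - set(design)
    if unknown_runs:
        raise DataError(f"runs missing from design table: {sorted(unknown_runs)}")
    df["condition_id"] = df["run_id"].map(dict(design))

    key = FEATURE_KEY + ["run_id"]
    dup_mask = df.duplicated(subset=key, keep=False)
    if dup_mask.any():
        dups = df.loc[dup_mask, key].drop_duplicates().head(10)
        raise DataError("duplicate (feature, run) keys:\n" + dups.to_string(index=False))

    ds = PeptideMapDataset(df[CANONICAL_COLUMNS].reset_index(drop=True), dict(design))
    log.info("read %s: %s", path, ds.summary(schema.unmodified_labels))
    return ds


def filter_idotp(ds: PeptideMapDataset, threshold: float = 0.7) -> PeptideMapDataset:
    """Drop measurements with idotp strictly below ``threshold``.

    Measurements with no idotp value are retained.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError("idotp threshold must lie in [0, 1]")
    m = ds.measurements
    drop = m["idotp"].notna() & (m["idotp"] < threshold)
    if drop.any():
        log.info("idotp filter (< %.3g): removed %d of %d measurements",
                 threshold, int(drop.sum()), len(m))
    return ds._replace(m[~drop])


def counting_sites(form_id: str, schema: Optional[SchemaConfig] = None) -> Tuple[str, ...]:
    """Sites at which ``form_id`` carries a *counting* modification.

    Tokens whose mass delta is whitelisted (carboxymethyl +58 by default) do
    not count.  An unmodified label yields an empty tuple.  Leftover text that
    is neither a token nor a separator raises :class:`DataError`.
    """
    schema = schema or SchemaConfig()
    if form_id in schema.unmodified_labels:
        return ()
    pattern = re.compile(schema.form_token)
    sites = []
    for match in pattern.finditer(form_id):
        mass = abs(float(match.group("mass")))
        if not any(abs(mass - abs(nc)) < 0.5 for nc in schema.noncounting_masses):
            sites.append(match.group("site"))
    residue = pattern.sub("", form_id)
    residue = re.sub(r"[\s+,;/_-]+", "", residue)
    if residue:
        raise DataError(f"unparseable modification string: {form_id!r}")
    return tuple(sites)


def restrict_single_site(ds: PeptideMapDataset,
                         schema: Optional[SchemaConfig] = None) -> PeptideMapDataset:
    """Remove peptide forms modified at more than one site.

    After this filter every retained feature is attributable to exactly one
    site, avoiding the confounding of a multi-site peptide's intensity among
    its sites.  Unmodified forms and forms whose only extra token is a
    whitelisted mass (carboxymethyl-cysteine) are always retained.
    """
    schema = schema or SchemaConfig()
    keep_form: Dict[str, bool] = {}
    for form in ds.measurements["form_id"].unique():
        keep_form[form] = len(counting_sites(form, schema)) <= 1
    mask = ds.measurements["form_id"].map(keep_form)
    removed = int((~mask).sum())
    if removed:
        log.info("single-site restriction: removed %d measurements (%d forms)",
                 removed, sum(not v for v in keep_form.values()))
    return ds._replace(ds.measurements[mask])


def write_dataset(ds: PeptideMapDataset, path: str | Path) -> None:
    """Write the canonical long-format CSV."""
    ds.measurements[CANONICAL_COLUMNS].to_csv(path, index=False)


def read_dataset(path: str | Path) -> PeptideMapDataset:
    """Read a canonical long-format CSV written by :func:`write_dataset`."""
    df = pd.read_csv(path, dtype={"site_id": str, "peptide_seq": str,
                                  "form_id": str, "run_id": str,
                                  "condition_id": str})
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path} lacks canonical column(s): {missing}")
    design = dict(df[["run_id", "condition_id"]].drop_duplicates().itertuples(index=False))
    return PeptideMapDataset(df[CANONICAL_COLUMNS], design)
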