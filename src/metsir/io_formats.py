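"""Reading, writing and validating spectra tables, clinical tables and reports.

The on-disk interchange format is plain CSV (comma separator, ``.`` decimal,
UTF-8).  Spectra are stored as a wide table — one row per spectrum, the header
row holding the wavenumber grid in cm⁻¹.  Internally wavenumbers are always
kept strictly descending (the FTIR plotting convention) and the absorbance
matrix is re-ordered to match on read.

A minimal JCAMP-DX reader for single spectra in the plain AFFN
``(X++(Y..Y))`` form is provided as a convenience; the wide CSV table is the
canonical representation.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical clinical column names and the aliases accepted on read
CLINICAL_COLUMNS = ("TGL", "HDL", "SP", "DP", "GLU")
_CLINICAL_ALIASES: dict[str, tuple[str, ...]] = {
    "TGL": ("tgl", "triglycerides", "tg"),
    "HDL": ("hdl", "hdl_cholesterol"),
    "SP": ("sp", "sbp", "systolic", "systolic_pressure"),
    "DP": ("dp", "dbp", "diastolic", "diastolic_pressure"),
    "GLU": ("glu", "glucose", "fasting_glucose"),
}

_REPLICATE_RE = re.compile(r"^(?P<base>.+)_rep(?P<num>\d+)$")


class FormatError(ValueError):
    """Raised when a file violates the interchange-format contract."""


@dataclass
class SpectraSet:
    """A set of FTIR spectra on a shared wavenumber grid.

    Attributes
    ----------
    wavenumbers : ndarray
        Strictly descending grid in cm⁻¹.
    absorbance : ndarray
        ``(n_samples, n_wavenumbers)`` matrix of absorbance values.
    sample_ids : list of str
        Unique identifiers, one per row.
    replicate_of : dict or None
        Maps a replicate row id to its biological sample id, when the set
        holds unaveraged replicates (``<sample>_rep<N>`` naming).
    labels : ndarray or None
        Per-row class label in ``{"MetS", "noMetS"}`` (or ``"unknown"``).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    replicate_of: dict[str, str] | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.sample_ids):
                raise FormatError("labels length does not match sample_ids")
        self.validate()

    def validate(self) -> None:
        nu, x = self.wavenumbers, self.absorbance
        if x.shape != (len(self.sample_ids), nu.size):
            raise FormatError(
                f"absorbance shape {x.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {nu.size} wavenumbers"
            )
        if nu.size != np.unique(nu).size:
            raise FormatError("duplicate wavenumbers in grid")
        if nu.size > 1 and not np.all(np.diff(nu) < 0):
            raise FormatError("wavenumber grid is not strictly descending")
        if np.isnan(x).any():
            raise FormatError("NaN absorbance values present")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def copy_with(self, **kw) -> "SpectraSet":
        base = dict(
            wavenumbers=self.wavenumbers.copy(),
            absorbance=self.absorbance.copy(),
            sample_ids=list(self.sample_ids),
            replicate_of=dict(self.replicate_of) if self.replicate_of else None,
            labels=None if self.labels is None else self.labels.copy(),
        )
        base.update(kw)
        return SpectraSet(**base)

    def segments(self, rel_tol: float = 0.5) -> list[slice]:
        """Contiguous uniformly spaced grid segments, split at spacing jumps.

        A break is declared where the step differs from the running segment
        spacing by more than ``rel_tol`` relative.
        """
        nu = self.wavenumbers
        if nu.size < 2:
            return [slice(0, nu.size)]
        d = np.diff(nu)
        breaks = [0]
        ref = d[0]  # spacing at the start of the current segment
        for i in range(1, d.size):
            if abs(d[i] - ref) > rel_tol * abs(ref):
                breaks.append(i + 1)
                if i + 1 < d.size:
                    ref = d[i + 1]
        breaks.append(nu.size)
        return [slice(a, b) for a, b in zip(breaks[:-1], breaks[1:])]

    def subset_rows(self, idx: Sequence[int] | np.ndarray) -> "SpectraSet":
        idx = np.asarray(idx)
        return SpectraSet(
            wavenumbers=self.wavenumbers,
            absorbance=self.absorbance[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            replicate_of=self.replicate_of,
            labels=None if self.labels is None else self.labels[idx],
        )


@dataclass
class ClinicalTable:
    """Per-sample clinical parameters (units fixed: mg/dL; pressures mmHg).

    Wraps a DataFrame indexed by sample id with columns
    TGL, HDL, SP, DP, GLU, sex (``M``/``F``/``unknown``) and label
    (``MetS``/``noMetS``/``unknown``).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in CLINICAL_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"clinical table missing column {col}")
            df[col] = pd.to_numeric(df[col], errors="raise")
        if "sex" not in df.columns:
            df["sex"] = "unknown"
        if "label" not in df.columns:
            df["label"] = "unknown"
        df["sex"] = df["sex"].fillna("unknown").astype(str)
        df["label"] = df["label"].fillna("unknown").astype(str)
        if df.index.has_duplicates:
            raise FormatError("duplicate sample ids in clinical table")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def labels(self) -> np.ndarray:
        return self.data["label"].to_numpy(dtype=object)

    def values(self) -> np.ndarray:
        """The five measured parameters as an (n, 5) float matrix."""
        return self.data[list(CLINICAL_COLUMNS)].to_numpy(dtype=float)

    def require_complete(self) -> None:
        """Error if any sample lacks one of the five parameters (or ≤ 0)."""
        vals = self.data[list(CLINICAL_COLUMNS)]
        bad = vals.isna().any(axis=1) | (vals <= 0).any(axis=1)
        if bad.any():
            ids = ", ".join(map(str, self.data.index[bad]))
            raise FormatError(f"incomplete/invalid clinical parameters for: {ids}")

    def subset(self, ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(ids)])


# ---------------------------------------------------------------------------
# spectra CSV
# ---------------------------------------------------------------------------

def read_spectra_csv(path: str | Path, orientation: str = "wide") -> SpectraSet:
    """Read a spectra table from CSV.

    ``orientation="wide"`` (default): rows are samples, the header holds
    wavenumbers, first column holds sample ids.  ``orientation="long"``:
    transposed layout (rows are wavenumbers).

    The grid is re-sorted descending and the matrix re-ordered to match.
    Replicate ids of the form ``<sample>_rep<N>`` populate ``replicate_of``.
    """
    if orientation == "wide":
        # check the raw header first: pandas silently renames duplicates
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(",")[1:]
        try:
            raw_nu = np.array([float(c) for c in header])
        except ValueError as exc:
            raise FormatError(
                f"non-numeric wavenumber in header of {path}: {exc}") from exc
        if np.unique(raw_nu).size != raw_nu.size:
            dup = raw_nu[pd.Index(raw_nu).duplicated()][0]
            raise FormatError(f"duplicate wavenumber {dup} in {path}")
    df = pd.read_csv(path, index_col=0)
    if orientation == "long":
        df = df.T
    elif orientation != "wide":
        raise ValueError(f"unknown orientation {orientation!r}")

    try:
        nu = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavenumber in header of {path}: {exc}") from exc
    if np.unique(nu).size != nu.size:
        dup = nu[pd.Index(nu).duplicated()][0]
        raise FormatError(f"duplicate wavenumber {dup} in {path}")

    mat = df.to_numpy()
    try:
        mat = mat.astype(float)
    except ValueError:
        for i, row in enumerate(mat):
            for j, v in enumerate(row):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric cell at row {df.index[i]!r}, "
                        f"column {df.columns[j]!r} in {path}"
                    ) from None
        raise
    if np.isnan(mat).any():
        i, j = map(int, np.argwhere(np.isnan(mat))[0])
        raise FormatError(
            f"missing value at row {df.index[i]!r}, column {df.columns[j]!r} in {path}"
        )

    order = np.argsort(nu)[::-1]
    ids = [str(i) for i in df.index]
    replicate_of = {}
    for s in ids:
        m = _REPLICATE_RE.match(s)
        if m:
            replicate_of[s] = m.group("base")
    return SpectraSet(
        wavenumbers=nu[order],
        absorbance=mat[:, order],
        sample_ids=ids,
        replicate_of=replicate_of or None,
    )


def write_spectra_csv(spectra: SpectraSet, path: str | Path,
                      float_format: str = "%.12g") -> None:
    df = pd.DataFrame(
        spectra.absorbance,
        index=pd.Index(spectra.sample_ids, name="sample_id"),
        columns=[f"{nu:.6f}" for nu in spectra.wavenumbers],
    )
    df.to_csv(path, float_format=float_format)


# ---------------------------------------------------------------------------
# clinical CSV
# ---------------------------------------------------------------------------

def read_clinical_csv(path: str | Path) -> ClinicalTable:
    """Read a clinical parameter table; column aliases are case-insensitive."""
    df = pd.read_csv(path, index_col=0)
    if df.empty:
        logger.warning("clinical table %s is empty", path)
        df = pd.DataFrame(columns=list(CLINICAL_COLUMNS))
    rename = {}
    lower = {c.lower().strip(): c for c in df.columns}
    for canon, aliases in _CLINICAL_ALIASES.items():
        for cand in (canon.lower(),) + aliases:
            if cand in lower:
                rename[lower[cand]] = canon
                break
    for extra in ("sex", "label"):
        if extra in lower:
            rename[lower[extra]] = extra
    df = df.rename(columns=rename)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing and not df.empty:
        raise FormatError(f"clinical table {path} missing columns: {missing}")
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            ids = ", ".join(map(str, df.index[bad]))
            raise FormatError(f"missing or non-numeric {col} for sample(s): {ids}")
    df.index = df.index.map(str)
    return ClinicalTable(df)


def write_clinical_csv(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def rates_frame(report) -> pd.DataFrame:
    """Classification / external prediction / total-rate table (one row per
    class plus a pooled ``Total rate`` row)."""
    rows, index = [], []
    for cls in report.classes:
        rows.append([report.classification_pct[cls],
                     report.external_pct.get(cls, np.nan),
                     report.total_rate_pct[cls]])
        index.append(cls)
    rows.append([report.classification_total,
                 report.external_total,
                 report.total_rate_total])
    index.append("Total rate")
    return pd.DataFrame(
        rows, index=pd.Index(index, name="Category"),
        columns=["Classification (%)", "External Prediction (%)", "Total Rate (%)"],
    )


def simca_summary_frame(diag) -> pd.DataFrame:
    """One-row SIMCA performance summary."""
    return pd.DataFrame(
        [[diag.classification_pct, diag.loo_pct, diag.cv_efficiency_pct,
          diag.forced_efficiency_pct, diag.total_rate_pct]],
        index=pd.Index([diag.name], name="Variables"),
        columns=["Classification (%)", "LOO (%)", "CV Efficiency (%)",
                 "Efficiency Forced Model (%)", "Total Rate (%)"],
    )


def power_frame(variables: Sequence, dp: np.ndarray,
                mp_class1: np.ndarray, mp_class2: np.ndarray,
                class_names: tuple[str, str] = ("MetS", "noMetS"),
                var_name: str = "wavenumber") -> pd.DataFrame:
    """Per-variable discriminant / modelling power table."""
    return pd.DataFrame(
        {
            "DP": np.asarray(dp, dtype=float),
            f"MP_{class_names[0]}": np.asarray(mp_class1, dtype=float),
            f"MP_{class_names[1]}": np.asarray(mp_class2, dtype=float),
        },
        index=pd.Index(list(variables), name=var_name),
    )


def write_report(frames: Mapping[str, pd.DataFrame], path: str | Path,
                 format: str = "csv") -> None:
    """Write named report tables to ``path``.

    ``format="csv"`` writes one ``<path>/<name>.csv`` per table;
    ``format="json"`` writes a single JSON file keyed by table name.
    """
    path = Path(path)
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        for name, df in frames.items():
            df.to_csv(path / f"{name}.csv", float_format="%.12g")
    elif format == "json":
        payload = {
            name: json.loads(df.to_json(orient="split", double_precision=12))
            for name, df in frames.items()
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report_json(path: str | Path) -> dict[str, pd.DataFrame]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for name, spec in payload.items():
        out[name] = pd.DataFrame(
            spec["data"], index=spec["index"], columns=spec["columns"]
        )
    return out


# ---------------------------------------------------------------------------
# JCAMP-DX (minimal, read-only)
# ---------------------------------------------------------------------------

def read_jcamp(path: str | Path, sample_id: str | None = None) -> SpectraSet:
    """Read a single spectrum from a JCAMP-DX file in plain ``(X++(Y..Y))``
    AFFN form (no compressed DIF/DUP encodings)."""
    text = Path(path).read_text()
    fields: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            if key == "XYDATA":
                in_data = True
                continue
            if key == "END":
                in_data = False
            fields[key] = val.strip()
        elif in_data and line:
            data_lines.append(line)
    if not data_lines:
        raise FormatError(f"no XYDATA block in {path}")
    yfac = float(fields.get("YFACTOR", 1.0))
    ys: list[float] = []
    for line in data_lines:
        toks = [t for t in re.split(r"[,\s]+", line) if t]
        # first token is the line's X start; remaining tokens are Y values
        ys.extend(float(t) * yfac for t in toks[1:])
    first_x = fields.get("FIRSTX")
    last_x = fields.get("LASTX")
    npts = int(float(fields.get("NPOINTS", len(ys))))
    if first_x is None or last_x is None or npts < 2:
        raise FormatError(f"JCAMP file {path} lacks FIRSTX/LASTX/NPOINTS")
    grid = np.linspace(float(first_x), float(last_x), npts)
    y = np.array(ys[:npts])
    if grid.size != y.size:
        raise FormatError(f"JCAMP point count mismatch in {path}")
    order = np.argsort(grid)[::-1]
    sid = sample_id or fields.get("TITLE", Path(path).stem) or Path(path).stem
    return SpectraSet(
        wavenumbers=grid[order], absorbance=y[order][None, :], sample_ids=[sid]
    )
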