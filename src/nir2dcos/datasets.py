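"""Spectral matrices and sample manifests.

A :class:`SpectrumSet` holds absorbance spectra on a shared wavenumber grid
(descending cm⁻¹, as FT-NIR instruments emit them); a manifest is a pandas
DataFrame with one row per recorded scan carrying the sample's region,
collection site, drying method and replicate index.  Replicate scans are
averaged before any correlation-map or model step; missing values are
rejected rather than imputed, because imputation would silently reshape the
correlation maps downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumSet", "default_grid", "read_spectra", "write_spectra",
    "read_manifest", "write_manifest", "validate_manifest",
    "average_replicates", "class_mean_spectrum", "class_means",
    "MANIFEST_COLUMNS", "DRYING_METHODS",
]

#: canonical manifest column order
MANIFEST_COLUMNS = ["sample_id", "region", "site", "drying_method", "replicate"]

#: the four post-harvest drying treatments
DRYING_METHODS = ("40C", "60C", "shade", "sun")

WAVENUMBER_COLUMN = "wavenumber_cm-1"


def default_grid(start: float = 10_000.0, stop: float = 4_000.0,
                 step: float = 4.0) -> np.ndarray:
    """Descending instrument grid, 10,000 → 4,000 cm⁻¹ at 4 cm⁻¹ (1501 points)."""
    n = int(round((start - stop) / step)) + 1
    return start - step * np.arange(n)


@dataclass
class SpectrumSet:
    """Absorbance spectra on a shared, strictly monotonic wavenumber grid.

    Parameters
    ----------
    wavenumbers : (n_points,) array of cm⁻¹ values, strictly monotonic
        (descending by instrument convention; all code indexes by position,
        never by assumed direction).
    absorbance : (n_samples, n_points) array of log(1/R) values, all finite.
    sample_ids : unique identifier per row.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float).ravel()
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        self._validate()

    def _validate(self) -> None:
        w = self.wavenumbers
        if w.size < 1:
            raise ValueError("empty wavenumber grid")
        d = np.diff(w)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber grid must be strictly monotonic")
        n, p = self.absorbance.shape
        if p != w.size:
            raise ValueError(
                f"absorbance has {p} columns but grid has {w.size} points")
        if n != len(self.sample_ids):
            raise ValueError(
                f"absorbance has {n} rows but {len(self.sample_ids)} sample ids")
        if len(set(self.sample_ids)) != n:
            dupes = sorted({s for s in self.sample_ids
                            if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values; "
                             "missing data is rejected, not imputed")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.absorbance.shape[1]

    def select(self, rows: Sequence[int] | np.ndarray) -> "SpectrumSet":
        """Row subset preserving the grid."""
        rows = np.asarray(rows, dtype=int)
        return SpectrumSet(self.wavenumbers, self.absorbance[rows],
                           [self.sample_ids[i] for i in rows])

    def index_of(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.absorbance.T, columns=self.sample_ids)
        df.insert(0, WAVENUMBER_COLUMN, self.wavenumbers)
        return df


def read_spectra(path: str | Path) -> SpectrumSet:
    """Read a spectral-matrix CSV (column 1 = wavenumber, one column per sample).

    Raises
    ------
    ValueError
        Non-monotonic grid, duplicate sample ids, or a non-numeric cell
        (reported with its row and column).
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("spectral CSV needs a wavenumber column plus "
                         "at least one sample column")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        nan_mask = bad.isna() & df[col].notna()
        if nan_mask.any():
            row = int(np.flatnonzero(nan_mask.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} at row {row + 2}, "
                f"column {col!r}")
        if bad.isna().any():
            row = int(np.flatnonzero(bad.isna().to_numpy())[0])
            raise ValueError(f"missing value at row {row + 2}, column {col!r}")
    sample_ids = [str(c) for c in df.columns[1:]]
    return SpectrumSet(df.iloc[:, 0].to_numpy(float),
                       df.iloc[:, 1:].to_numpy(float).T, sample_ids)


def write_spectra(spectra: SpectrumSet, path: str | Path) -> None:
    spectra.to_frame().to_csv(path, index=False, float_format="%.17g")


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Check manifest structure: required columns, unique (sample, replicate),
    every site mapped to exactly one region.  Returns the frame unchanged."""
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    if manifest["replicate"].lt(1).any():
        raise ValueError("replicate indices must be >= 1")
    key = manifest[["sample_id", "replicate"]]
    if key.duplicated().any():
        dupe = key[key.duplicated()].iloc[0]
        raise ValueError(
            f"duplicate (sample_id, replicate) record: {tuple(dupe)}")
    site_regions = manifest.groupby("site")["region"].nunique()
    conflicted = site_regions[site_regions > 1]
    if len(conflicted):
        raise ValueError(
            f"site(s) mapped to more than one region: {list(conflicted.index)}")
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "region": str,
                                  "site": str, "drying_method": str})
    return validate_manifest(df)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    validate_manifest(manifest)[MANIFEST_COLUMNS].to_csv(path, index=False)


def _scan_ids(manifest: pd.DataFrame) -> pd.Series:
    """Identifier linking a manifest row to a SpectrumSet row: the sample id
    itself when one scan per sample, else ``{sample_id}-r{replicate}``."""
    if manifest["sample_id"].is_unique:
        return manifest["sample_id"].astype(str)
    return (manifest["sample_id"].astype(str) + "-r"
            + manifest["replicate"].astype(int).astype(str))


def average_replicates(spectra: SpectrumSet,
                       manifest: pd.DataFrame) -> SpectrumSet:
    """Collapse replicate scans to one arithmetic-mean spectrum per sample.

    Each manifest row describes one scan; scans are matched to spectra rows
    by scan id (``sample_id`` or ``sample_id-r<replicate>``).  The result has
    one row per distinct sample, in order of first appearance.
    """
    validate_manifest(manifest)
    scan_ids = _scan_ids(manifest)
    rows = spectra.index_of(scan_ids)
    samples = manifest["sample_id"].astype(str)
    out_ids = list(dict.fromkeys(samples))
    means = np.empty((len(out_ids), spectra.n_points))
    for k, sid in enumerate(out_ids):
        members = rows[(samples == sid).to_numpy()]
        if members.size == 0:  # pragma: no cover - guarded by index_of
            raise ValueError(f"sample {sid!r} has zero replicates")
        means[k] = spectra.absorbance[members].mean(axis=0)
    return SpectrumSet(spectra.wavenumbers, means, out_ids)


def class_means(spectra: SpectrumSet | np.ndarray,
                labels: Sequence) -> tuple[list, np.ndarray]:
    """Column-wise mean spectrum of every class.

    Returns ``(classes, means)`` with classes in sorted label order and
    ``means[k]`` the mean over samples labelled ``classes[k]``.
    """
    X = spectra.absorbance if isinstance(spectra, SpectrumSet) else np.asarray(spectra, float)
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels length must match sample count")
    classes = sorted(pd.unique(labels).tolist())
    means = np.stack([X[labels == c].mean(axis=0) for c in classes])
    return classes, means


def class_mean_spectrum(spectra: SpectrumSet | np.ndarray, labels: Sequence,
                        cls) -> np.ndarray:
    """Mean spectrum of one class; raises ``KeyError`` for an unknown class."""
    classes, means = class_means(spectra, labels)
    try:
        return means[classes.index(cls)]
    except ValueError:
        raise KeyError(f"class {cls!r} not present in labels") from None
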