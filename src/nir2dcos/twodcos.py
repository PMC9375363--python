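"""Generalized two-dimensional correlation spectroscopy (2DCOS).

For a perturbation series of m spectra stacked as rows of Y (m × n), the
synchronous and asynchronous correlation intensities between wavenumbers
v₁ and v₂ are

    Φ(v₁, v₂) = Y(v₁)ᵀ · Y(v₂) / (m − 1)
    Ψ(v₁, v₂) = Y(v₁)ᵀ · D · Y(v₂) / (m − 1)

with D the Hilbert–Noda transformation matrix (D_jk = 0 on the diagonal,
1/(π(k−j)) off it), and the integrated map is the elementwise product
W = Φ ∘ Ψ.  Φ is symmetric with non-negative auto-peaks on its diagonal;
Ψ is antisymmetric with a zero diagonal and vanishes for in-phase signals.

Here the series is the two-row construction {class-mean spectrum, i-th
individual spectrum} (m = 2), which turns every labelled sample into
three n × n maps rendered as fixed-size RGB rasters for the CNN.  The
equations are applied to raw intensities: with m = 2, column-centered
rows are exact negatives of each other and Ψ would vanish identically,
so centering is opt-in and off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from matplotlib import colormaps
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator, TransformerMixin

from .datasets import SpectrumSet, class_means

__all__ = [
    "hilbert_noda_matrix", "sync_map", "async_map", "integrated_map",
    "CorrelationMaps", "correlation_maps", "decimate_indices",
    "render_map_image", "colormap_lut", "TwoDcosImager", "ImageDataset",
    "generate_image_set", "GROUPING_ALIASES",
]

#: CLI-facing grouping names → manifest columns
GROUPING_ALIASES = {"drying": "drying_method", "region": "region",
                    "drying_method": "drying_method"}


def hilbert_noda_matrix(m: int) -> np.ndarray:
    """The m × m Hilbert–Noda transformation matrix.

    ``D[j, k] = 0`` for ``j = k`` and ``1 / (π (k − j))`` otherwise
    (0-based or 1-based indexing give the same matrix).  Exactly
    antisymmetric.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    j, k = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    with np.errstate(divide="ignore"):
        D = np.where(j == k, 0.0, 1.0 / (np.pi * (k - j)))
    return D


def _as_rows(rows: np.ndarray) -> np.ndarray:
    Y = np.atleast_2d(np.asarray(rows, dtype=float))
    if Y.shape[0] < 2:
        raise ValueError(
            f"perturbation series needs at least 2 spectra, got {Y.shape[0]}")
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite values in dynamic spectra")
    return Y


def _maybe_center(Y: np.ndarray, center: bool) -> np.ndarray:
    return Y - Y.mean(axis=0, keepdims=True) if center else Y


def sync_map(rows: np.ndarray, center: bool = False) -> np.ndarray:
    """Synchronous correlation map Φ of an m × n series (n × n, symmetric)."""
    Y = _maybe_center(_as_rows(rows), center)
    m = Y.shape[0]
    P = Y.T @ Y / (m - 1)
    return 0.5 * (P + P.T)   # exact symmetry (analytic property of Phi)


def async_map(rows: np.ndarray, center: bool = False) -> np.ndarray:
    """Asynchronous map Ψ via the Hilbert–Noda transform (antisymmetric,
    zero diagonal; zero for in-phase signals such as identical rows)."""
    Y = _maybe_center(_as_rows(rows), center)
    m = Y.shape[0]
    if m == 2:
        # outer-product form keeps antisymmetry bit-exact and makes the
        # map of in-phase (identical) rows an exact zero matrix
        T = np.outer(Y[0], Y[1]) / np.pi
        return T - T.T
    P = Y.T @ (hilbert_noda_matrix(m) @ Y) / (m - 1)
    return 0.5 * (P - P.T)   # exact antisymmetry, identically zero diagonal


def integrated_map(sync: np.ndarray, async_: np.ndarray) -> np.ndarray:
    """Integrated map W = Φ ∘ Ψ (elementwise product)."""
    sync = np.asarray(sync, float)
    async_ = np.asarray(async_, float)
    if sync.shape != async_.shape:
        raise ValueError(f"shape mismatch {sync.shape} vs {async_.shape}")
    return sync * async_


@dataclass
class CorrelationMaps:
    """The three correlation maps of one sample on a shared grid."""
    sync: np.ndarray
    async_: np.ndarray
    integrated: np.ndarray
    grid: np.ndarray

    def by_type(self, map_type: str) -> np.ndarray:
        try:
            return {"sync": self.sync, "async": self.async_,
                    "integrated": self.integrated}[map_type]
        except KeyError:
            raise KeyError(f"unknown map type {map_type!r}") from None


def correlation_maps(rows: np.ndarray, grid: np.ndarray | None = None,
                     center: bool = False) -> CorrelationMaps:
    """Compute Φ, Ψ and W together for one perturbation series."""
    Y = _as_rows(rows)
    grid = np.arange(Y.shape[1], dtype=float) if grid is None else np.asarray(grid, float)
    phi = sync_map(Y, center)
    psi = async_map(Y, center)
    return CorrelationMaps(phi, psi, integrated_map(phi, psi), grid)


def decimate_indices(n_points: int, max_points: int = 512) -> np.ndarray:
    """Uniform-stride subset of grid positions with at most ``max_points``
    entries.  Maps on the decimated grid equal the corresponding sub-block
    of the full-grid maps (pure index selection, no smoothing)."""
    if max_points < 2:
        raise ValueError("max_points must be >= 2")
    stride = int(np.ceil(n_points / max_points))
    return np.arange(0, n_points, stride)


# -- rendering -------------------------------------------------------------

def colormap_lut(name: str = "jet") -> np.ndarray:
    """256-entry uint8 RGB lookup table of a matplotlib colormap."""
    rgba = colormaps[name](np.linspace(0.0, 1.0, 256))
    return (rgba[:, :3] * 255.0 + 0.5).astype(np.uint8)


def render_map_image(map_: np.ndarray, size: int = 224,
                     cmap: str = "jet") -> np.ndarray:
    """Deterministic raster of a correlation map: (size, size, 3) uint8.

    Values are scaled symmetrically about zero by the per-image absolute
    maximum, resized bilinearly, and mapped through a 256-level colormap.
    No axes, colorbar or margins.  An all-equal map has no scale and
    renders as the uniform mid-colormap color (documented behaviour, not
    an error).
    """
    M = np.atleast_2d(np.asarray(map_, float))
    if M.shape[0] < 2 or M.shape[0] != M.shape[1]:
        raise ValueError("map must be square with n >= 2")
    if size < 8:
        raise ValueError("size must be >= 8")
    centered = M - M.flat[0] if np.all(M == M.flat[0]) else M
    vmax = np.abs(centered).max()
    norm = np.full(M.shape, 0.5) if vmax == 0 else 0.5 * (centered / vmax + 1.0)
    if norm.shape != (size, size):
        norm = _sk_resize(norm, (size, size), order=1, mode="edge",
                          anti_aliasing=False, preserve_range=True)
    q = np.clip(np.rint(norm * 255.0), 0, 255).astype(np.intp)
    return colormap_lut(cmap)[q]


# -- the imaging transformer ----------------------------------------------

class TwoDcosImager(TransformerMixin, BaseEstimator):
    """Turn labelled spectra into per-sample 2DCOS rasters.

    ``fit(X, y)`` stores the class-mean spectra of the grouping ``y`` on a
    stride-decimated grid; ``transform(X, y)`` pairs each sample with the
    mean of *its own* class (labels are required at transform time — the
    construction is defined for labelled samples, with splitting done
    afterwards on the finished images) and renders the requested map type.

    Parameters
    ----------
    map_type : {"sync", "async", "integrated"}
    image_size : output raster edge in pixels (≥ 8).
    max_points : grid decimation bound before map construction.
    cmap : matplotlib colormap name.
    center : subtract the series column mean before the maps (off by
        default; with m = 2 centering annihilates the asynchronous map).
    """

    def __init__(self, map_type: str = "sync", image_size: int = 224,
                 max_points: int = 512, cmap: str = "jet",
                 center: bool = False):
        self.map_type = map_type
        self.image_size = image_size
        self.max_points = max_points
        self.cmap = cmap
        self.center = center

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, float))
        if self.map_type not in ("sync", "async", "integrated"):
            raise ValueError(f"unknown map type {self.map_type!r}")
        self.idx_ = decimate_indices(X.shape[1], self.max_points)
        classes, means = class_means(X, y)
        self.classes_ = classes
        self.class_means_ = means[:, self.idx_]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, y=None) -> np.ndarray:
        if y is None:
            raise ValueError("TwoDcosImager.transform requires class labels: "
                             "each sample is paired with its class mean")
        if not hasattr(self, "classes_"):
            raise AttributeError("imager is not fitted")
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        y = np.asarray(y)
        lookup = {c: i for i, c in enumerate(self.classes_)}
        out = np.empty((X.shape[0], self.image_size, self.image_size, 3),
                       dtype=np.uint8)
        for i in range(X.shape[0]):
            try:
                mean = self.class_means_[lookup[y[i]]]
            except KeyError:
                raise KeyError(f"class {y[i]!r} unseen at fit time") from None
            pair = np.stack([mean, X[i, self.idx_]])
            maps = correlation_maps(pair, center=self.center)
            out[i] = render_map_image(maps.by_type(self.map_type),
                                      self.image_size, self.cmap)
        return out

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, y).transform(X, y)


# -- bulk image-set construction ------------------------------------------

@dataclass
class ImageDataset:
    """Rendered 2DCOS rasters plus their provenance records.

    ``images`` is (N, size, size, 3) uint8; ``records`` has one row per
    image with columns ``sample_id, grouping, map_type, label``.
    """

    images: np.ndarray
    records: pd.DataFrame

    def __len__(self) -> int:
        return len(self.records)

    @property
    def image_size(self) -> int:
        return self.images.shape[1]

    def subset(self, mask) -> "ImageDataset":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask.astype(int)
        return ImageDataset(self.images[idx],
                            self.records.iloc[idx].reset_index(drop=True))

    def save(self, out_dir: str | Path) -> Path:
        """Write one PNG per image under grouping/type/class directories
        plus a ``dataset.json`` index; returns the index path."""
        from PIL import Image

        out_dir = Path(out_dir)
        entries = []
        for i, row in self.records.iterrows():
            rel = (Path(str(row["grouping"])) / str(row["map_type"])
                   / str(row["label"]) / f"{row['sample_id']}.png")
            path = out_dir / rel
            path.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray(self.images[i]).save(path)
            entries.append({"path": str(rel), "sample_id": row["sample_id"],
                            "grouping": row["grouping"],
                            "map_type": row["map_type"],
                            "class": row["label"]})
        index = out_dir / "dataset.json"
        index.write_text(json.dumps({"images": entries}, indent=1))
        return index


def generate_image_set(spectra: SpectrumSet, manifest: pd.DataFrame,
                       groupings: Sequence[str] = ("drying", "region"),
                       types: Sequence[str] = ("sync", "async", "integrated"),
                       image_size: int = 224, max_points: int = 512,
                       cmap: str = "jet", center: bool = False) -> ImageDataset:
    """Render every (sample × grouping × map type) combination.

    For each grouping the class mean is recomputed under that labelling,
    so a sample yields ``len(groupings) × len(types)`` images; with the
    full 534-sample manifest, two groupings and three types that is 3204
    images.
    """
    if spectra.n_samples == 0:
        raise ValueError("empty sample set")
    order = manifest.set_index("sample_id").loc[spectra.sample_ids]
    all_images, all_records = [], []
    for grouping in groupings:
        col = GROUPING_ALIASES.get(grouping, grouping)
        if col not in manifest.columns:
            raise ValueError(f"unknown grouping {grouping!r}")
        labels = order[col].to_numpy()
        if pd.isna(labels).any():
            raise ValueError(f"unlabelled sample(s) under grouping {grouping!r}")
        # maps are shared across types per (grouping, sample): compute once
        imagers = {t: TwoDcosImager(t, image_size, max_points, cmap, center)
                   .fit(spectra.absorbance, labels) for t in types}
        for t in types:
            imgs = imagers[t].transform(spectra.absorbance, labels)
            all_images.append(imgs)
            all_records.append(pd.DataFrame({
                "sample_id": spectra.sample_ids, "grouping": grouping,
                "map_type": t, "label": labels}))
    return ImageDataset(np.concatenate(all_images),
                        pd.concat(all_records, ignore_index=True))
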