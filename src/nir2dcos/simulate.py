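"""Synthetic FT-NIR spectra with the class structure of dried-leaf datasets.

Real FT-NIR absorbance spectra of dried *E. ulmoides* leaves are smooth
sums of broad overtone/combination bands whose *positions* are shared
across classes while their *intensities* differ systematically: oven- and
sun-drying reorder band intensities between the high-wavenumber
(10,000–7,000 cm⁻¹) and low-wavenumber (6,000–4,000 cm⁻¹) windows, and
geographic origin shifts intensities mainly below 5,350 cm⁻¹.  The
generator reproduces exactly that structure — Gaussian bands × smooth
window-scoped class factors × multiplicative scatter + additive noise —
so that every downstream stage (2DCOS imaging, splitting, PLS-DA, the
residual CNN) can be exercised and validated without access to the
original 534-sample dataset.

Class effects are intensity factors over wavenumber windows, not per-band
terms; magnitudes are configuration, since only the orderings of the real
intensity differences are known, not their sizes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import (DRYING_METHODS, MANIFEST_COLUMNS, SpectrumSet,
                       default_grid, validate_manifest)

__all__ = [
    "GeneratorConfig", "table1_counts", "uniform_counts",
    "generate_manifest", "generate_spectrum", "generate_dataset",
    "REGIONS",
]

#: the seven provinces of origin
REGIONS = ("Guizhou", "Henan", "Hubei", "Hunan", "Jiangxi", "Shaanxi",
           "Xinjiang")

# NIR band inventory: second overtone of CH3/CH2 C-H stretch (8300), first
# overtone of O-H stretch (6881), C-H stretch of R-OHCH3 (5775), O-H
# stretch / H2O OH deformation (5172), and polysaccharide/carbohydrate
# C-H and C=O combination bands crowding 5000-4000 cm-1.
_BAND_CENTERS = (8300.0, 6881.0, 5775.0, 5172.0, 4750.0, 4400.0, 4100.0)
_BAND_WIDTHS = (420.0, 320.0, 140.0, 200.0, 150.0, 130.0, 110.0)
_BAND_AMPLITUDES = (0.22, 0.55, 0.12, 0.72, 0.38, 0.34, 0.30)

# Drying-method intensity factors (high window 10,000-7,000; low window
# 6,000-4,000).  High-window ordering 40C > sun > shade > 60C; low-window
# ordering 60C > shade > sun > 40C.
_DRYING_EFFECTS = {
    "40C":   (1.30, 1.00),
    "sun":   (1.20, 1.10),
    "shade": (1.10, 1.20),
    "60C":   (1.00, 1.30),
}

# Region factors: high window descending Guizhou > Xinjiang > (Henan) >
# Jiangxi > Hunan > Hubei > Shaanxi; low window (5,350-4,000) highest for
# Shaanxi.  Each region gets a distinct (high, low) pair so the seven
# classes are geometrically separable.
_REGION_EFFECTS = {
    "Guizhou":  (1.12, 1.00),
    "Xinjiang": (1.10, 1.10),
    "Henan":    (1.09, 1.02),
    "Jiangxi":  (1.08, 1.08),
    "Hunan":    (1.06, 1.06),
    "Hubei":    (1.04, 1.04),
    "Shaanxi":  (1.02, 1.18),
}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic spectra generator.

    ``band_centers``/``band_widths``/``band_amplitudes`` define the shared
    Gaussian band inventory (cm⁻¹ / cm⁻¹ / absorbance).  ``drying_effects``
    and ``region_effects`` map class label → (high-window, low-window)
    multiplicative intensity factors, blended linearly across the
    7,000–6,000 cm⁻¹ gap (7,000–5,350 for regions) so the factor field is
    continuous.  ``separation`` exponentiates every class factor
    (``f**separation``): 1 is the default realism level, larger values give
    strongly separated classes.  ``site_sd``/``scatter_sd`` are
    multiplicative (site-level, sample-level) standard deviations,
    ``noise_sd`` is additive absorbance noise.
    """

    grid: np.ndarray = field(default_factory=default_grid)
    band_centers: Sequence[float] = _BAND_CENTERS
    band_widths: Sequence[float] = _BAND_WIDTHS
    band_amplitudes: Sequence[float] = _BAND_AMPLITUDES
    drying_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DRYING_EFFECTS))
    region_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_REGION_EFFECTS))
    separation: float = 1.0
    site_sd: float = 0.01
    scatter_sd: float = 0.02
    noise_sd: float = 0.002
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, float)
        lo, hi = g.min(), g.max()
        for c in self.band_centers:
            if not (lo <= c <= hi):
                raise ValueError(f"band center {c} outside grid range")
        if any(w <= 0 for w in self.band_widths):
            raise ValueError("band widths must be > 0")
        if self.noise_sd < 0 or self.scatter_sd < 0 or self.site_sd < 0:
            raise ValueError("noise/scatter/site sd must be >= 0")
        for effects in (self.drying_effects, self.region_effects):
            for k, (fh, fl) in effects.items():
                if fh <= 0 or fl <= 0:
                    raise ValueError(f"class factors must be > 0 ({k})")

    def strong(self, separation: float = 4.0) -> "GeneratorConfig":
        """Variant with strongly separated classes and low noise."""
        return replace(self, separation=separation, noise_sd=0.001,
                       scatter_sd=0.005, site_sd=0.0)

    # -- internal fields ---------------------------------------------------

    def _base_profile(self) -> np.ndarray:
        v = np.asarray(self.grid, float)
        prof = np.full(v.shape, float(self.baseline))
        for c, w, a in zip(self.band_centers, self.band_widths,
                           self.band_amplitudes):
            prof += a * np.exp(-0.5 * ((v - c) / w) ** 2)
        return prof

    def _factor_field(self, factors: tuple[float, float],
                      hi_edge: float, lo_edge: float) -> np.ndarray:
        """Smooth per-point factor: ``factors[0]`` above ``hi_edge``,
        ``factors[1]`` below ``lo_edge``, linear ramp between."""
        v = np.asarray(self.grid, float)
        fh, fl = (f ** self.separation for f in factors)
        t = np.clip((v - lo_edge) / (hi_edge - lo_edge), 0.0, 1.0)
        return fl + (fh - fl) * t

    def _drying_field(self, method: str) -> np.ndarray:
        try:
            f = self.drying_effects[method]
        except KeyError:
            raise KeyError(f"unknown drying method {method!r}") from None
        return self._factor_field(f, 7_000.0, 6_000.0)

    def _region_field(self, region: str) -> np.ndarray:
        try:
            f = self.region_effects[region]
        except KeyError:
            raise KeyError(f"unknown region {region!r}") from None
        return self._factor_field(f, 7_000.0, 5_350.0)

    def _site_factor(self, site: str | None) -> float:
        if site is None or self.site_sd == 0:
            return 1.0
        # deterministic in (seed, site name), independent of sample order
        key = zlib.crc32(str(site).encode("utf-8"))
        rng = np.random.default_rng([self.seed & 0x7FFFFFFF, key])
        return float(np.exp(rng.normal(0.0, self.site_sd)))


def generate_spectrum(config: GeneratorConfig, region: str, method: str,
                      rng: np.random.Generator,
                      site: str | None = None) -> np.ndarray:
    """One synthetic absorbance spectrum on ``config.grid``.

    Gaussian-band profile × region factor × drying factor × site factor ×
    (1 + multiplicative scatter) + additive noise.  Deterministic for a
    given generator state.
    """
    clean = (config._base_profile()
             * config._region_field(region)
             * config._drying_field(method)
             * config._site_factor(site))
    scatter = 1.0 + rng.normal(0.0, config.scatter_sd) if config.scatter_sd else 1.0
    noise = rng.normal(0.0, config.noise_sd, clean.size) if config.noise_sd else 0.0
    return clean * scatter + noise


# -- manifests -------------------------------------------------------------

def table1_counts() -> pd.DataFrame:
    """Per-site, per-drying-method sample counts of the 534-sample study:
    7 regions, 16 collection sites, 4 drying methods."""
    rows = [
        ("Guizhou", "Zunyi-Bozhou", 10, 10, 10, 10),
        ("Guizhou", "Zunyi-Huichuan", 10, 10, 10, 10),
        ("Guizhou", "Zunyi-Honghuagang", 11, 10, 10, 10),
        ("Henan", "Xingyang-Liujiahe", 10, 10, 9, 10),
        ("Henan", "Gongyi-Jialu", 10, 10, 10, 10),
        ("Henan", "Luanchuan-Miaozi", 10, 10, 10, 10),
        ("Hubei", "Shennongjia-Muyu", 3, 3, 3, 3),
        ("Hubei", "Xiangyang-Xiangzhou", 10, 10, 10, 10),
        ("Hubei", "Shennongjia-Guanmenshan", 3, 3, 3, 3),
        ("Hunan", "Zhangjiajie-Cili", 10, 10, 10, 10),
        ("Hunan", "Jishou-Zhaiyang", 10, 10, 10, 9),
        ("Jiangxi", "Pingxiang-Luxi", 11, 9, 9, 10),
        ("Shaanxi", "Hanzhong-Lueyang", 11, 11, 11, 11),
        ("Shaanxi", "Ankang-Hanyin", 10, 10, 10, 10),
        ("Xinjiang", "Urumqi-Liushihu", 5, 5, 5, 5),
        ("Xinjiang", "Fukang-Ziniquanzi", 2, 2, 2, 2),
    ]
    return pd.DataFrame(rows, columns=["region", "site", *DRYING_METHODS])


def uniform_counts(regions: Sequence[str] = ("Guizhou", "Shaanxi"),
                   n_per_cell: int = 5,
                   methods: Sequence[str] = DRYING_METHODS) -> pd.DataFrame:
    """Small balanced counts table (one site per region) for desk-scale runs."""
    rows = [(r, f"{r}-site", *[n_per_cell] * len(methods)) for r in regions]
    return pd.DataFrame(rows, columns=["region", "site", *methods])


def generate_manifest(counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Expand a per-site counts table into a one-row-per-sample manifest.

    ``counts`` has columns ``region, site`` plus one column per drying
    method holding nonnegative integer counts; ``None`` uses the study's
    default (534 samples).  Sample ids are ``EUL0001`` ….
    """
    if counts is None:
        counts = table1_counts()
    method_cols = [c for c in counts.columns if c not in ("region", "site")]
    records = []
    k = 0
    for _, row in counts.iterrows():
        for method in method_cols:
            n = int(row[method])
            if n < 0:
                raise ValueError("counts must be nonnegative")
            for _ in range(n):
                k += 1
                records.append((f"EUL{k:04d}", row["region"], row["site"],
                                method, 1))
    manifest = pd.DataFrame(records, columns=MANIFEST_COLUMNS)
    return validate_manifest(manifest)


def generate_dataset(config: GeneratorConfig,
                     manifest: pd.DataFrame) -> SpectrumSet:
    """One spectrum per manifest record, reproducible from ``config.seed``.

    Each sample draws from its own counter-derived substream
    (``default_rng([seed, row_index])``), so generation order cannot change
    the result.
    """
    validate_manifest(manifest)
    if not manifest["sample_id"].is_unique:
        raise ValueError("generate_dataset expects one record per sample "
                         "(average replicates upstream)")
    n = len(manifest)
    X = np.empty((n, len(np.asarray(config.grid))))
    for i, row in enumerate(manifest.itertuples(index=False)):
        rng = np.random.default_rng([config.seed & 0x7FFFFFFF, i])
        X[i] = generate_spectrum(config, row.region, row.drying_method, rng,
                                 site=row.site)
    return SpectrumSet(np.asarray(config.grid, float), X,
                       manifest["sample_id"].tolist())
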