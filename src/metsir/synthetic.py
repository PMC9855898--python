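"""Synthetic clinical tables and FTIR-like plasma spectra.

The generator emulates the statistical structure the downstream analysis
assumes: two patient groups (metabolic syndrome and controls, default sizes
19 / 86), five clinical parameters drawn per group from truncated normals
matching the reported group ranges, and absorbance spectra built as sums of
Gaussian bands whose intensities covary with the clinical values, on top of a
random linear baseline, multiplicative scatter and additive white noise.

Band centers default to the wavenumbers the study singled out: lipid
CH2/CH3 stretches (2860.22, 2948.94 cm⁻¹) linked to triglycerides,
carbohydrate C-O stretches (1108.98, 1133.09 cm⁻¹) linked to glucose, amide-II
protein bands (1557.40, 1562.22, 1578.61 cm⁻¹) negatively linked to HDL, plus
class-neutral bands shared by all samples (1423.36, 1316.32, 1247.85 cm⁻¹ and
broad background bands).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ClinicalTable, SpectraSet
from .mets_rules import MET_S, NO_MET_S

# (max, min, mean) per clinical parameter, per group — the reported ranges
CLINICAL_RANGES: dict[str, dict[str, tuple[float, float, float]]] = {
    MET_S: {
        "SP": (174.0, 120.0, 136.0),
        "DP": (109.0, 75.0, 87.0),
        "TGL": (338.0, 88.0, 242.0),
        "HDL": (58.0, 25.0, 37.0),
        "GLU": (164.0, 82.0, 114.0),
    },
    NO_MET_S: {
        "SP": (178.0, 94.0, 126.0),
        "DP": (115.0, 61.0, 79.0),
        "TGL": (215.0, 33.0, 109.0),
        "HDL": (95.0, 29.0, 55.0),
        "GLU": (123.0, 63.0, 91.0),
    },
}

#: default analysed wavenumber ranges (high, low) in cm⁻¹
DEFAULT_REGIONS: tuple[tuple[float, float], ...] = ((2973.0, 2700.0), (1583.0, 1050.0))
#: nominal grid spacing giving 838 points over the two default ranges
DEFAULT_SPACING = 806.0 / 836.0

#: the ten wavenumbers reported as most discriminating
REPORTED_WAVENUMBERS = (2860.22, 1423.36, 1562.22, 1578.61, 1108.98,
                        1316.32, 2948.94, 1557.40, 1133.09, 1247.85)


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band.

    ``linked_to`` names a clinical parameter ("TGL", "GLU", "HDL", ...),
    ``"class"`` for a direct group effect, or None for a neutral band.
    ``strength`` is the intensity change per 1 SD of the linked quantity
    (for ``"class"`` links: the between-group intensity shift expressed in
    units of the within-group intensity SD, i.e. an effect size).
    ``sign`` flips the direction of the link.
    """

    center: float            # cm⁻¹
    width: float = 10.0      # Gaussian sigma, cm⁻¹
    base: float = 0.3        # baseline intensity, absorbance units
    linked_to: str | None = None
    strength: float = 0.0
    sign: int = 1
    jitter: float = 0.02     # within-sample intensity SD, absorbance units

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")


def _pooled_stats(param: str) -> tuple[float, float]:
    """Fixed normalisation constants for a clinical parameter: midpoint of the
    two group means, and a scale of (pooled max − pooled min)/4."""
    m1 = CLINICAL_RANGES[MET_S][param]
    m2 = CLINICAL_RANGES[NO_MET_S][param]
    mean = 0.5 * (m1[2] + m2[2])
    scale = (max(m1[0], m2[0]) - min(m1[1], m2[1])) / 4.0
    return mean, scale


def default_band_library() -> list[Band]:
    """Clinically linked bands plus neutral background."""
    lib = [
        Band(2860.22, 9.0, 0.25, "TGL", 0.08),
        Band(2948.94, 9.0, 0.30, "TGL", 0.10),
        Band(1108.98, 8.0, 0.25, "GLU", 0.08),
        Band(1133.09, 8.0, 0.30, "GLU", 0.10),
        Band(1557.40, 7.0, 0.30, "HDL", 0.08, sign=-1),
        Band(1562.22, 7.0, 0.25, "HDL", 0.06, sign=-1),
        Band(1578.61, 7.0, 0.25, "HDL", 0.06, sign=-1),
        # class-neutral narrow bands at the remaining reported wavenumbers
        Band(1423.36, 8.0, 0.25),
        Band(1316.32, 8.0, 0.20),
        Band(1247.85, 8.0, 0.25),
        # broad background bands common to all plasma
        Band(1400.0, 60.0, 0.5),
        Band(1150.0, 80.0, 0.4),
        Band(2900.0, 60.0, 0.45),
    ]
    return lib


def class_effect_band_library(effect: float = 6.0,
                              centers=REPORTED_WAVENUMBERS) -> list[Band]:
    """Bands with a direct between-group intensity shift of ``effect``
    within-group SDs at each given center, plus broad neutral background."""
    lib = [Band(c, 8.0, 0.3, "class", float(effect)) for c in centers]
    lib += [Band(1400.0, 60.0, 0.5), Band(1150.0, 80.0, 0.4),
            Band(2900.0, 60.0, 0.45)]
    return lib


@dataclass
class GeneratorConfig:
    n_mets: int = 19
    n_nomets: int = 86
    seed: int = 0
    clinical_params: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in CLINICAL_RANGES.items()})
    band_library: list[Band] = field(default_factory=default_band_library)
    noise_sd: float = 0.002          # additive noise, absorbance units
    baseline_offset_sd: float = 0.01
    baseline_slope_sd: float = 0.005
    scatter_sd: float = 0.05         # multiplicative scatter factor SD
    regions: tuple = DEFAULT_REGIONS
    spacing: float = DEFAULT_SPACING
    n_replicates: int = 1
    sex_prob_female: float = 0.5

    def __post_init__(self) -> None:
        if self.n_mets < 0 or self.n_nomets < 0:
            raise ValueError("group sizes must be >= 0")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        for cls, params in self.clinical_params.items():
            for name, (mx, mn, mean) in params.items():
                if not mn <= mean <= mx:
                    raise ValueError(
                        f"{cls}/{name}: need min <= mean <= max, got {mn},{mean},{mx}")

    @classmethod
    def strong_signal(cls, effect: float = 6.0, seed: int = 0, **kw):
        """Study-size dataset with ten class-linked informative bands."""
        return cls(seed=seed, band_library=class_effect_band_library(effect), **kw)


@dataclass
class SyntheticDataset:
    spectra: SpectraSet
    clinical: ClinicalTable
    truth_labels: pd.Series           # per-sample generating class
    informative: np.ndarray           # per-wavenumber bool flags

    def __post_init__(self) -> None:
        ids = self.spectra.sample_ids
        if self.spectra.replicate_of:
            ids = sorted({self.spectra.replicate_of.get(s, s) for s in ids})
        else:
            ids = sorted(ids)
        if sorted(self.clinical.sample_ids) != ids:
            raise ValueError("sample ids differ between spectra and clinical table")


def default_grid(regions=DEFAULT_REGIONS, spacing: float = DEFAULT_SPACING) -> np.ndarray:
    """Descending wavenumber grid: uniform within each region.

    Point count per region is ``round(width / spacing) + 1``; each region's
    actual spacing is then ``width / (n - 1)`` so both endpoints are on the
    grid.  With the default two regions and nominal spacing 806/836 cm⁻¹ the
    grid has 554 + 284 = 838 points.
    """
    segs = []
    for high, low in sorted(regions, key=lambda r: -r[0]):
        if high <= low:
            raise ValueError(f"region ({high}, {low}) must have high > low")
        n = int(round((high - low) / spacing)) + 1
        segs.append(np.linspace(high, low, n))
    return np.concatenate(segs)


def generate_clinical(config: GeneratorConfig) -> ClinicalTable:
    """Draw per-group clinical parameters from truncated normals.

    Each parameter uses the group's reported (max, min, mean) with
    SD = (max − min)/4, truncated to [min, max].
    """
    rng = np.random.default_rng(config.seed)
    rows, ids, labels, sexes = [], [], [], []
    for cls, n in ((MET_S, config.n_mets), (NO_MET_S, config.n_nomets)):
        params = config.clinical_params[cls]
        cols = {}
        for name, (mx, mn, mean) in params.items():
            sd = (mx - mn) / 4.0
            a, b = (mn - mean) / sd, (mx - mean) / sd
            cols[name] = stats.truncnorm.rvs(
                a, b, loc=mean, scale=sd, size=n, random_state=rng)
        sex = np.where(rng.random(n) < config.sex_prob_female, "F", "M")
        for i in range(n):
            rows.append({k: cols[k][i] for k in cols})
            ids.append(f"{cls}_{i + 1:03d}")
            labels.append(cls)
            sexes.append(sex[i])
    df = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"))
    df["sex"] = sexes
    df["label"] = labels
    return ClinicalTable(df)


def _band_intensity(band: Band, clinical_row: pd.Series, rng) -> float:
    x = band.base
    if band.linked_to == "class":
        # between-group shift of `strength` within-group intensity SDs
        if clinical_row["label"] == MET_S:
            x += band.sign * band.strength * band.jitter
    elif band.linked_to is not None:
        mean, scale = _pooled_stats(band.linked_to)
        z = (float(clinical_row[band.linked_to]) - mean) / scale
        x += band.sign * band.strength * z
    x += rng.normal(0.0, band.jitter)
    return x


def generate_spectra(clinical: ClinicalTable, config: GeneratorConfig) -> SpectraSet:
    """Build spectra from the band library given a clinical table.

    spectrum(ν) = baseline(ν) + scatter × Σ_b intensity_b × g(ν; c_b, w_b) + ε
    """
    if len(clinical) == 0:
        raise ValueError("clinical table is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    nu = default_grid(config.regions, config.spacing)
    lo, hi = nu.min(), nu.max()
    bands = []
    for b in config.band_library:
        if not lo <= b.center <= hi:
            import warnings
            warnings.warn(f"band center {b.center} outside grid span; skipped")
            continue
        bands.append(b)
    profiles = np.stack([
        np.exp(-0.5 * ((nu - b.center) / b.width) ** 2) for b in bands
    ]) if bands else np.zeros((0, nu.size))

    span = hi - lo if hi > lo else 1.0
    mid = 0.5 * (hi + lo)
    ids, rows = [], []
    for sid, crow in clinical.data.iterrows():
        intens = np.array([_band_intensity(b, crow, rng) for b in bands])
        pure = intens @ profiles
        for r in range(config.n_replicates):
            scatter = 1.0 + rng.normal(0.0, config.scatter_sd)
            offset = rng.normal(0.0, config.baseline_offset_sd)
            slope = rng.normal(0.0, config.baseline_slope_sd)
            baseline = offset + slope * (nu - mid) / span
            eps = rng.normal(0.0, config.noise_sd, size=nu.size)
            rows.append(baseline + scatter * pure + eps)
            ids.append(sid if config.n_replicates == 1 else f"{sid}_rep{r + 1}")
    replicate_of = None
    labels = None
    if config.n_replicates > 1:
        replicate_of = {rid: rid.rsplit("_rep", 1)[0] for rid in ids}
        labels = np.array(
            [clinical.data.loc[replicate_of[rid], "label"] for rid in ids],
            dtype=object)
    else:
        labels = clinical.data.loc[ids, "label"].to_numpy(dtype=object)
    return SpectraSet(nu, np.vstack(rows), ids,
                      replicate_of=replicate_of, labels=labels)


def informative_flags(grid: np.ndarray, bands: list[Band]) -> np.ndarray:
    """Boolean flags marking the grid point nearest each linked band center."""
    flags = np.zeros(grid.size, dtype=bool)
    for b in bands:
        if b.linked_to is not None and b.strength != 0:
            if grid.min() <= b.center <= grid.max():
                flags[int(np.argmin(np.abs(grid - b.center)))] = True
    return flags


def make_dataset(config: GeneratorConfig | None = None, **kw) -> SyntheticDataset:
    """Generate a paired clinical table + spectra set with ground truth."""
    if config is None:
        config = GeneratorConfig(**kw)
    elif kw:
        config = replace(config, **kw)
    clinical = generate_clinical(config)
    spectra = generate_spectra(clinical, config)
    flags = informative_flags(spectra.wavenumbers, config.band_library)
    truth = clinical.data["label"].rename("truth")
    return SyntheticDataset(spectra, clinical, truth, flags)
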