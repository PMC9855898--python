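"""Spectral pre-treatment: replicate averaging, Savitzky–Golay filtering,
SNV, EMSC, wavenumber-region restriction and mean-centering.

The canonical order is average → Savitzky–Golay → SNV → restrict → center.
Savitzky–Golay filtering is applied independently within each contiguous
uniformly spaced grid segment (the filter is never convolved across the gap
between the analysed regions).  Grids are stored descending in wavenumber;
derivatives are reported with respect to wavenumber, with the sign corrected
for the descending storage order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .io_formats import SpectraSet

#: spacing uniformity tolerance within a segment, cm⁻¹
UNIFORMITY_TOL = 1e-6


@dataclass
class SavgolStep:
    window: int = 9
    polyorder: int = 2
    deriv: int = 0

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError("window must be odd and > polyorder")
        if self.deriv > self.polyorder:
            raise ValueError("deriv must be <= polyorder")


@dataclass
class PreprocessPlan:
    """Ordered pre-treatment recipe.

    ``steps`` is a list over {"average_replicates", SavgolStep, "snv",
    "emsc", "restrict", "center"}.  ``regions`` configures "restrict";
    ``emsc_reference`` (default: set mean) configures "emsc".
    """

    steps: list = field(default_factory=lambda: [
        "average_replicates", SavgolStep(9, 2, 0), "snv", "restrict"])
    regions: tuple = ((2973.0, 2700.0), (1583.0, 1050.0))
    emsc_reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        regs = sorted(self.regions, key=lambda r: -r[0])
        for (h1, l1), (h2, l2) in zip(regs[:-1], regs[1:]):
            if h2 >= l1:
                raise ValueError("regions overlap")

    def apply(self, spectra: SpectraSet) -> SpectraSet:
        out = spectra
        for step in self.steps:
            if step == "average_replicates":
                if out.replicate_of:
                    out = average_replicates(out)
            elif isinstance(step, SavgolStep):
                out = savitzky_golay(out, step.window, step.polyorder, step.deriv)
            elif step == "snv":
                out = snv(out)
            elif step == "emsc":
                out = emsc(out, self.emsc_reference)
            elif step == "restrict":
                out = restrict(out, self.regions)
            else:
                raise ValueError(f"unknown preprocessing step {step!r}")
        return out


def average_replicates(spectra: SpectraSet) -> SpectraSet:
    """One mean spectrum per biological sample (arithmetic mean of replicates)."""
    if not spectra.replicate_of:
        raise ValueError("spectra set carries no replicate map")
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(spectra.sample_ids):
        groups.setdefault(spectra.replicate_of.get(sid, sid), []).append(i)
    ids = list(groups)
    mat = np.vstack([spectra.absorbance[groups[g]].mean(axis=0) for g in ids])
    labels = None
    if spectra.labels is not None:
        labels = np.array([spectra.labels[groups[g][0]] for g in ids], dtype=object)
    return SpectraSet(spectra.wavenumbers, mat, ids, replicate_of=None, labels=labels)


def savitzky_golay(spectra: SpectraSet, window: int = 9, polyorder: int = 2,
                   deriv: int = 0) -> SpectraSet:
    """Least-squares polynomial smoothing / differentiation per grid segment.

    Boundary windows are handled by polynomial fits (no padding).  For
    ``deriv > 0`` the output is d^k A / dν^k in (absorbance · cm^k); since the
    grid is stored descending, the index-wise derivative is multiplied by
    (−1)^deriv to express it with respect to increasing wavenumber.
    """
    SavgolStep(window, polyorder, deriv)  # validate
    nu = spectra.wavenumbers
    out = np.empty_like(spectra.absorbance)
    for seg in spectra.segments():
        seg_nu = nu[seg]
        n = seg_nu.size
        if n < window:
            raise ValueError(
                f"segment of {n} points shorter than window {window}")
        d = np.diff(seg_nu)
        if np.ptp(d) > UNIFORMITY_TOL:
            raise ValueError(
                "non-uniform grid spacing within a segment "
                f"(spread {np.ptp(d):.3g} cm⁻¹ exceeds {UNIFORMITY_TOL})")
        spacing = abs(float(d.mean())) if n > 1 else 1.0
        filt = savgol_filter(spectra.absorbance[:, seg], window, polyorder,
                             deriv=deriv, delta=spacing, axis=1, mode="interp")
        out[:, seg] = filt * ((-1.0) ** deriv)
    return spectra.copy_with(absorbance=out)


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: per-spectrum centering and unit-SD scaling
    (SD with n−1 denominator).  Removes additive offsets and multiplicative
    scatter per spectrum."""
    x = spectra.absorbance
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        names = ", ".join(spectra.sample_ids[i] for i in bad)
        raise ValueError(f"constant spectrum (zero variance): {names}")
    return spectra.copy_with(absorbance=(x - mean) / sd)


def emsc(spectra: SpectraSet, reference: np.ndarray | None = None) -> SpectraSet:
    """Extended multiplicative scatter correction.

    Each spectrum is regressed on [1, reference, ν, ν²]; the corrected
    spectrum is (x − a − c·ν − d·ν²)/b.  Default reference: the set mean.
    """
    x = spectra.absorbance
    nu = spectra.wavenumbers
    ref = x.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.shape != nu.shape:
        raise ValueError("EMSC reference not on the spectra grid")
    # scale ν terms for conditioning
    nu1 = (nu - nu.mean()) / (np.ptp(nu) or 1.0)
    design = np.column_stack([np.ones_like(nu), ref, nu1, nu1 ** 2])
    coef, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    a, b, c, d = coef
    if np.any(np.abs(b) < 1e-8):
        i = int(np.argmin(np.abs(b)))
        raise ValueError(
            f"degenerate multiplicative EMSC term for sample {spectra.sample_ids[i]}")
    corrected = (x - np.outer(a, np.ones_like(nu)) - np.outer(c, nu1)
                 - np.outer(d, nu1 ** 2)) / b[:, None]
    return spectra.copy_with(absorbance=corrected)


def restrict(spectra: SpectraSet, regions) -> SpectraSet:
    """Keep grid points with low ≤ ν ≤ high for any region; order preserved."""
    nu = spectra.wavenumbers
    keep = np.zeros(nu.size, dtype=bool)
    for high, low in regions:
        keep |= (nu >= low) & (nu <= high)
    if not keep.any():
        raise ValueError("region restriction removed every grid point")
    return spectra.copy_with(wavenumbers=nu[keep], absorbance=spectra.absorbance[:, keep])


def mean_center(matrix: np.ndarray, means: np.ndarray | None = None):
    """Column-center a matrix.

    When ``means`` is given (a test block), those (training) means are
    subtracted instead of the block's own.  Returns (centered, means used).
    """
    x = np.asarray(matrix, dtype=float)
    if means is None:
        means = x.mean(axis=0)
    else:
        means = np.asarray(means, dtype=float)
    return x - means, means
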