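"""Clonal vs subclonal timing of mutations from variant ploidy.

The variant ploidy of a mutation is its tumor-purity-adjusted allele
fraction multiplied by the local total copy number; a fully clonal
heterozygous mutation on a diploid segment scores 1. Variants scoring
above 1 are clonal by definition. Among variants below 1, subclonal
populations appear as extra density modes below the main ploidy-1
peak, found by Gaussian kernel density estimation with a fixed
absolute bandwidth (default 0.05). Sub-unity variants are assigned to
their nearest density peak: a subclonal peak makes them subclonal, the
main peak keeps them clonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_catalog import MutationCatalog, TYPE_LABELS
from .signatures import SignatureMatrix, refit_nnls, relative_contribution

CLONAL = "clonal"
SUBCLONAL = "subclonal"
UNASSIGNED = "unassigned"


@dataclass
class ClonalityProfile:
    variant_ploidies: np.ndarray
    labels: np.ndarray  # clonal | subclonal | unassigned
    peaks: np.ndarray  # all density peaks, ascending
    bandwidth: float

    def __post_init__(self) -> None:
        self.peaks = np.sort(np.asarray(self.peaks, dtype=float))

    @property
    def n_subclonal(self) -> int:
        return int(np.sum(self.labels == SUBCLONAL))


def variant_ploidy(adjusted_vaf: float, copy_number: float) -> float:
    """Adjusted allele fraction times local copy number."""
    if not 0.0 <= adjusted_vaf <= 1.0:
        raise ValueError(f"adjusted_vaf {adjusted_vaf} outside [0, 1]")
    if copy_number < 0:
        raise ValueError(f"copy number {copy_number} is negative")
    return adjusted_vaf * copy_number


def gaussian_kde_grid(values: np.ndarray, bandwidth: float,
                      grid: np.ndarray) -> np.ndarray:
    """Gaussian kernel density with an absolute bandwidth, evaluated
    on ``grid``. The bandwidth is the kernel standard deviation in
    ploidy units (not a factor of the data SD)."""
    z = (grid[:, None] - values[None, :]) / bandwidth
    dens = np.exp(-0.5 * z ** 2).sum(axis=1)
    return dens / (values.size * bandwidth * np.sqrt(2 * np.pi))


def detect_subclonal_peaks(ploidies, bandwidth: float = 0.05,
                           grid_step: float = 0.01,
                           min_subclonal_search: int = 10) -> np.ndarray:
    """Density peaks of the variant-ploidy distribution.

    Returns all strict local maxima of the Gaussian KDE on a grid over
    [0, max(ploidy) + 3*bandwidth]; peaks below 1 - bandwidth are the
    subclonal candidates. When fewer than ``min_subclonal_search``
    variants lie below ploidy 1 no search is performed and an empty
    list is returned with a warning.
    """
    ploidies = np.asarray(ploidies, dtype=float)
    if ploidies.size == 0:
        raise ValueError("no variant ploidies given")
    if np.sum(ploidies < 1.0) < min_subclonal_search:
        warnings.warn(
            f"fewer than {min_subclonal_search} variants below ploidy 1; "
            "subclonal peak search skipped")
        return np.array([])
    hi = float(ploidies.max()) + 3 * bandwidth
    grid = np.arange(0.0, hi + grid_step, grid_step)
    dens = gaussian_kde_grid(ploidies, bandwidth, grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    return grid[1:-1][interior]


def subclonal_peaks(peaks: np.ndarray, bandwidth: float = 0.05) -> np.ndarray:
    peaks = np.asarray(peaks, dtype=float)
    return peaks[peaks < 1.0 - bandwidth]


def classify_clonality(ploidies, peaks, bandwidth: float = 0.05) -> np.ndarray:
    """Label variants clonal or subclonal.

    Ploidy > 1 is clonal unconditionally. Ploidy <= 1 is assigned to
    the nearest density peak: nearest peak below 1 - bandwidth makes
    the variant subclonal, otherwise it stays clonal. With no
    subclonal peaks all sub-unity variants are clonal.
    """
    ploidies = np.asarray(ploidies, dtype=float)
    peaks = np.asarray(peaks, dtype=float)
    labels = np.full(ploidies.shape, CLONAL, dtype=object)
    sub = subclonal_peaks(peaks, bandwidth)
    if sub.size == 0:
        return labels
    main = peaks[peaks >= 1.0 - bandwidth]
    if main.size == 0:
        main = np.array([1.0])  # no resolved main peak: anchor at ploidy 1
    below = ploidies <= 1.0
    d_sub = np.abs(ploidies[below, None] - sub[None, :]).min(axis=1)
    d_main = np.abs(ploidies[below, None] - main[None, :]).min(axis=1)
    labels[below] = np.where(d_sub < d_main, SUBCLONAL, CLONAL)
    return labels


def clonality_profile(ploidies, bandwidth: float = 0.05,
                      grid_step: float = 0.01) -> ClonalityProfile:
    ploidies = np.asarray(ploidies, dtype=float)
    peaks = detect_subclonal_peaks(ploidies, bandwidth, grid_step)
    labels = classify_clonality(ploidies, peaks, bandwidth)
    return ClonalityProfile(ploidies, labels, peaks, bandwidth)


def subclonal_eligibility(n_subclonal: int,
                          focal_contribution: float,
                          min_subclonal: int = 500,
                          min_contribution: float = 0.05) -> bool:
    """Sample-inclusion rule for the subclonal analysis: at least 500
    subclonal mutations and at least 5% overall focal-signature
    contribution (both inclusive)."""
    if n_subclonal < 0 or focal_contribution < 0:
        raise ValueError("inputs must be non-negative")
    return n_subclonal >= min_subclonal and focal_contribution >= min_contribution


def clonal_subclonal_contrast(type_indices, ploidies,
                              signatures: SignatureMatrix,
                              focal_signature: str,
                              bandwidth: float = 0.05) -> dict:
    """Focal-signature relative contribution in the clonal vs subclonal
    compartment of one sample.

    ``type_indices`` are canonical 96-class indices per variant
    (aligned with ``ploidies``). Each compartment's 96-vector is refit
    by NNLS against ``signatures``; the returned ratio is
    subclonal / clonal relative contribution of ``focal_signature``.
    Variants with missing ploidy (NaN) are unassigned and excluded.
    """
    type_indices = np.asarray(type_indices, dtype=int)
    ploidies = np.asarray(ploidies, dtype=float)
    valid = np.isfinite(ploidies)
    profile = clonality_profile(ploidies[valid], bandwidth)
    labels = np.full(ploidies.shape, UNASSIGNED, dtype=object)
    labels[valid] = profile.labels

    counts = np.zeros((96, 2))
    for col, lab in enumerate((CLONAL, SUBCLONAL)):
        idx, c = np.unique(type_indices[labels == lab], return_counts=True)
        counts[idx, col] = c
    if counts[:, 0].sum() == 0 or counts[:, 1].sum() == 0:
        warnings.warn("empty clonal or subclonal compartment; sample skipped")
        return {"skipped": True}

    catalog = MutationCatalog(counts.astype(int), [CLONAL, SUBCLONAL])
    rel = relative_contribution(refit_nnls(catalog, signatures))
    clonal_share = float(rel.loc[focal_signature, CLONAL])
    subclonal_share = float(rel.loc[focal_signature, SUBCLONAL])
    return {
        "skipped": False,
        "clonal_contribution": clonal_share,
        "subclonal_contribution": subclonal_share,
        "ratio": subclonal_share / clonal_share if clonal_share > 0 else np.inf,
        "n_clonal": int(counts[:, 0].sum()),
        "n_subclonal": int(counts[:, 1].sum()),
        "profile": profile,
    }
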