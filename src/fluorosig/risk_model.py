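"""Oncogenic-driver risk model for treatment mutagenesis.

Expected number of driver-activating mutations introduced into a
population of N cells accumulating mu mutations each with mutation
spectrum P:

    M_active(N) = f_coding * dp * N * mu * sum_c P_c * n_c / L

where f_coding is the fraction of the genome that is exon coding
(0.015), dp the mutational depletion of coding sequence relative to
the genome average (0.3094464), L the coding-sequence length
(22,563,618 bp), P_c the probability that a mutation falls in
96-class c, and n_c the number of genomic positions where a class-c
substitution activates a driver gene. Scenarios differ in rate
(mutations per cell per year), duration and spectrum; with matched
driver tables and spectra the risk fold between scenarios reduces to
the ratio of total mutation counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io_catalog import (TYPE_INDEX, ClassificationError, GenomicVariant,
                         classify_variant)

CODING_FRACTION = 0.015
CDS_DEPLETION = 0.3094464
CDS_LENGTH = 22_563_618
COLON_STEM_CELLS = 1e8
TREATMENT_RATE_PER_YEAR = 2000.0
BASELINE_RATE_PER_YEAR = 40.0
TREATMENT_DURATION_WEEKS = 24.0


@dataclass
class RiskParams:
    """All symbols of the driver risk formula."""

    P: np.ndarray  # 96-vector of mutation-class probabilities
    n: np.ndarray  # 96-vector of driver-activating position counts
    N: float = COLON_STEM_CELLS
    mu: float = 0.0  # mutations per cell for the scenario
    L: int = CDS_LENGTH
    coding_fraction: float = CODING_FRACTION
    dp: float = CDS_DEPLETION

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.P.shape != (96,) or self.n.shape != (96,):
            raise ValueError("P and n must be 96-vectors")
        if (self.P < 0).any() or (self.n < 0).any():
            raise ValueError("P and n must be non-negative")
        if not np.isclose(self.P.sum(), 1.0, atol=1e-6):
            raise ValueError(f"P must sum to 1, got {self.P.sum()}")
        if self.L <= 0:
            raise ValueError("CDS length must be positive")


@dataclass
class Scenario:
    """A mutagenesis scenario: exposure rate, duration, and spectrum."""

    name: str
    annual_rate: float  # mutations per cell per year
    duration_years: float
    params: RiskParams

    def __post_init__(self) -> None:
        if self.duration_years < 0:
            raise ValueError("duration must be non-negative")
        self.params = replace(self.params,
                              mu=self.annual_rate * self.duration_years)


def build_oncogenic_table(driver_variants: Sequence[GenomicVariant],
                          reference) -> tuple[np.ndarray, dict]:
    """Count driver-activating positions per 96-class.

    Duplicate (chrom, pos, ref, alt) rows collapse to one position;
    variants whose context cannot be classified are skipped and
    tallied. Returns the 96-vector n and per-class position lists.
    """
    n = np.zeros(96)
    per_class: dict[str, list] = {}
    seen = set()
    skipped = 0
    for v in driver_variants:
        key = (v.chrom, v.pos, v.ref.upper(), v.alt.upper())
        if key in seen:
            continue
        seen.add(key)
        try:
            mt = classify_variant(v, reference)
        except (ClassificationError, KeyError, IndexError):
            skipped += 1
            continue
        n[TYPE_INDEX[mt.label]] += 1
        per_class.setdefault(mt.label, []).append(key)
    per_class["__skipped__"] = skipped
    return n, per_class


def expected_driver_mutations(params: RiskParams) -> float:
    """Evaluate the risk formula M_active for one scenario."""
    return float(params.coding_fraction * params.dp * params.N * params.mu
                 * np.sum(params.P * params.n) / params.L)


def scenario_fold_change(a: Scenario, b: Scenario) -> float:
    """M_active(a) / M_active(b).

    With matched P and n tables this reduces exactly to
    (rate_a * duration_a) / (rate_b * duration_b).
    """
    mb = expected_driver_mutations(b.params)
    if mb == 0:
        raise ZeroDivisionError(
            f"scenario {b.name!r} yields zero expected driver mutations")
    return expected_driver_mutations(a.params) / mb


def treatment_equivalent_years(treatment_rate: float = TREATMENT_RATE_PER_YEAR,
                               duration_weeks: float = TREATMENT_DURATION_WEEKS,
                               baseline_rate: float = BASELINE_RATE_PER_YEAR
                               ) -> float:
    """Years of baseline mutation accumulation equivalent to one
    treatment course: (rate * weeks/52) / baseline_rate."""
    if baseline_rate <= 0:
        raise ValueError("baseline rate must be positive")
    return treatment_rate * (duration_weeks / 52.0) / baseline_rate


def germline_predisposition_fold(treated: Scenario, untreated: Scenario,
                                 gene_n) -> float:
    """Risk fold for a germline-predisposition (second-hit) scenario.

    Both scenarios are re-evaluated with the driver table restricted
    to the inactivating positions of the predisposition gene; with
    matched spectra the fold again reduces to the exposure ratio.
    """
    gene_n = np.asarray(gene_n, dtype=float)
    if gene_n.shape != (96,):
        raise ValueError("restricted table must be a 96-vector")
    if gene_n.sum() == 0:
        raise ValueError("restricted driver table is empty")
    a = Scenario(treated.name, treated.annual_rate, treated.duration_years,
                 replace(treated.params, n=gene_n))
    b = Scenario(untreated.name, untreated.annual_rate,
                 untreated.duration_years, replace(untreated.params, n=gene_n))
    return scenario_fold_change(a, b)
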