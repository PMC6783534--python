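"""Replication- and transcription-strand asymmetry of mutations.

Mutations are assigned a strand by intersecting them with labeled
regions and asking on which strand the pyrimidine of the mutated base
pair lies. For replication, regions flanking replication origins
carry the role of the reference plus strand (leading or lagging); a
pyrimidine-reference mutation takes that role directly and a
purine-reference mutation takes the opposite role. For transcription,
a pyrimidine on the strand complementary to the gene (the template
strand) is "transcribed", on the gene strand "untranscribed";
intergenic mutations and mutations under opposite-strand gene
overlaps are unassigned.

Asymmetry per substitution class is tested with an exact two-sided
conditional test of equal Poisson rates: given the total N, the count
on one strand is Binomial(N, 1/2) under the null, and the two-sided
p-value doubles the smaller tail (capped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_catalog import (PYRIMIDINES, SUBSTITUTIONS, GenomicVariant,
                         classify_variant, normalize_chrom)

LEADING = "leading"
LAGGING = "lagging"
TRANSCRIBED = "transcribed"
UNTRANSCRIBED = "untranscribed"
UNASSIGNED = "unassigned"

_REPLICATION_FLIP = {LEADING: LAGGING, LAGGING: LEADING}


@dataclass(frozen=True)
class StrandRegion:
    """A labeled genomic span (1-based inclusive).

    For replication mode ``strand_label`` is the role of the reference
    plus strand within the span ("leading" or "lagging"); for
    transcription mode it is the gene strand ("+" or "-").
    """

    chrom: str
    start: int
    end: int
    strand_label: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")
        if self.strand_label not in (LEADING, LAGGING, "+", "-"):
            raise ValueError(f"unknown strand label {self.strand_label!r}")

    def contains(self, chrom: str, pos: int) -> bool:
        return (normalize_chrom(chrom) == normalize_chrom(self.chrom)
                and self.start <= pos <= self.end)


def read_bed_regions(path, mode: str = "replication") -> list[StrandRegion]:
    """Read labeled regions from BED (0-based half-open on disk).

    Replication mode takes the plus-strand role from the name column
    (column 4); transcription mode takes the gene strand from the
    strand column (column 6).
    """
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if mode == "replication":
                label = fields[3].lower()
            elif mode == "transcription":
                label = fields[5]
            else:
                raise ValueError(f"unknown mode {mode!r}")
            regions.append(StrandRegion(normalize_chrom(chrom), start + 1,
                                        end, label))
    return regions


def select_cnt_context(variants: Sequence[GenomicVariant],
                       reference) -> list[GenomicVariant]:
    """Keep variants whose pyrimidine-normalized trinucleotide is
    C[N>N]T — the 5-FU / signature-17 informative context (the flanks
    select the context; the substituted base may be any pyrimidine
    change)."""
    kept = []
    for v in variants:
        mt = classify_variant(v, reference)
        if mt.five_prime == "C" and mt.three_prime == "T":
            kept.append(v)
    return kept


def high_contribution_filter(abs_contribution: float,
                             rel_contribution: float,
                             min_abs: float = 2000.0,
                             min_rel: float = 0.25) -> bool:
    """Sample filter for strand-bias cohorts: absolute focal-signature
    contribution strictly above 2000 mutations AND relative
    contribution strictly above 25%."""
    if abs_contribution < 0 or rel_contribution < 0:
        raise ValueError("contributions must be non-negative")
    return abs_contribution > min_abs and rel_contribution > min_rel


def _overlapping(variant: GenomicVariant,
                 regions: Iterable[StrandRegion]) -> list[StrandRegion]:
    return [r for r in regions if r.contains(variant.chrom, variant.pos)]


def assign_replication_strand(variant: GenomicVariant,
                              regions: Sequence[StrandRegion]) -> str:
    """Leading/lagging assignment of one variant.

    The region label gives the plus strand's replication role; the
    variant takes that role if its reference (pyrimidine-normalized)
    base lies on the plus strand, i.e. the VCF reference base is a
    pyrimidine, and the opposite role otherwise.
    """
    hits = _overlapping(variant, regions)
    if not hits:
        return UNASSIGNED
    labels = {r.strand_label for r in hits}
    if len(labels) > 1:
        raise ValueError(
            f"contradictory replication annotations at "
            f"{variant.chrom}:{variant.pos}: {sorted(labels)}")
    plus_role = labels.pop()
    if variant.ref.upper() in PYRIMIDINES:
        return plus_role
    return _REPLICATION_FLIP[plus_role]


def assign_transcription_strand(variant: GenomicVariant,
                                gene_regions: Sequence[StrandRegion]) -> str:
    """Transcribed/untranscribed assignment of one variant.

    The pyrimidine of the mutated pair is on the plus strand when the
    VCF reference base is a pyrimidine. A pyrimidine on the template
    strand (complementary to the gene strand) is transcribed; on the
    gene (coding) strand, untranscribed. Intergenic variants and
    variants under genes on both strands are unassigned.
    """
    hits = _overlapping(variant, gene_regions)
    if not hits:
        return UNASSIGNED
    gene_strands = {r.strand_label for r in hits}
    if len(gene_strands) > 1:
        return UNASSIGNED
    gene_strand = gene_strands.pop()
    pyr_on_plus = variant.ref.upper() in PYRIMIDINES
    pyr_strand = "+" if pyr_on_plus else "-"
    return UNTRANSCRIBED if pyr_strand == gene_strand else TRANSCRIBED


def poisson_asymmetry_test(n_strand1: int, n_strand2: int,
                           method: str = "exact") -> float:
    """Two-sided test of equal mutation rates on the two strands.

    ``exact``: conditional binomial — given N = n1 + n2, n1 is
    Binomial(N, 1/2) under the null; p doubles the smaller tail,
    capped at 1. ``wald``: normal-approximation rate-ratio test on
    log(n1/n2).
    """
    if n_strand1 < 0 or n_strand2 < 0:
        raise ValueError("counts must be non-negative")
    total = n_strand1 + n_strand2
    if total == 0:
        raise ValueError("cannot test asymmetry with zero total count")
    if method == "exact":
        k = min(n_strand1, n_strand2)
        return float(min(1.0, 2.0 * stats.binom.cdf(k, total, 0.5)))
    if method == "wald":
        a, b = max(n_strand1, 0.5), max(n_strand2, 0.5)
        z = np.log(a / b) / np.sqrt(1 / a + 1 / b)
        return float(2 * stats.norm.sf(abs(z)))
    raise ValueError(f"unknown method {method!r}")


def strand_count_matrix(variants: Sequence[GenomicVariant], reference,
                        assignments: Sequence[str],
                        strand_pair: tuple[str, str] = (LEADING, LAGGING)
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """12-category count matrix (6 substitution classes x 2 strands)
    and per-class asymmetry tests.

    Unassigned variants are excluded; the matrix total equals the
    number of strand-assigned variants. The test table carries raw
    two-sided p-values and Benjamini-Hochberg adjusted values.
    """
    if len(variants) != len(assignments):
        raise ValueError("variants and assignments differ in length")
    counts = pd.DataFrame(0, index=list(SUBSTITUTIONS),
                          columns=list(strand_pair))
    for v, a in zip(variants, assignments):
        if a == UNASSIGNED:
            continue
        if a not in strand_pair:
            raise ValueError(f"assignment {a!r} not in {strand_pair}")
        mt = classify_variant(v, reference)
        counts.loc[mt.substitution, a] += 1

    rows = []
    for sub in SUBSTITUTIONS:
        n1, n2 = int(counts.loc[sub, strand_pair[0]]), \
            int(counts.loc[sub, strand_pair[1]])
        p = poisson_asymmetry_test(n1, n2) if n1 + n2 > 0 else np.nan
        rows.append({"substitution": sub, strand_pair[0]: n1,
                     strand_pair[1]: n2, "p_value": p})
    tests = pd.DataFrame(rows).set_index("substitution")
    mask = tests["p_value"].notna()
    tests["p_bh"] = np.nan
    if mask.any():
        tests.loc[mask, "p_bh"] = _benjamini_hochberg(
            tests.loc[mask, "p_value"].to_numpy())
    return counts, tests


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method="fdr_bh")[1]
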