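"""Variant ingest and 96-context mutation catalogs.

Somatic single-base substitutions (SBSs) are classified into the 96
pyrimidine-centered trinucleotide classes (six substitution types
C>A, C>G, C>T, T>A, T>C, T>G, each with 16 flanking 5'/3' base
combinations, COSMIC ordering). Variants whose reference base is a
purine are reverse-complemented onto the pyrimidine strand before
classification, so catalogs are strand-symmetric.

Also provides the study filters (VAF window, autosome restriction,
hypermutant exclusion), tumor mutational burden, and extended
(11-base) context base-frequency matrices used for logo-style
flanking-sequence analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Number of mappable (ACGT) bases in the GRCh37 reference; the default
#: denominator for tumor mutational burden.
MAPPABLE_BASES = 2_858_674_662

AUTOSOMES = frozenset(str(i) for i in range(1, 23))


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class MutationType96(NamedTuple):
    """One of the 96 pyrimidine-centered trinucleotide mutation classes."""

    substitution: str  # e.g. "T>G", reference base always a pyrimidine
    five_prime: str
    three_prime: str

    @property
    def label(self) -> str:
        ref, alt = self.substitution.split(">")
        return f"{self.five_prime}[{ref}>{alt}]{self.three_prime}"

    @property
    def context(self) -> str:
        return self.five_prime + self.substitution[0] + self.three_prime


def _canonical_types() -> tuple[MutationType96, ...]:
    return tuple(
        MutationType96(sub, f, t)
        for sub in SUBSTITUTIONS
        for f in BASES
        for t in BASES
    )


#: Canonical COSMIC ordering of the 96 classes: substitution outer
#: (C>A ... T>G), 5' then 3' flanking base alphabetical inner.
CANONICAL_TYPES: tuple[MutationType96, ...] = _canonical_types()
TYPE_LABELS: tuple[str, ...] = tuple(t.label for t in CANONICAL_TYPES)
TYPE_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(TYPE_LABELS)}


class ClassificationError(ValueError):
    """Raised when a substitution cannot be mapped to a 96-class."""


@dataclass
class GenomicVariant:
    """A single-base substitution with optional clonality annotations."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vaf: float | None = None
    adjusted_vaf: float | None = None
    copy_number: float | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")
        for name in ("vaf", "adjusted_vaf"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def is_sbs(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and \
            self.ref in BASES and self.alt in BASES


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix ('chr17' and '17' are the same contig)."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def classify_sbs(ref: str, alt: str, context: str) -> MutationType96:
    """Classify a substitution into its pyrimidine-centered 96-class.

    ``context`` is the plus-strand trinucleotide around the mutated base.
    Purine-reference substitutions are reverse-complemented (both the
    substitution and its context) before classification, so e.g.
    A>C in an AAG context maps to T>G in CTT, i.e. C[T>G]T.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ClassificationError(
            f"context {context!r} does not center on ref {ref!r}")
    if ref == alt:
        raise ClassificationError(f"ref equals alt ({ref})")
    if any(b not in BASES for b in (ref, alt)) or any(b not in BASES for b in context):
        raise ClassificationError(
            f"ambiguous base in ref={ref} alt={alt} context={context}")
    if ref not in PYRIMIDINES:
        ref, alt, context = revcomp(ref), revcomp(alt), revcomp(context)
    return MutationType96(f"{ref}>{alt}", context[0], context[2])


def extract_context(reference, chrom: str, pos: int, flank: int) -> str:
    """Plus-strand sequence of length ``2*flank + 1`` centered on ``pos``.

    ``reference`` may be a ``pyfaidx.Fasta`` (or any mapping from contig
    name to a sliceable sequence). Coordinates are 1-based inclusive and
    the whole window must lie inside the contig.
    """
    key = _resolve_contig(reference, chrom)
    seq = reference[key]
    length = len(seq)
    lo, hi = pos - flank, pos + flank
    if lo < 1 or hi > length:
        raise IndexError(
            f"window [{lo}, {hi}] outside contig {chrom} (length {length})")
    out = seq[lo - 1:hi]
    return str(out).upper()


def _resolve_contig(reference, chrom: str):
    keys = reference.keys()
    if chrom in keys:
        return chrom
    norm = normalize_chrom(chrom)
    if norm in keys:
        return norm
    if "chr" + norm in keys:
        return "chr" + norm
    raise KeyError(f"contig {chrom!r} not found in reference")


def classify_variant(variant: GenomicVariant, reference) -> MutationType96:
    context = extract_context(reference, variant.chrom, variant.pos, flank=1)
    if context[1] != variant.ref.upper():
        raise ClassificationError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"VCF says {variant.ref}, FASTA says {context[1]}")
    return classify_sbs(variant.ref, variant.alt, context)


# ---------------------------------------------------------------------------
# VCF reading

def read_vcf(path, sbs_only: bool = True, sample: str | None = None,
             stats: dict | None = None) -> list[GenomicVariant]:
    """Read a VCF (plain or bgzipped) into a list of variants.

    Multi-allelic records are split into one variant per alternate
    allele. For multi-sample files, a variant is attributed to every
    sample whose genotype carries the alternate allele; ``sample``
    overrides the sample name for single-sample or site-only files.
    Records with a non-ACGT reference or alternate base are skipped
    with a warning (and tallied in ``stats`` when given).
    """
    import pysam

    path = str(path)
    variants: list[GenomicVariant] = []
    tally = {"records": 0, "skipped_non_sbs": 0, "skipped_ambiguous": 0}
    with pysam.VariantFile(path) as vcf:
        vcf_samples = list(vcf.header.samples)
        default_sample = sample or (vcf_samples[0] if len(vcf_samples) == 1
                                    else Path(path).name.split(".")[0])
        for rec in vcf:
            tally["records"] += 1
            if rec.alts is None:
                continue
            for ai, alt in enumerate(rec.alts, start=1):
                ref = rec.ref.upper()
                alt = alt.upper()
                is_snv_shaped = len(ref) == 1 and len(alt) == 1 and \
                    alt.isalpha()
                if is_snv_shaped and (ref not in BASES or alt not in BASES):
                    warnings.warn(
                        f"skipping record {rec.chrom}:{rec.pos} with "
                        f"ambiguous base {ref}>{alt}")
                    tally["skipped_ambiguous"] += 1
                    continue
                if not (is_snv_shaped and ref != alt):
                    if sbs_only:
                        tally["skipped_non_sbs"] += 1
                        continue
                carriers = _allele_carriers(rec, ai, vcf_samples)
                if not carriers:
                    carriers = [(default_sample, _record_vaf(rec, None))]
                for sid, vaf in carriers:
                    variants.append(GenomicVariant(
                        chrom=normalize_chrom(rec.chrom), pos=rec.pos,
                        ref=ref, alt=alt, vaf=vaf,
                        sample_id=sample or sid))
    if stats is not None:
        stats.update(tally)
    return variants


def _allele_carriers(rec, allele_index: int, vcf_samples: list[str]):
    """(sample, vaf) pairs for samples whose GT carries the allele."""
    carriers = []
    for sid in vcf_samples:
        s = rec.samples[sid]
        gt = s.get("GT")
        if gt is None or allele_index not in gt:
            continue
        vaf = None
        for key in ("VF", "AF"):
            if key in s and s[key] is not None:
                val = s[key]
                vaf = float(val[0] if isinstance(val, tuple) else val)
                break
        carriers.append((sid, vaf))
    return carriers


def _record_vaf(rec, default):
    af = rec.info.get("AF")
    if af is not None:
        return float(af[0] if isinstance(af, tuple) else af)
    return default


def read_variant_table(path) -> list[GenomicVariant]:
    """Read a TSV of variants (chrom, pos, ref, alt[, vaf, adjusted_vaf,
    copy_number, sample_id])."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(GenomicVariant(
            chrom=normalize_chrom(str(d["chrom"])), pos=int(d["pos"]),
            ref=str(d["ref"]), alt=str(d["alt"]),
            vaf=_opt(d.get("vaf")), adjusted_vaf=_opt(d.get("adjusted_vaf")),
            copy_number=_opt(d.get("copy_number")),
            sample_id=d.get("sample_id")))
    return out


def _opt(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


# ---------------------------------------------------------------------------
# Filters

def vaf_filter(variants: Iterable[GenomicVariant], low: float = 0.3,
               high: float = 0.7, stats: dict | None = None) -> list[GenomicVariant]:
    """Keep variants with ``low <= vaf <= high`` (closed interval).

    The window selects mutations fixed in the clone (heterozygous
    diploid expectation 0.5); variants lacking a VAF are excluded and
    tallied.
    """
    kept, missing, excluded = [], 0, 0
    for v in variants:
        if v.vaf is None:
            missing += 1
        elif low <= v.vaf <= high:
            kept.append(v)
        else:
            excluded += 1
    if stats is not None:
        stats.update({"missing_vaf": missing, "outside_window": excluded})
    if missing:
        logger.info("vaf_filter: %d variants lacked a VAF and were excluded",
                    missing)
    return kept


def autosome_filter(variants: Iterable[GenomicVariant]) -> list[GenomicVariant]:
    """Keep only variants on chromosomes 1-22 (chr prefix ignored)."""
    return [v for v in variants if normalize_chrom(v.chrom) in AUTOSOMES]


# ---------------------------------------------------------------------------
# Catalogs

@dataclass
class MutationCatalog:
    """96 x S matrix of per-sample mutation-class counts."""

    counts: np.ndarray
    sample_ids: list[str]
    type_order: tuple[str, ...] = TYPE_LABELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96, len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match 96 x "
                f"{len(self.sample_ids)} samples")
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.type_order),
                            columns=self.sample_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="type")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MutationCatalog":
        df = df.reindex(list(TYPE_LABELS))
        if df.isna().any().any():
            raise ValueError("catalog table missing canonical 96-class rows")
        return cls(df.to_numpy(), [str(c) for c in df.columns])

    @classmethod
    def from_tsv(cls, path) -> "MutationCatalog":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))


def build_catalog(variants_by_sample: Mapping[str, Sequence[GenomicVariant]],
                  reference) -> MutationCatalog:
    """Count context-classified SBSs per sample.

    Column sums equal the number of classified variants per sample;
    classification errors propagate with the variant's coordinates.
    """
    sample_ids = list(variants_by_sample)
    counts = np.zeros((96, len(sample_ids)), dtype=int)
    for s, sid in enumerate(sample_ids):
        for v in variants_by_sample[sid]:
            try:
                mt = classify_variant(v, reference)
            except (ClassificationError, KeyError, IndexError) as exc:
                raise type(exc)(
                    f"variant {v.chrom}:{v.pos} {v.ref}>{v.alt}: {exc}"
                ) from exc
            counts[TYPE_INDEX[mt.label], s] += 1
    return MutationCatalog(counts, sample_ids)


def group_by_sample(variants: Iterable[GenomicVariant],
                    default: str = "sample") -> dict[str, list[GenomicVariant]]:
    out: dict[str, list[GenomicVariant]] = {}
    for v in variants:
        out.setdefault(v.sample_id or default, []).append(v)
    return out


def tmb(sbs_count: float, mappable_bases: int = MAPPABLE_BASES) -> float:
    """Tumor mutational burden: SBS count per megabase of mappable genome."""
    if sbs_count < 0:
        raise ValueError("SBS count must be non-negative")
    if mappable_bases <= 0:
        raise ValueError("mappable_bases must be positive")
    return sbs_count / (mappable_bases / 1e6)


def hypermutant_filter(catalog: MutationCatalog, threshold: float = 10.0,
                       mappable_bases: int = MAPPABLE_BASES) -> MutationCatalog:
    """Drop samples with TMB strictly above ``threshold`` mutations/Mbp."""
    keep = [s for s in range(catalog.n_samples)
            if tmb(catalog.counts[:, s].sum(), mappable_bases) <= threshold]
    return MutationCatalog(catalog.counts[:, keep],
                           [catalog.sample_ids[s] for s in keep])


# ---------------------------------------------------------------------------
# Extended context

@dataclass
class ExtendedContextMatrix:
    """Per-offset base frequencies around a mutated base.

    Rows are offsets (-flank .. +flank on the pyrimidine-normalized
    strand), columns are A/C/G/T frequencies; each row of a non-empty
    matrix sums to 1.
    """

    positions: np.ndarray
    freqs: np.ndarray  # (2*flank+1) x 4
    mutation_class: str | None = None
    n_variants: int = 0

    @property
    def is_empty(self) -> bool:
        return self.n_variants == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freqs, index=self.positions,
                            columns=list(BASES))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="offset")


def extended_context_matrix(variants: Sequence[GenomicVariant], reference,
                            flank: int = 5,
                            mutation_class: str | None = None
                            ) -> ExtendedContextMatrix:
    """Base-frequency matrix of the ``2*flank+1``-base window around
    mutations of one class (default 11 bases, as in flanking-context
    logo analysis of C[T>G]T hotspots).

    Windows of purine-reference variants contribute their reverse
    complement with offsets mirrored, so all frequencies are on the
    pyrimidine-normalized strand.
    """
    width = 2 * flank + 1
    counts = np.zeros((width, 4), dtype=float)
    base_col = {b: i for i, b in enumerate(BASES)}
    n = 0
    for v in variants:
        mt = classify_variant(v, reference)
        if mutation_class is not None and mt.label != mutation_class:
            continue
        window = extract_context(reference, v.chrom, v.pos, flank)
        if v.ref.upper() not in PYRIMIDINES:
            window = revcomp(window)
        if any(b not in BASES for b in window):
            continue
        for i, b in enumerate(window):
            counts[i, base_col[b]] += 1
        n += 1
    positions = np.arange(-flank, flank + 1)
    if n == 0:
        warnings.warn(f"no variants of class {mutation_class} found; "
                      "extended-context matrix is empty")
        return ExtendedContextMatrix(positions, counts, mutation_class, 0)
    return ExtendedContextMatrix(positions, counts / n, mutation_class, n)
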