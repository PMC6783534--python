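"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: 96-context
catalogs drawn from known signature mixtures (including a
signature-17-like profile dominated by C[T>G]T), matching toy
reference + VCF pairs that round-trip through catalog construction,
clonal/subclonal variant-ploidy mixtures, strand-annotated mutation
sets with planted lagging-strand enrichment, and paired-biopsy
cohorts with patient-level random effects and a planted treatment
effect. All generators are pure functions of their parameters and
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_catalog import (BASES, PYRIMIDINES, TYPE_INDEX, TYPE_LABELS,
                         CANONICAL_TYPES, GenomicVariant, MutationCatalog,
                         revcomp)
from .signatures import SignatureMatrix
from .strand_bias import LAGGING, LEADING, StrandRegion

#: Share of the signature-17-like profile on its three dominant
#: classes: C[T>G]T carries 36% as in the 5-FU / COSMIC-17 spectrum.
SIG17_DOMINANT = {"C[T>G]T": 0.36, "C[T>C]T": 0.15, "G[T>G]T": 0.09}


@dataclass
class GeneratorSpec:
    """Bundle of generator parameters for CLI-driven simulation."""

    seed: int = 0
    n_samples: int = 50
    mutations_per_sample: int = 5000
    n_random_signatures: int = 1
    clonal_frac: float = 0.7
    subclonal_ploidy: float = 0.4
    ploidy_sd: float = 0.05
    strand_enrichment: float = 3.0
    n_patients: int = 20
    n_treated: int = 8
    paired_effect_sd: float = 3.0


def make_signature_set(seed: int = 0, n_random: int = 1) -> SignatureMatrix:
    """Reference set for simulations: a signature-17-like profile
    (36% C[T>G]T plus C[T>C]T / G[T>G]T and a low uniform floor), a
    flat profile, and ``n_random`` seeded Dirichlet profiles."""
    rng = np.random.default_rng(seed)
    cols, ids = [], []

    sig17 = np.zeros(96)
    for label, mass in SIG17_DOMINANT.items():
        sig17[TYPE_INDEX[label]] = mass
    floor = (1.0 - sig17.sum()) / (96 - len(SIG17_DOMINANT))
    sig17[sig17 == 0] = floor
    cols.append(sig17)
    ids.append("sig17like")

    cols.append(np.full(96, 1.0 / 96))
    ids.append("flat")

    for i in range(n_random):
        cols.append(rng.dirichlet(np.full(96, 0.5)))
        ids.append(f"random{i + 1}")
    probs = np.column_stack(cols)
    return SignatureMatrix(probs / probs.sum(axis=0), ids)


def sample_catalog(signatures: SignatureMatrix, exposures,
                   seed: int = 0) -> MutationCatalog:
    """Multinomial catalog from known exposures.

    ``exposures`` is K x S; each sample draws sum(exposures) mutations
    from the exposure-weighted mixture of signature profiles.
    """
    E = np.asarray(exposures, dtype=float)
    if E.ndim == 1:
        E = E[:, None]
    if (E < 0).any():
        raise ValueError("exposures must be non-negative")
    rng = np.random.default_rng(seed)
    S = E.shape[1]
    counts = np.zeros((96, S), dtype=int)
    for s in range(S):
        total = E[:, s].sum()
        if total == 0:
            continue
        p = signatures.probs @ (E[:, s] / total)
        counts[:, s] = rng.multinomial(int(round(total)), p / p.sum())
    return MutationCatalog(counts, [f"sample{s + 1}" for s in range(S)])


# ---------------------------------------------------------------------------
# Reference + VCF emission

def emit_reference_and_vcf(catalog: MutationCatalog, seed: int = 0,
                           out_dir=".", contig: str = "synth1"
                           ) -> tuple[Path, Path]:
    """Write a toy FASTA + multi-sample VCF that reproduce ``catalog``.

    The contig is a concatenation of one trinucleotide per mutation
    event; each event becomes a VCF record at the triplet center,
    genotyped 0/1 only for its owning sample. Roughly half the events
    (seeded) are placed in the purine-strand representation to
    exercise pyrimidine-strand normalization on read-back.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    triplets: list[str] = []
    records = []  # (pos, ref, alt, sample_index)
    offset = 0
    for i, mt in enumerate(CANONICAL_TYPES):
        for s in range(catalog.n_samples):
            for _ in range(int(catalog.counts[i, s])):
                ctx = mt.context
                ref, alt = mt.substitution.split(">")
                if rng.random() < 0.5:  # purine-strand representation
                    ctx, ref, alt = revcomp(ctx), revcomp(ref), revcomp(alt)
                triplets.append(ctx)
                records.append((offset + 2, ref, alt, s))
                offset += 3
    seq = "".join(triplets) if triplets else "ACGT"

    fasta_path = out_dir / "reference.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i:i + 60] + "\n")
    for suffix in (".fai",):  # stale index would shadow the new sequence
        idx = Path(str(fasta_path) + suffix)
        if idx.exists():
            idx.unlink()

    vcf_path = out_dir / "variants.vcf"
    samples = catalog.sample_ids
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=VF,Number=1,Type=Float,'
                 'Description="Variant allele fraction">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for pos, ref, alt, s in sorted(records):
            gt = ["0/0:0"] * len(samples)
            gt[s] = "0/1:0.5"
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:VF\t"
                     + "\t".join(gt) + "\n")
        fh.flush()
    return fasta_path, vcf_path


# ---------------------------------------------------------------------------
# Clonality

def simulate_clonality(n: int, clonal_frac: float = 0.7,
                       subclonal_ploidy: float = 0.4, sd: float = 0.05,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Variant-ploidy mixture: Normal(1, sd) clonal mode plus
    Normal(subclonal_ploidy, sd) subclonal mode, truncated at 0.
    Returns (ploidies, truth labels)."""
    if not 0 < clonal_frac <= 1:
        raise ValueError("clonal_frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    is_clonal = rng.random(n) < clonal_frac
    centers = np.where(is_clonal, 1.0, subclonal_ploidy)
    ploidies = np.clip(rng.normal(centers, sd), 0.0, None)
    labels = np.where(is_clonal, "clonal", "subclonal").astype(object)
    return ploidies, labels


# ---------------------------------------------------------------------------
# Paired-biopsy cohort

def simulate_paired_cohort(n_patients: int = 20, n_treated: int = 8,
                           baseline_total: float = 3000.0,
                           effect_sd: float = 3.0,
                           effect_types: tuple[str, ...] = ("C[T>G]T",),
                           focal_drug: str = "fu",
                           signatures: SignatureMatrix | None = None,
                           seed: int = 0
                           ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two biopsies per patient; treated patients gain extra mutations
    of the effect types in biopsy two.

    Baseline per-type rates follow a flat + signature-17-like mixture;
    biopsy counts are Poisson with patient-level and per-biopsy
    lognormal depth factors (the patient factor induces the
    within-patient correlation the mixed model absorbs; the biopsy
    factor is what median-of-ratios normalization removes). The
    planted effect adds ``effect_sd`` Poisson standard deviations
    (sqrt of the baseline rate) to each effect type.
    Returns (96 x 2P count table, design table, truth dict).
    """
    if n_treated > n_patients:
        raise ValueError("more treated patients than patients")
    rng = np.random.default_rng(seed)
    sigs = signatures or make_signature_set(seed=0, n_random=0)
    mix = 0.3 * sigs.column("sig17like") + 0.7 * sigs.column("flat")
    lam = baseline_total * mix / mix.sum()

    counts, design_rows = {}, []
    treated = set(range(n_treated))
    effect_idx = [TYPE_INDEX[t] for t in effect_types]
    for p in range(n_patients):
        patient_factor = rng.lognormal(mean=0.0, sigma=0.15)
        is_treated = p in treated
        dose = float(rng.uniform(0.5, 1.5)) if is_treated else 0.0
        weeks = float(rng.uniform(12, 36)) if is_treated else 0.0
        for b in (1, 2):
            depth = rng.lognormal(mean=0.0, sigma=0.2)
            rate = lam * patient_factor * depth
            c = rng.poisson(rate)
            if b == 2 and is_treated:
                for i in effect_idx:
                    c[i] += rng.poisson(effect_sd * np.sqrt(lam[i]))
            name = f"P{p + 1}_B{b}"
            counts[name] = c
            design_rows.append({
                "sample": name, "patient": f"P{p + 1}", "biopsy": b,
                focal_drug: int(b == 2 and is_treated),
                "dose": dose if (b == 2 and is_treated) else 0.0,
                "time": weeks if (b == 2 and is_treated) else 0.0,
            })
    table = pd.DataFrame(counts, index=list(TYPE_LABELS))
    design = pd.DataFrame(design_rows)
    truth = {"effect_types": list(effect_types),
             "treated_patients": [f"P{p + 1}" for p in sorted(treated)],
             "focal_drug": focal_drug, "effect_sd": effect_sd}
    return table, design, truth


# ---------------------------------------------------------------------------
# Strand annotations

def simulate_strand_annotations(variants, reference,
                                enrichment_ratio: float = 3.0,
                                enriched_classes: tuple[str, ...] = ("T>G",),
                                seed: int = 0
                                ) -> tuple[list[StrandRegion], list[str]]:
    """Plant a lagging-strand enrichment over a variant set.

    Each variant is wrapped in its own single-triplet region whose
    plus-strand role is chosen so the variant's realized assignment is
    lagging with odds ``enrichment_ratio`` when its substitution class
    (or full 96-label) is enriched, and 1:1 otherwise. Returns the
    region set and the truth assignments.
    """
    from .io_catalog import classify_variant
    if enrichment_ratio <= 0:
        raise ValueError("enrichment ratio must be positive")
    rng = np.random.default_rng(seed)
    p_lagging = enrichment_ratio / (1.0 + enrichment_ratio)
    regions, truth = [], []
    for v in variants:
        mt = classify_variant(v, reference)
        enriched = mt.substitution in enriched_classes \
            or mt.label in enriched_classes
        want = LAGGING if rng.random() < (p_lagging if enriched else 0.5) \
            else LEADING
        if v.ref.upper() in PYRIMIDINES:
            plus_role = want
        else:
            plus_role = LEADING if want == LAGGING else LAGGING
        regions.append(StrandRegion(v.chrom, v.pos - 1, v.pos + 1, plus_role))
        truth.append(want)
    return regions, truth
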