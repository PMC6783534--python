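"""Per-mutation signature attribution.

Given a sample's absolute signature exposures and the signature
probability profiles, the likelihood that a mutation of trinucleotide
class c arose from signature x is

    L_x(c) = e_x * p_x(c) / sum_s e_s * p_s(c)

i.e. the exposure-weighted share of signature x in the sample's
expected mutations of that class. Likelihoods over signatures sum to
1 for every class with a non-zero denominator. Mutations whose
likelihood for one signature strictly exceeds a threshold (default
0.5 — at most one signature can qualify) are assigned that origin.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io_catalog import TYPE_INDEX, TYPE_LABELS, GenomicVariant
from .signatures import ExposureMatrix, SignatureMatrix


def attribution_likelihood(exposures, signatures: SignatureMatrix,
                           tnc_class) -> np.ndarray:
    """Signature likelihood vector for one mutation class in one sample.

    ``exposures`` is the K-vector of absolute contributions;
    ``tnc_class`` a canonical 96-class label or index. Returns NaNs
    when no active signature places mass on the class (the mutation is
    unattributable).
    """
    e = np.asarray(exposures, dtype=float)
    if (e < 0).any():
        raise ValueError("exposures must be non-negative")
    if e.sum() <= 0:
        raise ValueError("sample has zero total exposure")
    idx = TYPE_INDEX[tnc_class] if isinstance(tnc_class, str) else int(tnc_class)
    weights = e * signatures.probs[idx, :]
    denom = weights.sum()
    if denom == 0:
        return np.full(e.shape, np.nan)
    return weights / denom


def attribution_table(class_indices: Sequence[int],
                      exposures, signatures: SignatureMatrix,
                      sample_id: str = "sample") -> pd.DataFrame:
    """Likelihood table for a list of mutations from one sample; one
    row per mutation, one likelihood column per signature."""
    lik = np.vstack([attribution_likelihood(exposures, signatures, int(c))
                     for c in class_indices])
    df = pd.DataFrame(lik, columns=signatures.signature_ids)
    df.insert(0, "type", [TYPE_LABELS[int(c)] for c in class_indices])
    df.insert(0, "sample_id", sample_id)
    return df


def assign_origin(attribution: pd.DataFrame, threshold: float = 0.5
                  ) -> pd.Series:
    """Per-mutation signature label: the unique signature whose
    likelihood strictly exceeds ``threshold``, else "unassigned".
    A likelihood of exactly 0.5 does not qualify."""
    sig_cols = [c for c in attribution.columns
                if c not in ("sample_id", "type", "chrom", "pos", "ref", "alt")]
    lik = attribution[sig_cols].to_numpy(dtype=float)
    best = np.nanmax(np.where(np.isnan(lik), -np.inf, lik), axis=1)
    arg = np.argmax(np.where(np.isnan(lik), -np.inf, lik), axis=1)
    labels = np.where(best > threshold,
                      np.asarray(sig_cols, dtype=object)[arg], "unassigned")
    return pd.Series(labels, index=attribution.index, name="origin")


def cohort_cumulative(attributions: Sequence[pd.DataFrame]) -> pd.Series:
    """Per-signature cumulative likelihood over all mutations of a
    cohort; the grand total equals the number of attributable
    mutations."""
    totals: pd.Series | None = None
    for df in attributions:
        sig_cols = [c for c in df.columns
                    if c not in ("sample_id", "type", "chrom", "pos",
                                 "ref", "alt")]
        valid = df[sig_cols].dropna(how="any")
        part = valid.sum(axis=0)
        totals = part if totals is None else totals.add(part, fill_value=0.0)
    if totals is None:
        return pd.Series(dtype=float)
    return totals


def export_assigned_variants(variants: Sequence[GenomicVariant],
                             origins: Sequence[str], signature_id: str,
                             path) -> pd.DataFrame:
    """Write the variants assigned to one signature as a TSV of
    (sample_id, chrom, pos, ref, alt) — the input list for downstream
    selection analysis (e.g. dN/dS)."""
    rows = [
        {"sample_id": v.sample_id or "sample", "chrom": v.chrom,
         "pos": v.pos, "ref": v.ref, "alt": v.alt}
        for v, o in zip(variants, origins) if o == signature_id
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref", "alt"])
    df.to_csv(path, sep="\t", index=False)
    return df
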