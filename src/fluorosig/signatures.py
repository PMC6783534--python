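"""Mutational-signature extraction and refitting.

De novo signatures are extracted from a 96 x S mutation catalog by
non-negative matrix factorization (NMF) minimizing the generalized
Kullback-Leibler divergence with multiplicative (Brunet) updates, the
default of the classic NMF implementation used throughout the
signature literature. The factorization rank is chosen by consensus
clustering over random restarts and the cophenetic correlation
coefficient. Known signature sets are refit to catalogs by
non-negative least squares (NNLS), and signatures are matched to
reference sets by cosine similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import squareform

from .io_catalog import TYPE_LABELS, MutationCatalog

_EPS = 1e-12


@dataclass
class SignatureMatrix:
    """96 x K matrix of mutation-type probabilities, one column per
    signature; columns sum to 1."""

    probs: np.ndarray
    signature_ids: list[str]
    type_order: tuple[str, ...] = TYPE_LABELS

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (96, len(self.signature_ids)):
            raise ValueError("signature matrix must be 96 x K")
        if (self.probs < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        sums = self.probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"signature columns must sum to 1, got {sums}")

    @property
    def n_signatures(self) -> int:
        return len(self.signature_ids)

    def column(self, signature_id: str) -> np.ndarray:
        return self.probs[:, self.signature_ids.index(signature_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(self.type_order),
                            columns=self.signature_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="type")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureMatrix":
        df = df.reindex(list(TYPE_LABELS))
        if df.isna().any().any():
            raise ValueError("signature table missing canonical 96-class rows")
        probs = df.to_numpy(dtype=float)
        probs = probs / probs.sum(axis=0, keepdims=True)
        return cls(probs, [str(c) for c in df.columns])

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class ExposureMatrix:
    """K x S matrix of absolute per-sample signature contributions."""

    values: np.ndarray
    signature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.signature_ids), len(self.sample_ids)):
            raise ValueError("exposure matrix shape mismatch")
        if (self.values < -1e-9).any():
            raise ValueError("exposures must be non-negative")
        self.values = np.clip(self.values, 0, None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.signature_ids,
                            columns=self.sample_ids)


@dataclass
class NMFResult:
    W: np.ndarray  # 96 x K column-stochastic basis
    H: np.ndarray  # K x S non-negative weights (absolute scale)
    objective_trace: np.ndarray
    consensus: np.ndarray | None = None
    cophenetic: float | None = None
    rank: int = 0

    def signature_matrix(self, prefix: str = "denovo") -> SignatureMatrix:
        ids = [f"{prefix}{i + 1}" for i in range(self.W.shape[1])]
        return SignatureMatrix(self.W, ids)


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    # generalized KL: sum(V log(V / WH) - V + WH), 0 log 0 := 0
    WH = np.maximum(WH, _EPS)
    mask = V > 0
    val = float(np.sum(WH) - np.sum(V))
    val += float(np.sum(V[mask] * np.log(V[mask] / WH[mask])))
    return val


def nmf_factorize(catalog, rank: int, seed: int = 0, max_iter: int = 10_000,
                  tol: float = 1e-6, objective: str = "kl") -> NMFResult:
    """Single seeded NMF run on a 96 x S count matrix.

    Multiplicative updates (Brunet for the generalized KL objective,
    Lee-Seung for the Frobenius variant) from seeded uniform(0, 1]
    initialization; the objective is non-increasing across iterations
    and the run stops when its relative change falls below ``tol``.
    The returned basis W is column-normalized to probabilities with
    the compensating scale moved into H, so W @ H is unchanged.
    """
    V = _as_matrix(catalog)
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank > min(V.shape):
        raise ValueError(f"rank {rank} exceeds min matrix dimension "
                         f"{min(V.shape)}")
    if not V.any():
        raise ValueError("cannot factorize an all-zero catalog")
    if objective not in ("kl", "frobenius"):
        raise ValueError(f"unknown objective {objective!r}")

    rng = np.random.default_rng(seed)
    n, m = V.shape
    # uniform (0, 1]: avoid exact zeros which are absorbing states
    W = 1.0 - rng.random((n, rank))
    H = 1.0 - rng.random((rank, m))

    trace = []
    prev = np.inf
    for _ in range(max_iter):
        if objective == "kl":
            WH = np.maximum(W @ H, _EPS)
            H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
            WH = np.maximum(W @ H, _EPS)
            W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
            obj = _kl_divergence(V, W @ H)
        else:
            H *= (W.T @ V) / np.maximum(W.T @ W @ H, _EPS)
            W *= (V @ H.T) / np.maximum(W @ H @ H.T, _EPS)
            obj = 0.5 * float(np.sum((V - W @ H) ** 2))
        trace.append(obj)
        if np.isfinite(prev) and prev - obj < tol * max(abs(prev), 1.0):
            break
        prev = obj

    scale = W.sum(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    W = W / scale
    H = H * scale[:, None]
    return NMFResult(W=W, H=H, objective_trace=np.asarray(trace), rank=rank)


def _as_matrix(catalog) -> np.ndarray:
    if isinstance(catalog, MutationCatalog):
        return catalog.counts.astype(float)
    V = np.asarray(catalog, dtype=float)
    if (V < 0).any():
        raise ValueError("catalog must be non-negative")
    return V


def consensus_cophenetic(catalog, rank: int, n_runs: int = 100,
                         seed: int = 0, max_iter: int = 2_000,
                         tol: float = 1e-6) -> NMFResult:
    """NMF with consensus clustering over random restarts.

    ``consensus[i, j]`` is the fraction of restarts in which samples i
    and j share the same dominant (argmax-exposure) signature; the
    cophenetic correlation coefficient measures how tree-like the
    consensus distances are under average-linkage clustering, and is
    the rank-selection statistic. The run with the best objective is
    returned as the point estimate.
    """
    if n_runs < 2:
        raise ValueError("consensus requires n_runs >= 2")
    V = _as_matrix(catalog)
    S = V.shape[1]
    co = np.zeros((S, S))
    best: NMFResult | None = None
    for run in range(n_runs):
        run_seed = int(np.random.default_rng([seed, run]).integers(2 ** 31))
        res = nmf_factorize(V, rank, seed=run_seed, max_iter=max_iter, tol=tol)
        # ties broken toward the lowest signature index (argmax default)
        labels = np.argmax(res.H, axis=0)
        co += (labels[:, None] == labels[None, :]).astype(float)
        if best is None or res.objective_trace[-1] < best.objective_trace[-1]:
            best = res
    consensus = co / n_runs
    best.consensus = consensus
    best.cophenetic = cophenetic_coefficient(consensus)
    return best


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Correlation between (1 - consensus) distances and the cophenetic
    distances of their average-linkage dendrogram; 1 for a perfectly
    stable (block-constant) consensus."""
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0] if condensed.size else 0.0):
        warnings.warn("degenerate consensus matrix; cophenetic reported as 1")
        return 1.0
    Z = linkage(condensed, method="average")
    c, _ = cophenet(Z, condensed)
    return float(c)


def select_rank(catalog, rank_range, n_runs: int = 20, seed: int = 0,
                stable_threshold: float = 0.95, drop_threshold: float = 0.05,
                **kwargs) -> tuple[pd.DataFrame, int]:
    """Scan factorization ranks and suggest one from the cophenetic
    profile.

    The suggestion is the largest rank whose cophenetic coefficient is
    at least ``stable_threshold`` before the first drop larger than
    ``drop_threshold``; it is advisory — headline analyses should pass
    an explicit rank.
    """
    ranks = list(rank_range)
    rows = []
    for r in ranks:
        res = consensus_cophenetic(catalog, r, n_runs=n_runs, seed=seed,
                                   **kwargs)
        rows.append({"rank": r, "cophenetic": res.cophenetic})
    table = pd.DataFrame(rows)
    if len(ranks) == 1:
        return table, ranks[0]
    coph = table["cophenetic"].to_numpy()
    suggested = None
    for i, r in enumerate(ranks):
        if i + 1 < len(ranks) and coph[i] - coph[i + 1] > drop_threshold:
            if coph[i] >= stable_threshold:
                suggested = r
            break
        if coph[i] >= stable_threshold:
            suggested = r
    if suggested is None:
        suggested = ranks[int(np.argmax(coph))]
        warnings.warn("no stable rank found; suggesting the cophenetic argmax")
    elif suggested == ranks[-1]:
        warnings.warn("cophenetic profile flat to the last rank scanned; "
                      "suggestion is the maximum rank")
    return table, int(suggested)


# ---------------------------------------------------------------------------
# Similarity and refitting

def cosine_sim(a, b) -> float:
    """Cosine similarity; in [0, 1] for non-negative spectra and
    invariant to positive rescaling."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def match_to_reference(denovo: SignatureMatrix,
                       reference: SignatureMatrix
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Best cosine match in ``reference`` for every de novo signature.

    Returns the per-signature best-match table and the full K x R
    score matrix.
    """
    if tuple(denovo.type_order) != tuple(reference.type_order):
        raise ValueError("signature matrices use different 96-class orders")
    scores = np.zeros((denovo.n_signatures, reference.n_signatures))
    for i in range(denovo.n_signatures):
        for j in range(reference.n_signatures):
            scores[i, j] = cosine_sim(denovo.probs[:, i], reference.probs[:, j])
    score_df = pd.DataFrame(scores, index=denovo.signature_ids,
                            columns=reference.signature_ids)
    best = score_df.idxmax(axis=1)
    matches = pd.DataFrame({
        "denovo": denovo.signature_ids,
        "best_match": best.values,
        "cosine": score_df.max(axis=1).values,
    })
    return matches, score_df


def refit_nnls(catalog, signatures: SignatureMatrix) -> ExposureMatrix:
    """Per-sample non-negative least-squares fit of known signatures.

    For each sample, exposures e >= 0 minimize ||counts - P e||_2 where
    P is the 96 x K signature probability matrix; exposures are on the
    absolute mutation-count scale.
    """
    V = _as_matrix(catalog)
    sample_ids = (catalog.sample_ids if isinstance(catalog, MutationCatalog)
                  else [f"s{i}" for i in range(V.shape[1])])
    K = signatures.n_signatures
    E = np.zeros((K, V.shape[1]))
    for s in range(V.shape[1]):
        E[:, s], _ = nnls(signatures.probs, V[:, s])
    return ExposureMatrix(E, list(signatures.signature_ids), list(sample_ids))


def relative_contribution(exposures: ExposureMatrix) -> pd.DataFrame:
    """Per-sample exposures divided by the sample's total; zero-total
    samples are reported as missing (NaN), not 0/0."""
    E = exposures.values
    totals = E.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals > 0, E / np.where(totals > 0, totals, 1.0),
                       np.nan)
    return pd.DataFrame(rel, index=exposures.signature_ids,
                        columns=exposures.sample_ids)


def difference_spectrum(p, q) -> np.ndarray:
    """Signed per-class difference p - q between two normalized
    96-spectra (positive where p is enriched); sums to zero."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    for name, v in (("p", p), ("q", q)):
        if not np.isclose(v.sum(), 1.0, atol=1e-6) or (v < 0).any():
            raise ValueError(f"{name} is not a normalized spectrum")
    return p - q


def cohort_contrast(group_a, group_b,
                    exact_limit: int = 25) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of two cohorts.

    Exact null distribution for small samples (combined n <= 25, no
    ties), normal approximation with tie correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= exact_limit and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "p_value": float(res.pvalue),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "method": method,
    }
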