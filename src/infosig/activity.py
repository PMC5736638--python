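"""Restricted PCA module-activity scoring.

For each (signature, dataset) pair, PCA is run on the expression submatrix
restricted to the signature's genes, with samples as observations and genes
as variables.  Two statistics summarize the spectrum of the gene-gene
sample covariance:

* ``L1`` — the fraction of variance carried by the first principal
  component (overdispersion: does the set contribute more variance than a
  random set of the same size?);
* ``L1/L2`` — the ratio of the first two eigenvalues (coordination: is
  there a significant spectral gap, i.e. a single dominant axis?).

Both are referred against an empirical null built from random gene sets of
the same size drawn from the dataset, and the two resulting p-value
families are Benjamini-Hochberg adjusted per dataset.

The first eigenvector (gene loadings) is the signature's *eigengene*; the
projection of the centered samples onto it is the *metasample* or sample
activity profile.  The PCA sign is fixed deterministically: the metasample
is oriented to correlate non-negatively with the mean centered expression
of the matched genes, with ties broken by making the largest-magnitude
loading positive.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io import ExpressionDataset, SignatureCollection, match_signature

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityConfig",
    "ActivityResult",
    "NullDistribution",
    "center_genes",
    "restricted_pca",
    "l1_statistic",
    "l1l2_statistic",
    "build_null",
    "empirical_pvalue",
    "bh_adjust",
    "score_collection",
    "derive_seed",
]


@dataclass
class ActivityConfig:
    """Tunable knobs of the scoring stage.

    min_genes:
        signatures matching fewer dataset genes are skipped (unscored).
    n_draws:
        random gene sets per empirical null; nulls are shared across
        signatures of identical matched size within one dataset.  The
        smallest attainable p-value is 1/(n_draws + 1); after BH at level
        alpha, signatures at that floor can only be called when the
        fraction of tested signatures at the floor is at least
        m / (k * (n_draws + 1)), so n_draws must comfortably exceed
        m / (alpha * k_expected).  The default of 300 supports
        informative fractions down to ~7% at alpha = 0.05.
    seed:
        root seed; per-(dataset, size) streams are derived from it.
    scale:
        if True, genes are scaled to unit variance before PCA (off by
        default: the variance-explained statistics are the object of
        study and scaling would change them).
    """

    min_genes: int = 10
    n_draws: int = 300
    seed: int = 0
    scale: bool = False


@dataclass
class ActivityResult:
    """Per-(signature, dataset) scoring output."""

    signature_name: str
    dataset_id: str
    n_matched: int
    l1: float
    l1l2: float
    p_l1: float
    p_l1l2: float
    padj_l1: float
    padj_l1l2: float
    matched_genes: list[str]
    eigengene: np.ndarray
    metasample: np.ndarray
    sample_ids: list[str]


@dataclass
class NullDistribution:
    """Empirical null of (L1, L1/L2) for random gene sets of one size."""

    set_size: int
    dataset_id: str
    l1_samples: np.ndarray
    l1l2_samples: np.ndarray
    n_draws: int
    seed: int


def derive_seed(root: int, *parts) -> int:
    """Derive a reproducible sub-seed (< 2^31) from a root seed and labels."""
    h = hashlib.blake2b(digest_size=4)
    h.update(str(int(root)).encode())
    for p in parts:
        h.update(b"|" + str(p).encode())
    return int.from_bytes(h.digest(), "little") % (2**31)


def center_genes(ds: ExpressionDataset, scale: bool = False) -> ExpressionDataset:
    """Return a copy with each gene row mean-centered across samples.

    No variance scaling by default.  Idempotent.
    """
    values = ds.values - ds.values.mean(axis=1, keepdims=True)
    if scale:
        sd = values.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        values = values / sd
    return ExpressionDataset(
        dataset_id=ds.dataset_id,
        gene_ids=list(ds.gene_ids),
        sample_ids=list(ds.sample_ids),
        values=values,
    )


def _pca_submatrix(sub: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of a genes x samples submatrix; returns (eigenvalues, eigengene, metasample).

    Eigenvalues are those of the gene-gene sample covariance (samples as
    observations, denominator n-1), in descending order; trailing zero
    eigenvalues beyond min(m, n) are implicit.
    """
    m, n = sub.shape
    centered = sub - sub.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise ValueError("restricted submatrix is constant (all-zero after centering)")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    eigengene = u[:, 0].copy()
    metasample = centered.T @ eigengene
    # deterministic sign: metasample should correlate >= 0 with the mean
    # centered expression of the matched genes
    mean_profile = centered.mean(axis=0)
    c = float(metasample @ mean_profile)
    if c < 0:
        eigengene = -eigengene
        metasample = -metasample
    elif c == 0:
        k = int(np.argmax(np.abs(eigengene)))
        if eigengene[k] < 0:
            eigengene = -eigengene
            metasample = -metasample
    return eigenvalues, eigengene, metasample


def restricted_pca(
    ds: ExpressionDataset, matched: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA restricted to ``matched`` genes of ``ds``.

    Returns (eigenvalues descending, unit-norm eigengene over matched genes,
    metasample over samples).  Centers genes internally, so pre-centering is
    optional.
    """
    if len(matched) < 2:
        raise ValueError(f"need >=2 matched genes, got {len(matched)}")
    idx = ds.gene_index
    rows = [idx[g] for g in matched]
    return _pca_submatrix(ds.values[rows])


def l1_statistic(eigenvalues: np.ndarray) -> float:
    """Fraction of total variance on the first principal component."""
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if np.any(eigenvalues < -1e-12):
        raise ValueError("eigenvalues must be non-negative")
    total = eigenvalues.sum()
    if total <= 0:
        raise ValueError("all eigenvalues are zero")
    return float(eigenvalues[0] / total)


def l1l2_statistic(eigenvalues: np.ndarray) -> float:
    """First-to-second eigenvalue ratio; +inf for rank-1 spectra.

    A rank-1 gene set is maximally coordinated: with a zero second
    eigenvalue the ratio is returned as ``inf``.
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if eigenvalues.size < 2:
        raise ValueError("need at least two eigenvalues")
    if eigenvalues[1] <= 0:
        return float("inf")
    return float(eigenvalues[0] / eigenvalues[1])


def build_null(
    ds: ExpressionDataset, set_size: int, n_draws: int, seed: int
) -> NullDistribution:
    """Empirical (L1, L1/L2) null from random gene subsets of ``set_size``.

    Subsets are drawn uniformly without replacement from the dataset's
    genes; reproducible given ``seed``.
    """
    n_genes, n = ds.shape
    if set_size > n_genes:
        raise ValueError(f"set_size {set_size} exceeds gene count {n_genes}")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    centered = ds.values - ds.values.mean(axis=1, keepdims=True)
    l1 = np.empty(n_draws)
    l1l2 = np.empty(n_draws)
    for i in range(n_draws):
        rows = rng.choice(n_genes, size=set_size, replace=False)
        s = np.linalg.svd(centered[rows], compute_uv=False)
        ev = s**2 / (n - 1)
        l1[i] = ev[0] / ev.sum()
        l1l2[i] = ev[0] / ev[1] if ev[1] > 0 else np.inf
    return NullDistribution(
        set_size=set_size,
        dataset_id=ds.dataset_id,
        l1_samples=l1,
        l1l2_samples=l1l2,
        n_draws=n_draws,
        seed=seed,
    )


def empirical_pvalue(observed: float, null_samples: np.ndarray) -> float:
    """Upper-tail empirical p-value with the +1 pseudo-count.

    p = (1 + #{null >= observed}) / (n + 1), never zero — required by BH
    and by log-scale downstream scores.
    """
    null_samples = np.asarray(null_samples, dtype=float)
    if null_samples.size == 0:
        raise ValueError("null_samples must be non-empty")
    k = int(np.count_nonzero(null_samples >= observed))
    return (1 + k) / (null_samples.size + 1)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    return padj


def score_collection(
    collection: SignatureCollection,
    ds: ExpressionDataset,
    config: ActivityConfig | None = None,
) -> list[ActivityResult]:
    """Score every signature of ``collection`` in one dataset.

    Signatures matching fewer than ``config.min_genes`` genes are skipped
    (reported via logging).  Null distributions are computed once per
    matched size and shared; BH adjustment runs per dataset, separately for
    the L1 and the L1/L2 p-value families, across all scored signatures.
    """
    if config is None:
        config = ActivityConfig()
    centered = center_genes(ds, scale=config.scale)

    matched_map: dict[str, list[str]] = {}
    skipped = 0
    for sig in collection:
        matched = match_signature(sig, centered)
        if len(matched) < config.min_genes:
            skipped += 1
            continue
        matched_map[sig.name] = matched
    if skipped:
        logger.info(
            "score_collection(%s): skipped %d/%d signatures with < %d matched genes",
            ds.dataset_id, skipped, len(collection), config.min_genes,
        )
    if not matched_map:
        return []

    sizes = sorted({len(m) for m in matched_map.values()})
    nulls: dict[int, NullDistribution] = {}
    for size in sizes:
        sub_seed = derive_seed(config.seed, "null", ds.dataset_id, size)
        nulls[size] = build_null(centered, size, config.n_draws, sub_seed)

    results: list[ActivityResult] = []
    for sig in collection:
        matched = matched_map.get(sig.name)
        if matched is None:
            continue
        eigenvalues, eigengene, metasample = restricted_pca(centered, matched)
        l1 = l1_statistic(eigenvalues)
        l1l2 = l1l2_statistic(eigenvalues)
        null = nulls[len(matched)]
        results.append(
            ActivityResult(
                signature_name=sig.name,
                dataset_id=ds.dataset_id,
                n_matched=len(matched),
                l1=l1,
                l1l2=l1l2,
                p_l1=empirical_pvalue(l1, null.l1_samples),
                p_l1l2=empirical_pvalue(l1l2, null.l1l2_samples),
                padj_l1=np.nan,
                padj_l1l2=np.nan,
                matched_genes=matched,
                eigengene=eigengene,
                metasample=metasample,
                sample_ids=list(centered.sample_ids),
            )
        )
    for key, adj in (
        ("p_l1", bh_adjust([r.p_l1 for r in results])),
        ("p_l1l2", bh_adjust([r.p_l1l2 for r in results])),
    ):
        attr = "padj_l1" if key == "p_l1" else "padj_l1l2"
        for r, a in zip(results, adj):
            setattr(r, attr, float(a))
    return results


def results_to_frame(results: Sequence[ActivityResult]):
    """Tidy table of scoring results (one row per signature x dataset)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "signature": [r.signature_name for r in results],
            "dataset": [r.dataset_id for r in results],
            "n_matched": [r.n_matched for r in results],
            "l1": [r.l1 for r in results],
            "l1l2": [r.l1l2 for r in results],
            "p_l1": [r.p_l1 for r in results],
            "p_l1l2": [r.p_l1l2 for r in results],
            "padj_l1": [r.padj_l1 for r in results],
            "padj_l1l2": [r.padj_l1l2 for r in results],
        }
    )
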