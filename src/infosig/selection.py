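"""Informative-signature selection and the random-signature null model.

A signature is *informative* when both of its BH-adjusted p-values
(overdispersion L1 and coordination L1/L2) fall below ``alpha`` in at
least ``k_min`` datasets.  The false-discovery rate of the whole selection
procedure is estimated by running it on random signatures built to mimic
the reference collection: sizes are sampled from the collection's size
distribution (percentile-stratified) and genes are drawn from the pooled
multiset of gene occurrences, so that a gene appearing in 100 signatures
is 100x as likely to be picked.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .activity import ActivityConfig, ActivityResult, derive_seed, score_collection
from .io import ExpressionDataset, GeneSignature, SignatureCollection

logger = logging.getLogger(__name__)

__all__ = [
    "InformativeCall",
    "NullModelReport",
    "classify_informative",
    "build_random_signatures",
    "estimate_fdr",
]


@dataclass
class InformativeCall:
    """Selection outcome for one signature across all datasets."""

    signature_name: str
    significant_datasets: list[str]
    n_significant: int
    informative: bool
    scored: bool = True  # False when the signature was unscored in every dataset


@dataclass
class NullModelReport:
    """FDR estimate from running the selection on random signatures."""

    n_random: int
    n_called_informative: int
    fdr_estimate: float
    seed: int


def classify_informative(
    results: Iterable[ActivityResult],
    alpha: float = 0.05,
    k_min: int = 2,
    signature_names: Sequence[str] | None = None,
) -> list[InformativeCall]:
    """Combine per-dataset activity results into informative calls.

    A dataset counts as significant for a signature only when *both*
    adjusted p-values are below ``alpha`` (the set must be simultaneously
    overdispersed and coordinated).  Datasets where a signature was
    unscored count as non-significant.  ``signature_names`` optionally
    fixes the output namespace (signatures absent from all datasets are
    reported with ``scored=False``).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    hits: dict[str, list[str]] = defaultdict(list)
    seen: set[str] = set()
    for r in results:
        seen.add(r.signature_name)
        if r.padj_l1 < alpha and r.padj_l1l2 < alpha:
            hits[r.signature_name].append(r.dataset_id)
    names = list(signature_names) if signature_names is not None else sorted(seen)
    calls = []
    for name in names:
        sig_datasets = sorted(hits.get(name, []))
        calls.append(
            InformativeCall(
                signature_name=name,
                significant_datasets=sig_datasets,
                n_significant=len(sig_datasets),
                informative=len(sig_datasets) >= k_min,
                scored=name in seen,
            )
        )
    return calls


def build_random_signatures(
    collection: SignatureCollection,
    n: int,
    seed: int,
    n_bins: int = 100,
    name_prefix: str = "RANDOM",
) -> SignatureCollection:
    """Build ``n`` random signatures mimicking a reference collection.

    Sizes are drawn by percentile stratification of the reference size
    distribution: the empirical sizes are partitioned into ``n_bins``
    quantile bins, a bin is picked proportionally to its occupancy, and a
    size is drawn uniformly from the observed sizes in that bin.  Genes
    are then drawn (distinct within one signature) with probability
    proportional to their occurrence count across the reference
    signatures, preserving the collection's gene multiplicities and hence,
    to some extent, the dependence structure between random signatures.
    """
    if len(collection) == 0:
        raise ValueError("reference collection is empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)

    sizes = np.array([len(s) for s in collection.signatures])
    edges = np.quantile(sizes, np.linspace(0, 1, n_bins + 1))
    # assign each observed size to a bin; right edge inclusive in last bin
    bin_of = np.clip(np.searchsorted(edges, sizes, side="right") - 1, 0, n_bins - 1)
    bin_sizes: dict[int, np.ndarray] = {
        b: sizes[bin_of == b] for b in np.unique(bin_of)
    }
    bins = sorted(bin_sizes)
    occupancy = np.array([bin_sizes[b].size for b in bins], dtype=float)
    occupancy /= occupancy.sum()

    genes = np.array(sorted(collection.gene_counts), dtype=object)
    counts = np.array([collection.gene_counts[g] for g in genes], dtype=float)
    probs = counts / counts.sum()
    n_distinct = genes.size

    width = max(4, len(str(n)))
    out: list[GeneSignature] = []
    n_resampled = 0
    for i in range(n):
        while True:
            b = bins[rng.choice(len(bins), p=occupancy)]
            size = int(rng.choice(bin_sizes[b]))
            if size <= n_distinct:
                break
            n_resampled += 1
        chosen = rng.choice(genes, size=size, replace=False, p=probs)
        out.append(
            GeneSignature(
                name=f"{name_prefix}_{i + 1:0{width}d}",
                category="random",
                genes=tuple(chosen.tolist()),
            )
        )
    if n_resampled:
        logger.info(
            "build_random_signatures: resampled %d sizes exceeding the "
            "distinct-gene count (%d)", n_resampled, n_distinct,
        )
    return SignatureCollection(out)


def estimate_fdr(
    collection: SignatureCollection,
    datasets: Sequence[ExpressionDataset],
    n_random: int = 1000,
    alpha: float = 0.05,
    k_min: int = 2,
    activity_config: ActivityConfig | None = None,
) -> NullModelReport:
    """Estimate the selection FDR by running the full procedure on random
    signatures built from ``collection``'s size and gene-multiplicity pools.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if activity_config is None:
        activity_config = ActivityConfig()
    rand_seed = derive_seed(activity_config.seed, "random-signatures")
    random_collection = build_random_signatures(collection, n_random, rand_seed)
    results: list[ActivityResult] = []
    for ds in datasets:
        results.extend(score_collection(random_collection, ds, activity_config))
    calls = classify_informative(
        results, alpha=alpha, k_min=k_min,
        signature_names=[s.name for s in random_collection],
    )
    n_info = sum(c.informative for c in calls)
    return NullModelReport(
        n_random=n_random,
        n_called_informative=n_info,
        fdr_estimate=n_info / n_random,
        seed=activity_config.seed,
    )
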