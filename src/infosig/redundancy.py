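"""Compositional and functional redundancy between signature pairs.

Two distinct notions of redundancy are quantified for every unordered
pair of signatures:

* *compositional* — the Jaccard index of their gene memberships, with a
  one-sided hypergeometric overlap test (BH-corrected across all pairs);
* *functional* — the mean, across datasets, of the absolute Pearson
  correlation between the two signatures' metasamples (sample activity
  profiles).  Two disjoint gene sets reading out the same underlying
  transcriptional program have high functional redundancy at zero Jaccard
  index — the dissociation this module exists to expose.

The absolute correlation is used because the PCA sign of each metasample
is arbitrary per signature and dataset.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .activity import ActivityResult, bh_adjust
from .io import SignatureCollection

logger = logging.getLogger(__name__)

__all__ = [
    "RedundancyEdge",
    "jaccard_index",
    "ji_significance",
    "functional_redundancy",
    "redundancy_table",
]


@dataclass
class RedundancyEdge:
    """Redundancy measurements for one unordered signature pair."""

    sig_a: str
    sig_b: str
    jaccard: float
    ji_pvalue: float
    ji_padj: float
    ji_significant: bool
    per_dataset_r: list[float]
    functional_redundancy: float
    n_datasets: int


def jaccard_index(a: frozenset | set, b: frozenset | set) -> float:
    """|A n B| / |A u B| for two non-empty gene sets."""
    if not a or not b:
        raise ValueError("gene sets must be non-empty")
    return len(a & b) / len(a | b)


def ji_significance(a: frozenset | set, b: frozenset | set, universe_size: int) -> float:
    """One-sided hypergeometric upper-tail p for the observed overlap.

    Probability of >= |A n B| shared genes when |A| genes are drawn
    without replacement from a universe of ``universe_size`` containing
    |B| marked genes.
    """
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set sizes exceed universe size")
    k = len(a & b)
    # P(X >= k) with X ~ Hypergeom(M=universe, n=|B| successes, N=|A| draws)
    return float(stats.hypergeom.sf(k - 1, universe_size, len(b), len(a)))


def functional_redundancy(
    ms_a: Mapping[str, np.ndarray],
    ms_b: Mapping[str, np.ndarray],
    min_shared_datasets: int = 2,
) -> tuple[float, int, list[float]] | None:
    """Average absolute metasample correlation across shared datasets.

    ``ms_a``/``ms_b`` map dataset_id to the signature's metasample vector;
    within a dataset both vectors must index the same samples in the same
    order.  Returns (mean |r|, n_datasets, per-dataset |r|), or None when
    fewer than ``min_shared_datasets`` datasets are shared (pair skipped).
    """
    shared = sorted(set(ms_a) & set(ms_b))
    if len(shared) < min_shared_datasets:
        return None
    rs: list[float] = []
    for d in shared:
        va, vb = np.asarray(ms_a[d]), np.asarray(ms_b[d])
        if va.shape != vb.shape:
            raise ValueError(f"metasample length mismatch in dataset {d}")
        if np.std(va) == 0 or np.std(vb) == 0:
            rs.append(0.0)
            continue
        r, _ = stats.pearsonr(va, vb)
        rs.append(abs(float(r)))
    return float(np.mean(rs)), len(shared), rs


def redundancy_table(
    activity: Sequence[ActivityResult],
    collection: SignatureCollection,
    names: Sequence[str] | None = None,
    min_shared_datasets: int = 2,
    alpha: float = 0.05,
) -> list[RedundancyEdge]:
    """All-pairs redundancy among the selected signatures.

    ``names`` restricts the pair set (default: all signatures with
    activity results).  The hypergeometric universe is the set of genes
    appearing anywhere in the scored collection; JI significance is
    BH-corrected across all evaluated pairs at ``alpha``.  Pairs sharing
    fewer than ``min_shared_datasets`` scored datasets are omitted.
    """
    ms: dict[str, dict[str, np.ndarray]] = defaultdict(dict)
    for r in activity:
        ms[r.signature_name][r.dataset_id] = r.metasample
    if names is None:
        names = sorted(ms)
    universe_size = len(collection.universe)
    sets = {n: collection.get(n).gene_set for n in names}

    edges: list[RedundancyEdge] = []
    n_skipped = 0
    for a, b in combinations(names, 2):
        fr = functional_redundancy(ms.get(a, {}), ms.get(b, {}), min_shared_datasets)
        if fr is None:
            n_skipped += 1
            continue
        value, n_ds, per_r = fr
        edges.append(
            RedundancyEdge(
                sig_a=a,
                sig_b=b,
                jaccard=jaccard_index(sets[a], sets[b]),
                ji_pvalue=ji_significance(sets[a], sets[b], universe_size),
                ji_padj=np.nan,
                ji_significant=False,
                per_dataset_r=per_r,
                functional_redundancy=value,
                n_datasets=n_ds,
            )
        )
    if n_skipped:
        logger.info(
            "redundancy_table: skipped %d pairs sharing < %d datasets",
            n_skipped, min_shared_datasets,
        )
    if edges:
        padj = bh_adjust([e.ji_pvalue for e in edges])
        for e, p in zip(edges, padj):
            e.ji_padj = float(p)
            e.ji_significant = bool(p < alpha)
    return edges
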