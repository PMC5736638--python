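"""Cross-dataset conservation of signature eigengenes.

A signature's eigengene (unit-norm gene-loading vector of the first
principal component of its restricted expression submatrix) is computed
independently in each dataset.  For every dataset pair, the two eigengenes
are restricted to their shared matched genes and compared by Pearson
correlation; because the PCA sign is arbitrary per dataset, the absolute
correlation is used.  The conservation score is

    score = -(1/N) * sum(log10 p_i)  =  |log10(geometric mean of p_i)|

over the N retained pairs, and a signature is called conserved when the
geometric mean p-value falls strictly below a threshold (default 1e-6,
i.e. score > 6).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .activity import ActivityResult

logger = logging.getLogger(__name__)

__all__ = [
    "ConservationResult",
    "eigengene_correlation",
    "conservation_score",
    "classify_conserved",
    "conservation_table",
]

P_FLOOR = 1e-300  # keeps log10 finite for essentially-zero p-values


@dataclass
class ConservationResult:
    signature_name: str
    dataset_pairs: list[tuple[str, str]]
    pair_r: list[float]
    pair_p: list[float]
    score: float | None
    conserved: bool | None  # None when no valid pairs exist


def eigengene_correlation(
    genes_a: Sequence[str],
    weights_a: np.ndarray,
    genes_b: Sequence[str],
    weights_b: np.ndarray,
    min_overlap: int = 10,
) -> tuple[float, float, int] | None:
    """Sign-invariant Pearson comparison of two eigengenes.

    Both vectors are restricted to their shared gene ids; returns
    (|r|, two-sided p, n_shared), or None when fewer than ``min_overlap``
    genes are shared (pair skipped).  The two-sided p-value from the
    t-distribution with n_shared - 2 df is symmetric in the sign of r, so
    taking |r| leaves it unchanged.
    """
    index_b = {g: i for i, g in enumerate(genes_b)}
    pairs = [(i, index_b[g]) for i, g in enumerate(genes_a) if g in index_b]
    if len(pairs) < min_overlap:
        return None
    ia, ib = zip(*pairs)
    va = np.asarray(weights_a, dtype=float)[list(ia)]
    vb = np.asarray(weights_b, dtype=float)[list(ib)]
    if np.std(va) == 0 or np.std(vb) == 0:
        # degenerate constant loading vector: correlation undefined
        return 0.0, 1.0, len(pairs)
    r, p = stats.pearsonr(va, vb)
    return abs(float(r)), max(float(p), P_FLOOR), len(pairs)


def conservation_score(pair_p: Sequence[float]) -> float:
    """Absolute log10 of the geometric mean of pairwise correlation p-values."""
    p = np.asarray(pair_p, dtype=float)
    if p.size == 0:
        raise ValueError("pair_p must be non-empty")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return float(-np.mean(np.log10(p)))


def classify_conserved(score: float, p_threshold: float = 1e-6) -> bool:
    """Conserved iff the geometric mean p-value is strictly below threshold."""
    return bool(score > -np.log10(p_threshold))


def conservation_table(
    results: Sequence[ActivityResult],
    min_overlap: int = 10,
    p_threshold: float = 1e-6,
) -> list[ConservationResult]:
    """Conservation scores for every signature scored in >=2 datasets.

    Pairs are evaluated only between datasets where the signature was
    scored; pairs with too small a gene overlap are skipped.  Signatures
    with no valid pair are reported unclassifiable (score/conserved None).
    """
    by_sig: dict[str, list[ActivityResult]] = defaultdict(list)
    for r in results:
        by_sig[r.signature_name].append(r)
    out: list[ConservationResult] = []
    for name in sorted(by_sig):
        rs = sorted(by_sig[name], key=lambda r: r.dataset_id)
        pairs: list[tuple[str, str]] = []
        rr: list[float] = []
        pp: list[float] = []
        for i in range(len(rs)):
            for j in range(i + 1, len(rs)):
                comp = eigengene_correlation(
                    rs[i].matched_genes, rs[i].eigengene,
                    rs[j].matched_genes, rs[j].eigengene,
                    min_overlap=min_overlap,
                )
                if comp is None:
                    continue
                r_abs, p, _ = comp
                pairs.append((rs[i].dataset_id, rs[j].dataset_id))
                rr.append(r_abs)
                pp.append(p)
        if not pairs:
            logger.info("conservation: signature %s has no valid dataset pair", name)
            out.append(ConservationResult(name, [], [], [], None, None))
            continue
        score = conservation_score(pp)
        out.append(
            ConservationResult(
                signature_name=name,
                dataset_pairs=pairs,
                pair_r=rr,
                pair_p=pp,
                score=score,
                conserved=classify_conserved(score, p_threshold),
            )
        )
    return out
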