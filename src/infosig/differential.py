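"""Two-group differential module-activity analysis.

Per signature, the per-sample activity scores (the metasample) are
compared between two sample groups with Student's equal-variance t-test.
The "fold change" is the *difference* of group means: activity scores are
centered PCA projections whose sign is conventional, so a ratio is
ill-defined on them.  Significance is the raw p < 0.05 cut used for map
coloring (no multiple-testing correction at this step; the selection
stage already controls the FDR of the signature list itself).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .io import SampleGroups

logger = logging.getLogger(__name__)

__all__ = ["DifferentialResult", "differential_activity", "score_map"]


@dataclass
class DifferentialResult:
    signature_name: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    fold_change: float  # mean_b - mean_a
    t_stat: float
    p_value: float
    significant: bool


def differential_activity(
    metasample: np.ndarray,
    sample_ids: Sequence[str],
    groups: SampleGroups,
    signature_name: str = "",
    alpha: float = 0.05,
    welch: bool = False,
) -> DifferentialResult:
    """Student's t-test on activity scores between the two groups.

    Groups are ordered alphabetically by label; ``fold_change`` is
    mean(group_b) - mean(group_a).  With zero variance in both groups and
    equal means, t = 0 and p = 1.
    """
    scores = {s: float(v) for s, v in zip(sample_ids, metasample)}
    ga, gb = groups.group_names
    xa = np.array([scores[s] for s in groups.members(ga) if s in scores])
    xb = np.array([scores[s] for s in groups.members(gb) if s in scores])
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError(
            f"each group needs >=2 scored samples (got {len(xa)}, {len(xb)})"
        )
    mean_a, mean_b = float(xa.mean()), float(xb.mean())
    if np.var(xa) == 0 and np.var(xb) == 0:
        if mean_a == mean_b:
            t, p = 0.0, 1.0
        else:
            t = float(np.sign(mean_b - mean_a)) * np.inf
            p = 0.0
    else:
        t, p = stats.ttest_ind(xb, xa, equal_var=not welch)
        t, p = float(t), float(p)
    return DifferentialResult(
        signature_name=signature_name,
        group_a=ga,
        group_b=gb,
        mean_a=mean_a,
        mean_b=mean_b,
        fold_change=mean_b - mean_a,
        t_stat=t,
        p_value=p,
        significant=bool(p < alpha),
    )


def score_map(graph: nx.Graph, diffs: Sequence[DifferentialResult]) -> nx.Graph:
    """Annotate a copy of the graph with differential-activity scores.

    Significant nodes carry their signed ``fold_change`` (positive =
    upregulated, rendered red; negative = downregulated, green);
    non-significant nodes carry no fold_change attribute (null score,
    rendered white).  Results for unknown nodes are skipped with a warning.
    """
    out = graph.copy()
    for d in diffs:
        if d.signature_name not in out:
            logger.warning("score_map: no node for signature %s; skipped", d.signature_name)
            continue
        node = out.nodes[d.signature_name]
        node["diff_significant"] = bool(d.significant)
        node["diff_pvalue"] = float(d.p_value)
        if d.significant:
            node["fold_change"] = float(d.fold_change)
    return out
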