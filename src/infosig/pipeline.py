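"""End-to-end orchestration: score -> select -> conserve -> redundancy -> map.

All randomness flows from one root seed in :class:`PipelineConfig`;
stage-level seeds are derived deterministically from it, so a rerun with
the same config and inputs is byte-identical.  Every run writes a
manifest recording the config, the seed and SHA-256 digests of the
inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import ActivityConfig, ActivityResult, score_collection
from .conservation import ConservationResult, conservation_table
from .io import (
    ExpressionDataset,
    GeneSignature,
    SignatureCollection,
    read_expression,
    read_gmt,
    write_gmt,
)
from .network import build_graph, connected_components, export_graph
from .redundancy import RedundancyEdge, redundancy_table
from .selection import InformativeCall, classify_informative

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All tunable thresholds of the workflow (defaults are the operative ones).

    alpha / k_min:
        informative rule — both BH-adjusted p-values < alpha in >= k_min
        datasets.
    n_draws:
        random gene sets per empirical null.
    min_genes:
        minimum matched genes for a signature to be scored in a dataset.
    min_overlap:
        minimum shared genes for an eigengene pair comparison.
    min_shared_datasets:
        minimum co-scored datasets for a redundancy pair.
    conservation_p_threshold:
        geometric-mean p-value below which a signature is conserved.
    edge_threshold:
        strict lower bound on functional redundancy for a network edge.
    """

    alpha: float = 0.05
    k_min: int = 2
    n_draws: int = 300
    min_genes: int = 10
    min_overlap: int = 10
    min_shared_datasets: int = 2
    conservation_p_threshold: float = 1e-6
    edge_threshold: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.k_min < 1 or self.n_draws < 1 or self.min_genes < 2:
            raise ValueError("k_min, n_draws >= 1 and min_genes >= 2 required")
        if not 0 < self.conservation_p_threshold < 1:
            raise ValueError("conservation_p_threshold must be in (0, 1)")
        if not 0 <= self.edge_threshold <= 1:
            raise ValueError("edge_threshold must be in [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def calls_to_frame(calls, collection: SignatureCollection) -> pd.DataFrame:
    cat = {s.name: s.category for s in collection}
    return pd.DataFrame(
        {
            "signature": [c.signature_name for c in calls],
            "category": [cat.get(c.signature_name, "") for c in calls],
            "n_significant": [c.n_significant for c in calls],
            "datasets": [",".join(c.significant_datasets) for c in calls],
            "informative": [c.informative for c in calls],
            "scored": [c.scored for c in calls],
        }
    )


def conservation_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "signature": [r.signature_name for r in results],
            "n_pairs": [len(r.dataset_pairs) for r in results],
            "score": [r.score if r.score is not None else np.nan for r in results],
            "conserved": [bool(r.conserved) for r in results],
        }
    )


def edges_to_frame(edges) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sig_a": [e.sig_a for e in edges],
            "sig_b": [e.sig_b for e in edges],
            "jaccard": [e.jaccard for e in edges],
            "ji_pvalue": [e.ji_pvalue for e in edges],
            "ji_padj": [e.ji_padj for e in edges],
            "ji_significant": [e.ji_significant for e in edges],
            "functional_redundancy": [e.functional_redundancy for e in edges],
            "n_datasets": [e.n_datasets for e in edges],
        }
    )


def calls_from_frame(df: pd.DataFrame) -> list[InformativeCall]:
    return [
        InformativeCall(
            signature_name=row.signature,
            significant_datasets=(
                str(row.datasets).split(",") if isinstance(row.datasets, str) and row.datasets else []
            ),
            n_significant=int(row.n_significant),
            informative=bool(row.informative),
            scored=bool(getattr(row, "scored", True)),
        )
        for row in df.itertuples(index=False)
    ]


def conservation_from_frame(df: pd.DataFrame) -> list[ConservationResult]:
    return [
        ConservationResult(
            signature_name=row.signature,
            dataset_pairs=[],
            pair_r=[],
            pair_p=[],
            score=None if pd.isna(row.score) else float(row.score),
            conserved=bool(row.conserved),
        )
        for row in df.itertuples(index=False)
    ]


def edges_from_frame(df: pd.DataFrame) -> list[RedundancyEdge]:
    return [
        RedundancyEdge(
            sig_a=row.sig_a,
            sig_b=row.sig_b,
            jaccard=float(row.jaccard),
            ji_pvalue=float(row.ji_pvalue),
            ji_padj=float(row.ji_padj),
            ji_significant=bool(row.ji_significant),
            per_dataset_r=[],
            functional_redundancy=float(row.functional_redundancy),
            n_datasets=int(row.n_datasets),
        )
        for row in df.itertuples(index=False)
    ]


def load_expression_dir(expr_dir: str | Path) -> list[ExpressionDataset]:
    """Load every ``*.tsv`` matrix of a directory (sorted for determinism)."""
    expr_dir = Path(expr_dir)
    paths = sorted(expr_dir.glob("*.tsv"))
    if not paths:
        raise PipelineError(f"input: no *.tsv expression matrices in {expr_dir}")
    return [read_expression(p) for p in paths]


def run_pipeline(
    config: PipelineConfig,
    gmt_path: str | Path,
    expr_dir: str | Path,
    out_dir: str | Path,
) -> dict:
    """Run the full workflow and write the artifact bundle to ``out_dir``.

    Outputs: ``activity.tsv``, ``calls.tsv``, ``conservation.tsv``,
    ``edges.tsv``, ``map.graphml``, ``map.json``, ``informative.gmt`` and
    ``manifest.json``.  Returns the in-memory bundle as a dict.
    """
    gmt_path, expr_dir, out_dir = Path(gmt_path), Path(expr_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    collection = read_gmt(gmt_path)
    datasets = load_expression_dir(expr_dir)
    input_digests = {gmt_path.name: _sha256(gmt_path)}
    for p in sorted(expr_dir.glob("*.tsv")):
        input_digests[p.name] = _sha256(p)

    acfg = ActivityConfig(
        min_genes=config.min_genes, n_draws=config.n_draws, seed=config.seed
    )
    results: list[ActivityResult] = []
    for ds in datasets:
        results.extend(score_collection(collection, ds, acfg))
    from .activity import results_to_frame

    results_to_frame(results).to_csv(out_dir / "activity.tsv", sep="\t", index=False)

    calls = classify_informative(
        results, alpha=config.alpha, k_min=config.k_min,
        signature_names=[s.name for s in collection],
    )
    calls_to_frame(calls, collection).to_csv(out_dir / "calls.tsv", sep="\t", index=False)

    if len(datasets) < 2:
        raise PipelineError(
            "conservation: cross-dataset stages require >=2 expression datasets "
            f"(got {len(datasets)}); selection outputs were written to {out_dir}"
        )

    cons = conservation_table(
        results, min_overlap=config.min_overlap,
        p_threshold=config.conservation_p_threshold,
    )
    conservation_to_frame(cons).to_csv(out_dir / "conservation.tsv", sep="\t", index=False)

    informative_names = [c.signature_name for c in calls if c.informative]
    informative_calls = [c for c in calls if c.informative]
    edges = redundancy_table(
        results, collection, names=informative_names,
        min_shared_datasets=config.min_shared_datasets, alpha=config.alpha,
    )
    edges_to_frame(edges).to_csv(out_dir / "edges.tsv", sep="\t", index=False)

    graph = build_graph(
        edges, informative_calls,
        [c for c in cons if c.signature_name in set(informative_names)],
        collection, edge_threshold=config.edge_threshold,
    )
    export_graph(graph, "graphml", out_dir / "map.graphml")
    export_graph(graph, "json", out_dir / "map.json")
    if informative_names:
        write_gmt(collection.subset(informative_names), out_dir / "informative.gmt")
    else:
        (out_dir / "informative.gmt").write_text("")

    components = connected_components(graph)
    manifest = {
        "tool": "infosig",
        "version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "inputs": input_digests,
        "counts": {
            "signatures": len(collection),
            "datasets": len(datasets),
            "scored_results": len(results),
            "informative": len(informative_names),
            "edges": graph.number_of_edges(),
            "components": len(components),
        },
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return {
        "results": results,
        "calls": calls,
        "conservation": cons,
        "edges": edges,
        "graph": graph,
        "components": components,
        "manifest": manifest,
    }
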