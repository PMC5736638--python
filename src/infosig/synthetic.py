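"""Synthetic multi-dataset expression compendia with planted ground truth.

The generator emulates the statistical structure the scoring method
assumes: a gene set is "informative" when its genes load on a common
latent axis of variation.  Expression follows a Gaussian linear factor
model,

    value(g, s) = sum_f w(g, f) * a(f, s) + eps(g, s),

with latent activities ``a ~ N(0, 1)`` per sample, loadings ``w`` nonzero
(magnitude ``loading_scale``, random signs) only for genes of the modules
attached to factor ``f``, and noise ``eps ~ N(0, noise_sd^2)``.

Planted structure, all with pairwise-disjoint gene sets:

* *modules* — one gene set per factor; the first ``n_conserved`` reuse a
  single loading vector in every dataset (conserved eigengenes), the
  rest redraw loadings per dataset;
* *redundant pairs* — two disjoint gene sets attached to the same factor
  (functionally redundant at zero Jaccard index);
* *background signatures* — random gene sets over the unassigned
  (pure-noise) genes.

With ``loading_scale = 0`` the data degenerate to pure noise and planted
modules are statistically indistinguishable from background.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .io import ExpressionDataset, GeneSignature, SampleGroups, SignatureCollection

__all__ = [
    "SyntheticSpec",
    "GroundTruthEntry",
    "generate_compendium",
    "generate_null_compendium",
    "generate_two_condition",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic compendium.

    Defaults give four datasets of 5000 genes x 100 samples with 20
    planted modules of 50 genes (half of them conserved across datasets),
    5 disjoint redundant pairs, 200 background signatures, unit loading
    scale and unit noise — a regime where planted modules are clearly
    detectable with 100-draw empirical nulls while background sets are not.
    """

    n_datasets: int = 4
    n_genes: int = 5000
    n_samples: int = 100
    n_planted_modules: int = 20
    module_size: int = 50
    loading_scale: float = 1.0
    noise_sd: float = 1.0
    n_conserved: int = 10
    n_redundant_pairs: int = 5
    n_background_signatures: int = 200
    group_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size > self.n_genes:
            raise ValueError("module_size exceeds n_genes")
        if self.n_conserved > self.n_planted_modules:
            raise ValueError("n_conserved exceeds n_planted_modules")
        for name in (
            "n_datasets", "n_genes", "n_samples", "n_planted_modules",
            "module_size", "n_conserved", "n_redundant_pairs",
            "n_background_signatures",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.noise_sd < 0 or self.loading_scale < 0 or self.group_shift < 0:
            raise ValueError("scales must be non-negative")

    @property
    def planted_gene_demand(self) -> int:
        return (self.n_planted_modules + 2 * self.n_redundant_pairs) * self.module_size


@dataclass
class GroundTruthEntry:
    """Per-signature ground truth of the generator."""

    planted: bool
    conserved_planted: bool = False
    redundant_partner: Optional[str] = None
    latent_factor_id: Optional[int] = None
    shifted: bool = False


GroundTruth = dict  # signature name -> GroundTruthEntry


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(n)]


def _sign_loadings(rng: np.random.Generator, size: int, scale: float) -> np.ndarray:
    """Random-sign loadings of constant magnitude ``scale``.

    The global sign of the vector is fixed so that the mean loading is
    positive (flipping w as a whole leaves the factor model invariant);
    this orients each module's activity score along increasing mean
    expression of its genes, making "upregulation" well-defined.
    """
    w = scale * rng.choice([-1.0, 1.0], size=size)
    s = w.sum()
    if s < 0:
        w = -w
    elif s == 0 and scale > 0:
        neg = np.flatnonzero(w < 0)
        if neg.size:
            w[neg[0]] = -w[neg[0]]
    return w


def _plan(spec: SyntheticSpec, rng: np.random.Generator):
    """Fixed (per-compendium) gene memberships and signature collection."""
    if spec.planted_gene_demand > spec.n_genes:
        raise ValueError(
            f"planted modules demand {spec.planted_gene_demand} genes but only "
            f"{spec.n_genes} are available"
        )
    gene_ids = _gene_ids(spec.n_genes)
    perm = rng.permutation(spec.n_genes)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        block = perm[cursor:cursor + k]
        cursor += k
        return block

    mod_w = max(2, len(str(max(1, spec.n_planted_modules))))
    pair_w = max(2, len(str(max(1, spec.n_redundant_pairs))))
    bg_w = max(3, len(str(max(1, spec.n_background_signatures))))

    members: dict[str, np.ndarray] = {}  # signature -> gene row indices
    factor_of: dict[str, int] = {}
    truth: GroundTruth = {}
    signatures: list[GeneSignature] = []

    for i in range(spec.n_planted_modules):
        name = f"MOD_{i + 1:0{mod_w}d}"
        rows = take(spec.module_size)
        members[name] = rows
        factor_of[name] = i
        conserved = i < spec.n_conserved
        truth[name] = GroundTruthEntry(
            planted=True, conserved_planted=conserved, latent_factor_id=i
        )
        signatures.append(
            GeneSignature(name, "planted-module", tuple(gene_ids[r] for r in rows))
        )
    for j in range(spec.n_redundant_pairs):
        fid = spec.n_planted_modules + j
        pair_names = (f"PAIR_{j + 1:0{pair_w}d}A", f"PAIR_{j + 1:0{pair_w}d}B")
        for k, name in enumerate(pair_names):
            rows = take(spec.module_size)
            members[name] = rows
            factor_of[name] = fid
            truth[name] = GroundTruthEntry(
                planted=True,
                redundant_partner=pair_names[1 - k],
                latent_factor_id=fid,
            )
            signatures.append(
                GeneSignature(name, "planted-redundant", tuple(gene_ids[r] for r in rows))
            )

    unassigned = perm[cursor:]
    for b in range(spec.n_background_signatures):
        if unassigned.size < 2:
            raise ValueError("no unassigned genes left for background signatures")
        lo = min(20, max(2, unassigned.size))
        hi = min(3 * max(spec.module_size, 10), unassigned.size)
        size = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        rows = rng.choice(unassigned, size=size, replace=False)
        name = f"BG_{b + 1:0{bg_w}d}"
        truth[name] = GroundTruthEntry(planted=False)
        signatures.append(
            GeneSignature(name, "background", tuple(gene_ids[r] for r in rows))
        )

    n_factors = spec.n_planted_modules + spec.n_redundant_pairs
    return gene_ids, members, factor_of, n_factors, SignatureCollection(signatures), truth


def _simulate_dataset(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    dataset_id: str,
    gene_ids: list[str],
    members: dict[str, np.ndarray],
    factor_of: dict[str, int],
    n_factors: int,
    conserved_w: dict[str, np.ndarray],
    activities: np.ndarray | None = None,
) -> ExpressionDataset:
    n_g, n_s = spec.n_genes, spec.n_samples
    if activities is None:
        activities = rng.standard_normal((max(n_factors, 1), n_s))
    values = spec.noise_sd * rng.standard_normal((n_g, n_s))
    for name, rows in members.items():
        w = conserved_w.get(name)
        if w is None:
            w = _sign_loadings(rng, rows.size, spec.loading_scale)
        values[rows] += np.outer(w, activities[factor_of[name]])
    width = max(3, len(str(n_s)))
    sample_ids = [f"{dataset_id}_S{j:0{width}d}" for j in range(n_s)]
    return ExpressionDataset(dataset_id, list(gene_ids), sample_ids, values)


def generate_compendium(
    spec: SyntheticSpec,
) -> tuple[list[ExpressionDataset], SignatureCollection, GroundTruth]:
    """Generate the multi-dataset compendium, its signature collection, and truth."""
    rng = np.random.default_rng(spec.seed)
    gene_ids, members, factor_of, n_factors, collection, truth = _plan(spec, rng)
    conserved_w = {
        name: _sign_loadings(rng, members[name].size, spec.loading_scale)
        for name, entry in truth.items()
        if entry.planted and entry.conserved_planted
    }
    width = len(str(max(1, spec.n_datasets)))
    datasets = [
        _simulate_dataset(
            spec, rng, f"D{d + 1:0{width}d}", gene_ids, members, factor_of,
            n_factors, conserved_w,
        )
        for d in range(spec.n_datasets)
    ]
    return datasets, collection, truth


def generate_null_compendium(
    n_datasets: int, n_genes: int, n_samples: int, seed: int
) -> list[ExpressionDataset]:
    """Pure-noise compendium: i.i.d. standard normal, no correlation structure."""
    rng = np.random.default_rng(seed)
    gene_ids = _gene_ids(n_genes)
    width = len(str(max(1, n_datasets)))
    out = []
    for d in range(n_datasets):
        sw = max(3, len(str(n_samples)))
        did = f"N{d + 1:0{width}d}"
        out.append(
            ExpressionDataset(
                did,
                list(gene_ids),
                [f"{did}_S{j:0{sw}d}" for j in range(n_samples)],
                rng.standard_normal((n_genes, n_samples)),
            )
        )
    return out


def generate_two_condition(
    spec: SyntheticSpec,
    group_shift: float | None = None,
    n_shifted: int = 1,
) -> tuple[ExpressionDataset, SampleGroups, SignatureCollection, GroundTruth]:
    """One dataset split 50/50 into groups A/B with shifted latent activities.

    The latent activity of the first ``n_shifted`` planted-module factors
    is increased by ``group_shift`` in group B; all other factors are
    identically distributed in the two groups.  Returns the dataset, the
    group labels, the signature collection and the ground truth (shifted
    modules flagged).
    """
    if group_shift is None:
        group_shift = spec.group_shift
    if group_shift < 0:
        raise ValueError("group_shift must be >= 0")
    if spec.n_samples % 2:
        spec = replace(spec, n_samples=spec.n_samples + 1)
    rng = np.random.default_rng(spec.seed)
    gene_ids, members, factor_of, n_factors, collection, truth = _plan(spec, rng)
    n_s = spec.n_samples
    half = n_s // 2
    activities = rng.standard_normal((max(n_factors, 1), n_s))
    n_shifted = min(n_shifted, spec.n_planted_modules)
    for f in range(n_shifted):
        activities[f, half:] += group_shift
    for name, entry in truth.items():
        if entry.latent_factor_id is not None and entry.latent_factor_id < n_shifted:
            entry.shifted = True
    ds = _simulate_dataset(
        spec, rng, "COND", gene_ids, members, factor_of, n_factors,
        conserved_w={}, activities=activities,
    )
    labels = {s: ("A" if j < half else "B") for j, s in enumerate(ds.sample_ids)}
    return ds, SampleGroups(labels), collection, truth
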