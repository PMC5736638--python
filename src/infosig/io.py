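"""Domain types and file I/O for gene signatures and expression matrices.

Signatures are carried in the GMT format used by MSigDB-style collections
(one tab-separated line per set: name, description, genes...).  Expression
data is a plain tab-separated genes x samples matrix with a header row of
sample identifiers and a first column of gene identifiers.

Gene identifiers are matched case-sensitively; no alias or synonym
resolution is attempted.  Missing values in expression matrices are
rejected rather than imputed, because downstream PCA statistics would be
silently altered by any imputation policy.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSignature",
    "SignatureCollection",
    "ExpressionDataset",
    "SampleGroups",
    "GmtParseError",
    "ExpressionParseError",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "match_signature",
]


class GmtParseError(ValueError):
    """Raised for malformed GMT content."""


class ExpressionParseError(ValueError):
    """Raised for malformed expression matrices."""


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with a category label.

    ``genes`` is an ordered tuple of unique gene identifiers; order is
    preserved from the source so that restricted analyses are reproducible.
    ``category`` typically names the source collection (a data-derived or
    knowledge-based compendium).
    """

    name: str
    category: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("signature name must be non-empty")
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SignatureCollection:
    """A list of uniquely-named signatures plus the pooled gene universe.

    ``gene_counts`` maps each gene to its number of occurrences across
    member signatures (multiplicity >= 1); this multiset is the sampling
    pool for the random-signature null model.
    """

    signatures: list[GeneSignature]
    gene_counts: Counter = field(init=False)

    def __post_init__(self) -> None:
        names = [s.name for s in self.signatures]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate signature names: {dupes}")
        self.gene_counts = Counter(g for s in self.signatures for g in s.genes)

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.gene_counts)

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures)

    def get(self, name: str) -> GeneSignature:
        for s in self.signatures:
            if s.name == name:
                return s
        raise KeyError(name)

    def subset(self, names: Iterable[str]) -> "SignatureCollection":
        wanted = set(names)
        return SignatureCollection([s for s in self.signatures if s.name in wanted])


@dataclass
class ExpressionDataset:
    """One genes x samples expression matrix (log-scale assumed).

    The matrix is the unit over which restricted PCA runs; rows are genes,
    columns are samples.
    """

    dataset_id: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.sample_ids) != n_samples:
            raise ValueError(
                f"dataset {self.dataset_id}: matrix shape {self.values.shape} does "
                f"not match {len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError(f"dataset {self.dataset_id}: duplicate gene ids")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError(f"dataset {self.dataset_id}: duplicate sample ids")
        if n_samples < 3 or n_genes < 2:
            raise ValueError(
                f"dataset {self.dataset_id}: need >=2 genes and >=3 samples, "
                f"got {n_genes} x {n_samples}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"dataset {self.dataset_id}: non-finite values present")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def gene_index(self) -> dict[str, int]:
        # cached lazily; datasets are effectively immutable after construction
        idx = getattr(self, "_gene_index", None)
        if idx is None:
            idx = {g: i for i, g in enumerate(self.gene_ids)}
            object.__setattr__(self, "_gene_index", idx)
        return idx


@dataclass
class SampleGroups:
    """Two-group sample labelling for differential activity analysis."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        groups = sorted(set(self.labels.values()))
        if len(groups) != 2:
            raise ValueError(f"exactly two group labels required, got {groups}")
        for g in groups:
            n = sum(1 for v in self.labels.values() if v == g)
            if n < 2:
                raise ValueError(f"group {g!r} has {n} samples; >=2 required")
        self.group_names = (groups[0], groups[1])

    def members(self, group: str) -> list[str]:
        return [s for s, g in self.labels.items() if g == group]

    def validate_against(self, ds: ExpressionDataset) -> None:
        missing = [s for s in self.labels if s not in ds.gene_index and s not in ds.sample_ids]
        missing = [s for s in self.labels if s not in set(ds.sample_ids)]
        if missing:
            raise ValueError(
                f"labelled samples absent from dataset {ds.dataset_id}: {missing[:5]}"
            )


def read_gmt(path: str | Path, category_map: Mapping[str, str] | None = None) -> SignatureCollection:
    """Read a GMT file into a :class:`SignatureCollection`.

    Each line must have at least three tab-separated fields
    (name, description, gene, ...).  Duplicate genes within one line are
    collapsed (with a logged count); duplicate signature names are an error.
    ``category_map`` optionally maps a signature-name prefix to a category
    label; by default the GMT description field is used as the category.
    """
    path = Path(path)
    signatures: list[GeneSignature] = []
    seen: set[str] = set()
    n_dupe_genes = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            if name in seen:
                raise GmtParseError(f"{path}:{lineno}: duplicate signature name {name!r}")
            seen.add(name)
            genes: list[str] = []
            present: set[str] = set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in present:
                    n_dupe_genes += 1
                    continue
                present.add(g)
                genes.append(g)
            category = description
            if category_map is not None:
                for prefix, cat in category_map.items():
                    if name.startswith(prefix):
                        category = cat
                        break
            signatures.append(GeneSignature(name=name, category=category, genes=tuple(genes)))
    if n_dupe_genes:
        logger.info("read_gmt(%s): collapsed %d duplicate gene entries", path, n_dupe_genes)
    return SignatureCollection(signatures)


def write_gmt(collection: SignatureCollection, path: str | Path) -> None:
    """Write a collection as GMT; round-trips exactly through :func:`read_gmt`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for sig in collection:
            for token in (sig.name, sig.category, *sig.genes):
                if "\t" in token:
                    raise ValueError(
                        f"signature {sig.name!r}: field {token!r} contains a tab and "
                        "cannot be represented in GMT"
                    )
                if "\n" in token:
                    raise ValueError(
                        f"signature {sig.name!r}: field {token!r} contains a newline"
                    )
            fh.write("\t".join((sig.name, sig.category, *sig.genes)) + "\n")


def read_expression(path: str | Path, dataset_id: str | None = None) -> ExpressionDataset:
    """Read a tab-separated genes x samples matrix.

    First row: sample identifiers; first column: gene identifiers.  Any
    non-numeric or missing cell is an error reported with its coordinates.
    """
    path = Path(path)
    if dataset_id is None:
        dataset_id = path.stem
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise ExpressionParseError(f"{path}: duplicated gene rows: {dupes[:5]}")
    if df.columns.has_duplicates:
        dupes = sorted(df.columns[df.columns.duplicated()].unique().tolist())
        raise ExpressionParseError(f"{path}: duplicated sample columns: {dupes[:5]}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ExpressionParseError(
                f"{path}: non-numeric value {df[col].iloc[i]!r} at gene "
                f"{df.index[i]!r}, sample {col!r}"
            )
        values[:, j] = converted.to_numpy()
    return ExpressionDataset(
        dataset_id=dataset_id,
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values,
    )


def write_expression(ds: ExpressionDataset, path: str | Path) -> None:
    """Write a dataset as a tab-separated genes x samples matrix."""
    df = pd.DataFrame(ds.values, index=ds.gene_ids, columns=ds.sample_ids)
    df.to_csv(path, sep="\t", index_label="gene")


def read_groups(path: str | Path) -> SampleGroups:
    """Read a two-column (sample_id TAB label) file into :class:`SampleGroups`."""
    labels: dict[str, str] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>label'")
            labels[parts[0]] = parts[1]
    return SampleGroups(labels)


def match_signature(sig: GeneSignature, ds: ExpressionDataset) -> list[str]:
    """Ordered intersection of the signature's genes with the dataset's genes.

    Order follows the signature; an empty intersection is a valid result.
    """
    present = ds.gene_index
    return [g for g in sig.genes if g in present]
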