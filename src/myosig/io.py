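"""Core containers and file I/O for the signature pipeline.

The universal expression container is :class:`CountMatrix`, a genes ×
observations table that carries a ``layer`` tag recording whether it holds
raw integer counts, linear normalized expression, or log-normalized
expression.  Gene and observation identifiers are opaque, case-sensitive
strings; no case folding is ever applied.

Supported on-disk formats:

* MatrixMarket coordinate matrices with ``genes.tsv`` / ``barcodes.tsv``
  sidecars (the common CellRanger-era layout),
* dense TSV matrices (genes as rows, first column the gene id, header row
  the observation ids),
* GMT gene-set files,
* two-column TSV ortholog tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "ClusterAnnotation",
    "GeneSignature",
    "OrthologTable",
    "read_count_matrix",
    "write_count_matrix",
    "read_signature_gmt",
    "write_signature_gmt",
    "read_ortholog_table",
    "map_orthologs",
    "load_reference_signatures",
    "RAW_COUNTS",
    "NORMALIZED",
    "LOG_NORMALIZED",
]

RAW_COUNTS = "raw_counts"
NORMALIZED = "normalized"
LOG_NORMALIZED = "log_normalized"
_LAYERS = (RAW_COUNTS, NORMALIZED, LOG_NORMALIZED)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class CountMatrix:
    """Genes × observations expression table.

    Parameters
    ----------
    values
        DataFrame with gene ids as the index and observation ids as columns.
        Entries must be non-negative; with ``layer='raw_counts'`` they must
        be integral.
    layer
        One of ``raw_counts``, ``normalized``, ``log_normalized``.
    """

    values: pd.DataFrame
    layer: str = RAW_COUNTS

    def __post_init__(self) -> None:
        if self.layer not in _LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {_LAYERS}")
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "observation")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("count matrix entries must be numeric")
        if np.isnan(arr).any():
            g, o = map(int, np.argwhere(np.isnan(arr))[0])
            raise ValueError(
                f"NaN entry at gene {self.values.index[g]!r}, "
                f"observation {self.values.columns[o]!r}"
            )
        if (arr < 0).any():
            g, o = map(int, np.argwhere(arr < 0)[0])
            raise ValueError(
                f"negative entry at gene {self.values.index[g]!r}, "
                f"observation {self.values.columns[o]!r}"
            )
        if self.layer == RAW_COUNTS and not np.allclose(arr, np.round(arr)):
            g, o = map(int, np.argwhere(~np.isclose(arr, np.round(arr)))[0])
            raise ValueError(
                f"non-integer raw count at gene {self.values.index[g]!r}, "
                f"observation {self.values.columns[o]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def obs_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]

    def subset_obs(self, obs: Sequence[str]) -> "CountMatrix":
        missing = [o for o in obs if o not in self.values.columns]
        if missing:
            raise KeyError(f"observations not in matrix: {missing}")
        return CountMatrix(self.values.loc[:, list(obs)], layer=self.layer)


@dataclass
class ClusterAnnotation:
    """Observation → cluster map plus the clusters forming the target population."""

    labels: pd.Series  # index = obs ids, values = cluster labels (str)
    target_clusters: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        _check_unique(list(self.labels.index), "observation")
        self.labels = self.labels.astype(str)
        self.target_clusters = frozenset(str(c) for c in self.target_clusters)
        observed = set(self.labels.unique())
        unknown = self.target_clusters - observed
        if unknown:
            raise ValueError(f"target clusters not present in annotation: {sorted(unknown)}")
        if self.target_clusters and not self.target_mask().any():
            raise ValueError("target population is empty")

    @property
    def obs_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def clusters(self) -> list[str]:
        return sorted(self.labels.unique())

    def target_mask(self) -> np.ndarray:
        return self.labels.isin(self.target_clusters).to_numpy()

    def check_matches(self, m: CountMatrix) -> None:
        if list(self.labels.index) != m.obs_ids:
            raise ValueError("annotation observation ids do not match the count matrix")


@dataclass
class GeneSignature:
    """Named, ordered gene list with species and selection provenance."""

    name: str
    genes: tuple[str, ...]
    species: str = "human"
    description: str = ""
    provenance: dict | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("signature name must be non-empty")
        self.genes = tuple(self.genes)
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        _check_unique(self.genes, f"gene (signature {self.name!r})")

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(self, universe: Iterable[str]) -> "GeneSignature":
        present = set(universe)
        kept = tuple(g for g in self.genes if g in present)
        if not kept:
            raise ValueError(f"no gene of signature {self.name!r} is present in the matrix")
        return GeneSignature(self.name, kept, self.species, self.description, self.provenance)


@dataclass
class OrthologTable:
    """One-to-one symbol map between species (missing targets allowed as None)."""

    pairs: Mapping[str, str | None]

    def __post_init__(self) -> None:
        clean: dict[str, str | None] = {}
        for k, v in self.pairs.items():
            if v is not None and v == "":
                v = None
            clean[k] = v
        self.pairs = clean

    def get(self, symbol: str) -> str | None:
        return self.pairs.get(symbol)


# ---------------------------------------------------------------------------
# count-matrix I/O


def read_count_matrix(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a raw count matrix from ``tsv`` or an ``mtx_dir`` layout.

    ``mtx_dir`` expects ``matrix.mtx`` plus ``genes.tsv`` and ``barcodes.tsv``
    sidecars (one id per line, first column used); sidecar order defines
    matrix order, with the 1-based MTX coordinates mapped onto it.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return CountMatrix(df, layer=RAW_COUNTS)
    if format == "mtx_dir":
        mtx = path / "matrix.mtx"
        genes = _read_sidecar(path / "genes.tsv")
        barcodes = _read_sidecar(path / "barcodes.tsv")
        mat = scipy.io.mmread(mtx)
        mat = scipy.sparse.coo_matrix(mat).toarray()
        if mat.shape != (len(genes), len(barcodes)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match sidecars "
                f"({len(genes)} genes, {len(barcodes)} barcodes)"
            )
        df = pd.DataFrame(mat, index=genes, columns=barcodes)
        return CountMatrix(df, layer=RAW_COUNTS)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'mtx_dir'")


def _read_sidecar(path: Path) -> list[str]:
    ids = [line.split("\t")[0].strip() for line in path.read_text().splitlines() if line.strip()]
    _check_unique(ids, f"sidecar ({path.name})")
    return ids


def write_count_matrix(m: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        out = m.values.copy()
        if m.layer == RAW_COUNTS:
            out = out.astype(int)
        out.to_csv(path, sep="\t")
        return
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        arr = m.values.to_numpy()
        sp = scipy.sparse.coo_matrix(arr)
        scipy.io.mmwrite(path / "matrix.mtx", sp, field="integer" if m.layer == RAW_COUNTS else "real")
        (path / "genes.tsv").write_text("".join(f"{g}\n" for g in m.gene_ids))
        (path / "barcodes.tsv").write_text("".join(f"{o}\n" for o in m.obs_ids))
        return
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'mtx_dir'")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_signature_gmt(path: str | Path, species: str = "human") -> list[GeneSignature]:
    """Read a GMT file: ``name TAB description TAB gene TAB gene ...`` per line."""
    sigs: list[GeneSignature] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: expected >= 3 tab-separated fields, got {len(fields)}")
        name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        if len(set(genes)) != len(genes):
            dup = next(g for i, g in enumerate(genes) if g in genes[:i])
            raise ValueError(f"GMT line {lineno}: duplicate gene {dup!r} in set {name!r}")
        sigs.append(GeneSignature(name=name, genes=tuple(genes), species=species, description=desc))
    return sigs


def write_signature_gmt(signatures: Sequence[GeneSignature], path: str | Path) -> None:
    with open(path, "w") as f:
        for sig in signatures:
            f.write("\t".join([sig.name, sig.description or "na", *sig.genes]) + "\n")


def load_reference_signatures() -> dict[str, GeneSignature]:
    """The three published myogenic signatures (human symbols), keyed by name.

    Satellite cell (10 genes), myoblast/myocyte (25 genes) and myonuclear
    type I/IIa/IIx (66 genes) marker sets derived from the integrated mouse
    muscle single-cell atlas.
    """
    ref = resources.files("myosig.data") / "myogenic_signatures.gmt"
    with resources.as_file(ref) as p:
        sigs = read_signature_gmt(p, species="human")
    return {s.name: s for s in sigs}


# ---------------------------------------------------------------------------
# ortholog mapping


def read_ortholog_table(path: str | Path) -> OrthologTable:
    """Two-column TSV: source symbol TAB target symbol (blank target = no ortholog)."""
    pairs: dict[str, str | None] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        src = fields[0].strip()
        tgt = fields[1].strip() if len(fields) > 1 else ""
        if src in pairs:
            raise ValueError(f"ortholog table line {lineno}: duplicate source symbol {src!r}")
        pairs[src] = tgt or None
    return OrthologTable(pairs)


def map_orthologs(
    sig: GeneSignature, table: OrthologTable, target_species: str
) -> tuple[GeneSignature, list[str]]:
    """Translate a signature between species, dropping genes without an ortholog.

    Returns the mapped signature (original order preserved) and the list of
    input symbols that had no ortholog.  Many-to-one collisions on the target
    side keep the first occurrence and warn.
    """
    if sig.species == target_species:
        raise ValueError(f"signature {sig.name!r} is already {target_species}")
    mapped: list[str] = []
    dropped: list[str] = []
    seen_targets: set[str] = set()
    for g in sig.genes:
        t = table.get(g)
        if t is None:
            dropped.append(g)
        elif t in seen_targets:
            warnings.warn(
                f"ortholog collision: {g!r} also maps to {t!r}; keeping first occurrence",
                stacklevel=2,
            )
            dropped.append(g)
        else:
            mapped.append(t)
            seen_targets.add(t)
    if not mapped:
        raise ValueError(
            f"signature {sig.name!r} has no ortholog in {target_species}; unusable in that species"
        )
    out = GeneSignature(
        name=sig.name,
        genes=tuple(mapped),
        species=target_species,
        description=sig.description,
        provenance={**(sig.provenance or {}), "mapped_from": sig.species, "dropped": list(dropped)},
    )
    return out, dropped
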