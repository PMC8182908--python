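"""Interactome data model and I/O.

Every molecule in this package is represented as a binary signal on one shared
undirected protein-protein interaction (PPI) graph: node j carries a 1 if the
gene is a target of the molecule and 0 otherwise.  This module reads and writes
the graph (edge-list TSV), pathway gene sets (GMT), molecule target tables and
labels, and builds the spectral operators every graph-convolution layer
consumes:

* ``gcn_operator``      D̃^{-1/2} (A + I) D̃^{-1/2}   (symmetric normalization
  with self-loops, degrees from A + I)
* ``rw_operator``       D̃^{-1} (A + I)              (random-walk normalization)
* ``scaled_laplacian``  L̂ = 2 L / λ_max − I with L = I − D^{-1/2} A D^{-1/2}
  (degrees from A *without* self-loops) and λ_max the largest eigenvalue of L.

Node order is lexicographic on gene identifier throughout, so matrices and
signal vectors are deterministic across runs and I/O round-trips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph

__all__ = [
    "Interactome",
    "SpectralOperators",
    "PathwayAnnotation",
    "MoleculeSignal",
    "LabeledDataset",
    "read_edge_list",
    "write_edge_list",
    "largest_connected_component",
    "build_spectral_operators",
    "read_gmt",
    "write_gmt",
    "read_cancer_flags",
    "write_cancer_flags",
    "read_molecule_targets",
    "write_molecule_targets",
    "read_labels",
    "write_labels",
]

DEFAULT_CANCER_KEYWORDS = ("cancer", "carcinoma", "leukemia", "melanoma", "glioma")


class EdgeListParseError(ValueError):
    """Raised for a malformed line in an edge-list file."""


@dataclass
class Interactome:
    """An undirected gene-gene interaction graph.

    Attributes
    ----------
    gene_ids : list of str
        Unique node identifiers; defines the node order of every matrix and
        signal vector in the package.
    adjacency : scipy.sparse.csr_matrix
        Symmetric |V|x|V| matrix with zero diagonal.  Binary unless weights
        were explicitly kept at read time.
    """

    gene_ids: list[str]
    adjacency: sp.csr_matrix

    def __post_init__(self) -> None:
        self.adjacency = sp.csr_matrix(self.adjacency)
        if len(self.gene_ids) != self.adjacency.shape[0]:
            raise ValueError("gene_ids length does not match adjacency size")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def edge_count(self) -> int:
        """Number of undirected edges (each counted once)."""
        return int(self.adjacency.nnz // 2)

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        a = self.adjacency
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if (a != a.T).nnz != 0:
            raise ValueError("adjacency is not symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency has nonzero diagonal (self-loops)")
        if a.nnz and a.data.min() < 0:
            raise ValueError("negative edge weight")
        if (self.degrees() == 0).any():
            warnings.warn("interactome contains isolated nodes", stacklevel=2)


@dataclass
class SpectralOperators:
    """Normalized propagation operators derived from one interactome."""

    gcn_operator: sp.csr_matrix
    rw_operator: sp.csr_matrix
    scaled_laplacian: sp.csr_matrix
    lambda_max: float
    n_nodes: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_nodes = self.gcn_operator.shape[0]


@dataclass
class PathwayAnnotation:
    """Binary pathway-membership matrix P (pathways x genes) with cancer flags."""

    pathway_ids: list[str]
    membership: np.ndarray  # (npathways, |V|) in {0,1}
    cancer_flag: np.ndarray  # (npathways,) bool

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership)
        self.cancer_flag = np.asarray(self.cancer_flag, dtype=bool)
        npath = len(self.pathway_ids)
        if self.membership.shape[0] != npath or self.cancer_flag.shape[0] != npath:
            raise ValueError("pathway_ids/membership/cancer_flag size mismatch")
        vals = np.unique(self.membership)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("membership matrix must be binary")

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_ids)

    def covered_genes(self) -> np.ndarray:
        """Boolean mask over genes that belong to at least one pathway."""
        return self.membership.any(axis=0)

    def cancer_gene_mask(self) -> np.ndarray:
        """Boolean mask over genes in at least one cancer-flagged pathway."""
        if not self.cancer_flag.any():
            return np.zeros(self.membership.shape[1], dtype=bool)
        return self.membership[self.cancer_flag].any(axis=0)


@dataclass
class MoleculeSignal:
    """A molecule's binary target-indicator vector over the interactome nodes."""

    molecule_id: str
    role: str  # "drug" | "food"
    x: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int8)
        if not np.isin(self.x, (0, 1)).all():
            raise ValueError(f"{self.molecule_id}: signal must be binary")
        if self.role not in ("drug", "food"):
            raise ValueError(f"{self.molecule_id}: role must be 'drug' or 'food'")

    @property
    def n_targets(self) -> int:
        return int(self.x.sum())


@dataclass
class LabeledDataset:
    """Drug signals with binary anticancer labels (1 = anticancer)."""

    signals: list[MoleculeSignal]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.labels) != len(self.signals):
            raise ValueError("labels and signals length mismatch")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    @property
    def class_counts(self) -> tuple[int, int]:
        """(n_pos, n_neg)."""
        n_pos = int(self.labels.sum())
        return n_pos, len(self.labels) - n_pos

    def feature_matrix(self) -> np.ndarray:
        """Stack signals into an (n_molecules, |V|) float array."""
        return np.stack([s.x for s in self.signals]).astype(np.float64)

    @property
    def molecule_ids(self) -> list[str]:
        return [s.molecule_id for s in self.signals]


# ---------------------------------------------------------------------------
# graph I/O


def read_edge_list(
    path: str | Path,
    directed_ok: bool = False,
    keep_weights: bool = False,
) -> Interactome:
    """Read a whitespace/tab-separated edge list into an :class:`Interactome`.

    Lines starting with ``#`` are comments.  Reciprocal and duplicate edges are
    collapsed; self-edges are dropped with a warning.  Node order is
    lexicographic on gene id.  Weights in an optional third column are kept
    only when ``keep_weights`` is true; otherwise any positive weight becomes 1.
    When ``directed_ok`` is false, reciprocal lines carrying *different*
    weights are treated as a malformed (directed) file and rejected; when
    true, the larger weight wins.
    """
    edges: dict[tuple[str, str], float] = {}
    genes: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise EdgeListParseError(f"line {lineno}: expected >=2 columns, got {line!r}")
            u, v = tokens[0], tokens[1]
            w = 1.0
            if len(tokens) >= 3:
                try:
                    w = float(tokens[2])
                except ValueError as exc:
                    raise EdgeListParseError(f"line {lineno}: bad weight {tokens[2]!r}") from exc
            if u == v:
                warnings.warn(f"line {lineno}: self-edge {u!r} dropped", stacklevel=2)
                genes.add(u)
                continue
            genes.update((u, v))
            key = (u, v) if u < v else (v, u)
            if key in edges and edges[key] != w and not directed_ok:
                raise EdgeListParseError(
                    f"line {lineno}: edge {u}-{v} repeats with a different "
                    f"weight ({edges[key]:g} vs {w:g}); asymmetric weights "
                    "imply a directed graph")
            edges[key] = max(edges.get(key, 0.0), w)
    gene_ids = sorted(genes)
    idx = {g: i for i, g in enumerate(gene_ids)}
    n = len(gene_ids)
    if edges:
        rows = np.fromiter((idx[u] for u, _ in edges), dtype=np.int64, count=len(edges))
        cols = np.fromiter((idx[v] for _, v in edges), dtype=np.int64, count=len(edges))
        data = np.fromiter(edges.values(), dtype=np.float64, count=len(edges))
    else:
        rows = cols = np.zeros(0, dtype=np.int64)
        data = np.zeros(0)
    if not keep_weights:
        data = (data > 0).astype(np.float64)
    a = sp.coo_matrix((data, (rows, cols)), shape=(n, n))
    a = (a + a.T).tocsr()
    return Interactome(gene_ids=gene_ids, adjacency=a)


def write_edge_list(g: Interactome, path: str | Path) -> None:
    """Write the upper triangle of the adjacency as a TSV edge list."""
    coo = sp.triu(g.adjacency, k=1).tocoo()
    with open(path, "w") as fh:
        fh.write("# gene1\tgene2\tweight\n")
        order = np.lexsort((coo.col, coo.row))
        for i in order:
            fh.write(f"{g.gene_ids[coo.row[i]]}\t{g.gene_ids[coo.col[i]]}\t{coo.data[i]:g}\n")


def largest_connected_component(g: Interactome) -> Interactome:
    """Restrict the graph to its largest connected component.

    Ties between equally-sized components are broken in favor of the component
    containing the lexicographically smallest gene id.  Node order of the kept
    nodes is preserved.
    """
    if g.n_genes == 0:
        raise ValueError("empty interactome")
    n_comp, labels = csgraph.connected_components(g.adjacency, directed=False)
    if n_comp == 1:
        return g
    sizes = np.bincount(labels, minlength=n_comp)
    best = sizes.max()
    candidates = [lab for lab in range(n_comp) if sizes[lab] == best]
    keep_label = min(
        candidates,
        key=lambda lab: min(g.gene_ids[i] for i in np.flatnonzero(labels == lab)),
    )
    mask = labels == keep_label
    keep = np.flatnonzero(mask)
    sub = g.adjacency[np.ix_(keep, keep)].tocsr()
    return Interactome(gene_ids=[g.gene_ids[i] for i in keep], adjacency=sub)


def _lambda_max(lap: sp.csr_matrix, mode: str) -> float:
    if mode == "fixed2":
        return 2.0
    n = lap.shape[0]
    if mode == "exact" or (mode == "auto" and n <= 2000):
        return float(np.linalg.eigvalsh(lap.toarray()).max())
    # power iteration on the symmetric PSD normalized Laplacian
    rng = np.random.default_rng(0)
    v = rng.standard_normal(n)
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(10000):
        w = lap @ v
        new_lam = float(v @ w)
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0
        v = w / nw
        if abs(new_lam - lam) < 1e-7:
            return new_lam
        lam = new_lam
    return lam


def build_spectral_operators(
    g: Interactome,
    lambda_max_mode: str = "auto",
) -> SpectralOperators:
    """Construct the propagation operators used by the graph layers.

    ``lambda_max_mode`` is one of ``auto`` (exact dense eigendecomposition for
    |V| <= 2000, power iteration above), ``exact``, ``power_iteration`` or
    ``fixed2`` (assume λ_max = 2, the upper bound for a normalized Laplacian).
    """
    if lambda_max_mode not in ("auto", "exact", "power_iteration", "fixed2"):
        raise ValueError(f"unknown lambda_max_mode {lambda_max_mode!r}")
    a = g.adjacency.astype(np.float64)
    n = a.shape[0]
    deg = np.asarray(a.sum(axis=1)).ravel()
    if (deg == 0).any():
        bad = g.gene_ids[int(np.flatnonzero(deg == 0)[0])]
        raise ValueError(
            f"gene {bad!r} has degree 0: normalized Laplacian undefined; "
            "remove isolated nodes first"
        )
    a_tilde = (a + sp.identity(n, format="csr")).tocsr()
    deg_tilde = np.asarray(a_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg_tilde))
    gcn_op = (d_inv_sqrt @ a_tilde @ d_inv_sqrt).tocsr()
    rw_op = (sp.diags(1.0 / deg_tilde) @ a_tilde).tocsr()
    d_inv_sqrt_noloop = sp.diags(1.0 / np.sqrt(deg))
    lap = (sp.identity(n, format="csr") - d_inv_sqrt_noloop @ a @ d_inv_sqrt_noloop).tocsr()
    lam = _lambda_max(lap, "power_iteration" if lambda_max_mode == "auto" and n > 2000 else
                      ("exact" if lambda_max_mode == "auto" else lambda_max_mode))
    scaled = ((2.0 / lam) * lap - sp.identity(n, format="csr")).tocsr()
    return SpectralOperators(
        gcn_operator=gcn_op,
        rw_operator=rw_op,
        scaled_laplacian=scaled,
        lambda_max=lam,
    )


# ---------------------------------------------------------------------------
# pathway I/O


def read_gmt(
    path: str | Path,
    g: Interactome,
    cancer_keywords: Sequence[str] = DEFAULT_CANCER_KEYWORDS,
    flag_file: str | Path | None = None,
) -> PathwayAnnotation:
    """Read GMT gene sets restricted to the interactome's genes.

    A pathway is cancer-flagged when its name contains any of
    ``cancer_keywords`` (case-insensitive substring match); an explicit
    ``flag_file`` (TSV ``pathway_id<TAB>is_cancer``) overrides the keywords.
    Pathways with no surviving member gene are dropped with a warning.
    """
    idx = g.index
    names: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line with fewer than 3 fields: {line!r}")
            name, _desc, members = parts[0], parts[1], parts[2:]
            row = np.zeros(g.n_genes, dtype=np.int8)
            for m in members:
                j = idx.get(m)
                if j is not None:
                    row[j] = 1
            if row.sum() == 0:
                warnings.warn(f"pathway {name!r} has no member in the graph; dropped",
                              stacklevel=2)
                continue
            names.append(name)
            rows.append(row)
    membership = np.stack(rows) if rows else np.zeros((0, g.n_genes), dtype=np.int8)
    if flag_file is not None:
        flags_map = read_cancer_flags(flag_file)
        cancer = np.array([flags_map.get(n, False) for n in names], dtype=bool)
    else:
        low = [k.lower() for k in cancer_keywords]
        cancer = np.array([any(k in n.lower() for k in low) for n in names], dtype=bool)
    return PathwayAnnotation(pathway_ids=names, membership=membership, cancer_flag=cancer)


def write_gmt(pa: PathwayAnnotation, gene_ids: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, name in enumerate(pa.pathway_ids):
            members = [gene_ids[j] for j in np.flatnonzero(pa.membership[i])]
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_cancer_flags(path: str | Path) -> dict[str, bool]:
    out: dict[str, bool] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            name, val = line.split("\t")[:2]
            out[name] = val.strip() in ("1", "true", "True")
    return out


def write_cancer_flags(pa: PathwayAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, flag in zip(pa.pathway_ids, pa.cancer_flag):
            fh.write(f"{name}\t{int(flag)}\n")


# ---------------------------------------------------------------------------
# molecule I/O


def read_molecule_targets(path: str | Path, g: Interactome) -> list[MoleculeSignal]:
    """Read a molecule target table (TSV: molecule_id, role, comma-separated targets).

    Targets absent from the graph are dropped (count logged per molecule);
    molecules left with no targets get an all-zero signal and a warning.
    """
    idx = g.index
    signals: list[MoleculeSignal] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["molecule_id", "role"]:
            raise ValueError("target table must have header molecule_id/role/targets")
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            mol_id, role = parts[0], parts[1]
            targets = parts[2].split(",") if len(parts) > 2 and parts[2] else []
            if mol_id in seen:
                raise ValueError(f"duplicate molecule_id {mol_id!r}")
            seen.add(mol_id)
            x = np.zeros(g.n_genes, dtype=np.int8)
            dropped = 0
            for t in targets:
                j = idx.get(t)
                if j is None:
                    dropped += 1
                else:
                    x[j] = 1
            if dropped:
                warnings.warn(f"{mol_id}: {dropped} target(s) not in the graph dropped",
                              stacklevel=2)
            if x.sum() == 0:
                warnings.warn(f"{mol_id}: no surviving targets (all-zero signal)",
                              stacklevel=2)
            signals.append(MoleculeSignal(molecule_id=mol_id, role=role, x=x))
    return signals


def write_molecule_targets(
    signals: Sequence[MoleculeSignal], gene_ids: Sequence[str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("molecule_id\trole\ttargets\n")
        for s in signals:
            targets = ",".join(gene_ids[j] for j in np.flatnonzero(s.x))
            fh.write(f"{s.molecule_id}\t{s.role}\t{targets}\n")


def read_labels(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["molecule_id", "label"]:
            raise ValueError("label table must have header molecule_id/label")
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            mol_id, lab = line.split("\t")[:2]
            if lab not in ("0", "1"):
                raise ValueError(f"label for {mol_id!r} must be 0 or 1, got {lab!r}")
            out[mol_id] = int(lab)
    return out


def write_labels(ds: LabeledDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("molecule_id\tlabel\n")
        for s, y in zip(ds.signals, ds.labels):
            fh.write(f"{s.molecule_id}\t{int(y)}\n")


def assemble_dataset(
    signals: Sequence[MoleculeSignal], labels: dict[str, int]
) -> LabeledDataset:
    """Join drug signals with a label map; every drug must be labeled."""
    drugs = [s for s in signals if s.role == "drug"]
    missing = [s.molecule_id for s in drugs if s.molecule_id not in labels]
    if missing:
        raise ValueError(f"missing labels for {missing[:5]}...")
    y = np.array([labels[s.molecule_id] for s in drugs], dtype=np.int64)
    return LabeledDataset(signals=list(drugs), labels=y)
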