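"""Input containers and parsers for the standard file formats.

Expression matrices arrive as tab-delimited text (first row condition ids,
first column gene ids, log2 ratios, empty cells = missing), promoters/3'UTRs
as FASTA, association networks as 3-column edge lists, gene sets as GMT and
reference regulons as 2-column TF\tgene tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# expression

@dataclass
class ExpressionMatrix:
    """Genes x conditions log-ratio matrix; NaN marks missing values."""

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValueError("matrix shape does not match identifier counts")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise ValueError("duplicate condition ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.condition_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def apply_thesaurus(ids: list[str], thesaurus: dict[str, str] | None) -> list[str]:
    """Map identifiers through a synonym thesaurus; idempotent.

    A thesaurus maps alias -> canonical id.  Canonical ids map to themselves
    so applying the mapping twice equals applying it once.
    """
    if not thesaurus:
        return list(ids)
    return [thesaurus.get(i, i) for i in ids]


def read_expression(path: str | Path, thesaurus: dict[str, str] | None = None,
                    duplicate_policy: str = "mean") -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    Duplicate gene rows (after thesaurus mapping) are resolved per
    ``duplicate_policy``: ``first`` keeps the first row, ``mean`` averages
    element-wise ignoring missing cells.  A duplicate condition id is an error.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    dupes = [c for c in header if c in seen or seen.add(c)]
    if dupes:
        raise ParseError(f"duplicate condition id(s): {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.columns = header
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                    or str(cell).strip() == "":
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric cell at gene {df.index[i]!r}, "
                    f"condition {col!r}: {cell!r}") from None
    genes = apply_thesaurus([str(g) for g in df.index], thesaurus)
    out = pd.DataFrame(values, index=genes, columns=[str(c) for c in df.columns])
    if out.index.duplicated().any():
        if duplicate_policy == "first":
            out = out[~out.index.duplicated(keep="first")]
        elif duplicate_policy == "mean":
            out = out.groupby(level=0, sort=False).mean()
        else:
            raise ValueError(f"unknown duplicate policy {duplicate_policy!r}")
    return ExpressionMatrix.from_frame(out)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# promoter / UTR sequences

@dataclass
class PromoterSet:
    """gene id -> upstream (or 3'UTR) sequence, uppercase DNA."""

    sequences: dict[str, str]
    region_kind: str = "promoter"   # promoter | utr3

    def __post_init__(self) -> None:
        if self.region_kind not in ("promoter", "utr3"):
            raise ValueError(f"unknown region kind {self.region_kind!r}")
        for gene, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for gene {gene!r}")
        self.sequences = {g: s.upper() for g, s in self.sequences.items()}

    def get(self, gene: str, operon_map: dict[str, str] | None = None) -> str | None:
        """Sequence for a gene; operon members use the operon head's promoter."""
        if operon_map and gene in operon_map:
            gene = operon_map[gene]
        return self.sequences.get(gene)

    def restrict(self, genes) -> dict[str, str]:
        return {g: self.sequences[g] for g in genes if g in self.sequences}


def read_fasta(path: str | Path, region_kind: str = "promoter") -> PromoterSet:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return PromoterSet(seqs, region_kind)


def write_fasta(promoters: PromoterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, seq in promoters.sequences.items():
            fh.write(f">{gene}\n{seq}\n")


# ---------------------------------------------------------------------------
# association networks

@dataclass
class AssociationNetwork:
    """Undirected weighted gene association network."""

    name: str
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    network_weight: float = 1.0

    def add_edge(self, a: str, b: str, weight: float,
                 duplicate_policy: str = "max") -> None:
        if a == b:
            warnings.warn(f"self-loop on {a!r} dropped")
            return
        if weight < 0:
            raise ParseError(f"negative edge weight for ({a}, {b}): {weight}")
        key = (a, b) if a < b else (b, a)
        if key in self.edges:
            if duplicate_policy == "max":
                self.edges[key] = max(self.edges[key], weight)
            elif duplicate_policy == "sum":
                self.edges[key] += weight
            else:
                raise ValueError(f"unknown duplicate policy {duplicate_policy!r}")
        else:
            self.edges[key] = weight

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def weight(self, a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        return self.edges.get(key, 0.0)

    def adjacency(self, gene_ids: list[str]) -> np.ndarray:
        """Dense symmetric weight matrix over ``gene_ids``."""
        index = {g: i for i, g in enumerate(gene_ids)}
        W = np.zeros((len(gene_ids), len(gene_ids)))
        for (a, b), w in self.edges.items():
            ia, ib = index.get(a), index.get(b)
            if ia is not None and ib is not None:
                W[ia, ib] = W[ib, ia] = w
        return W


def read_network(path: str | Path, name: str = "network",
                 network_weight: float = 1.0,
                 duplicate_policy: str = "max") -> AssociationNetwork:
    """Read a 3-column (gene_a, gene_b, weight) edge-list TSV."""
    net = AssociationNetwork(name=name, network_weight=network_weight)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected >= 2 columns")
            a, b = parts[0], parts[1]
            w = float(parts[2]) if len(parts) > 2 else 1.0
            net.add_edge(a, b, w, duplicate_policy)
    return net


def write_network(net: AssociationNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for (a, b), w in sorted(net.edges.items()):
            fh.write(f"{a}\t{b}\t{w:g}\n")


# ---------------------------------------------------------------------------
# gene sets

@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for sid, members in self.sets.items():
            extra = members - uni
            if extra:
                raise ValueError(f"set {sid!r} has members outside universe: "
                                 f"{sorted(extra)[:5]}")

    @property
    def set_ids(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path, universe: list[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (set id, description, members...).

    The universe defaults to the union of all members.  Empty sets are kept
    but flagged with a warning.
    """
    sets: dict[str, set[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: GMT line needs id and description")
        sid = parts[0]
        if sid in sets:
            raise ParseError(f"duplicate set id {sid!r}")
        members = {m for m in parts[2:] if m}
        if not members:
            warnings.warn(f"gene set {sid!r} has no members")
        sets[sid] = members
    if universe is None:
        universe = sorted(set().union(*sets.values())) if sets else []
    return GeneSetCollection(sets, list(universe))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, members in collection.sets.items():
            fh.write("\t".join([sid, "na", *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# reference regulons and operon maps

def read_regulons(path: str | Path) -> dict[str, set[str]]:
    """Read a TF\tgene two-column table into TF -> regulated gene set."""
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tf, gene = line.split("\t")[:2]
            table.setdefault(tf, set()).add(gene)
    return table


def write_regulons(table: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tf in sorted(table):
            for gene in sorted(table[tf]):
                fh.write(f"{tf}\t{gene}\n")


def read_operon_map(path: str | Path) -> dict[str, str]:
    """Read a gene -> operon-head two-column TSV."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            gene, head = line.split("\t")[:2]
            out[gene] = head
    return out
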