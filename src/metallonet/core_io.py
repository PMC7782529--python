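"""Shared data types, file readers/writers, configuration and logging.

All identifiers (protein symbols, gene names, metal names) are uppercased and
whitespace-stripped on ingestion so that tables merged from different sources
key consistently.  Edge lists are undirected, deduplicated and self-loop-free;
weights default to 1.0 when a file carries no weight column.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml

logger = logging.getLogger("metallonet")

GROUP_CONTROL = "control"
GROUP_CASE = "PD"
VALID_GROUPS = (GROUP_CONTROL, GROUP_CASE)


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


def clean_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MetalProteinTable:
    """Mapping metal symbol -> set of binding-protein symbols.

    A protein bound by several metals appears under each of them.
    """

    entries: dict[str, set[str]] = field(default_factory=dict)

    def add(self, metal: str, protein: str) -> None:
        self.entries.setdefault(clean_symbol(metal), set()).add(clean_symbol(protein))

    @property
    def metals(self) -> list[str]:
        return sorted(self.entries)

    @property
    def proteins(self) -> set[str]:
        out: set[str] = set()
        for members in self.entries.values():
            out |= members
        return out

    def __len__(self) -> int:
        return len(self.entries)

    def validate(self) -> None:
        for metal, members in self.entries.items():
            if not members:
                raise ValueError(f"metal {metal!r} has an empty protein set")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metal": metal, "protein": protein}
            for metal in self.metals
            for protein in sorted(self.entries[metal])
        ]
        return pd.DataFrame(rows, columns=["metal", "protein"])


@dataclass
class InteractionGraph:
    """Undirected weighted protein graph.

    One container serves the PPI reference, each metal protein network, the
    Erdős–Rényi nulls and the pathway networks; ``label`` tags the class.
    Invariants: no self-loops, no duplicate edges, weights > 0.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    label: str = "metal"
    name: str = ""

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        nodes: Iterable[str] = (),
        label: str = "metal",
        name: str = "",
    ) -> "InteractionGraph":
        g = nx.Graph()
        g.add_nodes_from(clean_symbol(n) for n in nodes)
        dropped_loops = 0
        for edge in edges:
            u, v = clean_symbol(edge[0]), clean_symbol(edge[1])
            w = float(edge[2]) if len(edge) > 2 else 1.0
            if w <= 0:
                raise ValueError(f"non-positive edge weight {w} on {u}-{v}")
            if u == v:
                g.add_node(u)
                dropped_loops += 1
                continue
            g.add_edge(u, v, weight=w)
        if dropped_loops:
            logger.info("dropped %d self-loop(s)", dropped_loops)
        return cls(graph=g, label=label, name=name)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, u: str, v: str) -> float:
        return float(self.graph[u][v].get("weight", 1.0))

    def subgraph(self, nodes: Iterable[str], label: str | None = None,
                 name: str | None = None) -> "InteractionGraph":
        sub = nx.Graph(self.graph.subgraph(nodes))
        return InteractionGraph(
            graph=sub,
            label=self.label if label is None else label,
            name=self.name if name is None else name,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionGraph):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges


@dataclass
class ExpressionStudy:
    """Genes x samples matrix of (log2) intensities with group/batch metadata."""

    matrix: pd.DataFrame                  # index: gene symbols; columns: samples
    groups: pd.Series                     # sample -> control | PD
    batch: pd.Series                      # sample -> dataset/batch ID
    platform: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.matrix.index = [clean_symbol(g) for g in self.matrix.index]
        missing = [s for s in self.matrix.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples lacking group metadata: {missing}")
        missing_b = [s for s in self.matrix.columns if s not in self.batch.index]
        if missing_b:
            raise ValueError(f"samples lacking batch metadata: {missing_b}")
        bad = set(self.groups[list(self.matrix.columns)]) - set(VALID_GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.matrix.index.duplicated().any():
            dups = self.matrix.index[self.matrix.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene IDs: {dups}")

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]


@dataclass
class CohortTable:
    """Per-subject measurements: metal concentrations (ug/L) and qPCR Ct values.

    ``data`` rows are subjects; a ``group`` column holds control/PD; analyte
    columns are named ``serum_<metal>`` / ``csf_<metal>`` and Ct columns
    ``ct_<gene>``.  Missing measurements (e.g. subjects without a CSF sample)
    are NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.data.columns:
            raise ValueError("cohort table requires a 'group' column")
        bad = set(self.data["group"]) - set(VALID_GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for col in self.analyte_columns:
            vals = self.data[col].dropna()
            if (vals < 0).any():
                raise ValueError(f"negative concentration in column {col}")
        for col in self.ct_columns:
            vals = self.data[col].dropna()
            if ((vals <= 0) | (vals >= 45)).any():
                raise ValueError(f"Ct values outside (0, 45) in column {col}")

    @property
    def analyte_columns(self) -> list[str]:
        return [c for c in self.data.columns
                if c.startswith(("serum_", "csf_"))]

    @property
    def ct_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("ct_")]

    def group_rows(self, group: str) -> pd.DataFrame:
        return self.data[self.data["group"] == group]

    def group_sizes(self) -> dict[str, int]:
        return self.data["group"].value_counts().to_dict()


@dataclass(frozen=True)
class SummaryStats:
    """Mean, SD and sample size of one analyte in one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, dialect: str = "tsv") -> InteractionGraph:
    """Read an undirected edge list (TSV or Cytoscape SIF).

    TSV lines: ``node1<TAB>node2[<TAB>weight]``.  SIF lines:
    ``node1 interaction node2 [node4 ...]`` (each trailing node forms an edge
    with node1).  Symmetric duplicates are deduplicated; self-loops dropped
    with a logged count.
    """
    path = Path(path)
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    edges: list[tuple[str, str, float]] = []
    nodes: list[str] = []
    text = path.read_text()
    if not text.strip():
        logger.warning("empty edge-list file %s -> empty graph", path)
        return InteractionGraph(label="metal", name=path.stem)
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if dialect == "tsv" else line.split()
        if dialect == "tsv":
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 columns, got {len(fields)}")
            u, v = fields[0], fields[1]
            if len(fields) >= 3:
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad weight {fields[2]!r}") from exc
                edges.append((u, v, w))
            else:
                edges.append((u, v, 1.0))
        else:  # sif
            if len(fields) == 1:
                nodes.append(fields[0])
                continue
            if len(fields) == 2:
                raise ParseError(f"{path}:{lineno}: SIF line with 2 tokens (missing targets)")
            u = fields[0]
            for v in fields[2:]:
                edges.append((u, v, 1.0))
    return InteractionGraph.from_edges(edges, nodes=nodes, name=path.stem)


def write_edge_list(graph: InteractionGraph, path: str | Path) -> None:
    """Write a TSV edge list (node1, node2, weight); isolated nodes as singleton lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# label=%s name=%s\n" % (graph.label, graph.name))
        isolated = sorted(n for n in graph.graph.nodes if graph.graph.degree(n) == 0)
        for u, v in sorted(tuple(sorted(e)) for e in graph.graph.edges):
            fh.write(f"{u}\t{v}\t{graph.weight(u, v)}\n")
        for n in isolated:
            fh.write(f"{n}\n")


def read_written_edge_list(path: str | Path) -> InteractionGraph:
    """Read back files produced by :func:`write_edge_list` (singleton lines allowed)."""
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    nodes: list[str] = []
    label, name = "metal", path.stem
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if tok.startswith("label="):
                    label = tok[6:]
                elif tok.startswith("name="):
                    name = tok[5:]
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            nodes.append(fields[0])
        elif len(fields) >= 2:
            w = float(fields[2]) if len(fields) >= 3 else 1.0
            edges.append((fields[0], fields[1], w))
    return InteractionGraph.from_edges(edges, nodes=nodes, label=label, name=name)


def read_metal_annotations(path: str | Path,
                           exclude: Iterable[str] = ()) -> MetalProteinTable:
    """Read a 2-column TSV (metal, protein symbol); header line optional.

    ``exclude`` drops listed proteins on ingestion (e.g. a membrane-protein
    list, which bind metals at non-functional sites); excluded hits are
    logged.
    """
    path = Path(path)
    excluded = {clean_symbol(s) for s in exclude}
    n_excluded = 0
    table = MetalProteinTable()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        if lineno == 1 and fields[0].lower() == "metal":
            continue
        if clean_symbol(fields[1]) in excluded:
            n_excluded += 1
            continue
        table.add(fields[0], fields[1])
    if n_excluded:
        logger.info("excluded %d annotation row(s) via the exclusion list",
                    n_excluded)
    table.entries = {m: ps for m, ps in table.entries.items() if ps}
    return table


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate set names raise; sets with no genes are skipped with a warning;
    gene symbols are uppercased.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected name and description columns")
        name = fields[0].strip()
        genes = {clean_symbol(g) for g in fields[2:] if g.strip()}
        if name in sets:
            raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
        if not genes:
            logger.warning("gene set %r has no genes; skipped", name)
            continue
        sets[name] = genes
    return sets


def write_gene_sets(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def read_expression(matrix_path: str | Path, meta_path: str | Path) -> ExpressionStudy:
    """Read a genes x samples TSV matrix plus a sample sheet.

    The sample sheet is a TSV with columns ``sample``, ``group``, ``batch``.
    Matrix columns must match sample-sheet rows exactly; non-numeric cells are
    reported by gene and sample.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    required = {"sample", "group", "batch"}
    if not required <= set(meta.columns):
        raise ParseError(f"sample sheet missing columns: {sorted(required - set(meta.columns))}")
    meta = meta.set_index("sample")
    extra = [s for s in matrix.columns if s not in meta.index]
    absent = [s for s in meta.index if s not in matrix.columns]
    if extra or absent:
        raise ValueError(
            f"matrix/sheet mismatch: samples only in matrix {extra}, only in sheet {absent}"
        )
    for col in matrix.columns:
        coerced = pd.to_numeric(matrix[col], errors="coerce")
        bad = matrix.index[coerced.isna() & matrix[col].notna()]
        if len(bad):
            raise ParseError(
                f"non-numeric expression value for gene {bad[0]!r}, sample {col!r}"
            )
        matrix[col] = coerced
    return ExpressionStudy(
        matrix=matrix,
        groups=meta["group"],
        batch=meta["batch"].astype(str),
    )


def write_expression(study: ExpressionStudy, matrix_path: str | Path,
                     meta_path: str | Path) -> None:
    study.matrix.to_csv(matrix_path, sep="\t", index_label="gene")
    meta = pd.DataFrame({
        "sample": study.samples,
        "group": [study.groups[s] for s in study.samples],
        "batch": [study.batch[s] for s in study.samples],
    })
    meta.to_csv(meta_path, sep="\t", index=False)


def read_cohort(path: str | Path) -> CohortTable:
    return CohortTable(pd.read_csv(path, sep="\t"))


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.data.to_csv(path, sep="\t", index=False)


def read_corpus(path: str | Path) -> dict[str, str]:
    """Read an abstract corpus.

    ``path`` may be a directory of ``.txt`` files (doc ID = file stem) or a
    2-column TSV (doc_id, text).
    """
    path = Path(path)
    corpus: dict[str, str] = {}
    if path.is_dir():
        for f in sorted(path.glob("*.txt")):
            corpus[f.stem] = f.read_text().strip()
        return corpus
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t", 1)
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected doc_id<TAB>text")
        corpus[fields[0]] = fields[1]
    return corpus


def write_corpus(corpus: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for doc_id in sorted(corpus):
            text = corpus[doc_id].replace("\t", " ").replace("\n", " ")
            fh.write(f"{doc_id}\t{text}\n")


# ---------------------------------------------------------------------------
# Run configuration and manifest
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a YAML mapping")
    return cfg


def write_manifest(manifest: Mapping, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
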