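"""File formats and run configuration.

Plain-text formats only: delimited expression tables, similarity TSV
with a ``#scale=`` header, two-column label TSV, Newick trees, CSV
benchmark grids with ``#key=value`` metadata lines, and a YAML run
config that round-trips losslessly.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .discovery import ClusterNode, ClusterTree
from .prediction import ClassTree, KnownLabels
from .preprocess import RAW_INTENSITY, ExpressionMatrix, SimilarityMatrix

_NEWICK_RESERVED = set("(),:;'\"[] \t\n")


# ---------------------------------------------------------------------------
# expression tables


def _resolve_sep(path: Path, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if "\t" in line else ","
    raise ValueError(f"{path}: empty file")


def read_expression_table(
    path,
    orientation: str = "genes-by-samples",
    delimiter: str | None = None,
    scale: str = RAW_INTENSITY,
) -> ExpressionMatrix:
    """Parse a delimited table with a header row and an id first column.

    ``orientation`` is ``"genes-by-samples"`` (default: header = sample
    ids) or ``"samples-by-genes"`` (table is transposed after reading).
    The delimiter is auto-detected (tab/comma) unless forced.
    """
    path = Path(path)
    sep = _resolve_sep(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#",
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row ids {dups}")
    if pd.Index(df.columns).has_duplicates:
        raise ValueError(f"{path}: duplicate column ids")
    try:
        values = df.astype(float)
    except (ValueError, TypeError):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[np.flatnonzero(bad)[0]]
                line = int(np.flatnonzero(bad)[0]) + 2  # + header line, 1-based
                raise ValueError(
                    f"{path}: non-numeric cell at row {row!r}, column {col!r} (line {line})"
                )
        raise ValueError(f"{path}: table contains missing values")
    if values.isna().any().any():
        raise ValueError(f"{path}: table contains missing values")
    if orientation == "samples-by-genes":
        values = values.T
    elif orientation != "genes-by-samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ExpressionMatrix(
        values.to_numpy(dtype=float),
        [str(g) for g in values.index],
        [str(s) for s in values.columns],
        scale=scale,
    )


def write_expression_table(expr: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.to_csv(path, sep=delimiter, float_format="%.17g")  # exact round-trip


# ---------------------------------------------------------------------------
# similarity matrices


def write_similarity(sim: SimilarityMatrix, path, metadata: dict | None = None) -> None:
    """Similarity TSV: ``#scale=`` (plus metadata) comment lines, then the
    id-indexed matrix."""
    lines = [f"#scale={sim.scale}"]
    for key, val in (metadata or {}).items():
        lines.append(f"#{key}={val}")
    df = pd.DataFrame(sim.values, index=sim.sample_ids, columns=sim.sample_ids)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", float_format="%.17g")  # exact round-trip


def read_similarity(path) -> SimilarityMatrix:
    path = Path(path)
    meta: dict[str, str] = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key] = val
            else:
                body.append(line)
    if "scale" not in meta:
        raise ValueError(f"{path}: missing #scale= header; refusing to guess the scale")
    df = pd.read_csv(_io.StringIO("".join(body)), sep="\t", index_col=0,
                     float_precision="round_trip")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: row and column sample ids differ")
    return SimilarityMatrix(
        df.to_numpy(dtype=float), [str(s) for s in df.index], meta["scale"]
    )


# ---------------------------------------------------------------------------
# labels and predictions


def read_known_labels(path, classes=None) -> KnownLabels:
    """Two-column TSV (sample_id, class_id); duplicate conflicting rows fail."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "class_id"],
                     dtype=str, comment="#")
    if df.isna().any().any():
        raise ValueError(f"{path}: malformed label file")
    return KnownLabels.from_pairs(df.itertuples(index=False), classes=classes)


def write_predictions(path, sample_ids, labels, confidence=None, metadata=None) -> None:
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"#{key}={val}\n")
        for i, (s, lab) in enumerate(zip(sample_ids, labels)):
            row = [str(s), str(lab)]
            if confidence is not None:
                row.append(f"{confidence[i]:.6f}")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# trees


def _quote(name: str) -> str:
    if any(ch in _NEWICK_RESERVED for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def tree_to_newick(tree: ClusterTree) -> str:
    """Newick rendering of a cluster tree.

    Internal nodes are labeled with their inner minimum similarity to 4
    decimals; a multi-member leaf cluster is rendered as a flat
    multifurcation of its sample ids.
    """

    def render(node: ClusterNode) -> str:
        if not node.is_leaf:
            left, right = node.children
            return f"({render(left)},{render(right)}){node.inner_min_similarity:.4f}"
        names = [_quote(tree.sample_ids[i]) for i in node.members]
        if len(names) == 1:
            return names[0]
        return "(" + ",".join(names) + f"){node.inner_min_similarity:.4f}"

    return render(tree.root) + ";"


def write_tree_newick(tree: ClusterTree, path) -> None:
    Path(path).write_text(tree_to_newick(tree) + "\n")


def write_assignments(tree: ClusterTree, path, metadata: dict | None = None) -> None:
    """Flat TSV of (sample_id, leaf id, root-to-leaf path bitstring)."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"#{key}={val}\n")
        fh.write("sample_id\tleaf\tpath\n")
        for _, row in tree.assignments().iterrows():
            fh.write(f"{row.sample_id}\t{row.leaf}\t{row.path or '-'}\n")


def parse_class_tree(newick: str) -> ClassTree:
    """Parse a Newick string over class ids into a binary class tree.

    Branch lengths and internal labels are ignored; quoted names are
    supported; every internal node must be binary.
    """
    s = newick.strip()
    if s.endswith(";"):
        s = s[:-1]
    pos = 0

    def skip_decoration() -> None:
        nonlocal pos
        while pos < len(s) and s[pos] not in "(),;":
            pos += 1

    def parse_name() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while pos < len(s):
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    break
                out.append(s[pos])
                pos += 1
            name = "".join(out)
            skip_decoration()  # drop any :length
            return name
        start = pos
        while pos < len(s) and s[pos] not in "(),;:":
            pos += 1
        name = s[start:pos].strip()
        skip_decoration()
        return name

    def parse_node() -> ClassTree:
        nonlocal pos
        if pos < len(s) and s[pos] == "(":
            pos += 1
            children = [parse_node()]
            while pos < len(s) and s[pos] == ",":
                pos += 1
                children.append(parse_node())
            if pos >= len(s) or s[pos] != ")":
                raise ValueError("unbalanced parentheses in class tree")
            pos += 1
            skip_decoration()  # internal label / branch length
            if len(children) != 2:
                raise ValueError("class tree must be strictly binary")
            return ClassTree.node(children[0], children[1])
        name = parse_name()
        if not name:
            raise ValueError("empty class name in tree")
        return ClassTree.leaf(name)

    tree = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters in class tree: {s[pos:]!r}")
    return tree


def read_class_tree(path) -> ClassTree:
    return parse_class_tree(Path(path).read_text())


# ---------------------------------------------------------------------------
# benchmark tables


def write_table_csv(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"#{key}={val}\n")
        df.to_csv(fh, index=False)


def read_table_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_edge_list(adjacency: np.ndarray, path, metadata: dict | None = None) -> None:
    """Adjacency as a TSV edge list of 1-based node pairs (i < j)."""
    adj = np.asarray(adjacency)
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"#{key}={val}\n")
        n = adj.shape[0]
        fh.write(f"#nodes={n}\n")
        for i in range(n):
            for j in range(i + 1, n):
                if adj[i, j]:
                    fh.write(f"{i + 1}\t{j + 1}\n")


def read_edge_list(path) -> np.ndarray:
    n = None
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                if key == "nodes":
                    n = int(val)
                continue
            i, j = map(int, line.split("\t"))
            edges.append((i - 1, j - 1))
    if n is None:
        n = max(max(e) for e in edges) + 1 if edges else 0
    adj = np.zeros((n, n), dtype=int)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return adj


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Resolved options for one run; round-trips through YAML losslessly."""

    order: str = "second"  # first | second
    scale: str = "unit"  # raw | unit
    negatives: str = "clip"  # error | clip
    tol: float = 1e-6
    max_iter: int = 10000
    threshold: float = 0.0
    criterion_scale: str = "input"
    strategy: str = "binary"
    cutoff: float = 0.5
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(**data)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
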