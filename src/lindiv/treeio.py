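"""Time-calibrated tree I/O, node ages, annotations, and clock scaling.

Trees are ultrametric and rooted, with ages measured *backward* from the
tips (tips at 0 My, root oldest).  Parsing is delegated to dendropy, which
understands Newick and NEXUS including BEAST/FigTree-style bracketed
comment metadata (``[&posterior=0.99,region.set={...}]``); the parsed tree
is re-packed into a light array-backed :class:`TimeTree` whose integer node
ids are assigned in preorder and are stable across a write/parse
round-trip (child order is preserved on output).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .regions import RegionSet, StatePosterior

__all__ = [
    "TimeTree",
    "ClockRate",
    "TreeError",
    "TreeParseError",
    "UltrametricityError",
    "AnnotationError",
    "parse_tree",
    "node_ages",
    "attach_state_probabilities",
    "scale_to_time",
    "write_node_table",
    "format_sigfig",
]


class TreeError(ValueError):
    """Base class for tree-structure and tree-format errors."""


class TreeParseError(TreeError):
    """Malformed Newick/NEXUS input."""


class UltrametricityError(TreeError):
    """Tip depths disagree beyond the configured tolerance."""


class AnnotationError(TreeError):
    """Node annotation/probability table cannot be matched or validated."""


# --------------------------------------------------------------------------
# TimeTree
# --------------------------------------------------------------------------


class TimeTree:
    """Rooted (usually ultrametric) tree with branch durations in My.

    Node ids are integers ``0..n_nodes-1`` in preorder (root is 0).  The
    root's branch length is 0 by convention; every other node carries the
    duration of the branch to its parent.
    """

    def __init__(
        self,
        parent: np.ndarray,
        lengths: np.ndarray,
        children: list[list[int]],
        tip_labels: dict[int, str],
    ) -> None:
        self._parent = np.asarray(parent, dtype=np.int64)
        self._lengths = np.asarray(lengths, dtype=float)
        self._children = [list(c) for c in children]
        self._tip_labels = dict(tip_labels)
        self._ages: np.ndarray | None = None
        roots = np.flatnonzero(self._parent < 0)
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        self._root = int(roots[0])
        if np.any(self._lengths < 0):
            bad = int(np.flatnonzero(self._lengths < 0)[0])
            raise TreeError(f"negative branch duration on node {self.describe(bad)}")
        labels = list(self._tip_labels.values())
        if len(set(labels)) != len(labels):
            raise TreeError("tip labels must be unique")

    # -- basic structure -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self._parent)

    @property
    def root(self) -> int:
        return self._root

    @property
    def tips(self) -> tuple[int, ...]:
        return tuple(v for v in range(self.n_nodes) if not self._children[v])

    @property
    def internal_nodes(self) -> tuple[int, ...]:
        return tuple(v for v in range(self.n_nodes) if self._children[v])

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def parent(self, v: int) -> int:
        return int(self._parent[v])

    def children(self, v: int) -> tuple[int, ...]:
        return tuple(self._children[v])

    def branch_length(self, v: int) -> float:
        return float(self._lengths[v])

    @property
    def branch_lengths(self) -> np.ndarray:
        return self._lengths.copy()

    def is_tip(self, v: int) -> bool:
        return not self._children[v]

    def label(self, v: int) -> str | None:
        return self._tip_labels.get(v)

    def tip_id(self, label: str) -> int:
        for v, lab in self._tip_labels.items():
            if lab == label:
                return v
        raise KeyError(f"no tip labelled {label!r}")

    def describe(self, v: int) -> str:
        lab = self.label(v)
        return f"{v} ({lab})" if lab is not None else str(v)

    def preorder(self) -> list[int]:
        order: list[int] = []
        stack = [self._root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self._children[v]))
        return order

    def postorder(self) -> list[int]:
        return list(reversed(self.preorder()))

    def descendant_tip_labels(self, v: int) -> frozenset[str]:
        out: list[str] = []
        stack = [v]
        while stack:
            u = stack.pop()
            if self.is_tip(u):
                out.append(self._tip_labels[u])
            else:
                stack.extend(self._children[u])
        return frozenset(out)

    # -- ages ----------------------------------------------------------------
    def depths(self) -> np.ndarray:
        """Time from the root down to each node."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder():
            p = self._parent[v]
            if p >= 0:
                d[v] = d[p] + self._lengths[v]
        return d

    def ages(self, tol: float | None = None) -> np.ndarray:
        """Node ages in My (tips 0, root oldest); validates ultrametricity.

        `tol` defaults to ``1e-4 * root_age``.  A tip deviating beyond it
        raises :class:`UltrametricityError` naming the worst offender —
        silent repair would shift richness breakpoints.
        """
        d = self.depths()
        tip_ids = list(self.tips)
        root_age = max(d[v] for v in tip_ids) if tip_ids else 0.0
        if tol is None:
            tol = 1e-4 * root_age
        ages = root_age - d
        worst = max(tip_ids, key=lambda v: abs(ages[v]))
        if abs(ages[worst]) > tol:
            raise UltrametricityError(
                f"tree is not ultrametric: tip {self.describe(worst)} has age "
                f"{ages[worst]:.6g} (tolerance {tol:.6g}); all tips must reach 0"
            )
        return ages

    @property
    def root_age(self) -> float:
        return float(self.depths()[list(self.tips)].max()) if self.n_tips else 0.0

    # -- output --------------------------------------------------------------
    def _newick_node(self, v: int, annotations, parts: list[str]) -> None:
        if self._children[v]:
            parts.append("(")
            for i, c in enumerate(self._children[v]):
                if i:
                    parts.append(",")
                self._newick_node(c, annotations, parts)
            parts.append(")")
        lab = self._tip_labels.get(v)
        if lab is not None:
            parts.append(_quote_label(lab))
        if annotations and v in annotations and annotations[v]:
            parts.append(_format_comment(annotations[v]))
        if v != self._root:
            parts.append(f":{float(self._lengths[v])!r}")

    def write_newick(self, annotations: dict | None = None) -> str:
        parts: list[str] = []
        self._newick_node(self._root, annotations, parts)
        parts.append(";")
        return "".join(parts)

    def __repr__(self) -> str:
        return (
            f"<TimeTree n_tips={self.n_tips} n_nodes={self.n_nodes} "
            f"root_age={self.root_age:.4g}>"
        )


def _quote_label(label: str) -> str:
    if any(c in label for c in "()[]{}:;, '\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_comment(ann: dict) -> str:
    items = []
    for key, value in ann.items():
        if isinstance(value, (list, tuple, np.ndarray)):
            inner = ",".join(_format_comment_value(x) for x in value)
            items.append(f"{key}={{{inner}}}")
        else:
            items.append(f"{key}={_format_comment_value(value)}")
    return "[&" + ",".join(items) + "]"


def _format_comment_value(x) -> str:
    if isinstance(x, (float, np.floating)):
        return repr(float(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    s = str(x)
    if any(c in s for c in ",{}[]= "):
        return '"' + s + '"'
    return s


# --------------------------------------------------------------------------
# Parsing
# --------------------------------------------------------------------------


def _clean_annotation_value(value):
    if isinstance(value, (list, tuple)):
        return tuple(_clean_annotation_value(x) for x in value)
    if isinstance(value, str):
        s = value.strip().strip('"')
        try:
            f = float(s)
        except ValueError:
            return s
        if f.is_integer() and "." not in s and "e" not in s.lower():
            return int(f)
        return f
    return value


def parse_tree(
    text: str | None = None,
    path=None,
    schema: str | None = None,
    *,
    require_branch_lengths: bool = True,
) -> tuple[TimeTree, dict[int, dict]]:
    """Parse a Newick or NEXUS document into (TimeTree, node annotations).

    Bracketed comment metadata on nodes (BEAST/FigTree style) is captured
    verbatim by key into ``annotations[node_id]``; list values become
    tuples, numeric strings become numbers.  `schema` is auto-detected
    (``#NEXUS`` header) when not given.
    """
    if (text is None) == (path is None):
        raise ValueError("pass exactly one of text= or path=")
    if text is None:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    if schema is None:
        schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema=schema,
            extract_comment_metadata=True,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises many concrete error classes
        detail = str(exc)
        pos = ""
        for attr in ("line_num", "col_num"):
            if hasattr(exc, attr) and getattr(exc, attr) is not None:
                pos += f" {attr.replace('_num', '')} {getattr(exc, attr)}"
        raise TreeParseError(f"cannot parse {schema} input{pos}: {detail}") from exc

    parent: list[int] = []
    lengths: list[float] = []
    children: list[list[int]] = []
    tip_labels: dict[int, str] = {}
    annotations: dict[int, dict] = {}

    ids: dict[int, int] = {}  # id(dendropy node) -> our id
    for nd in dtree.preorder_node_iter():
        v = len(parent)
        ids[id(nd)] = v
        par = ids[id(nd.parent_node)] if nd.parent_node is not None else -1
        length = nd.edge.length
        if par >= 0 and length is None:
            if require_branch_lengths:
                name = nd.taxon.label if nd.taxon else f"internal #{v}"
                raise TreeParseError(f"missing branch length on node {name!r}")
            length = 0.0
        parent.append(par)
        lengths.append(float(length) if (par >= 0 and length is not None) else 0.0)
        children.append([])
        if par >= 0:
            children[par].append(v)
        if nd.is_leaf():
            if nd.taxon is None or nd.taxon.label is None:
                raise TreeParseError(f"unlabelled tip (internal id {v})")
            tip_labels[v] = nd.taxon.label
        ann = {a.name: _clean_annotation_value(a.value) for a in nd.annotations}
        if ann:
            annotations[v] = ann

    tree = TimeTree(np.array(parent), np.array(lengths), children, tip_labels)
    return tree, annotations


def node_ages(tree: TimeTree, tol: float | None = None) -> dict[int, float]:
    """Map node id -> age (My, measured back from the tips)."""
    ages = tree.ages(tol=tol)
    return {v: float(ages[v]) for v in range(tree.n_nodes)}


# --------------------------------------------------------------------------
# State-probability attachment
# --------------------------------------------------------------------------


def _as_table_items(table) -> list[tuple[object, np.ndarray]]:
    # Accept dict {node-id or clade: vector} or a DataFrame with a
    # 'node' or 'clade' column plus one column per region.
    try:
        import pandas as pd

        if isinstance(table, pd.DataFrame):
            key_col = "node" if "node" in table.columns else "clade"
            if key_col not in table.columns:
                raise AnnotationError("node table needs a 'node' or 'clade' column")
            value_cols = [c for c in table.columns if c != key_col]
            return [
                (row[key_col], np.asarray([row[c] for c in value_cols], dtype=float))
                for _, row in table.iterrows()
            ]
    except ImportError:  # pragma: no cover
        pass
    return [(k, np.asarray(v, dtype=float)) for k, v in dict(table).items()]


def attach_state_probabilities(
    tree: TimeTree,
    table,
    regions: RegionSet,
    tip_regions: dict[str, str] | None = None,
    *,
    hard_tol: float = 0.05,
) -> StatePosterior:
    """Match a node/clade-keyed probability table onto a tree.

    Rows are keyed either by integer node id or by a clade — the set of
    descendant tip labels, given as a frozenset/tuple or a ``|``-joined
    string.  Every internal node must be matched exactly once.  Vectors
    whose sum deviates from 1 by more than `hard_tol` are rejected; smaller
    deviations are renormalized.  Tips receive exact one-hot vectors from
    `tip_regions` when provided.
    """
    clade_to_node = {
        tree.descendant_tip_labels(v): v for v in tree.internal_nodes
    }
    assigned: dict[int, np.ndarray] = {}
    for key, vec in _as_table_items(table):
        if vec.shape != (regions.k,):
            raise AnnotationError(
                f"row {key!r}: expected {regions.k} probabilities, got {vec.shape}"
            )
        if isinstance(key, (int, np.integer)) or (
            isinstance(key, str) and key.isdigit()
        ):
            node = int(key)
            if node < 0 or node >= tree.n_nodes or tree.is_tip(node):
                raise AnnotationError(f"row {key!r}: not an internal node id")
        else:
            if isinstance(key, str):
                clade = frozenset(s.strip() for s in key.split("|") if s.strip())
            else:
                clade = frozenset(key)
            if clade not in clade_to_node:
                raise AnnotationError(
                    f"no clade with tip set {sorted(clade)} exists in the tree"
                )
            node = clade_to_node[clade]
        if node in assigned:
            raise AnnotationError(f"node {tree.describe(node)} matched more than once")
        s = vec.sum()
        if abs(s - 1.0) > hard_tol:
            raise AnnotationError(
                f"node {tree.describe(node)}: probabilities sum to {s:.6g}, "
                f"more than {hard_tol} from 1"
            )
        assigned[node] = vec / s

    unmatched = [v for v in tree.internal_nodes if v not in assigned]
    if unmatched:
        sets = [sorted(tree.descendant_tip_labels(v)) for v in unmatched[:5]]
        raise AnnotationError(
            f"{len(unmatched)} internal node(s) not matched by the table; "
            f"first missing clades: {sets}"
        )
    if tip_regions is not None:
        for v in tree.tips:
            lab = tree.label(v)
            if lab not in tip_regions:
                raise AnnotationError(f"tip {lab!r} missing from region assignment")
            assigned[v] = regions.one_hot(tip_regions[lab])
    return StatePosterior(regions, assigned, atol=1e-12, renormalize=True)


# --------------------------------------------------------------------------
# Clock scaling
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ClockRate:
    """Strict clock rate in substitutions · site⁻¹ · My⁻¹ (point or interval)."""

    lower: float
    upper: float | None = None

    def __post_init__(self) -> None:
        up = self.lower if self.upper is None else self.upper
        if not (0 < self.lower <= up):
            raise ValueError(
                f"require 0 < lower <= upper, got ({self.lower}, {self.upper})"
            )

    @property
    def is_interval(self) -> bool:
        return self.upper is not None and self.upper != self.lower


def _divide_lengths(tree: TimeTree, rate: float) -> TimeTree:
    lengths = tree.branch_lengths / rate
    lengths[tree.root] = 0.0
    return TimeTree(
        np.array([tree.parent(v) for v in range(tree.n_nodes)]),
        lengths,
        [list(tree.children(v)) for v in range(tree.n_nodes)],
        {v: tree.label(v) for v in tree.tips},
    )


def scale_to_time(tree: TimeTree, rate: float | ClockRate):
    """Convert a substitution-scaled tree to a time tree (durations = length / rate).

    With an interval rate, returns the pair ``(tree_lower, tree_upper)``
    scaled by the lower and upper bound respectively — the lower rate gives
    the older ages.
    """
    if isinstance(rate, (int, float)):
        rate = ClockRate(float(rate))
    if rate.is_interval:
        return _divide_lengths(tree, rate.lower), _divide_lengths(tree, float(rate.upper))
    return _divide_lengths(tree, rate.lower)


# --------------------------------------------------------------------------
# Node-table output
# --------------------------------------------------------------------------


def format_sigfig(x, sig: int = 3) -> str:
    """Format to `sig` significant figures, positional, trailing zeros kept."""
    if x is None:
        return ""
    x = float(x)
    if math.isnan(x):
        return ""
    if x == 0:
        return "0"
    s = np.format_float_positional(
        x, precision=sig, unique=False, fractional=False, trim="k"
    )
    return s.rstrip(".")


def write_node_table(records, destination, regions: RegionSet = None, *, metadata=None) -> None:
    """Write Table-style node diversity records as TSV (3 significant figures).

    Columns: node id, mean age, CI bounds, support, one probability column
    per region, lineage diversity (blank for unprocessed nodes).  Support
    is printed with two decimals; everything else at three significant
    figures.  `metadata` (mapping) is emitted as ``# key=value`` header
    comment lines.
    """
    from .regions import DEFAULT_REGIONS

    if regions is None:
        regions = DEFAULT_REGIONS
    close = False
    if isinstance(destination, (str, bytes)) or hasattr(destination, "__fspath__"):
        fh = open(destination, "w", encoding="utf-8")
        close = True
    else:
        fh = destination
    try:
        if metadata:
            for key, value in metadata.items():
                fh.write(f"# {key}={value}\n")
        header = [
            "node",
            "age_mean",
            "age_ci_lower",
            "age_ci_upper",
            "support",
            *regions.labels,
            "lineage_diversity",
        ]
        fh.write("\t".join(header) + "\n")
        for rec in records:
            probs = np.asarray(rec.probs, dtype=float)
            fields = [
                str(rec.node_id),
                format_sigfig(rec.age),
                format_sigfig(rec.age_ci_lower),
                format_sigfig(rec.age_ci_upper),
                "" if rec.support is None else f"{rec.support:.2f}",
                *[format_sigfig(p) for p in probs],
                format_sigfig(rec.diversity) if rec.processed else "",
            ]
            fh.write("\t".join(fields) + "\n")
    finally:
        if close:
            fh.close()
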