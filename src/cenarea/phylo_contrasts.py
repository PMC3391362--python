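"""Phylogenetically independent contrasts under Brownian-motion evolution.

Cross-species trait correlations are pseudo-replicated: closely related
species are not independent draws, so a cluster of relatives can inflate an
ordinary regression.  Felsenstein's contrasts fix this by transforming n tip
values on a rooted tree with branch lengths into n-1 differences that are
independent and identically distributed when the trait evolves by Brownian
motion.  The pruning recursion implemented here, for a pair of sister
nodes with values x1, x2 on (adjusted) branches v1, v2:

    raw contrast          x1 - x2
    standardized contrast (x1 - x2) / sqrt(v1 + v2)
    ancestral value       (x1/v1 + x2/v2) / (1/v1 + 1/v2)
    parent branch         incremented by v1*v2 / (v1 + v2)

The contrasts regression is least squares *through the origin* on the
standardized contrasts, with each contrast pair positivized (sign flips
applied jointly to x and y) — the standard convention, since contrast signs
are arbitrary.

The module also parses the ten-taxon grass tree exactly as printed in its
source, a nonstandard Newick dialect in which "name, length" pairs are
comma-separated and sister taxa are separated by semicolons (or, for
clades, by juxtaposition).  ``normalize_printed_newick`` rewrites that
dialect into standard Newick before parsing; tree I/O proper is delegated
to dendropy.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

import dendropy
import numpy as np

from .comparative_stats import RegressionResult, fit_ols

__all__ = [
    "PhyloNode",
    "PhyloTree",
    "Contrast",
    "ContrastSet",
    "normalize_printed_newick",
    "parse_tree",
    "load_grass_tree",
    "independent_contrasts",
    "contrast_regression",
    "simulate_brownian",
    "GRASS_TIPS",
]

#: Tip set of the packaged ten-taxon grass phylogeny.
GRASS_TIPS = frozenset(
    {
        "sorghum", "maize", "Z. luxurians", "foxtail millet", "pearl millet",
        "oat", "barley", "rye", "wheat", "rice",
    }
)


@dataclass
class PhyloNode:
    name: str | None = None
    branch_length: float | None = None  # None only at the root
    children: list["PhyloNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self):
        yield self
        for child in self.children:
            yield from child.preorder()

    def tip_names(self) -> list[str]:
        return [n.name for n in self.postorder() if n.is_leaf]


@dataclass
class PhyloTree:
    """Rooted tree with branch lengths; tips uniquely named."""

    root: PhyloNode

    def __post_init__(self) -> None:
        tips = self.tip_names
        if len(tips) != len(set(tips)):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise ValueError(f"duplicate tip names: {dupes}")
        for node in self.root.postorder():
            if node is self.root:
                continue
            if node.branch_length is None:
                raise ValueError("every non-root node needs a branch length")
            if node.branch_length < 0:
                raise ValueError(
                    f"negative branch length {node.branch_length} "
                    f"at {node.name or 'internal node'}"
                )
            if node.is_leaf and not node.name:
                raise ValueError("unnamed tip")

    @property
    def tip_names(self) -> list[str]:
        return self.root.tip_names()

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def is_bifurcating(self) -> bool:
        return all(
            len(n.children) == 2
            for n in self.root.postorder()
            if not n.is_leaf
        )

    def resolve_polytomies(self) -> "PhyloTree":
        """Return a copy with polytomies arbitrarily resolved into
        zero-length bifurcations (first-listed children grouped first)."""
        resolved = False

        def copy(node: PhyloNode) -> PhyloNode:
            nonlocal resolved
            kids = [copy(c) for c in node.children]
            while len(kids) > 2:
                resolved = True
                merged = PhyloNode(branch_length=0.0, children=kids[:2])
                kids = [merged] + kids[2:]
            return PhyloNode(
                name=node.name, branch_length=node.branch_length, children=kids
            )

        tree = PhyloTree(root=copy(self.root))
        if resolved:
            warnings.warn(
                "polytomies resolved arbitrarily into zero-length "
                "bifurcations",
                stacklevel=2,
            )
        return tree

    def to_newick(self) -> str:
        def quote(name: str) -> str:
            if re.fullmatch(r"[A-Za-z0-9_]+", name):
                return name
            return "'" + name.replace("'", "''") + "'"

        def fmt(node: PhyloNode) -> str:
            if node.is_leaf:
                s = quote(node.name)
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.name:
                    s += quote(node.name)
            if node.branch_length is not None:
                s += f":{node.branch_length!r}"
            return s

        return fmt(self.root) + ";"


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _check_balanced(text: str) -> None:
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(
                    f"unbalanced parentheses: unmatched ')' at position {pos}"
                )
    if depth != 0:
        raise ValueError(
            f"unbalanced parentheses: {depth} '(' left open at end of text"
        )


_DIALECT_LENGTH = re.compile(r",\s*(?=[0-9])")


def _looks_like_printed_dialect(text: str) -> bool:
    # the printed dialect attaches branch lengths with ", L" instead of ":L"
    return ":" not in text and bool(_DIALECT_LENGTH.search(text))


def normalize_printed_newick(text: str) -> str:
    """Rewrite the printed tree dialect into standard Newick.

    The dialect writes "name, length" for every branch, separates sister
    taxa with semicolons, and juxtaposes a clade after its sister's branch
    length with no separator at all.  Normalization: semicolons become the
    standard sibling commas, each remaining ", length" becomes ":length",
    and a comma is inserted between a branch length and a following "(".
    """
    s = text.strip()
    s = s.replace(";", "\x00")                 # sibling separators, temporarily
    s = _DIALECT_LENGTH.sub(":", s)            # "node, L" -> "node:L"
    s = re.sub(r"(\d)\s+\(", r"\1,(", s)       # juxtaposed sibling clades
    s = s.replace("\x00", ",")

    def _tidy_name(m: re.Match) -> str:
        name = m.group(1).strip()
        if re.fullmatch(r"[A-Za-z0-9_]+", name):
            return name
        return "'" + name.replace("'", "''") + "'"

    # trim whitespace around tip names; quote the multi-word ones
    s = re.sub(r"(?<=[(,])\s*([A-Za-z][A-Za-z. ']*)(?=:)", _tidy_name, s)
    if not s.endswith(";"):
        s += ";"
    return s


def parse_tree(text: str) -> PhyloTree:
    """Parse standard Newick, or the printed grass-tree dialect (detected by
    its ", length" branch annotations and normalized first)."""
    text = text.strip()
    if not text:
        raise ValueError("empty tree text")
    _check_balanced(text)
    if _looks_like_printed_dialect(text):
        text = normalize_printed_newick(text)
    if not text.endswith(";"):
        text += ";"
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"Newick parse failed: {exc}") from exc

    def convert(dnode) -> PhyloNode:
        name = dnode.taxon.label if dnode.taxon is not None else dnode.label
        return PhyloNode(
            name=name,
            branch_length=(
                float(dnode.edge.length)
                if dnode.edge.length is not None
                else None
            ),
            children=[convert(c) for c in dnode.child_nodes()],
        )

    root = convert(dtree.seed_node)
    root.branch_length = None  # a root edge carries no information here
    return PhyloTree(root=root)


def load_grass_tree(form: str = "printed") -> PhyloTree:
    """The packaged ten-taxon grass phylogeny (trnL-trnF branch lengths).

    ``form="printed"`` parses the verbatim printed dialect text;
    ``form="newick"`` parses the pre-normalized standard Newick file.  Both
    yield the same tree.
    """
    data = resources.files("cenarea.data")
    if form == "printed":
        text = data.joinpath("grass_tree_printed.txt").read_text()
    elif form == "newick":
        text = data.joinpath("grass_tree.nwk").read_text()
    else:
        raise ValueError(f"unknown form {form!r}")
    return parse_tree(text)


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contrast:
    """One independent contrast at an internal node.

    ``node_id`` is the sorted tuple of descendant tip names — a stable
    identifier shared between contrast sets computed on the same tree.
    """

    node_id: tuple[str, ...]
    raw_contrast: float
    standardized_contrast: float
    combined_variance: float


@dataclass
class ContrastSet:
    contrasts: list[Contrast]
    ancestral_values: dict[tuple[str, ...], float]
    adjusted_branch_lengths: dict[tuple[str, ...], float]

    def __len__(self) -> int:
        return len(self.contrasts)

    @property
    def standardized(self) -> np.ndarray:
        return np.array([c.standardized_contrast for c in self.contrasts])

    def by_node(self) -> dict[tuple[str, ...], Contrast]:
        return {c.node_id: c for c in self.contrasts}

    @property
    def root_value(self) -> float:
        root_id = max(self.ancestral_values, key=len)
        return self.ancestral_values[root_id]


def independent_contrasts(
    tree: PhyloTree, traits: dict[str, float]
) -> ContrastSet:
    """Felsenstein's pruning recursion over a bifurcating tree.

    Polytomies, if present, are first resolved into zero-length
    bifurcations (with a warning).  Every tip must have a trait value.
    """
    missing = [t for t in tree.tip_names if t not in traits]
    if missing:
        raise KeyError(f"traits missing for tips: {sorted(missing)}")
    if not tree.is_bifurcating():
        tree = tree.resolve_polytomies()

    contrasts: list[Contrast] = []
    ancestral: dict[tuple[str, ...], float] = {}
    adjusted: dict[tuple[str, ...], float] = {}

    def prune(node: PhyloNode) -> tuple[float, float, tuple[str, ...]]:
        """Return (trait value, adjusted branch length, node id)."""
        bl = node.branch_length if node.branch_length is not None else 0.0
        if node.is_leaf:
            return float(traits[node.name]), float(bl), (node.name,)
        (x1, v1, id1), (x2, v2, id2) = (prune(c) for c in node.children)
        node_id = tuple(sorted(id1 + id2))
        combined = v1 + v2
        if combined <= 0:
            raise ValueError(
                f"zero combined variance at node {node_id}; sister branches "
                "cannot both have zero length"
            )
        raw = x1 - x2
        contrasts.append(
            Contrast(
                node_id=node_id,
                raw_contrast=raw,
                standardized_contrast=raw / np.sqrt(combined),
                combined_variance=combined,
            )
        )
        # weighted ancestral value is safe even when one branch is zero
        anc = (x1 * v2 + x2 * v1) / combined
        extra = v1 * v2 / combined
        ancestral[node_id] = anc
        adjusted[node_id] = bl + extra
        return anc, bl + extra, node_id

    prune(tree.root)
    return ContrastSet(
        contrasts=contrasts,
        ancestral_values=ancestral,
        adjusted_branch_lengths=adjusted,
    )


def contrast_regression(
    contrasts_x: ContrastSet, contrasts_y: ContrastSet
) -> RegressionResult:
    """Regression of standardized y-contrasts on standardized x-contrasts
    through the origin, with each pair positivized on x.

    Both sets must come from the same tree (matching node ids); the slope
    test uses n_contrasts - 1 degrees of freedom.
    """
    by_x = contrasts_x.by_node()
    by_y = contrasts_y.by_node()
    if set(by_x) != set(by_y):
        raise ValueError(
            "contrast sets come from different trees (node ids differ)"
        )
    xs, ys = [], []
    for node_id in by_x:
        cx = by_x[node_id].standardized_contrast
        cy = by_y[node_id].standardized_contrast
        if cx < 0:
            cx, cy = -cx, -cy
        xs.append(cx)
        ys.append(cy)
    return fit_ols(xs, ys, fit_intercept=False)


# ---------------------------------------------------------------------------
# Brownian-motion simulation (test harness for the contrasts machinery)
# ---------------------------------------------------------------------------

def simulate_brownian(
    tree: PhyloTree,
    sigma2: float,
    root_value: float = 0.0,
    seed: int = 0,
    correlated_pair: tuple[float, float] | None = None,
):
    """Simulate Brownian trait evolution along the tree.

    Each branch adds a Normal(0, sigma2 * branch_length) increment.  With
    ``correlated_pair=(sigma2_y, correlation)`` a second trait is evolved
    with correlated increments and the function returns ``(traits_x,
    traits_y)``; otherwise a single ``{tip: value}`` map.  Deterministic
    for a fixed seed.
    """
    if not sigma2 > 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    bivariate = correlated_pair is not None
    if bivariate:
        sigma2_y, rho = correlated_pair
        if not sigma2_y > 0:
            raise ValueError(f"sigma2_y must be positive, got {sigma2_y}")
        if abs(rho) > 1:
            raise ValueError(f"|correlation| must be <= 1, got {rho}")
        cov = np.array(
            [
                [sigma2, rho * np.sqrt(sigma2 * sigma2_y)],
                [rho * np.sqrt(sigma2 * sigma2_y), sigma2_y],
            ]
        )
        chol = np.linalg.cholesky(cov + 1e-15 * np.eye(2))

    rng = np.random.default_rng(seed)
    traits_x: dict[str, float] = {}
    traits_y: dict[str, float] = {}

    def walk(node: PhyloNode, value) -> None:
        bl = node.branch_length if node.branch_length is not None else 0.0
        if bivariate:
            step = chol @ rng.standard_normal(2) * np.sqrt(bl)
            value = value + step
        else:
            value = value + rng.normal(0.0, np.sqrt(sigma2 * bl))
        if node.is_leaf:
            if bivariate:
                traits_x[node.name] = float(value[0])
                traits_y[node.name] = float(value[1])
            else:
                traits_x[node.name] = float(value)
            return
        for child in node.children:
            walk(child, value)

    start = (
        np.array([root_value, root_value]) if bivariate else float(root_value)
    )
    for child in tree.root.children:
        walk(child, start)
    if tree.root.is_leaf:  # degenerate single-tip tree
        walk(tree.root, start)

    return (traits_x, traits_y) if bivariate else traits_x
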