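"""Phylogenies and the covariance structures evolutionary models need.

A time-calibrated phylogeny induces a covariance structure on trait values at
its tips: under Brownian motion the covariance between two species is the
shared branch length from the root to their most recent common ancestor
(MRCA), and the variance of each species is its root-to-tip depth.  All the
trait models in this package (Pagel's lambda, Ornstein--Uhlenbeck, Early
Burst, star phylogeny) are expressed as transforms of that base matrix.

Newick I/O is delegated to :mod:`dendropy`; this module owns validation,
label normalization, pruning, and the covariance algebra.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "NewickParseError",
    "TreeValidationError",
    "ParameterError",
    "parse_newick",
    "write_newick",
    "phylo_vcv",
    "transform_covariance",
    "normalize_label",
]


class NewickParseError(ValueError):
    """Malformed Newick input; message names the offending character offset."""


class TreeValidationError(ValueError):
    """Structurally valid Newick that violates a phylogeny invariant."""


class ParameterError(ValueError):
    """Covariance-transform parameter outside its admissible range."""


def normalize_label(label: str) -> str:
    """Canonical form used to match tip labels to trait-table species.

    Trims, collapses runs of whitespace/underscores to one underscore, and
    lower-cases, so ``"Pan  troglodytes"`` and ``"pan_troglodytes"`` compare
    equal.
    """
    return re.sub(r"[\s_]+", "_", label.strip()).lower()


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths in millions of years.

    Thin wrapper around a :class:`dendropy.Tree` that enforces the invariants
    the downstream models rely on: a single root, nonnegative branch lengths,
    unique nonempty tip labels, and at least two tips.
    """

    _tree: dendropy.Tree
    metadata: dict = field(default_factory=dict)

    # -- construction ---------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, metadata: dict | None = None) -> "Phylogeny":
        obj = cls(_tree=tree, metadata=dict(metadata or {}))
        obj._validate()
        return obj

    def _validate(self) -> None:
        tips = self._tree.leaf_nodes()
        if len(tips) < 2:
            raise TreeValidationError(f"tree must have >= 2 tips, found {len(tips)}")
        labels = []
        for leaf in tips:
            if leaf.taxon is None or not (leaf.taxon.label or "").strip():
                raise TreeValidationError("tip with empty label")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            bl = node.edge.length
            if bl is None:
                raise TreeValidationError(
                    f"missing branch length above node {node.taxon.label if node.taxon else '<internal>'}"
                )
            if bl < 0:
                raise TreeValidationError(f"negative branch length {bl}")

    # -- basic structure ------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    @property
    def n_internal(self) -> int:
        return sum(1 for n in self._tree.preorder_node_iter() if not n.is_leaf())

    def node_depths(self) -> dict:
        """Root-to-node path length for every node (root has depth 0)."""
        depths = {}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    def tip_depths(self) -> dict[str, float]:
        depths = self.node_depths()
        return {n.taxon.label: d for n, d in depths.items() if n.is_leaf()}

    @property
    def depth(self) -> float:
        """Maximum root-to-tip path length (the age of the tree for an
        ultrametric chronogram)."""
        return max(self.tip_depths().values())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        """All tips equidistant from the root within relative tolerance.

        Dated consensus trees carry rounding error, so the check is on the
        relative spread of root-to-tip depths, not exact equality.
        """
        d = np.asarray(list(self.tip_depths().values()))
        if d.max() == 0:
            return True
        return (d.max() - d.min()) / d.max() <= rtol

    # -- matching / pruning ---------------------------------------------

    def match_species(self, species: Sequence[str]) -> dict[str, str]:
        """Map each requested species name to the tip label it matches.

        Matching is by :func:`normalize_label`.  Species absent from the tree
        are a hard error listing the offenders: silently dropping data hides
        data loss.
        """
        by_norm = {normalize_label(l): l for l in self.tip_labels}
        mapping, missing = {}, []
        for sp in species:
            tip = by_norm.get(normalize_label(sp))
            if tip is None:
                missing.append(sp)
            else:
                mapping[sp] = tip
        if missing:
            raise TreeValidationError(
                f"species not found in tree (after label normalization): {missing}"
            )
        return mapping

    def prune_to(self, species: Sequence[str]) -> "Phylogeny":
        """Restrict the tree to the given species (extra tips are removed).

        Missing species raise; extra tips are pruned and recorded in
        ``metadata['pruned_tips']``.
        """
        mapping = self.match_species(species)
        keep = set(mapping.values())
        dropped = [l for l in self.tip_labels if l not in keep]
        tree = self._tree.clone(depth=1)
        if dropped:
            taxa = [t for t in tree.taxon_namespace if t.label in keep]
            tree.retain_taxa(taxa)
        meta = dict(self.metadata)
        if dropped:
            meta["pruned_tips"] = dropped
        return Phylogeny.from_dendropy(tree, meta)

    def mrca_depth_matrix(self, order: Sequence[str]) -> np.ndarray:
        """Shared root-to-MRCA path length for every ordered tip pair."""
        idx = {normalize_label(l): i for i, l in enumerate(order)}
        n = len(order)
        out = np.zeros((n, n))
        depths = self.node_depths()
        # Postorder: each node knows which requested tips live below it; a
        # pair's MRCA is the first node uniting tips from different children.
        below: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                j = idx.get(normalize_label(node.taxon.label))
                below[node] = [j] if j is not None else []
                if j is not None:
                    out[j, j] = depths[node]
                continue
            kids = [below[c] for c in node.child_nodes()]
            merged: list[int] = []
            for k, tips_k in enumerate(kids):
                for other in kids[k + 1:]:
                    for a in tips_k:
                        for b in other:
                            out[a, b] = out[b, a] = depths[node]
                merged.extend(tips_k)
            below[node] = merged
        return out

    def clone(self) -> "Phylogeny":
        return Phylogeny.from_dendropy(self._tree.clone(depth=1), self.metadata)

    def to_dendropy(self) -> dendropy.Tree:
        return self._tree

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        ultra = "ultrametric" if self.is_ultrametric() else "non-ultrametric"
        return f"<Phylogeny {self.n_tips} tips, depth {self.depth:.4g} my, {ultra}>"


@dataclass
class PhyloCovariance:
    """Among-species covariance matrix under a named evolutionary model.

    ``matrix[i, j]`` is the model covariance between ``taxa[i]`` and
    ``taxa[j]``; for plain Brownian motion it equals the shared root-to-MRCA
    path length.  ``params`` records the transform parameters (lambda, alpha,
    r) so fits are auditable.
    """

    matrix: np.ndarray
    taxa: list[str]
    model: str = "BM"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance matrix must be square")
        if m.shape[0] != len(self.taxa):
            raise ValueError("matrix size does not match taxa")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
        if np.any(np.diag(m) <= 0):
            raise ValueError("covariance diagonal must be positive")
        self.matrix = m

    def reorder(self, order: Sequence[str]) -> "PhyloCovariance":
        pos = {t: i for i, t in enumerate(self.taxa)}
        ix = [pos[t] for t in order]
        return PhyloCovariance(self.matrix[np.ix_(ix, ix)], list(order), self.model, dict(self.params))


# -- Newick I/O ---------------------------------------------------------


def _check_parentheses(text: str) -> None:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(f"unbalanced ')' at character offset {i}")
    if depth != 0:
        raise NewickParseError(f"{depth} unclosed '(' in Newick string")


def parse_newick(text: str, metadata: dict | None = None) -> Phylogeny:
    """Parse a Newick string (standard dialect; ``[...]`` comments ignored).

    Raises :class:`NewickParseError` for syntax problems (naming the character
    offset for unbalanced parentheses) and :class:`TreeValidationError` for
    structural violations such as negative branch lengths.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick string")
    _check_parentheses(re.sub(r"\[[^\]]*\]", "", text))
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        if "uplicate" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return Phylogeny.from_dendropy(tree, metadata)


def read_newick(path, metadata: dict | None = None) -> Phylogeny:
    """Read the first tree from a Newick file."""
    with open(path) as fh:
        return parse_newick(fh.read(), metadata={"source": str(path), **(metadata or {})})


def write_newick(tree: Phylogeny, precision: int = 10) -> str:
    """Serialize to Newick; round-trips through :func:`parse_newick`."""
    s = tree.to_dendropy().as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=f".{precision}g",
    )
    return s.strip()


# -- covariance construction and transforms ------------------------------


def phylo_vcv(tree: Phylogeny, order: Sequence[str] | None = None) -> PhyloCovariance:
    """Brownian-motion covariance: shared root-to-MRCA path length per pair.

    The diagonal is each species' root-to-tip depth.  ``order`` fixes the
    species ordering of the matrix (defaults to tree tip order).
    """
    taxa = list(order) if order is not None else tree.tip_labels
    mapping = tree.match_species(taxa)
    C = tree.mrca_depth_matrix(taxa)
    return PhyloCovariance(C, [mapping[t] for t in taxa], "BM", {"lambda": 1.0})


def transform_covariance(C: PhyloCovariance, model: str, params: Mapping[str, float] | None = None) -> PhyloCovariance:
    """Reshape a BM covariance under a named trait-evolution model.

    model:
        ``"lambda"`` — Pagel's lambda: off-diagonals scaled by ``lam``
        (``lam=0`` is the star phylogeny, ``lam=1`` the identity transform);
        ``"star"`` — shorthand for ``lambda`` with ``lam=0``;
        ``"ou"`` — Ornstein--Uhlenbeck with fixed root (non-stationary form),
        scalar pull strength ``alpha``; requires an ultrametric base matrix;
        ``"eb"`` — Early Burst with rate decay ``r <= 0`` (``r -> 0`` limit
        is BM).
    """
    params = dict(params or {})
    t = C.matrix
    if model in ("lambda", "bm", "bm-lambda"):
        lam = float(params.get("lam", params.get("lambda", 1.0)))
        if not 0.0 <= lam <= 1.0:
            raise ParameterError(f"lambda must be in [0, 1], got {lam}")
        out = lam * t + (1 - lam) * np.diag(np.diag(t))
        return PhyloCovariance(out, C.taxa, "BM-lambda", {"lambda": lam})
    if model == "star":
        return PhyloCovariance(np.diag(np.diag(t)), C.taxa, "star", {"lambda": 0.0})
    if model == "ou":
        alpha = float(params["alpha"])
        if alpha <= 0:
            raise ParameterError(f"alpha must be > 0, got {alpha}")
        d = np.diag(t)
        if (d.max() - d.min()) / d.max() > 1e-6:
            raise ParameterError("OU transform (fixed-root form) requires an ultrametric tree")
        ti = d[:, None]
        tj = d[None, :]
        out = np.exp(-alpha * (ti + tj - 2 * t)) * (1 - np.exp(-2 * alpha * t)) / (2 * alpha)
        return PhyloCovariance(out, C.taxa, "OU", {"alpha": alpha})
    if model == "eb":
        r = float(params["r"])
        if r > 0:
            raise ParameterError(f"EB rate parameter must be <= 0, got {r}")
        if r == 0:
            out = t.copy()
        else:
            out = np.expm1(r * t) / r   # expm1 keeps the r -> 0 limit exact
        return PhyloCovariance(out, C.taxa, "EB", {"r": r})
    raise ParameterError(f"unknown covariance model {model!r}")
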