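"""Phylogeny handling: newick I/O, cophenetic distances, and covariances.

Trees are represented as :class:`skbio.TreeNode` objects.  This module adds
the validated entry points the rest of the package relies on, plus the
phylogenetic (Brownian-motion) covariance matrix and the Kronecker-product
interaction covariances used by the cophylogenetic GLMMs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "CovMatrix",
    "Tree",
    "parse_newick",
    "write_newick",
    "tip_labels",
    "tip_depths",
    "is_ultrametric",
    "cophenetic_distances",
    "phylo_covariance",
    "standardize_covariance",
    "kronecker_covariance",
]

Tree = TreeNode

#: relative tolerance for symmetry / positive-semidefiniteness checks
PSD_RTOL = 1e-8


@dataclass
class CovMatrix:
    """A labeled symmetric positive-semidefinite covariance matrix.

    ``labels`` may be plain strings or ``(row, col)`` pair-labels for
    Kronecker products.  Validation enforces symmetry, a strictly positive
    diagonal, and eigenvalues >= -PSD_RTOL * max eigenvalue.
    """

    labels: tuple
    values: np.ndarray
    _validated: bool = field(default=False, repr=False)

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self._validated:
            return
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"covariance shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("covariance labels must be unique")
        scale = np.abs(self.values).max() if n else 1.0
        if not np.allclose(self.values, self.values.T,
                           atol=PSD_RTOL * max(scale, 1.0)):
            raise ValueError("covariance matrix is not symmetric")
        if np.any(np.diag(self.values) <= 0):
            raise ValueError("covariance diagonal must be positive")
        eig = np.linalg.eigvalsh(self.values)
        if eig[0] < -PSD_RTOL * max(eig[-1], 1e-300):
            raise ValueError(
                f"covariance matrix is not PSD (min eigenvalue {eig[0]:g})"
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_tsv(self, path) -> None:
        import pandas as pd

        labels = ["|".join(l) if isinstance(l, tuple) else l
                  for l in self.labels]
        pd.DataFrame(self.values, index=labels, columns=labels).to_csv(
            path, sep="\t")


def parse_newick(text: str) -> TreeNode:
    """Parse a single newick statement into a rooted tree.

    Unlabeled internal nodes get generated ids and missing branch lengths
    default to 0.  Raises ``ValueError`` on malformed input, duplicate tip
    labels, or negative branch lengths.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("newick statement must end with ';'")
    if text.count("(") != text.count(")"):
        raise ValueError(
            f"unbalanced parentheses in newick: {text.count('(')} '(' vs "
            f"{text.count(')')} ')'")
    try:
        tree = TreeNode.read(io.StringIO(text))
    except Exception as exc:  # skbio raises format-specific errors
        raise ValueError(f"newick parse error: {exc}") from exc
    seen = set()
    n_internal = 0
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValueError(
                f"negative branch length {node.length} at {node.name!r}")
        if node.is_tip():
            if node.name is None:
                raise ValueError("unlabeled tip in newick input")
            if node.name in seen:
                raise ValueError(f"duplicate tip label {node.name!r}")
            seen.add(node.name)
        elif node.name is None:
            node.name = f"_node{n_internal}"
            n_internal += 1
    if len(seen) == 0:
        raise ValueError("tree has no tips")
    return tree


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to a canonical single-line newick string."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def tip_labels(tree: TreeNode) -> list[str]:
    return [t.name for t in tree.tips()]


def tip_depths(tree: TreeNode) -> dict[str, float]:
    """Root-to-tip path length for every tip."""
    depths = {}

    def walk(node, acc):
        acc = acc + (node.length or 0.0)
        if node.is_tip():
            depths[node.name] = acc
        else:
            for child in node.children:
                walk(child, acc)

    for child in tree.children:
        walk(child, 0.0)
    if tree.is_tip():  # degenerate single-node tree
        depths[tree.name] = tree.length or 0.0
    return depths


def is_ultrametric(tree: TreeNode, rtol: float = 1e-6) -> bool:
    d = np.array(list(tip_depths(tree).values()))
    span = d.max() - d.min()
    return span <= rtol * max(d.max(), 1e-300)


def cophenetic_distances(tree: TreeNode) -> DistanceMatrix:
    """Patristic (cophenetic) tip-to-tip distance matrix.

    d(i, j) is the sum of branch lengths on the path between tips i and j.
    """
    tips = tip_labels(tree)
    if len(tips) < 2:
        raise ValueError("cophenetic distances require >= 2 tips")
    return tree.tip_tip_distances()


def phylo_covariance(tree: TreeNode,
                     scale_unit_depth: bool = False) -> CovMatrix:
    """Brownian-motion covariance matrix implied by a tree.

    C(i, j) is the shared root-to-MRCA branch length of tips i and j and
    C(i, i) the root-to-tip depth.  With ``scale_unit_depth`` the matrix is
    divided by the tree height so the diagonal is 1; this requires an
    ultrametric tree.
    """
    tips = tip_labels(tree)
    if len(tips) < 2:
        raise ValueError("phylogenetic covariance requires >= 2 tips")
    depths = tip_depths(tree)
    dvec = np.array([depths[t] for t in tips])
    dm = tree.tip_tip_distances()
    order = [dm.index(t) for t in tips]
    dist = dm.data[np.ix_(order, order)]
    # shared path from root = (depth_i + depth_j - d_ij) / 2, valid for any
    # rooted tree with non-negative branch lengths
    cov = 0.5 * (dvec[:, None] + dvec[None, :] - dist)
    np.fill_diagonal(cov, dvec)
    cov = np.clip(cov, 0.0, None)
    if scale_unit_depth:
        if not is_ultrametric(tree):
            raise ValueError(
                "unit-depth scaling requires an ultrametric tree "
                "(tip depths differ by more than 1e-6 relative)")
        cov = cov / dvec.max()
    return CovMatrix(tuple(tips), cov)


def standardize_covariance(cov: CovMatrix) -> CovMatrix:
    """Rescale a covariance matrix to unit diagonal (correlation form)."""
    d = np.sqrt(np.diag(cov.values))
    vals = cov.values / np.outer(d, d)
    np.fill_diagonal(vals, 1.0)
    return CovMatrix(cov.labels, vals, _validated=True)


def kronecker_covariance(a: CovMatrix, b: CovMatrix) -> CovMatrix:
    """Kronecker product A (x) B with (a, b) pair labels, row-major in a.

    value[(i, j), (k, l)] = A[i, k] * B[j, l].  The label order (outer
    factor first) matches observation ordering in the GLMM design builder.
    """
    labels = tuple((la, lb) for la in a.labels for lb in b.labels)
    return CovMatrix(labels, np.kron(a.values, b.values), _validated=True)
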