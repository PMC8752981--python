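"""Similarity and hierarchical clustering of mutation signatures.

Signatures are compared by cosine similarity of their 96-channel profiles and
clustered agglomeratively on the distance 1 - cosine.  Inputs are ordered
lexicographically by name before linkage, so the merge tree is deterministic
under input permutation and renaming up to that tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from . import channels as ch
from .catalog import SignatureCatalog
from .errors import DimensionError, UndefinedSimilarityError


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two nonnegative profiles, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DimensionError("vectors differ in length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedSimilarityError("cosine undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def _as_profile_frame(signatures) -> pd.DataFrame:
    """Accept a SignatureCatalog, DataFrame, or name->vector mapping."""
    if isinstance(signatures, SignatureCatalog):
        return signatures.profiles
    if isinstance(signatures, pd.DataFrame):
        return signatures
    return pd.DataFrame({name: np.asarray(vec, dtype=float)
                         for name, vec in signatures.items()}).T


def similarity_matrix(signatures) -> pd.DataFrame:
    """Symmetric cosine-similarity matrix with unit diagonal."""
    prof = _as_profile_frame(signatures)
    if len(prof) < 2:
        raise DimensionError("need at least 2 signatures")
    X = prof.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        raise UndefinedSimilarityError("zero-norm signature in input")
    sim = (X @ X.T) / np.outer(norms, norms)
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(np.clip(sim, 0.0, 1.0), index=prof.index, columns=prof.index)


@dataclass
class ClusterResult:
    """Agglomerative merge tree over signatures.

    ``linkage`` is a scipy linkage matrix over ``names`` (lexicographically
    sorted leaf order used as input); ``leaf_order`` is the dendrogram leaf
    sequence.
    """

    names: list[str]
    linkage: np.ndarray
    leaf_order: list[str]

    def first_merge_partners(self, name: str) -> list[str]:
        """Members of the cluster that leaf ``name`` first merges with."""
        idx = self.names.index(name)
        n = len(self.names)
        for a, b, _h, _c in self.linkage:
            a, b = int(a), int(b)
            if a == idx or b == idx:
                other = b if a == idx else a
                return [self.names[i] for i in _cluster_members(self.linkage, n, other)]
        raise ValueError(f"{name!r} not found in merge tree")


def _cluster_members(link: np.ndarray, n: int, node: int) -> list[int]:
    if node < n:
        return [node]
    a, b = int(link[node - n, 0]), int(link[node - n, 1])
    return _cluster_members(link, n, a) + _cluster_members(link, n, b)


def hcluster(signatures, linkage_method: str = "average") -> ClusterResult:
    """Hierarchical clustering on distance 1 - cosine.

    ``linkage_method`` is ``average`` or ``complete``.
    """
    if linkage_method not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    prof = _as_profile_frame(signatures).sort_index()
    sim = similarity_matrix(prof)
    names = list(prof.index)
    dist = 1.0 - sim.to_numpy()
    n = len(names)
    condensed = dist[np.triu_indices(n, k=1)]
    link = hierarchy.linkage(condensed, method=linkage_method)
    order = [names[i] for i in hierarchy.leaves_list(link)]
    return ClusterResult(names=names, linkage=link, leaf_order=order)


def nearest_known(derived: np.ndarray, catalog: SignatureCatalog) -> tuple[str, float]:
    """Catalog signature most similar to a derived profile (ties: first name)."""
    sims = [(name, cosine_similarity(derived, catalog.profiles.loc[name].to_numpy()))
            for name in catalog.names]
    sims.sort(key=lambda t: (-t[1], t[0]))
    return sims[0]


def to_newick(result: ClusterResult) -> str:
    """Serialize the merge tree as a Newick string (heights as branch lengths)."""
    tree = hierarchy.to_tree(result.linkage)

    def build(node):
        if node.is_leaf():
            return result.names[node.id], 0.0
        (ls, lh), (rs, rh) = build(node.left), build(node.right)
        h = node.dist
        return f"({ls}:{max(h - lh, 0.0):.6f},{rs}:{max(h - rh, 0.0):.6f})", h

    s, _ = build(tree)
    return s + ";"
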