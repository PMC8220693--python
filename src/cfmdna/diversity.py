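"""Alpha diversity, beta-diversity distances and UPGMA clustering.

Distances are returned as :class:`skbio.DistanceMatrix` so they plug
directly into the permutation tests and clustering.  The study workflow
computes Bray-Curtis on rarefied, square-root-transformed counts and the
Aitchison distance on raw counts with a +1 offset; both presets are
provided as convenience wrappers.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .tables import AsvCountTable, rarefy, transform


def richness(sample_counts) -> int:
    """Number of observed ASVs (strictly positive entries)."""
    x = np.asarray(sample_counts)
    return int(np.count_nonzero(x > 0))


def inverse_simpson(sample_counts) -> float:
    """Inverse Simpson index 1 / sum(p_i^2)."""
    x = np.asarray(sample_counts, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("inverse Simpson undefined for an all-zero sample")
    p = x / total
    return float(1.0 / np.sum(p**2))


def alpha_diversity_frame(table: AsvCountTable) -> pd.DataFrame:
    """Richness and inverse Simpson per sample, as a DataFrame."""
    rec = {
        s: {
            "richness": richness(table.counts[s]),
            "inverse_simpson": inverse_simpson(table.counts[s]),
        }
        for s in table.sample_ids
    }
    return pd.DataFrame(rec).T.rename_axis("sample_id")


def _as_matrix(table) -> tuple[np.ndarray, list]:
    if isinstance(table, AsvCountTable):
        return table.matrix.astype(float), table.sample_ids
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), list(table.columns)
    raise TypeError("expected AsvCountTable or DataFrame (ASV x sample)")


def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i).  Input columns are samples;
    values must be non-negative (counts or transformed abundances).
    """
    m, ids = _as_matrix(table)
    if np.any(m < 0):
        raise ValueError("Bray-Curtis requires non-negative input")
    if np.any(m.sum(axis=0) == 0):
        raise ValueError("all-zero sample in Bray-Curtis input")
    d = squareform(pdist(m.T, metric="braycurtis"))
    return DistanceMatrix(d, ids)


def aitchison(table: AsvCountTable, offset: float = 1.0) -> DistanceMatrix:
    """Aitchison distance: Euclidean distance of CLR-transformed counts.

    The offset is added to raw counts before the CLR so zeros are defined;
    the study convention is non-rarefied counts with offset 1.
    """
    clr = transform(table, "clr", offset=offset)
    d = squareform(pdist(clr.to_numpy().T, metric="euclidean"))
    return DistanceMatrix(d, table.sample_ids)


def bray_curtis_pipeline(table: AsvCountTable, depth: int | None = None, seed: int = 0) -> DistanceMatrix:
    """Study preset: rarefy to the minimum library size, sqrt-transform,
    then Bray-Curtis."""
    if depth is None:
        depth = int(table.library_sizes().min())
    rare = rarefy(table, depth, seed)
    return bray_curtis(transform(rare, "sqrt"))


def upgma(dist: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) hierarchical clustering of a distance matrix.

    Returns a rooted ultrametric tree whose root-to-leaf depth equals half
    the cophenetic distance.  Ties in the minimal linkage distance are
    broken by cluster creation order (deterministic for a fixed input).
    """
    if dist.shape[0] < 2:
        raise ValueError("UPGMA needs at least two samples")
    data = dist.condensed_form()
    if np.any(~np.isfinite(data)):
        raise ValueError("NaN/inf in distance matrix")
    ids = list(dist.ids)
    z = linkage(data, method="average")
    # Build newick with ultrametric heights (merge height / 2).
    n = len(ids)

    def quote(name: str) -> str:
        return "'" + str(name).replace("'", "''") + "'"

    nodes: dict[int, tuple[str, float]] = {i: (quote(ids[i]), 0.0) for i in range(n)}
    for k, (a, b, h, _cnt) in enumerate(z):
        height = h / 2.0
        (na, ha), (nb, hb) = nodes.pop(int(a)), nodes.pop(int(b))
        newick = f"({na}:{height - ha:.10g},{nb}:{height - hb:.10g})"
        nodes[n + k] = (newick, height)
    _, (newick, _height) = nodes.popitem()
    return TreeNode.read(io.StringIO(newick + ";"))


def is_ultrametric(tree: TreeNode, tol: float = 1e-9) -> bool:
    depths = [tree.distance(tip) for tip in tree.tips()]
    return max(depths) - min(depths) <= tol


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    pd.DataFrame(dist.data, index=dist.ids, columns=dist.ids).rename_axis(
        "sample_id"
    ).to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), list(df.index))
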