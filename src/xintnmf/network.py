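"""Block feature-feature interaction network over all omics layers.

The all-omics adjacency A is a symmetric binary M x M matrix partitioned into
D x D blocks A(pq), one per ordered layer pair.  Blocks come either from prior
knowledge (e.g. a miRNA-mRNA target edge list) or are computed from the data:
the absolute Pearson correlation between every feature of layer p and every
feature of layer q is thresholded by *density matching* — the top entries are
kept so that the computed block reaches the mean edge density of the supplied
prior blocks.

From A the symmetrically normalized adjacency Ã = Δ^{-1/2} A Δ^{-1/2} and the
normalized graph Laplacian L = I − Ã are derived; the quadratic form
Tr(W̄ᵀLW̄) is the network regularizer of the factorization objective.
Isolated (zero-degree) features get a 0 entry in Δ^{-1/2}, so their rows of Ã
are zero and L has a bare 1 on their diagonal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .data_model import MultiOmicsDataset, OmicsLayer

logger = logging.getLogger("xintnmf")

__all__ = [
    "BlockInteractionNetwork",
    "block_from_prior",
    "block_from_correlation",
    "assemble",
    "laplacian_quadratic",
]


@dataclass
class BlockInteractionNetwork:
    """Assembled block network with its normalized form and Laplacian.

    ``block_index`` maps each layer_id to its (offset, size) slab on the
    feature axis of A, matching the row blocks of the stacked factor matrix.
    """

    layer_ids: list[str]
    block_index: dict[str, tuple[int, int]]
    adjacency: sp.csr_matrix  # binary, symmetric, zero diagonal
    normalized: sp.csr_matrix  # Ã = Δ^{-1/2} A Δ^{-1/2}
    degree: np.ndarray  # row sums of A

    @property
    def M(self) -> int:
        return self.adjacency.shape[0]

    @property
    def laplacian(self) -> sp.csr_matrix:
        """L = I − Ã (materialized on demand)."""
        return (sp.eye(self.M, format="csr") - self.normalized).tocsr()

    def block_slice(self, layer_id: str) -> slice:
        off, size = self.block_index[layer_id]
        return slice(off, off + size)

    def block(self, layer_p: str, layer_q: str) -> sp.csr_matrix:
        return self.adjacency[self.block_slice(layer_p), :][:, self.block_slice(layer_q)]


def block_from_prior(
    edges: Sequence[tuple[str, str]],
    layer_p: OmicsLayer,
    layer_q: OmicsLayer,
) -> sp.coo_matrix:
    """Binary m_p x m_q block from an edge list of feature-ID pairs.

    Pairs with an unresolvable endpoint are skipped (count logged).  For an
    intra-layer block (p is q) the result is symmetrized with zero diagonal.
    """
    intra = layer_p.layer_id == layer_q.layer_id
    pos_p = {f: i for i, f in enumerate(layer_p.feature_ids)}
    pos_q = pos_p if intra else {f: i for i, f in enumerate(layer_q.feature_ids)}
    rows, cols = [], []
    skipped = 0
    for a, b in edges:
        hit = False
        if a in pos_p and b in pos_q:
            rows.append(pos_p[a])
            cols.append(pos_q[b])
            hit = True
        # cross-layer edge lists need not be oriented (p-feature, q-feature)
        if not intra and b in pos_p and a in pos_q:
            rows.append(pos_p[b])
            cols.append(pos_q[a])
            hit = True
        if not hit:
            skipped += 1
    if skipped:
        logger.info(
            "block (%s,%s): skipped %d/%d unresolvable edges",
            layer_p.layer_id, layer_q.layer_id, skipped, len(edges),
        )
    if edges and not rows:
        warnings.warn(
            f"block ({layer_p.layer_id},{layer_q.layer_id}): no edge resolved; "
            "using an empty block",
            stacklevel=2,
        )
    shape = (layer_p.n_features, layer_q.n_features)
    block = sp.coo_matrix(
        (np.ones(len(rows)), (np.array(rows, dtype=int), np.array(cols, dtype=int))),
        shape=shape,
    ).tocsr()
    if intra:
        block = block.maximum(block.T)
        block.setdiag(0)
        block.eliminate_zeros()
    block.data[:] = 1.0  # collapse duplicate triplets
    return block.tocoo()


def _abs_pcc(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """|Pearson correlation| between every row of X and every row of Y.

    Constant rows get correlation 0 (no linear association defined).
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((Yc**2).sum(axis=1))
    denom = np.outer(sx, sy)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.abs(Xc @ Yc.T) / denom
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, 0.0, 1.0)


def block_from_correlation(
    layer_p: OmicsLayer,
    layer_q: OmicsLayer,
    target_density: float,
) -> sp.coo_matrix:
    """Data-driven block: |PCC| across shared samples, thresholded to density.

    Keeps the top ``round(target_density * possible_entries)`` entries ranked
    by |PCC| (ties broken first-come in row-major order).  For an intra-layer
    block the ranking runs over the off-diagonal upper triangle and the result
    is mirrored.
    """
    if not 0 < target_density < 1:
        raise ValueError("target_density must lie in (0, 1)")
    if layer_p.n_samples < 3:
        raise ValueError("need at least 3 shared samples for correlation")
    intra = layer_p.layer_id == layer_q.layer_id
    r = _abs_pcc(layer_p.values, layer_q.values)
    m_p, m_q = r.shape

    if intra:
        iu, ju = np.triu_indices(m_p, k=1)
        vals = r[iu, ju]
        k = int(round(target_density * m_p * (m_p - 1) / 2))
    else:
        iu, ju = np.unravel_index(np.arange(m_p * m_q), (m_p, m_q))
        vals = r.ravel()
        k = int(round(target_density * m_p * m_q))

    if k == 0:
        warnings.warn(
            f"target_density {target_density} yields 0 edges for block "
            f"({layer_p.layer_id},{layer_q.layer_id})",
            stacklevel=2,
        )
        return sp.coo_matrix((m_p, m_q))
    top = np.argsort(-vals, kind="stable")[:k]
    rows, cols = iu[top], ju[top]
    block = sp.coo_matrix((np.ones(k), (rows, cols)), shape=(m_p, m_q))
    if intra:
        block = block + block.T
    return block.tocoo()


def _block_density(block: sp.spmatrix, intra: bool) -> float:
    m_p, m_q = block.shape
    ones = block.nnz
    possible = m_p * (m_p - 1) if intra else m_p * m_q
    return ones / possible if possible else 0.0


def _cache_key(layer_p: OmicsLayer, layer_q: OmicsLayer, target: float) -> str:
    import hashlib

    h = hashlib.sha256()
    for layer in (layer_p, layer_q):
        h.update(layer.layer_id.encode())
        h.update("\0".join(layer.feature_ids).encode())
        h.update(np.ascontiguousarray(layer.values).tobytes())
    h.update(f"{target:.12g}".encode())
    return h.hexdigest()[:24]


def _cache_load(path) -> sp.coo_matrix | None:
    try:
        trip = np.loadtxt(path, dtype=int, ndmin=2)
    except OSError:
        return None
    shape = tuple(trip[0])
    rows, cols = (trip[1:, 0], trip[1:, 1]) if trip.shape[0] > 1 else ([], [])
    return sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=shape)


def _cache_store(path, block: sp.coo_matrix) -> None:
    block = block.tocoo()
    trip = np.vstack([[block.shape[0], block.shape[1]], np.column_stack([block.row, block.col])]) \
        if block.nnz else np.array([[block.shape[0], block.shape[1]]])
    np.savetxt(path, trip, fmt="%d")


def assemble(
    dataset: MultiOmicsDataset,
    prior_blocks: Mapping[tuple[str, str], Sequence[tuple[str, str]]] | None = None,
    fallback_density: float | None = None,
    cache_dir: str | None = None,
) -> BlockInteractionNetwork:
    """Build the full block network A, its normalization Ã and degrees.

    Layer pairs with a supplied prior edge list use it directly; all other
    pairs are computed from |PCC| at a target density equal to the mean
    density of the prior blocks (or ``fallback_density`` when no prior block
    exists — required in that case).  A is symmetrized with zero diagonal.

    ``cache_dir`` caches computed |PCC| blocks as sparse triplet files keyed
    by a content hash of the two layers and the target density — recomputing
    correlations for large blocks is the dominant assembly cost.
    """
    prior_blocks = dict(prior_blocks or {})
    layers = {l.layer_id: l for l in dataset.layers}
    ids = dataset.layer_ids

    offsets: dict[str, tuple[int, int]] = {}
    off = 0
    for l in dataset.layers:
        offsets[l.layer_id] = (off, l.n_features)
        off += l.n_features

    # resolve prior blocks first (canonical unordered pair key)
    built: dict[tuple[str, str], sp.spmatrix] = {}
    densities = []
    for (p, q), edges in prior_blocks.items():
        if p not in layers or q not in layers:
            raise KeyError(f"prior block references unknown layer pair ({p},{q})")
        key = (p, q) if ids.index(p) <= ids.index(q) else (q, p)
        blk = block_from_prior(edges, layers[key[0]], layers[key[1]])
        built[key] = blk
        densities.append(_block_density(blk, intra=key[0] == key[1]))

    if densities:
        target = float(np.mean(densities))
    elif fallback_density is not None:
        target = float(fallback_density)
    else:
        raise ValueError(
            "no prior blocks supplied and no fallback_density given; "
            "one of the two is required"
        )

    for a in range(len(ids)):
        for b in range(a, len(ids)):
            key = (ids[a], ids[b])
            if key in built:
                continue
            if target <= 0:
                built[key] = sp.coo_matrix(
                    (layers[key[0]].n_features, layers[key[1]].n_features)
                )
                continue
            lp, lq = layers[key[0]], layers[key[1]]
            if cache_dir is not None:
                from pathlib import Path

                cpath = Path(cache_dir) / f"pcc_block_{_cache_key(lp, lq, target)}.tsv"
                cached = _cache_load(cpath)
                if cached is not None:
                    built[key] = cached
                    continue
                Path(cache_dir).mkdir(parents=True, exist_ok=True)
                block = block_from_correlation(lp, lq, target)
                _cache_store(cpath, block)
                built[key] = block
            else:
                built[key] = block_from_correlation(lp, lq, target)

    grid = [[None] * len(ids) for _ in range(len(ids))]
    for a, p in enumerate(ids):
        for b, q in enumerate(ids):
            if a <= b:
                grid[a][b] = built[(p, q)]
            else:
                grid[a][b] = built[(q, p)].T
    A = sp.bmat(grid, format="csr")
    A = A.maximum(A.T)
    A.setdiag(0)
    A.eliminate_zeros()
    if A.nnz:
        A.data[:] = 1.0

    degree = np.asarray(A.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = 1.0 / np.sqrt(degree)
    inv_sqrt[degree == 0] = 0.0  # isolated features: zero rows in Ã
    Dinv = sp.diags(inv_sqrt)
    normalized = (Dinv @ A @ Dinv).tocsr()

    return BlockInteractionNetwork(
        layer_ids=list(ids),
        block_index=offsets,
        adjacency=A,
        normalized=normalized,
        degree=degree,
    )


def laplacian_quadratic(network: BlockInteractionNetwork, Wbar: np.ndarray) -> float:
    """Tr(W̄ᵀ L W̄) for a stacked M x K factor matrix; always ≥ 0 up to tolerance."""
    Wbar = np.asarray(Wbar, dtype=float)
    if Wbar.shape[0] != network.M:
        raise ValueError(
            f"stacked factor matrix has {Wbar.shape[0]} rows, network has {network.M} features"
        )
    # Tr(W̄ᵀ(I − Ã)W̄) without materializing L
    return float((Wbar * Wbar).sum() - (Wbar * (network.normalized @ Wbar)).sum())
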