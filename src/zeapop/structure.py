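"""Relationship visualization inputs and the group-assignment rule.

PCA on a standardized-genotype relationship matrix, identity-by-state
distances, a neighbor-joining tree rooted on an outgroup, and the membership
threshold rule that turns a structure Q-matrix into discrete group labels.
The model-based clustering itself (ADMIXTURE) is an input, not reimplemented.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


def _standardized_genotypes(gm: GenotypeMatrix) -> np.ndarray:
    """Mean-impute missing dosages, center by 2p, scale by sqrt(2p(1-p)).

    Zero-variance SNPs are excluded automatically.
    """
    X = gm.dosage.astype(np.float64)
    p = np.nanmean(X, axis=0) / 2.0
    mu = 2.0 * p
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu, inds[1])
    var = 2.0 * p * (1.0 - p)
    keep = var > 1e-12
    if not np.all(keep):
        logger.info("excluding %d zero-variance SNPs", int(np.sum(~keep)))
    X = (X[:, keep] - mu[keep]) / np.sqrt(var[keep])
    return X


def grm(gm: GenotypeMatrix) -> np.ndarray:
    """Standardized genomic relationship matrix, cross-product / n_SNPs."""
    X = _standardized_genotypes(gm)
    return X @ X.T / X.shape[1]


def grm_pca(gm: GenotypeMatrix, n_components: int = 3) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the genomic relationship matrix.

    Returns sample coordinates (eigenvectors scaled by sqrt(eigenvalue)) and
    the non-increasing eigenvalues of the GRM.
    """
    if gm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    K = grm(gm)
    evals, evecs = np.linalg.eigh(K)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = min(n_components, len(evals))
    coords = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    df = pd.DataFrame(coords, index=gm.samples,
                      columns=[f"PC{i + 1}" for i in range(k)])
    return df, evals


def ibs_distance(gm: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise identity-by-state distance, 1 - (mean shared alleles / 2).

    Shared alleles at a SNP equal ``2 - |d_i - d_j|``; the mean runs over
    mutually non-missing SNPs.  Raises if a pair shares no called SNP.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    D = gm.dosage.astype(np.float64)
    valid = ~np.isnan(D)
    # |d_i - d_j| summed over shared SNPs via indicator cross-products
    I = [np.where(valid & (np.nan_to_num(D, nan=-1.0) == v), 1.0, 0.0)
         for v in (0.0, 1.0, 2.0)]
    n_shared = (valid.astype(np.float64)) @ valid.astype(np.float64).T
    if np.any(n_shared == 0):
        raise ValueError("at least one sample pair shares no called SNPs")
    absdiff = 2.0 * (I[0] @ I[2].T + I[2] @ I[0].T) \
        + (I[1] @ (I[0] + I[2]).T + (I[0] + I[2]) @ I[1].T)
    dist = 1.0 - (2.0 * n_shared - absdiff) / (2.0 * n_shared)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return pd.DataFrame(dist, index=gm.samples, columns=gm.samples)


def nj_tree(dm: pd.DataFrame, outgroup: str | None = None) -> str:
    """Saitou–Nei neighbor joining; returns a Newick string.

    Negative branch lengths are clamped to zero.  With an outgroup the tree
    is rooted at the midpoint of the outgroup's pendant edge.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj as _nj

    taxa = list(dm.index)
    if len(taxa) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if outgroup is not None and outgroup not in taxa:
        raise KeyError(f"outgroup {outgroup!r} not among taxa")
    sk_dm = DistanceMatrix(dm.to_numpy(), ids=[str(t) for t in taxa])
    tree = _nj(sk_dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            logger.info("clamping negative branch length %.4g at %s",
                        node.length, node.name)
            node.length = 0.0
    newick = str(tree).strip()
    if outgroup is None:
        return newick

    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick")
    node = t.find_node_with_taxon_label(str(outgroup))
    edge_len = node.edge.length or 0.0
    t.reroot_at_edge(node.edge, length1=edge_len / 2.0, length2=edge_len / 2.0,
                     update_bipartitions=True)
    return t.as_string(schema="newick", suppress_rooting=True).strip()


def assign_groups(q: pd.DataFrame, threshold: float = 0.70,
                  mixed_label: str = "Mix") -> pd.Series:
    """Assign each sample to the cluster where its membership >= threshold.

    Samples reaching the threshold in no cluster get ``mixed_label``.  The
    boundary is inclusive.  Ties (possible only when threshold <= 0.5) break
    to the lowest cluster index and are logged.
    """
    arr = q.to_numpy(dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("memberships must lie in [0, 1]")
    if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("membership rows must sum to 1 within 1e-6")
    if threshold <= 0.5 and q.shape[1] > 2:
        warnings.warn("threshold <= 0.5 with >2 clusters can produce ties",
                      UserWarning, stacklevel=2)
    labels = []
    for i, row in enumerate(arr):
        hits = np.flatnonzero(row >= threshold)
        if hits.size == 0:
            labels.append(mixed_label)
        else:
            if hits.size > 1:
                logger.info("sample %s: several clusters reach the threshold; "
                            "taking the largest (ties to lowest index)", q.index[i])
            best = hits[np.argmax(row[hits])]  # argmax ties break low
            labels.append(str(q.columns[best]))
    return pd.Series(labels, index=q.index, name="group")
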