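"""Community diversity: inverse Simpson, rank collapse, UniFrac, PCoA, and
covariate-adjusted PERMANOVA.

UniFrac and classical PCoA are delegated to scikit-bio. PERMANOVA is
implemented here because covariates must be adjusted for by sequential
sums of squares (covariates entered before the grouping factor), which the
stock implementations do not provide: with Gower-centered matrix
``G = -1/2 J D^2 J`` and hat matrices ``H_cov`` (intercept + covariates)
and ``H_full`` (+ group dummies),

    pseudo-F = [ (tr(H_full G) - tr(H_cov G)) / df_group ]
             / [ (tr(G) - tr(H_full G)) / df_residual ]

and the p-value is ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)`` under random
relabeling of the samples (rows/columns of G permuted jointly against the
fixed design).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio import TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .errors import ParameterError, ValidationError
from .io import RANKS, CountTable, SampleTable, TaxonomyTable


def inverse_simpson(counts, relative: bool = False) -> float:
    """Inverse Simpson index 1/sum(p_i^2): the effective number of equally
    abundant taxa. With ``relative=True`` the index is divided by the
    observed richness, giving an evenness measure in (0, 1]."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("inverse Simpson is undefined for an all-zero sample")
    p = counts / total
    value = 1.0 / np.sum(p**2)
    if relative:
        value /= np.count_nonzero(counts)
    return float(value)


def alpha_diversity_table(table: CountTable) -> pd.DataFrame:
    """Both inverse-Simpson columns for every sample."""
    rows = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        rows.append(
            {
                "sample_id": sid,
                "inverse_simpson": inverse_simpson(col),
                "relative_inverse_simpson": inverse_simpson(col, relative=True),
            }
        )
    return pd.DataFrame(rows)


def collapse_rank(table: CountTable, taxonomy: TaxonomyTable, rank: str) -> CountTable:
    """Sum counts over taxa sharing the lineage down to ``rank``.

    Taxa unclassified at the rank are pooled into one ``unclassified``
    bucket per parent lineage. Row identifiers of the result are the
    semicolon-joined lineage prefixes.
    """
    if rank not in RANKS:
        raise ParameterError(f"rank must be one of {RANKS}, got {rank!r}")
    depth = RANKS.index(rank) + 1
    groups: dict[str, np.ndarray] = {}
    order: list[str] = []
    for i, taxon in enumerate(table.taxon_ids):
        lineage = list(taxonomy.lineage(taxon)[:depth])
        if not lineage[-1]:
            lineage[-1] = "unclassified"
        key = ";".join(lineage)
        if key not in groups:
            groups[key] = np.zeros(table.n_samples, dtype=np.int64)
            order.append(key)
        groups[key] += table.counts[i]
    counts = np.vstack([groups[k] for k in order]) if order else np.empty((0, table.n_samples), dtype=np.int64)
    return CountTable(order, list(table.sample_ids), counts)


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distances with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValidationError("distance matrix shape does not match sample_ids")
        if not np.allclose(values, values.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0):
            raise ValidationError("distance matrix must have a zero diagonal")
        if not np.isfinite(values).all():
            raise ValidationError("distance matrix entries must be finite")
        self.values = values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def subset(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)])


def unifrac(table: CountTable, tree: TreeNode, weighted: bool = False) -> DistanceMatrix:
    """UniFrac distances between all sample pairs.

    Unweighted: fraction of the branch length of the union of the two
    communities that is unique to one of them. Weighted: the normalized
    abundance-weighted form (both lie in [0, 1]).
    """
    leaves = {leaf.name for leaf in tree.tips()}
    nonzero = table.counts.sum(axis=1) > 0
    offenders = [t for t, nz in zip(table.taxon_ids, nonzero) if nz and t not in leaves]
    if offenders:
        raise ValidationError(f"taxa absent from tree: {offenders[:10]}")
    if any(node.length is None for node in tree.traverse() if not node.is_root()):
        raise ValidationError("tree has nodes without branch lengths; UniFrac undefined")
    keep = [i for i, t in enumerate(table.taxon_ids) if t in leaves]
    matrix = table.counts[keep].T  # samples x taxa
    taxa = [table.taxon_ids[i] for i in keep]
    # validation is done above; skbio's own check would also reject the
    # legitimate multifurcating-root (star) case
    if weighted:
        dm = beta_diversity(
            "weighted_unifrac", matrix, ids=table.sample_ids, taxa=taxa, tree=tree,
            normalized=True, validate=False,
        )
    else:
        dm = beta_diversity(
            "unweighted_unifrac", matrix, ids=table.sample_ids, taxa=taxa, tree=tree,
            validate=False,
        )
    return DistanceMatrix(list(dm.ids), dm.data)


def pcoa(dm: DistanceMatrix, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical scaling of the distance matrix.

    Returns (coordinates [samples x k], eigenvalues). All eigenvalues are
    returned (negative ones included, for inspection); coordinate axes are
    only produced for positive eigenvalues, ordered decreasingly, and ``k``
    is capped at the count of positive eigenvalues.
    """
    n = len(dm.sample_ids)
    if k > n - 1:
        raise ParameterError(f"k must be <= n_samples - 1 = {n - 1}")
    result = _skbio_pcoa(SkbioDistanceMatrix(dm.values, ids=dm.sample_ids), method="eigh")
    eigvals = result.eigvals.to_numpy()
    coords = result.samples.to_numpy()
    positive = eigvals > max(eigvals.max(), 0) * 1e-12
    coords = coords[:, positive]
    k_eff = min(k, coords.shape[1])
    return coords[:, :k_eff], eigvals


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    terms: list[str]
    df_group: int
    df_residual: int

    def __post_init__(self) -> None:
        if self.p_value < 1.0 / (self.n_permutations + 1) - 1e-12:
            raise ValidationError("p-value below the attainable minimum")


def _hat(design: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(design)
    rank = np.linalg.matrix_rank(design)
    q = q[:, :rank]
    return q @ q.T


def permanova(
    dm: DistanceMatrix,
    samples: SampleTable,
    group_var: str,
    covariates: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational MANOVA of ``group_var`` on the distance matrix,
    adjusting for ``covariates`` by sequential sums of squares."""
    covariates = covariates or []
    meta = samples.data.loc[dm.sample_ids]
    labels = meta[group_var].astype(str)
    levels = labels.unique()
    if len(levels) < 2:
        raise ValidationError(f"group variable {group_var!r} needs >= 2 levels")
    if (labels.value_counts() < 2).any():
        raise ValidationError("every group level needs >= 2 samples")
    n = len(dm.sample_ids)

    d2 = dm.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j

    intercept = np.ones((n, 1))
    x_cov = [intercept]
    for cov in covariates:
        col = meta[cov]
        if col.dtype == object:
            x_cov.append(pd.get_dummies(col, drop_first=True).to_numpy(dtype=float))
        else:
            x_cov.append(col.to_numpy(dtype=float).reshape(-1, 1))
    x_cov = np.hstack(x_cov)
    dummies = pd.get_dummies(labels, drop_first=True).to_numpy(dtype=float)
    x_full = np.hstack([x_cov, dummies])

    h_cov = _hat(x_cov)
    h_full = _hat(x_full)
    df_group = np.linalg.matrix_rank(x_full) - np.linalg.matrix_rank(x_cov)
    df_resid = n - np.linalg.matrix_rank(x_full)
    h_delta = h_full - h_cov
    h_resid = np.eye(n) - h_full

    def pseudo_f(gmat: np.ndarray) -> float:
        ss_group = float(np.sum(h_delta * gmat.T))
        ss_resid = float(np.sum(h_resid * gmat.T))
        return (ss_group / df_group) / (ss_resid / df_resid)

    f_obs = pseudo_f(g)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    g_perm = g[perms[:, :, None], perms[:, None, :]]
    f_perm = np.einsum("ij,pji->p", h_delta, g_perm) / df_group
    f_perm /= np.einsum("ij,pji->p", h_resid, g_perm) / df_resid
    p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_perm)
    return PermanovaResult(
        pseudo_F=f_obs,
        p_value=float(p),
        n_permutations=n_perm,
        terms=list(covariates),
        df_group=int(df_group),
        df_residual=int(df_resid),
    )
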