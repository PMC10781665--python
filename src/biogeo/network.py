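"""Compositionally robust taxon-taxon correlation networks.

SparCC estimates linear (basis) correlations between taxa from compositional
count data: with fractions x_i, the pairwise log-ratio variances
``t_ij = var(log(x_i / x_j))`` relate to the latent basis variances
``omega_i`` by ``t_ij = omega_i + omega_j - 2 rho_ij sqrt(omega_i omega_j)``.
Under a sparsity assumption (most correlations near zero) the basis
variances solve the linear system ``(d_i) omega_i + sum_j omega_j = T_i``
over non-excluded pairs, and ``rho_ij = (omega_i + omega_j - t_ij) /
(2 sqrt(omega_i omega_j))`` clipped to [-1, 1]. Strongly correlated pairs
violate the sparsity assumption, so the strongest pair above a threshold is
iteratively excluded from the system and the variances re-solved. Counts
are converted to fractions by Dirichlet resampling with +1 pseudocounts;
the reported matrix is the median over resamples, and pseudo p-values come
from permutation of each taxon's samples.

Downstream, edges are kept per organ only when significant (BH FDR) with a
consistent correlation sign across all the organ's sites, and annotated as
organ-specific by the difference (>0.6 against every other organ carrying
the edge) or unique-strength (>0.6, present in this organ only) rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ValidationError
from .io import CountTable, SampleTable


@dataclass
class SparccConfig:
    n_dirichlet_resamples: int = 20
    n_exclusion_iterations: int = 10
    exclusion_threshold: float = 0.1
    n_permutations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_dirichlet_resamples", "n_exclusion_iterations", "n_permutations"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if not 0 < self.exclusion_threshold < 1:
            raise ParameterError("exclusion_threshold must be in (0, 1)")


def _logratio_variances(fractions: np.ndarray) -> np.ndarray:
    """t_ij = var(log(x_i/x_j)) for taxa x samples fractions."""
    logf = np.log(fractions)
    cov = np.cov(logf)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2.0 * cov


def solve_basis_variances(t: np.ndarray, excluded: np.ndarray | None = None) -> np.ndarray:
    """Solve the SparCC basis-variance linear system.

    ``excluded`` is a boolean matrix of pairs dropped from the sums (the
    iterative exclusion of strongly correlated pairs). Raises on a singular
    system (e.g. a taxon left with no usable pairs).
    """
    d = t.shape[0]
    include = np.ones((d, d), dtype=bool)
    np.fill_diagonal(include, False)
    if excluded is not None:
        include &= ~excluded
    degrees = include.sum(axis=1)
    if (degrees == 0).any():
        raise np.linalg.LinAlgError("taxon with all pairs excluded")
    m = include.astype(float)
    m[np.diag_indices(d)] = degrees
    rhs = np.where(include, t, 0.0).sum(axis=1)
    return np.linalg.solve(m, rhs)


def _basis_correlations(t: np.ndarray, omega: np.ndarray) -> np.ndarray:
    omega_pos = np.clip(omega, 1e-12, None)
    denom = 2.0 * np.sqrt(np.outer(omega_pos, omega_pos))
    rho = (omega_pos[:, None] + omega_pos[None, :] - t) / denom
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _sparcc_once(
    fractions: np.ndarray, n_iter: int, threshold: float
) -> np.ndarray:
    """One SparCC pass: solve, then iteratively exclude the strongest
    above-threshold pair and re-solve."""
    d = fractions.shape[0]
    t = _logratio_variances(fractions)
    excluded = np.zeros((d, d), dtype=bool)
    omega = solve_basis_variances(t)
    rho = _basis_correlations(t, omega)
    for _ in range(n_iter):
        masked = np.abs(rho.copy())
        masked[np.tril_indices(d)] = 0.0
        masked[excluded] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        try:
            omega = solve_basis_variances(t, excluded)
        except np.linalg.LinAlgError:
            excluded[i, j] = excluded[j, i] = False
            break
        rho = _basis_correlations(t, omega)
    return rho


class SparCC(BaseEstimator):
    """SparCC correlation estimator (sklearn-style).

    ``fit(X)`` takes taxa x samples counts. Fitted attributes:
    ``correlation_`` (median over Dirichlet resamples, symmetric, unit
    diagonal) and, when ``n_permutations`` > 0 permutation rounds are run
    via :meth:`fit` with ``compute_p=True``, ``pvalue_``.
    """

    def __init__(
        self,
        n_dirichlet_resamples: int = 20,
        n_exclusion_iterations: int = 10,
        exclusion_threshold: float = 0.1,
        n_permutations: int = 100,
        seed: int = 0,
    ):
        self.n_dirichlet_resamples = n_dirichlet_resamples
        self.n_exclusion_iterations = n_exclusion_iterations
        self.exclusion_threshold = exclusion_threshold
        self.n_permutations = n_permutations
        self.seed = seed

    def _estimate(self, counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        mats = []
        for _ in range(self.n_dirichlet_resamples):
            fractions = np.apply_along_axis(
                rng.dirichlet, 0, counts + 1.0
            )
            mats.append(
                _sparcc_once(
                    fractions, self.n_exclusion_iterations, self.exclusion_threshold
                )
            )
        return np.median(mats, axis=0)

    def fit(self, X: np.ndarray, y=None, compute_p: bool = False):
        counts = np.asarray(X, dtype=float)
        if counts.shape[0] < 4:
            raise ParameterError(
                "SparCC needs >= 4 taxa (basis-variance system under-determined below 4)"
            )
        if counts.shape[1] < 10:
            raise ParameterError("SparCC needs >= 10 samples")
        SparccConfig(
            self.n_dirichlet_resamples,
            self.n_exclusion_iterations,
            self.exclusion_threshold,
            max(self.n_permutations, 1),
            self.seed,
        )
        rng = np.random.default_rng(self.seed)
        self.correlation_ = self._estimate(counts, rng)
        if compute_p:
            exceed = np.zeros_like(self.correlation_)
            for _ in range(self.n_permutations):
                perm = np.vstack(
                    [row[rng.permutation(counts.shape[1])] for row in counts]
                )
                rho_perm = self._estimate(perm, rng)
                exceed += np.abs(rho_perm) >= np.abs(self.correlation_)
            p = (1.0 + exceed) / (1.0 + self.n_permutations)
            np.fill_diagonal(p, 0.0)
            self.pvalue_ = p
        return self


def sparcc(
    table: CountTable, config: SparccConfig | None = None, compute_p: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SparCC correlations (and permutation pseudo p-values) for a table."""
    config = config or SparccConfig()
    est = SparCC(
        n_dirichlet_resamples=config.n_dirichlet_resamples,
        n_exclusion_iterations=config.n_exclusion_iterations,
        exclusion_threshold=config.exclusion_threshold,
        n_permutations=config.n_permutations,
        seed=config.seed,
    ).fit(table.counts, compute_p=compute_p)
    ids = table.taxon_ids
    corr = pd.DataFrame(est.correlation_, index=ids, columns=ids)
    pval = (
        pd.DataFrame(est.pvalue_, index=ids, columns=ids)
        if compute_p
        else pd.DataFrame(np.ones_like(est.correlation_), index=ids, columns=ids)
    )
    return corr, pval


@dataclass
class OrganNetwork:
    """Signed, weighted undirected edges of one organ's taxon network.

    ``edges`` columns: taxon_a, taxon_b (taxon_a < taxon_b),
    mean_correlation, per-site correlations (``corr_<site>``), fdr_q (max
    over sites), organ, specificity_reason (filled by
    :func:`organ_specific_edges`).
    """

    organ: str
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)

    def edge_index(self) -> pd.DataFrame:
        if self.edges.empty:
            return self.edges
        return self.edges.set_index(["taxon_a", "taxon_b"])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for _, row in self.edges.iterrows():
            g.add_edge(
                row["taxon_a"],
                row["taxon_b"],
                weight=row["mean_correlation"],
                q=row["fdr_q"],
            )
        return g


def consistent_organ_correlations(
    per_site: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    organ: str,
    fdr_alpha: float = 0.05,
) -> OrganNetwork:
    """Keep edges that are BH-significant in every site of the organ with
    an identical correlation sign, averaging the correlation across sites."""
    if not per_site:
        raise ParameterError("need at least one site")
    sites = sorted(per_site)
    taxa = list(per_site[sites[0]][0].index)
    d = len(taxa)
    iu = np.triu_indices(d, k=1)
    q_by_site = {}
    for site in sites:
        corr, pval = per_site[site]
        if list(corr.index) != taxa:
            raise ValidationError("per-site matrices must share taxon ordering")
        q = np.ones((d, d))
        q[iu] = multipletests(pval.to_numpy()[iu], method="fdr_bh")[1]
        q_by_site[site] = q
    rows = []
    for i, j in zip(*iu):
        corrs = np.array([per_site[s][0].to_numpy()[i, j] for s in sites])
        qs = np.array([q_by_site[s][i, j] for s in sites])
        if np.all(qs < fdr_alpha) and (np.all(corrs > 0) or np.all(corrs < 0)):
            a, b = sorted((taxa[i], taxa[j]))
            row = {
                "taxon_a": a,
                "taxon_b": b,
                "mean_correlation": float(np.mean(corrs)),
                "fdr_q": float(np.max(qs)),
                "organ": organ,
                "specificity_reason": "",
            }
            for s, c in zip(sites, corrs):
                row[f"corr_{s}"] = float(c)
            rows.append(row)
    return OrganNetwork(organ, pd.DataFrame(rows))


def organ_specific_edges(
    networks: dict[str, OrganNetwork],
    diff_threshold: float = 0.6,
    strength_threshold: float = 0.6,
    any_organ: bool = False,
) -> dict[str, OrganNetwork]:
    """Annotate each organ's edges with the organ-specificity rules.

    An edge is specific to organ O if (a) its correlation differs by more
    than ``diff_threshold`` from the edge's correlation in every other organ
    carrying it (``any_organ=True`` relaxes this to at least one), or (b)
    its strength exceeds ``strength_threshold`` and no other organ carries
    the edge at all. Edges present in exactly one organ can qualify only
    via rule (b).
    """
    if len(networks) < 2:
        raise ParameterError("need >= 2 organs for specificity analysis")
    corr_lookup: dict[str, dict[tuple[str, str], float]] = {
        organ: {
            (row["taxon_a"], row["taxon_b"]): row["mean_correlation"]
            for _, row in net.edges.iterrows()
        }
        for organ, net in networks.items()
    }
    annotated: dict[str, OrganNetwork] = {}
    for organ, net in networks.items():
        edges = net.edges.copy()
        reasons = []
        for _, row in edges.iterrows():
            key = (row["taxon_a"], row["taxon_b"])
            corr_here = row["mean_correlation"]
            others = [
                corr_lookup[o][key]
                for o in networks
                if o != organ and key in corr_lookup[o]
            ]
            reason = ""
            if others:
                diffs = [abs(corr_here - c) for c in others]
                hit = any(d > diff_threshold for d in diffs) if any_organ else all(
                    d > diff_threshold for d in diffs
                )
                if hit:
                    reason = "difference_gt_{:g}".format(diff_threshold)
            elif abs(corr_here) > strength_threshold:
                reason = "unique_strength_gt_{:g}".format(strength_threshold)
            reasons.append(reason)
        if len(edges):
            edges["specificity_reason"] = reasons
        annotated[organ] = OrganNetwork(organ, edges)
    return annotated


def organ_networks(
    table: CountTable,
    samples: SampleTable,
    config: SparccConfig | None = None,
    fdr_alpha: float = 0.05,
    min_samples: int = 10,
) -> dict[str, OrganNetwork]:
    """Per-site SparCC across every organ, then the consistency rule."""
    config = config or SparccConfig()
    meta = samples.data
    networks: dict[str, OrganNetwork] = {}
    for organ in sorted(meta.loc[meta["organ"] != "negative_control", "organ"].unique()):
        per_site: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
        for site in sorted(meta.loc[meta["organ"] == organ, "site"].unique()):
            ids = [
                s
                for s in table.sample_ids
                if s in meta.index and meta.loc[s, "site"] == site
                and meta.loc[s, "organ"] == organ
            ]
            if len(ids) < min_samples:
                continue
            per_site[site] = sparcc(table.select_samples(ids), config)
        if per_site:
            networks[organ] = consistent_organ_correlations(per_site, organ, fdr_alpha)
    return networks
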