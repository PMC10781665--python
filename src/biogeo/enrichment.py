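"""Mucosa- vs lumen-enriched taxa by overdispersed beta-binomial logistic
regression.

For one taxon at one site, read counts C out of depth N across paired
lumen/mucosa samples follow

    C ~ Binomial(N, p),   p ~ Beta(a, b),
    logit(mean p) = beta0 + beta_type * R_type + beta_k * S_1 + ...

with R_type = 1 for mucosa and 0 for lumen/gastric juice, S_i subject
covariates, and a single intra-class correlation rho per fit relating the
Beta hyperparameters to the mean: a = p(1-rho)/rho, b = (1-p)(1-rho)/rho.
beta_type is the log-odds shift of the taxon's relative abundance in mucosa
versus lumen; (beta, rho) are estimated jointly by maximum likelihood, the
standard error comes from the inverse observed information, significance
from a two-sided Wald test, and taxa are classified mucosa-/lumen-enriched
by Benjamini-Hochberg FDR within site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import betaln, expit, gammaln, log_expit, logit
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ValidationError
from .io import CountTable, SampleTable

logger = logging.getLogger(__name__)

LUMINAL = ("lumen", "gastric_juice")
DEFAULT_COVARIATES = ("age", "sex", "BMI")


@dataclass
class EnrichmentModel:
    """Aligned design/counts/depths for one taxon at one site.

    ``design`` includes the intercept column; ``type_index`` locates the
    R_type (mucosa indicator) column within it.
    """

    design: np.ndarray
    counts: np.ndarray
    depths: np.ndarray
    column_names: list[str]
    type_index: int = 1

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.depths = np.asarray(self.depths, dtype=np.int64)
        n = len(self.counts)
        if self.design.shape[0] != n or len(self.depths) != n:
            raise ValidationError("design, counts and depths must align")
        if np.any(self.counts < 0) or np.any(self.depths < self.counts):
            raise ValidationError("need 0 <= C <= N elementwise")
        r = self.design[:, self.type_index]
        if not np.all(np.isin(r, (0.0, 1.0))):
            raise ValidationError("R_type column must be binary 0/1")


@dataclass
class EnrichmentFit:
    taxon_id: str
    site: str
    beta_type: float
    se: float
    wald_p: float
    rho_hat: float
    converged: bool
    fdr_q: float = np.nan
    enrichment_class: str = "ns"


def betabinom_loglik(beta: np.ndarray, rho: float, model: EnrichmentModel) -> float:
    """Log-likelihood of the beta-binomial logistic model.

    At rho = 0 this is the binomial log-likelihood limit. Invalid parameter
    corners return -inf instead of raising, so optimizers stay safe.
    """
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)) or not (0 <= rho < 1):
        return -np.inf
    eta = model.design @ beta
    c, n = model.counts, model.depths
    log_comb = gammaln(n + 1) - gammaln(c + 1) - gammaln(n - c + 1)
    # below ~1e-8 the direct Beta-function formula loses precision to
    # log-gamma cancellation (a, b ~ 1/rho); the binomial limit is then the
    # more accurate evaluation, off only by O((N-1) rho / 2)
    if rho < 1e-8:
        ll = log_comb + c * log_expit(eta) + (n - c) * log_expit(-eta)
    else:
        p = expit(eta)
        a = p * (1 - rho) / rho
        b = (1 - p) * (1 - rho) / rho
        if np.any(a <= 0) or np.any(b <= 0):
            return -np.inf
        ll = log_comb + betaln(c + a, n - c + b) - betaln(a, b)
    total = float(np.sum(ll))
    return total if np.isfinite(total) else -np.inf


class BetaBinomialLogistic(BaseEstimator):
    """Beta-binomial logistic regression estimator (sklearn-style).

    ``fit(X, y)`` takes the design matrix ``X`` *without* intercept and
    ``y`` of shape (n, 2) holding (successes C, trials N) per row. Fitted
    attributes: ``coef_`` (including ``intercept_`` separately), ``rho_``,
    ``se_`` (per coefficient incl. intercept), ``converged_``.
    """

    def __init__(self, rho_init: float = 0.05, max_iter: int = 500):
        self.rho_init = rho_init
        self.max_iter = max_iter

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        c, n = y[:, 0].astype(np.int64), y[:, 1].astype(np.int64)
        design = np.hstack([np.ones((len(c), 1)), X])
        model = EnrichmentModel(design, c, n, ["intercept"] + [f"x{i}" for i in range(X.shape[1])],
                                type_index=1 if X.shape[1] else 0)
        beta, rho, cov, converged = _maximize(model, self.rho_init, self.max_iter)
        self.intercept_ = beta[0]
        self.coef_ = beta[1:]
        self.rho_ = rho
        self.se_ = np.sqrt(np.diag(cov)[: len(beta)]) if cov is not None else np.full(len(beta), np.inf)
        self.converged_ = converged
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Mean success probability for new design rows."""
        X = np.asarray(X, dtype=float)
        return expit(self.intercept_ + X @ self.coef_)


def _negll_grad(theta: np.ndarray, model: EnrichmentModel) -> np.ndarray:
    """Analytic gradient of the negative log-likelihood in (beta, phi) with
    rho = expit(phi), using digamma identities for the Beta functions."""
    from scipy.special import digamma

    beta, phi = theta[:-1], theta[-1]
    rho = float(expit(phi))
    eta = model.design @ beta
    p = expit(eta)
    c, n = model.counts, model.depths
    s = (1 - rho) / rho
    a = np.clip(p * s, 1e-12, None)
    b = np.clip((1 - p) * s, 1e-12, None)
    dll_da = digamma(c + a) - digamma(n + a + b) - digamma(a) + digamma(a + b)
    dll_db = digamma(n - c + b) - digamma(n + a + b) - digamma(b) + digamma(a + b)
    dll_deta = p * (1 - p) * s * (dll_da - dll_db)
    grad_beta = model.design.T @ dll_deta
    ds_dphi = -(1 - rho) / rho  # d[(1-rho)/rho]/dphi with rho = expit(phi)
    grad_phi = ds_dphi * np.sum(p * dll_da + (1 - p) * dll_db)
    return -np.concatenate([grad_beta, [grad_phi]])


def _maximize(
    model: EnrichmentModel, rho_init: float, max_iter: int
) -> tuple[np.ndarray, float, np.ndarray | None, bool]:
    """Joint MLE of (beta, rho); rho optimized on the logit scale."""
    n_beta = model.design.shape[1]
    beta0 = _initial_beta(model)
    theta0 = np.concatenate([beta0, [logit(rho_init)]])

    def negll(theta: np.ndarray) -> float:
        rho = float(expit(theta[-1]))
        value = betabinom_loglik(theta[:-1], rho, model)
        return 1e12 if not np.isfinite(value) else -value

    result = optimize.minimize(
        negll,
        theta0,
        jac=lambda th: _negll_grad(th, model),
        method="L-BFGS-B",
        bounds=[(None, None)] * n_beta + [(-30.0, logit(1 - 1e-9))],
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    theta = result.x
    beta = theta[:-1]
    rho = float(expit(theta[-1]))
    grad_ok = np.max(np.abs(_negll_grad(theta, model)[:n_beta])) < 1e-2
    converged = (bool(result.success) or grad_ok) and np.isfinite(result.fun) and result.fun < 1e11
    cov = None
    if converged:
        try:
            hess = _hessian_from_grad(theta, model)
            cov_full = np.linalg.inv(hess)
            diag = np.diag(cov_full)[:n_beta]
            if np.all(np.isfinite(diag)) and np.all(diag > 0):
                cov = cov_full
            else:
                converged = False
        except np.linalg.LinAlgError:
            converged = False
    return beta, rho, cov, converged


def _hessian_from_grad(theta: np.ndarray, model: EnrichmentModel) -> np.ndarray:
    """Observed information by central differences of the analytic gradient."""
    k = len(theta)
    hess = np.empty((k, k))
    eps = 1e-5 * np.maximum(1.0, np.abs(theta))
    for i in range(k):
        up, down = theta.copy(), theta.copy()
        up[i] += eps[i]
        down[i] -= eps[i]
        hess[i] = (_negll_grad(up, model) - _negll_grad(down, model)) / (2 * eps[i])
    return 0.5 * (hess + hess.T)


def _initial_beta(model: EnrichmentModel) -> np.ndarray:
    """Plain logistic (binomial GLM) start values; pooled-proportion
    intercept fallback under separation."""
    import statsmodels.api as sm

    try:
        with np.errstate(all="ignore"):
            glm = sm.GLM(
                np.column_stack([model.counts, model.depths - model.counts]),
                model.design,
                family=sm.families.Binomial(),
            ).fit(maxiter=50)
        beta = np.asarray(glm.params, dtype=float)
        if np.all(np.isfinite(beta)) and np.max(np.abs(beta)) < 30:
            return beta
    except Exception:
        pass
    pooled = model.counts.sum() / max(model.depths.sum(), 1)
    pooled = np.clip(pooled, 1e-9, 1 - 1e-9)
    beta = np.zeros(model.design.shape[1])
    beta[0] = logit(pooled)
    return beta


def fit_taxon(model: EnrichmentModel, taxon_id: str = "", site: str = "") -> EnrichmentFit:
    """MLE fit of one taxon's model; Wald test on the R_type coefficient."""
    r = model.design[:, model.type_index]
    if len(np.unique(r)) < 2:
        raise ParameterError("R_type needs both niches represented")
    if model.counts.sum() == 0:
        raise ParameterError("all-zero counts: nothing to fit")
    beta, rho, cov, converged = _maximize(model, rho_init=0.05, max_iter=500)
    beta_type = float(beta[model.type_index])
    if converged and cov is not None:
        se = float(np.sqrt(cov[model.type_index, model.type_index]))
        wald_p = float(2.0 * stats.norm.sf(abs(beta_type) / se)) if se > 0 else 1.0
    else:
        se, wald_p = np.inf, 1.0
    return EnrichmentFit(
        taxon_id=taxon_id,
        site=site,
        beta_type=beta_type,
        se=se,
        wald_p=min(max(wald_p, np.nextafter(0, 1)), 1.0),
        rho_hat=rho,
        converged=converged,
    )


def build_site_models(
    table: CountTable,
    samples: SampleTable,
    site: str,
    covariates=DEFAULT_COVARIATES,
    min_pairs: int = 4,
) -> dict[str, EnrichmentModel]:
    """Assemble per-taxon models for one site's paired lumen/mucosa samples.

    Taxa detected in fewer than ``min_pairs`` paired samples at the site are
    skipped (too thin for a 2+-parameter model) and logged.
    """
    meta = samples.data
    site_samples = [
        s
        for s in table.sample_ids
        if s in meta.index
        and meta.loc[s, "site"] == site
        and meta.loc[s, "sample_type"] in LUMINAL + ("mucosa",)
    ]
    if not site_samples:
        return {}
    sub = meta.loc[site_samples]
    r_type = (sub["sample_type"] == "mucosa").to_numpy(dtype=float)
    if len(np.unique(r_type)) < 2:
        return {}
    cols = []
    names = ["intercept", "R_type"]
    for cov in covariates:
        if cov not in sub.columns:
            continue
        x = pd.to_numeric(sub[cov], errors="coerce").to_numpy(dtype=float)
        if np.isnan(x).any() or np.nanstd(x) == 0:
            continue
        cols.append((x - x.mean()) / x.std())
        names.append(cov)
    design = np.column_stack([np.ones(len(site_samples)), r_type] + cols)

    col_idx = [table.sample_ids.index(s) for s in site_samples]
    depths = table.library_sizes[col_idx]
    models: dict[str, EnrichmentModel] = {}
    for i, taxon in enumerate(table.taxon_ids):
        c = table.counts[i, col_idx]
        detected = np.unique(sub.loc[np.asarray(site_samples)[c > 0], "subject_id"])
        if c.sum() == 0 or len(detected) < min_pairs:
            logger.debug("site %s: skipping %s (detected in %d pairs)", site, taxon, len(detected))
            continue
        models[taxon] = EnrichmentModel(design, c, depths, names, type_index=1)
    return models


def fit_organ(
    table: CountTable,
    samples: SampleTable,
    organ: str,
    covariates=DEFAULT_COVARIATES,
    min_pairs: int = 4,
) -> list[EnrichmentFit]:
    """Fit every taxon at every paired site of an organ (per taxon per site)."""
    meta = samples.data
    sites = sorted(
        meta.loc[
            (meta["organ"] == organ) & (meta["sample_id"].isin(table.sample_ids)), "site"
        ].unique()
    )
    fits: list[EnrichmentFit] = []
    for site in sites:
        for taxon, model in build_site_models(
            table, samples, site, covariates=covariates, min_pairs=min_pairs
        ).items():
            try:
                fits.append(fit_taxon(model, taxon_id=taxon, site=site))
            except ParameterError as exc:
                logger.info("site %s taxon %s skipped: %s", site, taxon, exc)
    return fits


def classify_enrichment(
    fits: list[EnrichmentFit], alpha: float = 0.05, pool_sites: bool = False
) -> list[EnrichmentFit]:
    """Benjamini-Hochberg FDR within site (or pooled across sites), then
    classify: q < alpha with beta_type > 0 -> mucosa_enriched, < 0 ->
    lumen_enriched, else ns."""
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    if not fits:
        return []
    frame = pd.DataFrame({"site": [f.site for f in fits], "p": [f.wald_p for f in fits]})
    q = np.empty(len(fits))
    groups = [frame.index] if pool_sites else [idx for _, idx in frame.groupby("site").groups.items()]
    for idx in groups:
        q[np.asarray(idx)] = multipletests(frame.loc[idx, "p"], method="fdr_bh")[1]
    out = []
    for fit, q_i in zip(fits, q):
        if q_i < alpha and fit.beta_type > 0:
            cls = "mucosa_enriched"
        elif q_i < alpha and fit.beta_type < 0:
            cls = "lumen_enriched"
        else:
            cls = "ns"
        out.append(replace(fit, fdr_q=float(q_i), enrichment_class=cls))
    return out


def fits_to_frame(fits: list[EnrichmentFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon_id": [f.taxon_id for f in fits],
            "site": [f.site for f in fits],
            "beta_type": [f.beta_type for f in fits],
            "se": [f.se for f in fits],
            "wald_p": [f.wald_p for f in fits],
            "fdr_q": [f.fdr_q for f in fits],
            "rho_hat": [f.rho_hat for f in fits],
            "converged": [f.converged for f in fits],
            "class": [f.enrichment_class for f in fits],
        }
    )


def compare_enriched_sets(set_a, set_b) -> tuple[float, list[str]]:
    """Jaccard overlap of two enriched-taxon sets, as a percentage, plus the
    sorted shared members. Two empty sets give 0%."""
    a, b = set(set_a), set(set_b)
    union = a | b
    shared = sorted(a & b)
    percent = 100.0 * len(shared) / len(union) if union else 0.0
    return percent, shared
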