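"""Censored / MCAR missing-data model, filtering, imputation, p-adjustment.

Missing peptide intensities arise from two mechanisms:

* **MCAR** -- instrument "glitches" unrelated to abundance; a cell is missing
  with probability ``pi`` regardless of its value.
* **Left-censoring** -- the value fell below a detection cutoff ``c``; its
  absence is informative (the value must be below ``c``).

The per-protein likelihood treats each cell of the peptide x sample grid as

* observed ``y``:   ``(1 - pi) * N(y; mu, sigma_j^2)``
* missing:          ``pi + (1 - pi) * Phi((c - mu) / sigma_j)``

with cell mean ``mu = Prot_i + Pep_ij + Treat_ik`` under sum-to-zero
constraints and a separate error variance per peptide.  Maximising the sum of
cell log-likelihoods gives estimates, an observed (Fisher) information matrix,
and -- through the treatment-parameter block of that matrix -- an information
content used to filter peptides and proteins whose group difference is not
identifiable from the observed cells.

Imputation draws a single value per missing cell: from the left tail of the
fitted normal (truncated at ``c``) if the cell is classified censored, from
the full normal if MCAR.  Naive alternatives (row mean, minimum observed,
normal draws) are provided for comparison.  Finally, ``adjust_pvalues``
rescales a p-value list so its right tail -- assumed to be null -- matches
the uniform distribution, guarding downstream inference against overfitting
introduced by preprocessing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._design import ProteinDesign, build_protein_design, treat_contrast_matrix
from .core import AbundanceMatrix, ProteinMap, StudyDesign

__all__ = [
    "MissingnessParams",
    "ProteinModelFit",
    "CellClassification",
    "ImputationResult",
    "NonIdentifiableError",
    "cell_loglik",
    "fit_protein_ml",
    "fit_protein_quick",
    "observed_information",
    "estimate_missingness_params",
    "information_content",
    "greedy_select_peptides",
    "subset_information",
    "classify_missing",
    "impute_model_based",
    "impute_naive",
    "adjust_pvalues",
]

_LOG_SIGMA_BOUNDS = (-7.0, 7.0)
_SIGMA_FLOOR = 1e-3


class NonIdentifiableError(ValueError):
    """The protein model cannot be estimated from the observed cells."""


@dataclass
class MissingnessParams:
    """Global missingness mechanism: MCAR probability and censoring cutoff.

    ``cutoff`` is the left-censoring threshold on the log-abundance scale;
    ``-inf`` disables censoring.  A per-sample cutoff vector is accepted for
    data whose samples have been shifted individually (e.g. after global
    centering, where a single instrument threshold lands at a different
    value in each sample).
    """

    pi_mcar: float
    cutoff: float | np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi_mcar <= 1.0:
            raise ValueError("pi_mcar must be in [0, 1]")
        c = np.asarray(self.cutoff, dtype=float)
        if np.any(np.isnan(c)) or np.any(c == math.inf):
            raise ValueError("cutoff must be finite or -inf")

    @property
    def scalar_cutoff(self) -> bool:
        return np.ndim(self.cutoff) == 0

    def cutoff_for_samples(self, n_samples: int) -> np.ndarray:
        """Per-sample cutoff vector (broadcast if scalar)."""
        c = np.asarray(self.cutoff, dtype=float)
        if c.ndim == 0:
            return np.full(n_samples, float(c))
        if c.shape != (n_samples,):
            raise ValueError(
                f"cutoff vector length {c.shape[0]} != {n_samples} samples")
        return c


@dataclass
class ProteinModelFit:
    """Maximum-likelihood (or quick moment) fit of one protein's model."""

    protein_id: str
    peptide_ids: list[str]
    groups: list[str]
    protein_mean: float
    peptide_offset: np.ndarray     # length J, sums to zero
    treat_effect: np.ndarray       # length K, sums to zero
    resid_sd: np.ndarray           # length J, > 0
    loglik: float
    info_matrix: np.ndarray        # observed information over free parameters
    converged: bool
    n_obs: int
    method: str = "ml"
    group_index: np.ndarray | None = None  # group index per sample of the fit

    @property
    def n_peptides(self) -> int:
        return len(self.peptide_ids)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def cell_mean(self, j: int, k: int) -> float:
        return self.protein_mean + self.peptide_offset[j] + self.treat_effect[k]

    def treat_difference(self) -> float:
        """Group difference Treat_1 - Treat_2 (two-group designs)."""
        if self.n_groups != 2:
            raise ValueError("treat_difference is defined for two groups")
        return float(self.treat_effect[0] - self.treat_effect[1])


@dataclass
class CellClassification:
    """Posterior censoring probability for each missing cell of a protein."""

    rows: np.ndarray        # peptide index within the protein sub-matrix
    cols: np.ndarray        # sample index
    posterior: np.ndarray   # P(censored | missing)
    censored: np.ndarray    # boolean label, posterior >= threshold
    threshold: float


@dataclass
class ImputationResult:
    matrix: AbundanceMatrix
    skipped_cells: list[tuple[str, str]] = field(default_factory=list)
    seed: int | None = None
    method: str = "model"


# ---------------------------------------------------------------------------
# likelihood primitives
# ---------------------------------------------------------------------------


def _log_missing_prob(z: np.ndarray, pi: float) -> np.ndarray:
    """log(pi + (1 - pi) Phi(z)), stable for small Phi(z)."""
    if pi == 0.0:
        return stats.norm.logcdf(z)
    return np.logaddexp(math.log(pi), math.log1p(-pi) + stats.norm.logcdf(z))


def cell_loglik(y: float | None, mu: float, sigma: float,
                params: MissingnessParams) -> float:
    """Log-likelihood contribution of one cell (observed value or missing).

    Pass ``y=None`` or ``y=nan`` for a missing cell.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not params.scalar_cutoff:
        raise ValueError("cell_loglik takes a scalar cutoff; pick the "
                         "sample's entry from the cutoff vector")
    pi = params.pi_mcar
    if y is None or (isinstance(y, float) and math.isnan(y)):
        if params.cutoff == -math.inf:
            if pi == 0.0:
                return -math.inf
            return math.log(pi)
        z = (params.cutoff - mu) / sigma
        return float(_log_missing_prob(np.array(z), pi))
    if pi == 1.0:
        warnings.warn("observed value with pi_mcar = 1 is an impossible event")
        return -math.inf
    return float(math.log1p(-pi) + stats.norm.logpdf(y, loc=mu, scale=sigma))


def _cells_of(sub: AbundanceMatrix, design: StudyDesign,
              params: MissingnessParams):
    """Flattened cell grid, per-cell cutoffs and design for one protein."""
    design = design.aligned_to(sub.sample_ids)
    gidx = design.group_index()
    pd_ = build_protein_design(sub.n_peptides, gidx)
    y = sub.values.ravel()
    cut = np.tile(params.cutoff_for_samples(sub.n_samples), sub.n_peptides)
    return pd_, y, cut, design


def _loglik_parts(theta: np.ndarray, pd_: ProteinDesign, y: np.ndarray):
    """Per-cell quantities shared by value, gradient and Hessian."""
    p = pd_.n_params
    beta = theta[:p]
    eta = theta[p:]
    mu = pd_.X @ beta
    s = np.exp(eta)[pd_.peptide_of_cell]
    obs = ~np.isnan(y)
    return beta, eta, mu, s, obs


def _missing_terms(z: np.ndarray, pi: float):
    """logL, g = (1-pi) phi / L and g' for missing cells; z may be -inf
    (cutoff disabled), in which case the cell contributes log(pi) and zero
    derivatives."""
    finite = np.isfinite(z)
    logL = np.where(finite, _log_missing_prob(np.where(finite, z, 0.0), pi), 0.0)
    if not np.all(finite):
        off = math.log(pi) if pi > 0 else -math.inf
        logL = np.where(finite, logL, off)
    with np.errstate(invalid="ignore"):
        log_g = math.log1p(-pi) + stats.norm.logpdf(np.where(finite, z, 0.0)) - logL
    g = np.where(finite, np.exp(log_g), 0.0)
    zs = np.where(finite, z, 0.0)
    gp = -zs * g - g**2
    return logL, g, gp, zs


def _neg_loglik_grad(theta: np.ndarray, pd_: ProteinDesign, y: np.ndarray,
                     pi: float, cut: np.ndarray):
    _, eta, mu, s, obs = _loglik_parts(theta, pd_, y)
    nJ = eta.shape[0]
    ll = 0.0
    dl_dmu = np.zeros_like(mu)
    dl_deta_cell = np.zeros_like(mu)

    if obs.any():
        r = y[obs] - mu[obs]
        so = s[obs]
        ll += np.sum(math.log1p(-pi) - np.log(so) - 0.5 * math.log(2 * math.pi)
                     - r**2 / (2 * so**2))
        dl_dmu[obs] = r / so**2
        dl_deta_cell[obs] = -1.0 + r**2 / so**2

    mis = ~obs
    if mis.any():
        z = (cut[mis] - mu[mis]) / s[mis]
        logL, g, _, zs = _missing_terms(z, pi)
        ll += np.sum(logL)
        dl_dmu[mis] = -g / s[mis]
        dl_deta_cell[mis] = -g * zs

    grad_beta = pd_.X.T @ dl_dmu
    grad_eta = np.bincount(pd_.peptide_of_cell, weights=dl_deta_cell,
                           minlength=nJ)
    grad = np.concatenate([grad_beta, grad_eta])
    return -ll, -grad


def _observed_info(theta: np.ndarray, pd_: ProteinDesign, y: np.ndarray,
                   pi: float, cut: np.ndarray) -> np.ndarray:
    """Analytic negative Hessian of the log-likelihood (observed information)."""
    _, eta, mu, s, obs = _loglik_parts(theta, pd_, y)
    p = pd_.n_params
    nJ = eta.shape[0]
    c_mumu = np.zeros_like(mu)   # d2 l / d mu^2
    c_mueta = np.zeros_like(mu)  # d2 l / d mu d eta  (coefficient of x)
    c_etaeta = np.zeros_like(mu)

    if obs.any():
        r = y[obs] - mu[obs]
        so = s[obs]
        c_mumu[obs] = -1.0 / so**2
        c_mueta[obs] = -2.0 * r / so**2
        c_etaeta[obs] = -2.0 * r**2 / so**2

    mis = ~obs
    if mis.any():
        z = (cut[mis] - mu[mis]) / s[mis]
        _, g, gp, zs = _missing_terms(z, pi)
        c_mumu[mis] = gp / s[mis]**2
        c_mueta[mis] = (zs * gp + g) / s[mis]
        c_etaeta[mis] = zs**2 * gp + zs * g

    H = np.zeros((p + nJ, p + nJ))
    H[:p, :p] = pd_.X.T @ (c_mumu[:, None] * pd_.X)
    for j in range(nJ):
        in_j = pd_.peptide_of_cell == j
        H[:p, p + j] = pd_.X[in_j].T @ c_mueta[in_j]
        H[p + j, :p] = H[:p, p + j]
        H[p + j, p + j] = c_etaeta[in_j].sum()
    return -H


def observed_information(sub: AbundanceMatrix, design: StudyDesign,
                         params: MissingnessParams,
                         fit: ProteinModelFit) -> np.ndarray:
    """Observed information evaluated at a fit's parameter values.

    Ordering of the free parameters: intercept, peptide contrasts (J - 1),
    treatment contrasts (K - 1), then one log residual SD per peptide.
    """
    pd_, y, cut, _ = _cells_of(sub, design, params)
    theta = _pack(fit, pd_)
    return _observed_info(theta, pd_, y, params.pi_mcar, cut)


def _pack(fit: ProteinModelFit, pd_: ProteinDesign) -> np.ndarray:
    beta = np.concatenate([
        [fit.protein_mean],
        fit.peptide_offset[: pd_.n_peptides - 1],
        fit.treat_effect[: pd_.n_groups - 1],
    ])
    return np.concatenate([beta, np.log(fit.resid_sd)])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _check_identifiable(sub: AbundanceMatrix, design: StudyDesign):
    obs = ~sub.mask
    if obs.sum() == 0:
        raise NonIdentifiableError(
            f"all cells missing; protein model is non-identifiable"
        )
    gidx = design.aligned_to(sub.sample_ids).group_index()
    n_groups = int(gidx.max()) + 1
    observed_groups = np.unique(np.tile(gidx, sub.n_peptides)[obs.ravel()])
    if observed_groups.size < n_groups:
        raise NonIdentifiableError(
            "at least one treatment group has no observed value for this protein"
        )


def _init_theta(pd_: ProteinDesign, y: np.ndarray) -> np.ndarray:
    obs = ~np.isnan(y)
    beta, *_ = np.linalg.lstsq(pd_.X[obs], y[obs], rcond=None)
    resid = y[obs] - pd_.X[obs] @ beta
    pooled = np.std(resid) if resid.size > 1 else 1.0
    pooled = max(pooled, _SIGMA_FLOOR)
    sig = np.full(pd_.n_peptides, pooled)
    pep_obs = pd_.peptide_of_cell[obs]
    for j in range(pd_.n_peptides):
        rj = resid[pep_obs == j]
        if rj.size >= 3:
            sig[j] = max(np.std(rj), 0.25 * pooled, _SIGMA_FLOOR)
    return np.concatenate([beta, np.log(sig)])


def _irls_complete(pd_: ProteinDesign, y: np.ndarray, pi: float,
                   max_iter: int = 200, tol: float = 1e-12):
    """Exact ML for complete data: alternate WLS means and per-peptide
    sigma^2 = RSS / n (coordinate ascent on the heteroscedastic likelihood)."""
    J = pd_.n_peptides
    beta, *_ = np.linalg.lstsq(pd_.X, y, rcond=None)
    sig2 = np.ones(J)
    prev = -np.inf
    for _ in range(max_iter):
        resid = y - pd_.X @ beta
        for j in range(J):
            in_j = pd_.peptide_of_cell == j
            sig2[j] = max(np.mean(resid[in_j] ** 2), _SIGMA_FLOOR**2)
        w = 1.0 / sig2[pd_.peptide_of_cell]
        xw = pd_.X * w[:, None]
        beta = np.linalg.solve(pd_.X.T @ xw, xw.T @ y)
        ll = -0.5 * np.sum(np.log(sig2[pd_.peptide_of_cell]))
        resid = y - pd_.X @ beta
        ll -= 0.5 * np.sum(resid**2 / sig2[pd_.peptide_of_cell])
        ll += y.size * (math.log1p(-pi) - 0.5 * math.log(2 * math.pi))
        if abs(ll - prev) < tol * (1 + abs(ll)):
            break
        prev = ll
    theta = np.concatenate([beta, 0.5 * np.log(sig2)])
    return theta, ll


def _drop_sparse_peptides(sub: AbundanceMatrix, min_obs: int) -> AbundanceMatrix:
    """Exclude peptides whose own error variance is inestimable.

    Each peptide carries a free offset and a free variance; with fewer than
    ``min_obs`` observed cells the likelihood is unbounded along that
    peptide's variance direction (the offset can interpolate the data), which
    collapses sigma_j and wrecks the information matrix for the whole
    protein.
    """
    keep = (~sub.mask).sum(axis=1) >= min_obs
    if keep.all():
        return sub
    if not keep.any():
        raise NonIdentifiableError(
            f"no peptide has >= {min_obs} observed cells")
    return AbundanceMatrix(sub.values[keep].copy(),
                           [p for p, k in zip(sub.peptide_ids, keep) if k],
                           list(sub.sample_ids), sub.log_base)


def fit_protein_ml(sub: AbundanceMatrix, design: StudyDesign,
                   params: MissingnessParams, restarts: int = 3,
                   tol: float = 1e-8, seed: int = 0,
                   min_obs_per_peptide: int = 3) -> ProteinModelFit:
    """Maximum-likelihood fit of one protein's censored/MCAR model.

    Complete sub-matrices are solved exactly by iteratively reweighted least
    squares (the likelihood factorises into weighted least squares given the
    per-peptide variances).  With missing cells the likelihood is maximised by
    bounded quasi-Newton (L-BFGS-B) with analytic gradients, initialised from
    observed-cell least squares plus ``restarts`` jittered restarts.
    Peptides with fewer than ``min_obs_per_peptide`` observed cells are
    excluded (their error variance is a free parameter the data cannot pin
    down); the returned ``peptide_ids`` list the peptides actually fitted.
    """
    design = design.aligned_to(sub.sample_ids)
    sub = _drop_sparse_peptides(sub, min_obs_per_peptide)
    _check_identifiable(sub, design)
    pd_, y, cut, design = _cells_of(sub, design, params)
    pi = params.pi_mcar

    if not np.isnan(y).any():
        theta, ll = _irls_complete(pd_, y, pi)
        converged = True
    else:
        theta0 = _init_theta(pd_, y)
        bounds = ([(None, None)] * pd_.n_params
                  + [_LOG_SIGMA_BOUNDS] * pd_.n_peptides)
        rng = np.random.default_rng(seed)
        best = None
        starts = [theta0]
        for _ in range(restarts):
            jitter = rng.normal(0.0, 0.1, size=theta0.shape)
            starts.append(theta0 + jitter)
        for start in starts:
            res = optimize.minimize(
                _neg_loglik_grad, start, args=(pd_, y, pi, cut),
                jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 500, "ftol": tol})
            if best is None or res.fun < best.fun:
                best = res
        theta, ll = best.x, -best.fun
        converged = bool(best.success)

    info = _observed_info(theta, pd_, y, pi, cut)
    prot, pep, treat, _ = pd_.unpack(theta[: pd_.n_params])
    return ProteinModelFit(
        protein_id="", peptide_ids=list(sub.peptide_ids), groups=design.groups,
        protein_mean=prot, peptide_offset=pep, treat_effect=treat,
        resid_sd=np.exp(theta[pd_.n_params:]), loglik=float(ll),
        info_matrix=info, converged=converged, n_obs=int((~sub.mask).sum()),
        method="ml", group_index=design.group_index())


def fit_protein_quick(sub: AbundanceMatrix, design: StudyDesign,
                      params: MissingnessParams,
                      min_obs_per_peptide: int = 3) -> ProteinModelFit:
    """Rough per-protein estimates without numerical optimization.

    Least squares on the observed cells for the mean parameters and moment
    estimates for the per-peptide SDs.  Fast enough to drive model-based
    filtering and imputation over thousands of proteins; the observed
    information is still evaluated exactly at these rough estimates.
    """
    design = design.aligned_to(sub.sample_ids)
    sub = _drop_sparse_peptides(sub, min_obs_per_peptide)
    _check_identifiable(sub, design)
    pd_, y, cut, design = _cells_of(sub, design, params)
    obs = ~np.isnan(y)
    X_obs = pd_.X[obs]
    if np.linalg.matrix_rank(X_obs) < X_obs.shape[1]:
        raise NonIdentifiableError("observed-cell design is rank deficient")
    theta = _init_theta(pd_, y)
    nll, _ = _neg_loglik_grad(theta, pd_, y, params.pi_mcar, cut)
    info = _observed_info(theta, pd_, y, params.pi_mcar, cut)
    prot, pep, treat, _ = pd_.unpack(theta[: pd_.n_params])
    return ProteinModelFit(
        protein_id="", peptide_ids=list(sub.peptide_ids), groups=design.groups,
        protein_mean=prot, peptide_offset=pep, treat_effect=treat,
        resid_sd=np.exp(theta[pd_.n_params:]), loglik=float(-nll),
        info_matrix=info, converged=True, n_obs=int(obs.sum()),
        method="quick", group_index=design.group_index())


# ---------------------------------------------------------------------------
# missingness parameters
# ---------------------------------------------------------------------------


def estimate_missingness_params(m: AbundanceMatrix,
                                top_quantile: float = 0.75,
                                per_sample_cutoff: bool = False,
                                ) -> MissingnessParams:
    """Estimate the global MCAR probability and censoring cutoff from data.

    The cutoff defaults to the median across samples of each sample's minimum
    observed value; with ``per_sample_cutoff`` each sample keeps its own
    minimum (appropriate after per-sample shifts such as global centering,
    which move a single instrument threshold to sample-specific positions).
    The MCAR probability is the missing fraction among peptides whose
    observed mean lies in the top abundance quartile, where censoring is
    negligible.  Both are meant as defaults and can be overridden by
    constructing :class:`MissingnessParams` directly.
    """
    mask = m.mask
    for s in range(m.n_samples):
        if mask[:, s].all():
            raise ValueError(f"sample {m.sample_ids[s]!r} has no observed values")
    if not mask.any():
        return MissingnessParams(pi_mcar=0.0, cutoff=-math.inf)
    sample_mins = np.nanmin(m.values, axis=0)
    cutoff: float | np.ndarray
    cutoff = sample_mins.copy() if per_sample_cutoff else float(np.median(sample_mins))
    n_obs = (~mask).sum(axis=1)
    with np.errstate(invalid="ignore"):
        row_means = np.nansum(m.values, axis=1) / np.where(n_obs > 0, n_obs, 1)
    row_means = np.where(n_obs > 0, row_means, np.nan)
    thresh = np.nanquantile(row_means, top_quantile)
    top = row_means >= thresh
    pi = float(mask[top].mean()) if top.any() else float(mask.mean())
    return MissingnessParams(pi_mcar=pi, cutoff=cutoff)


# ---------------------------------------------------------------------------
# information content and greedy peptide selection
# ---------------------------------------------------------------------------


def information_content(fit: ProteinModelFit,
                        design: StudyDesign | None = None) -> float:
    """Scaled determinant of the treatment-difference information block.

    Nuisance parameters (protein mean, peptide offsets, log SDs) are profiled
    out of the observed information via the Schur complement; the remaining
    block is mapped to the pairwise group-difference scale and summarised as
    ``det(block)^(1/d)`` with ``d = n_groups - 1``.  Returns 0 for a
    non-identifiable model (singular nuisance block or non-positive
    determinant).
    """
    if not fit.converged:
        raise ValueError("information_content requires a converged fit")
    info = fit.info_matrix
    J, K = fit.n_peptides, fit.n_groups
    t_idx = np.arange(J, J + K - 1)        # treatment contrast columns
    n_idx = np.array([i for i in range(info.shape[0]) if i not in set(t_idx)])
    I_tt = info[np.ix_(t_idx, t_idx)]
    I_tn = info[np.ix_(t_idx, n_idx)]
    I_nn = info[np.ix_(n_idx, n_idx)]
    try:
        solved = np.linalg.solve(I_nn, I_tn.T)
    except np.linalg.LinAlgError:
        return 0.0
    if not np.all(np.isfinite(solved)):
        return 0.0
    S = I_tt - I_tn @ solved
    A = treat_contrast_matrix(K)
    Ainv = np.linalg.inv(A)
    block = Ainv.T @ S @ Ainv
    det = float(np.linalg.det(block))
    if not math.isfinite(det) or det <= 0:
        return 0.0
    return det ** (1.0 / (K - 1))


def subset_information(sub: AbundanceMatrix, design: StudyDesign,
                       params: MissingnessParams, fit: ProteinModelFit,
                       peptide_ids: list[str]) -> float:
    """Information content of a peptide subset at shared parameter values.

    The subset's cell means and SDs are taken from the full-protein ``fit``
    (peptide offsets re-centered within the subset so the sum-to-zero
    constraint holds), so subsets differ only in which cells contribute
    observed information -- not in re-estimated parameters.  Peptides the
    fit excluded contribute nothing and make the subset unscorable.
    """
    local = {pid: j for j, pid in enumerate(fit.peptide_ids)}
    if any(p not in local for p in peptide_ids):
        return 0.0
    idx = [local[p] for p in peptide_ids]
    pep = fit.peptide_offset[idx]
    shift = float(pep.mean())
    sub_fit = ProteinModelFit(
        fit.protein_id, list(peptide_ids), fit.groups,
        fit.protein_mean + shift, pep - shift, fit.treat_effect,
        fit.resid_sd[idx], 0.0, np.zeros(0), True, 0,
        group_index=fit.group_index)
    sub_m = sub.subset(list(peptide_ids))
    sub_fit.info_matrix = observed_information(sub_m, design, params, sub_fit)
    return information_content(sub_fit)


def greedy_select_peptides(sub: AbundanceMatrix, design: StudyDesign,
                           params: MissingnessParams,
                           min_gain: float = 1e-10):
    """Forward greedy peptide selection maximising information content.

    Parameters are estimated once for the whole protein (quick moment fit);
    candidate subsets are then scored by the observed information their
    cells carry at those shared estimates.  Starting from the single most
    informative peptide, the peptide with the largest information gain is
    added until no addition helps.  Returns ``(selected_ids, info_content,
    filtered)``; ``filtered`` is True when no subset yields positive
    information (the protein's group difference is not identifiable from
    its observed cells and the protein should be dropped).
    """
    if sub.n_peptides < 1:
        raise ValueError("protein sub-matrix has no peptides")
    try:
        full_fit = fit_protein_quick(sub, design, params)
    except (NonIdentifiableError, np.linalg.LinAlgError):
        return [], 0.0, True

    def info_of(ids: list[str]) -> float:
        return subset_information(sub, design, params, full_fit, ids)

    singles = [(info_of([p]), p) for p in sub.peptide_ids]
    best_info, best_pep = max(singles, key=lambda t: t[0])
    if best_info <= 0.0:
        return [], 0.0, True
    selected = [best_pep]
    remaining = [p for p in sub.peptide_ids if p != best_pep]
    current = best_info
    while remaining:
        gains = [(info_of(selected + [p]), p) for p in remaining]
        cand_info, cand_pep = max(gains, key=lambda t: t[0])
        if cand_info <= current + min_gain:
            break
        selected.append(cand_pep)
        remaining.remove(cand_pep)
        current = cand_info
    # report in the sub-matrix's row order
    selected = [p for p in sub.peptide_ids if p in selected]
    return selected, current, False


# ---------------------------------------------------------------------------
# classification and imputation
# ---------------------------------------------------------------------------


def classify_missing(sub: AbundanceMatrix, fit: ProteinModelFit,
                     params: MissingnessParams,
                     threshold: float = 0.5) -> CellClassification:
    """Posterior probability that each missing cell is censored.

    ``P(censored | missing) = (1-pi) Phi((c-mu)/sigma) / (pi + (1-pi) Phi(...))``
    with the fitted cell mean.  Ties at the threshold are labelled censored
    (conservative toward the informative mechanism).
    """
    if not fit.converged:
        raise ValueError("classify_missing requires a converged fit")
    if fit.group_index is None:
        raise ValueError("fit carries no sample-to-group index")
    # the fit may cover a subset of the sub-matrix peptides (sparse ones are
    # dropped during fitting); only cells of fitted peptides are classified
    local = {pid: j for j, pid in enumerate(fit.peptide_ids)}
    all_rows, all_cols = np.nonzero(sub.mask)
    keep = np.array([sub.peptide_ids[r] in local for r in all_rows],
                    dtype=bool)
    rows, cols = all_rows[keep], all_cols[keep]
    post = np.empty(rows.shape[0])
    pi = params.pi_mcar
    cut = params.cutoff_for_samples(sub.n_samples)
    gidx = fit.group_index
    for i, (r, s) in enumerate(zip(rows, cols)):
        c = cut[s]
        if c == -math.inf:
            post[i] = 0.0
            continue
        j = local[sub.peptide_ids[r]]
        mu = fit.cell_mean(j, gidx[s])
        phi = stats.norm.cdf((c - mu) / fit.resid_sd[j])
        if pi == 0.0:
            post[i] = 1.0
        else:
            denom = pi + (1 - pi) * phi
            post[i] = (1 - pi) * phi / denom
    return CellClassification(rows, cols, post, post >= threshold, threshold)


def impute_model_based(m: AbundanceMatrix, fits: dict[str, "ProteinModelFit"],
                       pmap: ProteinMap, design: StudyDesign,
                       params: MissingnessParams, seed: int = 0,
                       threshold: float = 0.5) -> ImputationResult:
    """Single model-based imputation of every missing cell.

    Cells classified censored are drawn from ``N(mu, sigma^2)`` truncated to
    ``(-inf, c]``; MCAR cells from the full normal.  Missing cells of proteins
    without a converged fit are left missing and reported in
    ``skipped_cells``.
    """
    design = design.aligned_to(m.sample_ids)
    gidx = design.group_index()
    rng = np.random.default_rng(seed)
    out = m.copy()
    skipped: list[tuple[str, str]] = []
    pi = params.pi_mcar
    cut = params.cutoff_for_samples(m.n_samples)
    by_prot = pmap.by_protein(m)
    row_of = {pid: i for i, pid in enumerate(m.peptide_ids)}
    for prot, rows in by_prot.items():
        miss_cells = [(r, s) for r in rows for s in range(m.n_samples)
                      if np.isnan(m.values[r, s])]
        if not miss_cells:
            continue
        fit = fits.get(prot)
        if fit is None or not fit.converged:
            skipped.extend((m.peptide_ids[r], m.sample_ids[s])
                           for r, s in miss_cells)
            continue
        local = {pid: j for j, pid in enumerate(fit.peptide_ids)}
        for r, s in miss_cells:
            pid = m.peptide_ids[r]
            if pid not in local:
                skipped.append((pid, m.sample_ids[s]))
                continue
            j = local[pid]
            mu = fit.cell_mean(j, gidx[s])
            sd = float(fit.resid_sd[j])
            c = cut[s]
            if c == -math.inf:
                post = 0.0
            elif pi == 0.0:
                post = 1.0
            else:
                phi = stats.norm.cdf((c - mu) / sd)
                post = (1 - pi) * phi / (pi + (1 - pi) * phi)
            if post >= threshold:
                b = (c - mu) / sd
                draw = stats.truncnorm.rvs(-np.inf, b, loc=mu, scale=sd,
                                           random_state=rng)
            else:
                draw = rng.normal(mu, sd)
            out.values[r, s] = draw
    return ImputationResult(out, skipped, seed, "model")


def impute_naive(m: AbundanceMatrix, method: str, seed: int = 0,
                 design: StudyDesign | None = None) -> AbundanceMatrix:
    """Naive single imputation: ``row_mean``, ``row_min``, ``min_observed``,
    ``normal_draw`` or ``group_normal_draw``.

    ``row_mean`` and the minimum-value methods are fast but distort moments:
    every imputed cell of a peptide gets the same value, shrinking the
    apparent variation, and minimum-value fills bias means toward the
    detection limit.  ``row_min`` uses the peptide's own minimum observed
    value (the classic censored-value fill); ``min_observed`` uses the
    matrix-wide minimum.  The normal-draw variants sample from the peptide's
    observed mean/variance, optionally per group.
    """
    methods = ("row_mean", "row_min", "min_observed", "normal_draw",
               "group_normal_draw")
    if method not in methods:
        raise ValueError(f"method must be one of {methods}")
    if method == "group_normal_draw" and design is None:
        raise ValueError("group_normal_draw requires a study design")
    rng = np.random.default_rng(seed)
    out = m.copy()
    mask = m.mask
    if not mask.any():
        return out
    if method == "min_observed":
        global_min = float(np.nanmin(m.values))
        out.values[mask] = global_min
        return out
    gidx = design.aligned_to(m.sample_ids).group_index() if design is not None else None
    min_obs = 2 if method in ("normal_draw", "group_normal_draw") else 1
    for r in np.nonzero(mask.any(axis=1))[0]:
        row = m.values[r]
        obs = ~np.isnan(row)
        if method in ("row_mean", "row_min"):
            if obs.sum() < min_obs:
                raise ValueError(
                    f"peptide {m.peptide_ids[r]!r} has no observed value to "
                    "impute from")
            fill = np.mean(row[obs]) if method == "row_mean" else np.min(row[obs])
            out.values[r, ~obs] = fill
        elif method == "normal_draw":
            if obs.sum() < min_obs:
                raise ValueError(
                    f"peptide {m.peptide_ids[r]!r} needs >= 2 observed values "
                    "for normal_draw imputation")
            mu, sd = np.mean(row[obs]), np.std(row[obs], ddof=1)
            out.values[r, ~obs] = rng.normal(mu, sd, size=int((~obs).sum()))
        else:  # group_normal_draw
            for s in np.nonzero(~obs)[0]:
                in_g = (gidx == gidx[s]) & obs
                if in_g.sum() < min_obs:
                    raise ValueError(
                        f"peptide {m.peptide_ids[r]!r} needs >= 2 observed "
                        f"values in group of sample {m.sample_ids[s]!r}")
                mu, sd = np.mean(row[in_g]), np.std(row[in_g], ddof=1)
                out.values[r, s] = rng.normal(mu, sd)
    return out


# ---------------------------------------------------------------------------
# p-value adjustment
# ---------------------------------------------------------------------------


def adjust_pvalues(p, null_tail_start: float = 0.5,
                   min_tail: int = 50):
    """Rescale p-values so the right (null) tail matches Uniform(0, 1).

    Only p-values above ``null_tail_start`` are assumed null.  The working
    model is a log-scale inflation ``p = U ** lambda`` with ``U`` uniform
    (overfitting stretches ``-log p`` by a common factor); ``lambda`` is
    estimated by matching the observed median of ``-log p`` restricted to
    the tail against its model-implied value -- the restriction threshold
    itself transforms under inflation, so the match is solved
    self-consistently rather than taken as a raw ratio.  All ``-log p`` are
    then divided by ``lambda`` (``p_adj = p ** (1 / lambda)``), a monotone
    transform that preserves ranking.  Returns ``(adjusted, lambda)``.
    """
    from scipy.optimize import brentq

    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < null_tail_start < 1.0:
        raise ValueError("null_tail_start must be in (0, 1)")
    tail = p[p > null_tail_start]
    if tail.size < min_tail:
        raise ValueError(
            f"only {tail.size} p-values exceed {null_tail_start}; need at "
            f"least {min_tail} to estimate the null inflation factor")
    observed = float(np.median(-np.log(tail)))
    if observed <= 0.0:
        raise ValueError("degenerate right tail (all tail p-values equal 1)")
    tau = -math.log(null_tail_start)

    def model_median(lam: float) -> float:
        # median of -log p in the tail when p = U^lam:
        # T = lam * Exp(1) conditioned on T < tau
        mass = -math.expm1(-tau / lam)           # F(tau / lam)
        return -lam * math.log1p(-0.5 * mass)    # lam * F^-1(mass / 2)

    lo, hi = 1e-3, 1e3
    if observed >= model_median(hi):
        lam = hi
    elif observed <= model_median(lo):
        lam = lo
    else:
        lam = brentq(lambda l: model_median(l) - observed, lo, hi,
                     xtol=1e-10, rtol=1e-12)
    with np.errstate(divide="ignore"):
        adjusted = np.exp(-(-np.log(p)) / lam)
    adjusted = np.clip(adjusted, 0.0, 1.0)
    return adjusted, lam
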