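"""Bias removal for label-free LC-MS abundance matrices.

Four normalizations are provided, in increasing order of flexibility:

``global_center``
    Shift each sample so a location statistic (mean or median) of its
    non-missing log abundances equals a target constant.  Corrects loading
    differences; cannot capture intensity-dependent bias.
``lowess_ma_normalize``
    Classic MA-plot smoothing against a reference sample: per sample, the
    difference M = x - r is smoothed as a function of the average
    A = (x + r) / 2 and the fitted curve is subtracted, removing
    intensity-dependent bias.
``fit_peptide_anova``
    Fixed-effects model  y = Prot_i + Pep_ij + Treat_ik [+ Batch_ib] + eps
    with sum-to-zero constraints and a separate error variance per peptide.
    Removes bias attributable to *known* factors (batches) and supplies the
    residuals that drive the SVD normalization below.
``eigenms_normalize``
    Surrogate-variable-style normalization: fit the group-effects model,
    run SVD on the complete-row residuals, keep the singular trends that beat
    a within-row permutation null ("bias eigentrends"), subtract each
    peptide's least-squares projection onto those trends (using whatever
    cells are observed), and restore the fitted group structure.  Because the
    trend removal consumes degrees of freedom, :func:`reinflate_residuals`
    adds back calibrated noise so downstream tests stay honest.

All normalizations preserve matrix shape and the missing mask exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from ._design import build_protein_design
from .core import AbundanceMatrix, ProteinMap, StudyDesign

__all__ = [
    "AnovaFit",
    "EigentrendSet",
    "NormalizationResult",
    "global_center",
    "lowess_ma_normalize",
    "fit_peptide_anova",
    "anova_normalize",
    "compute_eigentrends",
    "select_significant_trends",
    "eigenms_normalize",
    "reinflate_residuals",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class AnovaFit:
    """Per-protein fixed-effects fit of the peptide abundance model.

    ``fitted + residuals`` reproduces every observed cell; cells of proteins
    flagged non-estimable (a peptide set that does not cover every group, or
    a rank-deficient design) carry ``NaN`` in both.
    """

    protein_mean: dict[str, float]
    peptide_offset: dict[str, float]
    treat_effect: dict[str, np.ndarray]           # protein -> effect per group
    batch_effect: dict[str, np.ndarray] | None    # protein -> effect per batch
    residuals: np.ndarray                          # aligned with input matrix
    fitted: np.ndarray
    resid_var: dict[str, float]                    # peptide -> sigma^2_ij
    resid_df: dict[str, float]                     # peptide -> residual df
    groups: list[str]
    batches: list[str]
    non_estimable: set[str] = field(default_factory=set)


@dataclass
class EigentrendSet:
    """Right singular vectors of a row-centered residual matrix."""

    trends: np.ndarray             # n_trends x n_samples, orthonormal rows
    singular_values: np.ndarray    # non-increasing, >= 0
    variance_fraction: np.ndarray  # s_t^2 / sum s^2


@dataclass
class NormalizationResult:
    normalized: AbundanceMatrix
    method: str
    n_trends_removed: int = 0
    per_sample_offsets: np.ndarray | None = None
    rng_seed: int | None = None
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# global centering
# ---------------------------------------------------------------------------


def global_center(m: AbundanceMatrix, statistic: str = "median",
                  target: float = 0.0,
                  subset: Sequence[str] | None = None) -> NormalizationResult:
    """Center each sample's log-abundance distribution on ``target``.

    ``subset`` restricts the location statistic to the named peptides, e.g.
    peptides of housekeeping proteins expected to be constant across samples.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    if subset is not None:
        subset = list(subset)
        if not subset:
            raise ValueError("subset must be non-empty when given")
        rows = [m.row_index(p) for p in subset]
        ref_vals = m.values[rows]
    else:
        ref_vals = m.values
    stat = np.nanmean if statistic == "mean" else np.nanmedian
    offsets = np.empty(m.n_samples)
    for s in range(m.n_samples):
        col = ref_vals[:, s]
        if np.all(np.isnan(col)):
            raise ValueError(
                f"sample {m.sample_ids[s]!r} has no observed value in the "
                "centering subset"
            )
        offsets[s] = stat(col) - target
    out = m.copy()
    out.values -= offsets[np.newaxis, :]
    return NormalizationResult(out, "global_center", per_sample_offsets=offsets,
                               details={"statistic": statistic, "target": target})


# ---------------------------------------------------------------------------
# lowess MA normalization
# ---------------------------------------------------------------------------


def _pseudo_reference(m: AbundanceMatrix) -> np.ndarray:
    """Per-peptide median across samples, over observed cells."""
    with np.errstate(all="ignore"):
        return np.nanmedian(m.values, axis=1)


def lowess_ma_normalize(m: AbundanceMatrix, reference: str = "median_pseudo",
                        fraction: float = 0.4,
                        min_joint: int = 10) -> NormalizationResult:
    """Lowess normalization on MA plots against a reference sample.

    The reference is either a named sample or the default ``"median_pseudo"``
    (per-peptide median across samples), which avoids the arbitrary choice of
    a reference run.  ``fraction`` is the lowess smoothing span; 0.4 is the
    empirical default in the proteomics literature.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("lowess fraction must be in (0, 1]")
    if reference == "median_pseudo":
        ref = _pseudo_reference(m)
        skip_sample = None
    else:
        if reference not in m.sample_ids:
            raise ValueError(f"unknown reference sample {reference!r}")
        skip_sample = m.sample_ids.index(reference)
        ref = m.values[:, skip_sample]

    out = m.copy()
    for s in range(m.n_samples):
        if s == skip_sample:
            continue
        x = m.values[:, s]
        joint = ~np.isnan(x) & ~np.isnan(ref)
        if joint.sum() < min_joint:
            raise ValueError(
                f"sample {m.sample_ids[s]!r} shares only {int(joint.sum())} "
                f"observed peptides with the reference (need >= {min_joint})"
            )
        a = (x[joint] + ref[joint]) / 2.0
        mdiff = x[joint] - ref[joint]
        fit = _sm_lowess(mdiff, a, frac=fraction, return_sorted=True)
        xs, ys = fit[:, 0], fit[:, 1]
        obs = ~np.isnan(x)
        # evaluate the curve at each observed cell's A; where the reference is
        # missing, fall back to the cell's own value as the abscissa
        a_all = np.where(np.isnan(ref), x, (x + ref) / 2.0)
        adj = np.interp(a_all[obs], xs, ys)
        out.values[obs, s] = x[obs] - adj
    return NormalizationResult(out, "lowess_ma",
                               details={"reference": reference,
                                        "fraction": fraction})


# ---------------------------------------------------------------------------
# per-protein ANOVA
# ---------------------------------------------------------------------------


def _fit_one_protein_ls(y_obs: np.ndarray, X_obs: np.ndarray):
    """OLS with leverage-based residual df per row group.  Returns
    (beta, fitted, residuals, leverages)."""
    beta, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    fitted = X_obs @ beta
    q, _ = np.linalg.qr(X_obs)
    leverage = np.sum(q**2, axis=1)
    return beta, fitted, y_obs - fitted, leverage


def fit_peptide_anova(m: AbundanceMatrix, design: StudyDesign, pmap: ProteinMap,
                      include_batch: bool = False) -> AnovaFit:
    """Fit  y = Prot_i + Pep_ij + Treat_ik [+ Batch_ib] + eps  per protein.

    Proteins are independent blocks, so each is solved by its own constrained
    least squares.  A protein whose observed cells do not cover every group
    (or batch), or whose design is rank deficient, is flagged non-estimable
    and excluded from the residual-variance pool.
    """
    design = design.aligned_to(m.sample_ids)
    pmap.validate_against(m)
    gidx = design.group_index()
    bidx = design.batch_index() if include_batch else None
    if include_batch and bidx is None:
        raise ValueError("include_batch requested but design has no batch column")
    n_groups = len(design.groups)
    n_batches = len(design.batches) if include_batch else 0
    n_samples = m.n_samples

    residuals = np.full_like(m.values, np.nan)
    fitted = np.full_like(m.values, np.nan)
    protein_mean: dict[str, float] = {}
    peptide_offset: dict[str, float] = {}
    treat_effect: dict[str, np.ndarray] = {}
    batch_effect: dict[str, np.ndarray] = {} if include_batch else None
    resid_var: dict[str, float] = {}
    resid_df: dict[str, float] = {}
    non_estimable: set[str] = set()

    for prot, rows in pmap.by_protein(m).items():
        sub = m.values[rows]                       # J x N
        obs = ~np.isnan(sub)
        if obs.sum() == 0:
            non_estimable.add(prot)
            continue
        if np.any(obs.sum(axis=1) < 2):
            # a peptide observed in < 2 samples cannot contribute a variance
            non_estimable.add(prot)
            continue
        pd_full = build_protein_design(len(rows), gidx, bidx)
        flat_obs = obs.ravel()
        X_obs = pd_full.X[flat_obs]
        y_obs = sub.ravel()[flat_obs]
        covered_groups = np.unique(pd_full.group_of_cell[flat_obs]).size
        if covered_groups < n_groups:
            non_estimable.add(prot)
            continue
        if np.linalg.matrix_rank(X_obs) < X_obs.shape[1]:
            non_estimable.add(prot)
            continue
        beta, fit_obs, res_obs, lev = _fit_one_protein_ls(y_obs, X_obs)
        prot_mean, pep, treat, batch = pd_full.unpack(beta)
        protein_mean[prot] = prot_mean
        treat_effect[prot] = treat
        if include_batch:
            batch_effect[prot] = batch
        pep_cells = pd_full.peptide_of_cell[flat_obs]
        for local_j, row in enumerate(rows):
            pid = m.peptide_ids[row]
            peptide_offset[pid] = pep[local_j]
            in_j = pep_cells == local_j
            df_j = in_j.sum() - lev[in_j].sum()
            rss_j = float(np.sum(res_obs[in_j] ** 2))
            resid_var[pid] = rss_j / df_j if df_j > 0.5 else np.nan
            resid_df[pid] = float(df_j)
        flat_fit = np.full(len(rows) * n_samples, np.nan)
        flat_fit[flat_obs] = fit_obs
        fitted[rows] = flat_fit.reshape(len(rows), n_samples)
        flat_res = np.full(len(rows) * n_samples, np.nan)
        flat_res[flat_obs] = res_obs
        residuals[rows] = flat_res.reshape(len(rows), n_samples)

    return AnovaFit(protein_mean, peptide_offset, treat_effect, batch_effect,
                    residuals, fitted, resid_var, resid_df, design.groups,
                    design.batches if include_batch else [],
                    non_estimable)


def anova_normalize(m: AbundanceMatrix, design: StudyDesign,
                    pmap: ProteinMap) -> NormalizationResult:
    """Remove fitted batch effects via the fixed-effects model.

    Fits the full model including batch and subtracts each cell's fitted
    ``Batch_ib``; biological structure (protein, peptide, treatment terms)
    is untouched.  Requires a design with a batch column.  Rows of
    non-estimable proteins are left unadjusted.
    """
    if design.batch is None:
        raise ValueError("anova normalization requires a batch column in the design")
    fit = fit_peptide_anova(m, design, pmap, include_batch=True)
    aligned = design.aligned_to(m.sample_ids)
    bidx = aligned.batch_index()
    out = m.copy()
    for i, pid in enumerate(m.peptide_ids):
        prot = pmap.protein_of(pid)
        if prot in fit.non_estimable:
            continue
        eff = fit.batch_effect[prot][bidx]
        obs = ~np.isnan(out.values[i])
        out.values[i, obs] -= eff[obs]
    return NormalizationResult(out, "anova", details={"anova_fit": fit})


# ---------------------------------------------------------------------------
# eigentrends
# ---------------------------------------------------------------------------


def _as_complete_array(residuals) -> np.ndarray:
    r = residuals.values if isinstance(residuals, AbundanceMatrix) else np.asarray(residuals, float)
    if np.isnan(r).any():
        raise ValueError("residual matrix contains missing cells; apply "
                         "complete_rows first")
    return r


def compute_eigentrends(residuals) -> EigentrendSet:
    """SVD of the row-centered complete residual matrix.

    Each right singular vector is an across-sample trend ("eigentrend"); its
    squared singular value fraction is the share of total variance it explains.
    """
    r = _as_complete_array(residuals)
    if r.shape[0] < 2 or r.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    rc = r - r.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(rc, full_matrices=False)
    total = float(np.sum(s**2))
    vf = s**2 / total if total > 0 else np.zeros_like(s)
    return EigentrendSet(vt, s, vf)


def _singular_values(rc: np.ndarray) -> np.ndarray:
    """Singular values via the small-side Gram matrix (columns << rows)."""
    g = rc.T @ rc
    w = np.linalg.eigvalsh(g)[::-1]
    return np.sqrt(np.clip(w, 0.0, None))


def select_significant_trends(residuals, n_perm: int = 99, alpha: float = 0.05,
                              seed: int = 0) -> int:
    """Number of leading eigentrends that beat a within-row permutation null.

    Entries are permuted independently within each row, which preserves row
    (peptide) distributions while destroying any across-sample structure.
    Trends are tested sequentially against the permutation distribution of the
    matching singular value; testing stops at the first non-significant trend.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    r = _as_complete_array(residuals)
    rc = r - r.mean(axis=1, keepdims=True)
    s_obs = _singular_values(rc)
    rng = np.random.default_rng(seed)
    max_rank = min(rc.shape)
    exceed = np.zeros(max_rank, dtype=int)
    for _ in range(n_perm):
        perm = rng.permuted(rc, axis=1)
        s_perm = _singular_values(perm - perm.mean(axis=1, keepdims=True))
        exceed += s_perm >= s_obs
    # permutation p-value with the +1 correction; sequential stopping
    pvals = (1 + exceed) / (n_perm + 1)
    k = 0
    for t in range(max_rank):
        if pvals[t] <= alpha:
            k += 1
        else:
            break
    return k


# ---------------------------------------------------------------------------
# EigenMS-style normalization
# ---------------------------------------------------------------------------


def eigenms_normalize(m: AbundanceMatrix, design: StudyDesign, pmap: ProteinMap,
                      n_perm: int = 99, alpha: float = 0.05, seed: int = 0,
                      include_batch: bool = False) -> NormalizationResult:
    """Remove significant bias eigentrends from ANOVA residuals.

    Pipeline: fit the group-effects model (preserving treatment structure),
    estimate bias trends by SVD of the complete-row residuals, choose the
    number of significant trends by permutation, then for *every* peptide --
    complete or not -- estimate its loading on the bias trends from its
    observed cells by least squares and subtract the projection.  Peptides
    with fewer than ``k + 2`` observed cells (or belonging to non-estimable
    proteins) are left unadjusted and reported in the result details.

    Because fitted group structure is removed before the SVD and restored
    after, group-mean differences are untouched by construction.
    """
    fit = fit_peptide_anova(m, design, pmap, include_batch=include_batch)
    res = fit.residuals
    complete = ~np.isnan(res).any(axis=1)
    if complete.sum() < 1:
        raise ValueError("no complete residual row available for SVD")
    r_complete = res[complete]
    k = select_significant_trends(r_complete, n_perm=n_perm, alpha=alpha,
                                  seed=seed)
    if k == 0:
        return NormalizationResult(m.copy(), "eigenms", n_trends_removed=0,
                                   rng_seed=seed,
                                   details={"anova_fit": fit, "trends": None,
                                            "unadjusted_peptides": []})
    trends = compute_eigentrends(r_complete)
    v = trends.trends[:k]                       # k x N, orthonormal rows
    out = m.copy()
    has_res = ~np.isnan(res)                    # observed & estimable cells
    unadjusted: list[str] = []
    # batched least-squares projection of each row's observed residuals
    mask_f = has_res.astype(float)
    # gram[r] = V_obs V_obs^T restricted to the row's observed columns
    gram = np.einsum("rc,ic,jc->rij", mask_f, v, v)
    rhs = np.einsum("rc,ic->ri", np.where(has_res, res, 0.0), v)
    n_obs = has_res.sum(axis=1)
    for r_i in range(m.n_peptides):
        if n_obs[r_i] == 0:
            # non-estimable protein or fully missing row: nothing to project
            if not np.isnan(m.values[r_i]).all():
                unadjusted.append(m.peptide_ids[r_i])
            continue
        if n_obs[r_i] < k + 2:
            unadjusted.append(m.peptide_ids[r_i])
            continue
        beta = np.linalg.solve(gram[r_i], rhs[r_i])
        proj = beta @ v
        cells = has_res[r_i]
        out.values[r_i, cells] -= proj[cells]
    return NormalizationResult(out, "eigenms", n_trends_removed=k,
                               rng_seed=seed,
                               details={"anova_fit": fit,
                                        "trends": trends,
                                        "unadjusted_peptides": unadjusted})


def reinflate_residuals(r: NormalizationResult, seed: int = 0) -> NormalizationResult:
    """Re-inflate post-normalization residual variance.

    Subtracting each peptide's estimated projection onto ``k`` bias trends
    consumes ``k`` degrees of freedom per peptide: the residual covariance
    drops from ``sigma^2 I`` to ``sigma^2 (I - H)`` with ``H`` the hat matrix
    of the trend basis on the peptide's observed cells.  To keep downstream
    tests honest without carry-over covariates, fresh zero-mean Gaussian
    noise with covariance ``sigma_hat^2 H`` is added back -- i.e. the removed
    component is replaced by synthetic noise of the right size *along the
    removed directions*, restoring an isotropic residual covariance.  The
    per-peptide scale uses the df-corrected estimate
    ``sigma_hat^2 = RSS / (n_obs - k)`` (residual scatter inflated by
    ``n_obs / (n_obs - k)``).  ``k = 0`` is the identity; deterministic given
    the seed.
    """
    if r.method != "eigenms":
        raise ValueError("reinflate_residuals expects an eigenms result")
    k = r.n_trends_removed
    if k == 0:
        out = NormalizationResult(r.normalized.copy(), "eigenms_reinflated",
                                  0, r.per_sample_offsets, seed, dict(r.details))
        return out
    m = r.normalized
    fit: AnovaFit = r.details["anova_fit"]
    trends: EigentrendSet = r.details["trends"]
    v = trends.trends[:k]                      # k x N orthonormal rows
    unadjusted = set(r.details.get("unadjusted_peptides", []))
    if k >= m.n_samples:
        raise ValueError("k >= number of samples: no residual degrees of freedom")
    rng = np.random.default_rng(seed)
    out = m.copy()
    resid = m.values - fit.fitted              # post-removal residuals
    for r_i, pid in enumerate(m.peptide_ids):
        if pid in unadjusted:
            continue
        cells = ~np.isnan(resid[r_i])
        n_obs = int(cells.sum())
        if n_obs <= k:
            continue
        v_obs = v[:, cells]                    # k x n_obs
        gram = v_obs @ v_obs.T
        evals, evecs = np.linalg.eigh(gram)
        if evals[0] <= 1e-10:
            continue                           # trends indistinguishable here
        # L with L L^T = hat matrix of the trend basis on observed cells
        g_inv_half = evecs @ np.diag(evals**-0.5) @ evecs.T
        # df: leverage-corrected residual df of the model fit, minus the k
        # trend directions consumed by the projection
        nu = fit.resid_df.get(pid, float(n_obs)) - k
        if nu < 1.0:
            continue
        sigma2 = float(np.sum(resid[r_i, cells] ** 2)) / nu
        w = rng.normal(0.0, math.sqrt(sigma2), size=k)
        out.values[r_i, cells] += v_obs.T @ (g_inv_half @ w)
    return NormalizationResult(out, "eigenms_reinflated", k,
                               r.per_sample_offsets, seed, dict(r.details))
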