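"""Synthetic label-free LC-MS data with known bias and missingness.

Log-scale peptide abundances are generated from the additive model

    y_ijkm = Prot_i + Pep_ij + Treat_ik + Samp_m + eps_ijkm

where ``Prot_i`` is the protein's mean log2 abundance, ``Pep_ij`` a
sum-to-zero peptide offset, ``Treat_ik`` a sum-to-zero treatment effect
(non-zero for a configurable fraction of "differential" proteins), and
``Samp_m`` a sample-specific shift emulating loading differences.  Two
missingness mechanisms are then applied: each cell is deleted completely at
random with probability ``pi_mcar``, and of the remaining cells those whose
complete value falls below the censoring cutoff (a configured quantile of the
complete-value distribution) are deleted as left-censored.  Every cell keeps
a ground-truth mechanism label, so classification, imputation and coverage
can be scored exactly.

``inject_bias_trend`` adds a rank-1 across-sample bias (a trend vector with a
random per-peptide loading), the canonical shape of run-order or instrument
drift that SVD-based normalization targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .core import AbundanceMatrix, ProteinMap, StudyDesign

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "inject_bias_trend",
    "paper_main",
    "coverage_study",
    "null_study",
    "PRESETS",
]

#: integer codes of the per-cell mechanism labels
MECH_OBSERVED, MECH_MCAR, MECH_CENSORED = 0, 1, 2


@dataclass
class SimulationConfig:
    """Generator settings; defaults give a mid-sized two-group study.

    Variance components are on the log2 scale: protein means ~ N(20, 2^2),
    peptide offsets sd 1, sample shifts sd 0.5, residual error sd 0.5, and
    10% of proteins differential with group differences ~ N(0, 1).
    """

    n_proteins: int = 1400
    peptides_min: int = 2
    peptides_max: int = 12
    n_groups: int = 2
    samples_per_group: int = 10
    protein_mean_mu: float = 20.0
    protein_mean_sd: float = 2.0
    peptide_sd: float = 1.0
    diff_fraction: float = 0.10
    treat_sd: float = 1.0
    sample_sd: float = 0.5
    error_sd: float = 0.5
    pi_mcar: float = 0.0
    censor_quantile: float = 0.0   # quantile of the complete distribution
    cutoff: float | None = None    # explicit cutoff overrides the quantile
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.peptides_min < 1:
            raise ValueError("counts must be >= 1")
        if self.peptides_max < self.peptides_min:
            raise ValueError("peptides_max must be >= peptides_min")
        if self.samples_per_group < 2:
            raise ValueError("need >= 2 samples per group for inference")
        if self.n_groups < 2:
            raise ValueError("need >= 2 groups")
        for sd in (self.protein_mean_sd, self.peptide_sd, self.treat_sd,
                   self.sample_sd, self.error_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.pi_mcar <= 1.0:
            raise ValueError("pi_mcar must be in [0, 1]")
        if not 0.0 <= self.censor_quantile < 1.0:
            raise ValueError("censor_quantile must be in [0, 1)")
        if not 0.0 <= self.diff_fraction <= 1.0:
            raise ValueError("diff_fraction must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth for every simulated cell."""

    complete: AbundanceMatrix          # values before missingness
    true_treat_diff: dict[str, float]  # protein -> Treat_1 - Treat_2
    mechanism: np.ndarray              # int codes, same shape as the matrix
    cutoff: float                      # realized censoring threshold

    def mechanism_fractions(self) -> dict[str, float]:
        n = self.mechanism.size
        return {
            "observed": float(np.sum(self.mechanism == MECH_OBSERVED)) / n,
            "mcar": float(np.sum(self.mechanism == MECH_MCAR)) / n,
            "censored": float(np.sum(self.mechanism == MECH_CENSORED)) / n,
        }


@dataclass
class SimulatedDataset:
    matrix: AbundanceMatrix
    design: StudyDesign
    pmap: ProteinMap
    truth: SimTruth
    config: SimulationConfig


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset; bit-identical for identical configs (same seed)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_groups * cfg.samples_per_group
    group_of_sample = np.repeat(np.arange(cfg.n_groups), cfg.samples_per_group)

    n_peps = rng.integers(cfg.peptides_min, cfg.peptides_max + 1,
                          size=cfg.n_proteins)
    prot_of_row = np.repeat(np.arange(cfg.n_proteins), n_peps)
    P = int(n_peps.sum())

    prot_mean = rng.normal(cfg.protein_mean_mu, cfg.protein_mean_sd,
                           size=cfg.n_proteins)
    # sum-to-zero peptide offsets within each protein
    pep_off = rng.normal(0.0, cfg.peptide_sd, size=P)
    for i, (start, n) in enumerate(zip(np.cumsum(n_peps) - n_peps, n_peps)):
        if n > 1:
            pep_off[start:start + n] -= pep_off[start:start + n].mean()
        else:
            pep_off[start] = 0.0

    is_diff = rng.random(cfg.n_proteins) < cfg.diff_fraction
    treat = np.zeros((cfg.n_proteins, cfg.n_groups))
    if cfg.n_groups == 2:
        delta = np.where(is_diff, rng.normal(0.0, cfg.treat_sd,
                                             size=cfg.n_proteins), 0.0)
        treat[:, 0] = delta / 2.0
        treat[:, 1] = -delta / 2.0
    else:
        raw = rng.normal(0.0, cfg.treat_sd, size=(cfg.n_proteins, cfg.n_groups))
        raw -= raw.mean(axis=1, keepdims=True)
        treat = np.where(is_diff[:, None], raw, 0.0)

    samp = rng.normal(0.0, cfg.sample_sd, size=n_samples)
    eps = rng.normal(0.0, cfg.error_sd, size=(P, n_samples))

    values = (prot_mean[prot_of_row][:, None]
              + pep_off[:, None]
              + treat[prot_of_row][:, group_of_sample]
              + samp[None, :]
              + eps)

    # missingness: MCAR first, then censoring on the remainder; a cell is
    # counted under exactly one mechanism (MCAR wins ties)
    mech = np.zeros_like(values, dtype=np.int8)
    mcar_mask = rng.random(values.shape) < cfg.pi_mcar
    mech[mcar_mask] = MECH_MCAR
    if cfg.cutoff is not None:
        cut = float(cfg.cutoff)
    elif cfg.censor_quantile > 0.0:
        cut = float(np.quantile(values, cfg.censor_quantile))
    else:
        cut = -math.inf
    if cut != -math.inf:
        cens = (~mcar_mask) & (values < cut)
        mech[cens] = MECH_CENSORED

    peptide_ids = [f"PROT{p + 1:05d}_PEP{j + 1:02d}"
                   for p, n in enumerate(n_peps) for j in range(n)]
    sample_ids = [f"S{m + 1:02d}" for m in range(n_samples)]
    protein_ids = [f"PROT{p + 1:05d}" for p in range(cfg.n_proteins)]

    observed = np.where(mech == MECH_OBSERVED, values, np.nan)
    matrix = AbundanceMatrix(observed, peptide_ids, sample_ids, log_base=2.0)
    complete = AbundanceMatrix(values.copy(), list(peptide_ids),
                               list(sample_ids), log_base=2.0)
    design = StudyDesign(sample_ids, [f"G{g + 1}" for g in group_of_sample])
    pmap = ProteinMap({pid: protein_ids[prot_of_row[i]]
                       for i, pid in enumerate(peptide_ids)})
    true_diff = {protein_ids[p]: float(treat[p, 0] - treat[p, 1])
                 for p in range(cfg.n_proteins)}
    truth = SimTruth(complete, true_diff, mech, cut)
    return SimulatedDataset(matrix, design, pmap, truth, cfg)


def inject_bias_trend(m: AbundanceMatrix, trend: np.ndarray,
                      loading_sd: float, seed: int = 0) -> AbundanceMatrix:
    """Add a rank-1 sample bias: per-peptide random loading times ``trend``.

    The missing mask is untouched (bias is added to observed cells only,
    which is equivalent for downstream use since missing cells carry no
    value).
    """
    trend = np.asarray(trend, dtype=float)
    if trend.shape != (m.n_samples,):
        raise ValueError(
            f"trend length {trend.shape} does not match {m.n_samples} samples")
    if loading_sd < 0:
        raise ValueError("loading_sd must be >= 0")
    rng = np.random.default_rng(seed)
    loadings = rng.normal(0.0, loading_sd, size=m.n_peptides)
    out = m.copy()
    bias = loadings[:, None] * trend[None, :]
    obs = ~m.mask
    out.values[obs] += bias[obs]
    return out


def group_orthogonal_trend(design: StudyDesign) -> np.ndarray:
    """Unit-norm smooth across-sample trend orthogonal to the group step.

    Emulates run-order drift that is *not* confounded with the comparison
    groups (bias aligned with the groups is unremovable by any
    normalization).
    """
    n = design.n_samples
    t = np.sin(2.0 * math.pi * np.arange(n) / n)
    step = np.where(design.group_index() == 0, 1.0, -1.0)
    step /= np.linalg.norm(step)
    t = t - (t @ step) * step
    t = t - t.mean()
    nrm = np.linalg.norm(t)
    if nrm == 0:
        raise ValueError("degenerate design: cannot build an orthogonal trend")
    return t / nrm


# ---------------------------------------------------------------------------
# presets mirroring the simulation studies
# ---------------------------------------------------------------------------


def paper_main(seed: int = 0) -> SimulationConfig:
    """1400 proteins, 2 x 10 samples, 13% missing (5% MCAR + 8% censored)."""
    return SimulationConfig(n_proteins=1400, samples_per_group=10,
                            pi_mcar=0.05, censor_quantile=0.08 / 0.95,
                            seed=seed)


def coverage_study(total_missing: float = 0.0, pi_mcar: float = 0.05,
                   seed: int = 0) -> SimulationConfig:
    """200 proteins, 2 x 5 samples; total missingness set via the censoring
    quantile with the MCAR share fixed (MCAR-free when fully observed)."""
    if total_missing == 0.0:
        return SimulationConfig(n_proteins=200, samples_per_group=5, seed=seed)
    if total_missing < pi_mcar:
        pi_mcar = total_missing
    q = (total_missing - pi_mcar) / (1.0 - pi_mcar)
    return SimulationConfig(n_proteins=200, samples_per_group=5,
                            pi_mcar=pi_mcar, censor_quantile=q, seed=seed)


def null_study(seed: int = 0) -> SimulationConfig:
    """paper_main sizes with zero treatment effects everywhere."""
    return replace(paper_main(seed), diff_fraction=0.0)


PRESETS = {
    "paper_main": paper_main,
    "coverage_study": coverage_study,
    "null_study": null_study,
}
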