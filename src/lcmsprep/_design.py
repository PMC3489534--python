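"""Sum-to-zero (deviation) coded design matrices for the per-protein models.

The fixed-effects model for one protein is

    y_cell = Prot + Pep_j + Treat_k [+ Batch_b] + eps,

with Pep, Treat and Batch each constrained to sum to zero.  The free
parameterisation drops the last level of each factor and codes it as -1 on
the remaining columns, so the full effect vectors are recovered as
``full[:L-1] = free`` and ``full[L-1] = -sum(free)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def deviation_columns(index: np.ndarray, n_levels: int) -> np.ndarray:
    """Deviation-coded columns (n_cells x (n_levels - 1)) for a factor."""
    n = index.shape[0]
    cols = np.zeros((n, max(n_levels - 1, 0)))
    for lev in range(n_levels - 1):
        cols[index == lev, lev] = 1.0
    cols[index == n_levels - 1, :] = -1.0
    return cols


def expand_effects(free: np.ndarray, n_levels: int) -> np.ndarray:
    """Full sum-to-zero effect vector from its free coefficients."""
    full = np.empty(n_levels)
    full[: n_levels - 1] = free
    full[n_levels - 1] = -free.sum() if n_levels > 1 else 0.0
    return full


@dataclass
class ProteinDesign:
    """Mean-model design for all cells (observed and missing) of one protein.

    Cells are laid out peptide-major: cell ``(j, m)`` for peptide ``j`` and
    sample ``m`` sits at flat index ``j * n_samples + m``.
    """

    X: np.ndarray            # n_cells x p mean design
    peptide_of_cell: np.ndarray
    group_of_cell: np.ndarray
    n_peptides: int
    n_groups: int
    n_batches: int           # 0 when batch is not modelled

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def slices(self) -> dict[str, slice]:
        """Column slices of ``X`` per model term."""
        j, k, b = self.n_peptides, self.n_groups, self.n_batches
        out = {"intercept": slice(0, 1), "peptide": slice(1, j)}
        out["treat"] = slice(j, j + k - 1)
        if b:
            out["batch"] = slice(j + k - 1, j + k - 1 + b - 1)
        return out

    def unpack(self, beta: np.ndarray):
        """Split a free coefficient vector into named full effect vectors."""
        s = self.slices()
        prot = float(beta[0])
        pep = expand_effects(beta[s["peptide"]], self.n_peptides)
        treat = expand_effects(beta[s["treat"]], self.n_groups)
        batch = (expand_effects(beta[s["batch"]], self.n_batches)
                 if self.n_batches else None)
        return prot, pep, treat, batch


def build_protein_design(n_peptides: int, group_index: np.ndarray,
                         batch_index: np.ndarray | None = None) -> ProteinDesign:
    """Design over the full peptide x sample grid of one protein."""
    n_samples = group_index.shape[0]
    n_groups = int(group_index.max()) + 1
    pep_of_cell = np.repeat(np.arange(n_peptides), n_samples)
    grp_of_cell = np.tile(group_index, n_peptides)
    cols = [np.ones((n_peptides * n_samples, 1)),
            deviation_columns(pep_of_cell, n_peptides),
            deviation_columns(grp_of_cell, n_groups)]
    n_batches = 0
    if batch_index is not None:
        n_batches = int(batch_index.max()) + 1
        cols.append(deviation_columns(np.tile(batch_index, n_peptides), n_batches))
    X = np.hstack(cols)
    return ProteinDesign(X, pep_of_cell, grp_of_cell, n_peptides, n_groups, n_batches)


def treat_contrast_matrix(n_groups: int) -> np.ndarray:
    """Map free treatment coefficients t to differences Treat_k - Treat_K.

    With deviation coding ``Treat_K = -sum(t)``, so ``Delta = A t`` with
    ``A = I + 1`` (all-ones).  For two groups ``A = [[2]]``: the single free
    coefficient is half the group difference.
    """
    return np.eye(n_groups - 1) + np.ones((n_groups - 1, n_groups - 1))
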