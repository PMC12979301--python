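"""Bias-corrected compositional differential abundance.

Sequencing observes each sample through an unknown sampling fraction, so
raw log counts mix the biological signal with a per-sample depth bias.
Following the bias-correction idea of compositional differential
abundance analysis, this module

1. estimates a per-sample log sampling-fraction offset as the sample
   effect of a two-way model for ``log(count + 1)`` across all taxa,
   fitted by alternating least squares;
2. regresses each taxon's offset-corrected log counts on the lifestyle
   index plus covariates (Wald t-tests, Benjamini-Hochberg FDR across
   taxa); positive coefficients mean abundance rises with index points,
   i.e. with lower-risk lifestyles;
3. screens significant taxa for robustness to the pseudo-count: a taxon
   passes only if its FDR-significance decision and coefficient sign
   agree across a grid of pseudo-counts.

Taxa absent from an entire index-quintile stratum are flagged as
structural zeros and not tested.  This is a deliberately compact
re-implementation of the bias-offset + log-linear Wald idea for a single
continuous exposure; it is not a port of any published software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ConvergenceError, ValidationError
from .assoc import _as_design, bh_fdr
from .prep import FeatureTable
from .scoring import assign_quintiles

DEFAULT_PSEUDO_COUNTS = (0.1, 0.5, 1.0)
FDR_LEVEL = 0.05


@dataclass
class DAResult:
    """Per-taxon differential-abundance record set.

    ``table`` columns: ``taxon, lfc, se, W, p, q, structural_zero,
    sensitivity_pass`` (the last filled by :func:`sensitivity_screen`).
    """

    table: pd.DataFrame
    exposure_name: str = "index"

    def significant(self, level: float = FDR_LEVEL) -> pd.DataFrame:
        ok = (self.table["q"] < level) & ~self.table["structural_zero"]
        return self.table[ok]


def _design_matrix(exposure, covariates, n) -> np.ndarray:
    x = np.asarray(exposure, dtype=float)
    if x.std() == 0:
        raise ValidationError("exposure is constant")
    pieces = [np.ones((n, 1)), x[:, None]]
    cov = _as_design(covariates)
    if cov is not None:
        pieces.append(cov.to_numpy(dtype=float))
    X = np.hstack(pieces)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    return X


def estimate_sampling_bias(
    counts: FeatureTable,
    exposure,
    covariates=None,
    pseudo_count: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Per-sample log sampling-fraction offsets (mean-centered).

    Alternating least squares on ``log(count + pseudo_count)``: given
    offsets, fit per-taxon regressions on the design; the new offset is
    each sample's mean residual across taxa.  Converges when the largest
    offset update falls below ``tol``.
    """
    y = np.log(counts.data.to_numpy(dtype=float) + pseudo_count)
    n, k = y.shape
    X = _design_matrix(exposure, covariates, n)
    pinv = np.linalg.pinv(X)
    offsets = np.zeros(n)
    trace = []
    for _ in range(max_iter):
        resid = y - offsets[:, None]
        beta = pinv @ resid                  # p x k, all taxa at once
        resid = resid - X @ beta
        delta = resid.mean(axis=1)
        offsets = offsets + delta
        offsets -= offsets.mean()
        step = float(np.max(np.abs(delta - delta.mean())))
        trace.append(step)
        if step < tol:
            return offsets
    raise ConvergenceError(
        f"offset estimation did not converge in {max_iter} iterations",
        trace=trace)


def _structural_zeros(counts: np.ndarray, exposure) -> np.ndarray:
    """A taxon absent from an entire index-quintile stratum is a
    structural zero: its absence pattern is categorical, not a
    log-linear shift, so it is flagged rather than tested."""
    quintiles = assign_quintiles(np.asarray(exposure, dtype=float))
    flags = np.zeros(counts.shape[1], dtype=bool)
    for q in np.unique(quintiles):
        mask = quintiles == q
        flags |= (counts[mask].sum(axis=0) == 0) & (counts.sum(axis=0) > 0)
    return flags


def da_fit(
    counts: FeatureTable,
    exposure,
    covariates=None,
    offsets: np.ndarray | None = None,
    pseudo_count: float = 1.0,
) -> DAResult:
    """Per-taxon log-linear Wald tests of the exposure with BH FDR.

    ``offsets`` defaults to :func:`estimate_sampling_bias` on the same
    design.  All-zero taxa are excluded with a flag; structural zeros
    (absent in a whole exposure-quintile stratum) are flagged and their
    p-values set to NaN.
    """
    if counts.n_taxa < 2:
        raise ValidationError("need at least 2 taxa")
    raw = counts.data.to_numpy(dtype=float)
    n = raw.shape[0]
    X = _design_matrix(exposure, covariates, n)
    if offsets is None:
        offsets = estimate_sampling_bias(counts, exposure, covariates,
                                         pseudo_count=pseudo_count)
    y = np.log(raw + pseudo_count) - offsets[:, None]

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y                 # p x k
    resid = y - X @ beta
    dof = n - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    lfc = beta[1]
    w = lfc / se
    p = 2 * scipy.stats.t.sf(np.abs(w), dof)

    all_zero = raw.sum(axis=0) == 0
    structural = _structural_zeros(raw, exposure)
    testable = ~(all_zero | structural)
    q = np.full(p.shape, np.nan)
    if testable.any():
        q[testable] = bh_fdr(p[testable])
    p = np.where(testable, p, np.nan)

    table = pd.DataFrame({
        "taxon": counts.taxon_ids,
        "lfc": lfc, "se": se, "W": w, "p": p, "q": q,
        "all_zero": all_zero,
        "structural_zero": structural,
        "sensitivity_pass": False,
    }).set_index("taxon")
    if counts.taxonomy is not None:
        table["taxonomy"] = counts.taxonomy
    return DAResult(table)


def sensitivity_screen(
    counts: FeatureTable,
    exposure,
    covariates=None,
    pseudo_counts=DEFAULT_PSEUDO_COUNTS,
    level: float = FDR_LEVEL,
) -> pd.DataFrame:
    """Pseudo-count robustness screen.

    The fit is repeated for every pseudo-count in the grid; a taxon
    passes iff it is FDR-significant with the same coefficient sign in
    every refit.  Non-significant taxa have ``sensitivity_pass`` False
    by definition.  Returns the primary fit's table (pseudo-count 1.0,
    or the last grid entry) with the screen column filled.
    """
    if len(tuple(pseudo_counts)) == 0:
        raise ValidationError("pseudo_counts must be non-empty")
    fits = {pc: da_fit(counts, exposure, covariates, pseudo_count=pc)
            for pc in pseudo_counts}
    primary_pc = 1.0 if 1.0 in fits else tuple(pseudo_counts)[-1]
    primary = fits[primary_pc].table.copy()

    passes = np.ones(len(primary), dtype=bool)
    ref_sign = np.sign(primary["lfc"].to_numpy())
    for fit in fits.values():
        t = fit.table
        sig = (t["q"].to_numpy() < level) & ~t["structural_zero"].to_numpy()
        same_sign = np.sign(t["lfc"].to_numpy()) == ref_sign
        passes &= sig & same_sign
    primary["sensitivity_pass"] = passes
    return primary
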