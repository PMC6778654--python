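"""Sample-level ploidy and DNA admixture estimation.

**Ploidy.** Because the tumor/normal coverage ratio is normalized by the
mean coverage of each sample, an aneuploid tumor genome displaces the
logR of allelically balanced wild-type segments away from 0. Locating
that displacement (the *logR shift*) on length-weighted,
density-smoothed logR values of balanced segments gives the sample
ploidy through

    ploidy = 2 * 2**(-shift)

which is the average DNA content per cell of the sample (for an
admixed sample: ``2*G + (1 - G) * tumor ploidy``). A shift of 0 means
ploidy 2; a shift of -0.34 means ploidy 2.53. Balanced states above
diploid (4, 6, ...) produce additional modes to the right, so the
*leftmost* qualifying mode is taken; putative homozygous deletions
(lowest-logR tail) are excluded first as a confounder.

**DNA admixture** (G, the fraction of non-tumor DNA; purity = 1 - G) is
estimated locally from hemizygous deletions. A clonal hemizygous
deletion at admixture G has beta = 2G/(1+G), hence each candidate
deletion yields an *apparent admixture* G' = beta/(2-beta). Subclonal
deletions inflate G' (reads from tumor cells without the deletion are
indistinguishable from normal reads), so the sample admixture is the
mode of the lowest cluster of apparent values — the most clonal
deletions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._density import density_modes
from .beta_core import ErrorTable, default_error_table
from .errors import AdmixtureEstimationError, ShiftEstimationError

__all__ = [
    "PloidyEstimate",
    "AdmixtureEstimate",
    "ploidy_from_shift",
    "shift_from_ploidy",
    "compute_logR_shift",
    "compute_ploidy",
    "apparent_admixture_from_beta",
    "compute_dna_admixture",
]


def ploidy_from_shift(shift: float) -> float:
    """Average copies per cell implied by a wild-type logR shift."""
    return 2.0 * 2.0 ** (-shift)


def shift_from_ploidy(ploidy: float) -> float:
    """Inverse of :func:`ploidy_from_shift`."""
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    return -float(np.log2(ploidy / 2.0))


@dataclass
class PloidyEstimate:
    shift: float
    ploidy: float

    def __str__(self) -> str:
        return f"ploidy {self.ploidy:.2f} (logR shift {self.shift:+.3f})"


@dataclass
class AdmixtureEstimate:
    """Fraction of non-tumor DNA with error-propagated bounds."""

    adm: float
    adm_min: float
    adm_max: float
    n_support: int = 0

    def __str__(self) -> str:
        return (f"DNA admixture {self.adm:.2f} "
                f"[{self.adm_min:.2f}, {self.adm_max:.2f}] "
                f"({self.n_support} supporting deletions)")


def _eligible_balanced(beta_table: pd.DataFrame,
                       beta_limit_for_neutral_reads: float,
                       min_coverage: float,
                       min_required_snps: int,
                       min_n_beta: float = 0.9) -> pd.DataFrame:
    bt = beta_table
    keep = (bt["beta"].notna()
            & (bt["beta"] >= beta_limit_for_neutral_reads)
            & (bt["cov"] >= min_coverage)
            & (bt["nsnps"] >= min_required_snps)
            & bt["n_beta"].notna() & (bt["n_beta"] >= min_n_beta)
            & bt["logR"].notna())
    return bt.loc[keep]


def compute_logR_shift(beta_table: pd.DataFrame,
                       beta_limit_for_neutral_reads: float = 0.90,
                       max_homo_dels_fraction: float = 0.05,
                       min_coverage: float = 20,
                       min_required_snps: int = 10) -> float:
    """Estimate the wild-type logR shift from allelically balanced segments.

    Eligible segments have a defined beta at or above
    ``beta_limit_for_neutral_reads``, pass the coverage / SNP-count
    filters, and have a normal-sample beta >= 0.9 (germline CNV
    guard). The lowest-logR fraction ``max_homo_dels_fraction`` is
    discarded as putative homozygous deletions; the remaining logR
    values are density-smoothed with segment-length weights and the
    shift is the leftmost mode whose basin mass is at least 20% of the
    dominant mode's.

    Raises :class:`ShiftEstimationError` when no segment qualifies
    (e.g. an unanalyzable beta-vs-logR profile).
    """
    elig = _eligible_balanced(beta_table, beta_limit_for_neutral_reads,
                              min_coverage, min_required_snps)
    if elig.empty:
        raise ShiftEstimationError(
            "no allelically balanced segment passes the filters; cannot "
            "locate the wild-type logR mode", reason="no_balanced_segments")
    elig = elig.sort_values("logR")
    n_drop = int(np.floor(max_homo_dels_fraction * len(elig)))
    if n_drop:
        elig = elig.iloc[n_drop:]
    lengths = (elig["end"] - elig["start"] + 1).to_numpy(dtype=float)
    modes = density_modes(elig["logR"].to_numpy(), weights=lengths,
                          min_mass_ratio=0.2)
    return modes[0].location


def compute_ploidy(beta_table: pd.DataFrame,
                   beta_limit_for_neutral_reads: float = 0.90,
                   max_homo_dels_fraction: float = 0.05,
                   min_coverage: float = 20,
                   min_required_snps: int = 10,
                   force_shift: float | None = None) -> PloidyEstimate:
    """Sample ploidy from the wild-type logR shift.

    ``force_shift`` overrides the automatic shift search; it exists
    because conflicting (ploidy, admixture) interpretations of the same
    beta-vs-logR profile can be equally plausible, and the choice
    between them is the analyst's, guided by the diagnostic lattice
    plot — the estimator never switches interpretation on its own.
    """
    shift = (float(force_shift) if force_shift is not None else
             compute_logR_shift(beta_table, beta_limit_for_neutral_reads,
                                max_homo_dels_fraction, min_coverage,
                                min_required_snps))
    return PloidyEstimate(shift=shift, ploidy=ploidy_from_shift(shift))


def apparent_admixture_from_beta(beta) -> np.ndarray | float:
    """Apparent DNA admixture of a clonal hemizygous deletion.

    Inverts beta = 2G/(1+G): G = beta/(2 - beta); monotone increasing
    with G(0) = 0 and G(1) = 1.
    """
    arr = np.asarray(beta, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("beta must lie in [0, 1]")
    out = arr / (2.0 - arr)
    return float(out) if np.isscalar(beta) else out


def compute_dna_admixture(beta_table: pd.DataFrame,
                          ploidy: PloidyEstimate | float,
                          error_tb: ErrorTable | None = None,
                          min_coverage: float = 20,
                          min_required_snps: int = 10,
                          beta_limit_for_neutral_reads: float = 0.90,
                          logr_window_slack: float = 0.2,
                          consistency_tol: float = 0.25) -> AdmixtureEstimate:
    """Estimate DNA admixture from the most clonal hemizygous deletions.

    Candidate segments have defined beta below
    ``beta_limit_for_neutral_reads``, normal beta >= 0.9, pass the
    coverage / SNP filters, and a ploidy-adjusted
    ``logRp = logR - shift`` in ``[-1 - logr_window_slack, 0)``. Each
    candidate's apparent admixture ``G' = beta/(2 - beta)`` must be
    consistent with a clonal hemizygous deletion:
    ``|logRp - log2((1 + G')/2)| <= consistency_tol``. The admixture is
    the leftmost density mode of the retained apparent values; bounds
    re-evaluate G' at beta -/+ the error-table half-width over the
    supporting segments.

    Raises :class:`AdmixtureEstimationError` when no deletion is
    retained (copy-number-quiet profile or near-total admixture —
    indistinguishable cases that must not be silently defaulted).
    """
    if isinstance(ploidy, PloidyEstimate):
        shift = ploidy.shift
    else:
        shift = shift_from_ploidy(float(ploidy))
    if error_tb is None:
        error_tb = default_error_table()
    bt = beta_table
    cand = bt.loc[bt["beta"].notna()
                  & (bt["beta"] < beta_limit_for_neutral_reads)
                  & bt["n_beta"].notna() & (bt["n_beta"] >= 0.9)
                  & (bt["cov"] >= min_coverage)
                  & (bt["nsnps"] >= min_required_snps)
                  & bt["logR"].notna()].copy()
    cand["logRp"] = cand["logR"] - shift
    cand = cand.loc[(cand["logRp"] >= -1.0 - logr_window_slack)
                    & (cand["logRp"] < 0.0)]
    if cand.empty:
        raise AdmixtureEstimationError(
            "no hemizygous-deletion candidate segment: the profile is either "
            "copy-number quiet or near-fully admixed and cannot be resolved",
            reason="no_scna")
    g_seg = apparent_admixture_from_beta(cand["beta"].to_numpy())
    expected_logrp = np.log2((1.0 + g_seg) / 2.0)
    retained = np.abs(cand["logRp"].to_numpy() - expected_logrp) <= consistency_tol
    cand = cand.loc[retained]
    g_seg = g_seg[retained]
    if cand.empty:
        raise AdmixtureEstimationError(
            "no candidate deletion is consistent with a clonal hemizygous "
            "deletion; admixture cannot be estimated", reason="no_consistent_del")
    modes = density_modes(g_seg, min_mass_ratio=0.2)
    adm = float(np.clip(modes[0].location, 0.0, 1.0))
    support = np.abs(g_seg - adm) <= 0.1
    if not support.any():
        support = np.abs(g_seg - adm) == np.min(np.abs(g_seg - adm))
    sup = cand.loc[support]
    err = error_tb.lookup(sup["nsnps"].to_numpy(), sup["cov"].to_numpy())
    beta_sup = sup["beta"].to_numpy()
    g_lo = apparent_admixture_from_beta(np.clip(beta_sup - err, 0.0, 1.0))
    g_hi = apparent_admixture_from_beta(np.clip(beta_sup + err, 0.0, 1.0))
    adm_min = float(np.clip(min(np.median(g_lo), adm), 0.0, 1.0))
    adm_max = float(np.clip(max(np.median(g_hi), adm), 0.0, 1.0))
    return AdmixtureEstimate(adm=adm, adm_min=adm_min, adm_max=adm_max,
                             n_support=int(support.sum()))
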