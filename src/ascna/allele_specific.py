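"""Allele-specific copy number from (beta, logR) given ploidy and admixture.

With the ploidy-adjusted log ratio ``logRp = logR - shift`` and DNA
admixture ``G``, the copy numbers of the two parental alleles (the
assignment to "maternal"/"paternal" is arbitrary; outputs are ordered
as major ``cnA`` >= minor ``cnB``) are

    cnP = (beta * 2**logRp - G) / (1 - G)
    cnM = [(2 - beta)(beta * 2**logRp - G) + 2 G (1 - beta)]
          / [(1 - G) * beta]
        = ((2 - beta) * 2**logRp - G) / (1 - G)      (algebraically equal)

The simplified form of ``cnM`` is used throughout since it is defined
at beta = 0 as well. ``log2_corr`` is the logR the segment would show
in a diploid 100% pure sample, so that ``cnA + cnB = 2 * 2**log2_corr``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .beta_core import ErrorTable
from .errors import AscnaError
from .ploidy_admixture import AdmixtureEstimate, PloidyEstimate, shift_from_ploidy

__all__ = [
    "eq1_allele_specific",
    "log2_corr",
    "integer_calls",
    "compute_allele_specific_scna_table",
]


def eq1_allele_specific(beta, logRp, G):
    """Fractional allele-specific copy numbers ``(cnM, cnP)``.

    Vectorized over its arguments. Requires ``0 <= beta <= 1`` and
    ``0 <= G < 1``.
    """
    beta = np.asarray(beta, dtype=float)
    logRp = np.asarray(logRp, dtype=float)
    g = np.asarray(G, dtype=float)
    if np.any((beta < 0) | (beta > 1)):
        raise ValueError("beta must lie in [0, 1]")
    if np.any((g < 0) | (g >= 1)):
        raise ValueError("admixture G must lie in [0, 1)")
    r = np.power(2.0, logRp)
    cnP = (beta * r - g) / (1.0 - g)
    cnM = ((2.0 - beta) * r - g) / (1.0 - g)
    if cnM.ndim == 0:
        return float(cnM), float(cnP)
    return cnM, cnP


def log2_corr(logRp, G):
    """Ploidy- and purity-corrected log ratio.

    ``log2((2 * 2**logRp - 2G) / (2 (1 - G)))`` — undefined (NaN) when
    the implied tumor copy number is <= 0, e.g. a clonal homozygous
    deletion whose corrected position would be -inf.
    """
    logRp = np.asarray(logRp, dtype=float)
    g = np.asarray(G, dtype=float)
    if np.any((g < 0) | (g >= 1)):
        raise ValueError("admixture G must lie in [0, 1)")
    arg = (2.0 * np.power(2.0, logRp) - 2.0 * g) / (2.0 * (1.0 - g))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(arg > 0, np.log2(np.where(arg > 0, arg, 1.0)), np.nan)
    return float(out) if out.ndim == 0 else out


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def integer_calls(cnA, cnB, allelic_imbalance_th: float = 0.5):
    """Integer allele-specific calls, defined only near an integer.

    Each allele independently rounds (half away from zero) to its
    nearest integer; the call is defined iff the distance to that
    integer is strictly below ``allelic_imbalance_th``, otherwise NaN.
    Small negative minor-allele values above -0.2 (noise at the axis)
    are treated as 0 for the call; the fractional value is untouched.
    """
    if not (0 < allelic_imbalance_th <= 1):
        raise ValueError("allelic_imbalance_th must lie in (0, 1]")
    scalar = np.isscalar(cnA)
    cnA = np.atleast_1d(np.asarray(cnA, dtype=float))
    cnB = np.atleast_1d(np.asarray(cnB, dtype=float))

    def _call(x: np.ndarray) -> np.ndarray:
        x = np.where((x > -0.2) & (x < 0.0), 0.0, x)
        r = _round_half_away(x)
        out = np.where(np.abs(x - r) < allelic_imbalance_th, r, np.nan)
        return np.where(np.isnan(x), np.nan, out)

    a, b = _call(cnA), _call(cnB)
    if scalar:
        return float(a[0]), float(b[0])
    return a, b


def compute_allele_specific_scna_table(beta_table: pd.DataFrame,
                                       ploidy: PloidyEstimate | float,
                                       admixture: AdmixtureEstimate | float,
                                       error_tb: ErrorTable | None = None,
                                       allelic_imbalance_th: float = 0.5,
                                       ) -> pd.DataFrame:
    """Extend a beta table with allele-specific copy numbers.

    Adds ``logRp, log2_corr, cnA, cnB, cnA_int, cnB_int``. Segments
    with undefined beta still receive ``log2_corr`` (total copy number
    needs no allelic signal) but no allele-specific values. ``cnA`` and
    ``cnB`` are the major/minor fractional copy numbers; integer calls
    follow :func:`integer_calls`.
    """
    shift = (ploidy.shift if isinstance(ploidy, PloidyEstimate)
             else shift_from_ploidy(float(ploidy)))
    g = admixture.adm if isinstance(admixture, AdmixtureEstimate) else float(admixture)
    if not 0 <= g < 1:
        raise AscnaError("cannot compute allele-specific copy number at "
                         "admixture G = 1 (no tumor DNA)")
    out = beta_table.copy().reset_index(drop=True)
    out["logRp"] = out["logR"] - shift
    out["log2_corr"] = log2_corr(out["logRp"].to_numpy(), g)
    has_beta = out["beta"].notna().to_numpy()
    cnA = np.full(len(out), np.nan)
    cnB = np.full(len(out), np.nan)
    if has_beta.any():
        cnM, cnP = eq1_allele_specific(out.loc[has_beta, "beta"].to_numpy(),
                                       out.loc[has_beta, "logRp"].to_numpy(), g)
        cnA[has_beta] = np.maximum(cnM, cnP)
        cnB[has_beta] = np.minimum(cnM, cnP)
    out["cnA"] = cnA
    out["cnB"] = cnB
    out["cnA_int"], out["cnB_int"] = integer_calls(cnA, cnB, allelic_imbalance_th)
    return out
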