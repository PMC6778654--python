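"""Clonality of somatic copy-number aberrations and SNVs.

The forward model mixes three read sources at a locus: non-tumor DNA
(admixture fraction G), tumor cells carrying an aberrant allele-specific
state (a, b) at clonality c, and tumor cells with the wild-type (1, 1)
state. The per-allele read rates are

    rA = G + (1 - G) (c a + 1 - c)
    rB = G + (1 - G) (c b + 1 - c)

giving the expected signal beta = 2 min(rA, rB) / (rA + rB) and
logR = log2((rA + rB) / 2) (+ the sample's wild-type shift). A segment's
clonality is fitted by inverting this map; for a hemizygous deletion the
closed form is ``c = (1 - G') / (1 - G)`` with the apparent admixture
``G' = beta / (2 - beta)``.

For SNVs, the variant allele fraction of a mutation on m copies in a
fraction c of the tumor cells, on a segment with total tumor copy
number cnT, is ``vaf = m c (1 - G) / (2G + (1 - G) cnT)``; inversion
gives the SNV clonality and ``t_af_corr``, the VAF the variant would
show in a 100% pure sample with the same copy state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import allele_specific
from .beta_core import ErrorTable, default_error_table
from .errors import AscnaError
from .ploidy_admixture import (AdmixtureEstimate, PloidyEstimate,
                               shift_from_ploidy)

__all__ = [
    "expected_signal",
    "scna_clonality_fit",
    "ScnaFit",
    "discretize_clonality",
    "compute_scna_clonality_table",
    "snv_adjusted_vaf",
    "snv_clonality",
    "expected_snv_vaf",
    "compute_snv_clonality_table",
]

STATUSES = ("clonal", "uncertain.clonal", "uncertain.subclonal", "subclonal",
            "not.analysed")

#: weight of the logR axis in the squared fit distance
LOGR_WEIGHT = 0.25
#: residual above which a segment is left unexplained
FIT_TOLERANCE = 0.05
#: residual margin within which competing states count as tied
TIE_MARGIN = 0.0075


def expected_signal(a: float, b: float, c: float, G: float,
                    shift: float = 0.0) -> tuple[float, float]:
    """Expected (beta, logR) of state (a, b) at clonality c and admixture G.

    A fully deleted locus (both read rates 0) maps to
    ``(beta, logR) = (1, -inf)``.
    """
    if not (0 <= c <= 1):
        raise ValueError("clonality c must lie in [0, 1]")
    if not (0 <= G <= 1):
        raise ValueError("admixture G must lie in [0, 1]")
    if b < 0 or a < b:
        raise ValueError("allele copies must satisfy 0 <= b <= a")
    rA = G + (1.0 - G) * (c * a + 1.0 - c)
    rB = G + (1.0 - G) * (c * b + 1.0 - c)
    s = rA + rB
    if s <= 0:
        return 1.0, float("-inf")
    beta = 2.0 * min(rA, rB) / s
    return beta, float(np.log2(s / 2.0)) + shift


def _fit_distance(c: float, a: int, b: int, G: float, beta_obs: float,
                  logr_obs: float) -> float:
    beta_exp, logr_exp = expected_signal(a, b, c, G)
    if not np.isfinite(logr_exp):
        return float("inf")
    return (beta_exp - beta_obs) ** 2 + LOGR_WEIGHT * (logr_exp - logr_obs) ** 2


def _best_c(a: int, b: int, G: float, beta_obs: float,
            logr_obs: float) -> tuple[float, float]:
    """Clonality minimizing the fit distance for one state.

    For the hemizygous deletion the closed form
    ``c = (1 - G') / (1 - G)`` (G' the apparent admixture) is evaluated
    as an analytic candidate — it is exact whenever the observed signal
    is consistent with the state — alongside the numeric optimum.
    """
    closed: tuple[float, float] | None = None
    if (a, b) == (1, 0):
        g_app = beta_obs / (2.0 - beta_obs)
        c = float(np.clip((1.0 - g_app) / (1.0 - G), 0.0, 1.0))
        closed = (c, _fit_distance(c, a, b, G, beta_obs, logr_obs))
    # coarse grid then bounded refinement; the distance is smooth in c
    grid = np.linspace(0.0, 1.0, 21)
    vals = [_fit_distance(c, a, b, G, beta_obs, logr_obs) for c in grid]
    i = int(np.argmin(vals))
    best = (float(grid[i]), float(vals[i]))
    lo, hi = grid[max(0, i - 1)], grid[min(len(grid) - 1, i + 1)]
    if hi - lo > 1e-12:
        res = optimize.minimize_scalar(
            _fit_distance, bounds=(lo, hi), method="bounded",
            args=(a, b, G, beta_obs, logr_obs), options={"xatol": 1e-6})
        if res.fun <= best[1]:
            best = (float(np.clip(res.x, 0.0, 1.0)), float(res.fun))
    if closed is not None and closed[1] <= best[1]:
        best = closed
    return best


@dataclass
class ScnaFit:
    """Result of fitting one segment's (beta, logRp) to an aberrant state."""

    state: tuple[int, int] | None
    clonality: float
    clonality_min: float
    clonality_max: float
    residual: float
    analysed: bool


def scna_clonality_fit(beta: float, logRp: float,
                       beta_min: float, beta_max: float,
                       G: float, G_min: float, G_max: float,
                       max_cn: int = 8,
                       beta_threshold: float = 0.9,
                       fit_tolerance: float = FIT_TOLERANCE) -> ScnaFit:
    """Fit the aberrant state and clonality of a single segment.

    Wild-type segments (beta >= ``beta_threshold`` and |logRp| <= 0.1)
    are not analysed. Otherwise every integer state 0 <= b <= a <=
    ``max_cn`` except (1, 1) is scored by the squared (beta, logR)
    distance (logR weighted by 0.25) minimized over clonality; the
    minimal-residual state wins. The map is exactly degenerate along
    some directions (e.g. a clonal (2, 1) gain equals a 50%-subclonal
    (3, 1)), so states whose residual is within a small margin of the
    best are tie-broken by parsimony: smallest total copy number, then
    highest clonality. Clonality bounds refit the winning state at
    (beta_min, G_max) and (beta_max, G_min). A residual above
    ``fit_tolerance`` marks the segment not analysed — its signal does
    not fit any single-state mixture.
    """
    if G >= 1:
        raise AscnaError("clonality undefined at admixture G = 1")
    if np.isnan(beta) or np.isnan(logRp):
        return ScnaFit(None, np.nan, np.nan, np.nan, np.nan, False)
    if beta >= beta_threshold and abs(logRp) <= 0.1:
        return ScnaFit(None, np.nan, np.nan, np.nan, 0.0, False)
    fits = []
    for a in range(max_cn + 1):
        for b in range(a + 1):
            if (a, b) == (1, 1):
                continue
            c, dist = _best_c(a, b, G, beta, logRp)
            fits.append((dist, (a, b), c))
    dmin = min(f[0] for f in fits)
    tied = [f for f in fits if f[0] <= dmin + TIE_MARGIN]
    dist, state, c = min(tied, key=lambda f: (sum(f[1]), -f[2]))
    if dist > fit_tolerance:
        return ScnaFit(state, np.nan, np.nan, np.nan, dist, False)
    c_lo, _ = _best_c(*state, min(G_max, 0.999),
                      float(np.clip(beta_min, 0, 1)), logRp)
    c_hi, _ = _best_c(*state, max(G_min, 0.0),
                      float(np.clip(beta_max, 0, 1)), logRp)
    cs = [c, c_lo, c_hi]
    return ScnaFit(state, float(c), float(min(cs)), float(max(cs)),
                   float(dist), True)


def discretize_clonality(clonality: float, clonality_min: float,
                         clonality_max: float,
                         clonality_threshold: float = 0.85) -> str:
    """Discretize a clonality estimate with its bounds.

    clonal            : even the lower bound clears the threshold;
    uncertain.clonal  : the estimate clears it but the lower bound does not;
    uncertain.subclonal: the estimate is below but the upper bound is not;
    subclonal         : even the upper bound is below the threshold.
    """
    if np.isnan(clonality):
        return "not.analysed"
    if clonality_min > clonality or clonality > clonality_max:
        raise ValueError("clonality bounds must bracket the estimate")
    if clonality_min >= clonality_threshold:
        return "clonal"
    if clonality >= clonality_threshold:
        return "uncertain.clonal"
    if clonality_max >= clonality_threshold:
        return "uncertain.subclonal"
    return "subclonal"


def compute_scna_clonality_table(beta_table: pd.DataFrame,
                                 ploidy: PloidyEstimate | float,
                                 admixture: AdmixtureEstimate,
                                 error_tb: ErrorTable | None = None,
                                 clonality_threshold: float = 0.85,
                                 beta_threshold: float = 0.9,
                                 max_cn: int = 8) -> pd.DataFrame:
    """Extend a beta table with per-segment clonality calls.

    Adds ``clonality, clonality_min, clonality_max, clonality_status``
    on top of the allele-specific columns. Segments with undefined
    beta, wild-type signal, or a residual that no single aberrant state
    explains are reported as ``not.analysed``.
    """
    if error_tb is None:
        error_tb = default_error_table()
    ascn = allele_specific.compute_allele_specific_scna_table(
        beta_table, ploidy, admixture, error_tb)
    g, g_min, g_max = admixture.adm, admixture.adm_min, admixture.adm_max
    clon = np.full(len(ascn), np.nan)
    clo = np.full(len(ascn), np.nan)
    chi = np.full(len(ascn), np.nan)
    status = np.full(len(ascn), "not.analysed", dtype=object)
    for i, row in enumerate(ascn.itertuples(index=False)):
        if np.isnan(row.beta) or not np.isfinite(row.logRp):
            continue
        fit = scna_clonality_fit(row.beta, row.logRp, row.beta_min,
                                 row.beta_max, g, g_min, g_max,
                                 max_cn=max_cn, beta_threshold=beta_threshold)
        if not fit.analysed:
            continue
        clon[i], clo[i], chi[i] = fit.clonality, fit.clonality_min, fit.clonality_max
        status[i] = discretize_clonality(fit.clonality, fit.clonality_min,
                                         fit.clonality_max, clonality_threshold)
    ascn["clonality"] = clon
    ascn["clonality_min"] = clo
    ascn["clonality_max"] = chi
    ascn["clonality_status"] = status
    return ascn


# ---------------------------------------------------------------------------
# SNVs


def snv_adjusted_vaf(vaf: float, G: float, cnT: float) -> float:
    """VAF rescaled to a 100% pure sample with the same copy state."""
    if cnT <= 0:
        raise ValueError("total tumor copy number cnT must be positive")
    if G >= 1:
        raise ValueError("admixture G must be < 1")
    return vaf * (2.0 * G + (1.0 - G) * cnT) / ((1.0 - G) * cnT)


def snv_clonality(vaf: float, G: float, cnT: float, m: int = 1) -> float:
    """Fraction of tumor cells carrying an SNV of multiplicity ``m``.

    Capped at 1: sampling noise can push the raw value above the
    physical maximum.
    """
    if m < 1:
        raise ValueError("multiplicity m must be >= 1")
    if cnT <= 0:
        raise ValueError("total tumor copy number cnT must be positive")
    if G >= 1:
        raise ValueError("admixture G must be < 1")
    raw = vaf * (2.0 * G + (1.0 - G) * cnT) / ((1.0 - G) * m)
    return min(1.0, raw)


def expected_snv_vaf(clonality: float, G: float, cnT: float,
                     m: int = 1) -> float:
    """Forward model: VAF of an SNV at the given clonality (inverse of
    :func:`snv_clonality` below the cap)."""
    return clonality * m * (1.0 - G) / (2.0 * G + (1.0 - G) * cnT)


def _locate_segments(snv_tb: pd.DataFrame, segments: pd.DataFrame) -> np.ndarray:
    """Index (into ``segments``) of the segment containing each SNV, or -1."""
    out = np.full(len(snv_tb), -1, dtype=np.int64)
    for chrom, seg_group in segments.groupby("chrom"):
        mask = (snv_tb["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        pos = snv_tb.loc[mask, "pos"].to_numpy()
        starts = seg_group["start"].to_numpy()
        ends = seg_group["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        seg_idx = seg_group.index.to_numpy()[order]
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos <= ends[np.clip(j, 0, None)])
        res = np.where(ok, seg_idx[np.clip(j, 0, None)], -1)
        out[np.flatnonzero(mask)] = res
    return out


def _choose_multiplicity(vaf: float, G: float, cnT: float,
                         cnA_int: float) -> int:
    """Smallest multiplicity in 1..max(1, cnA_int) with clonality <= 1.05."""
    top = int(cnA_int) if np.isfinite(cnA_int) and cnA_int >= 1 else 1
    for m in range(1, top + 1):
        raw = vaf * (2.0 * G + (1.0 - G) * cnT) / ((1.0 - G) * m)
        if raw <= 1.05:
            return m
    return 1


def compute_snv_clonality_table(snv_tb: pd.DataFrame,
                                beta_table: pd.DataFrame,
                                ploidy: PloidyEstimate | float,
                                admixture: AdmixtureEstimate,
                                error_tb: ErrorTable | None = None,
                                error_rate: float = 0.05,
                                clonality_threshold: float = 0.85,
                                ) -> pd.DataFrame:
    """Extend an SNV read-count table with clonality calls.

    Each SNV is mapped to the unique segment containing it (unmapped
    SNVs are not analysed) and annotated with the segment's fractional
    ``cnA``/``cnB``, the adjusted VAF ``t_af_corr``, the chosen
    multiplicity, and the clonality with bounds from the admixture
    bounds. SNVs whose adjusted VAF falls in the upper ``error_rate``
    tail of the sample's adjusted-VAF distribution are flagged
    ``excluded`` (likely copy-state or mapping artifacts).
    """
    if snv_tb.empty:
        out = snv_tb.copy()
        for col in ("vaf", "cnA", "cnB", "t_af_corr", "multiplicity",
                    "SNV_clonality", "SNV_clonality_min", "SNV_clonality_max"):
            out[col] = pd.Series(dtype=float)
        out["SNV_clonality_status"] = pd.Series(dtype=object)
        out["excluded"] = pd.Series(dtype=bool)
        return out
    ascn = allele_specific.compute_allele_specific_scna_table(
        beta_table, ploidy, admixture, error_tb)
    g, g_min, g_max = admixture.adm, admixture.adm_min, admixture.adm_max
    g_max = min(g_max, 0.999)
    seg_of = _locate_segments(snv_tb, ascn)
    n = len(snv_tb)
    depth = (snv_tb["rc_ref_tumor"] + snv_tb["rc_alt_tumor"]).to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0,
                       snv_tb["rc_alt_tumor"].to_numpy(float) / depth, np.nan)
    cnA = np.full(n, np.nan)
    cnB = np.full(n, np.nan)
    t_af_corr = np.full(n, np.nan)
    mult = np.full(n, np.nan)
    clon = np.full(n, np.nan)
    clo = np.full(n, np.nan)
    chi = np.full(n, np.nan)
    status = np.full(n, "not.analysed", dtype=object)
    for i in range(n):
        j = seg_of[i]
        if j < 0 or np.isnan(vaf[i]):
            continue
        seg = ascn.iloc[j]
        if np.isnan(seg["cnA"]) or np.isnan(seg["cnB"]):
            continue
        cnt = float(seg["cnA"] + seg["cnB"])
        if cnt <= 0:
            continue
        cnA[i], cnB[i] = seg["cnA"], seg["cnB"]
        t_af_corr[i] = snv_adjusted_vaf(vaf[i], g, cnt)
        m = _choose_multiplicity(vaf[i], g, cnt, seg["cnA_int"])
        mult[i] = m
        est = snv_clonality(vaf[i], g, cnt, m)
        at_gmin = snv_clonality(vaf[i], g_min, cnt, m)
        at_gmax = snv_clonality(vaf[i], g_max, cnt, m)
        clon[i] = est
        clo[i] = min(est, at_gmin, at_gmax)
        chi[i] = max(est, at_gmin, at_gmax)
        status[i] = discretize_clonality(clon[i], clo[i], chi[i],
                                         clonality_threshold)
    out = snv_tb.copy().reset_index(drop=True)
    out["vaf"] = vaf
    out["cnA"] = cnA
    out["cnB"] = cnB
    out["t_af_corr"] = t_af_corr
    out["multiplicity"] = mult
    out["SNV_clonality"] = clon
    out["SNV_clonality_min"] = clo
    out["SNV_clonality_max"] = chi
    out["SNV_clonality_status"] = status
    defined = ~np.isnan(t_af_corr)
    excluded = np.zeros(n, dtype=bool)
    if defined.any() and 0 < error_rate < 1:
        cutoff = np.nanquantile(t_af_corr, 1.0 - error_rate)
        excluded = defined & (t_af_corr > cutoff)
    out["excluded"] = excluded
    return out
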