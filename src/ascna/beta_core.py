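"""Per-segment beta estimation from informative SNPs.

*beta* is the fraction of sequencing reads over a genomic segment that
are allelically neutral, i.e. drawn equally from both parental
chromosomes: 1 for an allelically balanced segment, 0 for a pure clonal
hemizygous deletion. It is estimated from *informative SNPs* — loci
heterozygous in the matched normal — whose tumor allelic fractions
concentrate at ``beta/2`` and ``1 - beta/2``.

The estimator maximizes the folded two-component binomial mixture
log-likelihood

    L(b) = sum_i log[ 1/2 B(k_i; n_i, b/2) + 1/2 B(k_i; n_i, 1 - b/2) ]

with ``k_i = round(af_i * cov_i)`` and ``n_i = cov_i`` (pileups store
allelic fractions, not raw counts), over ``b`` on a 0.001 grid followed
by bounded golden-section refinement. Reference-mapping bias is
ignored.

The module also builds the Monte-Carlo *error table*: the expected
half-width of the beta estimate for each (number of informative SNPs,
coverage) combination, used downstream to propagate uncertainty into
admixture and clonality bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import AscnaError

__all__ = [
    "select_informative_snps",
    "estimate_beta",
    "compute_beta_table",
    "summarize_beta_table",
    "BetaTableSummary",
    "ErrorTable",
    "build_error_table",
    "default_error_table",
]

_LOG_HALF = float(np.log(0.5))
_GRID = np.round(np.linspace(0.0, 1.0, 1001), 6)


def select_informative_snps(pileup_normal: pd.DataFrame,
                            pileup_tumor: pd.DataFrame,
                            min_af_het_snps: float = 0.2,
                            max_af_het_snps: float = 0.8) -> pd.DataFrame:
    """Intersect the two pileups and keep SNPs heterozygous in the normal.

    A SNP is *informative* when it is present in both pileups and its
    allelic fraction in the normal sample lies within
    ``[min_af_het_snps, max_af_het_snps]``.

    Returns a DataFrame with columns
    ``chrom, pos, af_tumor, cov_tumor, af_normal, cov_normal``.
    """
    merged = pileup_tumor.merge(
        pileup_normal, on=["chrom", "pos"], suffixes=("_tumor", "_normal"),
        how="inner")
    keep = (merged["af_normal"] >= min_af_het_snps) & \
           (merged["af_normal"] <= max_af_het_snps)
    out = merged.loc[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn("no informative SNP found in the pileup intersection",
                      stacklevel=2)
    return out


def _folded_loglik(b: np.ndarray, k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorized folded-mixture log-likelihood for each value in ``b``."""
    b = np.atleast_1d(np.asarray(b, dtype=float))
    p = b[:, None] / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        lp1 = stats.binom.logpmf(k[None, :], n[None, :], p)
        lp2 = stats.binom.logpmf(k[None, :], n[None, :], 1.0 - p)
    return np.logaddexp(_LOG_HALF + lp1, _LOG_HALF + lp2).sum(axis=1)


def estimate_beta(af: np.ndarray, cov: np.ndarray) -> tuple[float, int, float]:
    """Estimate beta from tumor allelic fractions and coverages.

    Parameters
    ----------
    af, cov
        Allelic fraction and read depth of the informative SNPs in one
        segment.

    Returns
    -------
    (beta, nsnps, mean_cov)
        ``beta`` is NaN when no SNP with positive coverage is
        available (undefined, not an exception). ``mean_cov`` is the
        mean coverage over all supplied SNPs.
    """
    af = np.asarray(af, dtype=float)
    cov = np.asarray(cov, dtype=float)
    nsnps = int(af.size)
    if nsnps == 0:
        return float("nan"), 0, float("nan")
    mean_cov = float(cov.mean())
    usable = cov > 0
    if not usable.any():
        return float("nan"), nsnps, mean_cov
    n = np.round(cov[usable]).astype(np.int64)
    k = np.clip(np.round(af[usable] * n), 0, n).astype(np.int64)
    ll = _folded_loglik(_GRID, k, n)
    b0 = _GRID[int(np.argmax(ll))]
    lo, hi = max(0.0, b0 - 0.001), min(1.0, b0 + 0.001)
    res = optimize.minimize_scalar(
        lambda b: -_folded_loglik(np.array([b]), k, n)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6})
    beta = float(np.clip(res.x, 0.0, 1.0))
    return beta, nsnps, mean_cov


def _segment_snp_indices(segments: pd.DataFrame,
                         snps: pd.DataFrame) -> list[np.ndarray]:
    """Indices of SNPs contained in each segment (1-based inclusive)."""
    out: list[np.ndarray] = []
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): g.sort_values("pos") for c, g in snps.groupby("chrom")}
    for row in segments.itertuples(index=False):
        g = by_chrom.get(str(row.chrom))
        if g is None:
            out.append(np.empty(0, dtype=np.int64))
            continue
        pos = g["pos"].to_numpy()
        i0 = np.searchsorted(pos, row.start, side="left")
        i1 = np.searchsorted(pos, row.end, side="right")
        out.append(g.index.to_numpy()[i0:i1])
    return out


def compute_beta_table(seg_tb: pd.DataFrame,
                       pileup_tumor: pd.DataFrame,
                       pileup_normal: pd.DataFrame,
                       min_af_het_snps: float = 0.2,
                       max_af_het_snps: float = 0.8,
                       min_required_snps: int = 10,
                       min_coverage: float = 20,
                       error_tb: "ErrorTable | None" = None,
                       n_jobs: int = 1) -> pd.DataFrame:
    """Extend the segment table with beta estimates.

    For every input segment the output reports ``beta`` (tumor),
    ``nsnps`` (informative-SNP count), ``cov`` (mean tumor coverage at
    informative SNPs), ``n_beta`` (the same estimator run on the
    matched normal pileup — expected to be 1 except over germline
    copy-number variants) and the error-table bounds
    ``beta_min``/``beta_max``. ``beta`` and ``n_beta`` are defined iff
    ``nsnps >= min_required_snps`` and ``cov >= min_coverage``.
    """
    snps = select_informative_snps(pileup_normal, pileup_tumor,
                                   min_af_het_snps, max_af_het_snps)
    if error_tb is None:
        error_tb = default_error_table()
    groups = _segment_snp_indices(seg_tb, snps)
    if snps.empty or all(len(g) == 0 for g in groups):
        warnings.warn("no informative SNP overlaps any segment; "
                      "all beta values are undefined", stacklevel=2)

    def _one(idx: np.ndarray) -> tuple[float, int, float, float]:
        sub = snps.loc[idx]
        beta, nsnps, cov = estimate_beta(sub["af_tumor"].to_numpy(),
                                         sub["cov_tumor"].to_numpy())
        n_beta, _, _ = estimate_beta(sub["af_normal"].to_numpy(),
                                     sub["cov_normal"].to_numpy())
        return beta, nsnps, cov, n_beta

    if n_jobs != 1:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=n_jobs)(delayed(_one)(g) for g in groups)
    else:
        results = [_one(g) for g in groups]

    out = seg_tb.copy().reset_index(drop=True)
    res = pd.DataFrame(results, columns=["beta", "nsnps", "cov", "n_beta"])
    retained = (res["nsnps"] >= min_required_snps) & (res["cov"] >= min_coverage)
    res.loc[~retained, ["beta", "n_beta"]] = np.nan
    err = np.where(
        retained,
        error_tb.lookup(res["nsnps"].to_numpy(), res["cov"].to_numpy()),
        np.nan)
    out[["beta", "nsnps", "cov", "n_beta"]] = res
    out["beta_min"] = np.clip(res["beta"] - err, 0.0, 1.0)
    out["beta_max"] = np.clip(res["beta"] + err, 0.0, 1.0)
    return out


@dataclass
class BetaTableSummary:
    """Sanity-check summary of a beta table."""

    sample: str
    n_segments: int
    n_valid_beta: int
    length_quantiles: dict[int, float] | None
    coverage_quantiles: dict[int, float] | None
    nsnps_quantiles: dict[int, float] | None

    @property
    def valid_beta_label(self) -> str:
        if self.n_segments == 0:
            return "0 (0%)"
        pct = round(100.0 * self.n_valid_beta / self.n_segments)
        return f"{self.n_valid_beta} ({pct:.0f}%)"

    def __str__(self) -> str:  # human-readable console report
        lines = [
            f"Computed beta table of sample \"{self.sample}\"",
            f"Number of processed segments: {self.n_segments}",
            f"Number of segments with valid beta: {self.valid_beta_label}",
        ]
        for title, q in (("input segment lengths", self.length_quantiles),
                         ("input segment coverage", self.coverage_quantiles),
                         ("number of informative SNPs per input segment",
                          self.nsnps_quantiles)):
            lines.append(f"Quantiles of {title}:")
            if q is None:
                lines.append("  undefined (empty table)")
            else:
                lines.extend(f"  {p}%: {v:g}" for p, v in q.items())
        return "\n".join(lines)


def summarize_beta_table(beta_table: pd.DataFrame) -> BetaTableSummary:
    """Counts and 0/25/50/75/100% quantiles of a beta table.

    Quantiles cover segment length (bp, inclusive coordinates), mean
    coverage at informative SNPs, and informative-SNP counts; all are
    reported as undefined for an empty table.
    """
    sample = str(beta_table["sample"].iloc[0]) if len(beta_table) else "?"
    n = len(beta_table)
    valid = int(beta_table["beta"].notna().sum()) if n else 0

    def _q(values: np.ndarray) -> dict[int, float] | None:
        values = values[~np.isnan(values)]
        if values.size == 0:
            return None
        pts = np.percentile(values, [0, 25, 50, 75, 100])
        return dict(zip((0, 25, 50, 75, 100), map(float, pts)))

    if n:
        lengths = (beta_table["end"] - beta_table["start"] + 1).to_numpy(float)
        covs = beta_table["cov"].to_numpy(float)
        nsnps = beta_table["nsnps"].to_numpy(float)
    else:
        lengths = covs = nsnps = np.empty(0)
    return BetaTableSummary(sample, n, valid, _q(lengths), _q(covs), _q(nsnps))


# ---------------------------------------------------------------------------
# Error table


@dataclass
class ErrorTable:
    """Beta-estimate uncertainty by (informative-SNP count, coverage).

    ``table`` has columns ``nsnps, cov, error`` on a Cartesian grid;
    ``error`` is the symmetric half-width such that
    ``|estimate - truth| <= error`` with probability ``confidence``
    (worst case over the true-beta grid used at build time). Lookups at
    off-grid points use the nearest available grid pair.
    """

    table: pd.DataFrame
    confidence: float = 0.9
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._nsnps = np.sort(self.table["nsnps"].unique())
        self._cov = np.sort(self.table["cov"].unique())
        self._err = {}
        for row in self.table.itertuples(index=False):
            self._err[(int(row.nsnps), int(row.cov))] = float(row.error)

    @staticmethod
    def _nearest(grid: np.ndarray, values: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(grid, values)
        idx = np.clip(idx, 1, len(grid) - 1)
        left, right = grid[idx - 1], grid[idx]
        # ties go to the smaller grid value
        return np.where(values - left <= right - values, left, right)

    def lookup(self, nsnps, cov) -> np.ndarray:
        """Half-width for each (nsnps, cov), nearest-grid-pair rule."""
        nsnps = np.atleast_1d(np.asarray(nsnps, dtype=float))
        cov = np.atleast_1d(np.asarray(cov, dtype=float))
        m = self._nearest(self._nsnps.astype(float), nsnps)
        c = self._nearest(self._cov.astype(float), cov)
        return np.array([self._err[(int(mi), int(ci))]
                         for mi, ci in zip(m, c)])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# confidence={self.confidence}")
            for key, val in sorted(self.meta.items()):
                fh.write(f" {key}={val}")
            fh.write("\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ErrorTable":
        meta: dict = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    key, _, val = tok.partition("=")
                    meta[key] = val
            else:
                raise AscnaError("error table file lacks the metadata header")
        table = pd.read_csv(path, sep="\t", comment="#")
        confidence = float(meta.pop("confidence", 0.9))
        return cls(table=table, confidence=confidence, meta=meta)


def _batch_grid_mle(rng: np.random.Generator, m: int, c: int, beta: float,
                    reps: int, logmix: np.ndarray) -> np.ndarray:
    """Grid-resolution beta MLEs for ``reps`` replicates of m SNPs at cov c.

    Uses the same folded-mixture likelihood as :func:`estimate_beta`,
    evaluated on the 0.001 grid only (refinement is below the grid
    resolution, which is itself below Monte-Carlo noise at the
    replicate counts used here). ``logmix`` is the precomputed
    (grid x coverage+1) log-likelihood matrix for coverage ``c``.
    """
    comp = rng.random((reps, m)) < 0.5
    p = np.where(comp, beta / 2.0, 1.0 - beta / 2.0)
    ks = rng.binomial(c, p)
    offsets = np.arange(reps)[:, None] * (c + 1)
    counts = np.bincount((ks + offsets).ravel(),
                         minlength=reps * (c + 1)).reshape(reps, c + 1)
    ll = counts.astype(float) @ logmix.T
    return _GRID[np.argmax(ll, axis=1)]


def build_error_table(nsnps_grid=(5, 10, 20, 50, 100, 200, 400),
                      cov_grid=(10, 20, 50, 100, 200, 500),
                      beta_grid=(0.2, 0.5, 0.8, 1.0),
                      reps: int = 1000,
                      confidence: float = 0.9,
                      seed: int = 0) -> ErrorTable:
    """Monte-Carlo error table for the beta estimator.

    For each grid pair (m SNPs, coverage c) and each true beta in
    ``beta_grid``, ``reps`` replicate segments are simulated (binomial
    allelic fractions at fixed coverage) and re-estimated; the recorded
    error is the ``confidence``-level quantile of ``|estimate - truth|``,
    maximized over ``beta_grid``. Deterministic given ``seed``.
    """
    if not len(nsnps_grid) or not len(cov_grid) or not len(beta_grid):
        raise AscnaError("error-table grids must be non-empty")
    if reps < 100:
        raise AscnaError("reps must be >= 100 for a stable quantile")
    rng = np.random.default_rng(seed)
    rows = []
    for c in sorted(int(v) for v in cov_grid):
        ks = np.arange(c + 1)
        p = _GRID[:, None] / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            lp1 = stats.binom.logpmf(ks[None, :], c, p)
            lp2 = stats.binom.logpmf(ks[None, :], c, 1.0 - p)
        # floor -inf cells so that 0 * -inf cannot produce NaN in the matmul
        logmix = np.maximum(np.logaddexp(_LOG_HALF + lp1, _LOG_HALF + lp2),
                            -1e30)
        for m in sorted(int(v) for v in nsnps_grid):
            worst = 0.0
            for beta in beta_grid:
                est = _batch_grid_mle(rng, m, c, float(beta), reps, logmix)
                err = float(np.quantile(np.abs(est - beta), confidence))
                worst = max(worst, err)
            rows.append((m, c, worst))
    table = pd.DataFrame(rows, columns=["nsnps", "cov", "error"])
    meta = {"reps": reps, "seed": seed,
            "beta_grid": ",".join(str(b) for b in beta_grid)}
    return ErrorTable(table=table.sort_values(["nsnps", "cov"])
                      .reset_index(drop=True),
                      confidence=confidence, meta=meta)


@lru_cache(maxsize=1)
def default_error_table() -> ErrorTable:
    """The packaged pre-computed error table (see ``data/`` and
    ``scripts/build_default_error_table.py`` for its provenance)."""
    ref = resources.files("ascna").joinpath("data/error_table_default.tsv")
    with resources.as_file(ref) as path:
        return ErrorTable.from_tsv(path)
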