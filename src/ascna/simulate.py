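"""Synthetic matched tumor/normal data with known truth.

The generator realizes the same cell-mixture model the estimators
invert: reads at a locus come from non-tumor DNA (admixture fraction G),
tumor cells carrying the segment's aberrant state (a, b) at clonality c,
and wild-type tumor cells. Informative-SNP positions are placed at the
density expected from common SNPs (~0.33 per kb by default); the normal
allelic fraction is Binomial(cov, 0.5)/cov; the tumor allelic fraction
is Binomial(cov_t, p)/cov_t with p the read rate of the allele carrying
the alternative base (assigned to either parental allele with
probability 1/2 per SNP). Per-SNP coverage is Poisson around the mean,
with the tumor mean scaled by the local DNA content relative to the
genome-wide average — the same normalization that produces the
wild-type logR shift in aneuploid genomes. Segment logR values receive
Gaussian noise (sd 0.05 by default). SNV read counts are binomial
around the VAF implied by the SNV's multiplicity and clonality.

Reference-mapping bias is not simulated (the estimators ignore it too).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tables_io
from .errors import AscnaError

__all__ = ["SegmentSpec", "SNVSpec", "TumorModel", "SimulatedTumor",
           "simulate_tumor", "random_tumor_model", "make_fixture_suite",
           "FIXTURE_NAMES"]


@dataclass(frozen=True)
class SegmentSpec:
    """One genomic segment of the truth model."""

    chrom: str
    start: int
    end: int
    cn_a: int = 1
    cn_b: int = 1
    clonality: float = 1.0

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def tumor_total_cn(self) -> float:
        """Clonality-mixed total copy number in tumor cells."""
        c = self.clonality
        return c * (self.cn_a + self.cn_b) + (1.0 - c) * 2.0


@dataclass(frozen=True)
class SNVSpec:
    chrom: str
    pos: int
    multiplicity: int = 1
    clonality: float = 1.0


@dataclass
class TumorModel:
    """Fully specified synthetic tumor sample."""

    admixture: float
    segments: list[SegmentSpec]
    snvs: list[SNVSpec] = field(default_factory=list)
    mean_coverage_tumor: float = 100.0
    mean_coverage_normal: float = 100.0
    snps_per_kb: float = 0.33
    logr_noise_sd: float = 0.05
    sample: str = "sim1"

    def __post_init__(self) -> None:
        if not (0 <= self.admixture < 1):
            raise AscnaError("admixture must lie in [0, 1)")
        if self.snps_per_kb <= 0:
            raise AscnaError("informative-SNP density must be positive")
        if not self.segments:
            raise AscnaError("the model needs at least one segment")
        by_chrom: dict[str, list[SegmentSpec]] = {}
        for seg in self.segments:
            if seg.end < seg.start:
                raise AscnaError(f"segment {seg} has end < start")
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for segs in by_chrom.values():
            segs = sorted(segs, key=lambda s: s.start)
            for prev, cur in zip(segs[:-1], segs[1:]):
                if cur.start <= prev.end:
                    raise AscnaError(
                        f"segments overlap on {cur.chrom}: {prev} / {cur}")

    @property
    def tumor_ploidy(self) -> float:
        """Length-weighted mean total copy number of the tumor cells."""
        w = np.array([s.length for s in self.segments], dtype=float)
        cn = np.array([s.tumor_total_cn for s in self.segments])
        return float(np.average(cn, weights=w))

    @property
    def sample_ploidy(self) -> float:
        """Average DNA content per cell of the admixed sample — the
        quantity the logR-shift ploidy estimator measures."""
        g = self.admixture
        return 2.0 * g + (1.0 - g) * self.tumor_ploidy

    @property
    def logr_shift(self) -> float:
        """Expected wild-type logR shift under coverage normalization."""
        return float(np.log2(2.0 / self.sample_ploidy))

    def _read_rates(self, seg: SegmentSpec) -> tuple[float, float]:
        g, c = self.admixture, seg.clonality
        rA = g + (1.0 - g) * (c * seg.cn_a + 1.0 - c)
        rB = g + (1.0 - g) * (c * seg.cn_b + 1.0 - c)
        return rA, rB


@dataclass
class SimulatedTumor:
    """Simulator output: the three input tables plus the truth record."""

    seg_tb: pd.DataFrame
    pileup_tumor: pd.DataFrame
    pileup_normal: pd.DataFrame
    snv_tb: pd.DataFrame
    truth: dict

    def write(self, out_dir: str | os.PathLike, prefix: str = "sim") -> None:
        os.makedirs(out_dir, exist_ok=True)
        p = os.path.join(out_dir, prefix)
        tables_io.write_table(self.seg_tb, p + ".seg.tsv")
        tables_io.write_table(self.pileup_tumor, p + ".tumor_pileup.tsv")
        tables_io.write_table(self.pileup_normal, p + ".normal_pileup.tsv")
        tables_io.write_table(self.snv_tb, p + ".snv.tsv")


def simulate_tumor(model: TumorModel, seed: int = 0) -> SimulatedTumor:
    """Generate matched segment, pileup and SNV tables with known truth.

    Deterministic given ``seed``: the same seed yields bit-identical
    tables.
    """
    rng = np.random.default_rng(seed)
    lengths = np.array([s.length for s in model.segments], dtype=float)
    rates = np.array([model._read_rates(s) for s in model.segments])
    rsum = rates.sum(axis=1)
    psi_bar = float(np.average(rsum, weights=lengths))  # 2 x mean DNA/cell

    seg_rows = []
    t_chrom, t_pos, t_af, t_cov = [], [], [], []
    n_chrom, n_pos, n_af, n_cov = [], [], [], []
    truth_rows = []
    for i, seg in enumerate(model.segments):
        rA, rB = rates[i]
        s = rsum[i]
        logr = float(np.log2(s / psi_bar)) if s > 0 else float("-inf")
        if model.logr_noise_sd > 0:
            logr += float(rng.normal(0.0, model.logr_noise_sd))
        seg_rows.append((model.sample, seg.chrom, seg.start, seg.end, logr))
        beta_true = 2.0 * min(rA, rB) / s if s > 0 else 1.0
        truth_rows.append((seg.chrom, seg.start, seg.end, seg.cn_a, seg.cn_b,
                           seg.clonality, beta_true, logr))
        n_snp = int(rng.poisson(seg.length / 1000.0 * model.snps_per_kb))
        if n_snp == 0:
            continue
        pos = np.unique(rng.integers(seg.start, seg.end + 1, size=n_snp))
        k = pos.size
        cov_n = rng.poisson(model.mean_coverage_normal, size=k)
        with np.errstate(divide="ignore", invalid="ignore"):
            af_n = np.where(cov_n > 0,
                            rng.binomial(cov_n, 0.5) / np.maximum(cov_n, 1), 0.0)
        cov_rate = model.mean_coverage_tumor * s / psi_bar
        cov_t = rng.poisson(max(cov_rate, 0.0), size=k)
        alt_on_a = rng.random(k) < 0.5
        p_alt = np.where(alt_on_a, rA / s, rB / s) if s > 0 else np.full(k, 0.5)
        with np.errstate(divide="ignore", invalid="ignore"):
            af_t = np.where(cov_t > 0,
                            rng.binomial(cov_t, p_alt) / np.maximum(cov_t, 1),
                            0.0)
        t_chrom += [seg.chrom] * k
        t_pos.append(pos)
        t_af.append(af_t)
        t_cov.append(cov_t)
        n_chrom += [seg.chrom] * k
        n_pos.append(pos)
        n_af.append(af_n)
        n_cov.append(cov_n)

    def _pileup(chroms, poss, afs, covs) -> pd.DataFrame:
        if not poss:
            return pd.DataFrame(columns=["chrom", "pos", "af", "cov"])
        return pd.DataFrame({
            "chrom": chroms,
            "pos": np.concatenate(poss).astype(np.int64),
            "af": np.concatenate(afs),
            "cov": np.concatenate(covs).astype(np.int64),
        })

    seg_tb = pd.DataFrame(seg_rows,
                          columns=["sample", "chrom", "start", "end", "logR"])
    truth_segments = pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "cn_a", "cn_b",
                             "clonality", "beta", "logR"])

    snv_rows = []
    snv_truth_rows = []
    seg_lookup = {s.chrom: [x for x in model.segments if x.chrom == s.chrom]
                  for s in model.segments}
    for snv in model.snvs:
        container = None
        for seg in seg_lookup.get(snv.chrom, ()):
            if seg.start <= snv.pos <= seg.end:
                container = seg
                break
        if container is None:
            cnt_mix, s = 2.0, 2.0 * (1.0 - model.admixture) + 2.0 * model.admixture
        else:
            cnt_mix = container.tumor_total_cn
            rA, rB = model._read_rates(container)
            s = rA + rB
        g = model.admixture
        denom = 2.0 * g + (1.0 - g) * cnt_mix
        vaf_exp = snv.multiplicity * snv.clonality * (1.0 - g) / denom
        cov = int(rng.poisson(model.mean_coverage_tumor * s / psi_bar))
        alt = int(rng.binomial(cov, min(vaf_exp, 1.0))) if cov > 0 else 0
        snv_rows.append((model.sample, snv.chrom, snv.pos, "A", "T",
                         cov - alt, alt))
        snv_truth_rows.append((snv.chrom, snv.pos, snv.multiplicity,
                               snv.clonality, vaf_exp, cnt_mix))
    snv_tb = pd.DataFrame(
        snv_rows, columns=["sample", "chrom", "pos", "ref", "alt",
                           "rc_ref_tumor", "rc_alt_tumor"])
    truth_snvs = pd.DataFrame(
        snv_truth_rows, columns=["chrom", "pos", "multiplicity", "clonality",
                                 "expected_vaf", "tumor_total_cn"])

    truth = {
        "admixture": model.admixture,
        "tumor_ploidy": model.tumor_ploidy,
        "ploidy": model.sample_ploidy,
        "logr_shift": model.logr_shift,
        "segments": truth_segments,
        "snvs": truth_snvs,
    }
    return SimulatedTumor(
        seg_tb=seg_tb,
        pileup_tumor=_pileup(t_chrom, t_pos, t_af, t_cov),
        pileup_normal=_pileup(n_chrom, n_pos, n_af, n_cov),
        snv_tb=snv_tb,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Named fixtures used by the test suite and the CLI `simulate` command


def _tiled_segments(states: list[tuple[int, int, float, int]],
                    seg_len: int = 400_000,
                    per_chrom: int = 8) -> list[SegmentSpec]:
    """Lay out (cn_a, cn_b, clonality, count) state blocks along chromosomes."""
    segs = []
    i = 0
    for cn_a, cn_b, clon, count in states:
        for _ in range(count):
            chrom = f"chr{i // per_chrom + 1}"
            offset = (i % per_chrom) * (seg_len + 10_000) + 1
            segs.append(SegmentSpec(chrom, offset, offset + seg_len - 1,
                                    cn_a, cn_b, clon))
            i += 1
    return segs


def diploid_clean_model(admixture: float = 0.25) -> TumorModel:
    """Near-diploid genome with a handful of clonal hemizygous deletions."""
    states = [(1, 1, 1.0, 20), (1, 0, 1.0, 5), (2, 1, 1.0, 3)]
    return TumorModel(admixture=admixture, segments=_tiled_segments(states),
                      snvs=[SNVSpec("chr1", 150_000 + j * 37_000, 1, 1.0)
                            for j in range(6)],
                      sample="diploid_clean")


def aneuploid_shifted_model() -> TumorModel:
    """Aneuploid genome whose wild-type logR mode sits near -0.34.

    Mixes diploid wild type with tetraploid balanced blocks (plus a few
    deletions) so the sample-average DNA content is ~2.53 copies per
    cell, i.e. ploidy 2.53 by the shift equation.
    """
    states = [(1, 1, 1.0, 24), (2, 2, 1.0, 14), (1, 0, 1.0, 2)]
    model = TumorModel(admixture=0.2, segments=_tiled_segments(states),
                       sample="aneuploid_shifted")
    return model


def subclonal_model() -> TumorModel:
    """Clonal and subclonal hemizygous deletions in the same genome."""
    states = [(1, 1, 1.0, 18), (1, 0, 1.0, 5), (1, 0, 4 / 7, 5)]
    return TumorModel(admixture=0.3, segments=_tiled_segments(states),
                      snvs=[SNVSpec("chr1", 120_000 + j * 31_000, 1, 1.0)
                            for j in range(4)],
                      sample="subclonal")


def quiet_model(admixture: float = 0.2) -> TumorModel:
    """Copy-number-quiet genome: every segment wild type.

    Admixture estimation must fail on this profile — it cannot be told
    apart from a fully admixed sample.
    """
    states = [(1, 1, 1.0, 24)]
    return TumorModel(admixture=admixture, segments=_tiled_segments(states),
                      sample="quiet")


def random_tumor_model(seed: int,
                       admixture: float | None = None,
                       seg_len: int = 150_000,
                       snv_clonalities: tuple[float, ...] = (1.0, 1.0, 0.4),
                       sample: str = "random") -> TumorModel:
    """A randomized but identifiable tumor genome for recovery studies.

    Segment counts per state are drawn so that wild-type segments stay
    the dominant balanced population (the leftmost-mode ploidy search
    needs an anchor; genomes without any wild-type mass are genuinely
    ambiguous) and at least five clonal hemizygous deletions support
    the admixture estimate. Admixture defaults to Uniform(0.1, 0.6).
    SNVs with the given clonalities are placed mid-segment on wild-type
    segments.
    """
    rng = np.random.default_rng(seed)
    g = float(rng.uniform(0.1, 0.6)) if admixture is None else float(admixture)
    states = [
        (1, 1, 1.0, int(rng.integers(12, 17))),
        (2, 2, 1.0, int(rng.integers(0, 9))),
        (1, 0, 1.0, int(rng.integers(5, 9))),
        (2, 1, 1.0, int(rng.integers(0, 4))),
        (1, 0, 0.5, int(rng.integers(0, 4))),
        (2, 0, 1.0, int(rng.integers(0, 3))),
    ]
    segments = _tiled_segments(states, seg_len=seg_len)
    wt = [s for s in segments if (s.cn_a, s.cn_b) == (1, 1)]
    snvs = [SNVSpec(seg.chrom, (seg.start + seg.end) // 2, 1, c)
            for seg, c in zip(wt, snv_clonalities * (len(wt) // 3 + 1))]
    return TumorModel(admixture=g, segments=segments, snvs=snvs,
                      sample=sample)


FIXTURE_NAMES = ("diploid-clean", "aneuploid-shifted", "subclonal", "quiet")

_FIXTURE_BUILDERS = {
    "diploid-clean": diploid_clean_model,
    "aneuploid-shifted": aneuploid_shifted_model,
    "subclonal": subclonal_model,
    "quiet": quiet_model,
}


def fixture_model(name: str) -> TumorModel:
    try:
        return _FIXTURE_BUILDERS[name]()
    except KeyError:
        raise AscnaError(f"unknown fixture '{name}'; "
                         f"choose from {FIXTURE_NAMES}") from None


def make_fixture_suite(out_dir: str | os.PathLike, seed: int = 0) -> dict[str, str]:
    """Write all named fixtures under ``out_dir``; returns name -> directory."""
    paths = {}
    for i, name in enumerate(FIXTURE_NAMES):
        sim = simulate_tumor(fixture_model(name), seed=seed + i)
        target = os.path.join(out_dir, name)
        sim.write(target, prefix=name)
        paths[name] = target
    return paths
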