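"""Pooling-corrected diversity estimators: π, Watterson's θ, Tajima's D,
πS/πNS and the bottleneck statistic ΔΘ = 1 − π/Θ.

The estimators model pool-seq as two-stage sampling: ``n_pool`` genomes are
drawn from the population, then reads are drawn binomially from the pool.
A site is only *detected* as a SNP when both alleles reach the min-count
threshold ``b``, so raw summaries are divided by their expected value under
the neutral site-frequency spectrum, computed per (b, coverage, n_pool) and
memoized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np
from scipy import special, stats

from .formats import Feature, FeatureSet, SiteCounts

__all__ = [
    "PoolSpec",
    "WindowSpec",
    "SiteState",
    "WindowStat",
    "CodingContext",
    "make_site_state",
    "site_pi",
    "pi_correction",
    "detection_correction",
    "watterson_denominator",
    "tajima_constants",
    "tajima_d",
    "window_stats",
    "delta_theta",
    "classify_coding_sites",
    "window_pi_syn_nonsyn",
    "EULER_GAMMA",
]

EULER_GAMMA = float(np.euler_gamma)

NAN = float("nan")


@dataclass(frozen=True)
class PoolSpec:
    """Pool metadata: size, min-count threshold and coverage bounds."""

    name: str
    n_pool: int
    min_count: int = 2
    min_coverage: int = 4
    max_coverage: int = 1_000_000

    def __post_init__(self):
        if self.n_pool < 2:
            raise ValueError("n_pool must be >= 2")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.min_coverage > self.max_coverage:
            raise ValueError("min_coverage > max_coverage")


@dataclass(frozen=True)
class WindowSpec:
    """Nonoverlapping genomic windows (step must equal size)."""

    size: int = 100_000
    step: int = 100_000
    min_covered_fraction: float = 0.6

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("window size must be >= 1")
        if self.step != self.size:
            raise ValueError("only nonoverlapping windows are supported (step == size)")
        if not 0 < self.min_covered_fraction <= 1:
            raise ValueError("min_covered_fraction must be in (0, 1]")

    def index(self, pos: int) -> int:
        return (pos - 1) // self.size

    def bounds(self, idx: int) -> Tuple[int, int]:
        return idx * self.size + 1, (idx + 1) * self.size


@dataclass(frozen=True)
class SiteState:
    """One pool's view of a site after validity/min-count filtering."""

    chrom: str
    pos: int
    ref: str
    counts: Tuple[int, int, int, int]  # raw A,T,C,G
    coverage: int
    valid: bool
    effective_counts: Tuple[int, int, int, int]  # alleles below b zeroed
    effective_coverage: int
    is_snp: bool


@dataclass
class WindowStat:
    chrom: str
    start: int
    end: int
    n_valid_sites: int
    covered_fraction: float
    pi: float = NAN
    theta_w: float = NAN
    tajima_d: float = NAN
    delta_theta: float = NAN
    pi_syn: float = NAN
    pi_nonsyn: float = NAN
    n_snps: int = 0


def make_site_state(site: SiteCounts, pool_index: int, spec: PoolSpec) -> SiteState:
    """Apply coverage bounds and the min-count allele filter to one pool."""
    raw = site.counts[pool_index][:4]
    cov = sum(raw)
    valid = spec.min_coverage <= cov <= spec.max_coverage
    b = spec.min_count
    eff = tuple(c if c >= b else 0 for c in raw)
    eff_cov = sum(eff)
    n_alleles = sum(1 for c in eff if c > 0)
    return SiteState(
        site.chrom, site.pos, site.ref, raw, cov, valid, eff, eff_cov,
        valid and n_alleles >= 2,
    )


# ---------------------------------------------------------------------------
# pooling corrections, memoized per (min_count, coverage, pool size)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _sfs_weights(n: int) -> np.ndarray:
    """Neutral expected SFS weights 1/k for derived counts k = 1..n−1."""
    return 1.0 / np.arange(1, n)


@lru_cache(maxsize=None)
def pi_correction(b: int, c: int, n: int) -> float:
    """Expected raw heterozygosity summed per unit of true π.

    E over the neutral SFS of (c/(c−1))·2m(c−m)/c² restricted to detectable
    read configurations b ≤ m ≤ c−b, with m ~ Binomial(c, k/n). Equals
    (n−1)/n when b = 1 (pure pool-size correction).
    """
    if c < 2 or c < 2 * b:
        return 0.0
    k = np.arange(1, n)
    m = np.arange(b, c - b + 1)
    pmf = stats.binom.pmf(m[None, :], c, (k / n)[:, None])
    h = (c / (c - 1.0)) * 2.0 * m * (c - m) / (c * c)
    return float(np.sum(_sfs_weights(n) * (pmf @ h)))


@lru_cache(maxsize=None)
def detection_correction(b: int, c: int, n: int) -> float:
    """Min-count detection factor for per-site π, normalized to 1 at b = 1."""
    base = pi_correction(1, c, n)
    if base == 0.0:
        return 0.0
    return pi_correction(b, c, n) / base


@lru_cache(maxsize=None)
def watterson_denominator(b: int, c: int, n: int) -> float:
    """Pool-adjusted replacement for the harmonic number a_n.

    Sum over derived pool counts k of (1/k)·P(SNP detected | k), i.e. the
    expected number of detected segregating sites per unit θ per site.
    """
    if c < 2 * b:
        return 0.0
    k = np.arange(1, n)
    p_detect = stats.binom.cdf(c - b, c, k / n) - stats.binom.cdf(b - 1, c, k / n)
    return float(np.sum(_sfs_weights(n) * p_detect))


def _raw_heterozygosity(eff_counts: Tuple[int, int, int, int], eff_cov: int) -> float:
    """(c/(c−1))·(1 − Σ f²): mean pairwise difference among the kept reads."""
    c = eff_cov
    if c < 2:
        return NAN
    ss = sum(x * x for x in eff_counts)
    return (c / (c - 1.0)) * (1.0 - ss / (c * c))


def site_pi(state: SiteState, pool: PoolSpec) -> float:
    """Per-site heterozygosity corrected for min-count detection bias.

    With b = 1 this is exactly the mean pairwise difference over all read
    pairs; for b > 1 the value is divided by the expected fraction of
    heterozygosity observable at threshold b given coverage and pool size.
    Monomorphic (post-filter) sites return 0.
    """
    if state.coverage < 2:
        return NAN
    if not state.is_snp:
        return 0.0
    h = _raw_heterozygosity(state.effective_counts, state.effective_coverage)
    k = detection_correction(pool.min_count, state.coverage, pool.n_pool)
    if k == 0.0:
        return NAN
    return h / k


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: float) -> Dict[str, float]:
    """Classical Tajima variance constants for a (possibly real) sample size.

    Harmonic numbers are evaluated through digamma/trigamma so a non-integer
    effective sample size (coverage-limited) is handled smoothly.
    """
    if n <= 1.0:
        raise ValueError("sample size must exceed 1")
    a1 = float(special.digamma(n) + EULER_GAMMA)
    a2 = float(math.pi ** 2 / 6.0 - special.polygamma(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    return {
        "a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
        "e1": c1 / a1, "e2": c2 / (a1 * a1 + a2),
    }


def tajima_d(pi_sum: float, n_segregating: float, n: float) -> float:
    """Tajima's D from the heterozygosity sum and segregating-site count."""
    if n_segregating <= 0 or n <= 1:
        return NAN
    k = tajima_constants(n)
    s = n_segregating
    var = k["e1"] * s + k["e2"] * s * (s - 1.0)
    numerator = pi_sum - s / k["a1"]
    if var <= 0:
        # degenerate variance (e.g. n = 2): a vanishing numerator still
        # pins D at 0, anything else is undefined
        return 0.0 if numerator == 0 else NAN
    return numerator / math.sqrt(var)


# ---------------------------------------------------------------------------
# windowed statistics
# ---------------------------------------------------------------------------

class _WindowAccumulator:
    __slots__ = (
        "chrom", "idx", "n_valid", "pi_sum", "theta_sum", "n_snps",
        "cov_sum", "neff_sum",
    )

    def __init__(self, chrom: str, idx: int):
        self.chrom = chrom
        self.idx = idx
        self.n_valid = 0
        self.pi_sum = 0.0  # Σ h / pi_correction — fully corrected
        self.theta_sum = 0.0  # Σ 1 / watterson_denominator over SNPs
        self.n_snps = 0
        self.cov_sum = 0
        self.neff_sum = 0.0

    def add(self, state: SiteState, pool: PoolSpec) -> None:
        if not state.valid:
            return
        self.n_valid += 1
        self.cov_sum += state.coverage
        self.neff_sum += min(pool.n_pool, state.coverage) * state.coverage
        if state.is_snp:
            self.n_snps += 1
            h = _raw_heterozygosity(state.effective_counts, state.effective_coverage)
            e_pi = pi_correction(pool.min_count, state.coverage, pool.n_pool)
            denom = watterson_denominator(pool.min_count, state.coverage, pool.n_pool)
            if e_pi > 0:
                self.pi_sum += h / e_pi
            if denom > 0:
                self.theta_sum += 1.0 / denom

    def finish(self, window: WindowSpec, pool: PoolSpec) -> WindowStat:
        start, end = window.bounds(self.idx)
        covered = self.n_valid / window.size
        stat = WindowStat(self.chrom, start, end, self.n_valid, covered)
        if covered < window.min_covered_fraction or self.n_valid == 0:
            return stat
        stat.pi = self.pi_sum / self.n_valid
        stat.theta_w = self.theta_sum / self.n_valid
        stat.n_snps = self.n_snps
        stat.delta_theta = delta_theta(stat.pi, stat.theta_w)
        # effective sample size: coverage-weighted mean of min(n_pool, c)
        n_eff = self.neff_sum / self.cov_sum if self.cov_sum else NAN
        if self.n_snps > 0 and n_eff > 1:
            a1 = float(special.digamma(n_eff) + EULER_GAMMA)
            s_eq = self.theta_sum * a1  # equivalent classical S
            stat.tajima_d = tajima_d(self.pi_sum, s_eq, n_eff)
        return stat


def window_stats(
    sites: Iterable[SiteCounts],
    window: WindowSpec,
    pool: PoolSpec,
    pool_index: int = 0,
) -> Iterator[WindowStat]:
    """Per-window π, θW, Tajima's D and ΔΘ for one pool.

    Sites must be sorted by (chrom, pos); windows whose covered fraction is
    below ``window.min_covered_fraction`` are emitted with NA statistics.
    Gap windows between covered windows of the same chromosome are emitted
    as empty rows so output tiles each chromosome contiguously.
    """
    acc: Optional[_WindowAccumulator] = None
    seen_chroms = set()
    last_chrom, last_pos = None, 0
    for site in sites:
        if site.chrom != last_chrom:
            if site.chrom in seen_chroms:
                raise ValueError(f"input not sorted: chromosome {site.chrom} reappears")
            seen_chroms.add(site.chrom)
            if acc is not None:
                yield acc.finish(window, pool)
            acc = None
            last_chrom, last_pos = site.chrom, 0
        elif site.pos <= last_pos:
            raise ValueError(
                f"input not sorted at {site.chrom}:{site.pos} (after {last_pos})"
            )
        last_pos = site.pos
        idx = window.index(site.pos)
        if acc is None:
            acc = _WindowAccumulator(site.chrom, idx)
        elif idx != acc.idx:
            yield acc.finish(window, pool)
            for gap in range(acc.idx + 1, idx):
                yield _WindowAccumulator(site.chrom, gap).finish(window, pool)
            acc = _WindowAccumulator(site.chrom, idx)
        acc.add(make_site_state(site, pool_index, pool), pool)
    if acc is not None:
        yield acc.finish(window, pool)


def delta_theta(pi: float, theta: float) -> float:
    """ΔΘ = 1 − π/Θ; NA when Θ = 0; 1 in the all-singleton limit."""
    if math.isnan(pi) or math.isnan(theta):
        return NAN
    if pi < 0 or theta < 0:
        raise ValueError("pi and theta must be non-negative")
    if theta == 0:
        return NAN
    return 1.0 - pi / theta


# ---------------------------------------------------------------------------
# synonymous / nonsynonymous classification
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@lru_cache(maxsize=1)
def _codon_table() -> Dict[str, str]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


@lru_cache(maxsize=None)
def _syn_fraction(codon: str, offset: int) -> float:
    """Fraction of the 3 possible substitutions at this codon position that
    preserve the encoded amino acid (stop treated as its own 'residue')."""
    code = _codon_table()
    aa = code[codon]
    syn = 0
    for base in _BASES:
        if base == codon[offset]:
            continue
        alt = codon[:offset] + base + codon[offset + 1:]
        if code[alt] == aa:
            syn += 1
    return syn / 3.0


@dataclass(frozen=True)
class CodingContext:
    """Coding annotation of one genomic position."""

    codon: str  # in gene (sense) orientation
    offset: int  # 0..2 within codon, gene orientation
    strand: str
    syn_length: float
    nonsyn_length: float

    def substitution_is_synonymous(self, allele_a: str, allele_b: str) -> bool:
        """Whether swapping the two observed (genomic-strand) alleles at this
        position preserves the amino acid."""
        code = _codon_table()
        if self.strand == "-":
            allele_a = allele_a.translate(_COMPLEMENT)
            allele_b = allele_b.translate(_COMPLEMENT)
        ca = self.codon[: self.offset] + allele_a + self.codon[self.offset + 1:]
        cb = self.codon[: self.offset] + allele_b + self.codon[self.offset + 1:]
        if ca not in code or cb not in code:
            return False
        return code[ca] == code[cb]


def classify_coding_sites(
    features: FeatureSet,
    genome: Dict[str, str],
    allow_incomplete: bool = True,
) -> Dict[Tuple[str, int], CodingContext]:
    """Annotate every CDS position with codon context and syn/nonsyn length.

    Transcript CDS parts are stitched in gene orientation with their frame
    offset applied. Transcripts whose stitched length is not a multiple of 3
    are trimmed when ``allow_incomplete`` is set, otherwise rejected.
    Positions covered by conflicting codon contexts (overlapping CDS in a
    different frame or strand) are excluded.
    """
    contexts: Dict[Tuple[str, int], CodingContext] = {}
    conflicted = set()
    for transcript, parts in features.cds_by_transcript().items():
        strand = parts[0].strand
        ordered = parts if strand != "-" else list(reversed(parts))
        positions: List[Tuple[str, int]] = []
        seq_chunks: List[str] = []
        for part in ordered:
            if part.chrom not in genome:
                raise KeyError(f"CDS chromosome {part.chrom!r} missing from genome")
            chunk = genome[part.chrom][part.start - 1: part.end]
            pos_range = range(part.start, part.end + 1)
            if strand == "-":
                chunk = chunk.translate(_COMPLEMENT)[::-1]
                pos_range = range(part.end, part.start - 1, -1)
            seq_chunks.append(chunk)
            positions.extend((part.chrom, p) for p in pos_range)
        frame = ordered[0].frame
        cds = "".join(seq_chunks)[frame:]
        positions = positions[frame:]
        if len(cds) % 3 != 0:
            if not allow_incomplete:
                raise ValueError(
                    f"CDS of transcript {transcript!r} length {len(cds)} "
                    "not divisible by 3"
                )
            trim = len(cds) % 3
            cds = cds[: len(cds) - trim]
            positions = positions[: len(positions) - trim]
        for i in range(0, len(cds) - 2, 3):
            codon = cds[i: i + 3]
            if any(b not in _BASES for b in codon):
                continue
            for offset in range(3):
                key = positions[i + offset]
                syn = _syn_fraction(codon, offset)
                ctx = CodingContext(codon, offset, strand, syn, 1.0 - syn)
                prev = contexts.get(key)
                if prev is not None and (
                    prev.codon != ctx.codon
                    or prev.offset != ctx.offset
                    or prev.strand != ctx.strand
                ):
                    conflicted.add(key)
                else:
                    contexts[key] = ctx
    for key in conflicted:
        contexts.pop(key, None)
    return contexts


def _top_two_alleles(state: SiteState) -> Tuple[str, str]:
    order = sorted(range(4), key=lambda i: (-state.effective_counts[i], i))
    return "ATCG"[order[0]], "ATCG"[order[1]]


def window_pi_syn_nonsyn(
    sites: Iterable[SiteCounts],
    contexts: Dict[Tuple[str, int], CodingContext],
    window: WindowSpec,
    pool: PoolSpec,
    pool_index: int = 0,
) -> List[WindowStat]:
    """πS and πNS per window, weighted by synonymous site lengths.

    Each valid coding site contributes its syn/nonsyn lengths to the window
    denominators; each coding SNP contributes its corrected site π to the
    numerator of the class its allele pair belongs to.
    """
    rows: Dict[Tuple[str, int], List[float]] = {}
    n_valid: Dict[Tuple[str, int], int] = {}
    for site in sites:
        ctx = contexts.get((site.chrom, site.pos))
        key = (site.chrom, window.index(site.pos))
        state = make_site_state(site, pool_index, pool)
        if not state.valid:
            continue
        n_valid[key] = n_valid.get(key, 0) + 1
        if ctx is None:
            continue
        acc = rows.setdefault(key, [0.0, 0.0, 0.0, 0.0])  # synL, nsL, piS, piNS
        acc[0] += ctx.syn_length
        acc[1] += ctx.nonsyn_length
        if state.is_snp:
            pi = site_pi(state, pool)
            if math.isnan(pi):
                continue
            a, b = _top_two_alleles(state)
            if ctx.substitution_is_synonymous(a, b):
                acc[2] += pi
            else:
                acc[3] += pi
    out = []
    for (chrom, idx), (syn_l, ns_l, pi_s, pi_ns) in sorted(rows.items()):
        start, end = window.bounds(idx)
        nv = n_valid.get((chrom, idx), 0)
        stat = WindowStat(chrom, start, end, nv, nv / window.size)
        stat.pi_syn = pi_s / syn_l if syn_l > 0 else NAN
        stat.pi_nonsyn = pi_ns / ns_l if ns_l > 0 else NAN
        out.append(stat)
    return out
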