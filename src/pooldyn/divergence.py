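"""Between-population statistics: windowed pairwise FST and major-allele
absolute divergence dXY."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np

from .formats import SiteCounts
from .popgen import PoolSpec, WindowSpec, make_site_state

__all__ = ["PairStat", "snp_fst", "window_fst", "window_dxy"]

NAN = float("nan")


@dataclass
class PairStat:
    chrom: str
    start: int
    end: int
    pop_a: str
    pop_b: str
    fst: float = NAN
    dxy: float = NAN
    n_joint_sites: int = 0
    n_snps: int = 0


def _heterozygosity(counts: Tuple[int, ...], sample_factor_c: Optional[int] = None) -> float:
    """1 − Σf² with the small-sample factor c/(c−1).

    ``sample_factor_c`` overrides the coverage used in the factor (the
    classical pooled estimator uses the *minimum* pool coverage for the
    total heterozygosity).
    """
    c = sum(counts)
    if c < 2:
        return NAN
    ss = sum(x * x for x in counts)
    cf = sample_factor_c if sample_factor_c is not None else c
    if cf < 2:
        return NAN
    return (cf / (cf - 1.0)) * (1.0 - ss / (c * c))


def snp_fst(
    counts_a: Tuple[int, int, int, int],
    counts_b: Tuple[int, int, int, int],
) -> float:
    """Per-SNP FST = (π_T − mean π_within)/π_T on read-count heterozygosities.

    π_T uses the summed counts of both pools with the small-sample factor
    evaluated at min(c_a, c_b); negative estimates are clamped to 0.
    """
    ca, cb = sum(counts_a), sum(counts_b)
    if ca < 2 or cb < 2:
        return NAN
    pi_a = _heterozygosity(counts_a)
    pi_b = _heterozygosity(counts_b)
    total = tuple(x + y for x, y in zip(counts_a, counts_b))
    pi_t = _heterozygosity(total, sample_factor_c=min(ca, cb))
    if not pi_t or math.isnan(pi_t):
        return NAN
    fst = (pi_t - 0.5 * (pi_a + pi_b)) / pi_t
    return max(0.0, min(1.0, fst))


def _joint_snp(
    counts_a: Tuple[int, int, int, int],
    counts_b: Tuple[int, int, int, int],
    min_count: int,
) -> bool:
    """SNP call from the combined pools at the min-count threshold."""
    total = [x + y for x, y in zip(counts_a, counts_b)]
    return sum(1 for c in total if c >= min_count) >= 2


def window_fst(
    joint_sites: Iterable[SiteCounts],
    window: WindowSpec,
    pools: Tuple[PoolSpec, PoolSpec],
    pool_indices: Tuple[int, int] = (0, 1),
) -> Iterator[PairStat]:
    """Mean per-SNP FST in nonoverlapping windows for one pool pair.

    Sites must be valid in both pools (each within its own coverage bounds);
    SNPs are called from the combined counts with the first pool's min-count.
    """
    spec_a, spec_b = pools
    if spec_a.name == spec_b.name:
        raise ValueError(f"pool pair shares the name {spec_a.name!r}")
    ia, ib = pool_indices
    acc: Optional[List] = None  # [chrom, idx, fst_sum, n_snps, n_joint]
    for site in joint_sites:
        sa = make_site_state(site, ia, spec_a)
        sb = make_site_state(site, ib, spec_b)
        if not (sa.valid and sb.valid):
            continue
        idx = window.index(site.pos)
        if acc is None or acc[0] != site.chrom or acc[1] != idx:
            if acc is not None:
                yield _finish_fst(acc, window, spec_a.name, spec_b.name)
            acc = [site.chrom, idx, 0.0, 0, 0]
        acc[4] += 1
        if _joint_snp(sa.counts, sb.counts, spec_a.min_count):
            value = snp_fst(sa.counts, sb.counts)
            if not math.isnan(value):
                acc[2] += value
                acc[3] += 1
    if acc is not None:
        yield _finish_fst(acc, window, spec_a.name, spec_b.name)


def _finish_fst(acc: List, window: WindowSpec, name_a: str, name_b: str) -> PairStat:
    chrom, idx, fst_sum, n_snps, n_joint = acc
    start, end = window.bounds(idx)
    stat = PairStat(chrom, start, end, name_a, name_b,
                    n_joint_sites=n_joint, n_snps=n_snps)
    if n_snps > 0:
        stat.fst = fst_sum / n_snps
    return stat


def _has_tie(counts: Tuple[int, int, int, int]) -> bool:
    top = max(counts)
    return sum(1 for c in counts if c == top) > 1


def _major_allele(
    counts: Tuple[int, int, int, int],
    priority: Optional[np.ndarray],
) -> int:
    """Most abundant allele; ties resolved by the per-site random priority.

    The priority is shared by both pools of a site so identical counts
    always select the same allele (self-dXY stays 0 for any seed)."""
    top = max(counts)
    winners = [i for i, c in enumerate(counts) if c == top]
    if len(winners) == 1:
        return winners[0]
    return min(winners, key=lambda i: priority[i])


def window_dxy(
    joint_sites: Iterable[SiteCounts],
    window: WindowSpec,
    pools: Tuple[PoolSpec, PoolSpec],
    rng_seed: Optional[int] = None,
    pool_indices: Tuple[int, int] = (0, 1),
    snps_only: bool = False,
) -> Iterator[PairStat]:
    """Fraction of jointly valid sites whose population-major alleles differ.

    Ties for most abundant allele are resolved uniformly at random from a
    generator seeded with ``rng_seed``; omitting the seed is an error the
    moment a tie occurs (reproducibility contract).
    """
    spec_a, spec_b = pools
    if spec_a.name == spec_b.name:
        raise ValueError(f"pool pair shares the name {spec_a.name!r}")
    ia, ib = pool_indices
    rng = np.random.default_rng(rng_seed) if rng_seed is not None else None
    acc: Optional[List] = None  # [chrom, idx, n_diff, n_joint]
    for site in joint_sites:
        sa = make_site_state(site, ia, spec_a)
        sb = make_site_state(site, ib, spec_b)
        if not (sa.valid and sb.valid):
            continue
        if snps_only and not _joint_snp(sa.counts, sb.counts, spec_a.min_count):
            continue
        idx = window.index(site.pos)
        if acc is None or acc[0] != site.chrom or acc[1] != idx:
            if acc is not None:
                yield _finish_dxy(acc, window, spec_a.name, spec_b.name)
            acc = [site.chrom, idx, 0, 0]
        acc[3] += 1
        priority = None
        if _has_tie(sa.counts) or _has_tie(sb.counts):
            if rng is None:
                raise ValueError(
                    "major-allele tie encountered but no rng seed was provided; "
                    "dXY tie-breaking must be seeded for reproducibility"
                )
            priority = rng.permutation(4)
        if _major_allele(sa.counts, priority) != _major_allele(sb.counts, priority):
            acc[2] += 1
    if acc is not None:
        yield _finish_dxy(acc, window, spec_a.name, spec_b.name)


def _finish_dxy(acc: List, window: WindowSpec, name_a: str, name_b: str) -> PairStat:
    chrom, idx, n_diff, n_joint = acc
    start, end = window.bounds(idx)
    stat = PairStat(chrom, start, end, name_a, name_b, n_joint_sites=n_joint)
    if n_joint > 0:
        stat.dxy = n_diff / n_joint
    return stat
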