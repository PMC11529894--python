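"""Synthetic pool-seq and TE-evidence generator with known truth.

Population allele frequencies come from the neutral coalescent: the pool of
``n_pool`` genomes is treated as the coalescent sample, so per-site derived
counts are drawn i.i.d. from the (demography-dependent) expected site
frequency spectrum — analytic at equilibrium, Monte-Carlo branch lengths
from msprime under a founder-event demography. Reads are then drawn
binomially from pool frequencies with a uniform re-distribution error model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .formats import SiteCounts
from .mobilome import PairEvidence, REF_CLASS

__all__ = [
    "DemographyModel",
    "SeqParams",
    "TruthRecord",
    "expected_branch_sfs",
    "simulate_pool_seq",
    "counts_to_sitecounts",
    "simulate_split_pair",
    "simulate_te_evidence",
    "simulate_te_copies",
    "draw_pool_counts",
]

_BASES = "ATCG"


@dataclass(frozen=True)
class DemographyModel:
    """Single-population demography: ancestral size, founder event, recovery.

    ``t_bottleneck`` generations ago the population was founded with ``nb``
    individuals out of an ancestral population of size ``n0`` and has grown
    exponentially to the present size ``nc``. ``nb is None`` (or t = 0)
    means equilibrium at ``n0``. ``inbreeding_f`` shrinks the number of
    distinct lineages a pool effectively samples (sib-mating).
    """

    n0: float
    mu: float
    nb: Optional[float] = None
    t_bottleneck: float = 0.0
    nc: Optional[float] = None
    inbreeding_f: float = 0.0

    def __post_init__(self):
        if self.n0 < 2:
            raise ValueError("n0 must be >= 2")
        if self.nb is not None and self.nb < 2:
            raise ValueError("nb must be >= 2")
        if self.t_bottleneck < 0:
            raise ValueError("t_bottleneck must be >= 0")
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ValueError("inbreeding_f must be in [0, 1]")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")

    @property
    def is_equilibrium(self) -> bool:
        return self.nb is None or self.t_bottleneck == 0

    @property
    def theta(self) -> float:
        """4·N0·μ, the per-site θ of the ancestral/equilibrium population."""
        return 4.0 * self.n0 * self.mu

    @classmethod
    def equilibrium(cls, theta: float, mu: float = 1e-8) -> "DemographyModel":
        return cls(n0=theta / (4.0 * mu), mu=mu)


@dataclass(frozen=True)
class SeqParams:
    """Sequencing layer: region length, Poisson coverage, error rate, pools."""

    length: int
    mean_coverage: float = 60.0
    error_rate: float = 0.001
    pool_sizes: Tuple[int, ...] = (40,)
    chrom: str = "sim1"

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if not self.pool_sizes:
            raise ValueError("need at least one pool")


@dataclass
class TruthRecord:
    """Ground truth twin of every emitted dataset."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    theta_true: float = float("nan")
    # pool name -> {pos: true pool-frequency of the derived allele}
    site_frequencies: Dict[str, Dict[int, float]] = field(default_factory=dict)
    te_insertions: List[dict] = field(default_factory=list)
    read_divergences: List[float] = field(default_factory=list)

    def to_json(self, indent: int = 0) -> str:
        payload = asdict(self)
        payload["site_frequencies"] = {
            pool: {str(k): v for k, v in sites.items()}
            for pool, sites in self.site_frequencies.items()
        }
        return json.dumps(payload, indent=indent or None)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        payload = json.loads(text)
        payload["site_frequencies"] = {
            pool: {int(k): v for k, v in sites.items()}
            for pool, sites in payload.get("site_frequencies", {}).items()
        }
        return cls(**payload)


# ---------------------------------------------------------------------------
# site-frequency spectra
# ---------------------------------------------------------------------------

def expected_branch_sfs(
    model: DemographyModel,
    n_lineages: int,
    n_replicates: int = 400,
    seed: int = 1,
) -> np.ndarray:
    """Expected branch lengths t_k (k = 1..n−1) subtending k of n lineages.

    Per-site mutation probability of frequency class k is μ·t_k. At
    equilibrium t_k = 4·N0/k exactly; under a founder event the lengths are
    Monte-Carlo means over msprime genealogies.
    """
    if model.is_equilibrium:
        return 4.0 * model.n0 / np.arange(1, n_lineages)
    import msprime

    nc = model.nc if model.nc is not None else model.n0
    growth = math.log(nc / model.nb) / model.t_bottleneck
    demography = msprime.Demography()
    demography.add_population(name="pop", initial_size=nc, growth_rate=growth)
    demography.add_population_parameters_change(
        time=model.t_bottleneck, initial_size=model.n0, growth_rate=0.0,
        population="pop",
    )
    acc = np.zeros(n_lineages + 1)
    reps = msprime.sim_ancestry(
        samples={"pop": n_lineages},
        ploidy=1,
        demography=demography,
        num_replicates=n_replicates,
        random_seed=seed,
    )
    for ts in reps:
        acc += ts.allele_frequency_spectrum(
            mode="branch", polarised=True, span_normalise=True
        )
    # haploid samples still coalesce pairwise at rate 1/(2N), so the branch
    # AFS is already on the 4Nμ diversity scale (t_k = 4N/k at equilibrium)
    return acc[1:n_lineages] / n_replicates


def _effective_lineages(n_pool: int, f: float) -> int:
    if f <= 0:
        return n_pool
    return int(round(n_pool * (1.0 - f))) + 1


# ---------------------------------------------------------------------------
# pool-seq simulation
# ---------------------------------------------------------------------------

def _apply_errors(
    counts: np.ndarray, source: np.ndarray, e: float, rng: np.random.Generator
) -> None:
    """Move each read with probability e from its source base to a uniform
    other base. ``counts`` is (L, 4); ``source`` gives the column the reads
    currently sit in."""
    if e <= 0:
        return
    n_reads = counts[np.arange(counts.shape[0]), source]
    errs = rng.binomial(n_reads, e)
    hot = np.nonzero(errs)[0]
    if hot.size == 0:
        return
    idx = np.repeat(hot, errs[hot])
    dest = (source[idx] + rng.integers(1, 4, size=idx.size)) % 4
    np.subtract.at(counts, (idx, source[idx]), 1)
    np.add.at(counts, (idx, dest), 1)


def simulate_pool_seq(
    model: DemographyModel,
    seq: SeqParams,
    rng_seed: int = 1,
) -> Tuple[str, TruthRecord]:
    """Emit sync text plus its truth twin for independent pools.

    Each pool is an independent coalescent sample from the same demography;
    per-site derived pool counts are drawn i.i.d. from the expected SFS
    (valid for θ·a_n « 1, at most one mutation per site), reads binomially
    with the error model on top.
    """
    rng = np.random.default_rng(rng_seed)
    L = seq.length
    truth = TruthRecord(
        kind="pool_seq",
        seed=rng_seed,
        params={"model": asdict(model), "seq": asdict(seq)},
        theta_true=model.theta,
    )
    ref = rng.integers(0, 4, size=L)
    alt = (ref + rng.integers(1, 4, size=L)) % 4
    pool_counts = []
    for p, n_pool in enumerate(seq.pool_sizes):
        n_lin = _effective_lineages(n_pool, model.inbreeding_f)
        t_k = expected_branch_sfs(model, n_lin, seed=rng_seed + 1000 + p)
        q = model.mu * t_k
        q_total = q.sum()
        if q_total >= 1.0:
            raise ValueError("theta too large for the one-mutation-per-site model")
        probs = np.concatenate([[1.0 - q_total], q])
        k = rng.choice(np.arange(n_lin), size=L, p=probs)  # derived pool counts
        cov = rng.poisson(seq.mean_coverage, size=L)
        m = rng.binomial(cov, k / n_lin)
        counts = np.zeros((L, 4), dtype=np.int32)
        np.add.at(counts, (np.arange(L), ref), cov - m)
        np.add.at(counts, (np.arange(L), alt), m)
        _apply_errors(counts, ref, seq.error_rate, rng)
        _apply_errors(counts, alt, seq.error_rate, rng)
        pool_counts.append(counts)
        name = f"pool{p + 1}"
        seg = np.nonzero(k)[0]
        truth.site_frequencies[name] = {
            int(pos + 1): float(k[pos] / n_lin) for pos in seg
        }
    sync = _counts_to_sync(seq.chrom, ref, pool_counts)
    return sync, truth


def _counts_to_sync(chrom: str, ref: np.ndarray, pool_counts: List[np.ndarray]) -> str:
    L = ref.shape[0]
    ref_chars = np.array(list(_BASES))[ref]
    lines = []
    for i in range(L):
        cols = "\t".join(
            f"{c[i, 0]}:{c[i, 1]}:{c[i, 2]}:{c[i, 3]}:0:0" for c in pool_counts
        )
        lines.append(f"{chrom}\t{i + 1}\t{ref_chars[i]}\t{cols}")
    return "\n".join(lines) + "\n"


def counts_to_sitecounts(
    chrom: str, ref: np.ndarray, pool_counts: List[np.ndarray]
) -> Iterator[SiteCounts]:
    """Yield SiteCounts directly from simulation arrays (fast path that
    skips text round-tripping)."""
    L = ref.shape[0]
    for i in range(L):
        counts = tuple(
            (int(c[i, 0]), int(c[i, 1]), int(c[i, 2]), int(c[i, 3]), 0, 0)
            for c in pool_counts
        )
        yield SiteCounts(chrom, i + 1, _BASES[ref[i]], counts)


def draw_pool_counts(
    pop_freq: np.ndarray,
    n_pool: int,
    coverage: np.ndarray,
    error_rate: float,
    rng: np.random.Generator,
    inbreeding_f: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Two-stage sampling from known population frequencies.

    Stage one draws the pool composition k ~ Binomial(n_pool, p); stage two
    draws reads from the realized pool frequency k/n_pool. Returns (derived
    read counts, realized pool counts k). Collapses to a single binomial as
    n_pool → ∞.
    """
    n_lin = _effective_lineages(n_pool, inbreeding_f)
    k = rng.binomial(n_lin, pop_freq)
    m = rng.binomial(coverage, k / n_lin)
    if error_rate > 0:
        # errors between the two tracked alleles only affect counts when they
        # cross; cross-flows each way at rate e/3
        loss = rng.binomial(m, error_rate)
        gain = rng.binomial(coverage - m, error_rate / 3.0)
        m = m - loss + gain
    return m, k


def simulate_split_pair(
    theta: float,
    t_split: int,
    n_e: int,
    seq: SeqParams,
    rng_seed: int = 1,
    snp_density: float = 0.02,
) -> Tuple[str, TruthRecord]:
    """Two pools drifting apart for ``t_split`` Wright-Fisher generations.

    A fraction ``snp_density`` of sites start polymorphic (ancestral
    frequency uniform on (0.1, 0.9)); both daughters drift independently at
    size ``n_e`` before pooled sequencing. Supports divergence-vs-time
    checks where dXY must grow with t_split.
    """
    if len(seq.pool_sizes) != 2:
        raise ValueError("simulate_split_pair needs exactly two pools")
    rng = np.random.default_rng(rng_seed)
    L = seq.length
    ref = rng.integers(0, 4, size=L)
    alt = (ref + rng.integers(1, 4, size=L)) % 4
    p_anc = np.zeros(L)
    seg = rng.random(L) < snp_density
    p_anc[seg] = rng.uniform(0.1, 0.9, size=int(seg.sum()))
    truth = TruthRecord(
        kind="split_pair",
        seed=rng_seed,
        params={"theta": theta, "t_split": t_split, "n_e": n_e, "seq": asdict(seq)},
        theta_true=theta,
    )
    pool_counts = []
    for p, n_pool in enumerate(seq.pool_sizes):
        freq = p_anc.copy()
        for _ in range(t_split):
            freq = rng.binomial(n_e, freq) / n_e
        cov = rng.poisson(seq.mean_coverage, size=L)
        m, k = draw_pool_counts(freq, n_pool, cov, 0.0, rng)
        counts = np.zeros((L, 4), dtype=np.int32)
        np.add.at(counts, (np.arange(L), ref), cov - m)
        np.add.at(counts, (np.arange(L), alt), m)
        _apply_errors(counts, ref, seq.error_rate, rng)
        _apply_errors(counts, alt, seq.error_rate, rng)
        pool_counts.append(counts)
        name = f"pool{p + 1}"
        truth.site_frequencies[name] = {
            int(i + 1): float(freq[i]) for i in np.nonzero(freq)[0]
        }
    return _counts_to_sync(seq.chrom, ref, pool_counts), truth


# ---------------------------------------------------------------------------
# TE evidence
# ---------------------------------------------------------------------------

def simulate_te_evidence(
    n_insertions: int,
    true_frequencies: Sequence[float],
    physical_coverage: int = 40,
    rng_seed: int = 1,
    families: Sequence[str] = ("TE_A", "TE_B", "TE_C"),
    chrom: str = "sim1",
    spacing: int = 2_500,
    span: int = 160,
    anchor_window: int = 150,
    mapq: int = 40,
    background_rate: float = 0.2,
) -> Tuple[List[PairEvidence], TruthRecord]:
    """Paired-end physical evidence for insertions at known frequencies.

    Each insertion gets ``physical_coverage`` pairs per side; a pair carries
    a TE-classed mate with probability f, a reference-classed mate
    otherwise. Anchors are jittered within ``anchor_window`` of the
    insertion point. Background reference-only pairs are laid down between
    insertions at ``background_rate`` per bp per strand.
    """
    freqs = list(true_frequencies)
    if len(freqs) == 1:
        freqs = freqs * n_insertions
    if len(freqs) != n_insertions:
        raise ValueError("true_frequencies must have length 1 or n_insertions")
    for f in freqs:
        if not 0.0 <= f <= 1.0:
            raise ValueError("frequencies must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    truth = TruthRecord(
        kind="te_evidence",
        seed=rng_seed,
        params={
            "n_insertions": n_insertions,
            "physical_coverage": physical_coverage,
            "spacing": spacing,
            "span": span,
            "anchor_window": anchor_window,
        },
    )
    pairs: List[PairEvidence] = []
    for i in range(n_insertions):
        pos = (i + 1) * spacing
        family = families[i % len(families)]
        f = freqs[i]
        truth.te_insertions.append(
            {"chrom": chrom, "pos": pos, "family": family, "frequency": f}
        )
        for strand in "+-":
            offsets = rng.integers(1, anchor_window + 1, size=physical_coverage)
            is_te = rng.random(physical_coverage) < f
            for off, te in zip(offsets, is_te):
                anchor = pos - int(off) if strand == "+" else pos + int(off)
                cls = family if te else REF_CLASS
                pairs.append(PairEvidence(chrom, anchor, strand, cls, mapq, span))
    # background reference pairs between insertion loci; pairs whose span
    # would cross a breakpoint are already modelled by the per-side draws
    region_end = (n_insertions + 1) * spacing
    n_background = rng.poisson(background_rate * region_end / span)
    bg_pos = rng.integers(span + 1, region_end, size=n_background)
    bg_strand = rng.integers(0, 2, size=n_background)
    insert_positions = np.arange(1, n_insertions + 1) * spacing
    for p, s in zip(bg_pos, bg_strand):
        if np.min(np.abs(insert_positions - p)) <= span:
            continue
        pairs.append(
            PairEvidence(chrom, int(p), "+-"[int(s)], REF_CLASS, mapq, span)
        )
    pairs.sort(key=lambda pr: (pr.chrom, pr.pos))
    return pairs, truth


# ---------------------------------------------------------------------------
# TE copies / landscape reads
# ---------------------------------------------------------------------------

def _mutate(seq: str, n_mutations: int, rng: np.random.Generator) -> Tuple[str, np.ndarray]:
    positions = rng.choice(len(seq), size=n_mutations, replace=False)
    out = list(seq)
    for p in positions:
        choices = [b for b in _BASES if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out), np.sort(positions)


def divergence_mutation_count(length: int, level: float) -> int:
    """Number of substitutions placing a copy at the *center* of the 1%
    landscape bin containing ``level`` (0 stays 0)."""
    if level == 0:
        return 0
    bin_i = int(round(level * 100))
    return max(1, int(length * (bin_i + 0.5) // 100))


def simulate_te_copies(
    consensus: str,
    n_copies: int,
    divergence_levels: Sequence[float],
    read_length: int = 300,
    rng_seed: int = 1,
) -> Tuple[List[str], TruthRecord]:
    """Mutated copies of a consensus, tiled into reads, with per-read truth.

    Each copy at level d carries a fixed substitution count targeting the
    center of the d-percent landscape bin, so recovered divergence falls in
    that bin deterministically up to alignment trimming.
    """
    for d in divergence_levels:
        if not 0.0 <= d <= 0.5:
            raise ValueError("divergence levels must lie in [0, 0.5]")
    rng = np.random.default_rng(rng_seed)
    reads: List[str] = []
    truth = TruthRecord(
        kind="te_copies",
        seed=rng_seed,
        params={
            "n_copies": n_copies,
            "read_length": read_length,
            "divergence_levels": list(divergence_levels),
            "consensus_length": len(consensus),
        },
    )
    for d in divergence_levels:
        count = divergence_mutation_count(len(consensus), d)
        for _ in range(n_copies):
            copy, positions = _mutate(consensus, count, rng)
            for start in range(0, len(copy) - read_length + 1, read_length):
                reads.append(copy[start: start + read_length])
                in_read = np.sum((positions >= start) & (positions < start + read_length))
                truth.read_divergences.append(float(in_read / read_length))
    return reads, truth
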