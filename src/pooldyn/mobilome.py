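"""TE insertion calling from paired-end signatures, insertion frequency
spectra, read-vs-library divergence landscapes, genome-architecture windows
and telomere-motif scans.

The signature caller reimplements the four-step physical-pileup procedure
(identify → frequency → filter → pair-up) in structure; parity is tested
against the synthetic-truth generator, not against any external tool.
"""

from __future__ import annotations

import math
import random
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

import numpy as np

from .formats import FeatureSet, TEHierarchy

__all__ = [
    "REF_CLASS",
    "SV_CLASS",
    "DEFAULT_TELOMERE_MOTIFS",
    "SignatureParams",
    "PairEvidence",
    "Signature",
    "TEInsertion",
    "LandscapeBin",
    "SpectrumResult",
    "build_te_merged_reference",
    "detect_te_insertions",
    "unique_insertions",
    "frequency_spectrum",
    "repeat_landscape",
    "window_composition",
    "telomere_scan",
    "read_pair_evidence",
    "write_pair_evidence",
]

REF_CLASS = "ref"
SV_CLASS = "sv"

#: Coleopteran telomeric repeat motifs screened at scaffold ends
DEFAULT_TELOMERE_MOTIFS = ("AACAGACCCG", "AACCC", "AACCT", "ACCTG")

NAN = float("nan")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SignatureParams:
    """Knobs of the physical-pileup signature caller."""

    map_qual: int = 15
    target_coverage: int = 10
    min_count: int = 2
    max_otherte_count: int = 2
    max_structvar_count: int = 2
    min_distance: int = -200
    max_distance: int = 300
    join_distance: int = 100  # max gap between supported positions in a run

    def __post_init__(self):
        if self.min_distance > self.max_distance:
            raise ValueError("min_distance > max_distance")
        for name in ("map_qual", "target_coverage", "min_count",
                     "max_otherte_count", "max_structvar_count", "join_distance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PairEvidence:
    """One read pair: anchor in the reference, mate classified by target.

    ``mate_class`` is a TE family id, :data:`REF_CLASS` for properly mapped
    reference pairs, or :data:`SV_CLASS` for structural-variant-like pairs.
    ``span`` is the physical stretch of reference covered by the pair,
    extending rightward from the anchor on '+' and leftward on '−'.
    """

    chrom: str
    pos: int
    strand: str
    mate_class: str
    mapq: int
    span: int = 1

    def __post_init__(self):
        if self.mapq < 0:
            raise ValueError("mapping quality must be >= 0")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.span < 1:
            raise ValueError("span must be >= 1")

    def interval(self) -> Tuple[int, int]:
        if self.strand == "+":
            return self.pos, self.pos + self.span - 1
        return self.pos - self.span + 1, self.pos


def write_pair_evidence(pairs: Iterable[PairEvidence]) -> str:
    lines = ["#chrom\tpos\tstrand\tmate_class\tmapq\tspan"]
    for p in pairs:
        lines.append(f"{p.chrom}\t{p.pos}\t{p.strand}\t{p.mate_class}\t{p.mapq}\t{p.span}")
    return "\n".join(lines) + "\n"


def read_pair_evidence(text: str) -> List[PairEvidence]:
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        span = int(f[5]) if len(f) > 5 else 1
        out.append(PairEvidence(f[0], int(f[1]), f[2], f[3], int(f[4]), span))
    return out


@dataclass
class Signature:
    """One strand-specific breakpoint-side cluster of TE-classed pairs."""

    chrom: str
    strand: str
    family: str
    center: int
    support: int
    frequency: float
    start: int
    end: int


@dataclass
class TEInsertion:
    chrom: str
    pos: int
    family: str
    order: str = ""
    frequency: float = NAN
    support: int = 0
    populations: frozenset = frozenset()
    paired: bool = False

    def __post_init__(self):
        if not math.isnan(self.frequency) and not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must be in [0, 1]")


@dataclass(frozen=True)
class LandscapeBin:
    label: str
    bin: int  # percent-divergence bin [bin, bin+1)
    proportion: float


# ---------------------------------------------------------------------------
# TE-merged reference
# ---------------------------------------------------------------------------

def build_te_merged_reference(
    genome: Dict[str, str],
    repeat_annotation: FeatureSet,
    te_library: Dict[str, str],
    hierarchy: TEHierarchy,
) -> Tuple[Dict[str, str], Dict[str, Tuple[str, str]]]:
    """Hard-mask annotated repeats and append the TE library records.

    Returns the merged sequence dict and a provenance table mapping each
    appended record id to its (family, order).
    """
    masked = {name: list(seq) for name, seq in genome.items()}
    for feat in repeat_annotation:
        if feat.chrom not in masked:
            raise KeyError(f"repeat interval on unknown sequence {feat.chrom!r}")
        seq = masked[feat.chrom]
        if feat.end > len(seq):
            raise ValueError(
                f"repeat {feat.chrom}:{feat.start}-{feat.end} exceeds sequence length"
            )
        for i in range(feat.start - 1, feat.end):
            seq[i] = "N"
    merged = {name: "".join(seq) for name, seq in masked.items()}
    provenance: Dict[str, Tuple[str, str]] = {}
    for te_id, seq in te_library.items():
        if te_id not in hierarchy:
            raise KeyError(f"TE library sequence {te_id!r} missing from hierarchy")
        if te_id in merged:
            raise ValueError(f"TE library id {te_id!r} collides with a genome record")
        merged[te_id] = seq
        provenance[te_id] = (hierarchy.family(te_id), hierarchy.order(te_id))
    return merged, provenance


# ---------------------------------------------------------------------------
# signature caller
# ---------------------------------------------------------------------------

class _Run:
    __slots__ = ("start", "end", "w_sum", "wpos_sum", "pair_ids", "ref_ids",
                 "other_ids", "sv_ids")

    def __init__(self, pos: int):
        self.start = pos
        self.end = pos
        self.w_sum = 0
        self.wpos_sum = 0
        self.pair_ids: Set[int] = set()
        self.ref_ids: Set[int] = set()
        self.other_ids: Set[int] = set()
        self.sv_ids: Set[int] = set()


def detect_te_insertions(
    evidence: Sequence[PairEvidence],
    params: SignatureParams,
    rng_seed: int = 0,
    hierarchy: Optional[TEHierarchy] = None,
) -> List[TEInsertion]:
    """Call TE insertions from a sorted physical-pileup evidence table.

    Per position the spanning pairs are subsampled (seeded, without
    replacement) to ``target_coverage``; strand-specific runs of family
    support become signatures when the family's distinct-pair support
    reaches ``min_count``; contaminated signatures are discarded; forward
    and reverse signatures of one family merge into a single insertion when
    their separation lies within the pairing window.
    """
    _check_sorted(evidence)
    rng = random.Random(rng_seed)
    signatures: List[Signature] = []
    by_chrom: Dict[str, List[PairEvidence]] = defaultdict(list)
    for pair in evidence:
        if pair.mapq >= params.map_qual:
            by_chrom[pair.chrom].append(pair)
    for chrom in by_chrom:
        signatures.extend(_chrom_signatures(chrom, by_chrom[chrom], params, rng))
    kept = [
        s for s in signatures
        if s.support >= params.min_count
    ]
    insertions = _pair_up(kept, params)
    if hierarchy is not None:
        # evidence mate classes may be library ids or family names
        order_of = {}
        for te_id, (family, order) in hierarchy.table.items():
            order_of.setdefault(family, order)
            order_of[te_id] = order
        for ins in insertions:
            ins.order = order_of.get(ins.family, "")
    insertions.sort(key=lambda i: (i.chrom, i.pos, i.family))
    return insertions


def _check_sorted(evidence: Sequence[PairEvidence]) -> None:
    seen = set()
    last_chrom, last_pos = None, -1
    for pair in evidence:
        if pair.chrom != last_chrom:
            if pair.chrom in seen:
                raise ValueError(f"evidence not sorted: {pair.chrom} reappears")
            seen.add(pair.chrom)
            last_chrom, last_pos = pair.chrom, pair.pos
        elif pair.pos < last_pos:
            raise ValueError(
                f"evidence not sorted at {pair.chrom}:{pair.pos} (after {last_pos})"
            )
        last_pos = pair.pos


def _chrom_signatures(
    chrom: str,
    pairs: List[PairEvidence],
    params: SignatureParams,
    rng: random.Random,
) -> List[Signature]:
    starts: Dict[int, List[int]] = defaultdict(list)
    ends: Dict[int, List[int]] = defaultdict(list)
    for j, pair in enumerate(pairs):
        s, e = pair.interval()
        starts[s].append(j)
        ends[e].append(j)
    if not starts:
        return []
    boundary = sorted(set(starts) | set(ends))
    runs: Dict[Tuple[str, str], _Run] = {}
    finished: List[Signature] = []

    def close(key: Tuple[str, str], run: _Run) -> None:
        if run.w_sum == 0:
            return
        strand, family = key
        center = int(round(run.wpos_sum / run.w_sum))
        # frequency from distinct retained pairs: TE-supporting over
        # TE-supporting + reference-supporting physical coverage of the run
        support = len(run.pair_ids)
        denom = support + len(run.ref_ids)
        freq = support / denom if denom else NAN
        sig = Signature(chrom, strand, family, center, support,
                        freq, run.start, run.end)
        if (len(run.other_ids) <= params.max_otherte_count
                and len(run.sv_ids) <= params.max_structvar_count):
            finished.append(sig)

    active: Set[int] = set()
    bi = 0
    pos = boundary[0]
    while bi < len(boundary):
        pos = boundary[bi]
        active |= set(starts.get(pos, ()))
        # flush runs whose gap exceeded the join distance
        for key in list(runs):
            if pos - runs[key].end > params.join_distance:
                close(key, runs.pop(key))
        _scan_position(chrom, pos, pos, active, pairs, params, rng, runs, close)
        for j in ends.get(pos, ()):
            active.discard(j)
        # walk interior positions until the next boundary
        nxt = boundary[bi + 1] if bi + 1 < len(boundary) else None
        if nxt is not None and active and nxt > pos + 1:
            _scan_position(chrom, pos + 1, nxt - 1, active, pairs, params, rng, runs, close)
        bi += 1
    for key in list(runs):
        close(key, runs.pop(key))
    return finished


def _scan_position(
    chrom: str,
    lo: int,
    hi: int,
    active: Set[int],
    pairs: List[PairEvidence],
    params: SignatureParams,
    rng: random.Random,
    runs: Dict[Tuple[str, str], _Run],
    close,
) -> None:
    if not active:
        return
    target = params.target_coverage
    act = sorted(active)
    for pos in range(lo, hi + 1):
        if len(act) > target:
            kept = rng.sample(act, target)
        else:
            kept = act
        per_strand: Dict[str, Dict[str, List[int]]] = {"+": defaultdict(list), "-": defaultdict(list)}
        sv_ids = []
        for j in kept:
            p = pairs[j]
            if p.mate_class == SV_CLASS:
                sv_ids.append(j)
            else:
                per_strand[p.strand][p.mate_class].append(j)
        for strand in "+-":
            classes = per_strand[strand]
            ref_ids = classes.get(REF_CLASS, [])
            for family, ids in classes.items():
                if family == REF_CLASS:
                    continue
                key = (strand, family)
                run = runs.get(key)
                if run is not None and pos - run.end > params.join_distance:
                    close(key, run)
                    run = None
                if run is None:
                    run = runs[key] = _Run(pos)
                w = len(ids)
                run.end = pos
                run.w_sum += w
                run.wpos_sum += w * pos
                run.pair_ids.update(ids)
                run.ref_ids.update(ref_ids)
                for other_fam, other_ids in classes.items():
                    if other_fam not in (REF_CLASS, family):
                        run.other_ids.update(other_ids)
                run.sv_ids.update(sv_ids)


def _pair_up(signatures: List[Signature], params: SignatureParams) -> List[TEInsertion]:
    out: List[TEInsertion] = []
    by_key: Dict[Tuple[str, str], Dict[str, List[Signature]]] = defaultdict(
        lambda: {"+": [], "-": []}
    )
    for sig in signatures:
        by_key[(sig.chrom, sig.family)][sig.strand].append(sig)
    for (chrom, family), sides in by_key.items():
        fwd = sorted(sides["+"], key=lambda s: s.center)
        rev = sorted(sides["-"], key=lambda s: s.center)
        used_rev: Set[int] = set()
        for f in fwd:
            best = None
            for ri, r in enumerate(rev):
                if ri in used_rev:
                    continue
                sep = r.center - f.center
                if params.min_distance <= sep <= params.max_distance:
                    if best is None or abs(sep) < abs(rev[best].center - f.center):
                        best = ri
            if best is not None:
                used_rev.add(best)
                r = rev[best]
                out.append(TEInsertion(
                    chrom, int(round((f.center + r.center) / 2)), family,
                    frequency=float(np.nanmean([f.frequency, r.frequency])),
                    support=f.support + r.support, paired=True,
                ))
            else:
                out.append(TEInsertion(chrom, f.center, family,
                                       frequency=f.frequency, support=f.support))
        for ri, r in enumerate(rev):
            if ri not in used_rev:
                out.append(TEInsertion(chrom, r.center, family,
                                       frequency=r.frequency, support=r.support))
    return out


# ---------------------------------------------------------------------------
# cross-population uniqueness
# ---------------------------------------------------------------------------

def unique_insertions(
    per_population: Dict[str, List[TEInsertion]],
    tolerance: int = 25,
) -> Dict[str, List[TEInsertion]]:
    """Per population, the insertions found in that population only.

    Insertions of the same family whose positions differ by at most
    ``tolerance`` (chained across populations) are one event.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    records = []
    for pop, insertions in per_population.items():
        for ins in insertions:
            records.append((ins.family, ins.chrom, ins.pos, pop, ins))
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    out: Dict[str, List[TEInsertion]] = {pop: [] for pop in per_population}
    cluster: List[Tuple[str, TEInsertion]] = []

    def flush():
        if not cluster:
            return
        pops = {pop for pop, _ in cluster}
        if len(pops) == 1:
            pop = next(iter(pops))
            out[pop].extend(ins for _, ins in cluster)
        cluster.clear()

    prev = None
    for family, chrom, pos, pop, ins in records:
        if prev is not None and (
            family != prev[0] or chrom != prev[1] or pos - prev[2] > tolerance
        ):
            flush()
        cluster.append((pop, ins))
        prev = (family, chrom, pos)
    flush()
    return out


# ---------------------------------------------------------------------------
# frequency spectrum
# ---------------------------------------------------------------------------

@dataclass
class SpectrumResult:
    histogram: np.ndarray
    bin_edges: np.ndarray
    low_fraction: float
    high_fraction: float
    fixed_fraction: float
    n: int


def frequency_spectrum(
    insertions: Sequence[TEInsertion],
    n_bins: int = 20,
    fixed_tolerance: float = 1e-9,
) -> SpectrumResult:
    """Equal-width histogram on [0, 1] plus low/high/fixed fractions.

    low: f < 0.5, high: f > 0.5, fixed: f = 1 (within tolerance).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    freqs = np.array([i.frequency for i in insertions if not math.isnan(i.frequency)])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    if freqs.size == 0:
        return SpectrumResult(np.zeros(n_bins, dtype=int), edges, NAN, NAN, NAN, 0)
    hist, _ = np.histogram(freqs, bins=edges)
    n = freqs.size
    return SpectrumResult(
        hist, edges,
        float(np.sum(freqs < 0.5) / n),
        float(np.sum(freqs > 0.5) / n),
        float(np.sum(np.abs(freqs - 1.0) <= fixed_tolerance) / n),
        n,
    )


# ---------------------------------------------------------------------------
# divergence landscape
# ---------------------------------------------------------------------------

def _make_aligner():
    from Bio import Align

    # overlap alignment: free end gaps on both sequences, substitutions
    # preferred over gap shuffles so mismatch counts stay exact
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -2.0
    aligner.end_gap_score = 0.0
    return aligner


def _alignment_stats(alignment) -> Tuple[int, int, int, int]:
    """(identities, mismatches, internal gap columns, read bases aligned)."""
    t_blocks, q_blocks = alignment.aligned
    target = str(alignment.target)
    query = str(alignment.query)
    ident = mism = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for a, b in zip(target[ts:te], query[qs:qe]):
            if a == b:
                ident += 1
            else:
                mism += 1
    gaps = 0
    for i in range(1, len(t_blocks)):
        gaps += (t_blocks[i][0] - t_blocks[i - 1][1]) + (q_blocks[i][0] - q_blocks[i - 1][1])
    read_aligned = int(q_blocks[-1][1] - q_blocks[0][0]) if len(q_blocks) else 0
    return ident, mism, gaps, read_aligned


def repeat_landscape(
    reads: Sequence[str],
    te_library: Dict[str, str],
    hierarchy: TEHierarchy,
    sample_coverage: float = 0.1,
    genome_size: Optional[int] = None,
    rng_seed: int = 0,
    label_by: str = "family",
    min_identities: int = 80,
    min_read_fraction: float = 0.5,
) -> List[LandscapeBin]:
    """Read-vs-library divergence landscape in 1%-divergence bins.

    Reads are subsampled (seeded, without replacement) down to
    ``sample_coverage × genome_size`` total bases, locally aligned against
    every library sequence (both strands), and assigned to their best hit.
    Hits with fewer than ``min_identities`` matching columns *and* less than
    ``min_read_fraction`` of the read aligned are discarded. Divergence is
    (mismatches + gaps) / aligned columns; the genome proportion of a
    (label, bin) cell is its aligned read bases over all sampled bases.
    """
    if not te_library:
        raise ValueError("TE library is empty")
    if label_by not in ("family", "order", "id"):
        raise ValueError("label_by must be 'family', 'order' or 'id'")
    reads = list(reads)
    rng = np.random.default_rng(rng_seed)
    if genome_size is not None:
        budget = sample_coverage * genome_size
        order = rng.permutation(len(reads))
        chosen: List[str] = []
        total = 0
        for i in order:
            if total >= budget:
                break
            chosen.append(reads[i])
            total += len(reads[i])
        reads = chosen
    total_bases = sum(len(r) for r in reads)
    if total_bases == 0:
        return []
    aligner = _make_aligner()
    lib_ids = list(te_library)
    labels = {}
    for te_id in lib_ids:
        if label_by == "id" or te_id not in hierarchy:
            labels[te_id] = te_id
        else:
            labels[te_id] = (hierarchy.family(te_id) if label_by == "family"
                             else hierarchy.order(te_id))
    mass: Dict[Tuple[str, int], float] = defaultdict(float)
    for read in reads:
        best = None  # (score, te_id, oriented read)
        for te_id in lib_ids:
            lib = te_library[te_id]
            for oriented in (read, _revcomp(read)):
                score = aligner.score(lib, oriented)
                if best is None or score > best[0]:
                    best = (score, te_id, oriented)
        if best is None or best[0] <= 0:
            continue
        _, te_id, oriented = best
        alignment = aligner.align(te_library[te_id], oriented)[0]
        ident, mism, gaps, read_aligned = _alignment_stats(alignment)
        if ident < min_identities and read_aligned < min_read_fraction * len(read):
            continue
        cols = ident + mism + gaps
        if cols == 0:
            continue
        divergence = 100.0 * (mism + gaps) / cols
        bin_i = min(99, int(divergence))
        mass[(labels[te_id], bin_i)] += read_aligned
    return [
        LandscapeBin(label, bin_i, aligned / total_bases)
        for (label, bin_i), aligned in sorted(mass.items())
    ]


# ---------------------------------------------------------------------------
# genome-architecture windows
# ---------------------------------------------------------------------------

_ORDER_CLASSES = ("DNA", "LTR", "LINE", "Unknown")


def _te_class(order: str) -> str:
    if not order:
        return "Unknown"
    head = order.split("/")[0]
    for cls in _ORDER_CLASSES:
        if head.lower().startswith(cls.lower()):
            return cls
    return "other"


def window_composition(
    features: FeatureSet,
    window: "WindowSpec",
    genome_lengths: Dict[str, int],
):
    """Per-window fractions of TE-derived (by order class) and exonic bases.

    Intervals are merged per class before fractions are computed; windows
    running past a scaffold end are truncated and use the truncated length
    as denominator. Returns a pandas DataFrame.
    """
    import pandas as pd

    classes = list(_ORDER_CLASSES) + ["other", "exon"]
    by_class: Dict[Tuple[str, str], List[Tuple[int, int]]] = defaultdict(list)
    for feat in features:
        if feat.ftype == "exon":
            cls = "exon"
        elif feat.ftype == "repeat":
            cls = _te_class(feat.order)
        else:
            continue
        end = min(feat.end, genome_lengths.get(feat.chrom, feat.end))
        by_class[(feat.chrom, cls)].append((feat.start, end))
    merged = {key: _merge(spans) for key, spans in by_class.items()}
    rows = []
    for chrom in sorted(genome_lengths):
        length = genome_lengths[chrom]
        n_windows = (length + window.size - 1) // window.size
        for idx in range(n_windows):
            start = idx * window.size + 1
            end = min((idx + 1) * window.size, length)
            row = {"chrom": chrom, "start": start, "end": end}
            span_len = end - start + 1
            for cls in classes:
                row[cls] = _overlap(merged.get((chrom, cls), []), start, end) / span_len
            rows.append(row)
    return pd.DataFrame(rows)


def _merge(spans: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    spans = sorted(spans)
    out: List[Tuple[int, int]] = []
    for s, e in spans:
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlap(merged: List[Tuple[int, int]], start: int, end: int) -> int:
    total = 0
    for s, e in merged:
        lo, hi = max(s, start), min(e, end)
        if lo <= hi:
            total += hi - lo + 1
    return total


# ---------------------------------------------------------------------------
# telomere scan
# ---------------------------------------------------------------------------

@dataclass
class TelomereEnrichment:
    chrom: str
    end: str  # 'start' | 'end'
    motif: str
    count: int
    median: float


def telomere_scan(
    genome: Dict[str, str],
    motifs: Sequence[str] = DEFAULT_TELOMERE_MOTIFS,
    window: int = 10_000,
    end_windows: int = 3,
    enrichment_factor: float = 10.0,
    min_absolute_count: int = 25,
):
    """Non-overlapping motif counts per window plus end-enrichment flags.

    Each window counts a motif and its reverse complement. A scaffold end is
    enriched for a motif when the best of its terminal windows reaches both
    ``enrichment_factor ×`` the scaffold's median window count and
    ``min_absolute_count``.
    """
    import pandas as pd

    if not motifs:
        raise ValueError("need at least one motif")
    for motif in motifs:
        if not motif or any(b not in "ACGT" for b in motif):
            raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    rows = []
    flags: List[TelomereEnrichment] = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        n_windows = max(1, (len(seq) + window - 1) // window)
        counts = {m: [] for m in motifs}
        for idx in range(n_windows):
            chunk = seq[idx * window: (idx + 1) * window]
            row = {"chrom": chrom, "window": idx,
                   "start": idx * window + 1, "end": min((idx + 1) * window, len(seq))}
            for motif in motifs:
                c = chunk.count(motif) + chunk.count(_revcomp(motif))
                counts[motif].append(c)
                row[motif] = c
            rows.append(row)
        for motif in motifs:
            series = counts[motif]
            med = float(np.median(series))
            threshold = max(enrichment_factor * med, float(min_absolute_count))
            head = max(series[:end_windows])
            tail = max(series[-end_windows:])
            if head >= threshold:
                flags.append(TelomereEnrichment(chrom, "start", motif, head, med))
            if tail >= threshold and n_windows > 1:
                flags.append(TelomereEnrichment(chrom, "end", motif, tail, med))
    return pd.DataFrame(rows), flags


from .popgen import WindowSpec  # noqa: E402  (re-export convenience for callers)
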