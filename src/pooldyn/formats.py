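"""Readers/writers for the text formats the pipeline touches.

Coordinates are 1-based inclusive internally (mpileup/sync/GFF convention);
BED content is converted to/from 0-based half-open at the boundary.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, TextIO, Tuple, Union

__all__ = [
    "ALLELE_ORDER",
    "SiteCounts",
    "MaskIntervals",
    "TEHierarchy",
    "Feature",
    "FeatureSet",
    "MpileupError",
    "SyncError",
    "read_mpileup",
    "read_sync",
    "write_sync",
    "identify_indel_regions",
    "apply_mask",
    "read_fasta",
    "write_fasta",
    "read_te_hierarchy",
    "read_gff3_features",
    "read_bed_features",
]

#: fixed allele column order of sync files: A, T, C, G, N, deletion
ALLELE_ORDER = "ATCGN*"

_NUC_INDEX = {"A": 0, "T": 1, "C": 2, "G": 3, "N": 4}


class MpileupError(ValueError):
    """Malformed mpileup input (carries the 1-based line number)."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class SyncError(ValueError):
    """Malformed sync input."""


@dataclass(frozen=True)
class SiteCounts:
    """Per-site, per-pool nucleotide counts — the atom of every estimator.

    ``counts[p]`` is the 6-tuple (A, T, C, G, N, deletion) for pool ``p``.
    ``indels[p]`` counts indel *events* seen in the pileup column (insertion
    strings plus deletion-spanning reads), used only for indel masking.
    Coverage excludes N and deletions: estimators live on the ACGT simplex.
    """

    chrom: str
    pos: int
    ref: str
    counts: Tuple[Tuple[int, int, int, int, int, int], ...]
    indels: Tuple[int, ...] = ()

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for pool in self.counts:
            if len(pool) != 6:
                raise ValueError("each pool needs 6 counts (A,T,C,G,N,del)")
            if any(c < 0 for c in pool):
                raise ValueError("negative allele count")
        if not self.indels:
            object.__setattr__(self, "indels", (0,) * len(self.counts))

    @property
    def n_pools(self) -> int:
        return len(self.counts)

    def coverage(self, pool: int) -> int:
        """ACGT read depth of one pool (N and '*' excluded)."""
        c = self.counts[pool]
        return c[0] + c[1] + c[2] + c[3]

    def indel_evidence(self) -> int:
        return sum(self.indels)


class MaskIntervals:
    """Sorted, merged, 1-based closed intervals to exclude, per chromosome."""

    def __init__(self, intervals: Optional[Dict[str, Iterable[Tuple[int, int]]]] = None):
        self._ivals: Dict[str, List[Tuple[int, int]]] = {}
        self._starts: Dict[str, List[int]] = {}
        if intervals:
            for chrom, spans in intervals.items():
                self._ivals[chrom] = _merge_intervals(list(spans))
        self._reindex()

    def _reindex(self) -> None:
        self._starts = {c: [s for s, _ in iv] for c, iv in self._ivals.items()}

    def intervals(self, chrom: str) -> List[Tuple[int, int]]:
        return list(self._ivals.get(chrom, []))

    @property
    def chroms(self) -> List[str]:
        return sorted(self._ivals)

    def __len__(self) -> int:
        return sum(len(v) for v in self._ivals.values())

    def __contains__(self, item: Tuple[str, int]) -> bool:
        return self.contains(*item)

    def contains(self, chrom: str, pos: int) -> bool:
        iv = self._ivals.get(chrom)
        if not iv:
            return False
        i = bisect.bisect_right(self._starts[chrom], pos) - 1
        return i >= 0 and iv[i][0] <= pos <= iv[i][1]

    def total_masked(self) -> int:
        return sum(e - s + 1 for iv in self._ivals.values() for s, e in iv)

    def to_bed(self) -> str:
        """Serialize as BED (0-based half-open)."""
        lines = []
        for chrom in sorted(self._ivals):
            for s, e in self._ivals[chrom]:
                lines.append(f"{chrom}\t{s - 1}\t{e}")
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_bed(cls, text: str) -> "MaskIntervals":
        spans: Dict[str, List[Tuple[int, int]]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            spans.setdefault(chrom, []).append((int(start) + 1, int(end)))
        return cls(spans)


def _merge_intervals(spans: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    for s, e in spans:
        if s > e:
            raise ValueError(f"interval start {s} > end {e}")
    spans = sorted(spans)
    merged: List[Tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass(frozen=True)
class TEHierarchy:
    """Maps every TE library sequence id to its (family, order)."""

    table: Dict[str, Tuple[str, str]]

    def family(self, te_id: str) -> str:
        return self.table[te_id][0]

    def order(self, te_id: str) -> str:
        return self.table[te_id][1]

    def __contains__(self, te_id: str) -> bool:
        return te_id in self.table

    def __len__(self) -> int:
        return len(self.table)


def read_te_hierarchy(text: Union[str, TextIO]) -> TEHierarchy:
    """Parse the 3-column tab-separated ``id  family  order`` table.

    A header line whose first field is ``id`` is skipped. Duplicate ids are
    rejected.
    """
    if hasattr(text, "read"):
        text = text.read()
    table: Dict[str, Tuple[str, str]] = {}
    for i, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"hierarchy line {i}: expected 3 tab-separated fields")
        te_id, family, order = fields
        if i == 1 and te_id.lower() == "id":
            continue
        if te_id in table:
            raise ValueError(f"hierarchy line {i}: duplicate id {te_id!r}")
        table[te_id] = (family, order)
    return TEHierarchy(table)


# ---------------------------------------------------------------------------
# mpileup
# ---------------------------------------------------------------------------

def read_mpileup(
    stream: Union[str, TextIO, Iterable[str]],
    n_pools: int,
    min_base_quality: int = 20,
    quality_offset: int = 33,
) -> Iterator[SiteCounts]:
    """Decode samtools mpileup text into :class:`SiteCounts`.

    One base/quality column pair per pool is expected after the leading
    ``chrom pos ref`` columns. Bases with Phred quality below
    ``min_base_quality`` are discarded; indel strings are consumed and
    recorded as per-pool indel evidence for masking.
    """
    if isinstance(stream, str):
        stream = stream.splitlines()
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 3 + 3 * n_pools:
            raise MpileupError(
                f"expected {3 + 3 * n_pools} columns for {n_pools} pools, got {len(fields)}",
                lineno,
            )
        chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
        try:
            pos = int(pos_s)
        except ValueError:
            raise MpileupError(f"non-integer position {pos_s!r}", lineno) from None
        counts = []
        indels = []
        for p in range(n_pools):
            depth_s, bases, quals = fields[3 + 3 * p: 6 + 3 * p]
            try:
                depth = int(depth_s)
            except ValueError:
                raise MpileupError(f"non-integer depth {depth_s!r}", lineno) from None
            pool_counts, n_indels = _decode_pileup_column(
                bases, quals, ref, depth, min_base_quality, quality_offset, lineno
            )
            counts.append(pool_counts)
            indels.append(n_indels)
        yield SiteCounts(chrom, pos, ref, tuple(counts), tuple(indels))


def _decode_pileup_column(
    bases: str,
    quals: str,
    ref: str,
    depth: int,
    min_q: int,
    offset: int,
    lineno: int,
) -> Tuple[Tuple[int, int, int, int, int, int], int]:
    counts = [0, 0, 0, 0, 0, 0]
    n_indels = 0
    n_events = 0
    qi = 0
    i = 0
    L = len(bases)
    if depth == 0 and bases in ("*", ""):
        return (0, 0, 0, 0, 0, 0), 0
    while i < L:
        ch = bases[i]
        if ch == "^":
            if i + 1 >= L:
                raise MpileupError("dangling '^' start marker", lineno)
            i += 2  # skip marker and mapping-quality byte
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            j = i + 1
            while j < L and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise MpileupError(f"indel marker {ch!r} without length", lineno)
            n = int(bases[i + 1: j])
            if j + n > L:
                raise MpileupError("indel length overruns base string", lineno)
            i = j + n
            n_indels += 1
            continue
        # every remaining symbol consumes one quality byte
        if qi >= len(quals):
            raise MpileupError("base and quality strings out of sync", lineno)
        q = ord(quals[qi]) - offset
        qi += 1
        n_events += 1
        i += 1
        if q < min_q:
            continue
        if ch in ".,":
            if ref in _NUC_INDEX:
                counts[_NUC_INDEX[ref]] += 1
            else:
                counts[4] += 1
        elif ch.upper() in _NUC_INDEX:
            counts[_NUC_INDEX[ch.upper()]] += 1
        elif ch == "*":
            counts[5] += 1
            n_indels += 1  # deletion-spanning read is indel evidence
        elif ch in "<>":
            counts[4] += 1
        else:
            raise MpileupError(f"unexpected pileup symbol {ch!r}", lineno)
    if qi != len(quals):
        raise MpileupError(
            f"quality string length {len(quals)} != decoded events {qi}", lineno
        )
    if n_events != depth:
        raise MpileupError(
            f"decoded events {n_events} != printed depth {depth}", lineno
        )
    return tuple(counts), n_indels  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# sync
# ---------------------------------------------------------------------------

def write_sync(sites: Iterable[SiteCounts]) -> str:
    """Serialize sites as PoPoolation2-style sync text."""
    lines = []
    for site in sites:
        cols = [":".join(str(c) for c in pool) for pool in site.counts]
        lines.append("\t".join([site.chrom, str(site.pos), site.ref] + cols))
    return "\n".join(lines) + ("\n" if lines else "")


def write_sync_to(sites: Iterable[SiteCounts], handle: TextIO) -> None:
    for site in sites:
        cols = [":".join(str(c) for c in pool) for pool in site.counts]
        handle.write("\t".join([site.chrom, str(site.pos), site.ref] + cols) + "\n")


def read_sync(text: Union[str, TextIO, Iterable[str]]) -> Iterator[SiteCounts]:
    """Parse sync text back into :class:`SiteCounts` (inverse of write_sync)."""
    if isinstance(text, str):
        text = text.splitlines()
    for lineno, line in enumerate(text, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise SyncError(f"line {lineno}: expected >= 4 columns")
        chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
        counts = []
        for col in fields[3:]:
            parts = col.split(":")
            if len(parts) != 6:
                raise SyncError(
                    f"line {lineno}: pool column {col!r} has {len(parts)} fields, expected 6"
                )
            try:
                counts.append(tuple(int(x) for x in parts))
            except ValueError:
                raise SyncError(f"line {lineno}: non-integer count in {col!r}") from None
        yield SiteCounts(chrom, int(pos_s), ref, tuple(counts))


# ---------------------------------------------------------------------------
# indel masking
# ---------------------------------------------------------------------------

def identify_indel_regions(
    sites: Iterable[SiteCounts],
    min_count: int = 2,
    flank: int = 5,
) -> MaskIntervals:
    """Mask a ±``flank`` window around every site with enough indel evidence.

    A site contributes [pos − flank, pos + flank] (floored at 1) when its
    indel evidence summed across pools reaches ``min_count``. Overlapping
    windows are merged.
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    spans: Dict[str, List[Tuple[int, int]]] = {}
    for site in sites:
        if site.indel_evidence() >= min_count:
            spans.setdefault(site.chrom, []).append(
                (max(1, site.pos - flank), site.pos + flank)
            )
    return MaskIntervals(spans)


def apply_mask(sites: Iterable[SiteCounts], mask: MaskIntervals) -> Iterator[SiteCounts]:
    """Drop sites falling inside any mask interval, preserving order."""
    for site in sites:
        if not mask.contains(site.chrom, site.pos):
            yield site


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(source: Union[str, TextIO]) -> Dict[str, str]:
    """Read FASTA into an ordered {id: sequence} dict (uppercased)."""
    from Bio import SeqIO
    import io
    import os

    if isinstance(source, str) and not os.path.exists(source) and source.lstrip().startswith(">"):
        handle: Union[TextIO, str] = io.StringIO(source)
    else:
        handle = source
    records = {}
    close = False
    if isinstance(handle, str):
        handle = open(handle)
        close = True
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            records[rec.id] = str(rec.seq).upper()
    finally:
        if close:
            handle.close()
    return records


def write_fasta(records: Dict[str, str], width: int = 80) -> str:
    chunks = []
    for name, seq in records.items():
        chunks.append(f">{name}")
        for i in range(0, len(seq), width):
            chunks.append(seq[i: i + width])
    return "\n".join(chunks) + ("\n" if chunks else "")


# ---------------------------------------------------------------------------
# genomic features (GFF3 / BED)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Feature:
    """Typed genomic interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    ftype: str  # exon | CDS | repeat | ...
    strand: str = "."
    frame: int = 0
    label: str = ""  # family for repeats, transcript id for CDS/exon
    order: str = ""  # TE order for repeats

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"feature start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class FeatureSet:
    """Bag of typed genomic intervals with simple selectors."""

    features: List[Feature] = field(default_factory=list)

    def of_type(self, ftype: str) -> List[Feature]:
        return [f for f in self.features if f.ftype == ftype]

    def add(self, feature: Feature) -> None:
        self.features.append(feature)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def cds_by_transcript(self) -> Dict[str, List[Feature]]:
        groups: Dict[str, List[Feature]] = {}
        for f in self.of_type("CDS"):
            groups.setdefault(f.label, []).append(f)
        for parts in groups.values():
            parts.sort(key=lambda f: f.start)
        return groups


def _gff3_attributes(field9: str) -> Dict[str, str]:
    attrs = {}
    for item in field9.strip().split(";"):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_gff3_features(
    text: Union[str, TextIO],
    types: Sequence[str] = ("exon", "CDS"),
) -> FeatureSet:
    """Load selected feature types from GFF3 text.

    CDS/exon labels are taken from the ``Parent`` (fallback ``ID``)
    attribute; repeat-like features use ``Name``/``Target``/``ID`` as the
    family label and ``classification``/``Order`` as the order when present.
    """
    if hasattr(text, "read"):
        text = text.read()
    wanted = set(types)
    fs = FeatureSet()
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            continue
        chrom, _src, ftype, start, end, _score, strand, phase, attr_s = fields
        if ftype not in wanted:
            continue
        attrs = _gff3_attributes(attr_s)
        frame = int(phase) if phase in ("0", "1", "2") else 0
        if ftype in ("CDS", "exon"):
            label = attrs.get("Parent", attrs.get("ID", ""))
        else:
            label = attrs.get("Name", attrs.get("Target", attrs.get("ID", "")))
        order = attrs.get("classification", attrs.get("Order", attrs.get("order", "")))
        fs.add(Feature(chrom, int(start), int(end), ftype, strand, frame, label, order))
    return fs


def read_bed_features(
    text: Union[str, TextIO],
    ftype: str = "repeat",
    hierarchy: Optional[TEHierarchy] = None,
) -> FeatureSet:
    """Load BED intervals (0-based half-open on disk) as 1-based features.

    The BED name column becomes the feature label; when a TE hierarchy is
    given, labels found in it also receive their order annotation.
    """
    if hasattr(text, "read"):
        text = text.read()
    fs = FeatureSet()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        label = fields[3] if len(fields) > 3 else ""
        strand = fields[5] if len(fields) > 5 else "."
        order = ""
        if hierarchy is not None and label in hierarchy:
            order = hierarchy.order(label)
        fs.add(Feature(chrom, start + 1, end, ftype, strand, 0, label, order))
    return fs
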