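"""iCLAE read preprocessing, coverage, peak calling and binding regions.

Pipeline order mirrors the experimental protocol: collapse identical raw
reads, demultiplex on the 4-nt barcode embedded in the 9-nt 5' prefix
(N3-XXXX-N2; the five random positions form the UMI), drop homopolymer
reads, then — on the alignments — MAPQ filter, UMI deduplication, per-base
coverage, rule-based peak calling, replicate consensus and binding-region
extraction.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats import AlignmentRecord, SeqRecord

log = logging.getLogger(__name__)

PREFIX_LEN = 9
BARCODE_SLICE = slice(3, 7)
UMI_POSITIONS = (0, 1, 2, 7, 8)
UNDETERMINED = "undetermined"


@dataclass
class DemuxedRead:
    sample: str
    umi: str
    insert: SeqRecord

    def __post_init__(self) -> None:
        if len(self.umi) != 5 or any(c not in "ACGTN" for c in self.umi):
            raise ValueError(f"bad UMI {self.umi!r}")


@dataclass
class CoverageVector:
    reference: str
    counts: np.ndarray


@dataclass
class Peak:
    reference: str
    start: int
    end: int
    read_count: int = 0
    cpm: float = 0.0
    replicate_support: int = 1

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def middle(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Peak") -> bool:
        return (
            self.reference == other.reference
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class BindingRegion:
    reference: str
    peak_start: int
    peak_end: int
    start: int
    end: int
    sequence: str
    g4: bool


# ---------------------------------------------------------------------------
# Read-level filters


def remove_identical_reads(reads: Sequence[SeqRecord]) -> list[SeqRecord]:
    """Collapse exact full-sequence duplicates, keeping the first occurrence."""
    seen: set[str] = set()
    out = []
    for r in reads:
        if r.sequence not in seen:
            seen.add(r.sequence)
            out.append(r)
    log.info("remove_identical_reads: %d -> %d", len(reads), len(out))
    return out


def demultiplex(
    reads: Sequence[SeqRecord], barcode_map: Mapping[str, str]
) -> tuple[list[DemuxedRead], Counter]:
    """Split reads by the exact 4-nt barcode at positions 3-6 of the 5' prefix.

    Positions 0-2 and 7-8 concatenate to the 5-nt UMI and the insert starts
    at position 9.  Reads shorter than 10 nt or with an unknown barcode go
    to the ``undetermined`` bin (counted, not returned).
    """
    if len(set(barcode_map)) != len(barcode_map):
        raise ValueError("duplicate barcodes in map")
    if len(set(barcode_map.values())) != len(barcode_map):
        raise ValueError("two barcodes map to the same sample")
    for code in barcode_map:
        if len(code) != 4:
            raise ValueError(f"barcode {code!r} is not 4 nt")
    demuxed: list[DemuxedRead] = []
    tally: Counter = Counter()
    for read in reads:
        seq = read.sequence
        if len(seq) <= PREFIX_LEN:
            tally[UNDETERMINED] += 1
            continue
        sample = barcode_map.get(seq[BARCODE_SLICE])
        if sample is None:
            tally[UNDETERMINED] += 1
            continue
        umi = "".join(seq[i] for i in UMI_POSITIONS)
        qual = read.quality[PREFIX_LEN:] if read.quality is not None else None
        demuxed.append(DemuxedRead(sample, umi, SeqRecord(read.id, seq[PREFIX_LEN:], qual)))
        tally[sample] += 1
    log.info("demultiplex: %s", dict(tally))
    return demuxed, tally


def filter_homopolymer(reads: Sequence[DemuxedRead], k: int = 10) -> list[DemuxedRead]:
    """Drop reads whose insert contains a run of >= k identical nucleotides."""
    if k < 2:
        raise ValueError("homopolymer run length must be >= 2")
    pattern = re.compile(r"(.)\1{%d,}" % (k - 1))
    out = [r for r in reads if not pattern.search(r.insert.sequence)]
    log.info("filter_homopolymer(k=%d): %d -> %d", k, len(reads), len(out))
    return out


def trim_reads(
    reads: Sequence[SeqRecord],
    adapter: str,
    min_qual: int = 10,
    min_len: int = 15,
    min_overlap: int = 3,
) -> list[SeqRecord]:
    """Remove a 3' adapter (longest read suffix matching an adapter prefix,
    requiring >= ``min_overlap`` nt), trim low-quality 3' tails, drop reads
    shorter than ``min_len``."""
    out = []
    for r in reads:
        seq, qual = r.sequence, r.quality
        for take in range(min(len(adapter), len(seq)), min_overlap - 1, -1):
            if seq.endswith(adapter[:take]):
                seq = seq[: len(seq) - take]
                if qual is not None:
                    qual = qual[: len(seq)]
                break
        if qual is not None:
            end = len(seq)
            while end > 0 and qual[end - 1] < min_qual:
                end -= 1
            seq, qual = seq[:end], qual[:end]
        if len(seq) >= min_len:
            out.append(SeqRecord(r.id, seq, qual))
    log.info("trim_reads: %d -> %d", len(reads), len(out))
    return out


# ---------------------------------------------------------------------------
# Alignment-level filters


def filter_mapq(
    alignments: Sequence[AlignmentRecord], min_mapq: int = 10
) -> list[AlignmentRecord]:
    out = [a for a in alignments if a.mapq >= min_mapq]
    log.info("filter_mapq(>=%d): %d -> %d", min_mapq, len(alignments), len(out))
    return out


def dedupe_umi(
    alignments: Sequence[AlignmentRecord],
) -> tuple[list[AlignmentRecord], float]:
    """Collapse PCR duplicates: one record per (reference, start, strand, umi).

    Input is sorted by (reference, start, end) first so the survivor is
    deterministic.  Returns the kept records and the duplicate rate.
    """
    for a in alignments:
        if not a.umi:
            raise ValueError("alignment without UMI")
    ordered = sorted(alignments, key=lambda a: (a.reference, a.start, a.end, a.umi))
    seen: set[tuple] = set()
    out = []
    for a in ordered:
        key = (a.reference, a.start, a.strand, a.umi)
        if key not in seen:
            seen.add(key)
            out.append(a)
    dup_rate = 1 - len(out) / len(alignments) if alignments else 0.0
    log.info("dedupe_umi: %d -> %d (dup rate %.3f)", len(alignments), len(out), dup_rate)
    return out, dup_rate


# ---------------------------------------------------------------------------
# Coverage and peaks


def coverage(
    alignments: Sequence[AlignmentRecord], reference_lengths: Mapping[str, int]
) -> dict[str, CoverageVector]:
    """Full-span per-base coverage (bedtools-style) per reference."""
    vectors = {
        ref: np.zeros(length, dtype=np.int64)
        for ref, length in reference_lengths.items()
    }
    for a in alignments:
        vec = vectors.get(a.reference)
        if vec is None:
            raise KeyError(f"alignment on unknown reference {a.reference!r}")
        vec[a.start : min(a.end, len(vec))] += 1
    return {ref: CoverageVector(ref, v) for ref, v in vectors.items()}


def crosslink_coverage(
    alignments: Sequence[AlignmentRecord], reference_lengths: Mapping[str, int]
) -> dict[str, CoverageVector]:
    """Alternative single-base coverage at read starts (off by default)."""
    vectors = {
        ref: np.zeros(length, dtype=np.int64)
        for ref, length in reference_lengths.items()
    }
    for a in alignments:
        vectors[a.reference][a.start] += 1
    return {ref: CoverageVector(ref, v) for ref, v in vectors.items()}


def call_peaks(
    cov: CoverageVector,
    min_cov: int = 10,
    merge_gap: int = 30,
    min_width: int = 30,
    alignments: Sequence[AlignmentRecord] | None = None,
    library_total: int | None = None,
) -> list[Peak]:
    """Rule-based peak calling on a coverage vector.

    1. take maximal runs of positions with coverage strictly > ``min_cov``;
    2. merge consecutive runs separated by a gap < ``merge_gap``;
    3. drop merged regions narrower than ``min_width``.

    When ``alignments`` are given, ``read_count`` is the number of alignments
    on this reference overlapping the final interval, and ``cpm`` is
    normalized to ``library_total`` reads.
    """
    counts = np.asarray(cov.counts)
    above = counts > min_cov
    if not above.any():
        return []
    # maximal runs of True
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = ([0] if above[0] else []) + [int(e) + 1 for e in edges if not above[e]]
    ends = [int(e) + 1 for e in edges if above[e]] + ([len(counts)] if above[-1] else [])
    runs = list(zip(starts, ends))
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    peaks = []
    ref_alignments = (
        [a for a in alignments if a.reference == cov.reference]
        if alignments is not None
        else None
    )
    for s, e in merged:
        if e - s < min_width:
            continue
        peak = Peak(cov.reference, s, e)
        if ref_alignments is not None:
            peak.read_count = sum(1 for a in ref_alignments if a.start < e and s < a.end)
            if library_total:
                peak.cpm = peak.read_count * 1e6 / library_total
        peaks.append(peak)
    return peaks


def call_peaks_all(
    coverages: Mapping[str, CoverageVector],
    alignments: Sequence[AlignmentRecord],
    min_cov: int = 10,
    merge_gap: int = 30,
    min_width: int = 30,
) -> list[Peak]:
    """call_peaks over every reference, with cpm against the full library."""
    library_total = len(alignments)
    peaks: list[Peak] = []
    for ref in sorted(coverages):
        peaks.extend(
            call_peaks(
                coverages[ref],
                min_cov=min_cov,
                merge_gap=merge_gap,
                min_width=min_width,
                alignments=alignments,
                library_total=library_total,
            )
        )
    log.info("call_peaks_all: %d peaks on %d references", len(peaks), len(coverages))
    return peaks


def replicate_consensus(
    replicate_peaks: Sequence[Sequence[Peak]], min_support: int = 2
) -> list[Peak]:
    """Union peaks supported by >= ``min_support`` replicates.

    Overlapping intervals across replicates (>= 1 nt) are clustered into
    connected components; each component with enough distinct replicates is
    emitted as the union interval, carrying the summed read count and mean
    cpm of its members.
    """
    if min_support > len(replicate_peaks):
        raise ValueError(
            f"min_support={min_support} exceeds {len(replicate_peaks)} replicates"
        )
    tagged = [
        (peak, rep_idx)
        for rep_idx, peaks in enumerate(replicate_peaks)
        for peak in peaks
    ]
    tagged.sort(key=lambda t: (t[0].reference, t[0].start, t[0].end))
    out: list[Peak] = []
    cluster: list[tuple[Peak, int]] = []

    def flush() -> None:
        if not cluster:
            return
        support = len({rep for _, rep in cluster})
        if support >= min_support:
            members = [p for p, _ in cluster]
            out.append(
                Peak(
                    members[0].reference,
                    min(p.start for p in members),
                    max(p.end for p in members),
                    read_count=sum(p.read_count for p in members),
                    cpm=float(np.mean([p.cpm for p in members])),
                    replicate_support=support,
                )
            )
        cluster.clear()

    cur_ref, cur_end = None, -1
    for peak, rep in tagged:
        if peak.reference != cur_ref or peak.start >= cur_end:
            flush()
            cur_ref, cur_end = peak.reference, peak.end
        else:
            cur_end = max(cur_end, peak.end)
        cluster.append((peak, rep))
    flush()
    log.info(
        "replicate_consensus: %d peaks with support >= %d", len(out), min_support
    )
    return out


def binding_regions(
    peaks: Sequence[Peak],
    sequences: Mapping[str, str],
    window_size: int = 100,
) -> list[BindingRegion]:
    """Extract binding-region windows and flag G4 motifs.

    Peaks narrower than ``window_size`` get a window of that width centered
    on the peak middle (clipped to the reference); wider peaks use their own
    interval.
    """
    from .rg4map import has_g4  # deferred: rg4map imports Peak from here

    regions = []
    half = window_size // 2
    for p in peaks:
        seq = sequences.get(p.reference)
        if seq is None:
            raise KeyError(f"no sequence for reference {p.reference!r}")
        if p.width < window_size:
            start = max(0, p.middle - half)
            end = min(len(seq), p.middle + half)
        else:
            start, end = p.start, min(p.end, len(seq))
        sub = seq[start:end]
        regions.append(
            BindingRegion(p.reference, p.start, p.end, start, end, sub, has_g4(sub))
        )
    return regions
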