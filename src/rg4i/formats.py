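"""Readers and writers for the tabular and sequence formats used by the pipeline.

All interval coordinates are 0-based half-open internally.  GTF input
(1-based closed) is converted on read.  Parsers raise :class:`ParseError`
naming the offending line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

FEATURE_KINDS = ("five_prime_utr", "cds", "three_prime_utr")
BIOTYPES = ("protein_coding", "lncRNA", "pseudogene", "antisense", "other_noncoding")
CONDITIONS = ("rG4", "mrG4", "SL", "beads")


class ParseError(ValueError):
    """Malformed input file; message carries file and line context."""


@dataclass
class SeqRecord:
    """A named sequence with optional per-base phred qualities."""

    id: str
    sequence: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read on a reference, half-open interval."""

    reference: str
    start: int
    end: int
    strand: str
    mapq: int
    umi: str
    sample: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")
        if not (0 <= self.mapq <= 255):
            raise ValueError(f"mapq {self.mapq} out of range")


@dataclass
class TranscriptModel:
    """Transcript with UTR/CDS features in transcript coordinates."""

    transcript_id: str
    gene_id: str
    biotype: str
    features: list[tuple[str, int, int]]
    length: int
    fpkm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.transcript_id}: unknown biotype {self.biotype!r}")
        last_end = None
        for kind, start, end in sorted(self.features, key=lambda f: f[1]):
            if kind not in FEATURE_KINDS:
                raise ValueError(f"{self.transcript_id}: unknown feature kind {kind!r}")
            if not (0 <= start < end <= self.length):
                raise ValueError(
                    f"{self.transcript_id}: feature ({kind},{start},{end}) "
                    f"outside [0,{self.length})"
                )
            if last_end is not None and start < last_end:
                raise ValueError(f"{self.transcript_id}: overlapping features")
            last_end = end
        if self.biotype == "protein_coding":
            order = {"five_prime_utr": 0, "cds": 1, "three_prime_utr": 2}
            kinds = [order[k] for k, _, _ in sorted(self.features, key=lambda f: f[1])]
            if kinds != sorted(kinds):
                raise ValueError(
                    f"{self.transcript_id}: features out of 5'UTR/CDS/3'UTR order"
                )

    def feature_at(self, pos: int) -> str | None:
        """Feature kind covering transcript position ``pos`` (or None)."""
        for kind, start, end in self.features:
            if start <= pos < end:
                return kind
        return None


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> list[SeqRecord]:
    records: list[SeqRecord] = []
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}:{header_line}: record {header!r} has no sequence")
        records.append(SeqRecord(header, seq))
        header, chunks = None, []

    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush(i)
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise ParseError(f"{path}:{i}: empty FASTA header")
                header_line = i
            else:
                if header is None:
                    raise ParseError(f"{path}:{i}: sequence before first header")
                chunks.append(line)
        flush(-1)
    log.info("read_fasta: %d records from %s", len(records), path)
    return records


def write_fasta(path, records: Iterable[SeqRecord], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path) -> list[SeqRecord]:
    records: list[SeqRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and not lines[-1]:
        lines.pop()
    if len(lines) % 4:
        raise ParseError(f"{path}:{len(lines)}: truncated FASTQ (not a multiple of 4 lines)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        line_no = i + 1
        if not head.startswith("@"):
            raise ParseError(f"{path}:{line_no}: expected '@' header")
        if not plus.startswith("+"):
            raise ParseError(f"{path}:{line_no + 2}: expected '+' separator")
        if len(qual) != len(seq):
            raise ParseError(
                f"{path}:{line_no + 3}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        rid = head[1:].split()[0] if head[1:].split() else ""
        if not rid:
            raise ParseError(f"{path}:{line_no}: empty FASTQ header")
        try:
            records.append(SeqRecord(rid, seq, [ord(c) - 33 for c in qual]))
        except ValueError as exc:
            raise ParseError(f"{path}:{line_no}: {exc}") from exc
    log.info("read_fastq: %d records from %s", len(records), path)
    return records


def write_fastq(path, records: Iterable[SeqRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else [30] * len(rec.sequence)
            fh.write(
                f"@{rec.id}\n{rec.sequence}\n+\n"
                + "".join(chr(q + 33) for q in qual)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Annotation (GTF subset and flat TSV)

_GTF_FEATURE_MAP = {
    "five_prime_utr": "five_prime_utr",
    "5utr": "five_prime_utr",
    "CDS": "cds",
    "cds": "cds",
    "three_prime_utr": "three_prime_utr",
    "3utr": "three_prime_utr",
}


def _gtf_attributes(field: str, path, line_no: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, value = chunk.split(None, 1)
        except ValueError as exc:
            raise ParseError(f"{path}:{line_no}: bad attribute {chunk!r}") from exc
        attrs[key] = value.strip().strip('"')
    return attrs


def read_annotation(path) -> list[TranscriptModel]:
    """Read a GTF-subset (or equivalent flat TSV) into transcript models.

    GTF rows use 1-based closed coordinates on the transcript reference
    (column 1 = transcript reference id); ``exon`` rows spanning the whole
    transcript set its length.  A flat TSV dialect with header
    ``transcript_id gene_id biotype kind start end length`` (0-based
    half-open already) is also accepted.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("transcript_id"):
        return _read_annotation_tsv(path)
    return _read_annotation_gtf(path)


def _read_annotation_gtf(path) -> list[TranscriptModel]:
    rows: dict[str, dict] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ParseError(f"{path}:{i}: expected 9 GTF columns, got {len(cols)}")
            feature = cols[2]
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-integer coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise ParseError(f"{path}:{i}: invalid GTF interval {start1}-{end1}")
            attrs = _gtf_attributes(cols[8], path, i)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ParseError(f"{path}:{i}: missing transcript_id attribute")
            entry = rows.setdefault(
                tid,
                {
                    "gene_id": attrs.get("gene_id", tid),
                    "biotype": attrs.get("transcript_type", "other_noncoding"),
                    "features": [],
                    "length": 0,
                },
            )
            start, end = start1 - 1, end1  # to 0-based half-open
            entry["length"] = max(entry["length"], end)
            if feature == "exon":
                continue
            if feature not in _GTF_FEATURE_MAP:
                raise ParseError(f"{path}:{i}: unsupported feature type {feature!r}")
            entry["features"].append((_GTF_FEATURE_MAP[feature], start, end))
    models = []
    for tid, entry in rows.items():
        try:
            models.append(
                TranscriptModel(
                    tid,
                    entry["gene_id"],
                    entry["biotype"],
                    sorted(entry["features"], key=lambda f: f[1]),
                    entry["length"],
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: transcript {tid}: {exc}") from exc
    log.info("read_annotation: %d transcripts from %s", len(models), path)
    return models


def _read_annotation_tsv(path) -> list[TranscriptModel]:
    df = pd.read_csv(path, sep="\t")
    models = []
    for (tid, gid, biotype, length), grp in df.groupby(
        ["transcript_id", "gene_id", "biotype", "length"], sort=False
    ):
        feats = [
            (str(r.kind), int(r.start), int(r.end))
            for r in grp.itertuples()
            if str(r.kind) != "none"
        ]
        try:
            models.append(
                TranscriptModel(str(tid), str(gid), str(biotype),
                                sorted(feats, key=lambda f: f[1]), int(length))
            )
        except ValueError as exc:
            raise ParseError(f"{path}: transcript {tid}: {exc}") from exc
    return models


def write_annotation_tsv(path, models: Sequence[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tgene_id\tbiotype\tkind\tstart\tend\tlength\n")
        for m in models:
            feats = m.features or [("none", 0, m.length)]
            for kind, start, end in feats:
                fh.write(
                    f"{m.transcript_id}\t{m.gene_id}\t{m.biotype}\t"
                    f"{kind}\t{start}\t{end}\t{m.length}\n"
                )


# ---------------------------------------------------------------------------
# Alignment TSV and count matrix


def read_alignments(path) -> list[AlignmentRecord]:
    """Read the BED-like alignment TSV: reference start end strand mapq umi sample."""
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 7:
                raise ParseError(f"{path}:{i}: expected 7 columns, got {len(cols)}")
            try:
                rec = AlignmentRecord(
                    cols[0], int(cols[1]), int(cols[2]), cols[3],
                    int(cols[4]), cols[5], cols[6],
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: {exc}") from exc
            records.append(rec)
    log.info("read_alignments: %d records from %s", len(records), path)
    return records


def write_alignments(path, records: Iterable[AlignmentRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.reference}\t{r.start}\t{r.end}\t{r.strand}\t{r.mapq}\t{r.umi}\t{r.sample}\n"
            )


def read_counts(counts_path, conditions_path):
    """Read the protein x sample count TSV plus its sample->condition side-car.

    Returns an :class:`rg4i.enrich_ms.CountMatrix`.
    """
    from .enrich_ms import CountMatrix  # deferred to avoid a cycle

    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ParseError(f"{counts_path}: missing values in count matrix")
    try:
        upc = df.to_numpy(dtype=int)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{counts_path}: non-integer counts") from exc
    cond_df = pd.read_csv(conditions_path, sep="\t")
    if list(cond_df.columns[:2]) != ["sample", "condition"]:
        raise ParseError(f"{conditions_path}: expected columns sample, condition")
    condition = dict(zip(cond_df["sample"].astype(str), cond_df["condition"].astype(str)))
    missing = [s for s in df.columns if s not in condition]
    if missing:
        raise ParseError(f"{conditions_path}: no condition for samples {missing}")
    bad = sorted(set(condition.values()) - set(CONDITIONS))
    if bad:
        raise ParseError(f"{conditions_path}: unknown conditions {bad}")
    return CountMatrix(
        proteins=[str(p) for p in df.index],
        samples=[str(s) for s in df.columns],
        condition={s: condition[s] for s in df.columns},
        upc=upc,
    )


def write_counts(counts_path, conditions_path, matrix) -> None:
    df = pd.DataFrame(matrix.upc, index=matrix.proteins, columns=matrix.samples)
    df.index.name = "protein"
    df.to_csv(counts_path, sep="\t")
    with open(conditions_path, "w") as fh:
        fh.write("sample\tcondition\n")
        for s in matrix.samples:
            fh.write(f"{s}\t{matrix.condition[s]}\n")


# ---------------------------------------------------------------------------
# FPKM and term-map tables


def read_fpkm(path) -> pd.DataFrame:
    """FPKM TSV with columns transcript_id, condition, fpkm (replicate rows allowed)."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "condition", "fpkm"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    if (df["fpkm"] < 0).any():
        raise ParseError(f"{path}: negative FPKM values")
    return df


def read_term_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"term_id", "term_name", "gene_id"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    return df
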