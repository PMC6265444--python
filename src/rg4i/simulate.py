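"""Synthetic-data generators with ground truth for every analysis stage.

Each generator takes an explicit seed and is bit-reproducible.  Planted
features are constructed so the matching scanner detects them exactly:
planted G4 sites satisfy the (G2-L12)4 regex, background sequence carries
no GG dinucleotide at all, and planted GAR repeats are padded so no
stronger repeat arises by accident.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats import AlignmentRecord, SeqRecord, TranscriptModel
from .enrich_ms import CountMatrix

G4_MIN_SPAN = 11  # 4 runs of 2 G + 3 loops of 1
READ_LENGTH = 35
_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CLASS_A_INSERTS = ("RGGRGG", "RGGRGGRGG", "RGRGRG")
_CLASS_B_INSERT = "RGRG"


@dataclass
class SimTruth:
    """Ground truth emitted alongside generated files."""

    enriched_proteins: set[str] = field(default_factory=set)
    g4_sites: list[tuple[str, int, int]] = field(default_factory=list)
    decoy_sites: list[tuple[str, int, int]] = field(default_factory=list)
    wt_bound_sites: set[str] = field(default_factory=set)
    mut_bound_sites: set[str] = field(default_factory=set)
    gar_classes: dict[str, str] = field(default_factory=dict)


def site_id(transcript_id: str, start: int, end: int) -> str:
    return f"{transcript_id}:{start}-{end}"


# ---------------------------------------------------------------------------
# Proteomics counts


def sim_count_matrix(
    n_proteins: int,
    n_enriched: int,
    n_reps_per_condition: int,
    base_mean: float = 10.0,
    dispersion: float = 0.2,
    log2_effect: float = 3.0,
    seed: int = 0,
    base_sigma: float = 0.6,
) -> tuple[CountMatrix, SimTruth]:
    """Negative-binomial UPC matrix with planted rG4-enriched proteins.

    Per-protein baseline means are log-normal around ``base_mean``; planted
    proteins have their mean multiplied by ``2**log2_effect`` in the rG4
    samples only.  ``dispersion=0`` gives Poisson marginals.
    """
    for name, v in (("n_proteins", n_proteins), ("n_enriched", n_enriched),
                    ("n_reps_per_condition", n_reps_per_condition)):
        if not isinstance(v, (int, np.integer)):
            raise TypeError(f"{name} must be an integer")
    if n_enriched > n_proteins:
        raise ValueError("n_enriched > n_proteins")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)

    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    enriched = set(rng.choice(proteins, size=n_enriched, replace=False).tolist())
    conditions = ["rG4", "mrG4", "SL", "beads"]
    samples, condition = [], {}
    for cond in conditions:
        for rep in range(1, n_reps_per_condition + 1):
            s = f"{cond}_{rep}"
            samples.append(s)
            condition[s] = cond

    base = (
        rng.lognormal(mean=np.log(base_mean), sigma=base_sigma, size=n_proteins)
        if base_sigma > 0
        else np.full(n_proteins, float(base_mean))
    )
    means = np.tile(base[:, None], (1, len(samples)))
    enriched_rows = np.array([p in enriched for p in proteins])
    rg4_cols = np.array([condition[s] == "rG4" for s in samples])
    means[np.ix_(enriched_rows, rg4_cols)] *= 2.0**log2_effect

    if dispersion == 0:
        upc = rng.poisson(means)
    else:
        n_param = 1.0 / dispersion
        p_param = n_param / (n_param + means)
        upc = rng.negative_binomial(n_param, p_param)

    matrix = CountMatrix(proteins, samples, condition, upc.astype(np.int64))
    return matrix, SimTruth(enriched_proteins=enriched)


# ---------------------------------------------------------------------------
# Transcriptome with planted G4 sites


def _background_sequence(rng: np.random.Generator, length: int) -> list[str]:
    """Random nucleotides with no GG dinucleotide (so no spurious G4)."""
    out: list[str] = []
    prev_g = False
    for _ in range(length):
        if prev_g:
            c = "ACT"[rng.integers(3)]
        else:
            c = "ACGT"[rng.integers(4)] if rng.random() < 0.6 else "ACT"[rng.integers(3)]
        out.append(c)
        prev_g = c == "G"
    return out


def _g4_motif(rng: np.random.Generator) -> str:
    runs = ["G" * int(rng.integers(2, 5)) for _ in range(4)]
    loops = [
        "".join("ACT"[rng.integers(3)] for _ in range(int(rng.integers(1, 13))))
        for _ in range(3)
    ]
    return runs[0] + loops[0] + runs[1] + loops[1] + runs[2] + loops[2] + runs[3]


def sim_transcriptome(
    n_transcripts: int,
    length_range: tuple[int, int] = (300, 1500),
    g4_rate_5utr: float = 0.5,
    g4_rate_other: float = 0.05,
    seed: int = 0,
    coding_fraction: float = 0.8,
) -> tuple[list[SeqRecord], list[TranscriptModel], SimTruth]:
    """Transcript FASTA + annotation with G4 motifs planted at region-specific rates.

    Every transcript also carries one G4-free decoy site (kept >= 50 nt from
    any planted G4) so downstream read simulation can contrast G4 and
    non-G4 binding.
    """
    for rate in (g4_rate_5utr, g4_rate_other):
        if not 0 <= rate <= 1:
            raise ValueError("rates must be in [0, 1]")
    lo, hi = length_range
    if lo < 120:
        raise ValueError("length_range too small to host a G4 site")
    rng = np.random.default_rng(seed)
    noncoding_biotypes = ("lncRNA", "pseudogene", "antisense", "other_noncoding")

    records, models = [], []
    truth = SimTruth()
    for i in range(n_transcripts):
        tid, gid = f"TX{i:05d}", f"GENE{i:05d}"
        length = int(rng.integers(lo, hi + 1))
        seq = _background_sequence(rng, length)
        if rng.random() < coding_fraction:
            biotype = "protein_coding"
            utr5_end = max(40, int(0.2 * length))
            cds_end = utr5_end + max(30, int(0.55 * length))
            cds_end = min(cds_end, length - 20)
            features = [
                ("five_prime_utr", 0, utr5_end),
                ("cds", utr5_end, cds_end),
                ("three_prime_utr", cds_end, length),
            ]
            regions = {"five_prime_utr": (0, utr5_end), "other": (utr5_end, length)}
        else:
            biotype = noncoding_biotypes[rng.integers(len(noncoding_biotypes))]
            features = []
            regions = {"other": (0, length)}

        occupied: list[tuple[int, int]] = []

        def plant(lo_pos: int, hi_pos: int, motif: str) -> tuple[int, int] | None:
            span = len(motif)
            for _ in range(50):
                start = int(rng.integers(lo_pos, max(lo_pos + 1, hi_pos - span)))
                end = start + span
                if all(end + 50 <= s or e + 50 <= start for s, e in occupied):
                    seq[start:end] = list(motif)
                    occupied.append((start, end))
                    return start, end
            return None

        if "five_prime_utr" in regions and rng.random() < g4_rate_5utr:
            placed = plant(*regions["five_prime_utr"], _g4_motif(rng))
            if placed:
                truth.g4_sites.append((tid, *placed))
        s, e = regions["other"]
        if e - s > 80 and rng.random() < g4_rate_other:
            placed = plant(s + 10, e - 10, _g4_motif(rng))
            if placed:
                truth.g4_sites.append((tid, *placed))
        # decoy site: a 20-nt G4-free stretch away from planted motifs
        for _ in range(50):
            start = int(rng.integers(0, length - 20))
            if all(start + 70 <= ds or de + 50 <= start for ds, de in occupied):
                truth.decoy_sites.append((tid, start, start + 20))
                occupied.append((start, start + 20))
                break

        records.append(SeqRecord(tid, "".join(seq)))
        models.append(TranscriptModel(tid, gid, biotype, features, length))
    return records, models, truth


# ---------------------------------------------------------------------------
# iCLAE reads


def sim_iclae_reads(
    annotation: list[TranscriptModel],
    sequences: list[SeqRecord],
    truth: SimTruth,
    barcode_map: dict[str, str],
    reads_per_site: int = 50,
    noise_reads: int = 0,
    dup_rate: float = 0.0,
    wt_g4_preference: float = 0.5,
    mut_g4_preference: float = 0.5,
    low_mapq_noise_fraction: float = 0.3,
    unique_umis: bool = False,
    seed: int = 0,
) -> tuple[dict[str, list[SeqRecord]], dict[str, list[AlignmentRecord]], SimTruth]:
    """Crosslink reads concentrated at planted sites, plus aligned-read TSVs.

    Samples whose name starts with ``wt`` use ``wt_g4_preference``, samples
    starting with ``mut`` use ``mut_g4_preference``; the preference p gives
    G4 sites ``2p`` and decoy sites ``2(1-p)`` times ``reads_per_site/2``
    reads (deterministic per-site counts), so p=0.5 is even coverage.
    Reads are N3 + barcode + N2 + insert; a ``dup_rate`` fraction of
    molecules is re-emitted with identical position and UMI; noise reads
    fall uniformly over the transcriptome and a fraction get MAPQ < 10.
    """
    seq_by_id = {r.id: r.sequence for r in sequences}
    tx_lengths = np.array([t.length for t in annotation], dtype=float)
    sample_by_barcode = dict(barcode_map)
    rng = np.random.default_rng(seed)
    barcode_of = {v: k for k, v in sample_by_barcode.items()}

    fastq: dict[str, list[SeqRecord]] = {}
    alignments: dict[str, list[AlignmentRecord]] = {}
    umi_counter = 0

    def draw_umi() -> str:
        nonlocal umi_counter
        if unique_umis:
            idx, umi_counter = umi_counter, umi_counter + 1
            return "".join("ACGT"[(idx // 4**k) % 4] for k in range(5))
        return "".join("ACGT"[rng.integers(4)] for _ in range(5))

    for barcode, sample in sample_by_barcode.items():
        if sample.startswith("wt"):
            pref = wt_g4_preference
        elif sample.startswith("mut"):
            pref = mut_g4_preference
        else:
            raise ValueError(f"sample {sample!r} must be named wt* or mut*")
        if not 0 <= pref <= 1:
            raise ValueError("preferences must be in [0, 1]")

        molecules: list[tuple[str, int, int, int]] = []  # ref, start, end, mapq
        bound: set[str] = set()
        for sites, weight in ((truth.g4_sites, pref), (truth.decoy_sites, 1 - pref)):
            n_per_site = int(round(reads_per_site * 2 * weight))
            for tid, s, e in sites:
                if n_per_site <= 0:
                    continue
                bound.add(site_id(tid, s, e))
                mid = (s + e) // 2
                length = len(seq_by_id[tid])
                for _ in range(n_per_site):
                    start = int(
                        rng.integers(mid - READ_LENGTH + 8, mid - 7)
                    )
                    start = max(0, min(start, length - READ_LENGTH))
                    molecules.append(
                        (tid, start, start + READ_LENGTH, int(rng.integers(30, 60)))
                    )
        for _ in range(noise_reads):
            ti = int(rng.choice(len(annotation), p=tx_lengths / tx_lengths.sum()))
            tx = annotation[ti]
            if tx.length <= READ_LENGTH:
                continue
            start = int(rng.integers(0, tx.length - READ_LENGTH))
            mapq = (
                int(rng.integers(0, 10))
                if rng.random() < low_mapq_noise_fraction
                else int(rng.integers(30, 60))
            )
            molecules.append((tx.transcript_id, start, start + READ_LENGTH, mapq))

        if sample.startswith("wt"):
            truth.wt_bound_sites |= bound
        else:
            truth.mut_bound_sites |= bound

        sample_reads, sample_alns = [], []
        for mi, (ref, start, end, mapq) in enumerate(molecules):
            umi = draw_umi()
            copies = 2 if rng.random() < dup_rate else 1
            for ci in range(copies):
                insert = seq_by_id[ref][start:end]
                read_seq = umi[:3] + barcode_of[sample] + umi[3:] + insert
                rid = f"{sample}_m{mi}_c{ci}"
                sample_reads.append(
                    SeqRecord(rid, read_seq, [38] * len(read_seq))
                )
                sample_alns.append(
                    AlignmentRecord(ref, start, end, "+", mapq, umi, sample)
                )
        order = rng.permutation(len(sample_reads))
        fastq[sample] = [sample_reads[i] for i in order]
        alignments[sample] = [sample_alns[i] for i in order]
    return fastq, alignments, truth


# ---------------------------------------------------------------------------
# Protein sequences with planted GAR repeats


def sim_protein_set(
    n: int,
    frac_class_a: float = 0.2,
    frac_class_b: float = 0.1,
    length_range: tuple[int, int] = (60, 200),
    seed: int = 0,
) -> tuple[list[SeqRecord], SimTruth]:
    """Protein FASTA with planted RG/RGG tandem repeats at controlled rates.

    Class-A proteins get an (RGG)>=2 or (RG)3 insert, class-B an (RG)2
    insert; background sequence has every R-G adjacency removed, so
    remaining proteins scan as class NONE.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if frac_class_a + frac_class_b > 1:
        raise ValueError("class fractions sum above 1")
    rng = np.random.default_rng(seed)
    n_a = int(round(n * frac_class_a))
    n_b = int(round(n * frac_class_b))

    records = []
    truth = SimTruth()
    alphabet = np.array(list(_AA_ALPHABET))
    for i in range(n):
        pid = f"PROT{i:05d}"
        length = int(rng.integers(*length_range))
        seq = list(rng.choice(alphabet, size=length))
        for j in range(length - 1):  # forbid RG bigrams in the background
            if seq[j] == "R" and seq[j + 1] == "G":
                seq[j + 1] = "A"
        if i < n_a:
            insert, cls = _CLASS_A_INSERTS[rng.integers(len(_CLASS_A_INSERTS))], "CLASS_A"
        elif i < n_a + n_b:
            insert, cls = _CLASS_B_INSERT, "CLASS_B"
        else:
            insert, cls = None, "NONE"
        if insert is not None:
            pos = int(rng.integers(1, length - 1))
            seq = seq[:pos] + list("A" + insert + "A") + seq[pos:]
        truth.gar_classes[pid] = cls
        records.append(SeqRecord(pid, "".join(seq)))
    return records, truth


# ---------------------------------------------------------------------------
# FPKM tables


def sim_fpkm(
    annotation: list[TranscriptModel],
    conditions: tuple[str, ...] = ("WT", "mut", "neg"),
    n_reps: int = 2,
    expressed_fraction: float = 0.9,
    seed: int = 0,
):
    """Long-format FPKM table; a fraction of transcripts is expressed."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for t in annotation:
        expressed = rng.random() < expressed_fraction
        for cond in conditions:
            for _ in range(n_reps):
                fpkm = float(rng.lognormal(1.0, 1.0)) if expressed else float(
                    rng.uniform(0, 0.05)
                )
                rows.append((t.transcript_id, cond, fpkm))
    return pd.DataFrame(rows, columns=["transcript_id", "condition", "fpkm"])
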