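"""G4-motif mapping of binding regions and WT-vs-mutant target selection.

Covers (G2-L12)4 motif scanning, peak classification against transcript
features, shuffle-based category enrichment, the expressed-transcript
filter, peak-set overlap, per-peak differential binding, target selection
and hypergeometric term enrichment.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats import AlignmentRecord, TranscriptModel
from .iclae_proc import BindingRegion, Peak

log = logging.getLogger(__name__)

# Four runs of >=2 G separated by three loops of 1-12 arbitrary nucleotides.
# Loops are unrestricted (G allowed), so the minimum match is 11 nt.
G4_PATTERN = re.compile(r"G{2,}(?:[ACGTU]{1,12}G{2,}){3}")

CATEGORIES = (
    "five_prime_utr",
    "cds",
    "three_prime_utr",
    "lncRNA",
    "pseudogene",
    "antisense",
    "other_noncoding",
    "intergenic",
)

LOG2FC_PSEUDO_CPM = 0.5


@dataclass
class G4Match:
    reference: str
    start: int
    end: int
    matched: str


@dataclass
class DiffBindRecord:
    peak: Peak
    wt_count: int
    mut_count: int
    wt_cpm: float
    mut_cpm: float
    log2fc: float
    pvalue: float
    qvalue: float = float("nan")


@dataclass
class CategoryEnrichment:
    category: str
    observed: int
    expected: float
    fold: float
    ci_low: float
    ci_high: float
    n_shuffles: int


# ---------------------------------------------------------------------------
# G4 scanning


def scan_g4(sequence: str, reference: str = "") -> list[G4Match]:
    """Non-overlapping left-to-right (G2-L12)4 matches; T and U equivalent."""
    seq = sequence.upper().replace("U", "T")
    return [
        G4Match(reference, m.start(), m.end(), m.group(0))
        for m in G4_PATTERN.finditer(seq)
    ]


def has_g4(sequence: str) -> bool:
    seq = sequence.upper().replace("U", "T")
    return G4_PATTERN.search(seq) is not None


def g4_fraction_and_test(
    regions_a: Sequence[BindingRegion], regions_b: Sequence[BindingRegion]
) -> tuple[float, float, float, float]:
    """G4 fractions of two region sets plus a two-proportion chi-square p.

    Mirrors R ``prop.test`` defaults: two-sided, Yates continuity
    correction.  Returns (prop_a, prop_b, chi2 statistic, p).
    """
    if not regions_a or not regions_b:
        raise ValueError("empty region set")
    k_a = sum(r.g4 for r in regions_a)
    k_b = sum(r.g4 for r in regions_b)
    n_a, n_b = len(regions_a), len(regions_b)
    stat, p = two_proportion_test(k_a, n_a, k_b, n_b)
    return round(k_a / n_a, 3), round(k_b / n_b, 3), stat, p


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-sided two-sample test of equal proportions with Yates correction."""
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Annotation-based classification


def classify_peak(peak: Peak, transcripts: Mapping[str, TranscriptModel]) -> str:
    """Category of a peak by its midpoint position on the reference transcript."""
    tx = transcripts.get(peak.reference)
    if tx is None:
        return "intergenic"
    mid = peak.middle
    if mid >= tx.length:
        return "intergenic"
    if tx.biotype == "protein_coding":
        kind = tx.feature_at(mid)
        return kind if kind is not None else "intergenic"
    return tx.biotype


def classify_peaks(
    peaks: Sequence[Peak], annotation: Sequence[TranscriptModel]
) -> tuple[list[str], dict[str, int]]:
    """Per-peak categories plus category tallies."""
    if not annotation:
        raise ValueError("empty annotation")
    transcripts = {t.transcript_id: t for t in annotation}
    categories = [classify_peak(p, transcripts) for p in peaks]
    tallies = {c: categories.count(c) for c in CATEGORIES}
    return categories, tallies


# ---------------------------------------------------------------------------
# Expressed set and shuffle enrichment


def expressed_set(fpkm: pd.DataFrame, min_fpkm: float = 0.1) -> set[str]:
    """Transcripts with mean FPKM >= ``min_fpkm`` in at least one condition."""
    if fpkm.empty:
        return set()
    means = fpkm.groupby(["transcript_id", "condition"])["fpkm"].mean()
    keep = means[means >= min_fpkm].index.get_level_values("transcript_id")
    return set(map(str, keep.unique()))


def shuffle_enrichment(
    peaks: Sequence[Peak],
    annotation: Sequence[TranscriptModel],
    n_shuffles: int = 100,
    seed: int | np.random.Generator = 0,
) -> list[CategoryEnrichment]:
    """Observed-vs-shuffled category fold enrichment.

    Each shuffle re-places every peak, width preserved, uniformly over all
    valid start positions across the supplied (expressed) transcripts; a
    transcript is chosen with probability proportional to its number of
    valid placements.  ``expected`` is the mean shuffled category count and
    the 95% interval is the Monte-Carlo percentile band of the fold.
    """
    if not annotation:
        raise ValueError("empty annotation")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    transcripts = {t.transcript_id: t for t in annotation}
    observed_cats, _ = classify_peaks(peaks, annotation)
    observed = {c: observed_cats.count(c) for c in CATEGORIES}

    lengths = np.array([t.length for t in annotation])
    counts = np.zeros((n_shuffles, len(CATEGORIES)), dtype=float)
    cat_index = {c: i for i, c in enumerate(CATEGORIES)}
    for peak in peaks:
        slots = lengths - peak.width + 1
        if (slots <= 0).all():
            raise ValueError(
                f"peak {peak.reference}:{peak.start}-{peak.end} wider than every transcript"
            )
        weights = np.clip(slots, 0, None).astype(float)
        weights /= weights.sum()
        tx_idx = rng.choice(len(annotation), size=n_shuffles, p=weights)
        for shuf, ti in enumerate(tx_idx):
            tx = annotation[ti]
            start = int(rng.integers(0, tx.length - peak.width + 1))
            placed = Peak(tx.transcript_id, start, start + peak.width)
            counts[shuf, cat_index[classify_peak(placed, transcripts)]] += 1

    out = []
    for cat, ci in cat_index.items():
        expected = float(counts[:, ci].mean())
        obs = observed[cat]
        if expected == 0 and obs == 0:
            continue
        fold = obs / expected if expected > 0 else float("inf")
        # pseudo-count of 0.5 keeps the MC band finite when a shuffle has 0
        folds = obs / np.maximum(counts[:, ci], 0.5)
        lo, hi = np.percentile(folds, [2.5, 97.5])
        out.append(
            CategoryEnrichment(cat, obs, expected, fold, float(lo), float(hi), n_shuffles)
        )
    return out


# ---------------------------------------------------------------------------
# WT vs mutant


def peak_overlap(
    peaks_wt: Sequence[Peak], peaks_mut: Sequence[Peak]
) -> tuple[list[Peak], list[Peak], list[Peak], list[Peak]]:
    """Split two peak sets by >=1-nt overlap across sets.

    Returns (wt_shared, mut_shared, wt_only, mut_only).
    """
    by_ref: dict[str, list[Peak]] = {}
    for p in peaks_mut:
        by_ref.setdefault(p.reference, []).append(p)

    def shared_with_mut(p: Peak) -> bool:
        return any(p.overlaps(q) for q in by_ref.get(p.reference, ()))

    wt_shared = [p for p in peaks_wt if shared_with_mut(p)]
    wt_only = [p for p in peaks_wt if not shared_with_mut(p)]
    by_ref_wt: dict[str, list[Peak]] = {}
    for p in peaks_wt:
        by_ref_wt.setdefault(p.reference, []).append(p)
    shared_ids = {
        id(p)
        for p in peaks_mut
        if any(p.overlaps(q) for q in by_ref_wt.get(p.reference, ()))
    }
    mut_shared = [p for p in peaks_mut if id(p) in shared_ids]
    mut_only = [p for p in peaks_mut if id(p) not in shared_ids]
    return wt_shared, mut_shared, wt_only, mut_only


def _count_overlapping(peak: Peak, by_ref: Mapping[str, list[tuple[int, int]]]) -> int:
    return sum(
        1
        for s, e in by_ref.get(peak.reference, ())
        if s < peak.end and peak.start < e
    )


def differential_binding(
    peaks: Sequence[Peak],
    wt_alignments: Sequence[AlignmentRecord],
    mut_alignments: Sequence[AlignmentRecord],
) -> list[DiffBindRecord]:
    """Per-peak WT-vs-mutant binding contrast.

    Counts are alignments overlapping each peak; cpm uses each library's
    total; log2fc = log2((wt_cpm + c) / (mut_cpm + c)) with pseudo-cpm
    c = 0.5; p from a two-proportion chi-square of peak count vs library
    total, BH-adjusted across peaks.
    """
    wt_total, mut_total = len(wt_alignments), len(mut_alignments)
    if wt_total == 0 or mut_total == 0:
        raise ValueError("zero library total")
    wt_by_ref: dict[str, list[tuple[int, int]]] = {}
    for a in wt_alignments:
        wt_by_ref.setdefault(a.reference, []).append((a.start, a.end))
    mut_by_ref: dict[str, list[tuple[int, int]]] = {}
    for a in mut_alignments:
        mut_by_ref.setdefault(a.reference, []).append((a.start, a.end))

    c = LOG2FC_PSEUDO_CPM
    records = []
    for peak in peaks:
        wt_k = _count_overlapping(peak, wt_by_ref)
        mut_k = _count_overlapping(peak, mut_by_ref)
        wt_cpm = wt_k * 1e6 / wt_total
        mut_cpm = mut_k * 1e6 / mut_total
        log2fc = float(np.log2((wt_cpm + c) / (mut_cpm + c)))
        _, p = two_proportion_test(wt_k, wt_total, mut_k, mut_total)
        records.append(DiffBindRecord(peak, wt_k, mut_k, wt_cpm, mut_cpm, log2fc, p))
    if records:
        qvals = stats.false_discovery_control([r.pvalue for r in records], method="bh")
        for rec, q in zip(records, qvals):
            rec.qvalue = float(q)
    return records


def select_targets(
    diffbind: Sequence[DiffBindRecord],
    regions: Sequence[BindingRegion],
    annotation: Sequence[TranscriptModel],
    logfc_min: float = 1.0,
    p_max: float = 0.05,
    quantile: float = 0.75,
) -> list[str]:
    """Genes with >=1 top-quartile, G4-positive, WT-enriched peak.

    A peak qualifies when its WT cpm is at or above the ``quantile`` of all
    WT peak cpms, its binding region contains a G4 motif, log2fc >
    ``logfc_min`` and p < ``p_max``.  Returns sorted unique gene ids.
    """
    if not diffbind:
        return []
    gene_of = {t.transcript_id: t.gene_id for t in annotation}
    g4_by_peak = {(r.reference, r.peak_start, r.peak_end): r.g4 for r in regions}
    threshold = float(np.percentile([r.wt_cpm for r in diffbind], quantile * 100))
    genes: set[str] = set()
    for rec in diffbind:
        key = (rec.peak.reference, rec.peak.start, rec.peak.end)
        if (
            rec.wt_cpm >= threshold
            and g4_by_peak.get(key, False)
            and rec.log2fc > logfc_min
            and rec.pvalue < p_max
        ):
            gene = gene_of.get(rec.peak.reference)
            if gene is not None:
                genes.add(gene)
    return sorted(genes)


# ---------------------------------------------------------------------------
# Term enrichment and correlation


def term_enrichment(
    gene_set: set[str], background: set[str], term_map: pd.DataFrame
) -> pd.DataFrame:
    """Right-tailed hypergeometric enrichment per term with BH correction.

    Population = background genes; successes = background genes in the
    term; draws = foreground genes (restricted to the background).
    """
    fg = set(gene_set) & set(background)
    population = len(background)
    rows = []
    for (term_id, term_name), grp in term_map.groupby(["term_id", "term_name"]):
        term_genes = set(grp["gene_id"].astype(str)) & set(background)
        k = len(fg & term_genes)
        p = float(stats.hypergeom.sf(k - 1, population, len(term_genes), len(fg)))
        rows.append((term_id, term_name, k, len(term_genes), min(p, 1.0)))
    df = pd.DataFrame(
        rows, columns=["term_id", "term_name", "overlap", "term_size", "pvalue"]
    )
    if not df.empty:
        df["qvalue"] = stats.false_discovery_control(df["pvalue"], method="bh")
        df = df.sort_values(["qvalue", "pvalue", "term_id"]).reset_index(drop=True)
    return df


def expression_binding_correlation(
    expression: Sequence[float], signal: Sequence[float], eps: float = 0.01
) -> tuple[float, int]:
    """Pearson r between log10(x + eps)-transformed expression and signal."""
    x = np.log10(np.asarray(expression, dtype=float) + eps)
    y = np.log10(np.asarray(signal, dtype=float) + eps)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >=3 paired observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("correlation undefined for constant input")
    r, _ = stats.pearsonr(x, y)
    return float(r), len(x)
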