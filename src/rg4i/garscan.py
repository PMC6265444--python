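"""Glycine-arginine-rich (GAR) motif scanning and class-frequency comparison.

Proteins are classified by the strongest contiguous tandem RG/RGG repeat
anywhere in the sequence:

* ``CLASS_A`` — at least one (RGG)>=2 or (RG)>=3 run,
* ``CLASS_B`` — at least one (RG)2 run but nothing stronger,
* ``NONE``    — neither.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

CLASS_A = "CLASS_A"
CLASS_B = "CLASS_B"
NONE = "NONE"

# Repeat units are contiguous: no spacer residues between units (max_spacer=0).
_MOTIF_PATTERNS = {
    "tri-RGG": "RGGRGGRGG",
    "di-RGG": "RGGRGG",
    "tri-RG": "RGRGRG",
    "di-RG": "RGRG",
}
_CLASS_A_MOTIFS = ("tri-RGG", "di-RGG", "tri-RG")
_CLASS_B_MOTIFS = ("di-RG",)


@dataclass
class GarCall:
    protein: str
    cls: str
    hits: list[tuple[str, int, int]]  # (motif name, start, end)


def scan_gar(sequence: str, protein: str = "") -> GarCall:
    """Classify one amino-acid sequence by its RG/RGG tandem repeats.

    All (overlapping) hits of the four repeat motifs are reported; the class
    is decided by the strongest hit anywhere in the sequence.  Non-standard
    letters are tolerated (they simply never match).
    """
    if not sequence:
        raise ValueError("empty sequence")
    hits: list[tuple[str, int, int]] = []
    for name, motif in _MOTIF_PATTERNS.items():
        for m in re.finditer(f"(?=({motif}))", sequence):
            hits.append((name, m.start(), m.start() + len(motif)))
    hits.sort(key=lambda h: (h[1], h[2]))
    if any(h[0] in _CLASS_A_MOTIFS for h in hits):
        cls = CLASS_A
    elif any(h[0] in _CLASS_B_MOTIFS for h in hits):
        cls = CLASS_B
    else:
        cls = NONE
    return GarCall(protein=protein, cls=cls, hits=hits)


def scan_gar_records(records) -> list[GarCall]:
    return [scan_gar(rec.sequence, protein=rec.id) for rec in records]


@dataclass
class GarClassComparison:
    cls: str
    fg_count: int
    fg_total: int
    bg_count: int
    bg_total: int
    fisher_p: float
    chi2_p: float

    @property
    def fg_prop(self) -> float:
        return self.fg_count / self.fg_total

    @property
    def bg_prop(self) -> float:
        return self.bg_count / self.bg_total


def compare_gar_frequencies(
    foreground: Sequence[GarCall], background: Sequence[GarCall]
) -> dict[str, GarClassComparison]:
    """Per-class foreground-vs-background proportions with Fisher exact p.

    A chi-square test with Yates correction is run as a cross-check.  The
    pooled ``any`` entry counts proteins with any GAR call (CLASS_A or
    CLASS_B).  Counting is per-protein presence, not motif density.
    """
    if not foreground:
        raise ValueError("empty foreground")
    if not background:
        raise ValueError("empty background")

    def tally(calls: Iterable[GarCall], predicate) -> int:
        return sum(1 for c in calls if predicate(c.cls))

    out: dict[str, GarClassComparison] = {}
    groups = {
        CLASS_A: lambda c: c == CLASS_A,
        CLASS_B: lambda c: c == CLASS_B,
        "any": lambda c: c in (CLASS_A, CLASS_B),
    }
    for name, pred in groups.items():
        fg_k, bg_k = tally(foreground, pred), tally(background, pred)
        table = [
            [fg_k, len(foreground) - fg_k],
            [bg_k, len(background) - bg_k],
        ]
        _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
        if fg_k + bg_k in (0, len(foreground) + len(background)):
            chi2_p = 1.0  # degenerate margin: no evidence either way
        else:
            chi2_p = stats.chi2_contingency(table, correction=True).pvalue
        out[name] = GarClassComparison(
            cls=name,
            fg_count=fg_k,
            fg_total=len(foreground),
            bg_count=bg_k,
            bg_total=len(background),
            fisher_p=float(fisher_p),
            chi2_p=float(chi2_p),
        )
    return out
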