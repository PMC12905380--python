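"""Structural-variant post-filtering, size classification and microhomology.

SVs are typed as deletions (DEL), tandem duplications (DUP), inversions (INV),
insertions (INS) and inter-chromosomal translocations (CTX), and binned into
three size classes split at log10(length) = 4.5 (~32 kb) and 6.0 (1 Mb) — the
trimodal strata seen in pan-cancer SV length distributions. Events shorter
than 100 bp belong to the small-indel analysis and are flagged as excluded.

Deletion-junction microhomology is the longest exact match between the bases
at the start of the deleted segment and the bases immediately following the
deletion end: an m-base match means the junction could have been created by
end-joining over m bases of homology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

SV_TYPES = ("DEL", "DUP", "INV", "CTX", "INS")

SMALL, MID, LARGE, NONE, EXCLUDED = "small", "mid", "large", "none", "excluded"


@dataclass(frozen=True)
class SizeClassScheme:
    """Trimodal size classes: boundaries in log10 bp, minimum analysed length."""

    boundaries: tuple[float, float] = (4.5, 6.0)
    min_length: int = 100

    def __post_init__(self) -> None:
        if not self.boundaries[0] < self.boundaries[1]:
            raise ValueError("boundaries must be strictly increasing")
        if self.min_length < 1:
            raise ValueError("min_length must be positive")


@dataclass
class SVRecord:
    """A typed structural event with 1-based breakends.

    ``length`` is derived for intra-chromosomal events (pos2 - pos1); CTX
    events span two chromosomes and carry no length. Insertions may carry an
    explicit inserted-sequence length.
    """

    svtype: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    support: int = 0
    sample: str = ""
    length: Optional[int] = None
    scheme: SizeClassScheme = field(default_factory=SizeClassScheme)

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.svtype!r}")
        if (self.chrom1 != self.chrom2) != (self.svtype == "CTX"):
            raise ValueError("CTX if and only if the breakends lie on different chromosomes")
        if self.svtype == "CTX":
            self.length = None
        elif self.svtype == "INS":
            pass  # inserted-sequence length, when known, is supplied explicitly
        elif self.length is None:
            self.length = self.pos2 - self.pos1

    @property
    def size_class(self) -> str:
        if self.length is None:
            return NONE
        return classify_size(self.length, self.scheme)


def classify_size(length: int | SVRecord, scheme: SizeClassScheme | None = None) -> str:
    """Size class of an event length under the trimodal scheme.

    Lengths below ``min_length`` are flagged excluded (they belong to the
    small-indel analysis). A value exactly on a boundary goes to the lower
    class, so 10**6 bp is "mid"; 10**4.5 is non-integer and never occurs.
    """
    if isinstance(length, SVRecord):
        if length.length is None:
            return NONE
        scheme = scheme or length.scheme
        length = length.length
    scheme = scheme or SizeClassScheme()
    if length <= 0:
        raise ValueError(f"non-positive SV length: {length}")
    if length < scheme.min_length:
        return EXCLUDED
    lg = math.log10(length)
    if lg < scheme.boundaries[0]:
        return SMALL
    if lg <= scheme.boundaries[1]:
        return MID
    return LARGE


def _breakends_match(a: SVRecord, b: SVRecord, tolerance_bp: int) -> bool:
    return (
        a.svtype == b.svtype
        and a.chrom1 == b.chrom1
        and a.chrom2 == b.chrom2
        and abs(a.pos1 - b.pos1) <= tolerance_bp
        and abs(a.pos2 - b.pos2) <= tolerance_bp
    )


def postfilter(
    calls: Sequence[SVRecord],
    panel_of_normals: Sequence[SVRecord] = (),
    min_support: int = 4,
    tolerance_bp: int = 100,
) -> list[SVRecord]:
    """Remove panel-of-normals matches, low-support calls, and calls shared
    between samples of the same run (non-unique events are artifacts or
    pre-existing variation, not sample-private mutations). Idempotent.
    """
    kept = []
    for c in calls:
        if c.support < min_support:
            continue
        if any(_breakends_match(c, p, tolerance_bp) for p in panel_of_normals):
            continue
        kept.append(c)
    unique = []
    for c in kept:
        shared = any(
            o.sample != c.sample and _breakends_match(c, o, tolerance_bp) for o in kept
        )
        if not shared:
            unique.append(c)
    return unique


def merge_callsets(
    small_events: Sequence[SVRecord],
    sv_events: Sequence[SVRecord],
    reciprocal_tolerance_bp: int = 100,
) -> tuple[list[SVRecord], list[SVRecord]]:
    """Route events to the small-event or the SV analysis.

    Indel-caller events and SV-caller events overlap in size range; events
    found by both (same type and sample, breakpoints within tolerance) are
    analysed with the small events only, and the SV analysis keeps the events
    seen by the SV caller alone. The two outputs partition the (matched)
    union: no event appears in both.
    """
    small_set = list(small_events)
    sv_only = []
    for sv in sv_events:
        matched = any(
            s.sample == sv.sample and _breakends_match(sv, s, reciprocal_tolerance_bp)
            for s in small_events
        )
        if not matched:
            sv_only.append(sv)
    return small_set, sv_only


def microhomology_length(
    reference: str, deletion: SVRecord | tuple[int, int], max_scan: int = 25
) -> int:
    """Junction microhomology of a deletion, in bp, capped at ``max_scan``.

    Returns the largest m <= max_scan such that the m bases at the start of
    the deleted segment equal the m bases immediately after the deletion end;
    0 when the first bases already differ.
    """
    if isinstance(deletion, SVRecord):
        if deletion.svtype == "CTX" or deletion.chrom1 != deletion.chrom2:
            raise ValueError("microhomology is defined for intra-chromosomal deletions")
        start, end = deletion.pos1, deletion.pos2
    else:
        start, end = deletion
    n = len(reference)
    if not (1 <= start <= end <= n):
        raise ValueError(f"deletion breakends ({start}, {end}) outside the {n} bp contig")
    s, e = start - 1, end - 1  # 0-based inclusive
    m = 0
    while m < max_scan and s + m < n and e + 1 + m < n:
        if reference[s + m].upper() != reference[e + 1 + m].upper():
            break
        m += 1
    return m


def microhomology_histogram(lengths: Sequence[int]) -> dict[str, int]:
    """Bin junction microhomology lengths as 0 / 1-3 / 4-9 / >=10 bp.

    The 1-3 bp bin is the hallmark of classical/alternative non-homologous
    end joining; >=10 bp suggests homology-mediated mechanisms.
    """
    bins = {"0": 0, "1-3": 0, "4-9": 0, ">=10": 0}
    for m in lengths:
        if m < 0:
            raise ValueError("negative microhomology length")
        if m == 0:
            bins["0"] += 1
        elif m <= 3:
            bins["1-3"] += 1
        elif m <= 9:
            bins["4-9"] += 1
        else:
            bins[">=10"] += 1
    return bins
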