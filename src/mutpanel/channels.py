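"""Trinucleotide channel conventions for single-base substitutions.

Substitutions are pyrimidine-normalized: a mutation whose reference base is a
purine is reverse-complemented before classification, so every event falls in
one of six base changes (C>A, C>G, C>T, T>A, T>C, T>G). Each change is split
into 16 sub-categories by the flanking 5' and 3' bases, in alphabetical order,
giving the standard 96-channel layout used by the COSMIC signature catalogues.
"""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _build_labels() -> list[str]:
    labels = []
    for change in SUBSTITUTION_TYPES:
        ref = change[0]
        alt = change[2]
        for f5 in BASES:
            for f3 in BASES:
                labels.append(f"{f5}[{ref}>{alt}]{f3}")
    return labels


#: Channel labels in fixed order, e.g. "A[C>A]A" ... "T[T>G]T".
CHANNEL_LABELS: tuple[str, ...] = tuple(_build_labels())

_LABEL_TO_INDEX = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}


def channel_index(f5: str, ref: str, alt: str, f3: str) -> int:
    """Channel index for a pyrimidine-normalized substitution with flanks."""
    change = f"{ref}>{alt}"
    if change not in SUBSTITUTION_TYPES:
        raise ValueError(f"not a pyrimidine-normalized change: {change!r}")
    ci = SUBSTITUTION_TYPES.index(change)
    try:
        i5 = BASES.index(f5)
        i3 = BASES.index(f3)
    except ValueError:
        raise ValueError(f"flanking bases must be one of ACGT, got {f5!r}/{f3!r}")
    return ci * 16 + i5 * 4 + i3


def normalize_context(triplet: str, alt: str) -> tuple[str, str]:
    """Pyrimidine-normalize a (triplet context, alt base) pair.

    If the central (reference) base is a purine, both the triplet and the
    alternate base are reverse-complemented.
    """
    if len(triplet) != 3:
        raise ValueError(f"context must be a triplet, got {triplet!r}")
    triplet = triplet.upper()
    alt = alt.upper()
    if triplet[1] in PURINES:
        return revcomp(triplet), revcomp(alt)
    return triplet, alt


def channel_of(triplet: str, alt: str) -> int:
    """Channel index for any (triplet, alt) pair, normalizing purines."""
    trip, a = normalize_context(triplet, alt)
    return channel_index(trip[0], trip[1], a, trip[2])


def parse_channel_label(label: str) -> int:
    """Parse a channel label in either "A[C>A]A" or "ACA>AAA" style."""
    label = label.strip()
    if "[" in label:
        idx = _LABEL_TO_INDEX.get(label.upper())
        if idx is None:
            raise ValueError(f"unrecognized channel label: {label!r}")
        return idx
    if ">" in label:
        left, right = label.upper().split(">")
        if len(left) == 3 and len(right) == 3 and left[0] == right[0] and left[2] == right[2]:
            return channel_of(left, right[1])
    raise ValueError(f"unrecognized channel label: {label!r}")


def sixfold_index(channel: int) -> int:
    """Map a 96-channel index to its base-change category (0..5)."""
    if not 0 <= channel < 96:
        raise ValueError(f"channel out of range: {channel}")
    return channel // 16
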