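"""Trinucleotide spectra, base-change tallies and transcriptional strand bias.

Called base substitutions are placed into the 96-channel pyrimidine-normalized
trinucleotide layout (see :mod:`mutpanel.channels`), aggregated into the six
base-change categories, and optionally annotated with transcriptional strand:
a mutation inside a gene is "transcribed" when its pyrimidine-normalized
reference base lies on the template (antisense) strand and "untranscribed"
when it lies on the coding strand. An excess on the transcribed strand is the
footprint of transcription-coupled repair acting on the complementary adduct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .channels import (
    CHANNEL_LABELS,
    PURINES,
    SUBSTITUTION_TYPES,
    channel_index,
    normalize_context,
    sixfold_index,
)

TRANSCRIBED = "transcribed"
UNTRANSCRIBED = "untranscribed"
INTERGENIC = "intergenic"
AMBIGUOUS = "ambiguous"


@dataclass
class MutationRecord:
    """A channelized base substitution."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    context: str  # pyrimidine-normalized triplet
    channel: int
    strand: str = INTERGENIC

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if not 0 <= self.channel < 96:
            raise ValueError(f"channel out of range: {self.channel}")


def _fetch(reference, chrom: str, start0: int, end0: int) -> str:
    """Extract reference sequence [start0, end0) from a dict of strings or a
    pyfaidx.Fasta-like object."""
    seq = reference[chrom]
    if isinstance(seq, str):
        return seq[start0:end0].upper()
    return str(seq[start0:end0]).upper()


def _contig_length(reference, chrom: str) -> int:
    seq = reference[chrom]
    return len(seq)


def triplet_channel(reference, chrom: str, pos: int, ref: str, alt: str):
    """Pyrimidine-normalized context and channel of a substitution.

    Returns (context, channel), or ``None`` when a flanking base falls off the
    contig end (the record is to be flagged and skipped by the caller). A
    mismatch between ``ref`` and the reference sequence raises, as it almost
    always indicates a coordinate convention bug upstream.
    """
    ref = ref.upper()
    alt = alt.upper()
    if pos < 2 or pos + 1 > _contig_length(reference, chrom):
        return None
    triplet = _fetch(reference, chrom, pos - 2, pos + 1)
    if triplet[1] != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: expected {ref!r}, found {triplet[1]!r}"
        )
    trip, a = normalize_context(triplet, alt)
    return trip, channel_index(trip[0], trip[1], a, trip[2])


def channelize(
    raw_calls: Iterable, reference
) -> tuple[list[MutationRecord], int]:
    """Turn raw (chrom, pos, ref, alt) call-like objects into MutationRecords.

    Accepts any object with chrom/pos/ref/alt attributes (e.g. CandidateCall)
    or 4-tuples. Records whose flanks fall off a contig end are skipped; the
    skip count is returned alongside.
    """
    records: list[MutationRecord] = []
    skipped = 0
    for c in raw_calls:
        if isinstance(c, tuple):
            chrom, pos, ref, alt = c
        else:
            chrom, pos, ref, alt = c.chrom, c.pos, c.ref, c.alt
        if alt not in "ACGT":
            continue  # indels have no trinucleotide channel
        out = triplet_channel(reference, chrom, pos, ref, alt)
        if out is None:
            skipped += 1
            continue
        context, channel = out
        records.append(MutationRecord(chrom, pos, ref, alt, context, channel))
    return records, skipped


def build_spectrum(records: Sequence[MutationRecord]) -> np.ndarray:
    """96-channel count spectrum over channelized records."""
    spectrum = np.zeros(96, dtype=np.int64)
    for r in records:
        spectrum[r.channel] += 1
    return spectrum


def sixfold_from_spectrum(spectrum: np.ndarray) -> np.ndarray:
    """Collapse a 96-channel spectrum into the six base-change categories."""
    spectrum = np.asarray(spectrum)
    if spectrum.shape != (96,):
        raise ValueError("expected a 96-channel spectrum")
    return spectrum.reshape(6, 16).sum(axis=1)


def sixfold_tally(records: Sequence[MutationRecord]) -> np.ndarray:
    """Counts per base-change category (C>A, C>G, C>T, T>A, T>C, T>G)."""
    return sixfold_from_spectrum(build_spectrum(records))


def spectrum_frame(spectrum: np.ndarray) -> pd.DataFrame:
    """Spectrum as a labelled DataFrame (channel label, base change, count)."""
    return pd.DataFrame(
        {
            "channel": CHANNEL_LABELS,
            "base_change": [SUBSTITUTION_TYPES[sixfold_index(i)] for i in range(96)],
            "count": np.asarray(spectrum),
        }
    )


@dataclass
class GeneInterval:
    """A stranded gene footprint, 1-based closed coordinates."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end or self.start < 1:
            raise ValueError(f"malformed interval {self.chrom}:{self.start}-{self.end}")


def annotate_strand(records: Sequence[MutationRecord], genes: Sequence[GeneInterval]) -> list[MutationRecord]:
    """Annotate each record with its transcriptional strand category.

    The reference strand carries the pyrimidine for C/T reference bases and
    its complement does for A/G. Inside a '+' gene, a reference-strand
    pyrimidine sits on the coding strand (untranscribed); inside a '-' gene it
    sits on the template strand (transcribed). Positions covered by genes on
    both strands are ambiguous; genes overlapping on the same strand count
    once.
    """
    by_chrom: dict[str, list[GeneInterval]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for r in records:
        strands = {
            g.strand
            for g in by_chrom.get(r.chrom, [])
            if g.start <= r.pos <= g.end
        }
        if not strands:
            cat = INTERGENIC
        elif len(strands) == 2:
            cat = AMBIGUOUS
        else:
            gene_strand = next(iter(strands))
            pyr_on_plus = r.ref not in PURINES
            if pyr_on_plus == (gene_strand == "+"):
                cat = UNTRANSCRIBED
            else:
                cat = TRANSCRIBED
        out.append(
            MutationRecord(r.chrom, r.pos, r.ref, r.alt, r.context, r.channel, strand=cat)
        )
    return out


def strand_bias(records: Sequence[MutationRecord], genes: Sequence[GeneInterval]) -> pd.DataFrame:
    """Per-category transcribed/untranscribed counts with binomial tests.

    Intergenic and ambiguous records are excluded. The p-value is a two-sided
    binomial test of the transcribed count against 0.5; categories with no
    genic records get p = 1.
    """
    annotated = annotate_strand(records, genes)
    rows = []
    for ci, change in enumerate(SUBSTITUTION_TYPES):
        t = sum(1 for r in annotated if sixfold_index(r.channel) == ci and r.strand == TRANSCRIBED)
        u = sum(1 for r in annotated if sixfold_index(r.channel) == ci and r.strand == UNTRANSCRIBED)
        n = t + u
        p = scipy.stats.binomtest(t, n, 0.5).pvalue if n > 0 else 1.0
        rows.append({"base_change": change, TRANSCRIBED: t, UNTRANSCRIBED: u, "p_value": float(p)})
    return pd.DataFrame(rows)


def group_count_tests(
    counts: pd.DataFrame,
    group_labels: Mapping[str, str] | Sequence[str],
    n_comparisons: int = 6,
) -> pd.DataFrame:
    """Unpaired two-sided t-tests of per-genome category counts between two
    groups, Bonferroni-corrected for ``n_comparisons``.

    ``counts`` has one row per genome and one column per category (typically
    the six base changes); ``group_labels`` assigns each row to one of exactly
    two groups. Classic pooled-variance t-test; the degenerate case of zero
    variance in both groups with equal means is reported as t = 0, p = 1.
    """
    if isinstance(group_labels, Mapping):
        labels = pd.Series({s: group_labels[s] for s in counts.index})
    else:
        labels = pd.Series(list(group_labels), index=counts.index)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    a_idx = labels[labels == groups[0]].index
    b_idx = labels[labels == groups[1]].index
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise ValueError("need at least 2 genomes per group")
    rows = []
    for col in counts.columns:
        a = counts.loc[a_idx, col].to_numpy(dtype=float)
        b = counts.loc[b_idx, col].to_numpy(dtype=float)
        if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
        rows.append(
            {
                "category": col,
                "t_statistic": float(t),
                "p_value": float(p),
                "p_bonferroni": min(1.0, n_comparisons * float(p)),
            }
        )
    return pd.DataFrame(rows)
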