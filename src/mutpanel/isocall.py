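"""Unique-mutation calling in isogenic clone panels from allele-count pileups.

All clones in a panel derive from one ancestral genome, so a genuine
experimentally induced mutation is private to one clone. At every genomic
position the candidate sample must show the variant clearly (allele frequency
and coverage filters) while every other sample in the panel must look clean
(reference allele frequency filter). Surviving candidates are scored with a
probability-based quality score: -log10 of the two-sided Fisher exact p-value
of the 2x2 allele-count table built from the candidate sample and the other
sample with the LOWEST reference allele frequency, i.e. the one most likely to
disprove uniqueness. Calls are emitted when the score reaches a class-specific
threshold (2.5 for base substitutions, 2.0 for insertions and deletions).

Insertions and deletions are carried through the same machinery as
pseudo-alleles occupying the fifth and sixth count columns of the pileup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.stats

#: Count-column order in a pileup site. INS/DEL are pseudo-alleles.
ALLELES = ("A", "C", "G", "T", "INS", "DEL")
_ALLELE_INDEX = {a: i for i, a in enumerate(ALLELES)}

SNV, INS, DEL = "SNV", "INS", "DEL"


@dataclass
class PileupSite:
    """Per-position allele counts for every sample of the panel.

    ``counts`` has shape (n_samples, 6) in :data:`ALLELES` order; sample order
    is fixed panel-wide.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(ALLELES):
            raise ValueError(f"counts must be (n_samples, {len(ALLELES)}), got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("negative allele counts")
        if self.ref not in "ACGT":
            raise ValueError(f"reference base must be one of ACGT, got {self.ref!r}")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]


@dataclass
class CallerParams:
    """Filter and score thresholds for unique-mutation calling."""

    min_mut_af: float = 0.2
    min_coverage: int = 5
    min_other_ref_af: float = 0.93
    score_threshold_snv: float = 2.5
    score_threshold_ins: float = 2.0
    score_threshold_del: float = 2.0
    two_sided: bool = True  # one-sided alternative kept switchable

    def __post_init__(self) -> None:
        for name in ("min_mut_af", "min_other_ref_af"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        for name in ("min_coverage", "score_threshold_snv", "score_threshold_ins", "score_threshold_del"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def threshold_for(self, call_class: str) -> float:
        return {
            SNV: self.score_threshold_snv,
            INS: self.score_threshold_ins,
            DEL: self.score_threshold_del,
        }[call_class]


@dataclass
class CandidateCall:
    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    coverage: int
    score: float
    call_class: str
    comparison_sample: str = ""


def _top_alt(site: PileupSite, sample_index: int) -> tuple[int, int]:
    """(allele index, count) of the strongest non-reference allele.

    Only the top non-reference allele is evaluated at multi-allelic sites;
    ties resolve in :data:`ALLELES` order.
    """
    ref_idx = _ALLELE_INDEX[site.ref]
    row = site.counts[sample_index].copy()
    row[ref_idx] = -1
    alt_idx = int(np.argmax(row))
    return alt_idx, int(site.counts[sample_index, alt_idx])


def _ref_af(site: PileupSite, sample_index: int) -> float:
    """Reference allele frequency; 1.0 for an uncovered sample (no evidence)."""
    total = int(site.counts[sample_index].sum())
    if total == 0:
        return 1.0
    return site.counts[sample_index, _ALLELE_INDEX[site.ref]] / total


def site_filter(site: PileupSite, sample_index: int, params: CallerParams) -> tuple[bool, str]:
    """Apply the three per-site filters for one candidate sample.

    Returns (passed, reason); ``reason`` names the first violated rule, or is
    empty on a pass.
    """
    if not 0 <= sample_index < site.n_samples:
        raise IndexError(f"sample index {sample_index} not in panel of {site.n_samples}")
    coverage = int(site.counts[sample_index].sum())
    _, alt_count = _top_alt(site, sample_index)
    vaf = alt_count / coverage if coverage else 0.0
    if vaf < params.min_mut_af:
        return False, "min_mut_af"
    if coverage < params.min_coverage:
        return False, "min_coverage"
    for other in range(site.n_samples):
        if other == sample_index:
            continue
        if _ref_af(site, other) < params.min_other_ref_af:
            return False, "min_other_ref_af"
    return True, ""


def fisher_score(mut_counts: tuple[int, int], other_counts: tuple[int, int], two_sided: bool = True) -> float:
    """-log10 of the Fisher exact p-value for a 2x2 allele-count table.

    Rows are (candidate sample, comparison sample); columns are (alt, ref)
    read counts. The all-zero table is defined to score 0.
    """
    a, b = mut_counts
    c, d = other_counts
    if min(a, b, c, d) < 0:
        raise ValueError("negative counts")
    if a + b + c + d == 0:
        return 0.0
    alternative = "two-sided" if two_sided else "greater"
    _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    p = max(float(p), 1e-300)
    return -np.log10(p)


def call_unique_mutations(
    sites: Iterable[PileupSite],
    params: CallerParams | None = None,
    sample_ids: Sequence[str] | None = None,
) -> list[CandidateCall]:
    """Call mutations unique to one sample across a panel of pileup sites.

    For every site x sample passing :func:`site_filter`, the comparison sample
    is the other sample with the lowest reference allele frequency (ties:
    higher coverage, then lower sample index); the call is emitted when the
    Fisher score reaches the class threshold. Output is sorted by
    (chrom, pos, sample).
    """
    params = params or CallerParams()
    calls: list[CandidateCall] = []
    n_samples = None
    for site in sites:
        if n_samples is None:
            n_samples = site.n_samples
            if n_samples < 2:
                raise ValueError("panel must contain at least 2 samples")
            if sample_ids is None:
                ids = [f"sample_{i}" for i in range(n_samples)]
            else:
                ids = list(sample_ids)
                if len(ids) != n_samples:
                    raise ValueError("sample_ids length does not match panel width")
        elif site.n_samples != n_samples:
            raise ValueError(
                f"inconsistent sample set: site {site.chrom}:{site.pos} has "
                f"{site.n_samples} samples, expected {n_samples}"
            )
        ref_idx = _ALLELE_INDEX[site.ref]
        # cheap screen: no non-reference reads anywhere -> nothing to call
        alt_any = site.counts.sum() - site.counts[:, ref_idx].sum()
        if alt_any == 0:
            continue
        totals = site.counts.sum(axis=1)
        ref_afs = np.where(totals > 0, site.counts[:, ref_idx] / np.maximum(totals, 1), 1.0)
        for s in range(site.n_samples):
            passed, _ = site_filter(site, s, params)
            if not passed:
                continue
            alt_idx, alt_count = _top_alt(site, s)
            coverage = int(totals[s])
            vaf = alt_count / coverage
            # comparison sample: lowest ref AF among others; tie -> higher
            # coverage, then lowest index
            comp = min(
                (o for o in range(site.n_samples) if o != s),
                key=lambda o: (ref_afs[o], -totals[o], o),
            )
            score = fisher_score(
                (alt_count, int(site.counts[s, ref_idx])),
                (int(site.counts[comp, alt_idx]), int(site.counts[comp, ref_idx])),
                two_sided=params.two_sided,
            )
            allele = ALLELES[alt_idx]
            call_class = allele if allele in (INS, DEL) else SNV
            if score < params.threshold_for(call_class):
                continue
            calls.append(
                CandidateCall(
                    sample=ids[s],
                    chrom=site.chrom,
                    pos=site.pos,
                    ref=site.ref,
                    alt=allele,
                    vaf=vaf,
                    coverage=coverage,
                    score=score,
                    call_class=call_class,
                    comparison_sample=ids[comp],
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.pos, c.sample))
    return calls
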