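"""Synthetic inputs for every pipeline stage.

The generators here emulate the study design the pipeline targets: an
isogenic clone panel carrying shared (clonal) and private (unique) mutations
at controlled allele frequency and coverage; mutation catalogs drawn from
known signature mixtures; structural-variant length sets with a trimodal
log10-length distribution split at 4.5 and 6.0; and reference sequences with
junction microhomology planted at deletion breakpoints.

All randomness flows from a single seed through spawned child generators, one
per sub-task, so adding a draw to one generator does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .channels import BASES, SUBSTITUTION_TYPES
from .isocall import ALLELES, PileupSite
from .signatures import SignatureMatrix
from .svclass import SVRecord, SizeClassScheme

_ALLELE_INDEX = {a: i for i, a in enumerate(ALLELES)}


# ---------------------------------------------------------------------------
# isogenic panel pileups


@dataclass
class PanelSimConfig:
    """Configuration of a synthetic isogenic-panel pileup.

    ``planted_unique`` holds (sample index, position [1-based], ref base,
    alt allele, target VAF) tuples; ``planted_clonal`` holds (position, ref,
    alt) tuples present in every sample at ``clonal_vaf`` (heterozygous by
    default). Alt alleles may be bases or the INS/DEL pseudo-alleles.
    """

    n_samples: int
    genome_length: int
    mean_coverage: float
    planted_unique: list = field(default_factory=list)
    planted_clonal: list = field(default_factory=list)
    noise_rate: float = 0.0
    clonal_vaf: float = 0.5
    seed: int = 0
    chrom: str = "chr_sim"

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if not 0.0 <= self.noise_rate <= 0.05:
            raise ValueError("noise_rate must lie in [0, 0.05]")
        seen: set[tuple[int, int]] = set()
        for s, pos, ref, alt, vaf in self.planted_unique:
            if not 0 <= s < self.n_samples:
                raise ValueError(f"sample index {s} out of range")
            if not 1 <= pos <= self.genome_length:
                raise ValueError(
                    f"planted position {pos} lies beyond the {self.genome_length} bp genome"
                )
            if not 0.0 < vaf <= 1.0:
                raise ValueError(f"target VAF must lie in (0, 1], got {vaf}")
            self._check_alleles(ref, alt)
            if (s, pos) in seen:
                raise ValueError(f"duplicate planted position {pos} for sample {s}")
            seen.add((s, pos))
        for pos, ref, alt in self.planted_clonal:
            if not 1 <= pos <= self.genome_length:
                raise ValueError(
                    f"planted position {pos} lies beyond the {self.genome_length} bp genome"
                )
            self._check_alleles(ref, alt)

    @staticmethod
    def _check_alleles(ref: str, alt: str) -> None:
        if ref not in "ACGT":
            raise ValueError(f"ref must be one of ACGT, got {ref!r}")
        if alt not in ALLELES or alt == ref:
            raise ValueError(f"alt must be a non-ref allele of {ALLELES}, got {alt!r}")


def simulate_panel(cfg: PanelSimConfig) -> tuple[str, list[PileupSite]]:
    """Simulate a reference sequence and per-position pileups for a panel.

    Coverage is Poisson(mean_coverage) floored at 1; planted mutations draw
    their alt counts binomially at the target VAF; sequencing noise converts
    each remaining reference read to one of the three other bases with
    probability ``noise_rate``, uniformly. Reproducible for a fixed seed.
    """
    rng_ref, rng_cov, rng_plant, rng_noise = (
        np.random.default_rng(c) for c in np.random.SeedSequence(cfg.seed).spawn(4)
    )
    L, S = cfg.genome_length, cfg.n_samples
    ref_arr = rng_ref.choice(list(BASES), size=L)
    # planted reference bases override the random background
    for pos, ref, _alt in cfg.planted_clonal:
        ref_arr[pos - 1] = ref
    for _s, pos, ref, _alt, _vaf in cfg.planted_unique:
        ref_arr[pos - 1] = ref

    coverage = np.maximum(rng_cov.poisson(cfg.mean_coverage, size=(L, S)), 1)
    counts = np.zeros((L, S, len(ALLELES)), dtype=np.int64)
    ref_idx = np.array([_ALLELE_INDEX[b] for b in ref_arr])
    np.put_along_axis(
        counts, ref_idx[:, None, None].repeat(S, axis=1), coverage[..., None], axis=2
    )

    def plant(pos: int, sample: int, ref: str, alt: str, vaf: float) -> None:
        cov = int(coverage[pos - 1, sample])
        alt_n = int(rng_plant.binomial(cov, vaf))
        counts[pos - 1, sample, _ALLELE_INDEX[alt]] += alt_n
        counts[pos - 1, sample, _ALLELE_INDEX[ref]] -= alt_n

    for pos, ref, alt in cfg.planted_clonal:
        for s in range(S):
            plant(pos, s, ref, alt, cfg.clonal_vaf)
    for s, pos, ref, alt, vaf in cfg.planted_unique:
        plant(pos, s, ref, alt, vaf)

    if cfg.noise_rate > 0:
        ref_remaining = np.take_along_axis(counts, ref_idx[:, None, None].repeat(S, axis=1), axis=2)[..., 0]
        n_noise = rng_noise.binomial(ref_remaining, cfg.noise_rate)
        for i, s in zip(*np.nonzero(n_noise)):
            k = int(n_noise[i, s])
            others = [j for j, b in enumerate("ACGT") if b != ref_arr[i]]
            split = rng_noise.multinomial(k, [1 / 3] * 3)
            for j, n in zip(others, split):
                counts[i, s, j] += int(n)
            counts[i, s, _ALLELE_INDEX[ref_arr[i]]] -= k

    reference = "".join(ref_arr)
    sites = [
        PileupSite(cfg.chrom, i + 1, str(ref_arr[i]), counts[i]) for i in range(L)
    ]
    return reference, sites


# ---------------------------------------------------------------------------
# signature-mixture catalogs


@dataclass
class CatalogSimConfig:
    """A mutation catalog drawn from a mixture of reference signatures."""

    signature_names: list[str]
    mixture_weights: list[float]
    n_mutations: int
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.signature_names) != len(self.mixture_weights):
            raise ValueError("names and weights differ in length")
        w = np.asarray(self.mixture_weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("mixture weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {w.sum()}")
        if self.n_mutations < 0:
            raise ValueError("n_mutations must be >= 0")


def simulate_catalog(cfg: CatalogSimConfig, signatures: SignatureMatrix) -> np.ndarray:
    """Multinomial 96-channel catalog of ``n_mutations`` draws from a mixture."""
    p = np.zeros(96)
    for name, w in zip(cfg.signature_names, cfg.mixture_weights):
        p += w * signatures.column(name)
    p = p / p.sum() if p.sum() > 0 else np.full(96, 1 / 96)
    rng = np.random.default_rng(cfg.seed)
    return rng.multinomial(cfg.n_mutations, p)


# ---------------------------------------------------------------------------
# structural-variant sets


@dataclass
class SVSimConfig:
    """A trimodal SV length set: per-class counts split at log10 = 4.5, 6.0.

    Lengths are drawn uniformly in log10 within each class, truncated at
    ``min_length`` and ``max_length``. Inter-chromosomal translocations
    (``n_ctx``) carry no length or size class.
    """

    n_small: int
    n_mid: int
    n_large: int
    type_mix: dict = field(default_factory=lambda: {"DEL": 0.45, "DUP": 0.35, "INV": 0.20})
    n_ctx: int = 0
    boundaries: tuple[float, float] = (4.5, 6.0)
    min_length: int = 100
    max_length: int = 10**8
    genome_length: int = 250_000_000
    seed: int = 0
    sample: str = "sim"
    chrom: str = "chr_sim"

    def __post_init__(self) -> None:
        if min(self.n_small, self.n_mid, self.n_large, self.n_ctx) < 0:
            raise ValueError("event counts must be >= 0")
        if not self.boundaries[0] < self.boundaries[1]:
            raise ValueError("class boundaries must be strictly increasing")
        bad = set(self.type_mix) - {"DEL", "DUP", "INV", "CTX"}
        if bad:
            raise ValueError(f"unknown SV types in mix: {bad}")


def simulate_sv_set(cfg: SVSimConfig) -> list[SVRecord]:
    """Draw SV records with exact per-class counts and log-uniform lengths."""
    rng = np.random.default_rng(cfg.seed)
    scheme = SizeClassScheme(boundaries=cfg.boundaries, min_length=cfg.min_length)
    lo1, lo2 = cfg.boundaries
    # integer length windows consistent with the <, <=, > boundary convention
    windows = [
        (cfg.min_length, int(np.floor(10**lo1))),
        (int(np.floor(10**lo1)) + 1, int(round(10**lo2))),
        (int(round(10**lo2)) + 1, cfg.max_length),
    ]
    intra_types = [t for t in ("DEL", "DUP", "INV") if cfg.type_mix.get(t, 0) > 0]
    probs = np.array([cfg.type_mix[t] for t in intra_types], dtype=float)
    probs /= probs.sum()
    records: list[SVRecord] = []
    for (low, high), n in zip(windows, (cfg.n_small, cfg.n_mid, cfg.n_large)):
        for _ in range(n):
            x = rng.uniform(np.log10(low), np.log10(high))
            length = int(np.clip(round(10**x), low, high))
            svtype = str(rng.choice(intra_types, p=probs))
            pos1 = int(rng.integers(1, cfg.genome_length - length))
            support = int(rng.integers(4, 60))
            records.append(
                SVRecord(
                    svtype=svtype,
                    chrom1=cfg.chrom,
                    pos1=pos1,
                    chrom2=cfg.chrom,
                    pos2=pos1 + length,
                    support=support,
                    sample=cfg.sample,
                    scheme=scheme,
                )
            )
    for _ in range(cfg.n_ctx):
        pos1 = int(rng.integers(1, cfg.genome_length))
        pos2 = int(rng.integers(1, cfg.genome_length))
        records.append(
            SVRecord(
                svtype="CTX",
                chrom1=cfg.chrom + "A",
                pos1=pos1,
                chrom2=cfg.chrom + "B",
                pos2=pos2,
                support=int(rng.integers(4, 60)),
                sample=cfg.sample,
                scheme=scheme,
            )
        )
    return records


# ---------------------------------------------------------------------------
# junction microhomology planting


def plant_microhomology(reference: str, deletion: tuple[int, int], k: int) -> str:
    """Edit a reference so a deletion junction shows exactly ``k`` bp homology.

    ``deletion`` is (start, end), 1-based closed. The k bases just inside the
    deletion's left edge are copied to the k positions immediately after the
    right edge, and the following base is forced to mismatch so a junction
    scan reports exactly k.
    """
    if not 0 <= k <= 10:
        raise ValueError("k must lie in [0, 10]")
    start, end = deletion
    n = len(reference)
    if not (1 <= start <= end <= n):
        raise ValueError(f"deletion ({start}, {end}) outside the {n} bp sequence")
    if end - start + 1 < k:
        raise ValueError(
            f"deletion of {end - start + 1} bp is too short to host {k} homologous bases"
        )
    if end + k + 1 > n:
        raise ValueError("not enough sequence after the deletion to plant the junction")
    seq = list(reference)
    s, e = start - 1, end - 1  # 0-based inclusive
    for i in range(k):
        seq[e + 1 + i] = seq[s + i]
    # force a mismatch right after the homologous stretch
    if seq[s + k] == seq[e + 1 + k]:
        b = seq[e + 1 + k].upper()
        seq[e + 1 + k] = BASES[(BASES.index(b) + 1) % 4]
    return "".join(seq)


# ---------------------------------------------------------------------------
# synthetic signature reference


def _sig_weight(name: str, change: str, f5: str, f3: str) -> float:
    """Raw (pre-jitter) channel weight for one synthetic signature."""
    if name == "SBS1":  # deamination-like: C>T at NpCpG
        if change == "C>T":
            return 20.0 if f3 == "G" else 0.6
        return 0.05
    if name == "SBS2":  # APOBEC-like: C>T at TpC
        if change == "C>T":
            return 20.0 if f5 == "T" else 0.3
        return 0.02
    if name == "SBS13":  # APOBEC-like: C>G at TpC
        if change == "C>G":
            return 20.0 if f5 == "T" else 0.3
        return 0.02
    if name == "SBS4":  # tobacco-like: broad C>A
        return 6.0 if change == "C>A" else 0.4
    if name == "SBS18":  # oxidative-damage-like: C>A at NpCpA / NpCpT
        if change == "C>A":
            return 10.0 if f3 in "AT" else 2.0
        return 0.1
    if name == "SBS5":  # flat clock-like with a mild T>C lean
        return 1.6 if change == "T>C" else 1.0
    if name == "SBS40":  # flat with a mild C>T lean
        return 1.3 if change == "C>T" else 1.0
    if name == "SBS3":  # featureless broad profile
        return 1.0
    if name == "SBS16":  # alcohol-associated: T>C dominated by ApTpN
        if change == "T>C":
            return 20.0 if f5 == "A" else 1.5
        return 0.1
    if name == "SBS17a":  # T>A at NpTpT
        if change == "T>A":
            return 15.0 if f3 == "T" else 0.5
        return 0.03
    if name == "SBS17b":  # T>G at NpTpT
        if change == "T>G":
            return 20.0 if f3 == "T" else 0.5
        return 0.03
    if name == "SBS7a":  # UV-like: C>T at pyrimidine dimers
        if change == "C>T":
            return 15.0 if f5 in "CT" else 0.5
        return 0.1
    raise KeyError(name)


SYNTHETIC_SIGNATURE_NAMES = (
    "SBS1", "SBS2", "SBS3", "SBS4", "SBS5", "SBS7a",
    "SBS13", "SBS16", "SBS17a", "SBS17b", "SBS18", "SBS40",
)


def synthetic_signature_matrix(seed: int = 20240117) -> SignatureMatrix:
    """A deterministic SYNTHETIC signature reference in the 96-channel layout.

    This is a stand-in constructed from the qualitative published shapes of a
    dozen well-known signatures (e.g. SBS1 as C>T at NpCpG, SBS16 as T>C with
    dominant ApTpN peaks, SBS5/SBS40 as flat clock-like profiles). It is NOT
    the COSMIC catalog; channel-level values are generated here, with mild
    multiplicative jitter for realism, and are reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    cols = []
    for name in SYNTHETIC_SIGNATURE_NAMES:
        w = np.empty(96)
        i = 0
        for change in SUBSTITUTION_TYPES:
            for f5 in BASES:
                for f3 in BASES:
                    w[i] = _sig_weight(name, change, f5, f3)
                    i += 1
        w *= rng.lognormal(0.0, 0.15, size=96)
        cols.append(w / w.sum())
    return SignatureMatrix(np.column_stack(cols), list(SYNTHETIC_SIGNATURE_NAMES))
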