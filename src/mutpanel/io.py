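"""File formats: FASTA, pileup TSV, signature TSV, VCF, BEDPE, metadata, manifests.

Coordinate conventions: pileup TSV and VCF positions are 1-based; BEDPE is
0-based half-open on disk and converted to the internal 1-based closed
representation on read. Every writer that emits coordinates states the
convention in a header line.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .channels import CHANNEL_LABELS, parse_channel_label
from .isocall import ALLELES, CandidateCall, PileupSite
from .signatures import SignatureMatrix
from .svclass import SVRecord, SizeClassScheme

# ---------------------------------------------------------------------------
# FASTA


def write_fasta(path, sequences: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read a (small) FASTA into chrom -> sequence strings."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


# ---------------------------------------------------------------------------
# pileup TSV


def write_pileup_tsv(path, sites: Sequence[PileupSite], sample_ids: Sequence[str]) -> None:
    """Pileup table: chrom, pos (1-based), ref, then per-sample allele counts.

    Each sample contributes six columns (<sample>_A,C,G,T,INS,DEL).
    """
    header = ["chrom", "pos", "ref"]
    for s in sample_ids:
        header += [f"{s}_{a}" for a in ALLELES]
    with open(path, "w") as fh:
        fh.write("# positions are 1-based\n")
        fh.write("\t".join(header) + "\n")
        for site in sites:
            row = [site.chrom, str(site.pos), site.ref]
            row += [str(int(v)) for v in site.counts.ravel()]
            fh.write("\t".join(row) + "\n")


def read_pileup_tsv(path) -> tuple[list[PileupSite], list[str]]:
    """Read a pileup TSV; accepts 4-column (ACGT) or 6-column per-sample blocks."""
    df = pd.read_csv(path, sep="\t", comment="#")
    count_cols = [c for c in df.columns if c not in ("chrom", "pos", "ref")]
    sample_ids: list[str] = []
    per_sample = None
    for width in (6, 4):
        if len(count_cols) % width == 0 and all(
            count_cols[i].rsplit("_", 1)[1] == ALLELES[i % width]
            for i in range(len(count_cols))
        ):
            per_sample = width
            break
    if per_sample is None:
        raise ValueError(f"unrecognized pileup column layout: {count_cols}")
    sample_ids = [count_cols[i].rsplit("_", 1)[0] for i in range(0, len(count_cols), per_sample)]
    n = len(sample_ids)
    values = df[count_cols].to_numpy(dtype=np.int64).reshape(len(df), n, per_sample)
    if per_sample == 4:
        values = np.concatenate([values, np.zeros((len(df), n, 2), dtype=np.int64)], axis=2)
    sites = [
        PileupSite(str(r.chrom), int(r.pos), str(r.ref), values[i])
        for i, r in enumerate(df.itertuples(index=False))
    ]
    return sites, sample_ids


# ---------------------------------------------------------------------------
# signature matrix TSV


def read_signature_matrix(path) -> SignatureMatrix:
    """Read a 96 x K signature TSV (header of names; first column channel
    labels in either "A[C>A]A" or "ACA>AAA" style; any row order).

    Columns within 1e-3 of unit sum are renormalized; anything farther off is
    rejected.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[0] != 96:
        raise ValueError(f"signature file must have 96 data rows, found {df.shape[0]}")
    labels = df.iloc[:, 0].astype(str)
    order = [parse_channel_label(lab) for lab in labels]
    if sorted(order) != list(range(96)):
        raise ValueError("channel labels do not cover the 96 channels exactly once")
    names = list(df.columns[1:])
    try:
        values = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric signature values: {exc}") from None
    matrix = np.empty_like(values)
    matrix[order, :] = values
    colsums = matrix.sum(axis=0)
    off = np.abs(colsums - 1.0)
    if np.any(off > 1e-3):
        bad = [names[i] for i in np.flatnonzero(off > 1e-3)]
        raise ValueError(f"signature columns are not normalized: {bad}")
    matrix = matrix / colsums
    return SignatureMatrix(matrix, names)


def write_signature_matrix(path, signatures: SignatureMatrix) -> None:
    df = pd.DataFrame(signatures.matrix, columns=signatures.names)
    df.insert(0, "Type", CHANNEL_LABELS)
    df.to_csv(path, sep="\t", index=False)


def write_spectrum_tsv(path, spectrum: np.ndarray) -> None:
    pd.DataFrame({"channel": CHANNEL_LABELS, "count": np.asarray(spectrum)}).to_csv(
        path, sep="\t", index=False
    )


def read_spectrum_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    order = [parse_channel_label(lab) for lab in df.iloc[:, 0].astype(str)]
    out = np.zeros(96, dtype=float)
    out[order] = df.iloc[:, 1].to_numpy(dtype=float)
    return out


# ---------------------------------------------------------------------------
# calls: VCF 4.2 + TSV mirror


def write_calls_vcf(path, calls: Sequence[CandidateCall], sample_ids: Sequence[str]) -> None:
    """Minimal VCF 4.2 with one genotype column per clone.

    INS/DEL pseudo-allele calls are written with symbolic ALT alleles.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=mutpanel {__version__}\n")
        fh.write('##INFO=<ID=SCORE,Number=1,Type=Float,Description="-log10 Fisher exact p">\n')
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">\n')
        fh.write('##INFO=<ID=COMP_SAMPLE,Number=1,Type=String,Description="Comparison sample">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        for c in calls:
            alt = c.alt if c.alt in "ACGT" else f"<{c.alt}>"
            info = f"SCORE={c.score:.4f};VAF={c.vaf:.4f};COMP_SAMPLE={c.comparison_sample}"
            gts = ["0/1" if s == c.sample else "0/0" for s in sample_ids]
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{alt}\t{c.score:.2f}\tPASS\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def calls_to_frame(calls: Sequence[CandidateCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": c.sample,
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "vaf": c.vaf,
                "coverage": c.coverage,
                "score": c.score,
                "class": c.call_class,
                "comparison_sample": c.comparison_sample,
            }
            for c in calls
        ]
    )


# ---------------------------------------------------------------------------
# SV sets: BEDPE (0-based half-open on disk)

_BEDPE_COLS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "svtype", "sample", "support",
]


def write_bedpe(path, records: Sequence[SVRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("# BEDPE, 0-based half-open\n")
        fh.write("\t".join(_BEDPE_COLS) + "\n")
        for i, r in enumerate(records):
            fh.write(
                "\t".join(
                    str(v)
                    for v in [
                        r.chrom1, r.pos1 - 1, r.pos1, r.chrom2, r.pos2 - 1, r.pos2,
                        f"sv{i}", r.support, "+", "-", r.svtype, r.sample, r.support,
                    ]
                )
                + "\n"
            )


def read_bedpe(path, scheme: SizeClassScheme | None = None) -> list[SVRecord]:
    scheme = scheme or SizeClassScheme()
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for r in df.itertuples(index=False):
        records.append(
            SVRecord(
                svtype=str(r.svtype),
                chrom1=str(r.chrom1),
                pos1=int(r.start1) + 1,
                chrom2=str(r.chrom2),
                pos2=int(r.start2) + 1,
                support=int(getattr(r, "support", 0)),
                sample=str(getattr(r, "sample", "")),
                scheme=scheme,
            )
        )
    return records


def read_sv_vcf(path, sample: str = "", scheme: SizeClassScheme | None = None) -> list[SVRecord]:
    """Read SVs from a VCF with SVTYPE/END INFO fields (plain-text or bgzipped)."""
    import pysam

    scheme = scheme or SizeClassScheme()
    records = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                continue
            svtype = str(svtype)
            if svtype == "BND" or svtype == "TRA":
                svtype = "CTX"
            chrom2 = str(rec.info.get("CHR2", rec.chrom))
            end = int(rec.info.get("END", rec.stop))
            records.append(
                SVRecord(
                    svtype=svtype,
                    chrom1=str(rec.chrom),
                    pos1=int(rec.pos),
                    chrom2=chrom2,
                    pos2=end,
                    support=int(rec.info.get("SUPPORT", 0)),
                    sample=sample,
                    scheme=scheme,
                )
            )
    return records


# ---------------------------------------------------------------------------
# metadata, genes, manifests


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV with at least sample_id and exposure columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "exposure"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    return df


def read_genes_bed(path):
    """BED6 (or BED12; extra columns ignored) gene intervals with strand."""
    from .spectra import GeneInterval

    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"BED line lacks a strand field: {line!r}")
            genes.append(GeneInterval(f[0], int(f[1]) + 1, int(f[2]), f[5]))
    return genes


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, seed: int, params: dict, inputs: Sequence[str | Path] = ()) -> None:
    manifest = {
        "tool": "mutpanel",
        "version": __version__,
        "seed": seed,
        "params": params,
        "inputs": {str(p): file_sha256(p) for p in inputs},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
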