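"""Pipeline driver: run the analysis stages in dependency order from a config.

The substitution arm runs call -> spectra -> refit -> spike-in; the SV arm
runs postfilter -> size classification -> cohort tests. Every stage writes its
outputs plus a manifest recording inputs (by hash), parameters and the seed,
so reruns with an identical config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io
from .cohort import cohort_report, count_by_class
from .isocall import CallerParams, call_unique_mutations
from .signatures import strict_refit
from .spectra import build_spectrum, channelize, sixfold_from_spectrum, strand_bias
from .spikein import SpikeDesign, detection_limit
from .svclass import SizeClassScheme, postfilter

log = logging.getLogger("mutpanel")


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run. All paths must exist at validation."""

    out_dir: str
    reference: str
    pileup: str
    signatures: str
    seed: int = 0
    genes: Optional[str] = None
    sv_calls: Optional[str] = None  # BEDPE
    panel_of_normals: Optional[str] = None  # BEDPE
    metadata: Optional[str] = None  # sample_id/exposure TSV for the cohort arm
    caller: CallerParams = field(default_factory=CallerParams)
    scheme: SizeClassScheme = field(default_factory=SizeClassScheme)
    max_delta: float = 0.08
    spike_target: Optional[str] = "SBS16"
    spike_replicates: int = 20
    min_support: int = 4
    tolerance_bp: int = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        caller = CallerParams(**raw.pop("caller", {}))
        scheme_raw = raw.pop("scheme", {})
        if "boundaries" in scheme_raw:
            scheme_raw["boundaries"] = tuple(scheme_raw["boundaries"])
        scheme = SizeClassScheme(**scheme_raw)
        return cls(caller=caller, scheme=scheme, **raw)

    def validate(self) -> None:
        for name in ("reference", "pileup", "signatures", "genes", "sv_calls", "panel_of_normals", "metadata"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name!r} does not exist: {p}")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all configured stages; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = {
        "caller": dataclasses.asdict(config.caller),
        "scheme": dataclasses.asdict(config.scheme),
        "max_delta": config.max_delta,
    }

    def stage(name):
        log.info("stage: %s", name)

    # --- substitution arm -------------------------------------------------
    stage("call")
    try:
        sites, sample_ids = io.read_pileup_tsv(config.pileup)
        calls = call_unique_mutations(sites, config.caller, sample_ids)
        io.write_calls_vcf(out / "calls.vcf", calls, sample_ids)
        io.calls_to_frame(calls).to_csv(out / "calls.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'call' failed on {config.pileup}: {exc}") from exc

    stage("spectra")
    try:
        reference = io.read_fasta(config.reference)
        records, skipped = channelize(calls, reference)
        spectrum = build_spectrum(records)
        io.write_spectrum_tsv(out / "spectrum.tsv", spectrum)
        sixfold = sixfold_from_spectrum(spectrum)
        with open(out / "sixfold.json", "w") as fh:
            json.dump(
                {
                    "C>A": int(sixfold[0]), "C>G": int(sixfold[1]), "C>T": int(sixfold[2]),
                    "T>A": int(sixfold[3]), "T>C": int(sixfold[4]), "T>G": int(sixfold[5]),
                    "skipped_edge_records": skipped,
                },
                fh,
                indent=2,
            )
        if config.genes:
            genes = io.read_genes_bed(config.genes)
            strand_bias(records, genes).to_csv(out / "strand_bias.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'spectra' failed on {config.reference}: {exc}") from exc

    stage("refit")
    try:
        sigs = io.read_signature_matrix(config.signatures)
        refit = strict_refit(spectrum.astype(float), sigs, max_delta=config.max_delta)
        contrib = {n: float(c) for n, c in zip(refit.names, refit.contributions) if c > 0}
        with open(out / "refit.json", "w") as fh:
            json.dump(
                {
                    "contributions": contrib,
                    "cosine": refit.cosine,
                    "initial_cosine": refit.initial_cosine,
                    "removal_trace": refit.removal_trace,
                },
                fh,
                indent=2,
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'refit' failed on {config.signatures}: {exc}") from exc

    if config.spike_target and config.spike_target in sigs.names and spectrum.sum() > 0:
        stage("spikein")
        design = SpikeDesign(
            background=spectrum,
            target=config.spike_target,
            replicates=config.spike_replicates,
            max_delta=config.max_delta,
            seed=config.seed,
        )
        result = detection_limit(design, sigs)
        result.table.to_csv(out / "spikein_rates.tsv", sep="\t", index=False)
        with open(out / "spikein.json", "w") as fh:
            json.dump(
                {
                    "target": config.spike_target,
                    "minimal_detectable_fraction": result.minimal_fraction,
                    "low_fit_replicates": result.low_fit_replicates,
                },
                fh,
                indent=2,
            )

    # --- SV arm ------------------------------------------------------------
    if config.sv_calls:
        stage("svfilter")
        try:
            svs = io.read_bedpe(config.sv_calls, config.scheme)
            pon = io.read_bedpe(config.panel_of_normals, config.scheme) if config.panel_of_normals else []
            filtered = postfilter(svs, pon, config.min_support, config.tolerance_bp)
            io.write_bedpe(out / "sv_filtered.bedpe", filtered)
        except Exception as exc:
            raise RuntimeError(f"stage 'svfilter' failed on {config.sv_calls}: {exc}") from exc

        stage("svclass")
        by_sample: dict[str, list] = {}
        for r in filtered:
            by_sample.setdefault(r.sample, []).append(r)
        table = count_by_class(by_sample, config.scheme)
        table.to_csv(out / "sv_counts.tsv", sep="\t")

        if config.metadata:
            stage("cohort")
            try:
                meta = io.read_metadata(config.metadata)
                exposure = dict(zip(meta["sample_id"], meta["exposure"]))
                table_full = count_by_class(by_sample, config.scheme, declared_samples=list(exposure))
                report = cohort_report(table_full, exposure)
                report.to_csv(out / "cohort_report.tsv", sep="\t", index=False)
            except Exception as exc:
                raise RuntimeError(f"stage 'cohort' failed on {config.metadata}: {exc}") from exc

    inputs = [
        p
        for p in (
            config.reference, config.pileup, config.signatures, config.genes,
            config.sv_calls, config.panel_of_normals, config.metadata,
        )
        if p
    ]
    io.write_manifest(out / "manifest.json", seed=config.seed, params=params, inputs=inputs)
    return out
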