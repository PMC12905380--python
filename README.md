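# mutpanel

Analysis toolkit for mutagenesis studies in isogenic clone panels:

- **Unique-mutation calling** (`mutpanel.isocall`) — calls mutations private to
  one clone from multi-sample pileups, using per-site allele-frequency and
  coverage filters and a Fisher-exact score against the least-clean other
  sample (separate score thresholds for SNVs and indel pseudo-alleles).
- **Trinucleotide spectra** (`mutpanel.channels`, `mutpanel.spectra`) — the
  standard 96-channel pyrimidine-normalized layout, six-category tallies, and
  transcriptional strand-bias tests against stranded gene annotations.
- **Signature refitting** (`mutpanel.signatures`) — non-negative least-squares
  fitting against a signature reference, followed by strict backward
  elimination: signatures are removed smallest-contribution-first while the
  reconstruction cosine similarity stays within a budget (`max_delta`, default
  0.08) of the initial fit. A `per_step` mode applies the budget per removal
  instead.
- **Spike-in sensitivity** (`mutpanel.spikein`) — estimates the smallest
  fraction of a target signature (e.g. SBS16) that the strict refit detects,
  by spiking multinomial draws into a background catalog across a fraction
  grid with replicates.
- **SV classification** (`mutpanel.svclass`) — structural-variant
  post-filtering (support, panel of normals, cross-sample sharing), trimodal
  size classes split at log10(length) = 4.5 (~32 kb) and 6.0 (1 Mb), and
  deletion-junction microhomology.
- **Cohort association** (`mutpanel.cohort`) — per-(type × size class) SV
  count tables and Wilcoxon rank-sum tests (exact permutation or
  tie-corrected normal approximation) between exposure groups.
- **Synthetic data** (`mutpanel.synthetic_data`) — seeded generators for panel
  pileups with planted clonal/unique mutations, signature-mixture catalogs,
  trimodal SV sets, planted junction microhomology, and a deterministic
  **synthetic** signature reference (12 columns emulating well-known signature
  shapes; it is *not* the COSMIC catalog).
- **Files and pipeline** (`mutpanel.io`, `mutpanel.pipeline`, `mutpanel.cli`)
  — FASTA / pileup TSV / signature TSV / VCF / BEDPE / metadata readers and
  writers, a YAML-configured end-to-end driver with manifests, and a `mutpanel`
  command-line interface.

## Quick start

```sh
# generate a synthetic panel, then run the full pipeline on it
mutpanel simulate --out-dir sim --seed 1
mutpanel call --pileup sim/pileup.tsv --out calls.vcf
```

Or drive everything from a config:

```python
from mutpanel.pipeline import PipelineConfig, run_pipeline
run_pipeline(PipelineConfig.from_yaml("config.yaml"))
```

## Tests

```sh
pip install -e .[test]
pytest
```

`tests/test_acceptance.py` encodes the project's acceptance criteria at their
stated tolerances. Two of them are left deliberately failing; see
`docs/methods.md` for the quantitative analysis (the strict-refit
sensitivity envelope at delta 0.08, and the exact-vs-asymptotic Wilcoxon
agreement bound under ties).

`scripts/acceptance.py --seed <int> --out <path>` recomputes the spike-in
detection limit from scratch and writes it as JSON.

## Methods

See [docs/methods.md](docs/methods.md) for numerical conventions, the
synthetic signature reference, and the sensitivity analysis of the strict
elimination rule.
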