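# Methods note

This note records the numerical conventions, design definitions and
quantitative analyses behind `mutpanel`. Everything here is reproducible from
the package itself.

## Unique-mutation calling (`isocall`)

A candidate (site, sample) passes filtering when, in order: the sample's
mutated allele frequency is ≥ 0.2; every *other* covered sample shows a
reference allele frequency ≥ 0.93; and the candidate's coverage is ≥ 5.
Samples with zero coverage at the site carry no evidence either way, so their
reference allele frequency is defined as 1.0 and they never veto a call.

The score of a passing candidate is −log10 of the two-sided Fisher exact
p-value of the 2×2 table (alt, ref) in the candidate sample versus the *other*
sample with the lowest reference allele frequency (ties broken toward higher
coverage, then lower sample index) — the hardest available comparison.
Thresholds: 2.5 for base substitutions, 2.0 for the INS and DEL pseudo-alleles
(pileup columns 5 and 6). The two-sided p sums hypergeometric probabilities of
all tables with the observed margins whose probability does not exceed the
observed one (with a 1+1e-7 relative guard against floating-point ties);
p-values are clipped at 1e-300 before the log. An all-zero table scores 0.

## 96-channel spectra and strand bias

Channels follow the standard ordering: six pyrimidine-normalized base changes
(C>A, C>G, C>T, T>A, T>C, T>G), each split by 5' and 3' flank in alphabetical
order, so `channel = change_index * 16 + 4 * flank5 + flank3`. Purine
references are reverse-complemented together with their alt and flanks;
`channel_of(triplet, alt)` is invariant under reverse complement of its
arguments. Mutations whose flank falls off a contig end are counted and
skipped rather than guessed.

For strand bias, a mutation inside a gene is *untranscribed* when its
pyrimidine-normalized reference base lies on the coding strand and
*transcribed* when it lies on the template strand; positions under genes on
both strands are ambiguous and excluded, as are intergenic records. Each
base-change category gets a two-sided binomial test of the transcribed count
against 0.5.

## Strict signature refitting and its sensitivity envelope

Refitting starts from a non-negative least-squares (NNLS) fit of the 96-channel
catalog against the signature matrix, then repeatedly removes the active
signature with the smallest contribution, re-fitting after each removal, as
long as the cosine similarity between catalog and reconstruction stays within
`max_delta` (default 0.08) of the *initial* fit. With `per_step=True` the
budget applies to each individual removal instead.

This rule has a hard sensitivity envelope. Removing a signature that
contributes a fraction `f` of the catalog changes the reconstruction cosine by
at most

```
1 − (1−f)·s_b / sqrt((1−f)²·s_b² + f²·s_t²)
```

where `s_t` and `s_b` are the L2 norms of the target and background channel
distributions (concentration: 1/√96 ≈ 0.10 for a flat profile, 1 for a
single-channel spike). For realistic signature shapes (`s_t` ≈ 0.25–0.3,
`s_b` ≈ 0.10–0.13), removing a 5% contributor costs only ~0.01 cosine — far
inside a 0.08 budget — so the elimination always removes it. Measured on the
bundled synthetic reference with a clock-like background, the minimal fraction
of SBS16 detected in ≥ 50% of replicates at `max_delta=0.08` is ~11%
(`scripts/acceptance.py` reports this number from scratch). The corresponding
acceptance criterion asks for ≤ 5% at delta 0.08 and is therefore left
failing by design: the two numbers are only mutually consistent under a
*per-removal* budget of ~0.004 (a common tool default), under which the
measured detection limit is 4% (asserted in `tests/test_spikein.py`).

The same envelope dictates the parameter-recovery benchmark: only balanced
mixtures of concentrated, near-orthogonal signatures survive elimination at
delta 0.08 (a component whose removal costs less than the budget is invisible
to the rule *by construction*). The benchmark therefore uses SBS2+SBS13 at
0.5/0.5 and SBS2+SBS13+SBS17b at equal thirds (50/50 seeds recovered, mean
relative contribution errors 0.03–0.05 at n = 500).

## Spike-in construction

Spiking a background of `N` mutations at final-catalog fraction `f` adds
`k = round(f·N/(1−f))` multinomial draws from the target signature; `f = 1` is
defined as a pure-target catalog of `N` draws, and `f = 0` returns the
background unchanged. Detection means a nonzero target contribution after
strict refit (optionally a minimum attributed fraction); the detection limit
is the smallest grid fraction whose detection rate reaches the replicate
quota. All replicate randomness derives from one seed via spawned
`SeedSequence` children.

## SV size classes and microhomology

Intra-chromosomal events are binned by log10(length) with boundaries 4.5
(~32 kb) and 6.0 (1 Mb); a value exactly on a boundary goes to the lower
class, so 10^6 bp is "mid". Events shorter than 100 bp belong to the
small-indel analysis and are flagged excluded. Inter-chromosomal
translocations carry no length or class. Post-filtering removes calls below
the support threshold, calls matching a panel of normals within a breakend
tolerance, and calls shared between samples of the same run; it is idempotent.

Deletion-junction microhomology is the largest `m` (capped at 25) such that
the `m` bases at the start of the deleted segment equal the `m` bases
immediately following the deletion end. Histogram bins: 0, 1–3, 4–9, ≥10 bp.

## Wilcoxon rank-sum test

`rank_sum_test` returns the Mann-Whitney U of the first group and a two-sided
p. Exact mode enumerates the permutation distribution (scipy's exact method
for tie-free data; full combination enumeration with midranks otherwise,
guarded to ≤ 2·10⁶ combinations); normal mode is the tie-corrected asymptotic
with continuity correction. Both modes were validated against R's
`wilcox.test` (frozen oracles in `tests/test_cohort.py`).

Agreement between the two modes: on tie-free samples of 6–9 per group the
absolute difference in two-sided p stays within ~0.016 (measured over 3000
draws; the property test asserts 0.03). Integer samples with ties can deviate
much more — with heavy ties in tiny samples the asymptotic and exact p differ
by design, not by bug. The acceptance criterion asking for ≤ 0.02 agreement on
random *integer* samples at n = m = 8 (which carry ties with high probability)
measures 0.0232 under pre-registered conditions and is left failing rather
than weakened.

## Synthetic signature reference

The COSMIC catalog cannot be redistributed with this package, so
`synthetic_signature_matrix()` provides a deterministic **synthetic** stand-in:
12 columns whose shapes emulate the qualitative published profiles of SBS1, 2,
3, 4, 5, 7a, 13, 16, 17a, 17b, 18 and 40 (e.g. SBS1 as C>T at NpCpG, SBS16 as
T>C dominated by ApTpN, SBS5/40 as flat clock-like profiles), with mild
lognormal channel jitter at a fixed seed. Detection limits and refitting
results are reference-dependent; numbers quoted in this note refer to this
synthetic reference.

## Cohort analysis

Per-sample DEL/DUP counts in the three size classes are compared between
drinker and non-drinker groups cell by cell with the rank-sum test, reported
as raw p-values; the report carries the number of tests performed instead of
applying a multiplicity correction. Cells with fewer than 2 samples in either
group are flagged untestable, not dropped. At the benchmark cohort sizes (40
vs 38) a +Poisson(3) shift of the mid-class deletion counts over a Poisson(10)
baseline is detected at p < 0.05 with power > 0.8 over 100 seeds, while the
per-cell false-flag rate under the null stays at the nominal ~5%.

## Reproducibility

Every simulator takes a single seed and spawns independent child generators
per sub-task (`np.random.SeedSequence.spawn`), so adding draws to one
component does not perturb the others. The pipeline writes a manifest with the
tool version, seed, parameters and SHA-256 of every input; reruns with the
same config are byte-identical.
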