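# Methods

## Problem and model

`skimdist` estimates the per-nucleotide substitution distance `D` between
two genomes from unassembled, low-coverage shotgun reads (genome skims).
The underlying model treats one genome as a copy of the other in which
each site was substituted independently with probability `d`; `D` is the
estimand. Genomes are assumed non-repetitive at the scale of `k`, i.e.
`k` is large enough (default 31) that each genomic k-mer is unique and
every sequencing error creates a novel k-mer. Under these assumptions:

- the number of reads covering a fixed k-mer window is Poisson with mean
  `λ = c (1 − k/ℓ)` for base coverage `c` and read length `ℓ`;
- the number of *error-free* reads covering it is Poisson with mean
  `ξ = λρ`, `ρ = (1−ε)^k`, for a constant per-base miscall rate `ε`;
- a shared k-mer survives mutation with probability `(1−d)^k`.

From these, the retention probability `η = 1 − e^{−ξ}`, the
observed-k-mer density `ζ = η + λ(1−ρ)`, and the corrected
Jaccard-to-distance inversion documented in the README follow. With
abundance filtering at threshold `m ≥ 2` both factors become the Poisson
tail `η = ζ = P[Poisson(ξ) ≥ m]`.

## Estimation pipeline and numerical choices

1. **Counting.** Canonical k-mers (lexicographic min of window and
   reverse complement) are counted exactly; windows containing non-ACGT
   characters are skipped, lowercase is uppercased. Counting is a
   vectorised sliding-window pass over 2-bit packed sequence, which caps
   `k` at 32.
2. **Spectrum peak.** `h = argmax_{i≥2} M_i`, smallest index on ties
   (deterministic, and favours the better-populated bin). Bin 1 is
   excluded because erroneous k-mers pile into it. If no bin `i ≥ 2` is
   populated the estimator refuses and asks for explicit `ε`/`c`
   overrides rather than guessing; spectra this sparse (coverage well
   below ~1/8×) do not support the bin-ratio estimator.
3. **Clamps.** The bin-ratio estimates can be inconsistent on noisy
   spectra: `λ` is clamped up to `ξ` (flagged), and `ε` to `[0, 0.5]`.
   `M_{h+1} = 0` yields `ξ = 0` and an "insufficient signal" flag.
4. **Filter and regime.** `m = 1` for estimated `c < 5`, else
   `m = ⌊c/5⌋ + 1`; the threshold 5 is exposed as
   `profile.COVERAGE_THRESHOLD`. The estimated coverage is always used,
   even if the true coverage is known: on repetitive genomes the
   spectrum-based estimate acts as an *effective* coverage and behaves
   better than the nominal one.
5. **Genome length.** `L` = total sequence length / estimated `c`; for
   assemblies, `L` is the assembly length and `η = ζ = 1`, `ε = 0`.
6. **Sketching.** Bottom-s MinHash over a seeded splitmix64 finalizer of
   the packed canonical k-mer (default seed 42, recorded in the sketch;
   sketches with different `k` or seed are never compared). Filtering by
   `m` happens before sketching. The Jaccard estimator is the
   merged-bottom form: among the `s` smallest distinct union hashes,
   count those present in both sketches — unbiased for bottom sketches.
7. **Clamping the distance.** The corrected radicand can leave (0, 1]
   out of model (e.g. a skim against itself): radicand > 1 ⇒ `D = 0`
   with a `clamped_zero` flag; `J = 0` or radicand ≤ 0 ⇒ `D = 1` with a
   `saturated` flag. Flags keep downstream rankings deterministic.
8. **Jukes-Cantor.** `d_JC = −(3/4)ln(1 − 4D/3)` is emitted only on
   request; `D ≥ 3/4` maps to `+inf`.

Defaults (`k = 31`, sketch size `10⁷`, coverage threshold 5, filter rule
`⌊c/5⌋+1`, ℓ taken as the observed mean read length) are the operating
point the estimator was designed around; `k = 21` is fully supported and
used in the analytic worked example.

## Leave-out search metrics

For a query against a reference library, references with ground-truth
distance ≤ `d` are removed; the method's top-ranked remaining reference
sits at ground-truth rank `r`. Rank error is the mean of `r − 1` over
queries; distance error is the mean of `(d_pick − d_best)/d_best`, where
`d_pick` is the ground-truth distance of the method's pick and `d_best`
that of the true best remaining reference. `r` is defined through the
method's *pick* (its top choice located in the ground-truth order); this
is the definition the distance error requires, and the one implemented.
Queries with fewer than two remaining references are skipped with a
warning, and ranking ties are broken lexicographically by name.

## Synthetic data: what it does and does not emulate

The simulator generates i.i.d. uniform ACGT genomes, sibling mutants with
independent uniform substitutions (two mutants at radii `d₁`, `d₂` sit at
expected distance `d₁ + d₂ − (4/3) d₁ d₂`), and skims with uniform read
starts and a flat substitution error rate — exactly the generative model
the estimator assumes. Deliberately absent: indels, structural variants,
repeats, GC-coverage bias, positional/quality-dependent error profiles,
contamination, and organelle over-representation. Passing tests therefore
demonstrate correctness of the estimator *under its own model* and
calibration of the pipeline, not robustness to those real-data artefacts
(a position-dependent error hook and a random-strand flag exist for
stress testing). Real skims also require external quality/contamination
filtering, which is out of scope here.

## Test-scale choices

Tests run on scaled-down but model-faithful conditions: 1 Mb genomes,
ℓ = 100, ε = 0.01, coverage 1/8×–8×, sketch sizes 10³–10⁶ (ample for the
k-mer universes involved; the default 10⁷ is simply never binding at
these genome sizes). Parameter-recovery tolerances are 10% (coverage) and
25% (error rate) at `c ∈ {2,4,8}`; spectrum round-trip sampling recovers
`λ` within 5% and `ε` within 20% for `λ ∈ [2,16]`, `ε ∈ [0.002,0.02]`.

One statistical subtlety: spectrum bin counts are *not* Poisson around
their expectations — a single read couples up to `ℓ−k+1` consecutive
windows, and one miscall spawns up to `k` novel singletons, so per-bin
variance is inflated by clustering. Comparisons of empirical spectra to
model expectations therefore use the conservative cluster bound
`σ_i = sqrt((ℓ−k+1) · E[M_i])` (each independent read perturbs at most
`ℓ−k+1` window counts, bounding the variance by cluster size × mean),
with a 3σ criterion per bin with expectation ≥ 50. A plain `sqrt(E)`
criterion would reject a correct model.

## Known limitations

- Repetitive genomes violate the k-mer-uniqueness assumption; the
  effective-coverage behaviour mitigates but does not remove the bias.
- Distances approaching saturation (`d ≳ 0.2`) and coverages below
  ~1/8× are increasingly noisy; below that the spectrum estimator may
  refuse outright.
- The error model is substitution-only and homogeneous; indel-rich
  platforms are not modelled.
- Sketch files are a private text format, not interoperable with Mash
  `.msh` sketches.
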