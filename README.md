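# skimdist

Assembly-free, alignment-free estimation of the genomic distance between
**genome skims** — low-pass shotgun read sets, typically at or below 1×
coverage, too shallow to assemble.

Genome skims are an attractive, cheap substitute for PCR barcoding in
sample identification and phylogenetics, but the standard k-mer sketching
estimate of distance (Mash-style) assumes the genome is essentially fully
covered. At skim coverage the Jaccard index between two read sets is
depressed by missing k-mers, inflated unions from sequencing errors, and
genome-length differences, so the naive conversion badly overestimates the
distance. `skimdist` corrects for all three effects without an assembly,
a reference, or prior knowledge of the coverage or error rate.

## The model

For k-mer sets of two fully covered, error-free genomes the Jaccard index
`J` satisfies `2J/(1+J) = (1−D)^k`, giving the uncorrected estimate
`D = 1 − (2J/(J+1))^{1/k}`. For skims, each genome `i` is modelled as
sequenced by uniformly placed reads of length ℓ at base coverage `c_i`
with a constant per-base miscall rate `ε_i`; the number of error-free
reads covering a k-mer is Poisson with mean `ξ_i = λ_i (1−ε_i)^k`, where
`λ_i = c_i (1 − k/ℓ)` is the k-mer coverage. This yields per-skim
correction factors

- `η_i = 1 − e^{−ξ_i}` — probability a genomic k-mer is observed
  error-free at least once (with abundance filtering at threshold `m`,
  `η_i = P[Poisson(ξ_i) ≥ m]`),
- `ζ_i = η_i + λ_i (1 − (1−ε_i)^k)` — expected observed distinct k-mers
  per genomic position, erroneous novel k-mers included (`ζ_i = η_i` when
  filtering),

and the corrected estimator

```
D = 1 − (  2 (ζ₁L₁ + ζ₂L₂) J  /  ( η₁η₂ (L₁+L₂)(1+J) )  )^{1/k}
```

with estimated genome lengths `L_i`. Coverage and error rate are
co-estimated from the k-mer abundance spectrum `M_i` (number of distinct
k-mers seen `i` times): with `h = argmax_{i≥2} M_i`,

```
ξ = (M_{h+1}/M_h)(h+1)
λ = (M_1/M_h)(ξ^h/h!) e^{−ξ} + ξ(1 − e^{−ξ})
ε = 1 − (ξ/λ)^{1/k}
```

`J` itself is estimated from bottom-s MinHash sketches (default
`s = 10⁷`, `k = 31`) of the canonical k-mers, after dropping k-mers seen
fewer than `m = ⌊c/5⌋ + 1` times when `c ≥ 5` (low-copy k-mers are almost
surely erroneous at high coverage; at low coverage nothing is dropped and
the `ζ` term absorbs the errors).

## Worked example

```python
import skimdist as sd

# two genomes at true distance 0.05, skimmed at 1x with 1% error
cfg = sd.SimConfig(genome_length=1_000_000, distance=0.05,
                   coverage=1.0, read_length=100, error_rate=0.01, seed=11)
skim1, skim2, truth = sd.make_pair_fixture(cfg)

def pipeline(reads):
    stats = sd.read_stats(reads)
    table = sd.count_kmers(reads, 31)
    prof = sd.build_profile(sd.histogram(table), stats, 31)
    return sd.build_sketch(table, m=prof.m), prof

(sk1, p1), (sk2, p2) = pipeline(skim1), pipeline(skim2)
print(f"estimated coverage {p1.coverage:.2f}, error {p1.epsilon:.4f}")
J = sd.jaccard(sk1, sk2)
print(f"J = {J:.4f}")
print(f"corrected D   = {sd.skim_distance(J, p1, p2).D:.4f}")
print(f"uncorrected D = {sd.jaccard_to_distance(J, 31).D:.4f}")
```

prints

```
estimated coverage 1.12, error 0.0111
J = 0.0284
corrected D   = 0.0505
uncorrected D = 0.0891
```

The spectrum-based estimates land close to the simulated coverage (1×)
and error rate (0.01); the corrected distance comes within ~1% of the
true 0.05 while the uncorrected conversion overestimates it by ~78%.

The same pipeline is available from the shell:

```bash
skimdist simulate --length 1000000 --distance 0.05 --coverage 1 -o sim/
skimdist dist sim/skim1.fq sim/skim2.fq            # tidy TSV to stdout
skimdist reference sim/*.fq -o lib/                # build a search library
skimdist query sim/skim1.fq lib/                   # ranked matches, best first
```

Per-sample estimates (`c`, `ε`, `L`, `m`, regime) are logged to stderr on
every run — they are the hidden quantities the correction depends on.

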