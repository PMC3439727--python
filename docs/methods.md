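# Methods

## Model and assumptions

`matefill` treats paired-end gap filling as repeated local consensus
assembly anchored at a seed read. The core assumptions are:

- **Substitution-dominated errors.** All comparisons are Hamming distances;
  overlaps, cluster policing and the mate check never open gaps. Indel
  sequencing errors (rare on the Illumina-style data the method targets)
  would shift frames and depress the certified fraction, not corrupt it.
- **Sufficient, roughly uniform coverage.** Extension needs at least `m`
  reads overlapping the contig suffix at every step; below ~30× the
  `NO_MORE_EXTENSION` fraction grows quickly.
- **The mate as certificate.** A contig is trusted only if the seed's mate
  occurs in it within Hamming distance `M`. A false certificate requires a
  ~|r|-length near-match at a wrong locus, which on non-repetitive sequence
  has vanishing probability; repeats defeat extension earlier (see below)
  rather than forging certificates.

## Fingerprint index

A window of `b` bases is read as a base-4 integer (A=0, C=1, G=2, T=3, most
significant digit first) and reduced mod the Mersenne number `q = 2^w − 1`.
Equal residues are a necessary condition for equal windows, so the index —
residue → list of (read, orientation) entries — returns a superset of the
true overlap candidates and character-level verification follows. Each read
is indexed twice: on its original strand at window start `x = 0`, and
reverse-complemented at `x = L − b`, which keeps both windows inside the
read's `L`-prefix so one contig fingerprint per orientation serves every
overlap length. With the default `b = 20`, `w = 30`, spurious candidates are
rare (they cost only a wasted Hamming check; correctness never depends on
them). Digit order is a free choice fixed package-wide; `q` need not be
prime. The mismatch-tolerant generalisation of the fingerprint test (witness
sets for `k > 0`) is represented in the parameter type but not implemented:
the assembler itself always uses `k = 0` and tolerates window-external
mismatches through `δ(l)` instead. Windows are hashed independently per
query; a rolling update would be an optimisation with identical output.

## Parameters

| name | default | meaning |
|------|---------|---------|
| `L` | 50 bp | minimum suffix–prefix overlap |
| `Δ` (`Delta`) | 40 bp | overlap slack; lengths range over `[L, L+Δ]` |
| `b` | 20 bp | fingerprint window; larger values suppress mismatched overlaps |
| `w` | 30 | modulus exponent, `q = 2^30 − 1` |
| `δ(l)` | `⌊M·l/|r|⌋` | per-length overlap mismatch budget (`delta_cap` overrides it with a constant) |
| `m` | 2 | minimum reads supporting a consensus position |
| `T1, T2` | 0.6, 0.9 | representation-rate thresholds (must satisfy `0.25 ≤ T1 < T2 < 1`; 0.25 is the floor of π over a 4-letter alphabet) |
| `M` | 10 | mate-check Hamming budget (~10% of a 100 bp read) |
| `Lmax` | insert mean + 3σ | contig length cap; a certified contig slightly longer than the insert is normal, far longer means the mate was missed |

Defaults suit ~100 bp reads; for other read lengths scale `L`, `Δ` and the
`δ` denominator (`avg_read_len`) accordingly.

## Numerical and tie-break choices

- **Consensus ties** (equal top counts at a column) resolve to the character
  contributed by the earliest read under (ascending `I(r)`, then input
  order) — a total-order refinement of "first read encountered, from left to
  right".
- **Duplicate candidates across overlap lengths**: a read surfacing at
  several `l` is kept once, at the largest `l` whose mismatch count passes
  `δ(l)` (the overlap set is a set; the largest overlap carries the most
  evidence).
- **Filtering vs trimming.** A read mismatching the consensus at a
  *low*-represented column is discarded; *non*-represented columns cut every
  surviving read just before them, matching or not. The two rules can be
  composed the other way (treating a mismatch at a non-represented column as
  grounds for discarding too); that composition makes the canonical worked
  scenario (four reads, `T1 = 0.3`) unsatisfiable — a non-represented column
  there is necessarily a four-way split, whose consensus character at most
  one read supports — so the trim-regardless reading is used.
- **Zero-depth columns.** Trimming can leave columns inside `[I(C), F(C)]`
  that no surviving read covers. Inside the existing contig such a column
  carries no new evidence and the contig's base stands; beyond the contig
  end nothing can be fabricated and the new consensus is truncated there.
  Without the first rule a single sequencing error at a depth-2 column deep
  inside the overlap window would kill the whole extension (observed as
  spurious `REPEAT_FOUND` on ~11% of noisy-library seeds).
- **Stop-label attribution.** A halt computed on the raw overlap set (no
  candidates, or no position reaches depth `m` beyond the contig end) is
  `NO_MORE_EXTENSION`; a halt after filtering, when the raw set was viable,
  is `REPEAT_FOUND`. The mate check runs before the `Lmax` check, so a
  contig that both contains its mate and exceeds `Lmax` is `MATE_FOUND`.
- **Mate orientation.** For the default forward–reverse library the mate is
  reverse-complemented before scanning (it must appear on the contig
  strand); `ff` scans it as sequenced; `rf` reverse-complements seed and
  mate, reducing the outie geometry to `fr`.
- **Degenerate inputs.** Reads with non-ACGT characters are rejected before
  packing (2 bits/base) and counted; reads shorter than `L` are excluded
  from the index and counted; a seed shorter than `L` simply finds no
  overlaps and stops as `NO_MORE_EXTENSION`.

## Repeat behaviour

Inside an exact repeat, reads from all copies agree, so extension proceeds
with correct (copy-ambiguous but character-identical) sequence. At a repeat
*exit*, reads from different copies disagree beyond the junction; those
columns drop to `π ≈ 0.5 ≤ T1`, every read is cut at the junction, and the
step fails with `REPEAT_FOUND`. When local coverage is skewed toward one
copy the junction column can classify as low- rather than non-represented;
the minority reads are then dropped and extension follows the majority copy
— the mate is no longer findable, so such contigs end `LENGTH_EXCEED` or
`REPEAT_FOUND`, never as a certified chimera. This is why seeds whose insert
sticks out past a repeat exit overwhelmingly fail closed instead of
producing certified crossings.

## Simulator

The generator emulates a fragment-library experiment: inserts of Gaussian
length (truncated to `[2·read_len, |G|]`) at uniform starts on a uniformly
random strand; forward–reverse read pairs off the insert ends;
independent per-base substitutions at a uniform rate, drawn from an RNG
stream separate from the geometry stream so the same seed yields identical
inserts at any error rate. Every pair's truth record (strand, insert locus,
seed coordinate, exact error positions) supports exact-locus validation.
Not modelled: position-dependent error profiles, indel errors, chimeric
pairs, quality-string realism, GC-coverage bias. Passing tests on this
generator therefore demonstrate the algorithm's behaviour under its own
assumptions (substitution noise, uniform coverage); on real libraries the
certified fraction depends additionally on upstream trimming/correction
quality, which is out of scope here (only the non-ACGT filter is provided).

## Validation

Correctness of a contig is decided by local alignment (match +1, mismatch
−1, indel −2, linear gap costs — `biotite`'s optimal aligner, cross-checked
against a textbook dynamic program in the tests) against
`G[x, x + |S| + g − 1]`, where `x` is the seed's recorded locus and
`g = ⌈3|S|/200⌉` the indel budget; the contig is correctly aligned when best
score / |S| ≥ 0.95 (≈5 mismatches, or 3 indels, per 200 bp). Reverse-strand
seeds grew leftwards on the reference strand: their contigs are
reverse-complemented and the window is anchored at the seed's 3′ coordinate.
Windows clamp at genome ends and never wrap; the best score anywhere in the
window counts (end-anchoring is not required). Trusted×aligned cross-tabulates
into TP/FP/FN/TN, and the union of aligned trusted loci gives the covered
genome fraction.

## Problem sizes used by the test suite

The end-to-end tests run a 50 kb genome at 50× (12,500 pairs), seeding every
pair for the error-free experiment (the uncovered-fraction statistic is an
all-seeds property; a 500-seed subset of the same deterministic run checks
the per-seed recovery rate) and 500 seeds for the 0.5%-error experiment; the
repeat experiment plants two exact 2 kb copies in 12 kb at 40×. These sizes
exercise every code path at bacterial-genome-like coverage while keeping the
suite in the minutes range.

## Known limitations

- Gapped overlaps are out of scope by design; high indel-error data
  (long-read chemistries) is unsuitable.
- Quality scores are read but ignored beyond the non-ACGT filter; there is
  no quality-weighted consensus.
- The certified fraction degrades below ~30× coverage, and `m`, `T1`, `T2`
  interact with coverage; the defaults assume tens-fold coverage.
- Extension is sequential per seed; the contract is purely functional, so
  any parallelisation must be observationally identical to the sequential
  loop.
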