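# Methods

This note documents the models, parameter choices, and numerical
conventions behind `ervkit`, and what the synthetic-data tests do and do
not demonstrate about real genome-derived data.

## Provirus model and structural validation

A full-length provirus is modeled as LTR–PBS–leader–gag–pro–pol–env–
spacer–LTR. Structural validation rests on three signals:

* **Terminal direct repeats.** `extract_ltrs` seeds candidate diagonals
  by exact 20-mer matches between the head and tail of the sequence,
  scores each diagonal's self-comparison with +1/−2 (match/mismatch), and
  takes the maximum-sum window (Kadane). Boundaries are then anchored on
  a run of 4 consecutive matches so isolated chance matches in the flanks
  (probability 0.25 each) cannot stretch the span. Defaults: minimum
  length 400 nt, minimum identity 0.85, terminal anchoring within 10% of
  each end — bounds chosen from observed LTR length statistics (mean
  ~484–486 nt, range 439–495 nt) with slack for deletion variants. The
  k-mer seeding assumes substitution-only divergence between the copies,
  which holds for LTR pairs young enough to be worth dating. Exact repeat
  pairs are recovered exactly; at 2% divergence spans are recovered to
  within a few nt, because a mutated terminal base makes the true
  boundary unknowable in principle. Boundary trimming changes the
  between-LTR K2P distance by well under 1% (checked explicitly in the
  acceptance suite).
* **Target-site duplication.** Integrase duplicates the host 6-mer at the
  insertion point. `detect_tsd` requires exact 6/6 identity between the
  two flank 6-mers: the duplication is treated as binary evidence, and
  fuzzy matching would fabricate evidence on mutated flanks.
* **Assembly-error screen.** A record is `suspect_assembly` when its
  5′–3′ LTR distance exceeds 3× the cohort median within-provirus LTR
  distance, exceeds an absolute cap of 0.15, or saturates the K2P
  correction outright (a shuffled or foreign LTR sits near the random
  expectation of 75% mismatch, where Q ≈ 0.5 and the correction has no
  value). The 3×-median multiple and the cap are declared package
  defaults — the underlying idea ("the two LTRs do not cluster") has no
  canonical numerical form. The median-multiple rule is skipped when the
  cohort median is 0, so a cohort of young identical-LTR proviruses
  cannot flag a modestly diverged genuine record.

## PBS classification

The 18 nt immediately 3′ of the 5′ LTR is compared to the two tRNA-lys
references (lys3 `TGGCGCCCGAACAGGGAC`, lys1,2 `TGGCGCCCAACGTGGGGC`) by
Levenshtein distance (edlib, global mode), not Hamming distance, because
single-nucleotide PBS insertions are a documented escape variant and must
classify correctly; when a 19 nt window fits both references strictly
better than the 18 nt window, the extended window is reported with its
insertion variant. Equal distances yield `ambiguous` rather than an
arbitrary label. Genotype assignment is deliberately *not* based on the
PBS (PBS switching between genotypes occurs); it is nearest-exemplar K2P
distance with a 0.01 tie margin resolving to `unassigned`.

## Distances

K2P separates transition proportion P from transversion proportion Q;
the gamma variant K = a/2[(1−2P−Q)^(−1/a) −1] + a/4[(1−2Q)^(−1/a) −1] is
exposed with no default shape: published distance tables in this domain
used gamma-distributed rates without printing the shape (the companion
tree used 0.3608), so both plain and gamma modes are available and the
shape is a config knob. Gap policy follows the two conventions in use:
pairwise deletion for cohort matrices, complete deletion for small
cross-species LTR sets. N counts as missing everywhere, including the
95% column-coverage filter (the "partial deletion" language groups gaps,
missing data and ambiguous bases together). The transition/transversion
ratio is the pooled count ratio over all pairs — an observed-count
approximation, not the ML estimate printed by phylogenetics packages —
and is validated only by recovery of simulated ts:tv biases.

## Dating

T = K/(2r) with r bracketed by 5×10⁻⁹ and 2.3×10⁻⁹ s/s/y. CpG sites are
*included* in the LTR distance: in heavily methylated proviruses they
carry most of the divergence, and removing them would discard the signal
(at the cost of an upward age bias, quantified below). K = 0 is reported
as "<0.3 Myr", the resolution of one substitution in a ~485 nt LTR at the
fast rate (1/485/(2·5×10⁻⁹) ≈ 0.21 Myr, rounded to the conventional
band). Event ages (shared-integration dating, TMRCA of species splits)
average *unrounded* component ages and round only in reports; this
reproduces the published event averages (e.g. 7.2/8.4/7.5 → 7.7) exactly,
which rounding components first does not.

## Mutation signatures

The hypermutation scan generalizes the HYPERMUT settings. A pattern is
`upstream-(from>to)-downstream` with IUPAC contexts of arbitrary length,
so both the one-base (`K-(G>A)-D`) and two-base (`D-(G>A)-AD`) readings
are expressible. Conventions, matching the "enforced context" mode of
the original tool:

* contexts must match on both reference and query, so a neighboring
  query mutation disqualifies a site;
* gap columns in either sequence are removed before scanning — a context
  interrupted by a gap does not match;
* the control arm is made disjoint from the primary arm (control context
  minus primary-context sites); overlapping arms would double-count
  every primary site;
* enrichment is the one-sided hypergeometric upper tail on
  [[mm, mp−mm], [cm, cp−cm]]; two-sided testing (used for ORF-fraction
  comparisons) sums outcomes with probability ≤ observed. Both are
  scipy-backed; the test suite checks the one-sided tail against direct
  combinatorial enumeration for every 2×2 table with total ≤ 60.

The CpG census does not use a mutation-pattern control (the published
control setting for it is not a well-formed pattern); it enumerates CpG
dinucleotides on the reference directly, reads the query state at each
site (TpG, CpA, other, intact), and skips sites where the query is
gapped or ambiguous. The TpG:CpA strand split near 1 indicates
orientation-independent methylation.

## Tajima's D

Computed on difference counts per alignment (not per site) with complete
deletion, matching the common implementation for this statistic; the
standard a₁…e₂ constant cascade is used. S = 0 leaves D undefined but
still reports S and π. n < 4 warns rather than errors (small
per-genotype ORF sets are legitimate); n ≤ 3 additionally leaves D
undefined because the variance approximation collapses to zero there.

## Synthetic endogenization model

The generator's defaults are the study conditions: provirus 8,393 nt,
LTR 485 nt, PBS lys3 (genotype-1 profile) or lys1,2 (genotype-2),
genome-wide CpG target 198 (genotype-1) or 144 (genotype-2) ± 5%, base
rate 5×10⁻⁹ s/s/y, CpG transition rate 1.6×10⁻⁷ s/s/y per CpG base, TSD
6 nt, ts:tv weighting 4:1 (the transversion spectrum is not constrained
by data; 4:1 is a modeling default matching the observed transition
bias). Regional base composition follows the type D profile: A-rich,
G-poor coding regions (gag/pol ~33% A, env ~30% A) and a GC-richer,
promoter-like LTR (~23% A). Coding regions are generated base-wise and
repaired to open reading frames; CpG density is tuned only in the
internal region so the LTR copies stay identical (planting CG pairs or
relaxing the G of a CpG to A can be shown never to create a stop codon,
so tuning preserves ORFs).

Evolution is per-site Bernoulli per epoch (10 epochs) with probability
r·Δt — a Poisson approximation chosen over a Gillespie scheme because
r·T ≤ 0.1 in all default regimes, making the error negligible and the
mutation log trivially replayable. CpG hotspot status is re-evaluated
each epoch against the current sequence, so destroyed CpGs stop being
hotspots (mutated CpGs are a historical record, not an ongoing process).
Deamination is strand-symmetric: the C of a CpG takes C→T, the G takes
G→A, each at the full hotspot rate. APOBEC editing is applied once,
before integration (the enzyme acts on replication intermediates), with
context evaluated on the pre-edit sequence — this makes the episode
order-independent. The default editing context is the first G of a GG
dinucleotide (the APOBEC3G plus-strand signature). Host background is
i.i.d. uniform unless a host sequence is supplied. Indels are not
simulated by default; recombination, solo-LTR formation and selection
are out of scope.

## What the synthetic tests show — and what they cannot

Passing the simulation suites demonstrates internal consistency: the
clock converts back to planted ages (mean of 50 replicates within 15% at
1/3/8 Myr with hotspots off; E[K] ≈ 2rT at 3 Myr), APOBEC episodes at
0.3 efficiency are detected with ≥ 98% sensitivity at ≤ a few percent
neutral false-positive rate, and planted TSD/PBS/CpG fractions round-trip
exactly on undamaged loci. With CpG hotspots *on*, fast-rate ages are
biased upward several-fold — reproducing, deliberately, the real
difficulty of rate choice for methylated ERVs. The simulator does not
emulate alignment error, assembly artifacts, indel processes, recurrent
ancestral polymorphism, or the phylogenetic correlation structure of a
real cohort, so quantitative agreement with genome-derived values
(per-species CpG fractions, ML ts/tv estimates, per-provirus Fisher
p-values, the published Tajima range) is out of reach by design; those
quantities are covered by property checks only.

## Numerical conventions

Coordinates are 0-based half-open internally, 1-based inclusive in all
reports. Consensus ties are called N (never a base, so the CpG census
cannot inherit a fabricated mutation direction). Saturated distances
raise rather than return NaN, except in matrix context where the pair
becomes a missing cell. All cohort randomness descends from one master
seed through spawned generators; the same seed reproduces cohorts
byte-identically.
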