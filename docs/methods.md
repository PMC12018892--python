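# Methods

## Scope and model

`nestkin` estimates the breeding structure of a nesting population from
genotyped hatchlings only. Three data layers are combined:

1. **Nuclear SNP kinship.** Pairwise identity by state (IBS) over a
   filtered biallelic SNP panel, scored per site as 1 (same genotype,
   including het-het), 0.5 (one shared allele), 0 (opposite homozygotes),
   averaged pairwise-complete over the sites called in both samples. The
   raw value is rescaled to `normalized = (raw − av_min)/(1 − av_min)`,
   where `av_min` is the mean raw IBS over all cross pairs of the two most
   distinct groups (families or nests) in the dataset. The baseline is
   dataset-relative by design: it removes the chance allele sharing of a
   common gene pool, so the same pair can score slightly differently in a
   different dataset context. Values below the baseline are reported as
   negative, never clipped.
2. **Matrilines.** Four-locus AT-dinucleotide repeat haplotypes from the 3'
   end of the mtDNA control region, written as barcodes such as `6-8-8-4`.
   Maternally inherited: full siblings must share a barcode; identical
   barcodes do **not** imply one female (matrilines persist for
   generations), but different barcodes exclude a shared mother.
3. **Nest metadata.** One female lays each nest; within a season a female
   lays several clutches roughly two weeks apart; she returns to nest after
   multi-year remigration intervals; nest sites are philopatric.

### Analytic expectations

With Cotterman coefficients (k0, k1, k2) and site allele frequency p
(q = 1 − p), exhaustive enumeration of the nine genotype-pair combinations
under Hardy-Weinberg and Mendelian transmission gives

    E[IBS | 2 IBD] = 1
    E[IBS | 1 IBD] = 1 − pq
    E[IBS | 0 IBD] = ½ (1 + (1 − 2pq)²)

Taking the unrelated expectation as the baseline, the expected normalized
IBS over a site panel is `k2 + k1·n̄₁`, with
`n̄₁ = Σ pq(1−2pq) / Σ 2pq(1−pq)`. Both the enumeration and the closed form
ship in `kinship_ibs` and are cross-checked to 1e-12 in the tests; the
closed form is what `expected_normalized_ibs` uses. On a MAF spectrum
uniform over [0.05, 0.5] this puts full siblings near 0.44, half siblings
near 0.19, parent-offspring near 0.37 and unrelated pairs at 0.

### Kinship bands

Classification thresholds (`KinshipBands`) default to full-sib ≥ 0.38,
half-sib [0.15, 0.38), distant kin [0.05, 0.15), unrelated < 0.05 —
midpoints between typical empirical band means. There is no universal
threshold (band positions move with founder relatedness and the frequency
spectrum), so all cut points are configuration, and values within ±0.03 of
a boundary are flagged ambiguous.

### Sibship clustering and parent rules

Full-sib groups are connected components of the graph whose edges are pairs
at or above the full-sib threshold. A component containing a pair below
`full_sib_min − 0.03` is split by average linkage until consistent; if the
split halves still cross-match at full-sib level the groups are flagged
`unresolved` rather than silently assigned. Cross-group means inside the
half-sib band become half-sib links. Parents are then enumerated minimally
under a fixed rule order: (R1) one female per nest; (R2) a full-sib group
spanning nests implies the same mother and father for those nests; (R3) a
within-nest half-sib link is multiple paternity (one mother, two fathers);
(R4) a cross-nest half-sib link with identical barcodes and compatible
dates is read as the same female remating — flagged ambiguous, since a
shared father would also explain it; (R5) a cross-nest half-sib link with
different barcodes can only be a shared father. Same-barcode links with
incompatible dates (same season, clutches further apart than the
internesting window, default 30 days) fall through to the paternal reading;
links touching nests with missing dates are recorded but never merged.
Mothers are brute-force-verifiably minimal on small instances (see tests).
Father labels (M01…) are synthetic: males are equivalence classes of
paternal evidence, never observed.

### Evidence-scaled merge guard

Pair values and cross-group means carry sampling noise that scales as
1/√(marker overlap). Merges are therefore gated on a conservative standard
error: per-site score variance is bounded by 0.25, so a pair's SE is
`√(0.25/n_overlap)/(1 − av_min)`, and a link's SE divides that by the
square root of the smaller group. A full-sib edge must also exceed the
half-sib threshold by z·SE, and a cross-nest merge (R4/R5) must exceed the
distant-kin floor by z·SE, with z = 4. At 2,000+ SNPs these guards sit far
below the band gaps and change nothing; with very sparse panels (hundreds
of SNPs) they make the method degrade by over-flagging — splitting groups
and refusing merges — rather than by wrongly merging parents. On the
default synthetic scenario at 200 SNPs this yields inflated parent counts
with zero wrong merge pairs.

### Permutation confidence intervals

Pairwise values are not independent, so within-group means are tested by
permutation: sample labels are permuted preserving group sizes (default
1,000 permutations), the pooled within-group mean recorded each time, and
the 95% CI taken as the empirical 2.5/97.5 percentiles. Calibration under a
null of randomly assigned groups is checked in the acceptance suite
(coverage 95% ± 2% over 500 replicates).

## Filtering

`apply_filters` codifies the standard vcftools/Stacks post-processing order
explicitly, since the flags alone do not fix semantics: (1) per-genotype
depth outside [dp_min, dp_max] (inclusive, defaults 10/120) masks the call;
(2) sites with mean depth out of bounds are dropped; (3) sites genotyped in
fewer than `locus_presence_r` (default 0.6) of individuals within any
population, or with overall missingness above `max_missing_fraction`
(default 0.2), are dropped; (4) minor allele frequency below `maf_min`
(default 0.05), computed on the calls surviving step 1, drops the site.
Filtering is idempotent and the per-step counts sum to input − output.
Multi-allelic and non-SNP records are dropped (and counted) at read time.

## mtSTR barcoding

The four repeat loci are located as the four maximal runs of the `AT` dimer
of at least three dimers, in sequence order on the forward strand; no
published flank anchors exist for a reference-free locator, so this rule is
the default and real amplicons with interrupted repeats should be checked
against the barcoding literature. Heteroplasmy is resolved per locus by
relative peak height: the major count is the argmax, a minor allele is
called when a secondary peak reaches `noise_floor` (default 0.2) of the
major, and an exact height tie is an error rather than an arbitrary call.

## Synthetic data generator

The generator exists so every downstream stage is testable with known
truth. It emulates: unrelated founders in Hardy-Weinberg proportions over a
post-filter MAF spectrum (uniform [0.05, 0.5] by default); Mendelian
transmission with unlinked sites; per-genotype missingness (default 5%) and
read depths ~ N(40, 17) truncated at 0; matrilineal barcodes (optionally
heteroplasmic); polyandry within clutches; sperm storage across a season's
clutches; one father shared across two matrilines; 1-4 clutches per season
8-23 days apart; 3-4 year remigration; philopatric placement on a
one-dimensional 150 km coastline (Gaussian scatter, SD 5 km) with rare
(p = 0.02) 60-90 km displacements.

Two scenario modes:

- **default** — a fixed structured plan sized like a two-decade nesting
  survey: 35 females, 59 males, 60 mating events, 84 nests, 257 sampled
  hatchlings; 18 nests have more than five sampled hatchlings and exactly 6
  of them (one third) are multi-paternal (10 multi-paternal nests overall);
  one male sires clutches of two matrilines three years apart; the female
  composition spans five barcodes (19/3/5/7/1 across 6-8-8-4, 6-8-9-4,
  6-9-6-4, 8-7-7-4, 8-7-8-4). Randomness is confined to genotypes, dates,
  coordinates, missingness and depths, so recovery tests have exact count
  targets. Recovery tests run this plan at 2,000 SNPs — comfortably inside
  the regime where the band gaps dwarf sampling noise — rather than at the
  full 12,795-SNP default panel size.
- **random** — the pedigree structure itself is drawn from the configured
  rates (polyandry probability per clutch, default 1/3, the
  detectability-corrected estimate from well-sampled nests; recurrence
  probability 0.3; clutch and sampling ranges). This mode drives the
  distributional property tests (e.g. empirical polyandry fraction within
  its binomial CI).

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real data: founder relatedness and historical
inbreeding (founders are exactly unrelated, so band positions are cleaner
than in a population with background kinship), linkage between sites,
genotyping error beyond missingness, mtSTR mutation between generations,
unsampled nests, and uneven spatial survey effort. Real-data band means
(e.g. full-sib ≈ 0.50 on the breeding-stock panel) shift with the actual
frequency spectrum and founder structure; the reproducible surface is the
band ordering, the unrelated mean of 0.00, and agreement with the analytic
expectation under the generator's assumptions.

Identical config + seed reproduces byte-identical outputs (VCF, CSVs,
truth JSON).

## Numerical and design choices

- Missing data: IBS is pairwise-complete; pairs sharing fewer than
  `min_overlap` (default 100) called sites are masked with a warning, and
  the per-pair overlap matrix is part of the result for audit.
- Baseline: ties between candidate group pairs break lexicographically and
  are logged. The reconstruction pipeline restricts baseline candidates to
  nests with ≥ 5 sampled hatchlings (falling back to all nests when fewer
  than two qualify): `av_min` is a minimum over group-pair means, and
  single-pair "means" would bias it low. `av_min` can be frozen explicitly
  to compare across datasets.
- Ratio formatting: the female:male ratio truncates (not rounds) to two
  decimals, e.g. 59/35 = 1.6857 → `1:1.68`.
- Seasons are calendar years; remigration uses year arithmetic, matching
  how recurrent nesting is tabulated in the field.
- Distances are haversine on a 6371 km sphere; at the ≤ 90 km scales of
  nest-site fidelity, ellipsoidal corrections are negligible (checked
  against spherical law of cosines to 1e-6 km).
- Degenerate inputs: a single labelled group cannot anchor a baseline
  (explicit `av_min` required); `av_min ≥ 1` is an error; an all-missing
  sample is flagged and excluded from heterozygosity summaries; empty
  filter output warns rather than errors.

## Known limitations

- Thresholded band classification is not a likelihood: with few hatchlings
  per female or related founders, full-sib vs half-sib separation degrades
  and the ambiguity flags should be inspected rather than the counts taken
  at face value.
- R4 is genuinely ambiguous: a same-barcode cross-nest half-sib link is
  counted as one female remating (the reading consistent with how recurrent
  nesting is tabulated), and the paternal alternative is retained in the
  output for audit.
- The minimum female census is a lower bound; it rises one-for-one with
  matriline barcodes observed in nests but absent from the genotyped
  sample, supplied as an explicit input.
- Parent counts are minimal consistent enumerations, not probabilistic
  estimates; two unlinked singleton nests of one female will count as two
  females.
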