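# Methods

This note documents the models and procedures implemented in `fawkit`,
the assumptions they make, the defaults and why, and what the
synthetic-data generator does and does not emulate.

## Diagnostic-site classification

Strain identity in fall armyworm is read off single-nucleotide markers
rather than inferred from full phylogenies. The rules are:

| marker | base | call |
|---|---|---|
| COI 1164 | T | rice strain (RS) |
| COI 1164 / 1287 | A/A, A/G, G/A, G/G | corn-strain h1, h2, h3, h4 |
| Tpi 183 | C / T / Y | TpiC / TpiR / TpiH (heterozygote) |

Classification is a total function: every specimen with a located
segment maps to exactly one COI class in {RS, h1–h4, unclassified} and
one Tpi class in {TpiC, TpiR, TpiH, unclassified}. Bases outside the
observed alphabets (anything but A/G/T at 1164, A/G at 1287, C/T/Y at
183, including N and gaps) are unclassified with a recorded reason.
The combination T₁₁₆₄G₁₂₈₇ has never been observed in field data; the
T₁₁₆₄-defines-RS rule is kept primary and the call is RS with a
data-quality warning rather than a rejection.

Segment location replaces a multiple-alignment step: amplicons are
curated single reads, so the diagnostic window is anchored by an
exhaustive ungapped scan maximizing exact identity against the
reference window. The acceptance threshold is 0.80 identity — low
enough to tolerate realistic within-species divergence plus ambiguity
codes, far above the ~0.25 expectation for an unrelated sequence.
Below it the specimen is excluded from that locus's denominators (and
reported), never guessed.

Intron frameshift heterozygotes: a male heterozygous for an intron
indel produces overlapping chromatograph traces from the indel onward,
which after base calling surfaces as a long run of ambiguity codes.
The desk proxy implemented here flags a run of ≥ 6 consecutive
ambiguity codes starting inside the intron (run length configurable).
Flagged records are excluded from haplotype-network input, since their
called sequence is not a real haplotype. This proxy cannot see indel
heterozygotes whose traces were manually resolved, and it will flag
any other cause of a long ambiguity run; both error modes are conservative for
network purposes.

## Z-linked chromosome estimation

*Tpi* sits on the Z chromosome: males are ZZ, females ZW. Unsexed
larvae therefore carry 1 + m copies on average, where m is the male
fraction (1.5 at the 1:1 default). Chromosome counts are estimated
from genotype classes as

    est_C = (1 + m)·nTpiC + nTpiH
    est_R = (1 + m)·nTpiR + nTpiH

and allele frequencies are always reported on estimated chromosomes.
At m = 0.5 the identity est_C + est_R = 1.5(nTpiC + nTpiR) + 2·nTpiH
holds exactly and is tested exactly. m is exposed so the 1:1
assumption itself can be stress-tested; the default stays 0.5.

**Known property: this estimator is exactly unbiased for the allele
frequency only at p = 0.5.** Taking expectations of the genotype-class
counts under random mating and a 1:1 sex ratio gives

    E[est_R] / E[est_C + est_R] = (1.75p − 0.25p²) / (1.5 + 0.5p(1−p)),

which equals p only at p = 0.5 (where C/R exchange symmetry forces
it). The class-count weighting ignores that an observed
homozygous-class specimen is more likely female than male, so a minor
allele is slightly overestimated: at p = 0.05 the estimator converges
to 0.0570 rather than 0.0500. The parameter-recovery suite therefore
checks unbiasedness at p = 0.5 and separately verifies that the
simulated small-p bias matches the analytic value above. For the
strongly skewed frequencies typical of corn-field collections (> 95%
TpiC) the absolute distortion is under one percentage point and does
not affect qualitative conclusions.

The TX/FL contrast (h4−h2)/(h2+h4) is reported as a raw number in
[−1, 1]; the cutoff separating the two geographic types has only ever
been shown graphically, so group labelling is applied only when the
caller supplies a threshold.

## Distances, trees, networks

**TN93.** The Tamura–Nei (1993) distance is computed from the closed
form using the empirical base frequencies of each pair, with pairwise
deletion of sites where either sequence carries a non-ACGT code
(complete deletion available at the matrix level). Saturated pairs
(logarithm of a non-positive argument) raise an explicit error rather
than returning a truncated value.

**Neighbor joining** is Saitou–Nei with two determinism contracts:
Q-criterion ties break at the lowest (row, column) index pair, and
negative branch-length estimates are clamped to zero with the deficit
moved to the sibling branch of the join (preserving the joined pair's
path length). On additive matrices the output tree metric reproduces
the input to 1e-9, which the suite verifies against randomly generated
trees and a least-squares topology-enumeration oracle.

**Haplotype networks.** Identical aligned haplotypes collapse into
nodes carrying total and per-site counts (ordered by count then
sequence — a determinism contract). Edges use mutational steps:
substitutions per column plus one step per maximal gap run, i.e. an
indel of any length is one event — consistent with treating intron
indels as single mutations; the per-base alternative was rejected
because it would make indel length, which is noisy, dominate the
network. The network itself is the epsilon = 0 minimum-spanning
network: Kruskal grouped by weight level, keeping every edge at a
level that joins components distinct when the level began, so tied
minimum alternatives are all retained. This is a deliberate,
documented substitute for 95% statistical parsimony: it is
deterministic, oracle-testable, and preserves the qualitative contrast
the analysis needs (within-cloud edges of 1–2 steps versus
between-cloud separations of ≥ 8 steps); it omits the parsimony
connection limit, so very distant clouds remain connected rather than
splitting into components.

Great-circle distances use the haversine formula on a 6371-km sphere;
the anchor site for distance annotations is a parameter, since a
multi-locality province has no single canonical anchor point.

## Simplified ecoclimatic index

The published parameter set (temperature thresholds DV0–DV3 = 12, 25,
30, 39 °C; soil-moisture thresholds SM0–SM3 = 0.15, 0.8, 1.5, 2.5;
cold/heat/dry/wet stress thresholds 12 °C, 39 °C, 0.1, 3 with weekly
rates 0.001, 0.005, 0.005, 0.002; PDD = 600 °C-days) comes with a
verbal model description but no equations, so the functional forms
here are explicit choices:

- weekly temperature and moisture indices are trapezoids on their four
  thresholds (0 outside, 1 on the optimal plateau, linear ramps);
  GI = 100 × the annual mean of their product;
- each stress accumulates |rate| × deficit × 100 per week past its
  threshold, capped at 100/year; signs printed on the cold and dry
  rates are treated as display conventions and magnitudes are used;
- degree-days = Σ max(0, T − DV0) × 7 over the 52 weeks; an annual
  total below PDD gates EI to 0 (a generation cannot complete);
- EI = GI × Π(1 − S/100), clipped to [0, 100].

This is a simplification of the commercial model it mimics: no stress
compounding over time, no internal soil-moisture hydrology (soil
moisture is a direct input supplied by the caller or the generator),
no irrigation or climate-change scenarios. Outputs are labelled "EI
(simplified)"; for marginal habitats the linear stress rule will
diverge from published outputs of the commercial model, and no attempt
is made to tune it toward them. The invariants that do hold exactly —
EI ∈ [0, 100], EI = 100 iff GI = 100 with zero stress and the
degree-day gate passed, continuity at all eight trapezoid breakpoints,
stress monotonicity — are tested. Both favorability conventions are
emitted (EI ≥ 30 favorable; EI ≥ 33 map shading), since the published
maps use the latter for display while citing the former.

## Synthetic data: what it emulates and what it does not

The generator stands in for undeposited field sequences and
unavailable gridded climate:

- **References** (`make_references`, fixed seed 20190919 for the
  bundled files): a random COIB amplicon backbone; corn- and
  rice-strain consensus differing at the 1164-equivalent site (plus
  five non-diagnostic sites, ~2% divergence); 13 panel taxa at 6–12%
  divergence from the corn-strain window with one deliberately
  identical pair (mirroring a documented identical pair of true
  species); *Tpi* corn and rice alleles differing at the 183 site plus
  two intron sites. Every diagnostic relationship the classifier
  relies on holds by construction. Amplicon geometry (340 bp COIB,
  300 bp Tpi, window offsets in `marker_offsets.cfg`) is synthetic and
  does not reproduce genomic numbering.
- **Populations**: per-specimen sex drawn at the configured male
  fraction (default 0.5, the study assumption); COI class drawn from
  site-level probabilities and instantiated as diagnostic bases on the
  strain backbone plus ≤ 2 non-diagnostic substitutions (default,
  matching the observed within-site similarity of at most two
  mutations to the closest variant); female *Tpi* haploid, male *Tpi*
  two independent allele draws with differing positions encoded as
  IUPAC codes; optional fraction of males given an 8-long intron
  ambiguity run to exercise the frameshift-heterozygote exclusion.
  Sex is latent (truth table only), as field larvae are unsexed.
  Default site mixtures (h4-dominant corn strain, ~2% rice allele)
  echo the strongly corn-strain, TX-type pattern reported for the
  region's corn fields.
- **Isolation**: private haplotypes built at exactly the programmed
  number of steps (default 8, the reported minimum between the
  isolated island population and mainland collections; default 7
  private haplotypes likewise mirrors the reported count) from the
  mainland base haplotype, using a position pool disjoint from all
  other mutation pools so programmed distances are exact, then 1–2
  extra steps per additional private haplotype.
- **Climate**: incubator (27 °C / 1.0 every week), frozen (4 °C),
  sinusoidal seasonal, and seasonal-plus-noise profiles, and small
  mixed grids with missing cells.

Not emulated: realistic mtDNA mutation processes or coalescent
genealogies, sequencing error, chromatogram-level artifacts, indel
length variation in the intron beyond the single-event convention, and
real gridded climatologies. Passing tests therefore demonstrate that
the pipeline's logic is correct under its stated assumptions, not that
those assumptions hold for any particular field dataset.

## Problem sizes and numerical choices

The parameter-recovery suite uses 200 replicates of n = 1000 specimens
(binomial standard errors small enough to detect sub-percent bias);
oracle suites use 100 random 5-taxon additive matrices and 1000 random
sequence pairs at agreement tolerances of 1e-9 (tree metric) and 1e-12
(TN93). Distance matrices require symmetry, zero diagonal and finite
entries at construction. All simulation entry points take explicit
seeds and are bit-reproducible per seed.
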