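# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `ovismap`, including what the synthetic-data
generator does and does not emulate.

## Phased-meiosis likelihood

The unit of observation is one parent→offspring transmission at one
marker. A transmission is **informative** when the parent is typed and
heterozygous and the transmitted allele is uniquely determined from the
offspring genotype, using the other parent's genotype where needed. When
the parent's own parents resolve which of its two haplotypes carries the
transmitted allele, the transmission additionally carries a
**grandparental-origin** indicator and is *phase-known*; otherwise the
transmitted allele is recorded against an arbitrary but fixed anchor
labelling of the parent's two alleles and the transmission is
*phase-uncertain*.

For a marker pair, phase-known meioses contribute θ^R (1−θ)^(N−R) with R
origin switches in N meioses. A phase-uncertain parent's offspring share
one unknown phase, so the parent contributes the equal-prior mixture
½[θ^r (1−θ)^(n−r) + θ^(n−r) (1−θ)^r], where r counts anchor switches
among its n doubly-informative offspring. The anchor labelling is
phase-symmetric, so the mixture is exact for a single linked pair under
random phase.

This is deliberately **not** a full multigeneration pedigree likelihood
(Elston–Stewart peeling, as inside CRI-MAP). It is exact for phase-known
meioses, treats each phase-uncertain parent's nuclear family exactly, and
ignores cross-generational phase propagation beyond the grandparental
step. In three-generation pedigrees most meioses phase-resolve and the
approximation is tight; its residual effects are visible as mild
overdispersion of two-point LODs between unlinked markers (see Grouping).

**Multipoint likelihood of an order.** Within each meiosis, switch events
are counted between consecutive *informative* markers and attributed once
to that nearest-informative-flank pair — no fractional allocation across
the spanned intervals. The order's score is the sum over observed flank
pairs of the profile (per-pair maximised θ) log₁₀-likelihood, with
phase-uncertain parents entering through the mixture as above. The score
is reported absolutely (no θ = 0.5 baseline), so for two markers it equals
the two-point LOD plus log₁₀ L(0.5). It is invariant under whole-order
reversal. Per-interval estimates in the fixed-order stage use only
meioses whose nearest informative flanks are exactly that interval's two
markers; spanning observations are excluded because their switch
probability composes several intervals and would bias single-interval θ
upward.

**θ maximisation.** Pure phase-known pairs use the closed form θ̂ = R/N
(capped at 0.5). Pairs with mixture terms use a 41-point coarse grid on
[0, 0.5] followed by golden-section refinement to 10⁻⁶, with endpoint
checks; the maximiser is validated in the tests against a 10⁻⁴ brute-force
grid. θ̂ within 10⁻⁶ of 0.5 is reported as unlinked (undefined cM).

## Pipeline stages and their parameters

| stage | parameter | default | why |
|---|---|---|---|
| grouping | LOD threshold | 4 | conventional genome-wide-safe two-point threshold |
| ordering | LOD ladder | 3, 2, 1, 0.5, 0 | place well-supported markers first; everything is placed at 0 |
| ordering | seed pair | highest LOD among pairs with ≥ 20 joint meioses | stable anchor; ties broken lexicographically for determinism |
| refinement | window | 5 adjacent loci | exhaustive permutation is affordable (120 orders/window) and catches local inversions |
| screening | double-recombinant span | 20 cM | an isolated origin state inside 20 cM is far more likely a genotyping error than two crossovers; masking is off by default |
| splitting | interval limit | 50 cM | two-point linkage is effectively exhausted near θ = 0.4; longer gaps are not credible within-group distances |
| reporting | lengths 0.1 cM, indices 2 d.p. | — | matches conventional map-table precision |

**Grouping curation.** Two-point LODs between truly unlinked markers are
overdispersed relative to nominal binomial sampling error: resolvable
transmissions are a selected subset, so per-parent observed-origin
marginals deviate from 0.5 and their products inflate the tail of the LOD
distribution. Single-linkage grouping at LOD > 4 therefore occasionally
welds two chromosomes through a single marginal edge. When a reference map
is supplied, `curate_synteny` removes a cross-reference-chromosome edge if
both endpoints link more strongly within their own reference chromosome —
an automated version of the manual synteny curation practised in
microsatellite mapping. Stragglers are then rescued: a singleton joins its
top-LOD partner's group when that partner is its immediate reference
neighbour, and two same-chromosome groups merge when the best end-marker
LOD between them ranks first for both end markers outside their own
groups. All actions are logged with their evidence.

**Sex-averaged vs sex-specific.** The sex-averaged θ is the pooled-meiosis
MLE (all transmissions in one likelihood), not the mean of the sex-specific
estimates, matching the equal-recombination-rates assumption of the
two-point stage. Sex-specific estimates maximise the same likelihood
restricted to transmissions of that parent sex; an interval with no
informative meioses in one sex (or θ̂ at the unlinked boundary) has an
undefined length in that sex and is excluded from sums and SDI.

**Coordinates.** Positions are cumulative cM from the group's first
ordered marker; orientation puts the reference map's lowest-positioned
shared marker at the low end, else lexicographic. Markers at θ̂ = 0 are
co-located and counted as one unique position.

## The synthetic-data generator

The generator emulates the two-population wild-pedigree design:

* **Pedigrees.** Founders (half male) plus offspring generations; the
  configured total number of sires is spread over the offspring
  generations, each sire drawing a zero-truncated negative-binomial
  sibship (Poisson when SD² ≤ mean, constant when SD = 0) matched to the
  field numbers (defaults: 42 sires of 4.4 ± 3.5 offspring with dams of
  3.4 ± 2.1 in one population; 43 sires of 3.9 ± 3.3 and dams of
  2.4 ± 1.3 in the other). Parents are never reused across generations, so
  realised per-parent counts follow the configured distributions. Zero
  truncation raises the realised sire mean slightly (~0.4 offspring at the
  default moments); tests allow for this bias explicitly.
* **Markers.** Allele counts drawn uniformly on 2–12 per marker, founder
  frequencies from a flat Dirichlet per population (shared allele pools,
  population-specific diversity). Typing success 0.95 and genotyping-error
  rate 0.005 by default; errors replace a call with a random genotype from
  the marker's allele pool. The error rate is not reported in the source
  study; 0.005 is an arbitrary, exposed default.
* **True maps.** Sex-averaged interval lengths are gamma(mean 14.3 cM,
  SD 9.1 cM) — the integrated map's printed interval moments — clipped to
  [4, 45] cM. The floor reflects panel design: mapping panels are selected
  for coverage, and markers a couple of cM apart are not orderable from
  realistic meiosis counts (the real map collapsed 7 of 247 markers into
  shared positions). The cap keeps every interval inside two-point linkage
  range, consistent with the downstream rule that breaks groups at gaps
  above 50 cM.
* **Heterochiasmy.** Each interval's female:male split follows
  SDI(x) = b₀ + b₁x + b₂x² of its relative centromere→telomere midpoint x
  (acrocentric convention: centromere at 0), after which the female map is
  rescaled so the genome-wide female:male ratio equals the configured value
  (1.12) exactly, preserving total sex-averaged length. The default
  profile (0.05, 0.45, −0.45) is concave with weak female bias at the
  chromosome ends and a mid-chromosome peak, giving a mean interval SDI
  ≈ 0.125 consistent with the 1.12 ratio. It deliberately does **not**
  reproduce the male-biased chromosome extremes seen in real sheep maps: a
  profile that crosses zero pins one third of the intervals' detection
  probability at one half regardless of study size, and the generator's
  role here is to make the genome-wide female bias and the quadratic shape
  recoverable at study scale. Conclusions about maps whose dimorphism
  reverses sign along the chromosome are outside what passing tests
  demonstrate.
* **Crossovers.** Gametes recombine between adjacent markers independently
  with probability θ = inverse-Kosambi of the transmitting parent's
  sex-specific interval length. Marginal two-point recombination fractions
  therefore match the true map exactly, but there is no crossover
  interference: multi-interval coincidence probabilities do not follow the
  Kosambi function's implied interference. Two-point and fixed-order
  estimation consume only marginal θ, so this does not bias the pipeline;
  analyses of double-recombinant rates, by contrast, see more tight
  doubles than a true interference model would produce.
* **Determinism.** One `numpy` generator seeded from the config drives the
  whole study; identical config + seed gives byte-identical outputs.

## The recovery study

The package's end-to-end self-check (`ovismap.recovery`) simulates two
large populations (500 sires each, same sibship moments as the field
pedigrees) over 4 chromosomes × 8 markers, maps them blind, and scores:
marker-order recovery up to reversal (pipeline includes reference-map
curation, as a field study would); per-interval θ̂ error in binomial
standard errors, scored on the true order so interval truth is well
defined; the genome-wide sign test for female-biased recombination; the
recovered female:male ratio; and the fitted SDI-position quadratic. The
study size was chosen so each marker has several hundred informative
meioses — well above the few-hundred scale of the real pedigrees — because
interval-level heterochiasmy detection, not ordering, is the binding
constraint on power. Twenty replicate seeds run in about five minutes on
one CPU.

Two scoring notes. First, with ~560 interval estimates per study, a few
legitimate 3-SE exceedances are expected (nominal coverage 99.7%); the
acceptance check therefore asserts ≥ 98% coverage plus a hard 6-SE cap
rather than literal universal containment. Second, genotyping errors
inflate both sexes' θ̂ slightly, which attenuates the recovered ratio by
roughly 0.01 at the default error rate; the ratio check allows for this.

## Known limitations

* No X-chromosome model: hemizygous males, pseudo-autosomal boundaries and
  sex-limited regions are not simulated or special-cased.
* The likelihood is the phased-meiosis approximation described above, not
  a full pedigree likelihood; deep pedigrees with many untyped ancestors
  would lose information relative to CRI-MAP-style peeling.
* Genotype correction is flag-and-delete only (plus optional masking of
  flagged double recombinants); no error-model-based correction.
* The simulator has no mutation, no immigration, and no interference (see
  above).
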