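# Methods

This note documents the models, parameter choices, and numerical decisions
behind whalepop, and what its synthetic-data validation does and does not
demonstrate.

## Wright–Fisher simulator

`whalepop.wf_simulator` implements a discrete-generation diploid
Wright–Fisher model. Each generation, every offspring draws two parents
uniformly from its deme (with probability *m* a parent comes from the other
deme); each parent contributes one gamete. Genomic elements assort
independently (they behave as separate chromosomes); within an element,
crossovers are Poisson with rate `rec` per site per meiosis. Mutation is
finite-sites: the number of new mutations per generation is Poisson with mean
`2N·μ·L`, each placed uniformly on the genome; a hit on a segregating site
flips that allele (back mutation), and a derived allele that fixes simply
becomes the new reference state. Selection, dominance, gene conversion and
non-random mating are out of scope.

Internally the population is a `(2N, columns)` byte matrix over currently
segregating sites only. Columns are re-sorted by genome position and purged
of fixed/lost sites at regular compactions, so per-element inheritance is a
contiguous slice copy; this is what makes desk-scale runs (millions of
genome-generations) take seconds. Reproducibility: one seeded generator
drives everything; replicate *k* of a batch uses `seed + k`.

The full-scale configuration of the emulated study — N₀ = 50,000 diploids,
three 10-Mbp elements, μ = 1.54 × 10⁻⁹ per site per generation, r = 10⁻⁸,
100,000 burn-in generations, 51 sampled diploids, generation time 25.9 years
— is expressible in `SimulationConfig`, but all tests and validation
experiments run scaled-down parameters that preserve N·μ (hence per-site
diversity) and express event times on the coalescent scale of the scaled N.

### Scenario library

`scenario_library()` parameterizes the demographic families the analysis is
meant to discriminate over a fixed horizon (default 30 generations ≈ 800
years at 25.9 y/generation): constant size; stepwise-linear decline to 50%;
bottlenecks of 20/50/80% severity held until sampling; an 80% bottleneck with
recovery; and migration variants fed from an unaffected deme of equal size.
The published event of interest — an ~80% drop roughly 100–150 years
(4–6 generations) before sampling — is directly expressible at full scale.
At desk scale a 4–6-generation event at N ≈ 100 is statistically invisible
(its coalescent-time footprint shrinks with N), so the *validation*
experiments use a bottleneck spanning the last 20 generations (0.1 × 2N
coalescent units at N = 100), which preserves the event's footprint rather
than its nominal duration. This choice is fixed in
`whalepop.experiments._RECOVERY_KW`.

## fSFS and scenario ranking

The folded SFS counts segregating sites by minor-allele count 1…n for n
diploids (complete-case per site: any missing genotype drops the site;
hypergeometric projection is a possible extension, not implemented).
Scenario ranking evaluates the full multinomial log-probability of the
observed spectrum under bin probabilities proportional to the candidate
spectrum plus a pseudocount (default 1, Laplace smoothing, so empty simulated
bins stay finite; the multinomial coefficient is included so values are
actual log-probabilities — it is constant across candidates and harmless).
Ties are broken lexicographically. Ranking is invariant to scaling all
candidate counts by a constant (up to the pseudocount's vanishing weight).

## Diversity statistics

* Heterozygosity: heterozygous calls over non-missing genotyped sites,
  computed on data that retain monomorphic sites.
* π per site: Σ 2p̂q̂ · 2n/(2n−1) over sites, divided by the callable length
  (monomorphic positions included). Because published whale-genome tables
  sometimes print π on a per-variant scale, `cohort_diversity_table` emits
  both `pi_per_site` and `pi_per_variant`, labeled.
* Watterson's θ per site: S/(a₁L) with a₁ the harmonic number of
  (haplotypes − 1).
* Tajima's D: classical constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂), total π
  in the numerator, complete-case sites so the sample size is constant;
  undefined (error) below 3 segregating sites. Positive D is the signature of
  a contraction, negative of an expansion.
* F_H: (O_hom − E_hom)/(L − E_hom) per individual, with
  E_hom = Σ (1 − 2p̂q̂ · 2n/(2n−1)) over that individual's called sites and
  allele frequencies from the whole sample. The 2n/(2n−1) finite-sample
  correction is the one the standard excess-homozygosity implementations
  apply; without it the estimator is biased by −1/(2n−1) under random mating
  (≈ −0.026 at n = 20), which would swamp the quantity being measured.
  Values are clamped to [−1, 1].

## ROH and F_ROH

Windows tile each contig left-to-right (the published window parameters —
10 kbp windows, ≥10 windows ≈ ≥100 kbp — imply tiling rather than overlapped
sliding, and tiling keeps length bookkeeping exact). A window's het rate is
heterozygous calls over callable sites in the window; windows with callable
counts below 10% of the median per-window callable count are masked, and
masked windows break runs (conservative; no bridging). A ROH is a maximal run
of ≥ `min_windows` consecutive unmasked windows below the 0.2% threshold;
segment coordinates snap to window boundaries, with no sub-window
refinement. Contigs shorter than 3 Mbp are excluded. F_ROH profiles are
cumulative by minimum-length cutoff (≥100 kbp, ≥200 kbp, … ≥1 Mbp), hence
monotone nonincreasing.

A calibration subtlety the fixtures must respect: with a 0.2% window
threshold, the *non-autozygous background* heterozygosity must exceed 0.2%
for window-based detection to have an operating point at all. A genome whose
background is 0.07% per bp (a realistic genome-wide whale average, which
mixes ROH and non-ROH sequence) sits entirely below the threshold and would
be called one giant ROH. The implanted-ROH fixtures therefore use a 0.4%/bp
background with tract interiors at 0.1× (0.04%/bp, emulating genotyping error
inside true autozygous tracts); 0.07% remains the package's reference scale
for genome-wide heterozygosity elsewhere.

## Mutational load

SNVs are classified against a canonical-transcript CDS annotation by
translating the affected codon on the coding strand: splice donor/acceptor
(first/last 2 bp of an intron), stop-gained and start-lost are LoF;
stop-lost is counted with missense by default (`stop_lost_is_lof=True`
reclassifies); other amino-acid changes are missense; silent changes are
synonymous; everything else is noncoding. When a variant touches several
transcripts the most severe category wins. Indels are rejected (they are
excluded upstream by the site filters). Reference-mismatch inputs raise a
data-integrity error. The genetic code is the standard nuclear table.
Load = n_LoF / n_variants carried by the individual (the "respective total
counts" convention); LoF counts are split into heterozygous and homozygous
carriers. The test oracle is a full-translation re-derivation: rebuild the
mutant CDS, translate the whole protein, and compare — an independent code
path from the codon-local classifier.

## Relatedness, filters, structure

π̂ uses the method-of-moments IBD decomposition from IBS counts and sample
allele frequencies (the algorithm behind the `--genome`-style tools):
P(IBD=0) from observed IBS0 over its null expectation, P(IBD=1) from the
IBS1 residual, P(IBD=2) as the remainder; negative moments are clamped to 0,
the triple renormalized, and π̂ = P(IBD=1)/2 + P(IBD=2) clamped to [0, 1].
Related-individual removal is greedy: repeatedly drop the higher-missingness
member of the worst pair above the cutoff (ties: the later sample), which is
deterministic and leaves no pair above the cutoff.

Site filters apply in a fixed order — indels → divergent coverage (outside
0.3–3× the expected mean) → missingness (>5%) → biallelic → heterozygosity
excess (>0.6 observed het fraction, a paralog-collapse heuristic) → minor
allele count — with a per-rule removal report whose counts sum to input −
output sites. LD pruning is a greedy left-to-right scan: a site is dropped
when its squared dosage correlation (pairwise-complete) with any retained
site within the window exceeds r²max; the earlier site wins, and the result
is idempotent. Random thinning keeps one site per spacing interval.

Coordinates are 1-based inclusive in VCF and 0-based half-open internally;
conversion happens only at the I/O boundary.

The genetic distance is the allele-sharing distance (mean |dosage
difference|/2 over pairwise-complete sites); the metric is deliberately
pluggable since wrapped published analyses rarely state theirs. PCoA is
classical scaling: double-center −D²/2, eigendecompose, scale eigenvectors by
√eigenvalues; negative eigenvalues (non-Euclidean inputs) are truncated to
zero and counted, with no Cailliez correction; axis signs follow a
first-nonzero-loading-positive convention.

## Synthetic fixtures

Fixtures are fully reproducible from (kind, parameters, seed) and carry truth
payloads sufficient to score the corresponding module without re-derivation:
implanted-ROH genomes (Poisson het placement, 0.1× rate inside tracts),
pedigree genotypes (Hardy–Weinberg founders, Mendelian transmission,
recursive-kinship truth), and annotated toy genomes with two-exon genes on
both strands whose variant effect truth comes from the full-translation
oracle; the first gene's leading codons are fixed (ATG TGG GCT AAA) so
stop-gained, synonymous and missense cases are always constructible, and a
splice and an intergenic variant are always included.

What the fixtures do *not* emulate: genotyping error outside ROH, linked
selection, GC-biased gene conversion, reference bias, callability that
correlates with diversity, and multi-transcript annotation complexity.
Passing these tests shows the estimators and detectors are correct under
their own model assumptions at realistic parameter scales — not that the
biological conclusions of any particular study are right.

## Validation experiments and problem sizes

`whalepop.experiments` (driven by `scripts/acceptance.py` and
`tests/test_acceptance.py`) uses these scaled conditions, chosen once:

* Calibration: N = 500, one 100-kb element, μ = 10⁻⁶ (4Nμ = 0.002),
  rec = 10⁻⁶ per site (nonzero so replicate genealogies decorrelate along the
  element; the realistic regime has r ≳ μ), burn-in 10N, 20 samples of 20
  diploids. Measured: mean θ_W/4Nμ, mean π/4Nμ, mean Tajima's D.
* Model recovery: N = 50, twenty 10-kb elements, μ = 4 × 10⁻⁵, burn-in 10N,
  horizon 15 generations, 80% bottleneck over the last 10 generations
  (0.1 × 2N), samples of 10 diploids. Candidate spectra for {constant,
  gradual decline, 80% bottleneck, bottleneck+migration} are averaged over 50
  simulations *branched from shared burn-in states* (common random numbers:
  the ranking depends on candidate differences, which pairing estimates with
  far less noise at a third of the cost). Each of the 50 observed datasets
  pools the spectra of 4 independent runs. The pooling is deliberate: an
  empirical genome-wide fSFS aggregates thousands of quasi-independent
  chromosome histories, while a single desk-scale run is dominated by its one
  shared pedigree — at N_bottleneck = 10 the pedigree correlates all loci, a
  small-N artifact with no analogue in the emulated regime. Without pooling,
  single-run recovery plateaus near 89% regardless of how many elements are
  simulated; with 4-run pooling it is ~98%. Also measured: the log-likelihood
  penalty from feeding the true bottleneck candidate with migration
  (m = 0.05) from an unaffected deme — migration should always weaken the
  bottleneck fit when the data lack it.
* ROH recovery: 10-Mbp genome, five tracts of 0.2–2 Mbp with window-aligned
  boundaries (the detector's coordinates snap to windows by design), study
  parameters exactly.
* Oracles: 300-site/8-individual matrices and a 1000-variant annotated
  fixture; every estimator must agree with its independent oracle to 1e-8
  relative, the classifier exactly.
* Pedigree: 30 founders, 10,000 sites; 15 parent-offspring pairs and 30
  selfed offspring.
* Qualitative patterns: a 12-step inbreeding gradient (0–60% of a 10-Mbp
  genome in implanted tracts) for the heterozygosity–F_ROH correlation, and a
  24-sample panmictic simulation with arbitrary cohort labels for the PCoA
  permutation test (999 permutations).

## Known limitations

* The simulator's finite-sites model allows back mutation; at the μL values
  used the recurrent-hit probability is negligible, but it is not the
  infinite-sites idealization.
* Multinomial SFS likelihoods treat sites as independent; linked sites make
  the likelihood overconfident, which is why scenario ranking is validated by
  recovery frequency rather than by likelihood-ratio calibration.
* fSFS missing-data handling is complete-case; no projection.
* One effect per variant per canonical transcript; no frameshift/indel
  effects, no polarization, no realized-vs-masked load decomposition.
* HMM/likelihood ROH callers, phasing-aware autozygosity and ROH age
  estimation are out of scope; the window method cannot resolve tracts below
  its window grid.
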