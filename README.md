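# whalepop

Conservation-genomics analyses for populations that went through a recent,
human-caused bottleneck — the motivating case is a baleen-whale population
depleted by 20th-century industrial whaling and sampled decades later.  The
package asks, on whole-genome diploid genotype data: did the bottleneck leave
detectable scars?  It answers with four coordinated analyses plus the
simulation machinery needed to interpret them:

* **Demography** — a native forward-in-time diploid Wright–Fisher simulator
  (mutation, recombination, piecewise-constant deme sizes, two-deme
  migration) generates expected folded site frequency spectra (fSFS) under
  candidate scenarios; candidates are ranked by the multinomial
  log-likelihood of the observed fSFS,
  `log P(obs | p_i ∝ sim_i + pseudocount)`.
* **Diversity** — genome-wide heterozygosity, nucleotide diversity
  π = Σ 2p̂q̂·2n/(2n−1) / L, Watterson's θ_W = S/(a₁L), Tajima's D, and the
  excess-homozygosity inbreeding coefficient
  F_H = (O_hom − E_hom)/(L − E_hom).
* **Inbreeding via ROH** — runs of homozygosity from tiled 10-kbp windows
  (het rate < 0.2%, ≥10 consecutive windows, contigs ≥3 Mbp), with
  F_ROH(c) = (summed length of ROH ≥ c) / analyzed genome, profiled from
  100 kbp to >1 Mbp.
* **Mutational load** — codon-level SNV effect classification
  (synonymous / missense / loss-of-function, where LoF = stop-gained,
  start-lost, or splice-site ±2 bp) against a GFF3+FASTA annotation; load =
  n_LoF / n_variants per individual, split by zygosity.

Population structure (allele-sharing distances + PCoA), PLINK-style
relatedness (method-of-moments π̂ from IBS counts), site/LD filtering, and a
synthetic-fixture module with known ground truth round out the pipeline.

## Worked example

```python
import numpy as np
from whalepop import SimulationConfig, DemographicScenario, simulate, fsfs_from_genotypes
from whalepop.diversity_stats import watterson_theta, nucleotide_diversity, tajimas_d

cfg = SimulationConfig(
    n_diploid_initial=500, genome_elements=(100_000,), mu=1e-6, rec=1e-6,
    burnin_generations=5000, sample_size=20, seed=1,
)
constant = DemographicScenario("constant", epochs=[(0, (500,)), (2, (500,))])
gm = simulate(cfg, constant)

S = int(gm.is_segregating().sum())
print("segregating sites:", S)
print("theta_W:", round(watterson_theta(S, 40, 100_000), 6))
print("pi     :", round(nucleotide_diversity(gm, 100_000), 6))
print("D      :", round(tajimas_d(gm), 3))
```

prints

```
segregating sites: 847
theta_W: 0.001991
pi     : 0.00189
D      : -0.19
```

i.e. both diversity estimators sit near the neutral equilibrium expectation
4Nμ = 0.002 for this configuration, and Tajima's D is near zero — a
constant-size population shows no bottleneck distortion.  Running the same
sample through `whalepop.sfs_demography.rank_scenarios` against simulated
candidate spectra ranks the generating scenario first.

A full run over a VCF:

```bash
whalepop run cohort.vcf --cohorts '{"s1": "1989", "s2": "2009"}' --seed 1
whalepop sfs compute cohort.vcf
whalepop roh call individual.vcf sampleA --contig-lengths '{"chr1": 50000000}'
```

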