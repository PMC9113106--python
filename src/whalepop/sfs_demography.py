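"""Folded site frequency spectra and multinomial-likelihood scenario ranking.

The folded SFS (fSFS) is the histogram of minor-allele counts over segregating
sites for a fixed sample of n diploids; it is robust to unknown ancestral
state.  Candidate demographic scenarios are compared by the log-probability of
the observed spectrum under a multinomial whose bin probabilities are the
(smoothed) simulated spectrum — the more probable the observed fSFS under a
scenario's expected spectrum, the better the scenario.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class FoldedSFS:
    """Minor-allele-count histogram for a sample of ``n_individuals`` diploids.

    ``counts[i-1]`` is the number of segregating sites with minor-allele count
    i, for i = 1..n_individuals; the last bin holds frequency-1/2 alleles.
    Counts are integers for observed spectra; replicate means may be floats.
    """

    counts: np.ndarray
    n_individuals: int
    n_sites_used: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != self.n_individuals:
            raise ValueError(
                f"expected {self.n_individuals} bins, got {len(self.counts)}"
            )
        if np.any(self.counts < 0):
            raise ValueError("fSFS counts must be nonnegative")

    @property
    def n_segregating(self) -> float:
        return float(self.counts.sum())

    def proportions(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty spectrum has no proportions")
        return self.counts / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "minor_allele_count": np.arange(1, self.n_individuals + 1),
                "n_sites": self.counts,
            }
        )


def fsfs_from_genotypes(gm: GenotypeMatrix) -> FoldedSFS:
    """Fold the sample allele counts of a biallelic SNP matrix into an fSFS.

    Sites with any missing genotype are excluded (complete-case rule);
    monomorphic sites are ignored.
    """
    n = gm.n_individuals
    complete = ~np.any(gm.genotypes == MISSING, axis=1)
    g = gm.genotypes[complete]
    alt = g.sum(axis=1, dtype=np.int64)
    minor = np.minimum(alt, 2 * n - alt)
    minor = minor[(alt > 0) & (alt < 2 * n)]
    if minor.size == 0:
        raise ValueError("no usable segregating sites")
    counts = np.bincount(minor, minlength=n + 1)[1 : n + 1]
    return FoldedSFS(counts=counts, n_individuals=n, n_sites_used=int(minor.size))


def fold(unfolded_counts: np.ndarray, n_haplotypes: int) -> FoldedSFS:
    """Fold an unfolded spectrum (bins 1..n_hap-1) into minor-allele bins.

    folded[i] = u[i] + u[2n-i] for i < n, folded[n] = u[n] (n = n_hap/2).
    Folding is idempotent: a symmetric unfolded spectrum folds to itself.
    """
    u = np.asarray(unfolded_counts, dtype=float)
    if n_haplotypes % 2 != 0:
        raise ValueError("n_haplotypes must be even (diploid samples)")
    if len(u) != n_haplotypes - 1:
        raise ValueError(
            f"unfolded spectrum must have {n_haplotypes - 1} bins, got {len(u)}"
        )
    n = n_haplotypes // 2
    folded = np.empty(n)
    for i in range(1, n):
        folded[i - 1] = u[i - 1] + u[n_haplotypes - i - 1]
    folded[n - 1] = u[n - 1]
    return FoldedSFS(counts=folded, n_individuals=n, n_sites_used=int(u.sum()))


def multinomial_loglik(
    observed: FoldedSFS, simulated: FoldedSFS, pseudocount: float = 1.0
) -> float:
    """Log-probability of the observed fSFS under the simulated spectrum.

    Bin probabilities are proportional to ``simulated.counts + pseudocount``
    (Laplace smoothing so empty simulated bins stay finite); the multinomial
    coefficient is included, so the value is an actual log-probability.
    """
    if observed.n_individuals != simulated.n_individuals:
        raise ValueError("spectra have different sample sizes")
    smoothed = simulated.counts + pseudocount
    if np.any(smoothed <= 0):
        raise ValueError("simulated counts + pseudocount must be positive everywhere")
    p = smoothed / smoothed.sum()
    x = np.round(observed.counts).astype(np.int64)
    return float(stats.multinomial.logpmf(x, n=int(x.sum()), p=p))


def rank_scenarios(
    observed: FoldedSFS, candidates: list, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Rank candidate ``(name, FoldedSFS)`` pairs by multinomial log-likelihood.

    Returns a table sorted by descending log-likelihood (ties broken by name)
    with the log-likelihood difference to the best candidate.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate scenarios")
    rows = [
        {"scenario": name, "loglik": multinomial_loglik(observed, sfs, pseudocount)}
        for name, sfs in candidates
    ]
    table = pd.DataFrame(rows).sort_values(
        ["loglik", "scenario"], ascending=[False, True], kind="stable"
    )
    table["delta_loglik"] = table["loglik"].iloc[0] - table["loglik"]
    return table.reset_index(drop=True)


def generations_to_years(g: float, generation_time_years: float = 25.9) -> float:
    """Convert generations to years (fin whale default: 25.9 y/generation)."""
    if g < 0:
        raise ValueError("generations must be nonnegative")
    return g * generation_time_years


def neutral_folded_expectation(n_haplotypes: int) -> np.ndarray:
    """Expected folded-SFS bin proportions at neutral equilibrium.

    Unfolded bins are proportional to 1/i; folding gives
    1/i + 1/(2n-i) for i < n and 1/n for i = n.
    """
    n = n_haplotypes // 2
    props = np.array(
        [
            1.0 / i + (1.0 / (n_haplotypes - i) if i != n_haplotypes - i else 0.0)
            for i in range(1, n + 1)
        ]
    )
    return props / props.sum()
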