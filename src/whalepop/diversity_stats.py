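"""Genome-wide diversity and inbreeding statistics.

Per-individual heterozygosity (het calls / callable genotyped sites, computed
on data that still include monomorphic sites), nucleotide diversity pi,
Watterson's theta, Tajima's D, and the excess-homozygosity inbreeding
coefficient F_H.

pi and theta_W are per-site quantities whose denominator is the callable
length including monomorphic sites; a per-variant scale (denominator = number
of SNPs) is also emitted where cohort tables are built, since published
summaries are sometimes on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class DiversityStats:
    het_frac: float
    pi_per_site: float
    theta_w_per_site: float
    tajimas_d: float
    f_h: float


def individual_heterozygosity(
    gm: GenotypeMatrix, individual, include_monomorphic: bool = True
) -> float:
    """Fraction of an individual's non-missing genotyped sites that are
    heterozygous.

    The denominator includes monomorphic sites when they are present in the
    matrix (the convention for genome-wide heterozygosity); pass a matrix read
    with ``keep_monomorphic=True`` for that.
    """
    j = gm.sample_ids.index(individual) if isinstance(individual, str) else int(individual)
    g = gm.genotypes[:, j]
    if not include_monomorphic:
        seg = gm.is_segregating()
        g = g[seg]
    called = g != MISSING
    n = int(called.sum())
    if n == 0:
        raise ValueError("no callable genotyped sites for this individual")
    return float((g[called] == 1).sum() / n)


def _site_pairwise_diversity(gm: GenotypeMatrix) -> np.ndarray:
    """Unbiased per-site mean pairwise difference 2*p*q*2n/(2n-1), complete
    cases per site."""
    called = gm.genotypes != MISSING
    n_called = called.sum(axis=1)
    alt = np.where(called, np.maximum(gm.genotypes, 0), 0).sum(axis=1)
    two_n = 2.0 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(two_n > 0, alt / two_n, 0.0)
        term = 2.0 * p * (1.0 - p) * np.where(two_n > 1, two_n / (two_n - 1.0), 0.0)
    return np.where(two_n > 1, term, 0.0)


def nucleotide_diversity(gm: GenotypeMatrix, L_callable: float) -> float:
    """Nucleotide diversity pi per site.

    pi = sum over sites of 2*p*(1-p) * 2n/(2n-1), divided by the callable
    length (which includes monomorphic positions).
    """
    if L_callable <= 0:
        raise ValueError("callable length must be positive")
    return float(_site_pairwise_diversity(gm).sum() / L_callable)


def watterson_theta(S: int, n_hap: int, L_callable: float) -> float:
    """Watterson's theta per site: S / (a1 * L), a1 = sum_{i<n_hap} 1/i."""
    if n_hap < 2:
        raise ValueError("need at least two haplotypes")
    if L_callable <= 0:
        raise ValueError("callable length must be positive")
    a1 = np.sum(1.0 / np.arange(1, n_hap))
    return float(S / (a1 * L_callable))


def count_segregating(gm: GenotypeMatrix) -> int:
    return int(gm.is_segregating().sum())


def tajimas_d(gm: GenotypeMatrix) -> float:
    """Tajima's D: standardized difference between pairwise diversity and the
    segregating-sites estimator (positive after contractions, negative after
    expansions).

    Uses the classical constants a1, a2, b1, b2, c1, c2, e1, e2 for the full
    sample of 2n haplotypes; sites with missing calls are excluded entirely so
    the sample size is constant across sites.
    """
    complete = ~np.any(gm.genotypes == MISSING, axis=1)
    sub = gm.take_sites(complete)
    n = 2 * sub.n_individuals
    if n < 4:
        raise ValueError("need at least two diploid individuals")
    alt = sub.genotypes.sum(axis=1, dtype=np.int64)
    seg = (alt > 0) & (alt < n)
    S = int(seg.sum())
    if S < 3:
        raise ValueError("Tajima's D undefined for fewer than 3 segregating sites")
    p = alt[seg] / n
    pi_total = float(np.sum(2.0 * p * (1.0 - p) * n / (n - 1.0)))
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    return float((pi_total - S / a1) / np.sqrt(var))


def f_h(gm: GenotypeMatrix, individual) -> float:
    """Excess-homozygosity inbreeding coefficient for one individual.

    F_H = (O_hom - E_hom) / (L - E_hom) with E_hom = sum over the individual's
    non-missing sites of 1 - 2*p*q*2n/(2n-1), allele frequencies taken from
    the whole sample (the 2n/(2n-1) factor is the finite-sample correction
    the standard excess-homozygosity tools apply).  0 under random mating,
    positive for inbred individuals, negative for heterozygote excess;
    clamped to [-1, 1].
    """
    j = gm.sample_ids.index(individual) if isinstance(individual, str) else int(individual)
    p = gm.alt_frequency()
    g = gm.genotypes[:, j]
    ok = (g != MISSING) & ~np.isnan(p)
    if not ok.any():
        raise ValueError("no callable sites for this individual")
    q = 1.0 - p[ok]
    two_n = 2.0 * (gm.genotypes != MISSING).sum(axis=1)[ok]
    corr = np.where(two_n > 1, two_n / (two_n - 1.0), 1.0)
    e_hom = float(np.sum(1.0 - 2.0 * p[ok] * q * corr))
    L = float(ok.sum())
    o_hom = float((g[ok] != 1).sum())
    denom = L - e_hom
    if denom <= 0:
        raise ValueError("all sites monomorphic: expected heterozygosity is zero")
    return float(np.clip((o_hom - e_hom) / denom, -1.0, 1.0))


def cohort_diversity_table(gm: GenotypeMatrix, L_callable: float) -> pd.DataFrame:
    """Per-individual diversity summary (heterozygosity and F_H per individual,
    cohort-level pi / theta_W / Tajima's D repeated per member)."""
    n_hap = 2 * gm.n_individuals
    S = count_segregating(gm)
    pi = nucleotide_diversity(gm, L_callable)
    theta = watterson_theta(S, n_hap, L_callable)
    try:
        D = tajimas_d(gm)
    except ValueError:
        D = np.nan
    rows = []
    for j, sid in enumerate(gm.sample_ids):
        rows.append(
            {
                "sample": sid,
                "cohort": gm.cohort_labels[j] if gm.cohort_labels else "all",
                "het_frac": individual_heterozygosity(gm, j),
                "f_h": f_h(gm, j),
                "pi_per_site": pi,
                "pi_per_variant": pi * L_callable / max(S, 1),
                "theta_w_per_site": theta,
                "tajimas_d": D,
            }
        )
    return pd.DataFrame(rows)
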