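"""Allele-sharing distances and principal coordinate analysis (classical MDS).

The distance between two individuals is the mean over pairwise-complete sites
of |dosage_i - dosage_j| / 2 (0 for identical genotypes everywhere, 1 for
opposite homozygotes everywhere).  PCoA double-centers -D^2/2, takes the
eigendecomposition, and scales eigenvectors by the square roots of their
eigenvalues; negative eigenvalues (non-Euclidean distances) are truncated to
zero and reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    values: np.ndarray
    sample_ids: list

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("diagonal must be zero")
        self.values = d

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class PCoAResult:
    coordinates: np.ndarray  # (n_samples, n_axes)
    eigenvalues: np.ndarray  # descending, length n_axes
    percent_variance: np.ndarray
    n_negative_eigenvalues: int
    sample_ids: list

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{k + 1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def allele_sharing_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise allele-sharing distance: mean |dosage difference| / 2 over
    sites where both individuals are called."""
    n = gm.n_individuals
    g = gm.genotypes.astype(np.int16)
    called = g != MISSING
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = called[:, i] & called[:, j]
            if not ok.any():
                raise ValueError(
                    f"no shared called sites for pair ({gm.sample_ids[i]}, {gm.sample_ids[j]})"
                )
            out[i, j] = out[j, i] = float(
                np.abs(g[ok, i] - g[ok, j]).mean() / 2.0
            )
    return DistanceMatrix(values=out, sample_ids=list(gm.sample_ids))


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> PCoAResult:
    """Classical metric scaling of a distance matrix.

    Deterministic up to sign; the sign convention makes the first nonzero
    loading of each axis positive.  Percent variance is relative to the sum of
    positive eigenvalues.
    """
    n = d.n
    if n_axes >= n:
        raise ValueError("n_axes must be smaller than the number of samples")
    D2 = d.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_neg = int((eigval < -1e-10 * max(1.0, abs(eigval[0]))).sum())
    pos = np.clip(eigval, 0.0, None)
    total = pos.sum()
    coords = eigvec[:, :n_axes] * np.sqrt(pos[:n_axes])
    for k in range(n_axes):
        col = coords[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    pct = 100.0 * pos[:n_axes] / total if total > 0 else np.zeros(n_axes)
    return PCoAResult(
        coordinates=coords,
        eigenvalues=eigval[:n_axes],
        percent_variance=pct,
        n_negative_eigenvalues=n_neg,
        sample_ids=list(d.sample_ids),
    )


def permutation_cohort_test(
    result: PCoAResult,
    cohort_labels: list,
    n_axes: int = 2,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple:
    """Permutation test for cohort separation in PCoA space.

    Statistic: between-cohort mean squared distance of cohort centroids,
    weighted by cohort size, over the first ``n_axes`` axes.  The p-value is
    the fraction of label permutations with a statistic at least as large
    (one cluster -> p not small).
    """
    coords = result.coordinates[:, :n_axes]
    labels = np.asarray(cohort_labels)
    rng = np.random.default_rng(seed)

    def stat(lab: np.ndarray) -> float:
        grand = coords.mean(axis=0)
        s = 0.0
        for c in np.unique(lab):
            sub = coords[lab == c]
            s += len(sub) * float(np.sum((sub.mean(axis=0) - grand) ** 2))
        return s

    observed = stat(labels)
    hits = 1
    for _ in range(n_permutations):
        if stat(rng.permutation(labels)) >= observed:
            hits += 1
    return observed, hits / (n_permutations + 1)
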