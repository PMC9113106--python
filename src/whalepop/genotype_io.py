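"""Genotype matrices, VCF I/O, and the study's site / linkage / relatedness filters.

The central container is :class:`GenotypeMatrix`: a sites x individuals array of
diploid genotype codes (0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing) with
per-site coordinates and alleles.  All downstream statistics consume it.

Filters mirror a short-read resequencing workflow: indel exclusion, divergent
read-coverage exclusion (0.3x-3x of the expected mean), per-site missingness,
biallelic restriction, heterozygosity-excess removal, minor-allele-count
thresholds, LD pruning on genotype dosages, and removal of related individuals
by a method-of-moments IBD estimate (pi_hat).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

MISSING = -1
_VALID_CODES = frozenset({0, 1, 2, MISSING})


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted as diploid genotypes."""


@dataclass
class GenotypeMatrix:
    """Diploid genotypes at a set of sites for a set of individuals.

    Parameters
    ----------
    chrom_ids : per-site contig name.
    positions : per-site 1-based coordinate (VCF convention).
    ref_allele, alt_alleles : per-site reference base(s) and list of ALT alleles
        (empty list for monomorphic records).
    genotypes : (n_sites, n_individuals) int8 array of codes
        {0: hom-ref, 1: het, 2: hom non-ref, -1: missing}.
    depths : optional (n_sites, n_individuals) per-call read depth.
    sample_ids : individual names, one per column.
    cohort_labels : optional grouping label per individual.
    is_indel : per-site flag; True when REF or any ALT is not a single base.
    """

    chrom_ids: np.ndarray
    positions: np.ndarray
    ref_allele: np.ndarray
    alt_alleles: list
    genotypes: np.ndarray
    sample_ids: list
    depths: Optional[np.ndarray] = None
    cohort_labels: Optional[list] = None
    is_indel: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.chrom_ids = np.asarray(self.chrom_ids, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D sites x individuals array")
        if self.genotypes.shape[1] != len(self.sample_ids):
            raise ValueError("genotype matrix width must equal len(sample_ids)")
        if self.genotypes.shape[0] != len(self.positions):
            raise ValueError("genotype matrix height must equal len(positions)")
        bad = set(np.unique(self.genotypes)) - _VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes present: {sorted(bad)}")
        if self.is_indel is None:
            self.is_indel = np.array(
                [
                    len(r) != 1 or any(len(a) != 1 for a in alts)
                    for r, alts in zip(self.ref_allele, self.alt_alleles)
                ],
                dtype=bool,
            )
        # positions strictly increasing within each contig
        for contig in pd.unique(self.chrom_ids):
            p = self.positions[self.chrom_ids == contig]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {contig!r}")

    # ------------------------------------------------------------------ helpers

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Row subset (boolean mask or integer index), preserving order."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            chrom_ids=self.chrom_ids[idx],
            positions=self.positions[idx],
            ref_allele=self.ref_allele[idx],
            alt_alleles=[self.alt_alleles[i] for i in idx],
            genotypes=self.genotypes[idx],
            sample_ids=list(self.sample_ids),
            depths=None if self.depths is None else self.depths[idx],
            cohort_labels=self.cohort_labels,
            is_indel=None if self.is_indel is None else self.is_indel[idx],
        )

    def take_individuals(self, index: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            chrom_ids=self.chrom_ids,
            positions=self.positions,
            ref_allele=self.ref_allele,
            alt_alleles=list(self.alt_alleles),
            genotypes=self.genotypes[:, idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            depths=None if self.depths is None else self.depths[:, idx],
            cohort_labels=None
            if self.cohort_labels is None
            else [self.cohort_labels[i] for i in idx],
            is_indel=self.is_indel,
        )

    def missingness_per_site(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=1)

    def missingness_per_individual(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)

    def alt_frequency(self) -> np.ndarray:
        """Sample ALT-allele frequency per site, missing calls excluded."""
        called = self.genotypes != MISSING
        n_called = called.sum(axis=1)
        alt = np.where(called, self.genotypes, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    def is_segregating(self) -> np.ndarray:
        p = self.alt_frequency()
        return (p > 0) & (p < 1)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.chrom_ids, other.chrom_ids)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.ref_allele, other.ref_allele)
            and self.alt_alleles == other.alt_alleles
            and np.array_equal(self.genotypes, other.genotypes)
            and self.sample_ids == other.sample_ids
        )


@dataclass
class SiteFilterConfig:
    """Thresholds for the per-site filters, applied in a fixed order.

    ``depth_lo_ratio`` / ``depth_hi_ratio`` are multipliers of the expected
    mean per-call coverage (defaults 0.3x and 3x); ``max_missing_frac`` is the
    maximum tolerated fraction of missing calls per site (default 5%);
    ``het_excess_max`` removes sites whose observed heterozygote fraction
    exceeds the threshold (paralog-collapse heuristic, default 0.6);
    ``min_minor_allele_count`` drops sites with minor allele count below the
    value (default 2, i.e. singletons removed).
    """

    max_missing_frac: float = 0.05
    depth_lo_ratio: float = 0.3
    depth_hi_ratio: float = 3.0
    biallelic_only: bool = True
    exclude_indels: bool = True
    het_excess_max: float = 0.6
    min_minor_allele_count: int = 2
    use_depth_filter: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_frac <= 1.0:
            raise ValueError("max_missing_frac must be in [0, 1]")
        if not 0.0 <= self.het_excess_max <= 1.0:
            raise ValueError("het_excess_max must be in [0, 1]")
        if self.depth_lo_ratio >= self.depth_hi_ratio:
            raise ValueError("depth_lo_ratio must be < depth_hi_ratio")


#: order in which `apply_site_filters` evaluates its rules
FILTER_ORDER = ("indel", "depth", "missingness", "biallelic", "het_excess", "mac")


@dataclass
class FilterReport:
    """Sites removed per rule, in application order."""

    removed: dict = field(default_factory=dict)
    n_input: int = 0
    n_output: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": list(self.removed), "sites_removed": list(self.removed.values())}
        )


# --------------------------------------------------------------------------- I/O


def _code_from_gt(alleles: tuple) -> int:
    """Map a pysam GT allele-index tuple to a genotype code."""
    if len(alleles) != 2:
        raise VcfParseError(f"unsupported ploidy {len(alleles)}")
    a, b = alleles
    if a is None or b is None:
        return MISSING
    n_alt = int(a > 0) + int(b > 0)
    if n_alt == 1:
        return 1
    return 0 if n_alt == 0 else 2


def read_vcf(path: str, keep_monomorphic: bool = False) -> GenotypeMatrix:
    """Read a VCF 4.x file into a :class:`GenotypeMatrix`.

    Genotypes are collapsed to codes: hom-ref 0, any heterozygote 1, any
    homozygote for a non-reference allele 2, ``./.`` missing.  Monomorphic
    records (no ALT) are kept only when ``keep_monomorphic`` is set.
    """
    chroms, poss, refs, alts, rows, depth_rows = [], [], [], [], [], []
    any_depth = False
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for line_no, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
            rec_alts = [a for a in (rec.alts or []) if a is not None]
            if not rec_alts and not keep_monomorphic:
                continue
            codes, dps = [], []
            for s in samples:
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None or all(a is None for a in gt):
                    codes.append(MISSING)
                else:
                    try:
                        codes.append(_code_from_gt(tuple(gt)))
                    except VcfParseError as exc:
                        raise VcfParseError(
                            f"{path}: record {line_no} ({rec.chrom}:{rec.pos}): {exc}"
                        ) from exc
                dp = call.get("DP")
                if dp is not None:
                    any_depth = True
                dps.append(np.nan if dp is None else float(dp))
            chroms.append(rec.chrom)
            poss.append(rec.pos)
            refs.append(rec.ref)
            alts.append(list(rec_alts))
            rows.append(codes)
            depth_rows.append(dps)
    genotypes = (
        np.asarray(rows, dtype=np.int8)
        if rows
        else np.zeros((0, len(samples)), dtype=np.int8)
    )
    depths = np.asarray(depth_rows, dtype=float) if (any_depth and rows) else None
    return GenotypeMatrix(
        chrom_ids=np.asarray(chroms, dtype=object),
        positions=np.asarray(poss, dtype=np.int64),
        ref_allele=np.asarray(refs, dtype=object),
        alt_alleles=alts,
        genotypes=genotypes,
        sample_ids=samples,
        depths=depths,
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 (CHROM POS REF ALT GT[, DP]) that round-trips
    through :func:`read_vcf`."""
    have_depth = gm.depths is not None
    contigs = list(pd.unique(gm.chrom_ids))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig in contigs:
            last = gm.positions[gm.chrom_ids == contig].max() if gm.n_sites else 1
            fh.write(f"##contig=<ID={contig},length={int(last) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if have_depth:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        fmt = "GT:DP" if have_depth else "GT"
        for i in range(gm.n_sites):
            alt = ",".join(gm.alt_alleles[i]) if gm.alt_alleles[i] else "."
            fields = []
            for j in range(gm.n_individuals):
                g = _GT_STR[int(gm.genotypes[i, j])]
                if have_depth:
                    d = gm.depths[i, j]
                    g += ":." if np.isnan(d) else f":{int(d)}"
                fields.append(g)
            fh.write(
                f"{gm.chrom_ids[i]}\t{int(gm.positions[i])}\t.\t{gm.ref_allele[i]}\t"
                f"{alt}\t.\tPASS\t.\t{fmt}\t" + "\t".join(fields) + "\n"
            )


# ----------------------------------------------------------------- site filters


def apply_site_filters(
    gm: GenotypeMatrix,
    cfg: SiteFilterConfig,
    expected_mean_depth: Optional[float] = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the per-site filters in the fixed order
    indel -> depth -> missingness -> biallelic -> het-excess -> MAC.

    Returns the surviving matrix and a :class:`FilterReport` whose per-rule
    counts sum to ``n_input - n_output``.
    """
    report = FilterReport(n_input=gm.n_sites)
    keep = np.ones(gm.n_sites, dtype=bool)

    def _drop(rule: str, bad: np.ndarray) -> None:
        bad = bad & keep
        report.removed[rule] = int(bad.sum())
        keep[bad] = False

    if cfg.exclude_indels:
        _drop("indel", gm.is_indel.copy())
    else:
        report.removed["indel"] = 0

    if cfg.use_depth_filter:
        if gm.depths is None:
            raise ValueError("depth filter enabled but matrix carries no depths")
        if expected_mean_depth is None:
            raise ValueError("depth filter enabled but expected_mean_depth missing")
        mean_dp = np.nanmean(gm.depths, axis=1)
        bad = (mean_dp > cfg.depth_hi_ratio * expected_mean_depth) | (
            mean_dp < cfg.depth_lo_ratio * expected_mean_depth
        )
        _drop("depth", np.nan_to_num(bad, nan=True).astype(bool))
    else:
        report.removed["depth"] = 0

    _drop("missingness", gm.missingness_per_site() > cfg.max_missing_frac)

    if cfg.biallelic_only:
        _drop("biallelic", np.array([len(a) > 1 for a in gm.alt_alleles], dtype=bool))
    else:
        report.removed["biallelic"] = 0

    called = gm.genotypes != MISSING
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(n_called > 0, (gm.genotypes == 1).sum(axis=1) / n_called, 0.0)
    _drop("het_excess", het_frac > cfg.het_excess_max)

    alt_count = np.where(called, np.maximum(gm.genotypes, 0), 0).sum(axis=1)
    mac = np.minimum(alt_count, 2 * n_called - alt_count)
    seg = (alt_count > 0) & (alt_count < 2 * n_called)
    _drop("mac", seg & (mac < cfg.min_minor_allele_count))

    out = gm.take_sites(keep)
    report.n_output = out.n_sites
    return out, report


# ------------------------------------------------------------------- LD pruning


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, missing pairwise-deleted."""
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = a[ok].astype(float)
    y = b[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(
    gm: GenotypeMatrix,
    window_kb: float = 1000.0,
    step_sites: int = 1,
    r2_max: float = 0.9,
) -> GenotypeMatrix:
    """Greedy LD pruning on genotype dosages.

    Scans sites left to right within each contig; a site is dropped when its
    squared dosage correlation with any already-retained site within
    ``window_kb`` kilobases exceeds ``r2_max`` (the earlier site wins).  With
    ``step_sites=1`` this is equivalent to pairwise window pruning and the
    result is idempotent under re-pruning.
    """
    if not 0.0 < r2_max <= 1.0:
        raise ValueError("r2_max must be in (0, 1]")
    window_bp = window_kb * 1000.0
    keep = np.ones(gm.n_sites, dtype=bool)
    for contig in pd.unique(gm.chrom_ids):
        idx = np.flatnonzero(gm.chrom_ids == contig)
        kept: list[int] = []
        for j in idx:
            pos_j = gm.positions[j]
            conflict = False
            for i in reversed(kept):
                if pos_j - gm.positions[i] > window_bp:
                    break
                if _pairwise_r2(gm.genotypes[i], gm.genotypes[j]) > r2_max:
                    conflict = True
                    break
            if conflict:
                keep[j] = False
            else:
                kept.append(j)
    return gm.take_sites(keep)


# --------------------------------------------------------------- relatedness


def estimate_pihat(gm: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise pi_hat (proportion of alleles shared IBD) for all individuals.

    Method-of-moments IBD from identity-by-state counts: for each pair the
    observed numbers of sites with IBS 0/1/2 are compared with their
    expectations given sample allele frequencies, yielding P(IBD=0/1/2);
    pi_hat = P(IBD=1)/2 + P(IBD=2), clamped to [0, 1].
    """
    if gm.n_individuals < 2:
        raise ValueError("need at least two individuals")
    p = gm.alt_frequency()
    seg = (p > 0) & (p < 1)
    if not seg.any():
        raise ValueError("no polymorphic sites: IBS moments undefined")
    g = gm.genotypes[seg].astype(np.int16)
    p = p[seg]
    q = 1.0 - p
    n = gm.n_individuals
    # per-site expected IBS probabilities conditional on IBD state
    e0_ibs0 = 2.0 * p**2 * q**2
    e0_ibs1 = 4.0 * p**3 * q + 4.0 * p * q**3
    e0_ibs2 = p**4 + q**4 + 4.0 * p**2 * q**2
    e1_ibs1 = 2.0 * p * q
    e1_ibs2 = p**2 + q**2
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = g[:, i], g[:, j]
            ok = (gi != MISSING) & (gj != MISSING)
            if not ok.any():
                raise ValueError(
                    f"no shared called sites for pair ({gm.sample_ids[i]}, {gm.sample_ids[j]})"
                )
            diff = np.abs(gi[ok] - gj[ok])
            ibs0 = float((diff == 2).sum())
            ibs1 = float((diff == 1).sum())
            ibs2 = float((diff == 0).sum())
            E0_0, E0_1, E0_2 = e0_ibs0[ok].sum(), e0_ibs1[ok].sum(), e0_ibs2[ok].sum()
            E1_1, E1_2 = e1_ibs1[ok].sum(), e1_ibs2[ok].sum()
            n_ok = float(ok.sum())
            z0 = ibs0 / E0_0 if E0_0 > 0 else 0.0
            z1 = (ibs1 - z0 * E0_1) / E1_1 if E1_1 > 0 else 0.0
            z2 = (ibs2 - z0 * E0_2 - z1 * E1_2) / n_ok
            z = np.clip([z0, z1, z2], 0.0, None)
            s = z.sum()
            if s > 0:
                z = z / s
            pihat = z[1] / 2.0 + z[2]
            out[i, j] = out[j, i] = float(np.clip(pihat, 0.0, 1.0))
    return pd.DataFrame(out, index=gm.sample_ids, columns=gm.sample_ids)


def remove_related(gm: GenotypeMatrix, pihat_cutoff: float = 0.2) -> GenotypeMatrix:
    """Drop individuals until no pair has pi_hat above the cutoff.

    Greedy: repeatedly take the worst pair and remove its higher-missingness
    member (ties broken by sample order: the later sample is dropped).
    """
    if not 0.0 < pihat_cutoff < 1.0:
        raise ValueError("pihat_cutoff must be in (0, 1)")
    pihat = estimate_pihat(gm).to_numpy()
    miss = gm.missingness_per_individual()
    active = list(range(gm.n_individuals))
    while True:
        worst, worst_val = None, pihat_cutoff
        for a_i, i in enumerate(active):
            for j in active[a_i + 1 :]:
                if pihat[i, j] > worst_val:
                    worst_val = pihat[i, j]
                    worst = (i, j)
        if worst is None:
            break
        i, j = worst
        drop = j if miss[j] >= miss[i] else i
        active.remove(drop)
    return gm.take_individuals(active)


def thin_sites(gm: GenotypeMatrix, min_spacing_bp: int = 1000, seed: int = 0) -> GenotypeMatrix:
    """Random thinning to at most one site per ``min_spacing_bp`` interval.

    Intervals are [k*spacing, (k+1)*spacing) per contig; within each interval
    one site is kept uniformly at random (reproducible under ``seed``).
    """
    rng = np.random.default_rng(seed)
    keep = np.zeros(gm.n_sites, dtype=bool)
    for contig in pd.unique(gm.chrom_ids):
        idx = np.flatnonzero(gm.chrom_ids == contig)
        bins = gm.positions[idx] // min_spacing_bp
        for b in np.unique(bins):
            members = idx[bins == b]
            keep[rng.choice(members)] = True
    return gm.take_sites(keep)
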