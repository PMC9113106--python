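"""Forward-in-time diploid Wright-Fisher simulator with mutation, recombination,
piecewise-constant demography, and optional two-deme migration.

The population is a matrix of haplotypes over the currently segregating sites
only (finite-sites model with back mutation): each generation every offspring
draws two parents from its deme (or, with probability ``m``, from the other
deme), receives one recombinant gamete per parent, and new mutations are placed
uniformly over the genome.  Columns that fix or are lost are compacted away
periodically; a fixed derived allele simply becomes the current reference
state, so a later mutation at the same position is a reversal.

Genomic elements behave as independently assorting chromosomes; within an
element crossovers are Poisson with rate ``rec`` per site per meiosis.

The scale of the emulated study (N0 = 50,000 diploids, three 10-Mbp elements,
mu = 1.54e-9, rec = 1e-8, 100,000 burn-in generations) is expressible in
:class:`SimulationConfig`; analyses and tests run scaled-down configurations
that preserve N*mu and N-relative event times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genotype_io import GenotypeMatrix

#: fin whale generation time in years used for reporting timescales
GENERATION_TIME_YEARS = 25.9


@dataclass
class SimulationConfig:
    """Wright-Fisher run parameters.

    ``n_diploid_initial`` diploids evolve for ``burnin_generations`` with
    mutation rate ``mu`` (per site per generation) and recombination
    probability ``rec`` (per site per meiosis) over ``genome_elements``
    (element lengths in bp); ``sample_size`` diploids are drawn from the focal
    deme at the end of the scenario.
    """

    n_diploid_initial: int = 50_000
    genome_elements: Sequence[int] = (10_000_000, 10_000_000, 10_000_000)
    mu: float = 1.54e-9
    rec: float = 1e-8
    burnin_generations: int = 100_000
    sample_size: int = 51
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu < 0 or self.rec < 0:
            raise ValueError("mu and rec must be nonnegative")
        if any(L <= 0 for L in self.genome_elements):
            raise ValueError("element lengths must be positive")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")

    @property
    def genome_length(self) -> int:
        return int(sum(self.genome_elements))


@dataclass
class DemographicScenario:
    """Piecewise-constant deme sizes with an optional migration schedule.

    ``epochs`` is an ordered list of ``(generation_offset_after_burnin,
    deme_sizes)``; each epoch's sizes apply from its offset until the next
    epoch's offset, and the last offset is the sampling generation.
    ``migration`` gives, per epoch, the probability that a parent is drawn
    from the other deme (0 for single-deme scenarios).  Deme 0 is the focal
    deme that is sampled.
    """

    name: str
    epochs: list
    migration: Optional[list] = None
    generation_time_years: float = GENERATION_TIME_YEARS

    def __post_init__(self) -> None:
        offsets = [int(e[0]) for e in self.epochs]
        if len(offsets) < 2:
            raise ValueError("scenario needs at least a start epoch and a sampling offset")
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("epoch offsets must be strictly increasing")
        for _, sizes in self.epochs:
            for s in sizes:
                if s < 2:
                    raise ValueError("deme sizes must be >= 2")
        if self.migration is None:
            self.migration = [0.0] * len(self.epochs)
        if len(self.migration) != len(self.epochs):
            raise ValueError("migration schedule must have one rate per epoch")
        if any(not 0.0 <= m <= 0.5 for m in self.migration):
            raise ValueError("migration rates must be in [0, 0.5]")

    @property
    def duration(self) -> int:
        """Generations simulated after burn-in (the sampling offset)."""
        return int(self.epochs[-1][0])

    def sizes_at(self, g: int) -> tuple:
        """(deme_sizes, m) in force at post-burn-in generation g (1-based births)."""
        sizes, m = self.epochs[0][1], self.migration[0]
        for (off, sz), mig in zip(self.epochs, self.migration):
            if g > off:
                sizes, m = sz, mig
        return tuple(int(s) for s in sizes), float(m)

    def epochs_in_years(self) -> list:
        """Epoch offsets converted to years before sampling."""
        end = self.duration
        return [
            ((end - off) * self.generation_time_years, tuple(sizes))
            for off, sizes in self.epochs
        ]


def save_scenario(scenario: DemographicScenario, path: str) -> None:
    """Write a scenario as structured text (JSON: name, epochs, migration,
    generation time)."""
    import json

    with open(path, "w") as fh:
        json.dump(
            {
                "name": scenario.name,
                "epochs": [[int(off), list(map(int, sizes))] for off, sizes in scenario.epochs],
                "migration": list(map(float, scenario.migration)),
                "generation_time_years": scenario.generation_time_years,
            },
            fh,
            indent=2,
        )


def load_scenario(path: str) -> DemographicScenario:
    """Read a scenario written by :func:`save_scenario`."""
    import json

    with open(path) as fh:
        d = json.load(fh)
    return DemographicScenario(
        name=d["name"],
        epochs=[(int(off), tuple(sizes)) for off, sizes in d["epochs"]],
        migration=list(d["migration"]),
        generation_time_years=float(d["generation_time_years"]),
    )


class WrightFisherPopulation:
    """Mutable simulation state: haplotypes over active segregating columns.

    Exposed for property tests (martingale / heterozygosity-decay checks need
    a hand-seeded initial state); :func:`simulate` is the high-level entry.
    """

    _COMPACT_EVERY = 32

    def __init__(
        self,
        cfg: SimulationConfig,
        deme_sizes: Sequence[int],
        rng: np.random.Generator,
        haplotypes: Optional[np.ndarray] = None,
        positions: Optional[np.ndarray] = None,
    ):
        self.cfg = cfg
        self.rng = rng
        self.deme_sizes = [int(n) for n in deme_sizes]
        self.L = cfg.genome_length
        bounds = np.cumsum([0] + list(cfg.genome_elements))
        self._elem_bounds = bounds  # len n_elem + 1
        n_hap = 2 * sum(self.deme_sizes)
        if haplotypes is None:
            self._cap = 1024
            self.haps = np.zeros((n_hap, self._cap), dtype=np.uint8)
            self.col_pos = np.zeros(0, dtype=np.int64)
        else:
            haplotypes = np.asarray(haplotypes, dtype=np.uint8)
            positions = np.asarray(positions, dtype=np.int64)
            self._cap = max(1024, 2 * haplotypes.shape[1])
            self.haps = np.zeros((n_hap, self._cap), dtype=np.uint8)
            self.haps[:, : haplotypes.shape[1]] = haplotypes
            self.col_pos = positions.copy()
        self._pos_map = np.full(self.L, -1, dtype=np.int32)  # genome pos -> column
        self._pos_map[self.col_pos] = np.arange(self.n_col, dtype=np.int32)
        self._gens_since_compact = 0
        self._nc_compacted = self.n_col
        self._body_bounds = np.zeros(len(self._elem_bounds), dtype=np.int64)
        self._compact()  # sort columns by position, set body bounds

    # ------------------------------------------------------------------ state

    @property
    def n_col(self) -> int:
        return len(self.col_pos)

    @property
    def n_hap(self) -> int:
        return self.haps.shape[0]

    def allele_frequencies(self) -> np.ndarray:
        if self.n_col == 0:
            return np.zeros(0)
        return self.haps[:, : self.n_col].sum(axis=0) / self.n_hap

    def mean_heterozygosity(self) -> float:
        """Expected per-individual heterozygous fraction over active columns
        (2pq summed over sites, Hardy-Weinberg pairing)."""
        p = self.allele_frequencies()
        return float(np.sum(2.0 * p * (1.0 - p)))

    # ------------------------------------------------------------- generation

    def _elem_of(self, positions: np.ndarray) -> np.ndarray:
        return np.searchsorted(self._elem_bounds, positions, side="right") - 1

    def _choose_parent_demes(self, n: int, deme: int, m: float, old_sizes) -> np.ndarray:
        """Global *individual* indices of 2 parents for each of n offspring."""
        n_demes = len(old_sizes)
        offsets = np.cumsum([0] + list(old_sizes))
        if n_demes == 1 or (m == 0.0 and old_sizes[min(deme, n_demes - 1)] > 0):
            src = min(deme, n_demes - 1)
            return offsets[src] + self.rng.integers(old_sizes[src], size=(n, 2))
        other = 1 - deme
        if old_sizes[deme] == 0:  # founding event: all parents from the other deme
            return offsets[other] + self.rng.integers(old_sizes[other], size=(n, 2))
        from_other = self.rng.random((n, 2)) < m
        idx_same = offsets[deme] + self.rng.integers(old_sizes[deme], size=(n, 2))
        idx_other = offsets[other] + self.rng.integers(old_sizes[other], size=(n, 2))
        return np.where(from_other, idx_other, idx_same)

    def step(self, new_sizes: Sequence[int], m: float = 0.0) -> None:
        """Advance one generation to deme sizes ``new_sizes`` with migration ``m``."""
        old_sizes = self.deme_sizes
        new_sizes = [int(s) for s in new_sizes]
        parent_blocks = [
            self._choose_parent_demes(nd, d, m, old_sizes)
            for d, nd in enumerate(new_sizes)
            if nd > 0
        ]
        parents = np.concatenate(parent_blocks, axis=0)  # (N_new, 2) individual idx
        n_new = parents.shape[0]
        gam_parent = parents.reshape(-1)  # (2*N_new,) one gamete per parent slot
        n_gam = gam_parent.size
        nc = self.n_col
        rng = self.rng

        # independent assortment: starting haplotype per gamete per element
        n_elem = len(self._elem_bounds) - 1
        start = rng.integers(2, size=(n_gam, n_elem), dtype=np.int64)
        new_haps = np.empty((2 * n_new, self._cap), dtype=np.uint8)
        new_haps[:, nc:] = 0  # buffer columns must stay zero
        if nc > 0:
            if n_elem == 1:
                # fast path: one gather row per gamete
                new_haps[:, :nc] = self.haps[2 * gam_parent + start[:, 0], :nc]
            else:
                # independent assortment: the column body (everything present
                # at the last compaction) is position-sorted, so each element
                # is a contiguous slice and gathers stay cache-friendly; only
                # the post-compaction tail needs scattered indexing
                body_n = self._nc_compacted
                for e in range(n_elem):
                    lo, hi = self._body_bounds[e], self._body_bounds[e + 1]
                    if hi > lo:
                        rows_e = 2 * gam_parent + start[:, e]
                        new_haps[:, lo:hi] = self.haps[rows_e, lo:hi]
                if nc > body_n:
                    tail = np.arange(body_n, nc)
                    elem_tail = self._elem_of(self.col_pos[body_n:nc])
                    for e in range(n_elem):
                        cols_e = tail[elem_tail == e]
                        if cols_e.size:
                            rows_e = 2 * gam_parent + start[:, e]
                            new_haps[:, cols_e] = self.haps[np.ix_(rows_e, cols_e)]

        # crossovers within elements (Poisson per gamete per element); gametes
        # with crossovers are re-derived with switch parity along the element,
        # vectorized per crossover-count group
        if self.cfg.rec > 0.0 and nc > 0:
            lam = self.cfg.rec * np.diff(self._elem_bounds).astype(float)
            n_x = rng.poisson(lam, size=(n_gam, n_elem))
            elem_of_col = self._elem_of(self.col_pos) if (n_elem > 1 and n_x.any()) else None
            for e in range(n_elem):
                lo, hi = self._elem_bounds[e], self._elem_bounds[e + 1]
                if not n_x[:, e].any():
                    continue
                if n_elem == 1:
                    cols = slice(0, nc)
                    cpos = self.col_pos
                else:
                    cols = np.flatnonzero(elem_of_col == e)
                    cpos = self.col_pos[cols]
                k_of = n_x[:, e]
                for k in np.unique(k_of[k_of > 0]):
                    grp = np.flatnonzero(k_of == k)
                    pts = rng.integers(lo, hi, size=(grp.size, k))
                    # switch parity: number of crossover points at or below
                    # each column position, mod 2
                    flip = (
                        (cpos[None, None, :] >= pts[:, :, None]).sum(axis=1) % 2
                    ).astype(bool)
                    s = start[grp, e]
                    rows_a = 2 * gam_parent[grp] + s
                    rows_b = 2 * gam_parent[grp] + 1 - s
                    if isinstance(cols, slice):
                        seg = np.where(flip, self.haps[rows_b, :nc], self.haps[rows_a, :nc])
                        new_haps[grp, :nc] = seg
                    else:
                        seg = np.where(
                            flip,
                            self.haps[np.ix_(rows_b, cols)],
                            self.haps[np.ix_(rows_a, cols)],
                        )
                        new_haps[grp[:, None], cols[None, :]] = seg

        self.haps = new_haps
        self.deme_sizes = new_sizes

        # mutation: Bernoulli per site per gamete, realized as a Poisson number
        # of uniformly placed hits; a hit on a segregating column toggles it
        if self.cfg.mu > 0.0:
            n_mut = rng.poisson(self.cfg.mu * self.L * 2 * n_new)
            if n_mut:
                mrows = rng.integers(2 * n_new, size=n_mut)
                mpos = rng.integers(self.L, size=n_mut)
                self._apply_mutations(mrows, mpos)

        self._gens_since_compact += 1
        # compact on schedule, or early once the unsorted mutation tail grows
        # past a quarter of the sorted body (keeps gathers slice-shaped)
        if (
            self._gens_since_compact >= self._COMPACT_EVERY
            or self.n_col > self._nc_compacted + max(512, self._nc_compacted // 4)
        ):
            self._compact()

    def _apply_mutations(self, rows: np.ndarray, positions: np.ndarray) -> None:
        cols = self._pos_map[positions]
        hit = cols >= 0
        if hit.any():  # back-mutation / recurrent hit on a segregating column
            np.bitwise_xor.at(self.haps, (rows[hit], cols[hit].astype(np.int64)), 1)
        new_pos = positions[~hit]
        new_rows = rows[~hit]
        if new_pos.size == 0:
            return
        # one new column per distinct position; repeated hits at the same new
        # position (or same row) resolve by XOR, exactly like back mutation
        uniq, inv = np.unique(new_pos, return_inverse=True)
        if self.n_col + uniq.size > self._cap:
            self._compact(grow=True)
        nc = self.n_col
        new_cols = nc + np.arange(uniq.size, dtype=np.int64)
        self._pos_map[uniq] = new_cols.astype(np.int32)
        self.col_pos = np.concatenate([self.col_pos, uniq])
        if uniq.size == new_pos.size:  # common case: no repeated position
            self.haps[new_rows, new_cols[inv]] = 1
        else:
            np.bitwise_xor.at(self.haps, (new_rows, new_cols[inv]), 1)

    def _compact(self, grow: bool = False) -> None:
        """Drop lost and fixed columns (fixed derived alleles become the new
        reference) and re-sort the surviving columns by genome position, so
        that per-element column ranges are contiguous slices."""
        nc = self.n_col
        if nc:
            sums = self.haps[:, :nc].sum(axis=0, dtype=np.int64)
            keep = (sums > 0) & (sums < self.n_hap)
            fixed = sums == self.n_hap
            if fixed.any():  # substitution: flip column to the new reference
                self.haps[:, :nc][:, fixed] = 0
            kept = np.flatnonzero(keep)
            kept = kept[np.argsort(self.col_pos[kept], kind="stable")]
        else:
            kept = np.zeros(0, dtype=np.int64)
        new_cap = max(1024, len(kept) + max(1024, len(kept) // 3))
        if grow:
            new_cap = max(new_cap, 2 * self._cap)
        new = np.zeros((self.n_hap, new_cap), dtype=np.uint8)
        new[:, : len(kept)] = self.haps[:, kept]
        self.haps = new
        self._cap = new_cap
        self.col_pos = self.col_pos[kept]
        self._pos_map.fill(-1)
        self._pos_map[self.col_pos] = np.arange(self.n_col, dtype=np.int32)
        self._gens_since_compact = 0
        self._nc_compacted = self.n_col
        self._body_bounds = np.searchsorted(self.col_pos, self._elem_bounds)

    def run(self, n_generations: int, sizes=None, m: float = 0.0) -> None:
        sizes = self.deme_sizes if sizes is None else sizes
        for _ in range(int(n_generations)):
            self.step(sizes, m)

    # ------------------------------------------------------------- extraction

    def sample_genotypes(self, n: int, deme: int = 0) -> GenotypeMatrix:
        """Genotypes of ``n`` diploids sampled without replacement from ``deme``."""
        if n > self.deme_sizes[deme]:
            raise ValueError(
                f"sample_size {n} exceeds deme {deme} size {self.deme_sizes[deme]}"
            )
        self._compact()
        offset = int(np.cumsum([0] + self.deme_sizes)[deme])
        chosen = np.sort(self.rng.choice(self.deme_sizes[deme], size=n, replace=False))
        rows = np.empty(2 * n, dtype=np.int64)
        rows[0::2] = 2 * (offset + chosen)
        rows[1::2] = 2 * (offset + chosen) + 1
        nc = self.n_col
        haps = self.haps[rows, :nc]
        geno = (haps[0::2].astype(np.int8) + haps[1::2].astype(np.int8)).T  # sites x ind
        order = np.argsort(self.col_pos, kind="stable")
        pos = self.col_pos[order]
        geno = geno[order]
        elem = self._elem_of(pos)
        chrom = np.array([f"elem{e + 1}" for e in elem], dtype=object)
        pos_in_elem = pos - self._elem_bounds[elem] + 1  # 1-based within element
        return GenotypeMatrix(
            chrom_ids=chrom,
            positions=pos_in_elem,
            ref_allele=np.array(["A"] * len(pos), dtype=object),
            alt_alleles=[["T"]] * len(pos),
            genotypes=geno,
            sample_ids=[f"ind{i}" for i in range(n)],
        )


def simulate(cfg: SimulationConfig, scenario: DemographicScenario) -> GenotypeMatrix:
    """Run burn-in plus the scenario and return sampled genotypes from deme 0.

    Reproducible: the same (cfg, scenario) with the same ``cfg.seed`` yields a
    bit-identical matrix.
    """
    final_sizes, _ = scenario.sizes_at(scenario.duration)
    if cfg.sample_size > final_sizes[0]:
        raise ValueError("sample_size exceeds final focal deme size")
    rng = np.random.default_rng(cfg.seed)
    pop = WrightFisherPopulation(cfg, deme_sizes=[cfg.n_diploid_initial], rng=rng)
    for _ in range(cfg.burnin_generations):
        pop.step([cfg.n_diploid_initial], 0.0)
    for g in range(1, scenario.duration + 1):
        sizes, m = scenario.sizes_at(g)
        pop.step(sizes, m)
    return pop.sample_genotypes(cfg.sample_size, deme=0)


def scenario_library(
    n_base: int = 50_000,
    horizon_generations: int = 30,
    bottleneck_duration: int = 5,
    decline_fraction: float = 0.5,
    migration_rate: float = 0.05,
    generation_time_years: float = GENERATION_TIME_YEARS,
) -> list:
    """Named demographic scenario families over a fixed horizon.

    The default horizon (30 generations = ~800 years at 25.9 y/generation)
    and the bottleneck timing (an ~80% drop within the last few generations,
    i.e. ~100-150 years before sampling) match the whaling-era hypotheses the
    simulations are meant to discriminate.  Families: constant size, gradual
    decline, bottlenecks of 20/50/80% severity, bottleneck with recovery, and
    migration variants fed from an unaffected equal-size deme.
    """
    H = int(horizon_generations)
    D = int(bottleneck_duration)
    if D >= H:
        raise ValueError("bottleneck_duration must be shorter than the horizon")
    N = int(n_base)
    out = [
        DemographicScenario(
            "constant",
            epochs=[(0, (N,)), (H, (N,))],
            generation_time_years=generation_time_years,
        )
    ]
    # stepwise linear decline to decline_fraction * N over the horizon
    n_steps = min(10, H)
    epochs = []
    for k in range(n_steps):
        off = round(k * H / n_steps)
        frac = 1.0 - (1.0 - decline_fraction) * (k / n_steps)
        epochs.append((off, (max(2, round(N * frac)),)))
    epochs.append((H, (max(2, round(N * decline_fraction)),)))
    out.append(
        DemographicScenario(
            "gradual_decline", epochs=epochs, generation_time_years=generation_time_years
        )
    )
    for sev in (0.2, 0.5, 0.8):
        nb = max(2, round(N * (1.0 - sev)))
        out.append(
            DemographicScenario(
                f"bottleneck_{int(sev * 100)}",
                epochs=[(0, (N,)), (H - D, (nb,)), (H, (nb,))],
                generation_time_years=generation_time_years,
            )
        )
    # drop followed by recovery to the pre-bottleneck size (recovery phase
    # shortened when the bottleneck occupies most of the horizon)
    nb = max(2, round(N * 0.2))
    rd = min(D, H // 3)
    out.append(
        DemographicScenario(
            "bottleneck_80_recovery",
            epochs=[(0, (N,)), (H - 2 * rd, (nb,)), (H - rd, (N,)), (H, (N,))],
            generation_time_years=generation_time_years,
        )
    )
    # migration variants: deme 1 is an unaffected population of size N
    out.append(
        DemographicScenario(
            "constant_migration",
            epochs=[(0, (N, N)), (H, (N, N))],
            migration=[migration_rate, migration_rate],
            generation_time_years=generation_time_years,
        )
    )
    out.append(
        DemographicScenario(
            "bottleneck_80_migration",
            epochs=[(0, (N, N)), (H - D, (nb, N)), (H, (nb, N))],
            migration=[migration_rate, migration_rate, migration_rate],
            generation_time_years=generation_time_years,
        )
    )
    return out


def sample_fsfs(
    cfg: SimulationConfig,
    scenario: DemographicScenario,
    n_replicates: int,
    seed: Optional[int] = None,
):
    """Average folded SFS over simulation replicates.

    Replicate k runs with seed ``(seed or cfg.seed) + k``.  Returns
    ``(mean_sfs, replicate_spectra)`` where ``mean_sfs`` carries per-bin mean
    counts (floats) and each replicate spectrum is a :class:`FoldedSFS`.
    """
    from dataclasses import replace

    from .sfs_demography import FoldedSFS, fsfs_from_genotypes

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    base = cfg.seed if seed is None else seed
    spectra = []
    for k in range(n_replicates):
        rep_cfg = replace(cfg, seed=int(base + k) % (2**31))
        gm = simulate(rep_cfg, scenario)
        spectra.append(fsfs_from_genotypes(gm))
    counts = np.mean([s.counts for s in spectra], axis=0)
    n_used = int(round(float(np.mean([s.n_sites_used for s in spectra]))))
    mean_sfs = FoldedSFS(
        counts=counts, n_individuals=cfg.sample_size, n_sites_used=n_used
    )
    return mean_sfs, spectra
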