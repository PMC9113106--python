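"""Runs of homozygosity (ROH) from per-individual heterozygosity tracks.

Contigs are tiled into fixed windows (default 10 kbp); a window is called
homozygous when its heterozygous fraction of callable sites is below a
threshold (default 0.2%), and a run of at least ``min_windows`` consecutive
homozygous windows (default 10, i.e. >= 100 kbp) is a ROH.  F_ROH at a length
cutoff is the fraction of the analyzed genome covered by ROH at least that
long; profiling cutoffs run from 100 kbp upward in 100-kbp steps.

Contigs shorter than 3 Mbp are excluded from the analysis by default, so that
window statistics are not dominated by scaffold edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from .stats_tests import anova_oneway

MIN_CONTIG_LENGTH = 3_000_000
DEFAULT_WINDOW = 10_000
DEFAULT_HET_THRESHOLD = 0.002
DEFAULT_MIN_WINDOWS = 10
DEFAULT_CUTOFFS = tuple(range(100_000, 1_100_000, 100_000))


@dataclass
class WindowTrack:
    """Tiled per-window heterozygosity for one individual on one contig."""

    contig: str
    window_size_bp: int
    n_callable: np.ndarray
    n_het: np.ndarray
    masked: np.ndarray  # True where too few callable sites

    def __post_init__(self) -> None:
        self.n_callable = np.asarray(self.n_callable, dtype=np.int64)
        self.n_het = np.asarray(self.n_het, dtype=np.int64)
        self.masked = np.asarray(self.masked, dtype=bool)

    @property
    def het_rate(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_callable > 0, self.n_het / self.n_callable, np.nan)

    @property
    def n_windows(self) -> int:
        return len(self.n_callable)


@dataclass
class ROHSegment:
    """One run of homozygosity (bp coordinates, half-open)."""

    contig: str
    start: int
    end: int
    n_windows: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FROHProfile:
    """Cumulative F_ROH by minimum ROH length cutoff."""

    cutoffs: np.ndarray
    froh_at_cutoff: np.ndarray
    analyzed_length_bp: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cutoff_bp": self.cutoffs, "froh": self.froh_at_cutoff})


def window_track_from_positions(
    het_positions: np.ndarray,
    contig_length: int,
    contig: str = "contig1",
    window_size: int = DEFAULT_WINDOW,
    callable_positions: Optional[np.ndarray] = None,
    min_callable_frac: float = 0.1,
    min_contig_length: int = MIN_CONTIG_LENGTH,
) -> Optional[WindowTrack]:
    """Build a :class:`WindowTrack` from heterozygous-site positions.

    When ``callable_positions`` is None the whole contig is treated as
    callable (the fixture convention); otherwise callable counts are tallied
    per window and windows with fewer than ``min_callable_frac`` times the
    median per-window callable count are masked (the floor adapts to the
    callable density of the input).  Returns None for contigs below the
    minimum length.
    """
    if contig_length is None or contig_length <= 0:
        raise ValueError("contig length required")
    if contig_length < min_contig_length:
        return None
    n_win = contig_length // window_size
    if n_win == 0:
        return None
    het_positions = np.asarray(het_positions, dtype=np.int64)
    het_positions = het_positions[het_positions < n_win * window_size]
    n_het = np.bincount(het_positions // window_size, minlength=n_win)[:n_win]
    if callable_positions is None:
        n_callable = np.full(n_win, window_size, dtype=np.int64)
    else:
        cp = np.asarray(callable_positions, dtype=np.int64)
        cp = cp[cp < n_win * window_size]
        n_callable = np.bincount(cp // window_size, minlength=n_win)[:n_win]
    floor = min_callable_frac * max(float(np.median(n_callable)), 1.0)
    masked = n_callable < floor
    return WindowTrack(
        contig=contig,
        window_size_bp=window_size,
        n_callable=n_callable,
        n_het=n_het,
        masked=masked,
    )


def window_heterozygosity(
    gm: GenotypeMatrix,
    individual,
    contig_lengths: dict,
    window_size: int = DEFAULT_WINDOW,
    min_callable_frac: float = 0.1,
    min_contig_length: int = MIN_CONTIG_LENGTH,
) -> list:
    """Per-contig window tracks for one individual of a genotype matrix that
    includes monomorphic sites (callable = non-missing calls)."""
    j = gm.sample_ids.index(individual) if isinstance(individual, str) else int(individual)
    tracks = []
    for contig in pd.unique(gm.chrom_ids):
        if contig not in contig_lengths:
            raise ValueError(f"length unknown for contig {contig!r}")
        sel = gm.chrom_ids == contig
        g = gm.genotypes[sel][:, j]
        pos0 = gm.positions[sel] - 1  # 0-based
        called = g != MISSING
        track = window_track_from_positions(
            het_positions=pos0[called & (g == 1)],
            contig_length=int(contig_lengths[contig]),
            contig=str(contig),
            window_size=window_size,
            callable_positions=pos0[called],
            min_callable_frac=min_callable_frac,
            min_contig_length=min_contig_length,
        )
        if track is not None:
            tracks.append(track)
    return tracks


def detect_roh(
    track: WindowTrack,
    het_threshold: float = DEFAULT_HET_THRESHOLD,
    min_windows: int = DEFAULT_MIN_WINDOWS,
) -> list:
    """Maximal runs of consecutive unmasked windows with het rate below the
    threshold, at least ``min_windows`` long.  Masked windows break runs."""
    rate = track.het_rate
    low = (~track.masked) & (rate < het_threshold)
    segments = []
    w = track.window_size_bp
    run_start = None
    for i, flag in enumerate(np.append(low, False)):  # sentinel closes final run
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            n = i - run_start
            if n >= min_windows:
                segments.append(
                    ROHSegment(
                        contig=track.contig,
                        start=run_start * w,
                        end=i * w,
                        n_windows=n,
                    )
                )
            run_start = None
    return segments


def froh_profile(
    segments: list,
    analyzed_length: int,
    cutoffs=DEFAULT_CUTOFFS,
) -> FROHProfile:
    """F_ROH at each minimum-length cutoff: summed length of ROH >= cutoff over
    the analyzed genome length.  Monotone nonincreasing in the cutoff."""
    if analyzed_length <= 0:
        raise ValueError("analyzed_length must be positive")
    cutoffs = np.asarray(sorted(cutoffs), dtype=np.int64)
    lengths = np.array([s.length for s in segments], dtype=np.int64)
    froh = np.array(
        [lengths[lengths >= c].sum() / analyzed_length for c in cutoffs], dtype=float
    )
    return FROHProfile(
        cutoffs=cutoffs, froh_at_cutoff=froh, analyzed_length_bp=int(analyzed_length)
    )


def cohort_froh_table(profiles_by_cohort: dict) -> tuple:
    """Long-format F_ROH table plus a per-cutoff one-way ANOVA across cohorts.

    ``profiles_by_cohort`` maps cohort label -> list of FROHProfile (one per
    individual).  Returns (long table, ANOVA table); zero-variance cutoffs are
    flagged with NaN statistics rather than raising.
    """
    if len(profiles_by_cohort) < 2:
        raise ValueError("need at least two cohorts")
    for label, profs in profiles_by_cohort.items():
        if len(profs) < 2:
            raise ValueError(f"cohort {label!r} needs at least two members")
    rows = []
    for label, profs in profiles_by_cohort.items():
        for k, prof in enumerate(profs):
            for c, f in zip(prof.cutoffs, prof.froh_at_cutoff):
                rows.append(
                    {"cohort": label, "member": k, "cutoff_bp": int(c), "froh": float(f)}
                )
    long = pd.DataFrame(rows)
    anova_rows = []
    for c, sub in long.groupby("cutoff_bp"):
        groups = [g["froh"].to_numpy() for _, g in sub.groupby("cohort")]
        means = {label: float(g["froh"].mean()) for label, g in sub.groupby("cohort")}
        try:
            f_stat, p = anova_oneway(groups)
        except ValueError:
            f_stat, p = np.nan, np.nan
        anova_rows.append(
            {"cutoff_bp": int(c), "F": f_stat, "p": p, **{f"mean_{k}": v for k, v in means.items()}}
        )
    return long, pd.DataFrame(anova_rows)


def segments_to_bed(segments: list) -> pd.DataFrame:
    """ROH segments as a BED-style frame (0-based half-open)."""
    return pd.DataFrame(
        [
            {"chrom": s.contig, "start": s.start, "end": s.end, "n_windows": s.n_windows}
            for s in segments
        ],
        columns=["chrom", "start", "end", "n_windows"],
    )
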