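"""Synthetic test inputs with known ground truth.

Stands in for study raw data: (a) diploid genomes with implanted autozygous
tracts of known coordinates (background heterozygosity calibrated to the
baleen-whale scale, ~0.07%), (b) pedigree genotypes with known kinship and
inbreeding, (c) toy CDS annotations with variants whose effect category is
derived by an independent full-translation oracle, and (d) Wright-Fisher
cohorts via :mod:`whalepop.wf_simulator`.

Every fixture is reproducible from (kind, parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .genotype_io import GenotypeMatrix
from .mutational_load import CodingAnnotation, Transcript, _revcomp

DEFAULT_BACKGROUND_HET = 7e-4  # per-bp heterozygous-site rate, baleen-whale scale

#: background rate for ROH fixtures.  Window-based ROH detection at a 0.2%
#: heterozygosity threshold requires the *non-autozygous* background to sit
#: above the threshold; 0.4%/bp puts the background at twice the threshold
#: while the 0.1x tract interior (4e-4) stays at the whale-like scale.
ROH_FIXTURE_BACKGROUND_HET = 4e-3


@dataclass
class FixtureTruth:
    kind: str
    payload: dict
    seed: int

    def write_jsonl(self, path: str) -> None:
        """Append the truth record as one JSON line (arrays to lists)."""
        import json

        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o).__name__)

        with open(path, "a") as fh:
            fh.write(
                json.dumps(
                    {"kind": self.kind, "seed": self.seed, "payload": self.payload},
                    default=default,
                )
                + "\n"
            )


# ------------------------------------------------------------------ ROH genome


def make_roh_genome(
    genome_length: int,
    background_het_rate: float = ROH_FIXTURE_BACKGROUND_HET,
    tracts: Sequence[tuple] = (),
    window_size: int = 10_000,
    seed: int = 0,
    tract_het_factor: float = 0.1,
) -> tuple:
    """Heterozygous-site positions for one diploid genome with implanted
    autozygous tracts.

    Het sites arise as a Poisson process at ``background_het_rate`` per bp
    outside the tracts and at ``tract_het_factor`` times that rate inside
    (residual heterozygosity emulates genotype error inside real ROH).
    Returns ``(het_positions, FixtureTruth)``; truth records the tract
    coordinates (0-based half-open).
    """
    tracts = sorted((int(a), int(b)) for a, b in tracts)
    for (a1, b1), (a2, b2) in zip(tracts, tracts[1:]):
        if a2 < b1:
            raise ValueError("tracts must not overlap")
    for a, b in tracts:
        if a < 0 or b > genome_length or b <= a:
            raise ValueError("tracts must lie within the genome")
    rng = np.random.default_rng(seed)
    regions = []
    cursor = 0
    for a, b in tracts:
        if a > cursor:
            regions.append((cursor, a, background_het_rate))
        regions.append((a, b, background_het_rate * tract_het_factor))
        cursor = b
    if cursor < genome_length:
        regions.append((cursor, genome_length, background_het_rate))
    positions = []
    for a, b, rate in regions:
        n = rng.poisson(rate * (b - a))
        if n:
            positions.append(rng.integers(a, b, size=n))
    het = (
        np.unique(np.concatenate(positions)) if positions else np.zeros(0, dtype=np.int64)
    )
    truth = FixtureTruth(
        kind="roh_genome",
        payload={
            "tracts": tracts,
            "genome_length": int(genome_length),
            "background_het_rate": background_het_rate,
            "window_size": int(window_size),
        },
        seed=seed,
    )
    return het, truth


def score_roh_detection(
    detected: list,
    truth: FixtureTruth,
    min_tract_length: int = 200_000,
) -> dict:
    """Score detected ROH segments against implanted tracts.

    Precision and recall are base-pair level: precision = overlap with any
    truth tract / total detected length; recall = overlap / total truth length
    (tracts >= ``min_tract_length`` only).  Boundary error is, per scored
    tract, the larger of the start and end offsets of the best-overlapping
    segment, in windows.
    """
    w = truth.payload["window_size"]
    tracts = [t for t in truth.payload["tracts"] if t[1] - t[0] >= min_tract_length]
    det = [(s.start, s.end) for s in detected]
    det_len = sum(e - s for s, e in det)
    truth_len = sum(e - s for s, e in tracts)

    def overlap(a, b):
        return max(0, min(a[1], b[1]) - max(a[0], b[0]))

    total_overlap = sum(overlap(t, d) for t in tracts for d in det)
    boundary_errors = []
    matched = 0
    for t in tracts:
        ovs = [(overlap(t, d), d) for d in det]
        best_ov, best = max(ovs, key=lambda x: x[0]) if ovs else (0, None)
        if best_ov > 0:
            matched += 1
            boundary_errors.append(
                max(abs(best[0] - t[0]), abs(best[1] - t[1])) / w
            )
    return {
        "precision": (total_overlap / det_len) if det_len else 1.0,
        "recall": (total_overlap / truth_len) if truth_len else 1.0,
        "tract_recall": (matched / len(tracts)) if tracts else 1.0,
        "max_boundary_error_windows": max(boundary_errors) if boundary_errors else 0.0,
        "n_detected": len(det),
        "n_truth": len(tracts),
    }


# ------------------------------------------------------------------- pedigrees


def _kinship_from_pedigree(order: list, parents: dict) -> np.ndarray:
    """Recursive kinship matrix; ``order`` lists individuals with parents
    before children, founders map to (None, None)."""
    n = len(order)
    idx = {name: i for i, name in enumerate(order)}
    phi = np.zeros((n, n))
    for i, a in enumerate(order):
        pa = parents.get(a, (None, None))
        if pa[0] is None:
            phi[i, i] = 0.5
        else:
            phi[i, i] = 0.5 * (1.0 + phi[idx[pa[0]], idx[pa[1]]])
        for j in range(i):
            if pa[0] is None:
                phi[i, j] = phi[j, i] = 0.0
            else:
                phi[i, j] = phi[j, i] = 0.5 * (
                    phi[idx[pa[0]], j] + phi[idx[pa[1]], j]
                )
    return phi


def make_pedigree_genotypes(
    n_founders: int,
    relationships: dict,
    n_sites: int = 10_000,
    seed: int = 0,
    allele_freqs: Optional[np.ndarray] = None,
) -> tuple:
    """Genotypes for founders plus pedigree offspring.

    Founders (named ``F0..``) draw phased alleles from Hardy-Weinberg at the
    given frequencies (default: uniform on [0.05, 0.5], so IBS moments are
    informative); each offspring in ``relationships`` (child -> (parent1,
    parent2); selfing allowed) receives one random allele per parent per site.
    Truth carries the pedigree kinship matrix and per-individual inbreeding
    coefficients F (= kinship of the parents).
    """
    rng = np.random.default_rng(seed)
    if allele_freqs is None:
        allele_freqs = rng.uniform(0.05, 0.5, size=n_sites)
    p = np.asarray(allele_freqs, dtype=float)
    founders = [f"F{i}" for i in range(n_founders)]
    order = list(founders)
    parents = {f: (None, None) for f in founders}
    remaining = dict(relationships)
    while remaining:  # topological insert; cycles leave remaining non-empty
        progressed = False
        for child, (p1, p2) in list(remaining.items()):
            if p1 in parents and p2 in parents:
                order.append(child)
                parents[child] = (p1, p2)
                del remaining[child]
                progressed = True
        if not progressed:
            raise ValueError(f"cyclic or dangling pedigree entries: {sorted(remaining)}")
    haplo = {}
    for f in founders:
        haplo[f] = (rng.random((2, n_sites)) < p).astype(np.int8)
    for name in order[n_founders:]:
        p1, p2 = parents[name]
        h1 = haplo[p1][rng.integers(2, size=n_sites), np.arange(n_sites)]
        h2 = haplo[p2][rng.integers(2, size=n_sites), np.arange(n_sites)]
        haplo[name] = np.stack([h1, h2])
    geno = np.stack([haplo[name].sum(axis=0) for name in order], axis=1).astype(np.int8)
    gm = GenotypeMatrix(
        chrom_ids=np.array(["chr1"] * n_sites, dtype=object),
        positions=np.arange(1, n_sites + 1),
        ref_allele=np.array(["A"] * n_sites, dtype=object),
        alt_alleles=[["T"]] * n_sites,
        genotypes=geno,
        sample_ids=order,
    )
    phi = _kinship_from_pedigree(order, parents)
    inbreeding = {
        name: (
            0.0
            if parents[name][0] is None
            else float(
                phi[order.index(parents[name][0]), order.index(parents[name][1])]
            )
        )
        for name in order
    }
    truth = FixtureTruth(
        kind="pedigree",
        payload={
            "order": order,
            "kinship": phi,
            "inbreeding_f": inbreeding,
            "expected_pihat": 2.0 * phi * (1 - np.eye(len(order))),
        },
        seed=seed,
    )
    return gm, truth


# ---------------------------------------------------------------- CDS fixtures

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
]


@dataclass
class CdsFixture:
    """A toy annotated genome plus SNVs with oracle-derived effect truth."""

    contig: str
    sequence: str
    transcripts: list
    variants: list  # (pos_1based, ref, alt)
    truth: FixtureTruth

    def annotation(self) -> CodingAnnotation:
        return CodingAnnotation(self.transcripts, {self.contig: self.sequence})

    def write_files(self, fasta_path: str, gff3_path: str) -> None:
        with open(fasta_path, "w") as fh:
            fh.write(f">{self.contig}\n")
            for i in range(0, len(self.sequence), 70):
                fh.write(self.sequence[i : i + 70] + "\n")
        with open(gff3_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for t in self.transcripts:
                iv = t.cds_intervals
                first = iv[0] if t.strand == "+" else iv[-1]
                for a, b in iv:
                    phase = t.phase if (a, b) == first else 0
                    fh.write(
                        f"{t.contig}\tsynthetic\tCDS\t{a + 1}\t{b}\t.\t{t.strand}\t"
                        f"{phase}\tParent={t.transcript_id}\n"
                    )


def true_effect_full_translation(
    ann: CodingAnnotation, contig: str, pos0: int, alt: str
) -> str:
    """Independent effect oracle: rebuild the full mutant CDS and translate it.

    Category rules mirror the classifier's contract (splice +-2 bp of intron
    boundaries is LoF; start loss and premature stop are LoF; stop-lost counts
    as missense-class) but are derived from whole-protein comparison, not from
    codon-local arithmetic.
    """
    best = "noncoding"
    for t in ann.transcripts_on(contig):
        if pos0 in t.splice_positions():
            return "lof"
        if t.cds_index_of(pos0) is None:
            continue
        seq = ann._reference[contig]
        mutant = seq[:pos0] + alt + seq[pos0 + 1 :]
        mut_ann = CodingAnnotation([t], {contig: mutant})
        cds_before = ann.coding_sequence(t)
        cds_after = mut_ann.coding_sequence(t)
        prot_before = str(Seq(cds_before).translate())
        prot_after = str(Seq(cds_after).translate())
        if cds_before[:3] == "ATG" and cds_after[:3] != "ATG":
            return "lof"
        stop_before = prot_before.find("*")
        stop_after = prot_after.find("*")
        if stop_after != -1 and (stop_before == -1 or stop_after < stop_before):
            return "lof"  # premature termination
        if prot_after == prot_before:
            cat = "synonymous"
        else:
            cat = "missense"  # includes stop-lost under the default convention
        if {"noncoding": 0, "synonymous": 1, "missense": 2, "lof": 3}[cat] > {
            "noncoding": 0,
            "synonymous": 1,
            "missense": 2,
            "lof": 3,
        }[best]:
            best = cat
    return best


def make_cds_fixture(
    n_genes: int = 4,
    gene_length: int = 300,
    strand_mix: Sequence[str] = ("+", "-"),
    n_variants: int = 100,
    seed: int = 0,
    intron_length: int = 100,
    spacer: int = 300,
) -> CdsFixture:
    """Random two-exon genes on both strands plus SNVs with truth categories.

    ``gene_length`` is the CDS length (divisible by 3).  The first gene is on
    the plus strand and starts with codons ATG TGG GCT AAA so that guaranteed
    stop-gained, synonymous and missense variants exist; a splice-donor and an
    intergenic variant are always included, so every category is represented.
    Truth categories come from :func:`true_effect_full_translation`.
    """
    if gene_length % 3 != 0:
        raise ValueError("gene_length must be divisible by 3")
    if n_genes < len(strand_mix):
        raise ValueError("need at least one gene per requested strand")
    rng = np.random.default_rng(seed)

    def random_cds(forced_prefix: str = "") -> str:
        n_codons = gene_length // 3
        body = [forced_prefix[i : i + 3] for i in range(0, len(forced_prefix), 3)]
        while len(body) < n_codons - 1:
            body.append(_NON_STOP_CODONS[rng.integers(len(_NON_STOP_CODONS))])
        return "".join(body) + "TAA"

    def random_bases(n: int) -> str:
        return "".join("ACGT"[i] for i in rng.integers(4, size=n))

    contig = "ctg1"
    seq_parts = [random_bases(spacer)]
    offset = spacer
    transcripts = []
    for g in range(n_genes):
        strand = strand_mix[g % len(strand_mix)]
        if g == 0:
            strand = "+"
            cds = random_cds("ATGTGGGCTAAA")
        else:
            cds = random_cds("ATG")
        cut = 3 * (gene_length // 6)  # exon split on a codon boundary for clarity
        intron = "GT" + random_bases(intron_length - 4) + "AG"
        block_tx = cds[:cut] + intron + cds[cut:]
        T = len(block_tx)
        if strand == "+":
            block = block_tx
            iv = [(offset, offset + cut), (offset + cut + intron_length, offset + T)]
        else:
            block = _revcomp(block_tx)
            len2 = T - cut - intron_length
            iv = [(offset, offset + len2), (offset + T - cut, offset + T)]
        transcripts.append(
            Transcript(
                transcript_id=f"gene{g}", contig=contig, strand=strand,
                cds_intervals=iv, phase=0,
            )
        )
        seq_parts.append(block)
        offset += T
        seq_parts.append(random_bases(spacer))
        offset += spacer
    sequence = "".join(seq_parts)
    ann = CodingAnnotation(transcripts, {contig: sequence})

    g0 = transcripts[0]
    start0 = g0.cds_intervals[0][0]
    guaranteed = [
        (start0 + 4 + 1, "G", "A"),  # TGG -> TAG : stop gained
        (start0 + 8 + 1, "T", "C"),  # GCT -> GCC : synonymous
        (start0 + 9 + 1, "A", "C"),  # AAA -> CAA : missense
        (g0.cds_intervals[0][1] + 1, "G", "T"),  # first donor base: splice LoF
        (1, sequence[0], next(b for b in "ACGT" if b != sequence[0])),  # intergenic
    ]
    variants = list(guaranteed)
    seen = {v[0] for v in variants}
    while len(variants) < n_variants:
        pos0 = int(rng.integers(len(sequence)))
        if pos0 + 1 in seen:
            continue
        ref = sequence[pos0]
        alt = "ACGT"[int(rng.integers(4))]
        if alt == ref:
            continue
        seen.add(pos0 + 1)
        variants.append((pos0 + 1, ref, alt))
    categories = [
        true_effect_full_translation(ann, contig, pos - 1, alt)
        for pos, ref, alt in variants
    ]
    truth = FixtureTruth(
        kind="cds_fixture",
        payload={"categories": categories, "contig": contig},
        seed=seed,
    )
    return CdsFixture(
        contig=contig,
        sequence=sequence,
        transcripts=transcripts,
        variants=variants,
        truth=truth,
    )


# ---------------------------------------------------------------- WF cohorts


def make_wf_cohort(
    scenario,
    n_diploid: int = 100,
    sample_size: int = 20,
    genome_length: int = 100_000,
    mu: float = 1e-5,
    rec: float = 1e-6,
    burnin_factor: int = 10,
    seed: int = 0,
    cohort_label: Optional[str] = None,
) -> GenotypeMatrix:
    """Scaled Wright-Fisher cohort sample under a demographic scenario."""
    from .wf_simulator import SimulationConfig, simulate

    cfg = SimulationConfig(
        n_diploid_initial=n_diploid,
        genome_elements=(genome_length,),
        mu=mu,
        rec=rec,
        burnin_generations=burnin_factor * n_diploid,
        sample_size=sample_size,
        seed=seed,
    )
    gm = simulate(cfg, scenario)
    if cohort_label is not None:
        gm.cohort_labels = [cohort_label] * gm.n_individuals
    return gm
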