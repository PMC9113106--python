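"""SNV effect classification against a CDS annotation and mutational-load
summaries.

Single-nucleotide variants are sorted into synonymous / missense / loss of
function (LoF) / noncoding by translating the affected codon on the coding
strand.  LoF covers stop-gained, start-lost and splice donor/acceptor sites
(the first and last 2 bp of each intron); stop-lost is counted as
missense-class by default with a flag to reclassify it as LoF.  Mutational
load is the proportion of LoF variants among all variants an individual
carries, with the LoF count split by zygosity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genotype_io import GenotypeMatrix

CATEGORY_SEVERITY = {"noncoding": 0, "synonymous": 1, "missense": 2, "lof": 3}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


class ReferenceMismatchError(ValueError):
    """The variant's REF base disagrees with the annotation's reference genome."""


class UnsupportedVariantError(ValueError):
    """Non-SNV input (indels are excluded upstream of load analysis)."""


@dataclass
class Transcript:
    """One protein-coding transcript: ordered CDS intervals on one contig.

    ``cds_intervals`` are 0-based half-open, sorted by genomic coordinate;
    ``phase`` is the number of bases to skip at the 5' end of the first CDS in
    transcription order.
    """

    transcript_id: str
    contig: str
    strand: str
    cds_intervals: list
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")
        iv = sorted((int(a), int(b)) for a, b in self.cds_intervals)
        for (a1, b1), (a2, b2) in zip(iv, iv[1:]):
            if a2 < b1:
                raise ValueError(f"overlapping CDS intervals in {self.transcript_id}")
        self.cds_intervals = iv
        total = sum(b - a for a, b in iv) - self.phase
        if total % 3 != 0:
            raise ValueError(
                f"CDS length of {self.transcript_id} not divisible by 3 after phase"
            )

    def splice_positions(self) -> set:
        """0-based genomic positions of the 2 bp at each intron boundary."""
        pos = set()
        for (_, end1), (start2, _) in zip(self.cds_intervals, self.cds_intervals[1:]):
            pos.update(range(end1, min(end1 + 2, start2)))
            pos.update(range(max(start2 - 2, end1), start2))
        return pos

    def cds_index_of(self, pos0: int) -> Optional[int]:
        """Index of a genomic position within the spliced CDS (coding-strand
        orientation), or None when outside every CDS interval."""
        offset = 0
        hit = None
        for a, b in self.cds_intervals:
            if a <= pos0 < b:
                hit = offset + (pos0 - a)
                break
            offset += b - a
        if hit is None:
            return None
        total = sum(b - a for a, b in self.cds_intervals)
        idx = hit if self.strand == "+" else total - 1 - hit
        idx -= self.phase
        return idx if idx >= 0 else None


@dataclass
class EffectCall:
    variant_id: str
    category: str
    lof_subtype: str = "none"
    codon_before: str = ""
    codon_after: str = ""
    aa_before: str = ""
    aa_after: str = ""

    def __post_init__(self) -> None:
        if (self.category == "lof") != (self.lof_subtype != "none"):
            raise ValueError("category 'lof' iff lof_subtype set")


class CodingAnnotation:
    """CDS annotation plus reference sequence access.

    Built either from in-memory objects (``transcripts`` + a contig->sequence
    mapping) or from a GFF3 file with CDS features and a FASTA reference via
    :meth:`from_files`.
    """

    def __init__(self, transcripts: list, reference: dict):
        self.transcripts = list(transcripts)
        self._reference = reference
        self._by_contig: dict = {}
        for t in self.transcripts:
            self._by_contig.setdefault(t.contig, []).append(t)

    @classmethod
    def from_files(cls, gff3_path: str, fasta_path: str) -> "CodingAnnotation":
        import pyfaidx

        fasta = pyfaidx.Fasta(fasta_path, as_raw=True, sequence_always_upper=True)
        reference = {name: str(fasta[name][:]) for name in fasta.keys()}
        cols = [
            "seqid", "source", "type", "start", "end",
            "score", "strand", "phase", "attributes",
        ]
        gff = pd.read_csv(
            gff3_path, sep="\t", comment="#", header=None, names=cols, dtype=str
        )
        cds = gff[gff["type"] == "CDS"]
        groups: dict = {}
        for _, row in cds.iterrows():
            attrs = dict(
                kv.split("=", 1) for kv in row["attributes"].split(";") if "=" in kv
            )
            tid = attrs.get("Parent") or attrs.get("ID")
            if tid is None:
                raise ValueError("CDS feature without Parent/ID attribute")
            groups.setdefault(tid, []).append(row)
        transcripts = []
        for tid, rows in groups.items():
            strand = rows[0]["strand"]
            contig = rows[0]["seqid"]
            iv = [(int(r["start"]) - 1, int(r["end"])) for r in rows]
            iv.sort()
            first = iv[0] if strand == "+" else iv[-1]
            phase_by_iv = {
                (int(r["start"]) - 1, int(r["end"])): (
                    0 if r["phase"] in (".", None) else int(r["phase"])
                )
                for r in rows
            }
            transcripts.append(
                Transcript(
                    transcript_id=tid,
                    contig=contig,
                    strand=strand,
                    cds_intervals=iv,
                    phase=phase_by_iv[first],
                )
            )
        return cls(transcripts, reference)

    # ------------------------------------------------------------- sequences

    def base(self, contig: str, pos0: int) -> str:
        return str(self._reference[contig][pos0]).upper()

    def coding_sequence(self, t: Transcript) -> str:
        parts = [str(self._reference[t.contig][a:b]).upper() for a, b in t.cds_intervals]
        seq = "".join(parts)
        if t.strand == "-":
            seq = _revcomp(seq)
        return seq[t.phase :]

    def transcripts_on(self, contig: str) -> list:
        return self._by_contig.get(contig, [])


def _classify_in_transcript(
    ann: CodingAnnotation,
    t: Transcript,
    pos0: int,
    ref: str,
    alt: str,
    stop_lost_is_lof: bool,
) -> Optional[EffectCall]:
    vid = f"{t.contig}:{pos0 + 1}:{ref}>{alt}"
    if pos0 in t.splice_positions():
        return EffectCall(vid, "lof", "splice_site")
    idx = t.cds_index_of(pos0)
    if idx is None:
        return None
    cds = ann.coding_sequence(t)
    codon_i = idx // 3
    within = idx % 3
    codon_before = cds[3 * codon_i : 3 * codon_i + 3]
    ref_c = ref if t.strand == "+" else _revcomp(ref)
    alt_c = alt if t.strand == "+" else _revcomp(alt)
    if codon_before[within] != ref_c.upper():
        raise ReferenceMismatchError(
            f"{vid}: annotation codon {codon_before} does not carry REF at offset {within}"
        )
    codon_after = codon_before[:within] + alt_c.upper() + codon_before[within + 1 :]
    aa_before = str(Seq(codon_before).translate())
    aa_after = str(Seq(codon_after).translate())
    common = dict(
        codon_before=codon_before,
        codon_after=codon_after,
        aa_before=aa_before,
        aa_after=aa_after,
    )
    if codon_i == 0 and codon_before == "ATG" and codon_after != "ATG":
        return EffectCall(vid, "lof", "start_lost", **common)
    if aa_after == "*" and aa_before != "*":
        return EffectCall(vid, "lof", "stop_gained", **common)
    if aa_before == "*" and aa_after != "*":
        if stop_lost_is_lof:
            return EffectCall(vid, "lof", "stop_lost", **common)
        return EffectCall(vid, "missense", **common)
    if aa_before == aa_after:
        return EffectCall(vid, "synonymous", **common)
    return EffectCall(vid, "missense", **common)


def classify_effect(
    contig: str,
    pos: int,
    ref: str,
    alt: str,
    ann: CodingAnnotation,
    stop_lost_is_lof: bool = False,
) -> EffectCall:
    """Classify one SNV (1-based ``pos``) against the annotation.

    When a variant touches several transcripts the most severe effect wins
    (lof > missense > synonymous > noncoding).
    """
    if len(ref) != 1 or len(alt) != 1:
        raise UnsupportedVariantError(f"only SNVs supported, got {ref}>{alt}")
    pos0 = int(pos) - 1
    genome_base = ann.base(contig, pos0)
    if genome_base != ref.upper():
        raise ReferenceMismatchError(
            f"{contig}:{pos}: REF {ref} does not match reference base {genome_base}"
        )
    best = EffectCall(f"{contig}:{pos}:{ref}>{alt}", "noncoding")
    for t in ann.transcripts_on(contig):
        call = _classify_in_transcript(ann, t, pos0, ref, alt, stop_lost_is_lof)
        if call is not None and CATEGORY_SEVERITY[call.category] > CATEGORY_SEVERITY[best.category]:
            best = call
    return best


def classify_variants(
    gm: GenotypeMatrix, ann: CodingAnnotation, stop_lost_is_lof: bool = False
) -> list:
    """Effect calls for every biallelic SNV site of a genotype matrix."""
    calls = []
    for i in range(gm.n_sites):
        alts = gm.alt_alleles[i]
        if len(alts) != 1:
            raise UnsupportedVariantError("classify_variants expects biallelic SNVs")
        calls.append(
            classify_effect(
                str(gm.chrom_ids[i]),
                int(gm.positions[i]),
                str(gm.ref_allele[i]),
                str(alts[0]),
                ann,
                stop_lost_is_lof,
            )
        )
    return calls


def load_summary(effects: list, gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-individual mutational-load summary.

    Counts run over the variants each individual carries (genotype code 1 or
    2); ``load = n_lof / n_total_variants``; LoF carriers are split into
    heterozygous and homozygous.  Individuals carrying no variants get zero
    counts and load 0 with ``no_variants=True``.
    """
    if len(effects) != gm.n_sites:
        raise ValueError("one effect call per site required")
    cats = np.array([e.category for e in effects])
    rows = []
    for j, sid in enumerate(gm.sample_ids):
        g = gm.genotypes[:, j]
        carried = (g == 1) | (g == 2)
        n_total = int(carried.sum())
        n_syn = int((cats[carried] == "synonymous").sum())
        n_mis = int((cats[carried] == "missense").sum())
        lof_mask = carried & (cats == "lof")
        n_lof = int(lof_mask.sum())
        n_lof_het = int((g[lof_mask] == 1).sum())
        n_lof_hom = int((g[lof_mask] == 2).sum())
        rows.append(
            {
                "sample": sid,
                "cohort": gm.cohort_labels[j] if gm.cohort_labels else "all",
                "n_total_variants": n_total,
                "n_syn": n_syn,
                "n_mis": n_mis,
                "n_lof": n_lof,
                "n_lof_het": n_lof_het,
                "n_lof_hom": n_lof_hom,
                "load": (n_lof / n_total) if n_total else 0.0,
                "prop_syn": (n_syn / n_total) if n_total else 0.0,
                "prop_mis": (n_mis / n_total) if n_total else 0.0,
                "no_variants": n_total == 0,
            }
        )
    return pd.DataFrame(rows)


def category_proportions(summaries: pd.DataFrame) -> tuple:
    """Cohort-level mean category proportions plus a one-way ANOVA of the load
    across cohorts."""
    from .stats_tests import anova_oneway

    counts = summaries.groupby("cohort").size()
    if (counts < 2).any():
        raise ValueError("every cohort needs at least two individuals")
    if counts.size < 2:
        raise ValueError("need at least two cohorts")
    table = summaries.groupby("cohort")[["prop_syn", "prop_mis", "load"]].mean()
    groups = [g["load"].to_numpy() for _, g in summaries.groupby("cohort")]
    try:
        f_stat, p = anova_oneway(groups)
    except ValueError:
        f_stat, p = np.nan, np.nan
    anova = pd.DataFrame([{"statistic": "load", "F": f_stat, "p": p}])
    return table, anova
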