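"""Ancestor-vs-strain variant calling from nucleotide count tables.

Strain-specific SNPs are inferred by comparing the per-position nucleotide
frequencies of an adapted strain against the ancestral strain: a call
requires the strain to be near-fixed for a non-ancestral base while the
ancestor shows (almost) none of it, with adequate depth in both tables.
Indel candidates come from ins/del read evidence and are filtered out of
low-complexity context.  Coding SNPs are classified by strand-aware codon
arithmetic; indels by frame preservation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from Bio.Seq import Seq

from .genomes import CoverageTrack, Gene, NucleotideCountTable, SyntheticReference
from .sequtils import BASES, is_low_complexity

logger = logging.getLogger(__name__)

FUNCTIONAL_CLASSES = (
    "intergenic",
    "synonymous",
    "missense",
    "nonsense",
    "inframe_indel",
    "frameshift",
)


@dataclass(frozen=True)
class CallerThresholds:
    """QC and frequency thresholds for the caller.

    ``min_depth`` and ``min_genome_covered`` implement the strain-inclusion
    rule (>= 5 reads per base over >= 80% of the nuclear genome);
    ``mixed_min_fraction`` is the consensus-sequencing detectability rule
    (minor allele >= 25%).  The two alt-fraction thresholds are explicit
    configuration, not measured values.
    """

    min_depth: int = 5
    min_alt_fraction_strain: float = 0.8
    max_alt_fraction_ancestor: float = 0.05
    #: ancestor alt evidence of at most this many reads is treated as
    #: sequencing error even when it exceeds the ancestor fraction cap
    #: (a single read at depth < 20 would otherwise trip the 5% rule)
    ancestor_error_reads: int = 1
    mixed_min_fraction: float = 0.25
    min_genome_covered: float = 0.8

    def __post_init__(self):
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not (
            0.0
            <= self.max_alt_fraction_ancestor
            < self.min_alt_fraction_strain
            <= 1.0
        ):
            raise ValueError(
                "need 0 <= max_alt_fraction_ancestor < min_alt_fraction_strain <= 1"
            )
        for name in ("mixed_min_fraction", "min_genome_covered"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class MutationCall:
    strain_id: str
    chrom: str
    pos: int  # 1-based; for deletions the first deleted base
    ref_allele: str
    alt_allele: str
    type: str  # snp | ins | del
    alt_fraction: float
    functional_class: str | None = None
    protein_pos: int | None = None
    aa_change: tuple[str, str] | None = None
    needs_review: bool = False

    @property
    def indel_length(self) -> int:
        if self.type == "del":
            return len(self.ref_allele)
        if self.type == "ins":
            return len(self.alt_allele)
        return 0


@dataclass(frozen=True)
class StrainQCReport:
    strain_id: str
    fraction_covered_ge_min_depth: float
    included: bool


def strain_qc(
    track: CoverageTrack,
    thresholds: CallerThresholds | None = None,
    mito_chrom: str | None = None,
) -> StrainQCReport:
    """Strain inclusion QC over nuclear positions only."""
    thresholds = thresholds or CallerThresholds()
    chroms = [c for c in track.depth if c != mito_chrom]
    if not chroms:
        raise ValueError("coverage track has no nuclear chromosomes")
    n_total = 0
    n_ok = 0
    for c in chroms:
        d = np.asarray(track.depth[c])
        n_total += d.size
        n_ok += int((d >= thresholds.min_depth).sum())
    if n_total == 0:
        raise ValueError("coverage track is empty")
    frac = n_ok / n_total
    return StrainQCReport(
        strain_id=track.strain_id,
        fraction_covered_ge_min_depth=frac,
        included=frac >= thresholds.min_genome_covered,
    )


def _major_base(arr: np.ndarray) -> np.ndarray:
    return arr[:, :4].argmax(axis=1)


def call_snps(
    ancestor: NucleotideCountTable,
    strain: NucleotideCountTable,
    thresholds: CallerThresholds | None = None,
) -> list[MutationCall]:
    """Strain-specific SNPs from per-position frequency comparison.

    Emits a call where the strain's majority base differs from the
    ancestor's, the strain alt fraction is >= ``min_alt_fraction_strain``,
    the ancestor carries that base at <= ``max_alt_fraction_ancestor``, and
    both depths are >= ``min_depth``.  Positions with no ancestor coverage
    are skipped and logged, never called.
    """
    thresholds = thresholds or CallerThresholds()
    calls: list[MutationCall] = []
    n_no_ancestor = 0
    for chrom in strain.counts:
        if chrom not in ancestor.counts:
            n_no_ancestor += strain.counts[chrom].shape[0]
            continue
        st = strain.counts[chrom][:, :4]
        anc = ancestor.counts[chrom][:, :4]
        if st.shape != anc.shape:
            raise ValueError(f"{chrom}: ancestor/strain table shapes differ")
        st_depth = st.sum(axis=1)
        anc_depth = anc.sum(axis=1)
        st_major = _major_base(strain.counts[chrom])
        anc_major = _major_base(ancestor.counts[chrom])
        n_no_ancestor += int(((anc_depth == 0) & (st_depth > 0)).sum())
        cand = (
            (st_major != anc_major)
            & (st_depth >= thresholds.min_depth)
            & (anc_depth >= thresholds.min_depth)
        )
        idx = np.nonzero(cand)[0]
        if idx.size == 0:
            continue
        rows = np.arange(st.shape[0])
        st_frac = st[rows[idx], st_major[idx]] / st_depth[idx]
        anc_count = anc[rows[idx], st_major[idx]]
        anc_frac = anc_count / anc_depth[idx]
        anc_ok = (anc_frac <= thresholds.max_alt_fraction_ancestor) | (
            anc_count <= thresholds.ancestor_error_reads
        )
        keep = (st_frac >= thresholds.min_alt_fraction_strain) & anc_ok
        for i, f in zip(idx[keep], st_frac[keep]):
            calls.append(
                MutationCall(
                    strain_id=strain.strain_id,
                    chrom=chrom,
                    pos=int(i) + 1,
                    ref_allele=BASES[anc_major[i]],
                    alt_allele=BASES[st_major[i]],
                    type="snp",
                    alt_fraction=float(f),
                )
            )
    if n_no_ancestor:
        logger.info(
            "%s: %d positions lacked ancestor coverage and were skipped",
            strain.strain_id,
            n_no_ancestor,
        )
    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls


def _indel_events(frac_ok: np.ndarray) -> list[tuple[int, int]]:
    """Merge consecutive flagged positions into (start_index, length) runs."""
    idx = np.nonzero(frac_ok)[0]
    events = []
    if idx.size == 0:
        return events
    start = prev = idx[0]
    for i in idx[1:]:
        if i == prev + 1:
            prev = i
            continue
        events.append((int(start), int(prev - start + 1)))
        start = prev = i
    events.append((int(start), int(prev - start + 1)))
    return events


def call_indels(
    ancestor: NucleotideCountTable,
    strain: NucleotideCountTable,
    ref: SyntheticReference,
    thresholds: CallerThresholds | None = None,
) -> list[MutationCall]:
    """Strain-specific indels from ins/del read evidence.

    Adjacent deleted positions are merged into one deletion event (giving
    the event length); insertion events keep the anchor position but an
    unknown inserted sequence.  Candidates inside low-complexity context
    (homopolymer >= 6 bp or 2-3-mer tandem repeat >= 12 bp) are dropped and
    logged, mirroring the removal of uncertain indels.
    """
    thresholds = thresholds or CallerThresholds()
    calls: list[MutationCall] = []
    n_lowcomp = 0
    for chrom in strain.counts:
        if chrom not in ancestor.counts:
            continue
        seq = ref.chromosomes[chrom]
        st = strain.counts[chrom]
        anc = ancestor.counts[chrom]
        st_depth = st[:, :4].sum(axis=1)
        anc_depth = anc[:, :4].sum(axis=1)
        depth_ok = (st_depth >= thresholds.min_depth) & (
            anc_depth >= thresholds.min_depth
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            for col, kind in ((4, "ins"), (5, "del")):
                st_frac = np.where(st_depth > 0, st[:, col] / st_depth, 0.0)
                anc_frac = np.where(anc_depth > 0, anc[:, col] / anc_depth, 0.0)
                anc_ok = (anc_frac <= thresholds.max_alt_fraction_ancestor) | (
                    anc[:, col] <= thresholds.ancestor_error_reads
                )
                flagged = (
                    depth_ok
                    & (st_frac >= thresholds.min_alt_fraction_strain)
                    & anc_ok
                )
                for start_i, length in _indel_events(flagged):
                    pos = start_i + 1
                    ev_len = length if kind == "del" else 1
                    if is_low_complexity(seq, pos, ev_len):
                        n_lowcomp += 1
                        logger.info(
                            "%s: dropped low-complexity %s candidate at %s:%d",
                            strain.strain_id,
                            kind,
                            chrom,
                            pos,
                        )
                        continue
                    frac = float(st_frac[start_i : start_i + length].mean())
                    if kind == "del":
                        ref_allele = seq[start_i : start_i + length]
                        alt_allele = ""
                    else:
                        ref_allele = ""
                        alt_allele = "N"  # length unresolvable from counts
                    calls.append(
                        MutationCall(
                            strain_id=strain.strain_id,
                            chrom=chrom,
                            pos=pos,
                            ref_allele=ref_allele,
                            alt_allele=alt_allele,
                            type=kind,
                            alt_fraction=frac,
                        )
                    )
    if n_lowcomp:
        logger.info(
            "%s: %d low-complexity indel candidates removed",
            strain.strain_id,
            n_lowcomp,
        )
    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls


def classify_mutation(
    call: MutationCall, ref: SyntheticReference
) -> MutationCall:
    """Fill in the functional class of a call.

    SNPs inside a gene are classified by translating the affected codon
    before and after the change (strand-aware); indels are in-frame when
    their length is divisible by 3.  ``protein_pos = ceil(cds_offset / 3)``
    with the CDS offset 1-based from the first base of the start codon.
    Events overlapping a gene boundary are refused and flagged for manual
    review.
    """
    span_lo = call.pos
    span_hi = call.pos + (len(call.ref_allele) - 1 if call.type == "del" else 0)
    overlapping = ref.genes_overlapping(call.chrom, span_lo, span_hi)
    if not overlapping:
        return replace(call, functional_class="intergenic")
    gene = overlapping[0]
    fully_inside = (
        len(overlapping) == 1 and gene.start <= span_lo and span_hi <= gene.end
    )
    if not fully_inside:
        logger.warning(
            "%s:%d overlaps a gene boundary; flagged for manual review",
            call.chrom,
            call.pos,
        )
        return replace(call, functional_class=None, needs_review=True)

    if call.type in ("ins", "del"):
        cls = "inframe_indel" if call.indel_length % 3 == 0 else "frameshift"
        offset = (
            call.pos - gene.start + 1
            if gene.strand == "+"
            else gene.end - span_hi + 1
        )
        return replace(
            call,
            functional_class=cls,
            protein_pos=math.ceil(offset / 3),
        )

    # SNP inside a gene: codon arithmetic
    if gene.strand == "+":
        offset = call.pos - gene.start + 1  # 1-based within CDS
        alt_cds_base = call.alt_allele
    else:
        offset = gene.end - call.pos + 1
        alt_cds_base = str(Seq(call.alt_allele).complement())
    codon_idx = math.ceil(offset / 3)  # 1-based codon number
    within = (offset - 1) % 3
    cds = ref.cds_sequence(gene)
    codon = cds[(codon_idx - 1) * 3 : codon_idx * 3]
    mut_codon = codon[:within] + alt_cds_base + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mut_codon).translate())
    if ref_aa == alt_aa:
        cls = "synonymous"
    elif alt_aa == "*":
        cls = "nonsense"
    else:
        cls = "missense"
    return replace(
        call,
        functional_class=cls,
        protein_pos=codon_idx,
        aa_change=(ref_aa, alt_aa),
    )


def detect_mixed_colony(
    site_fractions,
    thresholds: CallerThresholds | None = None,
) -> tuple[bool, list[int]]:
    """Flag a heterogeneous colony from per-site minor allele fractions.

    A site is mixed when its minor allele fraction is >= ``mixed_min_fraction``
    (inclusive, matching the 25%-or-more detectability rule); the colony is
    heterogeneous when at least one site is mixed.
    """
    thresholds = thresholds or CallerThresholds()
    mixed = []
    for pos, frac in site_fractions:
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"minor allele fraction {frac} outside [0, 1]")
        if frac >= thresholds.mixed_min_fraction:
            mixed.append(pos)
    return (len(mixed) > 0, mixed)
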