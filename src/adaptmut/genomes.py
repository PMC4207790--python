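"""Synthetic haploid genomes, planted mutations, and count-table simulation.

No read-level simulation is performed: per-position nucleotide counts and
coverage depths are drawn directly (Poisson depth, uniform substitution
error split across the three non-reference bases).  A whole-chromosome
duplication on the haploid background doubles expected depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .sequtils import BASES, BASE_INDEX, chrom_name, is_low_complexity

MUTATION_TYPES = ("snp", "ins", "del")

#: functional classes that can be requested from :func:`plant_mutations`
PLANTABLE_CLASSES = (
    "snp",  # any substitution, anywhere
    "intergenic",
    "synonymous",
    "missense",
    "nonsense",
    "frameshift",  # 1-bp coding deletion
    "inframe_indel",  # 3-bp coding deletion
)

# non-reference base indices for each reference base index
_OTHERS = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SyntheticReference:
    """Named chromosome sequences plus a non-overlapping gene model.

    Coordinates are 1-based inclusive throughout.
    """

    chromosomes: dict[str, str]
    genes: tuple[Gene, ...]
    mito_chrom: str | None = None

    def __post_init__(self):
        by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > len(self.chromosomes[g.chrom]):
                raise ValueError(f"gene {g.gene_id} exceeds chromosome bounds")
            if g.length % 3 != 0:
                raise ValueError(f"gene {g.gene_id} length not divisible by 3")
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, genes in by_chrom.items():
            genes = sorted(genes, key=lambda g: g.start)
            for a, b in zip(genes, genes[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping genes {a.gene_id} / {b.gene_id} on {chrom}"
                    )

    @property
    def nuclear_chromosomes(self) -> list[str]:
        return [c for c in self.chromosomes if c != self.mito_chrom]

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    @property
    def nuclear_genome_length(self) -> int:
        return sum(self.length(c) for c in self.nuclear_chromosomes)

    def gene_at(self, chrom: str, pos: int) -> Gene | None:
        for g in self.genes:
            if g.chrom == chrom and g.start <= pos <= g.end:
                return g
        return None

    def genes_overlapping(self, chrom: str, lo: int, hi: int) -> list[Gene]:
        return [
            g
            for g in self.genes
            if g.chrom == chrom and g.start <= hi and lo <= g.end
        ]

    def cds_sequence(self, gene: Gene) -> str:
        s = self.chromosomes[gene.chrom][gene.start - 1 : gene.end]
        if gene.strand == "-":
            s = str(Seq(s).reverse_complement())
        return s


@dataclass(frozen=True)
class PlantedMutation:
    """Ground-truth mutation.  For deletions ``pos`` is the first deleted
    base and ``ref_allele`` the deleted sequence; for insertions ``pos`` is
    the anchor base immediately left of the event and ``alt_allele`` the
    inserted sequence."""

    strain_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    type: str

    def __post_init__(self):
        if self.type not in MUTATION_TYPES:
            raise ValueError(f"bad mutation type {self.type!r}")


@dataclass
class NucleotideCountTable:
    """Per-position read counts for one strain.

    ``counts[chrom]`` is an ``(L, 6)`` integer array with columns
    (A, C, G, T, ins, del); depth at a position is the sum of the four base
    counts (ins/del evidence is bookkept separately)."""

    strain_id: str
    counts: dict[str, np.ndarray]

    COLUMNS = ("A", "C", "G", "T", "ins", "del")

    def __post_init__(self):
        for chrom, arr in self.counts.items():
            if arr.ndim != 2 or arr.shape[1] != 6:
                raise ValueError(f"{chrom}: count array must be (L, 6)")
            if (arr < 0).any():
                raise ValueError(f"{chrom}: negative counts")

    def depth(self, chrom: str) -> np.ndarray:
        return self.counts[chrom][:, :4].sum(axis=1)


@dataclass
class CoverageTrack:
    """Per-position read depth for one strain."""

    strain_id: str
    depth: dict[str, np.ndarray]

    def __post_init__(self):
        for chrom, arr in self.depth.items():
            if (np.asarray(arr) < 0).any():
                raise ValueError(f"{chrom}: negative depth")


def make_reference(
    n_chrom: int = 3,
    lengths=None,
    genes_per_chrom: int = 6,
    seed: int = 0,
    *,
    mito_length: int | None = None,
    gene_codon_range: tuple[int, int] = (100, 300),
) -> SyntheticReference:
    """Random haploid reference with non-overlapping genes.

    Deterministic for a fixed seed.  Raises if the requested genes cannot be
    packed into the chromosome lengths.
    """
    if lengths is None:
        lengths = [50_000, 40_000, 30_000, 25_000][:n_chrom]
        if len(lengths) < n_chrom:
            lengths = lengths + [25_000] * (n_chrom - len(lengths))
    lengths = [int(x) for x in lengths]
    if len(lengths) != n_chrom:
        raise ValueError("lengths must have one entry per chromosome")
    max_gene = 3 * gene_codon_range[1]
    for L in lengths:
        if L < 3 * max_gene:
            raise ValueError(
                "chromosome lengths must be at least 3x the longest gene"
            )
    rng = np.random.default_rng(seed)
    base_arr = np.array(list(BASES))
    chromosomes: dict[str, str] = {}
    genes: list[Gene] = []
    for ci, L in enumerate(lengths, start=1):
        name = chrom_name(ci)
        chromosomes[name] = "".join(base_arr[rng.integers(0, 4, size=L)])
        cursor = 1
        for gi in range(genes_per_chrom):
            gap = int(rng.integers(200, 801))
            glen = 3 * int(rng.integers(gene_codon_range[0], gene_codon_range[1] + 1))
            start = cursor + gap
            end = start + glen - 1
            if end > L - 200:
                raise ValueError(
                    f"cannot pack {genes_per_chrom} genes into {name} ({L} bp)"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(f"{name}_g{gi + 1}", name, start, end, strand))
            cursor = end
    mito = None
    if mito_length is not None:
        mito = "chrM"
        chromosomes[mito] = "".join(base_arr[rng.integers(0, 4, size=int(mito_length))])
    return SyntheticReference(
        chromosomes=chromosomes, genes=tuple(genes), mito_chrom=mito
    )


def _classify_substitution(ref: SyntheticReference, chrom: str, pos: int, alt: str):
    """Functional class of a substitution by brute-force full-CDS translation
    (independent of the caller's codon arithmetic)."""
    gene = ref.gene_at(chrom, pos)
    if gene is None:
        return "intergenic"
    seq = ref.chromosomes[chrom]
    mutant = seq[: pos - 1] + alt + seq[pos:]
    wt_cds = ref.cds_sequence(gene)
    mut_chrom_seq = mutant[gene.start - 1 : gene.end]
    if gene.strand == "-":
        mut_cds = str(Seq(mut_chrom_seq).reverse_complement())
    else:
        mut_cds = mut_chrom_seq
    wt_prot = str(Seq(wt_cds).translate())
    mut_prot = str(Seq(mut_cds).translate())
    if wt_prot == mut_prot:
        return "synonymous"
    diff = [i for i, (a, b) in enumerate(zip(wt_prot, mut_prot)) if a != b]
    if diff and mut_prot[diff[0]] == "*":
        return "nonsense"
    return "missense"


def plant_mutations(
    ref: SyntheticReference,
    assignments,
    seed: int = 0,
    *,
    max_tries: int = 10_000,
) -> list[PlantedMutation]:
    """Plant mutations of requested functional classes.

    ``assignments`` is a sequence of ``(strain_id, class)`` pairs with class
    drawn from :data:`PLANTABLE_CLASSES`.  Positions are distinct across all
    planted mutations, deletions avoid gene boundaries and low-complexity
    context (so the downstream indel filter cannot discard them), and the
    achieved class is verified by full-CDS translation.
    """
    rng = np.random.default_rng(seed)
    used: set[tuple[str, int]] = set()
    nuclear = ref.nuclear_chromosomes
    coding_genes = [g for g in ref.genes if g.chrom in nuclear]
    if not coding_genes:
        raise ValueError("reference has no genes on nuclear chromosomes")
    planted: list[PlantedMutation] = []

    def reserve(chrom: str, lo: int, hi: int) -> bool:
        span = {(chrom, p) for p in range(lo - 1, hi + 2)}
        if span & used:
            return False
        used.update(span)
        return True

    for strain_id, wanted in assignments:
        if wanted not in PLANTABLE_CLASSES:
            raise ValueError(f"unknown mutation class {wanted!r}")
        for _ in range(max_tries):
            if wanted in ("frameshift", "inframe_indel"):
                dlen = 1 if wanted == "frameshift" else 3
                g = coding_genes[rng.integers(len(coding_genes))]
                if g.length < dlen + 12:
                    continue
                pos = int(rng.integers(g.start + 3, g.end - dlen - 2))
                seq = ref.chromosomes[g.chrom]
                if is_low_complexity(seq, pos, dlen):
                    continue
                if not reserve(g.chrom, pos, pos + dlen - 1):
                    continue
                planted.append(
                    PlantedMutation(
                        strain_id=strain_id,
                        chrom=g.chrom,
                        pos=pos,
                        ref_allele=seq[pos - 1 : pos - 1 + dlen],
                        alt_allele="",
                        type="del",
                    )
                )
                break
            if wanted == "intergenic":
                chrom = nuclear[rng.integers(len(nuclear))]
                pos = int(rng.integers(1, ref.length(chrom) + 1))
                if ref.gene_at(chrom, pos) is not None:
                    continue
            elif wanted == "snp":
                chrom = nuclear[rng.integers(len(nuclear))]
                pos = int(rng.integers(1, ref.length(chrom) + 1))
            else:
                g = coding_genes[rng.integers(len(coding_genes))]
                chrom = g.chrom
                pos = int(rng.integers(g.start, g.end + 1))
            ref_base = ref.chromosomes[chrom][pos - 1]
            alt = BASES[rng.integers(0, 4)]
            if alt == ref_base:
                continue
            if wanted not in ("snp", "intergenic"):
                if _classify_substitution(ref, chrom, pos, alt) != wanted:
                    continue
            if not reserve(chrom, pos, pos):
                continue
            planted.append(
                PlantedMutation(
                    strain_id=strain_id,
                    chrom=chrom,
                    pos=pos,
                    ref_allele=ref_base,
                    alt_allele=alt,
                    type="snp",
                )
            )
            break
        else:
            raise RuntimeError(
                f"could not plant a {wanted!r} mutation after {max_tries} tries"
            )
    return planted


def simulate_coverage(
    ref: SyntheticReference,
    strain_id: str,
    mean_depth: float = 30.0,
    duplicated_chroms=(),
    seed: int = 0,
    *,
    dropout_fraction: float = 0.0,
) -> CoverageTrack:
    """Poisson coverage track; duplicated chromosomes get doubled depth.

    ``dropout_fraction`` zeroes a random fraction of positions (used to build
    QC-failing strains)."""
    rng = np.random.default_rng(seed)
    depth: dict[str, np.ndarray] = {}
    for chrom, seq in ref.chromosomes.items():
        lam = mean_depth * (2.0 if chrom in duplicated_chroms else 1.0)
        d = rng.poisson(lam, size=len(seq))
        if dropout_fraction > 0:
            mask = rng.random(len(seq)) < dropout_fraction
            d[mask] = 0
        depth[chrom] = d
    return CoverageTrack(strain_id=strain_id, depth=depth)


def simulate_counts(
    ref: SyntheticReference,
    planted,
    strain_ids,
    mean_depth: float = 30.0,
    error_rate: float = 0.005,
    duplicated=(),
    seed: int = 0,
) -> tuple[dict[str, NucleotideCountTable], dict[str, CoverageTrack]]:
    """Simulate per-strain nucleotide count tables and coverage tracks.

    Depth is Poisson(``mean_depth``), doubled on chromosomes listed in
    ``duplicated`` (pairs of ``(strain_id, chrom)``).  At a planted SNP the
    alternative base receives the non-error fraction of reads; elsewhere
    non-reference counts arise only from ``error_rate`` split evenly across
    the three non-reference bases.  Planted insertions/deletions contribute
    ins/del evidence for the non-error fraction of reads (deletions at every
    deleted position, insertions at the anchor).
    """
    if error_rate < 0 or error_rate >= 0.05:
        raise ValueError("error_rate must be in [0, 0.05)")
    if mean_depth < 1:
        raise ValueError("mean_depth must be >= 1")
    planted = list(planted)
    for m in planted:
        if m.chrom not in ref.chromosomes:
            raise ValueError(f"planted mutation on unknown chromosome {m.chrom}")
        end = m.pos + (len(m.ref_allele) - 1 if m.type == "del" else 0)
        if m.pos < 1 or end > ref.length(m.chrom):
            raise ValueError(
                f"planted mutation at {m.chrom}:{m.pos} outside the reference"
            )
        if m.type in ("snp", "del") and m.ref_allele != ref.chromosomes[m.chrom][
            m.pos - 1 : m.pos - 1 + len(m.ref_allele)
        ]:
            raise ValueError(
                f"ref allele mismatch for planted mutation at {m.chrom}:{m.pos}"
            )
    dup_set = set(duplicated)
    by_strain: dict[str, list[PlantedMutation]] = {s: [] for s in strain_ids}
    for m in planted:
        if m.strain_id not in by_strain:
            raise ValueError(f"planted strain {m.strain_id!r} not in strain_ids")
        by_strain[m.strain_id].append(m)

    ref_idx = {
        chrom: np.fromiter(
            (BASE_INDEX[b] for b in seq), dtype=np.int64, count=len(seq)
        )
        for chrom, seq in ref.chromosomes.items()
    }
    tables: dict[str, NucleotideCountTable] = {}
    tracks: dict[str, CoverageTrack] = {}
    for si, strain in enumerate(strain_ids):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(si,)))
        counts: dict[str, np.ndarray] = {}
        depth_track: dict[str, np.ndarray] = {}
        for chrom, seq in ref.chromosomes.items():
            L = len(seq)
            lam = mean_depth * (2.0 if (strain, chrom) in dup_set else 1.0)
            depth = rng.poisson(lam, size=L)
            correct = ref_idx[chrom].copy()
            for m in by_strain[strain]:
                if m.type == "snp" and m.chrom == chrom:
                    correct[m.pos - 1] = BASE_INDEX[m.alt_allele]
            err = rng.binomial(depth, error_rate)
            e1 = rng.binomial(err, 1.0 / 3.0)
            e2 = rng.binomial(err - e1, 0.5)
            e3 = err - e1 - e2
            arr = np.zeros((L, 6), dtype=np.int64)
            rows = np.arange(L)
            arr[rows, correct] = depth - err
            others = _OTHERS[correct]
            arr[rows, others[:, 0]] += e1
            arr[rows, others[:, 1]] += e2
            arr[rows, others[:, 2]] += e3
            for m in by_strain[strain]:
                if m.chrom != chrom or m.type == "snp":
                    continue
                if m.type == "ins":
                    arr[m.pos - 1, 4] = rng.binomial(
                        depth[m.pos - 1], 1.0 - error_rate
                    )
                else:  # del: evidence at every deleted position
                    for p in range(m.pos, m.pos + len(m.ref_allele)):
                        arr[p - 1, 5] = rng.binomial(
                            depth[p - 1], 1.0 - error_rate
                        )
            counts[chrom] = arr
            depth_track[chrom] = depth
        tables[strain] = NucleotideCountTable(strain_id=strain, counts=counts)
        tracks[strain] = CoverageTrack(strain_id=strain, depth=depth_track)
    return tables, tracks
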