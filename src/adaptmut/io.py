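"""Text readers and writers for the pipeline's tabular formats.

All positions are 1-based inclusive; every TSV carries a header row.
Variant calls are exported both as VCF 4.2 (haploid genotypes, allele
fraction in INFO) and as a TSV mirror.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import MutationCall, StrainQCReport
from .experiment import ColonyRecord, LineageTable
from .genomes import CoverageTrack, Gene, NucleotideCountTable, SyntheticReference

_FASTA_WIDTH = 60

LINEAGE_COLUMNS = (
    "lineage_id",
    "colony_id",
    "adapted",
    "locus_id",
    "emergence_generation",
    "mutant_fraction",
)


class ParseError(ValueError):
    """Malformed input row, reported with its line number."""


# ---------------------------------------------------------------- FASTA

def write_fasta(ref: SyntheticReference, path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in ref.chromosomes.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), _FASTA_WIDTH):
                fh.write(seq[i : i + _FASTA_WIDTH] + "\n")


def read_fasta(path) -> dict[str, str]:
    chromosomes: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    chromosomes[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif line:
                parts.append(line)
    if name is not None:
        chromosomes[name] = "".join(parts)
    return chromosomes


# ---------------------------------------------------------------- gene model

def write_gene_model(ref: SyntheticReference, path) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in ref.genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")


def read_gene_model(path) -> tuple[Gene, ...]:
    genes = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                expect = ["gene_id", "chrom", "start", "end", "strand"]
                if line.split("\t") != expect:
                    raise ParseError(
                        f"{path}:{lineno}: expected header {expect}"
                    )
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 fields")
            gene_id, chrom, start, end, strand = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: bad coordinate") from e
            try:
                genes.append(Gene(gene_id, chrom, start_i, end_i, strand))
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from e
    return tuple(genes)


# ---------------------------------------------------------------- count tables

def write_count_table(table: NucleotideCountTable, path) -> None:
    frames = []
    for chrom, arr in table.counts.items():
        df = pd.DataFrame(arr, columns=list(NucleotideCountTable.COLUMNS))
        df.insert(0, "pos", np.arange(1, arr.shape[0] + 1))
        df.insert(0, "chrom", chrom)
        df.insert(0, "strain", table.strain_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_count_table(path) -> NucleotideCountTable:
    df = pd.read_csv(path, sep="\t")
    expect = ["strain", "chrom", "pos", "A", "C", "G", "T", "ins", "del"]
    if list(df.columns) != expect:
        raise ParseError(f"{path}: expected columns {expect}, got {list(df.columns)}")
    strains = df["strain"].unique()
    if len(strains) != 1:
        raise ParseError(f"{path}: expected a single strain, found {len(strains)}")
    counts: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        if pos[0] != 1 or not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise ParseError(f"{path}: positions on {chrom} are not contiguous from 1")
        counts[str(chrom)] = sub[["A", "C", "G", "T", "ins", "del"]].to_numpy(
            dtype=np.int64
        )
    return NucleotideCountTable(strain_id=str(strains[0]), counts=counts)


# ---------------------------------------------------------------- coverage

def write_coverage(track: CoverageTrack, path) -> None:
    """Run-length-encoded BEDGRAPH-like TSV (start 0-based, end exclusive)."""
    with open(path, "w") as fh:
        fh.write("strain\tchrom\tstart\tend\tdepth\n")
        for chrom, depth in track.depth.items():
            depth = np.asarray(depth)
            change = np.nonzero(np.diff(depth))[0]
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [depth.size]))
            for s, e in zip(starts, ends):
                fh.write(
                    f"{track.strain_id}\t{chrom}\t{s}\t{e}\t{int(depth[s])}\n"
                )


def read_coverage(path) -> CoverageTrack:
    df = pd.read_csv(path, sep="\t")
    expect = ["strain", "chrom", "start", "end", "depth"]
    if list(df.columns) != expect:
        raise ParseError(f"{path}: expected columns {expect}")
    strains = df["strain"].unique()
    if len(strains) != 1:
        raise ParseError(f"{path}: expected a single strain")
    depth: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        size = int(sub["end"].max())
        arr = np.zeros(size, dtype=np.int64)
        for _, row in sub.iterrows():
            arr[int(row["start"]) : int(row["end"])] = int(row["depth"])
        depth[str(chrom)] = arr
    return CoverageTrack(strain_id=str(strains[0]), depth=depth)


# ---------------------------------------------------------------- lineage tables

def write_lineage_table(table: LineageTable, path) -> None:
    """One row per colony-mutation pair; mutation fields empty for
    mutation-free colonies."""
    with open(path, "w") as fh:
        fh.write(f"# n_lineages={table.n_lineages}\n")
        fh.write("\t".join(LINEAGE_COLUMNS) + "\n")
        for c in table.colonies:
            base = f"{c.lineage_id}\t{c.colony_id}\t{int(c.adapted)}"
            if c.mutations:
                for locus, gen in c.mutations:
                    fh.write(f"{base}\t{locus}\t{gen}\t{c.mutant_fraction}\n")
            else:
                fh.write(f"{base}\t\t\t{c.mutant_fraction}\n")


def read_lineage_table(path) -> LineageTable:
    n_lineages = None
    rows: dict[tuple[int, int], dict] = {}
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                if "n_lineages=" in line:
                    n_lineages = int(line.split("n_lineages=")[1])
                continue
            if not line:
                continue
            if not header_seen:
                header_seen = True
                if line.split("\t") != list(LINEAGE_COLUMNS):
                    raise ParseError(f"{path}:{lineno}: bad header")
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 fields")
            lid, cid, adapted, locus, gen, frac = fields
            key = (int(lid), int(cid))
            rec = rows.setdefault(
                key,
                {
                    "adapted": bool(int(adapted)),
                    "mutations": [],
                    "fraction": float(frac),
                },
            )
            if locus:
                rec["mutations"].append((locus, int(gen)))
    if n_lineages is None:
        n_lineages = max((k[0] for k in rows), default=0) + 1
    colonies = tuple(
        ColonyRecord(
            lineage_id=lid,
            colony_id=cid,
            adapted=rec["adapted"],
            mutations=tuple(rec["mutations"]),
            mutant_fraction=rec["fraction"],
        )
        for (lid, cid), rec in sorted(rows.items())
    )
    return LineageTable(n_lineages=n_lineages, colonies=colonies)


# ---------------------------------------------------------------- variant export

def _vcf_record(call: MutationCall, ref: SyntheticReference | None):
    """Map a call to (pos, ref, alt) in VCF anchor convention."""
    if call.type == "snp":
        return call.pos, call.ref_allele, call.alt_allele
    seq = ref.chromosomes[call.chrom] if ref is not None else None
    if call.type == "del":
        if seq is not None and call.pos > 1:
            anchor = seq[call.pos - 2]
            return call.pos - 1, anchor + call.ref_allele, anchor
        return call.pos, call.ref_allele or "N", "<DEL>"
    # insertion anchored at call.pos
    anchor = seq[call.pos - 1] if seq is not None else "N"
    if call.alt_allele and call.alt_allele != "N":
        return call.pos, anchor, anchor + call.alt_allele
    return call.pos, anchor, "<INS>"


def write_vcf(calls, path, ref: SyntheticReference | None = None) -> None:
    """Minimal VCF 4.2 with haploid genotypes and AF/TYPE/CLASS/STRAIN INFO."""
    calls = sorted(calls, key=lambda c: (c.chrom, c.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##ALT=<ID=INS,Description="Insertion of unresolved sequence">\n')
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        if ref is not None:
            for chrom, seq in ref.chromosomes.items():
                fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write(
            '##INFO=<ID=TYPE,Number=1,Type=String,Description="snp/ins/del">\n'
            '##INFO=<ID=CLASS,Number=1,Type=String,Description="Functional class">\n'
            '##INFO=<ID=AF,Number=1,Type=Float,Description="Alt allele fraction">\n'
            '##INFO=<ID=STRAIN,Number=1,Type=String,Description="Strain id">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for c in calls:
            pos, ref_a, alt_a = _vcf_record(c, ref)
            info = (
                f"TYPE={c.type};CLASS={c.functional_class or '.'};"
                f"AF={c.alt_fraction:.4f};STRAIN={c.strain_id}"
            )
            fh.write(
                f"{c.chrom}\t{pos}\t.\t{ref_a}\t{alt_a}\t.\tPASS\t{info}\tGT\t1\n"
            )


def write_calls_tsv(calls, path) -> None:
    cols = [
        "strain",
        "chrom",
        "pos",
        "ref",
        "alt",
        "type",
        "class",
        "alt_fraction",
        "protein_pos",
        "aa_change",
        "needs_review",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in sorted(calls, key=lambda c: (c.strain_id, c.chrom, c.pos)):
            aa = f"{c.aa_change[0]}>{c.aa_change[1]}" if c.aa_change else ""
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        c.strain_id,
                        c.chrom,
                        c.pos,
                        c.ref_allele,
                        c.alt_allele,
                        c.type,
                        c.functional_class or "",
                        f"{c.alt_fraction:.4f}",
                        c.protein_pos if c.protein_pos is not None else "",
                        aa,
                        int(c.needs_review),
                    )
                )
                + "\n"
            )


def write_qc_report(reports: list[StrainQCReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("strain\tfraction_covered\tincluded\n")
        for r in reports:
            fh.write(
                f"{r.strain_id}\t{r.fraction_covered_ge_min_depth:.4f}"
                f"\t{int(r.included)}\n"
            )


def write_summary(results: dict, path) -> None:
    Path(path).write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")
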