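"""End-to-end pipeline: simulate -> QC -> variant calling -> aneuploidy ->
statistics -> machine-readable summary.

Every stage derives its randomness from the master seed, so rerunning a
stage in isolation reproduces the pipeline-level result and the summary
JSON is byte-identical for a fixed configuration.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import aneuploidy as aneu
from . import calling, genomes, io, stats
from .config import PipelineConfig
from .experiment import ExperimentParams, fluctuation_summary, simulate_lineage

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


_STAGE_OFFSETS = {
    "reference": 1,
    "plant": 2,
    "counts": 3,
    "windows": 4,
    "experiment": 5,
}


def _stage_seed(master: int, stage: str) -> int:
    # stable per-stage split of the master seed
    return master * 1000 + _STAGE_OFFSETS[stage]


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all stages and write the artifact bundle under ``out_dir``.

    Returns the summary dictionary that is also written as
    ``summary.json``.  Any stage failure is re-raised as :class:`StageError`
    with a stage-labelled message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulate
    strain_ids = [f"s{i + 1}" for i in range(sim.n_strains)]
    ancestor_id = "ancestor"

    try:
        ref = genomes.make_reference(
            n_chrom=sim.n_chrom,
            lengths=sim.chrom_lengths,
            genes_per_chrom=sim.genes_per_chrom,
            seed=_stage_seed(config.seed, "reference"),
        )
        assignments = []
        for cls, n in sim.planted.items():
            for k in range(n):
                assignments.append((strain_ids[k % len(strain_ids)], cls))
        planted = genomes.plant_mutations(
            ref, assignments, seed=_stage_seed(config.seed, "plant")
        )
        duplicated = [
            (strain_ids[int(i)], chrom) for i, chrom in sim.duplicated
        ]
        tables, tracks = genomes.simulate_counts(
            ref,
            planted,
            [ancestor_id] + strain_ids,
            mean_depth=sim.mean_depth,
            error_rate=sim.error_rate,
            duplicated=duplicated,
            seed=_stage_seed(config.seed, "counts"),
        )
        io.write_fasta(ref, out / "reference.fa")
        io.write_gene_model(ref, out / "genes.tsv")
        if config.write_count_tables:
            for sid, table in tables.items():
                io.write_count_table(table, out / f"counts_{sid}.tsv")
    except StageError:
        raise
    except Exception as e:
        raise StageError("simulate", e) from e

    try:
        qc_reports = [
            calling.strain_qc(tracks[s], config.thresholds, ref.mito_chrom)
            for s in strain_ids
        ]
        included = [r.strain_id for r in qc_reports if r.included]
        io.write_qc_report(qc_reports, out / "qc.tsv")
    except Exception as e:
        raise StageError("qc", e) from e

    try:
        all_calls = []
        for sid in included:
            snps = calling.call_snps(
                tables[ancestor_id], tables[sid], config.thresholds
            )
            indels = calling.call_indels(
                tables[ancestor_id], tables[sid], ref, config.thresholds
            )
            for c in snps + indels:
                all_calls.append(calling.classify_mutation(c, ref))
        io.write_vcf(all_calls, out / "calls.vcf", ref)
        io.write_calls_tsv(all_calls, out / "calls.tsv")
    except Exception as e:
        raise StageError("variant_calling", e) from e

    try:
        dup_calls = []
        for sid in included:
            summary_w = aneu.sample_windows(
                tracks[sid],
                window_size=config.aneuploidy.window_size,
                n_windows=config.aneuploidy.n_windows,
                seed=_stage_seed(config.seed, "windows"),
            )
            dup_calls.extend(
                aneu.call_duplications(
                    summary_w, band=tuple(config.aneuploidy.band)
                )
            )
        with open(out / "duplications.tsv", "w") as fh:
            fh.write("strain\tchrom\tratio\tduplicated\n")
            for d in dup_calls:
                fh.write(
                    f"{d.strain_id}\t{d.chrom}\t{d.ratio:.4f}\t{int(d.duplicated)}\n"
                )
    except Exception as e:
        raise StageError("aneuploidy", e) from e

    try:
        exp = config.experiment
        params = ExperimentParams(
            n_lineages=exp.n_lineages,
            cells_per_well_range=tuple(exp.cells_per_well_range),
            p_adapt=exp.p_adapt,
            mutation_model=exp.mutation_model,
            mu_predivision=exp.mu_predivision,
            p_induced=exp.p_induced,
            seed=_stage_seed(config.seed, "experiment"),
        )
        lineages = simulate_lineage(params)
        io.write_lineage_table(lineages, out / "lineages.tsv")
        fluct = fluctuation_summary(lineages)
    except Exception as e:
        raise StageError("experiment", e) from e

    try:
        genome_length = config.stats.genome_length or ref.nuclear_genome_length
        inc = stats.incidence_table(all_calls, len(included), genome_length)
        hist = stats.per_strain_distribution(all_calls, included)
        mutant_colonies = int(lineages.mutant_counts_per_lineage().sum())
        n_colonies = len(lineages)
        enrich = stats.locus_enrichment(
            mutant_colonies,
            max(n_colonies, 1),
            config.stats.locus_len,
            genome_length,
            inc.per_genome_mean,
        )
        summary = {
            "n_strains_sequenced": len(strain_ids),
            "n_strains_included": len(included),
            "genome_length": genome_length,
            "n_planted": len(planted),
            "incidence": {
                row["class"]: {
                    "count": row["count"],
                    "per_base_incidence": row["incidence"],
                    "formatted_2sf": row["incidence_2sf"],
                    "formatted_3sf": row["incidence_3sf"],
                }
                for row in inc.rows()
            },
            "per_genome_mean": inc.per_genome_mean,
            "per_strain_histogram": {str(k): v for k, v in sorted(hist.items())},
            "duplications": [
                {"strain": d.strain_id, "chrom": d.chrom, "ratio": round(d.ratio, 4)}
                for d in dup_calls
                if d.duplicated
            ],
            "fluctuation": {
                "n_lineages": fluct.n_lineages,
                "variance_to_mean": fluct.variance_to_mean,
                "fraction_lineages_with_mutant": fluct.fraction_lineages_with_mutant,
            },
            "enrichment": {
                "observed_k": enrich.observed_k,
                "n_colonies": enrich.n_colonies,
                "observed_incidence": enrich.observed_incidence,
                "expected": enrich.expected,
                "p_value": enrich.p_value,
            },
        }
        io.write_summary(summary, out / "summary.json")
    except Exception as e:
        raise StageError("stats", e) from e

    logger.info(
        "pipeline complete: %d strains, %d calls, %d duplications",
        len(included),
        len(all_calls),
        sum(d.duplicated for d in dup_calls),
    )
    return summary
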