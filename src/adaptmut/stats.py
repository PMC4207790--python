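"""Incidence, enrichment, and emergence-timing statistics for mutation calls.

Per-base incidence divides class counts by (number of strains x nuclear
genome length).  Locus enrichment is an exact Poisson tail test on mutant
colony counts, computed by direct summation (no normal approximation).
Emergence timing inverts the deterministic-doubling mutant-fraction rule
f = 2^-g.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: display order of mutation classes in the incidence table
INCIDENCE_CLASSES = ("intergenic", "synonymous", "missense", "nonsense", "indel")

#: minor-allele fraction detectable by consensus (Sanger-style) sequencing
CONSENSUS_DETECTION_FRACTION = 0.25


def format_sig(x: float, digits: int = 2) -> str:
    """Format to a number of significant figures (scientific for small x)."""
    if x == 0:
        return "0"
    return f"{x:.{digits - 1}e}"


def round_sig(x: float, digits: int = 2) -> float:
    if x == 0:
        return 0.0
    return float(f"{x:.{digits - 1}e}")


def _call_class(call) -> str:
    if call.type in ("ins", "del"):
        return "indel"
    cls = call.functional_class
    if cls is None:
        raise ValueError(
            f"call at {call.chrom}:{call.pos} is unclassified; run "
            "classify_mutation first"
        )
    return cls


@dataclass(frozen=True)
class IncidenceTable:
    """Mutation counts and per-base incidences by functional class."""

    counts: dict[str, int]
    n_strains: int
    genome_length: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def per_genome_mean(self) -> float:
        return self.total / self.n_strains

    def incidence(self, cls: str) -> float:
        return self.counts.get(cls, 0) / (self.n_strains * self.genome_length)

    @property
    def r_all(self) -> float:
        return self.total / (self.n_strains * self.genome_length)

    def rows(self) -> list[dict]:
        """Raw and formatted rows in Table-style layout (one row per class
        plus a total row)."""
        out = []
        for cls in INCIDENCE_CLASSES:
            r = self.incidence(cls)
            out.append(
                {
                    "class": cls,
                    "count": self.counts.get(cls, 0),
                    "incidence": r,
                    "incidence_2sf": format_sig(r, 2),
                    "incidence_3sf": format_sig(r, 3),
                }
            )
        out.append(
            {
                "class": "all",
                "count": self.total,
                "incidence": self.r_all,
                "incidence_2sf": format_sig(self.r_all, 2),
                "incidence_3sf": format_sig(self.r_all, 3),
            }
        )
        return out


def incidence_table(calls, n_strains: int, genome_length: int) -> IncidenceTable:
    """Per-base mutation incidence by class.

    ``calls`` must already be restricted to included strains and nuclear
    chromosomes; indels of any frame count in the single ``indel`` class.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    counts: dict[str, int] = {c: 0 for c in INCIDENCE_CLASSES}
    for call in calls:
        cls = _call_class(call)
        if cls in ("inframe_indel", "frameshift"):
            cls = "indel"
        if cls not in counts:
            raise ValueError(f"unknown functional class {cls!r}")
        counts[cls] += 1
    return IncidenceTable(
        counts=counts, n_strains=n_strains, genome_length=genome_length
    )


def per_strain_distribution(calls, strain_ids) -> dict[int, int]:
    """Histogram of mutations per strain, including zero-mutation strains."""
    strain_ids = list(strain_ids)
    if not strain_ids:
        raise ValueError("strain_ids must be nonempty")
    per_strain = {s: 0 for s in strain_ids}
    for call in calls:
        if call.strain_id not in per_strain:
            raise ValueError(f"call for unknown strain {call.strain_id!r}")
        per_strain[call.strain_id] += 1
    hist: dict[int, int] = {}
    for n in per_strain.values():
        hist[n] = hist.get(n, 0) + 1
    return hist


def poisson_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam), by direct summation of the upper tail."""
    if k <= 0:
        return 1.0
    if lam == 0.0:
        return 0.0
    log_term = -lam + k * math.log(lam) - math.lgamma(k + 1)
    term = math.exp(log_term)
    total = 0.0
    i = k
    while True:
        total += term
        i += 1
        term *= lam / i
        if term <= total * 1e-18 or term == 0.0:
            break
    return min(total, 1.0)


@dataclass(frozen=True)
class EnrichmentResult:
    observed_k: int
    n_colonies: int
    locus_fraction: float
    per_genome_rate: float
    expected: float
    observed_incidence: float
    p_value: float
    method: str = "poisson"


def locus_enrichment(
    observed_k: int,
    n_colonies: int,
    locus_len: int,
    genome_len: int,
    per_genome_rate: float,
    *,
    binomial: bool = False,
) -> EnrichmentResult:
    """Exact enrichment test for mutations concentrating in one locus.

    Under the null, mutations fall uniformly in the genome at
    ``per_genome_rate`` per colony, so the expected number of mutant
    colonies at a locus occupying fraction ``f = locus_len / genome_len`` is
    ``n_colonies * per_genome_rate * f``.  The p-value is the exact Poisson
    tail P(X >= observed_k); a per-colony binomial alternative is available
    behind the ``binomial`` flag.
    """
    if locus_len > genome_len:
        raise ValueError("locus_len must not exceed genome_len")
    if per_genome_rate < 0:
        raise ValueError("per_genome_rate must be >= 0")
    if observed_k < 0 or n_colonies < 1:
        raise ValueError("need observed_k >= 0 and n_colonies >= 1")
    f = locus_len / genome_len
    expected = n_colonies * per_genome_rate * f
    if binomial:
        p_mut = per_genome_rate * f
        p_value = float(sps.binom.sf(observed_k - 1, n_colonies, min(p_mut, 1.0)))
        method = "binomial"
    else:
        if expected == 0.0 and observed_k > 0:
            warnings.warn(
                "expected count is 0 with observed_k > 0; reporting p_value 0",
                stacklevel=2,
            )
            p_value = 0.0
        else:
            p_value = poisson_tail(observed_k, expected)
        method = "poisson"
    return EnrichmentResult(
        observed_k=observed_k,
        n_colonies=n_colonies,
        locus_fraction=f,
        per_genome_rate=per_genome_rate,
        expected=expected,
        observed_incidence=observed_k / n_colonies,
        p_value=p_value,
        method=method,
    )


@dataclass(frozen=True)
class EmergenceEstimate:
    mutant_fraction: float
    generation: int
    detectable_by_consensus: bool


def emergence_generation(mutant_fraction: float) -> EmergenceEstimate:
    """Infer the emergence generation from a colony mutant fraction.

    Under deterministic doubling a mutation arising in one cell of the
    ``2**g`` cells present after g divisions ends up in a fraction ``2**-g``
    of the mature colony, so ``g = round(-log2(f))``.  Fractions >= 25% are
    detectable by consensus sequencing.
    """
    if not 0.0 < mutant_fraction <= 1.0:
        raise ValueError("mutant_fraction must be in (0, 1]")
    g = int(round(-math.log2(mutant_fraction)))
    return EmergenceEstimate(
        mutant_fraction=mutant_fraction,
        generation=g,
        detectable_by_consensus=mutant_fraction >= CONSENSUS_DETECTION_FRACTION,
    )


def standard_error(sd: float, n: int) -> float:
    """Standard error of a mean from a sample standard deviation."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return sd / math.sqrt(n)
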