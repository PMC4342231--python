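"""End-to-end drivers: reads -> SNPs -> homoeologue sets -> intactness -> interval.

Convenience layers over the module functions so the full study can run as
one call on simulated (or externally supplied) data.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, NamedTuple, Optional, Sequence, Tuple, Union

from .amplicon_caller import (
    AmpliconRead,
    CallerConfig,
    ControlDesign,
    HomoeoSnpSets,
    IntactnessCall,
    ReferenceSeq,
    SnpRecord,
    align_reads,
    assign_homoeologue_specific_snps,
    build_pileup,
    call_intactness,
    coverage_map,
    detect_snps,
    select_consensus_snps,
)
from .cross_model import SUBGENOMES
from .synteny_map import (
    DeletionInterval,
    IntactnessProfile,
    MarkerPanel,
    infer_deletion_interval,
)
from .synthetic_data import (
    HomoeologReferences,
    SampleGenotype,
    SimulationConfig,
    nulli_tetra_genotype,
    simulate_sample_reads,
    wild_type_genotype,
)

__all__ = [
    "SampleResult",
    "snps_for_sample",
    "process_sample",
    "snp_tables_for_samples",
    "default_control_design",
    "standard_control_genotypes",
    "homoeologue_sets_from_tables",
    "mutant_calls",
    "profile_from_calls",
    "interval_from_calls",
]


class SampleResult(NamedTuple):
    """One sample's called variants plus its per-position read depth."""

    records: List[SnpRecord]
    coverage: Dict[Tuple[str, int], int]


TableLike = Union[Sequence[SnpRecord], SampleResult]


def _records(table: TableLike) -> Sequence[SnpRecord]:
    return table.records if isinstance(table, SampleResult) else table


def _coverage(table: TableLike) -> Optional[Dict[Tuple[str, int], int]]:
    return table.coverage if isinstance(table, SampleResult) else None


def process_sample(
    reads: Sequence[AmpliconRead],
    refs: Sequence[ReferenceSeq],
    annotation: Mapping[str, Tuple[str, str]],
    cfg: CallerConfig = CallerConfig(),
) -> SampleResult:
    """Align one sample's reads; return its SNP table and depth profile."""
    alignments = align_reads(reads, refs, cfg)
    pileup = build_pileup(alignments, reads, refs)
    return SampleResult(
        records=detect_snps(pileup, cfg, annotation, refs),
        coverage=coverage_map(pileup, annotation),
    )


def snps_for_sample(
    reads: Sequence[AmpliconRead],
    refs: Sequence[ReferenceSeq],
    annotation: Mapping[str, Tuple[str, str]],
    cfg: CallerConfig = CallerConfig(),
) -> List[SnpRecord]:
    """Align one sample's reads and call its SNP table."""
    return process_sample(reads, refs, annotation, cfg).records


def standard_control_genotypes(gene_ids: Sequence[str]) -> Dict[str, SampleGenotype]:
    """Two wild-type replicates plus the three nulli-tetra controls."""
    controls = {
        "WT_1": wild_type_genotype("WT_1"),
        "WT_2": wild_type_genotype("WT_2"),
    }
    for sub in SUBGENOMES:
        name = f"N{sub}"
        controls[name] = nulli_tetra_genotype(name, sub, gene_ids)
    return controls


def default_control_design() -> ControlDesign:
    return ControlDesign(
        wild_type_samples=["WT_1", "WT_2"],
        null_tetra={sub: f"N{sub}" for sub in SUBGENOMES},
    )


def snp_tables_for_samples(
    genotypes: Mapping[str, SampleGenotype],
    references: HomoeologReferences,
    sim_cfg: SimulationConfig,
    caller_cfg: CallerConfig = CallerConfig(),
    seed: int = 0,
) -> Dict[str, SampleResult]:
    """Simulate reads for every sample and call per-sample SNP tables.

    Per-sample read seeds are derived deterministically from ``seed`` and the
    sorted sample order, so tables are reproducible sample by sample.
    """
    tables: Dict[str, SampleResult] = {}
    for i, sample_id in enumerate(sorted(genotypes)):
        reads = simulate_sample_reads(
            genotypes[sample_id], references, sim_cfg, seed=seed + 1000 * (i + 1)
        )
        tables[sample_id] = process_sample(
            reads, references.mapping_refs, references.annotation, caller_cfg
        )
    return tables


def homoeologue_sets_from_tables(
    snp_tables: Mapping[str, TableLike],
    design: ControlDesign,
) -> HomoeoSnpSets:
    plain = {s: _records(t) for s, t in snp_tables.items()}
    consensus = select_consensus_snps(plain, design)
    return assign_homoeologue_specific_snps(consensus, plain, design)


def mutant_calls(
    snp_tables: Mapping[str, TableLike],
    sets: HomoeoSnpSets,
    mutant_ids: Sequence[str],
    gene_ids: Optional[Sequence[str]] = None,
    caller_cfg: CallerConfig = CallerConfig(),
) -> Dict[str, List[IntactnessCall]]:
    """Intactness calls for each mutant on every subgenome.

    When a mutant's table carries its depth profile, absence of a variant is
    only treated as deletion evidence at positions the mutant actually covers
    at the calling floor.
    """
    out: Dict[str, List[IntactnessCall]] = {}
    for mutant in mutant_ids:
        calls: List[IntactnessCall] = []
        for sub in SUBGENOMES:
            calls.extend(
                call_intactness(
                    _records(snp_tables[mutant]),
                    sets,
                    sub,
                    gene_ids,
                    coverage=_coverage(snp_tables[mutant]),
                    min_coverage=caller_cfg.min_coverage,
                )
            )
        out[mutant] = calls
    return out


def profile_from_calls(
    calls: Sequence[IntactnessCall], mutant_id: str, subgenome: str
) -> IntactnessProfile:
    return IntactnessProfile(
        mutant_id=mutant_id,
        subgenome=subgenome,
        calls={c.gene_id: c.status for c in calls if c.subgenome == subgenome},
    )


def interval_from_calls(
    calls: Sequence[IntactnessCall],
    mutant_id: str,
    subgenome: str,
    panel: MarkerPanel,
) -> DeletionInterval:
    profile = profile_from_calls(calls, mutant_id, subgenome)
    return infer_deletion_interval(profile, panel)
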