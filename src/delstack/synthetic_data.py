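"""Seeded generators for every input the deletion-stacking pipeline consumes.

Real inputs to the analysis are wheat amplicon sequencing runs, aneuploid
control stocks, and F2 families from crosses between deletion mutants.  None
of those are desk-reproducible, so this module fabricates them with known
ground truth:

* homoeologous gene triplets at 96-98% pairwise identity, derived from a
  common ancestral sequence that doubles as the mapping reference (standing
  in for the diploid-progenitor scaffolds real reads are mapped to);
* sample genotypes — wild type, nullisomic-tetrasomic (one subgenome absent
  genome-wide), and deletion mutants with a known contiguous span on the
  flanking-marker panel;
* substitution-error amplicon reads at configurable coverage;
* F2 populations drawn from the selfing distribution of a cross's F1, with
  optional non-viable detected classes rejection-sampled away.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .amplicon_caller import AmpliconRead, ReferenceSeq, BASES
from .cross_model import (
    SUBGENOMES,
    CrossSpec,
    DetectedClass,
    HomoeoGenotype,
    detect_class,
    f1_genotype,
)
from .synteny_map import Marker, MarkerPanel

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "DivergenceSite",
    "HomoeologReferences",
    "SampleGenotype",
    "generate_homoeolog_references",
    "generate_deletion_mutant",
    "random_deletion_mutant",
    "simulate_sample_reads",
    "simulate_f2_population",
    "pairwise_identity",
    "wild_type_genotype",
    "nulli_tetra_genotype",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the real study's regime: ~800 bp amplicons (within the
    500-1500 bp design window), 96-98% homoeologue identity (pairwise
    divergence 0.02-0.04; 0.03 by default), 200 bp reads, 60x per-copy
    coverage (above the 50x calling floor) and a 1% per-base substitution
    error rate.
    """

    n_genes: int = 8
    amplicon_length: int = 800
    pairwise_divergence: float = 0.03
    read_length: int = 200
    coverage: float = 60.0
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pairwise_divergence < 0.2):
            raise ValueError("pairwise_divergence must be in [0, 0.2)")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if self.read_length > self.amplicon_length:
            raise ValueError("read_length must not exceed amplicon_length")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class DivergenceSite:
    """A planted subgenome-private substitution."""

    gene_id: str
    position: int  # 0-based on the gene's mapping reference
    subgenome: str
    allele: str  # the derived (subgenome-private) base


@dataclass
class HomoeologReferences:
    """Synthetic homoeologue triplets plus their common mapping references.

    ``mapping_refs`` hold the ancestral sequence per gene (ref_id equals the
    gene_id); ``homoeologs`` hold the realised A/B/D copies; ``sites`` is the
    planted divergence truth.  ``annotation`` maps ref_id -> (scaffold_id,
    gene_id) for the SNP caller.
    """

    mapping_refs: List[ReferenceSeq]
    homoeologs: Dict[str, Dict[str, str]]  # gene_id -> subgenome -> sequence
    sites: List[DivergenceSite]
    annotation: Dict[str, Tuple[str, str]]

    @property
    def gene_ids(self) -> List[str]:
        return [r.ref_id for r in self.mapping_refs]

    def sites_for(self, gene_id: str, subgenome: str) -> Set[Tuple[int, str]]:
        return {
            (s.position, s.allele)
            for s in self.sites
            if s.gene_id == gene_id and s.subgenome == subgenome
        }


@dataclass
class SampleGenotype:
    """Which gene x subgenome copies a sample carries.

    ``absent`` lists the missing (gene_id, subgenome) pairs; everything else
    is present.  Chromosome dosage is not modelled: only presence/absence
    matters to a hemizygote-blind readout and to read provenance.
    """

    sample_id: str
    absent: Set[Tuple[str, str]] = field(default_factory=set)

    def present(self, gene_id: str, subgenome: str) -> bool:
        return (gene_id, subgenome) not in self.absent


@dataclass
class TruthRecord:
    mutant_id: str
    subgenome: str
    deleted_gene_ids: Set[str]
    true_span_kb: float


def wild_type_genotype(sample_id: str) -> SampleGenotype:
    return SampleGenotype(sample_id=sample_id, absent=set())


def nulli_tetra_genotype(
    sample_id: str, subgenome: str, gene_ids: Sequence[str]
) -> SampleGenotype:
    """A nullisomic-tetrasomic control: one subgenome absent genome-wide."""
    if subgenome not in SUBGENOMES:
        raise ValueError(f"unknown subgenome {subgenome!r}")
    return SampleGenotype(
        sample_id=sample_id, absent={(g, subgenome) for g in gene_ids}
    )


def pairwise_identity(seq1: str, seq2: str) -> float:
    """Fraction of identical positions between two equal-length sequences."""
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    matches = sum(a == b for a, b in zip(seq1, seq2))
    return matches / len(seq1)


def _mutate_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in BASES if b != base]
    return choices[rng.integers(len(choices))]


def generate_homoeolog_references(
    cfg: SimulationConfig,
    gene_ids: Optional[Sequence[str]] = None,
) -> HomoeologReferences:
    """Ancestral references plus A/B/D copies with planted private alleles.

    Each subgenome copy receives ``round(L * d / 2)`` private substitutions at
    positions disjoint across subgenomes (no transition/transversion bias), so
    realised pairwise identity equals the 1 - d target up to rounding.
    """
    rng = np.random.default_rng(cfg.seed)
    if gene_ids is None:
        gene_ids = [f"gene{i:02d}" for i in range(cfg.n_genes)]
    L = cfg.amplicon_length
    k = int(round(L * cfg.pairwise_divergence / 2.0))
    if 3 * k > L:
        raise ValueError("divergence too high for disjoint private sites")
    mapping_refs: List[ReferenceSeq] = []
    homoeologs: Dict[str, Dict[str, str]] = {}
    sites: List[DivergenceSite] = []
    annotation: Dict[str, Tuple[str, str]] = {}
    for gene_id in gene_ids:
        ancestral = "".join(BASES[i] for i in rng.integers(0, 4, size=L))
        mapping_refs.append(ReferenceSeq(ref_id=gene_id, sequence=ancestral))
        annotation[gene_id] = (f"scaf_{gene_id}", gene_id)
        positions = rng.choice(L, size=3 * k, replace=False)
        homoeologs[gene_id] = {}
        for si, sub in enumerate(SUBGENOMES):
            seq = list(ancestral)
            for pos in sorted(positions[si * k : (si + 1) * k]):
                allele = _mutate_base(ancestral[pos], rng)
                seq[pos] = allele
                sites.append(DivergenceSite(gene_id, int(pos), sub, allele))
            homoeologs[gene_id][sub] = "".join(seq)
    return HomoeologReferences(
        mapping_refs=mapping_refs,
        homoeologs=homoeologs,
        sites=sites,
        annotation=annotation,
    )


def generate_deletion_mutant(
    panel: MarkerPanel,
    subgenome: str,
    span: Tuple[float, float],
    mutant_id: str = "mutant",
) -> Tuple[SampleGenotype, TruthRecord]:
    """Deletion mutant whose span (up_kb <= 0 <= down_kb) covers the anchor.

    Every marker whose offset falls inside the span loses its copy on the
    given subgenome; the true physical span is recorded as ground truth.
    """
    up_kb, down_kb = span
    if up_kb > 0 or down_kb < 0:
        raise ValueError(
            f"span ({up_kb}, {down_kb}) must cover the anchor (up_kb <= 0 <= down_kb)"
        )
    if subgenome not in SUBGENOMES:
        raise ValueError(f"unknown subgenome {subgenome!r}")
    deleted = {m.gene_id for m in panel if up_kb <= m.offset_kb <= down_kb}
    genotype = SampleGenotype(
        sample_id=mutant_id, absent={(g, subgenome) for g in deleted}
    )
    truth = TruthRecord(
        mutant_id=mutant_id,
        subgenome=subgenome,
        deleted_gene_ids=deleted,
        true_span_kb=float(down_kb - up_kb),
    )
    return genotype, truth


def random_deletion_mutant(
    panel: MarkerPanel,
    rng: np.random.Generator,
    mutant_id: str = "mutant",
    max_side_kb: float = 1250.0,
) -> Tuple[SampleGenotype, TruthRecord]:
    """Draw a mutant with a uniform random span on each side of the anchor.

    Side extents are U(0, max_side_kb), giving total spans from tens of kb to
    ~2.5 Mb — the regime observed for heavy-ion-induced deletions.
    """
    subgenome = SUBGENOMES[int(rng.integers(3))]
    up = -float(rng.uniform(0.0, max_side_kb))
    down = float(rng.uniform(0.0, max_side_kb))
    return generate_deletion_mutant(panel, subgenome, (up, down), mutant_id)


def simulate_sample_reads(
    genotype: SampleGenotype,
    references: HomoeologReferences,
    cfg: SimulationConfig,
    seed: int,
) -> List[AmpliconRead]:
    """Amplicon reads from every gene x subgenome copy the sample carries.

    Per present copy the read count is Poisson with mean
    ``amplicon_length * coverage / read_length``; starts are uniform and
    errors are i.i.d. substitutions at ``error_rate``.  Deterministic given
    the seed (reads are emitted in gene, subgenome, index order).
    """
    rng = np.random.default_rng(seed)
    L = cfg.amplicon_length
    rl = cfg.read_length
    lam = L * cfg.coverage / rl
    reads: List[AmpliconRead] = []
    for gene_id in references.gene_ids:
        for sub in SUBGENOMES:
            if not genotype.present(gene_id, sub):
                continue
            source = references.homoeologs[gene_id][sub]
            n_reads = int(rng.poisson(lam))
            starts = rng.integers(0, len(source) - rl + 1, size=n_reads)
            for idx, start in enumerate(starts):
                seq = np.frombuffer(
                    source[start : start + rl].encode("ascii"), dtype=np.uint8
                ).copy()
                if cfg.error_rate > 0:
                    err = rng.random(rl) < cfg.error_rate
                    for j in np.nonzero(err)[0]:
                        seq[j] = ord(_mutate_base(chr(seq[j]), rng))
                reads.append(
                    AmpliconRead(
                        read_id=f"{genotype.sample_id}:{gene_id}:{sub}:{idx}",
                        sequence=seq.tobytes().decode("ascii"),
                        sample_id=genotype.sample_id,
                    )
                )
    return reads


def simulate_f2_population(
    cross: CrossSpec,
    n: int,
    lethal_classes: Set[DetectedClass],
    seed: int,
) -> List[HomoeoGenotype]:
    """F2 genotypes from a selfed F1, with lethal detected classes rejected.

    Loci segregate independently; each hemizygous F1 locus transmits an
    intact allele with probability 1/2 per gamete.  Individuals whose
    detected class is lethal are redrawn (rejection sampling), so surviving
    class frequencies follow the renormalised distribution.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    f1 = f1_genotype(cross.parent1, cross.parent2)
    from .cross_model import f2_class_distribution

    dist = f2_class_distribution(f1)
    surviving_mass = sum(
        p for c, p in dist.probs.items() if c not in lethal_classes
    )
    if surviving_mass <= 0:
        raise ValueError("lethal classes cover the entire F2 distribution")
    out: List[HomoeoGenotype] = []
    while len(out) < n:
        batch = max(16, n - len(out))
        dosages = np.empty((batch, 3), dtype=np.int64)
        for k, d in enumerate(f1.dosages):
            if d == 1:
                dosages[:, k] = rng.integers(0, 2, size=batch) + rng.integers(
                    0, 2, size=batch
                )
            else:
                dosages[:, k] = d
        for row in dosages:
            g = HomoeoGenotype(int(row[0]), int(row[1]), int(row[2]))
            if detect_class(g) not in lethal_classes:
                out.append(g)
                if len(out) == n:
                    break
    return out
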