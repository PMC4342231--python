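"""Homoeologue-specific SNP calling from amplicon reads with aneuploid controls.

The three wheat subgenomes are ~96-98% identical, so amplicon reads from a
gene's A, B and D copies all map to one reference and the subgenome-private
divergence sites appear as variants.  Which variant belongs to which
subgenome is resolved with aneuploid stocks: a nullisomic-tetrasomic line
lacks one homoeologous chromosome pair, so variants carried on that
subgenome disappear from its read set.  A variant present in every wild-type
sample but absent from exactly one nulli-tetra control is homoeologue
specific.  A gene copy is then called deleted in a mutant when *all* of its
subgenome-specific variants are missing from the mutant's reads, intact when
all are present, and unknown otherwise.

Pipeline: align_reads -> build_pileup -> detect_snps -> select_consensus_snps
-> assign_homoeologue_specific_snps -> call_intactness.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .cross_model import SUBGENOMES

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

__all__ = [
    "ReferenceSeq",
    "AmpliconRead",
    "ReadAlignment",
    "PileupColumn",
    "SnpRecord",
    "ControlDesign",
    "HomoeoSnpSets",
    "IntactnessCall",
    "CallerConfig",
    "SnpKey",
    "align_reads",
    "build_pileup",
    "detect_snps",
    "select_consensus_snps",
    "assign_homoeologue_specific_snps",
    "call_intactness",
    "coverage_map",
    "duplicate_start_fraction",
]

SnpKey = Tuple[str, int, str]  # (gene_id, ref_position 0-based, allele_variant)


@dataclass(frozen=True)
class ReferenceSeq:
    ref_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference {self.ref_id} has empty sequence")
        seq = self.sequence.upper()
        if set(seq) - set("ACGTN"):
            raise ValueError(f"reference {self.ref_id} has non-ACGTN characters")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AmpliconRead:
    read_id: str
    sequence: str
    sample_id: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id} has empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    ref_id: str
    start: int  # 0-based offset on the reference
    identity: float
    mapped: bool


@dataclass
class PileupColumn:
    ref_id: str
    position: int  # 0-based
    base_counts: Dict[str, int]

    @property
    def coverage(self) -> int:
        return sum(self.base_counts.values())


@dataclass(frozen=True)
class SnpRecord:
    """One variant allele passing the frequency/coverage thresholds.

    ``ref_position`` is 0-based in memory; exported tables use 1-based
    positions (see io.write_snp_table).
    """

    scaffold_id: str
    gene_id: str
    ref_position: int
    ref_type: str
    allele_variant: str
    frequency: float  # percent of coverage
    coverage: int

    @property
    def key(self) -> SnpKey:
        return (self.gene_id, self.ref_position, self.allele_variant)


@dataclass
class ControlDesign:
    """Which samples are wild type and which are the aneuploid controls."""

    wild_type_samples: List[str]
    null_tetra: Dict[str, str]  # subgenome -> sample id
    extra_controls: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.wild_type_samples:
            raise ValueError("at least one wild-type sample is required")
        missing = set(SUBGENOMES) - set(self.null_tetra)
        if missing:
            raise ValueError(
                f"nullisomic-tetrasomic controls missing for subgenomes: {sorted(missing)}"
            )
        for name in self.extra_controls:
            if name.lower().startswith("monosomic"):
                # a single-copy chromosome still fluoresces / still yields reads,
                # so a monosomic stock cannot serve as an absence control
                raise ValueError("monosomic lines are not supported as controls")


@dataclass
class HomoeoSnpSets:
    """Per gene, per subgenome: the homoeologue-specific variant sites."""

    sets: Dict[str, Dict[str, Set[Tuple[int, str]]]]
    unassigned: List[SnpKey] = field(default_factory=list)

    def __post_init__(self) -> None:
        for gene, per_sub in self.sets.items():
            seen: Dict[Tuple[int, str], str] = {}
            for sub, pairs in per_sub.items():
                for pair in pairs:
                    if pair in seen and seen[pair] != sub:
                        raise ValueError(
                            f"gene {gene}: site {pair} assigned to both "
                            f"{seen[pair]} and {sub}"
                        )
                    seen[pair] = sub

    def for_gene(self, gene_id: str, subgenome: str) -> Set[Tuple[int, str]]:
        return self.sets.get(gene_id, {}).get(subgenome, set())

    @property
    def genes(self) -> List[str]:
        return sorted(self.sets)


@dataclass
class IntactnessCall:
    gene_id: str
    subgenome: str
    status: str  # intact | deleted | unknown
    supporting_snps: int
    absent_snps: int
    conflict: bool = False


@dataclass(frozen=True)
class CallerConfig:
    """Mapping and SNP-detection thresholds."""

    min_identity: float = 0.85
    min_allele_freq: float = 0.05
    min_coverage: int = 50

    def __post_init__(self) -> None:
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")
        if not (0.0 < self.min_allele_freq < 1.0):
            raise ValueError("min_allele_freq must be in (0, 1)")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


def encode_seq(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (N) -> 4."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


def _get_kernel():
    """Compile (once) the exhaustive best-placement scan."""
    global _KERNEL
    if _KERNEL is not None:
        return _KERNEL
    from numba import njit

    @njit(cache=True)
    def best_placements(
        reads_flat,
        read_starts,
        read_lens,
        refs_flat,
        ref_starts,
        ref_lens,
        cand_flat,
        cand_starts,
        kmer_span,
        out_ref,
        out_off,
        out_matches,
    ):
        """Exact argmax of ungapped matches over every (ref, offset) pair.

        Seed candidates (pairs of ref index / offset in ``cand_flat``, sorted
        by ref then offset) are scored first.  ``kmer_span`` = k + stride - 1:
        by the pigeonhole principle every placement with at most
        m = (L - kmer_span) // (kmer_span + 1) mismatches shares a sampled
        seed with the read, so when the best candidate reaches L - m matches
        the candidate set provably contains the global argmax (and its
        lowest-ref/lowest-offset tie-break) and the scan is skipped.
        Otherwise the full scan runs, with the candidate score (minus one, so
        the first placement attaining the maximum is still visited) priming
        the branch-and-bound bound; windows are abandoned as soon as they
        cannot beat the running best, leaving the argmax exact either way.
        """
        n_reads = read_starts.shape[0]
        n_refs = ref_starts.shape[0]
        for i in range(n_reads):
            L = read_lens[i]
            rs = read_starts[i]
            cand_best = -1
            cand_ref = -1
            cand_off = -1
            for c in range(cand_starts[i], cand_starts[i + 1], 2):
                r = cand_flat[c]
                off = cand_flat[c + 1]
                if ref_lens[r] < L or off < 0 or off > ref_lens[r] - L:
                    continue
                base = ref_starts[r] + off
                m = 0
                for j in range(L):
                    b = reads_flat[rs + j]
                    if b == refs_flat[base + j] and b < 4:
                        m += 1
                if m > cand_best:  # candidates pre-sorted: first max wins ties
                    cand_best = m
                    cand_ref = r
                    cand_off = off
            m_guard = (L - kmer_span) // (kmer_span + 1)
            if cand_best >= 0 and m_guard >= 0 and cand_best >= L - m_guard:
                out_ref[i] = cand_ref
                out_off[i] = cand_off
                out_matches[i] = cand_best
                continue
            best_matches = cand_best - 1
            best_ref = -1
            best_off = -1
            for r in range(n_refs):
                ref_len = ref_lens[r]
                if ref_len < L:
                    continue
                base = ref_starts[r]
                for off in range(ref_len - L + 1):
                    allowed = L - best_matches - 1  # mismatches must stay below
                    mism = 0
                    matches = 0
                    ok = True
                    for j in range(L):
                        b = reads_flat[rs + j]
                        if b == refs_flat[base + off + j] and b < 4:
                            matches += 1
                        else:
                            mism += 1
                            if mism > allowed:
                                ok = False
                                break
                    if ok and matches > best_matches:
                        best_matches = matches
                        best_ref = r
                        best_off = off
            out_ref[i] = best_ref
            out_off[i] = best_off
            out_matches[i] = best_matches

    _KERNEL = best_placements
    return _KERNEL


_KERNEL = None


def align_reads(
    reads: Sequence[AmpliconRead],
    refs: Sequence[ReferenceSeq],
    cfg: CallerConfig = CallerConfig(),
) -> List[ReadAlignment]:
    """Place each read at its best ungapped position over all references.

    The placement maximises exact-match identity over every (reference,
    offset) pair; ties break to the lexicographically lowest ref_id, then the
    lowest offset.  A read is mapped iff its best identity reaches
    ``cfg.min_identity``.
    """
    if not refs:
        raise ValueError("empty reference set")
    refs_sorted = sorted(refs, key=lambda r: r.ref_id)
    ref_arrays = [encode_seq(r.sequence) for r in refs_sorted]
    refs_flat = np.concatenate(ref_arrays) if ref_arrays else np.empty(0, np.int8)
    ref_lens = np.array([len(a) for a in ref_arrays], dtype=np.int64)
    ref_starts = np.concatenate(([0], np.cumsum(ref_lens)[:-1])).astype(np.int64)
    max_len = int(ref_lens.max())
    kernel = _get_kernel()

    # exact-match k-mer seeds: stride-sampled lookups whose hits are scored
    # before the scan; see the kernel docstring for the pigeonhole guarantee
    k, stride = 12, 4
    index: Dict[bytes, List[int]] = defaultdict(list)
    for ri, r in enumerate(refs_sorted):
        seq = r.sequence.encode("ascii")
        for off in range(0, max(len(seq) - k + 1, 0)):
            index[seq[off : off + k]].extend((ri, off))

    read_arrays = []
    cand_flat: List[int] = []
    cand_starts = [0]
    for read in reads:
        if len(read.sequence) > max_len:
            raise ValueError(
                f"read {read.read_id} is longer ({len(read.sequence)}) than the "
                f"longest reference ({max_len})"
            )
        read_arrays.append(encode_seq(read.sequence))
        rseq = read.sequence.encode("ascii")
        cands = set()
        for pos in range(0, max(len(rseq) - k + 1, 1), stride):
            hits = index.get(rseq[pos : pos + k])
            if hits:
                for h in range(0, len(hits), 2):
                    cands.add((hits[h], hits[h + 1] - pos))
        for ri, off in sorted(cands):
            cand_flat.extend((ri, off))
        cand_starts.append(len(cand_flat))

    if not reads:
        return []
    reads_flat = np.concatenate(read_arrays)
    read_lens = np.array([len(a) for a in read_arrays], dtype=np.int64)
    read_starts = np.concatenate(([0], np.cumsum(read_lens)[:-1])).astype(np.int64)
    out_ref = np.empty(len(reads), dtype=np.int64)
    out_off = np.empty(len(reads), dtype=np.int64)
    out_matches = np.empty(len(reads), dtype=np.int64)
    kernel(
        reads_flat,
        read_starts,
        read_lens,
        refs_flat,
        ref_starts,
        ref_lens,
        np.array(cand_flat, dtype=np.int64),
        np.array(cand_starts, dtype=np.int64),
        k + stride - 1,
        out_ref,
        out_off,
        out_matches,
    )
    alignments: List[ReadAlignment] = []
    for i, read in enumerate(reads):
        identity = out_matches[i] / len(read.sequence)
        alignments.append(
            ReadAlignment(
                read_id=read.read_id,
                ref_id=refs_sorted[out_ref[i]].ref_id,
                start=int(out_off[i]),
                identity=float(identity),
                mapped=identity >= cfg.min_identity,
            )
        )
    return alignments


def build_pileup(
    alignments: Sequence[ReadAlignment],
    reads: Sequence[AmpliconRead],
    refs: Sequence[ReferenceSeq],
) -> List[PileupColumn]:
    """Per-position base counts on each reference, from mapped reads only."""
    reads_by_id = {r.read_id: r for r in reads}
    ref_by_id = {r.ref_id: r for r in refs}
    counts: Dict[str, np.ndarray] = {
        r.ref_id: np.zeros((len(r), 4), dtype=np.int64) for r in refs
    }
    for aln in alignments:
        if not aln.mapped:
            continue
        if aln.read_id not in reads_by_id:
            raise ValueError(f"alignment refers to unknown read {aln.read_id}")
        if aln.ref_id not in ref_by_id:
            raise ValueError(f"alignment refers to unknown reference {aln.ref_id}")
        seq = encode_seq(reads_by_id[aln.read_id].sequence)
        mat = counts[aln.ref_id]
        valid = seq < 4
        positions = aln.start + np.nonzero(valid)[0]
        np.add.at(mat, (positions, seq[valid].astype(np.int64)), 1)
    columns: List[PileupColumn] = []
    for ref_id in sorted(counts):
        mat = counts[ref_id]
        covered = np.nonzero(mat.sum(axis=1))[0]
        for pos in covered:
            columns.append(
                PileupColumn(
                    ref_id=ref_id,
                    position=int(pos),
                    base_counts={
                        BASES[k]: int(mat[pos, k]) for k in range(4) if mat[pos, k] > 0
                    },
                )
            )
    return columns


def detect_snps(
    pileup: Sequence[PileupColumn],
    cfg: CallerConfig,
    annotation: Mapping[str, Tuple[str, str]],
    refs: Sequence[ReferenceSeq],
) -> List[SnpRecord]:
    """Call variant alleles passing the coverage and frequency thresholds.

    ``annotation`` maps ref_id -> (scaffold_id, gene_id).  One record is
    emitted per (position, non-reference allele) with coverage >=
    ``min_coverage`` and allele frequency >= ``min_allele_freq``; frequency is
    reported as a percentage of the column coverage.
    """
    ref_by_id = {r.ref_id: r for r in refs}
    records: List[SnpRecord] = []
    for col in pileup:
        if col.ref_id not in annotation:
            raise ValueError(f"pileup column on unannotated reference {col.ref_id}")
        if col.coverage < cfg.min_coverage:
            continue
        scaffold_id, gene_id = annotation[col.ref_id]
        ref_base = ref_by_id[col.ref_id].sequence[col.position]
        for allele in BASES:
            if allele == ref_base:
                continue
            count = col.base_counts.get(allele, 0)
            if count == 0:
                continue
            freq = count / col.coverage
            if freq < cfg.min_allele_freq:
                continue
            records.append(
                SnpRecord(
                    scaffold_id=scaffold_id,
                    gene_id=gene_id,
                    ref_position=col.position,
                    ref_type=ref_base,
                    allele_variant=allele,
                    frequency=100.0 * freq,
                    coverage=col.coverage,
                )
            )
    records.sort(key=lambda r: (r.gene_id, r.ref_position, r.allele_variant))
    return records


def _table_keys(records: Iterable[SnpRecord]) -> Set[SnpKey]:
    return {r.key for r in records}


def select_consensus_snps(
    snp_tables: Mapping[str, Sequence[SnpRecord]],
    design: ControlDesign,
) -> Set[SnpKey]:
    """Keep only variants present in *every* wild-type sample.

    Variants missing from any wild-type replicate are accession-specific or
    unreliable and are discarded.
    """
    missing = [s for s in design.wild_type_samples if s not in snp_tables]
    if missing:
        raise ValueError(f"missing wild-type SNP tables: {missing}")
    key_sets = [_table_keys(snp_tables[s]) for s in design.wild_type_samples]
    consensus = set.intersection(*key_sets)
    dropped = set.union(*key_sets) - consensus
    if dropped:
        logger.info("discarded %d non-consensus wild-type variants", len(dropped))
    return consensus


def assign_homoeologue_specific_snps(
    consensus: Set[SnpKey],
    snp_tables: Mapping[str, Sequence[SnpRecord]],
    design: ControlDesign,
) -> HomoeoSnpSets:
    """Partition consensus variants by which nulli-tetra control lost them.

    A consensus variant absent from exactly one nullisomic-tetrasomic control
    is carried by that control's missing subgenome.  Variants absent from
    zero or from multiple controls cannot be assigned and are logged.
    """
    control_keys: Dict[str, Set[SnpKey]] = {}
    for sub, sample in design.null_tetra.items():
        if sample not in snp_tables:
            raise ValueError(f"missing nulli-tetra SNP table for subgenome {sub}: {sample}")
        control_keys[sub] = _table_keys(snp_tables[sample])

    sets: Dict[str, Dict[str, Set[Tuple[int, str]]]] = defaultdict(
        lambda: {s: set() for s in SUBGENOMES}
    )
    unassigned: List[SnpKey] = []
    for key in sorted(consensus):
        gene_id, pos, allele = key
        absent_from = [s for s in SUBGENOMES if key not in control_keys[s]]
        if len(absent_from) == 1:
            sets[gene_id][absent_from[0]].add((pos, allele))
        else:
            unassigned.append(key)
    if unassigned:
        logger.info(
            "%d consensus variants absent from %s controls left unassigned",
            len(unassigned),
            "0 or multiple",
        )
    return HomoeoSnpSets(sets={g: d for g, d in sets.items()}, unassigned=unassigned)


def coverage_map(pileup: Sequence[PileupColumn], annotation: Mapping[str, Tuple[str, str]]) -> Dict[Tuple[str, int], int]:
    """Per (gene_id, position) read depth, for informativeness gating."""
    out: Dict[Tuple[str, int], int] = {}
    for col in pileup:
        _, gene_id = annotation[col.ref_id]
        out[(gene_id, col.position)] = col.coverage
    return out


def call_intactness(
    mutant_table: Sequence[SnpRecord],
    sets: HomoeoSnpSets,
    subgenome: str,
    gene_ids: Optional[Sequence[str]] = None,
    coverage: Optional[Mapping[Tuple[str, int], int]] = None,
    min_coverage: int = 50,
) -> List[IntactnessCall]:
    """Call each gene intact / deleted / unknown on one subgenome of a mutant.

    Deleted requires *all* subgenome-specific variants of the gene to be
    absent from the mutant; intact requires all present.  Genes with no
    specific variants, or with a partial (conflicting) pattern, are unknown.

    When the mutant's per-position read depth is supplied, a missing variant
    only counts as deletion evidence where the mutant had at least
    ``min_coverage`` reads: absence without calling power is uninformative,
    not evidence.  Sites below the floor are excluded from the vote.
    """
    if subgenome not in SUBGENOMES:
        raise ValueError(f"unknown subgenome {subgenome!r}")
    mutant_keys = _table_keys(mutant_table)
    genes = list(gene_ids) if gene_ids is not None else sets.genes
    calls: List[IntactnessCall] = []
    for gene in genes:
        specific = sets.for_gene(gene, subgenome)
        if coverage is not None:
            specific = {
                (pos, allele)
                for (pos, allele) in specific
                if coverage.get((gene, pos), 0) >= min_coverage
            }
        if not specific:
            calls.append(
                IntactnessCall(gene, subgenome, "unknown", supporting_snps=0, absent_snps=0)
            )
            continue
        absent = sum(
            1 for (pos, allele) in specific if (gene, pos, allele) not in mutant_keys
        )
        n = len(specific)
        if absent == n:
            status, conflict = "deleted", False
        elif absent == 0:
            status, conflict = "intact", False
        else:
            status, conflict = "unknown", True
            warnings.warn(
                f"gene {gene} subgenome {subgenome}: {absent}/{n} specific variants "
                "absent — conflicting pattern, intactness unknown"
            )
        calls.append(
            IntactnessCall(
                gene, subgenome, status, supporting_snps=n, absent_snps=absent,
                conflict=conflict,
            )
        )
    return calls


def duplicate_start_fraction(alignments: Sequence[ReadAlignment]) -> float:
    """Fraction of mapped reads sharing a start position with an earlier read.

    A logged stand-in for visual PCR-duplicate inspection; no filtering is
    performed.
    """
    mapped = [(a.ref_id, a.start) for a in alignments if a.mapped]
    if not mapped:
        return 0.0
    c = Counter(mapped)
    dup = sum(k - 1 for k in c.values() if k > 1)
    frac = dup / len(mapped)
    logger.info("duplicate-start fraction: %.3f", frac)
    return frac
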