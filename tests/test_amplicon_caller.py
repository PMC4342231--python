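"""Amplicon alignment, SNP detection, control subtraction and intactness calls."""

import numpy as np
import pytest

from delstack.amplicon_caller import (
    AmpliconRead,
    CallerConfig,
    ControlDesign,
    HomoeoSnpSets,
    PileupColumn,
    ReferenceSeq,
    SnpRecord,
    align_reads,
    assign_homoeologue_specific_snps,
    build_pileup,
    call_intactness,
    detect_snps,
    duplicate_start_fraction,
    select_consensus_snps,
)
from delstack.pipeline import (
    default_control_design,
    mutant_calls,
    process_sample,
    snps_for_sample,
    snp_tables_for_samples,
)
from delstack.synthetic_data import generate_deletion_mutant, simulate_sample_reads

BASES = "ACGT"


def brute_force_best(read_seq, refs):
    """Independent exhaustive placement oracle (lowest ref_id, lowest offset)."""
    best = (-1, None, None)
    for r in sorted(refs, key=lambda x: x.ref_id):
        for off in range(len(r.sequence) - len(read_seq) + 1):
            window = r.sequence[off : off + len(read_seq)]
            m = sum(a == b and a in BASES for a, b in zip(read_seq, window))
            if m > best[0]:
                best = (m, r.ref_id, off)
    return best


def random_seq(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


class TestAlignReads:
    def test_exact_substring_maps_with_identity_one(self):
        ref = ReferenceSeq("r1", "ACGTACGTACGTACGTACGT")
        read = AmpliconRead("q", "GTACGTAC", "s")
        (aln,) = align_reads([read], [ref])
        assert aln.mapped and aln.identity == 1.0
        assert aln.ref_id == "r1" and aln.start == 2

    def test_high_divergence_read_unmapped(self):
        rng = np.random.default_rng(0)
        ref_seq = random_seq(rng, 60)
        # flip every 4th base of a 40-mer window: 25% mismatch everywhere
        window = list(ref_seq[10:50])
        for i in range(0, 40, 4):
            window[i] = BASES[(BASES.index(window[i]) + 1) % 4]
        (aln,) = align_reads(
            [AmpliconRead("q", "".join(window), "s")], [ReferenceSeq("r1", ref_seq)]
        )
        assert not aln.mapped

    def test_matches_brute_force_oracle(self):
        """30-mer reads vs two 60-mer refs: placement equals the exhaustive scan."""
        rng = np.random.default_rng(123)
        refs = [ReferenceSeq("ra", random_seq(rng, 60)), ReferenceSeq("rb", random_seq(rng, 60))]
        reads = []
        for i in range(25):
            if i % 3 == 0:  # unrelated read
                seq = random_seq(rng, 30)
            else:  # read from a reference window with a few errors
                src = refs[int(rng.integers(2))].sequence
                off = int(rng.integers(31))
                seq = list(src[off : off + 30])
                for j in rng.choice(30, size=int(rng.integers(4)), replace=False):
                    seq[j] = BASES[(BASES.index(seq[j]) + 1 + int(rng.integers(3))) % 4]
                seq = "".join(seq)
            reads.append(AmpliconRead(f"q{i}", seq, "s"))
        alignments = align_reads(reads, refs)
        for read, aln in zip(reads, alignments):
            m, rid, off = brute_force_best(read.sequence, refs)
            assert (aln.ref_id, aln.start) == (rid, off)
            assert aln.identity == pytest.approx(m / 30)

    def test_empty_reference_set_errors(self):
        with pytest.raises(ValueError, match="empty reference"):
            align_reads([AmpliconRead("q", "ACGT", "s")], [])

    def test_read_longer_than_references_errors(self):
        with pytest.raises(ValueError, match="longer"):
            align_reads([AmpliconRead("q", "ACGTACGT", "s")], [ReferenceSeq("r", "ACGT")])


class TestBuildPileup:
    def test_no_mapped_reads_gives_empty_pileup(self):
        ref = ReferenceSeq("r1", "ACGTACGTACGTACGTACGT")
        read = AmpliconRead("q", "TTTTTTTT", "s")
        alns = align_reads([read], [ref])
        assert not alns[0].mapped
        assert build_pileup(alns, [read], [ref]) == []

    def test_identical_reads_stack(self):
        ref = ReferenceSeq("r1", "ACGTACGTACGTACGTACGT")
        reads = [AmpliconRead(f"q{i}", "GTACGTAC", "s") for i in range(60)]
        pileup = build_pileup(align_reads(reads, [ref]), reads, [ref])
        assert len(pileup) == 8
        assert all(c.coverage == 60 and len(c.base_counts) == 1 for c in pileup)

    def test_counts_equal_bruteforce_recount(self):
        rng = np.random.default_rng(5)
        ref = ReferenceSeq("r1", random_seq(rng, 80))
        reads = []
        for i in range(40):
            off = int(rng.integers(0, 61))
            seq = list(ref.sequence[off : off + 20])
            if i % 2:
                seq[5] = BASES[(BASES.index(seq[5]) + 1) % 4]
            reads.append(AmpliconRead(f"q{i}", "".join(seq), "s"))
        alns = align_reads(reads, [ref])
        pileup = build_pileup(alns, reads, [ref])
        expected = {}
        for read, aln in zip(reads, alns):
            if not aln.mapped:
                continue
            for j, b in enumerate(read.sequence):
                pos = aln.start + j
                expected.setdefault(pos, {}).setdefault(b, 0)
                expected[pos][b] += 1
        assert {c.position: c.base_counts for c in pileup} == expected


def column(pos, counts, ref_id="r1"):
    return PileupColumn(ref_id=ref_id, position=pos, base_counts=counts)


class TestDetectSnps:
    ANNOT = {"r1": ("scaf1", "gene1")}
    REFS = [ReferenceSeq("r1", "A" * 50)]

    def test_below_coverage_floor_not_called(self):
        cols = [column(3, {"A": 24, "C": 25})]  # coverage 49, variant at 51%
        assert detect_snps(cols, CallerConfig(), self.ANNOT, self.REFS) == []

    def test_below_frequency_floor_not_called(self):
        cols = [column(3, {"A": 96, "C": 4})]  # 4% < 5%
        assert detect_snps(cols, CallerConfig(), self.ANNOT, self.REFS) == []

    def test_two_passing_variants_reported_with_percent_frequency(self):
        cols = [column(3, {"A": 60, "C": 30, "G": 10})]
        records = detect_snps(cols, CallerConfig(), self.ANNOT, self.REFS)
        assert [(r.allele_variant, r.frequency) for r in records] == [
            ("C", 30.0),
            ("G", 10.0),
        ]
        assert all(r.ref_type == "A" and r.coverage == 100 for r in records)


def rec(gene, pos, allele, **kw):
    defaults = dict(
        scaffold_id="s", gene_id=gene, ref_position=pos, ref_type="A",
        allele_variant=allele, frequency=30.0, coverage=100,
    )
    defaults.update(kw)
    return SnpRecord(**defaults)


class TestControlLogic:
    def design(self, n_wt=2):
        return ControlDesign(
            wild_type_samples=[f"WT_{i}" for i in range(1, n_wt + 1)],
            null_tetra={"A": "NA", "B": "NB", "D": "ND"},
        )

    def test_variant_missing_from_one_wild_type_is_dropped(self):
        shared, extra = rec("g", 5, "C"), rec("g", 9, "G")
        tables = {
            "WT_1": [shared, extra], "WT_2": [shared, extra],
            "WT_3": [shared, extra], "WT_4": [shared],
        }
        design = self.design(n_wt=4)
        assert select_consensus_snps(tables, design) == {("g", 5, "C")}

    def test_single_wild_type_keeps_everything(self):
        tables = {"WT_1": [rec("g", 5, "C"), rec("g", 9, "G")]}
        design = ControlDesign(
            wild_type_samples=["WT_1"], null_tetra={"A": "NA", "B": "NB", "D": "ND"}
        )
        assert select_consensus_snps(tables, design) == {("g", 5, "C"), ("g", 9, "G")}

    def test_missing_wild_type_errors(self):
        with pytest.raises(ValueError, match="wild-type"):
            select_consensus_snps({"WT_1": []}, self.design())

    def test_absence_from_one_control_assigns_subgenome(self):
        key_a, key_all = rec("g", 5, "C"), rec("g", 9, "G")
        tables = {
            "NA": [key_all],  # A control lost the position-5 variant
            "NB": [key_a, key_all],
            "ND": [key_a, key_all],
        }
        sets = assign_homoeologue_specific_snps(
            {key_a.key, key_all.key}, tables, self.design()
        )
        assert sets.for_gene("g", "A") == {(5, "C")}
        assert key_all.key in sets.unassigned  # present in all three controls

    def test_gene_without_divergence_yields_empty_sets(self):
        tables = {"NA": [], "NB": [], "ND": []}
        sets = assign_homoeologue_specific_snps(set(), tables, self.design())
        assert sets.genes == []

    def test_missing_control_errors(self):
        with pytest.raises(ValueError, match="nulli-tetra"):
            assign_homoeologue_specific_snps(set(), {"NA": [], "NB": []}, self.design())

    def test_monosomic_control_rejected(self):
        with pytest.raises(ValueError, match="monosomic"):
            ControlDesign(
                wild_type_samples=["WT"],
                null_tetra={"A": "NA", "B": "NB", "D": "ND"},
                extra_controls={"monosomic_2A": "M2A"},
            )


class TestCallIntactness:
    SETS = HomoeoSnpSets(
        sets={"g1": {"A": {(i, "C") for i in range(5)}, "B": set(), "D": set()}}
    )

    def test_all_specific_snps_absent_is_deleted(self):
        calls = call_intactness([], self.SETS, "A")
        assert calls[0].status == "deleted"
        assert calls[0].supporting_snps == 5 and calls[0].absent_snps == 5

    def test_all_present_is_intact(self):
        table = [rec("g1", i, "C") for i in range(5)]
        assert call_intactness(table, self.SETS, "A")[0].status == "intact"

    def test_no_specific_snps_is_unknown(self):
        assert call_intactness([], self.SETS, "B")[0].status == "unknown"

    def test_partial_absence_is_unknown_with_conflict(self):
        table = [rec("g1", i, "C") for i in range(2)]  # 3 of 5 absent
        with pytest.warns(UserWarning, match="conflicting"):
            (call,) = call_intactness(table, self.SETS, "A")
        assert call.status == "unknown" and call.conflict


class TestEndToEnd:
    def test_zero_error_calls_match_truth(self, panel, small_sim):
        """Error-free reads recover every planted deletion exactly."""
        cfg, refs, genotypes, tables, sets = small_sim
        genotype, truth = generate_deletion_mutant(panel, "D", (-60.0, 60.0), "mut_d")
        reads = simulate_sample_reads(genotype, refs, cfg, seed=77)
        mutant_table = process_sample(reads, refs.mapping_refs, refs.annotation)
        all_tables = dict(tables, mut_d=mutant_table)
        calls = mutant_calls(all_tables, sets, ["mut_d"], refs.gene_ids)["mut_d"]
        for c in calls:
            expected = (
                "deleted"
                if (c.gene_id, c.subgenome) in genotype.absent
                else "intact"
            )
            assert c.status == expected, (c.gene_id, c.subgenome)

    def test_snp_calls_invariant_to_read_order(self, small_sim):
        cfg, refs, genotypes, tables, sets = small_sim
        reads = simulate_sample_reads(genotypes["WT_1"], refs, cfg, seed=9)
        fwd = snps_for_sample(reads, refs.mapping_refs, refs.annotation)
        rev = snps_for_sample(list(reversed(reads)), refs.mapping_refs, refs.annotation)
        assert fwd == rev

    def test_duplicate_samples_give_identical_calls(self, panel, small_sim):
        """Two read sets from one genotype (different seeds) call identically."""
        cfg, refs, genotypes, tables, sets = small_sim
        genotype, _ = generate_deletion_mutant(panel, "A", (-120.0, 20.0), "dup")
        calls = []
        for seed in (101, 202):
            reads = simulate_sample_reads(genotype, refs, cfg, seed=seed)
            table = process_sample(reads, refs.mapping_refs, refs.annotation)
            per_seed = mutant_calls(dict(tables, dup=table), sets, ["dup"], refs.gene_ids)
            calls.append([(c.gene_id, c.subgenome, c.status) for c in per_seed["dup"]])
        assert calls[0] == calls[1]

    def test_robustness_at_one_percent_error(self, panel):
        """>= 95% of gene x subgenome calls match truth over 20 noisy mutants."""
        from delstack.pipeline import (
            homoeologue_sets_from_tables,
            standard_control_genotypes,
        )
        from delstack.synthetic_data import (
            SimulationConfig,
            generate_homoeolog_references,
            random_deletion_mutant,
        )

        gene_ids = [m.gene_id for m in panel if -200 <= m.offset_kb <= 200]
        cfg = SimulationConfig(n_genes=len(gene_ids), seed=31, error_rate=0.01)
        refs = generate_homoeolog_references(cfg, gene_ids=gene_ids)
        genotypes = standard_control_genotypes(refs.gene_ids)
        rng = np.random.default_rng(13)
        truths = {}
        for i in range(20):
            mid = f"mut{i:02d}"
            genotypes[mid], truths[mid] = random_deletion_mutant(panel, rng, mid)
        tables = snp_tables_for_samples(genotypes, refs, cfg, seed=17)
        sets = homoeologue_sets_from_tables(tables, default_control_design())
        calls = mutant_calls(tables, sets, sorted(truths), refs.gene_ids)
        total = correct = 0
        for mid, truth in truths.items():
            genotype = genotypes[mid]
            for c in calls[mid]:
                expected = (
                    "deleted" if (c.gene_id, c.subgenome) in genotype.absent else "intact"
                )
                total += 1
                correct += c.status == expected
        assert total == 20 * len(gene_ids) * 3
        assert correct / total >= 0.95


def test_duplicate_start_fraction_logs_not_filters():
    ref = ReferenceSeq("r1", "ACGTACGTACGTACGTACGT")
    reads = [AmpliconRead(f"q{i}", "GTACGTAC", "s") for i in range(3)]
    alns = align_reads(reads, [ref])
    assert duplicate_start_fraction(alns) == pytest.approx(2 / 3)
    assert len(alns) == 3  # nothing removed
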