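"""Segregation of stacked homoeologous deletions through wheat crosses.

Bread wheat is allohexaploid: most genes exist as three homoeologous copies
on the A, B and D subgenomes, each locus carrying two alleles.  Deletion
mutants for single homoeoloci ("primary" mutants) can be crossed to stack
deletions, but the high-throughput probe screen used to genotype progeny is
hemizygote-blind: a line with one intact allele fluoresces like wild type,
so only *homozygous* deletions are detected.

This module models that process.  Given two homozygous parents it derives
the F1, enumerates the F2 under independent assortment of the three
homoeoloci, collapses genotypes through the hemizygote-blind detector, and
tests observed F2 class counts against the expected ratios with per-class
1-df chi-square goodness-of-fit tests.  A Monte-Carlo power helper estimates
how detectable a lethal (incompatible) genotype class is for a given family
size.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Set

import numpy as np
from scipy import stats

SUBGENOMES = ("A", "B", "D")

__all__ = [
    "SUBGENOMES",
    "HomoeoGenotype",
    "CrossSpec",
    "DetectedClass",
    "ClassDistribution",
    "ObservedCrossTable",
    "ChiSquareResult",
    "SignificanceConfig",
    "f1_genotype",
    "detect_class",
    "f2_class_distribution",
    "per_class_chi_square",
    "evaluate_cross_table",
    "incompatibility_power",
    "cross_from_index",
]


@dataclass(frozen=True)
class HomoeoGenotype:
    """Intact-allele dosage at the A/B/D homoeoloci of one target gene.

    Dosage 2 = homozygous intact, 1 = hemizygous (one allele deleted),
    0 = homozygous deleted.
    """

    dosage_A: int
    dosage_B: int
    dosage_D: int

    def __post_init__(self) -> None:
        for sub in SUBGENOMES:
            d = getattr(self, f"dosage_{sub}")
            if d not in (0, 1, 2):
                raise ValueError(f"dosage_{sub}={d!r}: allele dosage must be 0, 1 or 2")

    @property
    def dosages(self) -> tuple:
        return (self.dosage_A, self.dosage_B, self.dosage_D)

    def is_homozygous(self) -> bool:
        return all(d in (0, 2) for d in self.dosages)


@dataclass(frozen=True)
class DetectedClass:
    """What the hemizygote-blind screen reports: the set of homozygous deletions."""

    deleted_set: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        bad = set(self.deleted_set) - set(SUBGENOMES)
        if bad:
            raise ValueError(f"unknown subgenomes in deleted set: {sorted(bad)}")
        object.__setattr__(self, "deleted_set", frozenset(self.deleted_set))

    @classmethod
    def from_label(cls, label: str) -> "DetectedClass":
        """Parse labels like 'AB', 'none', '' into a detected class."""
        label = label.strip()
        if label.lower() in ("", "none"):
            return cls(frozenset())
        return cls(frozenset(label))

    @property
    def label(self) -> str:
        if not self.deleted_set:
            return "none"
        return "".join(s for s in SUBGENOMES if s in self.deleted_set)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.label


@dataclass(frozen=True)
class CrossSpec:
    """A cross between two homozygous deletion stocks."""

    parent1: HomoeoGenotype
    parent2: HomoeoGenotype
    label: str = ""
    index: Optional[int] = None


@dataclass
class ClassDistribution:
    """Probability law of detected classes among F2 progeny."""

    probs: Dict[DetectedClass, float]

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if any(p < 0 for p in self.probs.values()):
            raise ValueError("class probabilities must be non-negative")
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"class probabilities sum to {total}, not 1")

    def prob(self, cls: DetectedClass) -> float:
        return self.probs.get(cls, 0.0)


@dataclass
class ObservedCrossTable:
    """Observed F2 screen counts for one cross.

    ``counts`` lists only the classes the screen reported; the undetected
    ("none") class is implicit as ``n`` minus the listed counts.
    """

    cross: CrossSpec
    n: int
    counts: Dict[DetectedClass, int]
    gene: str = ""

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("class counts must be non-negative")
        listed = sum(self.counts.values())
        if listed > self.n:
            raise ValueError(
                f"listed class counts ({listed}) exceed progeny screened ({self.n})"
            )

    @property
    def none_count(self) -> int:
        return self.n - sum(self.counts.values())


@dataclass(frozen=True)
class SignificanceConfig:
    """Flagging thresholds: '*' below alpha1, '**' below alpha2."""

    alpha1: float = 0.05
    alpha2: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha2 < self.alpha1 < 1.0):
            raise ValueError("require 0 < alpha2 < alpha1 < 1")

    def flag(self, p_value: float) -> str:
        if p_value < self.alpha2:
            return "**"
        if p_value < self.alpha1:
            return "*"
        return ""


@dataclass
class ChiSquareResult:
    detected_class: DetectedClass
    observed: int
    expected: float
    statistic: float
    df: int
    p_value: float
    flag: str
    bold: bool


def f1_genotype(parent1: HomoeoGenotype, parent2: HomoeoGenotype) -> HomoeoGenotype:
    """F1 of two fully homozygous parents: one gamete from each.

    Each parent contributes exactly dosage/2 intact alleles per locus, so the
    F1 dosage is the mean of the parental dosages.
    """
    for name, parent in (("parent1", parent1), ("parent2", parent2)):
        if not parent.is_homozygous():
            raise ValueError(
                f"{name} has a hemizygous locus (dosages {parent.dosages}); "
                "F2 ratio derivation requires fully homozygous parents"
            )
    dosages = tuple((a + b) // 2 for a, b in zip(parent1.dosages, parent2.dosages))
    return HomoeoGenotype(*dosages)


def detect_class(g: HomoeoGenotype) -> DetectedClass:
    """Hemizygote-blind detection: only dosage-0 loci are reported deleted."""
    return DetectedClass(
        frozenset(s for s, d in zip(SUBGENOMES, g.dosages) if d == 0)
    )


def _selfing_offspring_dosages(d: int) -> List[int]:
    """Equally likely offspring dosages for one locus when an F1 selfs.

    Returned as four entries (one per ordered gamete pair) so that joint
    enumeration over loci stays uniform.
    """
    if d == 0:
        return [0, 0, 0, 0]
    if d == 2:
        return [2, 2, 2, 2]
    # hemizygous: gametes {intact, deleted} each 1/2
    return [g1 + g2 for g1 in (0, 1) for g2 in (0, 1)]


def f2_class_distribution(f1: HomoeoGenotype) -> ClassDistribution:
    """Detected-class law in the F2 of a selfed F1, loci assorting independently.

    Enumerates the 4**h equally likely zygotes (h = hemizygous loci in the F1)
    and maps each through the hemizygote-blind detector.  Dosage-0 loci put
    their subgenome in every class; dosage-2 loci never do.
    """
    per_locus = [_selfing_offspring_dosages(d) for d in f1.dosages]
    probs: Dict[DetectedClass, float] = {}
    combos = list(itertools.product(*per_locus))
    w = 1.0 / len(combos)
    for dosages in combos:
        cls = detect_class(HomoeoGenotype(*dosages))
        probs[cls] = probs.get(cls, 0.0) + w
    return ClassDistribution(probs)


def per_class_chi_square(
    observed: int,
    n: int,
    expected_p: float,
    cfg: SignificanceConfig = SignificanceConfig(),
    detected_class: DetectedClass = DetectedClass(),
) -> ChiSquareResult:
    """1-df goodness of fit on the two-cell split {class, not class}.

    statistic = (O - np)^2/(np) + ((n-O) - n(1-p))^2/(n(1-p)); no continuity
    correction.  For observed = 0 this reduces to the closed form np/(1-p).
    """
    if not (0 <= observed <= n):
        raise ValueError(f"observed={observed} outside [0, n={n}]")
    if expected_p == 0.0:
        if observed > 0:
            raise ValueError(
                f"impossible class observed: {detected_class.label} has expected "
                f"probability 0 but {observed} individuals were recorded"
            )
        raise ValueError("class with expected probability 0 should be skipped, not tested")
    if not (0.0 < expected_p < 1.0):
        raise ValueError("expected_p must lie strictly between 0 and 1")
    expected = n * expected_p
    other = n * (1.0 - expected_p)
    statistic = (observed - expected) ** 2 / expected + ((n - observed) - other) ** 2 / other
    p_value = float(stats.chi2.sf(statistic, df=1))
    flag = cfg.flag(p_value)
    return ChiSquareResult(
        detected_class=detected_class,
        observed=observed,
        expected=expected,
        statistic=float(statistic),
        df=1,
        p_value=p_value,
        flag=flag,
        bold=(observed == 0 and flag != ""),
    )


def evaluate_cross_table(
    table: ObservedCrossTable,
    cfg: SignificanceConfig = SignificanceConfig(),
) -> List[ChiSquareResult]:
    """Chi-square test each reported deletion class of one cross.

    Derives the F1 from the cross parents, computes the F2 detected-class
    distribution, and tests every class the screen reported (classes the
    table omits were not recorded — e.g. primary deletions in the
    tetra x tetra crosses — and are not assumed to be 0).  Raises if a
    recorded class has a positive count but expected probability 0.
    """
    if table.n == 0:
        warnings.warn("cross table with 0 progeny screened: nothing to test")
        return []
    f1 = f1_genotype(table.cross.parent1, table.cross.parent2)
    dist = f2_class_distribution(f1)
    results = []
    for cls in sorted(table.counts, key=lambda c: (len(c.deleted_set), c.label)):
        observed = table.counts[cls]
        p = dist.prob(cls)
        if p == 0.0:
            if observed > 0:
                raise ValueError(
                    f"observed count for class {cls.label} which has expected "
                    "probability 0 under this cross"
                )
            continue  # class cannot occur and none were seen: nothing to test
        results.append(per_class_chi_square(observed, table.n, p, cfg, cls))
    return results


# Table E index -> parental genotypes. Index 1-3 are primary x primary crosses
# (A x B, A x D, B x D); 4 is AD-tetra x BD-tetra; 5 is AB-tetra x D-primary.
_INDEX_PARENTS = {
    1: ((0, 2, 2), (2, 0, 2)),
    2: ((0, 2, 2), (2, 2, 0)),
    3: ((2, 0, 2), (2, 2, 0)),
    4: ((0, 2, 0), (2, 0, 0)),
    5: ((0, 0, 2), (2, 2, 0)),
}


def cross_from_index(index: int, label: str = "") -> CrossSpec:
    """Build the cross corresponding to an expected-ratio index (1-5)."""
    try:
        p1, p2 = _INDEX_PARENTS[index]
    except KeyError:
        raise ValueError(f"unknown expected-ratio index {index!r} (valid: 1-5)") from None
    return CrossSpec(HomoeoGenotype(*p1), HomoeoGenotype(*p2), label=label, index=index)


def simulate_detected_counts(
    dist: ClassDistribution,
    n: int,
    lethal_classes: Set[DetectedClass],
    rng: np.random.Generator,
) -> Dict[DetectedClass, int]:
    """Multinomial draw of detected classes with lethal classes removed."""
    surviving = {c: p for c, p in dist.probs.items() if c not in lethal_classes}
    total = sum(surviving.values())
    if total <= 0:
        raise ValueError("lethal classes cover the entire F2 distribution")
    classes = sorted(surviving, key=lambda c: c.label)
    p = np.array([surviving[c] / total for c in classes])
    draws = rng.multinomial(n, p)
    return {c: int(k) for c, k in zip(classes, draws)}


def incompatibility_power(
    cross: CrossSpec,
    n: int,
    lethal_classes: Set[DetectedClass],
    reps: int,
    seed: int,
    cfg: SignificanceConfig = SignificanceConfig(),
) -> float:
    """Monte-Carlo power of the per-class chi-square screen.

    Simulates ``reps`` F2 families of size ``n`` with the lethal detected
    classes removed (renormalised), runs the full evaluation, and returns the
    fraction of families in which *every* lethal class is flagged at alpha1.

    With an empty lethal set there is nothing to detect; the function then
    returns the mean per-class flag rate under the null, i.e. the empirical
    type-I error of the screen (expected to sit near alpha1 per class).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    f1 = f1_genotype(cross.parent1, cross.parent2)
    dist = f2_class_distribution(f1)
    unknown = set(lethal_classes) - set(dist.probs)
    if unknown:
        raise ValueError(
            "lethal classes not produced by this cross: "
            + ", ".join(sorted(c.label for c in unknown))
        )
    hits = 0
    null_flags = 0
    null_tests = 0
    expected_classes = [c for c, p in dist.probs.items() if c.deleted_set and p > 0]
    for _ in range(reps):
        counts = simulate_detected_counts(dist, n, set(lethal_classes), rng)
        table = ObservedCrossTable(
            cross=cross,
            n=n,
            counts={c: counts.get(c, 0) for c in expected_classes},
        )
        results = evaluate_cross_table(table, cfg)
        by_class = {r.detected_class: r for r in results}
        if lethal_classes:
            if all(
                c in by_class and by_class[c].p_value < cfg.alpha1
                for c in lethal_classes
            ):
                hits += 1
        else:
            null_tests += len(results)
            null_flags += sum(r.p_value < cfg.alpha1 for r in results)
    if lethal_classes:
        return hits / reps
    return null_flags / max(null_tests, 1)
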