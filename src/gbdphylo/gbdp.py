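"""Intergenomic distance computation (GBDP core).

A distance between two genomes is computed per search direction from the
filtered HSP summary, averaged over the two directions, and accompanied by
pseudo-bootstrap replicates obtained by resampling the retained per-HSP
contributions with replacement.

Distance formulas (L_A, L_B genome lengths; A = matched positions over both
genomes; C = retained alignment columns; I = retained identities):

    d0 = 1 - A / (L_A + L_B)        gene-content flavoured
    d4 = 1 - I / C                  identity per column; robust to incomplete
                                    genomes (1 when C = 0 by convention)
    d6 = 1 - 2I / (L_A + L_B)       identity per genome length

Results are clamped to [0, 1].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import hspfilter
from .alignment import (
    AMINO_ACID,
    NUCLEOTIDE,
    HSP,
    ScoringScheme,
    bidirectional_hsps,
    pair_stream_seed,
)
from .errors import UsageError, ValidationError
from .formats import GenomeRecord
from .hspfilter import Contribution, MatchSummary, summarize

EVALUE_GRID = (10.0, 1.0, 1e-1, 1e-2, 1e-3, 1e-8)
ALGORITHMS = ("trimming", "coverage")
CORE_FORMULAS = ("d0", "d4", "d6")

# Formula registry.  d0/d4/d6 are the normative formulas; the remaining
# registry slots are experimental placeholders mapping onto the same three
# families with min/max genome-length denominators, disabled by default.
_FormulaFn = Callable[[MatchSummary, int, int], float]


def _d0(s: MatchSummary, la: int, lb: int) -> float:
    return 1.0 - (s.matched_a + s.matched_b) / (la + lb)


def _d4(s: MatchSummary, la: int, lb: int) -> float:
    if s.columns == 0:
        return 1.0
    return 1.0 - s.identities / s.columns


def _d6(s: MatchSummary, la: int, lb: int) -> float:
    return 1.0 - 2.0 * s.identities / (la + lb)


FORMULAS: dict[str, _FormulaFn] = {
    "d0": _d0,
    "d4": _d4,
    "d6": _d6,
    # experimental denominators (not used by default settings)
    "d1": lambda s, la, lb: 1.0 - (s.matched_a + s.matched_b) / (2 * min(la, lb)),
    "d2": lambda s, la, lb: 1.0 - (s.matched_a + s.matched_b) / (2 * max(la, lb)),
    "d3": _d4,
    "d5": _d4,
    "d7": lambda s, la, lb: 1.0 - 2.0 * s.identities / (2 * min(la, lb)),
    "d8": lambda s, la, lb: 1.0 - 2.0 * s.identities / (2 * max(la, lb)),
    "d9": _d4,
}
ALL_FORMULAS = tuple(f"d{i}" for i in range(10))


@dataclass(frozen=True)
class GBDPSettings:
    """One point in the parameter grid."""

    seq_type: str = NUCLEOTIDE
    word_length: int | None = None  # None -> 11 (nt) / 3 (aa)
    evalue_max: float = 10.0
    algorithm: str = "trimming"
    formula: str = "d0"
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.seq_type not in (NUCLEOTIDE, AMINO_ACID):
            raise UsageError(f"unknown sequence type {self.seq_type!r}")
        if self.algorithm not in ALGORITHMS:
            raise UsageError(f"unknown filtering algorithm {self.algorithm!r}")
        if self.formula not in FORMULAS:
            raise UsageError(f"unknown distance formula {self.formula!r}")

    @property
    def effective_word_length(self) -> int:
        if self.word_length is not None:
            return self.word_length
        return 11 if self.seq_type == NUCLEOTIDE else 3

    def scheme(self) -> ScoringScheme:
        if self.seq_type == NUCLEOTIDE:
            return ScoringScheme.nucleotide_default(self.effective_word_length)
        return ScoringScheme.amino_acid_default(self.effective_word_length)


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix plus optional replicate matrices."""

    labels: list[str]
    values: np.ndarray
    replicates: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise UsageError("duplicate labels in distance matrix")
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match label count")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix asymmetric beyond 1e-12")
        if np.abs(np.diag(self.values)).max(initial=0.0) != 0.0:
            raise ValidationError("distance matrix diagonal must be exactly 0")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValidationError("distances must lie in [0, 1]")

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in keep]
        return DistanceMatrix(
            labels=list(keep),
            values=self.values[np.ix_(idx, idx)],
            replicates=[r[np.ix_(idx, idx)] for r in self.replicates],
        )


def formula_distance(
    summary: MatchSummary, length_a: int, length_b: int, formula: str
) -> float:
    """Apply one registered distance formula and clamp the result to [0, 1]."""
    if length_a <= 0 or length_b <= 0:
        raise ValidationError("genome lengths must be positive")
    if min(summary.matched_a, summary.matched_b, summary.columns, summary.identities) < 0:
        raise ValidationError("negative match summary fields")
    try:
        fn = FORMULAS[formula]
    except KeyError:
        raise UsageError(f"unknown distance formula {formula!r}")
    return float(min(1.0, max(0.0, fn(summary, length_a, length_b))))


def _direction_contributions(
    hsps: Sequence[HSP], algorithm: str
) -> list[Contribution]:
    if algorithm == "trimming":
        retained, _ = hspfilter.greedy_trim(hsps)
        return hspfilter.trim_contributions(retained)
    return hspfilter.coverage_contributions(hsps)


def pair_distance(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    settings: GBDPSettings,
    hsps_ab: Sequence[HSP] | None = None,
    hsps_ba: Sequence[HSP] | None = None,
) -> tuple[float, np.ndarray]:
    """Point distance and pseudo-bootstrap replicate distances for one pair.

    Replicate r resamples each direction's retained contribution list with
    replacement (same count) from a deterministic stream keyed by
    (seed, unordered pair, r), recomputes the summary by plain summation and
    re-applies the formula; the two directions are averaged as for the point
    estimate.
    """
    ab, ba = bidirectional_hsps(
        genome_a, genome_b, settings.scheme(), settings.evalue_max,
        hsps_ab=hsps_ab, hsps_ba=hsps_ba,
    )
    la, lb = genome_a.total_length, genome_b.total_length
    contrib_ab = _direction_contributions(ab, settings.algorithm)
    contrib_ba = _direction_contributions(ba, settings.algorithm)

    def dist(cab: Sequence[Contribution], cba: Sequence[Contribution]) -> float:
        d1 = formula_distance(summarize(cab), la, lb, settings.formula)
        d2 = formula_distance(summarize(cba), lb, la, settings.formula)
        return 0.5 * (d1 + d2)

    point = dist(contrib_ab, contrib_ba)
    reps = np.empty(settings.n_replicates)
    for r in range(settings.n_replicates):
        rng = pair_stream_seed(settings.seed, genome_a.genome_id, genome_b.genome_id, r)
        res_ab = (
            [contrib_ab[k] for k in rng.integers(len(contrib_ab), size=len(contrib_ab))]
            if contrib_ab
            else []
        )
        res_ba = (
            [contrib_ba[k] for k in rng.integers(len(contrib_ba), size=len(contrib_ba))]
            if contrib_ba
            else []
        )
        reps[r] = dist(res_ab, res_ba)
    return point, reps


def build_matrix(
    genomes: Sequence[GenomeRecord],
    settings: GBDPSettings,
    pair_hsps: dict[tuple[str, str], Sequence[HSP]] | None = None,
) -> DistanceMatrix:
    """All-pairs distance matrix with replicate matrices.

    ``pair_hsps`` optionally supplies pre-computed HSP lists keyed by the
    ordered (query_id, subject_id) pair; missing directions are mirrored.
    Deterministic for a fixed seed regardless of genome input order.
    """
    if len(genomes) < 2:
        raise UsageError("need at least two genomes")
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise UsageError(f"duplicate genome ids: {sorted(ids)}")
    n = len(genomes)
    values = np.zeros((n, n))
    reps = [np.zeros((n, n)) for _ in range(settings.n_replicates)]
    order = sorted(range(n), key=lambda i: ids[i])
    for ii, jj in itertools.combinations(order, 2):
        ga, gb = genomes[ii], genomes[jj]
        hab = hba = None
        if pair_hsps is not None:
            hab = pair_hsps.get((ga.genome_id, gb.genome_id))
            hba = pair_hsps.get((gb.genome_id, ga.genome_id))
        d, dr = pair_distance(ga, gb, settings, hsps_ab=hab, hsps_ba=hba)
        values[ii, jj] = values[jj, ii] = d
        for r in range(settings.n_replicates):
            reps[r][ii, jj] = reps[r][jj, ii] = dr[r]
    return DistanceMatrix(labels=ids, values=values, replicates=reps)
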