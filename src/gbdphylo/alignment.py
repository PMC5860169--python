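"""Built-in seed-and-extend local aligner producing HSPs.

The aligner finds exact word seeds (word length 11 for DNA, 3 for proteins by
default), extends them without gaps under an X-drop rule, and attaches
Karlin-Altschul e-values so hits can be filtered the same way externally
computed tabular hits are.  It deliberately does *not* aim at score parity
with any external local-alignment tool: downstream distance computation only
consumes the HSP list, so any aligner producing sane HSPs is interchangeable.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ParameterError, UsageError
from .formats import GenomeRecord

NUCLEOTIDE = "nucleotide"
AMINO_ACID = "amino_acid"

_DNA_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HSP:
    """One ungapped (built-in) or gapped (external) local alignment segment.

    Intervals are 0-based half-open on the forward strand of each genome.
    ``identities`` is real-valued: trimming scales it proportionally.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str  # "+" or "-"; "+" always for amino acids
    length: int
    identities: float
    raw_score: int
    bit_score: float
    evalue: float
    q_record: str = ""
    s_record: str = ""

    @property
    def q_interval(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)

    @property
    def s_interval(self) -> tuple[int, int]:
        return (self.s_start, self.s_end)

    def mirrored(self) -> "HSP":
        """Swap query and subject roles (used to synthesize the reverse search)."""
        return replace(
            self,
            query_id=self.subject_id,
            subject_id=self.query_id,
            q_start=self.s_start,
            q_end=self.s_end,
            s_start=self.q_start,
            s_end=self.q_end,
            q_record=self.s_record,
            s_record=self.q_record,
        )

    def validate(self) -> None:
        if not (0 <= self.identities <= self.length + 1e-9):
            raise UsageError(
                f"HSP identities {self.identities} outside [0, length={self.length}]"
            )
        if self.evalue < 0:
            raise UsageError("HSP e-value must be >= 0")


_AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"


def _blosum62_lookup() -> tuple[np.ndarray, str]:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    alphabet = str(mat.alphabet)
    lut = np.full((128, 128), -4, dtype=np.int32)
    for i, a in enumerate(alphabet):
        for j, b in enumerate(alphabet):
            lut[ord(a), ord(b)] = int(mat[i, j])
    return lut, alphabet


@dataclass
class ScoringScheme:
    """Scoring parameters plus Karlin-Altschul statistics for e-values.

    ``lambda_`` is solved from the background frequencies so that
    sum_ij p_i p_j exp(lambda * s_ij) = 1; ``K`` is fixed (e-values are used
    only as a monotone filter threshold, so the absolute scale is irrelevant).
    """

    seq_type: str = NUCLEOTIDE
    match: int = 2
    mismatch: int = -3
    matrix_name: str = "BLOSUM62"
    word_length: int = 11
    xdrop: int = 20
    K: float = 0.1
    background: np.ndarray | None = None
    _lambda: float | None = field(default=None, repr=False)
    _lut: np.ndarray | None = field(default=None, repr=False)
    _alphabet: str | None = field(default=None, repr=False)

    @classmethod
    def nucleotide_default(cls, word_length: int = 11) -> "ScoringScheme":
        return cls(seq_type=NUCLEOTIDE, match=2, mismatch=-3, word_length=word_length)

    @classmethod
    def amino_acid_default(cls, word_length: int = 3) -> "ScoringScheme":
        return cls(seq_type=AMINO_ACID, word_length=word_length, xdrop=15)

    def _ensure_tables(self) -> None:
        if self._lut is not None:
            return
        if self.seq_type == NUCLEOTIDE:
            alphabet = "ACGT"
            lut = np.full((128, 128), self.mismatch, dtype=np.int32)
            for a in alphabet:
                lut[ord(a), ord(a)] = self.match
        else:
            lut, alphabet = _blosum62_lookup()
            alphabet = alphabet.replace("*", "")[:20]  # 20 standard residues
        self._lut = lut
        self._alphabet = alphabet
        if self.background is None:
            self.background = np.full(len(alphabet), 1.0 / len(alphabet))

    @property
    def score_lut(self) -> np.ndarray:
        self._ensure_tables()
        return self._lut

    @property
    def alphabet(self) -> str:
        self._ensure_tables()
        return self._alphabet

    def pair_scores(self) -> np.ndarray:
        """Substitution scores restricted to the background alphabet."""
        self._ensure_tables()
        idx = np.array([ord(c) for c in self._alphabet])
        return self._lut[np.ix_(idx, idx)]

    @property
    def lambda_(self) -> float:
        if self._lambda is None:
            self._lambda = solve_lambda(self)
        return self._lambda


def solve_lambda(scheme: ScoringScheme, tol: float = 1e-9) -> float:
    """Unique positive root of sum_ij p_i p_j exp(lambda * s_ij) = 1.

    Requires a negative expected score under the background frequencies;
    solved by plain bisection after doubling out an upper bracket.
    """
    s = scheme.pair_scores().astype(float)
    p = np.asarray(scheme.background, dtype=float)
    w = np.outer(p, p)
    expected = float((w * s).sum())
    if expected >= 0:
        raise ParameterError(
            f"expected score per aligned pair is {expected:.4f} >= 0; "
            "e-value statistics are undefined for such a scheme"
        )
    if s.max() <= 0:
        raise ParameterError("scheme has no positive score; lambda undefined")

    def f(lam: float) -> float:
        return float((w * np.exp(lam * s)).sum()) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - defensive
            raise ParameterError("failed to bracket lambda")
    lo = 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _xdrop_right(scores: np.ndarray, xdrop: int) -> tuple[int, int]:
    """Best ungapped extension along ``scores`` with an X-drop stop.

    Returns (n_columns_taken, score_gain); the extension ends at the argmax
    of the cumulative score among positions reached before the running
    maximum drops by more than ``xdrop``.
    """
    if scores.size == 0:
        return 0, 0
    cum = np.cumsum(scores)
    runmax = np.maximum.accumulate(cum)
    dropped = runmax - cum > xdrop
    limit = int(np.argmax(dropped)) if dropped.any() else scores.size
    if limit == 0:
        return 0, 0
    best = int(np.argmax(cum[:limit]))
    gain = int(cum[best])
    if gain <= 0:
        return 0, 0
    return best + 1, gain


def _extend_seed(
    a: np.ndarray,
    b: np.ndarray,
    i: int,
    j: int,
    w: int,
    lut: np.ndarray,
    xdrop: int,
) -> tuple[int, int, int, int]:
    """Extend the exact seed a[i:i+w] == b[j:j+w] ungapped in both directions.

    Returns (q_start, q_end, raw_score, n_identities) in local coordinates.
    """
    seed_score = int(lut[a[i : i + w], b[j : j + w]].sum())
    # right extension
    nr = min(a.size - (i + w), b.size - (j + w))
    right_scores = lut[a[i + w : i + w + nr], b[j + w : j + w + nr]]
    took_r, gain_r = _xdrop_right(right_scores, xdrop)
    # left extension (reverse the prefix)
    nl = min(i, j)
    left_scores = lut[a[i - nl : i][::-1], b[j - nl : j][::-1]]
    took_l, gain_l = _xdrop_right(left_scores, xdrop)
    q_start = i - took_l
    q_end = i + w + took_r
    score = seed_score + gain_l + gain_r
    ident = int((a[q_start:q_end] == b[q_start - i + j : q_end - i + j]).sum())
    return q_start, q_end, score, ident


def _seed_hits(
    a: np.ndarray, b: np.ndarray, w: int, lut: np.ndarray, xdrop: int
) -> list[tuple[int, int, int, int, int]]:
    """All deduplicated ungapped extensions between two encoded sequences.

    Yields (q_start, q_end, s_start, s_end ... implicitly via diagonal, score,
    identities).  On each diagonal only the highest-scoring extension over any
    overlapping stretch is kept, and seeds already covered by a previous
    extension on their diagonal are skipped (standard seed-skip optimisation).
    """
    if a.size < w or b.size < w:
        return []
    index: dict[bytes, list[int]] = {}
    abytes = a.tobytes()
    for i in range(a.size - w + 1):
        index.setdefault(abytes[i : i + w], []).append(i)
    bbytes = b.tobytes()
    frontier: dict[int, int] = {}  # diagonal -> furthest q_end reached
    best_on_range: dict[tuple[int, int, int], tuple[int, int]] = {}
    hits: list[tuple[int, int, int, int, int]] = []
    for j in range(b.size - w + 1):
        word = bbytes[j : j + w]
        for i in index.get(word, ()):
            d = j - i
            if frontier.get(d, -1) >= i + w:
                continue
            qs, qe, score, ident = _extend_seed(a, b, i, j, w, lut, xdrop)
            frontier[d] = qe
            key = (d, qs, qe)
            prev = best_on_range.get(key)
            if prev is None or score > prev[0]:
                best_on_range[key] = (score, ident)
    for (d, qs, qe), (score, ident) in best_on_range.items():
        hits.append((qs, qe, d, score, ident))
    return hits


def _genome_arrays(genome: GenomeRecord) -> list[tuple[str, int, np.ndarray]]:
    """(record_id, offset into concatenated genome, encoded sequence) per record."""
    out = []
    off = 0
    for rid, seq in genome.sequences:
        out.append((rid, off, _encode(seq)))
        off += len(seq)
    return out


def find_hsps(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    scheme: ScoringScheme | None = None,
    evalue_max: float = 10.0,
) -> list[HSP]:
    """Seed-and-extend search of ``genome_a`` (query) against ``genome_b``.

    Nucleotide mode searches both strands; amino-acid mode aligns every
    protein of A against every protein of B, with coordinates offset into the
    concatenated proteome so occupied-interval bookkeeping stays per-genome.
    E-value: K * m * n * exp(-lambda * raw_score) with m, n total lengths.
    """
    if genome_a.seq_type != genome_b.seq_type:
        raise UsageError(
            f"sequence type mismatch: {genome_a.seq_type} vs {genome_b.seq_type}"
        )
    if scheme is None:
        scheme = (
            ScoringScheme.nucleotide_default()
            if genome_a.seq_type == NUCLEOTIDE
            else ScoringScheme.amino_acid_default()
        )
    if scheme.seq_type != genome_a.seq_type:
        raise UsageError("scoring scheme sequence type does not match genomes")
    lut = scheme.score_lut
    w = scheme.word_length
    lam = scheme.lambda_
    m = genome_a.total_length
    n = genome_b.total_length
    ln_kmn = math.log(scheme.K) + math.log(max(m, 1)) + math.log(max(n, 1))

    hsps: list[HSP] = []

    def emit(qs, qe, ss, se, strand, score, ident, qrec, srec):
        evalue = math.exp(ln_kmn - lam * score)
        if evalue > evalue_max:
            return
        length = qe - qs
        bit = (lam * score - math.log(scheme.K)) / math.log(2.0)
        hsps.append(
            HSP(
                query_id=genome_a.genome_id,
                subject_id=genome_b.genome_id,
                q_start=qs,
                q_end=qe,
                s_start=ss,
                s_end=se,
                strand=strand,
                length=length,
                identities=float(ident),
                raw_score=score,
                bit_score=round(bit, 2),
                evalue=evalue,
                q_record=qrec,
                s_record=srec,
            )
        )

    arrays_a = _genome_arrays(genome_a)
    arrays_b = _genome_arrays(genome_b)
    for rid_a, off_a, arr_a in arrays_a:
        for rid_b, off_b, arr_b in arrays_b:
            for qs, qe, d, score, ident in _seed_hits(arr_a, arr_b, w, lut, scheme.xdrop):
                emit(
                    off_a + qs, off_a + qe,
                    off_b + qs + d, off_b + qe + d,
                    "+", score, ident, rid_a, rid_b,
                )
            if genome_a.seq_type == NUCLEOTIDE:
                rc = _encode(reverse_complement(arr_b.tobytes().decode("ascii")))
                lb = arr_b.size
                for qs, qe, d, score, ident in _seed_hits(arr_a, rc, w, lut, scheme.xdrop):
                    # position p on the reverse complement maps to lb-1-p forward
                    emit(
                        off_a + qs, off_a + qe,
                        off_b + lb - (qe + d), off_b + lb - (qs + d),
                        "-", score, ident, rid_a, rid_b,
                    )
    hsps.sort(key=lambda h: (-h.raw_score, h.q_start, h.s_start))
    return hsps


def bidirectional_hsps(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    scheme: ScoringScheme | None = None,
    evalue_max: float = 10.0,
    hsps_ab: Sequence[HSP] | None = None,
    hsps_ba: Sequence[HSP] | None = None,
) -> tuple[list[HSP], list[HSP]]:
    """HSP lists for both search directions.

    The built-in scorer is symmetric, so the B->A list is the coordinate-swapped
    mirror of A->B.  Externally supplied hits for one direction are mirrored the
    same way when the other direction is missing.
    """
    if hsps_ab is not None or hsps_ba is not None:
        ab = list(hsps_ab) if hsps_ab is not None else [h.mirrored() for h in hsps_ba]
        ba = list(hsps_ba) if hsps_ba is not None else [h.mirrored() for h in hsps_ab]
        return ab, ba
    ab = find_hsps(genome_a, genome_b, scheme, evalue_max)
    ba = [h.mirrored() for h in ab]
    ba.sort(key=lambda h: (-h.raw_score, h.q_start, h.s_start))
    return ab, ba


def pair_stream_seed(seed: int, id_a: str, id_b: str, replicate: int) -> np.random.Generator:
    """Deterministic RNG for one genome pair and replicate, order-independent."""
    lo, hi = sorted((id_a, id_b))
    tag = zlib.crc32(f"{lo}|{hi}".encode())
    return np.random.default_rng(np.random.SeedSequence([seed, tag, replicate]))
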