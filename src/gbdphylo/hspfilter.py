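"""Paralogy-correcting HSP filters: greedy trimming and union coverage.

Both algorithms process HSPs in descending score order so that each genome
position contributes to the match summary at most once.  The *trimming*
filter shortens lower-scoring HSPs to their longest run of columns whose
query and subject positions are still unclaimed; the *coverage* filter keeps
HSPs intact but counts only newly covered positions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .alignment import HSP
from .errors import UsageError


@dataclass(frozen=True)
class MatchSummary:
    """Totals retained after filtering one search direction of a genome pair."""

    matched_a: float  # non-redundant matched positions on the query genome
    matched_b: float  # ... on the subject genome
    columns: float    # retained alignment columns (query direction)
    identities: float  # retained identical columns (real-valued)
    n_hsps: int

    def __post_init__(self):
        if min(self.matched_a, self.matched_b, self.columns, self.identities) < -1e-9:
            raise UsageError("match summary fields must be non-negative")


@dataclass(frozen=True)
class Contribution:
    """Per-HSP increment to a MatchSummary; the unit resampled by the
    pseudo-bootstrap."""

    matched_a: float
    matched_b: float
    columns: float
    identities: float


def summarize(contributions: Sequence[Contribution]) -> MatchSummary:
    return MatchSummary(
        matched_a=sum(c.matched_a for c in contributions),
        matched_b=sum(c.matched_b for c in contributions),
        columns=sum(c.columns for c in contributions),
        identities=sum(c.identities for c in contributions),
        n_hsps=len(contributions),
    )


# --- interval bookkeeping (sorted disjoint half-open intervals) -------------


class _IntervalSet:
    def __init__(self) -> None:
        self.ivals: list[tuple[int, int]] = []

    def overlap(self, lo: int, hi: int) -> int:
        return sum(max(0, min(hi, b) - max(lo, a)) for a, b in self.ivals)

    def covers(self, pos: int) -> bool:
        return any(a <= pos < b for a, b in self.ivals)

    def add(self, lo: int, hi: int) -> None:
        if hi <= lo:
            return
        merged = []
        for a, b in self.ivals:
            if b < lo or hi < a:
                merged.append((a, b))
            else:
                lo, hi = min(lo, a), max(hi, b)
        merged.append((lo, hi))
        merged.sort()
        self.ivals = merged

    def total(self) -> int:
        return sum(b - a for a, b in self.ivals)

    def uncovered(self, lo: int, hi: int) -> list[tuple[int, int]]:
        """Sub-intervals of [lo, hi) not covered by the set."""
        out = []
        cur = lo
        for a, b in self.ivals:
            if b <= cur:
                continue
            if a >= hi:
                break
            if a > cur:
                out.append((cur, min(a, hi)))
            cur = max(cur, b)
            if cur >= hi:
                break
        if cur < hi:
            out.append((cur, hi))
        return out


def _check_single_pair(hsps: Sequence[HSP]) -> None:
    pairs = {(h.query_id, h.subject_id) for h in hsps}
    if len(pairs) > 1:
        raise UsageError(f"HSPs from mixed genome pairs: {sorted(pairs)}")


def score_order(hsps: Iterable[HSP]) -> list[HSP]:
    """Descending raw score; ties: longer HSP first, then input order."""
    indexed = list(enumerate(hsps))
    indexed.sort(key=lambda t: (-t[1].raw_score, -t[1].length, t[0]))
    return [h for _, h in indexed]


def _column_positions(hsp: HSP, col: int) -> tuple[int, int]:
    """(query position, subject position) of alignment column ``col``.

    Exact for ungapped HSPs; gapped external hits (interval width != length)
    are mapped proportionally.
    """
    qw = hsp.q_end - hsp.q_start
    sw = hsp.s_end - hsp.s_start
    q = hsp.q_start + (col if qw == hsp.length else (col * qw) // hsp.length)
    if hsp.strand == "+":
        s = hsp.s_start + (col if sw == hsp.length else (col * sw) // hsp.length)
    else:
        off = col if sw == hsp.length else (col * sw) // hsp.length
        s = hsp.s_end - 1 - off
    return q, s


def _trim_hsp(hsp: HSP, occ_q: _IntervalSet, occ_s: _IntervalSet) -> HSP | None:
    """Longest contiguous run of columns whose query and subject positions are
    both unclaimed; identities scaled by the retained fraction."""
    L = hsp.length
    if occ_q.overlap(hsp.q_start, hsp.q_end) == 0 and (
        occ_s.overlap(hsp.s_start, hsp.s_end) == 0
    ):
        return hsp
    # blocked mask over columns, via uncovered-interval arithmetic on both axes
    free_q = occ_q.uncovered(hsp.q_start, hsp.q_end)
    free_s = occ_s.uncovered(hsp.s_start, hsp.s_end)

    def q_free(col: int) -> bool:
        q, _ = _column_positions(hsp, col)
        return any(a <= q < b for a, b in free_q)

    def s_free(col: int) -> bool:
        _, s = _column_positions(hsp, col)
        return any(a <= s < b for a, b in free_s)

    run_start = None
    best_len, best_start = 0, 0
    for col in range(L + 1):
        ok = col < L and q_free(col) and s_free(col)
        if ok and run_start is None:
            run_start = col
        if not ok and run_start is not None:
            run_len = col - run_start
            if run_len > best_len:
                best_len, best_start = run_len, run_start
            run_start = None
    if best_len == 0:
        return None
    c0, c1 = best_start, best_start + best_len
    q0, _ = _column_positions(hsp, c0)
    q1 = _column_positions(hsp, c1 - 1)[0] + 1
    if hsp.strand == "+":
        s0 = _column_positions(hsp, c0)[1]
        s1 = _column_positions(hsp, c1 - 1)[1] + 1
    else:
        s1 = _column_positions(hsp, c0)[1] + 1
        s0 = _column_positions(hsp, c1 - 1)[1]
    return replace(
        hsp,
        q_start=q0,
        q_end=q1,
        s_start=s0,
        s_end=s1,
        length=best_len,
        identities=hsp.identities * best_len / L,
    )


def greedy_trim(hsps: Sequence[HSP]) -> tuple[list[HSP], MatchSummary]:
    """Greedy-with-trimming filter.

    HSPs are visited in descending score order; each is reduced to its
    longest run of columns not yet claimed on either genome, dropped if
    nothing remains, and its retained intervals claim their positions.
    Idempotent: retained HSPs never overlap previously retained ones.
    """
    _check_single_pair(hsps)
    occ_q, occ_s = _IntervalSet(), _IntervalSet()
    retained: list[HSP] = []
    for hsp in score_order(hsps):
        trimmed = _trim_hsp(hsp, occ_q, occ_s)
        if trimmed is None or trimmed.length <= 0:
            continue
        retained.append(trimmed)
        occ_q.add(trimmed.q_start, trimmed.q_end)
        occ_s.add(trimmed.s_start, trimmed.s_end)
    summary = MatchSummary(
        matched_a=occ_q.total(),
        matched_b=occ_s.total(),
        columns=sum(h.length for h in retained),
        identities=sum(h.identities for h in retained),
        n_hsps=len(retained),
    )
    return retained, summary


def trim_contributions(retained: Sequence[HSP]) -> list[Contribution]:
    """Per-HSP increments for trimmed output (intervals are disjoint, so each
    HSP's own widths are its contribution)."""
    return [
        Contribution(
            matched_a=h.q_end - h.q_start,
            matched_b=h.s_end - h.s_start,
            columns=h.length,
            identities=h.identities,
        )
        for h in retained
    ]


def coverage_contributions(hsps: Sequence[HSP]) -> list[Contribution]:
    """Newly-covered-position increments in descending score order.

    matched positions are interval unions; identities are prorated by the
    fraction of the HSP's query span that was newly covered, so multiply
    covered positions contribute once.
    """
    _check_single_pair(hsps)
    cov_q, cov_s = _IntervalSet(), _IntervalSet()
    out: list[Contribution] = []
    for hsp in score_order(hsps):
        new_q = sum(b - a for a, b in cov_q.uncovered(hsp.q_start, hsp.q_end))
        new_s = sum(b - a for a, b in cov_s.uncovered(hsp.s_start, hsp.s_end))
        if new_q == 0 and new_s == 0:
            continue
        frac = new_q / hsp.length if hsp.length else 0.0
        out.append(
            Contribution(
                matched_a=new_q,
                matched_b=new_s,
                columns=new_q,
                identities=hsp.identities * frac,
            )
        )
        cov_q.add(hsp.q_start, hsp.q_end)
        cov_s.add(hsp.s_start, hsp.s_end)
    return out


def coverage_filter(hsps: Sequence[HSP]) -> MatchSummary:
    """Union-coverage filter: every genome position counts at most once."""
    return summarize(coverage_contributions(hsps))
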