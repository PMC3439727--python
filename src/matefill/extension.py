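"""The contig extension engine: overlap verification, consensus clustering,
read filtering/trimming, and the seed-extension loop with its four stop labels.

One extension step works on the current contig S:

1. collect reads whose oriented l-prefix overlaps S's l-suffix, for every
   overlap length l in [L, L + Delta], keeping those within the per-length
   mismatch budget delta(l);
2. place them at I(r) = |S| - l, F(r) = I(r) + |r| - 1, and compute a majority
   consensus over columns [I(C), F(C)], where F(C) is the rightmost position
   still supported by at least m reads;
3. classify each column by its representation rate pi(j) (non-represented if
   pi <= T1, low if T1 < pi <= T2, high otherwise); drop reads that mismatch
   the consensus at a low-represented column and cut every surviving read just
   before its first non-represented column, whether or not it matches there;
4. rebuild the consensus over the survivors; if at least m of them still reach
   past S's right end, append the new consensus and repeat.

The loop stops with MATE_FOUND (the seed's mate occurs in the contig within
Hamming distance M), NO_MORE_EXTENSION (step 2 fails on the raw overlap set),
REPEAT_FOUND (step 4 fails after filtering: the cluster collapsed, typically
at a repeat exit), or LENGTH_EXCEED (the contig outgrew Lmax).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fingerprint import _as_codes, codes_to_seq
from .read_index import FingerprintIndex, query_candidates

# stop labels
MATE_FOUND = "MATE_FOUND"
NO_MORE_EXTENSION = "NO_MORE_EXTENSION"
REPEAT_FOUND = "REPEAT_FOUND"
LENGTH_EXCEED = "LENGTH_EXCEED"
IN_PROGRESS = "IN_PROGRESS"

# column classes
NON_REPRESENTED = 0
LOW_REPRESENTED = 1
HIGH_REPRESENTED = 2


@dataclass
class ExtensionParams:
    """Tunables of the extension engine.

    L, Delta
        minimum overlap length and slack: overlap lengths range over
        [L, L + Delta].
    m
        minimum number of reads required to accept a consensus position.
    T1, T2
        representation-rate thresholds separating non-/low-/high-represented
        consensus columns (0.25 <= T1 < T2 < 1).
    M
        Hamming budget of the mate check, and numerator scale of the overlap
        mismatch budget delta(l) = floor(M * l / avg_read_len).
    avg_read_len
        average read length |r| used by the delta(l) rule.
    delta_cap
        optional fixed mismatch cap overriding the delta(l) rule.
    Lmax
        maximum contig length; None disables the length stop.
    """

    L: int = 50
    Delta: int = 40
    m: int = 2
    T1: float = 0.6
    T2: float = 0.9
    M: int = 10
    avg_read_len: int = 100
    delta_cap: Optional[int] = None
    Lmax: Optional[int] = None

    def __post_init__(self):
        if not (0.25 <= self.T1 < self.T2 < 1):
            raise ValueError("thresholds must satisfy 0.25 <= T1 < T2 < 1")
        if self.L <= 0 or self.Delta < 0 or self.m < 1:
            raise ValueError("invalid extension parameters")

    def delta(self, l: int) -> int:
        """Mismatch budget for an overlap of length l."""
        if self.delta_cap is not None:
            return self.delta_cap
        return (self.M * l) // self.avg_read_len


@dataclass
class OverlapRead:
    """A read placed against the current contig."""

    read_id: int
    is_rc: bool
    l: int  # overlap length with the contig suffix
    I: int  # start position in contig coordinates (= |S| - l)
    F: int  # end position (= I + |r| - 1)
    mismatches: int  # Hamming distance of l-prefix vs contig l-suffix
    codes: np.ndarray  # oriented read, full length
    effective_len: int  # current length after any trimming

    @property
    def F_eff(self) -> int:
        return self.I + self.effective_len - 1

    def covers(self, j: int) -> bool:
        return self.I <= j <= self.F_eff

    def char_at(self, j: int) -> int:
        return int(self.codes[j - self.I])


@dataclass
class ConsensusColumn:
    """Per-position view of the consensus (mainly for inspection and tests)."""

    j: int
    counts: np.ndarray  # occurrences of A,C,G,T at j
    consensus_char: int
    depth: int
    pi: float
    klass: int


class Consensus:
    """Majority consensus over [I_C, F_C] with per-column representation rates."""

    def __init__(self, I_C, F_C, chars, counts, depth, pi, klass):
        self.I_C = I_C
        self.F_C = F_C
        self.chars = chars  # consensus codes, one per column
        self.counts = counts  # (4, width)
        self.depth = depth
        self.pi = pi
        self.klass = klass

    @property
    def seq(self) -> str:
        return codes_to_seq(self.chars)

    def column(self, j: int) -> ConsensusColumn:
        i = j - self.I_C
        return ConsensusColumn(
            j=j,
            counts=self.counts[:, i].copy(),
            consensus_char=int(self.chars[i]),
            depth=int(self.depth[i]),
            pi=float(self.pi[i]),
            klass=int(self.klass[i]),
        )

    def columns(self):
        return [self.column(j) for j in range(self.I_C, self.F_C + 1)]


@dataclass
class Contig:
    """A labelled extension product; MATE_FOUND contigs are the certified output."""

    seq: str
    seed_id: str
    label: str = IN_PROGRESS
    mate_pos: Optional[int] = None
    steps: int = 0

    def __len__(self) -> int:
        return len(self.seq)


def positions(S_len: int, l: int, read_len: int) -> tuple[int, int]:
    """Start/end position of a read overlapping the l-suffix of a contig.

    I = |S| - l and F = I + |r| - 1; F beyond |S| - 1 is what makes the read
    useful for extension.
    """
    if l > S_len:
        raise ValueError(f"overlap length {l} exceeds contig length {S_len}")
    I = S_len - l
    return I, I + read_len - 1


def verify_overlaps(
    contig,
    candidates_by_l: dict[int, Sequence[tuple[int, bool]]],
    index: FingerprintIndex,
    params: ExtensionParams,
) -> list[OverlapRead]:
    """Character-verify fingerprint candidates into the overlap set R^(S).

    Candidates are checked per overlap length l against the Hamming budget
    delta(l); a read surfacing at several lengths is kept once, at the largest
    length at which it passes.
    """
    S = _as_codes(contig)
    kept: list[OverlapRead] = []
    seen: set[tuple[int, bool]] = set()
    for l in sorted(candidates_by_l, reverse=True):
        if l > S.size:
            continue
        suffix = S[S.size - l :]
        budget = params.delta(l)
        for rid, is_rc in candidates_by_l[l]:
            if (rid, is_rc) in seen:
                continue
            codes = index.oriented_codes(rid, is_rc)
            if codes.size < l:
                continue  # overlap longer than the read itself
            mism = int(np.count_nonzero(codes[:l] != suffix))
            if mism <= budget:
                I, F = positions(S.size, l, codes.size)
                kept.append(
                    OverlapRead(rid, is_rc, l, I, F, mism, codes, codes.size)
                )
                seen.add((rid, is_rc))
    return kept


def collect_overlaps(
    contig, index: FingerprintIndex, params: ExtensionParams
) -> list[OverlapRead]:
    """Query the index for every l in [L, L+Delta] and verify the candidates."""
    S = _as_codes(contig)
    lmax = min(params.L + params.Delta, S.size)
    cands = {
        l: query_candidates(index, S, l, params.Delta)
        for l in range(params.L, lmax + 1)
    }
    return verify_overlaps(S, cands, index, params)


def consensus_bounds(
    overlaps: Sequence[OverlapRead], m: int, S_len: int
) -> Optional[tuple[int, int]]:
    """Bounds (I_C, F_C) of the consensus, or None when extension must halt.

    I_C is the leftmost read start; F_C the rightmost position whose depth of
    read ends is still at least m.  None signals that no position reaches
    depth m or that the consensus would not reach past the contig end.
    """
    if len(overlaps) < m:
        return None
    ends = sorted((ov.F_eff for ov in overlaps), reverse=True)
    F_C = ends[m - 1]
    if F_C <= S_len - 1:
        return None
    I_C = min(ov.I for ov in overlaps)
    return I_C, F_C


def _read_order(overlaps: Sequence[OverlapRead]) -> list[int]:
    """Tie-break ranking: ascending I(r), then input order."""
    return sorted(range(len(overlaps)), key=lambda i: (overlaps[i].I, i))


def build_consensus(
    overlaps: Sequence[OverlapRead],
    I_C: int,
    F_C: int,
    T1: float,
    T2: float,
) -> Consensus:
    """Column-wise majority vote over [I_C, F_C].

    Ties pick the character contributed at that column by the earliest read in
    the (ascending I, then input order) ranking.  Columns nobody covers get
    depth 0, pi = 0 and are classed non-represented.
    """
    width = F_C - I_C + 1
    counts = np.zeros((4, width), dtype=np.int32)
    ar = np.arange(width)
    for ov in overlaps:
        lo = ov.I - I_C
        hi = min(ov.F_eff, F_C) - I_C
        if hi < lo:
            continue
        seg = ov.codes[: hi - lo + 1]
        np.add.at(counts, (seg, ar[lo : hi + 1]), 1)
    depth = counts.sum(axis=0)
    top = counts.max(axis=0)
    chars = counts.argmax(axis=0).astype(np.uint8)

    # resolve ambiguous columns with the first-read-encountered rule
    tied = np.nonzero(((counts == top).sum(axis=0) > 1) & (depth > 0))[0]
    if tied.size:
        order = _read_order(overlaps)
        for i in tied:
            j = I_C + int(i)
            for oi in order:
                ov = overlaps[oi]
                if ov.covers(j):
                    c = ov.char_at(j)
                    if counts[c, i] == top[i]:
                        chars[i] = c
                        break

    with np.errstate(invalid="ignore"):
        pi = np.where(depth > 0, top / np.maximum(depth, 1), 0.0)
    klass = np.full(width, HIGH_REPRESENTED, dtype=np.int8)
    klass[pi <= T2] = LOW_REPRESENTED
    klass[pi <= T1] = NON_REPRESENTED
    return Consensus(I_C, F_C, chars, counts, depth, pi, klass)


def filter_and_trim(
    overlaps: Sequence[OverlapRead], consensus: Consensus
) -> list[OverlapRead]:
    """Police the cluster against the consensus.

    A read is dropped if it mismatches the consensus character at any
    low-represented column it covers; surviving reads are cut just before
    their first non-represented column, regardless of whether they match
    there.  Reads trimmed to nothing are dropped.  Columns beyond F_C carry no
    class and impose no constraint.
    """
    I_C, F_C = consensus.I_C, consensus.F_C
    survivors: list[OverlapRead] = []
    for ov in overlaps:
        lo = ov.I - I_C
        hi = min(ov.F_eff, F_C) - I_C
        if hi < lo:
            survivors.append(ov)
            continue
        seg = ov.codes[: hi - lo + 1]
        klass = consensus.klass[lo : hi + 1]
        low = klass == LOW_REPRESENTED
        if np.any(seg[low] != consensus.chars[lo : hi + 1][low]):
            continue  # mismatch at a low-represented column: discard
        non = np.nonzero(klass == NON_REPRESENTED)[0]
        if non.size:
            j_not = I_C + lo + int(non[0])
            new_len = j_not - ov.I
            if new_len <= 0:
                continue
            ov.effective_len = new_len
        survivors.append(ov)
    return survivors


def extend_contig(
    contig,
    survivors: Sequence[OverlapRead],
    params: ExtensionParams,
) -> Optional[np.ndarray]:
    """Rebuild the consensus over the survivors and append it to the contig.

    Returns the new contig codes, or None when fewer than m survivors reach
    past the contig end (the caller maps this to REPEAT_FOUND when the
    pre-filter set was viable).
    """
    S = _as_codes(contig)
    bounds = consensus_bounds(survivors, params.m, S.size)
    if bounds is None:
        return None
    I_C, F_C = bounds
    cons = build_consensus(survivors, I_C, F_C, params.T1, params.T2)
    chars = cons.chars
    holes = np.nonzero(cons.depth == 0)[0]
    if holes.size:
        # trimming can leave zero-depth columns between survivor intervals;
        # inside the contig such a column carries no new evidence, so the
        # existing base stands; beyond the contig end nothing can be made up,
        # so the consensus is cut at the first uncovered position
        inside = holes[I_C + holes <= S.size - 1]
        if inside.size:
            chars = chars.copy()
            chars[inside] = S[I_C + inside]
        beyond = holes[I_C + holes > S.size - 1]
        if beyond.size:
            F_C = I_C + int(beyond[0]) - 1
            if F_C <= S.size - 1:
                return None
            chars = chars[: beyond[0]]
    return np.concatenate([S[:I_C], chars])


@dataclass
class StepResult:
    """Full record of one extension step, for inspection and tests."""

    overlaps: list[OverlapRead]
    bounds: Optional[tuple[int, int]]
    consensus: Optional[Consensus]
    survivors: list[OverlapRead]
    new_contig: Optional[np.ndarray]
    halt_label: Optional[str]  # None when the step extended the contig

    @property
    def dropped_ids(self) -> set[tuple[int, bool]]:
        kept = {(ov.read_id, ov.is_rc) for ov in self.survivors}
        return {
            (ov.read_id, ov.is_rc) for ov in self.overlaps
        } - kept

    @property
    def trimmed_ids(self) -> set[tuple[int, bool]]:
        return {
            (ov.read_id, ov.is_rc)
            for ov in self.survivors
            if ov.effective_len < ov.codes.size
        }


def extension_step(
    contig, index: FingerprintIndex, params: ExtensionParams
) -> StepResult:
    """Run steps 1-4 once on the current contig."""
    S = _as_codes(contig)
    overlaps = collect_overlaps(S, index, params)
    bounds = consensus_bounds(overlaps, params.m, S.size)
    if bounds is None:
        return StepResult(overlaps, None, None, [], None, NO_MORE_EXTENSION)
    cons = build_consensus(overlaps, *bounds, params.T1, params.T2)
    survivors = filter_and_trim(overlaps, cons)
    new = extend_contig(S, survivors, params)
    if new is None:
        return StepResult(overlaps, bounds, cons, survivors, None, REPEAT_FOUND)
    return StepResult(overlaps, bounds, cons, survivors, new, None)


def mate_check(contig, mate_oriented, M: int, start: int = 0) -> Optional[int]:
    """First position p >= start where the oriented mate occurs in the contig
    within Hamming distance M, or None.

    The caller keeps ``start`` at the number of positions already checked so
    the scan is on-the-fly and never re-checks old positions.
    """
    S = _as_codes(contig)
    mate = _as_codes(mate_oriented)
    n, k = S.size, mate.size
    if k > n or start > n - k:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(S, k)[start:]
    mism = (windows != mate[np.newaxis, :]).sum(axis=1)
    hits = np.nonzero(mism <= M)[0]
    if hits.size:
        return start + int(hits[0])
    return None


def extend_seed(
    seed,
    mate_oriented,
    index: FingerprintIndex,
    params: ExtensionParams,
    seed_id: str = "seed",
) -> Contig:
    """Extend a seed read until its mate is found or a stop criterion fires.

    ``mate_oriented`` must already be oriented as the mate should appear on
    the contig strand (for a forward-reverse library: the reverse complement
    of the mate as sequenced).
    """
    S = _as_codes(seed).copy()
    mate = _as_codes(mate_oriented)
    steps = 0
    checked = 0
    pos = mate_check(S, mate, params.M, 0)
    while pos is None:
        checked = max(checked, S.size - mate.size + 1) if S.size >= mate.size else 0
        step = extension_step(S, index, params)
        if step.halt_label is not None:
            return Contig(codes_to_seq(S), seed_id, step.halt_label, None, steps)
        S = step.new_contig
        steps += 1
        pos = mate_check(S, mate, params.M, checked)
        if pos is None and params.Lmax is not None and S.size > params.Lmax:
            return Contig(codes_to_seq(S), seed_id, LENGTH_EXCEED, None, steps)
    return Contig(codes_to_seq(S), seed_id, MATE_FOUND, pos, steps)
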