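"""Fingerprint-keyed read index answering "which reads may overlap this suffix".

Every indexed read contributes two entries: one for its original strand,
fingerprinted on the leftmost ``b``-length window (x = 0), and one for its
reverse complement, fingerprinted at x = L - b.  Both windows fall inside the
read's L-prefix, so a query for an overlap of any length l in [L, L + Delta]
can locate them from the contig suffix alone: forward-oriented reads are found
from the contig window starting at y = |S| - l, reverse-complemented ones from
y = |S| - l + L - b.

The residue table is a plain dict from fingerprint residue to the run of
entries sharing it, which keeps query semantics identical to a dense
counter/values array layout at desk-scale memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .fingerprint import (
    FingerprintParams,
    PackedSeq,
    _as_codes,
    fingerprint,
    revcomp_codes,
)


@dataclass
class Read:
    """A read with pairing metadata and status flags."""

    id: int
    seq: PackedSeq
    mate_id: Optional[int] = None
    pair_order: int = 1  # 1 = first in pair, 2 = second
    name: str = ""
    used_as_seed: bool = False
    available: bool = True

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class IndexEntry:
    read_id: int
    is_rc: bool


class FingerprintIndex:
    """Maps a b-mer fingerprint to the (read, orientation) entries bearing it."""

    def __init__(self, params: FingerprintParams, L: int):
        if L < params.b:
            raise ValueError(f"minimum overlap L={L} must be >= window b={params.b}")
        self.params = params
        self.L = L
        self.reads: dict[int, Read] = {}
        self.codes_fwd: dict[int, np.ndarray] = {}
        self.codes_rc: dict[int, np.ndarray] = {}
        self.n_short = 0  # reads excluded because shorter than L
        self._fwd: dict[int, list[int]] = {}
        self._rc: dict[int, list[int]] = {}

    # -- construction -------------------------------------------------------

    def add(self, read: Read) -> bool:
        """Index one read (both orientations); False if too short to index."""
        if len(read) < self.L:
            self.n_short += 1
            return False
        fwd = read.seq.codes
        rc = revcomp_codes(fwd)
        self.reads[read.id] = read
        self.codes_fwd[read.id] = fwd
        self.codes_rc[read.id] = rc
        f_fwd = fingerprint(fwd, 0, self.params)
        f_rc = fingerprint(rc, self.L - self.params.b, self.params)
        self._fwd.setdefault(f_fwd, []).append(read.id)
        self._rc.setdefault(f_rc, []).append(read.id)
        return True

    # -- inspection ---------------------------------------------------------

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def n_entries(self) -> int:
        """Total index entries; always two per indexed read."""
        return sum(len(v) for v in self._fwd.values()) + sum(
            len(v) for v in self._rc.values()
        )

    def entries_for(self, residue: int) -> list[IndexEntry]:
        """The run of entries stored under one fingerprint residue."""
        out = [IndexEntry(rid, False) for rid in self._fwd.get(residue, ())]
        out += [IndexEntry(rid, True) for rid in self._rc.get(residue, ())]
        return out

    def residues(self) -> set[int]:
        return set(self._fwd) | set(self._rc)

    def oriented_codes(self, read_id: int, is_rc: bool) -> np.ndarray:
        return self.codes_rc[read_id] if is_rc else self.codes_fwd[read_id]


def build_index(
    reads: Iterable[Read], params: FingerprintParams, L: int
) -> FingerprintIndex:
    """Index reads on both strands; reads shorter than L are excluded and counted."""
    index = FingerprintIndex(params, L)
    for read in reads:
        index.add(read)
    return index


def query_candidates(
    index: FingerprintIndex, contig, l: int, delta: Optional[int] = None
) -> set[tuple[int, bool]]:
    """Reads that may overlap the contig's l-suffix, as (read_id, is_rc) pairs.

    The result is a superset of every read whose oriented l-prefix matches the
    contig's l-suffix exactly on the orientation's b-window; character-level
    verification happens downstream.
    """
    L, b = index.L, index.params.b
    if delta is not None and not (L <= l <= L + delta):
        raise ValueError(f"overlap length {l} outside [{L}, {L + delta}]")
    if l < L:
        raise ValueError(f"overlap length {l} below minimum overlap {L}")
    S = _as_codes(contig)
    if S.size < l:
        return set()
    out: set[tuple[int, bool]] = set()
    f_fwd = fingerprint(S, S.size - l, index.params)
    for rid in index._fwd.get(f_fwd, ()):
        out.add((rid, False))
    y_rc = S.size - l + L - b
    if y_rc >= 0:
        f_rc = fingerprint(S, y_rc, index.params)
        for rid in index._rc.get(f_rc, ()):
            out.add((rid, True))
    return out
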