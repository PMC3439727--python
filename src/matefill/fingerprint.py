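"""2-bit DNA packing and the Karp-Rabin-style fingerprint used for overlap lookup.

A DNA window of length ``b`` is read as a base-4 number (A=00, C=01, G=10,
T=11, most significant digit first) and reduced modulo a Mersenne number
``q = 2**w - 1``.  Equal fingerprints are a *necessary* condition for the two
windows to be character-identical, so the fingerprint shortlists overlap
candidates that a character-level Hamming check then verifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CHAR = np.frombuffer(b"ACGT", dtype=np.uint8)

# full byte -> 4 base codes lookup, for unpacking
_ENC = np.full(256, 255, dtype=np.uint8)
for _c, _v in _CODE.items():
    _ENC[ord(_c)] = _v
    _ENC[ord(_c.lower())] = _v


class NonACGTError(ValueError):
    """Sequence contains a character outside {A, C, G, T}.

    Such reads cannot be packed and must be filtered upstream.
    """


def seq_to_codes(s: str) -> np.ndarray:
    """Map a DNA string to an array of 2-bit codes (A=0, C=1, G=2, T=3)."""
    raw = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    codes = _ENC[raw]
    if codes.size and codes.max() > 3:
        bad = chr(int(raw[int(np.argmax(codes > 3))]))
        raise NonACGTError(f"non-ACGT character {bad!r} in sequence")
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    """Inverse of :func:`seq_to_codes`."""
    return _CHAR[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space (complement of code c is 3 - c)."""
    return (3 - np.asarray(codes, dtype=np.uint8))[::-1]


class PackedSeq:
    """A DNA sequence stored 2 bits per base (4 bases per byte, MSB first)."""

    __slots__ = ("_data", "length")

    def __init__(self, data: bytes, length: int):
        self._data = data
        self.length = length

    @classmethod
    def from_codes(cls, codes: np.ndarray) -> "PackedSeq":
        codes = np.asarray(codes, dtype=np.uint8)
        n = codes.size
        pad = (-n) % 4
        if pad:
            codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
        quads = codes.reshape(-1, 4)
        packed = (
            (quads[:, 0] << 6) | (quads[:, 1] << 4) | (quads[:, 2] << 2) | quads[:, 3]
        ).astype(np.uint8)
        return cls(packed.tobytes(), n)

    @property
    def codes(self) -> np.ndarray:
        packed = np.frombuffer(self._data, dtype=np.uint8)
        out = np.empty(packed.size * 4, dtype=np.uint8)
        out[0::4] = packed >> 6
        out[1::4] = (packed >> 4) & 3
        out[2::4] = (packed >> 2) & 3
        out[3::4] = packed & 3
        return out[: self.length]

    @property
    def bits(self) -> str:
        """The packed bit string (2 bits per base, for inspection)."""
        return "".join(format(c, "02b") for c in self.codes)

    def reverse_complement(self) -> "PackedSeq":
        return PackedSeq.from_codes(revcomp_codes(self.codes))

    def __len__(self) -> int:
        return self.length

    def __str__(self) -> str:
        return codes_to_seq(self.codes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PackedSeq):
            return NotImplemented
        return self.length == other.length and self._data == other._data

    def __hash__(self) -> int:
        return hash((self._data, self.length))

    def __repr__(self) -> str:
        s = str(self)
        if len(s) > 40:
            s = s[:40] + "..."
        return f"PackedSeq('{s}', length={self.length})"


def encode_seq(s: str) -> PackedSeq:
    """Pack a DNA string; raises :class:`NonACGTError` on other characters."""
    return PackedSeq.from_codes(seq_to_codes(s))


def revcomp(s: PackedSeq) -> PackedSeq:
    return s.reverse_complement()


@dataclass(frozen=True)
class FingerprintParams:
    """Parameters of the Hamming-aware hash.

    b
        window length in bases on which fingerprints are computed.
    w
        modulus exponent; the modulus is the Mersenne number ``q = 2**w - 1``
        (2**30 - 1 by default; primality is not required).
    k
        maximum Hamming distance inside the window for which equality of
        fingerprints is still declared a candidate match.  Only ``k = 0``
        (exact window match, witness set {0}) is implemented.
    """

    b: int = 20
    w: int = 30
    k: int = 0

    def __post_init__(self):
        if self.b < 1:
            raise ValueError("window length b must be positive")
        if self.w < 2:
            raise ValueError("modulus exponent w must be >= 2")
        if self.k != 0:
            raise NotImplementedError("only k = 0 (exact window) is supported")

    @property
    def q(self) -> int:
        return (1 << self.w) - 1

    @property
    def witnesses(self) -> tuple[int, ...]:
        """Residues of fingerprint differences accepted as candidate matches."""
        return (0,)


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, PackedSeq):
        return seq.codes
    if isinstance(seq, str):
        return seq_to_codes(seq)
    return np.asarray(seq, dtype=np.uint8)


def fingerprint(seq, p: int, params: FingerprintParams) -> int:
    """Fingerprint of the length-``b`` window of ``seq`` starting at ``p``.

    Returns ``(base-4 value of seq[p : p + b]) mod q`` with the most
    significant digit first.
    """
    codes = _as_codes(seq)
    b, q = params.b, params.q
    if p < 0 or p + b > codes.size:
        raise ValueError(
            f"window [{p}, {p + b}) out of range for sequence of length {codes.size}"
        )
    v = 0
    for d in codes[p : p + b]:
        v = ((v << 2) | int(d)) % q
    return v


def candidate_match(f1: int, f2: int, params: FingerprintParams) -> bool:
    """True iff (f1 - f2) mod q is a witness residue (with k=0: f1 == f2)."""
    return (f1 - f2) % params.q in params.witnesses
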