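"""Synthetic genomes and paired-read libraries with truth coordinates.

Emulates a fragment-library sequencing experiment: inserts are sampled
uniformly over the genome with Gaussian length, each insert yields a
forward-reverse ("innie") read pair, and sequencing noise is independent
per-base substitution at a uniform rate.  Every pair is recorded in a truth
table (strand, insert coordinates, seed locus, error positions) so contigs
can later be validated at the exact locus they are supposed to reconstruct.

Deliberately not modelled: position-dependent Illumina error profiles,
indel sequencing errors, chimeric pairs, and GC-coverage bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fingerprint import codes_to_seq, revcomp_codes, seq_to_codes

TRUTH_COLUMNS = [
    "pair_id",
    "strand",
    "insert_start",
    "insert_len",
    "read_len",
    "seed_start",
    "errors1",
    "errors2",
]


@dataclass
class SimulatedGenome:
    """A random genome, possibly with planted exact repeat copies."""

    seq: str
    repeats: list[list[int]] = field(default_factory=list)
    # repeats[i] is the list of start positions of the i-th planted unit

    def __len__(self) -> int:
        return len(self.seq)


def make_genome(
    length: int,
    gc: float = 0.5,
    seed: int | None = None,
    repeat_spec: list[tuple[int, int]] | None = None,
) -> SimulatedGenome:
    """Random genome of the given length and GC fraction.

    ``repeat_spec`` is a list of (unit_len, copies); each unit is drawn once
    and pasted, character-identical, at recorded non-overlapping positions to
    exercise repeat detection downstream.
    """
    if length <= 0:
        raise ValueError("genome length must be positive")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    repeats: list[list[int]] = []
    if repeat_spec:
        taken: list[tuple[int, int]] = []
        for unit_len, copies in repeat_spec:
            if unit_len * copies > length:
                raise ValueError("repeat copies do not fit in the genome")
            unit = rng.choice(4, size=unit_len, p=p).astype(np.uint8)
            starts: list[int] = []
            guard = 0
            while len(starts) < copies:
                s = int(rng.integers(0, length - unit_len + 1))
                if all(
                    s + unit_len <= t0 or s >= t0 + tl for t0, tl in taken
                ):
                    codes[s : s + unit_len] = unit
                    taken.append((s, unit_len))
                    starts.append(s)
                guard += 1
                if guard > 10000:
                    raise RuntimeError("could not place repeat copies")
            repeats.append(sorted(starts))
    return SimulatedGenome(codes_to_seq(codes), repeats)


@dataclass
class PairedLibrary:
    """Paired reads plus the truth table describing how they were sampled."""

    reads1: list[str]
    reads2: list[str]
    truth: pd.DataFrame
    read_len: int
    insert_mean: float
    insert_sd: float
    orientation: str = "fr"

    def __len__(self) -> int:
        return len(self.reads1)


def _apply_errors(codes: np.ndarray, rate: float, rng) -> tuple[np.ndarray, list[int]]:
    if rate <= 0:
        return codes, []
    hit = np.nonzero(rng.random(codes.size) < rate)[0]
    if hit.size == 0:
        return codes, []
    out = codes.copy()
    out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out, [int(i) for i in hit]


def make_pairs(
    genome,
    coverage: float,
    read_len: int,
    insert_mean: float,
    insert_sd: float,
    err_rate: float = 0.0,
    orientation: str = "fr",
    seed: int | None = None,
) -> PairedLibrary:
    """Sample ceil(coverage * |G| / (2 * read_len)) read pairs from a genome.

    Insert lengths are Gaussian, truncated to [2 * read_len, |G|]; insert
    starts are uniform; each insert is read from a uniformly random strand.
    In fr orientation read 1 is the insert's 5' end on the sampled strand and
    read 2 the reverse complement of its 3' end.
    """
    if isinstance(genome, SimulatedGenome):
        genome = genome.seq
    G = len(genome)
    if insert_mean < read_len:
        raise ValueError("mean insert size must be at least the read length")
    if not 0 <= err_rate < 1:
        raise ValueError("error rate must be in [0, 1)")
    if 2 * read_len > G:
        raise ValueError("genome shorter than the minimum insert (2 * read_len)")
    if orientation not in ("fr", "ff", "rf"):
        raise ValueError(f"unknown orientation {orientation!r}")
    # separate streams so the error process never perturbs the sampling
    # geometry: the same seed yields the same inserts at any error rate
    ss_geom, ss_err = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(ss_geom)
    rng_err = np.random.default_rng(ss_err)
    gcodes = seq_to_codes(genome)
    n_pairs = math.ceil(coverage * G / (2 * read_len))
    reads1, reads2, rows = [], [], []
    for i in range(n_pairs):
        ins = int(round(rng.normal(insert_mean, insert_sd)))
        ins = min(max(ins, 2 * read_len), G)
        start = int(rng.integers(0, G - ins + 1))
        minus = bool(rng.integers(0, 2))
        frag = gcodes[start : start + ins]
        if minus:
            frag = revcomp_codes(frag)
        r1, r2 = frag[:read_len].copy(), frag[ins - read_len :]
        if orientation == "fr":
            r2 = revcomp_codes(r2)
        elif orientation == "rf":
            r1 = revcomp_codes(r1)
        r1, e1 = _apply_errors(r1, err_rate, rng_err)
        r2, e2 = _apply_errors(np.ascontiguousarray(r2), err_rate, rng_err)
        reads1.append(codes_to_seq(r1))
        reads2.append(codes_to_seq(r2))
        strand = "-" if minus else "+"
        seed_start = start if not minus else start + ins - read_len
        rows.append(
            {
                "pair_id": f"p{i}",
                "strand": strand,
                "insert_start": start,
                "insert_len": ins,
                "read_len": read_len,
                "seed_start": seed_start,
                "errors1": ",".join(map(str, e1)),
                "errors2": ",".join(map(str, e2)),
            }
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return PairedLibrary(
        reads1, reads2, truth, read_len, insert_mean, insert_sd, orientation
    )


# -- plain-text output ------------------------------------------------------


def write_genome_fasta(genome, path, name: str = "genome") -> None:
    seq = genome.seq if isinstance(genome, SimulatedGenome) else genome
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def write_library(lib: PairedLibrary, prefix: str) -> tuple[str, str, str]:
    """Write FASTQ pairs (constant quality 'I') and the truth TSV."""
    paths = (f"{prefix}_1.fastq", f"{prefix}_2.fastq", f"{prefix}_truth.tsv")
    for path, reads, mate in ((paths[0], lib.reads1, 1), (paths[1], lib.reads2, 2)):
        with open(path, "w") as fh:
            for i, seq in enumerate(reads):
                fh.write(f"@p{i}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")
    lib.truth.to_csv(paths[2], sep="\t", index=False)
    return paths


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"errors1": str, "errors2": str}, keep_default_na=False
    )
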