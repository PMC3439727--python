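"""Exact-locus validation of contigs and the trusted/aligned confusion table.

A contig grown from a seed whose genomic locus is known is aligned (local
Smith-Waterman, match +1, mismatch -1, indel -2, linear gaps) against the
genome window of length |S| + g anchored at the seed locus, where
g = ceil(3 |S| / 200) is the indel budget.  The contig is "correctly aligned"
when best score / |S| >= 0.95 (e.g. up to 5 mismatches, or 3 indels, per
200 bp).  Crossing the trusted label (mate found) with alignment gives the
TP/FP/FN/TN classification, and aligned trusted contigs yield the genome
coverage profile.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import biotite.sequence as _bseq
import biotite.sequence.align as _balign

from .extension import MATE_FOUND
from .fingerprint import codes_to_seq, revcomp_codes, seq_to_codes

DEFAULT_MIN_RATIO = 0.95


def _matrix(match: int, mismatch: int) -> _balign.SubstitutionMatrix:
    alph = _bseq.NucleotideSequence.alphabet_unamb
    scores = np.full((4, 4), mismatch, dtype=np.int32)
    np.fill_diagonal(scores, match)
    return _balign.SubstitutionMatrix(alph, alph, scores)


_DEFAULT_MATRIX = _matrix(1, -1)


def smith_waterman(a: str, b: str, match: int = 1, mismatch: int = -1, indel: int = -2) -> int:
    """Best local alignment score under linear (non-affine) gap costs."""
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    mat = _DEFAULT_MATRIX if (match, mismatch) == (1, -1) else _matrix(match, mismatch)
    aln = _balign.align_optimal(
        _bseq.NucleotideSequence(a),
        _bseq.NucleotideSequence(b),
        mat,
        gap_penalty=indel,
        local=True,
        max_number=1,
    )
    return int(aln[0].score)


def indel_budget(contig_len: int) -> int:
    """Maximum indels g = ceil(3 |S| / 200) tolerated by the 0.95 score ratio."""
    if contig_len <= 0:
        raise ValueError("contig length must be positive")
    return math.ceil(3 * contig_len / 200)


def validate_contig(
    contig: str,
    genome: str,
    seed_start: int,
    strand: str = "+",
    read_len: Optional[int] = None,
    min_ratio: float = DEFAULT_MIN_RATIO,
) -> tuple[bool, int, float]:
    """Align a contig at the exact locus its seed came from.

    For a forward-strand seed the window is G[x, x + |S| + g - 1] with x the
    seed's start.  A reverse-strand seed grew leftwards on the forward
    strand, so the contig is reverse-complemented and the window is anchored
    at the seed's 3' coordinate (seed_start + read_len) instead; ``read_len``
    is required in that case.  Windows are clamped at the genome ends, never
    wrapped.  Returns (aligned, score, ratio).
    """
    n = len(contig)
    if n == 0:
        return False, 0, 0.0
    g = indel_budget(n)
    if strand == "+":
        if not 0 <= seed_start < len(genome):
            return False, 0, 0.0
        window = genome[seed_start : seed_start + n + g]
    elif strand == "-":
        if read_len is None:
            raise ValueError("read_len is required for reverse-strand seeds")
        end = seed_start + read_len
        if not 0 < end <= len(genome):
            return False, 0, 0.0
        contig = codes_to_seq(revcomp_codes(seq_to_codes(contig)))
        window = genome[max(0, end - n - g) : end]
    else:
        raise ValueError(f"unknown strand {strand!r}")
    if not window:
        return False, 0, 0.0
    score = smith_waterman(contig, window)
    ratio = score / n
    return ratio >= min_ratio, score, ratio


def contig_interval(
    strand: str,
    seed_start: int,
    read_len: int,
    contig_len: int,
    genome_len: int,
) -> tuple[int, int]:
    """Half-open genome interval (forward strand) that the contig claims."""
    if strand == "+":
        lo, hi = seed_start, seed_start + contig_len
    else:
        end = seed_start + read_len
        lo, hi = end - contig_len, end
    return max(0, lo), min(genome_len, hi)


@dataclass
class Verdict:
    """Validation outcome of one contig."""

    contig_id: str
    trusted: bool  # label == MATE_FOUND
    aligned: bool
    score: int
    ratio: float
    klass: str  # TP / FP / FN / TN


def classify(trusted: bool, aligned: bool) -> str:
    if trusted:
        return "TP" if aligned else "FP"
    return "FN" if aligned else "TN"


@dataclass
class EvalSummary:
    counts: dict[str, int]
    rates: dict[str, float]
    covered_fraction: float
    uncovered_fraction: float

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for lo, hi in sorted(intervals):
        if hi <= lo:
            continue
        if last_end is None or lo > last_end:
            total += hi - lo
            last_end = hi
        elif hi > last_end:
            total += hi - last_end
            last_end = hi
    return total


def confusion_and_coverage(
    verdicts: Iterable[Verdict],
    intervals: Iterable[tuple[int, int]],
    genome_len: int,
) -> EvalSummary:
    """Tally TP/FP/FN/TN and the genome fraction covered by aligned trusted
    contigs (``intervals`` are their claimed forward-strand loci)."""
    counts = {"TP": 0, "FP": 0, "FN": 0, "TN": 0}
    for v in verdicts:
        counts[v.klass] += 1
    total = sum(counts.values())
    rates = {k: (c / total if total else 0.0) for k, c in counts.items()}
    clipped = [
        (max(0, lo), min(genome_len, hi)) for lo, hi in intervals
    ]
    covered = _union_length(clipped) / genome_len if genome_len else 0.0
    return EvalSummary(counts, rates, covered, 1.0 - covered)


_HEADER_RE = re.compile(
    r"seed=(?P<seed>\S+)\s+label=(?P<label>\S+)\s+len=(?P<len>\d+)"
    r"\s+steps=(?P<steps>\d+)\s+mate_pos=(?P<mate>\S+)"
)


def evaluate_run(
    contigs_fasta,
    genome: str,
    truth,
    min_ratio: float = DEFAULT_MIN_RATIO,
    out_verdicts=None,
    out_summary=None,
) -> tuple[list[Verdict], EvalSummary]:
    """Validate every contig of a run against the truth table.

    ``truth`` is the simulator's truth DataFrame (or a path to the TSV);
    contig headers carry the seed id ``p<i>/1`` linking back to pair ``p<i>``.
    Optionally writes a per-contig verdict TSV and a summary TSV.
    """
    import pandas as pd
    from Bio import SeqIO

    from .simulate import read_truth

    if not isinstance(truth, pd.DataFrame):
        truth = read_truth(truth)
    tbl = truth.set_index("pair_id")
    verdicts: list[Verdict] = []
    intervals: list[tuple[int, int]] = []
    for rec in SeqIO.parse(str(contigs_fasta), "fasta"):
        m = _HEADER_RE.search(rec.description)
        if not m:
            raise ValueError(f"unparseable contig header: {rec.description!r}")
        seed_id = m.group("seed")
        pair_id = seed_id.rsplit("/", 1)[0]
        row = tbl.loc[pair_id]
        trusted = m.group("label") == MATE_FOUND
        aligned, score, ratio = validate_contig(
            str(rec.seq),
            genome,
            int(row["seed_start"]),
            str(row["strand"]),
            read_len=int(row["read_len"]),
            min_ratio=min_ratio,
        )
        verdicts.append(
            Verdict(seed_id, trusted, aligned, score, ratio, classify(trusted, aligned))
        )
        if trusted and aligned:
            intervals.append(
                contig_interval(
                    str(row["strand"]),
                    int(row["seed_start"]),
                    int(row["read_len"]),
                    len(rec.seq),
                    len(genome),
                )
            )
    summary = confusion_and_coverage(verdicts, intervals, len(genome))
    if out_verdicts:
        pd.DataFrame([v.__dict__ for v in verdicts]).to_csv(
            out_verdicts, sep="\t", index=False
        )
    if out_summary:
        rows = [{"metric": k, "value": v} for k, v in summary.counts.items()]
        rows += [
            {"metric": f"{k}_rate", "value": v} for k, v in summary.rates.items()
        ]
        rows.append({"metric": "covered_fraction", "value": summary.covered_fraction})
        rows.append(
            {"metric": "uncovered_fraction", "value": summary.uncovered_fraction}
        )
        pd.DataFrame(rows).to_csv(out_summary, sep="\t", index=False)
    return verdicts, summary
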