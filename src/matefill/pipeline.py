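"""End-to-end driver: load paired libraries, build the index, iterate seeds,
and write labelled contigs plus run statistics.

Each seed pair contributes one contig: read 1 seeds the extension and read 2
is the mate whose rediscovery certifies the contig.  With a separate seed
library (the short-jump + fragment mode) the index is built over the union of
all libraries while seeds are drawn from the seed library only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import SeqIO

from .extension import (
    Contig,
    ExtensionParams,
    IN_PROGRESS,
    LENGTH_EXCEED,
    MATE_FOUND,
    NO_MORE_EXTENSION,
    REPEAT_FOUND,
    extend_seed,
)
from .fingerprint import (
    FingerprintParams,
    NonACGTError,
    encode_seq,
    revcomp_codes,
    seq_to_codes,
)
from .read_index import FingerprintIndex, Read, build_index

LABELS = (MATE_FOUND, NO_MORE_EXTENSION, REPEAT_FOUND, LENGTH_EXCEED)

_HIST_BIN = 100


@dataclass
class RunConfig:
    """Configuration of one run; defaults mirror the reference experiment
    setup (L=50, Delta=40, b=20, T1=0.6, T2=0.9, m=2, M=10)."""

    seed_reads1: str = ""
    seed_reads2: str = ""
    extension_pairs: list[tuple[str, str]] = field(default_factory=list)
    orientation: str = "fr"
    insert_mean: float = 600.0
    insert_sd: float = 200.0
    read_len: int = 100
    L: int = 50
    Delta: int = 40
    b: int = 20
    w: int = 30
    T1: float = 0.6
    T2: float = 0.9
    m: int = 2
    M: int = 10
    Lmax: Optional[int] = None
    seed_limit: Optional[int] = None
    seed_both: bool = False
    genome_length: Optional[int] = None
    out_fasta: str = "contigs.fasta"
    out_stats: str = "contigs.stats.tsv"

    @property
    def effective_Lmax(self) -> int:
        """Lmax defaults to the seed library's mean insert plus 3 sigma."""
        if self.Lmax is not None:
            return self.Lmax
        return int(round(self.insert_mean + 3 * self.insert_sd))

    def extension_params(self) -> ExtensionParams:
        return ExtensionParams(
            L=self.L,
            Delta=self.Delta,
            m=self.m,
            T1=self.T1,
            T2=self.T2,
            M=self.M,
            avg_read_len=self.read_len,
            Lmax=self.effective_Lmax,
        )

    def fingerprint_params(self) -> FingerprintParams:
        return FingerprintParams(b=self.b, w=self.w)


@dataclass
class RunStats:
    """Per-run bookkeeping mirrored into the stats TSV."""

    seeds_processed: int = 0
    seeds_skipped: int = 0
    reads_indexed: int = 0
    reads_filtered: int = 0  # non-ACGT, excluded upstream of the index
    reads_short: int = 0  # shorter than L, excluded by the index
    label_counts: dict[str, int] = field(default_factory=dict)
    label_length_hist: dict[str, dict[int, int]] = field(default_factory=dict)
    label_length_sum: dict[str, int] = field(default_factory=dict)
    output_coverage: Optional[float] = None

    def record(self, contig: Contig) -> None:
        lab = contig.label
        self.label_counts[lab] = self.label_counts.get(lab, 0) + 1
        self.label_length_sum[lab] = self.label_length_sum.get(lab, 0) + len(contig)
        hist = self.label_length_hist.setdefault(lab, {})
        b = (len(contig) // _HIST_BIN) * _HIST_BIN
        hist[b] = hist.get(b, 0) + 1


def _sniff_format(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".fq", ".fastq"):
        return "fastq"
    if ext in (".fa", ".fasta", ".fna"):
        return "fasta"
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fastq" if line[0] == "@" else "fasta"
    return "fasta"


def load_pairs(path1, path2) -> list[tuple[str, str, str]]:
    """Read two paired files (record i in file 1 pairs with record i in
    file 2); returns (name, read1, read2) triples."""
    recs1 = list(SeqIO.parse(str(path1), _sniff_format(path1)))
    recs2 = list(SeqIO.parse(str(path2), _sniff_format(path2)))
    if len(recs1) != len(recs2):
        raise ValueError(
            f"paired files have unequal record counts: "
            f"{len(recs1)} vs {len(recs2)}"
        )
    out = []
    for r1, r2 in zip(recs1, recs2):
        name = r1.id.rsplit("/", 1)[0]
        out.append((name, str(r1.seq).upper(), str(r2.seq).upper()))
    return out


def _build_run_index(
    pair_sets: Sequence[Sequence[tuple[str, str, str]]],
    fparams: FingerprintParams,
    L: int,
    stats: RunStats,
) -> FingerprintIndex:
    index = FingerprintIndex(fparams, L)
    next_id = 0
    for pairs in pair_sets:
        for name, s1, s2 in pairs:
            id1, id2 = next_id, next_id + 1
            next_id += 2
            for rid, mid, order, s in ((id1, id2, 1, s1), (id2, id1, 2, s2)):
                try:
                    seq = encode_seq(s)
                except NonACGTError:
                    stats.reads_filtered += 1
                    continue
                index.add(Read(rid, seq, mate_id=mid, pair_order=order, name=name))
    stats.reads_short = index.n_short
    stats.reads_indexed = index.n_reads
    return index


def _oriented_seed_and_mate(seed: str, mate: str, orientation: str):
    s = seq_to_codes(seed)
    m = seq_to_codes(mate)
    if orientation == "fr":
        return s, revcomp_codes(m)
    if orientation == "ff":
        return s, m
    if orientation == "rf":  # outie geometry reduces to fr after flipping both
        return revcomp_codes(s), m
    raise ValueError(f"unknown library orientation {orientation!r}")


def assemble_pairs(
    seed_pairs: Sequence[tuple[str, str, str]],
    extension_pair_sets: Optional[Sequence[Sequence[tuple[str, str, str]]]] = None,
    *,
    params: ExtensionParams,
    fparams: FingerprintParams,
    orientation: str = "fr",
    seed_limit: Optional[int] = None,
    seed_both: bool = False,
    genome_length: Optional[int] = None,
) -> tuple[list[Contig], RunStats]:
    """Run the full seed loop in memory.

    ``seed_pairs`` are (name, read1, read2) triples; ``extension_pair_sets``
    lists further libraries to index alongside the seed library (the index is
    always the union).  Returns one labelled contig per processed seed.
    """
    stats = RunStats()
    pair_sets = [seed_pairs] + list(extension_pair_sets or [])
    index = _build_run_index(pair_sets, fparams, params.L, stats)
    contigs: list[Contig] = []
    todo = seed_pairs if seed_limit is None else seed_pairs[:seed_limit]
    for i, (name, s1, s2) in enumerate(todo):
        roles = [(f"{name}/1", s1, s2)]
        if seed_both:
            roles.append((f"{name}/2", s2, s1))
        for seed_id, seed, mate in roles:
            try:
                s_codes, m_codes = _oriented_seed_and_mate(seed, mate, orientation)
            except NonACGTError:
                stats.seeds_skipped += 1
                continue
            contig = extend_seed(s_codes, m_codes, index, params, seed_id=seed_id)
            stats.seeds_processed += 1
            stats.record(contig)
            contigs.append(contig)
    if genome_length:
        trusted = stats.label_length_sum.get(MATE_FOUND, 0)
        stats.output_coverage = trusted / genome_length
    return contigs, stats


def write_contigs(contigs: Sequence[Contig], path) -> None:
    """FASTA output; headers carry seed id, label, length, steps, mate position."""
    with open(path, "w") as fh:
        for c in contigs:
            mate = c.mate_pos if c.mate_pos is not None else "NA"
            fh.write(
                f">seed={c.seed_id} label={c.label} len={len(c)} "
                f"steps={c.steps} mate_pos={mate}\n"
            )
            for i in range(0, len(c.seq), 70):
                fh.write(c.seq[i : i + 70] + "\n")


def write_stats(stats: RunStats, path) -> None:
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for k in (
            "seeds_processed",
            "seeds_skipped",
            "reads_indexed",
            "reads_filtered",
            "reads_short",
        ):
            fh.write(f"{k}\t{getattr(stats, k)}\n")
        for lab in LABELS:
            n = stats.label_counts.get(lab, 0)
            fh.write(f"count:{lab}\t{n}\n")
            if n:
                fh.write(
                    f"mean_len:{lab}\t{stats.label_length_sum[lab] / n:.2f}\n"
                )
                hist = stats.label_length_hist.get(lab, {})
                body = ",".join(f"{b}-{b + _HIST_BIN - 1}:{c}" for b, c in sorted(hist.items()))
                fh.write(f"len_hist:{lab}\t{body}\n")
        if stats.output_coverage is not None:
            fh.write(f"output_coverage\t{stats.output_coverage:.4f}\n")


@dataclass
class RunResult:
    contigs_path: str
    stats_path: str
    contigs: list[Contig]
    stats: RunStats


def run(config: RunConfig) -> RunResult:
    """File-to-file pipeline: load libraries, assemble, write FASTA + TSV."""
    seed_pairs = load_pairs(config.seed_reads1, config.seed_reads2)
    seen = {(os.path.abspath(config.seed_reads1), os.path.abspath(config.seed_reads2))}
    ext_sets = []
    for p1, p2 in config.extension_pairs:
        key = (os.path.abspath(p1), os.path.abspath(p2))
        if key in seen:
            continue  # the seed library is already part of the index
        seen.add(key)
        ext_sets.append(load_pairs(p1, p2))
    contigs, stats = assemble_pairs(
        seed_pairs,
        ext_sets,
        params=config.extension_params(),
        fparams=config.fingerprint_params(),
        orientation=config.orientation,
        seed_limit=config.seed_limit,
        seed_both=config.seed_both,
        genome_length=config.genome_length,
    )
    write_contigs(contigs, config.out_fasta)
    write_stats(stats, config.out_stats)
    return RunResult(config.out_fasta, config.out_stats, contigs, stats)


def dual_library_mode(config: RunConfig) -> RunResult:
    """Short-jump + fragment mode: index the union of all configured
    libraries, seed from the seed library only (Lmax still reflects the seed
    library's insert size).  Degenerates to :func:`run` when the extension
    library equals the seed library."""
    if not config.extension_pairs:
        raise ValueError("dual-library mode needs extension_pairs configured")
    return run(config)
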