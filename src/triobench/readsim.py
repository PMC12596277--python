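"""Illumina-like paired-end read simulation from diploid genomes.

Reads are drawn uniformly over each haplotype, given i.i.d. uniform base
substitution errors at a flat Phred quality, and emitted *pre-aligned at
their truth coordinates* with CIGARs derived from the haplotype's variant
set — no aligner runs. Pileup-style allelic counting (ref / alt / other
read classes per site) feeds the caller and the VAF analyses.
"""

from __future__ import annotations

import math
import os
import tempfile
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pysam

from ._seeding import stage_rng
from .types import HET, HOM_ALT, AllelicCounts, SimulationConfig, TrioSite, gt_alleles

__all__ = [
    "Haplotype",
    "build_haplotype",
    "build_diploid_genome",
    "ReadPair",
    "simulate_reads",
    "emit_bam",
    "emit_fastq",
    "collect_allelic_counts",
    "mean_depth",
    "base_counts",
]

_REVCOMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


@dataclass
class _Segment:
    hap_start: int
    ref_start: int
    hap_len: int
    ref_len: int
    op: str  # M | I | D


@dataclass
class Haplotype:
    """One haplotype sequence plus its alignment map back to the reference."""

    chrom: str
    seq: str
    segments: list[_Segment]
    _hap_starts: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self):
        self._hap_starts = [s.hap_start for s in self.segments]

    def __len__(self) -> int:
        return len(self.seq)

    def project(self, start: int, end: int) -> tuple[int, list[tuple[str, int]]]:
        """Map hap interval [start, end) to (reference start, CIGAR ops).

        Leading/trailing insertions become soft clips; deletions at the read
        edges are dropped. Requires the interval to touch at least one
        matched base (guaranteed for reads longer than any insertion).
        """
        segs = self.segments
        if len(segs) == 1:  # pure-match fast path
            return segs[0].ref_start + start, [("M", end - start)]
        j = bisect_right(self._hap_starts, start) - 1
        # step back over zero-length (D) segments sharing this hap_start
        while segs[j].hap_len == 0 and j + 1 < len(segs) and segs[j + 1].hap_start <= start:
            j += 1
        pos = start
        cigar: list[tuple[str, int]] = []
        ref_start_out = -1
        while pos < end and j < len(segs):
            seg = segs[j]
            if seg.hap_len == 0:  # deletion: internal only
                if cigar:
                    cigar.append(("D", seg.ref_len))
                j += 1
                continue
            if seg.hap_start > pos:
                raise AssertionError("segment walk out of register")
            take = min(end, seg.hap_start + seg.hap_len) - pos
            off = pos - seg.hap_start
            if seg.op == "M":
                if ref_start_out < 0:
                    ref_start_out = seg.ref_start + off
                cigar.append(("M", take))
            else:  # insertion relative to the reference
                cigar.append(("I", take))
            pos += take
            j += 1
        while cigar and cigar[-1][0] == "D":
            cigar.pop()
        if cigar and cigar[0][0] == "I":
            cigar[0] = ("S", cigar[0][1])
        if cigar and cigar[-1][0] == "I":
            cigar[-1] = ("S", cigar[-1][1])
        if ref_start_out < 0:
            raise ValueError("read interval maps to no reference-matched base")
        return ref_start_out, cigar


def build_haplotype(ref_seq: str, variants: list[tuple[int, str, str]], chrom: str = "chr1") -> Haplotype:
    """Apply (pos, ref, alt) variants carried by this haplotype to the reference.

    SNVs substitute in place; indels are left-anchored and must not overlap.
    """
    snv_seq = bytearray(ref_seq, "ascii")
    indels = []
    for pos, ref, alt in sorted(variants):
        r0 = pos - 1
        if ref_seq[r0 : r0 + len(ref)] != ref:
            raise ValueError(f"ref allele mismatch at {chrom}:{pos}: expected {ref!r}")
        if len(ref) == 1 and len(alt) == 1:
            snv_seq[r0] = ord(alt)
        else:
            indels.append((pos, ref, alt))

    parts: list[str] = []
    segs: list[_Segment] = []
    cur_ref = 0
    cur_hap = 0
    for pos, ref, alt in indels:
        anchor_end = pos  # ref index just past the anchor base (0-based, exclusive)
        if anchor_end <= cur_ref:
            raise ValueError(f"overlapping indels near {chrom}:{pos}")
        m_len = anchor_end - cur_ref
        parts.append(snv_seq[cur_ref:anchor_end].decode("ascii"))
        segs.append(_Segment(cur_hap, cur_ref, m_len, m_len, "M"))
        cur_hap += m_len
        cur_ref = anchor_end
        if len(alt) > len(ref):  # insertion
            ins = alt[1:]
            parts.append(ins)
            segs.append(_Segment(cur_hap, cur_ref, len(ins), 0, "I"))
            cur_hap += len(ins)
        else:  # deletion
            d = len(ref) - 1
            segs.append(_Segment(cur_hap, cur_ref, 0, d, "D"))
            cur_ref += d
    if cur_ref < len(ref_seq) or not segs:
        m_len = len(ref_seq) - cur_ref
        parts.append(snv_seq[cur_ref:].decode("ascii"))
        segs.append(_Segment(cur_hap, cur_ref, m_len, m_len, "M"))
    return Haplotype(chrom, "".join(parts), segs)


def build_diploid_genome(
    ref_seq: str, sites: list[TrioSite], member: str, chrom: str = "chr1"
) -> tuple[Haplotype, Haplotype]:
    """Realize one individual's genotypes as two haplotype sequences.

    Heterozygous variants go to haplotype 1, homozygous-alt to both; with no
    variants both haplotypes equal the reference.
    """
    gt_attr = f"gt_{member}"
    hap_vars: tuple[list, list] = ([], [])
    last_end = -1
    for site in sorted(sites, key=lambda s: s.pos):
        gt = getattr(site, gt_attr)
        alleles = gt_alleles(gt)
        if alleles is None or alleles == (0, 0):
            continue
        if site.pos <= last_end:
            raise ValueError(f"overlapping variants near {chrom}:{site.pos}")
        last_end = site.pos + len(site.ref) - 1
        if gt == HOM_ALT:
            hap_vars[0].append((site.pos, site.ref, site.alt))
            hap_vars[1].append((site.pos, site.ref, site.alt))
        elif gt == HET:
            hap_vars[1].append((site.pos, site.ref, site.alt))
    return (
        build_haplotype(ref_seq, hap_vars[0], chrom),
        build_haplotype(ref_seq, hap_vars[1], chrom),
    )


@dataclass
class ReadPair:
    """One simulated fragment with both mates, pre-aligned to the reference."""

    chrom: str
    fragment_start: int  # 0-based, haplotype coordinates
    fragment_length: int
    haplotype_of_origin: int  # 0 or 1
    mate1_seq: str  # reference-forward orientation
    mate2_seq: str
    mate1_quals: str  # Phred+33
    mate2_quals: str
    ref_start1: int  # 0-based reference coordinates
    cigar1: list[tuple[str, int]]
    ref_start2: int
    cigar2: list[tuple[str, int]]


def _quality_char(base_error_rate: float) -> str:
    q = 40 if base_error_rate <= 0 else min(40, round(-10.0 * math.log10(base_error_rate)))
    return chr(33 + q)


def _apply_errors(seq: str, rng: np.random.Generator, rate: float, read_length: int) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(read_length, rate)
    if n_err == 0:
        return seq
    positions = rng.choice(read_length, size=n_err, replace=False)
    s = list(seq)
    for p in positions.tolist():
        options = [b for b in "ACGT" if b != s[p]]
        s[p] = options[int(rng.integers(3))]
    return "".join(s)


def simulate_reads(
    haplotypes: tuple[Haplotype, Haplotype],
    config: SimulationConfig,
    seed: int,
    stage: str = "reads",
) -> list[ReadPair]:
    """Draw paired-end reads at the configured coverage from a diploid genome.

    Pair count is round(coverage x genome_length / (2 x read_length));
    fragment starts are uniform, haplotype of origin uniform, fragment
    lengths Normal(fragment_mean, fragment_sd) truncated below at
    read_length. Each base is substituted with a uniformly chosen different
    base with probability base_error_rate. Deterministic given seed.
    """
    config.validate()
    rng = stage_rng(seed, stage)
    L = config.read_length
    genome_length = haplotypes[0].segments[-1].ref_start + haplotypes[0].segments[-1].ref_len
    for hap in haplotypes:
        if L > len(hap):
            raise ValueError(f"read_length {L} exceeds haplotype length {len(hap)}")
    n_pairs = round(config.coverage * genome_length / (2 * L))
    if n_pairs == 0:
        return []
    hap_idx = rng.integers(0, 2, size=n_pairs)
    frag_len = rng.normal(config.fragment_mean, config.fragment_sd, size=n_pairs)
    frag_len = np.maximum(np.rint(frag_len).astype(int), L)
    qual = _quality_char(config.base_error_rate)
    pairs: list[ReadPair] = []
    for i in range(n_pairs):
        hap = haplotypes[int(hap_idx[i])]
        flen = min(int(frag_len[i]), len(hap))
        start = int(rng.integers(0, len(hap) - flen + 1))
        s1, e1 = start, start + L
        s2, e2 = start + flen - L, start + flen
        seq1 = _apply_errors(hap.seq[s1:e1], rng, config.base_error_rate, L)
        seq2 = _apply_errors(hap.seq[s2:e2], rng, config.base_error_rate, L)
        ref1, cig1 = hap.project(s1, e1)
        ref2, cig2 = hap.project(s2, e2)
        pairs.append(
            ReadPair(
                chrom=hap.chrom,
                fragment_start=start,
                fragment_length=flen,
                haplotype_of_origin=int(hap_idx[i]),
                mate1_seq=seq1,
                mate2_seq=seq2,
                mate1_quals=qual * L,
                mate2_quals=qual * L,
                ref_start1=ref1,
                cigar1=cig1,
                ref_start2=ref2,
                cigar2=cig2,
            )
        )
    return pairs


def _cigar_str(cigar: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def _ref_span(cigar: list[tuple[str, int]]) -> int:
    return sum(n for op, n in cigar if op in ("M", "D"))


def emit_bam(
    pairs: list[ReadPair],
    contigs: dict[str, int],
    path: str | os.PathLike,
    sample: str = "sample",
    read_prefix: str = "sim",
) -> None:
    """Write pairs as a coordinate-sorted, indexed BAM at truth coordinates.

    SAM text is assembled in bulk and handed to samtools (via pysam) for
    BAM conversion, sorting and indexing.
    """
    path = os.fspath(path)
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for name, length in contigs.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    lines.append(f"@RG\tID:{sample}\tSM:{sample}")
    for i, p in enumerate(pairs):
        qname = f"{read_prefix}{i}"
        pos1, pos2 = p.ref_start1 + 1, p.ref_start2 + 1
        tlen = (p.ref_start2 + _ref_span(p.cigar2)) - p.ref_start1
        # FR pair: mate1 forward (flag 99), mate2 reverse (flag 147)
        lines.append(
            f"{qname}\t99\t{p.chrom}\t{pos1}\t60\t{_cigar_str(p.cigar1)}\t=\t{pos2}\t"
            f"{tlen}\t{p.mate1_seq}\t{p.mate1_quals}\tRG:Z:{sample}"
        )
        lines.append(
            f"{qname}\t147\t{p.chrom}\t{pos2}\t60\t{_cigar_str(p.cigar2)}\t=\t{pos1}\t"
            f"{-tlen}\t{p.mate2_seq}\t{p.mate2_quals}\tRG:Z:{sample}"
        )
    with tempfile.TemporaryDirectory() as tmpdir:
        sam_path = os.path.join(tmpdir, "unsorted.sam")
        with open(sam_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        pysam.sort("-O", "bam", "-o", path, sam_path, catch_stdout=False)
    pysam.index(path)


def emit_fastq(pairs: list[ReadPair], path1: str | os.PathLike, path2: str | os.PathLike,
               read_prefix: str = "sim") -> None:
    """Paired FASTQ (Phred+33); mate 2 is written in sequencing orientation."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for i, p in enumerate(pairs):
            qname = f"{read_prefix}{i}"
            f1.write(f"@{qname}/1\n{p.mate1_seq}\n+\n{p.mate1_quals}\n")
            f2.write(f"@{qname}/2\n{_revcomp(p.mate2_seq)}\n+\n{p.mate2_quals[::-1]}\n")


def base_counts(bam_path: str | os.PathLike, chrom: str, start: int, end: int) -> np.ndarray:
    """4xN ACGT base counts over [start, end) (0-based), no quality filter."""
    with pysam.AlignmentFile(os.fspath(bam_path)) as bam:
        cov = bam.count_coverage(chrom, start, end, quality_threshold=0)
    return np.array(cov)


def mean_depth(bam_path: str | os.PathLike, chrom: str, length: int | None = None) -> float:
    """Mean per-base depth over the contig (aligned bases only)."""
    with pysam.AlignmentFile(os.fspath(bam_path)) as bam:
        if length is None:
            length = bam.get_reference_length(chrom)
        cov = bam.count_coverage(chrom, 0, length, quality_threshold=0)
    return float(np.array(cov).sum() / length)


def _classify_indel_read(read: pysam.AlignedSegment, pos0: int, ref: str, alt: str) -> str:
    """ref / alt / other support of one read for a left-anchored indel at pos0."""
    is_del = len(ref) > len(alt)
    event_len = abs(len(ref) - len(alt))
    ref_cursor = read.reference_start
    found_event = False
    covers = False
    span_end = pos0 + len(ref)  # ref bases the deletion removes end here
    for op, n in read.cigartuples:
        if op in (0, 7, 8):  # M/=/X
            if ref_cursor <= pos0 < ref_cursor + n:
                covers = True
            ref_cursor += n
        elif op == 2:  # D
            if is_del and ref_cursor == pos0 + 1 and n == event_len:
                found_event = True
            ref_cursor += n
        elif op == 1:  # I
            if not is_del and ref_cursor == pos0 + 1 and n == event_len:
                found_event = True
        # S/H consume no reference
    if found_event:
        return "alt"
    if not covers:
        return "none"
    # ref support requires spanning the whole event footprint plus one base
    if read.reference_start <= pos0 and read.reference_end >= span_end + 1:
        return "ref"
    return "other"


def collect_allelic_counts(
    bam_path: str | os.PathLike,
    sites: list[tuple[str, int, str, str]],
    reference_lengths: dict[str, int] | None = None,
) -> list[AllelicCounts]:
    """Per-site ref / alt / other read counts (SNVs by base, indels by CIGAR).

    VAF downstream is alt/(ref+alt+other), 0 at depth 0. Bases that are
    neither ref nor alt count toward depth but never as alt.
    """
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    out: list[AllelicCounts] = []
    with pysam.AlignmentFile(os.fspath(bam_path)) as bam:
        for chrom, pos, ref, alt in sites:
            clen = bam.get_reference_length(chrom)
            if reference_lengths is not None:
                clen = reference_lengths[chrom]
            if not (1 <= pos <= clen):
                raise ValueError(f"site {chrom}:{pos} outside reference bounds (1..{clen})")
            pos0 = pos - 1
            if len(ref) == 1 and len(alt) == 1:
                cov = bam.count_coverage(chrom, pos0, pos0 + 1, quality_threshold=0)
                counts = [int(cov[i][0]) for i in range(4)]
                r = counts[base_index[ref]]
                a = counts[base_index[alt]]
                other = sum(counts) - r - a
            else:
                r = a = other = 0
                for read in bam.fetch(chrom, pos0, pos0 + len(ref) + 1):
                    if read.is_unmapped or read.is_secondary or read.is_supplementary:
                        continue
                    cls = _classify_indel_read(read, pos0, ref, alt)
                    if cls == "ref":
                        r += 1
                    elif cls == "alt":
                        a += 1
                    elif cls == "other":
                        other += 1
            out.append(AllelicCounts(chrom, pos, r, a, other))
    return out
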