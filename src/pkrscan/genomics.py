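"""Inverted-repeat detection and CLIP-style coverage arithmetic.

Inverted repeats (IRs) — pairs of same-family repeat copies on opposite
strands within a short window — fold into long intramolecular duplexes and
are the dominant endogenous dsRNA in primate transcriptomes (IR-Alus).
``find_ir_pairs`` reproduces the standard screen: candidate pairs within
1.5 kb are aligned (one copy against the reverse complement of the other)
with exact affine-gap local alignment at blastn-style scores (match +2,
mismatch -3, gap open 5, gap extend 2) and accepted above 80% identity.
The exact Smith-Waterman replaces BLAST's word-seeded heuristic by design.

Coverage tracks (bedGraph-style interval lists, 0-based half-open) support
per-million normalization against total non-rRNA read counts, interval
subtraction over the union of breakpoints, a simple threshold/merge/length
peak caller, per-peak area-under-curve (sum of value x overlap width),
log2 fold-change enrichment filtering with a pseudo-count floor, near-IR
annotation of peaks, and A-to-G editing rates in counts per million reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Seq import Seq

__all__ = [
    "RepeatFeature",
    "IRPair",
    "CoverageTrack",
    "PeakQuant",
    "EditingStats",
    "find_ir_pairs",
    "normalize_coverage",
    "subtract_tracks",
    "call_peaks",
    "peak_auc",
    "quantify_peaks",
    "annotate_near_ir",
    "editing_cpm",
    "synth_genome",
]


@dataclass(frozen=True)
class RepeatFeature:
    """A repeat annotation, BED-style 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    family: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"feature {self.name or self.family}: "
                             f"start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IRPair:
    """Two opposite-strand repeat copies forming an inverted repeat."""

    upstream: RepeatFeature
    downstream: RepeatFeature
    gap: int
    identity: float       # percent over alignment columns
    coverage: float       # aligned fraction of the shorter repeat
    score: float


@dataclass
class CoverageTrack:
    """Sorted, non-overlapping (chrom, start, end, value) intervals.

    ``total_reads`` and ``scale_factor`` record the per-million
    normalization once applied.
    """

    intervals: list  # of (chrom, start, end, value)
    total_reads: Optional[float] = None
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        prev: dict[str, int] = {}
        for chrom, s, e, v in self.intervals:
            if s >= e:
                raise ValueError(f"interval {chrom}:{s}-{e} has start >= end")
            if not math.isfinite(v):
                raise ValueError(f"non-finite value at {chrom}:{s}-{e}")
            if chrom in prev and s < prev[chrom]:
                raise ValueError(
                    f"intervals overlap or are unsorted at {chrom}:{s} "
                    "(sort by chrom,start and merge overlaps first)")
            prev[chrom] = e

    def by_chrom(self) -> dict[str, list]:
        out: dict[str, list] = {}
        for chrom, s, e, v in self.intervals:
            out.setdefault(chrom, []).append((s, e, v))
        return out


@dataclass
class PeakQuant:
    """Per-peak AuC values, enrichment log2FCs and classification."""

    chrom: str
    start: int
    end: int
    auc: dict[str, float]
    log2fc: float
    control_log2fc: Optional[float] = None
    passes_enrichment: bool = False
    classification: str = "other"
    zero_input: bool = False


@dataclass
class EditingStats:
    """Strand-aware A-to-G mismatch rate per region, in CPM."""

    region: str
    mismatch_count: int
    total_mapped_reads: int
    cpm: float


_DEF_ALIGNER_KW = dict(match_score=2.0, mismatch_score=-3.0,
                       open_gap_score=-7.0, extend_gap_score=-2.0)


def _local_aligner() -> Align.PairwiseAligner:
    # blastn-style affine costs: a k-long gap costs 5 + 2k
    a = Align.PairwiseAligner(mode="local", **_DEF_ALIGNER_KW)
    return a


def _feature_seq(feat: RepeatFeature, sequences: dict[str, str]) -> str:
    if feat.chrom not in sequences:
        raise ValueError(f"no sequence for chromosome {feat.chrom!r}")
    seq = sequences[feat.chrom]
    if feat.end > len(seq):
        raise ValueError(
            f"feature {feat.name or feat.family} {feat.chrom}:"
            f"{feat.start}-{feat.end} extends past sequence end "
            f"({len(seq)} bp)")
    return seq[feat.start:feat.end]


def _alignment_stats(alignment) -> tuple[float, int, int]:
    """(percent identity over columns, target bp aligned, query bp aligned)."""
    counts = alignment.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    ident = 100.0 * counts.identities / columns if columns else 0.0
    t_cov = sum(int(e) - int(s) for s, e in alignment.aligned[0])
    q_cov = sum(int(e) - int(s) for s, e in alignment.aligned[1])
    return ident, t_cov, q_cov


def find_ir_pairs(repeats: Sequence[RepeatFeature],
                  sequences: dict[str, str],
                  window: int = 1500,
                  min_identity: float = 80.0,
                  min_coverage: float = 0.8) -> list[IRPair]:
    """Detect inverted-repeat pairs among annotated repeat copies.

    For every same-chromosome, same-family pair on opposite strands with a
    gap of at most ``window`` bp, the upstream sequence is locally aligned
    against the reverse complement of the downstream one (plus/minus match).
    Pairs pass if identity over alignment columns exceeds ``min_identity``
    percent and the alignment covers at least ``min_coverage`` of the
    shorter copy.  A repeat may belong to multiple pairs.
    """
    aligner = _local_aligner()
    by_chrom: dict[str, list[RepeatFeature]] = {}
    for f in repeats:
        by_chrom.setdefault(f.chrom, []).append(f)
    pairs: list[IRPair] = []
    for chrom, feats in by_chrom.items():
        feats = sorted(feats, key=lambda f: (f.start, f.end))
        for i, up in enumerate(feats):
            for dn in feats[i + 1:]:
                gap = dn.start - up.end
                if gap > window:
                    break
                if gap < 0:
                    continue
                if dn.family != up.family or dn.strand == up.strand:
                    continue
                s_up = _feature_seq(up, sequences).upper()
                s_dn = str(Seq(_feature_seq(dn, sequences).upper())
                           .reverse_complement())
                aln = aligner.align(s_up, s_dn)
                if len(aln) == 0:
                    continue
                best = aln[0]
                ident, t_cov, q_cov = _alignment_stats(best)
                shorter = min(len(s_up), len(s_dn))
                cov_bp = t_cov if len(s_up) <= len(s_dn) else q_cov
                coverage = cov_bp / shorter if shorter else 0.0
                if ident > min_identity and coverage >= min_coverage:
                    pairs.append(IRPair(upstream=up, downstream=dn, gap=gap,
                                        identity=ident, coverage=coverage,
                                        score=float(best.score)))
    return pairs


def normalize_coverage(track: CoverageTrack,
                       total_non_rrna_reads: float) -> CoverageTrack:
    """Scale values to 'per million non-rRNA mapped reads' units."""
    if total_non_rrna_reads <= 0:
        raise ValueError("total non-rRNA read count must be > 0")
    factor = 1e6 / total_non_rrna_reads
    return CoverageTrack(
        intervals=[(c, s, e, v * factor) for c, s, e, v in track.intervals],
        total_reads=float(total_non_rrna_reads), scale_factor=factor)


def _breakpoint_union(a_ivs, b_ivs):
    """Yield (start, end, va, vb) over the union breakpoint set (one chrom)."""
    points = sorted({p for s, e, _ in a_ivs + b_ivs for p in (s, e)})
    ai = bi = 0
    for s, e in zip(points[:-1], points[1:]):
        va = vb = 0.0
        while ai < len(a_ivs) and a_ivs[ai][1] <= s:
            ai += 1
        if ai < len(a_ivs) and a_ivs[ai][0] <= s < a_ivs[ai][1]:
            va = a_ivs[ai][2]
        while bi < len(b_ivs) and b_ivs[bi][1] <= s:
            bi += 1
        if bi < len(b_ivs) and b_ivs[bi][0] <= s < b_ivs[bi][1]:
            vb = b_ivs[bi][2]
        yield s, e, va, vb


def subtract_tracks(a: CoverageTrack, b: CoverageTrack) -> CoverageTrack:
    """Interval arithmetic a - b over the union of breakpoints.

    Regions covered by only one track treat the other as 0; adjacent
    segments with equal values are merged.
    """
    a_by, b_by = a.by_chrom(), b.by_chrom()
    out = []
    for chrom in sorted(set(a_by) | set(b_by)):
        segs = []
        for s, e, va, vb in _breakpoint_union(a_by.get(chrom, []),
                                              b_by.get(chrom, [])):
            covered = any(lo <= s < hi for lo, hi, _ in a_by.get(chrom, [])) \
                or any(lo <= s < hi for lo, hi, _ in b_by.get(chrom, []))
            if not covered:
                continue
            v = va - vb
            if segs and segs[-1][1] == s and segs[-1][2] == v:
                segs[-1] = (segs[-1][0], e, v)
            else:
                segs.append((s, e, v))
        out.extend((chrom, s, e, v) for s, e, v in segs)
    return CoverageTrack(intervals=out)


def call_peaks(track: CoverageTrack,
               min_value: float = 1.0,
               min_length: int = 50,
               merge_gap: int = 0) -> list[tuple[str, int, int]]:
    """Threshold/merge/length peak caller over a coverage track.

    Maximal runs with value >= ``min_value`` are merged across gaps of at
    most ``merge_gap`` bp and kept if at least ``min_length`` bp long.  This
    is a deliberately simple stand-in for a dedicated bedGraph peak caller
    and is not parameter-compatible with one.
    """
    if min_value < 0 or min_length < 0 or merge_gap < 0:
        raise ValueError("thresholds must be >= 0")
    peaks = []
    for chrom, ivs in track.by_chrom().items():
        runs = []
        for s, e, v in ivs:
            if v >= min_value:
                if runs and s - runs[-1][1] <= merge_gap:
                    runs[-1] = (runs[-1][0], e)
                else:
                    runs.append((s, e))
        peaks.extend((chrom, s, e) for s, e in runs if e - s >= min_length)
    return sorted(peaks)


def peak_auc(track: CoverageTrack, peak: tuple[str, int, int]) -> float:
    """Area under the coverage curve over a peak: sum(value * overlap_bp)."""
    chrom, ps, pe = peak
    total = 0.0
    for s, e, v in track.by_chrom().get(chrom, []):
        lo, hi = max(s, ps), min(e, pe)
        if hi > lo:
            total += v * (hi - lo)
    return total


def quantify_peaks(peaks: Sequence[tuple[str, int, int]],
                   fclip: CoverageTrack,
                   input_track: CoverageTrack,
                   control_fclip: Optional[CoverageTrack] = None,
                   control_input: Optional[CoverageTrack] = None,
                   pseudo_auc: float = 1.0,
                   min_log2fc: float = 1.0,
                   max_control_log2fc: float = 0.0) -> list[PeakQuant]:
    """AuC-based enrichment of peaks: log2FC(fCLIP/input) with a pseudo floor.

    A peak passes when log2FC >= ``min_log2fc`` and, if control tracks are
    given, the control log2FC <= ``max_control_log2fc`` (the tag-present /
    tag-absent criterion pair).  Zero input AuC is flagged; the pseudo-AuC
    floor keeps the ratio finite.
    """
    out: list[PeakQuant] = []
    for peak in peaks:
        auc_f = peak_auc(fclip, peak)
        auc_i = peak_auc(input_track, peak)
        zero_input = auc_i <= 0
        log2fc = math.log2((auc_f + pseudo_auc) / (auc_i + pseudo_auc))
        ctrl = None
        if control_fclip is not None and control_input is not None:
            cf = peak_auc(control_fclip, peak)
            ci = peak_auc(control_input, peak)
            ctrl = math.log2((cf + pseudo_auc) / (ci + pseudo_auc))
        passes = log2fc >= min_log2fc and (ctrl is None
                                           or ctrl <= max_control_log2fc)
        aucs = {"fclip": auc_f, "input": auc_i}
        out.append(PeakQuant(chrom=peak[0], start=peak[1], end=peak[2],
                             auc=aucs, log2fc=log2fc, control_log2fc=ctrl,
                             passes_enrichment=passes,
                             zero_input=zero_input))
    return out


def annotate_near_ir(peaks: Sequence[PeakQuant],
                     ir_pairs: Sequence[IRPair],
                     window: int = 300) -> list[PeakQuant]:
    """Classify peaks as IR-Alu / near IR-Alu / other (in place, returned).

    Overlapping a pair member -> "IR-Alu"; within ``window`` bp of a member,
    or lying between the two members of one pair (flanked) -> "near IR-Alu";
    otherwise "other".
    """
    for pk in peaks:
        cls = "other"
        for pair in ir_pairs:
            members = (pair.upstream, pair.downstream)
            if pair.upstream.chrom != pk.chrom:
                continue
            overlap = any(pk.start < m.end and m.start < pk.end
                          for m in members)
            if overlap:
                cls = "IR-Alu"
                break
            near = any(
                (pk.start >= m.end and pk.start - m.end < window)
                or (m.start >= pk.end and m.start - pk.end < window)
                for m in members)
            between = (pk.start >= pair.upstream.end
                       and pk.end <= pair.downstream.start)
            if near or between:
                cls = "near IR-Alu"
        pk.classification = cls
    return list(peaks)


def editing_cpm(mismatch_counts: dict[str, int],
                total_mapped_reads: int) -> list[EditingStats]:
    """A-to-G mismatch counts per million mapped reads, per region.

    Counts are expected to be strand-resolved upstream (A->G on plus-strand
    features, T->C on minus-strand ones).  Includes an ``__aggregate__``
    entry summing all regions.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be > 0")
    out = [EditingStats(region=r, mismatch_count=int(c),
                        total_mapped_reads=int(total_mapped_reads),
                        cpm=c * 1e6 / total_mapped_reads)
           for r, c in mismatch_counts.items()]
    agg = sum(mismatch_counts.values())
    out.append(EditingStats(region="__aggregate__", mismatch_count=int(agg),
                            total_mapped_reads=int(total_mapped_reads),
                            cpm=agg * 1e6 / total_mapped_reads))
    return out


_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute exactly round(divergence * len) positions with new bases.

    The substitution count is planted exactly (not Bernoulli-sampled) so the
    realised divergence of every copy equals the requested one; the residual
    spread of alignment identity then comes only from the aligner itself.
    """
    k = int(round(divergence * len(seq)))
    if k == 0:
        return seq
    chars = np.array(list(seq))
    for i in rng.choice(len(seq), size=k, replace=False):
        choices = [b for b in "ACGT" if b != chars[i]]
        chars[i] = choices[int(rng.integers(3))]
    return "".join(chars)


def synth_genome(n_pairs: int = 20,
                 repeat_len: int = 300,
                 divergence: float = 0.0,
                 gap_range: tuple[int, int] = (100, 1000),
                 n_same_strand_decoys: int = 20,
                 n_over_window_pairs: int = 10,
                 seed: int = 0,
                 spacer: int = 2500,
                 family: str = "AluSyn"
                 ) -> tuple[dict[str, str], list[RepeatFeature],
                            list[tuple[str, str]]]:
    """Synthetic genome with planted inverted repeats and decoys.

    Plants ``n_pairs`` true inverted pairs (downstream copy is the reverse
    complement of the upstream copy, mutated at the given divergence),
    ``n_same_strand_decoys`` direct-repeat pairs (same strand, so the
    plus/minus rule must reject them) and ``n_over_window_pairs`` inverted
    pairs with gaps beyond the 1.5 kb window.  Constructs are separated by
    ``spacer`` bp of random background so no cross-construct pair falls
    within the window.  Returns (sequences, features, truth) where truth
    lists the (upstream_name, downstream_name) of intended pairs.
    """
    if not (0.0 <= divergence < 1.0):
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    chunks: list[str] = []
    features: list[RepeatFeature] = []
    truth: list[tuple[str, str]] = []
    cursor = 0
    chrom = "chrSyn"

    def _bg(n: int) -> str:
        return "".join(_BASES[rng.integers(4, size=n)])

    def _emit(seq: str) -> tuple[int, int]:
        nonlocal cursor
        start = cursor
        chunks.append(seq)
        cursor += len(seq)
        return start, cursor

    def _plant(kind: str, idx: int, gap: int, inverted: bool) -> None:
        up_seq = _bg(repeat_len)
        if inverted:
            dn_core = str(Seq(_mutate(up_seq, divergence, rng))
                          .reverse_complement())
            dn_strand = "-"
        else:
            dn_core = _mutate(up_seq, divergence, rng)
            dn_strand = "+"
        _emit(_bg(spacer))
        s1, e1 = _emit(up_seq)
        _emit(_bg(gap))
        s2, e2 = _emit(dn_core)
        up = RepeatFeature(chrom, s1, e1, "+", family, f"{kind}{idx}_up")
        dn = RepeatFeature(chrom, s2, e2, dn_strand, family,
                           f"{kind}{idx}_dn")
        features.extend([up, dn])
        if kind == "ir":
            truth.append((up.name, dn.name))

    for i in range(n_pairs):
        gap = int(rng.integers(gap_range[0], gap_range[1] + 1))
        _plant("ir", i, gap, inverted=True)
    for i in range(n_same_strand_decoys):
        gap = int(rng.integers(gap_range[0], gap_range[1] + 1))
        _plant("decoy", i, gap, inverted=False)
    for i in range(n_over_window_pairs):
        gap = int(rng.integers(1600, 2200))
        _plant("far", i, gap, inverted=True)
    _emit(_bg(spacer))
    return {chrom: "".join(chunks)}, features, truth
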