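"""Paired-end amplicon reads -> clone-count table.

Re-implements the repertoire read-processing chain as a self-contained
pipeline: ungapped pair merging with Phred-aware consensus, MID
demultiplexing, semi-global V/J assignment with conserved-anchor mapping,
CDR3 extraction with a per-base quality filter, clustering of reads into
clones by 100% amino-acid CDR3 identity, and UMI-collapsed counting.

Coordinates are 0-based half-open throughout; the amplicon layout (MID,
UMI, template) matches the emission layout declared in
:class:`tcrtrack.simulate.ReadEmissionConfig`.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq

from .model import CloneCountTable, CloneKey, FormatError, SampleMeta
from .simulate import ReferenceSegment

logger = logging.getLogger(__name__)


class Read(NamedTuple):
    """A sequence with per-base Phred qualities."""

    seq: str
    qual: np.ndarray

    @staticmethod
    def from_record(rec) -> "Read":
        return Read(str(rec.seq).upper(), np.asarray(rec.letter_annotations["phred_quality"]))


@dataclass(frozen=True)
class ProcessConfig:
    min_overlap: int = 30
    max_mismatch_frac: float = 0.1
    max_mid_mismatch: int = 1
    mid_length: int = 8
    umi_length: int = 9
    min_score_frac: float = 0.6     # V/J acceptance: score >= frac * ref length
    min_phred: int = 30             # CDR3 per-base quality filter
    junction_inclusive: bool = True  # CDR3 = Cys..Phe/Trp codons inclusive
    key_includes_vj: bool = False
    umi_collapse_hamming: int = 0   # 1 enables single-linkage UMI collapse
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


@dataclass
class AnnotatedRead:
    """A merged, demultiplexed, V/J-annotated read."""

    seq: str
    qual: np.ndarray
    umi: str
    sample_id: str
    v_call: str
    j_call: str
    cdr3_interval: tuple[int, int]  # 0-based half-open on ``seq``
    cdr3_aa: str

    @property
    def cdr3_nt(self) -> str:
        a, b = self.cdr3_interval
        return self.seq[a:b]


# ---------------------------------------------------------------------------
# pair merging
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def merge_pairs(
    r1: Read, r2: Read, min_overlap: int = 30, max_mismatch_frac: float = 0.1
) -> Read | None:
    """Merge a read pair by its best ungapped 3' overlap.

    ``r2`` is reverse-complemented, every overlap length ``o`` in
    ``[min_overlap, min(l1, l2)]`` is scored as matches - mismatches, and the
    best-scoring overlap with mismatch fraction <= ``max_mismatch_frac`` wins
    (ties to the longer overlap).  Disagreeing bases resolve to the
    higher-Phred base; merged quality is the elementwise maximum.  Returns
    ``None`` (not an error) when no overlap qualifies.
    """
    if len(r1.seq) != len(r1.qual) or len(r2.seq) != len(r2.qual):
        raise FormatError("sequence/quality length mismatch")
    if not r1.seq or not r2.seq:
        raise FormatError("empty read")
    s1 = np.frombuffer(r1.seq.encode(), dtype=np.uint8)
    s2 = np.frombuffer(_revcomp(r2.seq).encode(), dtype=np.uint8)
    q1 = np.asarray(r1.qual)
    q2 = np.asarray(r2.qual)[::-1]
    l1, l2 = len(s1), len(s2)

    best: tuple[float, int] | None = None
    for o in range(min_overlap, min(l1, l2) + 1):
        a = s1[l1 - o:]
        b = s2[:o]
        mism = int((a != b).sum())
        if mism / o > max_mismatch_frac:
            continue
        score = o - 2 * mism
        if best is None or (score, o) > best:
            best = (score, o)
    if best is None:
        return None
    o = best[1]

    a = s1[l1 - o:]
    b = s2[:o]
    qa = q1[l1 - o:]
    qb = q2[:o]
    consensus = np.where((a == b) | (qa >= qb), a, b)
    merged_seq = r1.seq[: l1 - o] + consensus.tobytes().decode() + _revcomp(r2.seq)[o:]
    merged_qual = np.concatenate([q1[: l1 - o], np.maximum(qa, qb), q2[o:]])
    return Read(merged_seq, merged_qual)


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def validate_mid_table(mid_to_sample: dict[str, str], max_mid_mismatch: int) -> None:
    """MIDs must be mutually >= 2*max_mid_mismatch + 1 apart for unique rescue."""
    mids = list(mid_to_sample)
    need = 2 * max_mid_mismatch + 1
    for a, b in itertools.combinations(mids, 2):
        if len(a) != len(b):
            raise ValueError("MIDs must share a common length")
        if _hamming(a, b) < need:
            raise ValueError(
                f"ambiguous MID table: {a} and {b} closer than Hamming {need}"
            )


UNDETERMINED = "undetermined"


def demultiplex(
    reads: Iterable[Read],
    mid_to_sample: dict[str, str],
    max_mid_mismatch: int = 1,
    mid_length: int | None = None,
) -> dict[str, list[Read]]:
    """Partition merged reads by their leading MID (barcode), stripping it.

    A read is assigned to the unique MID within ``max_mid_mismatch``
    mismatches, otherwise it goes to ``"undetermined"`` (MID left in place).
    """
    validate_mid_table(mid_to_sample, max_mid_mismatch)
    mids = list(mid_to_sample)
    n = mid_length if mid_length is not None else len(mids[0])
    out: dict[str, list[Read]] = defaultdict(list)
    for read in reads:
        prefix = read.seq[:n]
        hits = [m for m in mids if _hamming(prefix, m) <= max_mid_mismatch]
        if len(hits) == 1:
            out[mid_to_sample[hits[0]]].append(Read(read.seq[n:], read.qual[n:]))
        else:
            out[UNDETERMINED].append(read)
    return dict(out)


# ---------------------------------------------------------------------------
# V/J assignment
# ---------------------------------------------------------------------------


def make_aligner(config: ProcessConfig = ProcessConfig()) -> Align.PairwiseAligner:
    """Semi-global aligner: the reference must align end to end, the read
    provides free end gaps; affine internal gap penalties."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = config.match_score
    aligner.mismatch_score = config.mismatch_score
    aligner.open_gap_score = config.gap_open
    aligner.extend_gap_score = config.gap_extend
    # free end gaps on the read side only: the reference aligns end to end,
    # unaligned read overhangs cost nothing
    aligner.open_left_deletion_score = 0.0
    aligner.extend_left_deletion_score = 0.0
    aligner.open_right_deletion_score = 0.0
    aligner.extend_right_deletion_score = 0.0
    return aligner


class VJAssignment(NamedTuple):
    v_call: str
    j_call: str
    v_anchor: int  # read index of the first base of the V Cys codon
    j_anchor: int  # read index of the first base of the J Phe/Trp codon


def _map_anchor(alignment, anchor: int) -> int | None:
    """Map a reference (query) position to a read (target) position."""
    t_blocks, q_blocks = alignment.aligned
    for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
        if q0 <= anchor < q1:
            return int(t0 + (anchor - q0))
    return None


def _best_segment(
    aligner: Align.PairwiseAligner,
    seq: str,
    refs: Sequence[ReferenceSegment],
    min_score_frac: float,
) -> tuple[str, int] | None:
    best = None
    for ref in refs:
        score = aligner.score(seq, ref.seq)
        if best is None or score > best[0]:
            best = (score, ref)
    score, ref = best
    if score < min_score_frac * len(ref.seq):
        return None
    alignment = aligner.align(seq, ref.seq)[0]
    pos = _map_anchor(alignment, ref.anchor)
    if pos is None:
        return None
    return ref.name, pos


def assign_vj(
    seq: str,
    v_refs: Sequence[ReferenceSegment],
    j_refs: Sequence[ReferenceSegment],
    config: ProcessConfig = ProcessConfig(),
    aligner: Align.PairwiseAligner | None = None,
) -> VJAssignment | None:
    """Best-scoring V and J assignment with anchor positions on the read.

    Returns ``None`` when either family scores below
    ``min_score_frac * len(reference)`` or an anchor cannot be mapped.
    """
    if not v_refs or not j_refs:
        raise ValueError("empty reference")
    aligner = aligner if aligner is not None else make_aligner(config)
    v = _best_segment(aligner, seq, v_refs, config.min_score_frac)
    if v is None:
        return None
    j = _best_segment(aligner, seq, j_refs, config.min_score_frac)
    if j is None:
        return None
    return VJAssignment(v[0], j[0], v[1], j[1])


# ---------------------------------------------------------------------------
# CDR3 extraction
# ---------------------------------------------------------------------------


class Cdr3Rejection(NamedTuple):
    reason: str


def extract_cdr3(
    seq: str,
    qual: np.ndarray,
    v_anchor: int,
    j_anchor: int,
    min_phred: int = 30,
    inclusive: bool = True,
) -> tuple[tuple[int, int], str, str] | Cdr3Rejection:
    """CDR3 interval, nucleotide and amino-acid sequence, or a rejection.

    The default (IMGT junction) convention spans the conserved V Cys codon
    through the J Phe/Trp codon inclusive; ``inclusive=False`` excludes both
    anchor codons.  Rejected when the anchors are out of order, the interval
    length is not a multiple of 3, any base scores below ``min_phred``, or
    the translation contains a stop codon.
    """
    if inclusive:
        start, stop = v_anchor, j_anchor + 3
    else:
        start, stop = v_anchor + 3, j_anchor
    if start >= stop:
        return Cdr3Rejection("anchors out of order")
    if (stop - start) % 3 != 0:
        return Cdr3Rejection("CDR3 length not divisible by 3")
    if stop > len(seq):
        return Cdr3Rejection("CDR3 interval outside read")
    if (np.asarray(qual[start:stop]) < min_phred).any():
        return Cdr3Rejection(f"base below Phred {min_phred} in CDR3")
    nt = seq[start:stop]
    aa = str(Seq(nt).translate())
    if "*" in aa:
        return Cdr3Rejection("stop codon in CDR3")
    return (start, stop), nt, aa


# ---------------------------------------------------------------------------
# clone table construction
# ---------------------------------------------------------------------------


def _collapse_umis(umis: set[str], max_hamming: int) -> int:
    """Number of UMI groups after single-linkage collapse at <= max_hamming."""
    items = sorted(umis)
    parent = list(range(len(items)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(items)), 2):
        if _hamming(items[i], items[j]) <= max_hamming:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    return len({find(i) for i in range(len(items))})


def build_clone_table(
    annotated: Iterable[AnnotatedRead],
    sample_meta: dict[str, SampleMeta],
    config: ProcessConfig = ProcessConfig(),
) -> CloneCountTable:
    """Group annotated reads into clones and count unique UMIs per sample.

    Reads cluster by CDR3 amino-acid identity (V/J added to the key when
    ``key_includes_vj``).  A (sample, UMI) pair observed with several clones
    is a collision: it is awarded to the clone with the most reads, ties to
    the lexicographically smaller CDR3, and logged.  With
    ``umi_collapse_hamming=1``, UMIs within Hamming distance 1 of each other
    inside one clone are merged (single linkage) before counting.
    """
    # (sample, umi) -> clone key -> read count
    per_umi: dict[tuple[str, str], Counter] = defaultdict(Counter)
    keys: dict[tuple, CloneKey] = {}
    for r in annotated:
        key = (r.cdr3_aa, r.v_call, r.j_call) if config.key_includes_vj else (r.cdr3_aa,)
        if key not in keys:
            keys[key] = CloneKey(r.cdr3_aa, r.v_call if config.key_includes_vj else "",
                                 r.j_call if config.key_includes_vj else "")
        per_umi[(r.sample_id, r.umi)][key] += 1

    clone_umis: dict[tuple[str, tuple], set[str]] = defaultdict(set)
    n_conflicts = 0
    for (sample_id, umi), votes in per_umi.items():
        if len(votes) > 1:
            n_conflicts += 1
            winner = min(votes, key=lambda k: (-votes[k], k))
            logger.info(
                "UMI conflict in %s (%s): %s -> kept %s",
                sample_id, umi, dict(votes), winner,
            )
        else:
            (winner,) = votes
        clone_umis[(sample_id, winner)].add(umi)
    if n_conflicts:
        logger.warning("resolved %d UMI-to-clone conflict(s)", n_conflicts)

    sample_ids = sorted({sid for sid, _ in clone_umis})
    clone_keys = sorted({key for _, key in clone_umis})
    counts = np.zeros((len(clone_keys), len(sample_ids)), dtype=np.int64)
    srow = {sid: j for j, sid in enumerate(sample_ids)}
    crow = {key: i for i, key in enumerate(clone_keys)}
    for (sid, key), umis in clone_umis.items():
        if config.umi_collapse_hamming > 0:
            n = _collapse_umis(umis, config.umi_collapse_hamming)
        else:
            n = len(umis)
        counts[crow[key], srow[sid]] = n
    return CloneCountTable(
        clones=[keys[key] for key in clone_keys],
        samples=[sample_meta[sid] for sid in sample_ids],
        counts=counts,
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def parse_sample_id(sample_id: str, ordinal: int = 1) -> SampleMeta:
    """Best-effort metadata from ids shaped like ``d10_r2`` / ``d10_sorted_r1``."""
    import re

    m = re.fullmatch(r"d(\d+)(_sorted)?_r(\d+)", sample_id)
    if m:
        return SampleMeta(
            sample_id,
            timepoint=int(m.group(1)),
            replicate=int(m.group(3)),
            fraction="sorted" if m.group(2) else "bulk",
        )
    return SampleMeta(sample_id, timepoint=0, replicate=ordinal)


def process_reads(
    r1_path: str | Path,
    r2_path: str | Path,
    v_refs: Sequence[ReferenceSegment],
    j_refs: Sequence[ReferenceSegment],
    mid_to_sample: dict[str, str],
    config: ProcessConfig = ProcessConfig(),
    sample_meta: dict[str, SampleMeta] | None = None,
) -> tuple[CloneCountTable, pd.DataFrame]:
    """Full chain: FASTQ pair -> merged -> demultiplexed -> annotated ->
    clone table, plus a per-stage attrition report.

    Deterministic given inputs and configuration.  V/J alignment is cached
    per distinct template sequence, so PCR duplicates cost nothing extra.
    """
    pairs = zip(
        SeqIO.parse(str(r1_path), "fastq"), SeqIO.parse(str(r2_path), "fastq")
    )
    merged: list[Read] = []
    n_pairs = 0
    for rec1, rec2 in pairs:
        n_pairs += 1
        m = merge_pairs(
            Read.from_record(rec1), Read.from_record(rec2),
            config.min_overlap, config.max_mismatch_frac,
        )
        if m is not None:
            merged.append(m)

    by_sample = demultiplex(merged, mid_to_sample, config.max_mid_mismatch,
                            mid_length=config.mid_length)
    n_demux = sum(len(v) for s, v in by_sample.items() if s != UNDETERMINED)

    aligner = make_aligner(config)
    vj_cache: dict[str, VJAssignment | None] = {}
    annotated: list[AnnotatedRead] = []
    n_assigned = 0
    for sample_id, reads in by_sample.items():
        if sample_id == UNDETERMINED:
            continue
        for read in reads:
            umi = read.seq[: config.umi_length]
            seq = read.seq[config.umi_length:]
            qual = read.qual[config.umi_length:]
            if seq not in vj_cache:
                vj_cache[seq] = assign_vj(seq, v_refs, j_refs, config, aligner)
            vj = vj_cache[seq]
            if vj is None:
                continue
            n_assigned += 1
            res = extract_cdr3(
                seq, qual, vj.v_anchor, vj.j_anchor,
                min_phred=config.min_phred, inclusive=config.junction_inclusive,
            )
            if isinstance(res, Cdr3Rejection):
                continue
            interval, _nt, aa = res
            annotated.append(
                AnnotatedRead(seq, qual, umi, sample_id, vj.v_call, vj.j_call,
                              interval, aa)
            )

    if sample_meta is None:
        sample_meta = {
            sid: parse_sample_id(sid, i + 1)
            for i, sid in enumerate(sorted(set(mid_to_sample.values())))
        }
    table = build_clone_table(annotated, sample_meta, config)
    attrition = pd.DataFrame(
        dict(
            stage=["pairs_in", "merged", "demultiplexed", "vj_assigned", "cdr3_pass"],
            reads=[n_pairs, len(merged), n_demux, n_assigned, len(annotated)],
        )
    )
    return table, attrition
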