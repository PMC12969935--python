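"""Integration-site calling and quantification from transposon junction reads.

Single-end amplicon reads that begin inside the transposon right end are
screened for quality (a read fails when at least half of its bases are below
Q20), searched for the last 20 bases of the right transposon end, and the
17-bp genomic "fingerprint" immediately 3' of that end is mapped back to the
reference by exact, unique both-strand lookup. Fingerprints absent from the
genome are checked against the donor vector (pME) and tallied as donor
contamination; fingerprints mapping uniquely to the vector when it is
supplied as a mapping target report self-targeting integration.

Insertions leave a short target-site duplication (TSD, 5 bp by default); an
event's coordinate is the fifth TSD base on the fwd strand, which makes both
junction orientations of one physical insertion coincide at the same
position. Events within a 100-bp window after the protospacer's 3' end are
on-target; everything else is untargeted. Per-sample site counts are
normalized by total transposon-end containing reads and scaled to the
deepest sample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .refio import FWD, REV, KmerIndex, ReadRecord

__all__ = [
    "DEFAULT_END_SEQ",
    "TnseqParams",
    "TargetSite",
    "FingerprintHit",
    "IntegrationEvent",
    "SampleStats",
    "passes_quality",
    "phred_error_prob",
    "extract_fingerprint",
    "locate_fingerprint",
    "call_events",
    "classify_event",
    "summarize_sample",
    "normalize_across_samples",
    "analyze_sample",
]

#: last 20 bases of the VchCAST right transposon end, 5'->3'
DEFAULT_END_SEQ = "TGTTGATACAACCATAAAAT"

T_RL = "T-RL"
T_LR = "T-LR"

CAT_UNIQUE = "unique"
CAT_MULTI = "multi"
CAT_UNMAPPED = "unmapped"
CAT_VECTOR = "vector"


@dataclass(frozen=True)
class TnseqParams:
    """Parameters of the junction-read pipeline.

    ``trl_same_strand`` fixes the orientation-label convention: when True an
    event whose fingerprint maps on the protospacer strand is labeled T-RL
    (right end proximal to the target), otherwise T-LR; the switch flips the
    labels for systems documented the other way around.
    """

    end_seq: str = DEFAULT_END_SEQ
    flank_len: int = 17
    min_q: int = 20
    max_lowq_frac: float = 0.5
    tsd_len: int = 5
    ontarget_window: int = 100
    end_max_mismatch: int = 0
    trl_same_strand: bool = True

    def __post_init__(self) -> None:
        if self.flank_len < 1:
            raise ValueError("flank_len must be >= 1")
        if not 0.0 <= self.max_lowq_frac <= 1.0:
            raise ValueError("max_lowq_frac must be in [0, 1]")
        if self.tsd_len < 1:
            raise ValueError("tsd_len must be >= 1")
        if self.end_max_mismatch < 0:
            raise ValueError("end_max_mismatch must be >= 0")


@dataclass(frozen=True)
class TargetSite:
    """The 32-nt protospacer interval targeted by a guide.

    ``start``/``end`` are 0-based half-open on the fwd strand; ``strand`` is
    the strand whose 5'->3' reading gives the protospacer sequence.
    """

    contig_id: str
    start: int
    end: int
    strand: str = FWD

    def __post_init__(self) -> None:
        if self.end - self.start != 32:
            raise ValueError("protospacer interval must be 32 bases")
        if self.strand not in (FWD, REV):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def three_prime_end(self) -> int:
        """0-based fwd-strand coordinate just past the protospacer 3' end."""
        return self.end if self.strand == FWD else self.start


@dataclass(frozen=True)
class FingerprintHit:
    """Mapping outcome of one read's 17-bp genomic fingerprint."""

    read_id: str
    category: str
    contig_id: str | None = None
    fwd_start: int | None = None
    map_strand: str | None = None


@dataclass(frozen=True)
class IntegrationEvent:
    """One deduplicated insertion call.

    ``position`` is 1-based: the fifth TSD base on the fwd strand.
    ``orientation`` and ``on_target`` are None until classified against a
    target site.
    """

    contig_id: str
    position: int
    strand: str
    read_count: int
    orientation: str | None = None
    on_target: bool | None = None

    @property
    def unique_site_key(self) -> tuple:
        return (self.contig_id, self.position, self.strand, self.orientation)


@dataclass
class SampleStats:
    """Per-sample read accounting and integration summary.

    ``totals`` conserves reads: raw_reads = qc_fail + no_end + short_flank +
    multi + unmapped + donor_vector + fingerprint_mapped_unique.
    ``specificity_pct`` is None when no uniquely mapped reads exist.
    """

    sample_id: str
    totals: dict[str, int]
    events: list[IntegrationEvent]
    ontarget_reads: int
    untargeted_reads: int
    specificity_pct: float | None
    unique_sites: int
    normalized: dict[tuple, float] | None = None
    scale_reference: int | None = None

    @property
    def end_containing(self) -> int:
        return self.totals["end_containing"]


# ---------------------------------------------------------------------------
# read-level operations
# ---------------------------------------------------------------------------

def passes_quality(read: ReadRecord, params: TnseqParams = TnseqParams()) -> bool:
    """Quality filter: fail when >= ``max_lowq_frac`` of bases are below Q20.

    The boundary case (exactly half the bases low-quality at defaults) fails,
    and an empty read fails.
    """
    n = len(read)
    if n == 0:
        return False
    n_low = int(np.count_nonzero(read.qualities < params.min_q))
    return n_low / n < params.max_lowq_frac


def phred_error_prob(q: float) -> float:
    """Per-base miscall probability for a Phred score: 10^(-q/10).

    Q=20 is exactly a 1% miscall probability.
    """
    if q < 0:
        raise ValueError(f"Phred score must be >= 0, got {q}")
    return 10.0 ** (-q / 10.0)


def _find_end(seq: str, params: TnseqParams) -> int:
    """Offset of the first occurrence of the transposon end in ``seq``, or -1.

    With ``end_max_mismatch`` > 0 the first window within that Hamming
    distance wins (ungapped).
    """
    if params.end_max_mismatch == 0:
        return seq.find(params.end_seq)
    end = params.end_seq
    m = len(end)
    limit = params.end_max_mismatch
    for i in range(len(seq) - m + 1):
        mism = 0
        window = seq[i : i + m]
        for a, b in zip(window, end):
            if a != b:
                mism += 1
                if mism > limit:
                    break
        else:
            return i
    return -1


def extract_fingerprint(
    read: ReadRecord | str, params: TnseqParams = TnseqParams()
) -> str | None:
    """The ``flank_len`` genomic bases immediately 3' of the transposon end.

    Returns None when the end sequence is absent or fewer than ``flank_len``
    bases follow it. The first end occurrence is used. A read with a
    returned fingerprint counts as transposon-end containing.
    """
    seq = read if isinstance(read, str) else read.sequence
    pos = _find_end(seq, params)
    if pos < 0:
        return None
    flank = seq[pos + len(params.end_seq) : pos + len(params.end_seq) + params.flank_len]
    if len(flank) < params.flank_len:
        return None
    return flank


def locate_fingerprint(
    genome_index: KmerIndex,
    vector_index: KmerIndex | None,
    fingerprint: str,
    read_id: str = "",
) -> FingerprintHit:
    """Map a fingerprint by exact both-strand lookup.

    Exactly one perfect genome occurrence -> ``unique`` (with coordinates);
    more than one -> ``multi``; none, but present in the vector -> ``vector``
    (donor contamination); otherwise ``unmapped``.
    """
    hits = genome_index.lookup(fingerprint)
    if len(hits) == 1:
        cid, start, strand = hits[0]
        return FingerprintHit(read_id, CAT_UNIQUE, cid, start, strand)
    if len(hits) > 1:
        return FingerprintHit(read_id, CAT_MULTI)
    if vector_index is not None and vector_index.lookup(fingerprint):
        return FingerprintHit(read_id, CAT_VECTOR)
    return FingerprintHit(read_id, CAT_UNMAPPED)


# ---------------------------------------------------------------------------
# event calling and classification
# ---------------------------------------------------------------------------

def call_events(
    hits: Iterable[FingerprintHit], params: TnseqParams = TnseqParams()
) -> list[IntegrationEvent]:
    """Collapse uniquely mapped fingerprints into deduplicated events.

    The event position is the fifth TSD base in 1-based fwd-strand
    coordinates. The right-end genomic flank begins with one TSD copy, so a
    fwd-mapping fingerprint at 0-based ``p`` gives position ``p + tsd_len``,
    and a rev-mapping fingerprint over fwd interval ``[p, p + flank_len)``
    gives ``p + flank_len`` — the two junction orientations of one insertion
    therefore coincide. Reads sharing (contig, position, strand) merge with
    summed read counts.
    """
    counts: dict[tuple[str, int, str], int] = {}
    for hit in hits:
        if hit.category != CAT_UNIQUE:
            raise ValueError(
                f"call_events requires unique hits; read {hit.read_id!r} is "
                f"{hit.category!r}"
            )
        if hit.map_strand == FWD:
            pos = hit.fwd_start + params.tsd_len
        else:
            pos = hit.fwd_start + params.flank_len
        key = (hit.contig_id, pos, hit.map_strand)
        counts[key] = counts.get(key, 0) + 1
    return [
        IntegrationEvent(contig_id=c, position=p, strand=s, read_count=n)
        for (c, p, s), n in sorted(counts.items())
    ]


def classify_event(
    event: IntegrationEvent, site: TargetSite, params: TnseqParams = TnseqParams()
) -> IntegrationEvent:
    """Label an event on/off target and with its orientation.

    On-target: the event position falls within the half-open
    ``ontarget_window`` starting at the protospacer 3' end, measured along
    the protospacer strand. Orientation: T-RL when the fingerprint mapped on
    the protospacer strand (convention switch ``trl_same_strand``).
    """
    pos0 = event.position - 1
    on = False
    if event.contig_id == site.contig_id:
        if site.strand == FWD:
            on = site.end <= pos0 < site.end + params.ontarget_window
        else:
            on = site.start - params.ontarget_window <= pos0 < site.start
    same = event.strand == site.strand
    orientation = T_RL if same == params.trl_same_strand else T_LR
    return replace(event, on_target=on, orientation=orientation)


def summarize_sample(
    events: Sequence[IntegrationEvent],
    totals: dict[str, int],
    sample_id: str = "",
) -> SampleStats:
    """Aggregate classified events and read-accounting totals for one sample.

    Specificity is 100 * on-target reads / uniquely mapped reads; with zero
    mapped reads it is undefined (None, written as "NA").
    """
    on = sum(e.read_count for e in events if e.on_target)
    off = sum(e.read_count for e in events if not e.on_target)
    spec = 100.0 * on / (on + off) if (on + off) > 0 else None
    return SampleStats(
        sample_id=sample_id,
        totals=dict(totals),
        events=list(events),
        ontarget_reads=on,
        untargeted_reads=off,
        specificity_pct=spec,
        unique_sites=len({e.unique_site_key for e in events}),
    )


def normalize_across_samples(stats: Sequence[SampleStats]) -> list[SampleStats]:
    """Depth-normalize site read counts across samples.

    Each site's raw count is divided by the sample's total transposon-end
    containing reads and scaled by the largest such total across samples, so
    the deepest sample's normalized values equal its raw counts. A sample
    with zero end-containing reads gets no normalized values (None).
    """
    if not stats:
        raise ValueError("no samples to normalize")
    scale = max(s.end_containing for s in stats)
    if scale == 0:
        raise ValueError("no sample has transposon-end containing reads")
    out = []
    for s in stats:
        ec = s.end_containing
        if ec == 0:
            s.normalized = None
        else:
            s.normalized = {
                e.unique_site_key: e.read_count / ec * scale for e in s.events
            }
        s.scale_reference = scale
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# whole-sample driver
# ---------------------------------------------------------------------------

def analyze_sample(
    reads: Iterable[ReadRecord],
    genome_index: KmerIndex,
    vector_index: KmerIndex | None,
    site: TargetSite,
    params: TnseqParams = TnseqParams(),
    sample_id: str = "sample",
) -> SampleStats:
    """Run the full pipeline on one read pool.

    QC -> end detection -> fingerprint extraction -> exact-unique mapping ->
    event calling -> on-target/orientation classification -> summary. The
    returned totals conserve every raw read across the categories qc_fail,
    no_end, short_flank, multi, unmapped, donor_vector and
    fingerprint_mapped_unique.
    """
    totals = {
        "raw_reads": 0,
        "qc_fail": 0,
        "no_end": 0,
        "short_flank": 0,
        "end_containing": 0,
        "fingerprint_mapped_unique": 0,
        "multi": 0,
        "unmapped": 0,
        "donor_vector": 0,
    }
    unique_hits: list[FingerprintHit] = []
    end_len = len(params.end_seq)
    for read in reads:
        totals["raw_reads"] += 1
        if not passes_quality(read, params):
            totals["qc_fail"] += 1
            continue
        pos = _find_end(read.sequence, params)
        if pos < 0:
            totals["no_end"] += 1
            continue
        flank = read.sequence[pos + end_len : pos + end_len + params.flank_len]
        if len(flank) < params.flank_len:
            totals["short_flank"] += 1
            continue
        totals["end_containing"] += 1
        hit = locate_fingerprint(genome_index, vector_index, flank, read.read_id)
        if hit.category == CAT_UNIQUE:
            totals["fingerprint_mapped_unique"] += 1
            unique_hits.append(hit)
        elif hit.category == CAT_MULTI:
            totals["multi"] += 1
        elif hit.category == CAT_VECTOR:
            totals["donor_vector"] += 1
        else:
            totals["unmapped"] += 1
    events = [classify_event(e, site, params) for e in call_events(unique_hits, params)]
    return summarize_sample(events, totals, sample_id)
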