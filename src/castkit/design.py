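"""Guide spacer design for Type I-F CRISPR-associated transposases.

The pipeline enumerates every 34-bp k-mer carrying a 5'-CN PAM on either
strand of a genome or metagenome, keeps only k-mers that occur exactly once
genome-wide (counted at 100% identity on both strands), and then removes
candidates with mismatch-bounded off-target matches of the 32-nt spacer.
Spacer positions that do not base-pair inside the Cascade R-loop ("flexible
bases", every 6th position from the PAM-proximal end) are masked to N and
excluded from the off-target mismatch count.

No scoring or ranking is applied: passing candidates are reported in genomic
order, grouped into tiling windows so a user can confirm each window of the
target region retains enough guides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .refio import FWD, REV, KmerIndex, Reference, build_kmer_index, encode, revcomp

__all__ = [
    "DesignParams",
    "SpacerCandidate",
    "OfftargetHit",
    "DesignReport",
    "enumerate_candidates",
    "classify_uniqueness",
    "masked_positions",
    "mask_flexible_positions",
    "find_offtargets",
    "design",
]

STATUS_SINGLE = "single"
STATUS_MULTI = "multi"
STATUS_REMOVED = "removed_offtarget"
STATUS_PASS = "pass"


@dataclass(frozen=True)
class DesignParams:
    """Tunable parameters of the spacer-design pipeline.

    ``pam`` is read 5'->3' immediately 5' of the protospacer; ``N`` in the
    pattern matches any of A/C/G/T (but not reference N). ``flexible_period``
    masks every that-many-th spacer position counted 1-based from the
    PAM-proximal end; ``extra_masked_positions`` (1-based) adds to the mask.
    """

    kmer_len: int = 34
    spacer_len: int = 32
    pam: str = "CN"
    flexible_period: int = 6
    max_mismatch: int = 3
    window_len: int = 1000
    require_pam_at_offtarget: bool = False
    extra_masked_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kmer_len != self.spacer_len + len(self.pam):
            raise ValueError("kmer_len must equal spacer_len + len(pam)")
        if self.flexible_period < 2:
            raise ValueError("flexible_period must be >= 2")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if any(p < 1 or p > self.spacer_len for p in self.extra_masked_positions):
            raise ValueError("extra_masked_positions must be within the spacer")


@dataclass
class SpacerCandidate:
    """One PAM-bearing k-mer: a 32-nt protospacer plus its 2-nt PAM.

    ``protospacer_start`` is the 0-based fwd-strand offset of the 32-nt
    protospacer interval regardless of strand; ``kmer``, ``protospacer_seq``
    and ``pam_seq`` are written 5'->3' on the candidate's own strand.
    """

    contig_id: str
    protospacer_start: int
    strand: str
    protospacer_seq: str
    pam_seq: str
    kmer: str
    occurrence_count: int | None = None
    offtarget_hits: list["OfftargetHit"] = field(default_factory=list)
    status: str | None = None

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity of the candidate's own locus: (contig, start, strand)."""
        return (self.contig_id, self.protospacer_start, self.strand)


@dataclass(frozen=True)
class OfftargetHit:
    """A mismatch-bounded match of the masked spacer away from its own locus.

    ``start`` is the 0-based fwd-strand offset of the matched 32-base
    interval; ``mismatches`` counts unmasked positions only.
    """

    contig_id: str
    start: int
    strand: str
    mismatches: int


@dataclass
class DesignReport:
    """Full output of :func:`design`: all candidates plus per-window tallies.

    ``windows`` holds ``(contig_id, start, end, n_passing)`` with 0-based
    half-open coordinates; windows with no passing candidate are echoed in
    ``warnings``.
    """

    candidates: list[SpacerCandidate]
    windows: list[tuple[str, int, int, int]]
    warnings: list[str]
    params: DesignParams

    @property
    def passing(self) -> list[SpacerCandidate]:
        return [c for c in self.candidates if c.status == STATUS_PASS]


def _pam_matches(observed: str, pattern: str) -> bool:
    return len(observed) == len(pattern) and all(
        p == "N" and o in "ACGT" or p == o for p, o in zip(pattern, observed)
    )


def _resolve_region(
    ref: Reference, region: tuple[str, int, int] | None
) -> list[tuple[str, int, int]]:
    if region is None:
        return [(cid, 0, len(seq)) for cid, seq in ref]
    cid, start, end = region
    seq = ref.sequence(cid)  # KeyError for unknown contig
    if not (0 <= start < end <= len(seq)):
        raise ValueError(
            f"region {cid}:{start}-{end} outside contig bounds (length {len(seq)})"
        )
    return [(cid, start, end)]


def enumerate_candidates(
    ref: Reference,
    region: tuple[str, int, int] | None = None,
    params: DesignParams = DesignParams(),
) -> list[SpacerCandidate]:
    """Enumerate every PAM-bearing 34-mer on both strands of ``region``.

    ``region`` is ``(contig_id, start, end)`` 0-based half-open, or ``None``
    for the whole reference. A k-mer qualifies on a strand when its first
    ``len(pam)`` bases (5' end on that strand) match the PAM pattern; the
    protospacer is the remainder. K-mers containing reference N are skipped.
    Overlapping candidates are all reported.
    """
    k = params.kmer_len
    npam = len(params.pam)
    out: list[SpacerCandidate] = []
    for cid, start, end in _resolve_region(ref, region):
        seq = ref.sequence(cid)
        for i in range(start, end - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            if _pam_matches(kmer[:npam], params.pam):
                out.append(
                    SpacerCandidate(
                        contig_id=cid,
                        protospacer_start=i + npam,
                        strand=FWD,
                        protospacer_seq=kmer[npam:],
                        pam_seq=kmer[:npam],
                        kmer=kmer,
                    )
                )
            rc = revcomp(kmer)
            if _pam_matches(rc[:npam], params.pam):
                out.append(
                    SpacerCandidate(
                        contig_id=cid,
                        protospacer_start=i,
                        strand=REV,
                        protospacer_seq=rc[npam:],
                        pam_seq=rc[:npam],
                        kmer=rc,
                    )
                )
    return out


def classify_uniqueness(
    index: KmerIndex, candidates: Iterable[SpacerCandidate], params: DesignParams = DesignParams()
) -> list[SpacerCandidate]:
    """Count exact genome-wide occurrences of each candidate's full k-mer.

    Occurrences are counted at 100% identity on both strands over the whole
    reference the index was built from; count 1 -> ``single``, else
    ``multi``. The index must have been built with k = ``kmer_len``.
    """
    if index.k != params.kmer_len:
        raise ValueError(f"index k={index.k} != kmer_len={params.kmer_len}")
    out = []
    for cand in candidates:
        n = index.occurrence_count(cand.kmer)
        cand.occurrence_count = n
        cand.status = STATUS_SINGLE if n == 1 else STATUS_MULTI
        out.append(cand)
    return out


def masked_positions(params: DesignParams = DesignParams()) -> tuple[int, ...]:
    """0-based spacer indices masked to N (flexible bases plus extras).

    Flexible bases sit at every ``flexible_period``-th position counted
    1-based from the PAM-proximal (5') end of the spacer: positions
    6, 12, 18, 24, 30 at defaults.
    """
    flex = range(params.flexible_period, params.spacer_len + 1, params.flexible_period)
    return tuple(sorted({p - 1 for p in flex} | {p - 1 for p in params.extra_masked_positions}))


def mask_flexible_positions(
    protospacer_seq: str, params: DesignParams = DesignParams()
) -> str:
    """Replace flexible spacer positions with N (idempotent)."""
    if len(protospacer_seq) != params.spacer_len:
        raise ValueError(
            f"sequence length {len(protospacer_seq)} != spacer_len {params.spacer_len}"
        )
    chars = list(protospacer_seq)
    for i in masked_positions(params):
        chars[i] = "N"
    return "".join(chars)


class _GenomeScan:
    """Precomputed sliding windows of a reference for the off-target scan."""

    def __init__(self, ref: Reference, width: int):
        self.width = width
        self.contigs: list[tuple[str, np.ndarray, np.ndarray]] = []
        for cid, seq in ref:
            if len(seq) < width:
                continue
            codes = encode(seq)
            self.contigs.append((cid, codes, sliding_window_view(codes, width)))


def _scan_one_strand(
    windows: np.ndarray, spacer_codes: np.ndarray, unmasked: np.ndarray, limit: int
) -> np.ndarray:
    """Positions whose unmasked mismatch count vs ``spacer_codes`` is <= limit.

    Reference N (code 4) never equals a concrete base code, so it mismatches
    at every unmasked position, as required.
    """
    mism = (windows[:, unmasked] != spacer_codes[unmasked]).sum(axis=1)
    return np.nonzero(mism <= limit)[0], mism


def find_offtargets(
    ref: Reference,
    candidate: SpacerCandidate,
    params: DesignParams = DesignParams(),
    scan: "_GenomeScan | None" = None,
) -> list[OfftargetHit]:
    """Genome-wide mismatch-bounded matches of the masked 32-nt spacer.

    The spacer is masked (:func:`mask_flexible_positions`) and slid over both
    strands of the whole reference; any locus other than the candidate's own
    with <= ``max_mismatch`` mismatches at unmasked positions is a hit. With
    ``require_pam_at_offtarget`` a hit must additionally carry a 5'-CN
    context on its own strand. The search is ungapped.
    """
    if scan is None:
        scan = _GenomeScan(ref, params.spacer_len)
    width = params.spacer_len
    masked = mask_flexible_positions(candidate.protospacer_seq, params)
    masked_rc = revcomp(masked)
    sp_f = encode(masked)
    sp_r = encode(masked_rc)
    unm_f = np.nonzero(sp_f != 4)[0]
    unm_r = np.nonzero(sp_r != 4)[0]

    hits: list[OfftargetHit] = []
    for cid, codes, windows in scan.contigs:
        L = len(codes)
        for strand, sp, unm in ((FWD, sp_f, unm_f), (REV, sp_r, unm_r)):
            pos, mism = _scan_one_strand(windows, sp, unm, params.max_mismatch)
            for j in map(int, pos):
                if (cid, j, strand) == candidate.key:
                    continue
                if params.require_pam_at_offtarget:
                    if strand == FWD:
                        # PAM occupies [j-2, j) on fwd; first base must be C
                        if j < len(params.pam) or codes[j - len(params.pam)] != 1:
                            continue
                    else:
                        # PAM on rev strand: fwd base just past the interval
                        # must be G (= C on the rev strand)
                        if j + width + len(params.pam) > L or codes[j + width + len(params.pam) - 1] != 2:
                            continue
                hits.append(OfftargetHit(cid, j, strand, int(mism[j])))
    hits.sort(key=lambda h: (h.contig_id, h.start, h.strand))
    return hits


def design(
    ref: Reference,
    region: tuple[str, int, int] | None = None,
    params: DesignParams = DesignParams(),
) -> DesignReport:
    """Run the full design pipeline over ``region`` of ``ref``.

    Stages: enumerate PAM-bearing k-mers -> count exact genome-wide
    occurrences (multi-mapping candidates are set aside) -> masked
    off-target search (candidates with any disqualifying hit are removed).
    Survivors get status ``pass`` and are tallied into non-overlapping
    ``window_len`` windows tiling the region; empty windows produce warnings,
    not errors.
    """
    candidates = enumerate_candidates(ref, region, params)
    index = build_kmer_index(ref, params.kmer_len)
    candidates = classify_uniqueness(index, candidates, params)

    scan = _GenomeScan(ref, params.spacer_len)
    for cand in candidates:
        if cand.status != STATUS_SINGLE:
            continue
        cand.offtarget_hits = find_offtargets(ref, cand, params, scan)
        cand.status = STATUS_REMOVED if cand.offtarget_hits else STATUS_PASS

    windows: list[tuple[str, int, int, int]] = []
    warnings: list[str] = []
    passing = [c for c in candidates if c.status == STATUS_PASS]
    for cid, start, end in _resolve_region(ref, region):
        for w in range(start, end, params.window_len):
            w_end = min(w + params.window_len, end)
            n = sum(
                1
                for c in passing
                if c.contig_id == cid and w <= c.protospacer_start < w_end
            )
            windows.append((cid, w, w_end, n))
            if n == 0:
                warnings.append(
                    f"no passing spacer in window {cid}:{w + 1}-{w_end} (1-based)"
                )
    return DesignReport(candidates=candidates, windows=windows, warnings=warnings, params=params)
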