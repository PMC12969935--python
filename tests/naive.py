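"""Independent brute-force reimplementations used as test oracles.

Everything here favors obviousness over speed: plain string scans of both
strands, explicit per-position mismatch counting, no indexes and no numpy.
These functions exist only to check the package; the package never imports
them.
"""

from castkit.refio import FWD, REV, Reference, revcomp

PAM_LEN = 2
KMER_LEN = 34
SPACER_LEN = 32


def naive_lookup(ref: Reference, kmer: str):
    """Both-strand occurrences of ``kmer`` by scanning every window."""
    k = len(kmer)
    hits = []
    for cid, seq in ref:
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if window == kmer:
                hits.append((cid, i, FWD))
            if revcomp(window) == kmer:
                hits.append((cid, i, REV))
    return hits


def naive_enumerate(ref: Reference):
    """All PAM-bearing 34-mers, scanning the fwd string and the rc string.

    Returns tuples (contig, protospacer_start, strand, pam, protospacer)
    with protospacer_start the 0-based fwd-strand offset of the 32-mer.
    """
    out = set()
    for cid, seq in ref:
        L = len(seq)
        for i in range(L - KMER_LEN + 1):
            kmer = seq[i : i + KMER_LEN]
            if "N" in kmer:
                continue
            if kmer[0] == "C":
                out.add((cid, i + PAM_LEN, FWD, kmer[:PAM_LEN], kmer[PAM_LEN:]))
        rc = revcomp(seq)
        for j in range(L - KMER_LEN + 1):
            kmer = rc[j : j + KMER_LEN]
            if "N" in kmer:
                continue
            if kmer[0] == "C":
                # rc index j covers fwd interval [L-j-34, L-j); the
                # protospacer is its first 32 fwd bases
                out.add((cid, L - j - KMER_LEN, REV, kmer[:PAM_LEN], kmer[PAM_LEN:]))
    return out


def naive_occurrences(ref: Reference, kmer: str) -> int:
    """Distinct loci of ``kmer`` on either strand (palindrome counts once)."""
    return len({(cid, i) for cid, i, _ in naive_lookup(ref, kmer)})


def naive_mask(spacer: str, period: int = 6) -> str:
    chars = list(spacer)
    for pos in range(period, len(spacer) + 1, period):
        chars[pos - 1] = "N"
    return "".join(chars)


def _mismatches(masked_spacer: str, window: str, limit: int) -> int:
    """Unmasked mismatch count, early-exiting past ``limit``."""
    mism = 0
    for a, b in zip(masked_spacer, window):
        if a != "N" and a != b:
            mism += 1
            if mism > limit:
                return mism
    return mism


def naive_offtargets(ref: Reference, candidate, max_mismatch: int = 3, period: int = 6):
    """Slide the masked spacer over every window of both strands.

    ``candidate`` is a castkit SpacerCandidate; returns a set of
    (contig, fwd_start, strand, mismatches) excluding the candidate's locus.
    Reference N mismatches every unmasked spacer base.
    """
    masked = naive_mask(candidate.protospacer_seq, period)
    hits = set()
    for cid, seq in ref:
        L = len(seq)
        for i in range(L - SPACER_LEN + 1):
            window = seq[i : i + SPACER_LEN]
            for strand, target in ((FWD, window), (REV, revcomp(window))):
                if (cid, i, strand) == (
                    candidate.contig_id,
                    candidate.protospacer_start,
                    candidate.strand,
                ):
                    continue
                m = _mismatches(masked, target, max_mismatch)
                if m <= max_mismatch:
                    hits.add((cid, i, strand, m))
    return hits


def naive_design_passing(ref: Reference, max_mismatch: int = 3, period: int = 6):
    """Full pipeline, brute force: enumerate -> count -> masked off-targets.

    Returns the passing set as (contig, protospacer_start, strand) keys.
    """
    from types import SimpleNamespace

    passing = set()
    for cid, ps, strand, pam, proto in naive_enumerate(ref):
        if naive_occurrences(ref, pam + proto) != 1:
            continue
        c = SimpleNamespace(
            contig_id=cid, protospacer_start=ps, strand=strand, protospacer_seq=proto
        )
        if not naive_offtargets(ref, c, max_mismatch, period):
            passing.add((cid, ps, strand))
    return passing
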