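"""Synthetic editing experiments with known ground truth.

Generates seeded random genomes with a planted unique protospacer (5'-CN
PAM), edited genomes carrying a payload integrated downstream of the
protospacer with a target-site duplication (TSD), junction-amplicon read
pools mixed with background genomic reads, and replicate qPCR measurements —
everything the analysis modules consume, with truth tables to score against.

Insertion geometry: for a TSD starting at 0-based ``t`` the edited contig is
``G[:t+tsd] + TN + G[t:]`` (or the reverse complement of the transposon for
the flipped orientation), so both junction orientations place the event at
1-based position ``t + tsd_len`` — the fifth TSD base at defaults. Junction
reads start inside the transposon right end: the last 20 bases of the right
end followed by the adjacent genomic flank, optionally preceded by a few
extra right-end bases to model tagmentation start heterogeneity.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .refio import FWD, REV, ReadRecord, Reference, decode, encode, revcomp
from .tnseq import DEFAULT_END_SEQ, T_LR, T_RL, TargetSite
from .quantify import QpcrMeasurement

__all__ = [
    "SimConfig",
    "TrueInsertion",
    "EditedGenome",
    "simulate_reference",
    "simulate_edited_genome",
    "simulate_read_pool",
    "simulate_qpcr",
]

_COMP_CODES = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one synthetic editing experiment.

    ``edited_fraction`` is the fraction of genome templates carrying the
    insertion; in a junction-amplicon pool it doubles as the default
    ``junction_read_frac`` when the latter is left unset.
    ``orientation_prob_TRL`` is the probability that the on-target insertion
    is in T-RL orientation (fingerprint mapping on the protospacer strand).
    ``offtarget_sites`` lists extra insertions as (contig_id, 1-based event
    position, map strand).
    """

    seed: int = 0
    genome_len: int = 100_000
    n_contigs: int = 1
    gc: float = 0.5
    protospacer_contig: str | None = None
    protospacer_start: int | None = None
    protospacer_strand: str = FWD
    payload_len: int = 500
    insertion_offset: int = 49
    orientation_prob_TRL: float = 1.0
    tsd_len: int = 5
    edited_fraction: float = 0.01
    n_reads: int = 100_000
    read_len: int = 150
    junction_read_frac: float | None = None
    error_rate: float = 0.001
    lowq_read_frac: float = 0.0
    tagmentation_offset_max: int = 0
    end_seq: str = DEFAULT_END_SEQ
    offtarget_sites: tuple[tuple[str, int, str], ...] = ()

    def __post_init__(self) -> None:
        for name in ("gc", "orientation_prob_TRL", "edited_fraction",
                     "error_rate", "lowq_read_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.junction_read_frac is not None and not 0.0 <= self.junction_read_frac <= 1.0:
            raise ValueError("junction_read_frac must be in [0, 1]")
        if self.genome_len < 200:
            raise ValueError("genome_len must be >= 200")
        if self.payload_len < len(self.end_seq) + self.tagmentation_offset_max:
            raise ValueError("payload_len too short for the right-end sequence")
        if self.tsd_len < 1:
            raise ValueError("tsd_len must be >= 1")

    @property
    def resolved_junction_frac(self) -> float:
        return (
            self.edited_fraction
            if self.junction_read_frac is None
            else self.junction_read_frac
        )


@dataclass(frozen=True)
class TrueInsertion:
    """Ground truth for one planted insertion.

    ``position`` is the 1-based fifth-TSD-base coordinate the pipeline must
    recover; ``strand`` is the strand its junction fingerprint maps on, and
    ``orientation`` the label under the default convention (T-RL when the
    map strand equals the protospacer strand).
    """

    contig_id: str
    tsd_start: int
    position: int
    strand: str
    orientation: str


@dataclass(frozen=True)
class EditedGenome:
    """An edited reference plus its ground truth and junction templates."""

    reference: Reference
    insertions: tuple[TrueInsertion, ...]
    junction_templates: tuple[str, ...]
    transposon: str


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stage])


def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    return rng.choice(4, size=n, p=[at, gc / 2.0, gc / 2.0, at]).astype(np.uint8)


def _count_loci(ref: Reference, kmer: str) -> int:
    """Distinct both-strand loci of ``kmer`` by exhaustive string search."""
    loci = set()
    for query, tag in ((kmer, FWD), (revcomp(kmer), REV)):
        for cid, seq in ref:
            start = seq.find(query)
            while start >= 0:
                loci.add((cid, start))
                start = seq.find(query, start + 1)
    return len(loci)


def simulate_reference(cfg: SimConfig) -> tuple[Reference, TargetSite]:
    """Seeded random genome with a planted, genome-unique protospacer.

    Contigs split ``genome_len`` evenly. The protospacer (32 nt) is planted
    at the configured locus (default: middle of the first contig, fwd
    strand) with its 5'-CN PAM; uniqueness of the planted 32-mer is verified
    by exact both-strand search, redrawing the protospacer if needed.
    """
    rng = _rng(cfg.seed, 0)
    lengths = [cfg.genome_len // cfg.n_contigs] * cfg.n_contigs
    lengths[-1] += cfg.genome_len - sum(lengths)
    names = [f"contig{i + 1}" for i in range(cfg.n_contigs)]
    codes = {name: _random_codes(rng, n, cfg.gc) for name, n in zip(names, lengths)}

    cid = cfg.protospacer_contig or names[0]
    contig_len = len(codes[cid])
    s = cfg.protospacer_start
    if s is None:
        s = contig_len // 2
    strand = cfg.protospacer_strand
    if strand == FWD and not 2 <= s <= contig_len - 32:
        raise ValueError("protospacer (with PAM) out of contig bounds")
    if strand == REV and not 0 <= s <= contig_len - 34:
        raise ValueError("protospacer (with PAM) out of contig bounds")

    for _ in range(50):
        proto = decode(_random_codes(rng, 32, cfg.gc))
        arr = codes[cid].copy()
        if strand == FWD:
            arr[s - 2] = 1  # C
            arr[s - 1] = rng.integers(0, 4)
            arr[s : s + 32] = encode(proto)
        else:
            arr[s : s + 32] = encode(revcomp(proto))
            arr[s + 32] = rng.integers(0, 4)
            arr[s + 33] = 2  # G on fwd = C on the protospacer strand
        trial = {**codes, cid: arr}
        ref = Reference([(n, decode(trial[n])) for n in names])
        if _count_loci(ref, proto) == 1:
            return ref, TargetSite(contig_id=cid, start=s, end=s + 32, strand=strand)
    raise RuntimeError("could not place a unique protospacer after 50 attempts")


def _ontarget_tsd_start(site: TargetSite, cfg: SimConfig) -> int:
    if site.strand == FWD:
        return site.end + cfg.insertion_offset
    return site.start - cfg.insertion_offset - cfg.tsd_len


def simulate_edited_genome(
    ref: Reference, site: TargetSite, cfg: SimConfig
) -> EditedGenome:
    """Insert the payload at the target (plus any configured extra sites).

    The transposon is a random cargo ending in the 20-nt right-end sequence;
    its orientation at the target is drawn from ``orientation_prob_TRL``.
    The edited contig grows by ``payload_len + tsd_len`` per insertion.
    Junction templates (right-end tail + genomic flank, read orientation)
    are precomputed for the read simulator; insertions must be at least
    ``read_len`` apart and clear of contig edges so templates are exact.
    """
    rng = _rng(cfg.seed, 1)
    cargo = decode(_random_codes(rng, cfg.payload_len - len(cfg.end_seq), cfg.gc))
    transposon = cargo + cfg.end_seq

    insertions: list[tuple[str, int, str]] = []  # (contig, tsd_start, map_strand)
    t0 = _ontarget_tsd_start(site, cfg)
    is_trl = bool(rng.random() < cfg.orientation_prob_TRL)
    map_strand = site.strand if is_trl else (REV if site.strand == FWD else FWD)
    insertions.append((site.contig_id, t0, map_strand))
    for ocid, pos, ostrand in cfg.offtarget_sites:
        insertions.append((ocid, pos - cfg.tsd_len, ostrand))

    tsd = cfg.tsd_len
    rl = cfg.read_len
    maxoff = cfg.tagmentation_offset_max
    prefix = transposon[-(len(cfg.end_seq) + maxoff) : -len(cfg.end_seq)] if maxoff else ""

    truths: list[TrueInsertion] = []
    templates: list[str] = []
    by_contig: dict[str, list[tuple[int, bool]]] = {}
    for cid, t, mstrand in insertions:
        seq = ref.sequence(cid)
        flip = mstrand == REV
        if not flip and not (0 <= t and t + tsd + rl <= len(seq)):
            raise ValueError(f"insertion at {cid}:{t} too close to contig edge")
        if flip and not (rl <= t + tsd and t + tsd <= len(seq)):
            raise ValueError(f"insertion at {cid}:{t} too close to contig edge")
        orientation = (
            T_RL if (mstrand == site.strand) else T_LR
        )
        truths.append(
            TrueInsertion(
                contig_id=cid,
                tsd_start=t,
                position=t + tsd,
                strand=mstrand,
                orientation=orientation,
            )
        )
        if flip:
            flank = revcomp(seq[t + tsd - rl : t + tsd])
        else:
            flank = seq[t : t + rl]
        templates.append(prefix + cfg.end_seq + flank)
        by_contig.setdefault(cid, []).append((t, flip))

    for cid, items in by_contig.items():
        starts = sorted(t for t, _ in items)
        for a, b in zip(starts, starts[1:]):
            if b - a < rl + tsd:
                raise ValueError("insertions closer than read_len are not supported")

    edited_contigs = []
    for cid, seq in ref:
        for t, flip in sorted(by_contig.get(cid, []), reverse=True):
            tn = revcomp(transposon) if flip else transposon
            seq = seq[: t + tsd] + tn + seq[t:]
        edited_contigs.append((cid, seq))

    return EditedGenome(
        reference=Reference(edited_contigs),
        insertions=tuple(truths),
        junction_templates=tuple(templates),
        transposon=transposon,
    )


def _quality_arrays(read_len: int) -> tuple[np.ndarray, np.ndarray]:
    good = np.full(read_len, 37, dtype=np.uint8)
    bad = good.copy()
    bad[: math.ceil(read_len / 2)] = 10  # >= half the bases below Q20 -> QC fail
    good.setflags(write=False)
    bad.setflags(write=False)
    return good, bad


def simulate_read_pool(
    wild: Reference,
    edited: EditedGenome,
    cfg: SimConfig,
    weights: Sequence[float] | None = None,
    fastq_path=None,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate a single-end amplicon read pool with a per-read truth table.

    Each read is independently a junction amplicon with probability
    ``junction_read_frac`` (default: ``edited_fraction``); junction reads are
    drawn from the edited genome's junction templates (uniformly, or by
    ``weights``), background reads uniformly from both strands of the wild
    genome. Substitution errors are applied at ``error_rate`` per base;
    a ``lowq_read_frac`` fraction of reads receives a low-quality block that
    fails the Q20/half rule, the rest constant Q37. Fully seeded: the same
    configuration yields byte-identical output. If ``fastq_path`` is given
    the pool is also written as Phred+33 FASTQ.

    Returns the reads plus a truth table with one row per read: ``read_id``,
    ``origin`` (junction/background), ``insertion`` (index into
    ``edited.insertions``, -1 for background) and ``lowq``.
    """
    rng = _rng(cfg.seed, 2)
    rl = cfg.read_len
    jfrac = cfg.resolved_junction_frac
    maxoff = cfg.tagmentation_offset_max

    contig_codes = [encode(seq) for _, seq in wild]
    n_pos = np.array([max(len(c) - rl + 1, 0) for c in contig_codes], dtype=np.int64)
    if n_pos.sum() == 0:
        raise ValueError("wild genome shorter than read_len")
    cum_pos = np.concatenate([[0], np.cumsum(n_pos)])

    tmpl_codes = np.stack([encode(t) for t in edited.junction_templates])
    n_templates = len(edited.junction_templates)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if len(w) != n_templates or w.sum() <= 0:
            raise ValueError("weights must match the number of insertions")
        w = w / w.sum()
    else:
        w = None

    good_q, bad_q = _quality_arrays(rl)
    base_lut = np.frombuffer(b"ACGT", dtype=np.uint8)

    reads: list[ReadRecord] = []
    origins = np.zeros(cfg.n_reads, dtype=np.int8)  # 0 background, 1 junction
    ins_idx = np.full(cfg.n_reads, -1, dtype=np.int32)
    lowq_all = np.zeros(cfg.n_reads, dtype=bool)

    chunk = 100_000
    col = np.arange(rl)
    for lo in range(0, cfg.n_reads, chunk):
        m = min(chunk, cfg.n_reads - lo)
        is_j = rng.random(m) < jfrac
        flat = rng.integers(0, cum_pos[-1], size=m)
        strands = rng.integers(0, 2, size=m)
        if w is None:
            tidx = rng.integers(0, n_templates, size=m)
        else:
            tidx = rng.choice(n_templates, size=m, p=w)
        offs = rng.integers(0, maxoff + 1, size=m)

        mat = np.empty((m, rl), dtype=np.uint8)
        bg = ~is_j
        if bg.any():
            f = flat[bg]
            ci = np.searchsorted(cum_pos, f, side="right") - 1
            local = f - cum_pos[ci]
            for c in np.unique(ci):
                sel = ci == c
                rows = contig_codes[c][local[sel][:, None] + col]
                mat[np.nonzero(bg)[0][sel]] = rows
            rev_rows = np.nonzero(bg & (strands == 1))[0]
            mat[rev_rows] = _COMP_CODES[mat[rev_rows][:, ::-1]]
        if is_j.any():
            ji = np.nonzero(is_j)[0]
            start = maxoff - offs[ji]
            mat[ji] = tmpl_codes[tidx[ji][:, None], start[:, None] + col]

        if cfg.error_rate > 0:
            err = rng.random((m, rl)) < cfg.error_rate
            n_err = int(err.sum())
            if n_err:
                mat[err] = (mat[err] + rng.integers(1, 4, size=n_err).astype(np.uint8)) % 4

        lowq = rng.random(m) < cfg.lowq_read_frac

        data = base_lut[mat].tobytes()
        for i in range(m):
            reads.append(
                ReadRecord(
                    read_id=f"r{lo + i}",
                    sequence=data[i * rl : (i + 1) * rl].decode("ascii"),
                    qualities=bad_q if lowq[i] else good_q,
                )
            )
        origins[lo : lo + m] = is_j
        ins_idx[lo : lo + m][is_j] = tidx[is_j]
        lowq_all[lo : lo + m] = lowq

    truth = pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "origin": pd.Categorical.from_codes(
                origins, categories=["background", "junction"]
            ),
            "insertion": ins_idx,
            "lowq": lowq_all,
        }
    )
    if fastq_path is not None:
        from .refio import write_fastq

        write_fastq(reads, fastq_path)
    return reads, truth


def simulate_qpcr(
    true_efficiency: float,
    sigma_cq: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
    cq_reference: float = 20.0,
    sample_id: str = "sim",
) -> list[QpcrMeasurement]:
    """Replicate Cq pairs consistent with a known transposition efficiency.

    dCq is drawn as -log2(efficiency/100) + Normal(0, sigma_cq); the
    reference gene Cq is held at a fixed baseline, so the junction Cq is
    ``cq_reference + dCq``.
    """
    if not 0.0 < true_efficiency <= 100.0:
        raise ValueError("true_efficiency must be in (0, 100]")
    rng = _rng(seed, 3)
    base = -math.log2(true_efficiency / 100.0)
    out = []
    for i in range(n_replicates):
        dcq = base + (rng.normal(0.0, sigma_cq) if sigma_cq > 0 else 0.0)
        out.append(
            QpcrMeasurement(
                sample_id=sample_id,
                cq_junction=cq_reference + dcq,
                cq_reference=cq_reference,
                replicate=i,
            )
        )
    return out
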