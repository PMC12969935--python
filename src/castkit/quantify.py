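"""Closed-form quantification of editing outcomes.

qPCR transposition efficiency, plasmid copy number, and plating-based
conjugation efficiency:

    transposition efficiency (%) = 2^-(Cq_junction - Cq_reference) * 100
    plasmid copy number          = 2^-(Cq_backbone - Cq_reference)
    conjugation efficiency       = selective CFU / non-selective CFU

The junction assay amplifies the T-RL integration product (forward primer in
the target flank, reverse primer in the payload); the reference assay is a
single-copy housekeeping gene (e.g. rpoB) of the target bacterium. A missing
Cq (no amplification) is censored — reported as below detection, never as
zero efficiency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Iterable, Sequence

__all__ = [
    "QpcrMeasurement",
    "PlateCounts",
    "EfficiencySummary",
    "transposition_efficiency",
    "summarize_replicates",
    "plasmid_copy_number",
    "conjugation_efficiency",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR replicate: junction and reference quantification cycles.

    ``cq_junction`` is None when the junction assay showed no amplification
    (below the detection limit).
    """

    sample_id: str
    cq_junction: float | None
    cq_reference: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.cq_junction is not None and not (
            math.isfinite(self.cq_junction) and self.cq_junction > 0
        ):
            raise ValueError("cq_junction must be finite and > 0 (or None)")
        if not (math.isfinite(self.cq_reference) and self.cq_reference > 0):
            raise ValueError("cq_reference must be finite and > 0")

    @property
    def delta_cq(self) -> float | None:
        if self.cq_junction is None:
            return None
        return self.cq_junction - self.cq_reference


@dataclass(frozen=True)
class PlateCounts:
    """Colony counts on selective vs non-selective media.

    ``dilution_*`` are fold-dilutions of the plated aliquot (10 means the
    plated material was diluted 10x), so the dilution-corrected abundance is
    count * dilution.
    """

    n_selective: int
    n_nonselective: int
    dilution_selective: float = 1.0
    dilution_nonselective: float = 1.0

    def __post_init__(self) -> None:
        if self.n_selective < 0 or self.n_nonselective < 0:
            raise ValueError("colony counts must be >= 0")
        if self.dilution_selective <= 0 or self.dilution_nonselective <= 0:
            raise ValueError("dilution factors must be > 0")


@dataclass(frozen=True)
class EfficiencySummary:
    """Replicate-set summary: mean +/- sd over detected replicates."""

    mean_pct: float | None
    sd_pct: float | None
    n_detected: int
    n_censored: int


def transposition_efficiency(m: QpcrMeasurement) -> float | None:
    """Editing efficiency in percent for one replicate.

    2^-dCq * 100 with dCq = Cq_junction - Cq_reference; equal cycles give
    exactly 100%. Returns None (below detection) when the junction assay did
    not amplify.
    """
    d = m.delta_cq
    if d is None:
        return None
    return 2.0 ** (-d) * 100.0


def summarize_replicates(
    measurements: Iterable[QpcrMeasurement], mode: str = "per_replicate"
) -> EfficiencySummary:
    """Aggregate technical replicates into mean +/- sd efficiency.

    ``per_replicate`` (default) transforms each replicate to an efficiency
    and averages those — honest about cycle-level variance. ``mean_cq``
    averages dCq first and transforms once. Censored replicates (no
    amplification) are excluded from the mean and counted separately.
    """
    detected = []
    n_censored = 0
    for m in measurements:
        d = m.delta_cq
        if d is None:
            n_censored += 1
        else:
            detected.append(d)
    if not detected:
        return EfficiencySummary(None, None, 0, n_censored)
    if mode == "per_replicate":
        effs = [2.0 ** (-d) * 100.0 for d in detected]
        mu = mean(effs)
        sd = stdev(effs) if len(effs) > 1 else 0.0
    elif mode == "mean_cq":
        mu = 2.0 ** (-mean(detected)) * 100.0
        sd = 0.0 if len(detected) < 2 else _mean_cq_sd(detected)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return EfficiencySummary(mu, sd, len(detected), n_censored)


def _mean_cq_sd(deltas: Sequence[float]) -> float:
    """Delta-method sd of 2^-mean(dCq)*100 from the sd of the mean dCq."""
    se = stdev(deltas) / math.sqrt(len(deltas))
    return 2.0 ** (-mean(deltas)) * 100.0 * math.log(2) * se


def plasmid_copy_number(cq_backbone: float, cq_reference: float) -> float:
    """Plasmid copies per chromosome: 2^-(Cq_backbone - Cq_reference).

    Same relative-quantification form as transposition efficiency but
    without the factor of 100; one cycle earlier backbone amplification
    doubles the copy number.
    """
    if not (math.isfinite(cq_backbone) and math.isfinite(cq_reference)):
        raise ValueError("Cq values must be finite")
    return 2.0 ** (-(cq_backbone - cq_reference))


def conjugation_efficiency(p: PlateCounts) -> float | None:
    """Transconjugant fraction: selective CFU over non-selective CFU.

    Counts are dilution-corrected before the ratio. Zero non-selective
    colonies leave the ratio undefined (None).
    """
    denom = p.n_nonselective * p.dilution_nonselective
    if denom == 0:
        return None
    return (p.n_selective * p.dilution_selective) / denom
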