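# Methods

This note documents the models, conventions and numerical choices behind
castkit, and what the synthetic-data generator does and does not emulate.

## Coordinates and sequence conventions

All library-internal coordinates are 0-based half-open; every writer emits
1-based inclusive coordinates and says so in its `#`-metadata header (BED
output is 0-based half-open per the BED convention). Sequences are uppercase
over {A, C, G, T, N}. N is reserved: in references it denotes ambiguity (it
is excluded from k-mer indexes and mismatches every unmasked spacer base in
the off-target scan); in spacers it marks masked positions. Other IUPAC
codes are rejected at load so masking semantics stay unambiguous.

## Guide design

The pipeline has three stages, deliberately kept separate because they
answer different questions:

1. **Enumeration.** Every 34-bp window on both strands whose first two bases
   (5′ on its own strand) match the CN PAM pattern yields a candidate; the
   remaining 32 nt are the protospacer. All overlapping candidates are
   reported; there is no scoring or ranking beyond genomic order.
2. **Uniqueness.** The *full 34-mer* (PAM included) is counted genome-wide
   at 100% identity on both strands using an exact k-mer index. Counting is
   per locus: a palindromic k-mer matching one locus on both strands counts
   once. Count ≠ 1 sets the candidate aside as multi-mapping.
3. **Off-target scan.** The 32-nt spacer (PAM excluded by default;
   `require_pam_at_offtarget` restores a CN requirement at hit loci) is
   masked at the flexible positions and slid, ungapped, over both strands of
   the whole reference. Any locus other than the candidate's own —
   identified by (contig, start, strand), so identical repeats elsewhere do
   count — with ≤ `max_mismatch` mismatches at unmasked positions removes
   the candidate.

Flexible positions are every `flexible_period`-th base counted 1-based from
the PAM-proximal end of the spacer: 6, 12, 18, 24, 30 at the defaults
(period 6, 32-nt spacer). PAM-proximal indexing matches Type I-F Cascade
R-loop geometry, where every sixth base is flipped out of the RNA–DNA
duplex; both the period and extra masked positions are parameters.

`max_mismatch` defaults to 3: small enough that random 32-mers essentially
never hit (the chance of ≤ 3 mismatches over 27 unmasked positions of a
random locus is astronomically small), strict enough that bona fide near
repeats disqualify a spacer. The search is ungapped — bulged off-targets are
out of scope, a documented divergence from aligner-based searches that
permit gaps.

Window tallies exist so a user can check each `window_len` (default 1000 bp)
stretch of the target region still has spacers after filtering; a window
with zero passing candidates is a warning, not an error, because sufficiency
thresholds are use-case dependent.

The scan is vectorized (numpy sliding windows over byte-encoded contigs);
the test suite checks it against a character-by-character brute-force
reimplementation for exact equality on random genomes.

## Integration-site mapping

**Quality rule.** A read fails QC when the fraction of bases with Q < 20 is
≥ 0.5 — "half the bases low-quality" removes the read, boundary inclusive.
Q20 corresponds to a 1% per-base miscall probability (p = 10^(−Q/10)).

**End detection and fingerprint.** The first occurrence of the 20-nt right
transposon-end tail in the read anchors the junction (nested PCR places the
end near the read start, so first-occurrence is the deterministic choice);
an exact match is required by default (`end_max_mismatch=0` maximizes
precision; a Hamming allowance is available). The 17 bases immediately 3′ of
the end are the genomic fingerprint; reads with an extracted fingerprint are
the sample's *transposon-end containing reads*. Mapping is an exact, unique,
both-strand 17-mer lookup — "perfect and only once" is precisely an
exact-unique index query, so no external aligner is involved. Fingerprints
absent from the genome but present in the donor vector are tallied as donor
contamination; running the same pipeline with the vector supplied as the
mapping reference measures self-targeting (integration into the vector
itself).

**Event coordinate.** An insertion with TSD starting at 0-based `t` in the
original genome produces the edited sequence `G[:t+tsd] + TN + G[t:]`; both
junction fingerprints therefore begin with one TSD copy. The event position
is the fifth TSD base (for `tsd_len=5`) in 1-based fwd-strand coordinates:

- fwd-mapping fingerprint at `p`: position = `p + tsd_len`;
- rev-mapping fingerprint over fwd interval `[p, p+17)`: position =
  `p + flank_len` (the interval's last fwd base).

These two formulas are the unique pair for which both junction orientations
of one physical insertion coincide at the same coordinate, which is the
contract the simulator round-trip tests enforce. `tsd_len` defaults to 5
(typical for VchCAST) and is a parameter.

**Orientation labels.** T-RL ⇔ the fingerprint maps on the protospacer
strand (right end proximal to the target); this matches a junction qPCR
design that captures T-RL with a target-flank forward primer and a payload
reverse primer. Because the literature is not uniform about the label
direction, `trl_same_strand=False` flips the mapping without touching any
coordinates.

**Classification and summary.** The on-target window is half-open:
`[protospacer 3′ end, +100)` measured along the protospacer strand.
Specificity is 100 × on-target / (on-target + untargeted) uniquely mapped
reads, undefined (reported "NA") when nothing mapped. Unique insertion sites
are deduplicated on (contig, position, strand, orientation). Read accounting
is conservative by construction: raw = qc_fail + no_end + short_flank +
multi + unmapped + donor_vector + unique, asserted in tests.

**Normalization.** normalized(site, s) = raw(site, s) / end_containing(s) ×
max_s end_containing — per-sample depth normalization scaled so the deepest
sample keeps its raw counts. A sample with zero end-containing reads gets
missing (not zero) normalized values.

## qPCR and plating quantification

Efficiency = 2^−ΔCq × 100 with ΔCq = Cq_junction − Cq_reference (single Δ;
one cycle of delay exactly halves the estimate). Copy number drops the ×100.
Replicates are aggregated per-replicate-then-mean by default, which is
honest about cycle-level variance; averaging Cq before transforming
(`mean_cq`) is also available and gives the geometric-mean-style estimate
(strictly smaller, by Jensen's inequality). No amplification is censored —
"below detection" — because a missing Cq bounds the efficiency from above
rather than measuring zero. Conjugation efficiency divides
dilution-corrected selective by non-selective CFU; zero non-selective
colonies make it undefined rather than infinite.

## The simulator: what it emulates, and what it does not

`simulate_reference` draws an i.i.d. genome at a configurable GC content and
plants a single 32-nt protospacer with its CN PAM, verifying genome-wide
uniqueness by exhaustive search (redrawing on collision).
`simulate_edited_genome` inserts a random-cargo transposon ending in the
20-nt right-end tail, with the TSD duplication geometry above, at the target
(orientation drawn from `orientation_prob_TRL`) plus any configured
untargeted loci; ground truth records exactly the (position, strand,
orientation) triple the pipeline must recover. `simulate_read_pool` emits
single-end reads (150 nt default): each read is independently a junction
amplicon (right-end tail + genomic flank, optionally offset 0–10 nt into the
end to model tagmentation start heterogeneity) or a uniform background
genomic read, with i.i.d. substitution errors and a configurable fraction of
QC-failing reads (low-quality block covering half the read; passing reads
are constant Q37 — deterministic, and exactly on either side of the QC
rule). `simulate_qpcr` inverts the efficiency formula with Gaussian cycle
noise.

Defaults mirror the assay geometry: `insertion_offset=49` places the
simulated event 54 bp after the protospacer, comfortably inside the 100-bp
on-target window (the window is specified; the precise offset within it is
free, so one value was fixed once for unambiguous truth); `tsd_len=5`;
`read_len=150`; `error_rate=0.001` (≈Q30 sequencing); `edited_fraction`
doubles as the junction-read fraction of an amplicon pool unless overridden.

Deliberately **not** modeled: indel errors, quality–error coupling beyond
the pass/fail dichotomy, PCR duplicates and amplification bias, tagmentation
sequence bias, left-end junction libraries, and structural variation between
the reference and the edited strain. Consequently, passing round-trip tests
demonstrates the correctness of the coordinate arithmetic, classification,
accounting and normalization — not robustness to real-library artifacts such
as chimeric reads or reference gaps.

Problem sizes in the tests and the acceptance script were chosen to exercise
the claims at full fidelity while staying desk-scale: detection-limit runs
use 10^6 reads over a 100-kb genome (the smallest tested junction fraction,
10⁻⁵, still leaves ~10 junction reads in expectation, of which ~96% survive
the 0.001 error rate across their 37 diagnostic bases); design-vs-oracle
equivalence uses 20 random genomes of ~1 kb, where the brute-force oracle —
a pure-Python full scan — is still exhaustive over every locus and strand.

## Degenerate inputs and tie-breaks

- Empty read → QC fail; zero mapped reads → specificity NA.
- Multiple end-sequence occurrences in one read → first wins.
- Candidate enumeration skips any k-mer containing reference N; the
  off-target scan instead charges reference N as a mismatch at unmasked
  positions (an unknown base cannot be assumed complementary).
- Events are emitted in (contig, position, strand) sort order; off-target
  hits in (contig, start, strand) order, for reproducible output.
- Insertions closer than one read length (or closer than that to a contig
  edge) are rejected by the simulator so junction flanks are exact.
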