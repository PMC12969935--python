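# castkit

Tools for engineering bacteria in situ with CRISPR-associated transposases
(CASTs): guide design against genomes and metagenome-assembled genomes,
integration-site mapping from transposon junction reads, and qPCR/plating
quantification of editing outcomes — plus a fully seeded simulator so every
stage can be validated against known ground truth.

## Who this is for

CASTs integrate a DNA payload at a fixed distance downstream of a 32-nt
protospacer matched by a guide RNA spacer, next to a 5′-CN PAM, leaving a
short target-site duplication (TSD). Anyone targeting a CAST into an isolate
genome or a complex microbiome faces the same three computational problems,
which this package solves:

1. **Which spacers are safe to use?** (`castkit design`)
2. **Where did the payload actually land, and how specifically?**
   (`castkit tnseq`)
3. **How efficient was editing?** (`castkit quantify`)

## The methods

**Guide design.** Every 34-bp k-mer of the target region is enumerated on
both strands and filtered for a 5′-CN PAM; the remaining 32 nt are the
protospacer. Candidates are counted genome-wide at 100% identity (exact
both-strand k-mer index) and multi-mapping candidates set aside. For the
survivors, "flexible" spacer positions — every 6th base from the PAM-proximal
end (6, 12, 18, 24, 30), which do not pair in the Type I-F Cascade R-loop —
are masked to N, and the masked spacer is slid over the whole (meta)genome;
any locus other than the candidate's own with ≤ `max_mismatch` mismatches at
unmasked positions disqualifies the candidate. No activity scoring is
applied; passing spacers are reported in genomic order, tallied per tiling
window.

**Integration-site mapping (Tn-seq junction reads).** Reads in which at
least half the bases are below Q20 (a Q20 base is exactly a 1% miscall
probability, p = 10^(−Q/10)) are removed. Reads containing the last 20 bases
of the transposon right end (5′-TGTTGATACAACCATAAAAT) are kept and the 17-bp
genomic *fingerprint* immediately 3′ of it is extracted; a fingerprint
mapping perfectly and uniquely (both strands) to the genome defines an
insertion. Unmapped fingerprints are checked against the donor vector (pME)
and tallied as donor contamination. The event coordinate is the fifth TSD
base on the fwd strand — a convention under which both junction orientations
of one insertion coincide. Events within the 100-bp window after the
protospacer 3′ end are on-target; specificity = 100 × on-target reads /
uniquely mapped reads. Per-site counts are normalized by each sample's total
transposon-end containing reads and scaled to the deepest sample.

**Quantification.** Editing efficiency from qPCR on the T-RL junction
amplicon versus a reference gene (e.g. *rpoB*):

    transposition efficiency (%) = 2^−ΔCq × 100,  ΔCq = Cq_junction − Cq_reference

plasmid copy number = 2^−ΔCq (backbone vs reference, no ×100), and
conjugation efficiency = selective CFU / non-selective CFU after dilution
correction. No amplification is reported as *below detection*, never as 0%.

## Worked example

Simulate an editing experiment on an 8-kb genome (protospacer planted at
contig1:4001–4032 on +, payload inserted with a 5-bp TSD, 5% of 3000 reads
being junction amplicons), then map the insertions back:

```sh
$ castkit simulate --config sim.yaml --outdir run1
wrote genome (8000 bp), 3000 reads, 1 insertion(s) to run1

$ castkit tnseq --reads run1/reads.fastq --ref run1/genome.fa \
    --target contig1:4001-4032:+ --out events.tsv --stats stats.tsv
1 unique sites; specificity 100.00%

$ head -6 events.tsv
#coordinates=1-based inclusive
#tool=castkit 0.1.0
#tsd=5
#window=100
contig	position	strand	orientation	read_count	on_target
contig1	4086	+	T-RL	150	True
```

The single called event sits at position 4086 = protospacer end (4032) +
insertion offset (49) + TSD (5): the fifth base of the duplicated target
site, 54 bp downstream of the protospacer — inside the 100-bp on-target
window, in T-RL orientation, supported by 150 junction reads. It matches
`run1/insertions_truth.tsv` exactly.

Guide design against the same genome and a qPCR efficiency table:

```sh
$ castkit design --ref run1/genome.fa --region contig1:3001-5000 --out cand.tsv
965 passing candidates of 965

$ castkit quantify --mode efficiency --in cq.tsv --out eff.tsv
$ cat eff.tsv
sample_id	efficiency_pct	sd_pct	n_detected	n_censored
s1	3.0203640492762602	0.14797758062531566	2	0
s2	below_detection		0	1
```

Sample s1 (Cq pairs 25.0/20.0 and 25.1/20.0, i.e. ΔCq ≈ 5) yields
2^−5 × 100 ≈ 3.0% efficiency; s2 never amplified and is censored.

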