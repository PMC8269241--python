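# virmatch

Virus–host prediction for viral contigs mined from plasmidome-style
assemblies — the circular-DNA fraction of an environmental sample, where
phages, plasmids and phage–plasmid hybrids co-occur.  The package is aimed at
environmental microbiologists who have (i) a set of viral contigs, (ii) a
collection of candidate host genomes with a taxonomy table, and optionally
(iii) the paired reads behind the assembly, and who want to know which
contigs are complete circular genomes and which bacteria they infect.

## What it computes

**Circularity.** A scaffold is called a complete circular genome when all
three criteria hold: length > 2 kb; a direct terminal repeat of ≥ 35 bp (the
signature an assembler leaves when it walks across the origin of a circular
template); and ≥ 2 read pairs in junction-spanning orientation with each mate
within 500 bp of a contig end.

**Host prediction** by three independent signals, reported per method and
merged into a consensus:

1. *Tetranucleotide composition* (`4mer`).  Phage genomes tend to mirror
   their host's oligonucleotide usage.  Both sides are reduced to canonical
   4-mer frequency vectors (136 entries; a k-mer and its reverse complement
   are counted together) and compared by the mean absolute error

   d(v, h) = (1/136) Σᵢ |vᵢ − hᵢ|.

   A host qualifies at d < 0.001; the top five qualifying strains by lowest
   d are collapsed to their lowest common ancestor (LCA), so five strains of
   one genus yield a genus-level call.
2. *Shared regions* (`blast`/`blast99`).  An ungapped seed-and-extend scan
   (exact 11-mer seeds, two-hit initiation, X-drop extension, +2/−3 scoring
   with Karlin–Altschul bit scores and E-values) finds virus-like regions in
   host genomes — prophage integrations or horizontal transfers.  A host
   qualifies with a region ≥ 4.9 kb at ≥ 70 % identity (bit ≥ 50, E ≤ 1e−3);
   top-5-by-bit-score strains are collapsed by LCA.  When > 99 % of the virus
   is covered at > 99 % identity with vanishing E-value, the entire virus is
   contained in the genome and a strain-level `blast99` call is emitted —
   per containing strain.
3. *CRISPR spacers* (`crispr`).  Repeat–spacer arrays are detected in host
   genomes (≥ 3 repeats of 19–38 bp, spacers of 19–48 bp, 8-bp search
   window); every spacer is scanned full-length and ungapped against every
   virus on both strands, keeping ≤ 1 mismatch; a spacer must additionally
   re-occur exactly in its host of origin (back-validation).  Each surviving
   (virus, host) pair is a strain-level call — direct evidence of past
   infection.

The consensus report records per-virus method agreement at genus rank and a
best-rank call using the methods' accuracy ordering
(crispr > blast99 > blast > 4mer), plus host consistency within viral
clusters (LCA of member calls).  A curation module filters hmmscan domtblout
domain hits (bit ≥ 30, E ≤ 1e−3) and sorts them into auxiliary-metabolic-gene
categories (metal resistance, antibiotic resistance, toxin–antitoxin, phage
hallmark, metabolism) via an editable keyword table.

**Synthetic communities.**  Because real host ranges are unknowable without
experiments, the package ships a generator that plants all of these signals
with ground truth: genus-specific order-3 Markov composition models shared
between hosts and their phages, full and partial prophage insertions at
controlled identity, CRISPR arrays with spacers at 0–2 mismatches, and reads
drawn from circular or linear templates.  Every detector is tested against
what was planted.

## Worked example

```
$ virmatch run-all --seed 1 --out-dir out/
18 viruses; 16 circular; 13 with host calls
```

`out/` then contains the simulated inputs (`inputs/` with FASTA, FASTQ,
lineage and truth tables), `circularity.tsv`, one predictions TSV per method,
`consensus.tsv`, `cluster_consistency.tsv` and a manifest.  Three rows of
`consensus.tsv` (columns: virus, 4mer, blast, blast99, crispr, agreement,
best method/taxon/rank):

```
v_cr_a         no_call             no_call                 no_call                 Pseudomonas_P3(strain)  single-method  crispr   Pseudomonas_P3   strain
v_full_pseudo  Pseudomonas(genus)  Pseudomonas_P1(strain)  Pseudomonas_P1(strain)  no_call                 agree          blast99  Pseudomonas_P1   strain
v_part_75      Streptomyces(genus) Streptomyces_S1(strain) no_call                 no_call                 agree          blast    Streptomyces_S1  strain
```

The planted full prophage is recovered at strain level by whole-virus
containment, the 0.75-identity partial prophage by the shared-region method
(with composition agreeing at genus rank), and the CRISPR-targeted virus by
its spacer.  The two below-threshold controls (a 4.5-kb region and a 6-kb
region at 65 % identity) correctly produce no shared-region calls, and the
three background viruses produce no calls at all.

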