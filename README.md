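# pseudoscan

Exon-alignment screening for gene loss across species: map the exons of an
orthologous reference gene onto target genomic regions, call the
gene-inactivating mutations that distinguish a pseudogene from an intact
ortholog, summarize coding erosion as a discrete **PseudoIndex**, and project
the results onto a phylogeny.

## Who this is for

Comparative genomicists asking "is gene *X* still protein-coding in species
*Y*?" at the scale of modern genome collections — dozens to hundreds of
assemblies, one candidate gene, one genomic region per species. The tool
needs only a reference gene (built automatically from a GFF3/GTF annotation,
or supplied as FASTA files) and a multi-FASTA of target regions; no
annotation of the targets is required.

## Method

For a reference gene with exons $e_1, \dots, e_k$ and CDS $C$ (the in-order
concatenation of the $e_i$), each exon is aligned to each target region by
**semi-global Needleman–Wunsch/Gotoh** dynamic programming: terminal gaps on
the region are free, so the exon is placed as an island inside genomic
context, under affine gap costs ($\mathrm{open} + L\cdot\mathrm{extend}$).
Because no single match/mismatch weighting suits both conserved and eroded
exons, a configurable **battery of scoring schemes**
$\{(1,-1),(1,-2),(1,-3),(2,-1),(2,-3),(4,-1)\}$ (gap open $-20$, extend $-1$)
is run per exon, and the winning placement is chosen by a two-key sort:

1. **splice-site viability** — conservation of the canonical intron
   dinucleotides (donor `GT`, acceptor `AG`) flanking the candidate
   footprint, gene-terminal sides exempt;
2. **percent identity** to the reference exon (gap columns included in the
   denominator), then raw score, then earliest footprint.

An exon whose best placement falls below an identity floor (default 65%,
chosen to clear the spurious-fit null of an unrelated sequence) is declared
**absent**. From the selected placements the caller reports:

* frameshift insertions/deletions (gap runs with $L \bmod 3 \neq 0$,
  left-normalized against the reference),
* premature termination codons, by frameshift-aware translation of the
  reconstructed target coding stream,
* splice-site losses (non-canonical donor/acceptor dinucleotides),
* absent exons, and start-codon loss,

each anchored to a reference-CDS coordinate so lesions can be compared across
species. The **disrupted fraction** $D$ is the size of the union of CDS
positions downstream of the first disruptive frame-breaking event, downstream
of the first disruptive premature stop, and inside absent exons, divided by
$|C|$; $D$ is binned onto the 0–5 PseudoIndex scale
($0$: intact; $(0,.05]\to1$, $(.05,.2]\to2$, $(.2,.5]\to3$, $(.5,.85]\to4$,
$(.85,1]\to5$). On a phylogeny, a leaf carries its target's PseudoIndex and
mutation set; an internal node carries the **maximum** PseudoIndex of its
descendants and the mutations **shared by all** matched descendant leaves.

See `docs/methods.md` for assumptions, parameter rationale, and limitations.

## Worked example

Generate a synthetic gene with eight targets (one intact, seven carrying one
known lesion each), run the screen, and annotate the accompanying tree:

```bash
pseudoscan fixtures --seed 7 --out fx
pseudoscan run --cds fx/ref_cds.fasta --exons fx/ref_exons.fasta \
    --targets fx/targets.fasta --newick fx/targets.nwk --out out --jobs 2
cat out/summary.tsv
```

which prints:

```
target_id	pseudoindex	disrupted_fraction	n_events	n_exons_placed
t_clean	0	0.000000	0	3
t_stop	4	0.639640	1	3
t_del	3	0.222222	1	3
t_ins	3	0.438438	2	3
t_donor	3	0.273273	1	3
t_acceptor	4	0.663664	1	3
t_exonloss	3	0.393393	1	2
t_start	0	0.000000	1	3
```

Reading this: `t_clean` is intact (PseudoIndex 0). `t_stop` carries a
premature stop that truncates 64% of the CDS (index 4). `t_ins` shows two
events — the injected frameshift plus the premature stop the shifted frame
runs into downstream (dual-reported; erosion is anchored on the first
lesion, so nothing is double-counted). `t_exonloss` has one exon absent
(2/3 placed). `t_start` has a changed start codon, reported but flagged
non-disruptive by default, hence index 0. Per-target detail lands in
`out/targets/*.json`, the cross-species mutation table in
`out/mutations.tsv`, per-exon alignments under `out/alignments/`, and the
NHX-annotated tree in `out/annotated.nwk` (internal nodes carry the max
PseudoIndex and shared-mutation counts of their descendants).

A reference can equally be built from an annotation:

```bash
pseudoscan reference --genome fx/genome.fasta --annotation fx/annotation.gff3 \
    --gene gene1 --out-prefix myref
```

To feed a downstream codon-aware multiple aligner, export the selected
target sequences of any exon with
`pseudoscan.export_exon_multifasta(...)` — the pipeline itself never invokes
an MSA tool.

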