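# editome

Prediction and comparative analysis of C-to-U and U-to-C RNA editing in
organellar protein-coding genes.

In many land-plant mitochondria, the genomic DNA does not spell out the
functional protein: cytidines in the transcript are post-transcriptionally
converted to uridines (and, more rarely, uridines to cytidines), so the
mature mRNA differs from its template. Lineages differ enormously in how
much editing they perform — from essentially none to many hundreds of
sites per mitogenome. `editome` implements the comparative workflow used
to study this phenomenon genome-wide when transcriptome data is not
available for every species: editing sites are *predicted* by comparing
each gene to its homologue in a reference species experimentally known to
perform little or no editing, and the predictions are then analysed
comparatively across species groups.

The package is aimed at researchers analysing organellar (typically
bryophyte mitochondrial) CDS sets who want a scripted, reproducible,
fully-testable version of that workflow.

## What it computes

**Site prediction.** For a query CDS and a reference protein, the two
proteins are globally aligned (BLOSUM62, affine gaps). For every aligned
codon whose translation differs from the reference residue, the predictor
enumerates minimal sets of same-direction edits — C→U first, then U→C —
that restore the reference amino acid; each position in a minimal set is a
predicted site. Start-codon repair (ACG→ATG) and terminal-stop creation
are handled; internal stop creation is rejected; codons with ambiguity
codes are skipped.

**Editing frequency.** For gene *g* in species *s* with *m* predicted
sites and CDS length *L* (nt),

    f(s, g) = 100 · m / L   (percent)

Per-gene group comparisons use the Kruskal–Wallis rank test, Dunn's
post-hoc *z* tests with Benjamini–Hochberg adjustment, Pearson correlation
of per-gene mean frequencies between groups, and an overall group scale
factor (ratio of mean per-species editing levels).

**Binary editing matrix.** The sorted union of edited positions of a gene
across species forms the gene's editing template; concatenated templates
define taxa × (gene, position) presence/absence characters, exported as a
MrBayes-compatible NEXUS DATA block.

**Trees.** Neighbor-joining on p-distances and maximum parsimony (Fitch
small parsimony; exhaustive search up to 9 taxa, NNI hill-climbing beyond)
with character bootstrap and strict >50% majority-rule consensus,
serialized as Newick with support values.

**Verification.** Transcripts are aligned to the genomic CDS; C→T
mismatches support C-to-U predictions (T→C supports U-to-C), giving
confirmed-to-predicted ratios per species, gene and direction.

**Synthetic data.** A first-class generator plants uniquely-reconciling
edits with known positions into CDS families derived from a shared
reference, with group-structured editing levels, per-gene rate
heterogeneity, background divergence, partially edited transcripts, and
site sets evolved by loss/gain along a known tree — so every stage can be
tested closed-loop against ground truth.

## Worked example

Predicting a single editing site (`examples/01_predict_editing_sites.py`):

```python
from editome import GeneRecord, predict_sites, translate

ref_protein = translate("ATGTGGTGA")            # "MW*"
query = GeneRecord(species_id="query_sp", gene="demo", seq="ATGCGGTGA")
for s in predict_sites(query, ref_protein):
    print(s.position, s.direction, s.aa_from, "->", s.aa_to)
```

prints

```
query protein : MR*
ref   protein : MW*
predicted C2U site at CDS position 4 (codon 2, codon position 1): R -> W
```

i.e. the genomic C at CDS position 4 must read as U in the transcript for
codon 2 (CGG, Arg) to encode the reference Trp (TGG).

At the other end of the scale, `examples/02_frequencies_and_group_stats.py`
simulates two groups of six species whose editing levels contrast
3.5-fold, predicts every editome, and recovers the contrast from the
predictions:

```
configured editing-level contrast : 3.50x
estimated  group scale factor     : 3.36x

gene   H      p       mean(rich)%  mean(poor)%
atp4    8.46   0.0036       2.38         0.57
atp6    8.46   0.0036       5.24         1.24
...
```

Genes left of the significance cutoff (p < 0.05) differ between groups;
the scale factor estimates the overall editing-level ratio. The other
examples cover the binary matrix and bootstrap trees
(`03_binary_matrix_and_trees.py`), transcript verification
(`04_transcript_verification.py`) and the end-to-end pipeline with its
output manifest (`05_full_pipeline.py`).

## Command line

A thin CLI wraps the library:

```sh
editome simulate --out-dir data --seed 4          # synthetic dataset + truth
editome predict  --query-dir data/species --reference data/reference.fasta --out sites.tsv
editome matrix   --sites sites.tsv --out matrix.nex
editome tree     --nexus matrix.nex --method mp --bootstrap 1000 --seed 42 --out tree.nwk
editome verify   --sites sites.tsv --cds-dir data/species --transcripts-dir data/transcripts --out verification.tsv
editome run      --query-dir ... --reference ... --out-dir out   # all stages + manifest
editome extract  --genbank mito.gb --genes atp9,nad5 --out cds.fasta
```

All stage outputs are plain TSV / NEXUS / Newick, and a `run` is
byte-reproducible under a fixed seed.

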