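# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `editome`, in the order the pipeline runs.

## Editing-site prediction by homologue reconciliation

The predictor assumes the query CDS and the reference protein are
orthologous, full-length and co-linear apart from RNA editing and modest
divergence. It works codon-wise on a global protein alignment:

1. The query CDS is translated (standard genetic code by default —
   appropriate for plant mitochondria — and configurable via
   `PredictionConfig.codon_table`).
2. Query and reference proteins are aligned globally with BLOSUM62 and
   affine gap penalties (open 11, extend 1, the BLAST protein defaults).
   Global rather than local alignment is used because inputs are curated
   full-length CDS; it makes the alignment, and hence the site list,
   deterministic. The first optimal traceback reported by the dynamic
   program is taken, fixing tie-breaks.
3. A reference counts as a usable homologue only if identity over aligned
   (non-gap) columns is ≥ `min_protein_identity` (default 0.30). This
   gate replaces the e-value cutoff a database-search tool would apply.
   With the chosen gap penalties, unrelated random 100-residue proteins
   fall below it in ≥95% of cases.
4. For each aligned codon column with an amino-acid difference, minimal
   sets of same-direction edits that convert the query codon into one
   translating to the reference residue are enumerated (at most
   `max_edits_per_codon` = 3 edits, i.e. full codon). C→U is tried first;
   U→C only if no C→U set reconciles. Mixed-direction sets are never
   formed. The minimal-edit principle is the parsimony assumption standard
   in this kind of prediction; when several minimal sets exist the union
   of their positions is reported with `ambiguous=True`. (Under the
   standard genetic code this situation cannot actually arise — verified
   exhaustively in the test suite — but it can under alternative codes.)
5. Special cases: edits creating an internal stop are rejected; an edit
   creating the terminal stop is accepted when the reference protein ends
   in one and the query's last codon is unaligned; start-codon repair
   (e.g. ACG→ATG) is accepted at codon 1 and can be disabled. Codons
   containing ambiguity codes are skipped and tallied, never predicted on.

Positions are 1-based nucleotide offsets within the spliced,
strand-corrected CDS, with `codon_index`/`codon_pos` giving the codon
coordinate. This is the convention used in all tables, the binary matrix
labels, and the NEXUS character names.

By construction the predictor is *sound* (every reported edit restores
the reference residue) but blind to synonymous edits, to editing outside
CDS (introns, structural RNAs, spacers are out of scope), and to sites in
codons whose difference has a non-editing explanation.

## Editing frequency and group statistics

Editing frequency is 100 × sites / CDS length (percent), computed per
species, gene and direction with each species' own CDS length as the
denominator (including the stop codon). Missing genes are absent cells,
not zeros.

Group comparisons are per gene across all groups: Kruskal–Wallis with tie
correction (convention: all-identical samples give H = 0, p = 1 rather
than an error, so invariant genes are reported, not dropped), followed by
Dunn's pairwise z tests,

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j)),

with Benjamini–Hochberg adjustment across the family of group pairs
(statsmodels' implementation). Group means are unweighted means over the
species of a group; standard errors are sd/√n. The overall group scale
factor divides the groups' mean per-species editing levels, where a
species' level is 100 × (total sites across genes) / (total CDS length);
it satisfies factor(A,B)·factor(B,A) = 1 exactly. Pearson correlation of
per-gene mean frequencies between groups quantifies whether the same
genes are editing-rich in both.

The Kruskal–Wallis chi-square approximation is slightly conservative at
the group sizes typical here (empirical type-I error ≈ 4.2–4.6% at
α = 0.05 with three groups of eight, measured over 2000 null
replicates) — within the 5% ± 1% band the test suite checks.

## Binary matrix and NEXUS interchange

A gene's editing template is the sorted union of its C-to-U positions
across species (U-to-C is excluded by default: those predictions are less
reliable and the downstream character analysis follows the C-to-U set; a
flag exposes the U-to-C matrix). Templates concatenated in a fixed gene
order define the character list; each species maps to a 0/1 row. The
prediction reference is excluded (it has no sites by construction);
all-zero rows are retained with a warning so the taxon set matches the
tree analysis; ambiguous sites count as ordinary presences. Matrix width
therefore equals the number of unique (gene, position) pairs, and row
sums equal per-species C-to-U totals — both asserted in tests.

Serialization writes a NEXUS DATA block (`DATATYPE=STANDARD
SYMBOLS="01"`) with CHARSTATELABELS `gene_position`, readable by MrBayes
and PAUP; reading uses dendropy's NEXUS parser with labels recovered from
CHARSTATELABELS, and write→read is an exact roundtrip. Bayesian inference
itself is out of scope — the export exists precisely so external tools
can run it.

## Tree inference

*Distances.* p-distance = differing characters / total characters.

*Neighbor-joining.* Standard Q-criterion agglomeration. Ties on Q are
broken by the lexicographically smallest pair of cluster labels (a
cluster is labelled by its alphabetically first taxon), making output
bit-stable. Negative branch lengths are clamped to zero with the deficit
logged. On additive matrices NJ provably recovers the generating
topology; the tests exercise this on hand-computed path-length matrices.

*Parsimony.* Characters are unordered binary with equal weights;
constant and uninformative characters are retained (they add zero).
Fitch small parsimony is vectorized over characters with 2-bit state
sets; it is invariant to the traversal rooting and matches a brute-force
minimization over all ancestral-state assignments in tests. Search is
exhaustive (all unrooted topologies, permitted to 9 taxa = 135,135
trees) or NNI hill-climbing from the NJ tree plus seeded random restarts
(default 3 starts), taking the first improving interchange until none
remains. On tree-derived characters with realistic homoplasy the NNI
search reaches the exhaustive optimum in ≥90% of seeded trials; on
uniform-random matrices (a much more rugged landscape than editing data
produces) it can stall in local optima — use more restarts there.

*Bootstrap and consensus.* Characters are resampled with replacement to
the original width; each replicate is re-inferred with the chosen method
(per-replicate seeds derive deterministically from the master seed).
Majority-rule consensus retains splits with frequency strictly greater
than the cutoff (default 0.5) with support = 100 × frequency; no greedy
completion with minority splits, so conflicting resolutions collapse to
polytomies. Trees are unrooted throughout; rooting on a named outgroup is
a display option of the Newick writer only.

## Transcript verification

Transcripts (assembled per-gene sequences, not reads) are globally
aligned to the genomic CDS at the nucleotide level (match 2, mismatch −3,
gap open −5, extend −2); a reverse-complement input is detected by score
comparison and reoriented, and alignments under 70% identity are rejected
as unassignable. Every non-gap mismatch is classified by its base pair:
C→T supports C-to-U, T→C supports U-to-C, anything else is "other". A
predicted site is confirmed when a direction-matching mismatch sits at
its exact CDS position (position-level identity, no frequency threshold —
inputs are consensus transcripts); direction-matching evidence wins over
conflicting mismatches at the same position, with conflicts logged. Zero
predictions give a 0/0 summary, not an error.

## Synthetic data generator

The generator emulates the statistical structure of a two-(or more-)group
comparative editome study. Defaults are the package's reference study
conditions: 33 genes named after the mitochondrial protein-coding set
shared by liverworts and mosses, lengths uniform in 100–400 codons, two
groups of 15 species with C-to-U levels 2.8 and 0.8 expected sites per
100 nt (a 3.5× contrast, the order of the liverwort-vs-moss difference),
U-to-C fractions of a few percent of the C-to-U level, zero background
divergence, and fully edited transcripts.

A random stop-free reference CDS set is the protein ground truth. Species
genomes are derived by *anti-editing*: for each planted C-to-U site a
codon position with a T is reverted to C (U-to-C symmetrically), chosen
so that (a) the genomic codon's translation differs from the reference
residue, (b) no stop codon is created, (c) the predictor's minimal-edit
enumeration yields exactly one reconciling set, and (d) for U-to-C sites
no C-to-U set exists (direction precedence would otherwise misclassify
them). Per-gene site counts are Poisson with mean level × length / 100;
at most one edit per codon; start and stop codons are never used. On such
data the predictor must achieve precision = recall = 1, and does — this
closed loop is the package's central acceptance property. An optional
mean-one lognormal per-gene rate multiplier (`gene_rate_sigma`) makes
some genes consistently editing-rich and others editing-poor across all
groups, reproducing the across-gene frequency consistency seen in real
editomes. Very high multipliers can saturate a short gene's supply of
plantable codons, in which case fewer sites are planted with a warning.

Background divergence adds synonymous-biased substitutions (default 90%
synonymous where available, never stops) away from planted codons;
because planted codons are shielded, recall stays 1 while precision
degrades with the nonsynonymous rate — quantifying the false-positive
pressure real divergence exerts. Transcripts apply each true site
independently with the configured efficiency. Site-set evolution on a
user tree applies per-branch loss (and optional gain over a slot pool),
emulating loss-dominated editing decay during diversification and feeding
the matrix/tree recovery tests.

What the generator does *not* emulate: real codon usage and GC content,
editing-factor (PPR) recognition contexts, indels and assembly errors,
intron structure, or correlated (non-Poisson) site placement. Passing
closed-loop tests therefore demonstrates algorithmic correctness under
the model's assumptions, not field accuracy on real mitogenomes, where
prediction quality is bounded by reference choice and true divergence.

## Numerical and engineering choices

- All randomness flows from a single integer master seed through
  `numpy.random.default_rng`; derived child seeds stay below 2³¹. Equal
  seeds give byte-identical pipeline outputs.
- GC percentages round half-up to one decimal.
- Alignment tie-breaks are fixed by taking the aligner's first optimal
  traceback; NJ ties by lexicographic cluster labels; NNI neighbor order
  is deterministic.
- Problem sizes in the test suite and acceptance script (3–15 species per
  group, 6–33 genes, 100-replicate bootstraps on 6-taxon matrices, 2000
  null replicates for the rank test) were chosen so the full closed loop
  remains a desk-scale computation while keeping every estimate's Monte
  Carlo error far inside the asserted bands.

## Known limitations

- A single designated reference species per analysis; evidence from
  multiple reference proteins per gene is not combined or weighted.
- Predictions are codon-bound: at most three edits per codon, no
  cross-codon interactions.
- U-to-C predictions inherit the method's lower reliability; downstream
  character analyses default to C-to-U only.
- Branch-and-bound parsimony and likelihood/Bayesian binary-character
  models are not implemented (NEXUS export serves the latter).
- GenBank extraction trusts the annotation's CDS coordinates; it does not
  re-annotate or detect introns.
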