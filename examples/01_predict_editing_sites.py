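"""Predict C-to-U and U-to-C editing sites in a single gene.

A query CDS is compared to the protein of a non-editing reference
homologue; wherever a minimal set of C->U (or U->C) substitutions in a
codon restores the reference amino acid, each such position is reported as
a predicted editing site.
"""

from editome import GeneRecord, predict_sites, translate

# Reference (non-editing species): the protein ground truth, here "MW*"
reference_cds = "ATGTGGTGA"
ref_protein = translate(reference_cds)

# Query genome: codon 2 is CGG (Arg) where the reference has Trp; editing
# the genomic C at CDS position 4 to U restores TGG = Trp on the transcript.
query = GeneRecord(species_id="query_sp", gene="demo", seq="ATGCGGTGA")

sites = predict_sites(query, ref_protein)
print(f"query protein : {translate(query.seq)}")
print(f"ref   protein : {ref_protein}")
for s in sites:
    print(
        f"predicted {s.direction} site at CDS position {s.position} "
        f"(codon {s.codon_index}, codon position {s.codon_pos}): "
        f"{s.aa_from} -> {s.aa_to}"
    )
# One C2U site at position 4: the genomic C that must read as U in the
# transcript for the protein to match the reference.
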