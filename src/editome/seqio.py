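"""Sequence I/O and basic CDS utilities.

Reads per-species gene sets from FASTA or GenBank flat files, translates
coding sequences, and computes simple composition summaries. All downstream
coordinates are 1-based positions within the spliced, strand-corrected CDS.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "GeneRecord",
    "SpeciesGeneSet",
    "CodonTable",
    "STANDARD_CODE",
    "SeqioError",
    "DuplicateGeneError",
    "read_gene_fasta",
    "write_gene_fasta",
    "extract_cds_from_genbank",
    "translate",
    "genome_summary",
]

_VALID_BASES = frozenset("ACGT")


class SeqioError(ValueError):
    """Malformed sequence input."""


class DuplicateGeneError(SeqioError):
    """Two records claim the same gene for one species."""


@dataclass(frozen=True)
class CodonTable:
    """A 64-entry codon -> one-letter amino acid map ('*' marks stops)."""

    forward: Mapping[str, str]
    start_codons: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.forward) != 64:
            raise ValueError(f"codon table must have 64 entries, got {len(self.forward)}")

    def __getitem__(self, codon: str) -> str:
        return self.forward[codon]


def _standard_code() -> CodonTable:
    bio = _BioCodonTable.unambiguous_dna_by_id[1]
    forward = dict(bio.forward_table)
    for stop in bio.stop_codons:
        forward[stop] = "*"
    return CodonTable(forward=forward, start_codons=frozenset(bio.start_codons))


#: Standard genetic code. Plant mitochondria translate with the standard code,
#: so this is the default everywhere.
STANDARD_CODE = _standard_code()


@dataclass
class GeneRecord:
    """One gene's coding sequence for one species.

    ``is_cds`` is False when the sequence length is not a codon multiple;
    such records are retained for bookkeeping but excluded from prediction.
    """

    species_id: str
    gene: str
    seq: str
    is_cds: bool = True

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        if len(self.seq) % 3 != 0:
            self.is_cds = False

    @property
    def length(self) -> int:
        return len(self.seq)

    def codon(self, codon_index: int) -> str:
        """Codon at 1-based ``codon_index``."""
        start = (codon_index - 1) * 3
        return self.seq[start : start + 3]


@dataclass
class SpeciesGeneSet:
    species_id: str
    records: dict[str, GeneRecord] = field(default_factory=dict)
    group: Optional[str] = None

    def add(self, record: GeneRecord) -> None:
        if record.gene in self.records:
            raise DuplicateGeneError(
                f"duplicate gene {record.gene!r} for species {self.species_id!r}"
            )
        self.records[record.gene] = record

    def genes(self) -> list[str]:
        return sorted(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene: str) -> bool:
        return gene in self.records

    def __getitem__(self, gene: str) -> GeneRecord:
        return self.records[gene]


def read_gene_fasta(
    path: str | Path,
    species_id: str,
    gene_regex: str | None = None,
) -> SpeciesGeneSet:
    """Read one species' gene set from FASTA.

    The gene name is the first whitespace-delimited header token, or group 1
    of ``gene_regex`` matched against the full description when given.
    Raises on duplicate gene names or an empty file.
    """
    gene_set = SpeciesGeneSet(species_id=species_id)
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        if gene_regex is not None:
            m = re.search(gene_regex, rec.description)
            if not m:
                raise SeqioError(
                    f"header {rec.description!r} does not match gene pattern {gene_regex!r}"
                )
            gene = m.group(1)
        else:
            gene = rec.id.split()[0]
        gene_set.add(GeneRecord(species_id=species_id, gene=gene, seq=str(rec.seq)))
    if n == 0:
        raise SeqioError(f"no FASTA records in {path}")
    return gene_set


def write_gene_fasta(gene_set: SpeciesGeneSet, path: str | Path) -> None:
    """Write a gene set as FASTA, one record per gene, header = gene name."""
    with open(path, "w") as fh:
        for gene in gene_set.genes():
            rec = gene_set[gene]
            fh.write(f">{gene}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i : i + 70] + "\n")


def extract_cds_from_genbank(
    path: str | Path,
    gene_whitelist: Iterable[str],
    species_id: str | None = None,
) -> tuple[SpeciesGeneSet, list[str]]:
    """Extract spliced, strand-corrected CDS for whitelisted genes.

    Multi-exon CDS are joined in annotation order and reverse-complemented
    when on the minus strand (Biopython's location extraction). CDS features
    without a /gene qualifier are skipped. Returns the gene set together with
    the list of whitelisted genes that were not found.
    """
    wanted = list(gene_whitelist)
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise SeqioError(f"no GenBank records in {path}")
    sid = species_id or records[0].annotations.get("organism", records[0].id)
    gene_set = SpeciesGeneSet(species_id=sid)
    for rec in records:
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            names = feat.qualifiers.get("gene")
            if not names:
                continue  # missing /gene qualifier: skip
            gene = names[0]
            if gene not in wanted or gene in gene_set:
                continue
            seq = str(feat.location.extract(rec.seq))
            gene_set.add(GeneRecord(species_id=sid, gene=gene, seq=seq))
    missing = [g for g in wanted if g not in gene_set]
    return gene_set, missing


def translate(seq: str, table: CodonTable = STANDARD_CODE) -> str:
    """Translate a codon-multiple DNA string to a 1-letter protein string.

    Internal stops are rendered as '*' and left to the caller to flag; a
    terminal stop yields a trailing '*'.
    """
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise SeqioError(f"sequence length {len(seq)} is not a multiple of 3")
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        out.append(table.forward.get(codon, "X"))
    return "".join(out)


def genome_summary(seq: str) -> dict[str, float]:
    """Length and GC content (percent, one decimal, half-up rounding)."""
    seq = seq.upper().replace("U", "T")
    if not seq:
        raise SeqioError("empty sequence")
    gc = sum(seq.count(b) for b in "GC")
    pct = Decimal(100 * gc) / Decimal(len(seq))
    gc_percent = float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return {"length": len(seq), "gc_percent": gc_percent}
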