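"""Prediction of C-to-U and U-to-C RNA editing sites in coding sequences.

The predictor reconciles amino-acid differences between a query CDS and a
homologous protein from a non-editing (or low-editing) reference species.
For every aligned codon whose translation differs from the reference
residue, it asks whether a minimal set of C->U (or, failing that, U->C)
substitutions in the codon restores the reference amino acid. Each position
in such a minimal set is reported as a predicted editing site.

Conventions: positions are 1-based nucleotide offsets within the query CDS;
C-to-U is tried before U-to-C within a codon (forward editing dominates in
land-plant organelles) and mixed-direction edit sets are never formed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import STANDARD_CODE, CodonTable, GeneRecord, SpeciesGeneSet, translate

__all__ = [
    "PredictionConfig",
    "EditingSite",
    "EditingProfile",
    "ProteinAlignment",
    "NoHomologueError",
    "align_proteins",
    "enumerate_codon_edits",
    "predict_sites",
    "predict_editome",
]

logger = logging.getLogger(__name__)

Direction = Literal["C2U", "U2C"]

#: genomic (pre-editing) base and transcript (edited) base per direction
_FROM_TO = {"C2U": ("C", "T"), "U2C": ("T", "C")}


class NoHomologueError(ValueError):
    """Reference protein too diverged to serve as a prediction template."""


@dataclass(frozen=True)
class PredictionConfig:
    """Tunable knobs of the edit-reconciliation predictor.

    ``min_protein_identity`` gates whether a reference protein counts as a
    usable homologue (the surrogate for an aligner e-value cutoff);
    ``max_edits_per_codon`` bounds the edit sets enumerated per codon.
    """

    max_edits_per_codon: int = 3
    min_protein_identity: float = 0.30
    directions: tuple[Direction, ...] = ("C2U", "U2C")
    allow_start_repair: bool = True
    allow_terminal_stop_creation: bool = True
    substitution_matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    codon_table: CodonTable = STANDARD_CODE

    def __post_init__(self) -> None:
        if not 1 <= self.max_edits_per_codon <= 3:
            raise ValueError("max_edits_per_codon must be in 1..3")
        if not 0.0 <= self.min_protein_identity <= 1.0:
            raise ValueError("min_protein_identity must be in [0, 1]")


@dataclass(frozen=True, order=True)
class EditingSite:
    """One predicted edit at a 1-based nucleotide position of a CDS."""

    species_id: str
    gene: str
    position: int
    direction: str
    codon_index: int
    codon_pos: int
    from_base: str
    to_base: str
    aa_from: str
    aa_to: str
    ambiguous: bool = False

    def __post_init__(self) -> None:
        want_from, want_to = _FROM_TO[self.direction]
        if self.from_base != want_from or self.to_base != want_to:
            raise ValueError(
                f"{self.direction} site must be {want_from}->{want_to}, "
                f"got {self.from_base}->{self.to_base}"
            )


@dataclass
class EditingProfile:
    """Predicted sites per species and gene, with per-direction totals."""

    sites: dict[str, dict[str, list[EditingSite]]] = field(default_factory=dict)

    def add(self, species_id: str, gene: str, site_list: Sequence[EditingSite]) -> None:
        per_gene = self.sites.setdefault(species_id, {})
        per_gene[gene] = sorted(set(site_list), key=lambda s: s.position)

    def species(self) -> list[str]:
        return sorted(self.sites)

    def genes(self, species_id: str) -> list[str]:
        return sorted(self.sites.get(species_id, {}))

    def sites_for(self, species_id: str, gene: str) -> list[EditingSite]:
        return self.sites.get(species_id, {}).get(gene, [])

    def totals(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for sp, per_gene in self.sites.items():
            counts = {"C2U": 0, "U2C": 0}
            for site_list in per_gene.values():
                for s in site_list:
                    counts[s.direction] += 1
            out[sp] = counts
        return out

    def all_sites(self) -> list[EditingSite]:
        out: list[EditingSite] = []
        for sp in self.species():
            for gene in self.genes(sp):
                out.extend(self.sites[sp][gene])
        return out


@dataclass
class ProteinAlignment:
    """Global protein alignment with a query-codon to reference-residue map."""

    aligned_query: str
    aligned_ref: str
    identity: float
    #: pairs of (query residue index, reference residue index), 0-based,
    #: one per aligned non-gap column
    pairs: list[tuple[int, int]]


def _make_aligner(config: PredictionConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(
        config.substitution_matrix_name
    )
    aligner.open_gap_score = -config.gap_open
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def align_proteins(
    query: str, ref: str, config: PredictionConfig = PredictionConfig(), gene: str = ""
) -> ProteinAlignment:
    """Globally align two proteins and map query residues to reference ones.

    Terminal stop characters are stripped before alignment, so proteins are
    compared over residues only. The first optimal alignment reported by the
    dynamic program is taken, which fixes tie-breaking deterministically.
    Raises :class:`NoHomologueError` when identity over aligned (non-gap)
    columns falls below ``config.min_protein_identity``.
    """
    q = query[:-1] if query.endswith("*") else query
    r = ref[:-1] if ref.endswith("*") else ref
    if not q or not r:
        raise ValueError("empty protein sequence")
    aligner = _make_aligner(config)
    aln = aligner.align(q, r)[0]
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (qs, qe), (rs, re_) in zip(*aln.aligned):
        for offset in range(qe - qs):
            qi, ri = qs + offset, rs + offset
            pairs.append((qi, ri))
            if q[qi] == r[ri]:
                matches += 1
    identity = matches / len(pairs) if pairs else 0.0
    if identity < config.min_protein_identity:
        raise NoHomologueError(
            f"no reliable homologue for gene {gene or '<unnamed>'}: "
            f"identity {identity:.3f} < {config.min_protein_identity:.2f}"
        )
    return ProteinAlignment(
        aligned_query=str(aln[0]),
        aligned_ref=str(aln[1]),
        identity=identity,
        pairs=pairs,
    )


def enumerate_codon_edits(
    codon: str,
    target_aa: str,
    direction: Direction,
    max_edits: int = 3,
    table: CodonTable = STANDARD_CODE,
) -> list[frozenset[int]]:
    """Minimal sets of same-direction edits turning ``codon`` into ``target_aa``.

    Returns every minimal-cardinality set of codon positions (1..3) whose
    from->to substitution makes the codon translate to ``target_aa``; the
    empty list when unreachable within ``max_edits`` edits.
    """
    from_base, to_base = _FROM_TO[direction]
    editable = [i for i, b in enumerate(codon, start=1) if b == from_base]
    hits: list[frozenset[int]] = []
    for k in range(1, min(max_edits, len(editable)) + 1):
        for combo in itertools.combinations(editable, k):
            bases = list(codon)
            for pos in combo:
                bases[pos - 1] = to_base
            if table["".join(bases)] == target_aa:
                hits.append(frozenset(combo))
        if hits:
            break  # minimal cardinality reached
    return hits


def _sites_from_edit_sets(
    record: GeneRecord,
    codon_index: int,
    direction: Direction,
    edit_sets: list[frozenset[int]],
    aa_from: str,
    aa_to: str,
) -> list[EditingSite]:
    from_base, to_base = _FROM_TO[direction]
    ambiguous = len(edit_sets) > 1
    positions = sorted(set().union(*edit_sets))
    return [
        EditingSite(
            species_id=record.species_id,
            gene=record.gene,
            position=(codon_index - 1) * 3 + codon_pos,
            direction=direction,
            codon_index=codon_index,
            codon_pos=codon_pos,
            from_base=from_base,
            to_base=to_base,
            aa_from=aa_from,
            aa_to=aa_to,
            ambiguous=ambiguous,
        )
        for codon_pos in positions
    ]


def predict_sites(
    query: GeneRecord,
    ref_protein: str,
    config: PredictionConfig = PredictionConfig(),
) -> list[EditingSite]:
    """Predict editing sites in ``query`` against a reference protein.

    For each aligned codon column with an amino-acid difference, C->U
    reconciliation is attempted first, then U->C (when enabled). Codons
    containing ambiguity codes are skipped; reconciliations that would
    create an internal stop are rejected; a terminal stop may be created by
    editing the query's final codon when the reference protein ends in one.
    """
    if not query.is_cds:
        raise ValueError(f"record {query.gene!r} is not a valid CDS (length % 3 != 0)")
    table = config.codon_table
    n_codons = query.length // 3
    skipped = {
        i
        for i in range(1, n_codons + 1)
        if any(b not in "ACGT" for b in query.codon(i))
    }
    if skipped:
        logger.warning(
            "%s/%s: skipped %d codon(s) with ambiguity codes",
            query.species_id,
            query.gene,
            len(skipped),
        )
    qprot_full = "".join(
        table.forward.get(query.codon(i), "X") for i in range(1, n_codons + 1)
    )
    ref_had_stop = ref_protein.endswith("*")
    ref_res = ref_protein[:-1] if ref_had_stop else ref_protein
    query_had_stop = qprot_full.endswith("*")
    qprot = qprot_full[:-1] if query_had_stop else qprot_full

    aln = align_proteins(qprot, ref_res, config, gene=query.gene)

    sites: list[EditingSite] = []
    aligned_query_codons = set()
    for qi, ri in aln.pairs:
        codon_index = qi + 1
        aligned_query_codons.add(codon_index)
        if codon_index in skipped:
            continue
        qaa, raa = qprot[qi], ref_res[ri]
        if qaa == raa:
            continue
        if raa == "*":
            continue  # internal stop creation rejected
        codon = query.codon(codon_index)
        for direction in ("C2U", "U2C"):
            if direction not in config.directions:
                continue
            edit_sets = enumerate_codon_edits(
                codon, raa, direction, config.max_edits_per_codon, table
            )
            if not edit_sets:
                continue
            if (
                codon_index == 1
                and raa == "M"
                and not config.allow_start_repair
            ):
                break  # start-codon repair disabled
            sites.extend(
                _sites_from_edit_sets(query, codon_index, direction, edit_sets, qaa, raa)
            )
            break  # C2U precedence: never also report U2C for the codon

    # Terminal stop creation: the query's final codon encodes a residue that
    # editing should convert to a stop, matching the reference's terminal '*'.
    if (
        config.allow_terminal_stop_creation
        and ref_had_stop
        and not query_had_stop
        and n_codons not in skipped
        and n_codons not in aligned_query_codons
    ):
        codon = query.codon(n_codons)
        for direction in ("C2U", "U2C"):
            if direction not in config.directions:
                continue
            edit_sets = enumerate_codon_edits(
                codon, "*", direction, config.max_edits_per_codon, table
            )
            if edit_sets:
                sites.extend(
                    _sites_from_edit_sets(
                        query, n_codons, direction, edit_sets, qprot_full[-1], "*"
                    )
                )
                break

    return sorted(set(sites), key=lambda s: s.position)


def predict_editome(
    species_sets: Iterable[SpeciesGeneSet],
    reference: SpeciesGeneSet,
    config: PredictionConfig = PredictionConfig(),
    genes: Optional[Sequence[str]] = None,
) -> EditingProfile:
    """Predict the editome of every species against one reference species.

    ``genes`` restricts the analysis; by default every gene occurring in any
    query species is analysed. The reference must cover all analysed genes.
    Genes missing in a particular species are skipped (absent from the
    profile, not zero-filled).
    """
    species_sets = list(species_sets)
    if genes is None:
        requested: set[str] = set()
        for ss in species_sets:
            requested.update(ss.records)
        genes = sorted(requested)
    missing_in_ref = [g for g in genes if g not in reference]
    if missing_in_ref:
        raise ValueError(
            f"reference {reference.species_id!r} lacks genes: {', '.join(missing_in_ref)}"
        )
    ref_proteins = {g: translate(reference[g].seq, config.codon_table) for g in genes}
    profile = EditingProfile()
    for ss in species_sets:
        for gene in genes:
            if gene not in ss:
                logger.info("species %s lacks gene %s; skipped", ss.species_id, gene)
                continue
            rec = ss[gene]
            if not rec.is_cds:
                logger.warning(
                    "species %s gene %s is not a codon-multiple CDS; skipped",
                    ss.species_id,
                    gene,
                )
                continue
            profile.add(ss.species_id, gene, predict_sites(rec, ref_proteins[gene], config))
    return profile
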