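"""Synthetic datasets with known editing ground truth.

Generates orthologous CDS families derived from a shared reference protein,
plants C-to-U (and rarer U-to-C) edits whose reversal restores the
reference amino acid, adds synonymous-biased background divergence,
produces partially edited transcripts, and evolves presence/absence site
sets along a known tree. Every generator is deterministic under its seed,
so each pipeline stage can be tested closed-loop without any download.

Planted edits are guaranteed to be uniquely reconciling under the
predictor's minimal-edit rule (candidates that admit more than one minimal
edit set, or that a C-to-U attempt would explain when a U-to-C edit was
planted, are simply never drawn), so on divergence-free data the predictor
must recover exactly the planted truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np

from .edit_predict import EditingSite, enumerate_codon_edits
from .seqio import STANDARD_CODE, CodonTable, GeneRecord, SpeciesGeneSet

__all__ = [
    "MITO_GENES",
    "GroupSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_reference",
    "plant_edits",
    "add_background_divergence",
    "simulate_transcripts",
    "evolve_sites_on_tree",
    "simulate_dataset",
]

logger = logging.getLogger(__name__)

#: The 33 mitochondrial protein-coding genes shared by liverworts and mosses.
MITO_GENES = (
    "atp4", "atp6", "atp8", "atp9", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "nad9",
    "rpl2", "rpl5", "rpl6", "rpl10", "rpl16",
    "rps1", "rps2", "rps3", "rps4", "rps7", "rps11", "rps12", "rps13",
    "rps14", "rps19", "sdh3", "sdh4", "tatC",
)

_BASES = "ACGT"
_STOPS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class GroupSpec:
    """Editing regime of one species group.

    ``c2u_level`` is the expected number of C-to-U sites per 100 nt of CDS;
    ``u2c_fraction`` scales the (rarer) U-to-C level relative to it.
    """

    n_species: int
    c2u_level: float
    u2c_fraction: float = 0.03


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic editome.

    Defaults mirror the structure of a two-lineage bryophyte comparison:
    33 orthologous mitochondrial genes of 100-400 codons, two groups of 15
    species whose C-to-U levels contrast 3.5-fold (roughly the
    liverwort-vs-moss overall difference), a small U-to-C share, no
    background divergence, and fully edited transcripts.
    """

    n_genes: int = 33
    gene_length_range: tuple[int, int] = (100, 400)  # codons
    groups: dict[str, GroupSpec] = field(
        default_factory=lambda: {
            "high": GroupSpec(n_species=15, c2u_level=2.8, u2c_fraction=0.03),
            "low": GroupSpec(n_species=15, c2u_level=0.8, u2c_fraction=0.07),
        }
    )
    background_rate: float = 0.0  # substitutions per site
    transcript_efficiency: float = 1.0
    seed: int = 0
    gene_names: Optional[Sequence[str]] = None
    #: spread (lognormal sigma) of per-gene editing-rate multipliers; 0 means
    #: every gene edits at the group level, >0 makes some genes consistently
    #: editing-rich and others editing-poor across all species and groups
    gene_rate_sigma: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.gene_length_range
        if lo < 10:
            raise ValueError("genes must be at least 10 codons")
        if not 0.0 <= self.transcript_efficiency <= 1.0:
            raise ValueError("transcript_efficiency must be in [0, 1]")
        for spec in self.groups.values():
            if spec.c2u_level < 0 or not 0 <= spec.u2c_fraction <= 1:
                raise ValueError("invalid group editing levels")

    def resolved_gene_names(self) -> list[str]:
        if self.gene_names is not None:
            names = list(self.gene_names)
        elif self.n_genes <= len(MITO_GENES):
            names = list(MITO_GENES[: self.n_genes])
        else:
            names = [f"gene{i+1:03d}" for i in range(self.n_genes)]
        if len(names) != self.n_genes:
            raise ValueError("gene_names length must equal n_genes")
        return names


@dataclass
class SyntheticTruth:
    """A generated dataset plus everything needed to score recovery."""

    reference: SpeciesGeneSet
    species: dict[str, SpeciesGeneSet]
    true_sites: dict[str, list[EditingSite]]
    transcripts: dict[str, dict[str, str]]
    groups: dict[str, str]
    config: SimulationConfig

    def sites_for(self, species_id: str, gene: str) -> list[EditingSite]:
        return [s for s in self.true_sites[species_id] if s.gene == gene]


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Stop-free random CDS: ATG start, uniform non-stop codons, TAA end."""
    sense = sorted(set(STANDARD_CODE.forward) - _STOPS)
    body = [sense[i] for i in rng.integers(0, len(sense), size=n_codons - 2)]
    return "ATG" + "".join(body) + "TAA"


def simulate_reference(config: SimulationConfig) -> SpeciesGeneSet:
    """Random reference gene set (the non-editing species' ground truth)."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_length_range
    ref = SpeciesGeneSet(species_id="reference")
    for gene in config.resolved_gene_names():
        n_codons = int(rng.integers(lo, hi + 1))
        ref.add(GeneRecord(species_id="reference", gene=gene, seq=_random_cds(n_codons, rng)))
    return ref


def _c2u_candidates(codon: str, aa: str, table: CodonTable) -> list[int]:
    """Codon positions where genomic T->C yields a uniquely C2U-reconciling edit."""
    out = []
    for pos in (1, 2, 3):
        if codon[pos - 1] != "T":
            continue
        genomic = codon[: pos - 1] + "C" + codon[pos:]
        if genomic in _STOPS or table[genomic] == aa:
            continue
        if enumerate_codon_edits(genomic, aa, "C2U", 3, table) == [frozenset({pos})]:
            out.append(pos)
    return out


def _u2c_candidates(codon: str, aa: str, table: CodonTable) -> list[int]:
    """Codon positions where genomic C->T yields a uniquely U2C-reconciling edit."""
    out = []
    for pos in (1, 2, 3):
        if codon[pos - 1] != "C":
            continue
        genomic = codon[: pos - 1] + "T" + codon[pos:]
        if genomic in _STOPS or table[genomic] == aa:
            continue
        # C2U must fail outright: the predictor tries it first.
        if enumerate_codon_edits(genomic, aa, "C2U", 3, table):
            continue
        if enumerate_codon_edits(genomic, aa, "U2C", 3, table) == [frozenset({pos})]:
            out.append(pos)
    return out


def plant_edits(
    reference: SpeciesGeneSet,
    species_id: str,
    c2u_level: float,
    u2c_fraction: float = 0.0,
    seed: int | None = None,
    rng: Optional[np.random.Generator] = None,
    gene_rate: Optional[Mapping[str, float]] = None,
) -> tuple[SpeciesGeneSet, list[EditingSite]]:
    """Derive a species' genomic CDS set from the reference by anti-editing.

    For each gene the number of C-to-U sites is Poisson with mean
    ``c2u_level x length / 100`` (U-to-C analogously, scaled by
    ``u2c_fraction``); each site replaces the edited base by its genomic
    precursor in a codon where the edit is uniquely reconciling. At most one
    edit is planted per codon; the start and stop codons are left intact.
    If a gene is too short to host the drawn number of sites, fewer are
    planted with a warning. ``gene_rate`` optionally multiplies the level
    per gene, making some genes consistently editing-rich across species.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    table = STANDARD_CODE
    gene_set = SpeciesGeneSet(species_id=species_id)
    sites: list[EditingSite] = []
    for gene in reference.genes():
        ref_seq = reference[gene].seq
        n_codons = len(ref_seq) // 3
        codons = [ref_seq[3 * i : 3 * i + 3] for i in range(n_codons)]
        cand: dict[str, list[tuple[int, list[int]]]] = {"C2U": [], "U2C": []}
        for ci in range(2, n_codons):  # skip start (1) and stop (last), 1-based
            codon = codons[ci - 1]
            aa = table[codon]
            c2u = _c2u_candidates(codon, aa, table)
            u2c = _u2c_candidates(codon, aa, table)
            if c2u:
                cand["C2U"].append((ci, c2u))
            if u2c:
                cand["U2C"].append((ci, u2c))
        level = c2u_level * (gene_rate or {}).get(gene, 1.0)
        want = {
            "C2U": int(rng.poisson(level * len(ref_seq) / 100.0)),
            "U2C": int(rng.poisson(level * u2c_fraction * len(ref_seq) / 100.0)),
        }
        chosen: dict[int, tuple[str, int]] = {}  # codon_index -> (direction, codon_pos)
        for direction in ("C2U", "U2C"):
            pool = [(ci, ps) for ci, ps in cand[direction] if ci not in chosen]
            n = want[direction]
            if n > len(pool):
                logger.warning(
                    "%s/%s: only %d of %d requested %s sites can be hosted",
                    species_id, gene, len(pool), n, direction,
                )
                n = len(pool)
            if n == 0:
                continue
            picks = rng.choice(len(pool), size=n, replace=False)
            for k in picks:
                ci, ps = pool[int(k)]
                chosen[ci] = (direction, ps[int(rng.integers(len(ps)))])
        new_codons = list(codons)
        for ci, (direction, pos) in sorted(chosen.items()):
            edited = new_codons[ci - 1]
            genomic_base = "C" if direction == "C2U" else "T"
            transcript_base = "T" if direction == "C2U" else "C"
            genomic = edited[: pos - 1] + genomic_base + edited[pos:]
            new_codons[ci - 1] = genomic
            sites.append(
                EditingSite(
                    species_id=species_id,
                    gene=gene,
                    position=(ci - 1) * 3 + pos,
                    direction=direction,
                    codon_index=ci,
                    codon_pos=pos,
                    from_base=genomic_base,
                    to_base=transcript_base,
                    aa_from=table[genomic],
                    aa_to=table[edited],
                )
            )
        gene_set.add(
            GeneRecord(species_id=species_id, gene=gene, seq="".join(new_codons))
        )
    return gene_set, sorted(sites, key=lambda s: (s.gene, s.position))


def add_background_divergence(
    gene_set: SpeciesGeneSet,
    rate: float,
    seed: int | None = None,
    rng: Optional[np.random.Generator] = None,
    protected: Mapping[str, set[int]] | None = None,
    synonymous_bias: float = 0.9,
) -> SpeciesGeneSet:
    """Add random substitutions away from planted codons.

    ``rate`` is a per-site substitution probability (keep it small, <0.05);
    substitutions prefer synonymous changes with probability
    ``synonymous_bias`` and never create stop codons. ``protected`` maps
    gene -> set of 1-based codon indices (typically the planted ones) left
    untouched, so recall of planted sites is unaffected by construction.
    """
    if rate < 0 or rate >= 0.05:
        raise ValueError("background rate must be in [0, 0.05)")
    if rng is None:
        rng = np.random.default_rng(seed)
    table = STANDARD_CODE
    protected = protected or {}
    out = SpeciesGeneSet(species_id=gene_set.species_id, group=gene_set.group)
    for gene in gene_set.genes():
        seq = gene_set[gene].seq
        n_codons = len(seq) // 3
        codons = [seq[3 * i : 3 * i + 3] for i in range(n_codons)]
        shielded = protected.get(gene, set())
        for ci in range(2, n_codons):
            if ci in shielded:
                continue
            if rng.random() >= 3 * rate:
                continue
            codon = codons[ci - 1]
            aa = table[codon]
            syn, nonsyn = [], []
            for pos in range(3):
                for b in _BASES:
                    if b == codon[pos]:
                        continue
                    alt = codon[:pos] + b + codon[pos + 1 :]
                    if alt in _STOPS:
                        continue
                    (syn if table[alt] == aa else nonsyn).append(alt)
            pool = syn if (syn and rng.random() < synonymous_bias) else nonsyn or syn
            if pool:
                codons[ci - 1] = pool[int(rng.integers(len(pool)))]
        out.add(GeneRecord(species_id=gene_set.species_id, gene=gene, seq="".join(codons)))
    return out


def simulate_transcripts(
    gene_set: SpeciesGeneSet,
    true_sites: Sequence[EditingSite],
    efficiency: float,
    seed: int | None = None,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, str]:
    """Transcript per gene: each true edit applied independently.

    With probability ``efficiency`` a site's genomic base is converted to
    its edited base (C->T for C-to-U, T->C for U-to-C); at efficiency 1 the
    transcript is the fully edited CDS, at 0 it equals the genomic CDS.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    by_gene: dict[str, list[EditingSite]] = {}
    for s in true_sites:
        by_gene.setdefault(s.gene, []).append(s)
    out = {}
    for gene in gene_set.genes():
        bases = list(gene_set[gene].seq)
        for s in sorted(by_gene.get(gene, []), key=lambda x: x.position):
            if rng.random() < efficiency:
                bases[s.position - 1] = s.to_base
        out[gene] = "".join(bases)
    return out


def evolve_sites_on_tree(
    tree: str | dendropy.Tree,
    root_sites: Sequence,
    loss_prob: float,
    gain_prob: float = 0.0,
    seed: int | None = None,
    gain_pool: Sequence | None = None,
) -> dict[str, set]:
    """Evolve a presence/absence site set along a tree by per-branch loss/gain.

    Each site present at a node survives each descendant branch with
    probability ``1 - loss_prob``; each absent slot of ``gain_pool``
    (default: the root set) is gained on a branch with probability
    ``gain_prob``. Returns the site set at every leaf, keyed by taxon label.
    This emulates the loss-dominated decay of editing during
    diversification.
    """
    if not 0 <= loss_prob <= 1 or not 0 <= gain_prob <= 1:
        raise ValueError("probabilities must be in [0, 1]")
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    if len(tree.leaf_nodes()) < 4:
        raise ValueError("tree must have at least 4 leaves")
    rng = np.random.default_rng(seed)
    pool = list(gain_pool) if gain_pool is not None else list(root_sites)
    states: dict[int, frozenset] = {id(tree.seed_node): frozenset(root_sites)}
    out: dict[str, set] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            parent_state = states[id(node.parent_node)]
            kept = {s for s in parent_state if rng.random() >= loss_prob}
            if gain_prob > 0:
                for slot in pool:
                    if slot not in kept and rng.random() < gain_prob:
                        kept.add(slot)
            states[id(node)] = frozenset(kept)
        if node.is_leaf():
            out[node.taxon.label] = set(states[id(node)])
    return out


def simulate_dataset(config: SimulationConfig) -> SyntheticTruth:
    """Full closed-loop dataset: reference, species, truth, transcripts."""
    master = np.random.default_rng(config.seed)
    reference = simulate_reference(config)
    gene_rate: Optional[dict[str, float]] = None
    if config.gene_rate_sigma > 0:
        sigma = config.gene_rate_sigma
        # mean-1 lognormal so the group level is preserved in expectation
        gene_rate = {
            g: float(master.lognormal(-sigma * sigma / 2.0, sigma))
            for g in config.resolved_gene_names()
        }
    species: dict[str, SpeciesGeneSet] = {}
    true_sites: dict[str, list[EditingSite]] = {}
    transcripts: dict[str, dict[str, str]] = {}
    groups: dict[str, str] = {}
    for group_name in sorted(config.groups):
        spec = config.groups[group_name]
        for k in range(spec.n_species):
            sid = f"{group_name}_{k+1:02d}"
            rng = np.random.default_rng(master.integers(2**31))
            gene_set, sites = plant_edits(
                reference, sid, spec.c2u_level, spec.u2c_fraction, rng=rng,
                gene_rate=gene_rate,
            )
            gene_set.group = group_name
            if config.background_rate > 0:
                shield = {}
                for s in sites:
                    shield.setdefault(s.gene, set()).add(s.codon_index)
                gene_set = add_background_divergence(
                    gene_set, config.background_rate, rng=rng, protected=shield
                )
            species[sid] = gene_set
            true_sites[sid] = sites
            transcripts[sid] = simulate_transcripts(
                gene_set, sites, config.transcript_efficiency, rng=rng
            )
            groups[sid] = group_name
    return SyntheticTruth(
        reference=reference,
        species=species,
        true_sites=true_sites,
        transcripts=transcripts,
        groups=groups,
        config=config,
    )
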