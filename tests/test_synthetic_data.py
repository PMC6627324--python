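import numpy as np
import pytest

from editome.edit_predict import predict_editome, predict_sites
from editome.seqio import STANDARD_CODE, translate
from editome.synthetic_data import (
    GroupSpec,
    SimulationConfig,
    add_background_divergence,
    evolve_sites_on_tree,
    plant_edits,
    simulate_dataset,
    simulate_reference,
    simulate_transcripts,
)

_STOPS = {"TAA", "TAG", "TGA"}


def small_config(**kw):
    defaults = dict(
        n_genes=4,
        gene_length_range=(60, 100),
        groups={"hi": GroupSpec(2, 2.5, 0.05), "lo": GroupSpec(2, 0.7, 0.05)},
        seed=9,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


# ---------------------------------------------------------------- reference


def test_reference_is_deterministic_under_seed():
    a = simulate_reference(small_config())
    b = simulate_reference(small_config())
    assert all(a[g].seq == b[g].seq for g in a.genes())
    c = simulate_reference(small_config(seed=10))
    assert any(a[g].seq != c[g].seq for g in a.genes())


def test_reference_genes_are_stop_free_cds():
    ref = simulate_reference(small_config(n_genes=33, gene_length_range=(100, 400)))
    assert len(ref) == 33
    for g in ref.genes():
        prot = translate(ref[g].seq)
        assert prot.endswith("*")
        assert "*" not in prot[:-1]
        assert ref[g].seq.startswith("ATG")


def test_default_gene_names_are_the_mitochondrial_set():
    ref = simulate_reference(small_config(n_genes=33, gene_length_range=(100, 400)))
    assert "atp9" in ref and "tatC" in ref and "nad4L" in ref


# ---------------------------------------------------------------- planting


def test_plant_edits_level_zero_is_identity():
    ref = simulate_reference(small_config())
    gs, sites = plant_edits(ref, "sp1", c2u_level=0.0, seed=1)
    assert sites == []
    assert all(gs[g].seq == ref[g].seq for g in ref.genes())


def test_planted_site_counts_are_poisson_with_the_configured_mean():
    config = SimulationConfig(
        n_genes=1, gene_length_range=(100, 100), seed=2,
        groups={"g": GroupSpec(1, 2.0)},
    )
    ref = simulate_reference(config)  # one 300-nt gene
    assert ref[ref.genes()[0]].length == 300
    counts = [
        len(plant_edits(ref, "sp", 2.0, 0.0, seed=s)[1]) for s in range(500)
    ]
    assert np.mean(counts) == pytest.approx(6.0, abs=0.3)


def test_planted_edits_reverse_to_the_reference_protein():
    ref = simulate_reference(small_config())
    gs, sites = plant_edits(ref, "sp1", c2u_level=3.0, u2c_fraction=0.1, seed=3)
    for s in sites:
        cds = gs[s.gene].seq
        assert cds[s.position - 1] == s.from_base
        codon = list(cds[(s.codon_index - 1) * 3 : s.codon_index * 3])
        codon[s.codon_pos - 1] = s.to_base
        ref_aa = translate(ref[s.gene].seq)[s.codon_index - 1]
        assert STANDARD_CODE["".join(codon)] == ref_aa
        assert s.aa_from != s.aa_to  # silent edits are never planted


def test_planted_edits_are_recovered_closed_loop():
    ref = simulate_reference(small_config())
    gs, sites = plant_edits(ref, "sp1", c2u_level=2.0, u2c_fraction=0.1, seed=4)
    for gene in gs.genes():
        predicted = predict_sites(gs[gene], translate(ref[gene].seq))
        want = [(s.position, s.direction) for s in sites if s.gene == gene]
        assert [(s.position, s.direction) for s in predicted] == want


# ---------------------------------------------------------------- background


def test_background_rate_zero_is_identity():
    ref = simulate_reference(small_config())
    gs, _ = plant_edits(ref, "sp1", 1.0, seed=5)
    out = add_background_divergence(gs, 0.0, seed=6)
    assert all(out[g].seq == gs[g].seq for g in gs.genes())


def test_background_divergence_spares_protected_codons_keeping_recall():
    config = small_config(n_genes=6, gene_length_range=(90, 150))
    ref = simulate_reference(config)
    gs, sites = plant_edits(ref, "sp1", 2.0, seed=7)
    shield = {}
    for s in sites:
        shield.setdefault(s.gene, set()).add(s.codon_index)
    noisy = add_background_divergence(
        gs, 0.04, seed=8, protected=shield, synonymous_bias=0.0
    )
    truth = {(s.gene, s.position, s.direction) for s in sites}
    predicted = set()
    for gene in noisy.genes():
        for s in predict_sites(noisy[gene], translate(ref[gene].seq)):
            predicted.add((gene, s.position, s.direction))
    assert truth <= predicted  # recall stays 1: planted codons untouched
    assert predicted - truth  # nonsynonymous noise produces false positives


def test_background_rate_bounds_enforced():
    ref = simulate_reference(small_config())
    with pytest.raises(ValueError):
        add_background_divergence(ref, 0.2, seed=1)


# ---------------------------------------------------------------- transcripts


def test_transcript_efficiency_extremes():
    ref = simulate_reference(small_config())
    gs, sites = plant_edits(ref, "sp1", 2.0, 0.1, seed=10)
    full = simulate_transcripts(gs, sites, 1.0, seed=11)
    none = simulate_transcripts(gs, sites, 0.0, seed=12)
    for gene in gs.genes():
        assert none[gene] == gs[gene].seq
        edited = list(gs[gene].seq)
        for s in sites:
            if s.gene == gene:
                edited[s.position - 1] = s.to_base
        assert full[gene] == "".join(edited)


def test_transcript_partial_editing_is_binomial():
    config = SimulationConfig(
        n_genes=8, gene_length_range=(300, 400), seed=13,
        groups={"g": GroupSpec(1, 5.0)},
    )
    ref = simulate_reference(config)
    gs, sites = plant_edits(ref, "sp", 5.0, seed=14)
    n = len(sites)
    assert n > 200
    tx = simulate_transcripts(gs, sites, 0.5, seed=15)
    applied = sum(
        1 for s in sites if tx[s.gene][s.position - 1] == s.to_base
    )
    assert abs(applied - 0.5 * n) < 0.1 * n


# ---------------------------------------------------------------- tree


NEWICK6 = "((A,B),((C,D),(E,F)));"


def test_evolution_without_loss_or_gain_copies_root():
    root = {("atp9", i) for i in range(1, 21)}
    leaves = evolve_sites_on_tree(NEWICK6, root, loss_prob=0.0, gain_prob=0.0, seed=1)
    assert set(leaves) == set("ABCDEF")
    assert all(s == root for s in leaves.values())


def test_total_loss_empties_every_leaf():
    root = {("atp9", i) for i in range(1, 21)}
    leaves = evolve_sites_on_tree(NEWICK6, root, loss_prob=1.0, seed=2)
    assert all(s == set() for s in leaves.values())


def test_loss_only_evolution_supports_topology_recovery():
    """NJ on loss-evolved presence/absence recovers the generating tree."""
    from editome.edit_matrix import BinaryEditingMatrix
    from editome.phylo_binary import hamming_distances, neighbor_joining

    root = [("g", i) for i in range(1, 301)]
    newick = "((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);"
    true_splits = {
        frozenset({"C", "D"}), frozenset({"E", "F"}),
        frozenset({"C", "D", "E", "F"}),
    }
    hits = 0
    reps = 20
    for rep in range(reps):
        leaves = evolve_sites_on_tree(newick, root, loss_prob=0.2, seed=rep)
        taxa = sorted(leaves)
        chars = sorted({c for s in leaves.values() for c in s})
        cells = np.array(
            [[1 if c in leaves[t] else 0 for c in chars] for t in taxa], dtype=np.uint8
        )
        m = BinaryEditingMatrix(taxa=taxa, characters=chars, cells=cells)
        tree = neighbor_joining(hamming_distances(m))
        hits += tree.splits() == true_splits
    assert hits >= 0.9 * reps


# ---------------------------------------------------------------- dataset


def test_dataset_determinism_and_group_structure(small_truth):
    assert len(small_truth.species) == 8
    assert set(small_truth.groups.values()) == {"high", "low"}
    config2 = SimulationConfig(
        n_genes=6, gene_length_range=(60, 120),
        groups={
            "high": GroupSpec(4, 2.8, 0.05),
            "low": GroupSpec(4, 0.8, 0.05),
        },
        seed=42,
    )
    again = simulate_dataset(config2)
    sid = sorted(small_truth.species)[0]
    assert [
        (s.gene, s.position) for s in again.true_sites[sid]
    ] == [(s.gene, s.position) for s in small_truth.true_sites[sid]]


def test_gene_rate_heterogeneity_is_shared_across_groups():
    """With a per-gene rate spread, the same genes are editing-rich in both
    groups, so per-gene mean frequencies correlate across groups."""
    from editome.edit_stats import pearson_correlation

    config = SimulationConfig(
        n_genes=33, gene_length_range=(100, 400),
        groups={"hi": GroupSpec(6, 2.8), "lo": GroupSpec(6, 0.8)},
        seed=77, gene_rate_sigma=0.6,
    )
    truth = simulate_dataset(config)
    genes = truth.reference.genes()

    def mean_freq(group):
        members = [s for s, g in truth.groups.items() if g == group]
        out = []
        for gene in genes:
            vals = [
                100.0 * len(truth.sites_for(sid, gene)) / truth.species[sid][gene].length
                for sid in members
            ]
            out.append(np.mean(vals))
        return out

    res = pearson_correlation(mean_freq("hi"), mean_freq("lo"))
    assert res.r > 0.5
    assert res.p < 0.01


def test_group_editing_levels_separate_in_expectation(small_truth):
    totals = {sid: len(sites) for sid, sites in small_truth.true_sites.items()}
    high = np.mean([totals[s] for s, g in small_truth.groups.items() if g == "high"])
    low = np.mean([totals[s] for s, g in small_truth.groups.items() if g == "low"])
    assert high > 2 * low
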