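"""Generator ground truth: event bookkeeping, determinism, and the closed-form
expectations the branching model implies."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from ohnolog_forge.config import SimulationConfig
from ohnolog_forge.errors import ConfigurationError
from ohnolog_forge import simulate as sim
from ohnolog_forge.network import find_bridged_pairs, pair_conservation


def cfg(**kw):
    return SimulationConfig(**kw)


class TestGeneFamilies:
    def test_no_event_config_gives_single_copy_families(self):
        c = cfg(n_families=25, per_branch_dup_rate=0.0,
                retention_round1=0.0, retention_round2=0.0, seed=1)
        fams = sim.simulate_gene_families(c)
        n_species = len(c.species_ladder) + 1
        for fam in fams.families:
            leaves = fam.root.leaf_names()
            assert len(leaves) == n_species
            species = {fams.gene_species_map[g] for g in leaves}
            assert len(species) == n_species
            assert fam.truth_events == []

    def test_full_retention_forces_four_ohnologs_and_three_wgd_nodes(self):
        c = cfg(n_families=20, per_branch_dup_rate=0.0,
                retention_round1=1.0, retention_round2=1.0, seed=2)
        fams = sim.simulate_gene_families(c)
        stree = c.species_tree()
        post_wgd = {s for s in stree.species
                    if stree.is_ancestor_or_equal(c.wgd_branch, s)}
        for fam in fams.families:
            by_species = {}
            for g in fam.root.leaf_names():
                by_species.setdefault(fams.gene_species_map[g], []).append(g)
            for s in post_wgd:
                assert len(by_species[s]) == 4
            kinds = [ev.kind for ev in fam.truth_events if ev.survived]
            assert kinds.count(sim.WGD_ROUND1) == 1
            assert kinds.count(sim.WGD_ROUND2) == 2

    def test_wgd_survival_fraction_matches_branching_model(self):
        # P(>=2 surviving copies) = 1 - (1 - r1)(1 - r2), loss-free
        r1 = r2 = 0.3
        c = cfg(n_families=2000, per_branch_dup_rate=0.0,
                retention_round1=r1, retention_round2=r2, seed=7)
        fams = sim.simulate_gene_families(c)
        expected = 1 - (1 - r1) * (1 - r2)
        hits = 0
        for fam in fams.families:
            focal = [g for g in fam.root.leaf_names()
                     if fams.gene_species_map[g] == c.focal_species]
            hits += len(focal) >= 2
        frac = hits / c.n_families
        se = math.sqrt(expected * (1 - expected) / c.n_families)
        assert abs(frac - expected) <= 3 * se

    def test_gene_counts_conserve_births_without_loss(self):
        c = cfg(n_families=40, per_branch_dup_rate=0.05, seed=3)
        fams = sim.simulate_gene_families(c)
        stree = c.species_tree()
        for fam in fams.families:
            for species in ("Homo_sapiens", "Danio_rerio",
                            "Drosophila_melanogaster"):
                n_genes = sum(
                    1 for g in fam.root.leaf_names()
                    if fams.gene_species_map[g] == species)
                on_path = sum(
                    1 for ev in fam.truth_events
                    if ev.survived and stree.is_ancestor_or_equal(ev.taxon, species))
                assert n_genes == 1 + on_path

    def test_gene_ids_unique_across_set(self):
        fams = sim.simulate_gene_families(cfg(n_families=30, seed=4))
        all_genes = [g for f in fams.families if f.root
                     for g in f.root.leaf_names()]
        assert len(all_genes) == len(set(all_genes))

    def test_identical_config_and_seed_is_bitwise_deterministic(self):
        c = cfg(n_families=40, per_branch_dup_rate=0.05, seed=9)
        a, b = sim.simulate_gene_families(c), sim.simulate_gene_families(c)
        assert ([f.root.to_newick() for f in a.families]
                == [f.root.to_newick() for f in b.families])
        la, lb = sim.simulate_genome_layout(a, c), sim.simulate_genome_layout(b, c)
        assert la.chromosomes == lb.chromosomes
        aa, ab = sim.simulate_expression_atlas(a, c), sim.simulate_expression_atlas(b, c)
        assert aa.equals(ab)
        na, nb = sim.simulate_signal_network(a, c), sim.simulate_signal_network(b, c)
        assert na.network.edges == nb.network.edges and na.pairs == nb.pairs

    @pytest.mark.parametrize("field,value", [
        ("retention_round1", 1.2),
        ("per_branch_dup_rate", -0.1),
        ("n_tissues", 1),
        ("wgd_branch", "Dinosauria"),
        ("n_families", 0),
    ])
    def test_invalid_configs_rejected(self, field, value):
        with pytest.raises(ConfigurationError):
            cfg(**{field: value}).validate()


class TestGenomeLayout:
    def test_every_gene_exactly_one_position(self):
        c = cfg(n_families=60, seed=5)
        fams = sim.simulate_gene_families(c)
        layout = sim.simulate_genome_layout(fams, c)
        placed = [g for genes in layout.chromosomes.values() for g in genes]
        focal = set(fams.genes_of_species(c.focal_species))
        assert sorted(placed) == sorted(focal)
        assert len(placed) == len(set(placed))

    def test_capacity_overflow_is_configuration_error(self):
        c = cfg(n_families=100, n_chromosomes=1, genes_per_chromosome=5, seed=5)
        fams = sim.simulate_gene_families(c)
        with pytest.raises(ConfigurationError):
            sim.simulate_genome_layout(fams, c)

    def test_tandem_duplicates_adjacent_when_fraction_one(self):
        c = cfg(n_families=120, per_branch_dup_rate=0.15, tandem_fraction=1.0,
                retention_round1=0.0, retention_round2=0.0, seed=6)
        fams = sim.simulate_gene_families(c)
        layout = sim.simulate_genome_layout(fams, c)
        by_key = {}
        for rec in fams.gene_records.values():
            if rec.species != c.focal_species:
                continue
            by_key.setdefault((rec.family, rec.lineage, rec.wgd_track),
                              []).append(rec.gene_id)
        checked = 0
        for genes in by_key.values():
            if len(genes) < 2:
                continue
            positions = sorted(layout.position[g] for g in genes)
            chroms = {c for c, _ in positions}
            assert len(chroms) == 1
            idxs = [i for _, i in positions]
            assert idxs == list(range(idxs[0], idxs[0] + len(idxs)))
            checked += 1
        assert checked > 0

    def test_collinear_ohnolog_blocks_recoverable(self):
        # retention 1 on few chromosomes -> paralogon detection must find the block
        from ohnolog_forge.paralogons import build_anchors, detect_multiplicons
        c = cfg(n_families=20, per_branch_dup_rate=0.0, retention_round1=1.0,
                retention_round2=0.0, n_chromosomes=2, genes_per_chromosome=40,
                seed=8)
        fams = sim.simulate_gene_families(c)
        layout = sim.simulate_genome_layout(fams, c)
        anchors = build_anchors(sim.wgd_pairs(fams), layout)
        mps = detect_multiplicons(anchors, layout)
        assert len(mps) >= 1
        assert max(len(m.anchors) for m in mps) >= 10


class TestExpressionAtlas:
    def test_zero_divergence_gives_identical_paralog_profiles(self):
        c = cfg(n_families=30, divergence_rate=0.0, retention_round1=0.5,
                retention_round2=0.5, seed=10)
        fams = sim.simulate_gene_families(c)
        atlas = sim.simulate_expression_atlas(fams, c)
        pairs = sim.wgd_pairs(fams)
        assert pairs
        for a, b in pairs:
            assert np.array_equal(atlas.loc[a].values, atlas.loc[b].values)
            assert sps.pearsonr(atlas.loc[a], atlas.loc[b]).statistic == pytest.approx(1.0)

    def test_median_pair_correlation_decays_with_age(self):
        from ohnolog_forge.timing import reconcile_families
        from ohnolog_forge.retention import paralog_pairs_by_age
        c = cfg(n_families=300, per_branch_dup_rate=0.06,
                retention_round1=0.3, retention_round2=0.3, seed=41)
        fams = sim.simulate_gene_families(c)
        st = c.species_tree()
        reconcile_families(fams, st)
        atlas = sim.simulate_expression_atlas(fams, c)
        medians = []
        for lo, hi in ((0, 4), (5, 7), (8, 11)):  # old, mid, young (ladder depth)
            vals = []
            for a, b, taxon in paralog_pairs_by_age(fams, st, c.focal_species):
                if lo <= st.depth[taxon] <= hi:
                    vals.append(sps.pearsonr(atlas.loc[a], atlas.loc[b]).statistic)
            assert len(vals) > 50
            medians.append(np.median(vals))
        assert medians[0] < medians[1] < medians[2]

    def test_expressed_fraction_matches_lognormal_tail(self):
        loc, scale, thr = 5.3, 1.0, 200.0
        c = cfg(n_families=400, per_branch_dup_rate=0.0, retention_round1=0.0,
                retention_round2=0.0, divergence_rate=0.0,
                expression_base=(loc, scale), seed=12)
        fams = sim.simulate_gene_families(c)
        atlas = sim.simulate_expression_atlas(fams, c)
        focal = atlas.loc[[g for g in atlas.index
                           if fams.gene_species_map[g] == c.focal_species]]
        f = 1 - sps.norm.cdf((math.log(thr) - loc) / scale)
        n_cells = focal.size
        realized = (focal.values >= thr).mean()
        se = math.sqrt(f * (1 - f) / n_cells)
        assert abs(realized - f) <= 3 * se

    def test_atlas_nonnegative_and_rejects_too_few_tissues(self):
        c = cfg(n_families=10, seed=13)
        fams = sim.simulate_gene_families(c)
        atlas = sim.simulate_expression_atlas(fams, c)
        assert (atlas.values > 0).all()
        bad = cfg(n_families=10, seed=13)
        object.__setattr__(bad, "n_tissues", 1)
        with pytest.raises(ConfigurationError):
            sim.simulate_expression_atlas(fams, bad)


class TestSignalNetwork:
    def test_full_inheritance_no_gain_conserves_every_edge(self):
        c = cfg(n_families=50, per_branch_dup_rate=0.0, retention_round1=1.0,
                retention_round2=0.0, edge_inheritance_q=1.0,
                edge_gain_rate=0.0, bridging_prob=0.0, seed=14)
        fams = sim.simulate_gene_families(c)
        simnet = sim.simulate_signal_network(fams, c)
        res = pair_conservation(simnet.network, simnet.pairs)
        fracs = [r.conserved_fraction for r in res["pairs"]
                 if r.conserved_fraction is not None]
        assert fracs and all(f == pytest.approx(1.0) for f in fracs)

    def test_shared_fraction_tracks_inheritance_probability(self):
        q = 0.5
        c = cfg(n_families=350, per_branch_dup_rate=0.0, retention_round1=1.0,
                retention_round2=0.0, edge_inheritance_q=q, edge_gain_rate=0.0,
                bridging_prob=0.0, ancestral_mean_degree=20, seed=15)
        fams = sim.simulate_gene_families(c)
        simnet = sim.simulate_signal_network(fams, c)
        res = pair_conservation(simnet.network, simnet.pairs)
        fracs = np.array([r.conserved_fraction for r in res["pairs"]
                          if r.conserved_fraction is not None])
        assert len(fracs) >= 300
        sem = fracs.std(ddof=1) / math.sqrt(len(fracs))
        assert abs(fracs.mean() - q) <= 3 * sem

    def test_no_bridging_probability_no_bridged_pairs(self):
        c = cfg(n_families=100, retention_round1=1.0, retention_round2=0.0,
                per_branch_dup_rate=0.0, bridging_prob=0.0, seed=16)
        fams = sim.simulate_gene_families(c)
        simnet = sim.simulate_signal_network(fams, c)
        assert find_bridged_pairs(simnet.network, simnet.pairs)["n_bridged"] == 0

    def test_bridged_fraction_tracks_bridging_probability(self):
        b = 0.3
        c = cfg(n_families=300, retention_round1=1.0, retention_round2=0.0,
                per_branch_dup_rate=0.0, bridging_prob=b, seed=17)
        fams = sim.simulate_gene_families(c)
        simnet = sim.simulate_signal_network(fams, c)
        res = find_bridged_pairs(simnet.network, simnet.pairs)
        n = res["n_bridged"] + res["n_unbridged"]
        se = math.sqrt(b * (1 - b) / n)
        assert abs(res["n_bridged"] / n - b) <= 3 * se
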