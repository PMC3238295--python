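"""Synthetic data with known ground truth for every downstream analysis stage.

Four generators share one seeded configuration:

* ``simulate_gene_families`` — gene families evolving along the species ladder
  by per-branch birth (tandem duplication), loss, and a two-round WGD on the
  configured stem branch.  Round 1 duplicates each lineage and retains the new
  copy with probability ``retention_round1``; round 2 then duplicates every
  surviving copy with retention ``retention_round2``, so a fully retained
  family carries four ohnologs and three WGD duplication nodes.
* ``simulate_genome_layout`` — focal-species genes placed in ordinal positions;
  co-ohnologs of consecutive families land collinearly on partner chromosomes
  (the genomic footprint paralogon detection looks for), tandem duplicates sit
  adjacent to their parent copy with probability ``tandem_fraction``.
* ``simulate_expression_atlas`` — per-family ancestral tissue profiles with
  independent multiplicative log-normal drift per unit age, so paralog
  expression similarity decays with duplication age.
* ``simulate_signal_network`` — an ancestral signed network whose duplicate
  descendants inherit incident edges with probability ``edge_inheritance_q``,
  gain Poisson novel edges and are bridged to co-duplicates with probability
  ``bridging_prob``.

Ages are measured in ladder steps (unit branch lengths).  All randomness flows
from ``config.seed`` through deterministic per-family substreams.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import ConfigurationError
from .network import Edge, SignalNetwork, POLARITIES, SCAFFOLD
from .trees import DUPLICATION, SPECIATION, SpeciesTree, TreeNode, prune_leaves

WGD_ROUND1 = "wgd_round1"
WGD_ROUND2 = "wgd_round2"
TANDEM = "tandem"

_DEAD = "__dead__"


@dataclass
class TruthEvent:
    """One true duplication event: where it happened and what kind it was."""
    node_label: str
    taxon: str
    kind: str  # wgd_round1 | wgd_round2 | tandem
    survived: bool = True


@dataclass
class GeneRecord:
    gene_id: str
    species: str
    family: str
    lineage: int            # pre-WGD lineage index within the family
    wgd_track: Optional[int]  # 0..3 ohnolog track, None outside the WGD clade


@dataclass
class Family:
    fam_id: str
    root: Optional[TreeNode]          # observed (pruned) gene tree; None if extinct
    truth_events: list[TruthEvent]
    node_taxa: dict[str, str]         # true taxon of every surviving internal node
    n_losses: int = 0


@dataclass
class FamilySet:
    families: list[Family]
    gene_species_map: dict[str, str]
    gene_records: dict[str, GeneRecord]
    config: SimulationConfig

    def genes_of_species(self, species: str) -> list[str]:
        return [g for g, s in self.gene_species_map.items() if s == species]


@dataclass
class GenomeLayout:
    """Ordinal gene positions: per chromosome an ordered gene list."""
    chromosomes: dict[str, list[str]]

    def __post_init__(self):
        self.position: dict[str, tuple[str, int]] = {}
        for chrom, genes in self.chromosomes.items():
            for idx, gene in enumerate(genes):
                if gene in self.position:
                    raise ConfigurationError(f"gene placed twice: {gene}")
                self.position[gene] = (chrom, idx)

    def total_positions(self) -> int:
        return sum(len(g) for g in self.chromosomes.values())


@dataclass
class SimulatedNetwork:
    network: SignalNetwork            # extant focal-species network
    ancestral: SignalNetwork          # pre-WGD network over family ids
    pairs: list[tuple[str, str]]      # WGD paralog pairs present in the network


# ---------------------------------------------------------------------------
# gene families
# ---------------------------------------------------------------------------

class _FamilySimulator:
    def __init__(self, fam_idx: int, config: SimulationConfig, stree: SpeciesTree,
                 rng: np.random.Generator):
        self.config = config
        self.stree = stree
        self.rng = rng
        self.fam_id = f"F{fam_idx:04d}"
        self.gene_counter = 0
        self.node_counter = 0
        self.lineage_counter = 0
        self.events: list[TruthEvent] = []
        self.node_taxa: dict[str, str] = {}
        self.records: dict[str, GeneRecord] = {}
        self.n_losses = 0

    def _label(self) -> str:
        self.node_counter += 1
        return f"{self.fam_id}N{self.node_counter:03d}"

    def _new_gene(self, species: str, lineage: int, track: Optional[int]) -> str:
        self.gene_counter += 1
        gid = f"{self.fam_id}G{self.gene_counter:03d}"
        self.records[gid] = GeneRecord(gid, species, self.fam_id, lineage, track)
        return gid

    def _dup(self, node: TreeNode, taxon: str, kind: str) -> tuple[TreeNode, TreeNode]:
        node.name = self._label()
        node.event = DUPLICATION
        node.bootstrap = round(float(self.rng.uniform(0.8, 1.0)), 3)
        self.node_taxa[node.name] = taxon
        self.events.append(TruthEvent(node.name, taxon, kind))
        return node.add_child(TreeNode()), node.add_child(TreeNode())

    def run(self) -> Family:
        cfg = self.config
        root = TreeNode()
        self._evolve(root, self.stree.root, lineage=0, track=None)
        pruned = prune_leaves(root, keep=lambda leaf: leaf.name != _DEAD)
        surviving_labels = (
            {n.name for n in pruned.postorder() if not n.is_leaf} if pruned else set())
        for ev in self.events:
            ev.survived = ev.node_label in surviving_labels
        surviving_genes = (
            {n.name for n in pruned.leaves()} if pruned else set())
        self.records = {g: r for g, r in self.records.items() if g in surviving_genes}
        self.node_taxa = {k: v for k, v in self.node_taxa.items()
                          if k in surviving_labels}
        # compact surviving WGD tracks to consecutive ranks (an unretained
        # round-2 copy leaves gaps like {0, 2} that would collide on layouts)
        tracks = sorted({r.wgd_track for r in self.records.values()
                         if r.wgd_track is not None})
        rank = {t: i for i, t in enumerate(tracks)}
        for rec in self.records.values():
            if rec.wgd_track is not None:
                rec.wgd_track = rank[rec.wgd_track]
        return Family(self.fam_id, pruned, self.events, self.node_taxa, self.n_losses)

    def _evolve(self, node: TreeNode, sp_node: TreeNode, lineage: int,
                track: Optional[int]) -> None:
        """Grow the gene subtree for one lineage entering the branch above
        ``sp_node``.  Branch events: tandem birth, the WGD (on its branch),
        loss; then a speciation or leaf at the branch bottom."""
        cfg, rng = self.config, self.rng
        taxon_here = sp_node.name
        lineages: list[tuple[TreeNode, int, Optional[int]]] = [(node, lineage, track)]

        # tandem/segmental birth (at most one per lineage per branch)
        nxt = []
        for ln, lg, tr in lineages:
            if rng.random() < cfg.per_branch_dup_rate:
                c1, c2 = self._dup(ln, taxon_here, TANDEM)
                self.lineage_counter += 1
                new_lg = self.lineage_counter if tr is None else lg
                nxt.append((c1, lg, tr))
                nxt.append((c2, new_lg if tr is None else lg, tr))
            else:
                nxt.append((ln, lg, tr))
        lineages = nxt

        # two-round WGD on its stem branch
        if taxon_here == cfg.wgd_branch:
            after_r1 = []
            for ln, lg, tr in lineages:
                if rng.random() < cfg.retention_round1:
                    c1, c2 = self._dup(ln, taxon_here, WGD_ROUND1)
                    after_r1.extend([(c1, lg, 0), (c2, lg, 1)])
                else:
                    after_r1.append((ln, lg, 0))
            after_r2 = []
            for ln, lg, tr in after_r1:
                if rng.random() < cfg.retention_round2:
                    c1, c2 = self._dup(ln, taxon_here, WGD_ROUND2)
                    after_r2.extend([(c1, lg, 2 * tr), (c2, lg, 2 * tr + 1)])
                else:
                    after_r2.append((ln, lg, 2 * tr))
            lineages = after_r2

        # loss
        survivors = []
        for ln, lg, tr in lineages:
            if cfg.loss_rate > 0 and rng.random() < cfg.loss_rate:
                ln.name = _DEAD
                self.n_losses += 1
            else:
                survivors.append((ln, lg, tr))
        lineages = survivors

        # branch bottom: speciation or extant gene
        for ln, lg, tr in lineages:
            if sp_node.is_leaf:
                ln.name = self._new_gene(sp_node.name, lg, tr)
            else:
                ln.name = self._label()
                ln.event = SPECIATION
                ln.bootstrap = round(float(rng.uniform(0.8, 1.0)), 3)
                self.node_taxa[ln.name] = taxon_here
                for sp_child in sp_node.children:
                    self._evolve(ln.add_child(TreeNode()), sp_child, lg, tr)


def simulate_gene_families(config: SimulationConfig) -> FamilySet:
    """Generate a :class:`FamilySet` with per-node ground truth."""
    config.validate()
    stree = config.species_tree()
    families: list[Family] = []
    gene_species: dict[str, str] = {}
    records: dict[str, GeneRecord] = {}
    root_seq = np.random.SeedSequence(config.seed)
    fam_seeds = root_seq.spawn(config.n_families)
    for idx in range(config.n_families):
        sim = _FamilySimulator(idx, config, stree, np.random.default_rng(fam_seeds[idx]))
        fam = sim.run()
        families.append(fam)
        for gid, rec in sim.records.items():
            gene_species[gid] = rec.species
            records[gid] = rec
    return FamilySet(families, gene_species, records, config)


def wgd_pairs(fams: FamilySet) -> list[tuple[str, str]]:
    """Ground-truth ohnolog pairs: focal-species gene pairs whose most recent
    common ancestor in the observed tree is a WGD duplication node."""
    focal = fams.config.focal_species
    pairs = []
    for fam in fams.families:
        if fam.root is None:
            continue
        wgd_labels = {ev.node_label for ev in fam.truth_events
                      if ev.kind in (WGD_ROUND1, WGD_ROUND2) and ev.survived}
        if not wgd_labels:
            continue
        leaves = [n for n in fam.root.leaves()
                  if fams.gene_species_map.get(n.name) == focal]
        index = {leaf.name: leaf for leaf in leaves}
        names = sorted(index)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                mrca = _mrca(index[a], index[b])
                if mrca.name in wgd_labels:
                    pairs.append((a, b))
    return pairs


def _mrca(a: TreeNode, b: TreeNode) -> TreeNode:
    seen = set(id(n) for n in a.ancestors(include_self=True))
    for node in b.ancestors(include_self=True):
        if id(node) in seen:
            return node
    raise ValueError("nodes share no ancestor")


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

def simulate_genome_layout(fams: FamilySet, config: SimulationConfig | None = None
                           ) -> GenomeLayout:
    """Place focal-species genes on chromosomes.

    Ohnolog track *t* of every family goes to chromosome ``t % n_chromosomes``
    in family order, so co-ohnologs of consecutive families form collinear
    blocks on partner chromosomes.  Within a family, later copies on the same
    (lineage, track) — tandem duplicates — are inserted adjacent to the
    previous copy with probability ``tandem_fraction``, otherwise appended to
    a random chromosome.  Single-copy families rotate across chromosomes as
    filler between anchors.
    """
    config = config or fams.config
    rng = np.random.default_rng([config.seed, 101])
    n_chrom = config.n_chromosomes
    capacity = n_chrom * config.genes_per_chromosome
    focal = config.focal_species
    focal_records = [r for r in fams.gene_records.values() if r.species == focal]
    if len(focal_records) > capacity:
        raise ConfigurationError(
            f"{len(focal_records)} focal genes exceed {capacity} positions")
    chrom_names = [f"chr{i + 1:02d}" for i in range(n_chrom)]
    chroms: dict[str, list[str]] = {c: [] for c in chrom_names}
    filler_cycle = 0
    by_family: dict[str, list[GeneRecord]] = {}
    for rec in focal_records:
        by_family.setdefault(rec.family, []).append(rec)
    for fam in fams.families:
        recs = sorted(by_family.get(fam.fam_id, []),
                      key=lambda r: (r.lineage, r.wgd_track or 0, r.gene_id))
        tracks = {r.wgd_track for r in recs}
        is_ohno = len({r.wgd_track for r in recs if r.wgd_track is not None}) >= 2
        placed_at: dict[tuple[int, Optional[int]], tuple[str, str]] = {}
        for rec in recs:
            key = (rec.lineage, rec.wgd_track)
            if key in placed_at:
                # tandem duplicate of an already placed copy
                chrom, anchor_gene = placed_at[key]
                if rng.random() < config.tandem_fraction:
                    pos = chroms[chrom].index(anchor_gene) + 1
                    chroms[chrom].insert(pos, rec.gene_id)
                    placed_at[key] = (chrom, rec.gene_id)
                else:
                    chrom = chrom_names[int(rng.integers(n_chrom))]
                    chroms[chrom].append(rec.gene_id)
            elif is_ohno and rec.wgd_track is not None:
                chrom = chrom_names[rec.wgd_track % n_chrom]
                chroms[chrom].append(rec.gene_id)
                placed_at[key] = (chrom, rec.gene_id)
            else:
                chrom = chrom_names[filler_cycle % n_chrom]
                filler_cycle += 1
                chroms[chrom].append(rec.gene_id)
                placed_at[key] = (chrom, rec.gene_id)
    for chrom, genes in chroms.items():
        if len(genes) > config.genes_per_chromosome:
            raise ConfigurationError(
                f"{chrom} holds {len(genes)} genes > capacity "
                f"{config.genes_per_chromosome}")
    return GenomeLayout({c: g for c, g in chroms.items()})


# ---------------------------------------------------------------------------
# expression atlas
# ---------------------------------------------------------------------------

def _node_age_depth(fams: FamilySet, stree: SpeciesTree, fam: Family) -> dict[int, float]:
    """Depth (in ladder steps from the root) of every node of an observed
    gene tree.  Duplication nodes sit slightly above their taxon node so WGD
    round 1 precedes round 2."""
    kind_of = {ev.node_label: ev.kind for ev in fam.truth_events}
    offsets = {WGD_ROUND1: -0.6, WGD_ROUND2: -0.3, TANDEM: -0.5}
    depths: dict[int, float] = {}
    for node in fam.root.preorder():
        if node.is_leaf:
            species = fams.gene_species_map[node.name]
            depths[id(node)] = float(stree.depth[species])
        else:
            taxon = fam.node_taxa[node.name]
            d = float(stree.depth[taxon])
            d += offsets.get(kind_of.get(node.name, ""), 0.0)
            depths[id(node)] = d
    return depths


def simulate_expression_atlas(fams: FamilySet, config: SimulationConfig | None = None
                              ) -> pd.DataFrame:
    """Genes x tissues matrix of non-negative signals.

    Each family draws an ancestral log-signal profile from
    Normal(location, scale) per tissue; along every gene-tree edge of length
    dt (ladder steps) each tissue drifts by Normal(0, divergence_rate^2 * dt)
    in log space.  ``wgd_tissue_boost`` multiplies the brain signal of genes
    descending from WGD duplication nodes.
    """
    config = config or fams.config
    if config.n_tissues < 2:
        raise ConfigurationError("n_tissues must be at least 2")
    stree = config.species_tree()
    tissues = config.tissue_names()
    loc, scale = config.expression_base
    rows: dict[str, np.ndarray] = {}
    for fam_idx, fam in enumerate(fams.families):
        if fam.root is None:
            continue
        rng = np.random.default_rng([config.seed, 202, fam_idx])
        depths = _node_age_depth(fams, stree, fam)
        wgd_labels = {ev.node_label for ev in fam.truth_events
                      if ev.kind in (WGD_ROUND1, WGD_ROUND2)}
        base = rng.normal(loc, scale, size=config.n_tissues)
        # walk the tree accumulating drift
        stack = [(fam.root, base, 0.0, False)]
        while stack:
            node, profile, depth, under_wgd = stack.pop()
            node_depth = depths[id(node)]
            dt = max(node_depth - depth, 0.0)
            if dt > 0 and config.divergence_rate > 0:
                profile = profile + rng.normal(
                    0.0, config.divergence_rate * np.sqrt(dt), size=config.n_tissues)
            if node.is_leaf:
                signal = np.exp(profile)
                if under_wgd and config.wgd_tissue_boost != 1.0:
                    signal = signal.copy()
                    signal[0] *= config.wgd_tissue_boost
                rows[node.name] = signal
            else:
                child_under = under_wgd or (node.name in wgd_labels)
                for child in node.children:
                    stack.append((child, profile, node_depth, child_under))
    atlas = pd.DataFrame.from_dict(rows, orient="index", columns=tissues)
    return atlas.sort_index()


# ---------------------------------------------------------------------------
# signalling network
# ---------------------------------------------------------------------------

def simulate_signal_network(fams: FamilySet, config: SimulationConfig | None = None
                            ) -> SimulatedNetwork:
    """Ancestral signed network plus its duplicated focal-species descendant.

    Each family contributes one ancestral node.  Duplication-divergence model:
    when the families at either end of an ancestral edge (A, B) are duplicated,
    the edge materialises as every descendant combination (a_i, b_j), each
    retained independently with probability ``edge_inheritance_q`` (probability
    1 when both families stayed single-copy), preserving polarity and
    direction.  Duplicate genes then gain Poisson(``edge_gain_rate``) novel
    random edges (never to their own co-duplicate, so bridging stays under
    ``bridging_prob``'s sole control) and each ground-truth WGD pair is
    bridged with probability ``bridging_prob``.
    """
    config = config or fams.config
    rng = np.random.default_rng([config.seed, 303])
    focal = config.focal_species
    desc: dict[str, list[str]] = {}
    for fam in fams.families:
        if fam.root is None:
            continue
        genes = sorted(g for g in (n.name for n in fam.root.leaves())
                       if fams.gene_species_map[g] == focal)
        if genes:
            desc[fam.fam_id] = genes
    anc_nodes = sorted(desc)
    n_anc = len(anc_nodes)
    anc_edges: list[Edge] = []
    if n_anc >= 2:
        m = int(round(config.ancestral_mean_degree * n_anc / 2))
        seen = set()
        attempts = 0
        while len(anc_edges) < m and attempts < 20 * m + 100:
            attempts += 1
            i, j = rng.choice(n_anc, size=2, replace=False)
            pol = POLARITIES[int(rng.choice(3, p=list(config.polarity_freqs)))]
            e = Edge(anc_nodes[i], anc_nodes[j], pol).canonical()
            if e not in seen:
                seen.add(e)
                anc_edges.append(e)
    ancestral = SignalNetwork(anc_edges, nodes=anc_nodes)

    q = config.edge_inheritance_q
    ext_edges: list[Edge] = []
    for e in anc_edges:
        src_genes, tgt_genes = desc[e.source], desc[e.target]
        keep_p = 1.0 if (len(src_genes) == 1 and len(tgt_genes) == 1) else q
        for s_gene in src_genes:
            for t_gene in tgt_genes:
                if rng.random() < keep_p:
                    ext_edges.append(Edge(s_gene, t_gene, e.polarity))

    all_genes = sorted(g for genes in desc.values() for g in genes)
    gene_idx = {g: i for i, g in enumerate(all_genes)}
    pairs = [p for p in wgd_pairs(fams) if p[0] in gene_idx and p[1] in gene_idx]
    mates: dict[str, set[str]] = {}
    for u, v in pairs:
        mates.setdefault(u, set()).add(v)
        mates.setdefault(v, set()).add(u)
    if config.edge_gain_rate > 0 and len(all_genes) > 1:
        for fam_genes in (desc[f] for f in anc_nodes):
            if len(fam_genes) < 2:
                continue
            for gene in fam_genes:
                for _ in range(int(rng.poisson(config.edge_gain_rate))):
                    j = int(rng.integers(len(all_genes)))
                    target = all_genes[j]
                    if target == gene or target in mates.get(gene, ()):
                        continue
                    pol = POLARITIES[int(rng.choice(3, p=list(config.polarity_freqs)))]
                    if pol != SCAFFOLD and rng.random() < 0.5:
                        ext_edges.append(Edge(target, gene, pol))
                    else:
                        ext_edges.append(Edge(gene, target, pol))

    if config.bridging_prob > 0:
        for u, v in pairs:
            if rng.random() < config.bridging_prob:
                pol = POLARITIES[int(rng.choice(3, p=list(config.polarity_freqs)))]
                ext_edges.append(Edge(u, v, pol))

    network = SignalNetwork(ext_edges, nodes=all_genes)
    return SimulatedNetwork(network=network, ancestral=ancestral, pairs=pairs)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_families(fams: FamilySet, out_dir) -> None:
    """One newick per family, a gene->species map and the truth table."""
    tree_dir = os.path.join(out_dir, "families")
    os.makedirs(tree_dir, exist_ok=True)
    for fam in fams.families:
        if fam.root is None:
            continue
        with open(os.path.join(tree_dir, f"{fam.fam_id}.nwk"), "w") as fh:
            fh.write(fam.root.to_newick(annotate=True) + "\n")
    with open(os.path.join(out_dir, "gene_species.tsv"), "w") as fh:
        fh.write("gene\tspecies\n")
        for gene in sorted(fams.gene_species_map):
            fh.write(f"{gene}\t{fams.gene_species_map[gene]}\n")
    with open(os.path.join(out_dir, "truth_events.tsv"), "w") as fh:
        fh.write("family\tnode\ttaxon\tkind\tsurvived\n")
        for fam in fams.families:
            for ev in fam.truth_events:
                fh.write(f"{fam.fam_id}\t{ev.node_label}\t{ev.taxon}\t{ev.kind}"
                         f"\t{int(ev.survived)}\n")


def write_layout(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tchromosome\tposition\n")
        for chrom in sorted(layout.chromosomes):
            for pos, gene in enumerate(layout.chromosomes[chrom]):
                fh.write(f"{gene}\t{chrom}\t{pos}\n")


def read_layout(path) -> GenomeLayout:
    chroms: dict[str, list[tuple[int, str]]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            chroms.setdefault(row["chromosome"], []).append(
                (int(row["position"]), row["gene"]))
    return GenomeLayout({
        c: [g for _, g in sorted(rows)] for c, rows in chroms.items()})


def write_atlas(atlas: pd.DataFrame, path) -> None:
    atlas.to_csv(path, sep="\t", index_label="gene", float_format="%.4f")


def read_atlas(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_pairs(pairs, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def read_pairs(path) -> list[tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            a, b = line.rstrip("\n").split("\t")[:2]
            pairs.append((a, b))
    return pairs
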