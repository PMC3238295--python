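"""Ohnolog collection and whole-genome-duplication retention estimation.

A two-round WGD initially quadruples the ancestral gene complement; the
overall retention percentage therefore compares the observed ohnolog count O
in a focal species against four times the ancestral pre-WGD gene count N:

    overall  = 100 * O / (4 N)
    upper    = 100 * (O - T) / (4 N + F_small)
    lower    = 100 * (O - T) / (4 N + F_large)

where T is the count of ohnolog-set genes actually created by duplications
younger than the WGD (tandem/segmental copies inflating O), and F_small /
F_large are two alternative counts of genes in families without ohnologs
(family-set-restricted vs all predicted genes), giving the two bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ComputationError, InputError
from .timing import DUPLICATION, assign_and_filter
from .trees import SpeciesTree, TreeNode


@dataclass
class OhnologSet:
    target_taxon: str
    genes: set[str]
    pairs: list[tuple[str, str]]
    #: creating duplication taxon per gene (nearest duplication ancestor), if any
    creating_taxon: dict[str, str] = field(default_factory=dict)


@dataclass
class RetentionInputs:
    ohnolog_genes: int          # O
    ancestral_genes: int        # N, pre-WGD gene count
    young_duplicates: int = 0   # T, post-WGD copies inside the ohnolog set
    family_nonohnolog_genes: int = 0   # F_small
    total_nonohnolog_genes: int = 0    # F_large


def _focal_leaves(fam, fams, focal_species: str) -> list[TreeNode]:
    return [n for n in fam.root.leaves()
            if fams.gene_species_map.get(n.name) == focal_species]


def _mrca(a: TreeNode, b: TreeNode) -> TreeNode:
    seen = {id(n) for n in a.ancestors(include_self=True)}
    for node in b.ancestors(include_self=True):
        if id(node) in seen:
            return node
    raise InputError("nodes share no ancestor")


def collect_ohnologs(fams, species_tree: SpeciesTree, taxon: str,
                     focal_species: str, sis_min: float = 0.0) -> OhnologSet:
    """Focal-species genes descending from >=1 SIS-supported duplication node
    timed to ``taxon``; pairs are gene pairs whose most recent common
    duplication node is so timed."""
    if taxon not in species_tree:
        raise InputError(f"unknown taxon {taxon!r}")
    genes: set[str] = set()
    pairs: list[tuple[str, str]] = []
    creating: dict[str, str] = {}
    for fam in fams.families:
        if fam.root is None:
            continue
        timed = {id(d.node) for d in assign_and_filter(fam.root, sis_min)
                 if d.taxon == taxon}
        leaves = _focal_leaves(fam, fams, focal_species)
        for leaf in leaves:
            dup_anc = None
            for anc in leaf.ancestors():
                if anc.event == DUPLICATION and (anc.sis or 0.0) > sis_min:
                    dup_anc = anc
                    break
            if dup_anc is not None:
                creating[leaf.name] = dup_anc.taxon
            if any(id(a) in timed for a in leaf.ancestors()):
                genes.add(leaf.name)
        if not timed:
            continue
        names = sorted(l.name for l in leaves)
        index = {l.name: l for l in leaves}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                mrca = _mrca(index[a], index[b])
                if mrca.event == DUPLICATION and id(mrca) in timed:
                    pairs.append((a, b))
    return OhnologSet(taxon, genes, pairs, creating)


def count_ancestral_genes(fams, species_tree: SpeciesTree, taxon: str,
                          focal_species: str) -> int:
    """Distinct gene lineages present immediately before the taxon's WGD:
    the focal species' genes are projected root-ward; lineages merge at their
    topmost ancestor still mapped inside the taxon's clade."""
    if taxon not in species_tree:
        raise InputError(f"unknown taxon {taxon!r}")
    total = 0
    for fam in fams.families:
        if fam.root is None:
            continue
        entries: set[int] = set()
        for leaf in _focal_leaves(fam, fams, focal_species):
            entry = leaf
            for anc in leaf.ancestors():
                if anc.taxon and species_tree.is_ancestor_or_equal(taxon, anc.taxon):
                    entry = anc
                else:
                    break
            entries.add(id(entry))
        total += len(entries)
    return total


def count_young_duplicates(fams, species_tree: SpeciesTree, taxon: str,
                           focal_species: str, sis_min: float = 0.0) -> int:
    """Extra gene copies inside the ohnolog set created by duplications timed
    strictly younger than the WGD taxon — the tandem/segmental copies that
    inflate the raw ohnolog count.

    Ohnolog-set genes are merged into one lineage whenever their most recent
    common ancestor is a supported duplication younger than the WGD; the
    inflation is (genes - lineages), i.e. one per younger duplication node.
    """
    oset = collect_ohnologs(fams, species_tree, taxon, focal_species, sis_min)
    total = 0
    for fam in fams.families:
        if fam.root is None:
            continue
        leaves = [l for l in _focal_leaves(fam, fams, focal_species)
                  if l.name in oset.genes]
        if len(leaves) < 2:
            continue
        parent = {l.name: l.name for l in leaves}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, a in enumerate(leaves):
            for b in leaves[i + 1:]:
                mrca = _mrca(a, b)
                if (mrca.event == DUPLICATION and (mrca.sis or 0.0) > sis_min
                        and mrca.taxon
                        and species_tree.is_strictly_younger(mrca.taxon, taxon)):
                    parent[find(a.name)] = find(b.name)
        classes = {find(l.name) for l in leaves}
        total += len(leaves) - len(classes)
    return total


def paralog_pairs_by_age(fams, species_tree: SpeciesTree, focal_species: str,
                         sis_min: float = 0.0) -> list[tuple[str, str, str]]:
    """All focal-species paralog pairs whose MRCA is a supported duplication
    node, with the pair's age class = that node's mapped taxon."""
    out: list[tuple[str, str, str]] = []
    for fam in fams.families:
        if fam.root is None:
            continue
        leaves = _focal_leaves(fam, fams, focal_species)
        names = sorted(l.name for l in leaves)
        index = {l.name: l for l in leaves}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                mrca = _mrca(index[a], index[b])
                if mrca.event == DUPLICATION and (mrca.sis or 0.0) > sis_min:
                    out.append((a, b, mrca.taxon))
    return out


def estimate_retention(r: RetentionInputs) -> dict[str, float]:
    """Overall retention percentage plus upper/lower bounds (see module doc)."""
    if r.ancestral_genes <= 0:
        raise ComputationError("ancestral gene count must be positive")
    four_n = 4 * r.ancestral_genes
    adjusted = r.ohnolog_genes - r.young_duplicates
    denom_up = four_n + r.family_nonohnolog_genes
    denom_lo = four_n + r.total_nonohnolog_genes
    if denom_up <= 0 or denom_lo <= 0:
        raise ComputationError("zero denominator in retention bounds")
    return {
        "overall_pct": 100.0 * r.ohnolog_genes / four_n,
        "upper_pct": 100.0 * adjusted / denom_up,
        "lower_pct": 100.0 * adjusted / denom_lo,
    }


def write_retention_report(oset: OhnologSet, estimates: dict[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write(f"target_taxon\t{oset.target_taxon}\n")
        fh.write(f"ohnolog_genes\t{len(oset.genes)}\n")
        fh.write(f"ohnolog_pairs\t{len(oset.pairs)}\n")
        for key, val in estimates.items():
            fh.write(f"{key}\t{val:.2f}\n")
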