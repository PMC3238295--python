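"""Gene-tree / species-tree reconciliation and phylogenetic timing.

Speciation/duplication inference uses standard LCA mapping: each internal
gene-tree node maps to the species-tree LCA of its descendant species, and is
a duplication iff at least one child maps to the same species-tree node.  The
mapped taxon of a duplication node is its *phylogenetic timing* — the taxon on
whose stem branch the duplication is inferred to have occurred.

Species-intersection support (SIS) guards against locally wrong gene-tree
topology: a duplication whose two child clades share no species (SIS = 0) is
more parsimoniously a rooting/topology artifact than a real duplication, and
is filtered out.  SIS here is |S_left ∩ S_right| / min(|S_left|, |S_right|);
the intersection/union variant can be selected per call.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

from .errors import InputError
from .trees import (DUPLICATION, SPECIATION, SpeciesTree, TreeNode,
                    resolve_multifurcations)


def _species_of_leaf(leaf: TreeNode, gene_species_map: Optional[dict[str, str]]) -> str:
    if gene_species_map is not None:
        try:
            return gene_species_map[leaf.name]
        except KeyError:
            raise InputError(f"gene {leaf.name!r} missing from species map") from None
    # fall back to the geneID_speciesID convention: species after first '_'
    if leaf.name and "_" in leaf.name:
        return leaf.name.split("_", 1)[1]
    raise InputError(f"cannot determine species of leaf {leaf.name!r}")


def reconcile(
    gene_tree: TreeNode,
    species_tree: SpeciesTree,
    gene_species_map: Optional[dict[str, str]] = None,
    sis_mode: str = "min",
) -> TreeNode:
    """Annotate a rooted gene tree in place with event / mapped taxon / SIS.

    Leaves map to their species; internal nodes to the LCA of their children's
    mappings.  Multifurcations are resolved to an arbitrary ladder first (the
    inserted nodes carry SIS = 0 so they can never contribute a supported
    duplication).  Returns the (possibly re-rooted-free) annotated tree.
    """
    resolve_multifurcations(gene_tree)
    mapped: dict[int, TreeNode] = {}
    species_sets: dict[int, frozenset[str]] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            sp = _species_of_leaf(node, gene_species_map)
            if sp not in species_tree:
                raise InputError(f"species {sp!r} not in species tree")
            mapped[id(node)] = species_tree.node(sp)
            species_sets[id(node)] = frozenset([sp])
            node.taxon = sp
            continue
        child_sets = [species_sets[id(c)] for c in node.children]
        all_species = frozenset().union(*child_sets)
        species_sets[id(node)] = all_species
        node_map = species_tree.lca(all_species)
        mapped[id(node)] = node_map
        node.taxon = node_map.name
        is_dup = any(mapped[id(c)] is node_map for c in node.children)
        node.event = DUPLICATION if is_dup else SPECIATION
        if node.sis == 0.0:
            # synthetic ladder node from a multifurcation keeps its zero flag
            pass
        else:
            left, right = child_sets[0], child_sets[-1]
            inter = len(left & right)
            if sis_mode == "min":
                denom = min(len(left), len(right))
            elif sis_mode == "union":
                denom = len(left | right)
            else:
                raise InputError(f"unknown sis_mode {sis_mode!r}")
            node.sis = inter / denom if denom else 0.0
    return gene_tree


@dataclass
class TimedDuplication:
    node: TreeNode
    taxon: str
    sis: float


def assign_and_filter(rec: TreeNode, sis_min: float = 0.0) -> list[TimedDuplication]:
    """Duplication nodes with SIS strictly above ``sis_min`` (default drops
    exactly the SIS = 0 artifacts), each with its mapped taxon."""
    out = []
    for node in rec.postorder():
        if node.event == DUPLICATION and (node.sis or 0.0) > sis_min:
            out.append(TimedDuplication(node, node.taxon, node.sis or 0.0))
    return out


def reconcile_families(fams, species_tree: SpeciesTree) -> None:
    """Reconcile every family tree of a FamilySet in place."""
    for fam in fams.families:
        if fam.root is not None:
            reconcile(fam.root, species_tree, fams.gene_species_map)


def tabulate_duplications(
    fams,
    species_tree: SpeciesTree,
    gene_subset: Optional[Iterable[str]] = None,
    sis_min: float = 0.0,
    filtered: bool = True,
) -> dict[str, int]:
    """Count retained duplication nodes per taxon across reconciled families.

    ``gene_subset`` keeps only families containing at least one listed gene
    (pathway-style restriction).  ``filtered=False`` skips the SIS filter."""
    subset = set(gene_subset) if gene_subset is not None else None
    counts: Counter[str] = Counter()
    for fam in fams.families:
        if fam.root is None:
            continue
        if subset is not None:
            genes = set(fam.root.leaf_names())
            if not genes & subset:
                continue
        for node in fam.root.postorder():
            if node.event != DUPLICATION:
                continue
            if filtered and (node.sis or 0.0) <= sis_min:
                continue
            counts[node.taxon] += 1
    return dict(counts)


def partition_wgd_rounds(dups: list[TimedDuplication], taxon: str
                         ) -> tuple[list[TimedDuplication], list[TimedDuplication]]:
    """Split taxon-timed duplications of one tree into the two WGD waves:
    round 1 = no like-timed duplication ancestor; round 2 = the rest."""
    timed = [d for d in dups if d.taxon == taxon]
    timed_nodes = {id(d.node) for d in timed}
    round1, round2 = [], []
    for d in timed:
        has_timed_ancestor = any(
            id(a) in timed_nodes for a in d.node.ancestors())
        (round2 if has_timed_ancestor else round1).append(d)
    return round1, round2


def write_taxon_table(counts: dict[str, int], species_tree: SpeciesTree, path) -> None:
    order = sorted(counts, key=lambda t: (species_tree.depth.get(t, 1_000_000), t))
    with open(path, "w") as fh:
        fh.write("taxon\tduplication_nodes\n")
        for taxon in order:
            fh.write(f"{taxon}\t{counts[taxon]}\n")
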