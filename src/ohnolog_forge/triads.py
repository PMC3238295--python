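"""Duplication triads: expression sub-/neofunctionalisation classification.

A triad is (ancestral outgroup ortholog; paralog 1, paralog 2): a unique
outgroup-species gene orthologous to a focal-species ohnolog pair.  Each of
the three genes gets a preferential-brain-expression (PBE) flag — brain signal
strictly above the gene's mean signal over all tissues — written 'b' / 'nb'.
The resulting six configurations (paralog order is meaningless) read
ancestor : paralog & paralog and are interpreted as:

    b:b&b      ancestral expression conservation (b)
    b:nb&b     subfunctionalisation (loss of PBE in one duplicate)
    b:nb&nb    gain/loss independent of duplication
    nb:b&b     gain/loss independent of duplication
    nb:nb&b    neofunctionalisation (gain of PBE in one duplicate)
    nb:nb&nb   ancestral expression conservation (nb)

Summary ratios: conservation/sub = n(b:b&b)/n(b:nb&b), conservation/neo =
n(nb:nb&nb)/n(nb:nb&b), sub/neo = n(b:nb&b)/n(nb:nb&b).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .errors import InputError
from .trees import SPECIATION, TreeNode

CONFIGURATIONS = ("b:b&b", "b:nb&b", "b:nb&nb", "nb:b&b", "nb:nb&b", "nb:nb&nb")


@dataclass
class Triad:
    ancestral_gene: str
    paralog_1: str
    paralog_2: str
    ancestral_b: Optional[str] = None   # 'b' | 'nb'
    p1_b: Optional[str] = None
    p2_b: Optional[str] = None
    age_class: Optional[str] = None

    @property
    def configuration(self) -> str:
        flags = {self.ancestral_b, self.p1_b, self.p2_b}
        if None in flags or not flags <= {"b", "nb"}:
            raise InputError("triad flags not assigned")
        p = sorted((self.p1_b, self.p2_b), key=lambda f: f == "b")  # nb before b
        return f"{self.ancestral_b}:{p[0]}&{p[1]}"


def _mrca(a: TreeNode, b: TreeNode) -> TreeNode:
    seen = {id(n) for n in a.ancestors(include_self=True)}
    for node in b.ancestors(include_self=True):
        if id(node) in seen:
            return node
    raise InputError("nodes share no ancestor")


def extract_ancestral_set(
    fams,
    pairs: Iterable[tuple[str, str]],
    outgroup_species: str,
    bootstrap_min: float = 0.75,
) -> tuple[list[Triad], Counter]:
    """Triads for ohnolog ``pairs`` whose family holds exactly one
    outgroup-species gene joined to the pair through a speciation node, with
    all supporting nodes (the joining speciation and the pair's duplication
    MRCA) at bootstrap strictly above ``bootstrap_min`` where recorded.

    Returns the triads plus a counter of skip reasons.
    """
    leaf_index: dict[str, tuple[TreeNode, object]] = {}
    for fam in fams.families:
        if fam.root is None:
            continue
        for leaf in fam.root.leaves():
            leaf_index[leaf.name] = (leaf, fam)
    triads: list[Triad] = []
    skipped: Counter = Counter()
    for a, b in pairs:
        if a not in leaf_index or b not in leaf_index:
            skipped["pair gene missing from families"] += 1
            continue
        (leaf_a, fam) = leaf_index[a]
        leaf_b = leaf_index[b][0]
        out_leaves = [l for l in fam.root.leaves()
                      if fams.gene_species_map.get(l.name) == outgroup_species]
        dup_node = _mrca(leaf_a, leaf_b)
        candidates = []
        for out_leaf in out_leaves:
            join = _mrca(out_leaf, dup_node)
            if join.event == SPECIATION:
                candidates.append((out_leaf, join))
        if not candidates:
            skipped["no outgroup ortholog"] += 1
            continue
        if len(candidates) > 1:
            skipped["non-unique outgroup ortholog"] += 1
            continue
        out_leaf, join = candidates[0]
        supports = [n.bootstrap for n in (dup_node, join) if n.bootstrap is not None]
        if any(s <= bootstrap_min for s in supports):
            skipped["low bootstrap"] += 1
            continue
        triads.append(Triad(out_leaf.name, a, b))
    return triads, skipped


def classify_pbe(expression_row: pd.Series, brain_tissue: str = "brain") -> str:
    """'b' iff the brain signal strictly exceeds the mean over all tissues
    (the mean includes brain)."""
    if brain_tissue not in expression_row.index:
        raise InputError(f"missing brain tissue column {brain_tissue!r}")
    if len(expression_row) < 2:
        raise InputError("need at least two tissues")
    return "b" if expression_row[brain_tissue] > expression_row.mean() else "nb"


def assign_pbe_flags(
    triads: list[Triad],
    focal_atlas: pd.DataFrame,
    outgroup_atlas: pd.DataFrame,
    brain_tissue: str = "brain",
) -> tuple[list[Triad], int]:
    """Fill PBE flags from the two atlases (the ancestral gene is judged
    against its own species' tissue mean).  Triads missing expression rows
    are dropped; returns (kept triads, dropped count)."""
    kept, dropped = [], 0
    for t in triads:
        if (t.ancestral_gene not in outgroup_atlas.index
                or t.paralog_1 not in focal_atlas.index
                or t.paralog_2 not in focal_atlas.index):
            dropped += 1
            continue
        t.ancestral_b = classify_pbe(outgroup_atlas.loc[t.ancestral_gene], brain_tissue)
        t.p1_b = classify_pbe(focal_atlas.loc[t.paralog_1], brain_tissue)
        t.p2_b = classify_pbe(focal_atlas.loc[t.paralog_2], brain_tissue)
        kept.append(t)
    return kept, dropped


@dataclass
class TriadSummary:
    counts: dict[str, int]
    conservation_over_sub: Optional[float]
    conservation_over_neo: Optional[float]
    sub_over_neo: Optional[float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def classify_triads(triads: Iterable[Triad]) -> TriadSummary:
    """Bin triads into the six configurations and form the summary ratios
    (flagged None when a denominator is zero)."""
    counts = {c: 0 for c in CONFIGURATIONS}
    for t in triads:
        counts[t.configuration] += 1

    def ratio(num: str, den: str) -> Optional[float]:
        return counts[num] / counts[den] if counts[den] else None

    return TriadSummary(
        counts=counts,
        conservation_over_sub=ratio("b:b&b", "b:nb&b"),
        conservation_over_neo=ratio("nb:nb&nb", "nb:nb&b"),
        sub_over_neo=ratio("b:nb&b", "nb:nb&b"),
    )


def summary_from_counts(counts: dict[str, int]) -> TriadSummary:
    """Summary ratios straight from configuration counts."""
    triads = []
    for config, n in counts.items():
        anc, rest = config.split(":")
        p1, p2 = rest.split("&")
        triads.extend(Triad("x", "y", "z", anc, p1, p2) for _ in range(n))
    return classify_triads(triads)
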