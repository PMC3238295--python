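"""Paralogon (multiplicon) detection from ohnolog anchors and gene order.

A multiplicon is a pair of chromosome segments with conserved paralogous gene
content and order — the genomic footprint of a whole-genome duplication.
Detection is gap-constrained collinear chaining over *anchors* (positioned
paralogous gene pairs): a chain must be strictly monotone in both segment
coordinates (same or inverted orientation), consecutive anchors may be
separated by at most ``max_gap`` intervening genes on either segment, at least
``min_anchors`` anchors are required, and the chain must be significant under
a uniform-scatter null.

Coordinates are ordinal gene indices (0-based, half-open segments), because
the gap parameter counts intervening *genes*, not base pairs.

Significance filter (simplified, swappable): for a chain of k of the m anchors
of a chromosome pair, with observed index steps (dx_i, dy_i) on chromosomes of
N1 and N2 genes, the expected number of equally tight chains under uniform
anchor placement is bounded by

    E = C(m, k) * 2 * prod_i (dx_i / N1) * (dy_i / N2)

and the chain is kept when min(1, E) <= prob_cutoff.  The ``quality``
parameter is the minimum fraction of the chromosome pair's anchors inside the
two segment windows that are *consistent* with the chain's monotone fit —
insertable between neighbouring chain anchors under non-strict monotonicity —
a guard against chaining a sparse monotone subset of a scrambled region while
tolerating the coordinate ties that multi-copy families produce.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

from .errors import ConfigurationError
from .simulate import GenomeLayout

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int


@dataclass
class MultipliconParams:
    max_gap: int = 30
    min_anchors: int = 5
    quality: float = 0.8
    prob_cutoff: float = 1e-5

    def validate(self) -> "MultipliconParams":
        if self.max_gap < 0:
            raise ConfigurationError("max_gap must be >= 0")
        if self.min_anchors < 2:
            raise ConfigurationError("min_anchors must be >= 2")
        if not 0.0 < self.prob_cutoff <= 1.0:
            raise ConfigurationError("prob_cutoff must be in (0, 1]")
        if not 0.0 <= self.quality <= 1.0:
            raise ConfigurationError("quality must be in [0, 1]")
        return self


@dataclass
class Multiplicon:
    segment_a: tuple[str, int, int]   # (chromosome, start, end) half-open
    segment_b: tuple[str, int, int]
    anchors: list[Anchor]
    orientation: str                  # "same" | "inverted"
    score: float                      # significance value (lower = stronger)


def build_anchors(pairs, layout: GenomeLayout) -> list[Anchor]:
    """Positioned paralog pairs; pairs with an unplaced gene are dropped (the
    drop count is logged)."""
    anchors, dropped = [], 0
    for a, b in pairs:
        pa, pb = layout.position.get(a), layout.position.get(b)
        if pa is None or pb is None:
            dropped += 1
            continue
        (ca, ia), (cb, ib) = pa, pb
        # canonical orientation: sort by chromosome name then position
        if (cb, ib, b) < (ca, ia, a):
            a, b, ca, ia, cb, ib = b, a, cb, ib, ca, ia
        anchors.append(Anchor(a, b, ca, ia, cb, ib))
    if dropped:
        logger.info("build_anchors: dropped %d pairs with unplaced genes", dropped)
    return anchors


def _collapse_tandem(anchors: list[Anchor]) -> list[Anchor]:
    """Drop self-synteny anchors from tandem arrays: pairs adjacent (or equal)
    on the same chromosome."""
    kept = [a for a in anchors
            if not (a.chrom_a == a.chrom_b and abs(a.pos_a - a.pos_b) <= 1)]
    if len(kept) != len(anchors):
        logger.info("collapsed %d tandem-array anchors", len(anchors) - len(kept))
    return kept


def _chain_score(chain: list[Anchor], m: int, n1: int, n2: int) -> float:
    """Expected-count significance bound for a chain (see module docstring)."""
    k = len(chain)
    log_e = math.lgamma(m + 1) - math.lgamma(k + 1) - math.lgamma(m - k + 1)
    log_e += math.log(2.0)
    for prev, cur in zip(chain, chain[1:]):
        dx = abs(cur.pos_a - prev.pos_a)
        dy = abs(cur.pos_b - prev.pos_b)
        log_e += math.log(max(dx, 1) / n1) + math.log(max(dy, 1) / n2)
    return min(1.0, math.exp(min(log_e, 0.0)))


def _best_chain(anchors: list[Anchor], sign: int, max_gap: int) -> list[Anchor]:
    """Longest strictly monotone chain (y increasing for sign=+1, decreasing
    for sign=-1) with both index gaps <= max_gap intervening genes.  O(m^2)
    DP with deterministic tie-breaking."""
    order = sorted(anchors, key=lambda a: (a.pos_a, sign * a.pos_b))
    n = len(order)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        ai = order[i]
        for j in range(i):
            aj = order[j]
            dx = ai.pos_a - aj.pos_a
            dy = (ai.pos_b - aj.pos_b) * sign
            if dx <= 0 or dy <= 0:
                continue
            if dx - 1 > max_gap or dy - 1 > max_gap:
                continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    if not order:
        return []
    end = max(range(n), key=lambda i: (best_len[i], -order[i].pos_a))
    chain = []
    while end != -1:
        chain.append(order[end])
        end = prev[end]
    return chain[::-1]


def _n_consistent(chain: list[Anchor], candidates: list[Anchor], sign: int) -> int:
    """Anchors insertable into the chain under non-strict monotonicity."""
    xs = [a.pos_a for a in chain]
    ys = [sign * a.pos_b for a in chain]
    chain_set = set(chain)
    n = len(chain_set)
    for a in candidates:
        if a in chain_set:
            continue
        x, y = a.pos_a, sign * a.pos_b
        lo = sum(1 for cx in xs if cx < x)        # insertion window by x
        hi = sum(1 for cx in xs if cx <= x)
        for pos in range(lo, hi + 1):
            y_prev = ys[pos - 1] if pos > 0 else -math.inf
            y_next = ys[pos] if pos < len(ys) else math.inf
            if y_prev <= y <= y_next:
                n += 1
                break
    return n


def detect_multiplicons(anchors, layout: GenomeLayout,
                        params: MultipliconParams | None = None) -> list[Multiplicon]:
    """Detect multiplicons by iterated best-chain extraction per chromosome
    pair (both orientations), applying the quality and significance filters."""
    params = (params or MultipliconParams()).validate()
    anchors = _collapse_tandem(list(anchors))
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.chrom_a, a.chrom_b), []).append(a)
    out: list[Multiplicon] = []
    for (ca, cb), group in sorted(groups.items()):
        n1 = len(layout.chromosomes.get(ca, ())) or 1
        n2 = len(layout.chromosomes.get(cb, ())) or 1
        m_total = len(group)
        remaining = list(group)
        while len(remaining) >= params.min_anchors:
            cand = []
            for sign, orientation in ((1, "same"), (-1, "inverted")):
                chain = _best_chain(remaining, sign, params.max_gap)
                if chain:
                    cand.append((len(chain), orientation, chain))
            if not cand:
                break
            cand.sort(key=lambda c: (-c[0], c[1]))
            k, orientation, chain = cand[0]
            if k < params.min_anchors:
                break
            xs = [a.pos_a for a in chain]
            ys = [a.pos_b for a in chain]
            seg_a = (ca, min(xs), max(xs) + 1)
            seg_b = (cb, min(ys), max(ys) + 1)
            in_window = [
                a for a in group
                if seg_a[1] <= a.pos_a < seg_a[2] and seg_b[1] <= a.pos_b < seg_b[2]]
            sign = 1 if orientation == "same" else -1
            quality = (_n_consistent(chain, in_window, sign) / len(in_window)
                       if in_window else 0.0)
            score = _chain_score(chain, m_total, n1, n2)
            chain_set = set(chain)
            remaining = [a for a in remaining if a not in chain_set]
            if quality + 1e-12 < params.quality or score > params.prob_cutoff:
                continue
            out.append(Multiplicon(seg_a, seg_b, chain, orientation, score))
    return out


def genome_coverage(multiplicons, layout: GenomeLayout) -> dict:
    """Fraction of ordinal gene positions inside >=1 multiplicon segment, per
    chromosome and overall; overlapping segments count once."""
    covered: dict[str, set[int]] = {c: set() for c in layout.chromosomes}
    for mp in multiplicons:
        for chrom, start, end in (mp.segment_a, mp.segment_b):
            if chrom in covered:
                covered[chrom].update(range(start, min(end, len(layout.chromosomes[chrom]))))
    per_chrom = {}
    total_cov = total_len = 0
    for chrom, genes in layout.chromosomes.items():
        n = len(genes)
        c = len(covered[chrom])
        per_chrom[chrom] = (c / n) if n else 0.0
        total_cov += c
        total_len += n
    return {
        "per_chromosome": per_chrom,
        "overall": (total_cov / total_len) if total_len else 0.0,
        "uncovered_chromosomes": sorted(
            c for c, f in per_chrom.items() if f == 0.0),
    }


def write_multiplicons(multiplicons, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom_a\tstart_a\tend_a\tchrom_b\tstart_b\tend_b\t"
                 "n_anchors\torientation\tscore\n")
        for mp in multiplicons:
            fh.write("\t".join(map(str, (*mp.segment_a, *mp.segment_b,
                                         len(mp.anchors), mp.orientation,
                                         f"{mp.score:.3g}"))) + "\n")
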