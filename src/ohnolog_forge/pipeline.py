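"""End-to-end orchestration: simulate -> time -> retention -> paralogons ->
expression -> network -> triads -> enrichment, under one config and one seed,
with a machine-readable run report.

Every stage logs dropped/filtered record counts (the SIS filter, AD-mean
bounds, unplaced genes and so on must stay auditable) and contributes a
section to the report; a stage failure marks the stage and skips dependents.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from typing import Optional

import numpy as np

from . import enrichment as enrich_mod
from . import expression as expr_mod
from . import network as net_mod
from . import paralogons as para_mod
from . import retention as ret_mod
from . import simulate as sim_mod
from . import timing as time_mod
from .config import SimulationConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "timing", "retention", "paralogons", "expression",
          "network", "triads", "enrichment")

_DEPENDS = {
    "timing": ("simulate",),
    "retention": ("timing",),
    "paralogons": ("retention",),
    "expression": ("retention",),
    "network": ("retention",),
    "triads": ("retention", "expression"),
    "enrichment": ("retention", "paralogons"),
}


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_all(config: SimulationConfig | dict | str,
            seed: Optional[int] = None,
            out_dir: Optional[str] = None) -> dict:
    """Run every stage in dependency order; returns the run report."""
    if isinstance(config, str):
        config = SimulationConfig.from_json_file(config)
    elif isinstance(config, dict):
        config = SimulationConfig.from_dict(config)
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    config.validate()
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)

    report: dict = {"config_digest": _digest(dataclasses.asdict(config)),
                    "seed": config.seed, "stages": {}}
    state: dict = {}
    failed: set[str] = set()

    def stage(name):
        def wrap(fn):
            deps = _DEPENDS.get(name, ())
            entry = {"status": "ok", "warnings": [], "outputs": {}}
            if any(d in failed for d in deps):
                entry["status"] = "skipped"
                report["stages"][name] = entry
                failed.add(name)
                return
            try:
                fn(entry)
            except Exception as exc:  # report, do not crash the pipeline
                logger.exception("stage %s failed", name)
                entry["status"] = "failed"
                entry["error"] = f"{type(exc).__name__}: {exc}"
                failed.add(name)
            report["stages"][name] = entry
        return wrap

    stree = config.species_tree()
    focal = config.focal_species
    wgd_taxon = config.wgd_branch

    @stage("simulate")
    def _simulate(entry):
        fams = sim_mod.simulate_gene_families(config)
        layout = sim_mod.simulate_genome_layout(fams, config)
        atlas = sim_mod.simulate_expression_atlas(fams, config)
        simnet = sim_mod.simulate_signal_network(fams, config)
        state.update(fams=fams, layout=layout, atlas=atlas, simnet=simnet)
        n_extinct = sum(1 for f in fams.families if f.root is None)
        if n_extinct:
            entry["warnings"].append(f"{n_extinct} families went extinct")
        entry["outputs"] = {
            "n_families": len(fams.families),
            "n_genes": len(fams.gene_species_map),
            "n_focal_genes": len(fams.genes_of_species(focal)),
            "n_network_edges": simnet.network.n_edges(),
        }
        entry["inputs_digest"] = _digest(dataclasses.asdict(config))
        if out_dir:
            sim_mod.write_families(fams, out_dir)
            sim_mod.write_layout(layout, os.path.join(out_dir, "layout.tsv"))
            sim_mod.write_atlas(atlas, os.path.join(out_dir, "atlas.tsv"))
            net_mod.write_edge_tsv(simnet.network, os.path.join(out_dir, "network.tsv"))
            sim_mod.write_pairs(simnet.pairs, os.path.join(out_dir, "wgd_pairs.tsv"))

    @stage("timing")
    def _timing(entry):
        fams = state["fams"]
        time_mod.reconcile_families(fams, stree)
        table = time_mod.tabulate_duplications(fams, stree)
        unfiltered = time_mod.tabulate_duplications(fams, stree, filtered=False)
        r1 = r2 = correct = total = 0
        for fam in fams.families:
            if fam.root is None:
                continue
            dups = time_mod.assign_and_filter(fam.root)
            a, b = time_mod.partition_wgd_rounds(dups, wgd_taxon)
            r1 += len(a)
            r2 += len(b)
            truth = {ev.node_label: ev.taxon for ev in fam.truth_events if ev.survived}
            for d in dups:
                if d.node.name in truth:
                    total += 1
                    correct += d.taxon == truth[d.node.name]
        entry["outputs"] = {
            "duplications_per_taxon": table,
            "duplications_per_taxon_unfiltered": unfiltered,
            "wgd_round1_nodes": r1,
            "wgd_round2_nodes": r2,
            "timing_accuracy": (correct / total) if total else None,
        }
        if out_dir:
            time_mod.write_taxon_table(table, stree,
                                       os.path.join(out_dir, "taxon_table.tsv"))

    @stage("retention")
    def _retention(entry):
        fams = state["fams"]
        oset = ret_mod.collect_ohnologs(fams, stree, wgd_taxon, focal)
        n_anc = ret_mod.count_ancestral_genes(fams, stree, wgd_taxon, focal)
        t_young = ret_mod.count_young_duplicates(fams, stree, wgd_taxon, focal)
        focal_genes = set(fams.genes_of_species(focal))
        f_small = len(focal_genes - oset.genes)
        inputs = ret_mod.RetentionInputs(
            ohnolog_genes=len(oset.genes), ancestral_genes=max(n_anc, 1),
            young_duplicates=t_young, family_nonohnolog_genes=f_small,
            total_nonohnolog_genes=f_small)
        estimates = ret_mod.estimate_retention(inputs)
        state.update(oset=oset)
        entry["outputs"] = {
            "ohnolog_genes": len(oset.genes),
            "ohnolog_pairs": len(oset.pairs),
            "ancestral_genes": n_anc,
            "young_duplicates": t_young,
            "non_ohnolog_genes": f_small,
            **{k: round(v, 3) for k, v in estimates.items()},
        }
        if out_dir:
            ret_mod.write_retention_report(
                oset, estimates, os.path.join(out_dir, "retention.tsv"))

    @stage("paralogons")
    def _paralogons(entry):
        layout, oset = state["layout"], state["oset"]
        anchors = para_mod.build_anchors(oset.pairs, layout)
        mps = para_mod.detect_multiplicons(anchors, layout)
        cov = para_mod.genome_coverage(mps, layout)
        state.update(multiplicons=mps)
        entry["outputs"] = {
            "n_anchors": len(anchors),
            "n_multiplicons": len(mps),
            "coverage_overall": round(cov["overall"], 4),
            "uncovered_chromosomes": cov["uncovered_chromosomes"],
        }
        if out_dir:
            para_mod.write_multiplicons(mps, os.path.join(out_dir, "multiplicons.tsv"))

    @stage("expression")
    def _expression(entry):
        fams, atlas, oset = state["fams"], state["atlas"], state["oset"]
        focal_atlas = atlas.loc[[g for g in atlas.index
                                 if fams.gene_species_map[g] == focal]]
        pem = expr_mod.compute_pem(focal_atlas)
        if pem.excluded:
            entry["warnings"].append(f"{len(pem.excluded)} genes excluded from PEM")
        taxon_matrix, row_order, col_order = expr_mod.taxon_tissue_matrix(
            pem, oset.creating_taxon)
        brain_genes = expr_mod.preferential_tissue_genes(pem, "brain", pem_min=0.4)
        pairs_age = ret_mod.paralog_pairs_by_age(fams, stree, focal)
        age_order = sorted({t for _, _, t in pairs_age},
                           key=lambda t: stree.depth.get(t, 10**6))
        div = expr_mod.pair_divergence(focal_atlas, pairs_age, metric="pearson",
                                       age_order=age_order)
        state.update(pem=pem, focal_atlas=focal_atlas)
        entry["outputs"] = {
            "n_pem_genes": int(pem.pem.shape[0]),
            "taxon_matrix_rows": list(taxon_matrix.index),
            "row_order": row_order,
            "col_order": col_order,
            "n_brain_preferential": len(brain_genes),
            "divergence_medians_by_age": {
                age: s["median"] for age, s in div["summaries"].items()},
        }
        if out_dir:
            expr_mod.write_pem(pem, os.path.join(out_dir, "pem.tsv"))

    @stage("network")
    def _network(entry):
        simnet, oset = state["simnet"], state["oset"]
        net = simnet.network
        ohnolog_nodes = [g for g in oset.genes if g in net]
        perm = (net_mod.permutation_pvalue(
                    net, ohnolog_nodes, "mean_degree", n_perm=200, seed=config.seed)
                if ohnolog_nodes else None)
        cons = net_mod.pair_conservation(net, simnet.pairs)
        bridged = net_mod.find_bridged_pairs(net, simnet.pairs)
        null = net_mod.random_pair_null(net, n_samples=500, seed=config.seed)
        cie = coe = 0
        for rec in cons["pairs"]:
            cc = net_mod.classify_cie_coe(net, rec.pair)
            cie += cc["cie_count"]
            coe += cc["coe_count"]
        entry["outputs"] = {
            "n_nodes": len(net.nodes),
            "n_edges": net.n_edges(),
            "degree_p_value": perm["p_value"] if perm else None,
            "pair_summary": cons["summary"],
            "cie_total": cie,
            "coe_total": coe,
            "n_bridged_pairs": bridged["n_bridged"],
            "null_any_shared": null["frac_pairs_any_shared"],
        }

    @stage("triads")
    def _triads(entry):
        from . import triads as tri_mod
        fams, atlas, oset = state["fams"], state["atlas"], state["oset"]
        outgroup = "Drosophila_melanogaster"
        triads, skipped = tri_mod.extract_ancestral_set(fams, oset.pairs, outgroup)
        out_atlas = atlas.loc[[g for g in atlas.index
                               if fams.gene_species_map[g] == outgroup]]
        triads, dropped = tri_mod.assign_pbe_flags(
            triads, state["focal_atlas"], out_atlas)
        summary = tri_mod.classify_triads(triads)
        if dropped:
            entry["warnings"].append(f"{dropped} triads without expression rows")
        entry["outputs"] = {
            "n_triads": summary.total,
            "skip_reasons": dict(skipped),
            "configuration_counts": summary.counts,
            "conservation_over_sub": summary.conservation_over_sub,
            "conservation_over_neo": summary.conservation_over_neo,
            "sub_over_neo": summary.sub_over_neo,
        }

    @stage("enrichment")
    def _enrichment(entry):
        fams, layout, oset = state["fams"], state["layout"], state["oset"]
        universe = set(layout.position)
        results = enrich_mod.chromosome_clustering_test(
            oset.genes & universe, layout, universe)
        min_adj = min((r.adjusted_p for r in results if r.adjusted_p is not None),
                      default=None)
        n_sig = sum(1 for r in results
                    if r.adjusted_p is not None and r.adjusted_p < 0.05)
        entry["outputs"] = {
            "n_terms_tested": len(results),
            "min_adjusted_p": min_adj,
            "n_significant_05": n_sig,
        }
        if out_dir:
            enrich_mod.write_enrichment(
                results, os.path.join(out_dir, "positional_enrichment.tsv"))

    report["headline_digest"] = _digest(report["stages"])
    if out_dir:
        with open(os.path.join(out_dir, "run_report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report
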