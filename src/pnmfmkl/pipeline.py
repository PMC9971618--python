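"""End-to-end pipeline: screening → fusion → kernels → MKL label search →
module detection → signature election and PAM evaluation.

``run_pipeline`` chains the stage modules on a list of layers plus a sample
annotation and returns a JSON-ready report (label-combination metrics table,
cluster-validity indices, module mean correlations, signature gene list and
repeated-CV classification summary) together with the intermediate objects
for programmatic use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import diffexp, fusion, kernels, labelsearch, netmodules, signature
from .io import OmicsLayer, SampleAnnotation, intersect_samples

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    report: dict
    uf_genes: list[str]
    kernel_set: kernels.KernelSet
    combinations: list
    best: labelsearch.LabelCombination
    modules: list
    signature_module: object
    signature_report: signature.SignatureReport


def _collapse_layer(
    layer: OmicsLayer, stats: diffexp.ModeratedStats, genes: list[str]
) -> OmicsLayer:
    """Restrict a layer to *genes*, one minimum-p feature per gene."""
    order = np.argsort(stats.p_value, kind="stable")
    chosen: dict[str, str] = {}
    for i in order:
        fid = stats.feature_ids[i]
        g = layer.gene_of(fid)
        if g not in chosen:
            chosen[g] = fid
    keep_genes = [g for g in genes if g in chosen]
    sub = layer.subset_features([chosen[g] for g in keep_genes])
    return OmicsLayer(layer.layer_name, sub.values, keep_genes, sub.sample_ids, None)


def run_pipeline(
    layers: list[OmicsLayer],
    annot: SampleAnnotation,
    alpha: float = 0.05,
    ranks: dict[str, int] | None = None,
    fusion_max_iter: int = 300,
    window: int = 3,
    pi: float = 1.0,
    C: float = 1.0,
    folds: int = 10,
    repeats: int = 10,
    min_module_size: int = 20,
    seed: int = 0,
) -> PipelineResult:
    """Run the full multi-omics fusion and signature-detection pipeline."""
    # 1. shared samples, missing-value filtering, normalization
    layers, annot = intersect_samples(layers, annot)
    clean = [diffexp.zero_mean_normalize(diffexp.drop_missing_features(l)) for l in layers]

    # 2. per-layer moderated tests, probe collapse, cross-layer union
    stats = [diffexp.fit_ebayes(l, annot) for l in clean]
    sig_sets = [
        diffexp.select_significant(s, mapping=l.feature_to_gene, alpha=alpha)
        for s, l in zip(stats, clean)
    ]
    uf = diffexp.union_features(sig_sets)
    if len(uf) < 2 * min_module_size:
        raise ValueError(
            f"only {len(uf)} genes in the significant union; "
            f"need >= {2 * min_module_size} for module detection"
        )
    collapsed = [_collapse_layer(l, s, uf) for l, s in zip(clean, stats)]

    # 3. relational system and tri-factorization
    system = fusion.build_relational_system(collapsed, annot)
    fac = fusion.fit_trifactorization(system, ranks=ranks, max_iter=fusion_max_iter, seed=seed)

    # 4. per-layer sample kernels from the reconstructed blocks
    mats, names = [], []
    sample_ids = collapsed[0].sample_ids
    feature_types = [t for t in system.type_names if t not in ("gene", "sample")]
    blocks = (["gene"] if ("gene", "sample") in system.relations else []) + feature_types
    for t in blocks:
        R_hat = fac.reconstruct(t, "sample")
        K = kernels.kernel_from_reconstruction(R_hat.T)
        mats.append(kernels.normalize_and_smooth(K, window=window))
        names.append(t)
    kset = kernels.KernelSet(mats, names, list(sample_ids))

    # 5. label-combination search by CV AUC of the MKL classifier
    combos = labelsearch.enumerate_combinations(annot.classes)
    scored = [
        labelsearch.score_combination(c, kset, annot, folds=folds, seed=seed, pi=pi, C=C)
        for c in combos
    ]
    best = labelsearch.best_combination(scored)

    # 6. co-expression modules on the best combination's expression sub-data
    y_all = annot.vector(sample_ids)
    keep = np.isin(y_all, best.left) | np.isin(y_all, best.right)
    expr_layer = collapsed[0]
    sub_expr = expr_layer.values[:, keep]
    power, curve = netmodules.pick_soft_power(sub_expr)
    adj = netmodules.adjacency(sub_expr, power, genes=expr_layer.feature_ids)
    T = netmodules.tom(adj)
    modules = netmodules.cut_modules(T.dissT, genes=adj.genes, min_module_size=min_module_size)
    validity = netmodules.validity_indices(adj, T.dissT, modules)

    # 7. signature election and PAM repeated-CV evaluation
    elected = signature.elect_signature(sub_expr, modules, adj.genes)
    y_bin = np.where(np.isin(y_all[keep], best.left), "pos", "neg")
    sig_report = signature.pam_cv_evaluate(
        sub_expr, adj.genes, elected, y_bin, folds=folds, repeats=repeats, seed=seed
    )

    report = {
        "significant_genes_per_layer": {
            s.layer_name: len(s.genes) for s in sig_sets
        },
        "uf_size": len(uf),
        "fusion_objective": fac.objective_trace_[-1],
        "combinations": [
            {"combination": c.name, **{k: c.metrics[k] for k in
             ("sensitivity", "specificity", "precision", "npv", "accuracy", "auc")}}
            for c in scored
        ],
        "max_row": {
            k: max(c.metrics[k] for c in scored)
            for k in ("sensitivity", "specificity", "precision", "npv", "accuracy", "auc")
        },
        "best_combination": best.name,
        "best_auc": best.auc,
        "soft_power": power,
        "power_curve": {str(k): v for k, v in curve.items()},
        "modules": [
            {"module": m.module_id, "size": len(m.genes),
             "mean_pcc": signature.module_mean_pcc(sub_expr, m, adj.genes)
             if len(m.genes) >= 2 else None}
            for m in modules
        ],
        "validity_indices": validity.as_dict(),
        "signature": {
            "module": elected.module_id,
            "n_features": len(elected.genes),
            "genes": list(elected.genes),
            "average_pcc": sig_report.mean_pcc,
        },
        "classification": {
            k: {"mean": v[0], "std": v[1]} for k, v in sig_report.summary.items()
        },
    }
    return PipelineResult(
        report=report,
        uf_genes=uf,
        kernel_set=kset,
        combinations=scored,
        best=best,
        modules=modules,
        signature_module=elected,
        signature_report=sig_report,
    )
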