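"""End-to-end pipeline orchestration.

Runs the enabled stages in the order the analysis proceeds — metabolomics
QC, multivariate separation, per-metabolite mixed models, quantitative
enrichment; antibody-array Z ratios and probe derivation; network
reduction — and writes per-stage TSV outputs plus one machine-readable JSON
summary with the counts at every filter, all seeds and the config hash.
Stage failures halt with the failing stage named; outputs of completed
stages are preserved.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment, io, mixed_models, multivariate, network, phospho
from . import preprocess

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "stages": {"metab": True, "phospho": True, "network": True},
    "missingness_threshold": 0.30,
    "mnar_threshold": 0.90,
    "k_mad": 3.0,
    "exclude_flagged_samples": False,
    "n_components": 2,
    "zratio_cutoff": 1.1,
    "n_perm": 1000,
    "centrality_fraction": 0.5,
    "threshold_mode": "all",
    "heat_time": 0.1,
    "mcode": {"vwp": 0.2, "degree_cut": 2, "haircut": True, "fluff": False},
    "seed": 0,
}


def merge_config(cfg: dict | None) -> dict:
    merged = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in DEFAULT_CONFIG.items()}
    for k, v in (cfg or {}).items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    _validate_config(merged)
    return merged


def _validate_config(cfg: dict) -> None:
    checks = [
        (0 < cfg["missingness_threshold"] < 1, "missingness_threshold in (0,1)"),
        (0 < cfg["mnar_threshold"] <= 1, "mnar_threshold in (0,1]"),
        (cfg["zratio_cutoff"] > 0, "zratio_cutoff > 0"),
        (0 < cfg["centrality_fraction"] <= 1, "centrality_fraction in (0,1]"),
        (cfg["n_perm"] >= 1, "n_perm >= 1"),
        (cfg["threshold_mode"] in ("all", "any"), "threshold_mode all|any"),
    ]
    for ok, msg in checks:
        if not ok:
            raise ValueError(f"bad config: expected {msg}")


def run_metabolomics(matrix: pd.DataFrame, design: pd.DataFrame, cfg: dict,
                     pathways: enrichment.PathwayDB | None = None,
                     out_dir: Path | None = None) -> dict:
    """QC -> multivariate -> mixed models -> enrichment on one matrix."""
    io.check_design_matches(matrix, design)
    grades = preprocess.grade_missingness(
        matrix, design, threshold=cfg["missingness_threshold"],
        mnar_threshold=cfg["mnar_threshold"])
    mva = grades.mva_features
    normalized, factors = preprocess.normalize_and_transform(matrix, mva)
    protein = (design["protein_content"]
               if "protein_content" in design.columns else None)
    qc = preprocess.qc_report(normalized[mva], design, protein,
                              k_mad=cfg["k_mad"])
    if cfg["exclude_flagged_samples"] and qc.flagged_samples:
        keep = [s for s in normalized.index if s not in qc.flagged_samples]
        normalized, design = normalized.loc[keep], design.loc[keep]

    scores, separations = multivariate.plsda_with_roc(
        normalized[mva], design, n_components=cfg["n_components"])
    pca = multivariate.run_pca(normalized[mva],
                               n_components=cfg["n_components"])

    fits = mixed_models.fit_and_compare_models(
        normalized[mva + grades.uva_only_features], design, grades)
    contrasts = mixed_models.contrasts_with_fdr(fits)
    comparison = mixed_models.comparison_table(fits)

    qea = None
    if pathways is not None:
        y = (design["CELL"] == "PLP").astype(float).to_numpy()
        qea = enrichment.global_test_qea(
            normalized[mva], y, pathways,
            n_perm=cfg["n_perm"], seed=cfg["seed"])

    summary = {
        "n_samples": int(len(matrix)),
        "n_features": int(matrix.shape[1]),
        "n_mva_uva": len(mva),
        "n_uva_only": len(grades.uva_only_features),
        "n_excluded": len(grades.excluded_features),
        "flagged_samples": qc.flagged_samples,
        "auc_by_group": {s.group: s.auc for s in separations},
        "min_auc": min((s.auc for s in separations), default=np.nan),
        "n_lmm_chosen": int((comparison["chosen"] == "LMM").sum()),
        "n_gls_chosen": int((comparison["chosen"] == "GLS").sum()),
        "n_significant_contrasts": int(
            (contrasts["p_adj"] < 0.05).sum()),
        "n_significant_pathways": (
            int((qea["p_adj"] < 0.05).sum()) if qea is not None else None),
    }
    results = {"grades": grades, "normalized": normalized, "factors": factors,
               "qc": qc, "pca": pca, "plsda_scores": scores,
               "separations": separations, "fits": fits,
               "contrasts": contrasts, "comparison": comparison, "qea": qea,
               "summary": summary}
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        grades.table.to_csv(out_dir / "missingness_grades.tsv", sep="\t")
        io.write_intensity_matrix(10 ** normalized,
                                  out_dir / "normalized_log10_backtransformed.tsv")
        contrasts.to_csv(out_dir / "univariate_contrasts.tsv", sep="\t",
                         index=False, na_rep="NA")
        comparison.to_csv(out_dir / "model_comparison.tsv", sep="\t",
                          na_rep="NA")
        if qea is not None:
            qea.to_csv(out_dir / "qea.tsv", sep="\t", index=False, na_rep="NA")
        io.write_json_report(qc.to_dict(), out_dir / "qc_report.json")
    return results


def run_phospho(matrix: pd.DataFrame, design: pd.DataFrame, cfg: dict,
                condition_a: str = "PTTH", condition_b: str = "CTRL",
                out_dir: Path | None = None) -> dict:
    zmat = phospho.compute_zscores(matrix, design)
    table = phospho.compute_zratios(zmat, condition_a, condition_b,
                                    cutoff=cfg["zratio_cutoff"])
    summary = {
        "n_proteins": int(len(table)),
        "n_significant": int(table["significant"].sum()),
        "n_up": int((table["significant"] & (table["direction"] == "up")).sum()),
        "n_down": int((table["significant"]
                       & (table["direction"] == "down")).sum()),
    }
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "zratios.tsv", sep="\t", na_rep="NA")
    return {"zscores": zmat, "zratios": table, "summary": summary}


def run_network(g, probe: set[str], cfg: dict,
                out_dir: Path | None = None) -> dict:
    fn = network.first_neighbors(g, probe)
    profile = network.compute_centralities(fn, heat_seeds=probe,
                                           heat_time=cfg["heat_time"])
    thresholded, directed = network.threshold_directed_subnetwork(
        fn, profile, fraction=cfg["centrality_fraction"],
        mode=cfg["threshold_mode"])
    modules = network.mcode_modules(directed, **cfg["mcode"])
    summary = {
        "n_nodes_input": int(g.number_of_nodes()),
        "n_edges_input": int(g.number_of_edges()),
        "n_nodes_fn": int(fn.number_of_nodes()),
        "n_edges_fn": int(fn.number_of_edges()),
        "n_nodes_thresholded": int(thresholded.number_of_nodes()),
        "n_edges_thresholded": int(thresholded.number_of_edges()),
        "n_nodes_directed": int(directed.number_of_nodes()),
        "n_edges_directed": int(directed.number_of_edges()),
        "n_modules": len(modules),
        "top_module": ({"members": modules[0].members,
                        "score": modules[0].score} if modules else None),
    }
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        profile.table.to_csv(out_dir / "centralities.tsv", sep="\t")
        io.write_json_report(
            {"modules": [{"members": m.members, "score": m.score,
                          "seed": m.seed} for m in modules]},
            out_dir / "modules.json")
    return {"fn": fn, "profile": profile, "thresholded": thresholded,
            "directed": directed, "modules": modules, "summary": summary}


def run_pipeline(config: dict, inputs: dict, out_dir: str | Path | None = None,
                 ) -> dict:
    """Execute all enabled stages; return the report bundle.

    ``inputs`` supplies in-memory objects: ``metab_matrix``/``metab_design``
    (+ optional ``pathways``), ``phospho_matrix``/``phospho_design``,
    ``graph``/``probe``.  A stage failure raises with the stage named.
    """
    cfg = merge_config(config)
    out = Path(out_dir) if out_dir is not None else None
    bundle: dict = {"config": cfg, "config_hash": io.config_hash(cfg),
                    "seed": cfg["seed"], "summary": {}}
    stages = cfg["stages"]

    def _run(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    if stages.get("metab") and "metab_matrix" in inputs:
        res = _run("metab", run_metabolomics, inputs["metab_matrix"],
                   inputs["metab_design"], cfg,
                   pathways=inputs.get("pathways"),
                   out_dir=(out / "metab" if out else None))
        bundle["metab"] = res
        bundle["summary"]["metab"] = res["summary"]
    if stages.get("phospho") and "phospho_matrix" in inputs:
        res = _run("phospho", run_phospho, inputs["phospho_matrix"],
                   inputs["phospho_design"], cfg,
                   out_dir=(out / "phospho" if out else None))
        bundle["phospho"] = res
        bundle["summary"]["phospho"] = res["summary"]
    if stages.get("network") and "graph" in inputs:
        res = _run("network", run_network, inputs["graph"], inputs["probe"],
                   cfg, out_dir=(out / "network" if out else None))
        bundle["network"] = res
        bundle["summary"]["network"] = res["summary"]

    if out is not None:
        io.write_json_report(
            {"config_hash": bundle["config_hash"], "seed": cfg["seed"],
             "summary": bundle["summary"]},
            out / "summary.json")
    return bundle
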