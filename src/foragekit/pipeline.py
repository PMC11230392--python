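"""End-to-end pipeline: simulate → segment → featurize → discover → stats.

Every stage writes plain-text artifacts (CSV/JSON) into the output
directory and the run is summarised in a manifest with SHA-256 checksums,
so a rerun with the same config and seed can be verified byte-for-byte on
all deterministic artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import features as feat
from . import modules as mod
from . import segmentation as seg
from . import simulate as sim
from . import stats as st
from .geometry import ArenaGeometry, PHASES

log = logging.getLogger("foragekit")

DEFAULT_CONFIG = {
    "preset": "paper_like",
    "min_duration_s": 2.0,
    "min_penetration_cm": 5.0,
    "standardize_method": "zscore",
    "k_range": [2, 16],
    "n_splits": 10,
    "stability_threshold": 0.5,
    "min_module_size": 5,
    "occupancy_min": 5,  # noise-robust phase expression call
    "embedding_method": "pca",
    "q_threshold": 0.2,
}


def load_config(path: str | Path | None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            cfg.update(yaml.safe_load(fh) or {})
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _frame_to_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def run_pipeline(outdir: str | Path, seed: int = 0,
                 config: dict | str | Path | None = None) -> dict:
    """Run all stages and return the manifest (also written to manifest.json)."""
    if isinstance(config, dict):
        cfg = {**DEFAULT_CONFIG, **config}
    else:
        cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geom = ArenaGeometry()
    manifest = {"seed": int(seed), "config": cfg, "stages": {}, "checksums": {}}

    def record(stage: str, paths: dict, t0: float, **extra) -> None:
        manifest["stages"][stage] = {
            "outputs": {k: str(p) for k, p in paths.items()},
            "elapsed_s": round(time.time() - t0, 2), **extra}
        for p in paths.values():
            manifest["checksums"][Path(p).name] = _sha256(Path(p))
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

    # -- simulate ----------------------------------------------------------
    t0 = time.time()
    simcfg = sim.make_default_config(cfg["preset"], seed=seed)
    traj, meta, gross_scalars, truth = sim.simulate_cohort(simcfg)
    paths = sim.write_cohort(outdir, traj, meta, truth)
    record("simulate", paths, t0, n_mice=len(meta), n_samples=len(traj))

    # -- segment -----------------------------------------------------------
    t0 = time.time()
    ann = seg.annotate_zones(traj, geom)
    exc = seg.segment_excursions(ann, geom, cfg["min_duration_s"],
                                 cfg["min_penetration_cm"])
    gross = seg.gross_latency_and_counts(exc, ann, geom, simcfg.phase_duration_s)
    gross = gross.merge(meta[["mouse_id", "food_g", "sand_g"]], on="mouse_id")
    p_exc, p_qc, p_gross = outdir / "excursions.csv", outdir / "qc.json", outdir / "gross.csv"
    seg.write_excursions(p_exc, exc)
    seg.write_qc(p_qc, seg.qc_report(ann))
    _frame_to_csv(gross, p_gross)
    record("segment", {"excursions": p_exc, "qc": p_qc, "gross": p_gross},
           t0, n_excursions=int(exc["valid"].sum()))

    # -- featurize ---------------------------------------------------------
    t0 = time.time()
    fm = feat.feature_matrix(exc, ann, geom)
    values = fm[list(feat.MEASURE_NAMES)]
    std, rec = feat.standardize(values, cfg["standardize_method"])
    p_fm, p_std, p_rec = (outdir / "features.csv", outdir / "features_std.csv",
                          outdir / "standardization.json")
    _frame_to_csv(fm, p_fm)
    _frame_to_csv(pd.concat([fm[["mouse_id", "phase", "index"]], std], axis=1), p_std)
    p_rec.write_text(json.dumps(rec.to_dict(), indent=1), encoding="utf-8")
    record("featurize", {"features": p_fm, "features_std": p_std,
                         "standardization": p_rec}, t0, n_rows=len(fm))

    # -- discover ----------------------------------------------------------
    t0 = time.time()
    X = std.to_numpy()
    kmin, kmax = cfg["k_range"]
    catalog = mod.select_module_count(
        X, range(kmin, kmax + 1), n_splits=cfg["n_splits"],
        stability_threshold=cfg["stability_threshold"],
        min_size=cfg["min_module_size"], seed=seed)
    assign = fm[["mouse_id", "phase", "index"]].copy()
    assign["module"] = catalog.assignment
    occ = mod.phase_occupancy(catalog.assignment, fm["phase"].to_numpy(),
                              cfg["occupancy_min"])
    emb = mod.embed_excursions(X, cfg["embedding_method"], seed=seed)
    emb_df = assign.copy()
    emb_df[["dim1", "dim2"]] = emb[:, :2]
    p_as, p_cat, p_emb = (outdir / "assignments.csv", outdir / "catalog.json",
                          outdir / "embedding.csv")
    _frame_to_csv(assign, p_as)
    catalog.to_json(p_cat)
    _frame_to_csv(emb_df, p_emb)
    record("discover", {"assignments": p_as, "catalog": p_cat, "embedding": p_emb},
           t0, K=catalog.K, venn=occ.counts)

    # -- stats -------------------------------------------------------------
    t0 = time.time()
    expr = st.expression_table(assign, meta)
    div = st.module_diversity(expr)
    results = st.diversity_regression(div, meta)
    counts_rows = []
    modules = sorted(assign["module"].unique())
    for sex in ("M", "F"):
        for age in ("young", "aged"):
            for phase in PHASES:
                res = st.test_module_expression(expr, sex, age, phase, modules)
                results.extend(res)
                counts_rows.append({"sex": sex, "age": age, "phase": phase,
                                    "n_significant": st.count_significant(
                                        res, cfg["q_threshold"])})
    counts = pd.DataFrame(counts_rows)
    results.append(st.significant_count_model(counts))
    results.extend(st.gross_measure_regression(gross, meta))
    series = st.secondguess_series(ann, geom)
    results.extend(st.secondguess_model(series, meta))
    curves = st.group_bin_curves(series, meta)
    # genotype prediction from whole-behavior profiles, per age × phase
    pca_summaries = {}
    for age in ("young", "aged"):
        for phase in PHASES:
            mids = meta.loc[meta["age"] == age, "mouse_id"]
            fmx = st.frequency_matrix(expr[expr["mouse_id"].isin(mids)], phase,
                                      modules)
            gsub = gross[(gross["phase"] == phase)
                         & gross["mouse_id"].isin(fmx.index)]
            prof = gsub.set_index("mouse_id")[list(st.GROSS_MEASURES)].join(fmx)
            genos = meta.set_index("mouse_id").loc[prof.index, "genotype"]
            try:
                r = st.pca_logit_predict(prof, genos)
                results.append(st.StatResult(
                    test="pca_logit", stratum=f"age={age},phase={phase}",
                    term="likelihood_ratio", statistic=r.lr_statistic,
                    p=r.lr_p, estimate=r.mcfadden_r2, df=r.n_pcs,
                    n1=len(prof), note=r.note))
                pca_summaries[f"{age}|{phase}"] = {
                    "n_pcs": r.n_pcs, "lr_p": r.lr_p, "pc_p": r.pc_p,
                    "mcfadden_r2": r.mcfadden_r2}
            except ValueError as e:
                pca_summaries[f"{age}|{phase}"] = {"skipped": str(e)}
    p_res = outdir / "stats_results.csv"
    p_counts = outdir / "significant_counts.csv"
    p_curves = outdir / "secondguess_curves.csv"
    p_div = outdir / "diversity.csv"
    p_sum = outdir / "summary.json"
    _frame_to_csv(st.results_frame(results), p_res)
    _frame_to_csv(counts, p_counts)
    _frame_to_csv(curves, p_curves)
    _frame_to_csv(div, p_div)
    summary = {
        "n_mice": int(len(meta)),
        "n_excursions": int(exc["valid"].sum()),
        "K": int(catalog.K),
        "venn": occ.counts,
        "significant_counts": counts_rows,
        "phase_age_interaction_p": float(
            [r for r in results if r.test == "significant_count_model"][0].p),
        "pca_logit": pca_summaries,
    }
    p_sum.write_text(json.dumps(summary, indent=1), encoding="utf-8")
    record("stats", {"results": p_res, "significant_counts": p_counts,
                     "secondguess_curves": p_curves, "diversity": p_div,
                     "summary": p_sum}, t0)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str),
                             encoding="utf-8")
    return manifest


def report(outdir: str | Path, figures: bool = True) -> Path:
    """Render a markdown report (plus PNG figures) from a completed run."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    lines = ["# Foraging pipeline report", ""]
    summary_path = outdir / "summary.json"
    if summary_path.exists():
        s = json.loads(summary_path.read_text())
        venn = s["venn"]
        lines += [
            f"- mice: {s['n_mice']}, valid excursions: {s['n_excursions']}",
            f"- modules discovered: K = {s['K']}",
            f"- phase occupancy: shared {venn['shared']}, Exploration-only "
            f"{venn['exploration_only']}, Foraging-only {venn['foraging_only']} "
            f"(sum = {venn['shared'] + venn['exploration_only'] + venn['foraging_only']})",
            f"- significant-module phase×age interaction p = "
            f"{s['phase_age_interaction_p']:.4g}", "",
        ]
    else:
        lines.append("- stats stage missing: summary skipped")
    if figures:
        try:
            _render_figures(outdir, lines)
        except Exception as e:  # figures are presentation-only
            lines.append(f"- figures skipped: {e}")
    path = outdir / "report.md"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def _render_figures(outdir: Path, lines: list) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    emb_path = outdir / "embedding.csv"
    if emb_path.exists():
        emb = pd.read_csv(emb_path)
        fig, ax = plt.subplots(figsize=(6, 5))
        sc = ax.scatter(emb["dim1"], emb["dim2"], c=emb["module"],
                        cmap="tab20", s=6, linewidths=0)
        ax.set_xlabel("dim 1")
        ax.set_ylabel("dim 2")
        ax.set_title("Excursion map coloured by module")
        fig.colorbar(sc, label="module")
        fig.savefig(outdir / "fig_embedding.png", dpi=120)
        plt.close(fig)
        lines.append("- figure: fig_embedding.png")
    cur_path = outdir / "secondguess_curves.csv"
    if cur_path.exists():
        cur = pd.read_csv(cur_path)
        fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharey=True)
        for ax, (sex, age) in zip(axes.ravel(),
                                  [("F", "young"), ("F", "aged"),
                                   ("M", "young"), ("M", "aged")]):
            for geno, g in cur[(cur.sex == sex) & (cur.age == age)].groupby("genotype"):
                ax.plot(g["bin"], g["dwell_mean_s"], label=geno)
                ax.fill_between(g["bin"], g["dwell_mean_s"] - g["dwell_sem_s"],
                                g["dwell_mean_s"] + g["dwell_sem_s"], alpha=0.3)
            ax.set_title(f"{sex} {age}")
            ax.legend(fontsize=7)
        fig.suptitle("Pot2 dwell per 1-min bin (second-guessing)")
        fig.supxlabel("minute bin")
        fig.supylabel("dwell (s)")
        fig.savefig(outdir / "fig_secondguess.png", dpi=120)
        plt.close(fig)
        lines.append("- figure: fig_secondguess.png")
    cnt_path = outdir / "significant_counts.csv"
    if cnt_path.exists():
        cnt = pd.read_csv(cnt_path)
        fig, ax = plt.subplots(figsize=(6, 4))
        labels = cnt["sex"] + "/" + cnt["age"] + "/" + cnt["phase"]
        ax.bar(labels, cnt["n_significant"])
        ax.set_ylabel("# significant modules (q<0.2)")
        ax.tick_params(axis="x", rotation=60, labelsize=7)
        fig.tight_layout()
        fig.savefig(outdir / "fig_significant_counts.png", dpi=120)
        plt.close(fig)
        lines.append("- figure: fig_significant_counts.png")
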