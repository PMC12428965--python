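"""End-to-end orchestration of the two-level analysis.

Stages: load/collapse/filter -> PCA overview -> differential expression per
comparison per fraction -> translational ratios and interaction tests ->
Up/Down/Stable set comparison (UpSet regions, Jaccard, stable cores) ->
co-expression modules at the transcriptional and translational level ->
cross-level module overlap -> over/under-representation analysis.  Every
table and figure is written beneath the output directory together with a
JSON manifest (sha256 per file) and a run log.  Identical config + inputs
give byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crosslevel as crosslevel_mod
from . import network, sets
from .diffexpr import classify_genes, test_differential, write_de_result
from .enrichment import enrich, read_gmt
from .io import (
    CONDITIONS,
    CountMatrix,
    NormalizedMatrix,
    collapse_technical_replicates,
    cpm_normalize,
    filter_low_expression,
    pca_overview,
    read_counts,
    read_sample_sheet,
)
from .translation import (
    test_differential_translation,
    tr_normalize_million,
    translational_ratio,
)

log = logging.getLogger("translatome")

DEFAULT_COMPARISONS = (
    "Combo_vs_Control",
    "Combo_vs_Hardening",
    "Combo_vs_Stress",
    "Hardening_vs_Control",
    "Stress_vs_Control",
    "Stress_vs_Hardening",
)
ALL_STAGES = ("pca", "de", "tr", "compare", "wgcna", "crosslevel", "enrich")


@dataclass
class PipelineConfig:
    counts_total: str = ""
    counts_polysome: str = ""
    sample_sheet: str = ""
    annotation: str | None = None
    outdir: str = "results"
    comparisons: tuple[str, ...] = DEFAULT_COMPARISONS
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    min_count: int = 10
    min_samples: int = 2
    module_min_size: int = 30
    cut_height: float = 0.99
    jaccard_threshold: float = 0.05
    term_size_max: int = 250
    intersection_min: int = 10
    tr_pseudocount: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for comp in self.comparisons:
            b, a = parse_comparison(comp)
            for cond in (a, b):
                if cond not in CONDITIONS:
                    raise ValueError(f"comparison {comp!r} uses unknown condition")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.lfc_threshold < 0 or self.jaccard_threshold < 0:
            raise ValueError("thresholds must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        raw = raw.get("pipeline", raw)
        raw.update(overrides)
        if "comparisons" in raw:
            raw["comparisons"] = tuple(raw["comparisons"])
        return cls(**raw)


def parse_comparison(name: str) -> tuple[str, str]:
    """'X_vs_Y' -> (X, Y); the fold change / deltaTR is X over Y."""
    parts = name.split("_vs_")
    if len(parts) != 2:
        raise ValueError(f"malformed comparison name: {name!r}")
    return parts[0], parts[1]


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_table(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(
    cfg: PipelineConfig, stages: set[str] | None = None
) -> dict:
    """Execute the pipeline; ``stages`` restricts which outputs are written
    (prerequisite computations still run).  Returns the manifest dict."""
    requested = set(ALL_STAGES) if stages is None else set(stages)
    unknown = requested - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fig_dir = outdir / "figures"
    fig_dir.mkdir(exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    written: list[Path] = []
    summary: dict = {"comparisons": list(cfg.comparisons)}

    def emit(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = outdir / name
        _write_table(df, path, index=index)
        written.append(path)

    try:
        log.info("config: %s", json.dumps(asdict(cfg), default=str))

        # ------------------------------------------------------------------
        log.info("stage load: reading counts and sample sheet")
        total = read_counts(cfg.counts_total, "total")
        poly = read_counts(cfg.counts_polysome, "polysome")
        ss = read_sample_sheet(cfg.sample_sheet)
        tc, tss = collapse_technical_replicates(total, ss)
        pc, pss = collapse_technical_replicates(poly, ss)
        sheet = pd.concat([tss, pss], ignore_index=True)

        common = tc.counts.index.intersection(pc.counts.index)
        keep_t = filter_low_expression(
            CountMatrix(tc.counts.loc[common], "total"),
            cfg.min_count, cfg.min_samples,
        ).counts.index
        keep_p = filter_low_expression(
            CountMatrix(pc.counts.loc[common], "polysome"),
            cfg.min_count, cfg.min_samples,
        ).counts.index
        keep = common[common.isin(keep_t.union(keep_p))]
        tc = CountMatrix(tc.counts.loc[keep], "total")
        pc = CountMatrix(pc.counts.loc[keep], "polysome")
        log.info("kept %d genes after filtering", len(keep))
        summary["n_genes_analysed"] = int(len(keep))

        total_cpm = cpm_normalize(tc)
        poly_cpm = cpm_normalize(pc)
        total_log = cpm_normalize(tc, log=True)
        poly_log = cpm_normalize(pc, log=True)

        # ------------------------------------------------------------------
        if "pca" in requested:
            log.info("stage pca")
            combined = NormalizedMatrix(
                pd.concat([total_log.values, poly_log.values], axis=1),
                scale="log2cpm",
            )
            coords, evr = pca_overview(combined, n_components=2)
            emit(coords, "pca_coordinates.tsv")
            emit(
                pd.DataFrame({"component": ["PC1", "PC2"], "explained_variance": evr}),
                "pca_explained_variance.tsv", index=False,
            )
            from .plotting import plot_pca

            written.append(plot_pca(coords, sheet, fig_dir / "pca.png"))
            summary["pca_explained_variance"] = [float(v) for v in evr]

        # ------------------------------------------------------------------
        need_sets = requested & {"de", "tr", "compare", "enrich"}
        de_results: dict[str, pd.DataFrame] = {}
        dtr_results: dict[str, pd.DataFrame] = {}
        if need_sets:
            log.info("stage de: %d comparisons x 2 fractions", len(cfg.comparisons))
            cond_cols = {
                (frac, cond): [
                    s for s in cm.sample_ids
                    if sheet.set_index("sample_id").at[s, "condition"] == cond
                ]
                for frac, cm in (("total", tc), ("polysome", pc))
                for cond in CONDITIONS
            }
            for comp in cfg.comparisons:
                b, a = parse_comparison(comp)
                for frac, cm in (("total", tc), ("polysome", pc)):
                    de = test_differential(
                        cm, cond_cols[(frac, a)], cond_cols[(frac, b)]
                    )
                    de = classify_genes(de, cfg.lfc_threshold, cfg.alpha)
                    name = sets.comparison_name(b, a, frac if frac == "total" else None)
                    if frac == "polysome":
                        name = f"{name}_polysome"
                    de_results[name] = de
                    if "de" in requested:
                        path = outdir / f"de_{name}.tsv"
                        write_de_result(de, path)
                        written.append(path)
            summary["de_class_counts"] = {
                name: de["class"].value_counts().to_dict()
                for name, de in de_results.items()
            }

            log.info("stage tr")
            tr = translational_ratio(
                total_cpm, poly_cpm, sheet, pseudocount=cfg.tr_pseudocount
            )
            if "tr" in requested:
                emit(tr.values, "tr_conditions.tsv")
            for comp in cfg.comparisons:
                b, a = parse_comparison(comp)
                dtr = test_differential_translation(
                    tc, pc, sheet, a, b,
                    lfc_threshold=cfg.lfc_threshold, alpha=cfg.alpha,
                )
                dtr_results[comp] = dtr
                if "tr" in requested:
                    path = outdir / f"dtr_{comp}.tsv"
                    write_de_result(dtr, path)
                    written.append(path)
            summary["dtr_class_counts"] = {
                comp: d["class"].value_counts().to_dict()
                for comp, d in dtr_results.items()
            }

        # ------------------------------------------------------------------
        collections: dict[tuple[str, str], dict[str, set]] = {}
        if need_sets:
            for klass in ("Up", "Down", "Stable"):
                transcription = {
                    name: set(de.index[de["class"] == klass])
                    for name, de in de_results.items()
                    if name.endswith("_T") or "_T_vs_" in name
                }
                translation = {
                    comp: set(d.index[d["class"] == klass])
                    for comp, d in dtr_results.items()
                }
                collections[("transcription", klass)] = transcription
                collections[("translation", klass)] = translation

        if "compare" in requested:
            log.info("stage compare")
            from .plotting import plot_heatmap, plot_upset

            for (level, klass), coll in collections.items():
                regions = sets.upset_intersections(coll)
                emit(regions, f"upset_{level}_{klass}.tsv", index=False)
                jac = sets.jaccard_matrix(coll)
                emit(jac, f"jaccard_{level}_{klass}.tsv")
                written.append(
                    plot_upset(
                        regions, fig_dir / f"upset_{level}_{klass}.png",
                        title=f"{level} {klass}",
                    )
                )
                written.append(
                    plot_heatmap(
                        jac, fig_dir / f"jaccard_{level}_{klass}.png",
                        title=f"Jaccard, {level} {klass}", vmin=0, vmax=1,
                    )
                )
            for level in ("transcription", "translation"):
                core = sets.stable_core(collections[(level, "Stable")].values())
                core_df = pd.DataFrame({"gene_id": sorted(core)})
                emit(core_df, f"stable_core_{level}.tsv", index=False)
                summary[f"stable_core_{level}_size"] = len(core)

        # ------------------------------------------------------------------
        assignments: dict[str, network.ModuleAssignment] = {}
        if requested & {"wgcna", "crosslevel"}:
            log.info("stage wgcna")
            from .plotting import plot_module_trait

            tr_rep = translational_ratio(
                total_cpm, poly_cpm, sheet,
                pseudocount=cfg.tr_pseudocount, per="replicate",
            )
            tr_million = tr_normalize_million(tr_rep)
            level_inputs = {
                "transcription": total_log.values,
                "translation": np.log2(tr_million.values + 1.0),
            }
            for level, values in level_inputs.items():
                values = values.loc[values.std(axis=1, ddof=0) > 0]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    beta, fit_table, low_fit = network.pick_soft_threshold(values)
                emit(fit_table, f"wgcna_{level}_soft_threshold.tsv", index=False)
                adj = network.adjacency(values, beta=beta)
                tom = network.topological_overlap(adj)
                ma = network.detect_modules(
                    tom, min_module_size=cfg.module_min_size,
                    cut_height=cfg.cut_height,
                )
                assignments[level] = ma
                emit(
                    ma.labels.rename("module").rename_axis("gene_id").to_frame(),
                    f"modules_{level}.tsv",
                )
                eig = network.module_eigengene(values, ma)
                emit(eig.rename_axis("module"), f"eigengenes_{level}.tsv")
                condition_of = (
                    sheet.set_index("sample_id").loc[list(values.columns), "condition"]
                    if level == "transcription"
                    else pd.Series(
                        [u.rsplit("_b", 1)[0] for u in values.columns],
                        index=values.columns,
                    )
                )
                traits = pd.get_dummies(condition_of).astype(float)
                mt = network.module_trait_correlation(eig, traits)
                emit(mt, f"module_trait_{level}.tsv", index=False)
                hubs = network.hub_genes(values, ma, eig, top_n=10)
                emit(hubs, f"hub_genes_{level}.tsv", index=False)
                if "wgcna" in requested:
                    written.append(
                        plot_module_trait(
                            mt, fig_dir / f"module_trait_{level}.png",
                            title=f"Module-trait correlation ({level})",
                        )
                    )
                summary[f"wgcna_{level}"] = {
                    "beta": int(beta),
                    "low_fit": bool(low_fit),
                    "n_modules": len(ma.module_names),
                    "module_sizes": {
                        m: int(s) for m, s in ma.sizes().items()
                    },
                }

        if "crosslevel" in requested:
            log.info("stage crosslevel")
            from .plotting import plot_heatmap

            overlap = crosslevel_mod.module_overlap(
                assignments["transcription"], assignments["translation"],
                threshold=cfg.jaccard_threshold, alpha=cfg.alpha,
            )
            emit(overlap, "crosslevel_overlap.tsv", index=False)
            if len(overlap):
                jac = overlap.pivot(
                    index="module_transcription",
                    columns="module_translation",
                    values="jaccard",
                )
                written.append(
                    plot_heatmap(
                        jac, fig_dir / "crosslevel_jaccard.png",
                        title="Cross-level module Jaccard", vmin=0,
                    )
                )
                summary["crosslevel_related_pairs"] = int(overlap["related"].sum())

        # ------------------------------------------------------------------
        if "enrich" in requested and cfg.annotation:
            log.info("stage enrich")
            from .plotting import plot_heatmap

            db = read_gmt(cfg.annotation)
            universe = set(keep)
            frames = []
            for (level, klass), coll in collections.items():
                if klass == "Stable":
                    continue
                for comp, genes in coll.items():
                    if not genes:
                        continue
                    res = enrich(
                        genes, db, universe,
                        term_size_max=cfg.term_size_max,
                        intersection_min=cfg.intersection_min,
                    )
                    res.insert(0, "comparison", comp)
                    res.insert(0, "class", klass)
                    res.insert(0, "level", level)
                    frames.append(res)
            frames = [f for f in frames if len(f)]
            if frames:
                all_enrich = pd.concat(frames, ignore_index=True)
                emit(all_enrich, "enrichment.tsv", index=False)
                over = all_enrich[all_enrich["direction"] == "over"]
                if len(over):
                    pivot = over.pivot_table(
                        index="term_id",
                        columns=["level", "class", "comparison"],
                        values="fdr", aggfunc="min",
                    )
                    heat = -np.log10(pivot.fillna(1.0).clip(lower=1e-300))
                    heat.columns = ["|".join(c) for c in heat.columns]
                    written.append(
                        plot_heatmap(
                            heat, fig_dir / "enrichment_over.png",
                            title="-log10 FDR (over-representation)",
                        )
                    )

        # ------------------------------------------------------------------
        manifest = {
            "config": asdict(cfg),
            "stages": sorted(requested),
            "outputs": {
                str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(written))
            },
            "summary": summary,
        }
        with open(outdir / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2, default=str, sort_keys=True)
        with open(outdir / "summary.json", "w") as handle:
            json.dump(summary, handle, indent=2, default=str, sort_keys=True)
        log.info("pipeline finished: %d outputs", len(written))
        return manifest
    except Exception as err:  # annotate failures with the failing stage
        log.error("pipeline aborted: %s", err)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
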