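"""End-to-end orchestration: filter -> CPM -> glycolysis scoring -> lncRNA
selection -> consensus clustering -> cluster characterization -> linkage.

Cluster indices are canonicalized by ascending median glycolysis score, so
cluster 1 is always the lowest-glycolysis group and cluster K the highest;
every downstream stage relies on that ordering.  A single global seed is
expanded per stage through a counter scheme so stages are independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, cluster, dge, scoring, stats
from .classifier import fit_lasso_multinomial_cv
from .io import LNCRNA, CountMatrix, GeneSetCollection
from .synthetic import CHECKPOINT_SET, GLYCOLYSIS_SET, CohortBundle

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage parameters; defaults are the analysis' standard thresholds."""

    min_count: int = 10
    min_fraction: float = 0.9
    ssgsea_weight: float = 0.25
    r_min: float = 0.3
    q_max: float = 0.05
    k_range: tuple[int, ...] = (2, 3, 4, 5)
    n_iter: int = 1000
    feature_fraction: float = 0.95
    distance_metric: str = "pearson"
    up_fc: float = 1.5
    down_fc: float = 0.7
    deg_q: float = 1e-4
    gsea_q: float = 0.01
    gsea_nperm: int = 10000
    gsea_weight: float = 1.0
    fisher_p: float = 0.01
    es_min: float = 0.5
    checkpoint_p: float = 0.01
    reg_coef_min: float = 0.3
    reg_q: float = 1e-6
    n_folds: int = 10
    n_lambdas: int = 100
    run_classifier: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.min_fraction <= 1:
            raise ValueError("min_fraction must lie in [0, 1]")
        if not 0 < self.feature_fraction <= 1:
            raise ValueError("feature_fraction must lie in (0, 1]")
        for name in ("q_max", "deg_q", "gsea_q", "fisher_p", "reg_q", "checkpoint_p"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.r_min < 0 or self.reg_coef_min < 0 or self.es_min < 0:
            raise ValueError("thresholds must be non-negative")
        if len(self.k_range) < 3:
            raise ValueError("k_range must cover >= 3 consecutive k")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "k_range" in data:
            data["k_range"] = tuple(data["k_range"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def stage_seed(self, stage: int) -> int:
        return (self.seed * 1000 + stage) % (2**31 - 1)


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's output."""

    retained_features: list[str] = field(default_factory=list)
    glycolysis_score: pd.Series | None = None
    association_table: pd.DataFrame | None = None
    selected_lncrnas: pd.DataFrame | None = None
    consensus_results: list = field(default_factory=list)
    areas: dict = field(default_factory=dict)
    deltas: dict = field(default_factory=dict)
    suggested_k: int = 0
    cluster_labels: pd.Series | None = None
    logrank: tuple | None = None
    km_fits: dict = field(default_factory=dict)
    kruskal: tuple | None = None
    dunn: pd.DataFrame | None = None
    mutation_enrichment: list = field(default_factory=list)
    deg_tables: dict = field(default_factory=dict)
    gsea_tables: dict = field(default_factory=dict)
    tf_activity: pd.DataFrame | None = None
    tf_screen: pd.DataFrame | None = None
    immune_scores: pd.DataFrame | None = None
    infiltration_groups: pd.Series | None = None
    checkpoint_screen: pd.DataFrame | None = None
    linkage: dict = field(default_factory=dict)
    classifier: object | None = None
    classifier_signature: list[str] = field(default_factory=list)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def canonicalize_clusters(labels: pd.Series, score: pd.Series) -> pd.Series:
    """Relabel clusters by ascending median glycolysis score (1 = lowest)."""
    medians = score.groupby(labels).median()
    order = medians.sort_values(kind="stable").index
    remap = {old: i + 1 for i, old in enumerate(order)}
    return labels.map(remap).astype(int)


def run_pipeline(
    bundle: CohortBundle, config: PipelineConfig | None = None, outdir=None
) -> PipelineResult:
    """Execute every stage on a cohort bundle; optionally write TSV outputs
    plus a manifest with content hashes under ``outdir``."""
    config = config or PipelineConfig()
    config.validate()
    res = PipelineResult()
    counts = bundle.counts
    current = {"stage": "start"}

    def stage(name):
        current["stage"] = name
        logger.info("stage: %s", name)

    try:
        stage("filter")
        res.retained_features = scoring.expression_filter(
            counts, config.min_count, config.min_fraction
        )
        filtered = counts.subset_features(res.retained_features)

        stage("cpm")
        expr = scoring.cpm_normalize(filtered)
        log_expr = expr.log2()

        stage("glycolysis_score")
        res.glycolysis_score = scoring.ssgsea_score(
            expr,
            bundle.gene_sets[GLYCOLYSIS_SET],
            weight_exponent=config.ssgsea_weight,
            score_name="glycolysis",
        )

        stage("lncrna_association")
        lnc_features = [
            f for f in res.retained_features
            if filtered.feature_class is not None and filtered.feature_class[f] == LNCRNA
        ]
        res.association_table = association.pearson_with_fdr(
            res.glycolysis_score, log_expr.values, lnc_features
        )
        res.selected_lncrnas = association.select_associated_features(
            res.association_table, config.r_min, config.q_max
        )

        stage("consensus_clustering")
        selected = list(res.selected_lncrnas.index)
        if len(selected) < 2:
            raise ValueError(f"only {len(selected)} lncRNAs selected; cannot cluster")
        feats = log_expr.values.loc[selected].T  # samples x lncRNAs
        z = (feats - feats.mean()) / feats.std(ddof=0).replace(0, 1.0)
        est = cluster.ConsensusCluster(
            k_range=config.k_range,
            n_iter=config.n_iter,
            feature_fraction=config.feature_fraction,
            metric=config.distance_metric,
            random_state=config.stage_seed(5),
        )
        est.fit(z)
        res.consensus_results = est.results_
        res.areas, res.deltas, res.suggested_k = est.areas_, est.deltas_, est.suggested_k_
        raw_labels = est.result_for(res.suggested_k).labels

        stage("canonicalize")
        res.cluster_labels = canonicalize_clusters(raw_labels, res.glycolysis_score)
        K = res.suggested_k

        stage("survival")
        clin = bundle.clinical.table.loc[res.cluster_labels.index]
        res.logrank = stats.logrank_test(
            clin["time"], clin["event"], res.cluster_labels.to_numpy()
        )
        for c in range(1, K + 1):
            mask = res.cluster_labels == c
            res.km_fits[c] = stats.kaplan_meier(
                clin.loc[mask.to_numpy(), "time"],
                clin.loc[mask.to_numpy(), "event"],
                group=str(c),
            )

        stage("score_comparison")
        res.kruskal = stats.kruskal_wallis(
            res.glycolysis_score.to_numpy(), res.cluster_labels.to_numpy()
        )
        res.dunn = stats.dunn_posthoc(
            res.glycolysis_score.to_numpy(), res.cluster_labels.to_numpy()
        )

        stage("mutation_enrichment")
        res.mutation_enrichment = stats.fisher_enrichment(
            bundle.mutations, res.cluster_labels, focus=K, p_max=config.fisher_p
        )

        stage("differential_expression")
        coding = [
            f for f in res.retained_features
            if filtered.feature_class is not None and filtered.feature_class[f] == "coding"
        ]
        coding_counts = filtered.subset_features(coding)
        by_cluster = {
            c: list(res.cluster_labels.index[res.cluster_labels == c])
            for c in range(1, K + 1)
        }
        comparisons = [(K, 1)]
        if K >= 3:
            comparisons += [(K, K - 1), (K - 1, 1) if K == 3 else (2, 1)]
        for hi, lo in comparisons:
            res.deg_tables[f"{hi}v{lo}"] = dge.differential_expression(
                coding_counts, by_cluster[lo], by_cluster[hi]
            )

        stage("gsea")
        pathway_sets = {
            name: bundle.gene_sets[name]
            for name in bundle.gene_sets.names()
            if name == GLYCOLYSIS_SET or name.startswith("DECOY")
        }
        pathway_collection = GeneSetCollection(
            pathway_sets, {n: "" for n in pathway_sets}
        )
        for key, table in res.deg_tables.items():
            ranked = dge.rank_by_logfc(table)
            res.gsea_tables[key] = dge.gsea_preranked(
                ranked,
                pathway_collection,
                weight=config.gsea_weight,
                n_perm=config.gsea_nperm,
                seed=config.stage_seed(9),
            )

        stage("tf_activity")
        res.tf_activity = scoring.area_tf_activity(log_expr, bundle.regulons)
        res.tf_screen = stats.anova_effect_screen(
            res.tf_activity, res.cluster_labels, es_min=config.es_min, p_max=None
        )

        stage("immune")
        marker_sets = GeneSetCollection(
            {
                n: bundle.gene_sets[n]
                for n in bundle.gene_sets.names()
                if n.startswith("IMMUNE_CELL")
            },
            {},
        ) if any(n.startswith("IMMUNE_CELL") for n in bundle.gene_sets.names()) else None
        if marker_sets is not None and len(marker_sets):
            res.immune_scores = scoring.immune_infiltration_scores(
                expr, marker_sets, weight_exponent=config.ssgsea_weight
            )
            res.infiltration_groups = cluster.hierarchical_ward(res.immune_scores)
        if CHECKPOINT_SET in bundle.gene_sets:
            chk = [g for g in bundle.gene_sets[CHECKPOINT_SET] if g in log_expr.values.index]
            if chk:
                res.checkpoint_screen = stats.anova_effect_screen(
                    log_expr.values.loc[chk],
                    res.cluster_labels,
                    es_min=config.es_min,
                    p_max=config.checkpoint_p,
                )

        stage("partial_correlation_linkage")
        coding_assoc = association.pearson_with_fdr(
            res.glycolysis_score, log_expr.values, coding
        )
        pos_genes = list(
            coding_assoc.index[(coding_assoc["r"] > config.r_min) & (coding_assoc["q"] < config.q_max)]
        )
        if len(pos_genes) >= 2:
            for lnc_id in selected:
                shift = association.partial_correlation_shift(
                    res.glycolysis_score,
                    log_expr.values.loc[pos_genes],
                    log_expr.values.loc[lnc_id],
                )
                res.linkage[lnc_id] = shift

        if config.run_classifier and K >= 2:
            stage("classifier")
            try:
                up, down = dge.consistent_deg_selection(
                    res.deg_tables.get("3v2", res.deg_tables[f"{K}v1"]),
                    res.deg_tables.get("2v1", res.deg_tables[f"{K}v1"]),
                    config.up_fc,
                    config.down_fc,
                    config.deg_q,
                )
                candidates = up + down
                if len(candidates) >= 2:
                    X = log_expr.values.loc[candidates].T
                    clf = fit_lasso_multinomial_cv(
                        X,
                        res.cluster_labels,
                        n_folds=min(config.n_folds, min(res.cluster_labels.value_counts())),
                        seed=config.stage_seed(12),
                        n_lambdas=config.n_lambdas,
                    )
                    res.classifier = clf
                    res.classifier_signature = clf.signature
                else:
                    logger.info("too few consistent DEGs (%d); classifier skipped", len(candidates))
            except ValueError as exc:
                logger.info("classifier stage skipped: %s", exc)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise StageError(current["stage"], exc) from exc

    if outdir is not None:
        write_outputs(res, config, Path(outdir))
    return res


# ---------------------------------------------------------------------------
# output + manifest
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(res: PipelineResult, config: PipelineConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df, name):
        path = outdir / name
        df.to_csv(path, sep="\t")
        written.append(path)

    save(res.glycolysis_score.to_frame(), "glycolysis_score.tsv")
    save(res.association_table, "lncrna_association.tsv")
    save(res.selected_lncrnas, "selected_lncrnas.tsv")
    save(res.cluster_labels.to_frame("cluster"), "cluster_labels.tsv")
    delta_table = pd.DataFrame(
        {"area": pd.Series(res.areas), "delta": pd.Series(res.deltas)}
    )
    delta_table.index.name = "k"
    save(delta_table, "consensus_delta_area.tsv")
    for r in res.consensus_results:
        save(r.consensus_matrix, f"consensus_matrix_k{r.k}.tsv")
    chi2, df_, p = res.logrank
    save(
        pd.DataFrame([{"chi2": chi2, "df": df_, "p": p}]),
        "logrank.tsv",
    )
    if res.kruskal is not None:
        save(pd.DataFrame([{"H": res.kruskal[0], "p": res.kruskal[1]}]), "kruskal.tsv")
    if res.dunn is not None:
        save(res.dunn, "dunn.tsv")
    if res.mutation_enrichment is not None:
        save(
            pd.DataFrame([dataclasses.asdict(e) for e in res.mutation_enrichment]),
            "mutation_enrichment.tsv",
        )
    for key, t in res.deg_tables.items():
        save(t, f"deg_{key}.tsv")
    for key, t in res.gsea_tables.items():
        save(t, f"gsea_{key}.tsv")
    if res.tf_screen is not None:
        save(res.tf_screen, "tf_screen.tsv")
    if res.immune_scores is not None:
        save(res.immune_scores, "immune_scores.tsv")
        save(res.infiltration_groups.to_frame(), "infiltration_groups.tsv")
    if res.checkpoint_screen is not None:
        save(res.checkpoint_screen, "checkpoint_screen.tsv")
    if res.linkage:
        rows = [
            {
                "lncRNA": lnc_id,
                "ks_statistic": d["ks_statistic"],
                "ks_p": d["ks_p"],
                "mean_raw_r": d["raw"].mean(),
                "mean_adjusted_r": d["adjusted"].mean(),
            }
            for lnc_id, d in res.linkage.items()
        ]
        save(pd.DataFrame(rows).set_index("lncRNA"), "linkage.tsv")
    if res.classifier is not None:
        (outdir / "classifier.json").write_text(res.classifier.to_json())
        written.append(outdir / "classifier.json")

    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "seed": config.seed,
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def make_report(run_dir) -> pd.DataFrame:
    """Cross-stage summary assembled from a run directory.

    Missing stage outputs are listed as absent rather than failing.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {run_dir}")
    rows = []

    def add(stage, status, detail=""):
        rows.append({"stage": stage, "status": status, "detail": detail})

    def try_read(name):
        path = run_dir / name
        if not path.exists():
            return None
        return pd.read_csv(path, sep="\t", index_col=0)

    labels = try_read("cluster_labels.tsv")
    if labels is not None:
        sizes = labels["cluster"].value_counts().sort_index()
        add("clusters", "present", "; ".join(f"cluster {c}: n={n}" for c, n in sizes.items()))
    else:
        add("clusters", "absent")
    score = try_read("glycolysis_score.tsv")
    if score is not None and labels is not None:
        med = score.iloc[:, 0].groupby(labels["cluster"]).median()
        add("glycolysis_score", "present", "; ".join(f"cluster {c}: median={v:.3f}" for c, v in med.items()))
    else:
        add("glycolysis_score", "present" if score is not None else "absent")
    sel = try_read("selected_lncrnas.tsv")
    if sel is not None:
        add(
            "selected_lncrnas",
            "present",
            f"{(sel['sign'] > 0).sum()} positive, {(sel['sign'] < 0).sum()} negative",
        )
    else:
        add("selected_lncrnas", "absent")
    for name, stage in [
        ("logrank.tsv", "survival"),
        ("mutation_enrichment.tsv", "mutations"),
        ("tf_screen.tsv", "tf_activity"),
        ("linkage.tsv", "linkage"),
    ]:
        t = try_read(name)
        add(stage, "present" if t is not None else "absent", "" if t is None else f"{len(t)} rows")
    gsea_files = sorted(run_dir.glob("gsea_*.tsv"))
    add("gsea", "present" if gsea_files else "absent", f"{len(gsea_files)} comparisons")
    clf = run_dir / "classifier.json"
    if clf.exists():
        sig = json.loads(clf.read_text())
        n_sig = int(np.sum(np.any(np.asarray(sig["coefficients"]) != 0, axis=0)))
        add("classifier", "present", f"signature size {n_sig}")
    else:
        add("classifier", "absent")
    report = pd.DataFrame(rows).set_index("stage")
    report.to_csv(run_dir / "report.tsv", sep="\t")
    return report
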