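"""End-to-end orchestration: generate/load -> preprocess -> categorize ->
curves -> cluster -> label -> summarize -> validate.

:func:`analyze_cohort` is the reusable core (claims + patients in, a
:class:`CohortAnalysis` out) used both for the main cohort and for stratum
re-runs.  :func:`run_pipeline` wraps it with file I/O, the pre-24 profile,
the urban reproduction, planted-truth recovery scoring, plots, and a
structured log, all under a single seed so a run is re-executable
bit-identically from its serialized config.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import claims_io, clustering, cost_curves, pre24_validation, subgroup_stats
from .claims_io import InflationIndex
from .clustering import (ClusterQuality, ElbowResult, LABEL_ORDER, SubgroupLabel,
                         TrajectoryKMeans, label_clusters, patient_visit_stats,
                         random_clustering_baseline, representative_patient)
from .cost_curves import AgeGrid
from .visit_categorizer import CodeTables, collapse_and_categorize

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; serialized into the run directory."""

    outdir: str = "ecdc_run"
    seed: int = 0
    # inputs: either explicit CSV paths, or n_patients to generate synthetically
    claims_path: str | None = None
    patients_path: str | None = None
    truth_path: str | None = None
    n_patients: int | None = 10_000
    # preprocessing
    index_path: str | None = None
    code_tables_path: str | None = None
    chronic_map_path: str | None = None
    eligible_window: tuple[int, int] = (6, 60)
    # analysis
    grid: tuple[int, int] = (24, 60)
    k: int | None = None
    k_range: tuple[int, int] = (2, 8)
    n_init: int = 10
    transform: str = "log1p"
    scale: bool = True
    silhouette_sample: int = 2000
    baseline_reps: int = 10
    urban_min_n: int = 500

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        for key in ("eligible_window", "grid", "k_range"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)


@dataclass
class CohortAnalysis:
    """All core analysis outputs for one cohort (or stratum)."""

    patient_ids: list[str]
    visits: pd.DataFrame                  # categorized window visits
    features: pd.DataFrame                # n x 148 cumulative-curve matrix
    elbow: ElbowResult | None
    model: TrajectoryKMeans
    label_map: dict[int, SubgroupLabel]
    labels_by_patient: pd.Series
    annual_costs: pd.Series
    subgroup_table: pd.DataFrame
    kruskal: tuple[float, float]
    quality: ClusterQuality | None
    baseline: ClusterQuality | None
    representatives: dict[SubgroupLabel, clustering.RepresentativePatient]

    @property
    def k(self) -> int:
        return self.model.n_clusters


def analyze_cohort(
    claims: pd.DataFrame,
    patients: pd.DataFrame,
    seed: int = 0,
    k: int | None = None,
    k_range=range(2, 9),
    n_init: int = 10,
    grid: AgeGrid = AgeGrid(),
    tables: CodeTables | None = None,
    transform: str = "log1p",
    scale: bool = True,
    eligible_window: tuple[int, int] = claims_io.ELIGIBLE_WINDOW,
    silhouette_sample: int | None = 2000,
    baseline_reps: int = 10,
    compute_quality: bool = True,
) -> CohortAnalysis:
    """Run categorization, curves, clustering, labeling and summaries.

    *claims* must already be preprocessed (pharmacy dropped, negatives
    clamped, 2017 dollars).  With ``k=None`` the number of clusters is
    selected by the elbow rule over *k_range*.
    """
    tables = tables or CodeTables()
    eligible = claims_io.filter_eligible(patients, eligible_window)
    claims = claims[claims["patient_id"].isin(set(eligible))]

    visits = collapse_and_categorize(claims, tables)
    window = visits[(visits["age_months"] >= grid.start) & (visits["age_months"] <= grid.stop)]
    features = cost_curves.curve_matrix(window, eligible, grid)

    elbow = None
    if k is None:
        elbow = clustering.elbow_select_k(features, k_range, seed=seed, n_init=n_init,
                                          transform=transform, scale=scale)
        k = elbow.k
    model = TrajectoryKMeans(n_clusters=k, n_init=n_init, random_state=seed,
                             transform=transform, scale=scale).fit(features)
    assignments = model.assignments()
    label_map = label_clusters(assignments, window)
    labels_by_patient = assignments.map(label_map)

    annual = cost_curves.annual_costs(features, grid)
    table = subgroup_stats.subgroup_cost_summary(labels_by_patient, annual)
    groups = [annual[labels_by_patient == lab] for lab in LABEL_ORDER
              if (labels_by_patient == lab).any()]
    kw = subgroup_stats.kruskal_wallis(groups)

    quality = baseline = None
    if compute_quality:
        Z = model._prepare_apply(features.to_numpy(dtype=float))
        sil = clustering.silhouette(Z, model.labels_, sample_size=min(silhouette_sample, len(features)),
                                    seed=seed)
        ch, nch = clustering.calinski_harabasz(Z, model.labels_)
        quality = ClusterQuality(sil, ch, nch)
        baseline = random_clustering_baseline(Z, k, seed=seed, reps=baseline_reps)

    stats = patient_visit_stats(window, eligible)
    reps = {}
    for cl, lab in label_map.items():
        rep = representative_patient(model, features, cl)
        age = stats.loc[rep.patient_id, "first_tor_age"]
        rep.first_tor_age_months = None if pd.isna(age) else int(age)
        reps[lab] = rep

    return CohortAnalysis(eligible, window, features, elbow, model, label_map,
                          labels_by_patient, annual, table, kw, quality, baseline, reps)


# ---------------------------------------------------------------------------
# Artifacts


def _plot_representative_curves(analysis: CohortAnalysis, grid: AgeGrid, path: Path, title: str) -> None:
    fig, ax = plt.subplots(figsize=(7, 4.5))
    T = len(grid)
    for lab in LABEL_ORDER:
        rep = analysis.representatives.get(lab)
        if rep is None:
            continue
        row = analysis.features.loc[rep.patient_id].to_numpy()
        total = row.reshape(4, T).sum(0)
        ax.plot(grid.months, total, label=f"{lab.value} ({rep.patient_id})")
    ax.set_xlabel("age (months)")
    ax.set_ylabel("cumulative dental cost (2017 USD)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _quality_report(analysis: CohortAnalysis) -> dict:
    doc = {
        "k": int(analysis.k),
        "kruskal_wallis_H": float(analysis.kruskal[0]),
        "kruskal_wallis_p": float(analysis.kruskal[1]),
    }
    if analysis.elbow is not None:
        doc["elbow"] = {"selected_k": analysis.elbow.k,
                        "inertia": {int(k): float(i) for k, i in
                                    zip(analysis.elbow.ks, analysis.elbow.inertias)}}
    if analysis.quality is not None:
        doc["ours"] = dataclasses.asdict(analysis.quality)
        doc["random_baseline"] = dataclasses.asdict(analysis.baseline)
    return doc


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full reproducible run; returns the run directory.

    Artifacts: ``table1_pmpy.csv``, ``table2_subgroups.csv``,
    ``table4_pre24.csv``, ``assignments.csv``, ``quality.yaml``,
    ``fig1_cost_curves.png``, urban analogs (``table2_urban.csv``,
    ``fig2_urban_cost_curves.png``, ``urban_comparison.csv``),
    ``recovery.yaml`` when planted truth is available, the serialized
    config, and a stage-timing log.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t0 = time.perf_counter()

    def stage(name):
        log_lines.append(f"{time.perf_counter() - t0:8.2f}s  {name}")
        logger.info("stage: %s", name)

    # ---- inputs
    truth = None
    if config.claims_path is not None:
        for p in (config.claims_path, config.patients_path):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        claims = claims_io.read_claims(config.claims_path)
        patients = claims_io.read_patients(config.patients_path)
        if config.truth_path and Path(config.truth_path).exists():
            truth = pd.read_csv(config.truth_path, dtype={"patient_id": str})
        stage(f"loaded {len(claims)} claim lines, {len(patients)} patients")
    else:
        from .synthetic_data import GeneratorConfig, generate_cohort

        gen = GeneratorConfig(n_patients=config.n_patients or 10_000, seed=config.seed)
        claims, patients, truth = generate_cohort(gen, outdir / "inputs")
        stage(f"generated {len(patients)} patients / {len(claims)} claim lines")

    # ---- preprocessing
    index = InflationIndex.from_yaml(config.index_path) if config.index_path else None
    tables = CodeTables.from_yaml(config.code_tables_path) if config.code_tables_path else CodeTables()
    chronic_map = (pre24_validation.load_chronic_code_map(config.chronic_map_path)
                   if config.chronic_map_path else pre24_validation.DEFAULT_CHRONIC_CODE_MAP)
    claims = claims_io.preprocess(claims, index)
    stage("preprocessed claims")

    grid = AgeGrid(*config.grid)
    k_range = range(config.k_range[0], config.k_range[1] + 1)
    analysis = analyze_cohort(
        claims, patients, seed=config.seed, k=config.k, k_range=k_range,
        n_init=config.n_init, grid=grid, tables=tables, transform=config.transform,
        scale=config.scale, eligible_window=config.eligible_window,
        silhouette_sample=config.silhouette_sample, baseline_reps=config.baseline_reps)
    stage(f"analyzed cohort (k={analysis.k})")

    # ---- tables
    eligible_patients = patients[patients["patient_id"].isin(set(analysis.patient_ids))]
    table1 = subgroup_stats.pmpy_by_stratum(analysis.visits, eligible_patients)
    table1.to_csv(outdir / "table1_pmpy.csv", float_format="%.4f")
    analysis.subgroup_table.to_csv(outdir / "table2_subgroups.csv", float_format="%.4f")
    analysis.labels_by_patient.map(lambda l: l.value).rename("subgroup").to_frame().assign(
        cluster=analysis.model.assignments()).to_csv(outdir / "assignments.csv")
    with open(outdir / "quality.yaml", "w") as fh:
        yaml.safe_dump(_quality_report(analysis), fh, sort_keys=False)
    stage("wrote cohort tables")

    table4 = pre24_validation.pre24_profile(claims, eligible_patients,
                                            analysis.labels_by_patient, chronic_map)
    table4.to_csv(outdir / "table4_pre24.csv", float_format="%.4f")
    stage("wrote pre-24 profile")

    _plot_representative_curves(analysis, grid, outdir / "fig1_cost_curves.png",
                                "Representative cumulative cost curves by subgroup")

    # ---- urban reproduction
    urban_doc = None
    if patients["urban"].sum() >= config.urban_min_n:
        urban = pre24_validation.reproduce_on_stratum(
            claims, patients, lambda row: bool(row["urban"]), min_n=config.urban_min_n,
            seed=config.seed, k=5, n_init=config.n_init, grid=grid, tables=tables,
            transform=config.transform, scale=config.scale,
            eligible_window=config.eligible_window, compute_quality=False)
        urban.subgroup_table.to_csv(outdir / "table2_urban.csv", float_format="%.4f")
        _plot_representative_curves(urban, grid, outdir / "fig2_urban_cost_curves.png",
                                    "Urban stratum: representative cumulative cost curves")
        comp = pd.DataFrame({
            "cohort_pct": analysis.subgroup_table["pct_of_population"],
            "urban_pct": urban.subgroup_table["pct_of_population"],
            "cohort_cost_share": analysis.subgroup_table["pct_of_total_annual_cost"],
            "urban_cost_share": urban.subgroup_table["pct_of_total_annual_cost"],
        })
        comp.to_csv(outdir / "urban_comparison.csv", float_format="%.4f")
        urban_doc = comp
        stage(f"urban reproduction (n={len(urban.patient_ids)})")

    # ---- recovery vs planted truth
    if truth is not None:
        from sklearn.metrics import adjusted_rand_score

        merged = truth.set_index("patient_id").loc[analysis.labels_by_patient.index]
        ari = adjusted_rand_score(merged["subgroup"],
                                  analysis.labels_by_patient.map(lambda l: l.value))
        agree = float((merged["subgroup"] == analysis.labels_by_patient.map(lambda l: l.value)).mean())
        with open(outdir / "recovery.yaml", "w") as fh:
            yaml.safe_dump({"adjusted_rand_index": float(ari), "label_agreement": agree}, fh)
        stage(f"recovery ARI={ari:.4f}")

    config.to_yaml(outdir / "run_config.yaml")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir
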