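"""End-to-end orchestration: simulate/load -> normative model -> anomalies ->
response labels -> summaries -> classification -> cohort statistics.

A single seed governs every stochastic stage; per-stage substreams are
derived from it so that adding a stage does not perturb the draws of the
earlier ones.  The run report echoes every defaulted decision and is
sufficient to re-run identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .anomaly import (
    AnomalyProfile,
    anomaly_table,
    fit_normative,
    flag_anomalies,
    network_counts_table,
    summarize_groups,
)
from .atlas import build_edge_index, load_parcellation
from .classify import (
    build_feature_table,
    crossval_classify,
    feature_attributions,
    network_importance,
    top_features,
)
from .response import RciParameters, label_cohort
from .simulate import (
    SimulationConfig,
    SyntheticCohort,
    read_cohort_inputs,
    read_fc_matrix,
    simulate_cohort,
    write_cohort,
)
from .stats import (
    ContingencyTable2x2,
    chi_squared_independence,
    fisher_exact_two_sided,
    mann_whitney_u,
)

log = logging.getLogger("fcanomaly")

SCORE_RANGES = {"isi": (0, 28), "psqi": (0, 21), "ess": (0, 24)}


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    Defaults follow the analysis conventions used throughout the package:
    a 3-MAD anomaly threshold, 5-fold cross-validation, RCI threshold 1.96
    with reliability 0.85, both-endpoint network counting.
    """

    out_dir: Path = Path("fcanomaly_out")
    seed: int = 0
    # input source: simulate a cohort, or load files from disk
    simulate: bool = True
    n_regions: int = 379
    sim_overrides: dict = field(default_factory=dict)
    parcellation_path: Optional[Path] = None
    phenotype_path: Optional[Path] = None
    fc_dir: Optional[Path] = None
    write_cohort_files: bool = False
    # anomaly detection
    threshold: float = 3.0
    zero_mad_tol: float = 1e-6
    count_mode: str = "both_endpoints"
    # response scoring
    rci_reliability: float = 0.85
    rci_sd_source: str = "treated_cohort"
    rci_sd: Optional[float] = None
    # classification
    folds: int = 5
    tune: bool = False

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        return d


def _substream_seeds(seed: int, n: int) -> list[int]:
    """Independent per-stage integer seeds (< 2**31) derived from one seed."""
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


def validate_inputs(
    parcellation_path: Path, phenotype_path: Path, fc_dir: Path
) -> list[str]:
    """Check inputs against the format contracts; list every violation.

    Nothing is repaired: matrix symmetry (1e-9), correlation range, matrix
    dimension against the parcellation, phenotype completeness for treated
    subjects, and questionnaire score ranges (ISI 0-28, PSQI 0-21, ESS 0-24).
    """
    violations: list[str] = []
    parc = load_parcellation(parcellation_path)
    phenotype = pd.read_csv(phenotype_path)
    r = parc.n_regions
    for _, row in phenotype.iterrows():
        sid = str(row["subject_id"])
        for instrument, (lo, hi) in SCORE_RANGES.items():
            for col in (f"{instrument}_base", f"{instrument}_fu"):
                v = row.get(col)
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    continue
                if not lo <= v <= hi:
                    violations.append(
                        f"{sid}: {col} = {v} outside [{lo}, {hi}]"
                    )
        treated = row["group"] == "patient" and row["arm"] != "none"
        if treated and (
            pd.isna(row.get("isi_fu")) or pd.isna(row.get("psqi_fu"))
        ):
            violations.append(f"{sid}: treated subject missing follow-up scores")
        base_path = Path(fc_dir) / f"{sid}_baseline.csv"
        if not base_path.exists():
            violations.append(f"{sid}: missing baseline FC matrix {base_path}")
            continue
        paths = [base_path]
        fu_path = Path(fc_dir) / f"{sid}_follow_up.csv"
        if treated:
            if fu_path.exists():
                paths.append(fu_path)
            else:
                violations.append(f"{sid}: missing follow-up FC matrix {fu_path}")
        for p in paths:
            m = read_fc_matrix(p)
            if m.shape != (r, r):
                violations.append(
                    f"{sid}: {p.name} has shape {m.shape}, parcellation has {r} regions"
                )
                continue
            if np.max(np.abs(m - m.T)) > 1e-9:
                violations.append(f"{sid}: {p.name} is not symmetric")
            if np.nanmax(np.abs(m)) > 1.0 + 1e-12:
                violations.append(f"{sid}: {p.name} has entries outside [-1, 1]")
            if np.max(np.abs(np.diag(m) - 1.0)) > 1e-9:
                violations.append(f"{sid}: {p.name} diagonal is not 1")
    return violations


def _obtain_cohort(cfg: RunConfig, sim_seed: int):
    if cfg.simulate:
        sim_cfg = SimulationConfig(
            n_regions=cfg.n_regions, seed=sim_seed, **cfg.sim_overrides
        )
        cohort = simulate_cohort(sim_cfg)
        if cfg.write_cohort_files:
            write_cohort(cohort, Path(cfg.out_dir) / "cohort")
        return (
            cohort.parcellation,
            cohort.phenotype,
            cohort.baseline,
            cohort.follow_up,
            cohort,
        )
    for name in ("parcellation_path", "phenotype_path", "fc_dir"):
        if getattr(cfg, name) is None:
            raise ValueError(f"load mode requires {name}")
    parc, phenotype, baseline, follow_up = read_cohort_inputs(
        cfg.parcellation_path, cfg.phenotype_path, cfg.fc_dir
    )
    return parc, phenotype, baseline, follow_up, None


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; write per-stage outputs and a JSON run report."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_seed, clf_seed = _substream_seeds(cfg.seed, 2)

    parc, phenotype, baseline, follow_up, cohort = _obtain_cohort(cfg, sim_seed)
    ei = build_edge_index(parc)
    log.info(
        "cohort: %d subjects, %d regions, %d edges",
        len(phenotype), parc.n_regions, ei.n_edges,
    )

    # --- normative model over controls --------------------------------------
    control_ids = phenotype.loc[
        phenotype["group"] == "control", "subject_id"
    ].astype(str)
    model = fit_normative([baseline[s] for s in control_ids], ei)

    # --- anomaly profiles ----------------------------------------------------
    patient_ids = phenotype.loc[
        phenotype["group"] == "patient", "subject_id"
    ].astype(str)
    base_profiles: dict[str, AnomalyProfile] = {}
    fu_profiles: dict[str, AnomalyProfile] = {}
    edge_values: dict[tuple[str, str], np.ndarray] = {}
    for sid in patient_ids:
        base_profiles[sid] = flag_anomalies(
            baseline[sid], model, parc, subject_id=sid, timepoint="baseline",
            threshold=cfg.threshold, zero_mad_tol=cfg.zero_mad_tol,
            mode=cfg.count_mode,
        )
        edge_values[(sid, "baseline")] = ei.edge_values(baseline[sid])
        if sid in follow_up:
            fu_profiles[sid] = flag_anomalies(
                follow_up[sid], model, parc, subject_id=sid, timepoint="follow_up",
                threshold=cfg.threshold, zero_mad_tol=cfg.zero_mad_tol,
                mode=cfg.count_mode,
            )
            edge_values[(sid, "follow_up")] = ei.edge_values(follow_up[sid])
    all_profiles = list(base_profiles.values()) + list(fu_profiles.values())
    log.info(
        "anomalies: %d patients flagged, mean %.1f anomalous edges at baseline",
        len(base_profiles),
        float(np.mean([p.n_anomalies for p in base_profiles.values()])),
    )
    anomaly_table(all_profiles, model, edge_values).to_csv(
        out / "anomalies.csv", index=False
    )
    network_counts_table(all_profiles).to_csv(
        out / "network_counts.csv", index=False
    )

    # --- response labels -----------------------------------------------------
    rci = RciParameters(
        reliability=cfg.rci_reliability,
        sd_source=cfg.rci_sd_source,
        sd=cfg.rci_sd,
    )
    resp = label_cohort(phenotype, rci)
    resp.table.to_csv(out / "labels.csv", index=False)
    log.info(
        "response: %d/%d treated improved on either instrument",
        resp.counts["improved_either"], resp.counts["n_treated"],
    )

    # --- network summaries per instrument ------------------------------------
    arms = {l.subject_id: l.arm for l in resp.labels}
    summaries = {}
    for instrument in ("isi", "psqi"):
        responder = {
            l.subject_id: getattr(l, f"{instrument}_responder")
            for l in resp.labels
        }
        summary = summarize_groups(base_profiles, fu_profiles, responder, arms)
        summaries[instrument] = summary.to_dict()
    (out / "anomaly_summary.json").write_text(json.dumps(summaries, indent=1))

    # --- classification -------------------------------------------------------
    table = build_feature_table(baseline, phenotype, ei)
    cv = crossval_classify(table, folds=cfg.folds, seed=clf_seed, tune=cfg.tune)
    attr = feature_attributions(cv, table)
    mean_abs = attr.mean_abs()
    top = top_features(attr, table, k=20)
    net_imp = network_importance(mean_abs, ei, parc)
    log.info("classification: mean AUC %.3f over %d folds", cv.mean_auc, cfg.folds)
    classification = {
        "fold_aucs": cv.fold_aucs,
        "mean_auc": cv.mean_auc,
        "top_features": top.to_dict(orient="records"),
        "network_importance": net_imp,
        "params": cv.params,
    }
    (out / "classification.json").write_text(json.dumps(classification, indent=1))

    # --- cohort statistics ----------------------------------------------------
    stats_rows = cohort_statistics_table(phenotype, resp.counts)
    stats_rows.to_csv(out / "stats.csv", index=False)

    report = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.echo(),
        "stage_seeds": {"simulate": sim_seed, "classify": clf_seed},
        "outputs": {
            name: str(out / name)
            for name in (
                "anomalies.csv", "network_counts.csv", "labels.csv",
                "anomaly_summary.json", "classification.json", "stats.csv",
            )
        },
        "key_numbers": {
            "n_subjects": int(len(phenotype)),
            "n_regions": parc.n_regions,
            "n_edges": ei.n_edges,
            "mean_auc": cv.mean_auc,
            "network_importance": net_imp,
            "responder_counts": resp.counts,
            "rci_s_diff": resp.s_diff,
            "anomaly_summary": summaries,
        },
    }
    if cohort is not None:
        report["ground_truth_available"] = True
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report


def cohort_statistics_table(phenotype: pd.DataFrame, counts: dict) -> pd.DataFrame:
    """Demographic and outcome tests: chi-squared on sex, Mann-Whitney U on
    continuous baseline variables, Fisher's exact on arm x improvement."""
    ctrl = phenotype[phenotype["group"] == "control"]
    pat = phenotype[phenotype["group"] == "patient"]
    rows = []

    def iqr_summary(s: pd.Series) -> str:
        s = s.dropna()
        if not len(s):
            return "n/a"
        return f"{s.median():g} ({s.quantile(0.75) - s.quantile(0.25):g})"

    if len(ctrl) and len(pat):
        sex = ContingencyTable2x2(
            int((ctrl["sex"] == 0).sum()), int((ctrl["sex"] == 1).sum()),
            int((pat["sex"] == 0).sum()), int((pat["sex"] == 1).sum()),
        )
        res = chi_squared_independence(sex)
        rows.append(
            {
                "variable": "sex", "test": res.test, "statistic": res.statistic,
                "p_value": res.p_value,
                "group_a": f"F/M {sex.a}/{sex.b}", "group_b": f"F/M {sex.c}/{sex.d}",
            }
        )
        for var in ("age", "audit", "ftnd", "ess_base", "isi_base", "psqi_base"):
            res = mann_whitney_u(ctrl[var].to_numpy(), pat[var].to_numpy())
            rows.append(
                {
                    "variable": var, "test": res.test, "statistic": res.statistic,
                    "p_value": res.p_value,
                    "group_a": iqr_summary(ctrl[var]),
                    "group_b": iqr_summary(pat[var]),
                }
            )

    per_arm = counts.get("per_arm", {})
    if len(per_arm) == 2:
        (arm_a, ca), (arm_b, cb) = sorted(per_arm.items())
        for instrument in ("isi", "psqi"):
            improved_a = ca[f"{instrument}_improved"]
            improved_b = cb[f"{instrument}_improved"]
            t = ContingencyTable2x2(
                improved_a, ca["n"] - improved_a, improved_b, cb["n"] - improved_b
            )
            res = fisher_exact_two_sided(t)
            rows.append(
                {
                    "variable": f"{instrument}_improvement_by_arm",
                    "test": res.test, "statistic": np.nan, "p_value": res.p_value,
                    "group_a": f"{arm_a} {improved_a}/{ca['n']}",
                    "group_b": f"{arm_b} {improved_b}/{cb['n']}",
                }
            )
    return pd.DataFrame(
        rows, columns=["variable", "test", "statistic", "p_value",
                       "group_a", "group_b"]
    )
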