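"""Synthetic study generator: FC matrices and phenotypes with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without MRI data:

* controls share a per-edge normative distribution (Normal around a
  per-edge mean, clipped to the correlation range);
* patients carry network-localized anomalous edges, displaced by a multiple
  of the control spread, more numerous in eventual responders;
* treated responders' anomalous edges partially normalize at follow-up;
* ISI/PSQI scores are drawn near the cohort medians (patients 15/16,
  controls 0/3) and follow-ups are constructed so that true responders cross
  the ISI category boundary and the PSQI reliable-change threshold while
  true non-responders do not.

Everything is reproducible from a single seed (per-stage substreams, so the
draws of one stage do not perturb another's).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .atlas import (
    EdgeIndex,
    Parcellation,
    build_edge_index,
    load_parcellation,
    synthetic_parcellation,
    write_parcellation,
)
from .response import RCI_THRESHOLD, DEFAULT_ISI_BANDS, _severity

PHENOTYPE_COLUMNS = (
    "subject_id", "group", "arm", "age", "sex", "audit", "ftnd",
    "ess_base", "isi_base", "psqi_base", "ess_fu", "isi_fu", "psqi_fu",
)

ARM_DRUG = "drug"
ARM_DRUG_RTMS = "drug+rTMS"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Cohort sizes follow the study design this generator emulates: 42
    controls, 51 patients, 24 treated (12 per arm).  Displacements are in
    units of the control edge noise SD.
    """

    n_controls: int = 42
    n_patients: int = 51
    n_treated: int = 24
    n_regions: int = 379
    seed: int = 0
    edge_mean_range: tuple[float, float] = (-0.2, 0.6)
    edge_noise_sd: float = 0.1
    anomaly_rate_responder: float = 40.0
    anomaly_rate_nonresponder: float = 10.0
    anomaly_shift: float = 5.0
    target_networks: frozenset[str] = frozenset({"DMN", "CEN", "SMN"})
    target_edge_fraction: float = 0.8
    normalization_fraction: float = 0.8
    responder_fraction: float = 0.7
    discordance: float = 0.2
    #: optional size of a fixed pool of candidate anomalous edges shared by
    #: all patients; None = each patient samples edges independently.
    signal_edge_pool: Optional[int] = None
    rci_reliability: float = 0.85

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_patients", "n_treated", "n_regions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_treated > self.n_patients:
            raise ValueError("n_treated cannot exceed n_patients")
        if self.anomaly_rate_responder < 0 or self.anomaly_rate_nonresponder < 0:
            raise ValueError("anomaly rates must be >= 0")
        if not 0.0 <= self.normalization_fraction <= 1.0:
            raise ValueError("normalization_fraction must lie in [0, 1]")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must lie in [0, 1]")
        if not 0.0 <= self.target_edge_fraction <= 1.0:
            raise ValueError("target_edge_fraction must lie in [0, 1]")
        if not 0.0 <= self.discordance <= 1.0:
            raise ValueError("discordance must lie in [0, 1]")
        if self.edge_noise_sd <= 0:
            raise ValueError("edge_noise_sd must be positive")
        if self.edge_mean_range[0] >= self.edge_mean_range[1]:
            raise ValueError("edge_mean_range must be an increasing interval")


@dataclass
class GroundTruth:
    """Per-patient ledger of what the generator injected."""

    anomalous_edges: dict[str, list[tuple[int, int]]]
    responder: dict[str, Optional[bool]]  # None for untreated patients
    isi_responder: dict[str, Optional[bool]]
    psqi_responder: dict[str, Optional[bool]]


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    parcellation: Parcellation
    edge_index: EdgeIndex
    phenotype: pd.DataFrame
    baseline: dict[str, np.ndarray]  # subject_id -> symmetric FC matrix
    follow_up: dict[str, np.ndarray]  # treated patients only
    ground_truth: GroundTruth

    @property
    def control_ids(self) -> list[str]:
        return self.phenotype.loc[
            self.phenotype["group"] == "control", "subject_id"
        ].tolist()

    @property
    def patient_ids(self) -> list[str]:
        return self.phenotype.loc[
            self.phenotype["group"] == "patient", "subject_id"
        ].tolist()

    @property
    def treated_ids(self) -> list[str]:
        return self.phenotype.loc[
            (self.phenotype["group"] == "patient") & (self.phenotype["arm"] != "none"),
            "subject_id",
        ].tolist()


def _matrix_from_edges(values: np.ndarray, ei: EdgeIndex) -> np.ndarray:
    m = np.eye(ei.n_regions)
    m[ei.row, ei.col] = values
    m[ei.col, ei.row] = values
    return m


def _sample_anomalous_edges(
    rng: np.random.Generator,
    k: int,
    target_pool: np.ndarray,
    rest_pool: np.ndarray,
    target_fraction: float,
) -> np.ndarray:
    """k distinct edge indices, drawn preferentially from the target pool."""
    k_target = int(rng.binomial(k, target_fraction))
    k_target = min(k_target, target_pool.size)
    k_rest = min(k - k_target, rest_pool.size)
    chosen = []
    if k_target:
        chosen.append(rng.choice(target_pool, size=k_target, replace=False))
    if k_rest:
        chosen.append(rng.choice(rest_pool, size=k_rest, replace=False))
    if not chosen:
        return np.empty(0, dtype=int)
    return np.concatenate(chosen)


def _draw_isi_in_severity(rng: np.random.Generator, severity: int) -> int:
    low, high, _ = DEFAULT_ISI_BANDS[severity]
    return int(rng.integers(low, high + 1))


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Generate the full synthetic study from a configuration."""
    parc = synthetic_parcellation(cfg.n_regions)
    ei = build_edge_index(parc)
    max_rate = max(cfg.anomaly_rate_responder, cfg.anomaly_rate_nonresponder)
    if max_rate > ei.n_edges:
        raise ValueError(
            f"anomaly rate {max_rate} exceeds the {ei.n_edges} available edges"
        )

    ss = np.random.SeedSequence(cfg.seed)
    (rng_mu, rng_ctrl, rng_status, rng_anom, rng_pat,
     rng_fu, rng_scores, rng_demo) = (np.random.default_rng(s) for s in ss.spawn(8))

    # --- normative edge structure -------------------------------------------
    mu = rng_mu.uniform(*cfg.edge_mean_range, size=ei.n_edges)
    sd = cfg.edge_noise_sd

    control_ids = [f"CTRL_{k:03d}" for k in range(cfg.n_controls)]
    patient_ids = [f"PAT_{k:03d}" for k in range(cfg.n_patients)]
    treated_ids = patient_ids[: cfg.n_treated]
    arms = {
        sid: (ARM_DRUG if k % 2 == 0 else ARM_DRUG_RTMS)
        for k, sid in enumerate(treated_ids)
    }

    baseline: dict[str, np.ndarray] = {}
    for sid in control_ids:
        vals = np.clip(mu + rng_ctrl.normal(0.0, sd, ei.n_edges), -1.0, 1.0)
        baseline[sid] = _matrix_from_edges(vals, ei)

    # --- latent status: every patient draws a responder-like severity so the
    # patient/control signal spans the whole cohort; the response label is
    # only meaningful (and recorded) for treated subjects -------------------
    latent_high = rng_status.random(cfg.n_patients) < cfg.responder_fraction

    nets = parc.network_array()
    touches_target = np.array(
        [n in cfg.target_networks for n in nets[ei.row]]
    ) | np.array([n in cfg.target_networks for n in nets[ei.col]])
    target_pool = np.flatnonzero(touches_target)
    rest_pool = np.flatnonzero(~touches_target)
    if cfg.signal_edge_pool is not None:
        pool = _sample_anomalous_edges(
            rng_anom,
            min(cfg.signal_edge_pool, ei.n_edges),
            target_pool,
            rest_pool,
            cfg.target_edge_fraction,
        )
        pool_target = pool[np.isin(pool, target_pool)]
        pool_rest = pool[~np.isin(pool, target_pool)]
    else:
        pool_target, pool_rest = target_pool, rest_pool

    anomalous: dict[str, np.ndarray] = {}
    signs: dict[str, np.ndarray] = {}
    for sid, high in zip(patient_ids, latent_high):
        rate = (
            cfg.anomaly_rate_responder if high else cfg.anomaly_rate_nonresponder
        )
        k = int(rng_anom.poisson(rate))
        k = min(k, pool_target.size + pool_rest.size)
        edges = _sample_anomalous_edges(
            rng_anom, k, pool_target, pool_rest, cfg.target_edge_fraction
        )
        anomalous[sid] = np.sort(edges)
        signs[sid] = rng_anom.choice([-1.0, 1.0], size=edges.size)

    for sid in patient_ids:
        vals = mu + rng_pat.normal(0.0, sd, ei.n_edges)
        vals[anomalous[sid]] += signs[sid] * cfg.anomaly_shift * sd
        baseline[sid] = _matrix_from_edges(np.clip(vals, -1.0, 1.0), ei)

    # --- response status of treated subjects --------------------------------
    true_responder = {sid: bool(latent_high[k]) for k, sid in enumerate(treated_ids)}
    isi_resp: dict[str, bool] = {}
    psqi_resp: dict[str, bool] = {}
    for sid in treated_ids:
        if true_responder[sid]:
            if rng_status.random() < cfg.discordance:
                one = rng_status.random() < 0.5
                isi_resp[sid], psqi_resp[sid] = one, not one
            else:
                isi_resp[sid] = psqi_resp[sid] = True
        else:
            isi_resp[sid] = psqi_resp[sid] = False

    # --- follow-up matrices (treated only) ----------------------------------
    follow_up: dict[str, np.ndarray] = {}
    for sid in treated_ids:
        keep = 1.0 - cfg.normalization_fraction if true_responder[sid] else 1.0
        vals = mu + rng_fu.normal(0.0, sd, ei.n_edges)
        vals[anomalous[sid]] += keep * signs[sid] * cfg.anomaly_shift * sd
        follow_up[sid] = _matrix_from_edges(np.clip(vals, -1.0, 1.0), ei)

    # --- questionnaire scores ------------------------------------------------
    rows = []
    for sid in control_ids:
        rows.append(
            {
                "subject_id": sid, "group": "control", "arm": "none",
                "age": float(np.clip(rng_demo.normal(56.0, 5.0), 45, 75).round(1)),
                "sex": int(rng_demo.random() < 0.22),  # 1 = male
                "audit": int(rng_demo.poisson(0.2)),
                "ftnd": int(rng_demo.poisson(0.2)),
                "ess_base": int(np.clip(rng_scores.poisson(2.5), 0, 24)),
                "isi_base": int(np.clip(rng_scores.poisson(0.6), 0, 7)),
                "psqi_base": int(np.clip(round(rng_scores.normal(3.2, 2.0)), 0, 7)),
                "ess_fu": np.nan, "isi_fu": np.nan, "psqi_fu": np.nan,
            }
        )
    pat_rows = {}
    for sid in patient_ids:
        pat_rows[sid] = {
            "subject_id": sid, "group": "patient",
            "arm": arms.get(sid, "none"),
            "age": float(np.clip(rng_demo.normal(57.0, 8.0), 45, 75).round(1)),
            "sex": int(rng_demo.random() < 0.27),
            "audit": int(rng_demo.poisson(0.2)),
            "ftnd": int(rng_demo.poisson(0.2)),
            "ess_base": int(np.clip(rng_scores.poisson(5.0), 0, 24)),
            "isi_base": int(np.clip(round(rng_scores.normal(15.0, 3.5)), 8, 28)),
            "psqi_base": int(np.clip(round(rng_scores.normal(16.0, 2.5)), 8, 21)),
            "ess_fu": np.nan, "isi_fu": np.nan, "psqi_fu": np.nan,
        }

    # Follow-up scores are constructed against the RCI denominator the
    # scoring module will use (treated-cohort baseline SD).
    psqi_base_treated = np.array(
        [pat_rows[sid]["psqi_base"] for sid in treated_ids], dtype=float
    )
    s1 = float(np.std(psqi_base_treated, ddof=1))
    s_diff = s1 * math.sqrt(2.0 * (1.0 - cfg.rci_reliability))
    d_min = max(1, math.ceil(RCI_THRESHOLD * s_diff - 1e-9))
    # largest integer drop a non-responder may show while staying below the
    # reliable-change threshold (capped at 1 to keep them visibly static)
    d_max_nr = min(1, int(math.floor(RCI_THRESHOLD * s_diff - 1e-9)))

    for sid in treated_ids:
        row = pat_rows[sid]
        psqi_b = int(row["psqi_base"])
        if psqi_resp[sid]:
            drop = min(int(d_min + rng_scores.integers(0, 3)), psqi_b)
            if drop < d_min:  # baseline too low to express the change
                drop = d_min  # scores floor at 0 below; keep RCI valid
            row["psqi_fu"] = max(0, psqi_b - drop)
        else:
            change = int(rng_scores.integers(-2, d_max_nr + 1))
            row["psqi_fu"] = int(np.clip(psqi_b - change, 0, 21))
        isi_b = int(row["isi_base"])
        sev = _severity(isi_b)
        if isi_resp[sid]:
            target = max(0, sev - int(rng_scores.integers(1, 3)))
            row["isi_fu"] = _draw_isi_in_severity(rng_scores, target)
        else:
            row["isi_fu"] = _draw_isi_in_severity(rng_scores, sev)
        row["ess_fu"] = int(
            np.clip(row["ess_base"] - rng_scores.integers(0, 4), 0, 24)
        )
    rows.extend(pat_rows[sid] for sid in patient_ids)
    phenotype = pd.DataFrame(rows, columns=list(PHENOTYPE_COLUMNS))

    gt = GroundTruth(
        anomalous_edges={
            sid: [(int(ei.row[e]), int(ei.col[e])) for e in anomalous[sid]]
            for sid in patient_ids
        },
        responder={
            sid: true_responder.get(sid) for sid in patient_ids
        },
        isi_responder={sid: isi_resp.get(sid) for sid in patient_ids},
        psqi_responder={sid: psqi_resp.get(sid) for sid in patient_ids},
    )
    return SyntheticCohort(
        config=cfg,
        parcellation=parc,
        edge_index=ei,
        phenotype=phenotype,
        baseline=baseline,
        follow_up=follow_up,
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# disk round-trip
# ---------------------------------------------------------------------------

def write_fc_matrix(matrix: np.ndarray, path: Path) -> None:
    """FC matrix CSV: first row and first column are region ids."""
    n = matrix.shape[0]
    df = pd.DataFrame(matrix, index=range(n), columns=range(n))
    df.to_csv(path, float_format="%.17g")


def read_fc_matrix(path: Path) -> np.ndarray:
    df = pd.read_csv(path, index_col=0)
    m = df.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: FC matrix is not square ({m.shape})")
    return m


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict:
    """Write the cohort to disk; returns a manifest of files with checksums."""
    out = Path(out_dir)
    fc_dir = out / "fc"
    fc_dir.mkdir(parents=True, exist_ok=True)

    files: list[Path] = []
    parc_path = out / "parcellation.tsv"
    write_parcellation(cohort.parcellation, parc_path)
    files.append(parc_path)

    pheno_path = out / "phenotype.csv"
    cohort.phenotype.to_csv(pheno_path, index=False)
    files.append(pheno_path)

    for sid, m in cohort.baseline.items():
        p = fc_dir / f"{sid}_baseline.csv"
        write_fc_matrix(m, p)
        files.append(p)
    for sid, m in cohort.follow_up.items():
        p = fc_dir / f"{sid}_follow_up.csv"
        write_fc_matrix(m, p)
        files.append(p)

    gt_path = out / "ground_truth.json"
    gt_path.write_text(
        json.dumps(
            {
                "anomalous_edges": cohort.ground_truth.anomalous_edges,
                "responder": cohort.ground_truth.responder,
                "isi_responder": cohort.ground_truth.isi_responder,
                "psqi_responder": cohort.ground_truth.psqi_responder,
            },
            indent=1,
        )
    )
    files.append(gt_path)

    manifest = {
        "n_files": len(files),
        "files": {
            str(p.relative_to(out)): _sha256(p) for p in files
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_cohort_inputs(
    parcellation_path: Path, phenotype_path: Path, fc_dir: Path
) -> tuple[Parcellation, pd.DataFrame, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Load analysis inputs written by :func:`write_cohort` (or equivalent)."""
    parc = load_parcellation(parcellation_path)
    phenotype = pd.read_csv(phenotype_path)
    baseline: dict[str, np.ndarray] = {}
    follow_up: dict[str, np.ndarray] = {}
    for sid in phenotype["subject_id"]:
        p = Path(fc_dir) / f"{sid}_baseline.csv"
        if not p.exists():
            raise FileNotFoundError(f"missing baseline FC matrix for {sid}: {p}")
        baseline[sid] = read_fc_matrix(p)
        fu = Path(fc_dir) / f"{sid}_follow_up.csv"
        if fu.exists():
            follow_up[sid] = read_fc_matrix(fu)
    return parc, phenotype, baseline, follow_up
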