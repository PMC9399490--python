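"""Normative MAD-based outlier detection on functional-connectivity edges.

For every edge the control cohort defines a normative band: the median of
the control FC values and the raw median absolute deviation around it (no
1.4826 consistency constant — the band is "3 or more MAD" in raw units by
default, with an optional consistency scale for callers who want
normal-equivalent sigma units).  A patient's edge is an anomaly when its FC
falls 3 or more MAD from the control median.  Anomalies are then counted
per large-scale network: a cross-network edge increments both endpoint
networks once each (configurable to within-network-only counting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .atlas import EdgeIndex, Parcellation

DEFAULT_THRESHOLD = 3.0
DEFAULT_ZERO_MAD_TOL = 1e-6

CountMode = Literal["both_endpoints", "within_only"]


@dataclass(frozen=True)
class NormativeModel:
    """Per-edge control median and raw MAD."""

    median: np.ndarray  # shape (E,)
    mad: np.ndarray  # shape (E,), raw MAD, >= 0
    n_controls: int
    edge_index: EdgeIndex
    #: multiplicative constant applied to the MAD when thresholding;
    #: 1.0 = raw MAD (default convention), 1.4826 = normal-consistent.
    consistency_scale: float = 1.0


@dataclass(frozen=True)
class AnomalyProfile:
    subject_id: str
    timepoint: str  # "baseline" | "follow_up"
    flags: np.ndarray  # boolean per edge
    network_counts: dict[str, int]

    @property
    def n_anomalies(self) -> int:
        return int(self.flags.sum())


def _edge_matrix(matrices: Sequence[np.ndarray], edge_index: EdgeIndex) -> np.ndarray:
    """Stack subjects' upper-triangle edge vectors into an (n, E) array."""
    return np.stack([edge_index.edge_values(m) for m in matrices])


def fit_normative(
    control_matrices: Sequence[np.ndarray],
    edge_index: EdgeIndex,
    consistency_scale: float = 1.0,
) -> NormativeModel:
    """Fit per-edge median and raw MAD over the healthy-control cohort.

    MAD is the median of absolute deviations from the per-edge median; no
    scaling constant is applied to the stored value.
    """
    if len(control_matrices) < 3:
        raise ValueError(
            f"need >= 3 control matrices to fit a normative model, "
            f"got {len(control_matrices)}"
        )
    values = _edge_matrix(control_matrices, edge_index)
    med = np.median(values, axis=0)
    mad = np.median(np.abs(values - med), axis=0)
    return NormativeModel(
        median=med,
        mad=mad,
        n_controls=len(control_matrices),
        edge_index=edge_index,
        consistency_scale=consistency_scale,
    )


def flag_edges(
    edge_values: np.ndarray,
    model: NormativeModel,
    threshold: float = DEFAULT_THRESHOLD,
    zero_mad_tol: float = DEFAULT_ZERO_MAD_TOL,
) -> np.ndarray:
    """Boolean anomaly flags for one subject's edge vector.

    An edge is flagged when |value - median| >= threshold * scale * MAD.
    Where the control MAD is (numerically) zero the band degenerates, and the
    edge is flagged only when the deviation exceeds the zero-MAD tolerance —
    exact agreement with a degenerate control distribution is not an anomaly.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    dev = np.abs(edge_values - model.median)
    band = threshold * model.consistency_scale * model.mad
    zero = model.mad <= zero_mad_tol
    return np.where(zero, dev > zero_mad_tol, dev >= band)


def count_by_network(
    flags: np.ndarray,
    edge_index: EdgeIndex,
    parc: Parcellation,
    mode: CountMode = "both_endpoints",
) -> dict[str, int]:
    """Anomaly count per network.

    both_endpoints (default): a flagged edge increments every distinct
    endpoint network once (a DMN-SMN edge counts for DMN and for SMN).
    within_only: only edges with both endpoints in the network count.
    """
    nets = parc.network_array()
    net_i = nets[edge_index.row]
    net_j = nets[edge_index.col]
    counts: dict[str, int] = {}
    for network in parc.networks:
        if mode == "both_endpoints":
            touches = (net_i == network) | (net_j == network)
        elif mode == "within_only":
            touches = (net_i == network) & (net_j == network)
        else:
            raise ValueError(f"unknown counting mode {mode!r}")
        counts[network] = int(np.count_nonzero(flags & touches))
    return counts


def flag_anomalies(
    subject_matrix: np.ndarray,
    model: NormativeModel,
    parc: Parcellation,
    subject_id: str = "",
    timepoint: str = "baseline",
    threshold: float = DEFAULT_THRESHOLD,
    zero_mad_tol: float = DEFAULT_ZERO_MAD_TOL,
    mode: CountMode = "both_endpoints",
) -> AnomalyProfile:
    """Score one subject against the normative model."""
    values = model.edge_index.edge_values(subject_matrix)
    flags = flag_edges(values, model, threshold, zero_mad_tol)
    return AnomalyProfile(
        subject_id=subject_id,
        timepoint=timepoint,
        flags=flags,
        network_counts=count_by_network(flags, model.edge_index, parc, mode),
    )


def anomaly_table(
    profiles: Iterable[AnomalyProfile],
    model: NormativeModel,
    edge_values: Mapping[tuple[str, str], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Long-format anomaly listing (one row per flagged edge per subject)."""
    ei = model.edge_index
    rows = []
    for p in profiles:
        idx = np.flatnonzero(p.flags)
        vals = (
            edge_values[(p.subject_id, p.timepoint)]
            if edge_values is not None
            else None
        )
        for e in idx:
            mad = model.mad[e]
            value = float(vals[e]) if vals is not None else np.nan
            dev = value - model.median[e] if vals is not None else np.nan
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "timepoint": p.timepoint,
                    "region_i": int(ei.row[e]),
                    "region_j": int(ei.col[e]),
                    "value": value,
                    "median": float(model.median[e]),
                    "mad": float(mad),
                    "deviation_in_mads": float(abs(dev) / mad)
                    if vals is not None and mad > 0
                    else np.inf
                    if vals is not None
                    else np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "timepoint", "region_i", "region_j",
            "value", "median", "mad", "deviation_in_mads",
        ],
    )


def network_counts_table(profiles: Iterable[AnomalyProfile]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": p.subject_id,
            "timepoint": p.timepoint,
            "network": network,
            "count": count,
        }
        for p in profiles
        for network, count in p.network_counts.items()
    ]
    return pd.DataFrame(rows, columns=["subject_id", "timepoint", "network", "count"])


@dataclass
class AnomalySummary:
    """Group-level anomaly-count summaries.

    mean_counts: network x response-group x timepoint mean anomaly count.
    mean_abs_change: network x response-group mean |follow-up - baseline|.
    mean_signed_change_by_arm: network x treatment-arm mean signed change.
    """

    mean_counts: pd.DataFrame
    mean_abs_change: pd.DataFrame
    mean_signed_change_by_arm: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "mean_counts": self.mean_counts.to_dict(orient="records"),
            "mean_abs_change": self.mean_abs_change.to_dict(orient="records"),
            "mean_signed_change_by_arm": self.mean_signed_change_by_arm.to_dict(
                orient="records"
            ),
        }


def summarize_groups(
    baseline: Mapping[str, AnomalyProfile],
    follow_up: Mapping[str, AnomalyProfile],
    responder: Mapping[str, bool],
    arms: Mapping[str, str],
) -> AnomalySummary:
    """Aggregate per-network anomaly counts over treated subjects.

    ``responder`` maps each treated subject to its response label under one
    instrument; call once per instrument.  Every subject in ``responder``
    must appear in both timepoint maps.
    """
    for sid in responder:
        if sid not in baseline:
            raise ValueError(f"subject {sid!r} missing a baseline profile")
        if sid not in follow_up:
            raise ValueError(f"subject {sid!r} missing a follow-up profile")

    networks = list(next(iter(baseline.values())).network_counts)
    rows, abs_rows, arm_rows = [], [], []
    groups = {
        "responder": [s for s, r in responder.items() if r],
        "non_responder": [s for s, r in responder.items() if not r],
    }
    for network in networks:
        for group, members in groups.items():
            if not members:
                continue
            base = np.array([baseline[s].network_counts[network] for s in members])
            fu = np.array([follow_up[s].network_counts[network] for s in members])
            rows.append(
                {"network": network, "group": group, "timepoint": "baseline",
                 "mean_count": base.mean()}
            )
            rows.append(
                {"network": network, "group": group, "timepoint": "follow_up",
                 "mean_count": fu.mean()}
            )
            abs_rows.append(
                {"network": network, "group": group,
                 "mean_abs_change": np.abs(fu - base).mean()}
            )
        for arm in sorted(set(arms.values())):
            members = [s for s in responder if arms[s] == arm]
            if not members:
                continue
            base = np.array([baseline[s].network_counts[network] for s in members])
            fu = np.array([follow_up[s].network_counts[network] for s in members])
            arm_rows.append(
                {"network": network, "arm": arm,
                 "mean_signed_change": (fu - base).mean()}
            )
    return AnomalySummary(
        mean_counts=pd.DataFrame(rows),
        mean_abs_change=pd.DataFrame(abs_rows),
        mean_signed_change_by_arm=pd.DataFrame(arm_rows),
    )
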