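"""Treatment-response labelling from ISI and PSQI questionnaires.

Two instruments, two response definitions:

* **ISI** (Insomnia Severity Index, 0-28): a responder moves to a strictly
  less severe interpretive category between baseline and follow-up
  (e.g. severe -> moderate).  Standard category bands: 0-7 none,
  8-14 subthreshold, 15-21 moderate, 22-28 severe.
* **PSQI** (Pittsburgh Sleep Quality Index, 0-21, higher = worse): a
  responder achieves a reliable change index of at least 1.96 in the
  improvement direction.  The RCI is the Jacobson-Truax form,
  RCI = (base - fu) / S_diff with S_diff = s1 * sqrt(2 * (1 - r)), where s1
  is the baseline standard deviation of the reference cohort and r the
  test-retest reliability of the instrument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

ISI_MAX = 28
PSQI_MAX = 21

#: (low, high, name) bands of the ISI, least to most severe.
DEFAULT_ISI_BANDS: tuple[tuple[int, int, str], ...] = (
    (0, 7, "none"),
    (8, 14, "subthreshold"),
    (15, 21, "moderate"),
    (22, 28, "severe"),
)

RCI_THRESHOLD = 1.96


@dataclass(frozen=True)
class RciParameters:
    """Constants entering the reliable change index.

    reliability: test-retest reliability r of the PSQI, in (0, 1).
    sd_source: where the baseline SD s1 comes from — the treated cohort,
        all patients, or a user-supplied value.
    sd: the SD when sd_source == "user_supplied".
    """

    reliability: float = 0.85
    sd_source: str = "treated_cohort"
    sd: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.reliability < 1.0:
            raise ValueError(f"reliability must lie in (0, 1), got {self.reliability}")
        if self.sd_source not in ("treated_cohort", "all_patients", "user_supplied"):
            raise ValueError(f"unknown sd_source {self.sd_source!r}")
        if self.sd_source == "user_supplied":
            if self.sd is None or self.sd <= 0:
                raise ValueError("user_supplied sd must be a positive number")


@dataclass(frozen=True)
class ResponseLabel:
    subject_id: str
    arm: str
    isi_responder: bool
    psqi_responder: bool
    psqi_rci: float
    isi_category_base: str
    isi_category_fu: str


def isi_category(
    score: int, bands: Sequence[tuple[int, int, str]] = DEFAULT_ISI_BANDS
) -> str:
    """Interpretive severity category of an ISI total score."""
    if not float(score).is_integer() or not bands[0][0] <= score <= bands[-1][1]:
        raise ValueError(f"ISI score must be an integer in "
                         f"[{bands[0][0]}, {bands[-1][1]}], got {score}")
    for low, high, name in bands:
        if low <= score <= high:
            return name
    raise ValueError(f"ISI score {score} falls outside the configured bands")


def _severity(
    score: int, bands: Sequence[tuple[int, int, str]] = DEFAULT_ISI_BANDS
) -> int:
    cat = isi_category(score, bands)
    return [name for _, _, name in bands].index(cat)


def label_isi_response(
    base: int, fu: int, bands: Sequence[tuple[int, int, str]] = DEFAULT_ISI_BANDS
) -> bool:
    """True iff the follow-up category is strictly less severe than baseline."""
    return _severity(fu, bands) < _severity(base, bands)


def rci_denominator(
    params: RciParameters, baseline_scores: Optional[Sequence[float]] = None
) -> float:
    """S_diff = s1 * sqrt(2 * (1 - r)), the SE of the difference score."""
    if params.sd_source == "user_supplied":
        s1 = float(params.sd)  # validated positive
    else:
        if baseline_scores is None or len(baseline_scores) < 2:
            raise ValueError(
                f"sd_source {params.sd_source!r} needs >= 2 baseline scores"
            )
        s1 = float(np.std(np.asarray(baseline_scores, dtype=float), ddof=1))
    if s1 <= 0:
        raise ValueError("baseline standard deviation is zero; RCI undefined")
    return s1 * math.sqrt(2.0 * (1.0 - params.reliability))


def psqi_rci(
    base: float,
    fu: float,
    params: RciParameters = RciParameters(),
    baseline_scores: Optional[Sequence[float]] = None,
) -> float:
    """Reliable change index of a PSQI pre/post pair.

    Positive values are improvements (PSQI decreases as sleep improves);
    antisymmetric under swapping base and fu.
    """
    for s in (base, fu):
        if not 0 <= s <= PSQI_MAX:
            raise ValueError(f"PSQI score {s} outside [0, {PSQI_MAX}]")
    return (base - fu) / rci_denominator(params, baseline_scores)


@dataclass
class CohortResponse:
    labels: list[ResponseLabel]
    table: pd.DataFrame  # one row per treated subject, the labels CSV layout
    counts: dict  # aggregate counts feeding the contingency analyses
    s_diff: float


def label_cohort(
    phenotype: pd.DataFrame,
    params: RciParameters = RciParameters(),
    bands: Sequence[tuple[int, int, str]] = DEFAULT_ISI_BANDS,
) -> CohortResponse:
    """Label every treated patient on both instruments and aggregate counts.

    ``phenotype`` needs columns subject_id, group, arm, isi_base, psqi_base,
    isi_fu, psqi_fu; treated subjects are those with arm != "none".  The RCI
    baseline SD is taken from the source configured in ``params``.
    """
    treated = phenotype[
        (phenotype["group"] == "patient") & (phenotype["arm"] != "none")
    ]
    missing = treated[treated["isi_fu"].isna() | treated["psqi_fu"].isna()]
    if len(missing):
        raise ValueError(
            "treated subject(s) missing follow-up scores: "
            + ", ".join(missing["subject_id"].astype(str))
        )
    if params.sd_source == "all_patients":
        sd_pool = phenotype.loc[phenotype["group"] == "patient", "psqi_base"]
    else:
        sd_pool = treated["psqi_base"]
    s_diff = rci_denominator(params, sd_pool.to_numpy(dtype=float))

    labels: list[ResponseLabel] = []
    rows = []
    for _, r in treated.iterrows():
        isi_b, isi_f = int(r["isi_base"]), int(r["isi_fu"])
        psqi_b, psqi_f = float(r["psqi_base"]), float(r["psqi_fu"])
        rci = (psqi_b - psqi_f) / s_diff
        lab = ResponseLabel(
            subject_id=str(r["subject_id"]),
            arm=str(r["arm"]),
            isi_responder=label_isi_response(isi_b, isi_f, bands),
            psqi_responder=rci >= RCI_THRESHOLD,
            psqi_rci=rci,
            isi_category_base=isi_category(isi_b, bands),
            isi_category_fu=isi_category(isi_f, bands),
        )
        labels.append(lab)
        rows.append(
            {
                "subject_id": lab.subject_id,
                "arm": lab.arm,
                "isi_base": isi_b,
                "isi_fu": isi_f,
                "isi_cat_base": lab.isi_category_base,
                "isi_cat_fu": lab.isi_category_fu,
                "isi_responder": lab.isi_responder,
                "psqi_base": psqi_b,
                "psqi_fu": psqi_f,
                "psqi_rci": rci,
                "psqi_responder": lab.psqi_responder,
            }
        )
    table = pd.DataFrame(rows)

    arms = sorted({lab.arm for lab in labels})
    counts = {
        "n_treated": len(labels),
        "improved_either": sum(l.isi_responder or l.psqi_responder for l in labels),
        "improved_both": sum(l.isi_responder and l.psqi_responder for l in labels),
        "per_arm": {
            arm: {
                "n": sum(l.arm == arm for l in labels),
                "isi_improved": sum(l.arm == arm and l.isi_responder for l in labels),
                "psqi_improved": sum(
                    l.arm == arm and l.psqi_responder for l in labels
                ),
            }
            for arm in arms
        },
    }
    return CohortResponse(labels=labels, table=table, counts=counts, s_diff=s_diff)
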