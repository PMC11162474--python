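"""Downstream utilization of patient-level uncertainty.

Implements the quality-control suite: calibrating an uncertainty threshold
from a calibration cohort, accuracy-vs-uncertainty contingency analysis,
certainty/DSC correlation, batch referral curves with their AUC summary,
and instance (threshold-based) referral.

Conventions (documented tie-breaks):

* a patient is *certain* iff ``uncertainty <= tau``; NaN (degenerate)
  uncertainty is always *uncertain*;
* a segmentation is *accurate* iff ``DSC >= dsc_cut`` (default 0.61, the
  literature value for expert interobserver agreement on this structure);
* referral sorts descending by uncertainty with ties broken
  lexicographically by patient id; degenerate patients sort as most
  uncertain;
* the referral-curve AUC is the unweighted mean of retained-set means over
  all referral steps, including the 0-referred point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .measures import MEASURE_NAMES

__all__ = [
    "CohortRecord",
    "UncertaintyThreshold",
    "Contingency",
    "ReferralCurve",
    "DEFAULT_DSC_ANCHOR",
    "calibrate_threshold",
    "classify",
    "conditional_probs",
    "certainty_correlation",
    "batch_referral",
    "referral_auc",
    "instance_referral",
    "records_to_frame",
    "frame_to_records",
    "evaluate_cohort",
]

#: expert interobserver agreement level used as the accurate/inaccurate cut
DEFAULT_DSC_ANCHOR = 0.61

MetricName = Literal["dsc", "msd", "hd95"]


@dataclass
class CohortRecord:
    """Per-patient uncertainty values and quality metrics vs ground truth."""

    patient_id: str
    uncertainty: dict[str, float]
    dsc: float
    msd: float = float("nan")
    hd95: float = float("nan")
    split: Literal["calibration", "evaluation"] = "evaluation"
    flags: tuple[str, ...] = ()

    def metric(self, name: MetricName) -> float:
        return {"dsc": self.dsc, "msd": self.msd, "hd95": self.hd95}[name]

    def is_degenerate(self, measure: str) -> bool:
        u = self.uncertainty.get(measure, float("nan"))
        return isinstance(u, float) and math.isnan(u)


@dataclass(frozen=True)
class UncertaintyThreshold:
    """A calibrated uncertainty threshold tau for one measure.

    Calibrated by ordinary least squares of uncertainty on DSC over the
    calibration cohort, read off at ``dsc_anchor``.
    """

    measure: str
    tau: float
    dsc_anchor: float
    slope: float
    intercept: float


@dataclass(frozen=True)
class Contingency:
    """Counts of the four accuracy x certainty cells."""

    n_ac: int  # accurate & certain
    n_au: int  # accurate & uncertain
    n_ic: int  # inaccurate & certain
    n_iu: int  # inaccurate & uncertain

    @property
    def n(self) -> int:
        return self.n_ac + self.n_au + self.n_ic + self.n_iu


@dataclass(frozen=True)
class ReferralCurve:
    """Mean retained quality after k referrals, k = 0 .. max removals."""

    points: tuple[tuple[int, float], ...]
    metric: MetricName
    stop_fraction: float

    @property
    def retained_means(self) -> np.ndarray:
        return np.array([v for _, v in self.points])


def _usable(records: Sequence[CohortRecord], measure: str) -> list[CohortRecord]:
    return [r for r in records if not r.is_degenerate(measure)]


def calibrate_threshold(
    records: Sequence[CohortRecord],
    measure: str,
    dsc_target: float = DEFAULT_DSC_ANCHOR,
) -> UncertaintyThreshold:
    """Fit ``uncertainty = a * DSC + b`` by OLS and return tau = a*target + b.

    DSC is the independent variable.  Records with degenerate (NaN)
    uncertainty are excluded from the fit.  Raises if fewer than two
    distinct DSC values remain (singular fit).
    """
    usable = _usable(records, measure)
    x = np.array([r.dsc for r in usable], dtype=float)
    u = np.array([r.uncertainty[measure] for r in usable], dtype=float)
    if len(x) < 2 or np.unique(x).size < 2:
        raise ValueError(
            f"calibration of {measure!r} needs >= 2 records with distinct DSC"
        )
    slope, intercept = np.polyfit(x, u, 1)
    return UncertaintyThreshold(
        measure=measure,
        tau=float(slope * dsc_target + intercept),
        dsc_anchor=float(dsc_target),
        slope=float(slope),
        intercept=float(intercept),
    )


def classify(
    records: Sequence[CohortRecord],
    th: UncertaintyThreshold,
    dsc_cut: float = DEFAULT_DSC_ANCHOR,
) -> Contingency:
    """Count the four accuracy x certainty cells on an evaluation cohort.

    Certain iff uncertainty <= tau (ties certain); degenerate records are
    uncertain.  Accurate iff DSC >= dsc_cut (ties accurate).
    """
    n_ac = n_au = n_ic = n_iu = 0
    for r in records:
        accurate = r.dsc >= dsc_cut
        certain = (not r.is_degenerate(th.measure)) and (
            r.uncertainty[th.measure] <= th.tau
        )
        if accurate and certain:
            n_ac += 1
        elif accurate:
            n_au += 1
        elif certain:
            n_ic += 1
        else:
            n_iu += 1
    return Contingency(n_ac=n_ac, n_au=n_au, n_ic=n_ic, n_iu=n_iu)


def conditional_probs(
    c: Contingency,
) -> tuple[float | None, float | None, float | None]:
    """(p(accurate|certain), p(inaccurate|uncertain), AU).

    AU = (n_ac + n_iu) / N, the probability of the desirable outcomes
    (accurate-and-certain or inaccurate-and-uncertain).  Ratios with a zero
    denominator are returned as None (flagged absent), never silently 0.
    """
    n_cert = c.n_ac + c.n_ic
    n_unc = c.n_iu + c.n_au
    p_acc_cert = c.n_ac / n_cert if n_cert else None
    p_inacc_unc = c.n_iu / n_unc if n_unc else None
    au = (c.n_ac + c.n_iu) / c.n if c.n else None
    return p_acc_cert, p_inacc_unc, au


def certainty_correlation(
    records: Sequence[CohortRecord], measure: str
) -> tuple[float, float]:
    """Pearson correlation between DSC and certainty (negative uncertainty),
    with the two-sided p-value.  Degenerate records are excluded."""
    usable = _usable(records, measure)
    if len(usable) < 3:
        raise ValueError("correlation needs >= 3 non-degenerate records")
    d = np.array([r.dsc for r in usable])
    cert = np.array([-r.uncertainty[measure] for r in usable])
    if d.std() == 0 or cert.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    rho, p = stats.pearsonr(d, cert)
    return float(rho), float(p)


def _referral_order(
    records: Sequence[CohortRecord], measure: str
) -> list[CohortRecord]:
    """Most-uncertain-first ordering; degenerate first, ties by patient id."""
    def key(r: CohortRecord):
        if r.is_degenerate(measure):
            return (0, 0.0, r.patient_id)
        return (1, -r.uncertainty[measure], r.patient_id)

    return sorted(records, key=key)


def batch_referral(
    records: Sequence[CohortRecord],
    measure: str,
    metric: MetricName = "dsc",
    stop_fraction: float = 0.10,
) -> ReferralCurve:
    """Simulate batch referral: repeatedly remove the most uncertain patient
    and track the mean quality of the retained set.

    Referral stops when only ``ceil(stop_fraction * N)`` patients remain,
    i.e. after ``floor((1 - stop_fraction) * N)`` removals.
    """
    if len(records) < 2:
        raise ValueError("batch referral needs >= 2 records")
    order = _referral_order(records, measure)
    values = np.array([r.metric(metric) for r in order])
    n = len(order)
    max_removals = int(math.floor((1.0 - stop_fraction) * n))
    points = []
    for k in range(max_removals + 1):
        retained = values[k:]
        points.append((k, float(retained.mean())))
    return ReferralCurve(points=tuple(points), metric=metric, stop_fraction=stop_fraction)


def referral_auc(curve: ReferralCurve) -> float:
    """Unweighted mean of the retained-set means over all referral steps
    (including the 0-referred point)."""
    if not curve.points:
        raise ValueError("empty referral curve")
    return float(curve.retained_means.mean())


def instance_referral(
    records: Sequence[CohortRecord],
    th: UncertaintyThreshold,
    metric: MetricName = "dsc",
) -> tuple[list[str], float | None, int]:
    """Retain patients whose uncertainty is <= tau; refer the rest.

    Returns (retained patient ids, mean metric over retained or None when
    nobody is retained, number retained).  Degenerate patients are always
    referred.
    """
    retained = [
        r
        for r in records
        if not r.is_degenerate(th.measure) and r.uncertainty[th.measure] <= th.tau
    ]
    ids = sorted(r.patient_id for r in retained)
    if not retained:
        return [], None, 0
    mean = float(np.mean([r.metric(metric) for r in retained]))
    return ids, mean, len(retained)


# ---------------------------------------------------------------------------
# cohort CSV round-trip and the one-call evaluation report
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, object] = {
            "patient_id": r.patient_id,
            "split": r.split,
            "dsc": r.dsc,
            "msd_mm": r.msd,
            "hd95_mm": r.hd95,
        }
        for m in MEASURE_NAMES:
            row[m] = r.uncertainty.get(m, float("nan"))
        row["flags"] = ";".join(r.flags)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[CohortRecord]:
    records = []
    for _, row in df.iterrows():
        flags = row.get("flags", "")
        flags = tuple(str(flags).split(";")) if isinstance(flags, str) and flags else ()
        records.append(
            CohortRecord(
                patient_id=str(row["patient_id"]),
                uncertainty={m: float(row[m]) for m in MEASURE_NAMES if m in row},
                dsc=float(row["dsc"]),
                msd=float(row.get("msd_mm", float("nan"))),
                hd95=float(row.get("hd95_mm", float("nan"))),
                split=str(row.get("split", "evaluation")),  # type: ignore[arg-type]
                flags=flags,
            )
        )
    return records


def evaluate_cohort(
    records: Sequence[CohortRecord],
    measures: Iterable[str] = MEASURE_NAMES,
    dsc_cut: float = DEFAULT_DSC_ANCHOR,
    instance_anchors: Sequence[float] = (0.80, 0.85, 0.90),
    metrics: Sequence[MetricName] = ("dsc", "msd", "hd95"),
    stop_fraction: float = 0.10,
) -> dict:
    """Run the full utilization suite and return a JSON-serializable report.

    Thresholds are calibrated on the ``calibration`` split (at ``dsc_cut``
    for the contingency analysis and at each instance anchor for instance
    referral) and everything is evaluated on the ``evaluation`` split.
    """
    cal = [r for r in records if r.split == "calibration"]
    ev = [r for r in records if r.split == "evaluation"]
    if not cal or not ev:
        raise ValueError("cohort needs both calibration and evaluation records")

    report: dict = {
        "dsc_cut": dsc_cut,
        "n_calibration": len(cal),
        "n_evaluation": len(ev),
        "measures": {},
    }
    for m in measures:
        entry: dict = {}
        th = calibrate_threshold(cal, m, dsc_target=dsc_cut)
        entry["threshold"] = {
            "tau": th.tau,
            "dsc_anchor": th.dsc_anchor,
            "slope": th.slope,
            "intercept": th.intercept,
        }
        cont = classify(ev, th, dsc_cut=dsc_cut)
        p_ac, p_iu, au = conditional_probs(cont)
        entry["contingency"] = {
            "n_ac": cont.n_ac, "n_au": cont.n_au,
            "n_ic": cont.n_ic, "n_iu": cont.n_iu,
        }
        entry["p_accurate_given_certain"] = p_ac
        entry["p_inaccurate_given_uncertain"] = p_iu
        entry["au"] = au
        rho, pval = certainty_correlation(ev, m)
        entry["pearson_certainty_dsc"] = {"rho": rho, "p_value": pval}
        entry["referral"] = {}
        for metric in metrics:
            curve = batch_referral(ev, m, metric=metric, stop_fraction=stop_fraction)
            entry["referral"][metric] = {
                "auc": referral_auc(curve),
                "n_points": len(curve.points),
            }
        entry["instance_referral"] = {}
        for anchor in instance_anchors:
            th_a = calibrate_threshold(cal, m, dsc_target=anchor)
            _, mean, n_kept = instance_referral(ev, th_a, metric="dsc")
            entry["instance_referral"][f"tau_{anchor:.2f}"] = {
                "tau": th_a.tau, "retained_mean_dsc": mean, "n_retained": n_kept,
            }
        report["measures"][m] = entry
    return report
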