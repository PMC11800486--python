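"""Diagnostic accuracy and rater-agreement statistics.

Contingency construction against the iron ground truth, sensitivity /
specificity / predictive values / accuracy with half-up integer-percent
rounding (the convention under which 10/16 prints as 63%), Cohen's kappa
for two reading sessions, Fleiss' kappa for multiple raters, Landis-Koch
qualitative bands, and majority-vote consolidation of reader calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

POSITIVE = "rim+"
NEGATIVE = "rim-"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of rim calls (test) against iron status (truth)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def build_contingency(calls, truth) -> ContingencyTable:
    """Cross-tabulate per-lesion calls ('rim+'/'rim-') against truth
    ('iron+'/'iron-'). Both arguments are mappings or Series keyed by
    lesion id, or equal-length sequences."""
    calls = pd.Series(calls)
    truth = pd.Series(truth)
    if not calls.index.sort_values().equals(truth.index.sort_values()):
        raise ValueError("calls and truth cover different lesion sets")
    truth = truth.reindex(calls.index)
    pos_call = calls.str.endswith("+")
    pos_truth = truth.str.endswith("+")
    return ContingencyTable(
        tp=int((pos_call & pos_truth).sum()),
        fp=int((pos_call & ~pos_truth).sum()),
        fn=int((~pos_call & pos_truth).sum()),
        tn=int((~pos_call & ~pos_truth).sum()),
    )


def percent_round_half_up(fraction: float) -> int:
    """Round 100*fraction to the nearest integer, halves away from zero up."""
    return int(math.floor(100.0 * fraction + 0.5))


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Diagnostic accuracy metrics; ``None`` marks an undefined metric
    (zero denominator). ``*_pct`` are half-up-rounded integer percentages."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None

    def _pct(self, value: float | None) -> int | None:
        return None if value is None else percent_round_half_up(value)

    @property
    def sensitivity_pct(self):
        return self._pct(self.sensitivity)

    @property
    def specificity_pct(self):
        return self._pct(self.specificity)

    @property
    def ppv_pct(self):
        return self._pct(self.ppv)

    @property
    def npv_pct(self):
        return self._pct(self.npv)

    @property
    def accuracy_pct(self):
        return self._pct(self.accuracy)

    def as_dict(self) -> dict:
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            frac = getattr(self, name)
            out[name] = frac
            out[f"{name}_pct"] = getattr(self, f"{name}_pct")
        return out


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def diagnostic_metrics(table: ContingencyTable) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy from a 2x2 table.

    Zero denominators yield ``None`` rather than raising.
    """
    return DiagnosticMetrics(
        sensitivity=_ratio(table.tp, table.tp + table.fn),
        specificity=_ratio(table.tn, table.tn + table.fp),
        ppv=_ratio(table.tp, table.tp + table.fp),
        npv=_ratio(table.tn, table.tn + table.fn),
        accuracy=_ratio(table.tp + table.tn, table.total),
    )


def majority_vote(ratings: pd.DataFrame) -> pd.Series:
    """Per-item modal category over raters (columns). Requires an odd number
    of raters so no tie is possible with binary categories."""
    if ratings.shape[1] % 2 == 0:
        raise ValueError("majority vote needs an odd number of raters")
    return ratings.mode(axis=1).iloc[:, 0]


def cohen_kappa(session1, session2) -> float:
    """Cohen's kappa between two categorical call sequences.

    kappa = (p_o - p_e) / (1 - p_e). If p_e = 1 (both marginals degenerate):
    1.0 when agreement is perfect, NaN otherwise.
    """
    s1 = np.asarray(session1)
    s2 = np.asarray(session2)
    if s1.shape != s2.shape:
        raise ValueError("sessions differ in length")
    n = s1.size
    if n == 0:
        raise ValueError("empty sessions")
    cats = np.union1d(s1, s2)
    p_o = float(np.mean(s1 == s2))
    p_e = sum(
        np.mean(s1 == c) * np.mean(s2 == c) for c in cats
    )
    if abs(1.0 - p_e) < 1e-15:
        return 1.0 if p_o == 1.0 else float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def fleiss_kappa(ratings: pd.DataFrame) -> float:
    """Fleiss' kappa for an items x raters matrix of categorical calls.

    Standard formulation: per-item agreement P_i = (sum_j n_ij^2 - n) /
    (n (n - 1)); kappa = (P_bar - P_bar_e) / (1 - P_bar_e), with expected
    agreement P_bar_e = sum_j p_j^2 from the pooled category proportions.
    """
    arr = pd.DataFrame(ratings)
    if arr.isna().any().any():
        raise ValueError("rating matrix has missing cells")
    n_raters = arr.shape[1]
    if n_raters < 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 raters and >= 2 items")
    cats = sorted(pd.unique(arr.to_numpy().ravel()))
    counts = np.stack(
        [(arr.to_numpy() == c).sum(axis=1) for c in cats], axis=1
    )  # items x categories
    n = counts.sum(axis=1)
    if np.any(n < 2):
        raise ValueError("every item needs >= 2 ratings")
    p_i = (np.sum(counts**2, axis=1) - n) / (n * (n - 1))
    p_bar = float(p_i.mean())
    p_j = counts.sum(axis=0) / counts.sum()
    p_bar_e = float(np.sum(p_j**2))
    if abs(1.0 - p_bar_e) < 1e-15:
        return 1.0 if p_bar == 1.0 else float("nan")
    return (p_bar - p_bar_e) / (1.0 - p_bar_e)


#: Standard Landis-Koch interpretation bands; edges closed on the right.
LANDIS_KOCH_BANDS: tuple[tuple[float, str], ...] = (
    (0.0, "poor"),  # kappa < 0
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


def landis_koch_label(
    kappa: float, bands: tuple[tuple[float, str], ...] = LANDIS_KOCH_BANDS
) -> str:
    """Qualitative agreement label for a kappa value."""
    if kappa > 1.0:
        raise ValueError("kappa cannot exceed 1")
    if kappa < bands[0][0]:
        return bands[0][1]
    for upper, label in bands[1:]:
        if kappa <= upper:
            return label
    return bands[-1][1]  # pragma: no cover


@dataclass
class AgreementStats:
    """Inter-rater (Fleiss) and per-rater intra-rater (Cohen) agreement."""

    fleiss_kappa: float
    fleiss_label: str
    cohen_kappas: dict[str, float]
    cohen_labels: dict[str, str]


def agreement_stats(
    ratings_session1: pd.DataFrame, ratings_session2: pd.DataFrame | None = None
) -> AgreementStats:
    """Fleiss kappa across raters of session 1; per-rater Cohen kappa between
    the two sessions when a second session is given."""
    fk = fleiss_kappa(ratings_session1)
    cks: dict[str, float] = {}
    if ratings_session2 is not None:
        if list(ratings_session1.columns) != list(ratings_session2.columns):
            raise ValueError("sessions have different raters")
        for col in ratings_session1.columns:
            cks[col] = cohen_kappa(
                ratings_session1[col].to_numpy(), ratings_session2[col].to_numpy()
            )
    return AgreementStats(
        fleiss_kappa=fk,
        fleiss_label=landis_koch_label(fk) if np.isfinite(fk) else "undefined",
        cohen_kappas=cks,
        cohen_labels={
            k: landis_koch_label(v) if np.isfinite(v) else "undefined"
            for k, v in cks.items()
        },
    )
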