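"""Model adequacy statistics computed from a fitted model's posterior matrix.

Four diagnostics summarise how confidently the posterior classifies
subjects: the average posterior probability of assignment (APPA, per
class), the odds of correct classification (OCC, per class), the mismatch
between estimated mixing proportions and modal-assignment shares, and the
relative entropy E_K of the whole posterior matrix.  Conventional
acceptability thresholds: APPA > 0.70 in every class, OCC > 5.0, and
E_K > 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import DataError, FittedModel

__all__ = [
    "AdequacyReport",
    "appa",
    "occ",
    "mismatch",
    "relative_entropy",
    "adequacy_report",
    "APPA_THRESHOLD",
    "OCC_THRESHOLD",
    "ENTROPY_THRESHOLD",
]

APPA_THRESHOLD = 0.70
OCC_THRESHOLD = 5.0
ENTROPY_THRESHOLD = 0.5


def modal_assignment(posterior: np.ndarray) -> np.ndarray:
    """Arg-max class per row; ties broken toward the lower class index."""
    return np.argmax(posterior, axis=1)


def appa(posterior: np.ndarray, assignment: np.ndarray | None = None) -> np.ndarray:
    """Average posterior probability of assignment, per class.

    ``APPA_k`` is the mean of ``p_ik`` over the subjects modally assigned
    to class ``k``.  A class with no members yields ``nan`` (reported as
    missing, never as zero) plus a warning, so collapse is distinguishable
    from poor separation.
    """
    posterior = np.asarray(posterior, dtype=float)
    K = posterior.shape[1]
    if assignment is None:
        assignment = modal_assignment(posterior)
    out = np.full(K, np.nan)
    for k in range(K):
        members = assignment == k
        if members.any():
            out[k] = posterior[members, k].mean()
        else:
            warnings.warn(f"class {k} has no assigned members; APPA missing", stacklevel=2)
    return out


def occ(appa_k: float, pi_k: float) -> float:
    """Odds of correct classification for one class.

    ``OCC_k = [APPA_k / (1 - APPA_k)] / [pi_k / (1 - pi_k)]`` — the
    posterior classification odds relative to the chance odds implied by
    the mixing proportion.  ``OCC_k = 1`` means classification no better
    than chance; perfect assignment (APPA 1) returns ``+inf``.
    """
    if not (0.0 < pi_k < 1.0):
        raise DataError(f"OCC undefined for mixing proportion {pi_k}")
    if np.isnan(appa_k):
        return float("nan")
    if appa_k >= 1.0:
        return float("inf")
    chance_odds = pi_k / (1.0 - pi_k)
    return float((appa_k / (1.0 - appa_k)) / chance_odds)


def mismatch(pi_hat: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    """``delta_k = pi_hat_k - N_k / N``; the components sum to zero exactly."""
    pi_hat = np.asarray(pi_hat, dtype=float)
    K = pi_hat.shape[0]
    counts = np.bincount(np.asarray(assignment), minlength=K).astype(float)
    return pi_hat - counts / counts.sum()


def relative_entropy(posterior: np.ndarray) -> float:
    """Relative entropy ``E_K = 1 - sum_ik -p_ik ln p_ik / (N ln K)``.

    1 means one-hot (perfectly separated) posteriors, 0 means uniform
    (uninformative) ones; the logarithm base cancels in the normalisation.
    Undefined for K = 1.
    """
    posterior = np.asarray(posterior, dtype=float)
    N, K = posterior.shape
    if K < 2:
        raise DataError("relative entropy is undefined for a single class")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(posterior > 0, -posterior * np.log(posterior), 0.0)
    ent = terms.sum()
    return float(np.clip(1.0 - ent / (N * np.log(K)), 0.0, 1.0))


@dataclass
class AdequacyReport:
    """All step-4 statistics for one fitted model, plus threshold booleans."""

    appa: np.ndarray
    occ: np.ndarray
    mismatch: np.ndarray
    relative_entropy: float
    empty_classes: np.ndarray
    thresholds_met: dict[str, bool]

    @property
    def all_met(self) -> bool:
        return all(self.thresholds_met.values())

    def to_dict(self) -> dict:
        return {
            "appa": [None if np.isnan(v) else float(v) for v in self.appa],
            "occ": [None if np.isnan(v) else float(v) for v in self.occ],
            "mismatch": [float(v) for v in self.mismatch],
            "relative_entropy": self.relative_entropy,
            "empty_classes": self.empty_classes.tolist(),
            "thresholds_met": self.thresholds_met,
        }


def adequacy_report(model: FittedModel) -> AdequacyReport:
    """Assemble APPA, OCC, mismatch and E_K for a fitted model.

    The APPA criterion requires every class to clear 0.70; an empty class
    fails it by definition (collapse is itself an adequacy violation).
    E_K is reported as ``nan`` for K = 1 models, where it is undefined.
    """
    post = model.posterior
    assign = model.assignment
    K = post.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        appa_vals = appa(post, assign)
    occ_vals = np.array([occ(appa_vals[k], model.pi[k])
                         if 0.0 < model.pi[k] < 1.0 else np.nan for k in range(K)])
    mm = mismatch(model.pi, assign)
    ent = relative_entropy(post) if K >= 2 else float("nan")
    empty = np.where(np.isnan(appa_vals))[0]
    thresholds = {
        "appa": bool(np.all(~np.isnan(appa_vals)) and np.all(appa_vals > APPA_THRESHOLD)),
        "occ": bool(np.all(~np.isnan(occ_vals)) and np.all(occ_vals > OCC_THRESHOLD)) if K >= 2 else True,
        "relative_entropy": bool(not np.isnan(ent) and ent > ENTROPY_THRESHOLD) if K >= 2 else True,
    }
    return AdequacyReport(appa=appa_vals, occ=occ_vals, mismatch=mm,
                          relative_entropy=ent, empty_classes=empty,
                          thresholds_met=thresholds)
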