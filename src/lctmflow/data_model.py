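"""Domain types and long-format I/O for latent class trajectory models.

A latent class trajectory model (LCTM) describes repeated measurements
``y_ij`` of one outcome (e.g. BMI in kg/m^2) on subject ``i`` at occasion
``j`` (time ``t_ij``, e.g. age in years) as a finite mixture of polynomial
mixed-effects models.  This module holds the universal input container
(:class:`TrajectoryDataset`), the declarative description of one candidate
model (:class:`ModelStructure`, covering the seven covariance structures
A-G), the container for a fitted model (:class:`FittedModel`), per-subject
design matrices (:func:`build_design`), and the closed-form free-parameter
count used by the BIC penalty (:func:`count_parameters`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "DataError",
    "TimeTransform",
    "TrajectoryDataset",
    "ModelStructure",
    "SubjectDesign",
    "SufficientSummaries",
    "FittedModel",
    "STRUCTURE_CODES",
    "read_long_csv",
    "write_long_csv",
    "count_parameters",
    "build_design",
]


class ConfigurationError(ValueError):
    """A user-supplied configuration (column map, structure, ...) is invalid."""


class DataError(ValueError):
    """The data themselves violate an invariant (duplicates, non-finite, empty)."""


# --------------------------------------------------------------------------
# Time transform
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeTransform:
    """Affine rescaling of the time axis, ``t' = (t - center) / scale``.

    The default centres mid-adulthood (45 years) and measures time in
    decades, which conditions the quadratic design matrix on an adult age
    axis (roughly 18-71 years maps to about -2.7 .. +2.6).  Fitted
    trajectories are always reported back on the natural axis.
    """

    center: float = 45.0
    scale: float = 10.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.center) or not np.isfinite(self.scale) or self.scale == 0:
            raise ConfigurationError("time transform needs finite center and nonzero scale")

    def apply(self, t: np.ndarray) -> np.ndarray:
        return (np.asarray(t, dtype=float) - self.center) / self.scale

    def invert(self, u: np.ndarray) -> np.ndarray:
        return np.asarray(u, dtype=float) * self.scale + self.center

    @classmethod
    def identity(cls) -> "TimeTransform":
        return cls(center=0.0, scale=1.0)


# --------------------------------------------------------------------------
# TrajectoryDataset
# --------------------------------------------------------------------------

class TrajectoryDataset:
    """Long-format repeated measures: one row per (subject, time, outcome).

    Invariants enforced on construction: finite times and outcomes, unique
    (subject, time) pairs, at least one observation per subject (vacuous by
    construction) and a non-empty table.  ``n_dropped`` records how many
    rows an optional plausibility window removed at load time.
    """

    def __init__(self, frame: pd.DataFrame, n_dropped: int = 0) -> None:
        required = {"id", "time", "y"}
        if not required.issubset(frame.columns):
            raise ConfigurationError(f"dataset frame must have columns {sorted(required)}")
        if len(frame) == 0:
            raise DataError("empty dataset: no observations")
        frame = frame.loc[:, ["id", "time", "y"]].copy()
        frame["time"] = frame["time"].astype(float)
        frame["y"] = frame["y"].astype(float)
        if not np.isfinite(frame["time"]).all():
            raise DataError("non-finite time values present")
        if not np.isfinite(frame["y"]).all():
            raise DataError("non-finite outcome values present")
        dup = frame.duplicated(subset=["id", "time"])
        if dup.any():
            bad = frame.loc[dup, "id"].iloc[0]
            raise DataError(f"duplicate (subject, time) pair for subject {bad!r}")
        # stable subject order = order of first appearance; rows sorted by time
        order = {s: k for k, s in enumerate(frame["id"].drop_duplicates())}
        frame = frame.sort_values(
            by=["id", "time"], key=lambda c: c.map(order) if c.name == "id" else c,
            kind="mergesort",
        ).reset_index(drop=True)
        self._frame = frame
        self.n_dropped = int(n_dropped)

    # -- basic accessors ---------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def subject_ids(self) -> np.ndarray:
        """Subject identifiers in first-appearance order."""
        return self._frame["id"].drop_duplicates().to_numpy()

    @property
    def n_subjects(self) -> int:
        return self._frame["id"].nunique()

    @property
    def n_observations(self) -> int:
        return len(self._frame)

    def observation_counts(self) -> pd.Series:
        return self._frame.groupby("id", sort=False).size()

    def __len__(self) -> int:
        return self.n_observations

    def __repr__(self) -> str:
        return (f"TrajectoryDataset(n_subjects={self.n_subjects}, "
                f"n_observations={self.n_observations}, n_dropped={self.n_dropped})")

    # -- derived datasets --------------------------------------------------
    def filter_min_observations(self, min_obs: int) -> "TrajectoryDataset":
        """Subjects with at least ``min_obs`` observations (sensitivity refits)."""
        counts = self.observation_counts()
        keep = counts.index[counts >= min_obs]
        sub = self._frame[self._frame["id"].isin(keep)]
        if len(sub) == 0:
            raise DataError(f"no subjects with >= {min_obs} observations")
        return TrajectoryDataset(sub)

    def baseline_values(self) -> pd.Series:
        """Outcome at each subject's earliest observation time."""
        first = self._frame.groupby("id", sort=False).first()
        return first["y"]


def read_long_csv(
    path,
    column_map: dict[str, str] | None = None,
    window: tuple[float, float] | None = None,
    **read_csv_kwargs,
) -> TrajectoryDataset:
    """Read a long-format delimited file into a :class:`TrajectoryDataset`.

    Parameters
    ----------
    path
        CSV file with one row per subject-visit.
    column_map
        Maps the canonical names ``id``, ``time``, ``y`` to the file's
        column names; defaults to ``{"id": "id", "time": "time", "y": "y"}``.
    window
        Optional plausibility window ``(y_min, y_max)``; rows with outcome
        outside the closed interval are dropped and counted in
        ``n_dropped`` (e.g. BMI outside 15-70 kg/m^2).
    """
    cmap = {"id": "id", "time": "time", "y": "y"}
    if column_map:
        cmap.update(column_map)
    try:
        raw = pd.read_csv(path, **read_csv_kwargs)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty input file: {path}") from exc
    missing = [v for v in cmap.values() if v not in raw.columns]
    if missing:
        raise ConfigurationError(f"missing column(s) {missing} in {path}")
    frame = raw.rename(columns={v: k for k, v in cmap.items()})
    n_dropped = 0
    if window is not None:
        y_min, y_max = window
        keep = frame["y"].between(y_min, y_max)
        n_dropped = int((~keep).sum())
        frame = frame[keep]
        if len(frame) == 0:
            raise DataError("plausibility window removed every row")
    return TrajectoryDataset(frame, n_dropped=n_dropped)


def write_long_csv(dataset: TrajectoryDataset, path) -> None:
    dataset.frame.to_csv(path, index=False)


# --------------------------------------------------------------------------
# ModelStructure: the A-G ladder
# --------------------------------------------------------------------------

#: structure code -> (number of random effects q, residual mode, random-cov mode)
_STRUCTURE_TABLE = {
    "A": (0, "common", "none"),          # fixed effects only, homoscedastic
    "B": (0, "by_class", "none"),        # fixed effects, class-specific residual variance
    "C": (1, "common", "shared"),        # random intercept
    "D": (2, "common", "shared"),        # random slope
    "E": (3, "common", "shared"),        # random quadratic, equal covariance
    "F": (3, "common", "proportional"),  # random quadratic, proportional covariance
    "G": (3, "common", "by_class"),      # random quadratic, unrestricted covariance
}

STRUCTURE_CODES: tuple[str, ...] = tuple(_STRUCTURE_TABLE)

STRUCTURE_DESCRIPTIONS = {
    "A": "Homoscedastic",
    "B": "Heteroscedastic",
    "C": "Random intercept",
    "D": "Random slope",
    "E": "Random quadratic, Equal",
    "F": "Random quadratic, Proportional",
    "G": "Random quadratic, Unrestricted",
}


@dataclass(frozen=True)
class ModelStructure:
    """One candidate model: covariance structure code, class count, degree.

    The structure code uniquely determines the random-effect order, the
    residual-variance mode (shared sigma^2 vs class-specific sigma_k^2, the
    latter only for B) and the random-effects covariance mode (absent for
    A/B, one shared matrix for C-E, shared-with-class-scale for F,
    class-specific for G).
    """

    structure_code: str
    n_classes: int
    fixed_degree: int = 2
    time_transform: TimeTransform = field(default_factory=TimeTransform)

    def __post_init__(self) -> None:
        if self.structure_code not in _STRUCTURE_TABLE:
            raise ConfigurationError(
                f"unknown structure code {self.structure_code!r}; expected one of {STRUCTURE_CODES}")
        if self.n_classes < 1:
            raise ConfigurationError("n_classes must be >= 1")
        if self.fixed_degree < 0:
            raise ConfigurationError("fixed_degree must be >= 0")
        if self.random_degree is not None and self.random_degree > self.fixed_degree:
            raise ConfigurationError(
                f"structure {self.structure_code} needs random degree {self.random_degree} "
                f"<= fixed degree {self.fixed_degree}")

    # -- derived attributes -------------------------------------------------
    @property
    def n_random(self) -> int:
        """Number of random effects q (0 for A/B, 1 for C, 2 for D, 3 for E-G)."""
        return _STRUCTURE_TABLE[self.structure_code][0]

    @property
    def random_degree(self) -> int | None:
        q = self.n_random
        return None if q == 0 else q - 1

    @property
    def residual_mode(self) -> str:
        return _STRUCTURE_TABLE[self.structure_code][1]

    @property
    def random_cov_mode(self) -> str:
        return _STRUCTURE_TABLE[self.structure_code][2]

    @property
    def description(self) -> str:
        return STRUCTURE_DESCRIPTIONS[self.structure_code]

    def with_classes(self, n_classes: int) -> "ModelStructure":
        return dataclasses.replace(self, n_classes=n_classes)

    def with_code(self, code: str) -> "ModelStructure":
        return dataclasses.replace(self, structure_code=code)


def count_parameters(structure: ModelStructure) -> int:
    """Free-parameter count p entering the BIC penalty.

    p = K*(d+1) fixed effects + (K-1) mixing proportions + random-effects
    covariance parameters (0 for A/B; q(q+1)/2 for one shared matrix, plus
    K-1 proportional scale factors for F, or K*q(q+1)/2 for G) + residual
    variances (1, or K for B).  For the quadratic model F this is
    p(K) = 5K + 5: 10, 15, ..., 40 at K = 1..7.
    """
    K = structure.n_classes
    d = structure.fixed_degree
    q = structure.n_random
    p = K * (d + 1) + (K - 1)
    tri = q * (q + 1) // 2
    mode = structure.random_cov_mode
    if mode == "shared":
        p += tri
    elif mode == "proportional":
        p += tri + (K - 1)  # omega_K = 1 fixed for identifiability
    elif mode == "by_class":
        p += K * tri
    p += K if structure.residual_mode == "by_class" else 1
    return p


# --------------------------------------------------------------------------
# Design matrices
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectDesign:
    """Per-subject outcome vector and polynomial design matrices.

    ``X`` has ``fixed_degree + 1`` columns of transformed-time powers;
    ``Z`` is the first ``q`` columns of ``X`` (empty for structures A/B).
    """

    subject_id: object
    times: np.ndarray     # natural time axis, sorted
    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray

    @property
    def n_obs(self) -> int:
        return len(self.y)


class SufficientSummaries:
    """All per-subject designs for one (dataset, structure) pair.

    Subjects sharing an identical visit-time pattern also share ``X`` and
    ``Z``; :attr:`pattern_groups` exposes that grouping so downstream code
    can factorise each marginal covariance once per pattern instead of once
    per subject.
    """

    def __init__(self, subjects: list[SubjectDesign], structure: ModelStructure) -> None:
        if not subjects:
            raise DataError("no subjects in design")
        self.subjects = subjects
        self.structure = structure
        self.subject_ids = np.array([s.subject_id for s in subjects], dtype=object)
        self.total_obs = int(sum(s.n_obs for s in subjects))
        self._groups: list[dict] | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def pattern_groups(self) -> list[dict]:
        """Group subjects by identical (rounded) visit-time pattern.

        Each group dict has keys ``X``, ``Z``, ``Y`` (m_g x n_g outcome
        matrix) and ``idx`` (subject positions).
        """
        if self._groups is None:
            buckets: dict[bytes, list[int]] = {}
            for i, s in enumerate(self.subjects):
                key = np.round(s.times, 9).tobytes()
                buckets.setdefault(key, []).append(i)
            groups = []
            for idx in buckets.values():
                ref = self.subjects[idx[0]]
                Y = np.vstack([self.subjects[i].y for i in idx])
                groups.append({"X": ref.X, "Z": ref.Z, "Y": Y,
                               "idx": np.asarray(idx, dtype=int)})
            self._groups = groups
        return self._groups


def _poly_design(t: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(t, degree + 1, increasing=True)


def build_design(dataset: TrajectoryDataset, structure: ModelStructure) -> SufficientSummaries:
    """Construct per-subject (y_i, X_i, Z_i) under the structure's transform."""
    tt = structure.time_transform
    subjects: list[SubjectDesign] = []
    for sid, sub in dataset.frame.groupby("id", sort=False):
        t_nat = sub["time"].to_numpy(dtype=float)
        t = tt.apply(t_nat)
        if not np.isfinite(t).all():
            raise DataError(f"non-finite transformed time for subject {sid!r}")
        X = _poly_design(t, structure.fixed_degree)
        Z = X[:, : structure.n_random]
        subjects.append(SubjectDesign(subject_id=sid, times=t_nat,
                                      y=sub["y"].to_numpy(dtype=float), X=X, Z=Z))
    return SufficientSummaries(subjects, structure)


# --------------------------------------------------------------------------
# FittedModel
# --------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A maximum-likelihood fit of one :class:`ModelStructure`.

    Classes are stored in canonical order (descending mixing proportion
    ``pi``), with the posterior matrix's columns permuted to match, so
    otherwise label-symmetric fits serialise identically.
    """

    structure: ModelStructure
    beta: np.ndarray                    # (K, fixed_degree+1)
    pi: np.ndarray                      # (K,)
    B: np.ndarray | None                # shared (q, q); None for A/B/G
    omega: np.ndarray | None            # (K,) class scales, model F only; omega[K-1] == 1
    B_by_class: np.ndarray | None       # (K, q, q), model G only
    sigma2: np.ndarray                  # (1,) common or (K,) for model B
    loglik: float
    n_subjects: int
    n_params: int
    posterior: np.ndarray               # (N, K)
    assignment: np.ndarray              # (N,) modal class indices
    subject_ids: np.ndarray
    converged: bool
    n_iter: int
    n_starts_used: int
    seed: int
    warnings_: list[str] = field(default_factory=list)
    loglik_trace: np.ndarray | None = None  # per-iteration l of the winning start

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if abs(self.pi.sum() - 1.0) > 1e-8 or (self.pi < -1e-12).any():
            raise ValueError("mixing proportions must be a probability vector")
        rows = self.posterior.sum(axis=1)
        if np.abs(rows - 1.0).max() > 1e-10:
            raise ValueError("posterior rows must sum to 1 within 1e-10")

    # -- covariance access --------------------------------------------------
    @property
    def n_classes(self) -> int:
        return self.structure.n_classes

    def class_random_cov(self, k: int) -> np.ndarray:
        """Effective random-effects covariance B_k of class k (q x q)."""
        q = self.structure.n_random
        mode = self.structure.random_cov_mode
        if mode == "none":
            return np.zeros((q, q))
        if mode == "shared":
            return self.B
        if mode == "proportional":
            return self.omega[k] ** 2 * self.B
        return self.B_by_class[k]

    def class_sigma2(self, k: int) -> float:
        if self.structure.residual_mode == "by_class":
            return float(self.sigma2[k])
        return float(self.sigma2[0])

    def mean_trajectory(self, times: np.ndarray, k: int) -> np.ndarray:
        """Class-k fitted mean curve evaluated on the natural time axis."""
        t = self.structure.time_transform.apply(np.asarray(times, dtype=float))
        X = _poly_design(t, self.structure.fixed_degree)
        return X @ self.beta[k]

    # -- serialisation -------------------------------------------------------
    def to_dict(self) -> dict:
        s = self.structure
        return {
            "structure": {
                "structure_code": s.structure_code,
                "n_classes": s.n_classes,
                "fixed_degree": s.fixed_degree,
                "time_transform": {"center": s.time_transform.center,
                                   "scale": s.time_transform.scale},
            },
            "beta": self.beta.tolist(),
            "pi": self.pi.tolist(),
            "B": None if self.B is None else self.B.tolist(),
            "omega": None if self.omega is None else self.omega.tolist(),
            "B_by_class": None if self.B_by_class is None else self.B_by_class.tolist(),
            "sigma2": self.sigma2.tolist(),
            "loglik": self.loglik,
            "n_subjects": self.n_subjects,
            "n_params": self.n_params,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_starts_used": self.n_starts_used,
            "seed": self.seed,
            "warnings": list(self.warnings_),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict, posterior: np.ndarray | None = None,
                  subject_ids: np.ndarray | None = None) -> "FittedModel":
        s = d["structure"]
        structure = ModelStructure(
            structure_code=s["structure_code"], n_classes=s["n_classes"],
            fixed_degree=s["fixed_degree"],
            time_transform=TimeTransform(**s["time_transform"]))
        K = structure.n_classes
        if posterior is None:
            posterior = np.full((1, K), 1.0 / K)
        if subject_ids is None:
            subject_ids = np.arange(posterior.shape[0])
        return cls(
            structure=structure,
            beta=np.asarray(d["beta"], dtype=float),
            pi=np.asarray(d["pi"], dtype=float),
            B=None if d["B"] is None else np.asarray(d["B"], dtype=float),
            omega=None if d["omega"] is None else np.asarray(d["omega"], dtype=float),
            B_by_class=None if d["B_by_class"] is None else np.asarray(d["B_by_class"], dtype=float),
            sigma2=np.asarray(d["sigma2"], dtype=float),
            loglik=float(d["loglik"]),
            n_subjects=int(d["n_subjects"]),
            n_params=int(d["n_params"]),
            posterior=np.asarray(posterior, dtype=float),
            assignment=np.argmax(posterior, axis=1),
            subject_ids=np.asarray(subject_ids, dtype=object),
            converged=bool(d["converged"]),
            n_iter=int(d["n_iter"]),
            n_starts_used=int(d["n_starts_used"]),
            seed=int(d["seed"]),
            warnings_=list(d.get("warnings", [])),
        )

    @classmethod
    def load_json(cls, path, posterior=None, subject_ids=None) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh), posterior=posterior, subject_ids=subject_ids)


def posterior_to_frame(model: FittedModel) -> pd.DataFrame:
    """Posterior matrix as a table with header ``id, class_1..class_K, assigned``."""
    K = model.n_classes
    out = pd.DataFrame({"id": model.subject_ids})
    for k in range(K):
        out[f"class_{k + 1}"] = model.posterior[:, k]
    out["assigned"] = model.assignment + 1
    return out
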