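"""Domain types, CSV readers/writers and design-matrix construction.

The package works with two tidy, UTF-8, comma-separated file schemas:

* longitudinal: ``subject_id, time, outcome, value`` plus one column per
  subject-level covariate (e.g. ``gender``), one row per
  (subject, outcome, visit);
* survival: ``subject_id, time, event`` plus baseline-covariate columns,
  one row per subject.

A :class:`ModelSpec` declares the model family: the K outcome labels, the
fixed-effect terms per outcome (``intercept``, ``time``, ``time2`` or a
covariate column name), the random-effect terms (a subset of the fixed
terms), the survival covariates and which random effects are linked into
the hazard.  Design-matrix columns are ordered exactly as declared, so the
coefficient indices are unambiguous: for the default growth model the fixed
row is ``(1, Age, Age^2, Gender)`` and the random row ``(1, Age)``.

Outcome values are *not* standardised internally; ``standardize_outcomes``
offers an optional z-score preprocessing step, default off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "SpecError",
    "ModelSpec",
    "LongitudinalDataset",
    "SurvivalDataset",
    "DesignMatrices",
    "read_longitudinal",
    "write_longitudinal",
    "read_survival",
    "write_survival",
    "build_designs",
    "standardize_outcomes",
]

_STRUCTURAL_TERMS = ("intercept", "time", "time2")


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class ValidationError(ValueError):
    """Input data violate a dataset invariant."""


class SpecError(ValueError):
    """A model specification references an unknown term or is inconsistent."""


@dataclass(frozen=True)
class ModelSpec:
    """Structure of the K-variate mixed model and the linked hazard.

    ``fixed_terms`` and ``random_terms`` are shared across outcomes (each of
    the K outcomes has the same design with its own coefficient vector);
    ``random_terms`` must be a subset of ``fixed_terms``.  ``linkage``
    selects which random effects enter the hazard as ``(outcome, term)``
    pairs; ``None`` links them all, in outcome-major order
    ``(b_{i,0,1}, b_{i,1,1}, ..., b_{i,0,K}, b_{i,1,K})``.
    """

    outcomes: tuple[str, ...] = ("height", "weight")
    fixed_terms: tuple[str, ...] = ("intercept", "time", "time2", "gender")
    random_terms: tuple[str, ...] = ("intercept", "time")
    survival_covariates: tuple[str, ...] = (
        "finland",
        "germany",
        "sweden",
        "gender",
        "hla",
        "fdr",
    )
    linkage: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        if len(self.outcomes) < 1:
            raise SpecError("at least one outcome is required")
        if len(set(self.outcomes)) != len(self.outcomes):
            raise SpecError("outcome labels must be unique")
        if not self.fixed_terms:
            raise SpecError("fixed_terms must be non-empty")
        missing = set(self.random_terms) - set(self.fixed_terms)
        if missing:
            raise SpecError(f"random terms not in the fixed-term span: {sorted(missing)}")
        if self.linkage is not None:
            for outcome, term in self.linkage:
                if outcome not in self.outcomes or term not in self.random_terms:
                    raise SpecError(f"unknown linkage entry {(outcome, term)}")

    @property
    def n_outcomes(self) -> int:
        return len(self.outcomes)

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_terms)

    @property
    def n_random(self) -> int:
        return len(self.random_terms)

    @property
    def covariate_columns(self) -> tuple[str, ...]:
        """Covariate columns required in the longitudinal file."""
        return tuple(t for t in self.fixed_terms if t not in _STRUCTURAL_TERMS)

    def linked_indices(self) -> np.ndarray:
        """Indices into the flat random-effect vector that enter the hazard."""
        q = self.n_random
        if self.linkage is None:
            return np.arange(self.n_outcomes * q)
        idx = []
        for outcome, term in self.linkage:
            k = self.outcomes.index(outcome)
            idx.append(k * q + self.random_terms.index(term))
        return np.asarray(idx, dtype=int)


def _check_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file is missing columns {missing}")


class LongitudinalDataset:
    """Repeated measures of K outcomes with visit times and covariates.

    Rows are stored sorted by (subject, outcome, time).  Invariants: outcome
    labels drawn from the declared set, no missing values in required or
    covariate columns, strictly increasing visit times within every
    (subject, outcome) series, and covariates constant within subject.
    """

    REQUIRED = ("subject_id", "time", "outcome", "value")

    def __init__(self, df: pd.DataFrame, outcomes, covariates=()):
        self.outcomes = tuple(outcomes)
        self.covariates = tuple(covariates)
        _check_columns(df, self.REQUIRED + self.covariates, "longitudinal")
        df = df.loc[:, list(self.REQUIRED + self.covariates)].copy()
        if df[list(self.REQUIRED + self.covariates)].isna().any().any():
            raise ValidationError("longitudinal data contain missing values")
        unknown = set(df["outcome"]) - set(self.outcomes)
        if unknown:
            raise ValidationError(f"undeclared outcome labels: {sorted(unknown)}")
        df = df.sort_values(["subject_id", "outcome", "time"], kind="mergesort")
        df = df.reset_index(drop=True)
        for (sid, _), grp in df.groupby(["subject_id", "outcome"], sort=False):
            t = grp["time"].to_numpy(float)
            if np.any(np.diff(t) <= 0):
                raise ValidationError(
                    f"visit times not strictly increasing for subject {sid!r}"
                )
        for cov in self.covariates:
            per_subject = df.groupby("subject_id")[cov].nunique()
            bad = per_subject[per_subject > 1]
            if len(bad):
                raise ValidationError(
                    f"covariate {cov!r} varies within subject {bad.index[0]!r}"
                )
        self.df = df

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.df["subject_id"].to_numpy())

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def covariate_table(self) -> pd.DataFrame:
        """One row per subject with its (constant) covariate values."""
        cols = ["subject_id", *self.covariates]
        return (
            self.df[cols].drop_duplicates("subject_id").set_index("subject_id").sort_index()
        )

    def equals(self, other: "LongitudinalDataset", rtol: float = 1e-9) -> bool:
        if self.outcomes != other.outcomes or self.covariates != other.covariates:
            return False
        a, b = self.df, other.df
        if len(a) != len(b):
            return False
        if not (a["subject_id"].to_numpy() == b["subject_id"].to_numpy()).all():
            return False
        if not (a["outcome"].to_numpy() == b["outcome"].to_numpy()).all():
            return False
        num = ["time", "value", *self.covariates]
        return bool(
            np.allclose(a[num].to_numpy(float), b[num].to_numpy(float), rtol=rtol)
        )


class SurvivalDataset:
    """Per-subject observed time, event indicator and baseline covariates.

    ``time`` is the observed follow-up ``T_i = min(T_i*, C_i)`` and ``event``
    is 1 when the event was observed, 0 under censoring.  One row per
    subject; times must be positive.
    """

    REQUIRED = ("subject_id", "time", "event")

    def __init__(self, df: pd.DataFrame, covariates=()):
        self.covariates = tuple(covariates)
        _check_columns(df, self.REQUIRED + self.covariates, "survival")
        df = df.loc[:, list(self.REQUIRED + self.covariates)].copy()
        if df.isna().any().any():
            raise ValidationError("survival data contain missing values")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValidationError(f"duplicate survival row for subject {dup!r}")
        if not (df["time"].to_numpy(float) > 0).all():
            raise ValidationError("observed times must be positive")
        ev = df["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise ValidationError("event indicator must be 0 or 1")
        df = df.sort_values("subject_id", kind="mergesort").reset_index(drop=True)
        df["event"] = df["event"].astype(int)
        self.df = df

    @property
    def subjects(self) -> np.ndarray:
        return self.df["subject_id"].to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    @property
    def n_events(self) -> int:
        return int(self.df["event"].sum())

    def covariate_matrix(self, columns=None) -> np.ndarray:
        cols = list(self.covariates if columns is None else columns)
        return self.df[cols].to_numpy(float)

    def equals(self, other: "SurvivalDataset", rtol: float = 1e-9) -> bool:
        if self.covariates != other.covariates or len(self.df) != len(other.df):
            return False
        if not (self.subjects == other.subjects).all():
            return False
        num = ["time", "event", *self.covariates]
        return bool(
            np.allclose(
                self.df[num].to_numpy(float), other.df[num].to_numpy(float), rtol=rtol
            )
        )


def read_longitudinal(path, spec: ModelSpec) -> LongitudinalDataset:
    """Read and validate a tidy longitudinal CSV against ``spec``."""
    df = pd.read_csv(path)
    return LongitudinalDataset(df, spec.outcomes, spec.covariate_columns)


def write_longitudinal(data: LongitudinalDataset, path) -> None:
    data.df.to_csv(path, index=False)


def read_survival(path, spec: ModelSpec) -> SurvivalDataset:
    """Read and validate a per-subject survival CSV against ``spec``."""
    df = pd.read_csv(path)
    return SurvivalDataset(df, spec.survival_covariates)


def write_survival(data: SurvivalDataset, path) -> None:
    data.df.to_csv(path, index=False)


def _term_column(term: str, time: np.ndarray, cov: Mapping[str, np.ndarray]):
    if term == "intercept":
        return np.ones_like(time)
    if term == "time":
        return time
    if term == "time2":
        return time**2
    if term in cov:
        return cov[term]
    raise SpecError(f"unknown design term {term!r}")


@dataclass
class DesignMatrices:
    """Stacked fixed/random design rows aligned across outcomes.

    One row per (subject, visit); the outcome dimension lives in the columns
    of ``y``.  ``subject_index`` maps each row to ``subjects``.  Row order is
    (subject, time) ascending, independent of input row order.
    """

    x: np.ndarray  # (M, p) fixed-effects rows
    z: np.ndarray  # (M, q) random-effects rows
    y: np.ndarray  # (M, K) outcome values, columns in spec.outcomes order
    time: np.ndarray  # (M,)
    subject_index: np.ndarray  # (M,) int
    subjects: np.ndarray  # unique subject ids, ascending
    spec: ModelSpec = field(repr=False, default=None)

    @property
    def n_rows(self) -> int:
        return self.x.shape[0]

    def rows_for(self, subject) -> np.ndarray:
        (idx,) = np.nonzero(self.subjects == subject)
        if len(idx) == 0:
            raise KeyError(subject)
        return np.nonzero(self.subject_index == idx[0])[0]


def build_designs(data: LongitudinalDataset, spec: ModelSpec) -> DesignMatrices:
    """Build X/Z design rows and the aligned outcome matrix.

    The joint error model shares one latent per visit across outcomes, so
    every subject must have the *same* visit times for all K outcomes; a
    subject with misaligned series raises :class:`ValidationError`.
    Deterministic and invariant to input row permutations (rows are sorted
    internally).
    """
    for term in spec.fixed_terms:
        if term not in _STRUCTURAL_TERMS and term not in data.covariates:
            raise SpecError(f"unknown design term {term!r}")
    wide = data.df.pivot(index=["subject_id", "time"], columns="outcome", values="value")
    missing_out = [o for o in spec.outcomes if o not in wide.columns]
    if missing_out and len(data.df):
        raise ValidationError(f"no observations for outcomes {missing_out}")
    if len(data.df) == 0:
        empty = np.empty((0,))
        return DesignMatrices(
            x=np.empty((0, spec.n_fixed)),
            z=np.empty((0, spec.n_random)),
            y=np.empty((0, spec.n_outcomes)),
            time=empty,
            subject_index=np.empty((0,), dtype=int),
            subjects=np.empty((0,)),
            spec=spec,
        )
    wide = wide[list(spec.outcomes)].sort_index()
    if wide.isna().any().any():
        sid = wide[wide.isna().any(axis=1)].index[0][0]
        raise ValidationError(
            f"visit times are not aligned across outcomes for subject {sid!r}"
        )
    sid = wide.index.get_level_values("subject_id").to_numpy()
    time = wide.index.get_level_values("time").to_numpy(float)
    subjects, subject_index = np.unique(sid, return_inverse=True)
    covtab = data.covariate_table().loc[subjects]
    cov = {c: covtab[c].to_numpy(float)[subject_index] for c in data.covariates}
    x = np.column_stack([_term_column(t, time, cov) for t in spec.fixed_terms])
    z = np.column_stack([_term_column(t, time, cov) for t in spec.random_terms])
    return DesignMatrices(
        x=x,
        z=z,
        y=wide.to_numpy(float),
        time=time,
        subject_index=subject_index,
        subjects=subjects,
        spec=spec,
    )


def standardize_outcomes(data: LongitudinalDataset):
    """Optional z-score preprocessing per outcome (off by default everywhere).

    Returns the transformed dataset and a dict ``{outcome: (mean, sd)}`` so
    fitted values can be mapped back to the original scale.
    """
    df = data.df.copy()
    params: dict[str, tuple[float, float]] = {}
    for outcome in data.outcomes:
        mask = df["outcome"] == outcome
        vals = df.loc[mask, "value"].to_numpy(float)
        mu, sd = float(vals.mean()), float(vals.std(ddof=1))
        if sd == 0:
            raise ValidationError(f"outcome {outcome!r} has zero variance")
        df.loc[mask, "value"] = (vals - mu) / sd
        params[outcome] = (mu, sd)
    return LongitudinalDataset(df, data.outcomes, data.covariates), params
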