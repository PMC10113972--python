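"""Synthetic trauma-cohort tables for exercising the statistics battery.

Covariates are drawn independently conditional on pneumonia status from
truncated normals (the configured mean/SD are the pre-truncation parameters);
severity is derived from the drawn contusion ratio via the 20% rule, and age
is drawn conditional on severity.  Complication flags use small
severity-conditional probabilities purely to exercise the 2x2-test code
paths.  Only marginal group summaries are modeled — no cross-covariate
correlation structure is assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import ConfigError, SchemaError
from .volumetrics import classify_severity

__all__ = [
    "CohortConfig",
    "simulate_cohort",
    "cohort_to_csv",
    "cohort_from_csv",
    "REQUIRED_COLUMNS",
]

REQUIRED_COLUMNS = [
    "id",
    "age",
    "sex",
    "mechanism",
    "iss",
    "chest_ais",
    "gcs",
    "lactate",
    "contusion_ratio",
    "severity",
    "pneumonia",
    "ards",
    "mortality",
]

MECHANISMS = ("MVC", "fall", "crush", "stab", "assault")


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; defaults calibrated to the printed group summaries."""

    n: int = 73
    p_pneumonia: float = 28 / 73
    p_male: float = 56 / 73
    # (mean, sd) conditional on pneumonia status: {covariate: (pneumonia, no-pneumonia)}
    by_pneumonia: dict = field(
        default_factory=lambda: {
            "contusion_ratio": ((33.04, 11.4), (18.3, 8.5)),
            "gcs": ((11.3, 4.1), (14.8, 1.0)),
            "iss": ((26.0, 9.4), (20.0, 7.8)),
            "lactate": ((4.9, 3.6), (3.0, 2.1)),
        }
    )
    # (mean, sd) of age conditional on derived severity
    age_by_severity: dict = field(
        default_factory=lambda: {"moderate": (39.3, 16.1), "severe": (50.9, 13.7)}
    )
    # severity-conditional complication probabilities
    p_ards: dict = field(default_factory=lambda: {"moderate": 0.0, "severe": 5 / 38})
    p_mortality: dict = field(default_factory=lambda: {"moderate": 0.0, "severe": 2 / 38})
    bounds: dict = field(
        default_factory=lambda: {
            "contusion_ratio": (0.0, 100.0),
            "gcs": (3.0, 15.0),
            "iss": (1.0, 75.0),
            "lactate": (0.0, np.inf),
            "age": (0.0, 120.0),
        }
    )
    seed: int = 0

    def __post_init__(self):
        if self.n < 0:
            raise ConfigError("n must be >= 0")
        for name, p in (("p_pneumonia", self.p_pneumonia), ("p_male", self.p_male)):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        for cov, groups in self.by_pneumonia.items():
            for mean, sd in groups:
                if sd <= 0:
                    raise ConfigError(f"{cov}: SD must be > 0, got {sd}")
        for sev, (mean, sd) in self.age_by_severity.items():
            if sd <= 0:
                raise ConfigError(f"age[{sev}]: SD must be > 0, got {sd}")
        for d in (self.p_ards, self.p_mortality):
            for sev, p in d.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"probability for {sev} must be in [0, 1], got {p}")


def _truncated(rng, mean, sd, lo, hi, size):
    a = (lo - mean) / sd
    b = (hi - mean) / sd if np.isfinite(hi) else np.inf
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Draw a synthetic patient table; fixed seed gives a reproducible table."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n

    pneumonia = rng.random(n) < config.p_pneumonia
    cols: dict[str, np.ndarray] = {}
    for cov, (params_p, params_np) in config.by_pneumonia.items():
        lo, hi = config.bounds[cov]
        vals = np.empty(n)
        for flag, (mean, sd) in ((True, params_p), (False, params_np)):
            idx = pneumonia == flag
            if idx.any():
                vals[idx] = _truncated(rng, mean, sd, lo, hi, int(idx.sum()))
        cols[cov] = vals
    cols["gcs"] = np.clip(np.round(cols["gcs"]), 3, 15).astype(int)

    severity = np.array([classify_severity(r) for r in cols["contusion_ratio"]])
    age = np.empty(n)
    lo, hi = config.bounds["age"]
    for sev, (mean, sd) in config.age_by_severity.items():
        idx = severity == sev
        if idx.any():
            age[idx] = _truncated(rng, mean, sd, lo, hi, int(idx.sum()))

    ards = np.zeros(n, dtype=bool)
    mortality = np.zeros(n, dtype=bool)
    for sev in ("moderate", "severe"):
        idx = severity == sev
        ards[idx] = rng.random(int(idx.sum())) < config.p_ards.get(sev, 0.0)
        mortality[idx] = rng.random(int(idx.sum())) < config.p_mortality.get(sev, 0.0)

    sex = np.where(rng.random(n) < config.p_male, "M", "F")
    mechanism = rng.choice(MECHANISMS, size=n, p=(0.5, 0.25, 0.1, 0.1, 0.05))
    chest_ais = np.clip(np.round(_truncated(rng, 3.1, 0.8, 0, 6, n)), 0, 6).astype(int)

    # blood gas: ARDS patients get P/F <= 200 by construction, others above
    fio2 = np.round(rng.uniform(0.3, 0.8, n), 2)
    pf = np.where(ards, rng.uniform(80, 200, n), rng.uniform(220, 450, n))
    pao2 = np.round(pf * fio2, 1)

    table = pd.DataFrame(
        {
            "id": [f"P{i:05d}" for i in range(n)],
            "age": np.round(age, 1),
            "sex": sex,
            "mechanism": mechanism,
            "iss": cols["iss"],
            "chest_ais": chest_ais,
            "gcs": cols["gcs"],
            "lactate": cols["lactate"],
            "contusion_ratio": cols["contusion_ratio"],
            "severity": severity,
            "pneumonia": pneumonia,
            "ards": ards,
            "mortality": mortality,
            "pao2": pao2,
            "fio2": fio2,
        }
    )
    return table


def cohort_to_csv(table: pd.DataFrame, path) -> None:
    """Write the cohort table as CSV (lossless for the documented columns)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table missing required columns: {missing}")
    table.to_csv(path, index=False)


def cohort_from_csv(path) -> pd.DataFrame:
    """Read a cohort CSV, validating the schema; unknown columns are kept."""
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort CSV missing required columns: {missing}")
    extra = [c for c in table.columns if c not in REQUIRED_COLUMNS + ["pao2", "fio2"]]
    if extra:
        warnings.warn(f"cohort CSV has unrecognized columns (kept): {extra}", stacklevel=2)
    for col in ("pneumonia", "ards", "mortality"):
        table[col] = table[col].astype(bool)
    return table
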