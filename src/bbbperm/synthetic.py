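"""Synthetic data emulating the statistical structure the pipeline assumes.

Two generator families:

* noisy Soczewinski-Wachtmeister retention series — a straight line
  log k = log_kw - s*phi plus iid Gaussian noise on log k, mirroring how
  isocratic retention behaves over the organic-modifier range used in
  reversed-phase work (default noise 0.02 log units, a typical replicate
  scatter for averaged retention times);

* descriptor tables with a known linear log BB ground truth — descriptors
  drawn independently and uniformly over the ranges observed for small
  drug-like azole solutes, response built from stored true coefficients
  plus Gaussian noise (default 0.13 log units, matching the residual SD of
  a well-calibrated solvation-parameter model).

Everything is seeded and bit-reproducible; zero noise composed with the
matching fitter recovers the generating parameters exactly, which is the
backbone identity the test suite leans on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateDesignError, InsufficientDataError

__all__ = [
    "RetentionSimSpec",
    "ModelSimSpec",
    "DEFAULT_DESCRIPTOR_RANGES",
    "DEFAULT_TRUE_COEFFICIENTS",
    "gen_retention_series",
    "gen_training_table",
    "recovery_report",
]

# Observed descriptor ranges for the drug-like solutes this package models.
DEFAULT_DESCRIPTOR_RANGES: dict[str, tuple[float, float]] = {
    "E": (0.87, 2.90),
    "S": (0.92, 3.18),
    "A": (0.0, 0.75),
    "B": (0.80, 2.05),
    "V": (1.1, 3.0),
}

# Plausible solvation-parameter coefficients (intercept first).
DEFAULT_TRUE_COEFFICIENTS: dict[str, float] = {
    "intercept": 0.934,
    "E": 0.191,
    "S": -0.605,
    "A": -0.743,
    "B": -0.768,
    "V": 0.545,
}


@dataclass(frozen=True)
class RetentionSimSpec:
    """Ground truth and noise level for one synthetic retention series."""

    true_log_kw: float = 2.0
    true_s: float = 4.0
    phi_grid: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6)
    noise_sd: float = 0.02
    seed: int | None = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        grid = np.asarray(self.phi_grid, dtype=float)
        if np.any(grid <= 0) or np.any(grid >= 1):
            raise ValueError("phi_grid values must lie in (0, 1)")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("phi_grid must be strictly increasing")


@dataclass(frozen=True)
class ModelSimSpec:
    """Ground truth for a synthetic descriptor table with linear response."""

    n_compounds: int = 65
    true_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_TRUE_COEFFICIENTS)
    )
    descriptor_ranges: dict = field(
        default_factory=lambda: dict(DEFAULT_DESCRIPTOR_RANGES)
    )
    noise_sd: float = 0.13
    seed: int | None = None

    def __post_init__(self):
        if "intercept" not in self.true_coefficients:
            raise ValueError("true_coefficients must include 'intercept'")
        names = self.descriptor_names
        missing = [d for d in names if d not in self.descriptor_ranges]
        if missing:
            raise ValueError(
                "descriptor_ranges missing: " + ", ".join(missing)
            )
        if self.n_compounds <= len(names) + 1:
            raise ValueError(
                f"n_compounds must exceed {len(names) + 1} for "
                f"{len(names)} descriptors"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def descriptor_names(self) -> tuple[str, ...]:
        return tuple(k for k in self.true_coefficients if k != "intercept")


def gen_retention_series(spec: RetentionSimSpec) -> pd.DataFrame:
    """Simulate (phi, log_k) points on the generating line plus noise."""
    grid = np.asarray(spec.phi_grid, dtype=float)
    if grid.size < 3:
        raise InsufficientDataError(
            f"phi_grid needs >= 3 points, got {grid.size}"
        )
    rng = np.random.default_rng(spec.seed)
    log_k = spec.true_log_kw - spec.true_s * grid
    if spec.noise_sd > 0:
        log_k = log_k + rng.normal(0.0, spec.noise_sd, size=grid.size)
    return pd.DataFrame({"phi": grid, "log_k": log_k})


def gen_training_table(spec: ModelSimSpec) -> pd.DataFrame:
    """Simulate a descriptor table with a linear log BB ground truth.

    Returns a DataFrame with one column per descriptor plus ``log_bb``;
    the generating coefficients and noise level travel in ``df.attrs``.
    """
    names = spec.descriptor_names
    rng = np.random.default_rng(spec.seed)
    data = {}
    for name in names:
        lo, hi = spec.descriptor_ranges[name]
        if not hi > lo:
            raise DegenerateDesignError(
                f"descriptor {name}: degenerate sampling range [{lo}, {hi}]"
            )
        data[name] = rng.uniform(lo, hi, size=spec.n_compounds)
    df = pd.DataFrame(data)
    y = np.full(spec.n_compounds, spec.true_coefficients["intercept"])
    for name in names:
        y = y + spec.true_coefficients[name] * df[name].to_numpy()
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=spec.n_compounds)
    df["log_bb"] = y
    df.attrs["true_coefficients"] = dict(spec.true_coefficients)
    df.attrs["noise_sd"] = spec.noise_sd
    return df


def recovery_report(spec: ModelSimSpec, replicates: int = 100) -> pd.DataFrame:
    """Monte-Carlo parameter-recovery summary for the OLS fitter.

    For each replicate, generates a table under ``spec`` (with a
    replicate-specific child seed), fits OLS of log_bb on the descriptors,
    and accumulates estimate - truth.  Returns a DataFrame indexed by
    coefficient name with columns ``truth``, ``bias`` and ``rmse``.
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    from .regression import OLSModel  # local import avoids cycle at import time

    names = spec.descriptor_names
    coef_names = ("intercept",) + names
    truth = np.array([spec.true_coefficients[c] for c in coef_names])
    seeds = np.random.SeedSequence(spec.seed).spawn(replicates)
    errors = np.empty((replicates, truth.size))
    for r, child in enumerate(seeds):
        rep_spec = ModelSimSpec(
            n_compounds=spec.n_compounds,
            true_coefficients=spec.true_coefficients,
            descriptor_ranges=spec.descriptor_ranges,
            noise_sd=spec.noise_sd,
            seed=child,
        )
        df = gen_training_table(rep_spec)
        model = OLSModel().fit(df[list(names)], df["log_bb"])
        est = np.concatenate([[model.intercept_], model.coef_])
        errors[r] = est - truth
    return pd.DataFrame(
        {
            "truth": truth,
            "bias": errors.mean(axis=0),
            "rmse": np.sqrt((errors**2).mean(axis=0)),
        },
        index=list(coef_names),
    )
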