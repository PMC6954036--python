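"""Per-species life-history traits and the analysis-ready trait matrix.

For each retained, truncation-eligible species eight traits are derived from
its MPM: generation time T, mean life expectancy η_e, mean survival σ, mature
life expectancy L_{α−ω}, degree of iteroparity S (Demetrius entropy), mean
sexual reproduction φ, growth γ and shrinkage ρ (the latter six SSD-weighted
or computed on the truncated age schedules).  Keyfitz entropy H rides along
as the senescence response variable; it is not a PCA input.

The trait matrix is prepared for multivariate analysis the way comparative
life-history studies do it: natural-log transform (traits that can be zero
are shifted by ε = half the smallest positive observed value), per-trait
outlier masking outside the 2.5th–97.5th percentiles of the logged
distribution, and standardization to mean 0, variance 1.  Any value that
cannot be computed is an explicit missing value — never a silent zero — and
is later a candidate for imputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import life_tables, mpm_core
from .mpm_core import MPM, ContractViolation, MPMError
from .selection import ReproductionMode, classify_reproduction_mode

__all__ = [
    "PCA_TRAITS",
    "TraitVector",
    "TraitMatrix",
    "derive_traits",
    "build_trait_matrix",
]

#: the eight ordination traits, in their conventional order
PCA_TRAITS = ["T", "eta_e", "sigma", "L_am", "S", "phi", "gamma", "rho"]

#: traits that can legitimately equal zero and therefore get the shifted log
ZERO_OK = {"gamma", "rho", "S"}


@dataclass
class TraitVector:
    """One species' trait values; NaN marks a missing (uncomputable) value."""

    species_id: str
    T: float = math.nan
    eta_e: float = math.nan
    sigma: float = math.nan
    L_am: float = math.nan
    S: float = math.nan
    phi: float = math.nan
    gamma: float = math.nan
    rho: float = math.nan
    H: float = math.nan
    mode: Optional[ReproductionMode] = None
    trunc: Optional[life_tables.TruncationRecord] = None
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def eligible(self) -> bool:
        """Truncation-rule eligibility: the cohort dies (l_x < 0.01) before
        its structure converges to the quasi-stationary distribution."""
        return bool(self.trunc and self.trunc.eligible)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in PCA_TRAITS + ["H"]}


@dataclass
class TraitMatrix:
    """Species × traits table with its transform state.

    ``values`` holds the current (possibly logged/standardized) trait columns;
    ``mask`` is True where a value is missing or was masked as an outlier.
    Standardization parameters are kept so the transform round-trips.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    logged: bool = False
    standardized: bool = False
    outliers_masked: bool = False
    log_eps: dict[str, float] = field(default_factory=dict)
    outlier_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    col_means: Optional[pd.Series] = None
    col_stds: Optional[pd.Series] = None
    H: Optional[pd.Series] = None
    modes: Optional[pd.Series] = None

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.index)

    def destandardize(self) -> pd.DataFrame:
        if not self.standardized:
            return self.values.copy()
        return self.values * self.col_stds + self.col_means


def derive_traits(
    m: MPM,
    include_clonal: bool = True,
    span_variant: life_tables.SpanVariant = life_tables.SpanVariant.TABLE1,
    qsd_threshold: float = 0.10,
    lx_threshold: float = 0.01,
    max_age: int = 1000,
) -> TraitVector:
    """Compose the full per-species derivation: eigen-system, fundamental
    matrix, age trajectories, truncation, entropies, SSD-weighted rates.

    Component failures (λ = 1 so T undefined, no reproduction in the window,
    etc.) are recorded as missing trait values, not raised: one species'
    quirk must not abort a comparative analysis.
    """
    tv = TraitVector(species_id=m.species_id)
    try:
        tv.mode = classify_reproduction_mode(m)
    except MPMError as e:
        tv.errors["mode"] = str(e)

    try:
        eigen = mpm_core.dominant_eigen(m)
    except MPMError as e:
        tv.errors["eigen"] = str(e)
        return tv

    try:
        tv.T = mpm_core.generation_time(m, include_clonal=include_clonal)
    except MPMError as e:
        tv.errors["T"] = str(e)

    try:
        sigma, phi, gamma, rho = mpm_core.ssd_weighted_rates(m, eigen)
        tv.sigma, tv.phi, tv.gamma, tv.rho = sigma, phi, gamma, rho
    except MPMError as e:
        tv.errors["rates"] = str(e)

    try:
        c0 = life_tables.recruit_distribution(m, include_clonal=include_clonal)
        tv.eta_e = mpm_core.mean_life_expectancy(m, c0)
        traj = life_tables.age_trajectories(m, c0, max_age=max_age)
        trunc = life_tables.qsd_truncate(
            traj, m, qsd_threshold=qsd_threshold, lx_threshold=lx_threshold
        )
    except MPMError as e:
        tv.errors["trajectories"] = str(e)
        return tv
    tv.trunc = trunc.trunc

    try:
        tv.H = life_tables.keyfitz_entropy(trunc.lx)
    except MPMError as e:
        tv.errors["H"] = str(e)

    try:
        tv.S = life_tables.demetrius_entropy(
            trunc.lx, trunc.mx, trunc.cx, lam=eigen.lam, include_clonal=include_clonal
        )
    except MPMError as e:
        tv.errors["S"] = str(e)

    try:
        _, _, span = life_tables.reproductive_span(
            trunc, eta_e=tv.eta_e, variant=span_variant, include_clonal=include_clonal
        )
        tv.L_am = span
    except MPMError as e:
        tv.errors["L_am"] = str(e)
    return tv


def build_trait_matrix(
    collection: Sequence[TraitVector],
    pcts: tuple[float, float] = (2.5, 97.5),
) -> TraitMatrix:
    """Assemble, log-transform, outlier-mask and standardize the trait matrix.

    Steps per trait column: (1) non-positive values of strictly-positive
    traits become missing, then natural log; zero-tolerant traits (γ, ρ, S)
    use log(x + ε) with ε = half the smallest positive observed value;
    (2) logged values outside the [2.5th, 97.5th] percentile band of their
    column are masked to missing (bounds recorded, so re-application is
    idempotent); (3) columns standardized to mean 0, variance 1 (sample
    variance) over the surviving values.
    """
    if len(collection) < 3:
        raise ContractViolation("need at least 3 species to build a trait matrix")
    raw = pd.DataFrame(
        {tv.species_id: tv.as_dict() for tv in collection}
    ).T.astype(float)
    raw.index.name = "species_id"
    H = raw.pop("H")
    modes = pd.Series(
        {tv.species_id: (tv.mode.value if tv.mode else None) for tv in collection},
        name="mode",
    )

    logged = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    log_eps: dict[str, float] = {}
    for col in raw.columns:
        x = raw[col].to_numpy(dtype=float)
        if col in ZERO_OK:
            pos = x[np.isfinite(x) & (x > 0)]
            if pos.size == 0:
                raise ContractViolation(
                    f"trait column {col!r} has no positive values to anchor log(x + eps)"
                )
            eps = 0.5 * float(pos.min())
            log_eps[col] = eps
            with np.errstate(invalid="ignore"):
                y = np.where(x >= 0, np.log(x + eps), np.nan)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                y = np.where(x > 0, np.log(x), np.nan)
        logged[col] = y

    bounds: dict[str, tuple[float, float]] = {}
    masked = logged.copy()
    for col in logged.columns:
        y = logged[col].to_numpy(dtype=float)
        if np.isfinite(y).sum() == 0:
            raise ContractViolation(f"trait column {col!r} is entirely missing")
        lo, hi = np.nanpercentile(y, pcts)
        bounds[col] = (float(lo), float(hi))
        out = (y < lo) | (y > hi)
        masked.loc[out, col] = np.nan

    means = masked.mean()
    stds = masked.std(ddof=1)
    for col in masked.columns:
        if not np.isfinite(stds[col]) or stds[col] <= 0:
            raise ContractViolation(
                f"trait column {col!r} has zero variance: cannot standardize"
            )
    std = (masked - means) / stds

    return TraitMatrix(
        values=std,
        mask=std.isna(),
        logged=True,
        standardized=True,
        outliers_masked=True,
        log_eps=log_eps,
        outlier_bounds=bounds,
        col_means=means,
        col_stds=stds,
        H=H,
        modes=modes,
    )
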