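"""Age-from-stage life tables, truncation rules, and life-table entropies.

A stage-based MPM carries no explicit age axis, but a cohort projected
through the survival matrix U yields one: with n_x = Uˣ c0 the survivorship
to age x is l_x = 1ᵀ n_x (summed over active stages only — residence in a
seed bank is left-truncated, so "age 0" is active establishment), and the
per-capita sexual and clonal reproduction trajectories are
m_x = 1ᵀ F n_x / l_x and c_x = 1ᵀ C n_x / l_x.

Two artefacts of stage structure are handled before any senescence metric is
computed.  First, stasis loops in the most-developed stage create spurious
mortality/fertility plateaus once the surviving cohort's structure has
converged; trajectories are right-truncated at the age (QSD₉₀) where the
cohort is within 10% (Keyfitz's Δ) of the quasi-stationary distribution of U.
Second, a species is only eligible for senescence metrics when 99% of its
cohort dies (l_x < 0.01) before that convergence age, so the truncated window
actually covers the distribution of ages at death.

On the truncated schedules two entropies are computed.  Keyfitz's life-table
entropy H = −∫ l log l dx / ∫ l dx is 1 for constant mortality (Type II
survivorship), < 1 under increasing mortality (senescence, Type I) and > 1
under declining mortality (escape from senescence, Type III).  Demetrius's
entropy S = −Σ p_x log p_x, with p_x ∝ λ^{−x} l_x m_x, measures the spread of
reproduction over the lifespan: 0 for strict semelparity, up to log k for
reproduction spread evenly over k ages.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .mpm_core import (
    MPM,
    ContractViolation,
    EigenSummary,
    MPMError,
    dominant_eigen,
)

__all__ = [
    "AgeTrajectories",
    "TruncationRecord",
    "EntropyPair",
    "SpanVariant",
    "NoReproductionError",
    "DegenerateCohortError",
    "recruit_distribution",
    "age_trajectories",
    "qsd_truncate",
    "keyfitz_entropy",
    "demetrius_entropy",
    "reproductive_span",
]

#: reproduction below this per-capita rate is treated as zero when locating
#: first/last reproductive ages
REPRO_EPS = 1e-7


class NoReproductionError(MPMError):
    """No reproduction inside the truncated age window: S, L_α undefined."""


class DegenerateCohortError(MPMError):
    """The cohort is extinct before age 1: no age trajectory exists."""


class SpanVariant(str, enum.Enum):
    """Two printed definitions of mature life expectancy L_{α−ω}: last minus
    first reproductive age (``fig2``) or mean life expectancy minus age at
    first reproduction (``table1``)."""

    FIG2 = "fig2"
    TABLE1 = "table1"


@dataclass
class TruncationRecord:
    seed_bank_removed: bool
    qsd90_age: int
    lx99_age: int
    eligible: bool
    qsd_converged: bool = True


@dataclass
class AgeTrajectories:
    """Yearly age schedules l_x (survivorship, l_0 = 1), m_x (sexual) and
    c_x (clonal per-capita reproduction), optionally right-truncated."""

    lx: np.ndarray
    mx: np.ndarray
    cx: np.ndarray
    trunc: Optional[TruncationRecord] = None
    #: cohort stage composition by age (ages × stages), kept for the QSD test
    cohort: Optional[np.ndarray] = None
    #: True when the cohort died out completely at the age after the last one
    #: recorded (possible only in life cycles with a terminal age class)
    extinct: bool = False

    def __post_init__(self) -> None:
        self.lx = np.asarray(self.lx, dtype=float)
        self.mx = np.asarray(self.mx, dtype=float)
        self.cx = np.asarray(self.cx, dtype=float)
        if not (len(self.lx) == len(self.mx) == len(self.cx)):
            raise ContractViolation("lx, mx, cx must have equal length")
        if len(self.lx) == 0:
            raise ContractViolation("empty trajectory")
        if abs(self.lx[0] - 1.0) > 1e-9:
            raise ContractViolation("l_0 must equal 1")
        if np.any(np.diff(self.lx) > 1e-9):
            raise ContractViolation("survivorship must be non-increasing")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(len(self.lx))

    @property
    def rx(self) -> np.ndarray:
        """Total per-capita reproduction m_x + c_x."""
        return self.mx + self.cx


@dataclass
class EntropyPair:
    H: float
    S: float


def recruit_distribution(m: MPM, include_clonal: bool = True) -> np.ndarray:
    """Stage distribution c0 of newly *actively established* recruits.

    Recruits are produced proportionally to (F + C) w at the stable stage
    structure; any mass recruited into seed-bank stages is dropped (those
    individuals have not established) and the rest renormalized to sum 1.
    """
    eigen = dominant_eigen(m)
    R = m.F + (m.C if include_clonal else 0.0)
    c0 = R @ eigen.w
    c0[~m.active_mask] = 0.0
    total = c0.sum()
    if total <= 0:
        raise ContractViolation(
            f"{m.species_id}: all recruits land in seed-bank stages"
        )
    return c0 / total


def age_trajectories(
    m: MPM,
    c0: np.ndarray,
    max_age: int = 1000,
    lx_floor: float = 1e-7,
) -> AgeTrajectories:
    """Project a recruit cohort through U and read off l_x, m_x, c_x.

    The projection stops at ``max_age`` or once survivorship falls below
    ``lx_floor`` (well past the l_x < 0.01 mark the truncation rules need).
    Survivorship counts active stages only; seed-bank residence does not add
    years of life.
    """
    c0 = np.asarray(c0, dtype=float)
    active = m.active_mask
    l0 = c0[active].sum()
    if not np.isclose(l0, 1.0, atol=1e-8) or np.any(c0[~active] > 0):
        raise ContractViolation("c0 must sum to 1 over active stages only")

    n_vec = c0.copy()
    lx, mx, cx, cohort = [], [], [], []
    extinct = False
    for _x in range(max_age + 1):
        alive = n_vec[active].sum()
        if _x == 0:
            alive = 1.0
        if alive <= 0:
            if _x <= 1:
                raise DegenerateCohortError(
                    f"{m.species_id}: cohort extinct before age 1"
                )
            extinct = True
            break
        lx.append(alive)
        mx.append(float(m.F.sum(axis=0) @ n_vec) / alive)
        cx.append(float(m.C.sum(axis=0) @ n_vec) / alive)
        cohort.append(n_vec.copy())
        if alive < lx_floor and _x > 0:
            break
        n_vec = m.U @ n_vec
    return AgeTrajectories(
        lx=np.array(lx),
        mx=np.array(mx),
        cx=np.array(cx),
        cohort=np.array(cohort),
        extinct=extinct,
    )


def _qsd(U_active: np.ndarray) -> np.ndarray:
    """Quasi-stationary distribution: dominant right eigenvector of U over
    active stages, normalized to sum 1."""
    vals, vecs = np.linalg.eig(U_active)
    idx = int(np.argmax(np.abs(vals)))
    if np.abs(vals[idx]) < 1e-12:
        # nilpotent survival (pure age chain with no stasis): the surviving
        # cohort never stabilizes; treat the last age class as the QSD limit
        q = np.zeros(U_active.shape[0])
        q[-1] = 1.0
        return q
    q = vecs[:, idx].real
    if q.sum() < 0:
        q = -q
    q = np.clip(q, 0.0, None)
    return q / q.sum()


def keyfitz_delta(p: np.ndarray, q: np.ndarray) -> float:
    """Keyfitz's Δ: half the L1 distance between two stage distributions."""
    return 0.5 * float(np.abs(p - q).sum())


def qsd_truncate(
    t: AgeTrajectories,
    m: MPM,
    qsd_threshold: float = 0.10,
    lx_threshold: float = 0.01,
) -> AgeTrajectories:
    """Right-truncate trajectories at QSD₉₀ and record eligibility.

    QSD₉₀ is the first age at which the surviving cohort's active-stage
    composition is within ``qsd_threshold`` (Keyfitz's Δ) of the
    quasi-stationary distribution of U; ages beyond it reflect the stasis-loop
    plateau artefact and are discarded.  l_x99 is the first age with
    l_x < ``lx_threshold``.  The species is eligible for senescence metrics
    iff l_x99 ≤ QSD₉₀ — its cohort dies before the artefact sets in.
    """
    if t.cohort is None:
        raise ContractViolation("trajectories lack cohort structure; rerun age_trajectories")
    active = m.active_mask
    U_active = m.U[np.ix_(active, active)]
    q = _qsd(U_active)

    qsd90_age = None
    for x in range(t.cohort.shape[0]):
        struct = t.cohort[x][active]
        tot = struct.sum()
        if tot <= 0:
            break
        if keyfitz_delta(struct / tot, q) <= qsd_threshold:
            qsd90_age = x
            break
    converged = qsd90_age is not None
    if qsd90_age is None:
        # a cohort that died out completely never hit the plateau artefact:
        # its whole (finished) life course stands; an unconverged but still
        # surviving cohort is truncated at the end of the computed window
        qsd90_age = len(t.lx) if t.extinct else len(t.lx) - 1

    below = np.flatnonzero(t.lx < lx_threshold)
    # if 99% mortality was never observed, lx99 = window end: that only
    # counts as "died first" when the cohort actually went extinct there
    lx99_age = int(below[0]) if below.size else len(t.lx)
    eligible = bool(lx99_age <= qsd90_age)

    end = qsd90_age + 1
    bank_removed = bool((~active).any())
    rec = TruncationRecord(
        seed_bank_removed=bank_removed,
        qsd90_age=int(qsd90_age),
        lx99_age=lx99_age,
        eligible=eligible,
        qsd_converged=converged,
    )
    return AgeTrajectories(
        lx=t.lx[:end],
        mx=t.mx[:end],
        cx=t.cx[:end],
        trunc=rec,
        cohort=t.cohort[:end],
        extinct=t.extinct and end >= len(t.lx),
    )


def keyfitz_entropy(lx: np.ndarray, ages: np.ndarray | None = None) -> float:
    """Keyfitz's life-table entropy H = [−∫ log(l) l dx] / [∫ l dx].

    Both integrals use trapezoidal quadrature on the supplied grid (yearly
    for empirical MPM trajectories, arbitrarily fine for analytic curves).
    H = 1 marks constant mortality; H < 1 senescence; H > 1 escape from it.
    """
    lx = np.asarray(lx, dtype=float)
    if ages is None:
        ages = np.arange(len(lx), dtype=float)
    ages = np.asarray(ages, dtype=float)
    if lx.ndim != 1 or len(lx) < 2:
        raise ContractViolation("need at least two survivorship points")
    if np.any(lx <= 0):
        raise ContractViolation("survivorship must be strictly positive")
    if np.any(np.diff(lx) > 1e-12):
        raise ContractViolation("survivorship must be non-increasing")
    if abs(lx[0] - 1.0) > 1e-9:
        raise ContractViolation("l_0 must equal 1")
    num = -np.trapezoid(np.log(lx) * lx, ages)
    den = np.trapezoid(lx, ages)
    return float(num / den)


def demetrius_entropy(
    lx: np.ndarray,
    mx: np.ndarray,
    cx: np.ndarray | None = None,
    lam: float = 1.0,
    include_clonal: bool = True,
) -> float:
    """Demetrius's entropy S = −Σ p_x log p_x with p_x ∝ λ^{−x} l_x r_x.

    r_x is the reproduction schedule (m_x, plus c_x when clonal recruits are
    counted).  p is renormalized over the truncated window, making S invariant
    to positive rescaling of the schedule: 0 for a single reproductive age,
    log k for reproduction spread evenly over k ages (discount aside).
    """
    lx = np.asarray(lx, dtype=float)
    rx = np.asarray(mx, dtype=float).copy()
    if include_clonal and cx is not None:
        rx = rx + np.asarray(cx, dtype=float)
    if lam <= 0:
        raise ContractViolation("lambda must be positive")
    x = np.arange(len(lx), dtype=float)
    p = lam ** (-x) * lx * rx
    total = p.sum()
    if total <= 0:
        raise NoReproductionError("no reproduction in the truncated age window")
    p = p / total
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum() + 0.0)  # +0.0 avoids -0.0


def reproductive_span(
    t: AgeTrajectories,
    eta_e: float | None = None,
    variant: SpanVariant = SpanVariant.TABLE1,
    include_clonal: bool = True,
) -> tuple[int, int, float]:
    """Ages at first (L_α) and last (L_ω) reproduction — clonal or sexual,
    whichever comes first/last — and the mature life expectancy L_{α−ω}.

    ``fig2`` variant: L_ω − L_α.  ``table1`` variant (default, the one that
    feeds the trait matrix): η_e − L_α, which requires ``eta_e``.
    """
    rx = t.mx + (t.cx if include_clonal else 0.0)
    repro_ages = np.flatnonzero(rx > REPRO_EPS)
    if repro_ages.size == 0:
        raise NoReproductionError("no reproductive age inside the truncated window")
    l_alpha = int(repro_ages[0])
    l_omega = int(repro_ages[-1])
    if variant == SpanVariant.FIG2:
        span = float(l_omega - l_alpha)
    else:
        if eta_e is None:
            raise ContractViolation("table1 variant requires eta_e")
        span = float(eta_e - l_alpha)
    return l_alpha, l_omega, span
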