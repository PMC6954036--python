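"""Matrix population model (MPM) data structures and matrix-algebra primitives.

A matrix population model projects a stage-structured population one time step
(here: one year) forward,

    n(t+1) = A n(t),      A = U + F + C,

where ``U`` holds stage-specific survival together with growth, stasis and
shrinkage, ``F`` per-capita sexual recruitment and ``C`` per-capita clonal
(ramet) recruitment.  Columns index the source stage and rows the destination
stage, the standard convention for published plant MPMs.

Everything downstream — age-from-stage life tables, life-history traits,
senescence metrics — consumes the primitives defined here: structural
validation, the dominant eigen-system, the fundamental matrix
``N = (I − U)⁻¹`` of expected stage residence times, mean life expectancy,
generation time and stable-stage-weighted vital rates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "GrowthForm",
    "Treatment",
    "StageInfo",
    "SpeciesMeta",
    "MPM",
    "EigenSummary",
    "CheckResult",
    "ValidationReport",
    "MPMError",
    "StructuralError",
    "ContractViolation",
    "DegenerateSpectrumError",
    "SingularLifeCycleError",
    "UndefinedGenerationTime",
    "validate_mpm",
    "dominant_eigen",
    "fundamental_matrix",
    "mean_life_expectancy",
    "generation_time",
    "ssd_weighted_rates",
]

#: Numerical tolerance below which the dominant eigenvalue is treated as
#: exactly 1 (generation time undefined → reported missing).
LAMBDA_UNITY_TOL = 1e-10


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class MPMError(Exception):
    """Base class for demographic model errors."""


class StructuralError(MPMError):
    """Matrices are malformed (non-square, mismatched sizes, bad metadata)."""


class ContractViolation(MPMError):
    """An operation was called outside its contract."""


class DegenerateSpectrumError(MPMError):
    """The projection matrix has no meaningful dominant eigenvalue."""


class SingularLifeCycleError(MPMError):
    """spectral radius of U ≥ 1: individuals never die (immortal life cycle)."""


class UndefinedGenerationTime(MPMError):
    """λ = 1 (within tolerance): T = log R0 / log λ is undefined."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class GrowthForm(str, enum.Enum):
    EPIPHYTE = "epiphyte"
    HERBACEOUS_PERENNIAL = "herbaceous_perennial"
    SUCCULENT = "succulent"
    SHRUB = "shrub"
    TREE = "tree"
    PALM = "palm"
    ANNUAL = "annual"
    ALGA = "alga"
    OTHER = "other"


class Treatment(str, enum.Enum):
    UNMANIPULATED = "unmanipulated"
    MANIPULATED = "manipulated"


@dataclass(frozen=True)
class StageInfo:
    """One life-cycle stage.

    ``order_index`` orders stages by developmental rank (0 = smallest / least
    developed); it defines which transitions count as growth (to a higher
    rank) versus shrinkage (to a lower rank).  Seed-bank stages are inactive:
    residence in them is left-truncated from age trajectories.
    """

    label: str
    order_index: int
    is_seed_bank: bool = False

    @property
    def is_active(self) -> bool:
        return not self.is_seed_bank


@dataclass
class SpeciesMeta:
    """Study-level metadata used by the selection criteria."""

    growth_form: GrowthForm = GrowthForm.HERBACEOUS_PERENNIAL
    study_years: int = 0
    n_annual_matrices: int = 0
    treatment: Treatment = Treatment.UNMANIPULATED
    annual_timestep: bool = True
    #: botanical-knowledge clonality flag (CLO-PLA stand-in): the species is
    #: known to be clonal even if the model quantifies no clonal rates.
    clonal_per_knowledge: bool = False
    gps: Optional[tuple[float, float]] = None
    study_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.study_years < 0 or self.n_annual_matrices < 0:
            raise StructuralError("study_years and n_annual_matrices must be >= 0")


@dataclass
class MPM:
    """One species' matrix population model: A = U + F + C plus metadata."""

    species_id: str
    stages: list[StageInfo]
    U: np.ndarray
    F: np.ndarray
    C: np.ndarray
    meta: SpeciesMeta = field(default_factory=SpeciesMeta)

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.stages)
        for name, mat in (("U", self.U), ("F", self.F), ("C", self.C)):
            if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
                raise StructuralError(
                    f"{self.species_id}: {name} must be square, got {mat.shape}"
                )
            if mat.shape[0] != n:
                raise StructuralError(
                    f"{self.species_id}: {name} is {mat.shape[0]}x{mat.shape[1]} "
                    f"but {n} stages are declared"
                )
        if sorted(s.order_index for s in self.stages) != list(range(n)):
            raise StructuralError(
                f"{self.species_id}: order_index values must be a permutation of 0..{n - 1}"
            )

    @property
    def n(self) -> int:
        return len(self.stages)

    @property
    def A(self) -> np.ndarray:
        return self.U + self.F + self.C

    @property
    def active_mask(self) -> np.ndarray:
        """Boolean mask over stages: True for non-seed-bank stages."""
        return np.array([s.is_active for s in self.stages], dtype=bool)

    def copy(self) -> "MPM":
        return replace(
            self,
            stages=list(self.stages),
            U=self.U.copy(),
            F=self.F.copy(),
            C=self.C.copy(),
            meta=replace(self.meta),
        )


@dataclass
class EigenSummary:
    """Dominant eigen-system of A: growth rate λ, stable stage distribution w
    (right eigenvector, sums to 1) and reproductive values v (left eigenvector,
    scaled so v·w = 1)."""

    lam: float
    w: np.ndarray
    v: np.ndarray


@dataclass
class CheckResult:
    name: str
    passed: bool
    reason: str = ""


@dataclass
class ValidationReport:
    species_id: str
    checks: list[CheckResult]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def check(self, name: str) -> CheckResult:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _boolean_power_all_positive(adj: np.ndarray, k: int) -> bool:
    """Is every entry of adj**k positive?  Computed on the boolean semiring by
    exponentiation-by-squaring so large k cannot overflow."""
    result = np.eye(adj.shape[0], dtype=bool)
    base = adj.copy()
    while k:
        if k & 1:
            result = result @ base
        base = base @ base
        k >>= 1
    return bool(result.all())


def validate_mpm(m: MPM, min_dim: int = 2) -> ValidationReport:
    """Run the structural admissibility checks on one model.

    Checks (each reported, none raised): non-negativity of U/F/C,
    irreducibility and primitivity of the life-cycle graph of A, dimension
    n > ``min_dim``, and stage-specific survival (column sums of U) < 1.
    Irreducibility is decided by strong connectivity of A's directed adjacency
    graph; primitivity by positivity of the boolean adjacency raised to
    (n−1)·n + 1, an index-of-primitivity bound.

    Malformed input (non-square or mismatched matrices) raises
    :class:`StructuralError` instead — a broken record is not a failed check.
    """
    checks: list[CheckResult] = []
    finite = all(np.isfinite(mat).all() for mat in (m.U, m.F, m.C))
    nonneg = finite and all((mat >= 0).all() for mat in (m.U, m.F, m.C))
    checks.append(
        CheckResult(
            "nonnegative",
            nonneg,
            "" if nonneg else "U, F or C has a negative or non-finite entry",
        )
    )

    A = m.A if nonneg else None
    if A is not None:
        adj = A > 0
        # edge j -> i when A[i, j] > 0 (column = source stage)
        graph = nx.from_numpy_array(adj.T, create_using=nx.DiGraph)
        irreducible = nx.is_strongly_connected(graph)
        primitive = irreducible and _boolean_power_all_positive(
            adj, (m.n - 1) * m.n + 1
        )
    else:
        irreducible = primitive = False
    checks.append(
        CheckResult(
            "irreducible",
            irreducible,
            "" if irreducible else "life-cycle graph of A is not strongly connected",
        )
    )
    checks.append(
        CheckResult(
            "primitive",
            primitive,
            "" if primitive else "A is not primitive (imprimitive or reducible)",
        )
    )

    dim_ok = m.n > min_dim
    checks.append(
        CheckResult(
            "dim_gt_min",
            dim_ok,
            "" if dim_ok else f"dimension {m.n} <= required minimum {min_dim}",
        )
    )

    col_sums = m.U.sum(axis=0)
    surv_ok = bool(np.all(col_sums < 1.0))
    bad = np.flatnonzero(col_sums >= 1.0)
    checks.append(
        CheckResult(
            "survival_lt_1",
            surv_ok,
            ""
            if surv_ok
            else "stage-specific survival >= 1 in column(s) "
            + ", ".join(str(j) for j in bad),
        )
    )
    return ValidationReport(m.species_id, checks)


# ---------------------------------------------------------------------------
# eigen-system
# ---------------------------------------------------------------------------

def dominant_eigen(m: MPM | np.ndarray) -> EigenSummary:
    """Dominant eigenvalue λ (spectral radius) of A with its right and left
    eigenvectors; w is normalized to sum 1, v so that v·w = 1."""
    A = m.A if isinstance(m, MPM) else np.asarray(m, dtype=float)
    vals, right = np.linalg.eig(A)
    mods = np.abs(vals)
    # several eigenvalues can share the spectral radius (imprimitive life
    # cycles); the Perron root is the real, positive one among them
    cand = np.flatnonzero(mods >= mods.max() * (1.0 - 1e-9))
    idx = int(cand[np.argmax(vals[cand].real)])
    if np.abs(vals[idx]) < 1e-12:
        raise DegenerateSpectrumError("zero spectral radius: no dominant eigenvalue")
    lam = float(vals[idx].real)
    w = right[:, idx].real
    if w.sum() < 0:
        w = -w
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise DegenerateSpectrumError("degenerate dominant eigenvector")
    w = w / total

    lvals, left = np.linalg.eig(A.T)
    lidx = int(np.argmin(np.abs(lvals - vals[idx])))
    v = left[:, lidx].real
    if v.sum() < 0:
        v = -v
    scale = v @ w
    v = v / scale if abs(scale) > 1e-300 else v
    return EigenSummary(lam=lam, w=w, v=v)


def fundamental_matrix(U: np.ndarray) -> np.ndarray:
    """Expected stage residence times N = (I − U)⁻¹.

    N[i, j] is the expected number of years an individual now in stage j will
    spend in stage i before death.  Requires the spectral radius of U to be
    below 1 — otherwise the life cycle is immortal and residence times diverge.
    """
    U = np.asarray(U, dtype=float)
    rho = np.max(np.abs(np.linalg.eigvals(U))) if U.size else 0.0
    if rho >= 1.0 - 1e-12:
        raise SingularLifeCycleError(
            f"spectral radius of U is {rho:.6f} >= 1: residence times diverge"
        )
    N = np.linalg.inv(np.eye(U.shape[0]) - U)
    N[(N < 0) & (N > -1e-12)] = 0.0  # inversion round-off
    return N


def mean_life_expectancy(m: MPM, c0: np.ndarray) -> float:
    """Mean number of years lived, η_e = 1ᵀ N c0, from the recruit
    distribution c0 over stages (must place no mass on seed-bank stages)."""
    c0 = np.asarray(c0, dtype=float)
    if c0.shape != (m.n,):
        raise ContractViolation(f"c0 must have length {m.n}")
    if not np.isclose(c0.sum(), 1.0, atol=1e-8):
        raise ContractViolation("c0 must sum to 1")
    if np.any(c0[~m.active_mask] > 0):
        raise ContractViolation("c0 places mass on a seed-bank stage")
    N = fundamental_matrix(m.U)
    eta = float(N.sum(axis=0) @ c0)
    if eta <= 0:
        raise ContractViolation("non-positive life expectancy")
    return eta


def net_reproductive_rate(m: MPM, include_clonal: bool = True) -> float:
    """R0: spectral radius of (F [+ C]) N, the expected lifetime production of
    recruits per recruit."""
    N = fundamental_matrix(m.U)
    R = m.F + (m.C if include_clonal else 0.0)
    vals = np.linalg.eigvals(R @ N)
    return float(np.max(np.abs(vals)))


def generation_time(m: MPM, include_clonal: bool = True) -> float:
    """Generation time T = log R0 / log λ: years for the population to be
    fully replaced, i.e. to grow by its net reproductive rate.

    Clonal recruits are counted in R0 by default (the population is replaced
    by sexual and ramet recruits alike); set ``include_clonal=False`` for the
    strictly sexual variant.  Raises :class:`UndefinedGenerationTime` when λ
    is 1 within tolerance — the trait is then reported missing and becomes a
    candidate for imputation downstream.
    """
    lam = dominant_eigen(m).lam
    if abs(lam - 1.0) <= LAMBDA_UNITY_TOL:
        raise UndefinedGenerationTime("lambda = 1: generation time undefined")
    R0 = net_reproductive_rate(m, include_clonal=include_clonal)
    if not np.isfinite(R0) or R0 <= 0:
        raise ContractViolation("R0 must be finite and positive")
    return float(np.log(R0) / np.log(lam))


def ssd_weighted_rates(m: MPM, eigen: EigenSummary | None = None) -> tuple[float, float, float, float]:
    """Stable-stage-weighted mean vital rates (σ, φ, γ, ρ) over active stages.

    For each active stage j: survival is the column sum of U restricted to
    active rows; sexual reproduction the column sum of F; growth the U-mass
    flowing to more developed active stages (higher ``order_index``);
    shrinkage the mass to less developed ones.  Each is averaged with the
    stable stage distribution w renormalized over active stages.  Per column,
    growth + shrinkage + stasis = survival exactly.
    """
    active = m.active_mask
    if not active.any():
        raise ContractViolation("model has no active (non-seed-bank) stage")
    eigen = eigen or dominant_eigen(m)
    w = eigen.w[active]
    total = w.sum()
    if total <= 0:
        raise ContractViolation("stable stage distribution has no active mass")
    w = w / total

    order = np.array([s.order_index for s in m.stages])
    idx = np.flatnonzero(active)
    surv = np.empty(idx.size)
    repro = np.empty(idx.size)
    grow = np.empty(idx.size)
    shrink = np.empty(idx.size)
    for k, j in enumerate(idx):
        col = m.U[:, j]
        surv[k] = col[active].sum()
        repro[k] = m.F[:, j].sum()
        higher = active & (order > order[j])
        lower = active & (order < order[j])
        grow[k] = col[higher].sum()
        shrink[k] = col[lower].sum()
    sigma = float(surv @ w)
    phi = float(repro @ w)
    gamma = float(grow @ w)
    rho = float(shrink @ w)
    return sigma, phi, gamma, rho
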