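"""Synthetic MPM collections, phylogenies and traits with known ground truth.

No curated plant-matrix compilation ships with this package, so every
pipeline stage is exercised against generated data whose answers are known
by construction.  Species are built from explicit age-specific mortality
regimes —

* ``TYPE_I``: Gompertz hazard μ(x) = a·e^{bx} (mortality increases with age →
  senescence, Keyfitz H < 1),
* ``TYPE_II``: constant hazard μ (Type II survivorship, H = 1),
* ``TYPE_III``: declining hazard μ(x) = a/(1 + bx) (escape from senescence,
  H > 1),

— combined with semelparous or iteroparous fertility schedules whose level is
solved from the Euler–Lotka relation so each species hits a prescribed
population growth rate λ.  Reproduction is split between sexual (F) and
clonal (C) recruitment by a clonal fraction, an optional seed-bank stage is
prepended, and the age-classified Leslie model is pooled into a handful of
contiguous stages to mimic the stage-based models found in the wild —
including the stasis-loop plateau artefact the truncation rules exist for.

Phylogenies are pure-birth (Yule) trees; traits evolve along them by
Brownian motion with a chosen covariance, giving the phylogenetic PCA a
recoverable ground truth.  Everything is driven by one integer seed and
regenerates bit-identically.
"""

from __future__ import annotations

import enum
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .mpm_core import (
    MPM,
    ContractViolation,
    GrowthForm,
    SpeciesMeta,
    StageInfo,
    StructuralError,
    Treatment,
    dominant_eigen,
)
from .selection import ReproductionMode

__all__ = [
    "Regime",
    "FertilitySchedule",
    "SyntheticSpec",
    "GroundTruth",
    "ScenarioConfig",
    "hazard",
    "make_age_mpm",
    "aggregate_to_stages",
    "make_yule_tree",
    "simulate_bm_traits",
    "make_collection",
    "reference_scenario",
]


class Regime(str, enum.Enum):
    TYPE_I = "type_i"  # increasing hazard -> senescence, H < 1
    TYPE_II = "type_ii"  # constant hazard -> H = 1
    TYPE_III = "type_iii"  # decreasing hazard -> escape, H > 1


class FertilitySchedule(str, enum.Enum):
    SEMELPAROUS = "semelparous"
    ITEROPAROUS = "iteroparous"


#: expected side of Keyfitz entropy relative to 1 per regime (0 = on it)
H_SIDE = {Regime.TYPE_I: -1, Regime.TYPE_II: 0, Regime.TYPE_III: +1}


def hazard(regime: Regime, params: dict[str, float], x: np.ndarray) -> np.ndarray:
    """Age-specific mortality hazard μ(x) for the three regimes."""
    x = np.asarray(x, dtype=float)
    if regime == Regime.TYPE_I:
        return params["a"] * np.exp(params["b"] * x)
    if regime == Regime.TYPE_II:
        return np.full_like(x, params["mu"])
    if regime == Regime.TYPE_III:
        return params["a"] / (1.0 + params["b"] * x)
    raise ContractViolation(f"unknown regime {regime}")


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic species."""

    species_id: str
    regime: Regime
    hazard_params: dict[str, float]
    fertility: FertilitySchedule = FertilitySchedule.ITEROPAROUS
    maturity_age: int = 3
    lam_target: float = 1.02
    clonal_fraction: float = 0.0
    n_ages: int = 45
    n_stages: int = 12
    seed_bank: bool = False
    bank_stasis: float = 0.2
    bank_germination: float = 0.4
    seed_to_bank: float = 0.3
    seed: int = 0


@dataclass
class GroundTruth:
    """What the generator planted, kept beside the collection it produced."""

    per_species: dict[str, dict] = field(default_factory=dict)
    trait_cov: Optional[np.ndarray] = None
    planted_failures: dict[str, str] = field(default_factory=dict)

    def expected_h_side(self, species_id: str) -> int:
        return self.per_species[species_id]["h_side"]


@dataclass
class ScenarioConfig:
    """Species counts per (regime × reproduction mode) cell plus options."""

    cells: dict[tuple[Regime, ReproductionMode], int] = field(default_factory=dict)
    plant_failures: bool = False
    n_ages: int = 45
    n_stages_range: tuple[int, int] = (10, 16)
    seed_bank_prob: float = 0.25
    semelparous_prob: float = 0.10
    #: per-species share of stasis redirected to the previous stage
    shrink_range: tuple[float, float] = (0.005, 0.04)
    seed: int = 0


# ---------------------------------------------------------------------------
# age-classified Leslie models
# ---------------------------------------------------------------------------

def make_age_mpm(spec: SyntheticSpec) -> MPM:
    """Build the age-classified (Leslie) MPM a synthetic species starts from.

    Yearly survival p_x = exp(−μ(x)) fills the subdiagonal; the fertility
    level over the schedule window is solved from the Euler–Lotka relation
    Σ f l_x λ^{−(x+1)} = 1 so the model's growth rate equals ``lam_target``
    (exactly, before any seed bank is added).  Reproduction is split between
    F and C by ``clonal_fraction``; an optional seed-bank stage is prepended.
    """
    n = spec.n_ages
    if spec.fertility == FertilitySchedule.SEMELPAROUS:
        # fatal reproduction: life ends at the single reproductive age
        n = min(n, spec.maturity_age + 1)
    x = np.arange(n)
    mu = hazard(spec.regime, spec.hazard_params, x)
    if np.any(mu <= 0):
        raise ContractViolation(
            f"{spec.species_id}: hazard yields survival outside (0,1)"
        )
    p = np.exp(-mu)

    # survivorship to the start of each age class; trim the age axis where
    # the cohort is effectively extinct so steep hazards keep p in (0,1)
    l = np.concatenate([[1.0], np.cumprod(p[:-1])])
    alive = l >= 1e-9
    n = min(n, max(int(alive.sum()), min(spec.maturity_age, n - 1) + 1))
    x, mu, p, l = x[:n], mu[:n], p[:n], l[:n]
    if np.any(p <= 0) or np.any(p >= 1):
        raise ContractViolation(
            f"{spec.species_id}: hazard yields survival outside (0,1)"
        )
    if spec.fertility == FertilitySchedule.SEMELPAROUS:
        window = np.zeros(n, dtype=bool)
        window[min(spec.maturity_age, n - 1)] = True
    else:
        window = x >= spec.maturity_age
    lam = spec.lam_target
    denom = float((l[window] * lam ** (-(x[window] + 1.0))).sum())
    if denom <= 0:
        raise ContractViolation(f"{spec.species_id}: empty fertility window")
    f_level = 1.0 / denom

    U = np.zeros((n, n))
    U[np.arange(1, n), np.arange(n - 1)] = p[:-1]
    fert = np.where(window, f_level, 0.0)
    F = np.zeros((n, n))
    C = np.zeros((n, n))
    F[0, :] = (1.0 - spec.clonal_fraction) * fert
    C[0, :] = spec.clonal_fraction * fert

    stages = [StageInfo(label=f"age_{i}", order_index=i) for i in range(n)]
    m = MPM(species_id=spec.species_id, stages=stages, U=U, F=F, C=C)
    if spec.seed_bank:
        m = _prepend_seed_bank(m, spec)
    return m


def _prepend_seed_bank(m: MPM, spec: SyntheticSpec) -> MPM:
    n = m.n
    U = np.zeros((n + 1, n + 1))
    F = np.zeros((n + 1, n + 1))
    C = np.zeros((n + 1, n + 1))
    U[1:, 1:] = m.U
    U[0, 0] = spec.bank_stasis
    U[1, 0] = spec.bank_germination
    # a share of sexual seeds enters the bank instead of establishing directly
    F[0, 1:] = spec.seed_to_bank * m.F[0, :]
    F[1, 1:] = (1.0 - spec.seed_to_bank) * m.F[0, :]
    C[1:, 1:] = m.C
    stages = [StageInfo(label="seed_bank", order_index=0, is_seed_bank=True)] + [
        StageInfo(label=s.label, order_index=s.order_index + 1) for s in m.stages
    ]
    return MPM(species_id=m.species_id, stages=stages, U=U, F=F, C=C, meta=m.meta)


def add_shrinkage(m: MPM, fraction: float) -> MPM:
    """Redirect a fraction of each stage's stasis to the previous active
    stage, emulating the retrogression (shrinkage) real plant stage models
    show.  Column sums of U — hence survival and l_x — are unchanged."""
    if not 0.0 <= fraction < 1.0:
        raise ContractViolation("shrink fraction must be in [0, 1)")
    out = m.copy()
    active_idx = np.flatnonzero(m.active_mask)
    for k in range(1, active_idx.size):
        j, prev = active_idx[k], active_idx[k - 1]
        moved = fraction * out.U[j, j]
        out.U[j, j] -= moved
        out.U[prev, j] += moved
    return out


def aggregate_to_stages(m: MPM, n_stages: int) -> MPM:
    """Pool contiguous age classes of a Leslie model into stage bins.

    Within-bin composition is taken from the model's stable stage
    distribution (uniform fallback for bins the stationary population never
    occupies), so the pooled transition rates are the rates an observer of
    the stationary population would estimate.  A seed-bank stage, if present,
    is kept as its own stage.  Column sums of U — and hence SSD-weighted
    survival — are preserved as the within-bin weighted means of the age
    model's column sums; identity pooling (n_stages = number of age classes)
    returns the model unchanged.
    """
    active_idx = np.flatnonzero(m.active_mask)
    bank_idx = np.flatnonzero(~m.active_mask)
    n_active = active_idx.size
    if n_stages > n_active:
        raise ContractViolation(
            f"{m.species_id}: cannot pool {n_active} age classes into {n_stages} stages"
        )
    bins = np.array_split(np.arange(n_active), n_stages)
    if any(len(b) == 0 for b in bins):
        raise ContractViolation("empty stage bin")

    try:
        w_full = dominant_eigen(m).w
    except Exception:
        w_full = np.ones(m.n) / m.n
    w_active = w_full[active_idx]

    n_new = n_stages + bank_idx.size
    # P pools destination rows; Wt spreads source columns by within-bin weights
    P = np.zeros((n_new, m.n))
    Wt = np.zeros((m.n, n_new))
    for k, bi in enumerate(bank_idx):
        P[k, bi] = 1.0
        Wt[bi, k] = 1.0
    for b, members in enumerate(bins):
        cols = active_idx[members]
        P[bank_idx.size + b, cols] = 1.0
        wb = w_active[members]
        wb = wb / wb.sum() if wb.sum() > 0 else np.full(len(members), 1.0 / len(members))
        Wt[cols, bank_idx.size + b] = wb

    U = P @ m.U @ Wt
    F = P @ m.F @ Wt
    C = P @ m.C @ Wt
    stages = [
        StageInfo(label=m.stages[bi].label, order_index=k, is_seed_bank=True)
        for k, bi in enumerate(bank_idx)
    ] + [
        StageInfo(label=f"stage_{b + 1}", order_index=bank_idx.size + b)
        for b in range(n_stages)
    ]
    return MPM(species_id=m.species_id, stages=stages, U=U, F=F, C=C, meta=m.meta)


# ---------------------------------------------------------------------------
# trees and Brownian-motion traits
# ---------------------------------------------------------------------------

def make_yule_tree(n_tips: int, seed: int = 0, labels: Optional[Sequence[str]] = None) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree with ``n_tips`` extant tips."""
    if n_tips < 4:
        raise ContractViolation("need at least 4 tips")
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    leaves = list(tree.leaf_node_iter())
    # the simulation stops at the n-th speciation, leaving the newest cherry
    # with zero-length tip branches (a singular Brownian covariance); extend
    # every tip edge by the expected waiting time to the next event, which
    # keeps the tree ultrametric
    delta = 1.0 / n_tips
    for leaf in leaves:
        leaf.edge.length = (leaf.edge.length or 0.0) + delta
    if labels is not None:
        if len(labels) != len(leaves):
            raise ContractViolation("label count does not match tip count")
        ns = dendropy.TaxonNamespace()
        for leaf, lab in zip(leaves, labels):
            leaf.taxon = ns.new_taxon(label=str(lab))
        tree.taxon_namespace = ns
    return tree


def simulate_bm_traits(
    tree: dendropy.Tree, cov: np.ndarray, seed: int = 0
) -> pd.DataFrame:
    """Multivariate Brownian motion along the tree: each branch adds a
    N(0, t·Σ) increment.  Returns a tips × traits DataFrame."""
    cov = np.asarray(cov, dtype=float)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ContractViolation("trait covariance must be positive definite")
    rng = np.random.default_rng(seed)
    p = cov.shape[0]
    states: dict[int, np.ndarray] = {}
    rows = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            state = np.zeros(p)
        else:
            t = node.edge.length or 0.0
            z = rng.standard_normal(p)
            state = states[id(node.parent_node)] + np.sqrt(t) * (chol @ z)
        states[id(node)] = state
        if node.is_leaf():
            rows[node.taxon.label] = state
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"trait_{j + 1}" for j in range(p)]
    return df


# ---------------------------------------------------------------------------
# full collections
# ---------------------------------------------------------------------------

def _sample_hazard_params(regime: Regime, rng: np.random.Generator) -> dict[str, float]:
    if regime == Regime.TYPE_I:
        return {"a": rng.uniform(0.03, 0.08), "b": rng.uniform(0.15, 0.25)}
    if regime == Regime.TYPE_II:
        return {"mu": rng.uniform(0.15, 0.30)}
    return {"a": rng.uniform(0.55, 0.80), "b": rng.uniform(0.25, 0.35)}


def _default_meta(rng: np.random.Generator, clonal_known: bool) -> SpeciesMeta:
    return SpeciesMeta(
        growth_form=GrowthForm(
            rng.choice(
                ["herbaceous_perennial", "shrub", "succulent", "epiphyte"],
                p=[0.7, 0.15, 0.1, 0.05],
            )
        ),
        study_years=int(rng.integers(3, 12)),
        n_annual_matrices=int(rng.integers(2, 8)),
        treatment=Treatment.UNMANIPULATED,
        annual_timestep=True,
        clonal_per_knowledge=clonal_known,
    )


def reference_scenario(seed: int = 0) -> ScenarioConfig:
    """Default study conditions: 124 strictly sexual, 35 clonal-but-
    unquantified and 22 sexual-and-clonal species, with senescence regimes
    allotted so that most species senesce — 24 of the strictly sexual and a
    single sexual-and-clonal species escape (declining hazard), everything
    else follows an increasing (Gompertz) hazard."""
    cells = {
        (Regime.TYPE_I, ReproductionMode.ONLY_SEXUAL): 100,
        (Regime.TYPE_III, ReproductionMode.ONLY_SEXUAL): 24,
        (Regime.TYPE_I, ReproductionMode.ONLY_SEXUAL_BUT_CLONAL): 35,
        (Regime.TYPE_I, ReproductionMode.SEXUAL_AND_CLONAL): 21,
        (Regime.TYPE_III, ReproductionMode.SEXUAL_AND_CLONAL): 1,
    }
    return ScenarioConfig(cells=cells, plant_failures=True, seed=seed)


def _planted_failures(rng: np.random.Generator, n_ages: int) -> tuple[list[MPM], dict[str, str]]:
    """A handful of deliberately inadmissible species, labelled by the
    selection criterion each must fail."""
    mk = lambda i: SyntheticSpec(
        species_id=f"fail_{i}",
        regime=Regime.TYPE_II,
        hazard_params={"mu": 0.2},
        lam_target=1.02,
        n_ages=n_ages,
        n_stages=4,
    )
    failures: list[MPM] = []
    labels: dict[str, str] = {}

    m1 = aggregate_to_stages(make_age_mpm(mk(1)), 4)
    m1.meta = _default_meta(rng, False)
    m1.meta.growth_form = GrowthForm.ANNUAL
    failures.append(m1)
    labels[m1.species_id] = "criterion_4_annual"

    m2 = aggregate_to_stages(make_age_mpm(mk(2)), 4)
    m2.meta = _default_meta(rng, False)
    m2.F[:] = 0.0
    m2.C[:] = 0.0
    failures.append(m2)
    labels[m2.species_id] = "criterion_9_no_reproduction"

    m3 = aggregate_to_stages(make_age_mpm(mk(3)), 4)
    m3.meta = _default_meta(rng, False)
    m3.U[:, 1] *= 1.5 / m3.U[:, 1].sum()  # survival column inflated to 1.5
    failures.append(m3)
    labels[m3.species_id] = "criterion_8_survival_ge_1"

    return failures, labels


def make_collection(
    scenario: ScenarioConfig,
) -> tuple[list[MPM], dendropy.Tree, GroundTruth]:
    """Generate a full pipeline input: MPM collection (with metadata and,
    optionally, planted filter failures), a Yule tree over every species, and
    the ground-truth record."""
    rng = np.random.default_rng(scenario.seed)
    collection: list[MPM] = []
    truth = GroundTruth()
    counter = 0
    for (regime, mode), count in scenario.cells.items():
        for _ in range(count):
            counter += 1
            sid = f"sp_{counter:04d}"
            # semelparity (fatal single-age reproduction) forces deaths to
            # cluster at the reproductive age, i.e. H < 1 regardless of the
            # hazard family — so it is only planted in the senescent regime
            # to keep the per-species H-side ground truth unambiguous
            semel = regime == Regime.TYPE_I and (
                rng.random() < scenario.semelparous_prob
            )
            clonal_fraction = (
                float(rng.uniform(0.1, 0.5))
                if mode == ReproductionMode.SEXUAL_AND_CLONAL
                else 0.0
            )
            spec = SyntheticSpec(
                species_id=sid,
                regime=regime,
                hazard_params=_sample_hazard_params(regime, rng),
                fertility=FertilitySchedule.SEMELPAROUS
                if semel
                else FertilitySchedule.ITEROPAROUS,
                maturity_age=int(rng.integers(5, 9)) if semel else int(rng.integers(2, 6)),
                lam_target=float(np.exp(rng.normal(np.log(1.02), 0.04))),
                clonal_fraction=clonal_fraction,
                n_ages=scenario.n_ages,
                n_stages=int(rng.integers(*scenario.n_stages_range)),
                seed_bank=bool(rng.random() < scenario.seed_bank_prob),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            age_model = make_age_mpm(spec)
            n_stages = min(spec.n_stages, age_model.n - 1)
            m = aggregate_to_stages(age_model, n_stages)
            m = add_shrinkage(m, float(rng.uniform(*scenario.shrink_range)))
            m.meta = _default_meta(
                rng, clonal_known=mode != ReproductionMode.ONLY_SEXUAL
            )
            collection.append(m)
            truth.per_species[sid] = {
                "regime": regime.value,
                "h_side": H_SIDE[regime],
                "mode": mode.value,
                "spec": spec,
            }
    if scenario.plant_failures:
        failures, labels = _planted_failures(rng, scenario.n_ages)
        collection.extend(failures)
        truth.planted_failures = labels

    tip_labels = [m.species_id for m in collection]
    if len(tip_labels) >= 4:
        tree = make_yule_tree(
            len(tip_labels), seed=int(rng.integers(0, 2**31 - 1)), labels=tip_labels
        )
    else:
        tree = None  # too few species for a meaningful phylogeny
    return collection, tree, truth
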