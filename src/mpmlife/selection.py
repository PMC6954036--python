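"""Study-selection criteria, replicate averaging and reproduction-mode classes.

Comparative MPM analyses only admit models that are structurally sound and
comparable across species: primitive/irreducible/non-negative matrices, field
studies of sufficient duration, unmanipulated conditions, annual time steps,
a restricted set of growth forms, dimension above 2, survival below 1, and
some recorded reproduction.  The filter engine applies these as pure
per-species predicates and reports, for every species, the first criterion it
fails — exclusions are data, not errors.

Species that pass are classified by reproduction mode: strictly sexual,
sexual with unquantified clonality (per external botanical knowledge, the
CLO-PLA stand-in flag), or sexual and clonal with quantified ramet rates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .mpm_core import (
    MPM,
    ContractViolation,
    GrowthForm,
    StructuralError,
    Treatment,
    validate_mpm,
)

__all__ = [
    "ReproductionMode",
    "SelectionConfig",
    "CriterionResult",
    "FilterReport",
    "average_mpms",
    "apply_selection_criteria",
    "classify_reproduction_mode",
    "pick_best_study",
]


class ReproductionMode(str, enum.Enum):
    ONLY_SEXUAL = "only_sexual"
    ONLY_SEXUAL_BUT_CLONAL = "only_sexual_but_clonal"
    SEXUAL_AND_CLONAL = "sexual_and_clonal"


@dataclass
class SelectionConfig:
    """Tunable thresholds of the selection criteria."""

    min_years: int = 3
    min_matrices: int = 2
    allowed_growth_forms: tuple[GrowthForm, ...] = (
        GrowthForm.EPIPHYTE,
        GrowthForm.HERBACEOUS_PERENNIAL,
        GrowthForm.SUCCULENT,
        GrowthForm.SHRUB,
    )
    min_dim: int = 2  # criterion: n must be strictly greater than this


@dataclass
class CriterionResult:
    criterion_id: int
    passed: bool
    reason: str = ""


@dataclass
class FilterReport:
    per_species: dict[str, list[CriterionResult]]
    retained: list[str]

    def first_failure(self, species_id: str) -> Optional[CriterionResult]:
        for r in self.per_species[species_id]:
            if not r.passed:
                return r
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid, results in self.per_species.items():
            for r in results:
                rows.append(
                    {
                        "species_id": sid,
                        "criterion_id": r.criterion_id,
                        "passed": r.passed,
                        "reason": r.reason,
                        "retained": sid in self.retained,
                    }
                )
        return pd.DataFrame(rows)


def average_mpms(models: Sequence[MPM]) -> MPM:
    """Element-by-element mean of replicate models of one species.

    Replicates from contiguous annual transitions or multiple populations of
    one study are pooled into a single average model; stage structure must
    match exactly.  Metadata merges as study_years = max, n_annual_matrices =
    total.
    """
    if not models:
        raise ContractViolation("no models to average")
    first = models[0]
    for m in models[1:]:
        if m.n != first.n:
            raise StructuralError(
                f"{first.species_id}: cannot average models of dimension "
                f"{first.n} and {m.n}"
            )
        same_stages = all(
            a.label == b.label
            and a.order_index == b.order_index
            and a.is_seed_bank == b.is_seed_bank
            for a, b in zip(first.stages, m.stages)
        )
        if not same_stages:
            raise StructuralError(f"{first.species_id}: stage metadata mismatch")
    out = first.copy()
    out.U = np.mean([m.U for m in models], axis=0)
    out.F = np.mean([m.F for m in models], axis=0)
    out.C = np.mean([m.C for m in models], axis=0)
    out.meta.study_years = max(m.meta.study_years for m in models)
    out.meta.n_annual_matrices = sum(m.meta.n_annual_matrices for m in models)
    return out


def _criteria(cfg: SelectionConfig) -> list[tuple[int, Callable[[MPM], tuple[bool, str]]]]:
    def c1(m: MPM) -> tuple[bool, str]:
        rep = validate_mpm(m, min_dim=cfg.min_dim)
        bad = [c for c in rep.checks if c.name in ("nonnegative", "irreducible", "primitive") and not c.passed]
        if bad:
            return False, "; ".join(c.reason or c.name for c in bad)
        return True, ""

    def c2(m: MPM) -> tuple[bool, str]:
        ok = (
            m.meta.study_years >= cfg.min_years
            and m.meta.n_annual_matrices >= cfg.min_matrices
        )
        return ok, "" if ok else (
            f"study spans {m.meta.study_years} y / {m.meta.n_annual_matrices} "
            f"annual matrices (need >= {cfg.min_years} y and >= {cfg.min_matrices})"
        )

    def c3(m: MPM) -> tuple[bool, str]:
        ok = m.meta.treatment == Treatment.UNMANIPULATED
        return ok, "" if ok else "manipulated / non-control conditions"

    def c4(m: MPM) -> tuple[bool, str]:
        if not m.meta.annual_timestep:
            return False, "non-annual (seasonal) projection interval"
        if m.meta.growth_form == GrowthForm.ANNUAL:
            return False, "annual species"
        return True, ""

    def c5(m: MPM) -> tuple[bool, str]:
        ok = m.meta.growth_form in cfg.allowed_growth_forms
        return ok, "" if ok else f"growth form {m.meta.growth_form.value} excluded"

    def c7(m: MPM) -> tuple[bool, str]:
        ok = m.n > cfg.min_dim
        return ok, "" if ok else f"dimension {m.n} <= {cfg.min_dim}"

    def c8(m: MPM) -> tuple[bool, str]:
        cols = m.U.sum(axis=0)
        ok = bool(np.all(cols < 1.0))
        return ok, "" if ok else "stage-specific survival >= 1"

    def c9(m: MPM) -> tuple[bool, str]:
        sF, sC = m.F.sum(), m.C.sum()
        if sF == 0 and sC == 0:
            return False, "no reproduction recorded (sum F = sum C = 0)"
        if sF == 0 and sC > 0:
            return False, "exclusively clonal reproduction (sum F = 0, sum C > 0)"
        return True, ""

    # criterion 6 (averaging) is applied upstream via average_mpms; criterion
    # 10 (mode classification) and 11 (best study per species) act on the
    # retained set, not as exclusion predicates.
    return [(1, c1), (2, c2), (3, c3), (4, c4), (5, c5), (7, c7), (8, c8), (9, c9)]


def apply_selection_criteria(
    collection: Iterable[MPM], cfg: SelectionConfig | None = None
) -> FilterReport:
    """Evaluate criteria 1–9 on every species; retained iff all pass.

    Each criterion is a pure predicate on one species record, so filtering is
    order-independent; the report nevertheless records every criterion result
    so an exclusion can be traced to its first failing criterion.
    """
    cfg = cfg or SelectionConfig()
    crits = _criteria(cfg)
    per_species: dict[str, list[CriterionResult]] = {}
    retained: list[str] = []
    for m in collection:
        results = []
        for cid, pred in crits:
            ok, reason = pred(m)
            results.append(CriterionResult(cid, ok, reason))
        per_species[m.species_id] = results
        if all(r.passed for r in results):
            retained.append(m.species_id)
    return FilterReport(per_species=per_species, retained=retained)


def classify_reproduction_mode(m: MPM) -> ReproductionMode:
    """Criterion-10 classification of a retained model.

    ΣF>0 ∧ ΣC>0 → sexual and clonal (ramet rates quantified); ΣF>0 ∧ ΣC=0 →
    either strictly sexual or clonal-but-unquantified, split by the botanical
    knowledge flag.  ΣF=0 should never reach here (criterion 9).
    """
    sF, sC = m.F.sum(), m.C.sum()
    if sF == 0:
        raise ContractViolation(
            f"{m.species_id}: sum F = 0 should have been excluded by criterion 9"
        )
    if sC > 0:
        return ReproductionMode.SEXUAL_AND_CLONAL
    if m.meta.clonal_per_knowledge:
        return ReproductionMode.ONLY_SEXUAL_BUT_CLONAL
    return ReproductionMode.ONLY_SEXUAL


def pick_best_study(candidates: Sequence[MPM]) -> MPM:
    """Criterion 11: among several studies of one species keep the one with
    greater replication, preferring explicit clonality quantification.

    Lexicographic preference: quantified clonality (ΣC>0 for a species known
    to be clonal) > study_years > n_annual_matrices > matrix dimension; ties
    resolved by first occurrence, so the choice is deterministic.
    """
    if not candidates:
        raise ContractViolation("no candidate studies")

    def key(im: tuple[int, MPM]) -> tuple:
        i, m = im
        clonal_quantified = int(m.C.sum() > 0)
        return (
            clonal_quantified,
            m.meta.study_years,
            m.meta.n_annual_matrices,
            m.n,
            -i,  # earlier candidate wins ties
        )

    return max(enumerate(candidates), key=key)[1]
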