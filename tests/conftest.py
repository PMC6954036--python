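"""Shared fixtures and independent oracles.

The Monte-Carlo cohort simulator here is the independent check for the
matrix-algebra life-table machinery: it pushes a finite cohort of discrete
individuals through the survival matrix one year at a time, so any agreement
with the analytic l_x / m_x / η_e is evidence, not circularity.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from mpmlife import MPM, SpeciesMeta, StageInfo


def make_mpm(U, F=None, C=None, species_id="sp", seed_bank_stages=(), meta=None):
    """Terse MPM constructor for tests: stages ordered 0..n-1."""
    U = np.asarray(U, dtype=float)
    n = U.shape[0]
    Z = np.zeros((n, n))
    stages = [
        StageInfo(label=f"s{i}", order_index=i, is_seed_bank=i in seed_bank_stages)
        for i in range(n)
    ]
    return MPM(
        species_id=species_id,
        stages=stages,
        U=U,
        F=Z if F is None else np.asarray(F, dtype=float),
        C=Z if C is None else np.asarray(C, dtype=float),
        meta=meta or SpeciesMeta(study_years=5, n_annual_matrices=4),
    )


def simulate_cohort(
    m: MPM,
    c0: np.ndarray,
    n_individuals: int = 100_000,
    n_batches: int = 10,
    max_age: int = 200,
    seed: int = 0,
):
    """Individual-based cohort simulation, run as independent batches.

    Each individual transitions stage-to-stage by a multinomial draw over the
    columns of U (death = 1 − column sum).  Returns per-batch arrays of l_x,
    m_x and mean lifespan, so callers can form Monte-Carlo means and standard
    errors.  Entirely independent of the fundamental-matrix / projection
    machinery it is used to check.
    """
    rng = np.random.default_rng(seed)
    n = m.n
    active = m.active_mask
    fcol = m.F.sum(axis=0)
    batch_size = n_individuals // n_batches
    lx_batches, mx_batches, eta_batches = [], [], []
    for _b in range(n_batches):
        counts = rng.multinomial(batch_size, c0)
        lx, mx = [], []
        person_years = 0.0
        for _x in range(max_age + 1):
            alive = counts[active].sum()
            if alive == 0:
                break
            lx.append(alive / batch_size)
            mx.append(float(fcol @ counts) / alive)
            person_years += alive
            new_counts = np.zeros(n, dtype=np.int64)
            for j in range(n):
                if counts[j] == 0:
                    continue
                pj = np.append(m.U[:, j], max(0.0, 1.0 - m.U[:, j].sum()))
                pj = pj / pj.sum()
                draw = rng.multinomial(counts[j], pj)
                new_counts += draw[:n]
            counts = new_counts
        lx_batches.append(np.array(lx))
        mx_batches.append(np.array(mx))
        eta_batches.append(person_years / batch_size)
    return lx_batches, mx_batches, np.array(eta_batches)


def batch_mean_se(batches, age):
    """Mean and MC standard error of a per-age statistic across batches."""
    vals = np.array([b[age] if age < len(b) else 0.0 for b in batches])
    return vals.mean(), vals.std(ddof=1) / np.sqrt(len(vals))


def star_tree(labels, branch_length=1.0):
    """Star phylogeny: all tips attach to the root with equal branch lengths."""
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    for lab in labels:
        node = tree.seed_node.new_child(edge_length=branch_length)
        node.taxon = ns.new_taxon(label=str(lab))
    return tree


@pytest.fixture
def two_stage():
    """The work-horse 2-stage model: U=[[0,0],[0.5,0.8]], F sends stage-2
    offspring to stage 1."""
    return make_mpm([[0.0, 0.0], [0.5, 0.8]], F=[[0.0, 1.0], [0.0, 0.0]])


@pytest.fixture
def single_stage():
    return make_mpm([[0.8]], F=[[0.5]])
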