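"""Shared fixtures and independent oracles used across the suite."""

import itertools

import numpy as np
import pytest

from ppgl_grading import CohortConfig, generate_cohort
from ppgl_grading.grading_core import (
    Cellularity,
    HistologyProfile,
)

PASS_TRUE = {
    k: True
    for k in (
        "large_nests_or_diffuse_growth",
        "central_or_confluent_necrosis",
        "high_cellularity",
        "cellular_monotony",
        "tumor_cell_spindling",
        "mitotic_count_gt3_per_10hpf",
        "atypical_mitotic_figures",
        "extension_into_adipose_tissue",
        "profound_nuclear_pleomorphism",
        "nuclear_hyperchromasia",
    )
}
PASS_FALSE = {k: False for k in PASS_TRUE}


def make_histology(**overrides) -> HistologyProfile:
    """A fully specified, all-features-absent histology profile."""
    base = dict(
        large_irregular_nest=False,
        pseudorosette=False,
        comedo_necrosis=False,
        cellularity_class=Cellularity.LOW,
        ki67_percent=0.5,
        vascular_invasion=False,
        capsular_invasion=False,
        sdhb_ihc_positive=True,
        pass_features_own=dict(PASS_FALSE),
    )
    base.update(overrides)
    return HistologyProfile(**base)


def breslow_partial_loglik(beta, times, events, x):
    """Hand-written Cox partial log-likelihood (Breslow ties), one covariate.

    Independent of the package implementation: straightforward summation
    over distinct event times.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    x = np.asarray(x, float)
    ll = 0.0
    for t in sorted(set(times[events])):
        dead = (times == t) & events
        risk = times >= t
        ll += beta * x[dead].sum()
        ll -= dead.sum() * np.log(np.exp(beta * x[risk]).sum())
    return ll


def grid_search_cox(times, events, x, lo=-4.0, hi=4.0):
    """Dense two-stage grid maximization of the hand-written likelihood."""
    grid = np.linspace(lo, hi, 8001)
    ll = [breslow_partial_loglik(b, times, events, x) for b in grid]
    best = grid[int(np.argmax(ll))]
    fine = np.linspace(best - 0.002, best + 0.002, 4001)
    ll = [breslow_partial_loglik(b, times, events, x) for b in fine]
    return float(fine[int(np.argmax(ll))])


# small survival fixtures (<= 5 subjects, no separation): (times, events, x)
COX_FIXTURES = [
    ([1, 2, 3], [1, 1, 0], [1, 0, 1]),
    ([1, 2, 3, 4], [1, 1, 1, 1], [1, 0, 0, 1]),
    ([1, 1, 2, 3, 4], [1, 0, 1, 1, 0], [0, 1, 1, 0, 1]),
    ([2, 2, 3, 5, 7], [1, 1, 0, 1, 1], [1, 1, 0, 0, 1]),
    ([1, 2, 2, 4], [0, 1, 1, 1], [1, 1, 0, 0]),
]


def enumerate_gapp_inputs():
    """Every combination of the discrete GAPP inputs (Ki-67 by band)."""
    from ppgl_grading import CatecholamineType

    for nest, rosette, necrosis, invasion in itertools.product([False, True], repeat=4):
        for cellularity in Cellularity:
            for ki67 in (0.5, 2.0, 5.0):  # representatives of the three bands
                for ctype in CatecholamineType:
                    yield (
                        make_histology(
                            large_irregular_nest=nest,
                            pseudorosette=rosette,
                            comedo_necrosis=necrosis,
                            cellularity_class=cellularity,
                            ki67_percent=ki67,
                            vascular_invasion=invasion,
                        ),
                        ctype,
                    )


def bootstrap_auc_diff_p(s1, s2, y, n_boot, rng):
    """Stratified-bootstrap normal test of a paired AUC difference.

    Independent oracle for DeLong's test: resample metastatic and
    non-metastatic subjects separately (same resampled subjects for both
    scores, preserving their correlation), estimate the SD of the AUC
    difference, and refer the observed difference to a normal.
    """
    from scipy import stats as sps

    s1, s2, y = map(np.asarray, (s1, s2, y))
    pos_idx, neg_idx = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    m, n = pos_idx.size, neg_idx.size

    def auc_batch(pos, neg):
        diff = pos[:, :, None] - neg[:, None, :]
        return ((diff > 0) + 0.5 * (diff == 0)).mean(axis=(1, 2))

    def auc_one(pos, neg):
        diff = pos[:, None] - neg[None, :]
        return float(((diff > 0) + 0.5 * (diff == 0)).mean())

    ip = rng.choice(pos_idx, size=(n_boot, m), replace=True)
    iq = rng.choice(neg_idx, size=(n_boot, n), replace=True)
    d = auc_batch(s1[ip], s1[iq]) - auc_batch(s2[ip], s2[iq])
    d0 = auc_one(s1[pos_idx], s1[neg_idx]) - auc_one(s2[pos_idx], s2[neg_idx])
    sd = d.std(ddof=1)
    if sd == 0:
        return 1.0
    return float(2 * sps.norm.sf(abs(d0) / sd))


@pytest.fixture(scope="session")
def default_cohort():
    """A default-condition synthetic cohort (n=72), fixed seed."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def large_cohort():
    """A large synthetic cohort for Monte-Carlo calibration checks."""
    return generate_cohort(CohortConfig(n_patients=10_000, seed=11))
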