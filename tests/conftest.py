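"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import pytest

import wintercjs as w


@pytest.fixture(scope="session")
def default_dataset():
    """One paper-shaped synthetic cohort (484 individuals, seed 1)."""
    cfg = w.default_config(seed=1)
    ds, away, truth = w.simulate(cfg)
    return ds, away, truth


@pytest.fixture(scope="session")
def m100_spec():
    return w.ParameterSpec(
        phi1=("age2", "dis"), phi2=("age2",), p=("ct", "age3", "dis")
    )


# ---------------------------------------------------------------------------
# Independent brute-force oracle for the conditional CJS likelihood
# ---------------------------------------------------------------------------

def history_prob_bruteforce(
    pattern: tuple[int, ...],
    phi: tuple[float, ...],
    p: tuple[float, ...],
) -> float:
    """P(detection pattern | released) by explicit path enumeration.

    ``phi[k]`` is survival over interval k (release -> occasion 1 is k=0),
    ``p[k]`` the detection probability at post-release occasion k+1;
    ``pattern`` is the 0/1 detection vector over those occasions.  Sums over
    every possible number of survived intervals; detections beyond death are
    impossible.
    """
    T = len(pattern)
    assert len(phi) == T and len(p) == T
    total = 0.0
    for d in range(T + 1):  # number of intervals survived
        if any(pattern[k] for k in range(d, T)):
            continue  # detected after death: impossible path
        pr = 1.0
        for k in range(d):
            pr *= phi[k]
        if d < T:
            pr *= 1.0 - phi[d]
        for k in range(d):
            pr *= p[k] if pattern[k] else 1.0 - p[k]
        total += pr
    return total


def all_patterns(T: int):
    return list(itertools.product((0, 1), repeat=T))
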