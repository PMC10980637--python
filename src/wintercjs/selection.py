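"""QAICc ranking, Akaike weights, parsimony rule, and stepwise selection.

Ranking uses the quasi-likelihood information criterion with small-sample
correction,

    QAICc = deviance / c-hat + 2K + 2K(K+1) / (n - K - 1),

with the number of marked individuals as effective sample size (a
conservative, configurable choice).  When several models sit within two
QAICc points of the best one, the one with the fewest parameters wins.

The stepwise procedure selects structure in two blocks (resighting p and
survival phi1/phi2): the non-focal block is held at its fullest candidate
parameterisation while the focal block's candidates are ranked, then the
winner is frozen and the other block is swept.  Both orders can be run and
compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cjs import FittedModel, ParameterSpec, fit
from .encounter import Dataset

__all__ = [
    "qaicc",
    "akaike_weights",
    "rank_models",
    "select_best",
    "stepwise",
    "stepwise_both_orders",
    "DEFAULT_PHI_CANDIDATES",
    "DEFAULT_P_CANDIDATES",
]

#: Survival candidates as (model id, phi1 terms, phi2 terms), mirroring the
#: main-text candidate structure (combinations of age, distance, flyway and
#: their region interaction on the two survival classes).
DEFAULT_PHI_CANDIDATES: list[tuple[str, tuple[str, ...], tuple[str, ...]]] = [
    ("m68",  ("age2", "region"), ("age2", "fly")),
    ("m69",  ("age2", "region"), ("age2", "dis")),
    ("m70",  ("age2", "region"), ("age2",)),
    ("m80",  ("age2", "dis", "fly"), ("age2",)),
    ("m98",  ("age2", "dis"), ("age2", "fly")),
    ("m99",  ("age2", "dis"), ("age2", "dis")),
    ("m100", ("age2", "dis"), ("age2",)),
    ("m104", ("age2", "region"), ("age2", "region")),
    ("m110", ("age2",), ("age2",)),
]

#: Resighting candidates as (model id, p terms).
DEFAULT_P_CANDIDATES: list[tuple[str, tuple[str, ...]]] = [
    ("p_t_age_dis", ("t", "age3", "dis")),
    ("p4",          ("ct", "age3", "dis")),
    ("p_ct_age",    ("ct", "age3")),
    ("p_ct_dis",    ("ct", "dis")),
    ("p_age_dis",   ("age3", "dis")),
    ("p_ct",        ("ct",)),
]


def qaicc(deviance: float, K: int, chat: float = 1.0, n: int = 0) -> float:
    """Quasi-AIC with small-sample correction; equals AICc when chat = 1."""
    if chat < 1.0:
        raise ValueError("chat must be >= 1 (floored for ranking)")
    if n <= K + 1:
        raise ValueError(f"effective sample size n={n} must exceed K+1={K + 1}")
    return deviance / chat + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def akaike_weights(qaicc_values) -> np.ndarray:
    """Shift-stable Akaike weights exp(-delta/2) normalised to sum 1."""
    q = np.asarray(qaicc_values, dtype=float)
    if q.size == 0 or not np.all(np.isfinite(q)):
        raise ValueError("need at least one finite QAICc value")
    delta = q - q.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def rank_models(
    fits: list[tuple[str, FittedModel]],
    chat: float = 1.0,
    n: int | None = None,
) -> pd.DataFrame:
    """Ranking table (Table-1 style), sorted by QAICc."""
    rows = []
    for mid, fm in fits:
        n_eff = fm.n_individuals if n is None else n
        q = qaicc(fm.deviance, fm.K, chat, n_eff)
        rows.append((mid, fm.spec.label, fm.K, fm.deviance, q, fm.converged))
    df = pd.DataFrame(
        rows, columns=["model", "spec", "K", "deviance", "QAICc", "converged"]
    )
    df = df.sort_values(["QAICc", "K"], kind="mergesort").reset_index(drop=True)
    df["dQAICc"] = df["QAICc"] - df["QAICc"].iloc[0]
    df["weight"] = akaike_weights(df["QAICc"].to_numpy())
    df.attrs["chat"] = chat
    df.attrs["n"] = n
    return df


def select_best(ranking: pd.DataFrame, threshold: float = 2.0) -> str:
    """Most parsimonious model within ``threshold`` QAICc of the best.

    Among rows with dQAICc < threshold, the smallest K wins; ties on K are
    broken by lower QAICc.
    """
    if len(ranking) == 0:
        raise ValueError("empty ranking")
    near = ranking[ranking["dQAICc"] < threshold]
    near = near.sort_values(["K", "QAICc"], kind="mergesort")
    return str(near["model"].iloc[0])


@dataclass
class StepwiseTrail:
    order: str
    step1: pd.DataFrame
    step2: pd.DataFrame
    best_spec: ParameterSpec
    best_id: tuple[str, str]
    warnings: list[str] = field(default_factory=list)


_FACTOR_BREADTH = {"age2": 2, "age3": 3, "dis": 3, "fly": 3, "region": 5,
                   "ct": 2, "t": 13}


def _breadth(terms: tuple[str, ...]) -> int:
    return sum(_FACTOR_BREADTH.get(t, 1) for t in terms)


def _fullest_p(candidates_p) -> tuple[str, ...]:
    return max((terms for _, terms in candidates_p), key=_breadth)


def _fullest_phi(candidates_phi) -> tuple[tuple[str, ...], tuple[str, ...]]:
    return max(
        ((p1, p2) for _, p1, p2 in candidates_phi),
        key=lambda t: _breadth(t[0]) + _breadth(t[1]),
    )


def _sweep(specs, dataset, chat_value, n, fit_kwargs, notes):
    fits = []
    for mid, spec in specs:
        try:
            fm = fit(spec, dataset, **fit_kwargs)
        except Exception as exc:  # non-convergent candidate: warn, exclude
            msg = f"model {mid} failed to fit: {exc}"
            warnings.warn(msg)
            notes.append(msg)
            continue
        if not fm.converged:
            notes.append(f"model {mid} flagged non-convergent (kept in table)")
        fits.append((mid, fm))
    if not fits:
        raise RuntimeError("no candidate model could be fitted")
    return rank_models(fits, chat=chat_value, n=n)


def stepwise(
    candidates_p: list[tuple[str, tuple[str, ...]]],
    candidates_phi: list[tuple[str, tuple[str, ...], tuple[str, ...]]],
    dataset: Dataset,
    chat: float = 1.0,
    order: str = "p_first",
    n: int | None = None,
    full_p: tuple[str, ...] | None = None,
    full_phi: tuple[tuple[str, ...], tuple[str, ...]] | None = None,
    **fit_kwargs,
) -> StepwiseTrail:
    """Two-step stepwise selection in the given order.

    ``order='p_first'`` keeps survival fully parameterised while ranking the
    resighting candidates, then freezes the winning p structure and ranks
    the survival candidates; ``'phi_first'`` reverses the two steps.
    """
    if order not in ("p_first", "phi_first"):
        raise ValueError("order must be 'p_first' or 'phi_first'")
    if not candidates_p or not candidates_phi:
        raise ValueError("candidate lists must be nonempty")
    full_p = _fullest_p(candidates_p) if full_p is None else full_p
    full_phi = _fullest_phi(candidates_phi) if full_phi is None else full_phi
    notes: list[str] = []

    if order == "p_first":
        specs1 = [
            (mid, ParameterSpec(phi1=full_phi[0], phi2=full_phi[1], p=terms))
            for mid, terms in candidates_p
        ]
        rank1 = _sweep(specs1, dataset, chat, n, fit_kwargs, notes)
        best_p_id = select_best(rank1)
        best_p = dict((m, t) for m, t in candidates_p)[best_p_id]
        specs2 = [
            (mid, ParameterSpec(phi1=p1, phi2=p2, p=best_p))
            for mid, p1, p2 in candidates_phi
        ]
        rank2 = _sweep(specs2, dataset, chat, n, fit_kwargs, notes)
        best_phi_id = select_best(rank2)
        p1, p2 = dict((m, (a, b)) for m, a, b in candidates_phi)[best_phi_id]
        best_spec = ParameterSpec(phi1=p1, phi2=p2, p=best_p)
        return StepwiseTrail("p_first", rank1, rank2, best_spec,
                             (best_p_id, best_phi_id), notes)

    specs1 = [
        (mid, ParameterSpec(phi1=p1, phi2=p2, p=full_p))
        for mid, p1, p2 in candidates_phi
    ]
    rank1 = _sweep(specs1, dataset, chat, n, fit_kwargs, notes)
    best_phi_id = select_best(rank1)
    p1, p2 = dict((m, (a, b)) for m, a, b in candidates_phi)[best_phi_id]
    specs2 = [
        (mid, ParameterSpec(phi1=p1, phi2=p2, p=terms))
        for mid, terms in candidates_p
    ]
    rank2 = _sweep(specs2, dataset, chat, n, fit_kwargs, notes)
    best_p_id = select_best(rank2)
    best_p = dict((m, t) for m, t in candidates_p)[best_p_id]
    best_spec = ParameterSpec(phi1=p1, phi2=p2, p=best_p)
    return StepwiseTrail("phi_first", rank1, rank2, best_spec,
                         (best_phi_id, best_p_id), notes)


def stepwise_both_orders(
    candidates_p,
    candidates_phi,
    dataset: Dataset,
    chat: float = 1.0,
    n: int | None = None,
    **fit_kwargs,
) -> tuple[StepwiseTrail, StepwiseTrail, bool]:
    """Run both orders; the agreement flag compares the final specs."""
    a = stepwise(candidates_p, candidates_phi, dataset, chat, "p_first",
                 n=n, **fit_kwargs)
    b = stepwise(candidates_p, candidates_phi, dataset, chat, "phi_first",
                 n=n, **fit_kwargs)
    agree = (a.best_spec.phi1 == b.best_spec.phi1
             and a.best_spec.phi2 == b.best_spec.phi2
             and a.best_spec.p == b.best_spec.p)
    return a, b, agree
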