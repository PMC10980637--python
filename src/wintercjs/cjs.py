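"""Constrained Cormack-Jolly-Seber model: design, likelihood, fitting, CIs.

The model conditions on first release (the winter-entry sighting) and
estimates three parameter classes on the logit scale:

* ``phi1`` — apparent survival over the half-year from winter entry to the
  next breeding season,
* ``phi2`` — apparent survival over each subsequent annual interval,
* ``p``   — breeding-season resighting probability, with a block of years
  structurally fixed to zero (no colony resightings despite effort).

Each class is constrained by an additive factor formula with treatment
(reference-level) coding; the only interaction supported is distance x
flyway, which spans exactly the five wintering-region cells.

Factor vocabulary
-----------------
survival:   ``age2`` (immature/adult at interval start), ``dis``, ``fly``,
            ``region`` (= dis*fly), ``t`` (interval-start year), ``const``
resighting: ``age3`` (2 cy / 3 cy / 4+ cy, capped), ``dis``, ``fly``,
            ``ct`` (camera-trap effort period), ``t``, ``const``

Ages follow the calendar-year (cy) convention with hatch year = 1 cy: a bird
is adult from its fourth breeding season.  For the half-year entry interval
the age label is the half-age at the entry winter (0.5 ... 4.5; adult iff
>= 4).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .encounter import Dataset

__all__ = [
    "DEFAULT_FIXED_P_YEARS",
    "CAMERA_TRAP_START",
    "ParameterSpec",
    "DesignMatrices",
    "FittedModel",
    "IdentifiabilityError",
    "build_design",
    "neg2_log_likelihood",
    "fit",
    "profile_ci",
    "marray_neg2_log_likelihood",
]

DEFAULT_FIXED_P_YEARS: tuple[int, ...] = tuple(range(2008, 2014))
CAMERA_TRAP_START = 2016

_PHI_FACTORS = ("const", "age2", "dis", "fly", "region", "t")
_P_FACTORS = ("const", "age3", "dis", "fly", "ct", "t")
_ALIASES = {
    "2age": "age2",
    "3age": "age3",
    "dis*fly": "region",
    "dis:fly": "region",
    "1": "const",
}


class IdentifiabilityError(ValueError):
    """Raised when a design block is rank deficient after fixing."""


def _normalise_terms(terms, allowed) -> tuple[str, ...]:
    out = []
    for t in terms:
        t = _ALIASES.get(str(t).strip(), str(t).strip())
        if t not in allowed:
            raise ValueError(f"unknown factor {t!r}; allowed: {allowed}")
        if t != "const" and t not in out:
            out.append(t)
    return tuple(out)


@dataclass(frozen=True)
class ParameterSpec:
    """Symbolic structure of one candidate model.

    ``phi1``, ``phi2`` and ``p`` are tuples of factor names (an empty tuple
    is the constant model).  ``fixed_p_years`` are occasions whose resighting
    probability is a hard structural zero, excluded from the free-parameter
    count.
    """

    phi1: tuple[str, ...] = ()
    phi2: tuple[str, ...] = ()
    p: tuple[str, ...] = ()
    fixed_p_years: tuple[int, ...] = DEFAULT_FIXED_P_YEARS

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi1", _normalise_terms(self.phi1, _PHI_FACTORS))
        object.__setattr__(self, "phi2", _normalise_terms(self.phi2, _PHI_FACTORS))
        object.__setattr__(self, "p", _normalise_terms(self.p, _P_FACTORS))
        object.__setattr__(self, "fixed_p_years", tuple(sorted(self.fixed_p_years)))

    @staticmethod
    def _fmt(terms: tuple[str, ...]) -> str:
        return " + ".join(terms) if terms else "const"

    @property
    def label(self) -> str:
        return (
            f"phi1 ~ {self._fmt(self.phi1)}; phi2 ~ {self._fmt(self.phi2)}; "
            f"p ~ {self._fmt(self.p)}"
        )

    @classmethod
    def parse(cls, text: str) -> "ParameterSpec":
        """Parse the small model-formula syntax, e.g.

        ``"phi1 ~ age2 + dis; phi2 ~ age2; p ~ ct + age3 + dis;
        fix p[2008:2013]=0"``
        """
        blocks: dict[str, tuple[str, ...]] = {}
        fixed: tuple[int, ...] | None = None
        for clause in filter(None, (c.strip() for c in text.split(";"))):
            m = re.fullmatch(r"fix\s+p\[(\d+):(\d+)\]\s*=\s*0", clause)
            if m:
                fixed = tuple(range(int(m.group(1)), int(m.group(2)) + 1))
                continue
            if "~" not in clause:
                raise ValueError(f"cannot parse clause {clause!r}")
            lhs, rhs = (s.strip() for s in clause.split("~", 1))
            terms = tuple(t.strip() for t in rhs.split("+") if t.strip())
            if terms == ("const",) or terms == ("1",):
                terms = ()
            blocks[lhs] = terms
        kwargs = {}
        if fixed is not None:
            kwargs["fixed_p_years"] = fixed
        return cls(
            phi1=blocks.get("phi1", ()),
            phi2=blocks.get("phi2", ()),
            p=blocks.get("p", ()),
            **kwargs,
        )


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _treatment_matrix(
    cells: pd.DataFrame, terms: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded model matrix over the observed factor cells."""
    cols = [np.ones(len(cells))]
    names = ["(intercept)"]
    for term in terms:
        col = cells[term]
        if isinstance(col.dtype, pd.CategoricalDtype):
            present = set(col.dropna())
            levels = [lv for lv in col.cat.categories if lv in present]
        else:
            levels = list(pd.unique(col))
        if term == "fly" and "dis" in terms and "RES" in levels:
            # residents form one cell: their flyway level is structurally
            # aliased with dis[RES] in an additive dis + fly model
            levels = [lv for lv in levels if lv != "RES"]
        for lev in levels[1:]:
            cols.append((cells[term] == lev).to_numpy(dtype=float))
            names.append(f"{term}[{lev}]")
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names: list[str], block: str) -> None:
    if X.size == 0:
        return
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True)
        aliased = [names[j] for j in piv[r:]]
        raise IdentifiabilityError(
            f"{block} design is rank deficient; aliased columns: {aliased}"
        )


_AGE2_LEVELS = ("imm", "ad")
_DIS_ORDER = ("LD", "SD", "RES")
_FLY_ORDER = ("EAF", "CEF", "RES")
_REGION_ORDER = ("EAF LD", "EAF SD", "CEF LD", "CEF SD", "RES")
_CT_ORDER = ("no_ct", "ct")


def _ordered(series_values, order) -> pd.Series:
    cat = pd.Categorical(series_values, categories=list(order), ordered=True)
    return pd.Series(cat)


@dataclass
class DesignMatrices:
    """Mapping from free link-scale parameters to per-class probabilities.

    The three blocks are independent; the full parameter vector is the
    concatenation ``[beta_phi1, beta_phi2, beta_p]``.  ``phi_cells`` rows
    are the distinct survival-parameter classes (first entry interval then
    annual intervals), ``p_cells`` the free resighting classes; structurally
    fixed resighting occasions carry probability zero and no columns.
    """

    spec: ParameterSpec
    phi_cells: pd.DataFrame       # block ('phi1'/'phi2') + factor levels
    p_cells: pd.DataFrame
    X_phi: np.ndarray             # (n_phi_cells, k1 + k2) block diagonal
    X_p: np.ndarray               # (n_p_cells, kp)
    colnames: list[str]
    k1: int
    k2: int
    kp: int
    # per-pseudo-individual arrays (identical histories collapsed, weighted)
    w: np.ndarray                 # (n,) multiplicities
    f: np.ndarray                 # (n,) first post-entry occasion index
    L: np.ndarray                 # (n,) last detection index (f-1 if none)
    Y: np.ndarray                 # (n, T) detections
    phi_idx: np.ndarray           # (n, T) cell index of interval ending at j, -1 invalid
    p_idx: np.ndarray             # (n, T) free p-cell index, -1 fixed/invalid
    valid: np.ndarray             # (n, T) j >= f
    n_individuals: int
    T: int
    years: tuple[int, ...]

    @property
    def K(self) -> int:
        return self.k1 + self.k2 + self.kp

    def split(self, theta: np.ndarray):
        return (
            theta[: self.k1],
            theta[self.k1 : self.k1 + self.k2],
            theta[self.k1 + self.k2 :],
        )

    def probabilities(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Real-scale per-cell (phi, p) probabilities.

        Clipped away from 0/1 by 1e-12 so the likelihood stays finite while
        the optimizer explores the link scale.
        """
        b1, b2, bp = self.split(np.asarray(theta, dtype=float))
        eps = 1e-12
        phi = np.clip(special.expit(self.X_phi @ np.concatenate([b1, b2])),
                      eps, 1 - eps)
        p = (np.clip(special.expit(self.X_p @ bp), eps, 1 - eps)
             if self.kp else np.zeros(0))
        return phi, p

    def real_estimates(self, theta: np.ndarray) -> pd.DataFrame:
        """Per-class real-scale estimates (no intervals)."""
        phi, p = self.probabilities(theta)
        a = self.phi_cells.copy()
        a["estimate"] = phi
        b = self.p_cells.copy()
        b["estimate"] = p
        return pd.concat([a, b], ignore_index=True)


def build_design(spec: ParameterSpec, dataset: Dataset) -> DesignMatrices:
    """Construct treatment-coded design matrices and likelihood index arrays.

    Identical pseudo-individuals (same covariates and detection history) are
    collapsed with multiplicity weights; this changes nothing numerically.
    """
    if not dataset.histories:
        raise ValueError("dataset is empty")
    years = dataset.axis.breeding_years
    T = len(years)
    y0 = years[0]
    fixed = set(spec.fixed_p_years)

    rows = []
    for h in dataset.histories:
        rows.append((
            h.region.label,
            h.region.distance,
            h.region.flyway,
            h.birth_year,
            h.entry_winter,
            tuple(int(d) for d in h.detections),
        ))
    uniq: dict[tuple, int] = {}
    order: list[tuple] = []
    counts: list[int] = []
    for r in rows:
        if r in uniq:
            counts[uniq[r]] += 1
        else:
            uniq[r] = len(order)
            order.append(r)
            counts.append(1)
    n = len(order)
    w = np.asarray(counts, dtype=float)

    f = np.empty(n, dtype=np.int64)
    Y = np.zeros((n, T), dtype=np.int8)
    for i, (_, _, _, b, e, det) in enumerate(order):
        fi = e - y0 + 1
        f[i] = fi
        for k, d in enumerate(det):
            if d:
                Y[i, fi + k] = 1

    # --- survival cells -----------------------------------------------------
    def phi_record(block, b, e, region, dis, fly, j):
        # interval ending at occasion index j; start year and age at start
        if block == "phi1":
            start_year = e
            adult = (e - b) >= 4
        else:
            start_year = y0 + j - 1
            adult = (start_year - b + 1) >= 4
        rec = {"block": block}
        for term in (spec.phi1 if block == "phi1" else spec.phi2):
            rec[term] = {
                "age2": _AGE2_LEVELS[int(adult)],
                "dis": dis,
                "fly": fly,
                "region": region,
                "t": start_year,
            }[term]
        return rec

    phi_idx = np.full((n, T), -1, dtype=np.int64)
    p_idx = np.full((n, T), -1, dtype=np.int64)
    phi_key_to_cell: dict[tuple, int] = {}
    phi_records: list[dict] = []
    p_key_to_cell: dict[tuple, int] = {}
    p_records: list[dict] = []
    for i, (region, dis, fly, b, e, det) in enumerate(order):
        for j in range(f[i], T):
            block = "phi1" if j == f[i] else "phi2"
            rec = phi_record(block, b, e, region, dis, fly, j)
            key = tuple(sorted(rec.items()))
            if key not in phi_key_to_cell:
                phi_key_to_cell[key] = len(phi_records)
                phi_records.append(rec)
            phi_idx[i, j] = phi_key_to_cell[key]
            year = y0 + j
            if year in fixed:
                continue
            prec = {}
            for term in spec.p:
                prec[term] = {
                    "age3": min(year - b + 1, 4),
                    "dis": dis,
                    "fly": fly,
                    "ct": "ct" if year >= CAMERA_TRAP_START else "no_ct",
                    "t": year,
                }[term]
            pkey = tuple(sorted(prec.items()))
            if pkey not in p_key_to_cell:
                p_key_to_cell[pkey] = len(p_records)
                p_records.append(prec)
            p_idx[i, j] = p_key_to_cell[pkey]

    def cells_frame(records, blockname, terms) -> pd.DataFrame:
        df = pd.DataFrame(records) if records else pd.DataFrame()
        if "block" not in df.columns:
            df.insert(0, "block", blockname)
        # impose canonical level order so the reference level is stable
        orders = {"age2": _AGE2_LEVELS, "dis": _DIS_ORDER, "fly": _FLY_ORDER,
                  "region": _REGION_ORDER, "ct": _CT_ORDER,
                  "age3": (2, 3, 4)}
        for term in terms:
            if term in df.columns:
                if term == "t":
                    lv = sorted(df[term].unique())
                else:
                    lv = [x for x in orders[term] if x in set(df[term])]
                df[term] = _ordered(df[term], lv)
        return df

    phi_df = cells_frame(phi_records, None, _PHI_FACTORS[1:])
    p_df = cells_frame(p_records, "p", _P_FACTORS[1:])

    mats, names, sizes = [], [], []
    for blockname, terms in (("phi1", spec.phi1), ("phi2", spec.phi2)):
        sub = phi_df[phi_df["block"] == blockname] if len(phi_df) else phi_df
        if len(sub) == 0:
            # no interval of this kind in the data: block has no parameters
            mats.append((np.zeros(0, dtype=int), np.zeros((0, 0))))
            sizes.append(0)
            continue
        X, nm = _treatment_matrix(sub.reset_index(drop=True), terms)
        _check_rank(X, nm, blockname)
        mats.append((sub.index.to_numpy(), X))
        names.extend(f"{blockname}:{s}" for s in nm)
        sizes.append(X.shape[1])
    k1, k2 = sizes
    n_phi = len(phi_df)
    X_phi = np.zeros((n_phi, k1 + k2))
    (idx1, X1), (idx2, X2) = mats
    X_phi[idx1, :k1] = X1
    X_phi[idx2, k1:] = X2

    if p_records:
        Xp, nmp = _treatment_matrix(p_df.drop(columns=["block"]).reset_index(drop=True), spec.p)
        _check_rank(Xp, nmp, "p")
        names.extend(f"p:{s}" for s in nmp)
        kp = Xp.shape[1]
    else:
        Xp = np.zeros((0, 0))
        kp = 0

    det_any = Y.astype(bool)
    L = np.where(det_any.any(axis=1), T - 1 - det_any[:, ::-1].argmax(axis=1), f - 1)
    valid = np.arange(T)[None, :] >= f[:, None]

    return DesignMatrices(
        spec=spec, phi_cells=phi_df.reset_index(drop=True),
        p_cells=p_df.reset_index(drop=True),
        X_phi=X_phi, X_p=Xp, colnames=names, k1=k1, k2=k2, kp=kp,
        w=w, f=f, L=L.astype(np.int64), Y=Y, phi_idx=phi_idx, p_idx=p_idx,
        valid=valid, n_individuals=len(dataset.histories), T=T, years=tuple(years),
    )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _expand(design: DesignMatrices, theta: np.ndarray):
    phi_cells, p_cells = design.probabilities(theta)
    PHI = np.where(design.phi_idx >= 0,
                   phi_cells[np.clip(design.phi_idx, 0, None)], 1.0)
    if design.kp:
        P = np.where(design.p_idx >= 0, p_cells[np.clip(design.p_idx, 0, None)], 0.0)
    else:
        P = np.zeros_like(PHI)
    return PHI, P, phi_cells, p_cells


def _chi(PHI: np.ndarray, P: np.ndarray) -> np.ndarray:
    """CH[:, j] = P(never detected at occasions > j | alive at slot j)."""
    n, T = PHI.shape
    CH = np.ones((n, T))
    for j in range(T - 2, -1, -1):
        CH[:, j] = (1.0 - PHI[:, j + 1]) + PHI[:, j + 1] * (1.0 - P[:, j + 1]) * CH[:, j + 1]
    return CH


def neg2_log_likelihood(
    theta: np.ndarray,
    design: DesignMatrices,
    gradient: bool = False,
):
    """-2 x conditional log-likelihood of the detection histories.

    Conditions on the winter-entry release (initial state probability 1);
    each history contributes the product of survival and detection terms up
    to the last detection, times the never-seen-again tail probability
    computed by backward recursion.  With ``gradient=True`` also returns the
    analytic gradient with respect to the free link-scale parameters.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (design.K,):
        raise ValueError(f"theta must have length K={design.K}")
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    PHI, P, phi_cells, p_cells = _expand(design, theta)
    Y, w, f, L, T = design.Y, design.w, design.f, design.L, design.T
    n = PHI.shape[0]
    CH = _chi(PHI, P)
    jj = np.arange(T)[None, :]
    obs = design.valid & (jj <= L[:, None])

    with np.errstate(divide="ignore"):
        logPHI = np.where(obs, np.log(PHI), 0.0)
        term_p = np.where(Y == 1, np.log(np.where(P > 0, P, 1.0)),
                          np.log1p(-P))
    if np.any((Y == 1) & (P <= 0.0) & obs):
        raise ValueError("detection at an occasion with p fixed to zero")
    rows = np.arange(n)
    ll = (np.where(obs, logPHI + term_p, 0.0)).sum(axis=1) + np.log(CH[rows, L])
    value = -2.0 * float(np.dot(w, ll))
    if not gradient:
        return value

    # adjoint of the tail probability: A[i, j] = d ll_i / d CH[i, j]
    A = np.zeros((n, T))
    A[rows, L] = 1.0 / CH[rows, L]
    for j in range(1, T):
        prop = A[:, j - 1] * PHI[:, j] * (1.0 - P[:, j])
        A[:, j] = np.where(j > L, prop, A[:, j])
    Ashift = np.zeros((n, T))
    Ashift[:, 1:] = A[:, :-1]          # A[:, j-1] aligned at column j

    G_PHI = np.where(obs, 1.0 / PHI, 0.0) + Ashift * (
        -1.0 + (1.0 - P) * CH
    ) * (jj > L[:, None])
    G_P = np.where(obs, np.where(Y == 1, 1.0 / np.where(P > 0, P, 1.0),
                                 -1.0 / (1.0 - P)), 0.0)
    G_P = G_P - Ashift * PHI * CH * (jj > L[:, None])

    Wg = w[:, None]
    mask_phi = design.phi_idx >= 0
    g_phi_cells = np.bincount(
        design.phi_idx[mask_phi],
        weights=(G_PHI * Wg)[mask_phi],
        minlength=len(phi_cells),
    )
    g_eta_phi = g_phi_cells * phi_cells * (1.0 - phi_cells)
    grad = np.zeros(design.K)
    grad[: design.k1 + design.k2] = design.X_phi.T @ g_eta_phi
    if design.kp:
        mask_p = design.p_idx >= 0
        g_p_cells = np.bincount(
            design.p_idx[mask_p],
            weights=(G_P * Wg)[mask_p],
            minlength=len(p_cells),
        )
        g_eta_p = g_p_cells * p_cells * (1.0 - p_cells)
        grad[design.k1 + design.k2 :] = design.X_p.T @ g_eta_p
    return value, -2.0 * grad


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    spec: ParameterSpec
    design: DesignMatrices
    theta: np.ndarray
    deviance: float
    K: int
    converged: bool
    grad_norm: float
    n_individuals: int
    n_starts_used: int = 1
    boundary: bool = False
    message: str = ""

    def real_estimates(self) -> pd.DataFrame:
        est = self.design.real_estimates(self.theta)
        est["boundary"] = (est["estimate"] > 1 - 1e-6) | (est["estimate"] < 1e-6)
        return est


def fit(
    spec: ParameterSpec,
    dataset: Dataset,
    n_starts: int = 5,
    seed: int = 0,
    gtol: float = 1e-8,
    design: DesignMatrices | None = None,
) -> FittedModel:
    """Maximum-likelihood fit on the logit link with seeded multi-start.

    The first start is the origin; the remaining ``n_starts - 1`` are drawn
    uniform(-2, 2) on the link scale from a seeded generator.  The best
    optimum is retained; non-convergence is reported, never silently
    ignored.
    """
    if design is None:
        design = build_design(spec, dataset)
    K = design.K
    rng = np.random.default_rng([int(seed) % (2**31), 0xC15])
    starts = [np.zeros(K)]
    starts += [rng.uniform(-2, 2, size=K) for _ in range(max(0, n_starts - 1))]

    def objective(th):
        return neg2_log_likelihood(th, design, gradient=True)

    best = None
    failures = []
    for th0 in starts:
        res = optimize.minimize(
            objective, th0, jac=True, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": gtol / 10},
        )
        if not np.isfinite(res.fun):
            failures.append(res.message)
            continue
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None:
        raise RuntimeError(f"all starts failed to optimize: {failures}")
    if np.max(np.abs(best.jac)) > gtol and not np.any(np.abs(best.x) > 15):
        # polish: BFGS terminates on gradient norm rather than f-decrease
        pol = optimize.minimize(
            objective, best.x, jac=True, method="BFGS",
            options={"maxiter": 200, "gtol": gtol},
        )
        if np.isfinite(pol.fun) and pol.fun <= best.fun + 1e-9:
            best = pol
    gnorm = float(np.max(np.abs(best.jac)))
    boundary = bool(np.any(np.abs(best.x) > 15))
    # tolerance scales with the deviance: float64 limits the achievable
    # gradient norm to roughly 1e-7 of the objective's magnitude; near a
    # boundary the link-scale gradient legitimately plateaus
    converged = gnorm < max(gtol, 1e-7 * (1.0 + abs(best.fun))) or boundary
    return FittedModel(
        spec=spec, design=design, theta=np.asarray(best.x),
        deviance=float(best.fun), K=K, converged=converged, grad_norm=gnorm,
        n_individuals=design.n_individuals, n_starts_used=len(starts),
        boundary=boundary, message=str(best.message),
    )


def wald_se(fitted: FittedModel) -> np.ndarray:
    """Link-scale standard errors from a numerical Hessian."""
    from statsmodels.tools.numdiff import approx_hess1

    def f(th):
        return 0.5 * neg2_log_likelihood(th, fitted.design)

    H = approx_hess1(fitted.theta, f)
    cov = np.linalg.pinv(H)
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


# ---------------------------------------------------------------------------
# Profile-likelihood intervals
# ---------------------------------------------------------------------------

@dataclass
class ProfileInterval:
    lower: float
    upper: float
    estimate: float
    level: float
    flag: str = ""


def _profile_deviance(design, x_vec, Z, eta, gamma0):
    """Minimised deviance subject to x'beta = eta (null-space reparam)."""
    base = x_vec * eta / float(x_vec @ x_vec)

    def obj(g):
        th = base + Z @ g
        return neg2_log_likelihood(th, design, gradient=True)

    def obj_g(g):
        v, gr = obj(g)
        return v, Z.T @ gr

    if Z.shape[1] == 0:
        return neg2_log_likelihood(base, design), gamma0
    res = optimize.minimize(obj_g, gamma0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 300, "ftol": 1e-12})
    return float(res.fun), res.x


def profile_ci(
    fitted: FittedModel,
    cell: int | dict,
    level: float = 0.95,
    chat: float = 1.0,
) -> ProfileInterval:
    """Profile-likelihood interval for one real-scale parameter class.

    ``cell`` is a row index into the concatenated cell table
    (``fitted.real_estimates()``) or a dict of factor levels selecting a
    unique row.  Bounds sit where the c-hat-scaled profile deviance rises by
    the chi-square(1) quantile above its minimum; each bound is located by
    monotone root bracketing on the link scale.
    """
    design = fitted.design
    est = design.real_estimates(fitted.theta)
    if isinstance(cell, dict):
        m = np.ones(len(est), dtype=bool)
        for k, v in cell.items():
            m &= est[k].to_numpy() == v
        idx = np.flatnonzero(m)
        if len(idx) != 1:
            raise ValueError(f"cell selector {cell} matches {len(idx)} rows")
        cell = int(idx[0])
    n_phi = len(design.phi_cells)
    x_vec = np.zeros(design.K)
    if cell < n_phi:
        x_vec[: design.k1 + design.k2] = design.X_phi[cell]
    else:
        x_vec[design.k1 + design.k2 :] = design.X_p[cell - n_phi]

    eta_hat = float(x_vec @ fitted.theta)
    p_hat = float(special.expit(eta_hat))
    if level <= 0:
        return ProfileInterval(p_hat, p_hat, p_hat, level, flag="degenerate")
    if not fitted.converged:
        raise RuntimeError("profile_ci requires a converged fit")
    crit = float(stats.chi2.ppf(level, df=1)) * float(chat)
    dev0 = fitted.deviance

    from scipy.linalg import null_space

    Z = null_space(x_vec[None, :])
    # gamma for the MLE under the reparameterisation
    gamma_hat = Z.T @ (fitted.theta - x_vec * eta_hat / float(x_vec @ x_vec))

    if abs(eta_hat) > 15:  # estimate effectively at the boundary
        if eta_hat > 0:
            return ProfileInterval(np.nan, 1.0, p_hat, level, flag="boundary_upper")
        return ProfileInterval(0.0, np.nan, p_hat, level, flag="boundary_lower")

    def excess(eta, state={"g": gamma_hat}):
        dev, state["g"] = _profile_deviance(design, x_vec, Z, eta, state["g"])
        return dev - dev0 - crit

    bounds = []
    flags = []
    for direction in (-1.0, +1.0):
        step = 0.25
        eta_in, val_in = eta_hat, -crit
        eta_out = None
        for _ in range(60):
            eta_try = eta_in + direction * step
            v = excess(eta_try)
            if v > 0:
                eta_out = eta_try
                break
            eta_in, val_in = eta_try, v
            step *= 1.6
            if abs(eta_try) > 20:
                break
        if eta_out is None:
            bounds.append(1.0 if direction > 0 else 0.0)
            flags.append("boundary_upper" if direction > 0 else "boundary_lower")
            continue
        lo, hi = sorted((eta_in, eta_out))
        root = optimize.brentq(excess, lo, hi, xtol=1e-5)
        bounds.append(float(special.expit(root)))
    lo, hi = min(bounds), max(bounds)
    return ProfileInterval(lo, hi, p_hat, level, flag=";".join(flags))


# ---------------------------------------------------------------------------
# m-array (multinomial) likelihood for time-structured models
# ---------------------------------------------------------------------------

def marray_neg2_log_likelihood(
    marray,
    phi1_by_year: dict[int, float],
    phi2_by_year: dict[int, float],
    p_by_year: dict[int, float],
) -> float:
    """-2 log multinomial likelihood of a new/old-stratified m-array.

    Valid when survival depends only on (interval-end year, whether the
    release was the winter entry) and detection only on year; exactly equal
    to the individual-history likelihood in that case (the m-array is the
    sufficient statistic).  Omits the multinomial coefficient, matching the
    convention of :func:`neg2_log_likelihood`.
    """
    years = marray.occasions
    T = len(years)
    ll = 0.0
    for g in range(len(marray.groups)):
        for s in (0, 1):
            for i in range(T):
                R = marray.releases[g, s, i]
                if R == 0:
                    continue
                probs = np.zeros(T)
                for j in range(i + 1, T):
                    pr = 1.0
                    for k in range(i + 1, j + 1):
                        yk = years[k]
                        phi = (phi1_by_year[yk] if (s == 0 and k == i + 1)
                               else phi2_by_year[yk])
                        pr *= phi
                        pk = p_by_year[yk]
                        pr *= pk if k == j else (1.0 - pk)
                    probs[j] = pr
                chi = 1.0 - probs.sum()
                for j in range(i + 1, T):
                    if marray.m[g, s, i, j]:
                        ll += marray.m[g, s, i, j] * np.log(probs[j])
                nv = R - marray.m[g, s, i].sum()
                if nv:
                    ll += nv * np.log(chi)
    return -2.0 * ll
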