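"""Gaussian mixed-model inference on log tracking error.

The analysis model is a linear mixed model with a subject random
intercept:

    log(error)_ij = x_ij' beta + u_i + eps_ij,
    u_i ~ N(0, sigma_u^2),  eps_ij ~ N(0, sigma_e^2),

fitted by maximum likelihood (ML, not REML, because nested-model deviance
tests change the fixed effects). Group size enters as orthogonal
polynomial codes over the levels {1, 10, 30, 50}; coloration and speed
condition are treatment-coded factors (reference levels: trinary,
constant). Nested models are compared by the change in deviance referred
to a chi-square with df equal to the difference in parameter counts.

The fit profiles the likelihood over the variance ratio
lambda = sigma_u^2 / sigma_e^2: given lambda, the GLS estimate of beta and
the ML estimate of sigma_e^2 are closed-form via the classic
"partial group-mean centring" transform y_ij - theta_g ybar_g with
theta_g = 1 - (1 + lambda n_g)^(-1/2), leaving a one-dimensional
optimization. This keeps a full fit at a few milliseconds, which the
simulation-based calibration and recovery checks rely on.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: factor component name -> column in the records table
FACTOR_COLUMNS = {"coloration": "coloration", "speed": "speed_cond"}
DEFAULT_REFERENCES = {"coloration": "trinary", "speed": "constant"}


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def orthogonal_poly(levels: Sequence[float], degree: int) -> np.ndarray:
    """Orthonormal polynomial contrast codes over distinct levels.

    Returns an array of shape (len(levels), degree) whose columns are
    mutually orthogonal, orthogonal to the constant, and unit-norm over
    the levels (the coding R's ``poly`` uses).
    """
    x = np.asarray(sorted(levels), dtype=float)
    if degree >= len(x):
        raise ValueError(f"degree {degree} needs > {degree} distinct levels")
    V = np.vander(x - x.mean(), degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    Q = Q * np.sign(np.diag(R))  # fix signs so codes increase with x
    return Q[:, 1:]


def _parse_term(term: str) -> tuple[tuple[str, ...], int]:
    """Canonicalize a term string; returns (components, poly order or 0)."""
    comps = [c.strip() for c in term.split(":") if c.strip()]
    if not comps:
        raise ValueError(f"empty term: {term!r}")
    poly_order = 0
    factors = []
    for c in comps:
        if c.startswith("n^"):
            if poly_order:
                raise ValueError(f"term {term!r} has two group-size components")
            poly_order = int(c[2:])
            if poly_order < 1:
                raise ValueError(f"bad polynomial order in {term!r}")
        elif c in FACTOR_COLUMNS:
            if c in factors:
                raise ValueError(f"repeated component in {term!r}")
            factors.append(c)
        else:
            raise ValueError(f"unknown term component {c!r} in {term!r}")
    ordered = ([f"n^{poly_order}"] if poly_order else []) + sorted(factors)
    return tuple(ordered), poly_order


def _canonical(term: str) -> str:
    comps, _ = _parse_term(term)
    return ":".join(comps)


def _check_hierarchy(canon: set[str]) -> None:
    """Every marginal sub-term of an included term must be included."""
    for term in canon:
        comps, poly_order = _parse_term(term)
        for r in range(1, len(comps)):
            for sub in combinations(comps, r):
                sub_t = ":".join(sub)
                if sub_t not in canon:
                    raise ValueError(
                        f"ill-formed term set: {term!r} requires marginal "
                        f"term {sub_t!r}"
                    )
        if poly_order >= 2:
            lower = term.replace(f"n^{poly_order}", f"n^{poly_order - 1}")
            if lower not in canon:
                raise ValueError(
                    f"ill-formed term set: {term!r} requires {lower!r} "
                    "(polynomial hierarchy)"
                )


@dataclass
class Design:
    """Response, fixed-effects matrix and grouping for one model."""

    y: np.ndarray
    X: np.ndarray
    column_names: list[str]
    groups: np.ndarray  # integer subject codes, 0..n_groups-1
    group_labels: np.ndarray
    terms: frozenset[str]

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)


def build_design(
    records: pd.DataFrame,
    terms: Sequence[str],
    references: dict[str, str] | None = None,
    drop_practice: bool = True,
) -> Design:
    """Build the fixed-effects design for a term specification.

    ``terms`` are strings such as ``"n^1"``, ``"n^2"``, ``"coloration"``,
    ``"speed"`` and interactions like ``"n^2:coloration:speed"``. The term
    set must respect marginality (all sub-terms present). Group size is
    coded with orthogonal polynomials over the distinct values present;
    factors are treatment-coded against their reference level.
    """
    if len(records) == 0:
        raise ValueError("empty records table")
    if drop_practice and "is_practice" in records:
        records = records.loc[~records["is_practice"].astype(bool)]
    refs = {**DEFAULT_REFERENCES, **(references or {})}

    canon = {_canonical(t) for t in terms}
    _check_hierarchy(canon)
    max_order = max((_parse_term(t)[1] for t in canon), default=0)

    n_vals = np.asarray(records["n_agents"], dtype=float)
    levels = np.unique(n_vals)
    poly_cols: dict[int, np.ndarray] = {}
    if max_order:
        codes = orthogonal_poly(levels, max_order)
        level_index = {v: i for i, v in enumerate(levels)}
        row_idx = np.array([level_index[v] for v in n_vals])
        for k in range(1, max_order + 1):
            poly_cols[k] = codes[row_idx, k - 1]

    factor_cols: dict[str, list[tuple[str, np.ndarray]]] = {}
    for fac, col in FACTOR_COLUMNS.items():
        if col not in records:
            continue
        vals = records[col].astype(str).to_numpy()
        lv = sorted(set(vals))
        ref = refs.get(fac)
        if ref not in lv:
            if any(fac in _parse_term(t)[0] for t in canon):
                raise ValueError(f"reference level {ref!r} absent for factor {fac!r}")
            continue
        factor_cols[fac] = [
            (f"{fac}[{l}]", (vals == l).astype(float)) for l in lv if l != ref
        ]

    columns = [np.ones(len(records))]
    names = ["Intercept"]

    def term_sort_key(t):
        comps, order = _parse_term(t)
        return (len(comps), order, t)

    for term in sorted(canon, key=term_sort_key):
        comps, order = _parse_term(term)
        pieces: list[list[tuple[str, np.ndarray]]] = []
        if order:
            pieces.append([(f"n^{order}", poly_cols[order])])
        for c in comps:
            if c.startswith("n^"):
                continue
            if c not in factor_cols:
                raise ValueError(f"factor {c!r} not present in records")
            pieces.append(factor_cols[c])
        prods = [("", np.ones(len(records)))]
        for piece in pieces:
            prods = [
                (f"{nm}:{pn}" if nm else pn, col * pc)
                for nm, col in prods
                for pn, pc in piece
            ]
        for nm, col in prods:
            names.append(nm)
            columns.append(col)

    X = np.column_stack(columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    codes_g, labels_g = pd.factorize(records["subject_id"])
    y = np.asarray(records["log_error"], dtype=float)
    return Design(
        y=y,
        X=X,
        column_names=names,
        groups=codes_g,
        group_labels=np.asarray(labels_g),
        terms=frozenset(canon),
    )


def factorial_terms(
    degree: int = 2,
    two_way: bool = True,
    three_way: bool = True,
    drop: Sequence[str] = (),
) -> list[str]:
    """Term set for the factorial analysis: poly(n, degree) x coloration x speed.

    ``drop`` removes whole interaction families by canonical name stem,
    e.g. ``drop=["n:speed"]`` removes every ``n^k:speed`` term.
    """
    terms = [f"n^{k}" for k in range(1, degree + 1)] + ["coloration", "speed"]
    if two_way:
        terms += [f"n^{k}:coloration" for k in range(1, degree + 1)]
        terms += [f"n^{k}:speed" for k in range(1, degree + 1)]
        terms += ["coloration:speed"]
    if three_way:
        terms += [f"n^{k}:coloration:speed" for k in range(1, degree + 1)]

    def dropped(t: str) -> bool:
        comps, order = _parse_term(t)
        stem = ":".join(("n" if c.startswith("n^") else c) for c in comps)
        return stem in drop

    return [t for t in terms if not dropped(t)]


# ---------------------------------------------------------------------------
# maximum-likelihood fit
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    """ML fit of the random-intercept Gaussian mixed model."""

    beta: np.ndarray
    se: np.ndarray
    column_names: list[str]
    sigma_u2: float
    sigma_e2: float
    loglik: float
    n_obs: int
    n_groups: int
    n_params: int  # fixed effects + 2 variance components
    converged: bool
    terms: frozenset[str]
    y_key: int

    def coef(self, name: str) -> float:
        return float(self.beta[self.column_names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.column_names.index(name)])

    def wald_ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        b, s = self.coef(name), self.coef_se(name)
        return b - z * s, b + z * s

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.beta, "se": self.se}, index=self.column_names
        )


def _profiled_negloglik(lam, X, y, codes, sizes):
    """Negative profiled ML log-likelihood at variance ratio ``lam``.

    Also returns the profiled (beta, sigma_e^2, XtX of the transformed
    design) for reuse at the optimum.
    """
    n = len(y)
    theta = 1.0 - 1.0 / np.sqrt(1.0 + lam * sizes)
    ybar = np.bincount(codes, weights=y) / sizes
    yt = y - theta[codes] * ybar[codes]
    Xt = np.empty_like(X)
    for j in range(X.shape[1]):
        xbar = np.bincount(codes, weights=X[:, j]) / sizes
        Xt[:, j] = X[:, j] - theta[codes] * xbar[codes]
    XtX = Xt.T @ Xt
    beta = np.linalg.solve(XtX, Xt.T @ yt)
    resid = yt - Xt @ beta
    rss = float(resid @ resid)
    sigma_e2 = rss / n
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma_e2) + 1.0) - 0.5 * float(
        np.log1p(lam * sizes).sum()
    )
    return -ll, beta, sigma_e2, XtX


def fit_lmm(design: Design, tol: float = 1e-10) -> ModelFit:
    """Maximum-likelihood fit by profiling the subject-variance ratio."""
    X, y, codes = design.X, design.y, design.groups
    sizes = np.bincount(codes).astype(float)
    if design.n_groups < 2:
        raise ValueError("need >= 2 subjects to separate variance components")
    if sizes.min() < 2:
        raise ValueError("every subject needs >= 2 records")

    def nll_of_log(u):
        return _profiled_negloglik(np.exp(u), X, y, codes, sizes)[0]

    res = optimize.minimize_scalar(
        nll_of_log, bounds=(-14.0, 10.0), method="bounded",
        options={"xatol": tol},
    )
    cands = [(nll_of_log(res.x), float(np.exp(res.x)))]
    cands.append((_profiled_negloglik(0.0, X, y, codes, sizes)[0], 0.0))
    nll_best, lam = min(cands)
    _, beta, sigma_e2, XtX = _profiled_negloglik(lam, X, y, codes, sizes)

    cov = sigma_e2 * np.linalg.inv(XtX)
    return ModelFit(
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        column_names=list(design.column_names),
        sigma_u2=lam * sigma_e2,
        sigma_e2=sigma_e2,
        loglik=-nll_best,
        n_obs=design.n_obs,
        n_groups=design.n_groups,
        n_params=X.shape[1] + 2,
        converged=bool(res.success),
        terms=design.terms,
        y_key=hash(y.tobytes()),
    )


def fit_terms(records: pd.DataFrame, terms: Sequence[str], **kw) -> ModelFit:
    """Convenience: build the design and fit in one call."""
    return fit_lmm(build_design(records, terms, **kw))


# ---------------------------------------------------------------------------
# nested-model deviance tests and post hoc estimates
# ---------------------------------------------------------------------------


@dataclass
class LRTResult:
    chisq: float
    df: int
    p: float


def lrt(full: ModelFit, reduced: ModelFit) -> LRTResult:
    """Deviance test of nested ML fits against chi-square."""
    if not reduced.terms <= full.terms:
        raise ValueError("models are not nested (reduced terms not a subset)")
    if reduced.n_obs != full.n_obs or reduced.y_key != full.y_key:
        raise ValueError("models were fitted to different data")
    df = full.n_params - reduced.n_params
    chisq = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = 1.0 if df == 0 else float(stats.chi2.sf(chisq, df))
    return LRTResult(chisq=chisq, df=df, p=p)


def deviance_ladder(records: pd.DataFrame) -> dict:
    """The full model-comparison sequence of the analysis.

    Tests, in order: quadratic vs linear group-size coding (in the
    all-interactions model), then — with number quadratic — the three-way
    interaction, and each two-way interaction dropped from the
    two-way-only model.
    """
    fits = {
        "full_quad": fit_terms(records, factorial_terms(degree=2)),
        "full_lin": fit_terms(records, factorial_terms(degree=1)),
        "two_way": fit_terms(records, factorial_terms(degree=2, three_way=False)),
    }
    for name in ("n:speed", "n:coloration", "coloration:speed"):
        fits[f"no_{name}"] = fit_terms(
            records, factorial_terms(degree=2, three_way=False, drop=[name])
        )
    tests = {
        "quadratic_vs_linear": lrt(fits["full_quad"], fits["full_lin"]),
        "three_way": lrt(fits["full_quad"], fits["two_way"]),
        "speed_by_n": lrt(fits["two_way"], fits["no_n:speed"]),
        "coloration_by_n": lrt(fits["two_way"], fits["no_n:coloration"]),
        "speed_by_coloration": lrt(fits["two_way"], fits["no_coloration:speed"]),
    }
    return {"fits": fits, "tests": tests}


@dataclass
class ContrastResult:
    estimate: float
    t_stat: float
    df: int
    p: float
    per_subject: np.ndarray


def subject_contrast(
    records: pd.DataFrame,
    term: str = "n^2",
    factor: str = "speed",
    pair: tuple[str, str] = ("constant", "variable"),
    degree: int = 2,
) -> ContrastResult:
    """Paired t test across subjects on a per-subject polynomial coefficient.

    For each subject and each level of ``factor`` in ``pair`` (pooling the
    other factor), fit OLS of log error on orthogonal polynomial codes of
    group size and extract the ``term`` coefficient; then a paired t test
    on the per-subject differences pair[0] - pair[1], df = subjects - 1.
    """
    if "is_practice" in records:
        records = records.loc[~records["is_practice"].astype(bool)]
    col = FACTOR_COLUMNS[factor]
    _, order = _parse_term(term)
    if order < 1 or order > degree:
        raise ValueError(f"term {term!r} must be a polynomial term within degree")

    levels = np.unique(records["n_agents"].astype(float))
    codes = orthogonal_poly(levels, degree)
    level_index = {v: i for i, v in enumerate(levels)}

    subjects = np.unique(records["subject_id"])
    diffs = np.empty(len(subjects))
    for i, s in enumerate(subjects):
        coefs = {}
        for lv in pair:
            sub = records[(records["subject_id"] == s) & (records[col] == lv)]
            if set(sub["n_agents"].astype(float)) != set(levels):
                raise ValueError(
                    f"subject {s!r} lacks some group sizes in condition {lv!r}"
                )
            idx = np.array([level_index[v] for v in sub["n_agents"].astype(float)])
            Xs = np.column_stack([np.ones(len(sub)), codes[idx]])
            b, *_ = np.linalg.lstsq(Xs, sub["log_error"].to_numpy(), rcond=None)
            coefs[lv] = b[order]
        diffs[i] = coefs[pair[0]] - coefs[pair[1]]

    t_res = stats.ttest_1samp(diffs, 0.0)
    return ContrastResult(
        estimate=float(diffs.mean()),
        t_stat=float(t_res.statistic),
        df=len(subjects) - 1,
        p=float(t_res.pvalue),
        per_subject=diffs,
    )


@dataclass
class OddityRatio:
    """Multiplicative modulation, by a coloration, of the speed-variation
    effect on error, with Wald 95% CI (estimated on the log scale)."""

    ratio: float
    ci_low: float
    ci_high: float
    coefficient: str
    se: float


def oddity_ratio_at_n(
    records: pd.DataFrame,
    n_level: int = 30,
    coloration_pair: tuple[str, str] = ("orthogonal", "trinary"),
    level: float = 0.95,
) -> OddityRatio:
    """Post hoc speed-by-coloration interaction ratio at one group size.

    Fits the mixed model with speed x coloration on the ``n_level`` subset
    only (reference levels: ``coloration_pair[1]``, constant speed) and
    exponentiates the interaction coefficient contrasting
    ``coloration_pair[0]`` against the reference.
    """
    if "is_practice" in records:
        records = records.loc[~records["is_practice"].astype(bool)]
    sub = records[records["n_agents"] == n_level]
    if sub["subject_id"].nunique() < 2 or len(sub) < 8:
        raise ValueError(f"too few records at n_agents={n_level}")
    design = build_design(
        sub,
        ["coloration", "speed", "coloration:speed"],
        references={"coloration": coloration_pair[1]},
    )
    fit = fit_lmm(design)
    name = f"coloration[{coloration_pair[0]}]:speed[variable]"
    lo, hi = fit.wald_ci(name, level=level)
    return OddityRatio(
        ratio=float(np.exp(fit.coef(name))),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        coefficient=name,
        se=fit.coef_se(name),
    )
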