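"""Estimating conformity strength from choice-frequency data.

The logistic learning rule ``p(q) = q**beta / (q**beta + (1-q)**beta)``
implies a linear relationship between log odds::

    ln(p/(1-p)) = beta * ln(q/(1-q))

so the conformity exponent ``beta`` is the through-origin slope of the
observers' response log odds on the demonstrators' frequency log odds,
estimable by simple linear regression.  A slope significantly above 1
(one-sided test) is evidence for conformist transmission — adopting the
majority variant *disproportionately* more often than random copying.
With K traits the same slope appears pairwise:
``ln(p_A/p_B) = beta * ln(q_A/q_B)`` for any two traits A, B.

The error-mixture variant ``p'(q) = alpha/2 + (1-alpha)*p(q)`` allows a
fraction ``alpha`` of learners to pick a trait at random, which produces
the empirically ubiquitous departures from unanimous majorities; its
``(alpha, beta)`` are fitted by maximum binomial likelihood.

Input is a :class:`ChoiceTable`: grouped counts of how many of
``observers`` naive individuals adopted each trait after watching
demonstrators with the given trait frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .errors import DomainError, EstimationError, InsufficientDataError
from .learning_rules import LogisticRule, logistic_prob

__all__ = [
    "ChoiceTable",
    "BetaEstimate",
    "ChoiceDesign",
    "fit_beta_binary",
    "fit_beta_multitrait",
    "fit_error_mixture",
    "simulate_choices",
    "exact_choice_table",
    "exact_multitrait_table",
    "power_study",
]

log = logging.getLogger(__name__)

COLUMNS = ["group", "trait", "freq", "observers", "adoptions"]


class ChoiceTable:
    """Grouped choice-frequency observations.

    One row per (group, trait): the demonstrator frequency of that trait
    in the group, the number of observers exposed to the group, and how
    many of them adopted the trait.  Within a group the frequencies sum
    to 1 and the observer count is constant.  Adoption counts may be
    non-integral so that exact adoption *proportions* (the
    infinite-observer limit) can be represented.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise DomainError(f"choice table is missing columns {missing}")
        df = df.loc[:, COLUMNS].copy()
        df["freq"] = df["freq"].astype(float)
        df["observers"] = df["observers"].astype(float)
        df["adoptions"] = df["adoptions"].astype(float)
        if np.any((df["freq"] < 0) | (df["freq"] > 1)):
            raise DomainError("demonstrator frequencies must lie in [0, 1]")
        if np.any(df["observers"] <= 0):
            raise DomainError("observer counts must be positive")
        if np.any(df["adoptions"] < 0) or np.any(df["adoptions"] > df["observers"]):
            raise DomainError("adoptions must lie in [0, observers]")
        for gid, grp in df.groupby("group", sort=False):
            if abs(grp["freq"].sum() - 1.0) > 1e-9:
                raise DomainError(
                    f"group {gid!r}: demonstrator frequencies sum to "
                    f"{grp['freq'].sum()!r}, expected 1"
                )
            if grp["observers"].nunique() != 1:
                raise DomainError(f"group {gid!r}: observer count differs across trait rows")
        self.df = df

    @classmethod
    def read_csv(cls, path) -> "ChoiceTable":
        return cls(pd.read_csv(path, float_precision="round_trip"))

    def to_csv(self, path) -> None:
        # %.17g keeps float columns bit-identical across a write/read cycle
        self.df.to_csv(path, index=False, float_format="%.17g")

    @property
    def traits(self) -> list:
        return sorted(self.df["trait"].unique().tolist())

    @property
    def n_groups(self) -> int:
        return self.df["group"].nunique()

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, ChoiceTable) and self.df.equals(other.df)


@dataclass
class BetaEstimate:
    """Fitted conformity strength with uncertainty and the beta > 1 test.

    ``p_value`` is one-sided for H0: beta <= 1 against H1: beta > 1
    (conformist transmission).  ``alpha_hat`` is populated only by the
    error-mixture fit.
    """

    beta_hat: float
    se: float
    p_value: float
    n_points: int
    correction_applied: bool
    method: str
    df: Optional[int] = None
    alpha_hat: Optional[float] = None
    alpha_se: Optional[float] = None
    notes: list = field(default_factory=list)

    def significant(self, level: float = 0.05) -> bool:
        return bool(np.isfinite(self.p_value) and self.p_value < level)

    def to_record(self) -> dict:
        return {
            "method": self.method,
            "beta_hat": self.beta_hat,
            "se": self.se,
            "p_value_beta_gt_1": self.p_value,
            "n_points": self.n_points,
            "correction_applied": self.correction_applied,
            "alpha_hat": self.alpha_hat,
            "alpha_se": self.alpha_se,
            "notes": "; ".join(self.notes),
        }

    def report(self) -> str:
        lines = [
            f"Conformity estimate ({self.method})",
            f"  beta_hat = {self.beta_hat:.6g}  (SE {self.se:.3g}, {self.n_points} points)",
            f"  one-sided test of beta > 1: p = {self.p_value:.4g}"
            + ("  ** conformist transmission **" if self.significant() else ""),
        ]
        if self.alpha_hat is not None:
            se = f"{self.alpha_se:.3g}" if self.alpha_se is not None else "n/a"
            lines.insert(2, f"  alpha_hat = {self.alpha_hat:.6g}  (SE {se})")
        if self.correction_applied:
            lines.append("  note: unanimity handling modified at least one data point")
        for n in self.notes:
            lines.append(f"  note: {n}")
        return "\n".join(lines)


def _through_origin(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float, int]:
    """Weighted least-squares slope of y on x with no intercept.

    Returns (slope, standard error, residual df).  The df is n-1: one
    parameter estimated.  A perfect fit yields se exactly 0.
    """
    sxx = float(np.sum(w * x * x))
    if sxx == 0.0:
        raise EstimationError("all regressor log odds are zero; slope undefined")
    b = float(np.sum(w * x * y)) / sxx
    resid = y - b * x
    dof = len(x) - 1
    if dof <= 0:
        return b, np.nan, dof
    sigma2 = float(np.sum(w * resid * resid)) / dof
    return b, float(np.sqrt(sigma2 / sxx)), dof


def _one_sided_p(beta_hat: float, se: float, dof: int) -> float:
    """P(slope > 1) under H0 beta <= 1, t reference with `dof` df.

    Exact-fit data (se == 0) gives a degenerate test: p = 0 if the slope
    exceeds 1, else 1.
    """
    if not np.isfinite(se) or dof <= 0:
        return float("nan")
    if se == 0.0:
        return 0.0 if beta_hat > 1.0 else 1.0
    return float(stats.t.sf((beta_hat - 1.0) / se, dof))


def _binary_points(
    data: ChoiceTable, unanimity: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Per-group (q, p_hat, observers) for the focal trait, after
    unanimity handling.  The focal trait is the lexicographically first
    label; the slope is invariant to that choice (swapping labels negates
    both log odds)."""
    traits = data.traits
    if len(traits) != 2:
        raise DomainError(f"binary estimator needs exactly 2 traits, table has {len(traits)}")
    focal = traits[0]
    if unanimity not in ("haldane", "drop"):
        raise DomainError(f"unknown unanimity handling {unanimity!r}")
    qs, ps, ns = [], [], []
    corrected = False
    for gid, grp in data.df.groupby("group", sort=False):
        row = grp[grp["trait"] == focal]
        if len(row) != 1:
            raise DomainError(f"group {gid!r} lacks a single row for focal trait {focal!r}")
        q = float(row["freq"].iloc[0])
        n = float(row["observers"].iloc[0])
        a = float(row["adoptions"].iloc[0])
        if q in (0.0, 1.0):
            # a unanimous demonstrator pool has infinite log odds and no
            # count to correct; such groups carry no slope information
            log.warning("group %r dropped: unanimous demonstrator frequency q=%g", gid, q)
            corrected = True
            continue
        if a in (0.0, n):
            if unanimity == "drop":
                log.warning("group %r dropped: unanimous adoption proportion", gid)
                corrected = True
                continue
            # Haldane-Anscombe continuity correction
            p_hat = (a + 0.5) / (n + 1.0)
            corrected = True
        else:
            p_hat = a / n
        qs.append(q)
        ps.append(p_hat)
        ns.append(n)
    if not qs:
        raise EstimationError(
            "estimation impossible: no usable groups remain after unanimity handling"
        )
    if len(qs) < 2:
        raise InsufficientDataError(f"need >= 2 usable groups, have {len(qs)}")
    return np.array(qs), np.array(ps), np.array(ns), corrected


def fit_beta_binary(
    data: ChoiceTable,
    weighting: str = "binomial",
    unanimity: str = "haldane",
) -> BetaEstimate:
    """Estimate beta for two traits by the log-odds regression.

    Regresses ``ln(p_hat/(1-p_hat))`` on ``ln(q/(1-q))`` through the
    origin.  ``weighting``: "binomial" (default; weights
    ``n*p_hat*(1-p_hat)``, the inverse sampling variance of an empirical
    log odds, which keeps the test's type-I error at its nominal level)
    or "ols" (the unweighted simple regression, which is mildly
    anti-conservative at moderate observer counts).  ``unanimity``: "haldane" applies
    the Haldane-Anscombe continuity correction (+0.5 to counts, +1 to
    totals) to groups with unanimous adoptions; "drop" removes them.
    """
    q, p_hat, n, corrected = _binary_points(data, unanimity)
    x = logit(q)
    y = logit(p_hat)
    if weighting == "ols":
        w = np.ones_like(x)
    elif weighting == "binomial":
        w = n * p_hat * (1.0 - p_hat)
    else:
        raise DomainError(f"unknown weighting mode {weighting!r}")
    b, se, dof = _through_origin(x, y, w)
    return BetaEstimate(
        beta_hat=b,
        se=se,
        p_value=_one_sided_p(b, se, dof),
        n_points=len(x),
        correction_applied=corrected,
        method=f"binary log-odds regression ({weighting}, unanimity={unanimity})",
        df=dof,
    )


def fit_beta_multitrait(data: ChoiceTable, unanimity: str = "haldane") -> BetaEstimate:
    """Estimate a single beta from K >= 2 traits by pooled pairwise
    log-ratio regression.

    For every unordered within-group trait pair (A, B), taken once in a
    fixed canonical (sorted-label) order, the point
    ``(ln(q_A/q_B), ln(p_hat_A/p_hat_B))`` is formed; one through-origin
    slope is fitted over all pairs.  Pairs whose log ratios are undefined
    after unanimity handling are dropped with a logged warning.
    """
    if unanimity not in ("haldane", "drop"):
        raise DomainError(f"unknown unanimity handling {unanimity!r}")
    xs, ys = [], []
    corrected = False
    for gid, grp in data.df.groupby("group", sort=False):
        grp = grp.sort_values("trait")
        if len(grp) < 2:
            raise DomainError(f"group {gid!r} has fewer than 2 trait rows")
        n = float(grp["observers"].iloc[0])
        rows = list(grp.itertuples(index=False))
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                qa, qb = float(rows[i].freq), float(rows[j].freq)
                aa, ab = float(rows[i].adoptions), float(rows[j].adoptions)
                if qa == 0.0 or qb == 0.0:
                    log.warning(
                        "group %r pair (%r, %r) dropped: zero demonstrator share",
                        gid, rows[i].trait, rows[j].trait,
                    )
                    corrected = True
                    continue
                if aa == 0.0 or ab == 0.0:
                    if unanimity == "drop":
                        log.warning(
                            "group %r pair (%r, %r) dropped: zero adoption count",
                            gid, rows[i].trait, rows[j].trait,
                        )
                        corrected = True
                        continue
                    aa, ab = aa + 0.5, ab + 0.5
                    corrected = True
                xs.append(np.log(qa / qb))
                ys.append(np.log(aa / ab))
    if not xs:
        raise EstimationError("estimation impossible: no usable trait pairs remain")
    if len(xs) < 2:
        raise InsufficientDataError(f"need >= 2 usable pairs, have {len(xs)}")
    x, y = np.array(xs), np.array(ys)
    b, se, dof = _through_origin(x, y, np.ones_like(x))
    return BetaEstimate(
        beta_hat=b,
        se=se,
        p_value=_one_sided_p(b, se, dof),
        n_points=len(x),
        correction_applied=corrected,
        method=f"multi-trait pairwise log-ratio regression (unanimity={unanimity})",
        df=dof,
    )


def _mixture_prob(q: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Error-mixture adoption probability, with the continuous extension
    of the logistic core at q in {0, 1} for every beta (needed so the
    likelihood stays defined while the optimizer explores beta <= 0)."""
    at_zero = q == 0.0
    at_one = q == 1.0
    core = np.empty_like(q)
    interior = ~(at_zero | at_one)
    core[interior] = expit(beta * logit(q[interior]))
    if beta > 0:
        lo, hi = 0.0, 1.0
    elif beta == 0:
        lo, hi = 0.5, 0.5
    else:
        lo, hi = 1.0, 0.0
    core[at_zero] = lo
    core[at_one] = hi
    return alpha / 2.0 + (1.0 - alpha) * core


def fit_error_mixture(
    data: ChoiceTable,
    beta_bound: float = 50.0,
) -> BetaEstimate:
    """Fit ``(alpha, beta)`` of the error-mixture rule by maximum
    binomial likelihood.

    Maximizes ``sum_g [a_g*ln(p'(q_g)) + (n_g-a_g)*ln(1-p'(q_g))]`` over
    alpha in [0, 1] and beta in [-beta_bound, beta_bound].  Standard
    errors come from the observed information (numerical Hessian at the
    optimum); estimates on a box boundary are flagged in ``notes`` and
    their Wald standard errors treated as unreliable.  The beta > 1 test
    uses a normal reference on the Wald statistic.
    """
    traits = data.traits
    if len(traits) != 2:
        raise DomainError(f"error-mixture fit needs exactly 2 traits, table has {len(traits)}")
    focal = traits[0]
    sub = data.df[data.df["trait"] == focal]
    q = sub["freq"].to_numpy(float)
    n = sub["observers"].to_numpy(float)
    a = sub["adoptions"].to_numpy(float)
    if np.all((q == 0.0) | (q == 1.0)):
        raise EstimationError(
            "estimation impossible: beta is unidentifiable from unanimous "
            "demonstrator groups only"
        )
    if len(np.unique(q)) < 3:
        raise InsufficientDataError(
            "need >= 3 distinct demonstrator frequency levels for the "
            "two-parameter error-mixture fit"
        )

    tiny = 1e-12

    def nll(theta: np.ndarray) -> float:
        al, be = theta
        p = np.clip(_mixture_prob(q, al, be), tiny, 1.0 - tiny)
        return -float(np.sum(a * np.log(p) + (n - a) * np.log1p(-p)))

    bounds = [(0.0, 1.0), (-beta_bound, beta_bound)]
    starts = [(0.05, b0) for b0 in (0.5, 1.0, 2.0, 5.0, -1.0)] + [(0.3, 2.0), (0.0, 1.0)]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    # derivative-free polish for the last decimals
    polish = optimize.minimize(
        nll, best.x, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    if polish.fun <= best.fun:
        best = polish
    if not np.all(np.isfinite(best.x)) or not np.isfinite(best.fun):
        raise EstimationError(
            "error-mixture optimizer failed to converge",
            diagnostics={"result": best},
        )
    alpha_hat = float(np.clip(best.x[0], 0.0, 1.0))
    beta_hat = float(np.clip(best.x[1], -beta_bound, beta_bound))

    notes = []
    on_boundary = (
        alpha_hat <= 1e-8 or alpha_hat >= 1.0 - 1e-8 or abs(beta_hat) >= beta_bound - 1e-6
    )
    if on_boundary:
        notes.append(
            f"estimate on parameter boundary (alpha_hat={alpha_hat:.3g}, "
            f"beta_hat={beta_hat:.3g}); Wald standard errors unreliable"
        )
    se_alpha, se_beta = _observed_information_se(nll, np.array([alpha_hat, beta_hat]))
    p_value = float("nan")
    if np.isfinite(se_beta):
        p_value = float(stats.norm.sf((beta_hat - 1.0) / se_beta)) if se_beta > 0 else (
            0.0 if beta_hat > 1.0 else 1.0
        )
    return BetaEstimate(
        beta_hat=beta_hat,
        se=se_beta,
        p_value=p_value,
        n_points=len(q),
        correction_applied=False,
        method="error-mixture maximum likelihood",
        alpha_hat=alpha_hat,
        alpha_se=se_alpha if np.isfinite(se_alpha) else None,
        notes=notes,
    )


def _observed_information_se(nll, theta: np.ndarray, h: float = 1e-4) -> tuple[float, float]:
    """Standard errors from the inverse numerical Hessian of the negative
    log-likelihood; (nan, nan) when the Hessian is not positive definite
    (typical at a boundary optimum)."""
    k = len(theta)
    H = np.empty((k, k))
    f0 = nll(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            if i == j:
                H[i, i] = (nll(theta + ei) - 2.0 * f0 + nll(theta - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    nll(theta + ei + ej) - nll(theta + ei - ej)
                    - nll(theta - ei + ej) + nll(theta - ei - ej)
                ) / (4.0 * h**2)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return float("nan"), float("nan")
    diag = np.diag(cov)
    if np.any(diag <= 0):
        return float("nan"), float("nan")
    se = np.sqrt(diag)
    return float(se[0]), float(se[1])


@dataclass(frozen=True)
class ChoiceDesign:
    """Design of a synthetic choice experiment: demonstrator frequency
    levels, observers exposed per group, and replicate groups per level."""

    frequency_levels: Sequence[float]
    observers: int
    groups: int = 1

    def __post_init__(self) -> None:
        if len(self.frequency_levels) == 0:
            raise DomainError("design needs at least one frequency level")
        if any(not (0.0 <= q <= 1.0) for q in self.frequency_levels):
            raise DomainError("frequency levels must lie in [0, 1]")
        if self.observers < 1 or self.groups < 1:
            raise DomainError("observers and groups must be >= 1")


def simulate_choices(
    rule: LogisticRule,
    design: ChoiceDesign,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ChoiceTable:
    """Generate a synthetic binary :class:`ChoiceTable` under ``rule``.

    For each group at demonstrator frequency ``q``, adoptions of trait
    "A" are binomial with success probability ``logistic_prob(q, rule)``
    and trait "B" receives the remainder.  Deterministic given ``seed``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for li, q in enumerate(design.frequency_levels):
        p = logistic_prob(float(q), rule)
        for g in range(design.groups):
            gid = f"q{li}_r{g}"
            adopt_a = int(rng.binomial(design.observers, p))
            rows.append((gid, "A", float(q), design.observers, adopt_a))
            rows.append((gid, "B", 1.0 - float(q), design.observers, design.observers - adopt_a))
    return ChoiceTable(pd.DataFrame(rows, columns=COLUMNS))


def exact_choice_table(
    rule: LogisticRule,
    frequency_levels: Sequence[float],
    observers: float = 1.0,
) -> ChoiceTable:
    """Binary :class:`ChoiceTable` whose adoption *proportions* equal the
    rule's probabilities exactly — the infinite-observer limit, with
    (possibly fractional) adoptions ``p(q) * observers``.

    On such data the log-odds regression recovers the generating beta to
    numerical precision, and the error-mixture likelihood is maximized
    at the generating (alpha, beta).
    """
    rows = []
    for i, q in enumerate(frequency_levels):
        p = logistic_prob(float(q), rule)
        rows.append((f"g{i}", "A", float(q), observers, p * observers))
        rows.append((f"g{i}", "B", 1.0 - float(q), observers, (1.0 - p) * observers))
    return ChoiceTable(pd.DataFrame(rows, columns=COLUMNS))


def exact_multitrait_table(
    rule: LogisticRule,
    frequency_vectors: Sequence[Sequence[float]],
    observers: float = 1.0,
) -> ChoiceTable:
    """K-trait :class:`ChoiceTable` with exact adoption proportions from
    the multi-trait logistic rule (one group per frequency vector)."""
    from .learning_rules import multi_logistic_probs

    rows = []
    for i, freqs in enumerate(frequency_vectors):
        probs = multi_logistic_probs(freqs, rule)
        for j, (q, p) in enumerate(zip(freqs, probs)):
            rows.append((f"g{i}", f"t{j}", float(q), observers, p * observers))
    return ChoiceTable(pd.DataFrame(rows, columns=COLUMNS))


def power_study(
    betas: Sequence[float],
    design: ChoiceDesign,
    replicates: int,
    seed: int,
    alpha: float = 0.0,
    level: float = 0.05,
    weighting: str = "binomial",
    unanimity: str = "haldane",
) -> pd.DataFrame:
    """Monte-Carlo rejection rates of the one-sided beta > 1 test.

    For each generating ``beta``, simulates ``replicates`` choice tables
    and records the fraction in which :func:`fit_beta_binary` rejects
    H0: beta <= 1 at ``level``.  Including beta = 1 in the grid yields
    the type-I error estimate.
    """
    if replicates < 1:
        raise DomainError(f"replicates must be >= 1, got {replicates}")
    rng = np.random.default_rng(seed)
    records = []
    for beta in betas:
        rule = LogisticRule(beta=float(beta), alpha=alpha)
        rejections = 0
        usable = 0
        for _ in range(replicates):
            table = simulate_choices(rule, design, rng=rng)
            try:
                est = fit_beta_binary(table, weighting=weighting, unanimity=unanimity)
            except (EstimationError, InsufficientDataError):
                continue
            usable += 1
            if est.significant(level):
                rejections += 1
        rate = rejections / usable if usable else float("nan")
        records.append(
            {"beta": float(beta), "rejection_rate": rate,
             "replicates": usable, "level": level}
        )
    return pd.DataFrame.from_records(records)
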