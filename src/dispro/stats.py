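"""Disproportionality statistics for spontaneous-report signal detection.

For each drug–event stratum (a MedDRA PT or SOC) the reports are reduced to
a 2x2 contingency table against the database background::

                      target event    other events
    target drug            a               b
    all other drugs        c               d

with N = a+b+c+d and expected count E = (a+b)(a+c)/N.  Four established
measures are computed on each table:

* ROR  — reporting odds ratio (a*d)/(b*c) with a Woolf 95% CI,
* PRR  — proportional reporting ratio with a Yates-corrected chi-squared,
* IC   — the BCPNN information component log2(observed/expected) with
  Bayesian shrinkage and a lower 2.5% credible bound (IC025),
* EBGM — the MGPS empirical-Bayes geometric mean of the relative reporting
  ratio under a two-component gamma mixture prior fitted database-wide,
  with its posterior 5th percentile (EBGM05).

Counting unit: one increment per (report, term) pair; a term repeated
within one report counts once.  Signal criteria follow the dominant
pharmacovigilance convention and every threshold is exposed as
configuration (:class:`SignalCriteria`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps
from sklearn.base import BaseEstimator

__all__ = [
    "ContingencyTable", "SignalCriteria", "SignalResult", "MgpsPrior", "MGPS",
    "build_tables", "ror_with_ci", "prr_with_chi2", "bcpnn_ic",
    "mgps_fit_prior", "mgps_ebgm", "apply_criteria", "compute_signals",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """2x2 drug–event counts; ``a`` is the target drug / target event cell."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"negative count {name}={v}")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """E = (a+b)(a+c)/N, the count expected under independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n


@dataclass(frozen=True)
class SignalCriteria:
    """Per-algorithm signal thresholds (all configurable)."""

    min_a: int = 3            # minimum case count for ROR and PRR
    ror_lo_gt: float = 1.0    # lower ROR CI bound must exceed this
    prr_ge: float = 2.0
    chi2_ge: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0


@dataclass
class SignalResult:
    """All four statistics plus criterion flags for one stratum."""

    stratum: str
    n: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    flags: dict[str, bool] = field(default_factory=dict)
    reasons: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

def build_tables(cohort_events: pd.DataFrame, background_events: pd.DataFrame,
                 level: str = "pt") -> pd.DataFrame:
    """Build one 2x2 table per stratum observed in the target cohort.

    Both inputs are long tables of (``primaryid``, term) pairs carrying a
    column named ``level`` ("pt" or "soc"); each (report, term) pair counts
    once even if the report listed the term repeatedly.  Returns a frame
    indexed by stratum with columns ``a``, ``b``, ``c``, ``d``, ``E``.
    """
    if background_events is None or len(background_events) == 0:
        raise ValueError("background events are empty: a single-drug world "
                         "has no comparator for disproportionality")
    tgt = cohort_events[["primaryid", level]].drop_duplicates()
    bkg = background_events[["primaryid", level]].drop_duplicates()
    a = tgt[level].value_counts()
    c = bkg[level].value_counts()
    total_tgt = len(tgt)
    total_bkg = len(bkg)
    out = pd.DataFrame({"a": a})
    out["c"] = c.reindex(out.index).fillna(0).astype(int)
    out["b"] = total_tgt - out["a"]
    out["d"] = total_bkg - out["c"]
    n = total_tgt + total_bkg
    out["E"] = (out.a + out.b) * (out.a + out.c) / n
    out.index.name = level
    return out[["a", "b", "c", "d", "E"]]


# ---------------------------------------------------------------------------
# frequentist measures
# ---------------------------------------------------------------------------

def ror_with_ci(table: ContingencyTable, continuity: float = 0.0,
                ) -> tuple[float, float, float]:
    """Reporting odds ratio with Woolf 95% CI.

    ROR = (a*d)/(b*c); CI = exp(ln ROR +- 1.96*sqrt(1/a+1/b+1/c+1/d)).
    Any zero cell makes the estimate (and CI) undefined — NaN is returned
    rather than applying a silent correction; pass ``continuity=0.5`` for
    the Haldane–Anscombe corrected variant.
    """
    a, b, c, d = (x + continuity for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) <= 0:
        return (math.nan, math.nan, math.nan)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-Z_95 * se), ror * math.exp(Z_95 * se)


def prr_with_chi2(table: ContingencyTable, yates: bool = True,
                  continuity: float = 0.0) -> tuple[float, float]:
    """Proportional reporting ratio and the (Yates-corrected) chi-squared.

    PRR = [a/(a+b)] / [c/(c+d)]; undefined when c == 0 or a+b == 0.
    """
    a, b, c, d = (x + continuity for x in (table.a, table.b, table.c, table.d))
    n = a + b + c + d
    if a + b <= 0 or c <= 0:
        prr = math.nan
    else:
        prr = (a / (a + b)) / (c / (c + d))
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins <= 0:
        return prr, math.nan
    dev = abs(a * d - b * c)
    if yates:
        dev = max(dev - n / 2, 0.0)
    chi2 = n * dev**2 / margins
    return prr, chi2


# ---------------------------------------------------------------------------
# BCPNN information component
# ---------------------------------------------------------------------------

def bcpnn_ic(table: ContingencyTable, variant: str = "gamma",
             ) -> tuple[float, float]:
    """Information component with its lower 2.5% credible bound.

    ``variant="gamma"`` (default): the shrunk observed/expected form.  The
    relative reporting rate gets a Gamma(a + 1/2, rate E + 1/2) posterior,
    IC = log2 of its mean = log2[(a+0.5)/(E+0.5)] and IC025 is log2 of its
    2.5th percentile.  Defined for a = 0.

    ``variant="bate1998"``: the original closed-form posterior moments of
    the full BCPNN model with Beta(1, ...) priors on the marginals;
    IC025 = E[IC] - 1.96*sd[IC].
    """
    a, n = table.a, table.n
    e = table.expected
    if variant == "gamma":
        shape = a + 0.5
        rate = e + 0.5
        ic = math.log2(shape / rate)
        ic025 = math.log2(sps.gamma.ppf(0.025, shape, scale=1 / rate))
        return ic, ic025
    if variant == "bate1998":
        a1 = b1 = 1.0
        g11 = 1.0
        alpha = beta = 2.0
        row = table.a + table.b
        col = table.a + table.c
        gamma = g11 * (n + alpha) * (n + beta) / ((row + a1) * (col + b1))
        e_ic = math.log2((a + g11) * (n + alpha) * (n + beta)
                         / ((n + gamma) * (row + a1) * (col + b1)))
        v_ic = ((n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
                + (n - row + alpha - a1) / ((row + a1) * (1 + n + alpha))
                + (n - col + beta - b1) / ((col + b1) * (1 + n + beta))
                ) / math.log(2) ** 2
        return e_ic, e_ic - Z_95 * math.sqrt(v_ic)
    raise ValueError(f"unknown BCPNN variant: {variant!r}")


# ---------------------------------------------------------------------------
# MGPS: two-component gamma–Poisson mixture shrinkage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MgpsPrior:
    """Prior on the relative reporting ratio: P*Gamma(a1,b1) + (1-P)*Gamma(a2,b2).

    Shapes ``alpha``, rates ``beta`` (mean of a component is alpha/beta).
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p: float

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma parameters must be strictly positive")
        if not 0 < self.p < 1:
            raise ValueError("mixture weight must lie in (0, 1)")


def _nb_logpmf(n: np.ndarray, e: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """log marginal P(n | E) when lambda ~ Gamma(alpha, rate beta)."""
    return (special.gammaln(alpha + n) - special.gammaln(alpha)
            - special.gammaln(n + 1.0)
            + alpha * (np.log(beta) - np.log(beta + e))
            + n * (np.log(e) - np.log(beta + e)))


def _mixture_loglik(prior: MgpsPrior, n: np.ndarray, e: np.ndarray) -> float:
    l1 = np.log(prior.p) + _nb_logpmf(n, e, prior.alpha1, prior.beta1)
    l2 = np.log1p(-prior.p) + _nb_logpmf(n, e, prior.alpha2, prior.beta2)
    return float(np.logaddexp(l1, l2).sum())


class MGPS(BaseEstimator):
    """Multi-item gamma Poisson shrinker (empirical-Bayes EBGM).

    Scikit-learn-style estimator.  ``fit`` receives the full database of
    drug–event cells as an array of shape (n_cells, 2) with columns
    ``(n, E)`` — observed count and expected count under independence — and
    maximises the marginal (negative-binomial mixture) likelihood over the
    five hyperparameters.  ``predict`` returns the EBGM for new cells and
    ``predict_quantile`` posterior quantiles such as EBGM05.

    Parameters are the classic starting values of the two-component model:
    a near-null component and a broad signal component.
    """

    def __init__(self, alpha1: float = 0.2, beta1: float = 0.1,
                 alpha2: float = 2.0, beta2: float = 4.0, p: float = 1 / 3,
                 tol: float = 1e-8, max_iter: int = 500):
        self.alpha1 = alpha1
        self.beta1 = beta1
        self.alpha2 = alpha2
        self.beta2 = beta2
        self.p = p
        self.tol = tol
        self.max_iter = max_iter

    # -- fitting ---------------------------------------------------------

    @staticmethod
    def _validate(X) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("X must have two columns: observed n, expected E")
        n, e = arr[:, 0], arr[:, 1]
        if len(n) == 0:
            raise ValueError("no drug–event cells supplied")
        if np.any(e <= 0) or np.any(n < 0) or np.any(~np.isfinite(arr)):
            raise ValueError("counts must be >= 0 and expectations > 0")
        return n, e

    def fit(self, X, y=None) -> "MGPS":
        n, e = self._validate(X)
        if len(n) < 2:
            raise ValueError("need at least 2 drug–event cells to fit a prior")
        if n.sum() == 0:
            raise ValueError("degenerate data: every observed count is zero")

        def unpack(theta: np.ndarray) -> MgpsPrior:
            a1, b1, a2, b2 = np.exp(theta[:4])
            p = special.expit(theta[4])
            return MgpsPrior(a1, b1, a2, b2, p)

        def nll_and_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
            pr = unpack(theta)
            l1 = np.log(pr.p) + _nb_logpmf(n, e, pr.alpha1, pr.beta1)
            l2 = np.log1p(-pr.p) + _nb_logpmf(n, e, pr.alpha2, pr.beta2)
            norm = np.logaddexp(l1, l2)
            w1, w2 = np.exp(l1 - norm), np.exp(l2 - norm)
            grad = np.empty(5)
            for k, (alpha, beta, w) in enumerate(
                    [(pr.alpha1, pr.beta1, w1), (pr.alpha2, pr.beta2, w2)]):
                dl_da = (special.digamma(alpha + n) - special.digamma(alpha)
                         + np.log(beta) - np.log(beta + e))
                dl_db = alpha / beta - (alpha + n) / (beta + e)
                grad[2 * k] = -(w * dl_da).sum() * alpha      # d/d log(alpha)
                grad[2 * k + 1] = -(w * dl_db).sum() * beta   # d/d log(beta)
            grad[4] = -(w1 - pr.p).sum()                      # d/d logit(p)
            return -float(norm.sum()), grad

        theta0 = np.array([math.log(self.alpha1), math.log(self.beta1),
                           math.log(self.alpha2), math.log(self.beta2),
                           special.logit(self.p)])
        # bounds keep exp/expit away from under/overflow on sparse data
        bounds = [(-12.0, 12.0)] * 4 + [(-12.0, 12.0)]
        res = optimize.minimize(
            nll_and_grad, theta0, method="L-BFGS-B", jac=True, bounds=bounds,
            options={"maxiter": self.max_iter, "ftol": self.tol})
        self.prior_ = unpack(res.x)
        self.loglik_ = -float(res.fun)
        self.n_iter_ = int(res.nit)
        self.converged_ = bool(res.success)
        return self

    # -- posterior -------------------------------------------------------

    def _posterior(self, n: np.ndarray, e: np.ndarray,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Posterior mixture (weights, shapes, rates) per cell; shape (m, 2)."""
        pr = self.prior_
        l1 = np.log(pr.p) + _nb_logpmf(n, e, pr.alpha1, pr.beta1)
        l2 = np.log1p(-pr.p) + _nb_logpmf(n, e, pr.alpha2, pr.beta2)
        norm = np.logaddexp(l1, l2)
        w = np.stack([np.exp(l1 - norm), np.exp(l2 - norm)], axis=1)
        shapes = np.stack([pr.alpha1 + n, pr.alpha2 + n], axis=1)
        rates = np.stack([pr.beta1 + e, pr.beta2 + e], axis=1)
        return w, shapes, rates

    def predict(self, X) -> np.ndarray:
        """EBGM = exp(E[ln lambda | n, E]) per cell (geometric-mean shrinkage)."""
        n, e = self._validate(X)
        w, shapes, rates = self._posterior(n, e)
        e_ln = (w * (special.digamma(shapes) - np.log(rates))).sum(axis=1)
        return np.exp(e_ln)

    def predict_quantile(self, X, q: float = 0.05, tol: float = 1e-6) -> np.ndarray:
        """Posterior quantile of lambda (q=0.05 gives EBGM05) by root-finding
        on the monotone mixture CDF."""
        n, e = self._validate(X)
        w, shapes, rates = self._posterior(n, e)
        out = np.empty(len(n))
        for i in range(len(n)):
            wi, si, ri = w[i], shapes[i], rates[i]

            def cdf(x: float) -> float:
                return float((wi * special.gammainc(si, ri * x)).sum()) - q

            comp_q = sps.gamma.ppf(q, si, scale=1 / ri)
            lo = max(min(comp_q) * 0.5, 1e-12)
            hi = max(comp_q) * 2 + 1e-9
            while cdf(lo) > 0:
                lo *= 0.5
            while cdf(hi) < 0:
                hi *= 2
            out[i] = optimize.brentq(cdf, lo, hi, xtol=tol)
        return out

    def score(self, X, y=None) -> float:
        """Marginal log-likelihood of cells under the fitted prior."""
        n, e = self._validate(X)
        return _mixture_loglik(self.prior_, n, e)


def mgps_fit_prior(cells: pd.DataFrame | np.ndarray, **kwargs) -> MgpsPrior:
    """Fit the MGPS hyperprior on the full database of (n, E) cells."""
    if isinstance(cells, pd.DataFrame):
        cells = cells[["a", "E"]] if "a" in cells.columns else cells
    return MGPS(**kwargs).fit(np.asarray(cells)).prior_


def mgps_ebgm(table: ContingencyTable, prior: MgpsPrior) -> tuple[float, float]:
    """EBGM and EBGM05 for one table under a fitted prior."""
    model = MGPS()
    model.prior_ = prior
    X = np.array([[table.a, table.expected]])
    return float(model.predict(X)[0]), float(model.predict_quantile(X)[0])


# ---------------------------------------------------------------------------
# criteria and the full screen
# ---------------------------------------------------------------------------

def apply_criteria(result: SignalResult, criteria: SignalCriteria = SignalCriteria(),
                   ) -> dict[str, bool]:
    """Evaluate the four signal criteria; undefined statistics fail closed.

    ROR: n >= 3 and lower CI bound > 1; PRR: n >= 3, PRR >= 2, chi2 >= 4;
    BCPNN: IC025 > 0 (strict); MGPS: EBGM05 > 2; ``all``: conjunction.
    """
    flags: dict[str, bool] = {}
    reasons = result.reasons

    def defined(*vals: float) -> bool:
        return all(v == v for v in vals)  # NaN-safe

    if not defined(result.ror_lo):
        flags["ror"] = False
        reasons.setdefault("ror", "undefined (zero cell)")
    else:
        flags["ror"] = result.n >= criteria.min_a and result.ror_lo > criteria.ror_lo_gt
    if not defined(result.prr, result.chi2):
        flags["prr"] = False
        reasons.setdefault("prr", "undefined (empty comparator)")
    else:
        flags["prr"] = (result.n >= criteria.min_a
                        and result.prr >= criteria.prr_ge
                        and result.chi2 >= criteria.chi2_ge)
    flags["bcpnn"] = defined(result.ic025) and result.ic025 > criteria.ic025_gt
    flags["mgps"] = defined(result.ebgm05) and result.ebgm05 > criteria.ebgm05_gt
    flags["all"] = flags["ror"] and flags["prr"] and flags["bcpnn"] and flags["mgps"]
    result.flags = flags
    return flags


def compute_signals(tables: pd.DataFrame, prior: MgpsPrior | None = None,
                    criteria: SignalCriteria = SignalCriteria(),
                    bcpnn_variant: str = "gamma", yates: bool = True,
                    continuity: float = 0.0) -> pd.DataFrame:
    """Run all four measures over a frame of tables (from :func:`build_tables`).

    If no MGPS prior is supplied, one is fitted to the supplied tables
    themselves; for a database-wide prior fit it on the full drug–event
    count matrix first and pass it in.
    """
    if prior is None:
        prior = mgps_fit_prior(tables[["a", "E"]].to_numpy())
    model = MGPS()
    model.prior_ = prior
    X = tables[["a", "E"]].to_numpy(dtype=float)
    ebgm = model.predict(X)
    ebgm05 = model.predict_quantile(X)
    rows = []
    for i, (stratum, r) in enumerate(tables.iterrows()):
        t = ContingencyTable(int(r.a), int(r.b), int(r.c), int(r.d))
        ror, lo, hi = ror_with_ci(t, continuity=continuity)
        prr, chi2 = prr_with_chi2(t, yates=yates, continuity=continuity)
        ic, ic025 = bcpnn_ic(t, variant=bcpnn_variant)
        res = SignalResult(stratum=str(stratum), n=t.a, ror=ror, ror_lo=lo,
                           ror_hi=hi, prr=prr, chi2=chi2, ic=ic, ic025=ic025,
                           ebgm=float(ebgm[i]), ebgm05=float(ebgm05[i]))
        flags = apply_criteria(res, criteria)
        rows.append({
            "stratum": res.stratum, "n": res.n, "ror": res.ror,
            "ror95_lo": res.ror_lo, "ror95_hi": res.ror_hi, "prr": res.prr,
            "chi2": res.chi2, "ic": res.ic, "ic025": res.ic025,
            "ebgm": res.ebgm, "ebgm05": res.ebgm05,
            "flag_ror": flags["ror"], "flag_prr": flags["prr"],
            "flag_bcpnn": flags["bcpnn"], "flag_mgps": flags["mgps"],
            "flag_all": flags["all"],
        })
    out = pd.DataFrame(rows)
    return out.sort_values("n", ascending=False).reset_index(drop=True)
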