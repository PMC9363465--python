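"""Statistical primitives used throughout the pipeline.

Every procedure here — the Wilcoxon rank-sum test, the 2x2 chi-square test,
Spearman correlation, Benjamini-Hochberg FDR, the Kaplan-Meier estimator,
the log-rank test and Cox partial-likelihood regression — is implemented
directly from its definition so the whole analysis has a single, auditable
numerical core.  Only distribution tail functions (normal, t, chi-square)
come from scipy.

Conventions
-----------
* All tests are two-sided by default.
* The 2x2 chi-square applies the Yates continuity correction by default.
* Cox regression uses Efron's tie correction by default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _dist


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...] = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0,1]: {self.p_value}")


@dataclass
class CoxFit:
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    hazard_ratio: np.ndarray
    log_likelihood: float
    converged: bool
    n_events: int
    n_iter: int
    diagnostic: str = ""


@dataclass
class KMCurve:
    """Product-limit survival curve.

    ``times`` are the distinct event times in ascending order; ``survival``
    the estimate just after each event time; ``at_risk`` the number at risk
    at that time; ``censor_times`` every censoring time (for tick marks).
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        if len(self.times) == 0 or t < self.times[0]:
            return 1.0
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx])

    def median_survival(self) -> float:
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else math.inf


def _rankdata(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), ties receive the mean of their rank span."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def wilcoxon_ranksum(
    x,
    y,
    alternative: str = "two-sided",
    continuity: bool = True,
    exact_max_n: int = 10,
) -> TestResult:
    """Wilcoxon-Mann-Whitney rank-sum test.

    Uses exact enumeration of the U distribution when the combined sample
    size is at most ``exact_max_n`` and there are no ties; otherwise a
    normal approximation with tie correction and (optionally) a continuity
    correction.  If every value is identical across both groups, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = _rankdata(combined)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0  # Mann-Whitney U for x

    has_ties = len(np.unique(combined)) < combined.size
    if not has_ties and n1 + n2 <= exact_max_n:
        p = _exact_u_p(u, n1, n2, alternative)
        return TestResult(u, p, "wilcoxon-ranksum-exact", (n1, n2))

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult(u, 1.0, "wilcoxon-ranksum-normal", (n1, n2))
    diff = u - mu
    cc = 0.5 if continuity else 0.0
    sd = math.sqrt(var)
    if alternative == "two-sided":
        z = (abs(diff) - cc) / sd
        z = max(z, 0.0)
        p = 2.0 * _dist.norm.sf(z)
    elif alternative == "greater":
        z = (diff - cc) / sd
        p = _dist.norm.sf(z)
    else:
        z = (diff + cc) / sd
        p = _dist.norm.cdf(z)
    return TestResult(u, min(p, 1.0), "wilcoxon-ranksum-normal", (n1, n2))


def _exact_u_p(u: float, n1: int, n2: int, alternative: str) -> float:
    """Exact p by enumerating every assignment of ranks to group x."""
    n = n1 + n2
    offset = n1 * (n1 + 1) / 2.0
    us = [
        sum(comb) - offset for comb in itertools.combinations(range(1, n + 1), n1)
    ]
    total = len(us)
    us = np.asarray(us)
    if alternative == "two-sided":
        p = 2.0 * min((us <= u).sum(), (us >= u).sum()) / total
    elif alternative == "greater":
        p = (us >= u).sum() / total
    else:
        p = (us <= u).sum() / total
    return float(min(p, 1.0))


def chisq_2x2(a: int, b: int, c: int, d: int, yates: bool = True) -> TestResult:
    """Chi-square test of independence on a 2x2 table [[a, b], [c, d]].

    Yates continuity correction is applied by default.  Requires all four
    margins to be positive.
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("cell counts must be non-negative integers")
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if min(margins) == 0:
        raise ValueError("chi-square undefined: a table margin is zero")
    delta = abs(a * d - b * c)
    if yates:
        delta = max(delta - n / 2.0, 0.0)
    chi2 = n * delta**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(_dist.chi2.sf(chi2, df=1))
    method = "chi-square (Yates)" if yates else "chi-square"
    return TestResult(float(chi2), p, method, (a + b, c + d))


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with a t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("spearman rho undefined for a constant vector")
    rx, ry = _rankdata(x), _rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * _dist.t.sf(abs(t), df=n - 2))
    return TestResult(rho, min(p, 1.0), "spearman", (n,))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Subjects censored at an event time are counted in the risk set at that
    time (censoring processed after the events), the standard convention.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size != events.size:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    event_times = np.unique(times[events == 1])
    surv = []
    at_risk = []
    n_ev = []
    s = 1.0
    for t in event_times:
        n = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n
        surv.append(s)
        at_risk.append(n)
        n_ev.append(d)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(n_ev, dtype=int),
        censor_times=np.sort(times[events == 0]),
    )


def logrank_test(times, events, group) -> TestResult:
    """Two-sided log-rank test between two groups.

    chi2 = (sum(O - E))^2 / sum(V) with the hypergeometric variance
    accumulated over distinct event times; p from the chi-square(1) tail.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError(f"need exactly two groups, got {labels.size}")
    if events.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    g = group == labels[1]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g).sum()
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & g).sum())
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return TestResult(0.0, 1.0, "log-rank", (int((~g).sum()), int(g.sum())))
    chi2 = o_minus_e**2 / var
    p = float(_dist.chi2.sf(chi2, df=1))
    return TestResult(float(chi2), p, "log-rank", (int((~g).sum()), int(g.sum())))


def _cox_loglik(beta, times, events, X, ties):
    """Partial log-likelihood, gradient and information matrix."""
    eta = X @ beta
    # clip to keep exp finite during step search; final fits live well inside
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    logl = 0.0
    p = X.shape[1]
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for t in np.unique(times[events == 1]):
        risk = times >= t
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        xd = X[dead]
        s0 = w[risk].sum()
        s1 = (w[risk, None] * X[risk]).sum(axis=0)
        s2 = np.einsum("i,ij,ik->jk", w[risk], X[risk], X[risk])
        if ties == "breslow" or d == 1:
            logl += eta[dead].sum() - d * math.log(s0)
            grad += xd.sum(axis=0) - d * s1 / s0
            info += d * (s2 / s0 - np.outer(s1 / s0, s1 / s0))
        else:  # efron
            s0d = w[dead].sum()
            s1d = (w[dead, None] * xd).sum(axis=0)
            s2d = np.einsum("i,ij,ik->jk", w[dead], xd, xd)
            logl += eta[dead].sum()
            for l in range(d):
                f = l / d
                a0 = s0 - f * s0d
                a1 = s1 - f * s1d
                a2 = s2 - f * s2d
                logl -= math.log(a0)
                grad -= a1 / a0
                info += a2 / a0 - np.outer(a1 / a0, a1 / a0)
            grad += xd.sum(axis=0)
    return logl, grad, info


def cox_ph(
    times,
    events,
    covariates,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Cox proportional-hazards regression by Newton-Raphson.

    Maximizes the partial likelihood with step-halving to guarantee a
    monotone log-likelihood ascent; converges when |delta logL| < ``tol``.
    Monotone-likelihood (complete separation) is reported via
    ``converged=False`` and a diagnostic instead of a silently huge beta.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    if events.sum() == 0:
        raise ValueError("cox_ph requires at least one event")
    if not np.isfinite(X).all():
        raise ValueError("covariates must be finite")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        raise ValueError("constant covariate supplied to cox_ph")

    # center for numerical stability; beta is translation-invariant
    Xc = X - X.mean(axis=0)
    p = Xc.shape[1]
    beta = np.zeros(p)
    logl, grad, info = _cox_loglik(beta, times, events, Xc, ties)
    converged = False
    diagnostic = ""
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            diagnostic = "singular information matrix"
            break
        # step-halving until the likelihood does not decrease
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            new_logl, new_grad, new_info = _cox_loglik(cand, times, events, Xc, ties)
            if new_logl >= logl - 1e-12:
                break
            factor *= 0.5
        else:
            diagnostic = "step-halving failed to find ascent"
            break
        delta = new_logl - logl
        beta, logl, grad, info = cand, new_logl, new_grad, new_info
        if abs(delta) < tol:
            converged = True
            break

    # monotone likelihood: coefficients running away on the standardized scale
    if np.any(np.abs(beta * sds) > 20):
        converged = False
        diagnostic = diagnostic or "monotone partial likelihood (separation)"

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * _dist.norm.sf(np.abs(z))
    return CoxFit(
        beta=beta,
        se=se,
        z=z,
        p=pvals,
        hazard_ratio=np.exp(beta),
        log_likelihood=float(logl),
        converged=converged,
        n_events=int(events.sum()),
        n_iter=it,
        diagnostic=diagnostic,
    )


def cox_score_test(times, events, covariate, ties: str = "efron") -> TestResult:
    """Cox partial-likelihood score test at beta = 0 (one covariate).

    With a binary covariate and no tied event times this statistic equals
    the log-rank chi-square exactly.
    """
    x = np.asarray(covariate, dtype=float)
    _, grad, info = _cox_loglik(
        np.zeros(1), np.asarray(times, float), np.asarray(events, int),
        (x - x.mean())[:, None], ties,
    )
    if info[0, 0] <= 0:
        return TestResult(0.0, 1.0, "cox-score", (len(x),))
    chi2 = float(grad[0] ** 2 / info[0, 0])
    return TestResult(chi2, float(_dist.chi2.sf(chi2, df=1)), "cox-score", (len(x),))
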