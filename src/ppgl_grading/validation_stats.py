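"""Statistical machinery for validating metastatic-risk scores.

Everything the validation pipeline reports flows through the functions
here: contingency tests (Pearson / Yates / Fisher with an automatic
small-cell switch), two-group comparisons (Student's t, Mann-Whitney U),
Cox proportional-hazards regression (hand-written Newton-Raphson on the
partial likelihood, Breslow or Efron ties), ROC analysis with DeLong's
test for correlated AUCs, the Youden-index cutoff, Kaplan-Meier /
log-rank metastasis-free-survival analysis, and Pearson correlation.

Conventions fixed across the package: all tests are two-sided; a higher
score means higher predicted metastatic potential; the ROC operating-point
convention is "score >= cutoff calls the tumor metastatic"; Wald CIs are
exp(coef +/- 1.96 SE); no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

from .errors import (
    ConvergenceError,
    DegenerateTableError,
    DomainError,
)

__all__ = [
    "ContingencyTable",
    "CoxResult",
    "RocResult",
    "SurvivalCurve",
    "compare_groups",
    "contingency_test",
    "delong_compare",
    "fit_cox",
    "km_estimate",
    "log_rank",
    "pearson_mfs_corr",
    "roc_auc",
    "youden_cutoff",
]


# ---------------------------------------------------------------------------
# contingency tables and group comparisons


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c count table with row (score class) and column (outcome) labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise DomainError("contingency table must be at least 2x2")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise DomainError("contingency table requires non-negative integer counts")
        object.__setattr__(self, "counts", counts)


def contingency_test(
    table, method: str = "auto"
) -> tuple[Optional[float], float]:
    """Two-sided test of association on a count table.

    Methods: ``pearson`` (uncorrected chi-square, any r x c), ``yates``
    (continuity-corrected chi-square, 2x2 only, correction clamped at 0),
    ``fisher`` (exact, 2x2 only), and ``auto`` — Yates for a 2x2 unless any
    expected count falls below 5, in which case Fisher's exact is used;
    Pearson for larger tables.

    Returns ``(statistic, p)``; the statistic is ``None`` for Fisher.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise DomainError("contingency table must be at least 2x2")
    if np.any(counts < 0):
        raise DomainError("counts must be non-negative")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise DegenerateTableError("table has a zero margin; no test is defined")

    is_2x2 = counts.shape == (2, 2)
    if method == "auto":
        if is_2x2:
            expected = sps.contingency.expected_freq(counts)
            method = "fisher" if np.any(expected < 5) else "yates"
        else:
            method = "pearson"

    if method == "fisher":
        if not is_2x2:
            raise DomainError("Fisher's exact test requires a 2x2 table")
        _, p = sps.fisher_exact(counts, alternative="two-sided")
        return None, float(p)
    if method == "yates":
        if not is_2x2:
            raise DomainError("Yates correction applies to 2x2 tables only")
        stat, p, _, _ = sps.chi2_contingency(counts, correction=True)
        return float(stat), float(p)
    if method == "pearson":
        stat, p, _, _ = sps.chi2_contingency(counts, correction=False)
        return float(stat), float(p)
    raise DomainError(f"unknown contingency method {method!r}")


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "mann_whitney",
) -> tuple[float, float]:
    """Two-sided comparison of a continuous variable between two groups.

    ``t_test`` is Student's t (pooled variance); ``mann_whitney`` uses exact
    enumeration when both groups have n <= 8 and the data are tie-free, and
    the tie-corrected normal approximation otherwise.  If every value in
    both groups is identical the comparison is vacuous and P = 1 is
    returned by convention (statistic: t = 0 or U = n1*n2/2).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both groups must be non-empty")

    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        stat = 0.0 if method == "t_test" else a.size * b.size / 2.0
        return stat, 1.0

    if method == "t_test":
        if a.size < 2 or b.size < 2:
            raise DomainError("t test requires at least 2 observations per group")
        res = sps.ttest_ind(a, b, equal_var=True)
        return float(res.statistic), float(res.pvalue)
    if method == "mann_whitney":
        tie_free = np.unique(pooled).size == pooled.size
        how = "exact" if (a.size <= 8 and b.size <= 8 and tie_free) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=how)
        return float(res.statistic), float(res.pvalue)
    raise DomainError(f"unknown comparison method {method!r}")


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass(frozen=True)
class CoxResult:
    """Per-covariate Wald inference from a Cox proportional-hazards fit."""

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    loglik: float
    ties: str
    n_iter: int
    converged: bool

    def summary_row(self, name: str) -> dict:
        i = self.names.index(name)
        return {
            "covariate": name,
            "coef": float(self.coef[i]),
            "se": float(self.se[i]),
            "hr": float(self.hr[i]),
            "ci_low": float(self.ci_low[i]),
            "ci_high": float(self.ci_high[i]),
            "p": float(self.p[i]),
        }


def _cox_loglik_grad_hess(beta, times, events, x, ties):
    """Partial log-likelihood with gradient and Hessian.

    Subjects are pre-sorted by time.  For each distinct event time the risk
    set is every subject with time >= that event time; Breslow treats tied
    events against the full risk-set denominator, Efron downweights the
    tied events' own contribution progressively.
    """
    n, p = x.shape
    eta = x @ beta
    w = np.exp(eta)
    wx = w[:, None] * x
    wxx = w[:, None, None] * (x[:, :, None] * x[:, None, :])

    # suffix sums over the risk set (times sorted ascending)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        d_idx = [k for k in range(i, j) if events[k]]
        m = len(d_idx)
        if m:
            ll += float(eta[d_idx].sum())
            sd0 = float(w[d_idx].sum())
            sd1 = wx[d_idx].sum(axis=0)
            sd2 = wxx[d_idx].sum(axis=0)
            for ell in range(m):
                frac = ell / m if ties == "efron" else 0.0
                d0 = s0[i] - frac * sd0
                d1 = s1[i] - frac * sd1
                d2 = s2[i] - frac * sd2
                ll -= np.log(d0)
                xbar = d1 / d0
                grad -= xbar
                hess -= d2 / d0 - np.outer(xbar, xbar)
            grad += x[d_idx].sum(axis=0)
        i = j
    return ll, grad, hess


def fit_cox(
    times,
    events,
    covariates,
    names: Optional[Sequence[str]] = None,
    ties: str = "breslow",
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    ``covariates`` is an (n,) vector (univariate) or an (n, p) matrix
    (multivariate, fitted jointly).  Ties are handled by the Breslow
    (default) or Efron method.  A monotone partial likelihood — complete
    separation, e.g. every event in one covariate category — is reported as
    a :class:`ConvergenceError` with a diagnostic instead of a silently
    enormous hazard ratio.
    """
    if ties not in ("breslow", "efron"):
        raise DomainError(f"ties must be 'breslow' or 'efron', got {ties!r}")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if t.shape != (n,) or e.shape != (n,):
        raise DomainError("times, events and covariates must have matching length")
    if e.sum() == 0:
        raise DomainError("Cox fit requires at least one event")
    if np.any(x.std(axis=0) == 0):
        dead = [i for i in range(p) if x[:, i].std() == 0]
        raise DomainError(f"zero-variance covariate(s) at column(s) {dead}")
    if names is None:
        names = tuple(f"x{i}" for i in range(p))
    names = tuple(names)
    if len(names) != p:
        raise DomainError("names must match the number of covariates")

    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]

    beta = np.zeros(p)
    ll, grad, hess = _cox_loglik_grad_hess(beta, t, e, x, ties)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Hessian at iteration {n_iter}") from exc
        new_beta = beta - step
        new_ll, new_grad, new_hess = _cox_loglik_grad_hess(new_beta, t, e, x, ties)
        # step-halving keeps Newton ascent monotone
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta - step
            new_ll, new_grad, new_hess = _cox_loglik_grad_hess(new_beta, t, e, x, ties)
            halvings += 1
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.max(np.abs(beta)) > 15:
            raise ConvergenceError(
                "monotone partial likelihood (complete separation): "
                f"|beta| diverged beyond exp(+/-15) for covariates {names}"
            )
        if np.max(np.abs(grad)) < 1e-9 or np.max(np.abs(step)) < tol:
            break
    else:
        raise ConvergenceError(f"Newton-Raphson did not converge in {max_iter} iterations")

    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError("singular information matrix at the optimum") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2 * sps.norm.sf(np.abs(z))
    return CoxResult(
        names=names,
        coef=beta,
        se=se,
        hr=np.exp(beta),
        ci_low=np.exp(beta - 1.96 * se),
        ci_high=np.exp(beta + 1.96 * se),
        p=pvals,
        loglik=float(ll),
        ties=ties,
        n_iter=n_iter,
        converged=True,
    )


# ---------------------------------------------------------------------------
# ROC / AUC, DeLong, Youden


def _split_by_label(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise DomainError("scores and labels must be matching 1-d vectors")
    if not set(np.unique(y)) <= {0, 1}:
        raise DomainError("labels must be binary (0/1)")
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise DomainError("both outcome classes must be present")
    return pos, neg


def _placements(pos, neg):
    """AUC and DeLong placement values (ties count one half)."""
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0) + 0.5 * (diff == 0)
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


@dataclass(frozen=True)
class RocResult:
    """ROC operating points ("score >= cutoff is positive") and the AUC."""

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    n_positive: int
    n_negative: int

    @property
    def auc_ci(self) -> tuple[float, float]:
        """Normal-approximation 95% CI for the AUC, clipped to [0, 1]."""
        lo = max(0.0, self.auc - 1.96 * self.auc_se)
        hi = min(1.0, self.auc + 1.96 * self.auc_se)
        return lo, hi


def roc_auc(scores, labels) -> RocResult:
    """ROC analysis of a score against a binary metastasis outcome.

    The AUC equals the Mann-Whitney probability that a random metastatic
    subject outscores a random non-metastatic one (ties counted 1/2); its
    standard error is DeLong's placement-value estimate.  Operating points
    are evaluated at every distinct observed score.
    """
    pos, neg = _split_by_label(scores, labels)
    auc, v10, v01 = _placements(pos, neg)
    m, n = pos.size, neg.size
    var = 0.0
    if m > 1:
        var += v10.var(ddof=1) / m
    if n > 1:
        var += v01.var(ddof=1) / n
    cutoffs = np.unique(np.concatenate([pos, neg]))
    sens = np.array([(pos >= c).mean() for c in cutoffs])
    spec = np.array([(neg < c).mean() for c in cutoffs])
    return RocResult(
        cutoffs=cutoffs,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_se=float(np.sqrt(var)),
        n_positive=m,
        n_negative=n,
    )


def delong_compare(scores_1, scores_2, labels) -> tuple[float, float, float, float]:
    """DeLong's test for two correlated AUCs measured on the same subjects.

    Returns ``(auc_1, auc_2, auc_1 - auc_2, two-sided P)``.  The comparison
    is antisymmetric in the score arguments (same P, negated difference).
    Identical score vectors give a zero difference with zero variance,
    reported as P = 1.
    """
    pos1, neg1 = _split_by_label(scores_1, labels)
    pos2, neg2 = _split_by_label(scores_2, labels)
    auc1, v10_1, v01_1 = _placements(pos1, neg1)
    auc2, v10_2, v01_2 = _placements(pos2, neg2)
    m, n = pos1.size, neg1.size
    var = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc1 - auc2
    if var <= 0:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
    return auc1, auc2, diff, p


def youden_cutoff(scores, labels) -> tuple[float, float, float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidate cutoffs are the distinct observed scores ("score >= cutoff is
    positive"); ties in J are broken toward the smallest cutoff, which
    maximizes sensitivity at equal J.  Returns
    ``(cutoff, J, sensitivity, specificity)``.
    """
    pos, neg = _split_by_label(scores, labels)
    cutoffs = np.unique(np.concatenate([pos, neg]))
    best = None
    for c in cutoffs:
        sens = float((pos >= c).mean())
        spec = float((neg < c).mean())
        j = sens + spec - 1.0
        if best is None or j > best[1] + 1e-12:
            best = (float(c), j, sens, spec)
    return best


# ---------------------------------------------------------------------------
# survival


@dataclass(frozen=True)
class SurvivalCurve:
    """A Kaplan-Meier product-limit curve on the observed-time grid.

    ``times`` starts at 0 with survival 1; ``censored_times`` lists the
    censoring marks for plotting.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censored_times: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimate of (metastasis-free) survival.

    Ties between events and censorings at the same time are resolved
    events-first, the product-limit convention.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if t.size == 0:
        raise DomainError("km_estimate requires at least one subject")
    if np.any(t < 0):
        raise DomainError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    grid = np.asarray(table.index, dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    at_risk = table["at_risk"].to_numpy()
    if grid.size == 0 or grid[0] != 0.0:
        grid = np.concatenate([[0.0], grid])
        surv = np.concatenate([[1.0], surv])
        at_risk = np.concatenate([[t.size], at_risk])
    return SurvivalCurve(
        times=grid,
        survival=surv,
        at_risk=at_risk,
        censored_times=np.sort(t[~e]),
    )


def log_rank(groups: Sequence[tuple]) -> tuple[float, float]:
    """Log-rank test across >= 2 groups of (times, events).

    Standard observed-minus-expected statistic over the pooled event times,
    chi-square with (number of groups - 1) degrees of freedom.
    """
    if len(groups) < 2:
        raise DomainError("log-rank requires at least two groups")
    times, events, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e).astype(bool)
        if t.size == 0:
            raise DomainError(f"group {g} is empty")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, g))
    times = np.concatenate(times)
    events = np.concatenate(events)
    labels = np.concatenate(labels)
    if events.sum() == 0:
        raise DomainError("log-rank requires at least one event overall")
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


def pearson_mfs_corr(scores, times) -> tuple[float, float]:
    """Pearson correlation between a score and time to metastasis.

    Two-sided t test on n - 2 degrees of freedom; requires n >= 3 and
    nonzero variance in both vectors.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    if s.size != t.size or s.size < 3:
        raise DomainError("Pearson correlation requires n >= 3 paired values")
    if s.std() == 0 or t.std() == 0:
        raise DomainError("Pearson correlation undefined for zero-variance input")
    r, p = sps.pearsonr(s, t)
    return float(r), float(p)
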