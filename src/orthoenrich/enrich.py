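"""Gene-set enrichment: Fisher overrepresentation and cutoff-free logistic
regression with a Wald test.

Two complementary tests are provided per gene set:

* **Fisher's exact test** dichotomizes genes at a differential-expression
  significance cut-off and tests the 2x2 table (in-set x significant)
  against the hypergeometric null,

      p(a) = C(a+b, a) * C(c+d, d) / C(N, a+c)

  where ``a`` counts genes in the set and significant, ``b`` significant
  genes outside the set, ``c`` non-significant genes in the set, ``d`` the
  rest, and ``N = a+b+c+d`` is the background universe.

* **Logistic regression** uses the whole continuum of DE evidence: set
  membership is regressed on x = -log(p_DE),

      log(p / (1 - p)) = alpha + beta * x,

  and the Wald statistic W = beta_hat / se(beta_hat) is referred, squared,
  to a chi-square distribution with one degree of freedom.  beta > 0 means
  stronger DE evidence raises the odds of set membership, i.e. enrichment.

Directional (up/down) variants restrict which genes count as significant
(Fisher) or carry evidence (logistic; see :func:`enrich_collection`).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "Direction",
    "Method",
    "Tail",
    "Correction",
    "MIN_PVALUE",
    "DETable",
    "read_de_table",
    "ContingencyTable",
    "build_contingency",
    "hypergeom_point_prob",
    "fisher_pvalue",
    "LogisticFit",
    "logistic_fit",
    "wald_test",
    "adjust_pvalues",
    "pct_sig_genes",
    "enrich_collection",
    "write_enrichment",
    "ENRICHMENT_COLUMNS",
]

MIN_PVALUE = 1e-300  # DE p-values of exactly 0 are clamped here before log


class Direction(str, enum.Enum):
    NONDIRECTIONAL = "nondirectional"
    UP = "up"
    DOWN = "down"


class Method(str, enum.Enum):
    FISHER = "fisher"
    LOGISTIC = "logistic"


class Tail(str, enum.Enum):
    OVER = "over"
    UNDER = "under"


class Correction(str, enum.Enum):
    BH = "bh"
    BONFERRONI = "bonferroni"
    NONE = "none"


class ConvergenceError(RuntimeError):
    """A logistic fit did not converge (e.g. complete separation)."""


# ---------------------------------------------------------------------------
# Differential-expression table


class DETable:
    """Per-gene differential-expression evidence defining the universe.

    One record per gene: duplicate genes are collapsed to their minimum
    p-value (conservative toward enrichment) and p-values are clamped into
    (0, 1].  The universe size N is the number of distinct genes.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"gene", "pvalue", "log2fc"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")
        frame = frame[["gene", "pvalue", "log2fc"]].copy()
        frame["gene"] = frame["gene"].astype(str).str.strip()
        frame = frame[frame["gene"] != ""]
        frame["pvalue"] = pd.to_numeric(frame["pvalue"]).clip(MIN_PVALUE, 1.0)
        frame["log2fc"] = pd.to_numeric(frame["log2fc"])
        n_before = len(frame)
        frame = (
            frame.sort_values(["gene", "pvalue"], kind="mergesort")
            .drop_duplicates("gene", keep="first")
            .reset_index(drop=True)
        )
        self.n_duplicates_collapsed = n_before - len(frame)
        if len(frame) < 1:
            raise ValueError("DE table is empty after cleaning")
        self.frame = frame
        self._index = {g: i for i, g in enumerate(frame["gene"])}

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def genes(self) -> np.ndarray:
        return self.frame["gene"].to_numpy()

    @property
    def pvalues(self) -> np.ndarray:
        return self.frame["pvalue"].to_numpy()

    @property
    def log2fc(self) -> np.ndarray:
        return self.frame["log2fc"].to_numpy()

    def membership_mask(self, members: Iterable[str]) -> np.ndarray:
        """Boolean mask over the universe for a gene set's members."""
        mask = np.zeros(len(self.frame), dtype=bool)
        index = self._index
        for g in members:
            i = index.get(g)
            if i is not None:
                mask[i] = True
        return mask


def read_de_table(path: str | Path) -> DETable:
    """Read a DE results TSV with header ``gene  pvalue  log2fc``
    (extra columns are ignored)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return DETable(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Fisher / hypergeometric


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 gene-set-by-significance table; a+b+c+d = N (the universe)."""

    a: int  # in set, significant
    b: int  # not in set, significant
    c: int  # in set, not significant
    d: int  # not in set, not significant

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def set_size(self) -> int:
        return self.a + self.c

    @property
    def n_significant(self) -> int:
        return self.a + self.b

    @property
    def degenerate(self) -> bool:
        """Set empty in the universe, or set equal to the whole universe."""
        return self.set_size == 0 or self.set_size == self.n

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return (self.a * self.d) / (self.b * self.c)


def _sig_mask(
    pvalues: np.ndarray,
    log2fc: np.ndarray,
    sig_threshold: float,
    direction: Direction,
) -> np.ndarray:
    sig = pvalues < sig_threshold
    if direction == Direction.UP:
        sig &= log2fc > 0
    elif direction == Direction.DOWN:
        sig &= log2fc < 0
    return sig


def build_contingency(
    de: DETable,
    geneset: GeneSet,
    sig_threshold: float = 0.05,
    direction: str | Direction = Direction.NONDIRECTIONAL,
) -> ContingencyTable:
    """Count the 2x2 table for one gene set against the DE universe.

    Significance means ``pvalue < sig_threshold`` and, for directional
    tests, a fold change of the matching sign (genes with log2fc == 0 are
    neither up nor down).  Set membership is restricted to genes present in
    the universe.
    """
    if not (0 < sig_threshold < 1):
        raise ValueError("sig_threshold must be in (0, 1)")
    direction = Direction(direction)
    member = de.membership_mask(geneset.members)
    sig = _sig_mask(de.pvalues, de.log2fc, sig_threshold, direction)
    a = int(np.sum(member & sig))
    b = int(np.sum(~member & sig))
    c = int(np.sum(member & ~sig))
    d = int(np.sum(~member & ~sig))
    return ContingencyTable(a, b, c, d)


def _log_binom(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_point_prob(t: ContingencyTable) -> float:
    """Exact point probability of the observed table under the
    hypergeometric null, computed in log space:
    C(a+b, a) * C(c+d, d) / C(N, a+c)."""
    logp = (
        _log_binom(t.a + t.b, t.a)
        + _log_binom(t.c + t.d, t.d)
        - _log_binom(t.n, t.a + t.c)
    )
    return float(np.exp(logp))


def fisher_pvalue(t: ContingencyTable, tail: str | Tail = Tail.OVER) -> float:
    """One-sided Fisher exact p-value at fixed margins.

    ``OVER`` sums point probabilities of all tables at least as enriched
    (a' >= a); ``UNDER`` of all tables at most as enriched (a' <= a).
    """
    tail = Tail(tail)
    n, s, k = t.n, t.n_significant, t.set_size
    lo, hi = max(0, s + k - n), min(s, k)
    support = np.arange(lo, hi + 1)
    logpmf = (
        _log_binom(k, support)
        + _log_binom(n - k, s - support)
        - _log_binom(n, s)
    )
    pmf = np.exp(logpmf)
    if tail == Tail.OVER:
        p = float(pmf[support >= t.a].sum())
    else:
        p = float(pmf[support <= t.a].sum())
    return min(1.0, max(p, MIN_PVALUE))


# ---------------------------------------------------------------------------
# Logistic regression + Wald


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood fit of log-odds(membership) = alpha + beta * x."""

    alpha: float
    beta: float
    se_beta: float
    W: float
    pvalue: float
    converged: bool
    n_iter: int
    message: str = ""


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # sum_i [ y_i * eta_i - log(1 + exp(eta_i)) ], overflow-safe
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def logistic_fit(
    x: Sequence[float],
    membership: Sequence[int],
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Fit the single-covariate logistic model by Newton-Raphson IRLS.

    Convergence is declared when the relative log-likelihood change drops
    below ``tol`` (default 1e-8) or after ``max_iter`` iterations; the
    standard error of beta comes from the observed information at the
    optimum.  Complete separation is detected up front and reported as a
    non-converged fit rather than silently diverging estimates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(membership, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and membership must be 1-D and the same length")
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("membership must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("membership has a single class; the model is not identifiable")

    x1, x0 = x[y == 1], x[y == 0]
    if x1.min() > x0.max() or x0.min() > x1.max():
        return LogisticFit(
            alpha=float("nan"), beta=float("nan"), se_beta=float("nan"),
            W=float("nan"), pvalue=float("nan"), converged=False, n_iter=0,
            message="complete separation: class x-ranges do not overlap",
        )

    ybar = y.mean()
    alpha = float(np.log(ybar / (1.0 - ybar)))
    beta = 0.0
    eta = np.clip(alpha + beta * x, -35, 35)
    ll = _loglik(eta, y)
    converged = False
    n_iter = 0
    message = ""
    for n_iter in range(1, max_iter + 1):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        resid = y - mu
        g0, g1 = resid.sum(), float(resid @ x)
        h00 = w.sum()
        h01 = float(w @ x)
        h11 = float(w @ (x * x))
        det = h00 * h11 - h01 * h01
        if det <= 0 or not np.isfinite(det):
            message = "singular information matrix"
            break
        d_alpha = (h11 * g0 - h01 * g1) / det
        d_beta = (h00 * g1 - h01 * g0) / det
        # step-halving keeps Newton monotone on ill-conditioned starts
        step = 1.0
        for _ in range(25):
            eta_new = np.clip(alpha + step * d_alpha + (beta + step * d_beta) * x, -35, 35)
            ll_new = _loglik(eta_new, y)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        alpha += step * d_alpha
        beta += step * d_beta
        eta = np.clip(alpha + beta * x, -35, 35)
        if abs(ll_new - ll) <= tol * (abs(ll) + 1e-12):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged and not message:
        message = f"no convergence in {max_iter} iterations"

    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    h00 = w.sum()
    h01 = float(w @ x)
    h11 = float(w @ (x * x))
    det = h00 * h11 - h01 * h01
    if det <= 0 or not np.isfinite(det):
        return LogisticFit(alpha, beta, float("nan"), float("nan"), float("nan"),
                           False, n_iter, message or "singular information matrix")
    se_beta = float(np.sqrt(h00 / det))
    W = beta / se_beta
    pvalue = float(chi2.sf(W * W, df=1))
    return LogisticFit(alpha=float(alpha), beta=float(beta), se_beta=se_beta,
                       W=float(W), pvalue=max(pvalue, MIN_PVALUE),
                       converged=converged, n_iter=n_iter, message=message)


def wald_test(fit: LogisticFit) -> tuple[float, float, bool]:
    """Wald test of beta = 0: W = beta_hat / se(beta_hat), with W^2 referred
    to chi-square(1).  Returns (W, p-value, enriched), where enriched means
    beta > 0."""
    if not fit.converged:
        raise ConvergenceError(fit.message or "logistic fit did not converge")
    return fit.W, fit.pvalue, fit.beta > 0


# ---------------------------------------------------------------------------
# Collection-level analysis


def adjust_pvalues(
    p: Sequence[float], method: str | Correction = Correction.BH
) -> np.ndarray:
    """Multiple-testing adjustment across the tested sets (BH step-up,
    Bonferroni, or none)."""
    method = Correction(method)
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if method == Correction.NONE:
        return p.copy()
    sm_name = {Correction.BH: "fdr_bh", Correction.BONFERRONI: "bonferroni"}[method]
    return multipletests(p, method=sm_name)[1]


def pct_sig_genes(
    de: DETable,
    geneset: GeneSet,
    sig_threshold: float = 0.05,
    direction: str | Direction = Direction.NONDIRECTIONAL,
) -> float:
    """Percentage of a set's in-universe genes that are significant:
    100 * a / (a + c), or 0 when the set is absent from the universe."""
    t = build_contingency(de, geneset, sig_threshold, direction)
    return 100.0 * t.a / t.set_size if t.set_size else 0.0


ENRICHMENT_COLUMNS = [
    "set_id",
    "set_name",
    "annotation_organism",
    "method",
    "direction",
    "effect",
    "statistic",
    "pvalue",
    "adj_pvalue",
    "n_set_in_universe",
    "pct_sig_genes",
]


def _directional_x(pvalues: np.ndarray, log2fc: np.ndarray, direction: Direction):
    """Explanatory variable for the logistic model: x = -log(p_DE), with
    evidence from the wrong-sign genes zeroed out in directional tests."""
    x = -np.log(np.clip(pvalues, MIN_PVALUE, 1.0))
    if direction == Direction.UP:
        x = np.where(log2fc > 0, x, 0.0)
    elif direction == Direction.DOWN:
        x = np.where(log2fc < 0, x, 0.0)
    return x


def enrich_collection(
    de: DETable,
    coll: GeneSetCollection,
    method: str | Method = Method.FISHER,
    direction: str | Direction = Direction.NONDIRECTIONAL,
    sig_threshold: float = 0.05,
    correction: str | Correction = Correction.BH,
    subset_ids: Sequence[str] | None = None,
    tail: str | Tail = Tail.OVER,
) -> pd.DataFrame:
    """Test every gene set (or a chosen subset) for enrichment.

    Returns one row per tested set with columns ``ENRICHMENT_COLUMNS``,
    sorted by p-value ascending (ties broken by set id).  The adjusted
    p-value is computed across exactly the tested sets.  Sets that are
    degenerate against the universe (no member in it, or every universe
    gene a member; for the logistic model, a single membership class) are
    skipped with a logged notice.
    """
    method = Method(method)
    direction = Direction(direction)
    correction = Correction(correction)
    tail = Tail(tail)

    sets = list(coll.sets)
    if subset_ids is not None:
        known = set(coll.ids)
        unknown = [i for i in subset_ids if i not in known]
        if unknown:
            raise ValueError(f"subset ids not in collection: {unknown}")
        wanted = set(subset_ids)
        sets = [s for s in sets if s.set_id in wanted]

    if method == Method.LOGISTIC:
        x = _directional_x(de.pvalues, de.log2fc, direction)

    rows = []
    for s in sets:
        t = build_contingency(de, s, sig_threshold, direction)
        if t.degenerate:
            logger.info("skipping degenerate set %s (size in universe: %d)",
                        s.set_id, t.set_size)
            continue
        if method == Method.FISHER:
            pvalue = fisher_pvalue(t, tail)
            effect = t.odds_ratio
            statistic = hypergeom_point_prob(t)
        else:
            member = de.membership_mask(s.members)
            fit = logistic_fit(x, member.astype(float))
            if not fit.converged:
                # routine for wrong-direction tests of strongly regulated
                # sets (quasi-separation); the fit's diagnostic is preserved
                logger.info("skipping set %s: %s", s.set_id, fit.message)
                continue
            _, pvalue, _ = wald_test(fit)
            effect = fit.beta
            statistic = fit.W
        rows.append(
            {
                "set_id": s.set_id,
                "set_name": s.name,
                "annotation_organism": s.annotation_organism.value,
                "method": method.value,
                "direction": direction.value,
                "effect": effect,
                "statistic": statistic,
                "pvalue": pvalue,
                "n_set_in_universe": t.set_size,
                "pct_sig_genes": 100.0 * t.a / t.set_size,
            }
        )
    if not rows:
        raise ValueError("no testable gene sets after subsetting/degenerate filtering")
    table = pd.DataFrame(rows)
    table["adj_pvalue"] = adjust_pvalues(table["pvalue"].to_numpy(), correction)
    table = (
        table.sort_values(["pvalue", "set_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return table[ENRICHMENT_COLUMNS]


def write_enrichment(table: pd.DataFrame, path: str | Path, as_json: bool = False) -> None:
    if as_json:
        table.to_json(path, orient="records", indent=2)
    else:
        table.to_csv(path, sep="\t", index=False)
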