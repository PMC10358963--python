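"""Slow/fast growth-assemblage classification.

Per-isolate mean standardized growth in an endophyte culture collection is
strongly bimodal: a tight mode of slow growers near 0.04 OD590 and a broad
mode of fast growers near 0.29 OD590. A two-component univariate Gaussian
mixture is fitted by EM and the classification cutoff is the equal-posterior
point between the component means — the Bayes decision boundary
``w1 * phi(x; mu1, s1) = w2 * phi(x; mu2, s2)``, which reduces to the
midpoint when weights and variances are equal. Isolates below the cutoff
are labeled slow, at or above it fast.

The variances of the two components are allowed to differ (the slow mode is
much tighter than the fast mode), which is why the cutoff is found
numerically rather than in closed form.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureFit",
    "AssemblageAssignment",
    "fit_mixture",
    "classification_cutoff",
    "assign",
]

_LOG_SQRT_2PI = 0.5 * math.log(2 * math.pi)


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture, components ordered so mu1 < mu2."""

    w1: float
    w2: float
    mu1: float
    mu2: float
    s1: float
    s2: float
    loglik: float
    converged: bool
    n_iter: int
    cutoff: float | None = None

    @property
    def separation(self) -> float:
        """|mu2 - mu1| relative to the pooled component sd; < 2 means the
        components overlap heavily and the slow/fast dichotomy is doubtful."""
        pooled = math.sqrt(self.w1 * self.s1**2 + self.w2 * self.s2**2)
        return abs(self.mu2 - self.mu1) / pooled

    def report(self) -> dict:
        d = asdict(self)
        d["separation"] = self.separation
        d["well_separated"] = self.separation >= 2.0
        return d

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.report(), fh, indent=2)


@dataclass
class AssemblageAssignment:
    """Per-isolate slow/fast labels and the cutoff that produced them."""

    labels: pd.Series  # values in {"slow", "fast"}
    cutoff: float

    def counts(self) -> dict[str, int]:
        c = self.labels.value_counts()
        return {"slow": int(c.get("slow", 0)), "fast": int(c.get("fast", 0))}


def _component_loglik(x: np.ndarray, w: np.ndarray, mu: np.ndarray,
                      s: np.ndarray) -> np.ndarray:
    """Per-component log w_k + log phi(x; mu_k, s_k), shape (2, n)."""
    z = (x[None, :] - mu[:, None]) / s[:, None]
    return (np.log(w)[:, None] - np.log(s)[:, None] - _LOG_SQRT_2PI
            - 0.5 * z * z)


def _em_once(x: np.ndarray, w: np.ndarray, mu: np.ndarray, s: np.ndarray,
             tol: float, max_iter: int, min_sd: float):
    n = x.size
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        comp = _component_loglik(x, w, mu, s)
        norm = logsumexp(comp, axis=0)
        ll = float(norm.sum())
        r = np.exp(comp - norm[None, :])
        nk = r.sum(axis=1)
        if nk.min() < 1e-8:  # one component lost all responsibility
            return None
        mu = (r @ x) / nk
        var = (r @ (x * x)) / nk - mu * mu
        s = np.sqrt(np.maximum(var, min_sd**2))
        w = nk / n
        # convergence on the loglik *increment*, which is invariant under
        # affine data transforms (the loglik itself shifts by -n log b)
        if abs(ll - ll_old) < tol * n:
            converged = True
            break
        ll_old = ll
    collapsed = bool(np.any(s <= min_sd * (1 + 1e-12)))
    return w, mu, s, ll, converged, it, collapsed


def fit_mixture(
    values,
    seed: int,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MixtureFit:
    """Fit a two-component univariate Gaussian mixture by EM.

    The first start splits the sorted data at its median (lower/upper half
    means and sds); the remaining ``n_starts - 1`` starts seed the means
    from random pairs of data points. The best non-degenerate start by
    log-likelihood wins; components are relabeled so ``mu1 < mu2``. The
    component standard deviations are floored at 1e-4 times the data sd to
    keep the likelihood bounded. Deterministic given ``seed``.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 10:
        raise ValueError("need at least 10 values to fit a mixture")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    sd = float(np.std(x))
    if sd <= 1e-10 * max(1.0, abs(float(np.mean(x)))):
        raise ValueError("degenerate data: all values identical")
    min_sd = 1e-4 * sd
    rng = np.random.default_rng(seed)

    starts = []
    xs = np.sort(x)
    half = x.size // 2
    lo, hi = xs[:half], xs[half:]
    starts.append((
        np.array([0.5, 0.5]),
        np.array([lo.mean(), hi.mean()]),
        np.maximum(np.array([lo.std(), hi.std()]), min_sd),
    ))
    for _ in range(max(0, n_starts - 1)):
        mu = rng.choice(x, size=2, replace=False)
        if mu[0] == mu[1]:
            mu = mu + np.array([-0.5, 0.5]) * sd
        starts.append((np.array([0.5, 0.5]), np.sort(mu),
                       np.array([sd, sd])))

    best = None
    diagnostics = []
    for w0, mu0, s0 in starts:
        res = _em_once(x, w0, mu0, s0, tol, max_iter, min_sd)
        if res is None:
            diagnostics.append("responsibility collapse")
            continue
        w, mu, s, ll, converged, it, collapsed = res
        if collapsed:
            diagnostics.append(f"variance floor hit (loglik={ll:.3f})")
            continue
        if best is None or ll > best[3]:
            best = (w, mu, s, ll, converged, it)
    if best is None:
        raise RuntimeError(
            "EM failed in all starts: " + "; ".join(diagnostics)
        )
    w, mu, s, ll, converged, it = best
    order = np.argsort(mu)
    w, mu, s = w[order], mu[order], s[order]
    fit = MixtureFit(
        w1=float(w[0]), w2=float(w[1]), mu1=float(mu[0]), mu2=float(mu[1]),
        s1=float(s[0]), s2=float(s[1]), loglik=ll, converged=bool(converged),
        n_iter=int(it),
    )
    try:
        fit.cutoff = classification_cutoff(fit)
    except ValueError as exc:
        logger.warning("no classification cutoff: %s", exc)
    if fit.separation < 2.0:
        logger.warning(
            "mixture components overlap heavily (separation %.2f sd); "
            "the slow/fast dichotomy may not be meaningful", fit.separation
        )
    return fit


def classification_cutoff(fit: MixtureFit) -> float:
    """Equal-posterior point between the component means.

    Solves ``w1 * phi(x; mu1, s1) = w2 * phi(x; mu2, s2)`` for x in
    (mu1, mu2) by bracketing on a dense grid followed by Brent's method.
    With unequal variances the equation is quadratic in x and may have no
    root between the means; that case is reported as an error so the user
    can set a cutoff manually.
    """
    if not fit.mu1 < fit.mu2:
        raise ValueError("requires mu1 < mu2")

    def f(x: float) -> float:
        z1 = (x - fit.mu1) / fit.s1
        z2 = (x - fit.mu2) / fit.s2
        return (math.log(fit.w1) - math.log(fit.s1) - 0.5 * z1 * z1) - (
            math.log(fit.w2) - math.log(fit.s2) - 0.5 * z2 * z2
        )

    grid = np.linspace(fit.mu1, fit.mu2, 2001)
    vals = np.array([f(g) for g in grid])
    sign_changes = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    # keep slow->fast transitions (posterior of the slow component drops)
    down = [i for i in sign_changes if vals[i] > 0 and vals[i + 1] <= 0]
    if not down:
        raise ValueError(
            "no equal-posterior point between the component means; "
            "set a manual cutoff"
        )
    i = down[0]
    return float(brentq(f, grid[i], grid[i + 1], xtol=1e-10))


def assign(values, cutoff: float) -> AssemblageAssignment:
    """Label isolates slow (< cutoff) or fast (>= cutoff)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    v = pd.Series(values, dtype=float)
    labels = pd.Series(
        np.where(v < cutoff, "slow", "fast"), index=v.index, name="assemblage"
    )
    return AssemblageAssignment(labels=labels, cutoff=float(cutoff))
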