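"""One-dimensional statistical parametric mapping for gait waveforms.

A two-sample SPM{t} compares two groups of 101-node waveforms (one
time-normalized mean waveform per participant). The node-wise pooled-
variance t statistic forms a 1D random field; its family-wise critical
threshold t* at level alpha comes from the random-field-theory (RFT)
expected Euler characteristic of a smooth t field:

    alpha = P(T > t*) + (L / W) * sqrt(4 ln 2) / (2 pi)
                       * (1 + t*^2 / nu)^(-(nu - 1) / 2)

with nu the degrees of freedom, L the search length in nodes and W the
field smoothness (FWHM, in nodes) estimated from the normalized model
residuals. Two-sided inference thresholds |t| at level alpha/2 per tail.
Maximal runs of |t| > t* are reported as suprathreshold clusters in
percent-of-stride coordinates. A permutation threshold (max-|t| null
distribution over group-label relabellings) is available as a
distribution-free cross-check.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from scipy import stats as st

__all__ = ["SpmTTest", "SpmResults", "Cluster", "rft_threshold", "estimate_fwhm"]


@dataclass
class Cluster:
    """A maximal suprathreshold run of the t field."""

    start_node: int
    end_node: int  # inclusive
    direction: int  # +1: group A above B; -1: below

    @property
    def extent_pct(self) -> float:
        """Cluster extent as percent of the gait cycle."""
        return float(self.end_node - self.start_node)

    def __str__(self) -> str:
        sign = "+" if self.direction > 0 else "-"
        return f"[{self.start_node}%..{self.end_node}%] ({sign})"


def estimate_fwhm(residuals: np.ndarray) -> float:
    """Field smoothness (FWHM, in nodes) from normalized residual gradients.

    ``residuals`` is (observations, nodes). The gradient variance of the
    unit-normalized residual field determines the resel density; FWHM is
    its reciprocal scaled by sqrt(4 ln 2). Infinite smoothness (constant
    residual field) returns inf.
    """
    r = np.asarray(residuals, dtype=float)
    ssq = (r**2).sum(axis=0)
    grad = np.diff(r, axis=1)
    denom = 0.5 * (ssq[:-1] + ssq[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (grad**2).sum(axis=0) / denom
    v = v[np.isfinite(v)]
    if v.size == 0 or np.all(v == 0):
        return float("inf")
    resels_per_node = np.sqrt(v / (4.0 * math.log(2.0)))
    return float(1.0 / resels_per_node.mean())


def _ec_density_t(t: float, nu: float) -> float:
    """1D Euler-characteristic density of a t field (per unit FWHM)."""
    return (
        math.sqrt(4.0 * math.log(2.0))
        / (2.0 * math.pi)
        * (1.0 + t * t / nu) ** (-(nu - 1.0) / 2.0)
    )


def rft_threshold(alpha: float, nu: float, n_nodes: int, fwhm: float) -> float:
    """Critical t* with family-wise level alpha for a smooth 1D t field.

    Solves alpha = sf_t(t*) + resels * ec_density(t*) where resels =
    (n_nodes - 1) / fwhm. For a one-sided level pass alpha directly; for
    two-sided |t| inference pass alpha / 2.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    resels = (n_nodes - 1) / fwhm if np.isfinite(fwhm) else 0.0

    def excess(t: float) -> float:
        return st.t.sf(t, nu) + resels * _ec_density_t(t, nu) - alpha

    lo, hi = 1e-6, 100.0
    while excess(hi) > 0 and hi < 1e9:  # heavy tails at tiny df need a wider bracket
        hi *= 10.0
    if excess(hi) > 0:
        raise ValueError("alpha unattainably small for this field")
    return float(optimize.brentq(excess, lo, hi, xtol=1e-10, rtol=1e-12))


@dataclass
class SpmResults:
    """Fitted two-sample SPM{t}: the t field and its inference.

    ``clusters`` are exactly the maximal runs where |t| exceeds the
    critical threshold (two-sided inference).
    """

    t_field: np.ndarray
    critical_threshold: float
    clusters: list[Cluster]
    fwhm: float
    alpha: float
    df: float
    n: tuple[int, int]
    excluded_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    permutation_threshold_: float | None = None

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0

    def summary(self) -> str:
        lines = [
            f"two-sample SPM{{t}}  n={self.n[0]}/{self.n[1]}  df={self.df:g}  "
            f"FWHM={self.fwhm:.1f} nodes",
            f"critical |t*|={self.critical_threshold:.3f} at alpha={self.alpha} (two-sided, RFT)",
        ]
        if self.permutation_threshold_ is not None:
            lines.append(f"permutation |t*|={self.permutation_threshold_:.3f}")
        if self.clusters:
            lines.append("suprathreshold clusters: " + ", ".join(map(str, self.clusters)))
        else:
            lines.append("no suprathreshold clusters")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the t field with the critical threshold band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(self.t_field.size)
        ax.plot(x, self.t_field, color="k", lw=1.5, label="SPM{t}")
        ax.axhline(self.critical_threshold, ls="--", color="r", label="t*")
        ax.axhline(-self.critical_threshold, ls="--", color="r")
        for c in self.clusters:
            ax.axvspan(c.start_node, c.end_node, alpha=0.25, color="r")
        ax.set_xlabel("gait cycle (%)")
        ax.set_ylabel("t")
        ax.legend(loc="best", frameon=False)
        return ax


class SpmTTest:
    """Two-sample SPM{t} over 101-node waveforms.

    Parameters
    ----------
    group_a, group_b
        (participants, nodes) arrays; one mean waveform per participant.
    alpha
        Family-wise significance level (two-sided), default 0.05.
    """

    def __init__(self, group_a: np.ndarray, group_b: np.ndarray, alpha: float = 0.05):
        self.a = np.atleast_2d(np.asarray(group_a, dtype=float))
        self.b = np.atleast_2d(np.asarray(group_b, dtype=float))
        if self.a.shape[1] != self.b.shape[1]:
            raise ValueError("groups must share the node grid")
        if self.a.shape[0] < 2 or self.b.shape[0] < 2:
            raise ValueError("need at least 2 participants per group")
        self.alpha = alpha

    @staticmethod
    def _t_field(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Node-wise pooled-variance t; zero-variance nodes flagged."""
        na, nb = a.shape[0], b.shape[0]
        va = a.var(axis=0, ddof=1)
        vb = b.var(axis=0, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        bad = se == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (a.mean(axis=0) - b.mean(axis=0)) / se
        return t, np.flatnonzero(bad)

    def fit(self) -> SpmResults:
        na, nb = self.a.shape[0], self.b.shape[0]
        nu = na + nb - 2
        t, excluded = self._t_field(self.a, self.b)
        if excluded.size:
            warnings.warn(
                f"{excluded.size} zero-variance nodes excluded from inference",
                stacklevel=2,
            )
            t = t.copy()
            t[excluded] = 0.0
        residuals = np.vstack(
            [self.a - self.a.mean(axis=0), self.b - self.b.mean(axis=0)]
        )
        fwhm = estimate_fwhm(residuals)
        tstar = rft_threshold(self.alpha / 2.0, nu, t.size, fwhm)
        clusters = self._clusters(t, tstar)
        return SpmResults(
            t_field=t,
            critical_threshold=tstar,
            clusters=clusters,
            fwhm=fwhm,
            alpha=self.alpha,
            df=float(nu),
            n=(na, nb),
            excluded_nodes=excluded,
        )

    @staticmethod
    def _clusters(t: np.ndarray, tstar: float) -> list[Cluster]:
        above = np.abs(t) > tstar
        clusters: list[Cluster] = []
        start = None
        for i, flag in enumerate(above):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                clusters.append(Cluster(start, i - 1, int(np.sign(t[start:i].mean()))))
                start = None
        if start is not None:
            clusters.append(
                Cluster(start, len(t) - 1, int(np.sign(t[start:].mean())))
            )
        return clusters

    def permutation_threshold(
        self, n_permutations: int = 10_000, seed: int | np.random.Generator = 0
    ) -> float:
        """(1 - alpha) quantile of the max-|t| permutation null.

        Group labels are permuted; when the total number of distinct
        relabellings is at most 20,000 they are enumerated exactly,
        otherwise ``n_permutations`` random relabellings are drawn. Warns
        when the permutation resolution cannot resolve alpha.
        """
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        data = np.vstack([self.a, self.b])
        n, na = data.shape[0], self.a.shape[0]
        total = special.comb(n, na, exact=True)
        if total <= 20_000:
            picks = [np.array(c) for c in itertools.combinations(range(n), na)]
        else:
            picks = [rng.permutation(n)[:na] for _ in range(n_permutations)]
        if len(picks) < 1.0 / self.alpha:
            warnings.warn(
                f"only {len(picks)} permutations: attainable minimum p is "
                f"{1.0 / len(picks):.3g} > alpha={self.alpha}",
                stacklevel=2,
            )
        mask = np.zeros((len(picks), n), dtype=bool)
        for i, p in enumerate(picks):
            mask[i, p] = True
        maxima = np.empty(len(picks))
        for i in range(len(picks)):
            t, _ = self._t_field(data[mask[i]], data[~mask[i]])
            maxima[i] = np.nanmax(np.abs(t))
        return float(np.quantile(maxima, 1.0 - self.alpha))

    def fit_with_permutation(
        self, n_permutations: int = 10_000, seed: int | np.random.Generator = 0
    ) -> SpmResults:
        """Fit with the RFT threshold and attach the permutation cross-check."""
        res = self.fit()
        res.permutation_threshold_ = self.permutation_threshold(n_permutations, seed)
        return res
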