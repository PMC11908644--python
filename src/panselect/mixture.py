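"""Gaussian + log-normal null model for the -log Jaccard score distribution.

Across a chromosome, most windows are near-identical between haplotypes,
so their scores x = -ln(J) pile up in a narrow bulk that is well described
by a Gaussian N(mu, sigma^2).  Divergent windows produce a heavy right
tail that a Gaussian cannot absorb; it is modelled by a log-normal
logN(mu_L, sigma_L).  The final null is the equal-weight average of the
two fitted densities,

    f(x) = pi * N(x; mu, sigma) + (1 - pi) * logN(x; mu_L, sigma_L),

with pi = 0.5 by default (optionally re-estimated by EM on pi alone).
Per-bin tail probabilities under the mixture CDF F flag windows as
significantly conserved (F(x) <= alpha) or divergent (1 - F(x) <= alpha).

The model is exposed statsmodels-style: build :class:`ScoreMixture` from
the scores, call :meth:`ScoreMixture.fit`, and read estimates,
classification and diagnostics off the returned
:class:`ScoreMixtureResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .binning import Bin
from .similarity import BinScore

#: Phi^-1(0.75); converts a half-sample median absolute deviation to sigma.
_MAD_TO_SIGMA = 0.6744897501960817

CONSERVED = "conserved"
DIVERGENT = "divergent"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class ClassifiedBin:
    bin_index: int
    label: str  # conserved | divergent | neutral
    p_value: float


@dataclass(frozen=True)
class SignificantRegion:
    """A maximal run of adjacent same-class significant bins."""

    start: int
    end: int
    label: str
    n_bins: int
    min_p: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _degenerate_sigma(mu: float) -> float:
    return float(np.finfo(float).eps) * max(1.0, abs(mu))


def fit_gaussian_core(
    scores: Sequence[float],
    max_iter: int = 25,
) -> tuple[float, float]:
    """Robust location/scale of the conserved (low-score) bulk.

    The bulk is the dominant low mode, contaminated on the right by the
    divergent tail, so a plain mean/SD is badly biased.  Instead the fit
    iterates two robust steps anchored on the left:

    1. scale from the left half only: sigma = median(mu - x | x <= mu)
       / Phi^-1(0.75) — the tail never enters;
    2. location as the median of the scores inside mu +/- 3 sigma.

    Started from the global median, this walks into the bulk and is a
    fixed point at (mu, sigma) for a clean Gaussian left flank.

    Returns ``(mu, sigma)``.  Degenerate input (all scores equal, or more
    than half the window sitting exactly at mu) gets a machine-epsilon
    scale and a warning.
    """
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite scores to fit")
    if x.size < 30:
        warnings.warn(
            f"only {x.size} scores; Gaussian bulk fit will be noisy",
            stacklevel=2,
        )
    mu = float(np.median(x))
    sigma = _degenerate_sigma(mu)
    for _ in range(max_iter):
        left = x[x <= mu]
        dev = float(np.median(mu - left))
        if dev <= 0.0:
            warnings.warn(
                "degenerate score distribution; using machine-epsilon "
                "Gaussian scale",
                stacklevel=2,
            )
            return mu, _degenerate_sigma(mu)
        sigma = dev / _MAD_TO_SIGMA
        window = x[(x >= mu - 3.0 * sigma) & (x <= mu + 3.0 * sigma)]
        new_mu = float(np.median(window))
        if abs(new_mu - mu) <= 1e-10 * max(1.0, abs(mu)):
            mu = new_mu
            break
        mu = new_mu
    left = x[x <= mu]
    dev = float(np.median(mu - left))
    if dev <= 0.0:
        warnings.warn(
            "degenerate score distribution; using machine-epsilon "
            "Gaussian scale",
            stacklevel=2,
        )
        return mu, _degenerate_sigma(mu)
    return mu, dev / _MAD_TO_SIGMA


def fit_lognormal_tail(
    scores: Sequence[float],
    gaussian: tuple[float, float],
    tail_k: float = 2.0,
    min_tail: int = 10,
) -> tuple[float, float] | None:
    """Log-normal fit of the divergent right tail.

    Fits mean and SD of ln(x) by maximum likelihood on the tail subset
    {x > mu + k*sigma} (k = ``tail_k``).  One model-based trimming pass
    then discards tail points that the already-fitted Gaussian explains
    better than the log-normal (they are bulk spill-over, not divergence)
    and refits.  An empty tail marks the model tail-free (``None``: no
    divergence calls possible); a tail below ``min_tail`` points falls
    back to fitting all positive scores, with a warning either way.
    """
    mu, sigma = gaussian
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    positive = x[x > 0]
    if positive.size == 0:
        warnings.warn(
            "no positive scores: model is tail-free, divergence calls "
            "disabled",
            stacklevel=2,
        )
        return None
    floor = float(positive.min()) / 2.0
    tail = x[x > mu + tail_k * sigma]
    if tail.size == 0:
        warnings.warn(
            "no scores above the tail threshold: model is tail-free, "
            "divergence calls disabled",
            stacklevel=2,
        )
        return None
    if tail.size < min_tail:
        warnings.warn(
            f"only {tail.size} tail scores; fitting the log-normal on all "
            "positive scores instead",
            stacklevel=2,
        )
        tail = positive
    tail = np.maximum(tail, floor)

    def ml(values: np.ndarray) -> tuple[float, float]:
        logs = np.log(values)
        mu_l = float(np.mean(logs))
        sigma_l = float(np.std(logs))
        if sigma_l <= 0.0:
            sigma_l = _degenerate_sigma(mu_l)
        return mu_l, sigma_l

    mu_l, sigma_l = ml(tail)
    dens_l = stats.lognorm.pdf(tail, sigma_l, scale=math.exp(mu_l))
    dens_g = stats.norm.pdf(tail, mu, sigma)
    keep = dens_l >= dens_g
    if min_tail <= keep.sum() < tail.size:
        mu_l, sigma_l = ml(tail[keep])
    return mu_l, sigma_l


class ScoreMixture:
    """Model object holding the scores to which the null is fitted.

    Parameters
    ----------
    scores : array-like of float, or sequence of :class:`BinScore`
        The per-bin -log Jaccard scores.
    """

    def __init__(self, scores):
        if len(scores) and isinstance(scores[0], BinScore):
            scores = [s.score for s in scores]
        self.scores = np.asarray(scores, dtype=float)
        if self.scores.size == 0:
            raise ValueError("no scores")

    @classmethod
    def from_bin_scores(cls, bin_scores: Sequence[BinScore]):
        return cls([s.score for s in bin_scores])

    def fit(
        self,
        tail_k: float = 2.0,
        estimate_weight: bool = False,
        max_em_iter: int = 200,
        em_tol: float = 1e-6,
    ) -> "ScoreMixtureResults":
        """Fit the two components in stages, then combine.

        The Gaussian bulk and the log-normal tail are fitted separately
        (see :func:`fit_gaussian_core`, :func:`fit_lognormal_tail`) and
        averaged with weight pi = 0.5.  With ``estimate_weight`` an EM
        loop re-estimates pi only, component parameters frozen, for at
        most ``max_em_iter`` iterations or until ``|delta pi| < em_tol``.
        """
        mu, sigma = fit_gaussian_core(self.scores)
        tail = fit_lognormal_tail(self.scores, (mu, sigma), tail_k=tail_k)
        if tail is None:
            return ScoreMixtureResults(
                self, mu, sigma, math.nan, math.nan, pi=1.0, tail_free=True
            )
        mu_l, sigma_l = tail
        pi = 0.5
        em_iterations = 0
        if estimate_weight:
            x = self.scores[np.isfinite(self.scores)]
            dens_g = stats.norm.pdf(x, mu, sigma)
            dens_l = stats.lognorm.pdf(x, sigma_l, scale=math.exp(mu_l))
            for em_iterations in range(1, max_em_iter + 1):
                num = pi * dens_g
                den = num + (1.0 - pi) * dens_l
                resp = np.where(den > 0, num / np.where(den > 0, den, 1.0),
                                0.5)
                new_pi = float(np.mean(resp))
                if abs(new_pi - pi) < em_tol:
                    pi = new_pi
                    break
                pi = new_pi
        return ScoreMixtureResults(
            self, mu, sigma, mu_l, sigma_l, pi=pi, tail_free=False,
            em_iterations=em_iterations,
        )


class ScoreMixtureResults:
    """Fitted mixture null: estimates, CDF, classification, simulation."""

    def __init__(
        self,
        model: ScoreMixture,
        mu: float,
        sigma: float,
        mu_log: float,
        sigma_log: float,
        pi: float,
        tail_free: bool,
        em_iterations: int = 0,
    ):
        self.model = model
        self.mu = mu
        self.sigma = sigma
        self.mu_log = mu_log
        self.sigma_log = sigma_log
        self.pi = pi
        self.tail_free = tail_free
        self.em_iterations = em_iterations
        self.n_obs = int(model.scores.size)

    @property
    def params(self) -> dict[str, float]:
        return {
            "mu": self.mu,
            "sigma": self.sigma,
            "mu_log": self.mu_log,
            "sigma_log": self.sigma_log,
            "pi": self.pi,
        }

    def _lognorm(self):
        return stats.lognorm(self.sigma_log, scale=math.exp(self.mu_log))

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        gauss = stats.norm.pdf(x, self.mu, self.sigma)
        if self.tail_free:
            return gauss
        return self.pi * gauss + (1.0 - self.pi) * self._lognorm().pdf(x)

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        gauss = stats.norm.cdf(x, self.mu, self.sigma)
        if self.tail_free:
            return gauss
        return self.pi * gauss + (1.0 - self.pi) * self._lognorm().cdf(x)

    def sf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        gauss = stats.norm.sf(x, self.mu, self.sigma)
        if self.tail_free:
            return gauss
        return self.pi * gauss + (1.0 - self.pi) * self._lognorm().sf(x)

    def p_values(self, x, null: str = "mixture"):
        """Left- and right-tail probabilities of scores under the null.

        ``p_conserved = F(x)`` (an unusually small score means unusually
        high similarity) and ``p_divergent = 1 - F(x)``.  ``null`` may be
        ``"mixture"`` (default) or ``"gaussian"`` to use the Gaussian
        component alone.
        """
        if null == "gaussian":
            p_cons = stats.norm.cdf(x, self.mu, self.sigma)
            p_div = stats.norm.sf(x, self.mu, self.sigma)
        elif null == "mixture":
            p_cons = self.cdf(x)
            p_div = self.sf(x)
        else:
            raise ValueError(f"unknown null {null!r}")
        return np.asarray(p_cons, dtype=float), np.asarray(p_div, float)

    def classify(
        self,
        bin_scores: Sequence[BinScore],
        alpha: float = 0.05,
        fdr: bool = False,
        null: str = "mixture",
    ) -> list[ClassifiedBin]:
        """Call each bin conserved, divergent or neutral at level alpha.

        Tail p-values come from :meth:`p_values`; the two calls are
        mutually exclusive for alpha < 0.5 since the tails sum to 1.
        ``fdr`` applies a Benjamini-Hochberg correction per tail.  On a
        tail-free model divergence is never called.  Annotates each
        :class:`BinScore`'s ``p_conserved``/``p_divergent`` in place.
        """
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        x = np.array([s.score for s in bin_scores], dtype=float)
        p_cons, p_div = self.p_values(x, null=null)
        for s, pc, pd in zip(bin_scores, p_cons, p_div):
            s.p_conserved = float(pc)
            s.p_divergent = float(pd)
        sig_cons = (
            _bh_reject(p_cons, alpha) if fdr else p_cons <= alpha
        )
        sig_div = (
            _bh_reject(p_div, alpha) if fdr else p_div <= alpha
        )
        out = []
        for s, pc, pd, sc, sd in zip(
            bin_scores, p_cons, p_div, sig_cons, sig_div
        ):
            if sc:
                out.append(ClassifiedBin(s.bin_index, CONSERVED, float(pc)))
            elif sd and not self.tail_free:
                out.append(ClassifiedBin(s.bin_index, DIVERGENT, float(pd)))
            else:
                out.append(
                    ClassifiedBin(s.bin_index, NEUTRAL, float(min(pc, pd)))
                )
        return out

    def simulate(self, n: int, seed: int = 1) -> np.ndarray:
        """Draw n scores from the fitted mixture."""
        rng = np.random.default_rng(seed)
        if self.tail_free:
            return rng.normal(self.mu, self.sigma, size=n)
        from_gauss = rng.random(n) < self.pi
        out = np.where(
            from_gauss,
            rng.normal(self.mu, self.sigma, size=n),
            rng.lognormal(self.mu_log, self.sigma_log, size=n),
        )
        return out

    def summary(self) -> str:
        """Plain-text parameter table."""
        lines = [
            "Score mixture null model",
            "=" * 44,
            f"{'observations':<28}{self.n_obs:>16d}",
            f"{'Gaussian mu':<28}{self.mu:>16.6g}",
            f"{'Gaussian sigma':<28}{self.sigma:>16.6g}",
        ]
        if self.tail_free:
            lines.append(f"{'log-normal tail':<28}{'absent':>16}")
        else:
            lines += [
                f"{'log-normal mu (of ln x)':<28}{self.mu_log:>16.6g}",
                f"{'log-normal sigma':<28}{self.sigma_log:>16.6g}",
            ]
        lines.append(f"{'Gaussian weight pi':<28}{self.pi:>16.6g}")
        if self.em_iterations:
            lines.append(
                f"{'EM iterations (pi)':<28}{self.em_iterations:>16d}"
            )
        lines.append("=" * 44)
        return "\n".join(lines)

    def plot_fit(self, ax=None, bins: int = 80):
        """Histogram of scores with the fitted density overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.model.scores[np.isfinite(self.model.scores)]
        ax.hist(x, bins=bins, density=True, alpha=0.4, label="scores")
        grid = np.linspace(float(x.min()), float(x.max()), 512)
        ax.plot(grid, self.pdf(grid), label="fitted mixture")
        ax.set_xlabel("-log mean Jaccard")
        ax.set_ylabel("density")
        ax.legend()
        return ax


def _bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg rejection mask at level alpha."""
    n = p.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = alpha * (np.arange(1, n + 1) / n)
    passing = np.nonzero(ranked <= thresh)[0]
    mask = np.zeros(n, dtype=bool)
    if passing.size:
        mask[order[: passing[-1] + 1]] = True
    return mask


def classify_bins(
    bin_scores: Sequence[BinScore],
    results: ScoreMixtureResults,
    alpha: float = 0.05,
    fdr: bool = False,
    null: str = "mixture",
) -> list[ClassifiedBin]:
    """Functional wrapper around :meth:`ScoreMixtureResults.classify`."""
    return results.classify(bin_scores, alpha=alpha, fdr=fdr, null=null)


def merge_regions(
    classified: Sequence[ClassifiedBin],
    bins: Sequence[Bin],
) -> list[SignificantRegion]:
    """Merge maximal runs of adjacent same-class significant bins.

    ``classified`` and ``bins`` must be parallel and in reference order
    (bins tile the reference, so list adjacency is genomic adjacency).
    Each region carries the smallest p-value of its bins.  Returns
    regions sorted by start; all-neutral input yields an empty list.
    """
    if len(classified) != len(bins):
        raise ValueError("classified bins and bins must be parallel")
    regions: list[SignificantRegion] = []
    run_label: str | None = None
    run_start = run_end = 0
    run_bins = 0
    run_min_p = math.inf

    def close() -> None:
        if run_label is not None:
            regions.append(
                SignificantRegion(
                    run_start, run_end, run_label, run_bins, run_min_p
                )
            )

    for cls, bin_ in zip(classified, bins):
        if cls.label == NEUTRAL:
            close()
            run_label = None
            continue
        if cls.label == run_label and bin_.start == run_end:
            run_end = bin_.end
            run_bins += 1
            run_min_p = min(run_min_p, cls.p_value)
        else:
            close()
            run_label = cls.label
            run_start, run_end = bin_.reference_interval
            run_bins = 1
            run_min_p = cls.p_value
    close()
    regions.sort(key=lambda r: r.start)
    return regions
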