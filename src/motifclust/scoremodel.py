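"""Alignment-space score normalization and the motif-family classifier.

Raw alignment scores of PFM pairs are not comparable across motif
lengths: longer motifs admit more candidate windows and systematically
higher best scores.  The adjustment model regresses background
(between-class) scores on the *alignment space* ``a = L_a * L_b`` —
proportional to the number of possible ungapped alignments — and
standardizes:

    s_adj = (x - mu(a)) / sigma(a)

with mu and sigma estimated by Nadaraya–Watson kernel regression on
log(a) (Gaussian kernel, Silverman's rule-of-thumb bandwidth), sigma
from a second kernel regression on the squared residuals.

The family classifier is a logistic regression on the adjusted score:

    P(same family | s_adj) = 1 / (1 + exp(-(beta0 + beta1 * s_adj)))

The shipped default coefficients (beta1 = 5.294, beta0 = -3.3296) were
obtained for adjusted ED.sqr scores trained with intra-family scores as
positives and inter-class scores as negatives; the natural decision
threshold is P > 0.5, crossed at s_adj = -beta0/beta1 ≈ 0.629.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

import numpy as np

SIGMA_FLOOR = 1e-6
_GRID_SIZE = 101
_MIN_TRAINING_PAIRS = 50


@dataclass
class AdjustmentModel:
    """Tabulated conditional mean/sd curves over log alignment space.

    Evaluation interpolates linearly on the stored grid and extrapolates
    with constant values outside the training range.
    """

    grid: np.ndarray  # log(a) grid
    mu: np.ndarray
    sigma: np.ndarray
    sigma_floor: float = SIGMA_FLOOR
    fitted_on: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.maximum(np.asarray(self.sigma, dtype=float), self.sigma_floor)

    def mu_at(self, space: float) -> float:
        return float(np.interp(np.log(space), self.grid, self.mu))

    def sigma_at(self, space: float) -> float:
        return float(np.interp(np.log(space), self.grid, self.sigma))

    def to_json(self) -> str:
        return json.dumps(
            {
                "grid": self.grid.tolist(),
                "mu": self.mu.tolist(),
                "sigma": self.sigma.tolist(),
                "sigma_floor": self.sigma_floor,
                "fitted_on": self.fitted_on,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AdjustmentModel":
        d = json.loads(text)
        return cls(
            grid=np.array(d["grid"]),
            mu=np.array(d["mu"]),
            sigma=np.array(d["sigma"]),
            sigma_floor=d.get("sigma_floor", SIGMA_FLOOR),
            fitted_on=d.get("fitted_on", ""),
        )


@dataclass
class FamilyClassifier:
    """Logistic classifier P(same motif family | adjusted score)."""

    beta0: float
    beta1: float

    def __post_init__(self) -> None:
        if self.beta1 <= 0:
            warnings.warn(
                "beta1 <= 0: probability does not increase with similarity",
                stacklevel=2,
            )

    @property
    def threshold_score(self) -> float:
        """Adjusted score at which the probability crosses 0.5."""
        return -self.beta0 / self.beta1

    def to_json(self) -> str:
        return json.dumps({"beta0": self.beta0, "beta1": self.beta1})

    @classmethod
    def from_json(cls, text: str) -> "FamilyClassifier":
        d = json.loads(text)
        return cls(beta0=d["beta0"], beta1=d["beta1"])


#: coefficients shipped for adjusted ED.sqr scores
DEFAULT_CLASSIFIER = FamilyClassifier(beta0=-3.3296, beta1=5.294)


def _silverman_bandwidth(t: np.ndarray) -> float:
    n = len(t)
    sd = t.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(t, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(sd, 1e-3)
    return 0.9 * spread * n ** (-0.2)


def _nw_regression(t: np.ndarray, y: np.ndarray, grid: np.ndarray, h: float) -> np.ndarray:
    # Gaussian-kernel Nadaraya–Watson estimate of E[y | t] on the grid
    z = (grid[:, None] - t[None, :]) / h
    w = np.exp(-0.5 * z * z)
    denom = w.sum(axis=1)
    denom = np.where(denom > 0, denom, 1.0)
    return (w @ y) / denom


def fit_adjustment(
    scores: Iterable[Tuple[float, int, int]], fitted_on: str = ""
) -> AdjustmentModel:
    """Fit the conditional mean/sd curves from background score triples.

    Parameters
    ----------
    scores : iterable of (raw_score, L_a, L_b)
        Background alignments, typically between-class pairs.

    Raises
    ------
    ValueError
        With fewer than 50 training pairs.
    """
    data = [(float(s), int(la), int(lb)) for s, la, lb in scores]
    if len(data) < _MIN_TRAINING_PAIRS:
        raise ValueError(
            f"need at least {_MIN_TRAINING_PAIRS} training pairs, got {len(data)}"
        )
    y = np.array([s for s, _, _ in data])
    t = np.log([la * lb for _, la, lb in data])
    h = _silverman_bandwidth(t)
    grid = np.linspace(t.min(), t.max(), _GRID_SIZE)
    mu = _nw_regression(t, y, grid, h)
    resid2 = (y - np.interp(t, grid, mu)) ** 2
    var = _nw_regression(t, resid2, grid, h)
    if np.all(var < SIGMA_FLOOR**2):
        warnings.warn("zero residual variance; sigma floored", stacklevel=2)
    sigma = np.sqrt(np.maximum(var, SIGMA_FLOOR**2))
    return AdjustmentModel(grid=grid, mu=mu, sigma=sigma, fitted_on=fitted_on)


def adjust(raw: float, L_a: int, L_b: int, model: AdjustmentModel) -> float:
    """Standardize a raw score for the alignment space of its pair."""
    space = L_a * L_b
    return (raw - model.mu_at(space)) / model.sigma_at(space)


def family_probability(s_adj, clf: FamilyClassifier = DEFAULT_CLASSIFIER):
    """Probability that two motifs belong to the same family."""
    z = clf.beta0 + clf.beta1 * np.asarray(s_adj, dtype=float)
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    if out.ndim == 0:
        return float(out)
    return out


def train_classifier(
    positives: Sequence[float], negatives: Sequence[float]
) -> FamilyClassifier:
    """Maximum-likelihood logistic fit from labeled adjusted scores.

    Positives are intra-family scores, negatives between-class scores.
    Perfectly separable inputs fall back to a weakly ridge-regularized
    fit with a warning.

    Raises
    ------
    ValueError
        If either list is empty.
    """
    import statsmodels.api as sm

    positives = np.asarray(positives, dtype=float)
    negatives = np.asarray(negatives, dtype=float)
    if positives.size == 0 or negatives.size == 0:
        raise ValueError("both positive and negative examples are required")
    x = np.concatenate([positives, negatives])
    yy = np.concatenate([np.ones(positives.size), np.zeros(negatives.size)])
    X = sm.add_constant(x)
    separable = positives.min() > negatives.max() or positives.max() < negatives.min()
    if separable:
        warnings.warn(
            "perfectly separable training scores; using ridge-regularized fit",
            stacklevel=2,
        )
        res = sm.Logit(yy, X).fit_regularized(
            alpha=1.0, L1_wt=0.0, disp=False, maxiter=200
        )
    else:
        res = sm.Logit(yy, X).fit(disp=False, maxiter=200)
    beta0, beta1 = float(res.params[0]), float(res.params[1])
    return FamilyClassifier(beta0=beta0, beta1=beta1)
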