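"""Column–column similarity scores for aligned PFM positions.

Five scores are provided; in all of them a higher value means more
similar columns, so they can drive local alignment directly:

* ``ED`` — alpha minus the Euclidean distance between the two
  probability 4-vectors.  Distances lie in [0, sqrt(2)]; a column pair
  contributes positively iff its distance is below alpha.
* ``SSD`` — alpha minus the sum of squared differences (distances in
  [0, 2]).
* ``PCC`` — Pearson correlation of the two 4-vectors (a zero-variance
  vector yields 0 by convention).
* ``LSO`` — log-sum-of-odds, ``ln sum_b p(b) q(b) / bg(b)``.
* ``LSO_KL`` — LSO minus the symmetrized Kullback–Leibler divergence
  ``(KL(p||q) + KL(q||p)) / 2`` (natural log).

The subtractive alpha offset turns the ED/SSD distances into local
alignment contributions: with the default alphas the contribution is
positive exactly when the columns are closer than alpha, which lets the
alignment reject dissimilar columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: alphas optimized per score/coverage variant (coverage modes: none/ave/sqr)
DEFAULT_ALPHAS = {
    ("ED", "none"): 0.55,
    ("ED", "ave"): 0.5,
    ("ED", "sqr"): 0.5,
    ("SSD", "none"): 0.3,
    ("SSD", "ave"): 0.25,
    ("SSD", "sqr"): 0.25,
}

_METHODS = ("ED", "SSD", "PCC", "LSO", "LSO_KL")


@dataclass
class ColumnScoreSpec:
    """Column scoring method plus its parameters.

    ``alpha`` is meaningful only for ED and SSD; ``background`` (default
    uniform) only for the log-odds scores.
    """

    method: str = "ED"
    alpha: Optional[float] = None
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        method = self.method.upper().replace(".", "_")
        if method not in _METHODS:
            raise ValueError(f"unknown column score method {self.method!r}")
        self.method = method
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValueError("background distribution must sum to 1")
        if method in ("ED", "SSD"):
            if self.alpha is not None and not (0.0 < self.alpha < 1.0):
                raise ValueError("alpha must lie in (0, 1)")
        elif self.alpha is not None:
            raise ValueError(f"alpha is not a parameter of the {method} score")

    def resolved_alpha(self, ic_mode: str = "none") -> Optional[float]:
        """Alpha to use: the explicit value, else the optimized default."""
        if self.method not in ("ED", "SSD"):
            return None
        if self.alpha is not None:
            return self.alpha
        return DEFAULT_ALPHAS[(self.method, ic_mode)]


def column_score(p, q, spec: ColumnScoreSpec, ic_mode: str = "none") -> float:
    """Score one pair of aligned columns (probability 4-vectors)."""
    P = np.asarray(p, dtype=float).reshape(4, 1)
    Q = np.asarray(q, dtype=float).reshape(4, 1)
    return float(score_matrix(P, Q, spec, ic_mode)[0, 0])


def score_matrix(
    P: np.ndarray, Q: np.ndarray, spec: ColumnScoreSpec, ic_mode: str = "none"
) -> np.ndarray:
    """All column-pair scores of two probability matrices.

    Parameters
    ----------
    P, Q : ndarray of shape (4, Lx) and (4, Ly)

    Returns
    -------
    ndarray of shape (Lx, Ly)
        ``S[i, j]`` scores column i of P against column j of Q.
    """
    method = spec.method
    if method == "ED":
        d2 = _sq_dists(P, Q)
        return spec.resolved_alpha(ic_mode) - np.sqrt(np.maximum(d2, 0.0))
    if method == "SSD":
        return spec.resolved_alpha(ic_mode) - _sq_dists(P, Q)
    if method == "PCC":
        Pc = P - P.mean(axis=0, keepdims=True)
        Qc = Q - Q.mean(axis=0, keepdims=True)
        pn = np.linalg.norm(Pc, axis=0)
        qn = np.linalg.norm(Qc, axis=0)
        num = Pc.T @ Qc
        denom = np.outer(pn, qn)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
        return np.clip(r, -1.0, 1.0)
    if method == "LSO":
        return _lso(P, Q, spec.background)
    if method == "LSO_KL":
        return _lso(P, Q, spec.background) - _sym_kl(P, Q)
    raise AssertionError(method)


def _sq_dists(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    diff = P[:, :, None] - Q[:, None, :]
    return np.einsum("bij,bij->ij", diff, diff)


def _lso(P: np.ndarray, Q: np.ndarray, bg: np.ndarray) -> np.ndarray:
    return np.log((P / bg[:, None]).T @ Q)


def _sym_kl(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    logP, logQ = np.log(P), np.log(Q)
    # KL(p||q)[i,j] = sum_b P[b,i] (logP[b,i] - logQ[b,j])
    kl_pq = (P * logP).sum(axis=0)[:, None] - P.T @ logQ
    kl_qp = (Q * logQ).sum(axis=0)[None, :] - (logP.T @ Q)
    return 0.5 * (kl_pq + kl_qp)
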