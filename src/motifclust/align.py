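"""Best ungapped local alignment of two PFMs with information coverage.

The aligner exhaustively scores every window ``(s_x, s_y, w)`` with
``w >= min(5, L_x, L_y)`` on both orientations of the second motif and
keeps the window maximizing the final score.  The raw score is the sum
of the column scores inside the window; with an information-coverage
mode the raw score is multiplied by a factor in [0, 1]:

* ``ave`` — the arithmetic mean of the two per-motif coverages,
* ``sqr`` — the geometric mean (square root of their product),

where each per-motif coverage is the aligned fraction of that motif's
total column information.  The multiplier shrinks the score towards 0
when the alignment leaves informative columns uncovered.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd

from .colscores import ColumnScoreSpec, score_matrix
from .pfm import PFM, column_information, reverse_complement

IC_MODES = ("none", "ave", "sqr")


@dataclass
class Alignment:
    """An ungapped local alignment between two PFMs.

    ``start_y`` refers to column offsets within the reverse-complemented
    second motif when ``orientation == "revcomp"``.
    """

    id_x: str
    id_y: str
    start_x: int
    start_y: int
    width: int
    orientation: str
    column_scores: np.ndarray
    raw_score: float
    ic_x: float
    ic_y: float
    ic_combined: float
    final_score: float

    @property
    def ic_factor(self) -> float:
        if self.raw_score == 0:
            return 1.0
        return self.final_score / self.raw_score


def _ic_multiplier(ic_x: float, ic_y: float, ic_mode: str) -> float:
    if ic_mode == "none":
        return 1.0
    if ic_mode == "ave":
        return 0.5 * (ic_x + ic_y)
    if ic_mode == "sqr":
        return float(np.sqrt(ic_x * ic_y))
    raise ValueError(f"unknown ic_mode {ic_mode!r}")


def information_coverage(
    x: PFM, y: PFM, s_x: int, s_y: int, w: int
) -> Tuple[float, float, float]:
    """Fractions of each motif's information covered by a window.

    Returns ``(ic_x, ic_y, ic_combined)`` where ``ic_combined`` pools
    the aligned and total information of both motifs.  A motif with
    zero total information has coverage 1 by convention.
    """
    if w <= 0 or s_x < 0 or s_y < 0 or s_x + w > x.length or s_y + w > y.length:
        raise ValueError("invalid alignment window")
    ix = column_information(x).values
    iy = column_information(y).values
    tot_x, tot_y = ix.sum(), iy.sum()
    in_x = ix[s_x : s_x + w].sum()
    in_y = iy[s_y : s_y + w].sum()
    ic_x = in_x / tot_x if tot_x > 0 else 1.0
    ic_y = in_y / tot_y if tot_y > 0 else 1.0
    tot = tot_x + tot_y
    ic_c = (in_x + in_y) / tot if tot > 0 else 1.0
    return float(ic_x), float(ic_y), float(ic_c)


def align(
    x: PFM, y: PFM, spec: ColumnScoreSpec, ic_mode: str = "sqr"
) -> Alignment:
    """Best ungapped local alignment over all windows and orientations.

    Both PFMs must be normalized (and should be trimmed).  Ties are
    broken deterministically: smaller ``s_x``, then smaller ``s_y``,
    then forward orientation before reverse complement, then larger
    width.

    Raises
    ------
    ValueError
        If either PFM has no columns (e.g. fully trimmed).
    """
    if ic_mode not in IC_MODES:
        raise ValueError(f"unknown ic_mode {ic_mode!r}")
    if x.length < 1 or y.length < 1:
        raise ValueError(
            f"cannot align {x.id!r} vs {y.id!r}: empty PFM after trimming"
        )
    if x.probs is None or y.probs is None:
        raise ValueError("PFMs must be normalized before alignment")

    w_min = min(5, x.length, y.length)
    ix = column_information(x).values
    tot_x = ix.sum()
    cum_x = np.concatenate([[0.0], np.cumsum(ix)])

    best = None  # (final, sx, sy, orient_idx(0=fwd), -w, raw, ...)
    for orient_idx, (orient, y_or) in enumerate(
        (("forward", y), ("revcomp", reverse_complement(y)))
    ):
        iy = column_information(y_or).values
        tot_y = iy.sum()
        cum_y = np.concatenate([[0.0], np.cumsum(iy)])
        S = score_matrix(x.probs, y_or.probs, spec, ic_mode)
        Lx, Ly = x.length, y_or.length
        for sx in range(Lx - w_min + 1):
            for sy in range(Ly - w_min + 1):
                diag_len = min(Lx - sx, Ly - sy)
                if diag_len < w_min:
                    continue
                diag = S[sx + np.arange(diag_len), sy + np.arange(diag_len)]
                csum = np.cumsum(diag)
                for w in range(w_min, diag_len + 1):
                    raw = csum[w - 1]
                    icx = (
                        (cum_x[sx + w] - cum_x[sx]) / tot_x if tot_x > 0 else 1.0
                    )
                    icy = (
                        (cum_y[sy + w] - cum_y[sy]) / tot_y if tot_y > 0 else 1.0
                    )
                    final = raw * _ic_multiplier(icx, icy, ic_mode)
                    key = (-final, sx, sy, orient_idx, -w)
                    if best is None or key < best[0]:
                        best = (
                            key,
                            (orient, sx, sy, w, raw, final, icx, icy),
                        )
    assert best is not None
    orient, sx, sy, w, raw, final, icx, icy = best[1]
    y_or = y if orient == "forward" else reverse_complement(y)
    S = score_matrix(x.probs, y_or.probs, spec, ic_mode)
    col_scores = S[sx + np.arange(w), sy + np.arange(w)]
    _, _, ic_c = information_coverage(x, y_or, sx, sy, w)
    return Alignment(
        id_x=x.id,
        id_y=y.id,
        start_x=sx,
        start_y=sy,
        width=w,
        orientation=orient,
        column_scores=col_scores,
        raw_score=float(raw),
        ic_x=float(icx),
        ic_y=float(icy),
        ic_combined=float(ic_c),
        final_score=float(final),
    )


def all_pairs_scores(
    pfms: Iterable[PFM],
    spec: ColumnScoreSpec,
    ic_mode: str = "sqr",
    include_self: bool = True,
) -> Tuple[pd.DataFrame, Dict[Tuple[str, str], Alignment]]:
    """Final alignment scores for every pair of motifs.

    Returns
    -------
    scores : DataFrame
        Symmetric square table of final scores indexed by motif id; the
        diagonal holds self-alignment scores (NaN if ``include_self`` is
        False).
    alignments : dict
        ``(id_x, id_y) -> Alignment`` for every unordered pair (stored
        under the id order in which it was computed, sorted input
        order).
    """
    pfms = sorted(pfms, key=lambda p: p.id)
    if len(pfms) < 2:
        raise ValueError("need at least two PFMs")
    ids = [p.id for p in pfms]
    mat = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    alignments: Dict[Tuple[str, str], Alignment] = {}
    for a, b in itertools.combinations_with_replacement(pfms, 2):
        if a.id == b.id and not include_self:
            continue
        try:
            aln = align(a, b, spec, ic_mode)
        except ValueError as exc:
            raise ValueError(f"alignment failed for pair ({a.id}, {b.id}): {exc}")
        mat.loc[a.id, b.id] = aln.final_score
        mat.loc[b.id, a.id] = aln.final_score
        alignments[(a.id, b.id)] = aln
    return mat, alignments


def alignment_table(alignments: Dict[Tuple[str, str], Alignment]) -> pd.DataFrame:
    """Long-format table of alignments for TSV export (1-based starts)."""
    rows = []
    for (ida, idb), aln in sorted(alignments.items()):
        rows.append(
            {
                "id_x": ida,
                "id_y": idb,
                "score": aln.final_score,
                "raw_score": aln.raw_score,
                "s_x": aln.start_x + 1,
                "s_y": aln.start_y + 1,
                "w": aln.width,
                "orientation": aln.orientation,
                "ic_x": aln.ic_x,
                "ic_y": aln.ic_y,
            }
        )
    return pd.DataFrame(rows)
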