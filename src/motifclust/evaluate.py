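"""Leave-one-out evaluation statistics, the alpha sweep, and the Rand index.

Two statistics grade how well a similarity score retrieves motifs of
the same transcription-factor class:

* *best hit* — the proportion of held-out motifs whose top-scoring
  match belongs to their own class;
* *class depth* — for each held-out motif, the proportion of its
  same-class motifs ranked above the first out-of-class motif
  (denominator: class size minus one, since the hold-out cannot detect
  itself), summarized per class by median and quartiles.

Score ties are broken pessimistically by default: a non-class motif
tied at the decisive rank counts against the method (an ``optimistic``
mode is available for sensitivity analysis).
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import all_pairs_scores
from .colscores import ColumnScoreSpec
from .pfm import PFM


def _check_scores(scores: pd.DataFrame, classes: Mapping[str, str]) -> List[str]:
    ids = [m for m in scores.index if m in classes]
    if len(ids) < 2:
        raise ValueError("need scores for at least two classified motifs")
    return ids


def best_hit(
    scores: pd.DataFrame,
    classes: Mapping[str, str],
    holdout_exclude: Iterable[str] = (),
    ties: str = "pessimistic",
) -> Tuple[pd.Series, pd.Series]:
    """Leave-one-out best-hit correctness per motif and per class.

    ``holdout_exclude`` names classes whose motifs still compete as
    candidate (false-positive) matches but are never held out
    themselves — the convention used for catch-all families.

    Returns
    -------
    per_motif : Series of bool indexed by motif id
    per_class : Series of float (proportion correct) indexed by class
    """
    if ties not in ("pessimistic", "optimistic"):
        raise ValueError(f"unknown tie mode {ties!r}")
    ids = _check_scores(scores, classes)
    excluded = set(holdout_exclude)
    if len({classes[m] for m in ids}) < 2:
        raise ValueError("best hit needs at least two classes")
    results = {}
    for m in ids:
        if classes[m] in excluded:
            continue
        others = [x for x in ids if x != m]
        s = scores.loc[m, others]
        top = s.max()
        top_classes = {classes[x] for x in others if s[x] == top}
        if ties == "pessimistic":
            correct = top_classes == {classes[m]}
        else:
            correct = classes[m] in top_classes
        results[m] = bool(correct)
    per_motif = pd.Series(results, dtype=bool)
    per_class = per_motif.groupby(lambda m: classes[m]).mean()
    return per_motif, per_class.astype(float)


def class_depth(
    scores: pd.DataFrame,
    classes: Mapping[str, str],
    holdout_exclude: Iterable[str] = (),
    ties: str = "pessimistic",
) -> Tuple[pd.Series, pd.DataFrame]:
    """Leave-one-out class-depth per motif and per-class robust summary.

    For each held-out motif the remaining motifs are ranked by score;
    the depth is the fraction of its same-class motifs that appear
    before the first out-of-class motif.  Per class the median, lower
    and upper quartile (linear-interpolation quantiles) are reported.
    """
    if ties not in ("pessimistic", "optimistic"):
        raise ValueError(f"unknown tie mode {ties!r}")
    ids = _check_scores(scores, classes)
    excluded = set(holdout_exclude)
    depths = {}
    for m in ids:
        if classes[m] in excluded:
            continue
        others = [x for x in ids if x != m]
        n_same = sum(1 for x in others if classes[x] == classes[m])
        if n_same == 0:
            depths[m] = 0.0
            continue
        s = scores.loc[m, others]
        # pessimistic: at equal score the non-class motif is ranked first
        same = np.array([classes[x] == classes[m] for x in others])
        vals = s.to_numpy(dtype=float)
        if ties == "pessimistic":
            order = np.lexsort((same, -vals))
        else:
            order = np.lexsort((~same, -vals))
        count = 0
        for k in order:
            if same[k]:
                count += 1
            else:
                break
        depths[m] = count / n_same
    per_motif = pd.Series(depths, dtype=float)
    rows = []
    for cls, grp in per_motif.groupby(lambda m: classes[m]):
        lq, med, uq = np.percentile(grp.to_numpy(), [25, 50, 75])
        rows.append(
            {"class": cls, "median": med, "lower_quartile": lq, "upper_quartile": uq,
             "n": len(grp)}
        )
    return per_motif, pd.DataFrame(rows).set_index("class")


def class_subsets(
    classes: Mapping[str, str], top: int = 5, minimums: Sequence[int] = (20, 10)
) -> Dict[str, List[str]]:
    """Standard class subsets: the ``top`` largest classes and classes
    with at least each of the ``minimums`` members."""
    sizes = pd.Series(list(classes.values())).value_counts()
    subsets = {f"Top{top}": list(sizes.index[:top])}
    for m in minimums:
        subsets[f"Min{m}"] = list(sizes.index[sizes >= m])
    return subsets


def summarize_subsets(
    scores: pd.DataFrame,
    classes: Mapping[str, str],
    subsets: Optional[Mapping[str, Sequence[str]]] = None,
    holdout_exclude: Iterable[str] = (),
    ties: str = "pessimistic",
) -> pd.DataFrame:
    """Best-hit and class-depth aggregates per class subset.

    Per subset: the pooled best-hit proportion and the averages of the
    per-class class-depth median/quartiles.
    """
    if subsets is None:
        subsets = class_subsets(classes)
    bh_motif, _ = best_hit(scores, classes, holdout_exclude, ties)
    cd_motif, cd_class = class_depth(scores, classes, holdout_exclude, ties)
    rows = []
    for name, members in subsets.items():
        members = [c for c in members if c in cd_class.index]
        motifs = [m for m in bh_motif.index if classes[m] in members]
        sub = cd_class.loc[members]
        rows.append(
            {
                "subset": name,
                "best_hit": bh_motif.loc[motifs].mean() if motifs else np.nan,
                "depth_median": sub["median"].mean(),
                "depth_lower_quartile": sub["lower_quartile"].mean(),
                "depth_upper_quartile": sub["upper_quartile"].mean(),
                "n_classes": len(members),
                "n_motifs": len(motifs),
            }
        )
    return pd.DataFrame(rows).set_index("subset")


def alpha_sweep(
    pfms: Sequence[PFM],
    classes: Mapping[str, str],
    method: str,
    ic_mode: str,
    alphas: Sequence[float],
    holdout_exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Recompute all-pairs scores and both statistics over an alpha grid.

    Returns one row per alpha with pooled best-hit and mean class-depth
    median; the argmax rows are flagged in columns ``best_by_hit`` /
    ``best_by_depth``.
    """
    alphas = list(alphas)
    if not all(0.0 < a < 1.0 for a in alphas):
        raise ValueError("alpha grid must lie within (0, 1)")
    rows = []
    for a in alphas:
        spec = ColumnScoreSpec(method=method, alpha=a)
        scores, _ = all_pairs_scores(pfms, spec, ic_mode)
        bh_motif, _ = best_hit(scores, classes, holdout_exclude)
        _, cd_class = class_depth(scores, classes, holdout_exclude)
        rows.append(
            {
                "alpha": a,
                "best_hit": float(bh_motif.mean()),
                "depth_median": float(cd_class["median"].mean()),
            }
        )
    table = pd.DataFrame(rows)
    table["best_by_hit"] = table["best_hit"] == table["best_hit"].max()
    table["best_by_depth"] = table["depth_median"] == table["depth_median"].max()
    return table


def rand_index(U: Mapping[str, int], V: Mapping[str, int]) -> float:
    """Rand index of two partitions of the same item set.

    ``(#C + #S) / (n choose 2)`` where #C counts item pairs placed
    together in both partitions and #S pairs separated in both.
    """
    if set(U) != set(V):
        raise ValueError("partitions cover different item sets")
    items = sorted(U)
    n = len(items)
    if n < 2:
        raise ValueError("need at least two items")
    agree = 0
    for a, b in combinations(items, 2):
        same_u = U[a] == U[b]
        same_v = V[a] == V[b]
        if same_u == same_v:
            agree += 1
    return agree / (n * (n - 1) // 2)


def partition_from_sets(sets: Iterable[Iterable[str]]) -> Dict[str, int]:
    """Convert a list of disjoint member collections to an item->label map."""
    out: Dict[str, int] = {}
    for i, s in enumerate(sets):
        for m in s:
            if m in out:
                raise ValueError(f"item {m!r} appears in two clusters")
            out[m] = i
    return out
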