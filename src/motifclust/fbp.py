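"""Familial Binding Profiles and unsupervised hierarchical motif clustering.

A Familial Binding Profile (FBP) is a consensus PFM representing a
cluster of motifs, built by weighted averaging of aligned columns.  The
weight of a real matrix column is the square root of the number of
underlying binding-site sequences, capped at 200 sites so that
ChIP-derived matrices with thousands of sites cannot override the other
members; unaligned flanking positions are filled with uniform columns
of weight 1.

Clustering proceeds in two tracks.  Average-linkage hierarchical
clustering on the distance matrix ``1 - P(same family | s_adj)`` fixes
the *order* in which merges are proposed; each proposed merge is then
*validated* on the FBPs themselves: the FBP–FBP alignment probability
must exceed the family threshold, and the candidate merged FBP must
re-detect every original member matrix above the same threshold.  A
failed merge marks the would-be cluster invalid: by default its
children are frozen and survive as final clusters of their own (an
alternative mode lets them retry with other partners).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .align import Alignment, align, all_pairs_scores
from .colscores import ColumnScoreSpec
from .pfm import PFM, prepare, reverse_complement
from .scoremodel import (
    AdjustmentModel,
    FamilyClassifier,
    adjust,
    family_probability,
)

#: cap on binding-site counts entering column weights
MAX_SITES = 200
UNIFORM = np.full(4, 0.25)


@dataclass
class FBP:
    """A weighted consensus PFM over a set of member motifs."""

    profile: PFM
    column_weights: np.ndarray
    members: Dict[str, str]  # motif id -> resolved strand ("+" / "-")
    valid: bool = True

    def __post_init__(self) -> None:
        self.column_weights = np.asarray(self.column_weights, dtype=float)
        if len(self.column_weights) != self.profile.length:
            raise ValueError("column_weights length must equal profile length")
        if not self.members:
            raise ValueError("an FBP needs at least one member")

    @property
    def member_ids(self) -> Set[str]:
        return set(self.members)

    @classmethod
    def from_pfm(cls, pfm: PFM) -> "FBP":
        """Initial single-motif FBP with weight sqrt(min(n_sites, 200))."""
        if pfm.probs is None:
            raise ValueError(f"PFM {pfm.id!r} must be normalized")
        if pfm.n_sites is not None:
            w = float(np.sqrt(min(pfm.n_sites, MAX_SITES)))
        else:
            w = 1.0
        return cls(
            profile=pfm,
            column_weights=np.full(pfm.length, w),
            members={pfm.id: "+"},
        )


def merge_fbps(a: FBP, b: FBP, alignment: Alignment) -> FBP:
    """Weighted-average merge of two FBPs along their alignment.

    Aligned columns combine as weight-weighted averages with summed
    weights.  Overhanging columns of either profile are kept; the
    absent partner contributes a uniform column of weight 1.
    """
    if alignment.orientation == "revcomp":
        b_profile = reverse_complement(b.profile)
        b_weights = b.column_weights[::-1]
        b_members = {m: ("-" if s == "+" else "+") for m, s in b.members.items()}
    else:
        b_profile, b_weights, b_members = b.profile, b.column_weights, dict(b.members)
    sx, sy = alignment.start_x, alignment.start_y
    La, Lb = a.profile.length, b_profile.length
    off = max(sx, sy)
    ax, ay = off - sx, off - sy  # shifts of a and b in the output frame
    new_len = max(ax + La, ay + Lb)
    probs = np.empty((4, new_len))
    weights = np.empty(new_len)
    for j in range(new_len):
        ja, jb = j - ax, j - ay
        if 0 <= ja < La:
            pa, wa = a.profile.probs[:, ja], a.column_weights[ja]
        else:
            pa, wa = UNIFORM, 1.0
        if 0 <= jb < Lb:
            pb, wb = b_profile.probs[:, jb], b_weights[jb]
        else:
            pb, wb = UNIFORM, 1.0
        probs[:, j] = (wa * pa + wb * pb) / (wa + wb)
        weights[j] = wa + wb
    members = {**a.members, **b_members}
    profile = PFM(
        id="FBP(" + ",".join(sorted(members)) + ")",
        counts=probs.copy(),
        probs=probs,
        source_format="internal",
    )
    return FBP(profile=profile, column_weights=weights, members=members)


def fbp_detects(
    fbp: FBP,
    motif: PFM,
    spec: ColumnScoreSpec,
    ic_mode: str,
    model: AdjustmentModel,
    clf: FamilyClassifier,
    threshold: float = 0.5,
) -> Tuple[float, bool]:
    """Probability that the FBP and a motif share a family, and whether
    it clears the threshold."""
    aln = align(fbp.profile, motif, spec, ic_mode)
    s_adj = adjust(aln.final_score, fbp.profile.length, motif.length, model)
    p = family_probability(s_adj, clf)
    return float(p), bool(p > threshold)


def _fbp_pair_probability(
    a: FBP,
    b: FBP,
    spec: ColumnScoreSpec,
    ic_mode: str,
    model: AdjustmentModel,
    clf: FamilyClassifier,
) -> Tuple[float, Alignment]:
    aln = align(a.profile, b.profile, spec, ic_mode)
    s_adj = adjust(aln.final_score, a.profile.length, b.profile.length, model)
    return float(family_probability(s_adj, clf)), aln


@dataclass
class FBPClustering:
    """Result of the hierarchical FBP clustering."""

    clusters: List[FBP]
    merge_log: pd.DataFrame
    linkage_matrix: np.ndarray
    ids: List[str]  # leaf order of the linkage matrix

    @property
    def partition(self) -> Dict[str, int]:
        return {m: i for i, f in enumerate(self.clusters) for m in f.member_ids}


@dataclass
class _Entry:
    fbp: FBP
    frozen: bool = False


def cluster(
    pfms: Sequence[PFM],
    spec: ColumnScoreSpec,
    ic_mode: str,
    model: AdjustmentModel,
    clf: FamilyClassifier,
    threshold: float = 0.5,
    freeze_on_reject: bool = True,
) -> FBPClustering:
    """Unsupervised FBP clustering of a motif collection.

    Raw (un-normalized) inputs are normalized and trimmed first.  The
    merge order comes from average-linkage clustering of the distances
    ``1 - P(same family)`` computed once on the input motifs; merge
    acceptance is decided by the FBP validity rules (see module
    docstring), never by the linkage height itself.
    """
    prepared = [p if p.probs is not None else prepare(p) for p in pfms]
    prepared = sorted(prepared, key=lambda p: p.id)
    if len(prepared) < 2:
        raise ValueError("need at least two PFMs to cluster")
    if len({p.id for p in prepared}) != len(prepared):
        raise ValueError("duplicate motif ids")
    by_id = {p.id: p for p in prepared}
    ids = [p.id for p in prepared]
    n = len(ids)

    scores, _ = all_pairs_scores(prepared, spec, ic_mode)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s_adj = adjust(
                scores.iloc[i, j],
                by_id[ids[i]].length,
                by_id[ids[j]].length,
                model,
            )
            dist[i, j] = dist[j, i] = 1.0 - family_probability(s_adj, clf)
    Z = linkage(squareform(dist, checks=False), method="average")

    pools: Dict[int, List[_Entry]] = {
        k: [_Entry(FBP.from_pfm(by_id[ids[k]]))] for k in range(n)
    }
    log: List[dict] = []

    def attempt(e1: _Entry, e2: _Entry, height: float, step: int) -> Optional[FBP]:
        prob, aln = _fbp_pair_probability(
            e1.fbp, e2.fbp, spec, ic_mode, model, clf
        )
        rec = {
            "step": step,
            "height": height,
            "left": ",".join(sorted(e1.fbp.member_ids)),
            "right": ",".join(sorted(e2.fbp.member_ids)),
            "fbp_probability": prob,
            "detect_ok": None,
            "outcome": None,
        }
        if prob <= threshold:
            rec["outcome"] = "rejected_fbp_score"
            log.append(rec)
            return None
        candidate = merge_fbps(e1.fbp, e2.fbp, aln)
        ok = all(
            fbp_detects(candidate, by_id[m], spec, ic_mode, model, clf, threshold)[1]
            for m in sorted(candidate.member_ids)
        )
        rec["detect_ok"] = ok
        rec["outcome"] = "accepted" if ok else "rejected_detection"
        log.append(rec)
        return candidate if ok else None

    for step, row in enumerate(Z):
        c1, c2, height = int(row[0]), int(row[1]), float(row[2])
        p1, p2 = pools.pop(c1), pools.pop(c2)
        node = n + step
        if freeze_on_reject:
            if (
                len(p1) == 1
                and len(p2) == 1
                and not p1[0].frozen
                and not p2[0].frozen
            ):
                merged = attempt(p1[0], p2[0], height, step)
                if merged is not None:
                    pools[node] = [_Entry(merged)]
                else:
                    p1[0].frozen = p2[0].frozen = True
                    p1[0].fbp.valid = p2[0].fbp.valid = False
                    pools[node] = p1 + p2
            else:
                log.append(
                    {
                        "step": step,
                        "height": height,
                        "left": ";".join(
                            ",".join(sorted(e.fbp.member_ids)) for e in p1
                        ),
                        "right": ";".join(
                            ",".join(sorted(e.fbp.member_ids)) for e in p2
                        ),
                        "fbp_probability": np.nan,
                        "detect_ok": None,
                        "outcome": "skipped_invalid_child",
                    }
                )
                pools[node] = p1 + p2
        else:
            pools[node] = _greedy_pool_merge(p1, p2, attempt, height, step)

    clusters = [e.fbp for pool in pools.values() for e in pool]
    clusters.sort(key=lambda f: min(f.member_ids))
    cols = ["step", "height", "left", "right", "fbp_probability", "detect_ok", "outcome"]
    return FBPClustering(
        clusters=clusters,
        merge_log=pd.DataFrame(log, columns=cols),
        linkage_matrix=Z,
        ids=ids,
    )


def _greedy_pool_merge(p1, p2, attempt, height, step):
    """Retry semantics: pool pairs are attempted in lexicographic order
    (by smallest member id) and merge whenever the validity rules pass;
    after a successful merge the search restarts on the reduced pool."""
    pool = p1 + p2
    tried: Set[Tuple[str, str]] = set()
    progress = True
    while progress and len(pool) > 1:
        progress = False
        pairs = sorted(
            (
                (min(pool[i].fbp.member_ids), min(pool[j].fbp.member_ids), i, j)
                for i in range(len(pool))
                for j in range(i + 1, len(pool))
            ),
        )
        for ka, kb, i, j in pairs:
            if (ka, kb) in tried:
                continue
            merged = attempt(pool[i], pool[j], height, step)
            tried.add((ka, kb))
            if merged is not None:
                pool = [e for k, e in enumerate(pool) if k not in (i, j)]
                pool.append(_Entry(merged))
                tried = set()
                progress = True
                break
    return pool


def clusters_to_table(result: FBPClustering) -> pd.DataFrame:
    rows = [
        {"cluster_id": i, "motif_id": m, "strand": f.members[m]}
        for i, f in enumerate(result.clusters)
        for m in sorted(f.member_ids)
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "motif_id", "strand"])


def dendrogram_newick(result: FBPClustering) -> str:
    """Newick string of the average-linkage dendrogram (branch lengths
    from linkage heights)."""
    n = len(result.ids)
    heights = {k: 0.0 for k in range(n)}
    trees = {k: result.ids[k] for k in range(n)}
    for step, row in enumerate(result.linkage_matrix):
        c1, c2, h = int(row[0]), int(row[1]), float(row[2])
        node = n + step
        b1 = max(h - heights[c1], 0.0)
        b2 = max(h - heights[c2], 0.0)
        trees[node] = f"({trees[c1]}:{b1:.6g},{trees[c2]}:{b2:.6g})"
        heights[node] = h
    return trees[n + len(result.linkage_matrix) - 1] + ";"
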