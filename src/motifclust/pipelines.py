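"""End-to-end workflows composing the library modules.

Two pipelines mirror the two clustering tracks:

* the *network* pipeline scores all motif pairs, builds one similarity
  network per transcription-factor class (classes with at least five
  motifs are analyzed) and extracts families with MCL;
* the *FBP* pipeline converts scores into motif-family probabilities
  and runs the hierarchical FBP clustering.

Every run writes a manifest (configuration, package version, input
digests) next to its outputs so results can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from .align import all_pairs_scores, alignment_table
from .colscores import ColumnScoreSpec
from .fbp import FBPClustering, cluster, clusters_to_table as fbp_table, dendrogram_newick
from .io import read_pfms, write_pfms
from .network import (
    MIN_CLASS_SIZE,
    NetworkClustering,
    build_network,
    clusters_to_table as net_table,
    mcl,
    write_network,
)
from .pfm import PFM, prepare
from .scoremodel import (
    AdjustmentModel,
    DEFAULT_CLASSIFIER,
    FamilyClassifier,
    fit_adjustment,
)

logger = logging.getLogger("motifclust")


@dataclass
class RunConfig:
    """Configuration of a pipeline run."""

    inputs: List[str]
    outdir: str
    input_format: str = "transfac"
    score: str = "ED"
    ic_mode: str = "sqr"
    alpha: Optional[float] = None
    threshold: float = 0.5
    model_path: Optional[str] = None
    inflation: float = 2.0
    seed: int = 0
    log_level: str = "INFO"

    def spec(self) -> ColumnScoreSpec:
        return ColumnScoreSpec(method=self.score, alpha=self.alpha)


def _load_inputs(config: RunConfig) -> List[PFM]:
    pfms: List[PFM] = []
    if not config.inputs:
        raise ValueError("no input files given")
    for path in config.inputs:
        if not Path(path).exists():
            raise FileNotFoundError(path)
        pfms.extend(read_pfms(path, format=config.input_format))
    if not pfms:
        raise ValueError("input files contained no motifs")
    return pfms


def _write_manifest(config: RunConfig, outdir: Path) -> None:
    from . import __version__

    digests = {}
    for path in config.inputs:
        h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        digests[str(path)] = h
    manifest = {
        "config": asdict(config),
        "version": __version__,
        "input_sha256": digests,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def fit_adjustment_from_pfms(
    pfms: Sequence[PFM],
    spec: ColumnScoreSpec,
    ic_mode: str,
    classes: Optional[Mapping[str, str]] = None,
) -> AdjustmentModel:
    """Fit the score-adjustment curves from a motif collection.

    Uses between-class pairs as background when class labels are
    available, otherwise all off-diagonal pairs.
    """
    prepared = [p if p.probs is not None else prepare(p) for p in pfms]
    scores, _ = all_pairs_scores(prepared, spec, ic_mode)
    lengths = {p.id: p.length for p in prepared}
    triples = []
    ids = list(scores.index)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if classes is not None and classes.get(a) == classes.get(b):
                continue
            triples.append((scores.loc[a, b], lengths[a], lengths[b]))
    background = "between-class pairs" if classes else "all pairs"
    return fit_adjustment(triples, fitted_on=f"{len(triples)} {background}")


def homogeneity_report(result: FBPClustering, classes: Mapping[str, str]) -> pd.DataFrame:
    """Per-cluster class composition: size, majority class, homogeneity
    (fraction of members carrying the majority class label)."""
    rows = []
    for i, f in enumerate(result.clusters):
        labels = pd.Series([classes.get(m) for m in sorted(f.member_ids)])
        top = labels.value_counts()
        rows.append(
            {
                "cluster_id": i,
                "size": len(labels),
                "majority_class": top.index[0],
                "homogeneity": top.iloc[0] / len(labels),
            }
        )
    return pd.DataFrame(rows, columns=["cluster_id", "size", "majority_class", "homogeneity"])


def train_classifier_from_pfms(
    pfms: Sequence[PFM],
    spec: ColumnScoreSpec,
    ic_mode: str,
    model: AdjustmentModel,
    families: Mapping[str, int],
    classes: Optional[Mapping[str, str]] = None,
):
    """Train the family classifier from a labeled motif collection.

    Positives are adjusted scores of intra-family pairs; negatives are
    between-class pairs (between-family pairs when no class labels are
    given) — the careful negative choice that avoids mislabeling
    related same-class pairs.
    """
    from .scoremodel import adjust, train_classifier

    prepared = [p if p.probs is not None else prepare(p) for p in pfms]
    scores, _ = all_pairs_scores(prepared, spec, ic_mode)
    lengths = {p.id: p.length for p in prepared}
    ids = list(scores.index)
    pos, neg = [], []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            s_adj = adjust(scores.loc[a, b], lengths[a], lengths[b], model)
            if families.get(a) is not None and families.get(a) == families.get(b):
                pos.append(s_adj)
            elif classes is None or classes.get(a) != classes.get(b):
                neg.append(s_adj)
    return train_classifier(pos, neg)


def run_network_pipeline(config: RunConfig) -> Dict[str, NetworkClustering]:
    """Per-class network construction and MCL clustering.

    Writes, per analyzed class, an edge list and a cluster table, plus
    a summary TSV of cluster counts; returns the clusterings keyed by
    class label.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pfms = _load_inputs(config)
    classes = {p.id: p.class_label for p in pfms}
    if any(c is None for c in classes.values()):
        missing = sorted(m for m, c in classes.items() if c is None)
        raise ValueError(f"motifs without class labels: {missing}")
    prepared = [prepare(p) for p in pfms]
    spec = config.spec()
    logger.info("scoring %d motifs (all pairs)", len(prepared))
    scores, _ = all_pairs_scores(prepared, spec, config.ic_mode)
    results: Dict[str, NetworkClustering] = {}
    summary = []
    for cls in sorted(set(classes.values())):
        network = build_network(scores, classes, cls)
        write_network(network, outdir / f"network_{cls}.tsv")
        if network.below_analysis_threshold:
            logger.info("class %s below analysis threshold (<%d motifs)",
                        cls, MIN_CLASS_SIZE)
            summary.append({"class": cls, "n_motifs": len(network.nodes),
                            "n_clusters": None, "analyzed": False})
            continue
        clustering = mcl(network, inflation=config.inflation)
        results[cls] = clustering
        net_table(clustering).to_csv(
            outdir / f"clusters_{cls}.tsv", sep="\t", index=False
        )
        summary.append({"class": cls, "n_motifs": len(network.nodes),
                        "n_clusters": len(clustering.clusters), "analyzed": True})
    pd.DataFrame(summary).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    _write_manifest(config, outdir)
    logger.info("network pipeline done in %.1fs", time.time() - t0)
    return results


def run_fbp_pipeline(
    config: RunConfig, clf: Optional[FamilyClassifier] = None
) -> FBPClustering:
    """Hierarchical FBP clustering of a motif collection.

    Model and classifier resolution keeps the two on the same score
    scale:

    * with ``config.model_path`` (a previously fitted adjustment
      model), the shipped classifier coefficients — trained for
      adjusted ED.sqr scores — are used unless ``clf`` is passed;
    * without a model but with class-labeled inputs, the full
      self-training procedure runs: the adjustment is fitted on
      between-class pairs, motif families are derived by per-class
      network analysis + MCL, and the logistic classifier is trained on
      the collection's own adjusted scores;
    * without labels, the adjustment is fitted on all pairs and the
      shipped classifier is applied with a warning (its coefficients
      come from a different collection).

    Writes clusters.tsv, the FBP matrices in TRANSFAC dialect, the
    merge log, a Newick dendrogram and (for labeled inputs) a
    class-homogeneity report.
    """
    import warnings as _warnings

    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pfms = _load_inputs(config)
    prepared = [prepare(p) for p in pfms]
    spec = config.spec()
    class_map = {p.id: p.class_label for p in pfms}
    have_classes = all(c is not None for c in class_map.values())
    if config.model_path:
        model = AdjustmentModel.from_json(Path(config.model_path).read_text())
        if clf is None:
            clf = DEFAULT_CLASSIFIER
    else:
        logger.info("fitting adjustment model on input collection")
        model = fit_adjustment_from_pfms(
            prepared, spec, config.ic_mode, class_map if have_classes else None
        )
        if clf is None and have_classes:
            logger.info("deriving families by network analysis for training")
            scores, _ = all_pairs_scores(prepared, spec, config.ic_mode)
            families: Dict[str, int] = {}
            offset = 0
            for cls in sorted(set(class_map.values())):
                clustering = mcl(
                    build_network(scores, class_map, cls), inflation=config.inflation
                )
                for i, members in enumerate(clustering.clusters):
                    for m in members:
                        families[m] = offset + i
                offset += len(clustering.clusters)
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                clf = train_classifier_from_pfms(
                    prepared, spec, config.ic_mode, model, families, class_map
                )
            logger.info(
                "trained classifier beta0=%.4f beta1=%.4f", clf.beta0, clf.beta1
            )
        elif clf is None:
            _warnings.warn(
                "no class labels: applying the shipped classifier to a freshly "
                "fitted adjustment model; coefficients come from a different "
                "collection",
                stacklevel=2,
            )
            clf = DEFAULT_CLASSIFIER
    result = cluster(
        prepared, spec, config.ic_mode, model, clf, threshold=config.threshold
    )
    fbp_table(result).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    classes = {p.id: p.class_label for p in pfms}
    if all(c is not None for c in classes.values()):
        homogeneity_report(result, classes).to_csv(
            outdir / "class_homogeneity.tsv", sep="\t", index=False
        )
    result.merge_log.to_csv(outdir / "merge_log.tsv", sep="\t", index=False)
    profiles = [f.profile for f in result.clusters]
    write_pfms(profiles, outdir / "fbps.tf", format="transfac")
    (outdir / "dendrogram.nwk").write_text(dendrogram_newick(result) + "\n")
    (outdir / "model.json").write_text(model.to_json() + "\n")
    (outdir / "classifier.json").write_text(clf.to_json() + "\n")
    _write_manifest(config, outdir)
    logger.info(
        "FBP pipeline done in %.1fs: %d clusters from %d motifs",
        time.time() - t0, len(result.clusters), len(prepared),
    )
    return result
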