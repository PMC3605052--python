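"""Synthetic PFM collections with planted family and class structure.

The generator mimics how related binding-motif matrices arise in
practice: each family has a seed profile with a shared informative core
(peaked Dirichlet columns) surrounded by near-uniform background
columns; each member matrix is produced by multinomial resampling of
``n_sites`` binding sites per column from the seed, a random shift,
random background flanks, and optional reverse complementation.
Families are grouped into classes so that the per-class network
pipeline has non-class motifs to define its edge threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .io import write_pfms
from .pfm import BASES, PFM


@dataclass
class FamilySpec:
    """Parameters of the planted-structure generator.

    Defaults give 4 families of 6 motifs with binding-site counts of
    50, informative cores of 8–12 columns, and moderate positional
    jitter — a regime where related motifs are clearly but not
    trivially similar.  By default each family carries its own class
    label: the per-class network rule thresholds on the best
    out-of-class score, and with only a couple of dozen motifs that
    maximum is too noisy to separate multiple families *inside* one
    class reliably (in real databases the threshold is a maximum over
    hundreds of outsiders).  ``families_per_class`` > 1 plants the
    harder multi-family-per-class structure when wanted.
    """

    n_families: int = 4
    motifs_per_family: int = 6
    families_per_class: int = 1
    core_length: Tuple[int, int] = (8, 12)
    informative_fraction: float = 0.8
    n_sites: int = 50
    flank_columns: Tuple[int, int] = (0, 2)
    dirichlet_concentration_informative: float = 0.3
    dirichlet_concentration_background: float = 5.0
    shift_range: int = 2
    revcomp_probability: float = 0.25
    seed: int = 0

    @classmethod
    def noisy(cls, seed: int = 0) -> "FamilySpec":
        """A harder regime for score-evaluation experiments.

        With the default settings retrieval saturates (every alpha is
        equally good); this configuration — fewer binding sites, weaker
        cores, longer flanks — makes the ranking statistics sensitive
        to the alignment parameters, which is what alpha optimization
        experiments need.
        """
        return cls(
            n_families=6,
            motifs_per_family=5,
            n_sites=12,
            informative_fraction=0.6,
            flank_columns=(1, 3),
            shift_range=2,
            seed=seed,
        )

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.motifs_per_family < 1:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.informative_fraction <= 1.0):
            raise ValueError("informative_fraction must lie in [0, 1]")
        if not (0.0 <= self.revcomp_probability <= 1.0):
            raise ValueError("revcomp_probability must lie in [0, 1]")
        if self.shift_range >= min(self.core_length):
            raise ValueError("shift_range must be smaller than the core length")


def _seed_profile(rng: np.random.Generator, spec: FamilySpec) -> np.ndarray:
    lo, hi = spec.core_length
    L = int(rng.integers(lo, hi + 1))
    informative = rng.random(L) < spec.informative_fraction
    # guarantee informative ends so family members share an anchored core
    informative[0] = informative[-1] = True
    cols = np.empty((4, L))
    for j in range(L):
        conc = (
            spec.dirichlet_concentration_informative
            if informative[j]
            else spec.dirichlet_concentration_background
        )
        cols[:, j] = rng.dirichlet(np.full(4, conc))
    return cols


def _background_column(rng: np.random.Generator, spec: FamilySpec) -> np.ndarray:
    return rng.dirichlet(np.full(4, spec.dirichlet_concentration_background))


def generate(spec: FamilySpec) -> Tuple[List[PFM], Dict[str, int]]:
    """Generate a labeled motif collection and its true family partition.

    Returns
    -------
    pfms : list of PFM
        Count matrices with ``class_label`` and ``n_sites`` set, ids
        ``F<family>_M<member>``.
    truth : dict id -> family index
    """
    rng = np.random.default_rng(spec.seed)
    pfms: List[PFM] = []
    truth: Dict[str, int] = {}
    for fam in range(spec.n_families):
        seed_profile = _seed_profile(rng, spec)
        L = seed_profile.shape[1]
        class_idx = fam // spec.families_per_class
        for mem in range(spec.motifs_per_family):
            shift = int(rng.integers(-spec.shift_range, spec.shift_range + 1))
            # a positive shift drops columns on the left, negative on the right
            if shift >= 0:
                core = seed_profile[:, shift:]
            else:
                core = seed_profile[:, : L + shift]
            nl, nr = (
                int(rng.integers(spec.flank_columns[0], spec.flank_columns[1] + 1)),
                int(rng.integers(spec.flank_columns[0], spec.flank_columns[1] + 1)),
            )
            flanks_l = [_background_column(rng, spec) for _ in range(nl)]
            flanks_r = [_background_column(rng, spec) for _ in range(nr)]
            probs = np.column_stack(flanks_l + [core[:, j] for j in range(core.shape[1])] + flanks_r) \
                if (flanks_l or flanks_r) else core
            counts = np.empty_like(probs)
            for j in range(probs.shape[1]):
                counts[:, j] = rng.multinomial(spec.n_sites, probs[:, j])
            if rng.random() < spec.revcomp_probability:
                counts = counts[[3, 2, 1, 0]][:, ::-1]
            pid = f"F{fam:02d}_M{mem:02d}"
            pfms.append(
                PFM(
                    id=pid,
                    counts=counts,
                    n_sites=spec.n_sites,
                    class_label=f"C{class_idx:02d}",
                    source_format="internal",
                )
            )
            truth[pid] = fam
    return pfms, truth


def write_fixture(spec: FamilySpec, outdir) -> Tuple[Path, Path]:
    """Emit the collection as a TRANSFAC-dialect file plus a truth table.

    Returns the paths ``(motifs.tf, truth.tsv)``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pfms, truth = generate(spec)
    motifs_path = outdir / "motifs.tf"
    truth_path = outdir / "truth.tsv"
    write_pfms(pfms, motifs_path, format="transfac")
    pd.DataFrame(
        {
            "motif_id": list(truth),
            "family": [truth[m] for m in truth],
            "class": [p.class_label for p in pfms],
        }
    ).to_csv(truth_path, sep="\t", index=False)
    return motifs_path, truth_path
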