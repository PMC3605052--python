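"""Position frequency matrix data model and preprocessing.

A PFM is a 4×L matrix over the bases A, C, G, T (rows, in that fixed
order) whose columns hold nucleotide counts or probabilities for the L
positions of a binding motif.  Raw matrices as read from a file keep
their counts verbatim; :func:`normalize` derives the probability matrix
with a pseudocount (for count matrices) or a probability floor (for
frequency matrices), and :func:`trim_flanks` removes uninformative
flanking columns before alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

BASES = "ACGT"
#: row indices after complementation: A<->T, C<->G
_COMPLEMENT_ORDER = np.array([3, 2, 1, 0])

#: guaranteed minimal probability of any nucleotide in a normalized column
PROB_FLOOR = 1e-3

#: flanking columns whose max-min base frequency falls below this are trimmed
TRIM_THRESHOLD = 0.25


@dataclass
class PFM:
    """A position frequency matrix with optional annotations.

    Parameters
    ----------
    id : str
        Unique motif identifier.
    counts : ndarray of shape (4, L)
        Raw matrix entries as read (counts or frequencies).
    name : str, optional
        Human-readable motif name.
    probs : ndarray of shape (4, L), optional
        Normalized probability matrix; ``None`` until :func:`normalize`.
    n_sites : int, optional
        Number of binding-site sequences underlying the matrix.
    class_label : str, optional
        Transcription-factor class annotation.
    source_format : str
        One of ``transfac``, ``jaspar``, ``internal``.
    empty : bool
        True when flank trimming removed every column.
    """

    id: str
    counts: np.ndarray
    name: Optional[str] = None
    probs: Optional[np.ndarray] = None
    n_sites: Optional[int] = None
    class_label: Optional[str] = None
    source_format: str = "internal"
    empty: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(
                f"PFM {self.id!r}: matrix must be 4×L, got shape {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError(f"PFM {self.id!r}: negative matrix entries")
        if self.probs is not None:
            self.probs = np.asarray(self.probs, dtype=float)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def is_normalized(self) -> bool:
        return self.probs is not None

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.length


@dataclass
class ColumnInformation:
    """Per-column information of a PFM, in bits.

    ``values[i] = 2 + sum_b p_i(b) * log2 p_i(b)``, i.e. two bits minus
    the Shannon entropy of column i; 0 for a uniform column, 2 for a
    single-base column.
    """

    values: np.ndarray
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.total = float(self.values.sum())


def _looks_like_counts(counts: np.ndarray) -> bool:
    """Heuristic for the two normalization branches.

    A matrix whose columns all sum to (approximately) one is taken to be
    a frequency matrix; anything else is treated as counts.
    """
    colsums = counts.sum(axis=0)
    return not np.allclose(colsums, 1.0, atol=0.02)


def _floor_frequencies(col: np.ndarray) -> np.ndarray:
    """Renormalize a frequency column so every entry is >= PROB_FLOOR.

    Entries below the floor are raised to exactly PROB_FLOOR and the
    required mass is taken proportionally from the remaining entries.
    E.g. (1, 0, 0, 0) -> (0.997, 0.001, 0.001, 0.001).
    """
    col = col / col.sum()
    out = col.copy()
    for _ in range(8):
        low = out < PROB_FLOOR
        if not low.any():
            break
        out[low] = PROB_FLOOR
        excess = out.sum() - 1.0
        high = ~low
        # remove the excess proportionally from the above-floor entries
        out[high] -= excess * out[high] / out[high].sum()
    if out.min() < PROB_FLOOR - 1e-12 or abs(out.sum() - 1.0) > 1e-9:
        raise ValueError("column cannot satisfy the probability floor")
    return out


def normalize(pfm: PFM) -> PFM:
    """Derive the probability matrix of a PFM.

    Count matrices receive a pseudocount of 1 in every cell before
    column normalization.  Frequency matrices are renormalized with a
    floor so that every probability is at least ``PROB_FLOOR`` (1e-3).
    Both branches end with the floor guarantee.

    Raises
    ------
    ValueError
        If any column is all zero.
    """
    counts = pfm.counts
    if pfm.length == 0:
        raise ValueError(f"PFM {pfm.id!r}: cannot normalize an empty matrix")
    if np.any(counts.sum(axis=0) <= 0):
        raise ValueError(f"PFM {pfm.id!r}: all-zero column cannot be normalized")
    if _looks_like_counts(counts):
        work = counts + 1.0
    else:
        work = counts.copy()
    probs = np.empty_like(work)
    for j in range(work.shape[1]):
        probs[:, j] = _floor_frequencies(work[:, j])
    return replace(pfm, probs=probs)


def _require_normalized(pfm: PFM) -> np.ndarray:
    if pfm.probs is None:
        raise ValueError(f"PFM {pfm.id!r} is not normalized; call normalize() first")
    return pfm.probs


def trim_flanks(pfm: PFM) -> PFM:
    """Remove uninformative flanking columns.

    Working inward from each end, a column is removed while the highest
    difference between any two of its nucleotide frequencies is below
    0.25.  Interior columns are never removed.  If every column fails
    the test the returned PFM is flagged ``empty`` (length 0).
    """
    probs = _require_normalized(pfm)
    spread = probs.max(axis=0) - probs.min(axis=0)
    keep = spread >= TRIM_THRESHOLD
    if not keep.any():
        z = np.zeros((4, 0))
        return replace(pfm, counts=z, probs=z, empty=True)
    lo = int(np.argmax(keep))
    hi = len(keep) - int(np.argmax(keep[::-1]))
    return replace(pfm, counts=pfm.counts[:, lo:hi], probs=probs[:, lo:hi])


def reverse_complement(pfm: PFM) -> PFM:
    """Reverse-complement a PFM: reverse column order, swap A<->T, C<->G."""
    counts = pfm.counts[_COMPLEMENT_ORDER][:, ::-1].copy()
    probs = None
    if pfm.probs is not None:
        probs = pfm.probs[_COMPLEMENT_ORDER][:, ::-1].copy()
    return replace(pfm, counts=counts, probs=probs)


def column_information(pfm: PFM) -> ColumnInformation:
    """Per-column information content in bits (2 minus Shannon entropy)."""
    probs = _require_normalized(pfm)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, probs * np.log2(probs), 0.0)
    values = np.clip(2.0 + terms.sum(axis=0), 0.0, 2.0)
    return ColumnInformation(values=values)


def prepare(pfm: PFM) -> PFM:
    """Normalize then trim a raw PFM — the standard preprocessing chain."""
    return trim_flanks(normalize(pfm))
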