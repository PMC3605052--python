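"""Readers and writers for PFM file formats.

Three dialects are supported:

* ``transfac`` — flat files with ``ID``/``NA`` headers, a ``P0`` column
  header, numbered count rows and a ``//`` record terminator.  Optional
  ``CC class:`` and ``CC sites:`` comment lines carry the motif class
  and the number of underlying binding sites.
* ``jaspar`` — ``>``-headed records followed by four matrix rows, either
  plain whitespace-separated numbers or the bracketed
  ``A [ 1 2 3 ]`` style.
* ``internal`` — a tab-separated long table with columns
  ``id, name, class, n_sites, pos, A, C, G, T`` used for fixtures.

Counts are preserved verbatim on read; writers emit what round-trips.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

from .pfm import BASES, PFM


class PFMParseError(ValueError):
    """Raised for malformed motif records, naming the record and line."""


def read_pfms(path, format: str = "transfac") -> List[PFM]:
    """Read all PFM records from a file.

    Parameters
    ----------
    path : path-like
    format : {"transfac", "jaspar", "internal"}

    Returns
    -------
    list of PFM
        One per record, in file order, counts as written.

    Raises
    ------
    PFMParseError
        On malformed records (with record id and line number) or on
        duplicate motif ids.
    """
    path = Path(path)
    text = path.read_text()
    if format == "transfac":
        pfms = _parse_transfac(text)
    elif format == "jaspar":
        pfms = _parse_jaspar(text)
    elif format == "internal":
        pfms = _parse_internal(path)
    else:
        raise ValueError(f"unknown PFM format {format!r}")
    seen = set()
    for p in pfms:
        if p.id in seen:
            raise PFMParseError(f"duplicate motif id {p.id!r} in {path}")
        seen.add(p.id)
    return pfms


def write_pfms(pfms: Iterable[PFM], path, format: str = "transfac") -> None:
    """Write PFMs to a file in the named dialect."""
    path = Path(path)
    pfms = list(pfms)
    if format == "transfac":
        path.write_text("".join(_format_transfac(p) for p in pfms))
    elif format == "jaspar":
        path.write_text("".join(_format_jaspar(p) for p in pfms))
    elif format == "internal":
        _write_internal(pfms, path)
    else:
        raise ValueError(f"unknown PFM format {format!r}")


# ---------------------------------------------------------------------------
# TRANSFAC dialect

_ROW_RE = re.compile(r"^\d+$")


def _parse_transfac(text: str) -> List[PFM]:
    pfms: List[PFM] = []
    rec_id: Optional[str] = None
    name = None
    class_label = None
    n_sites = None
    rows: List[List[float]] = []
    in_matrix = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip()
        if not line:
            continue
        tag, _, rest = line.partition(" ")
        rest = rest.strip()
        if tag == "ID":
            rec_id = rest or None
            if rec_id is None:
                raise PFMParseError(f"line {lineno}: ID line without identifier")
        elif tag == "NA":
            name = rest
        elif tag == "CC":
            m = re.match(r"(class|sites):\s*(.+)", rest)
            if m:
                if m.group(1) == "class":
                    class_label = m.group(2).strip()
                else:
                    n_sites = int(float(m.group(2)))
        elif tag in ("P0", "PO"):
            in_matrix = True
            rows = []
        elif _ROW_RE.match(tag):
            if not in_matrix:
                raise PFMParseError(
                    f"record {rec_id!r}, line {lineno}: matrix row before P0 header"
                )
            fields = rest.split()
            if len(fields) < 4:
                raise PFMParseError(
                    f"record {rec_id!r}, line {lineno}: expected 4 counts, "
                    f"got {len(fields)}"
                )
            try:
                rows.append([float(v) for v in fields[:4]])
            except ValueError as exc:
                raise PFMParseError(
                    f"record {rec_id!r}, line {lineno}: {exc}"
                ) from None
        elif line.startswith("//"):
            if rec_id is None:
                raise PFMParseError(f"line {lineno}: record terminator without ID")
            if not rows:
                raise PFMParseError(f"record {rec_id!r}: no matrix rows")
            counts = np.array(rows, dtype=float).T  # rows are positions in file
            pfms.append(
                PFM(
                    id=rec_id,
                    name=name,
                    counts=counts,
                    n_sites=n_sites if n_sites is not None else _default_sites(counts),
                    class_label=class_label,
                    source_format="transfac",
                )
            )
            rec_id, name, class_label, n_sites = None, None, None, None
            rows, in_matrix = [], False
        # other tags (XX, BF, DE, ...) are ignored
    if rec_id is not None:
        raise PFMParseError(f"record {rec_id!r}: missing '//' terminator")
    return pfms


def _default_sites(counts: np.ndarray) -> Optional[int]:
    """Count matrices default to the maximum column sum; frequency-only
    matrices (columns summing to ~1) get no site count."""
    colsums = counts.sum(axis=0)
    if np.allclose(colsums, 1.0, atol=0.02):
        return None
    return int(round(colsums.max()))


def _format_transfac(p: PFM) -> str:
    lines = [f"ID {p.id}"]
    if p.name:
        lines.append(f"NA {p.name}")
    if p.class_label:
        lines.append(f"CC class: {p.class_label}")
    if p.n_sites is not None:
        lines.append(f"CC sites: {p.n_sites}")
    lines.append("P0" + "".join(f"{b:>12}" for b in BASES))
    for j in range(p.length):
        vals = "".join(f"{v:>12g}" for v in p.counts[:, j])
        lines.append(f"{j + 1:02d}{vals}")
    lines.append("XX")
    lines.append("//")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# JASPAR dialect

_BRACKET_RE = re.compile(r"^([ACGTacgt])?\s*\[?\s*([-\d.eE+\s]*?)\s*\]?\s*$")


def _parse_jaspar(text: str) -> List[PFM]:
    pfms: List[PFM] = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise PFMParseError(f"line {i + 1}: expected '>' record header")
        fields = header[1:].split(None, 1)
        if not fields:
            raise PFMParseError(f"line {i + 1}: empty record header")
        rec_id = fields[0]
        name = fields[1].strip() if len(fields) > 1 else None
        rows: List[List[float]] = []
        row_bases: List[Optional[str]] = []
        j = i + 1
        while j < len(lines) and not lines[j].startswith(">"):
            m = _BRACKET_RE.match(lines[j].strip())
            if m is None or not m.group(2).strip():
                raise PFMParseError(
                    f"record {rec_id!r}, line {j + 1}: malformed matrix row"
                )
            try:
                rows.append([float(v) for v in m.group(2).split()])
            except ValueError as exc:
                raise PFMParseError(
                    f"record {rec_id!r}, line {j + 1}: {exc}"
                ) from None
            row_bases.append(m.group(1).upper() if m.group(1) else None)
            j += 1
        if len(rows) != 4:
            raise PFMParseError(
                f"record {rec_id!r}: expected 4 matrix rows, got {len(rows)}"
            )
        if len({len(r) for r in rows}) != 1:
            raise PFMParseError(f"record {rec_id!r}: ragged matrix rows")
        counts = np.array(rows, dtype=float)
        if all(b is not None for b in row_bases):
            order = [row_bases.index(b) for b in BASES]
            counts = counts[order]
        pfms.append(
            PFM(
                id=rec_id,
                name=name,
                counts=counts,
                n_sites=_default_sites(counts),
                source_format="jaspar",
            )
        )
        i = j
    return pfms


def _format_jaspar(p: PFM) -> str:
    header = f">{p.id}" + (f" {p.name}" if p.name else "")
    lines = [header]
    for bi, b in enumerate(BASES):
        vals = " ".join(f"{v:g}" for v in p.counts[bi])
        lines.append(f"{b}  [ {vals} ]")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# internal tab-separated long format

_INTERNAL_COLS = ["id", "name", "class", "n_sites", "pos", "A", "C", "G", "T"]


def _parse_internal(path: Path) -> List[PFM]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "name": str, "class": str})
    missing = set(_INTERNAL_COLS) - set(df.columns)
    if missing:
        raise PFMParseError(f"{path}: missing columns {sorted(missing)}")
    pfms = []
    for rec_id, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("pos")
        counts = grp[list(BASES)].to_numpy(dtype=float).T
        first = grp.iloc[0]
        n_sites = None if pd.isna(first["n_sites"]) else int(first["n_sites"])
        pfms.append(
            PFM(
                id=str(rec_id),
                name=None if pd.isna(first["name"]) else str(first["name"]),
                counts=counts,
                n_sites=n_sites,
                class_label=None if pd.isna(first["class"]) else str(first["class"]),
                source_format="internal",
            )
        )
    return pfms


def _write_internal(pfms: List[PFM], path: Path) -> None:
    records = []
    for p in pfms:
        for j in range(p.length):
            records.append(
                {
                    "id": p.id,
                    "name": p.name or "",
                    "class": p.class_label or "",
                    "n_sites": p.n_sites if p.n_sites is not None else "",
                    "pos": j + 1,
                    **{b: p.counts[bi, j] for bi, b in enumerate(BASES)},
                }
            )
    pd.DataFrame.from_records(records, columns=_INTERNAL_COLS).to_csv(
        path, sep="\t", index=False
    )
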