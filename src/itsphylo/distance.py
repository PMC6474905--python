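"""Kimura 2-parameter distances.

The K2P model separates transitions (A<->G, C<->T) from transversions.
With observed proportions P (transitions) and Q (transversions) over the
compared sites, the evolutionary distance is

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

which is undefined (saturated) once 1 - 2P - Q <= 0 or 1 - 2Q <= 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .align import Alignment
from .regions import round_half_up
from .seqio import AMBIGUOUS

log = logging.getLogger(__name__)

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T", "U"}


@dataclass
class SitePattern:
    """Observed transition/transversion proportions over n compared sites."""

    n: int
    P: float
    Q: float

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("no comparable sites")
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise ValueError(f"invalid proportions P={self.P}, Q={self.Q}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over an ordered taxon list.

    NaN marks pairs whose distance could not be estimated (saturation).
    """

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape must match taxon count")
        if not np.allclose(np.nan_to_num(self.d), np.nan_to_num(self.d.T)):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        finite = self.d[np.isfinite(self.d)]
        if np.any(finite < 0):
            raise ValueError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])

    def submatrix(self, taxa: Sequence[str]) -> "DistanceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return DistanceMatrix(list(taxa), self.d[np.ix_(idx, idx)])

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(len(self.taxa), k=1)
        return self.d[iu]


def _comparable(a: str, b: str) -> bool:
    return a not in AMBIGUOUS and b not in AMBIGUOUS and a != "-" and b != "-"


def site_patterns(row_a: str, row_b: str, mask: Optional[np.ndarray] = None) -> SitePattern:
    """Transition/transversion proportions between two aligned rows.

    Sites with a gap or ambiguity code in either row are skipped (pairwise
    deletion); an optional boolean ``mask`` (True = usable) implements
    complete deletion at the matrix level.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    n = ts = tv = 0
    for k, (a, b) in enumerate(zip(row_a, row_b)):
        if mask is not None and not mask[k]:
            continue
        if not _comparable(a, b):
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    return SitePattern(n=n, P=ts / n, Q=tv / n)


def k2p(P: float, Q: float) -> float:
    """Kimura 2-parameter distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("K2P undefined (saturation)")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def distance_matrix(aln: Alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """All-pairs K2P distances for an alignment.

    ``deletion='pairwise'`` drops a site only for the pair it is missing in;
    ``'complete'`` drops every column containing any gap or ambiguity.
    Saturated pairs become NaN with a warning rather than aborting.
    """
    if len(aln.rows) < 2:
        raise ValueError("need at least 2 rows")
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion policy {deletion!r}")
    mask = None
    if deletion == "complete":
        mask = np.ones(aln.column_count, dtype=bool)
        for row in aln.rows:
            mask &= np.fromiter((_comparable(c, c) for c in row), dtype=bool,
                                count=len(row))
    n = len(aln.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                sp = site_patterns(aln.rows[i], aln.rows[j], mask)
                d[i, j] = d[j, i] = k2p(sp.P, sp.Q)
            except ValueError as exc:
                log.warning("pair (%s, %s): %s; distance set to NaN",
                            aln.taxa[i], aln.taxa[j], exc)
                d[i, j] = d[j, i] = math.nan
    return DistanceMatrix(list(aln.taxa), d)


# ---------------------------------------------------------------------------
# printed lower-triangular matrices (as journals typeset them)

TABLE3_FIXTURE = Path(__file__).parent / "data" / "table3_k2p.tsv"


def parse_printed_matrix(source: str | Path) -> DistanceMatrix:
    """Parse a printed lower-triangular distance table.

    Input: one line per taxon, ``<row index><TAB><d1> <d2> ...`` with
    row *i* carrying *i - 1* entries; ``# index<TAB>name`` comment lines
    supply taxon labels.  Returns the full symmetric matrix.
    """
    if isinstance(source, Path) or (
            isinstance(source, str) and source.strip() and "\n" not in source
            and Path(source).is_file()):
        text = Path(source).read_text()
    else:
        text = str(source)
    labels: dict[int, str] = {}
    rows: list[list[float]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            parts = body.split(None, 1)
            if len(parts) == 2 and parts[0].isdigit():
                labels[int(parts[0])] = parts[1].strip()
            continue
        fields = line.split()
        if not fields[0].isdigit():
            raise ValueError(f"row must start with its index: {line!r}")
        idx = int(fields[0])
        values = [float(v) for v in fields[1:]]
        if idx != len(rows) + 1:
            raise ValueError(f"expected row {len(rows) + 1}, got {idx}")
        if len(values) != idx - 1:
            raise ValueError(
                f"row {idx} has {len(values)} entries, expected {idx - 1}")
        rows.append(values)
    if not rows:
        raise ValueError("empty distance-matrix input")
    n = len(rows)
    d = np.zeros((n, n))
    for i, values in enumerate(rows):
        for j, v in enumerate(values):
            d[i, j] = d[j, i] = v
    taxa = [labels.get(i + 1, str(i + 1)) for i in range(n)]
    return DistanceMatrix(taxa, d)


def load_table3() -> DistanceMatrix:
    """The packaged 14-taxon ITS K2P matrix fixture (13 species + out-group)."""
    return parse_printed_matrix(TABLE3_FIXTURE)


def write_square_tsv(dm: DistanceMatrix, path: str | Path, decimals: int = 3) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(dm.taxa) + "\n")
        for i, taxon in enumerate(dm.taxa):
            vals = "\t".join(f"{round_half_up(v, decimals):.{decimals}f}"
                             if math.isfinite(v) else "nan"
                             for v in dm.d[i])
            fh.write(f"{taxon}\t{vals}\n")


def write_phylip_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f" {len(dm.taxa)}\n")
        for i, taxon in enumerate(dm.taxa):
            vals = " ".join(f"{v:.6f}" for v in dm.d[i])
            fh.write(f"{taxon:<12s} {vals}\n")
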