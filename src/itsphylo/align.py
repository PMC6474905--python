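"""Pairwise and progressive multiple alignment, and variable-site counts.

Pairwise alignment is global Needleman–Wunsch with affine (Gotoh) gap
costs and a fully deterministic traceback: on ties, diagonal is preferred
over a gap in the second sequence ("up"), which is preferred over a gap in
the first ("left").  The multiple aligner is ClustalW-style progressive:
a neighbor-joining guide tree on pairwise K2P distances fixes the merge
order, and profiles are merged with profile–profile dynamic programming.

MEGA-style exact replication of any particular GUI aligner is a non-goal;
the algorithms here are standard and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .regions import round_half_up
from .seqio import AMBIGUOUS, ItsRecord, RegionPartition

NEG_INF = -1e30
_EPS = 1e-9


@dataclass
class AlignParams:
    """Affine-gap scoring.  ``gap_open`` is the cost of a gap's first
    residue; each additional residue costs ``gap_extend``."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass
class Alignment:
    """A gapped sequence matrix over {A,C,G,T,-,ambiguity}."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows must be parallel")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("all alignment rows must have equal length")

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def subalignment(self, taxa: Sequence[str]) -> "Alignment":
        idx = [self.taxa.index(t) for t in taxa]
        return Alignment(taxa=[self.taxa[i] for i in idx],
                         rows=[self.rows[i] for i in idx])

    def columns(self, start: int, stop: int) -> "Alignment":
        return Alignment(taxa=list(self.taxa),
                         rows=[r[start:stop] for r in self.rows])


@dataclass
class VariationSummary:
    region: str
    n_variable_sites: int
    alignment_length: int

    @property
    def percent(self) -> float:
        return round_half_up(100.0 * self.n_variable_sites / self.alignment_length, 1)


def _gotoh_matrices(a: str, b: str, p: AlignParams):
    """Fill Gotoh DP matrices M (diagonal), X (gap in b, "up"), Y (gap in a,
    "left") row by row; the in-row dependence of Y is resolved with a
    running-maximum trick so each row is a vectorised numpy pass."""
    m, n = len(a), len(b)
    go, ge = p.gap_open, p.gap_extend
    code_a = np.frombuffer(a.encode(), dtype=np.uint8)
    code_b = np.frombuffer(b.encode(), dtype=np.uint8)
    sub = np.where(code_a[:, None] == code_b[None, :], p.match, p.mismatch)

    M = np.full((m + 1, n + 1), NEG_INF)
    X = np.full((m + 1, n + 1), NEG_INF)
    Y = np.full((m + 1, n + 1), NEG_INF)
    M[0, 0] = 0.0
    if m:
        X[1:, 0] = go + ge * np.arange(m)
    if n:
        Y[0, 1:] = go + ge * np.arange(n)

    js = np.arange(n)
    for i in range(1, m + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = sub[i - 1] + prev_best[:-1]
        X[i, 1:] = np.maximum(np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) + go,
                              X[i - 1, 1:] + ge)
        X[i, 0] = go + ge * (i - 1)
        # Y[i, j] = max_{k<j} ( max(M,X)[i, k] + go + ge*(j-1-k) )
        best_mx = np.maximum(M[i, :-1], X[i, :-1])
        shifted = np.maximum.accumulate(best_mx - ge * js)
        Y[i, 1:] = shifted + go + ge * js
    return M, X, Y, sub


def pairwise_align(a: str, b: str, params: AlignParams | None = None,
                   ta: str = "A", tb: str = "B") -> Alignment:
    """Optimal global alignment of two sequences (affine gaps).

    Traceback is deterministic: ties resolve diagonal, then up (gap in
    ``b``), then left (gap in ``a``).
    """
    if params is None:
        params = AlignParams()
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    a, b = a.upper(), b.upper()
    M, X, Y, sub = _gotoh_matrices(a, b, params)
    go, ge = params.gap_open, params.gap_extend

    i, j = len(a), len(b)
    state = _pick((M[i, j], X[i, j], Y[i, j]))  # ties: M > X > Y
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # M: consumed a[i-1], b[j-1]
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = _pick(prev)
        elif state == 1:  # X: gap in b ("up"), consumed a[i-1]
            out_a.append(a[i - 1])
            out_b.append("-")
            opts = (M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            state = _pick_from(X[i, j], opts)
            i -= 1
        else:  # Y: gap in a ("left"), consumed b[j-1]
            out_a.append("-")
            out_b.append(b[j - 1])
            opts = (M[i, j - 1] + go, X[i, j - 1] + go, Y[i, j - 1] + ge)
            state = _pick_from(Y[i, j], opts)
            j -= 1
    return Alignment(taxa=[ta, tb], rows=["".join(reversed(out_a)), "".join(reversed(out_b))])


def _pick(scores: tuple[float, float, float]) -> int:
    best = max(scores)
    for k, s in enumerate(scores):
        if s >= best - _EPS:
            return k
    return 0


def _pick_from(target: float, opts: tuple[float, float, float]) -> int:
    for k, s in enumerate(opts):
        if abs(s - target) < _EPS:
            return k
    return int(np.argmax(opts))


def alignment_score(aln: Alignment, params: AlignParams | None = None) -> float:
    """Score an existing 2-row alignment under the affine model (for checks)."""
    if params is None:
        params = AlignParams()
    ra, rb = aln.rows
    score = 0.0
    gap_a = gap_b = False
    for ca, cb in zip(ra, rb):
        if ca == "-" and cb == "-":
            raise ValueError("all-gap column")
        if ca == "-":
            score += params.gap_extend if gap_a else params.gap_open
            gap_a, gap_b = True, False
        elif cb == "-":
            score += params.gap_extend if gap_b else params.gap_open
            gap_b, gap_a = True, False
        else:
            score += params.match if ca == cb else params.mismatch
            gap_a = gap_b = False
    return score


# ---------------------------------------------------------------------------
# profile-profile progressive alignment


def _profile_counts(rows: list[str]) -> np.ndarray:
    """Column base counts over A,C,G,T (ambiguity and gaps excluded)."""
    order = "ACGT"
    n = len(rows[0])
    counts = np.zeros((n, 4))
    for r in rows:
        arr = np.frombuffer(r.encode(), dtype=np.uint8)
        for k, base in enumerate(order):
            counts[:, k] += arr == ord(base)
    return counts


def _profile_align(rows_a: list[str], rows_b: list[str], p: AlignParams) -> tuple[list[int], list[int]]:
    """Global DP between two profiles; returns per-profile gap masks encoded
    as column index lists (-1 marks an inserted gap column)."""
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    na, nb = ca.shape[0], cb.shape[0]
    tot_a, tot_b = ca.sum(axis=1), cb.sum(axis=1)
    # expected substitution score between columns, averaged over base pairs
    same = ca @ cb.T  # identical-base pair count per column pair
    pairs = np.outer(tot_a, tot_b)
    sub = np.where(pairs > 0,
                   (same * p.match + (pairs - same) * p.mismatch) / np.maximum(pairs, 1),
                   0.0)
    go, ge = p.gap_open, p.gap_extend

    M = np.full((na + 1, nb + 1), NEG_INF)
    X = np.full((na + 1, nb + 1), NEG_INF)
    Y = np.full((na + 1, nb + 1), NEG_INF)
    M[0, 0] = 0.0
    if na:
        X[1:, 0] = go + ge * np.arange(na)
    if nb:
        Y[0, 1:] = go + ge * np.arange(nb)
    js = np.arange(nb)
    for i in range(1, na + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = sub[i - 1] + prev_best[:-1]
        X[i, 1:] = np.maximum(np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) + go,
                              X[i - 1, 1:] + ge)
        X[i, 0] = go + ge * (i - 1)
        best_mx = np.maximum(M[i, :-1], X[i, :-1])
        shifted = np.maximum.accumulate(best_mx - ge * js)
        Y[i, 1:] = shifted + go + ge * (np.arange(1, nb + 1) - 1)

    i, j = na, nb
    state = _pick((M[i, j], X[i, j], Y[i, j]))
    path_a: list[int] = []
    path_b: list[int] = []
    while i > 0 or j > 0:
        if state == 0:
            path_a.append(i - 1)
            path_b.append(j - 1)
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i, j = i - 1, j - 1
            state = _pick(prev) if (i or j) else 0
        elif state == 1:
            path_a.append(i - 1)
            path_b.append(-1)
            opts = (M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            state = _pick_from(X[i, j], opts)
            i -= 1
        else:
            path_a.append(-1)
            path_b.append(j - 1)
            opts = (M[i, j - 1] + go, X[i, j - 1] + go, Y[i, j - 1] + ge)
            state = _pick_from(Y[i, j], opts)
            j -= 1
    path_a.reverse()
    path_b.reverse()
    return path_a, path_b


def _apply_path(rows: list[str], path: list[int]) -> list[str]:
    return ["".join(r[k] if k >= 0 else "-" for k in path) for r in rows]


def progressive_msa(records: Sequence[ItsRecord], params: AlignParams | None = None) -> Alignment:
    """Progressive multiple alignment.

    Pairwise K2P distances (from pairwise alignments) feed a
    neighbor-joining guide tree whose join order drives profile merges.
    Deterministic for a given input order.
    """
    if params is None:
        params = AlignParams()
    if len(records) < 2:
        raise ValueError("progressive_msa needs at least 2 records")
    if len(records) == 2:
        a, b = records
        return pairwise_align(a.seq, b.seq, params, ta=a.id, tb=b.id)

    from .distance import DistanceMatrix, k2p, site_patterns  # local: avoids cycle
    from .phylo import nj_join_order

    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = pairwise_align(records[i].seq, records[j].seq, params)
            try:
                sp = site_patterns(aln.rows[0], aln.rows[1])
                d[i, j] = d[j, i] = k2p(sp.P, sp.Q)
            except ValueError:
                d[i, j] = d[j, i] = 1.0  # saturated / incomparable: max weight
    order = nj_join_order(DistanceMatrix([r.id for r in records], d))

    profiles: dict[int, tuple[list[str], list[str]]] = {
        i: ([rec.id], [rec.seq]) for i, rec in enumerate(records)
    }
    for a_idx, b_idx, new_idx in order:
        taxa_a, rows_a = profiles.pop(a_idx)
        taxa_b, rows_b = profiles.pop(b_idx)
        pa, pb = _profile_align(rows_a, rows_b, params)
        profiles[new_idx] = (taxa_a + taxa_b, _apply_path(rows_a, pa) + _apply_path(rows_b, pb))
    remaining = [profiles[k] for k in sorted(profiles)]
    taxa, rows = remaining[0]
    for taxa_b, rows_b in remaining[1:]:
        pa, pb = _profile_align(rows, rows_b, params)
        rows = _apply_path(rows, pa) + _apply_path(rows_b, pb)
        taxa = taxa + taxa_b
    # restore input order
    aln = Alignment(taxa=taxa, rows=rows)
    return aln.subalignment([r.id for r in records])


# ---------------------------------------------------------------------------
# variable (polymorphic) sites


def count_variable_sites(aln: Alignment, column_range: Optional[tuple[int, int]] = None,
                         region: str = "ITS", substitutions_only: bool = False) -> VariationSummary:
    """Count polymorphic columns in a column range.

    A column is variable iff it holds >= 2 distinct states; a gap counts as
    a state (indel polymorphism) unless ``substitutions_only``.  Ambiguity
    codes never contribute states.
    """
    if not aln.rows:
        raise ValueError("empty alignment")
    lo, hi = column_range if column_range is not None else (0, aln.column_count)
    if hi <= lo:
        raise ValueError(f"empty column range {lo}:{hi}")
    n_var = 0
    for col in range(lo, hi):
        states = set()
        for row in aln.rows:
            c = row[col]
            if c in AMBIGUOUS:
                continue
            if c == "-" and substitutions_only:
                continue
            states.add(c)
        if len(states) >= 2:
            n_var += 1
    return VariationSummary(region=region, n_variable_sites=n_var, alignment_length=hi - lo)


def project_partition(aln: Alignment, reference: str, partition: RegionPartition) -> dict[str, tuple[int, int]]:
    """Map a reference row's ungapped region intervals to alignment columns."""
    row = aln.row(reference)
    col_of: list[int] = []  # alignment column of each ungapped reference base
    for col, c in enumerate(row):
        if c != "-":
            col_of.append(col)
    out = {}
    for name in ("ITS", "ITS1", "5.8S", "ITS2"):
        lo, hi = partition.region(name)
        if hi > len(col_of):
            raise ValueError("partition exceeds reference sequence length")
        out[name] = (col_of[lo], col_of[hi - 1] + 1)
    return out


# ---------------------------------------------------------------------------
# alignment I/O


def write_aligned_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(aln.taxa, aln.rows):
            fh.write(f">{taxon}\n{row}\n")


def read_aligned_fasta(path: str | Path) -> Alignment:
    from Bio import SeqIO

    taxa, rows = [], []
    for entry in SeqIO.parse(str(path), "fasta"):
        taxa.append(entry.description.split("|")[0].strip())
        rows.append(str(entry.seq).upper())
    if not taxa:
        raise ValueError(f"no records in {path}")
    return Alignment(taxa=taxa, rows=rows)


def write_phylip(aln: Alignment, path: str | Path) -> None:
    """Relaxed PHYLIP (names up to whitespace, single block)."""
    with open(path, "w") as fh:
        fh.write(f" {len(aln.taxa)} {aln.column_count}\n")
        for taxon, row in zip(aln.taxa, aln.rows):
            fh.write(f"{taxon:<12s} {row}\n")
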