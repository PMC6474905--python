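"""Partitioning ITS amplicons into ITS1 / 5.8S / ITS2 and per-region statistics.

The 5.8S rDNA gene is highly conserved across land plants while the two
spacers diverge quickly, so the partition is anchored by a semi-global
alignment of a 5.8S reference against each amplicon: ITS1 is everything
5' of the first aligned reference column, ITS2 everything 3' of the last.
PCR primer tails (18S/26S fragments carried in by universal primers) can be
trimmed first when the primer pair is supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import reverse_complement

from .seqio import AMBIGUOUS, ItsRecord, RegionPartition

REGION_NAMES = ("ITS", "ITS1", "5.8S", "ITS2")

#: Default packaged 5.8S anchor (synthetic stand-in; replace with a curated
#: reference for real data — any conserved 163-nt 5.8S works).
DEFAULT_REF_5P8S = Path(__file__).parent / "data" / "synthetic_5p8s_reference.fasta"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero (presentation convention)."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class RegionStats:
    """Lengths (nt) and GC content (%) for ITS, ITS1, 5.8S, ITS2.

    ``gc`` holds the presentation value (one decimal, half-up); ``gc_raw``
    keeps full precision so that group means are not computed on rounded
    numbers.
    """

    lengths: dict[str, int]
    gc: dict[str, float]
    gc_raw: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.lengths[r] for r in ("ITS1", "5.8S", "ITS2"))
        if self.lengths["ITS"] != total:
            raise ValueError("ITS length must equal the sum of its regions")


def _semi_global_aligner(match: float = 2.0, mismatch: float = -1.0,
                         gap_open: float = -5.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps on the amplicon (target): the short 5.8S reference may
    # land anywhere inside it
    for attr, legacy in (
        ("open_left_deletion_score", "query_left_open_gap_score"),
        ("extend_left_deletion_score", "query_left_extend_gap_score"),
        ("open_right_deletion_score", "query_right_open_gap_score"),
        ("extend_right_deletion_score", "query_right_extend_gap_score"),
    ):
        try:
            setattr(aligner, attr, 0.0)
        except AttributeError:
            setattr(aligner, legacy, 0.0)
    return aligner


def _anchor_58s(seq: str, ref58s: str, min_identity: float) -> tuple[int, int]:
    """Locate ref58s in seq by semi-global alignment; return (start, stop)."""
    aligner = _semi_global_aligner()
    alignment = aligner.align(seq, ref58s)[0]
    blocks_t, blocks_q = alignment.aligned
    if len(blocks_t) == 0:
        raise ValueError("5.8S anchor not found (no aligned blocks)")
    matches = 0
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        matches += sum(1 for a, b in zip(seq[ts:te], ref58s[qs:qe]) if a == b)
    identity = matches / len(ref58s)
    if identity < min_identity:
        raise ValueError(
            f"5.8S anchor not found (best identity {identity:.2f} "
            f"< threshold {min_identity:.2f})"
        )
    return int(blocks_t[0][0]), int(blocks_t[-1][1])


def _find_primer(seq: str, primer: str, min_identity: float = 0.8) -> Optional[tuple[int, int]]:
    """Best local match of a primer in seq, or None below the identity bar."""
    idx = seq.find(primer)
    if idx >= 0:
        return idx, idx + len(primer)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    try:
        alignment = aligner.align(seq, primer)[0]
    except IndexError:
        return None
    blocks_t, blocks_q = alignment.aligned
    if len(blocks_t) == 0:
        return None
    matches = sum(
        1
        for (ts, te), (qs, qe) in zip(blocks_t, blocks_q)
        for a, b in zip(seq[ts:te], primer[qs:qe])
        if a == b
    )
    if matches / len(primer) < min_identity:
        return None
    return int(blocks_t[0][0]), int(blocks_t[-1][1])


def trim_primer_tails(seq: str, primers: tuple[str, str]) -> tuple[str, int]:
    """Trim 18S/26S tails flanking the amplicon.

    ``primers`` are the forward and reverse PCR primers (each written
    5'→3' on its own strand).  The amplicon proper is taken to start just
    after the forward-primer match and end just before the
    reverse-complemented reverse-primer match.  Returns (trimmed sequence,
    offset of the trim start in the input).
    """
    fwd, rev = primers
    start, stop = 0, len(seq)
    hit = _find_primer(seq, fwd.upper())
    if hit is not None:
        start = hit[1]
    hit = _find_primer(seq, reverse_complement(rev.upper()))
    if hit is not None and hit[0] > start:
        stop = hit[0]
    return seq[start:stop], start


def partition_regions(
    record: ItsRecord,
    ref58s: str,
    primers: Optional[tuple[str, str]] = None,
    min_identity: float = 0.8,
) -> RegionPartition:
    """Partition an ITS amplicon into ITS1 / 5.8S / ITS2.

    The 5.8S gene is located by semi-global alignment of ``ref58s`` (a
    conserved reference, 140–190 nt); boundaries sit at the reference's
    first and last aligned columns.  With ``primers`` given, primer-derived
    flanking tails are trimmed before partitioning and coordinates refer to
    the trimmed amplicon (the record's ``seq`` is left untouched; apply
    :func:`trim_primer_tails` yourself if you want the trimmed sequence).
    """
    ref58s = ref58s.upper()
    if not 140 <= len(ref58s) <= 190:
        raise ValueError(f"5.8S reference length {len(ref58s)} outside [140, 190]")
    seq = record.seq
    if primers is not None:
        seq, _ = trim_primer_tails(seq, primers)
    start, stop = _anchor_58s(seq, ref58s, min_identity)
    return RegionPartition(its1=(0, start), r58s=(start, stop), its2=(stop, len(seq)))


def gc_percent(seq: str) -> float:
    """GC content in percent over unambiguous bases only."""
    counted = [c for c in seq if c not in AMBIGUOUS and c != "-"]
    if not counted:
        raise ValueError("region contains only ambiguity codes")
    gc = sum(1 for c in counted if c in "GC")
    return 100.0 * gc / len(counted)


def region_stats(record: ItsRecord) -> RegionStats:
    """Lengths and GC contents per region (the barcoding-report statistics)."""
    if record.regions is None:
        raise ValueError(f"record {record.id!r} has no region partition")
    lengths: dict[str, int] = {}
    gc_raw: dict[str, float] = {}
    for name in REGION_NAMES:
        lo, hi = record.regions.region(name)
        lengths[name] = hi - lo
        gc_raw[name] = gc_percent(record.seq[lo:hi])
    gc = {k: round_half_up(v, 1) for k, v in gc_raw.items()}
    return RegionStats(lengths=lengths, gc=gc, gc_raw=gc_raw)


def summarize_sections(
    records: Sequence[ItsRecord], stats: Sequence[RegionStats]
) -> pd.DataFrame:
    """Per-section min/max region lengths and mean GC.

    Means are taken over full-precision GC values and rounded (half-up, one
    decimal) only for presentation, as reports conventionally do.
    """
    if len(records) != len(stats):
        raise ValueError("records and stats must be parallel")
    rows = []
    by_section: dict[str, list[RegionStats]] = {}
    for rec, st in zip(records, stats):
        by_section.setdefault(rec.section, []).append(st)
    for section, group in by_section.items():
        if not group:
            raise ValueError(f"empty section group {section!r}")
        for region in REGION_NAMES:
            lengths = [g.lengths[region] for g in group]
            mean_gc = sum(g.gc_raw[region] for g in group) / len(group)
            rows.append(
                {
                    "section": section,
                    "region": region,
                    "n": len(group),
                    "min_length": min(lengths),
                    "max_length": max(lengths),
                    "mean_gc": round_half_up(mean_gc, 1),
                }
            )
    return pd.DataFrame(rows)


def stats_table(records: Sequence[ItsRecord], stats: Sequence[RegionStats]) -> pd.DataFrame:
    """Per-record table in the conventional column order (lengths then GC)."""
    rows = []
    for rec, st in zip(records, stats):
        row: dict[str, object] = {"id": rec.id, "species": rec.species, "section": rec.section}
        for region in REGION_NAMES:
            row[f"len_{region}"] = st.lengths[region]
        for region in REGION_NAMES:
            row[f"gc_{region}"] = st.gc[region]
        rows.append(row)
    return pd.DataFrame(rows)


def load_reference_58s(path: str | Path = DEFAULT_REF_5P8S) -> str:
    """Load a single-record FASTA holding the 5.8S anchor reference."""
    entries = list(SeqIO.parse(str(path), "fasta"))
    if len(entries) != 1:
        raise ValueError(f"expected exactly one 5.8S reference record in {path}")
    return str(entries[0].seq).upper()
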