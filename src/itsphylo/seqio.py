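"""Reading ITS sequence data.

The nuclear ribosomal ITS region (ITS1-5.8S-ITS2) is the standard plant
barcode this package analyses.  Records carry a taxonomic *section* label
(a rank between genus and species) so that downstream statistics can be
grouped the way barcoding studies report them.

FASTA headers may encode metadata as ``id|species|section``; a bare header
is accepted and yields ``section='unknown'``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO

#: Canonical section labels.  Anything else in a header is an error.
SECTIONS = ("Formosae", "Chrysotoxae", "outgroup", "unknown")

IUPAC_DNA = set("ACGTNRYSWKMBDHV")
IUPAC_RNA = (IUPAC_DNA - {"T"}) | {"U"}
#: Ambiguity codes (everything that is not an unambiguous base).
AMBIGUOUS = set("NRYSWKMBDHV")


@dataclass
class RegionPartition:
    """0-based half-open intervals for ITS1, 5.8S and ITS2 on a sequence.

    Invariant: the intervals are contiguous, ordered and non-empty —
    ``its1.stop == r58s.start`` and ``r58s.stop == its2.start``.
    """

    its1: tuple[int, int]
    r58s: tuple[int, int]
    its2: tuple[int, int]

    def __post_init__(self) -> None:
        a, b, c = self.its1, self.r58s, self.its2
        for name, (lo, hi) in (("ITS1", a), ("5.8S", b), ("ITS2", c)):
            if hi - lo <= 0:
                raise ValueError(f"{name} interval is empty: {lo}:{hi}")
        if a[1] != b[0] or b[1] != c[0]:
            raise ValueError("regions must be contiguous: ITS1 < 5.8S < ITS2")

    def region(self, name: str) -> tuple[int, int]:
        key = name.upper().replace(" ", "")
        if key == "ITS1":
            return self.its1
        if key in ("5.8S", "58S", "R58S"):
            return self.r58s
        if key == "ITS2":
            return self.its2
        if key == "ITS":
            return (self.its1[0], self.its2[1])
        raise KeyError(name)


@dataclass
class ItsRecord:
    """One taxon: identifier, labels, and its (normalized, uppercase) sequence."""

    id: str
    species: str = ""
    section: str = "unknown"
    seq: str = ""
    regions: Optional[RegionPartition] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        self.seq = self.seq.upper()
        if self.section not in SECTIONS:
            raise ValueError(
                f"record {self.id!r}: unknown section {self.section!r}; "
                f"expected one of {SECTIONS}"
            )

    def region_seq(self, name: str) -> str:
        if self.regions is None:
            raise ValueError(f"record {self.id!r} has no region partition")
        lo, hi = self.regions.region(name)
        return self.seq[lo:hi]


def _validate_alphabet(seq: str, rec_id: str, rna: bool) -> None:
    allowed = IUPAC_RNA if rna else IUPAC_DNA
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            mode = "RNA" if rna else "DNA"
            raise ValueError(
                f"record {rec_id!r}: non-IUPAC {mode} character {ch!r} at position {pos}"
            )


def _parse_header(header: str) -> tuple[str, str, str]:
    parts = [p.strip() for p in header.split("|")]
    if len(parts) >= 3:
        return parts[0], parts[1], parts[2]
    if len(parts) == 2:
        return parts[0], parts[1], "unknown"
    return parts[0], "", "unknown"


def read_fasta(path: str | Path, rna: bool = False) -> list[ItsRecord]:
    """Read a multi-FASTA file into :class:`ItsRecord` objects.

    Headers are parsed as ``id|species|section`` when pipe-delimited.
    Raises on an empty file, duplicate ids or non-IUPAC characters.
    """
    path = Path(path)
    records: list[ItsRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rec_id, species, section = _parse_header(entry.description)
        if rec_id in seen:
            raise ValueError(f"duplicate record id {rec_id!r} in {path}")
        seen.add(rec_id)
        seq = str(entry.seq).upper()
        _validate_alphabet(seq, rec_id, rna)
        records.append(ItsRecord(id=rec_id, species=species, section=section, seq=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_genbank(path: str | Path) -> list[ItsRecord]:
    """Read a GenBank flat file; use ITS1/5.8S/ITS2 feature annotations when present.

    Features qualify by a ``product``/``note``/``gene`` qualifier mentioning
    ITS1, 5.8S or ITS2.  If all three are found and contiguous they become the
    record's :class:`RegionPartition`; otherwise the record is returned
    unpartitioned (the alignment-based partitioner can be applied later).
    """
    path = Path(path)
    records: list[ItsRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "genbank"):
        rec_id = entry.id
        if rec_id in seen:
            raise ValueError(f"duplicate record id {rec_id!r} in {path}")
        seen.add(rec_id)
        seq = str(entry.seq).upper()
        _validate_alphabet(seq, rec_id, rna=False)
        organism = entry.annotations.get("organism", "")
        found: dict[str, tuple[int, int]] = {}
        for feat in entry.features:
            text = " ".join(
                " ".join(feat.qualifiers.get(k, []))
                for k in ("product", "note", "gene", "standard_name")
            ).lower()
            iv = (int(feat.location.start), int(feat.location.end))
            if "5.8s" in text:
                found["r58s"] = iv
            elif "spacer 1" in text or "its1" in text:
                found["its1"] = iv
            elif "spacer 2" in text or "its2" in text:
                found["its2"] = iv
        regions = None
        if len(found) == 3:
            try:
                regions = RegionPartition(found["its1"], found["r58s"], found["its2"])
            except ValueError as exc:
                warnings.warn(
                    f"{rec_id}: GenBank ITS features not contiguous ({exc}); "
                    "record left unpartitioned"
                )
        records.append(
            ItsRecord(id=rec_id, species=organism, section="unknown", seq=seq,
                      regions=regions)
        )
    if not records:
        raise ValueError(f"no GenBank records found in {path}")
    return records


def write_fasta(records: list[ItsRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.species or rec.section != "unknown":
                header = f"{rec.id}|{rec.species}|{rec.section}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
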