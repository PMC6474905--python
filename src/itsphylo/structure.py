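"""ITS2 secondary structure: parsing, a fallback folder, and the
four-helix feature extraction.

The ITS2 transcript folds into a conserved "four-fingered hand": four
helices (I–IV) radiating from a central loop.  Three feature classes
describe each helix — its angular position around the central loop, its
stem length in base pairs, and the number of loops (bulges, internal
loops and the terminal hairpin) it carries.  Because published structure
drawings carry no angle formula, angles here follow an explicit equal-arc
convention: walking the central loop 5'→3', every element (unpaired base
or helix attachment) occupies an equal arc of 360°, a helix sits at its
arc midpoint, and Helix I is anchored at 0°.  Clustering of the resulting
feature vectors — not the raw angle values — is what downstream analyses
consume.

Structures arrive as Vienna dot-bracket or CT files from an external
predictor; a deterministic Nussinov-style maximum-base-pairing folder is
provided as a simple offline fallback (thermodynamic MFE folding is a
non-goal).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

HELIX_IDS = ("I", "II", "III", "IV")
_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
MIN_HAIRPIN = 3


@dataclass
class SecondaryStructure:
    """A sequence plus a well-nested dot-bracket pairing string."""

    seq: str
    pairing: str

    def __post_init__(self) -> None:
        self.seq = transcribe(self.seq)
        if len(self.seq) != len(self.pairing):
            raise ValueError(
                f"sequence length {len(self.seq)} != structure length {len(self.pairing)}")
        self.pair_map  # force bracket validation

    @property
    def pair_map(self) -> dict[int, int]:
        return _pair_map(self.pairing)

    def validate_pairs(self) -> None:
        """Check paired bases are complementary (AU/GC/GU) and hairpin
        loops have >= 3 unpaired bases."""
        pm = self.pair_map
        for i, j in pm.items():
            if i < j:
                if (self.seq[i], self.seq[j]) not in _CANONICAL:
                    raise ValueError(
                        f"non-complementary pair {self.seq[i]}{self.seq[j]} "
                        f"at positions {i},{j}")
                if _is_hairpin_closing(pm, i, j) and j - i - 1 < MIN_HAIRPIN:
                    raise ValueError(f"hairpin loop at {i},{j} shorter than {MIN_HAIRPIN}")


def transcribe(seq: str) -> str:
    """DNA -> RNA (T -> U), uppercase."""
    return seq.upper().replace("T", "U")


def _pair_map(pairing: str) -> dict[int, int]:
    stack: list[int] = []
    pm: dict[int, int] = {}
    for pos, c in enumerate(pairing):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            i = stack.pop()
            pm[i] = pos
            pm[pos] = i
        elif c == ".":
            continue
        elif c in "[]{}<>":
            raise ValueError(f"pseudoknot notation {c!r} at position {pos} not supported")
        else:
            raise ValueError(f"invalid structure character {c!r} at position {pos}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pm


def _is_hairpin_closing(pm: dict[int, int], i: int, j: int) -> bool:
    return all(k not in pm for k in range(i + 1, j))


# ---------------------------------------------------------------------------
# input formats


def parse_vienna(text: str, validate: bool = False) -> SecondaryStructure:
    """Parse Vienna/dot-bracket text: optional '>' header, sequence line(s),
    then structure line(s) (a trailing energy annotation is tolerated)."""
    seq_parts: list[str] = []
    db_parts: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(">") or line.startswith("#"):
            continue
        token = line.split()[0]
        if set(token) <= set(".()[]{}<>"):
            db_parts.append(token)
        else:
            seq_parts.append(token)
    if not seq_parts or not db_parts:
        raise ValueError("Vienna input needs a sequence line and a structure line")
    ss = SecondaryStructure(seq="".join(seq_parts), pairing="".join(db_parts))
    if validate:
        ss.validate_pairs()
    return ss


def parse_ct(text: str, validate: bool = False) -> SecondaryStructure:
    """Parse CT (connectivity table) format into a dot-bracket structure."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty CT input")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (ValueError, IndexError):
        raise ValueError("CT header must start with the sequence length")
    if len(lines) - 1 < n:
        raise ValueError(f"CT file has {len(lines) - 1} rows, expected {n}")
    seq = []
    partner = [0] * (n + 1)
    for ln in lines[1 : n + 1]:
        fields = ln.split()
        idx, base, pair = int(fields[0]), fields[1], int(fields[4])
        seq.append(base)
        partner[idx] = pair
    db = []
    for i in range(1, n + 1):
        p = partner[i]
        if p == 0:
            db.append(".")
        elif p > i:
            db.append("(")
        else:
            if partner[p] != i:
                raise ValueError(f"inconsistent CT pairing at position {i}")
            db.append(")")
    ss = SecondaryStructure(seq="".join(seq), pairing="".join(db))
    if validate:
        ss.validate_pairs()
    return ss


def parse_structure(path: str | Path, validate: bool = False) -> SecondaryStructure:
    """Read a structure file; format chosen by extension (.ct vs Vienna)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".ct":
        return parse_ct(text, validate=validate)
    return parse_vienna(text, validate=validate)


def to_ct(ss: SecondaryStructure, title: str = "structure") -> str:
    pm = ss.pair_map
    n = len(ss.seq)
    out = [f"{n} {title}"]
    for i in range(n):
        out.append(
            f"{i + 1} {ss.seq[i]} {i} {i + 2 if i + 1 < n else 0} "
            f"{pm.get(i, -1) + 1} {i + 1}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# fallback folder (maximum base pairing)


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _CANONICAL


def fold_fallback(seq: str) -> SecondaryStructure:
    """Nussinov-style maximum base pairing with minimum hairpin loop 3.

    Deterministic traceback: prefer pairing, leftmost partner first.  A
    simple structural stand-in when no external prediction is available;
    it maximizes pair count, not thermodynamic stability.
    """
    rna = transcribe(seq)
    n = len(rna)
    if not 1 <= n <= 2000:
        raise ValueError("fold_fallback handles sequences of length 1..2000")
    dp = np.zeros((n + 1, n + 1), dtype=np.int32)  # dp[i][j]: max pairs in [i, j)
    for span in range(MIN_HAIRPIN + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            best = dp[i + 1, j]  # i unpaired
            for k in range(i + MIN_HAIRPIN + 1, j):
                if _can_pair(rna[i], rna[k]):
                    cand = 1 + dp[i + 1, k] + dp[k + 1, j]
                    if cand > best:
                        best = cand
            dp[i, j] = best
    db = ["."] * n

    def traceback(i: int, j: int) -> None:
        while i < j:
            target = dp[i, j]
            if target == 0:
                return
            paired = False
            for k in range(i + MIN_HAIRPIN + 1, j):
                if _can_pair(rna[i], rna[k]) and 1 + dp[i + 1, k] + dp[k + 1, j] == target:
                    db[i], db[k] = "(", ")"
                    traceback(i + 1, k)
                    i = k + 1
                    paired = True
                    break
            if not paired:
                i += 1

    traceback(0, n)
    return SecondaryStructure(seq=rna, pairing="".join(db))


# ---------------------------------------------------------------------------
# four-helix decomposition and features


@dataclass
class HelixFeatures:
    helix_id: str
    angle: float  # degrees in [0, 360)
    stem_length: int  # base pairs along the main stack path
    loop_count: int  # bulges + internal loops + hairpin loops in the arm

    def __post_init__(self) -> None:
        if self.helix_id not in HELIX_IDS:
            raise ValueError(f"helix_id must be one of {HELIX_IDS}")
        if not 0 <= self.angle < 360:
            raise ValueError("angle must be in [0, 360)")


@dataclass
class Its2Features:
    """Fixed-order 12-vector: [angle I–IV, stem length I–IV, loop count I–IV]."""

    taxon: str
    helices: list[HelixFeatures]

    @property
    def vector(self) -> np.ndarray:
        v = ([h.angle for h in self.helices]
             + [float(h.stem_length) for h in self.helices]
             + [float(h.loop_count) for h in self.helices])
        if len(v) != 12:
            raise ValueError("feature vector must have length 12")
        return np.array(v, dtype=float)


def _exterior_elements(ss: SecondaryStructure) -> list[tuple[str, int]]:
    """Walk the exterior (central) loop 5'→3': ('u', pos) for an unpaired
    base, ('h', open_pos) for a helix attachment."""
    pm = ss.pair_map
    out = []
    i = 0
    n = len(ss.seq)
    while i < n:
        if i in pm:
            out.append(("h", i))
            i = pm[i] + 1
        else:
            out.append(("u", i))
            i += 1
    return out


def _arm_features(ss: SecondaryStructure, open_pos: int) -> tuple[int, int]:
    """(stem_length, loop_count) for the arm rooted at the pair
    (open_pos, pair[open_pos]).

    Stem length counts base pairs along the main path (first child at each
    branch); loop count tallies bulges, internal loops and hairpin loops
    over the whole arm (multibranch loops separate helices but are not
    themselves counted, matching how hand-annotated structure drawings
    count loops).
    """
    pm = ss.pair_map

    def children(i: int, j: int) -> list[int]:
        out = []
        k = i + 1
        while k < j:
            if k in pm:
                out.append(k)
                k = pm[k] + 1
            else:
                k += 1
        return out

    stem = 0
    loops = 0

    def visit(i: int, on_main_path: bool) -> None:
        nonlocal stem, loops
        j = pm[i]
        # walk the contiguous stack
        pairs = 1
        while i + 1 in pm and pm[i + 1] == j - 1:
            i, j = i + 1, j - 1
            pairs += 1
        if on_main_path:
            stem += pairs
        kids = children(i, j)
        if not kids:
            loops += 1  # terminal hairpin
            return
        if len(kids) == 1:
            k = kids[0]
            l = pm[k]
            left = k - i - 1
            right = j - l - 1
            if left or right:
                loops += 1  # bulge (one side) or internal loop (both)
            visit(k, on_main_path)
        else:
            for idx, k in enumerate(kids):
                visit(k, on_main_path and idx == 0)

    visit(open_pos, True)
    return stem, loops


def decompose_helices(ss: SecondaryStructure, warn=None) -> list[HelixFeatures]:
    """Decompose a structure into the four canonical helix arms.

    Arms are numbered I–IV in 5'→3' order of attachment to the central
    loop.  Fewer than four arms are padded with (0, 0, 0); extra arms are
    truncated; both cases are reported through ``warn`` (a callable taking
    a message) or the module logger.
    """
    import logging

    if warn is None:
        warn = logging.getLogger(__name__).warning
    elements = _exterior_elements(ss)
    helix_positions = [pos for kind, pos in elements if kind == "h"]
    angles = helix_angles(ss)
    if len(helix_positions) != 4:
        warn("structure has %d arms on its central loop, expected 4"
             % len(helix_positions))
    feats: list[HelixFeatures] = []
    for idx in range(4):
        if idx < len(helix_positions):
            stem, loops = _arm_features(ss, helix_positions[idx])
            feats.append(HelixFeatures(HELIX_IDS[idx], angles[idx], stem, loops))
        else:
            feats.append(HelixFeatures(HELIX_IDS[idx], 0.0, 0, 0))
    return feats


def helix_angles(ss: SecondaryStructure) -> list[float]:
    """Angular positions of the helix attachments under the equal-arc
    convention (Helix I anchored at 0°), truncated/padded to 4 entries."""
    elements = _exterior_elements(ss)
    n_slots = len(elements)
    helix_slots = [k for k, (kind, _) in enumerate(elements) if kind == "h"]
    if not helix_slots:
        return [0.0, 0.0, 0.0, 0.0]
    anchor = helix_slots[0]
    angles = [((slot - anchor) % n_slots) * 360.0 / n_slots for slot in helix_slots]
    angles = angles[:4]
    while len(angles) < 4:
        angles.append(0.0)
    return angles


def feature_vector(ss: SecondaryStructure, taxon: str, warn=None) -> Its2Features:
    """The 12-element feature vector for one taxon's ITS2 structure."""
    return Its2Features(taxon=taxon, helices=decompose_helices(ss, warn=warn))


def write_feature_table(features: list[Its2Features], path: str | Path) -> None:
    header = (["id"]
              + [f"angle_{h}" for h in HELIX_IDS]
              + [f"stem_{h}" for h in HELIX_IDS]
              + [f"loops_{h}" for h in HELIX_IDS])
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for feat in features:
            vals = "\t".join(f"{v:g}" for v in feat.vector)
            fh.write(f"{feat.taxon}\t{vals}\n")


def read_feature_table(path: str | Path) -> list[Its2Features]:
    feats = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError("feature table must start with an 'id' header")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 13:
                raise ValueError(f"expected 13 columns, got {len(fields)}")
            vals = [float(v) for v in fields[1:]]
            helices = [
                HelixFeatures(HELIX_IDS[k], vals[k], int(vals[4 + k]), int(vals[8 + k]))
                for k in range(4)
            ]
            feats.append(Its2Features(taxon=fields[0], helices=helices))
    return feats
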