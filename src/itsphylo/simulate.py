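"""Synthetic data generators.

Two generators mirror the statistical structure of an ITS barcoding
dataset so every analysis stage can be exercised offline:

* :func:`simulate_alignment` evolves an ITS1–5.8S–ITS2 amplicon along a
  phylogeny under the Kimura 2-parameter model, with per-region rate
  multipliers (a highly conserved ~163-nt 5.8S between fast-evolving
  spacers), configurable GC bias at the root, and optional
  spacer-restricted deletions with geometric lengths (rDNA length
  variation is confined to the spacers in real amplicons).

* :func:`simulate_structures` emits ITS2 four-helix dot-bracket
  structures realizing requested stem lengths, loop counts and
  central-loop angles exactly under the same equal-arc convention the
  feature extractor uses, so generator and extractor are mutual inverses
  on the feature subspace.

All randomness flows from an explicit seed; sub-streams per stage are
derived with fixed offsets so stages stay reproducible independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align import Alignment
from .seqio import ItsRecord, RegionPartition
from .structure import HELIX_IDS, HelixFeatures, Its2Features, SecondaryStructure
from .tree import Node, Tree, parse_newick

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-condition parameters for sequence simulation.

    Defaults mirror the amplicon structure of an ITS barcode dataset:
    spacer lengths of a few hundred nt around a 163-nt conserved 5.8S,
    transition bias kappa = 2, the 5.8S evolving an order of magnitude
    slower than the spacers, and GC around 53%.
    """

    n_taxa: int = 6
    newick: Optional[str] = None  # fixed tree; None -> random Yule shape
    birth_scale: float = 0.05  # mean branch length for random trees
    kappa: float = 2.0
    sites: dict = field(default_factory=lambda: {"ITS1": 230, "5.8S": 163, "ITS2": 246})
    rate_multipliers: dict = field(
        default_factory=lambda: {"ITS1": 1.0, "5.8S": 0.1, "ITS2": 1.0})
    indel_rate: float = 0.0  # per-branch per-spacer-site deletion rate
    indel_mean_length: float = 2.0  # geometric mean deletion length
    gc: float = 0.53
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required (no wall-clock seeding)")
        if any(v <= 0 for v in self.sites.values()):
            raise ValueError("all region site counts must be positive")
        if self.kappa < 0 or self.indel_rate < 0:
            raise ValueError("rates must be non-negative")
        if any(v < 0 for v in self.rate_multipliers.values()):
            raise ValueError("rate multipliers must be non-negative")


@dataclass
class SimResult:
    tree: Tree
    records: list[ItsRecord]
    alignment: Alignment  # true alignment (gaps where deletions occurred)
    partition: RegionPartition  # on the root/reference coordinate system


def _k2p_transition_matrix(d: float, kappa: float) -> np.ndarray:
    """K2P substitution probabilities for branch length d (subs/site).

    With transition rate alpha and (per-pathway) transversion rate beta,
    kappa = alpha/beta and d = (alpha + 2 beta) t.
    """
    if d < 0:
        raise ValueError("branch length must be non-negative")
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    e1 = np.exp(-4.0 * beta_t)
    e2 = np.exp(-2.0 * (alpha_t + beta_t))
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    # base order A C G T; transitions: A<->G, C<->T
    P = np.full((4, 4), p_tv)
    np.fill_diagonal(P, p_same)
    P[0, 2] = P[2, 0] = p_ts
    P[1, 3] = P[3, 1] = p_ts
    return P


def random_yule_tree(n_taxa: int, rng: np.random.Generator,
                     branch_scale: float) -> Tree:
    """Random Yule-shape topology with exponential branch lengths."""
    tips = [Node(name=f"t{i + 1}", length=float(rng.exponential(branch_scale)))
            for i in range(n_taxa)]
    while len(tips) > 3:
        k = rng.integers(0, len(tips))
        l = rng.integers(0, len(tips) - 1)
        a = tips.pop(int(k))
        b = tips.pop(int(l))
        parent = Node(length=float(rng.exponential(branch_scale)))
        parent.add(a)
        parent.add(b)
        tips.append(parent)
    root = Node()
    for t in tips:
        root.add(t)
    return Tree(root, rooted=False)


def simulate_alignment(config: SimConfig) -> SimResult:
    """Evolve an ITS amplicon along a tree under K2P; see module docstring.

    Returns the true tree, the (possibly deletion-bearing) unaligned
    records, and the true alignment.  Bit-for-bit reproducible per seed.
    """
    rng = np.random.default_rng(config.seed)
    if config.newick is not None:
        tree = parse_newick(config.newick)
    else:
        tree = random_yule_tree(config.n_taxa, rng, config.birth_scale)

    region_order = ("ITS1", "5.8S", "ITS2")
    lengths = [config.sites[r] for r in region_order]
    total = sum(lengths)
    bounds = np.cumsum([0] + lengths)
    partition = RegionPartition(
        its1=(int(bounds[0]), int(bounds[1])),
        r58s=(int(bounds[1]), int(bounds[2])),
        its2=(int(bounds[2]), int(bounds[3])),
    )
    rate = np.empty(total)
    for r, lo, hi in zip(region_order, bounds[:-1], bounds[1:]):
        rate[lo:hi] = config.rate_multipliers[r]

    gc = config.gc
    root_probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    root_seq = rng.choice(4, size=total, p=root_probs)

    seqs: dict[str, np.ndarray] = {}

    def evolve(node: Node, parent_seq: np.ndarray) -> None:
        seq = parent_seq
        d = node.length or 0.0
        if d > 0:
            seq = parent_seq.copy()
            for mult in np.unique(rate):
                sel = rate == mult
                if mult == 0:
                    continue
                P = _k2p_transition_matrix(d * mult, config.kappa)
                cum = np.cumsum(P, axis=1)
                u = rng.random(sel.sum())
                rows = cum[parent_seq[sel]]
                seq[sel] = (u[:, None] > rows).sum(axis=1)
        if node.is_leaf:
            seqs[node.name] = seq
        else:
            for child in node.children:
                evolve(child, seq)

    for child in tree.root.children:
        evolve(child, root_seq)
    if not tree.root.children:  # single-node tree
        seqs[tree.root.name] = root_seq

    taxa = tree.leaf_names()
    rows = {t: list(_BASES[seqs[t]]) for t in taxa}

    if config.indel_rate > 0:
        spacer = np.zeros(total, dtype=bool)
        for name in ("ITS1", "ITS2"):
            lo, hi = partition.region(name)
            spacer[lo:hi] = True
        p_geom = 1.0 / max(config.indel_mean_length, 1.0)
        for t in taxa:
            n_events = rng.poisson(config.indel_rate * spacer.sum())
            for _ in range(n_events):
                length = int(rng.geometric(p_geom))
                start = int(rng.integers(0, total))
                for pos in range(start, min(start + length, total)):
                    if spacer[pos]:
                        rows[t][pos] = "-"

    aln = Alignment(taxa=list(taxa), rows=["".join(rows[t]) for t in taxa])
    records = [
        ItsRecord(id=t, species=f"synthetic {t}", section="unknown",
                  seq=aln.rows[i].replace("-", ""))
        for i, t in enumerate(taxa)
    ]
    return SimResult(tree=tree, records=records, alignment=aln, partition=partition)


# ---------------------------------------------------------------------------
# structure simulation


@dataclass
class StructureSpec:
    """Requested features for one synthetic four-helix structure.

    Angles must be realizable on an equal-arc central loop: each must be a
    multiple of 360/N for the N the generator selects (multiples of 15°
    always work).  ``loops`` counts include the terminal hairpin, so
    ``loops[i] >= 1`` and ``stems[i] >= loops[i]`` (each stack segment
    needs at least one pair).
    """

    angles: tuple[float, float, float, float] = (0.0, 90.0, 180.0, 270.0)
    stems: tuple[int, int, int, int] = (5, 5, 5, 5)
    loops: tuple[int, int, int, int] = (1, 1, 1, 1)

    def __post_init__(self) -> None:
        if self.angles[0] != 0.0:
            raise ValueError("Helix I is the angular anchor; angles[0] must be 0")
        if list(self.angles) != sorted(self.angles):
            raise ValueError("angles must increase in helix order (5'→3')")
        for s, l in zip(self.stems, self.loops):
            if l < 1:
                raise ValueError("each arm needs at least its hairpin loop")
            if s < l:
                raise ValueError(f"stem of {s} bp cannot carry {l} loops "
                                 "(every stack segment needs >= 1 pair)")


def _slot_layout(angles: Sequence[float], max_slots: int = 720) -> tuple[int, list[int]]:
    """Smallest slot count N (>= 4) putting every requested angle on the
    equal-arc grid, plus the helix slot indices."""
    for n_slots in range(4, max_slots + 1):
        slots = []
        ok = True
        for a in angles:
            raw = a * n_slots / 360.0
            if abs(raw - round(raw)) > 1e-9:
                ok = False
                break
            slots.append(int(round(raw)))
        if ok and len(set(slots)) == 4 and slots == sorted(slots) and slots[-1] < n_slots:
            return n_slots, slots
    raise ValueError(f"angles {tuple(angles)} not realizable on <= {max_slots} "
                     "equal arcs")


def _build_arm(stem: int, loops: int) -> tuple[str, str]:
    """Sequence and dot-bracket for one unbranched arm: ``loops - 1``
    single-nt bulges split the stack into ``loops`` segments, closed by a
    3-nt hairpin."""
    segments = loops
    base_len = stem // segments
    sizes = [base_len + (1 if k < stem % segments else 0) for k in range(segments)]
    seq_parts: list[str] = []
    db_parts: list[str] = []
    for k, size in enumerate(sizes):
        if k > 0:
            seq_parts.append("A")  # 5'-side bulge
            db_parts.append(".")
        seq_parts.append("G" * size)
        db_parts.append("(" * size)
    seq_parts.append("AAA")
    db_parts.append("...")
    for size in reversed(sizes):
        seq_parts.append("C" * size)
        db_parts.append(")" * size)
    return "".join(seq_parts), "".join(db_parts)


def build_structure(spec: StructureSpec) -> SecondaryStructure:
    """Construct a dot-bracket structure realizing ``spec`` exactly under
    the extractor's conventions."""
    n_slots, slots = _slot_layout(spec.angles)
    arms = [_build_arm(s, l) for s, l in zip(spec.stems, spec.loops)]
    seq_parts: list[str] = []
    db_parts: list[str] = []
    arm_iter = iter(arms)
    slot_set = dict(zip(slots, range(4)))
    for slot in range(n_slots):
        if slot in slot_set:
            seq, db = arms[slot_set[slot]]
            seq_parts.append(seq)
            db_parts.append(db)
        else:
            seq_parts.append("A")
            db_parts.append(".")
    return SecondaryStructure(seq="".join(seq_parts), pairing="".join(db_parts))


def spec_vector(spec: StructureSpec) -> np.ndarray:
    return np.array(list(spec.angles)
                    + [float(s) for s in spec.stems]
                    + [float(l) for l in spec.loops])


def simulate_structures(
    n: int,
    seed: int,
    angle_choices: Sequence[float] = tuple(15.0 * k for k in range(1, 24)),
    stem_mean: float = 6.0,
    stem_sd: float = 2.0,
    loop_mean: float = 2.0,
    base_spec: Optional[StructureSpec] = None,
    jitter: float = 0.0,
) -> tuple[list[SecondaryStructure], list[Its2Features]]:
    """Draw n synthetic four-helix structures and their true feature vectors.

    Without ``base_spec``, each structure samples angles on the 15° grid,
    normal stem lengths and Poisson(+1) loop counts.  With ``base_spec``,
    structures jitter around it: stems move by at most ``jitter`` (rounded
    integer steps) and angles stay fixed — useful for building tight
    clusters.  The emitted structures reproduce their feature vectors
    exactly by construction.
    """
    rng = np.random.default_rng(seed)
    structures: list[SecondaryStructure] = []
    features: list[Its2Features] = []
    angle_grid = list(angle_choices)
    for k in range(n):
        if base_spec is not None:
            stems = tuple(
                max(int(round(s + rng.normal(0.0, jitter))), max(l, 1))
                for s, l in zip(base_spec.stems, base_spec.loops))
            spec = StructureSpec(angles=base_spec.angles, stems=stems,
                                 loops=base_spec.loops)
        else:
            picks = sorted(rng.choice(len(angle_grid), size=3, replace=False))
            angles = (0.0, *[angle_grid[p] for p in picks])
            loops = tuple(int(rng.poisson(loop_mean - 1.0)) + 1 for _ in range(4))
            stems = tuple(
                max(int(round(rng.normal(stem_mean, stem_sd))), l)
                for l in loops)
            spec = StructureSpec(angles=angles, stems=stems, loops=loops)
        ss = build_structure(spec)
        structures.append(ss)
        helices = [
            HelixFeatures(HELIX_IDS[i], spec.angles[i], spec.stems[i], spec.loops[i])
            for i in range(4)
        ]
        features.append(Its2Features(taxon=f"s{k + 1}", helices=helices))
    return structures, features
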