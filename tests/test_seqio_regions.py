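"""Sequence input, region partitioning and per-region statistics."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from itsphylo.regions import (gc_percent, load_reference_58s, partition_regions,
                              region_stats, round_half_up, stats_table,
                              summarize_sections, trim_primer_tails)
from itsphylo.seqio import ItsRecord, RegionPartition, read_fasta, write_fasta


@pytest.fixture(scope="module")
def ref58():
    return load_reference_58s()


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# FASTA reading


def test_read_fasta_preserves_order_and_metadata(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(
        ">MK522197|D. longicorna|Formosae\nACGTACGT\n"
        ">plain_id\nGGGGCCCC\n"
    )
    records = read_fasta(path)
    assert [r.id for r in records] == ["MK522197", "plain_id"]
    assert records[0].species == "D. longicorna"
    assert records[0].section == "Formosae"
    assert records[1].section == "unknown"


@pytest.mark.parametrize(
    "content, match",
    [
        ("", "no FASTA records"),
        (">a\nACGT\n>a\nACGT\n", "duplicate record id 'a'"),
        (">x\nACGU\n", "position 3"),
        (">x\nAC!T\n", "position 2"),
    ],
)
def test_read_fasta_rejects_bad_input(tmp_path, content, match):
    path = tmp_path / "bad.fasta"
    path.write_text(content)
    with pytest.raises(ValueError, match=match):
        read_fasta(path)


def test_read_fasta_rna_mode_accepts_u(tmp_path):
    path = tmp_path / "rna.fasta"
    path.write_text(">x\nACGU\n")
    assert read_fasta(path, rna=True)[0].seq == "ACGU"


def test_fasta_round_trip(tmp_path, rng):
    records = [ItsRecord(id="a", species="sp a", section="Formosae",
                         seq=random_dna(rng, 90)),
               ItsRecord(id="b", seq=random_dna(rng, 45))]
    path = tmp_path / "rt.fasta"
    write_fasta(records, path)
    back = read_fasta(path)
    assert [(r.id, r.seq, r.section) for r in back] == \
        [(r.id, r.seq, r.section) for r in records]


# ---------------------------------------------------------------------------
# region partitioning


def test_partition_recovers_construction(ref58, rng):
    its1, its2 = random_dna(rng, 228), random_dna(rng, 247)
    rec = ItsRecord(id="x", seq=its1 + ref58 + its2)
    part = partition_regions(rec, ref58)
    widths = (part.its1[1] - part.its1[0],
              part.r58s[1] - part.r58s[0],
              part.its2[1] - part.its2[0])
    assert widths == (228, 163, 247)


def test_partition_survives_divergence(ref58, rng):
    # mutate ~10% of the 5.8S copy; anchor must still land on it
    body = list(ref58)
    for pos in rng.choice(len(body), size=16, replace=False):
        body[pos] = "ACGT"[(("ACGT".index(body[pos])) + 1) % 4]
    rec = ItsRecord(id="x", seq=random_dna(rng, 200) + "".join(body) + random_dna(rng, 220))
    part = partition_regions(rec, ref58)
    assert part.its1 == (0, 200)
    assert part.its2[1] - part.its2[0] == 220


def test_partition_degenerate_inputs(ref58, rng):
    with pytest.raises(ValueError):  # ITS1/ITS2 would be empty
        partition_regions(ItsRecord(id="x", seq=ref58), ref58)
    with pytest.raises(ValueError, match="5.8S anchor not found"):
        partition_regions(ItsRecord(id="x", seq=random_dna(rng, 600)), ref58)
    with pytest.raises(ValueError, match="outside"):
        partition_regions(ItsRecord(id="x", seq=random_dna(rng, 600)), "ACGT" * 10)


def test_partition_with_primer_tails_matches_untailed(ref58, rng):
    fwd = "CGTAACAAGGTTTCCGTAGGTGAAC"
    rev = "TTATTGATATGCTTAAACTCAGCGGG"
    amplicon = random_dna(rng, 228) + ref58 + random_dna(rng, 247)
    untailed = partition_regions(ItsRecord(id="a", seq=amplicon), ref58)
    tailed = (random_dna(rng, 20) + fwd + amplicon
              + reverse_complement(rev) + random_dna(rng, 20))
    with_primers = partition_regions(ItsRecord(id="b", seq=tailed), ref58,
                                     primers=(fwd, rev))
    assert (with_primers.its1, with_primers.r58s, with_primers.its2) == \
        (untailed.its1, untailed.r58s, untailed.its2)


def test_partition_idempotent(ref58, rng):
    rec = ItsRecord(id="x", seq=random_dna(rng, 230) + ref58 + random_dna(rng, 240))
    part = partition_regions(rec, ref58)
    rec.regions = part
    concat = "".join(rec.region_seq(r) for r in ("ITS1", "5.8S", "ITS2"))
    assert concat == rec.seq  # concatenation reproduces the amplicon
    again = partition_regions(ItsRecord(id="y", seq=concat), ref58)
    assert (again.its1, again.r58s, again.its2) == (part.its1, part.r58s, part.its2)


def test_region_partition_invariants():
    with pytest.raises(ValueError):
        RegionPartition(its1=(0, 0), r58s=(0, 10), its2=(10, 20))
    with pytest.raises(ValueError, match="contiguous"):
        RegionPartition(its1=(0, 5), r58s=(6, 10), its2=(10, 20))


# ---------------------------------------------------------------------------
# GC and summaries


@pytest.mark.parametrize("seq, expected", [
    ("GGCC", 100.0), ("ATAT", 0.0), ("ACGT", 50.0), ("ACGTN", 50.0),
])
def test_gc_percent(seq, expected):
    assert gc_percent(seq) == expected


def test_gc_ambiguity_only_region_errors():
    with pytest.raises(ValueError, match="ambiguity"):
        gc_percent("NNNN")


def test_gc_reverse_complement_invariant(rng):
    for _ in range(25):
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(4, 60))))
        assert gc_percent(seq) == pytest.approx(gc_percent(reverse_complement(seq)))


def test_round_half_up_ties():
    assert round_half_up(53.85, 1) == 53.9
    assert round_half_up(53.25, 1) == 53.3  # banker's rounding would give 53.2


def _record_with_stats(seq_by_region, section="Formosae", rid="r"):
    seq = "".join(seq_by_region)
    n1, n2 = len(seq_by_region[0]), len(seq_by_region[1])
    rec = ItsRecord(id=rid, section=section, seq=seq)
    rec.regions = RegionPartition((0, n1), (n1, n1 + n2), (n1 + n2, len(seq)))
    return rec


def test_region_stats_lengths_sum():
    rec = _record_with_stats(["ATAT" * 40, "GCGC" * 40, "ACGT" * 40])
    st = region_stats(rec)
    assert st.lengths["ITS"] == sum(st.lengths[r] for r in ("ITS1", "5.8S", "ITS2"))
    assert st.gc == {"ITS": 50.0, "ITS1": 0.0, "5.8S": 100.0, "ITS2": 50.0}


def test_summarize_sections_single_and_mean():
    recs = [
        _record_with_stats(["ATAT" * 10, "GC" * 40, "ACGT" * 10], rid="a"),  # ITS1 gc 0
        _record_with_stats(["ATGC" * 10, "GC" * 40, "ACGT" * 10], rid="b"),  # ITS1 gc 50
        _record_with_stats(["GCGC" * 10, "GC" * 40, "ACGT" * 10], rid="c"),  # ITS1 gc 100
    ]
    stats = [region_stats(r) for r in recs]
    summary = summarize_sections(recs, stats)
    row = summary[(summary.section == "Formosae") & (summary.region == "ITS1")].iloc[0]
    assert row.mean_gc == 50.0
    assert (row.min_length, row.max_length) == (40, 40)
    one = summarize_sections(recs[:1], stats[:1])
    its = one[one.region == "ITS"].iloc[0]
    assert its.min_length == its.max_length == stats[0].lengths["ITS"]
    assert its.mean_gc == stats[0].gc["ITS"]


def test_stats_table_columns():
    rec = _record_with_stats(["ATAT" * 10, "GC" * 40, "ACGT" * 10])
    table = stats_table([rec], [region_stats(rec)])
    assert list(table.columns[3:7]) == ["len_ITS", "len_ITS1", "len_5.8S", "len_ITS2"]


def test_trim_primer_tails_noop_without_match(rng):
    seq = "".join(rng.choice(list("ACGT"), size=100))
    trimmed, offset = trim_primer_tails(seq, ("GGGGGGGGGGGGGGGGGGGGGGG",
                                              "CCCCCCCCCCCCCCCCCCCCCCC"))
    assert offset == 0 and len(trimmed) <= len(seq)
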