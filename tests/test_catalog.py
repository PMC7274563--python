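"""polySeq construction, family assignment, naming and abundance."""

import numpy as np
import pytest

from tandemkit import catalog as cat
from tandemkit.consensus import derive_consensus
from tandemkit.detect import detect_read, offset_histogram
from tandemkit.selfalign import seed_matches
from tandemkit.seqio import LongRead
from tandemkit.synth import mutate, random_monomer

from conftest import random_dna


@pytest.fixture(scope="module")
def six_family_catalog():
    units = [60, 120, 225, 335, 450, 600]
    return cat.build_polyseq(
        [dict(name=cat.family_name(u), consensus=random_monomer(u, 0.6, 500 + u))
         for u in units]
    )


def test_make_block_sizes(monomer120):
    assert len(cat.make_block(monomer120)) == 1000
    assert cat.make_block(monomer120) == (monomer120 * 9)[:1000]
    big = random_monomer(600, 0.6, 2)
    assert len(cat.make_block(big)) == 2000  # large units get 2-kb blocks
    with pytest.raises(ValueError):
        cat.make_block("")


def test_build_polyseq_offsets_and_append_stability():
    fams = [dict(name=f"F{i}", consensus=random_monomer(100, 0.5, i)) for i in range(4)]
    ps = cat.build_polyseq(fams)
    assert len(ps.sequence) == 4000
    assert [f.block_start for f in ps.families] == [0, 1000, 2000, 3000]
    assert [f.block_offset_kb for f in ps.families] == [0, 1, 2, 3]
    before = [(f.name, f.block_start) for f in ps.families]
    ps2 = cat.build_polyseq(fams + [dict(name="F4", consensus=random_monomer(100, 0.5, 9))])
    assert [(f.name, f.block_start) for f in ps2.families[:4]] == before
    with pytest.raises(ValueError):
        cat.build_polyseq([dict(name="X", consensus="ACGT" * 30)] * 2)


def test_polyseq_mixed_block_sizes():
    fams = [dict(name=f"S{i}", consensus=random_monomer(100, 0.5, 20 + i))
            for i in range(33)]
    fams.append(dict(name="L", consensus=random_monomer(600, 0.6, 60)))
    ps = cat.build_polyseq(fams)
    assert len(ps.sequence) == 35_000


def test_polyseq_no_cross_block_similarity(six_family_catalog):
    """Blocks self-match internally but show no similarity between families."""
    ps = six_family_catalog
    ms = seed_matches(ps.sequence, ps.sequence, word=10, both_strands=False,
                      query_id="ps", target_id="ps")
    blocks = [(f.block_start, f.block_end) for f in ps.families]

    def block_of(pos):
        for i, (s, e) in enumerate(blocks):
            if s <= pos < e:
                return i
        return -1

    def mid_blocks(m):  # classify a match by its midpoints
        return (block_of(m.q_start + m.length // 2),
                block_of(m.t_start + m.length // 2))

    off = [m for m in ms.matches if m.t_start > m.q_start]
    cross = [m for m in off if mid_blocks(m)[0] != mid_blocks(m)[1]]
    within = [m for m in off if mid_blocks(m)[0] == mid_blocks(m)[1]]
    # chance 10-mers only between blocks; dense periodic structure within
    assert sum(m.length for m in cross) < 0.05 * sum(m.length for m in within)
    assert sum(m.length for m in within) > 10_000


def test_assign_read_recovers_family(six_family_catalog):
    ps = six_family_catalog
    fam = ps.families[1]  # the 120-bp family
    noisy = mutate(fam.consensus * 50, 0.02, 0.015, 0.015, 31)
    read = LongRead("q", "q", noisy)
    regions, _ = detect_read(read)
    asg = cat.assign_read(read, regions, ps)
    assert asg and asg[0].family_name == fam.name
    assert asg[0].block_offset_kb == fam.block_offset_kb
    assert asg[0].match_fraction > 0.9


def test_assign_read_combo_two_blocks(six_family_catalog):
    ps = six_family_catalog
    f1, f2 = ps.families[1], ps.families[2]
    rng = np.random.default_rng(8)
    seq = (random_dna(rng, 500) + f1.consensus * 10 + random_dna(rng, 1500)
           + f2.consensus * 6 + random_dna(rng, 500))
    read = LongRead("q", "q", seq)
    regions, _ = detect_read(read)
    asg = cat.assign_read(read, regions, ps)
    assert {a.family_name for a in asg} == {f1.name, f2.name}


def test_assign_read_novel_is_new(six_family_catalog):
    novel = random_monomer(300, 0.6, 999)
    read = LongRead("q", "q", novel * 20)
    regions, _ = detect_read(read)
    asg = cat.assign_read(read, regions, six_family_catalog)
    assert [a.family_name for a in asg] == [cat.NEW_FAMILY]


def test_assign_random_read_gets_nothing(six_family_catalog):
    read = LongRead("q", "q", random_dna(np.random.default_rng(77), 6000))
    regions, _ = detect_read(read)
    assert cat.assign_read(read, regions, six_family_catalog) == []


def test_register_new_family_and_idempotence():
    ps = cat.PolySeq()
    mono = random_monomer(120, 0.6, 479)
    read = LongRead("r479", "r479", mono * 12)
    regions, _ = detect_read(read)
    reg = [r for r in regions if not r.low_complexity][0]
    unit = derive_consensus(read, reg, reg.period_bp)
    ps, fam = cat.register_new_family(ps, read, reg, unit)
    assert fam.name == "HuluTR120" and fam.block_start == 0
    assert fam.discovery_read == "r479"
    # second distinct family appends after the first
    mono2 = random_monomer(225, 0.6, 91)
    read2 = LongRead("r91", "r91", mono2 * 8)
    regions2, _ = detect_read(read2)
    reg2 = [r for r in regions2 if not r.low_complexity][0]
    unit2 = derive_consensus(read2, reg2, reg2.period_bp)
    ps, fam2 = cat.register_new_family(ps, read2, reg2, unit2)
    assert fam2.block_start == 1000
    # re-registering the same consensus returns the existing family
    n_before = len(ps.families)
    ps, fam3 = cat.register_new_family(ps, read, reg, unit)
    assert fam3 is fam and len(ps.families) == n_before


def test_family_name_rules():
    assert cat.family_name(120, read_id="r479") == "HuluTR120-r479"
    assert cat.family_name(60) == "HuluTR060"
    assert cat.family_name(55) == "HuluTR055"
    assert cat.family_name(120, taken=["HuluTR120"]) == "HuluTR120b"
    with pytest.raises(ValueError):
        cat.family_name(0)


def test_abundance_table():
    def asg(read_id, fam):
        return cat.FamilyAssignment(read_id, None, fam, 0, 1.0)

    assignments = [asg(f"r{i}", "HuluTR120") for i in range(72)]
    assignments += [asg("x1", "HuluTR225"), asg("x1", cat.NEW_FAMILY)]
    df = cat.abundance_table(assignments, 1_037_871)
    row = df.set_index("family").loc["HuluTR120"]
    assert row["n_reads"] == 72 and row["reads_per_million"] == 69
    assert cat.abundance_table([asg("a", "F")], 1_000_000).iloc[0]["reads_per_million"] == 1
    assert cat.NEW_FAMILY not in set(df["family"])
    with pytest.raises(ValueError):
        cat.abundance_table(assignments, 0)


def test_polyseq_round_trip(tmp_path, six_family_catalog):
    ps = six_family_catalog
    ps.to_json(tmp_path / "cat.json")
    back = cat.PolySeq.from_json(tmp_path / "cat.json")
    assert back.sequence == ps.sequence
    assert [f.name for f in back.families] == [f.name for f in ps.families]
    ps.write(tmp_path / "ps.fasta", tmp_path / "ps.tsv")
    assert (tmp_path / "ps.fasta").read_text().startswith(">polySeq6")


def test_known_families_seed_catalog():
    ps = cat.build_polyseq(cat.known_families())
    names = [f.name for f in ps.families]
    assert names == ["Telo", "HuluTR180", "HuluTR385", "HuluTR335"]
    aliases = [f.known_alias for f in ps.families]
    assert aliases == ["telomere", "HSR0", "HSR1", "5SrDNA"]
    assert ps.families[0].consensus == "CCCTAAA"
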