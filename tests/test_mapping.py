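import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import satscan as ss
from satscan._seq import revcomp
from satscan.genome import ConfigurationError
from satscan.mapping import averaged_coverage_ratio, karlin_lambda

from conftest import mutate_seq, random_seq


def make_genome(focal_seq, bg_seq="ACGT" * 300):
    return ss.GenomeSet(
        focal=[ss.Chromosome("X", focal_seq)],
        background=[ss.Chromosome("A", bg_seq)],
    )


def test_karlin_lambda_solves_scoring_distribution():
    lam = karlin_lambda()
    assert 0.25 * np.exp(lam) + 0.75 * np.exp(-2 * lam) == pytest.approx(1.0)


def test_verbatim_monomer_found_once_at_full_identity():
    rng = np.random.default_rng(101)
    monomer = ss.Monomer("m", random_seq(rng, 359), 0)
    flank_a, flank_b = random_seq(rng, 50_000), random_seq(rng, 49_641)
    genome = make_genome(flank_a + monomer.consensus + flank_b)
    hits = ss.search(monomer, genome)
    assert len(hits) == 1
    hit = hits[0]
    assert (hit.chrom, hit.start, hit.end) == ("X", 50_000, 50_359)
    assert hit.identity == pytest.approx(1.0)
    assert hit.strand == "+"
    assert hit.evalue < 1e-4


def test_reverse_complement_found_on_minus_strand():
    rng = np.random.default_rng(103)
    monomer = ss.Monomer("m", random_seq(rng, 200), 0)
    genome = make_genome(
        random_seq(rng, 5000) + revcomp(monomer.consensus) + random_seq(rng, 5000)
    )
    hits = ss.search(monomer, genome)
    assert len(hits) == 1
    assert hits[0].strand == "-"
    assert hits[0].identity == pytest.approx(1.0)


def test_divergent_copies_recovered():
    """>= 95% of copies at 10% divergence are overlapped by a hit."""
    rng = np.random.default_rng(107)
    monomer = random_seq(rng, 359)
    parts, intervals, cursor = [], [], 0
    for _ in range(40):
        gap = random_seq(rng, int(rng.integers(500, 2000)))
        parts.append(gap)
        cursor += len(gap)
        copy = mutate_seq(rng, monomer, 0.10)
        parts.append(copy)
        intervals.append((cursor, cursor + len(copy)))
        cursor += len(copy)
    genome = make_genome("".join(parts))
    hits = ss.search(ss.Monomer("m", monomer, 0), genome)
    overlapped = sum(
        any(h.start < e and h.end > s for h in hits) for s, e in intervals
    )
    assert overlapped >= 0.95 * len(intervals)


def test_no_hits_on_pure_background():
    """E < 1e-4 yields zero hits on random sequence in >= 19/20 replicates,
    and hit counts are monotone in the E-value threshold."""
    zero_runs = 0
    for i in range(20):
        rng = np.random.default_rng(200 + i)
        monomer = ss.Monomer("m", random_seq(rng, 359), 0)
        genome = make_genome(random_seq(rng, 20_000), random_seq(rng, 1000))
        strict = ss.search(monomer, genome, evalue_threshold=1e-4)
        loose = ss.search(monomer, genome, evalue_threshold=1e-1)
        assert len(loose) >= len(strict)
        zero_runs += len(strict) == 0
    assert zero_runs >= 19


def test_monomer_shorter_than_seed_is_configuration_error():
    with pytest.raises(ConfigurationError):
        ss.search(ss.Monomer("m", "ACGTACG", 0), make_genome("ACGT" * 100))


def test_coverage_percent_arithmetic():
    genome = make_genome("A" * 100_000, "C" * 50_000)
    hits = [ss.SatelliteHit("X", 1000, 4590, "+", 1.0, 100, 1e-9, "h1")]
    table = ss.coverage(hits, genome)
    x = table.rows.set_index("chrom")
    assert x.loc["X", "percent"] == pytest.approx(3.59)
    assert table.ratio is None  # background uncovered, flagged
    assert table.skipped_background == ["A"]


def test_coverage_union_rule():
    genome = make_genome("A" * 1000, "C" * 1000)
    hits = [
        ss.SatelliteHit("X", 100, 200, "+", 1.0, 50, 1e-9, "h1"),
        ss.SatelliteHit("X", 150, 300, "+", 1.0, 50, 1e-9, "h2"),
    ]
    table = ss.coverage(hits, genome)
    assert table.rows.set_index("chrom").loc["X", "covered_bp"] == 200


def test_coverage_hit_beyond_chromosome_end():
    genome = make_genome("A" * 100, "C" * 100)
    with pytest.raises(ValueError, match="beyond"):
        ss.coverage([ss.SatelliteHit("X", 50, 150, "+", 1.0, 10, 1e-9)], genome)


def test_footnote_averaged_ratio():
    """Focal percent 2.91 against background percents 0.41/0.06/0.03/0.11
    averages to ~45 under the per-comparison rule."""
    ratio = averaged_coverage_ratio(2.91, [0.41, 0.06, 0.03, 0.11])
    assert ratio == pytest.approx(44.77, abs=0.01)
    assert round(ratio) == 45


def test_group_loci_examples():
    def hit(s, e):
        return ss.SatelliteHit("X", s, e, "+", 1.0, 10, 1e-9, f"h{s}")

    two = ss.group_loci([hit(1000, 1500), hit(5000, 5400)])
    assert len(two) == 2

    chained = ss.group_loci([hit(0, 400), hit(900, 1300), hit(2200, 2600)])
    assert len(chained) == 1
    assert (chained[0].span_start, chained[0].span_end) == (0, 2600)

    single = ss.group_loci([hit(10, 20)])
    assert len(single) == 1 and single[0].members == ["h10"]


def brute_force_loci(intervals, max_gap):
    """Transitive-closure oracle: hits are in one locus iff connected by a
    chain of pairs within max_gap."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(n):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            gap = max(s1, s2) - min(e1, e2)
            if gap <= max_gap:
                parent[find(i)] = find(j)
    return {frozenset(k for k in range(n) if find(k) == r)
            for r in {find(i) for i in range(n)}}


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 30_000), st.integers(1, 800)),
        min_size=1, max_size=25,
    )
)
def test_group_loci_matches_transitive_closure(raw):
    intervals = [(s, s + ln) for s, ln in raw]
    hits = [
        ss.SatelliteHit("X", s, e, "+", 1.0, 10, 1e-9, f"h{i}")
        for i, (s, e) in enumerate(intervals)
    ]
    loci = ss.group_loci(hits, max_gap=1000)
    ours = {frozenset(int(m[1:]) for m in l.members) for l in loci}
    assert ours == brute_force_loci(intervals, 1000)


def test_group_loci_order_and_translation_invariant():
    rng = np.random.default_rng(109)
    starts = np.sort(rng.choice(50_000, 30, replace=False))
    hits = [
        ss.SatelliteHit("X", int(s), int(s) + 300, "+", 1.0, 10, 1e-9, f"h{i}")
        for i, s in enumerate(starts)
    ]
    base = {frozenset(l.members) for l in ss.group_loci(hits)}
    rng.shuffle(hits)
    shuffled = {frozenset(l.members) for l in ss.group_loci(hits)}
    assert base == shuffled
    moved = [
        ss.SatelliteHit(h.chrom, h.start + 7777, h.end + 7777, h.strand,
                        h.identity, h.score, h.evalue, h.id)
        for h in hits
    ]
    assert {frozenset(l.members) for l in ss.group_loci(moved)} == base


def test_planted_density_ratio_recovered(default_sim, default_hits):
    """The focal:background coverage ratio estimate is within 25% of the
    planted truth on generator defaults."""
    cfg, genome, _, truth = default_sim
    table = ss.coverage(default_hits, genome)
    planted = {c.name: truth.planted_bp(c.name) for c in genome.chromosomes}
    focal_pct = 100 * planted["X"] / cfg.focal_length
    truth_ratio = np.mean([
        focal_pct / (100 * planted[name] / length)
        for name, length in zip(cfg.background_names, cfg.background_lengths)
    ])
    assert table.ratio == pytest.approx(truth_ratio, rel=0.25)
    # chromosome-level coverage within 10% of planted truth
    covered = dict(zip(table.rows.chrom, table.rows.covered_bp))
    assert covered["X"] == pytest.approx(planted["X"], rel=0.10)
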