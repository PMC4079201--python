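import itertools

import numpy as np
import pytest

import satscan as ss
from satscan.io import genome_to_fasta, write_recomb_map


SMALL = dict(
    focal_length=250_000, background_lengths=(150_000,),
    n_loci_focal=4, n_loci_background=1,
)


def within_distances(genome, truth, max_pairs_per_locus=10):
    out = []
    for locus in truth.loci:
        seq = genome.get(locus.chrom).sequence
        pairs = itertools.islice(
            itertools.combinations(locus.copies, 2), max_pairs_per_locus
        )
        for c1, c2 in pairs:
            a, b = seq[c1.start : c1.end], seq[c2.start : c2.end]
            out.append(np.mean([x != y for x, y in zip(a, b)]))
    return out


def test_seeded_runs_are_byte_identical(tmp_path):
    outputs = []
    for run in ("a", "b"):
        genome, rmap, _ = ss.simulate_genome(ss.SimConfig(seed=77, **SMALL))
        fasta = tmp_path / f"{run}.fasta"
        tsv = tmp_path / f"{run}.tsv"
        genome_to_fasta(genome, fasta)
        write_recomb_map(rmap, tsv)
        outputs.append((fasta.read_bytes(), tsv.read_bytes()))
    assert outputs[0] == outputs[1]


def test_ground_truth_structure():
    cfg = ss.SimConfig(seed=5, **SMALL)
    genome, rmap, truth = ss.simulate_genome(cfg)
    assert len(truth.loci_on("X")) == 4
    # planted copies are traceable, non-overlapping, and match the genome
    intervals = sorted((c.start, c.end) for c in truth.copies if c.chrom == "X")
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        assert e1 <= s2
    locus = truth.loci_on("X")[0]
    seq = genome.get("X").sequence
    copy = locus.copies[0]
    planted = seq[copy.start : copy.end]
    # the copy differs from the founder exactly at its recorded sites
    diffs = {i for i, (a, b) in enumerate(zip(planted, locus.founder)) if a != b}
    assert diffs == set(copy.mutated_sites)
    # map windows tile each chromosome at the configured window size
    assert rmap.mean_rate("X", 0, cfg.focal_length) is not None


def test_full_homogenization_makes_same_locus_copies_identical():
    cfg = ss.SimConfig(seed=13, homogenization=1.0, **SMALL)
    genome, _, truth = ss.simulate_genome(cfg)
    assert max(within_distances(genome, truth)) == 0.0
    # between-locus divergence persists
    l1, l2 = truth.loci_on("X")[:2]
    founder_dist = np.mean([a != b for a, b in zip(l1.founder, l2.founder)])
    assert founder_dist > 0


def test_no_homogenization_matches_closed_form_distance():
    """At h = 0 the expected within-locus distance equals the closed-form
    pairwise substitution distance 2u(1-u) + (2/3)u^2."""
    mu = 0.05
    expected = 2 * mu * (1 - mu) + (2 / 3) * mu**2
    dists = []
    for seed in range(4):
        cfg = ss.SimConfig(seed=900 + seed, homogenization=0.0,
                           copy_mutation_rate=mu, **SMALL)
        genome, _, truth = ss.simulate_genome(cfg)
        dists.extend(within_distances(genome, truth))
    assert np.mean(dists) == pytest.approx(expected, rel=0.10)


def test_homogenization_monotonically_reduces_within_distance():
    means = []
    for h in (0.0, 0.5, 1.0):
        per_seed = []
        for seed in range(3):
            cfg = ss.SimConfig(seed=600 + seed, homogenization=h, **SMALL)
            genome, _, truth = ss.simulate_genome(cfg)
            per_seed.append(np.mean(within_distances(genome, truth)))
        means.append(np.mean(per_seed))
    assert means[0] > means[1] > means[2]


def test_zero_slope_places_loci_uniformly():
    """With b = 0, planted locus counts are uniform over equal-rate windows
    (chi-square goodness of fit rarely rejects)."""
    from scipy.stats import chisquare

    passes = 0
    n_runs = 20
    for seed in range(n_runs):
        cfg = ss.SimConfig(
            seed=700 + seed, focal_length=1_000_000, background_lengths=(250_000,),
            n_loci_focal=24, n_loci_background=1, density_b=0.0,
            copies_min=3, copies_max=6,
        )
        _, _, truth = ss.simulate_genome(cfg)
        counts = np.zeros(4)
        for locus in truth.loci_on("X"):
            counts[locus.start // 250_000] += 1
        if chisquare(counts).pvalue > 0.01:
            passes += 1
    assert passes >= 0.9 * n_runs


def test_positive_slope_biases_loci_toward_high_rate_windows():
    placed_rates, genome_rates = [], []
    for seed in range(5):
        cfg = ss.SimConfig(seed=800 + seed)
        _, _, truth = ss.simulate_genome(cfg)
        rates = truth.window_rates["X"]
        genome_rates.extend(rates)
        placed_rates.extend(
            rates[l.start // cfg.window] for l in truth.loci_on("X")
        )
    assert np.mean(placed_rates) > np.mean(genome_rates)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        ss.SimConfig(focal_length=0)
    with pytest.raises(ValueError):
        ss.SimConfig(between_locus_divergence=0.5)
    with pytest.raises(ValueError):
        ss.SimConfig(homogenization=1.5)
    with pytest.raises(ValueError):
        ss.simulate_genome(ss.SimConfig(monomer="ACGTN" * 40))


def test_overcrowded_chromosome_raises():
    cfg = ss.SimConfig(seed=1, focal_length=40_000,
                       background_lengths=(40_000,), n_loci_focal=8,
                       n_loci_background=0)
    with pytest.raises(RuntimeError, match="crowded"):
        ss.simulate_genome(cfg)


def test_truth_eval_perfect_outputs(default_sim):
    _, genome, _, truth = default_sim
    clusters = [
        ss.SatelliteCluster(l.chrom, l.start, l.end, 100.0, 50.0)
        for l in truth.loci
    ]
    called_loci = [
        ss.Locus(f"L{i}", l.chrom, [c.locus_id for c in l.copies],
                 l.start, l.end)
        for i, l in enumerate(truth.loci)
    ]
    covered = {}
    for l in truth.loci:
        covered[l.chrom] = covered.get(l.chrom, 0) + (l.end - l.start)
    fit = ss.ExponentialFit("hits", -4.56, 2.14, 0.1, 0.1, 100, "poisson")
    report = ss.truth_eval(
        truth, clusters=clusters, estimated_period=len(truth.monomer),
        called_loci=called_loci, covered_bp=covered, fit=fit,
        true_coefficients=(-4.56, 2.14),
    )
    assert report.cluster_recall == 1.0
    assert report.cluster_precision == 1.0
    assert report.period_error == 0
    assert report.locus_accuracy == 1.0
    assert report.coverage_relative_error == 0.0
    assert report.fit_intercept_error == 0.0 and report.fit_slope_error == 0.0
    assert report.flags == []


def test_truth_eval_empty_outputs_flagged(default_sim):
    _, _, _, truth = default_sim
    report = ss.truth_eval(truth, clusters=[], called_loci=[],
                           covered_bp={"X": 0})
    assert report.cluster_recall == 0.0
    assert report.locus_accuracy == 0.0
    assert "no clusters called" in report.flags
    assert "no coverage recovered" in report.flags


def test_pipeline_recall_on_defaults(default_sim, default_profile):
    """End-to-end: clusters called on generator defaults recover >= 0.9 of
    planted focal arrays."""
    _, genome, _, truth = default_sim
    clusters = ss.call_clusters(default_profile, chromosome=genome.focal[0])
    focal_truth = ss.GroundTruth(
        truth.seed, truth.monomer, truth.loci_on("X"), truth.window_rates
    )
    report = ss.truth_eval(focal_truth, clusters=clusters)
    assert report.cluster_recall >= 0.9
    assert report.cluster_precision >= 0.9
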