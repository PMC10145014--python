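"""Chi-squared machinery and the four distribution analyses."""

import math

import numpy as np
import pytest
from scipy import stats

from hfscan.enrichment import (
    bonferroni,
    chi2_gof,
    distance_enrichment,
    neighbor_distances,
    region_enrichment,
    scaffold_enrichment,
    window_enrichment,
)
from hfscan.annotation import derive_regions
from hfscan.hf_host import HostHF
from hfscan.intervals import GenomicInterval, ScaffoldLengths
from hfscan.synthetic_data import generate_gene_annotation, generate_host_genome, scaffold_lengths_of


def hf(sc, start, end, hf_id="", viruses=("v1",), bit=100.0):
    return HostHF(
        hf_id=hf_id or f"{sc}:{start}",
        interval=GenomicInterval(sc, start, end),
        supporting_alignments=[],
        best_evalue=1e-20,
        best_bit_score=bit,
        virus_ids=frozenset(viruses),
    )


def test_perfect_fit_gives_zero_statistic():
    chi2, p = chi2_gof(5, 5.0, 10, 10.0)
    assert chi2 == 0 and p == 1.0


def test_twofold_excess_closed_form():
    chi2, p = chi2_gof(10, 5.0, 10, 10.0)
    assert chi2 == pytest.approx(10.0)
    assert p == pytest.approx(1.565e-3, rel=1e-3)


def test_symmetric_depletion_same_statistic():
    chi2, p = chi2_gof(0, 5.0, 10, 10.0)
    assert chi2 == pytest.approx(10.0)
    assert p == pytest.approx(1.565e-3, rel=1e-3)


def test_zero_expected_cell_is_an_error():
    with pytest.raises(ValueError, match="drop or pool"):
        chi2_gof(1, 0.0, 10, 10.0)
    with pytest.raises(ValueError):
        chi2_gof(1, 10.0, 10, 10.0)  # rest-expected cell is 0


def test_pvalues_match_independent_chi2_tail():
    # independent oracle: survival function via the regularized gamma function
    from scipy.special import gammaincc

    for o in range(0, 30):
        for e in (0.5, 1.0, 3.7, 10.0, 25.0):
            total_o, total_e = 40, 40.0
            if total_e - e <= 0:
                continue
            chi2, p = chi2_gof(o, e, total_o, total_e)
            assert p == pytest.approx(float(gammaincc(0.5, chi2 / 2.0)), abs=1e-10)


def test_bonferroni_is_clipped_product():
    assert bonferroni([0.01]) == [0.01]
    assert bonferroni([0.01, 0.02, 0.5]) == pytest.approx([0.03, 0.06, 1.0])
    rng = np.random.default_rng(0)
    ps = rng.uniform(size=100)
    assert bonferroni(list(ps)) == pytest.approx(np.minimum(1.0, 100 * ps))
    with pytest.raises(ValueError):
        bonferroni([1.5])


def test_two_scaffold_all_on_one_is_enriched():
    lengths = ScaffoldLengths({"A": 100_000, "B": 100_000})
    hfs = [hf("A", i * 1000, i * 1000 + 100) for i in range(10)]
    res = scaffold_enrichment(hfs, lengths)
    a = next(r for r in res if r.unit_id == "A")
    b = next(r for r in res if r.unit_id == "B")
    assert a.chi2 == pytest.approx(10.0)
    assert a.enriched and not b.tested  # B has 0 observed -> untested
    assert a.p_adj == pytest.approx(min(1.0, a.p * 1))  # family = tested scaffolds


def test_proportional_distribution_no_enrichment():
    lengths = ScaffoldLengths({"A": 100_000, "B": 300_000})
    hfs = [hf("A", i * 100, i * 100 + 50) for i in range(5)] + [
        hf("B", i * 100, i * 100 + 50) for i in range(15)
    ]
    res = scaffold_enrichment(hfs, lengths)
    for r in res:
        assert r.chi2 == pytest.approx(0.0)
        assert not r.enriched


def test_expected_counts_sum_to_total_over_partition():
    lengths = ScaffoldLengths({"A": 137_000, "B": 63_000, "C": 250_000})
    rng = np.random.default_rng(1)
    hfs = []
    for sc in lengths:
        for _ in range(rng.integers(2, 20)):
            s = int(rng.integers(0, lengths[sc] - 200))
            hfs.append(hf(sc, s, s + 100))
    res = scaffold_enrichment(hfs, lengths)
    assert sum(r.expected for r in res) == pytest.approx(len(hfs), rel=1e-9)
    win = window_enrichment(hfs, lengths, window=50_000)
    total_expected = len(hfs) * sum(
        lengths[sc] for sc in lengths if any(h.interval.seq_id == sc for h in hfs)
    ) / lengths.genome_length
    assert sum(r.expected for r in win) == pytest.approx(total_expected, rel=1e-9)


def test_neighbor_distances_gap_definition():
    hfs = [hf("A", 100, 200), hf("A", 1150, 1300)]
    assert neighbor_distances(hfs) == [950]
    assert neighbor_distances([hf("A", 0, 50)]) == []
    # overlapping neighbours yield distance 0
    assert neighbor_distances([hf("A", 0, 100), hf("A", 50, 150)]) == [0]


def test_neighbor_distances_match_sort_scan_oracle():
    rng = np.random.default_rng(2)
    hfs = []
    for sc in ("A", "B", "C"):
        for _ in range(70):
            s = int(rng.integers(0, 500_000))
            hfs.append(hf(sc, s, s + int(rng.integers(30, 280))))
    rng.shuffle(hfs)
    got = sorted(neighbor_distances(hfs))
    oracle = []
    for sc in ("A", "B", "C"):
        ivs = sorted(
            (h.interval.start, h.interval.end) for h in hfs if h.interval.seq_id == sc
        )
        oracle.extend(max(0, b[0] - a[1]) for a, b in zip(ivs, ivs[1:]))
    assert got == sorted(oracle)


def test_distance_null_is_deterministic_under_seed():
    lengths = ScaffoldLengths({"A": 200_000, "B": 200_000})
    rng = np.random.default_rng(3)
    hfs = [hf("A", int(s), int(s) + 100) for s in rng.integers(0, 199_000, size=30)]
    r1 = distance_enrichment(hfs, lengths, n_sim=5, seed=42)
    r2 = distance_enrichment(hfs, lengths, n_sim=5, seed=42)
    assert [(a.expected, a.p) for a in r1] == [(b.expected, b.p) for b in r2]


def test_window_scan_flags_the_loaded_window():
    lengths = ScaffoldLengths({"A": 200_000})
    hfs = [hf("A", 1000 + i * 500, 1000 + i * 500 + 100) for i in range(20)]
    res = window_enrichment(hfs, lengths, window=100_000)
    first = next(r for r in res if r.unit_id.startswith("A:0-"))
    second = next(r for r in res if r.unit_id.startswith("A:100000-"))
    assert first.enriched
    assert second.observed == 0 and not second.enriched


def test_scaffold_without_hfs_emits_no_windows():
    lengths = ScaffoldLengths({"A": 200_000, "B": 200_000})
    hfs = [hf("A", 1000, 1100)]
    res = window_enrichment(hfs, lengths, window=100_000)
    assert all(r.unit_id.startswith("A:") for r in res)


def test_window_reporting_filter():
    lengths = ScaffoldLengths({"A": 2_000_000, "B": 500_000})
    hfs = [hf("A", i * 1000, i * 1000 + 100) for i in range(12)] + [
        hf("B", 1000, 1100)
    ]
    res = window_enrichment(
        hfs, lengths, window=100_000,
        min_hfs_per_scaffold=10, min_scaffold_length=1_000_000,
    )
    assert res and all(r.unit_id.startswith("A:") for r in res)


def test_region_enrichment_closed_forms():
    genome = generate_host_genome(1, [100_000], seed=7)
    genes = generate_gene_annotation(genome, 10, gene_length_range=(2000, 5000), seed=7)
    lengths = scaffold_lengths_of(genome)
    index = derive_regions(genes, lengths)
    # all HFs inside genes -> gene category strongly enriched
    inside = []
    for g in genes[:10]:
        inside.append(hf(g.scaffold, g.span.start + 10, g.span.start + 110))
    res = {r.unit_id: r for r in region_enrichment(inside, index)}
    g = res["gene"]
    ratio = index.category_base_counts["gene"] / index.genome_length
    e = ratio * 10
    expected_chi2 = (10 - e) ** 2 / e + (0 - (10 - e)) ** 2 / (10 - e)
    assert g.chi2 == pytest.approx(expected_chi2)
    assert g.enriched


def test_region_chi2_zero_when_observed_matches_base_fraction():
    # a synthetic two-cell case built directly on the formula
    chi2, p = chi2_gof(5, 5.0, 10, 10.0)
    assert chi2 == 0.0 and p == 1.0


def test_null_pvalues_approximately_uniform():
    """Under uniform placement, raw scaffold-test p-values are ~Uniform(0,1)."""
    # counts of 250 per cell keep the discrete p-value lattice finer than
    # the 0.05 KS budget (the exact KS of the lattice itself is ~0.036)
    lengths = ScaffoldLengths({"A": 500_000, "B": 500_000})
    rng = np.random.default_rng(8)
    pvals = []
    for _ in range(1000):
        n = 500
        scafs = rng.random(n) < 0.5
        placed = []
        for i in range(n):
            sc = "A" if scafs[i] else "B"
            s = int(rng.integers(0, 499_800))
            placed.append(hf(sc, s, s + 100))
        res = scaffold_enrichment(placed, lengths)
        pvals.extend(r.p for r in res if r.tested)
    ks = stats.kstest(pvals, "uniform").statistic
    assert ks < 0.05
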