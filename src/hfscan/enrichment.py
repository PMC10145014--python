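"""Distribution analyses of host HFs against uniform-placement nulls.

Four analyses are provided, each built from the same primitive: a
one-degree-of-freedom chi-squared goodness-of-fit test on the two-cell
partition (count in the tested unit, count in the rest of the genome)
against the expectation under uniform per-base placement.

* per-scaffold enrichment, Bonferroni-adjusted across tested scaffolds;
* neighbour-distance enrichment against a Monte-Carlo uniform null that
  preserves the observed HF lengths;
* fixed-width window scan (default 100 kb tiles), raw p per window;
* functional-region enrichment over the annotation categories.

Units whose expected count is below 1 are excluded from testing (and from
the Bonferroni family) but still reported, flagged untested: the chi-squared
approximation is unreliable there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .annotation import CATEGORIES, RegionIndex, classify_hf
from .hf_host import HostHF
from .intervals import ScaffoldLengths

DEFAULT_DISTANCE_BINS = (0, 1_000, 10_000, 100_000)
DEFAULT_WINDOW = 100_000
DEFAULT_N_SIM = 1000
MIN_EXPECTED = 1.0


@dataclass
class EnrichmentResult:
    """Observed vs expected counts and the test outcome for one unit."""

    unit_id: str
    observed: int
    expected: float
    chi2: float
    p: float
    p_adj: float | None
    enriched: bool
    depleted: bool = False
    tested: bool = True


def chi2_gof(
    observed: int, expected: float, total_observed: int, total_expected: float
) -> tuple[float, float]:
    """Two-cell 1-df goodness-of-fit of a unit count against its expectation.

    chi2 = (o-e)^2/e + ((O-o)-(E-e))^2/(E-e), p from the upper tail of the
    chi-squared distribution with 1 df; no continuity correction.
    """
    if expected <= 0:
        raise ValueError("expected cell is 0; drop or pool this unit before testing")
    rest_expected = total_expected - expected
    if rest_expected <= 0:
        raise ValueError("rest-of-genome expected cell is 0; cannot form 2-cell test")
    if total_observed < observed:
        raise ValueError("total_observed < observed")
    rest_observed = total_observed - observed
    chi2 = (observed - expected) ** 2 / expected + (
        rest_observed - rest_expected
    ) ** 2 / rest_expected
    return chi2, float(stats.chi2.sf(chi2, df=1))


def bonferroni(pvals: Sequence[float]) -> list[float]:
    """Family-wise adjustment p_adj = min(1, m * p)."""
    m = len(pvals)
    out = []
    for p in pvals:
        if not (0 <= p <= 1):
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, m * p))
    return out


def scaffold_enrichment(
    hfs: Sequence[HostHF],
    scaffold_lengths: ScaffoldLengths,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-scaffold HF enrichment with Bonferroni-adjusted p-values.

    Expected count per scaffold is proportional to scaffold length. Only
    scaffolds with at least one observed HF and expected >= 1 enter the
    test family; a scaffold is enriched iff adjusted p < alpha and
    observed > expected.
    """
    total = len(hfs)
    if total < 1:
        raise ValueError("need at least one HF")
    genome = scaffold_lengths.genome_length
    obs: dict[str, int] = {sc: 0 for sc in scaffold_lengths}
    for hf in hfs:
        obs[hf.interval.seq_id] += 1

    results: list[EnrichmentResult] = []
    tested_idx: list[int] = []
    for sc in sorted(scaffold_lengths):
        expected = total * scaffold_lengths[sc] / genome
        o = obs[sc]
        if o < 1 or expected < MIN_EXPECTED:
            results.append(
                EnrichmentResult(sc, o, expected, math.nan, math.nan, None, False,
                                 tested=False)
            )
            continue
        chi2, p = chi2_gof(o, expected, total, total)
        results.append(EnrichmentResult(sc, o, expected, chi2, p, None, False))
        tested_idx.append(len(results) - 1)

    adj = bonferroni([results[i].p for i in tested_idx])
    for i, pa in zip(tested_idx, adj):
        r = results[i]
        r.p_adj = pa
        r.enriched = pa < alpha and r.observed > r.expected
        r.depleted = pa < alpha and r.observed < r.expected
    return results


def neighbor_distances(hfs: Sequence[HostHF]) -> list[int]:
    """Gaps between consecutive HFs per scaffold (0 when overlapping).

    Cross-scaffold pairs are never counted; scaffolds with a single HF emit
    nothing.
    """
    by_sc: dict[str, list[HostHF]] = {}
    for hf in hfs:
        by_sc.setdefault(hf.interval.seq_id, []).append(hf)
    dists: list[int] = []
    for sc in sorted(by_sc):
        ordered = sorted(by_sc[sc], key=lambda h: (h.interval.start, h.interval.end))
        for a, b in zip(ordered, ordered[1:]):
            dists.append(max(0, b.interval.start - a.interval.end))
    return dists


def _bin_label(edges: Sequence[int], i: int) -> str:
    lo = edges[i]
    hi = edges[i + 1] if i + 1 < len(edges) else None
    return f"[{lo},{hi})" if hi is not None else f"[{lo},inf)"


def _bin_counts(dists: Sequence[int], edges: Sequence[int]) -> np.ndarray:
    full_edges = list(edges) + [np.inf]
    counts, _ = np.histogram(np.asarray(dists, dtype=float), bins=full_edges)
    return counts


def sample_uniform_intervals(
    lengths: Sequence[int],
    scaffold_lengths: ScaffoldLengths,
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    """Place fragments of the given lengths uniformly per-base on the genome.

    A fragment's scaffold is chosen with probability proportional to
    scaffold length; its start is uniform over positions where it fits.
    Fragments may overlap (the null does not forbid it).
    """
    scaffolds = sorted(scaffold_lengths)
    slens = np.array([scaffold_lengths[s] for s in scaffolds], dtype=float)
    probs = slens / slens.sum()
    out: list[tuple[str, int, int]] = []
    choices = rng.choice(len(scaffolds), size=len(lengths), p=probs)
    for length, ci in zip(lengths, choices):
        cap = int(slens[ci]) - length
        if cap < 0:  # fragment longer than scaffold: drop on a fitting scaffold
            fit = [i for i in range(len(scaffolds)) if slens[i] >= length]
            ci = fit[rng.integers(len(fit))]
            cap = int(slens[ci]) - length
        start = int(rng.integers(0, cap + 1))
        out.append((scaffolds[ci], start, start + length))
    return out


def _distances_of(placed: list[tuple[str, int, int]]) -> list[int]:
    by_sc: dict[str, list[tuple[int, int]]] = {}
    for sc, s, e in placed:
        by_sc.setdefault(sc, []).append((s, e))
    dists: list[int] = []
    for sc in by_sc:
        ivs = sorted(by_sc[sc])
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            dists.append(max(0, s2 - e1))
    return dists


def distance_enrichment(
    hfs: Sequence[HostHF],
    scaffold_lengths: ScaffoldLengths,
    bins: Sequence[int] = DEFAULT_DISTANCE_BINS,
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Neighbour-distance bin enrichment against a Monte-Carlo uniform null.

    The null keeps the number and lengths of the observed HFs and resamples
    their positions uniformly per-base across the genome ``n_sim`` times;
    the expected per-bin ratio is the pooled bin fraction across
    simulations. The run is reproducible under a fixed seed.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if list(bins) != sorted(bins) or bins[0] != 0:
        raise ValueError("bins must be ascending and start at 0")
    obs_d = neighbor_distances(hfs)
    obs_counts = _bin_counts(obs_d, bins)
    n_obs = len(obs_d)

    rng = np.random.default_rng(seed)
    lengths = [hf.length for hf in hfs]
    sim_counts = np.zeros(len(bins), dtype=float)
    sim_total = 0
    for _ in range(n_sim):
        placed = sample_uniform_intervals(lengths, scaffold_lengths, rng)
        d = _distances_of(placed)
        sim_counts += _bin_counts(d, bins)
        sim_total += len(d)
    ratios = sim_counts / sim_total if sim_total else np.zeros(len(bins))

    results: list[EnrichmentResult] = []
    for i in range(len(bins)):
        label = _bin_label(bins, i)
        expected = float(ratios[i] * n_obs)
        o = int(obs_counts[i])
        if expected < MIN_EXPECTED or n_obs == 0:
            results.append(
                EnrichmentResult(label, o, expected, math.nan, math.nan, None, False,
                                 tested=False)
            )
            continue
        chi2, p = chi2_gof(o, expected, n_obs, n_obs)
        results.append(
            EnrichmentResult(
                label, o, expected, chi2, p, None,
                enriched=p < alpha and o > expected,
                depleted=p < alpha and o < expected,
            )
        )
    return results


def window_enrichment(
    hfs: Sequence[HostHF],
    scaffold_lengths: ScaffoldLengths,
    window: int = DEFAULT_WINDOW,
    step: int | None = None,
    alpha: float = 0.01,
    min_hfs_per_scaffold: int = 0,
    min_scaffold_length: int = 0,
) -> list[EnrichmentResult]:
    """Fixed-width window scan; raw p per window (no multiplicity adjustment).

    Windows tile each scaffold (default step = window, i.e. disjoint tiles;
    a smaller step multiply-counts HFs and is flagged in the unit id). An HF
    is assigned to the window containing its midpoint. The optional
    reporting filter restricts output to scaffolds with at least
    ``min_hfs_per_scaffold`` HFs and length above ``min_scaffold_length``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    step = window if step is None else step
    if not (0 < step <= window):
        raise ValueError("step must satisfy 0 < step <= window")
    sliding = step < window
    total = len(hfs)
    genome = scaffold_lengths.genome_length

    per_sc: dict[str, list[int]] = {}
    for hf in hfs:
        per_sc.setdefault(hf.interval.seq_id, []).append(
            (hf.interval.start + hf.interval.end) // 2
        )

    results: list[EnrichmentResult] = []
    for sc in sorted(scaffold_lengths):
        slen = scaffold_lengths[sc]
        mids = per_sc.get(sc, [])
        if len(mids) < min_hfs_per_scaffold or slen <= min_scaffold_length:
            continue
        if not mids:
            continue  # no tests for scaffolds without HFs
        start = 0
        while start < slen:
            end = min(start + window, slen)
            span = end - start
            o = sum(start <= m < end for m in mids)
            expected = total * span / genome
            label = f"{sc}:{start}-{end}" + ("(sliding)" if sliding else "")
            if expected < MIN_EXPECTED:
                results.append(
                    EnrichmentResult(label, o, expected, math.nan, math.nan, None,
                                     False, tested=False)
                )
            else:
                chi2, p = chi2_gof(o, expected, total, total)
                results.append(
                    EnrichmentResult(
                        label, o, expected, chi2, p, None,
                        enriched=p < alpha and o > expected,
                        depleted=p < alpha and o < expected,
                    )
                )
            start += step
    return results


def region_enrichment(
    hfs: Sequence[HostHF],
    index: RegionIndex,
    categories: Sequence[str] = CATEGORIES,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Functional-region enrichment over annotation categories.

    Observed = number of HFs whose classification contains the category;
    expected ratio = category bases / genome length (the uniform per-base
    null); expected count = ratio x total HFs. Because categories overlap,
    each is tested marginally with no cross-category correction.
    """
    unknown = set(categories) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    total = len(hfs)
    classifications = [classify_hf(hf.interval, index) for hf in hfs]
    results: list[EnrichmentResult] = []
    for cat in categories:
        o = sum(cat in c for c in classifications)
        ratio = index.category_base_counts[cat] / index.genome_length
        expected = ratio * total
        if expected < MIN_EXPECTED or total == 0:
            results.append(
                EnrichmentResult(cat, o, expected, math.nan, math.nan, None, False,
                                 tested=False)
            )
            continue
        chi2, p = chi2_gof(o, expected, total, total)
        results.append(
            EnrichmentResult(
                cat, o, expected, chi2, p, None,
                enriched=p < alpha and o > expected,
                depleted=p < alpha and o < expected,
            )
        )
    return results


def write_results(
    results: Sequence[EnrichmentResult], path, header: str | None = None
) -> None:
    """One TSV per analysis: unit, observed, expected, chi2, p, p_adj, flags."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("unit\tobserved\texpected\tchi2\tp\tp_adj\tenriched\tdepleted\ttested\n")
        for r in results:
            pa = "" if r.p_adj is None else f"{r.p_adj:.6g}"
            chi2 = "" if math.isnan(r.chi2) else f"{r.chi2:.6g}"
            p = "" if math.isnan(r.p) else f"{r.p:.6g}"
            fh.write(
                f"{r.unit_id}\t{r.observed}\t{r.expected:.6g}\t{chi2}\t{p}\t{pa}\t"
                f"{int(r.enriched)}\t{int(r.depleted)}\t{int(r.tested)}\n"
            )


def write_enriched_windows_bed(
    results: Sequence[EnrichmentResult], path, header: str | None = None
) -> None:
    """BED of enriched windows from a window_enrichment result list."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for r in results:
            if not r.enriched:
                continue
            loc = r.unit_id.replace("(sliding)", "")
            sc, rng_ = loc.rsplit(":", 1)
            s, e = rng_.split("-")
            fh.write(f"{sc}\t{s}\t{e}\t{r.unit_id}\t{r.observed}\t.\n")
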