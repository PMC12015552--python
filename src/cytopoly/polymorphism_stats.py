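"""Polymorphism summaries, Hardy-Weinberg tests and between-sample comparison.

The summary statistics follow the conventions of quantitative karyological
surveys: a larva is *heterozygous* when at least one of its seven arms
carries two different banding sequences, and its number of *heterozygous
inversions* is the count of heterozygous arms.  Across populations the
statistics are aggregated unweighted (populations, not larvae, are the
sampling unit) as mean +/- standard error, with the standard deviation also
reported.

Hardy-Weinberg deviations are tested with the exact conditional test
(Levene's distribution; Monte Carlo for more than two alleles), with the
classical chi-square test as an alternative.  Between-sample frequency
comparison uses Fisher's exact test per sequence on 2x2 allele-count tables
with Bonferroni correction; the angular (arcsine) phi-transformation z-test
of classical Russian biometry is available as an alternative method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .band_model import ARMS
from .population_io import FrequencyTable, PopulationSample, sequence_frequencies

__all__ = [
    "PolymorphismSummary",
    "HWResult",
    "ComparisonResult",
    "summarize",
    "aggregate_summaries",
    "genotype_counts",
    "allele_counts",
    "hardy_weinberg_test",
    "hw_scan",
    "compare_samples",
    "pooling_test",
]


@dataclass(frozen=True)
class PolymorphismSummary:
    population: str
    n: int
    pct_heterozygotes: float  # % larvae with >= 1 heterozygous arm
    het_inversions_per_larva: float  # mean count of heterozygous arms
    n_sequences: int  # distinct (arm, serial) observed
    n_genotype_combinations: int  # distinct (arm, pair) observed


@dataclass(frozen=True)
class HWResult:
    population: str
    arm: str
    p_value: float
    statistic: float | None  # chi-square statistic when method="chisq"
    direction: str  # "excess het" | "deficit het" | "none"
    significant: bool
    method: str


@dataclass(frozen=True)
class ComparisonResult:
    p_values: dict[tuple[str, int], float]  # (arm, serial) -> raw p
    corrected: dict[tuple[str, int], float]  # Bonferroni-corrected
    differs: bool
    alpha: float


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize(sample: PopulationSample) -> PolymorphismSummary:
    """Per-population polymorphism summary (deterministic recount)."""
    n_het_larvae = 0
    total_het_arms = 0
    sequences: set[tuple[str, int]] = set()
    combos: set[tuple[str, int, int]] = set()
    for larva in sample.larvae:
        het_arms = larva.heterozygous_arms()
        if het_arms:
            n_het_larvae += 1
        total_het_arms += len(het_arms)
        for arm in ARMS:
            c = larva.combinations[arm]
            sequences.add((arm, c.seq1))
            sequences.add((arm, c.seq2))
            combos.add((arm, c.seq1, c.seq2))
    n = sample.n
    return PolymorphismSummary(
        population=sample.locality,
        n=n,
        pct_heterozygotes=100.0 * n_het_larvae / n,
        het_inversions_per_larva=total_het_arms / n,
        n_sequences=len(sequences),
        n_genotype_combinations=len(combos),
    )


_SUMMARY_FIELDS = (
    "pct_heterozygotes",
    "het_inversions_per_larva",
    "n_sequences",
    "n_genotype_combinations",
)


def aggregate_summaries(
    summaries: Sequence[PolymorphismSummary], min_n: int = 10
) -> dict:
    """Unweighted across-population mean, SE and SD of each summary field.

    Populations with fewer than ``min_n`` larvae are excluded (and listed
    under ``"excluded"``); SE = SD / sqrt(k) over the k retained populations.
    """
    kept = [s for s in summaries if s.n >= min_n]
    excluded = [s.population for s in summaries if s.n < min_n]
    if not kept:
        raise ValueError(f"no population reaches min_n={min_n}")
    out: dict = {"k": len(kept), "excluded": excluded, "populations": [s.population for s in kept]}
    for fld in _SUMMARY_FIELDS:
        vals = np.array([getattr(s, fld) for s in kept], dtype=float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[fld] = {
            "mean": float(vals.mean()),
            "se": sd / math.sqrt(len(vals)),
            "sd": sd,
        }
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------


def genotype_counts(sample: PopulationSample, arm: str) -> dict[tuple[int, int], int]:
    """Counts of each genotypic combination (unordered serial pair) at one arm."""
    counts: dict[tuple[int, int], int] = {}
    for larva in sample.larvae:
        c = larva.combinations[arm]
        counts[(c.seq1, c.seq2)] = counts.get((c.seq1, c.seq2), 0) + 1
    return counts


def allele_counts(counts: dict[tuple[int, int], int]) -> dict[int, int]:
    out: dict[int, int] = {}
    for (i, j), n in counts.items():
        out[i] = out.get(i, 0) + n
        out[j] = out.get(j, 0) + n
    return out


def _log_table_prob(counts: dict[tuple[int, int], int]) -> float:
    """Log probability of a genotype table under HWE conditional on allele counts:
    N! * 2^h * prod_a(n_a!) / (prod_g(n_g!) * (2N)!)."""
    n = sum(counts.values())
    alleles = allele_counts(counts)
    h = sum(cnt for (i, j), cnt in counts.items() if i != j)
    logp = math.lgamma(n + 1) + h * math.log(2.0)
    for cnt in alleles.values():
        logp += math.lgamma(cnt + 1)
    for cnt in counts.values():
        logp -= math.lgamma(cnt + 1)
    logp -= math.lgamma(2 * n + 1)
    return logp


def _exact_two_allele_p(counts: dict[tuple[int, int], int], mid_p: bool = False) -> float:
    """Exact conditional HW test for two alleles: sum the Levene probabilities
    of all heterozygote counts no more probable than the observed table.

    ``mid_p`` counts tables exactly as probable as the observed one with
    weight 1/2 (the mid-p correction that removes the conservatism of
    discrete exact tests; its average size is close to the nominal level).
    """
    alleles = sorted(allele_counts(counts))
    a, b = alleles[0], alleles[1]
    n_het_obs = counts.get((a, b), 0)
    n1 = allele_counts(counts)[a]
    n2 = allele_counts(counts)[b]

    def logp(n_het: int) -> float:
        n11, n22 = (n1 - n_het) // 2, (n2 - n_het) // 2
        table = {(a, a): n11, (a, b): n_het, (b, b): n22}
        return _log_table_prob({k: v for k, v in table.items() if v > 0 or k == (a, b)})

    lp_obs = logp(n_het_obs)
    total = 0.0
    n_het = n1 % 2  # heterozygote count shares parity with the minor allele count
    p = 0.0
    while n_het <= min(n1, n2):
        lp = logp(n_het)
        pr = math.exp(lp)
        total += pr
        if abs(lp - lp_obs) <= 1e-12:
            p += 0.5 * pr if mid_p else pr
        elif lp < lp_obs:
            p += pr
        n_het += 2
    return min(1.0, p / total)


def hardy_weinberg_test(
    counts: dict[tuple[int, int], int],
    population: str = "",
    arm: str = "",
    method: str = "exact",
    alpha: float = 0.05,
    n_mc: int = 10_000,
    seed: int = 0,
) -> HWResult:
    """Test one arm's genotype counts for Hardy-Weinberg deviation.

    ``method="exact"`` uses the conditional exact test (full enumeration for
    two alleles, Monte Carlo permutation of the allele vector otherwise,
    seeded); ``method="chisq"`` the classical chi-square with expected counts
    from the observed allele frequencies.  Direction compares observed to
    expected heterozygote totals.
    """
    n = sum(counts.values())
    if n == 0:
        raise ValueError("empty genotype table")
    alleles = allele_counts(counts)
    obs_het = sum(cnt for (i, j), cnt in counts.items() if i != j)
    exp_het = n * (1.0 - sum((c / (2 * n)) ** 2 for c in alleles.values()))
    if obs_het > exp_het + 1e-12:
        direction = "excess het"
    elif obs_het < exp_het - 1e-12:
        direction = "deficit het"
    else:
        direction = "none"

    if len(alleles) < 2:
        return HWResult(population, arm, 1.0, None, "none", False, method)

    statistic: float | None = None
    if method == "chisq":
        serials = sorted(alleles)
        p_hat = {s: alleles[s] / (2 * n) for s in serials}
        chi2 = 0.0
        for ai, i in enumerate(serials):
            for j in serials[ai:]:
                exp = n * (p_hat[i] ** 2 if i == j else 2 * p_hat[i] * p_hat[j])
                if exp == 0:
                    continue
                obs = counts.get((i, j), 0)
                chi2 += (obs - exp) ** 2 / exp
        g = len(serials)
        df = g * (g + 1) // 2 - g
        p = float(stats.chi2.sf(chi2, df))
        statistic = chi2
    elif method in ("exact", "exact-midp"):
        mid_p = method == "exact-midp"
        if len(alleles) == 2:
            p = _exact_two_allele_p(counts, mid_p=mid_p)
        else:
            p = _monte_carlo_exact_p(counts, n_mc=n_mc, seed=seed, mid_p=mid_p)
    else:
        raise ValueError(f"unknown method {method!r}")
    return HWResult(population, arm, p, statistic, direction, p < alpha, method)


def _monte_carlo_exact_p(
    counts: dict[tuple[int, int], int], n_mc: int, seed: int, mid_p: bool = False
) -> float:
    """Monte Carlo version of the exact conditional test for > 2 alleles:
    permute the allele vector, re-pair into genotypes, compare table
    probabilities (Guo-Thompson style)."""
    rng = np.random.default_rng(seed)
    pool = []
    for serial, cnt in allele_counts(counts).items():
        pool.extend([serial] * cnt)
    pool = np.array(pool)
    lp_obs = _log_table_prob(counts)
    hits = 0.0
    for _ in range(n_mc):
        rng.shuffle(pool)
        table: dict[tuple[int, int], int] = {}
        for i, j in zip(pool[0::2], pool[1::2]):
            key = (int(min(i, j)), int(max(i, j)))
            table[key] = table.get(key, 0) + 1
        lp = _log_table_prob(table)
        if abs(lp - lp_obs) <= 1e-9:
            hits += 0.5 if mid_p else 1.0
        elif lp < lp_obs:
            hits += 1.0
    return (hits + 1) / (n_mc + 1)


def hw_scan(
    sample: PopulationSample,
    method: str = "exact",
    alpha: float = 0.05,
    seed: int = 0,
) -> list[HWResult]:
    """Hardy-Weinberg test on every arm of one population sample."""
    return [
        hardy_weinberg_test(
            genotype_counts(sample, arm),
            population=sample.locality,
            arm=arm,
            method=method,
            alpha=alpha,
            seed=seed,
        )
        for arm in ARMS
    ]


# ---------------------------------------------------------------------------
# between-sample comparison (pooling test)
# ---------------------------------------------------------------------------


def _allele_count_table(sample: PopulationSample, arm: str) -> dict[int, int]:
    return allele_counts(genotype_counts(sample, arm))


def _phi_z_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Angular-transformation z-test on two proportions (phi-criterion):
    phi = 2 arcsin sqrt(p); var(phi) = 1/n."""
    phi1 = 2 * math.asin(math.sqrt(k1 / n1))
    phi2 = 2 * math.asin(math.sqrt(k2 / n2))
    z = (phi1 - phi2) / math.sqrt(1 / n1 + 1 / n2)
    return float(2 * stats.norm.sf(abs(z)))


def compare_samples(
    a: PopulationSample,
    b: PopulationSample,
    arm: str | None = None,
    alpha: float = 0.05,
    method: str = "fisher",
) -> ComparisonResult:
    """Compare banding-sequence frequencies between two samples.

    For each sequence of each tested arm, a 2x2 allele-count table (focal
    sequence vs all others, sample A vs sample B) is tested with Fisher's
    exact test (default) or the angular phi-criterion z-test.  P-values are
    Bonferroni-corrected across all tested sequences; the samples "differ"
    if any corrected p < alpha.  Degenerate tables give p = 1.
    """
    arms = [arm] if arm is not None else list(ARMS)
    raw: dict[tuple[str, int], float] = {}
    for current in arms:
        ca = _allele_count_table(a, current)
        cb = _allele_count_table(b, current)
        na, nb = 2 * a.n, 2 * b.n
        for serial in sorted(set(ca) | set(cb)):
            ka, kb = ca.get(serial, 0), cb.get(serial, 0)
            if (ka == 0 and kb == 0) or (ka == na and kb == nb):
                raw[(current, serial)] = 1.0
                continue
            if method == "fisher":
                _, p = stats.fisher_exact([[ka, na - ka], [kb, nb - kb]])
            elif method == "phi":
                p = _phi_z_test(ka, na, kb, nb)
            else:
                raise ValueError(f"unknown method {method!r}")
            raw[(current, serial)] = float(p)
    m = len(raw)
    corrected = {k: min(1.0, p * m) for k, p in raw.items()}
    differs = any(p < alpha for p in corrected.values())
    return ComparisonResult(raw, corrected, differs, alpha)


def pooling_test(alpha: float = 0.05, method: str = "fisher"):
    """Callback for :func:`cytopoly.population_io.merge_samples`: True when two
    same-locality samples show no significant frequency difference."""

    def _test(a: PopulationSample, b: PopulationSample) -> bool:
        return not compare_samples(a, b, alpha=alpha, method=method).differs

    return _test


def frequency_tables(samples: Iterable[PopulationSample]) -> list[FrequencyTable]:
    """Convenience: frequency table per sample."""
    return [sequence_frequencies(s) for s in samples]
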