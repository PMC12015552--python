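"""Seeded synthetic data with the statistical structure of a karyological survey.

The generator emulates the shape of a multi-population cytogenetic data
set: per-arm banding-sequence frequencies per population, larvae drawn
genotype-by-genotype under Hardy-Weinberg with an optional inbreeding-style
deviation F (P(hom ii) = p_i^2 + F p_i (1 - p_i); P(het ij) = 2 p_i p_j
(1 - F); negative F, down to -min_i p_i/(1-p_i), models heterozygote
excess), Bernoulli B-chromosome carriers, and band orders derived from an
ancestral order by a known series of reversals.

The built-in "paper-like" scenario mirrors a published survey design of 21
quantitatively scored populations of a Palearctic *Chironomus* species:
European, Ural and East-Siberian populations carry dominant main sequences
everywhere (cytogenetic type 0), most West-Siberian populations have the
arm-G main sequence displaced by its alternative (type G, with DG/FG/DFG
variants and elevated arm-D/arm-F alternative frequencies), and the two
Far-East populations have ADG and F profiles.  All randomness flows through
one ``numpy.random.Generator`` passed explicitly or derived from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .band_model import ARMS, BandOrder, apply_reversal, breakpoint_count
from .classification import assign_type
from .population_io import (
    FrequencyTable,
    GenotypeCombination,
    LarvaKaryotype,
    PopulationSample,
)

__all__ = [
    "PopulationConfig",
    "ScenarioConfig",
    "generate_population",
    "generate_scenario",
    "paper_like_scenario",
    "generate_reversal_series",
    "scenario_from_yaml",
]


@dataclass
class PopulationConfig:
    population: str
    region: str
    n: int
    freqs: dict[str, dict[int, float]]  # arm -> serial -> frequency
    inbreeding_f: float = 0.0
    b_carrier_freq: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"{self.population}: N must be >= 1")
        if not 0.0 <= self.b_carrier_freq <= 1.0:
            raise ValueError("B-chromosome carrier frequency must be in [0, 1]")
        for arm, table in self.freqs.items():
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{self.population} arm {arm}: frequencies sum to {total}")
            for p in table.values():
                if 0 < p < 1 and self.inbreeding_f < -p / (1 - p) - 1e-12:
                    raise ValueError(
                        f"{self.population}: F={self.inbreeding_f} makes a homozygote "
                        f"probability negative at p={p}"
                    )
        if self.inbreeding_f > 1.0:
            raise ValueError("F must be <= 1")

    def truth_table(self) -> FrequencyTable:
        return FrequencyTable(self.population, self.n, {a: dict(t) for a, t in self.freqs.items()})


@dataclass
class ScenarioConfig:
    populations: list[PopulationConfig]
    seed: int = 0
    name: str = "custom"


def _genotype_distribution(
    freqs: dict[int, float], f: float
) -> tuple[list[tuple[int, int]], np.ndarray]:
    serials = sorted(s for s, p in freqs.items() if p > 0)
    pairs, probs = [], []
    for ai, i in enumerate(serials):
        pi = freqs[i]
        for j in serials[ai:]:
            pj = freqs[j]
            if i == j:
                pr = pi * pi + f * pi * (1 - pi)
            else:
                pr = 2 * pi * pj * (1 - f)
            pairs.append((i, j))
            probs.append(max(0.0, pr))
    probs = np.array(probs)
    return pairs, probs / probs.sum()


def generate_population(
    config: PopulationConfig, rng: np.random.Generator | int | None = None
) -> PopulationSample:
    """Draw one population sample from per-arm frequencies.

    Genotypes are sampled independently per arm from the F-deviated
    Hardy-Weinberg distribution; B-chromosome carriers are Bernoulli with
    the configured carrier frequency (carriers get count 1).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    dists = {arm: _genotype_distribution(t, config.inbreeding_f) for arm, t in config.freqs.items()}
    missing = [a for a in ARMS if a not in dists]
    if missing:
        raise ValueError(f"{config.population}: no frequencies for arms {missing}")
    draws = {
        arm: rng.choice(len(dists[arm][0]), size=config.n, p=dists[arm][1])
        for arm in ARMS
    }
    carriers = rng.random(config.n) < config.b_carrier_freq
    larvae = []
    for k in range(config.n):
        combos = {}
        for arm in ARMS:
            i, j = dists[arm][0][draws[arm][k]]
            combos[arm] = GenotypeCombination(arm, i, j)
        larvae.append(
            LarvaKaryotype(
                larva_id=f"{config.population}-{k + 1:04d}",
                combinations=combos,
                b_chromosome_count=int(carriers[k]),
            )
        )
    return PopulationSample(
        locality=config.population, larvae=larvae, region=config.region
    )


def generate_scenario(
    config: ScenarioConfig,
) -> tuple[list[PopulationSample], dict]:
    """Generate all populations of a scenario plus the truth record.

    The truth record carries the true frequency tables, the cytogenetic type
    implied by each true table, the region map, and the designated
    main/alternative serials — everything an end-to-end recovery test needs.
    """
    rng = np.random.default_rng(config.seed)
    samples = [generate_population(pc, rng) for pc in config.populations]
    truth_tables = {pc.population: pc.truth_table() for pc in config.populations}
    truth = {
        "scenario": config.name,
        "seed": config.seed,
        "frequencies": truth_tables,
        "types": {
            pc.population: assign_type(truth_tables[pc.population]).type_string
            for pc in config.populations
        },
        "regions": {pc.population: pc.region for pc in config.populations},
        "b_carrier_freq": {pc.population: pc.b_carrier_freq for pc in config.populations},
        "inbreeding_f": {pc.population: pc.inbreeding_f for pc in config.populations},
        "classes": _expected_classes(config.populations),
    }
    return samples, truth


def _expected_classes(configs: Sequence[PopulationConfig]) -> dict[str, str]:
    """Class labels implied by the true frequencies: serial 1 is the
    designated main sequence; a sequence dominant (> 0.5) somewhere is
    alternative; everything else recurrent-but-never-dominant is rare.
    (No sequence is unique by construction: uniqueness is a property of a
    single realized larva, not of a frequency profile.)"""
    dominant: dict[tuple[str, int], int] = {}
    for pc in configs:
        for arm, t in pc.freqs.items():
            for serial, p in t.items():
                if p <= 0:
                    continue
                key = (arm, serial)
                dominant[key] = dominant.get(key, 0) + (p > 0.5)
    out = {}
    for (arm, serial), n_dom in sorted(dominant.items()):
        if serial == 1:
            label = "main"
        elif n_dom >= 1:
            label = "alternative"
        else:
            label = "rare"
        out[f"{arm}{serial}"] = label
    return out


# ---------------------------------------------------------------------------
# the paper-like preset
# ---------------------------------------------------------------------------

# Regional frequency profiles.  Monomorphic arms C and E reflect the survey
# narrative (both arms essentially monomorphic in most populations); the
# alternative serial is 2 in every polymorphic arm.
_BASE = {  # Europe / Ural / E-Siberia: every main sequence dominant (type 0)
    "A": {1: 0.80, 2: 0.15, 4: 0.05},
    "B": {1: 0.85, 2: 0.15},
    "C": {1: 1.0},
    "D": {1: 0.85, 2: 0.15},
    "E": {1: 1.0},
    "F": {1: 0.85, 2: 0.15},
    "G": {1: 0.95, 2: 0.05},
}

_WSIB_G = {  # W-Siberia: arm-G alternative nearly fixed, D/F alternatives elevated
    "A": {1: 0.75, 2: 0.15, 4: 0.05, 5: 0.05},
    "B": {1: 0.85, 2: 0.15},
    "C": {1: 1.0},
    "D": {1: 0.60, 2: 0.40},
    "E": {1: 1.0},
    "F": {1: 0.60, 2: 0.40},
    "G": {1: 0.10, 2: 0.90},
}


def _variant(base: dict, **arm_tables) -> dict:
    out = {a: dict(t) for a, t in base.items()}
    out.update(arm_tables)
    return out


_PROFILES = {
    "0": _BASE,
    "G": _WSIB_G,
    "DG": _variant(_WSIB_G, D={1: 0.40, 2: 0.60}),
    "FG": _variant(_WSIB_G, F={1: 0.35, 2: 0.65}),
    "DFG": _variant(_WSIB_G, D={1: 0.40, 2: 0.60}, F={1: 0.35, 2: 0.65}),
    "ADG": _variant(
        _BASE,
        A={1: 0.45, 2: 0.45, 4: 0.10},
        D={1: 0.40, 2: 0.60},
        G={1: 0.20, 2: 0.80},
    ),
    "F": _variant(_BASE, F={1: 0.30, 2: 0.70}, G={1: 0.90, 2: 0.10}),
}

# (population, region, N, profile, B-chromosome carrier frequency);
# localities and sample sizes follow the 21 quantitatively scored
# populations of the survey design this generator emulates.
_PAPER_LIKE = [
    ("YAR-GR", "Europe", 100, "0", 0.00),
    ("SVE-OS", "Ural", 30, "0", 0.00),
    ("SVE-KH", "Ural", 45, "0", 0.05),
    ("SVE-BO", "Ural", 43, "0", 0.00),
    ("SVE-YU", "Ural", 16, "0", 0.00),
    ("SVE-VP", "Ural", 12, "0", 0.00),
    ("SVE-KR", "Ural", 29, "0", 0.05),
    ("IRK-KO", "E-Siberia", 26, "0", 0.05),
    ("IRK-DU", "E-Siberia", 30, "0", 0.00),
    ("ZAB-IV", "E-Siberia", 10, "0", 0.00),
    ("NSK-BE", "W-Siberia", 734, "G", 0.20),
    ("NSK-CH", "W-Siberia", 16, "G", 0.15),
    ("NSK-OR", "W-Siberia", 134, "G", 0.25),
    ("NSK-KY", "W-Siberia", 34, "G", 0.30),
    ("ALT-AN", "W-Siberia", 116, "DG", 0.10),
    ("ALT-SA", "W-Siberia", 117, "G", 0.20),
    ("RAL-MA", "W-Siberia", 123, "G", 0.10),
    ("KEM-SU", "W-Siberia", 100, "FG", 0.15),
    ("KEM-BA", "W-Siberia", 94, "DFG", 0.10),
    ("KHA-CH", "Far-East", 17, "ADG", 0.05),
    ("PRI-CH", "Far-East", 17, "F", 0.00),
]


def paper_like_scenario(seed: int = 0, n_override: int | None = None) -> ScenarioConfig:
    """The built-in 21-population scenario.

    ``n_override`` replaces every population size (the end-to-end recovery
    check uses N = 500 per population so sampling noise stays below the
    recovery tolerance).
    """
    pops = [
        PopulationConfig(
            population=pid,
            region=region,
            n=n_override or n,
            freqs={a: dict(t) for a, t in _PROFILES[profile].items()},
            b_carrier_freq=b,
        )
        for pid, region, n, profile, b in _PAPER_LIKE
    ]
    return ScenarioConfig(populations=pops, seed=seed, name="paper-like")


# ---------------------------------------------------------------------------
# reversal series with known ground truth
# ---------------------------------------------------------------------------


def generate_reversal_series(
    n_segments: int,
    k: int,
    seed: int = 0,
    non_overlapping: bool = False,
    arm: str = "A",
    centromere_index: int = 0,
    max_tries: int = 1000,
):
    """Ancestral band order (identity) plus a derived order built by ``k``
    random reversals, with the applied reversals returned as ground truth.

    With ``non_overlapping`` the k reversed intervals are pairwise disjoint
    and non-adjacent, which forces 2k breakpoints and hence a minimal
    reversal distance of exactly k (verified at generation time; requires
    n_segments >= 2k - 1).
    """
    if n_segments > 12:
        raise ValueError("n_segments must be <= 12 (exact-search regime)")
    if k > 4:
        raise ValueError("k must be <= 4")
    if non_overlapping and n_segments < 2 * k - 1:
        raise ValueError("non-overlapping series needs n_segments >= 2k - 1")
    rng = np.random.default_rng(seed)
    ancestral = BandOrder.from_labels(
        arm, [str(i) for i in range(1, n_segments + 1)], centromere_index
    )
    for _ in range(max_tries):
        order = ancestral
        reversals = []
        if non_overlapping:
            intervals = _disjoint_intervals(rng, n_segments, k)
            if intervals is None:
                continue
            for i, j in intervals:
                order, rec = apply_reversal(order, i, j)
                reversals.append(rec)
        else:
            for _ in range(k):
                i = int(rng.integers(0, n_segments))
                j = int(rng.integers(i, n_segments))
                order, rec = apply_reversal(order, i, j)
                reversals.append(rec)
        if not non_overlapping or k == 0 or breakpoint_count(ancestral, order) == 2 * k:
            return ancestral, order, reversals
    raise RuntimeError("could not generate a reversal series meeting the constraints")


def _disjoint_intervals(rng: np.random.Generator, n: int, k: int):
    """k random intervals over 0..n-1, pairwise separated by >= 1 segment."""
    if k == 0:
        return []
    for _ in range(200):
        ivs = []
        for _ in range(k):
            i = int(rng.integers(0, n))
            j = int(rng.integers(i, n))
            ivs.append((i, j))
        ivs.sort()
        if all(ivs[t + 1][0] - ivs[t][1] >= 2 for t in range(k - 1)):
            return ivs
    return None


# ---------------------------------------------------------------------------
# scenario file format
# ---------------------------------------------------------------------------


def scenario_from_yaml(path) -> ScenarioConfig:
    """Load a scenario config from YAML/JSON.

    Layout: ``name``, ``seed`` and ``populations:`` a list of mappings with
    ``population``, ``region``, ``n``, ``inbreeding_f``, ``b_carrier_freq``
    and ``freqs`` (arm -> {serial: frequency}).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    pops = [
        PopulationConfig(
            population=p["population"],
            region=p.get("region", ""),
            n=int(p["n"]),
            freqs={
                str(arm): {int(s): float(f) for s, f in table.items()}
                for arm, table in p["freqs"].items()
            },
            inbreeding_f=float(p.get("inbreeding_f", 0.0)),
            b_carrier_freq=float(p.get("b_carrier_freq", 0.0)),
        )
        for p in raw["populations"]
    ]
    return ScenarioConfig(populations=pops, seed=int(raw.get("seed", 0)), name=raw.get("name", "custom"))
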