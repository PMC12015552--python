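"""Four-class banding-sequence classification and cytogenetic population typing.

Banding sequences fall into four classes: *main* (the designated reference
sequence of each arm, serial 1 by naming convention), *alternative*
(observed in both homo- and heterozygous state and dominant — frequency
above 0.5 — in at least one population), *rare* (recurrent but never
dominant, typically at low frequency) and *unique* (a single larva in the
whole data set).  A population's *cytogenetic structure type* lists the
arms at which the main sequence is not dominant ("0" when every main
sequence is dominant; e.g. "G", "DFG").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .band_model import ARMS
from .population_io import FrequencyTable, PopulationSample, sequence_frequencies

__all__ = [
    "SequenceClassReport",
    "CytogeneticType",
    "ClassParams",
    "classify_sequences",
    "assign_type",
    "type_census",
]


@dataclass
class ClassParams:
    """Thresholds of the classification rules.

    dominance_threshold: frequency strictly above which a sequence is
    "dominant" (exactly 0.5 counts as NOT dominant).  rare_threshold: the
    frequency below which a recurrent, never-dominant sequence is typical of
    the rare class.  min_populations: minimum number of populations carrying
    a sequence for the alternative class.
    """

    dominance_threshold: float = 0.5
    rare_threshold: float = 0.10
    min_populations: int = 2


@dataclass
class SequenceClassReport:
    arm: str
    serial: int
    seq_class: str  # main | alternative | rare | unique
    n_larvae: int  # larvae carrying the sequence, all populations
    populations: list[str] = field(default_factory=list)
    seen_homozygous: bool = False
    seen_heterozygous: bool = False
    n_dominant: int = 0  # populations where frequency > dominance threshold


@dataclass(frozen=True)
class CytogeneticType:
    population: str
    type_string: str  # "0" or arm letters in A..G order

    def __post_init__(self) -> None:
        if self.type_string != "0":
            letters = list(self.type_string)
            if letters != sorted(set(letters)) or any(l not in ARMS for l in letters):
                raise ValueError(f"malformed type string {self.type_string!r}")


def classify_sequences(
    samples: Sequence[PopulationSample],
    params: ClassParams | None = None,
    main_serials: dict[str, int] | None = None,
) -> list[SequenceClassReport]:
    """Assign every observed (arm, serial) exactly one of the four classes.

    Mains are designated a priori (serial 1 per arm unless overridden) — in
    type-G populations the main sequence is non-dominant yet remains main.
    Precedence for the rest: unique (exactly one larva overall), then
    alternative (both zygosity states seen, present in >= min_populations,
    dominant somewhere), then rare (the residual never-dominant class).
    """
    params = params or ClassParams()
    mains = main_serials or {arm: 1 for arm in ARMS}
    bad = [a for a in mains if a not in ARMS]
    if bad:
        raise ValueError(f"main designation names unknown arms {bad}")

    evidence: dict[tuple[str, int], SequenceClassReport] = {}
    for sample in samples:
        table = sequence_frequencies(sample)
        carriers: dict[tuple[str, int], set[str]] = {}
        for larva in sample.larvae:
            for arm in ARMS:
                c = larva.combinations[arm]
                for serial in {c.seq1, c.seq2}:
                    key = (arm, serial)
                    rep = evidence.setdefault(
                        key, SequenceClassReport(arm, serial, "rare", 0)
                    )
                    carriers.setdefault(key, set()).add(larva.larva_id)
                    if c.is_heterozygous:
                        rep.seen_heterozygous = True
                    else:
                        rep.seen_homozygous = True
        for key, ids in carriers.items():
            rep = evidence[key]
            rep.n_larvae += len(ids)
            rep.populations.append(sample.locality)
            if table.frequency(*key) > params.dominance_threshold:
                rep.n_dominant += 1

    for (arm, serial), rep in evidence.items():
        if serial == mains.get(arm):
            rep.seq_class = "main"
        elif rep.n_larvae == 1:
            rep.seq_class = "unique"
        elif (
            rep.seen_homozygous
            and rep.seen_heterozygous
            and rep.n_dominant >= 1
            and len(rep.populations) >= params.min_populations
        ):
            rep.seq_class = "alternative"
        else:
            rep.seq_class = "rare"
    return [evidence[k] for k in sorted(evidence)]


def assign_type(
    table: FrequencyTable,
    main_serials: dict[str, int] | None = None,
    dominance_threshold: float = 0.5,
) -> CytogeneticType:
    """Cytogenetic structure type of one population.

    Letters of the arms whose main-sequence frequency is <= the dominance
    threshold (0.5 exactly counts as not dominant), concatenated in A..G
    order; "0" when every main sequence is dominant.
    """
    mains = main_serials or {arm: 1 for arm in ARMS}
    missing = [arm for arm in ARMS if arm not in table.freqs]
    if missing:
        raise ValueError(f"{table.population}: no frequencies for arms {missing}")
    letters = [
        arm for arm in ARMS if table.frequency(arm, mains[arm]) <= dominance_threshold
    ]
    return CytogeneticType(table.population, "".join(letters) or "0")


def type_census(assignments: Iterable[CytogeneticType]) -> dict:
    """Distinct cytogenetic types with the populations carrying each."""
    by_type: dict[str, list[str]] = {}
    for t in assignments:
        by_type.setdefault(t.type_string, []).append(t.population)
    return {
        "n_types": len(by_type),
        "types": {k: sorted(v) for k, v in sorted(by_type.items())},
    }
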