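"""Reading, writing and summarising larval genotype and frequency tables.

One larva carries, for each of the seven chromosomal arms A-G, an unordered
pair of banding sequences (a *genotypic combination*, e.g. ``A1.2`` for the
A1/A2 heterozygote), plus a B-chromosome count and optional flags.  A
population sample is a set of larvae from one locality; its per-arm
banding-sequence frequencies are the allele frequencies used by every
downstream statistic.

CSV dialect: UTF-8, comma-separated, dot decimal, ISO-8601 dates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import pandas as pd

from .band_model import ARMS, BandingSequence

__all__ = [
    "GenotypeCombination",
    "LarvaKaryotype",
    "PopulationSample",
    "FrequencyTable",
    "GenotypeTableError",
    "read_genotype_table",
    "write_genotype_table",
    "sequence_frequencies",
    "read_frequency_tables",
    "write_frequency_tables",
    "merge_samples",
    "b_chromosome_carrier_frequency",
]

REGIONS = ("Europe", "Ural", "W-Siberia", "E-Siberia", "Far-East")


class GenotypeTableError(ValueError):
    """A genotype CSV failed validation; message carries row context."""


@dataclass(frozen=True)
class GenotypeCombination:
    """Unordered pair of banding-sequence serials carried at one arm."""

    arm: str
    seq1: int
    seq2: int

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.seq1 < 1 or self.seq2 < 1:
            raise ValueError(f"{self.arm}{self.seq1}.{self.seq2}: serials start at 1")
        if self.seq1 > self.seq2:  # store as an unordered pair
            lo, hi = self.seq2, self.seq1
            object.__setattr__(self, "seq1", lo)
            object.__setattr__(self, "seq2", hi)

    @property
    def is_heterozygous(self) -> bool:
        return self.seq1 != self.seq2

    @classmethod
    def parse(cls, arm: str, cell: str) -> "GenotypeCombination":
        """Parse a genotype cell like ``"1.2"`` (serial.serial)."""
        parts = str(cell).strip().split(".")
        if len(parts) != 2 or not all(p.isdigit() for p in parts):
            raise GenotypeTableError(f"arm {arm}: malformed genotype cell {cell!r}")
        return cls(arm, int(parts[0]), int(parts[1]))

    def __str__(self) -> str:
        return f"{self.seq1}.{self.seq2}"


@dataclass
class LarvaKaryotype:
    """Per-arm genotypic combinations of one larva (haploid n=4, arms AB CD EF G)."""

    larva_id: str
    combinations: dict[str, GenotypeCombination]
    b_chromosome_count: int = 0
    het_heterochromatin: bool = False
    translocation_note: str | None = None

    def __post_init__(self) -> None:
        missing = [a for a in ARMS if a not in self.combinations]
        if missing:
            raise ValueError(f"larva {self.larva_id}: missing arms {missing}")
        if self.b_chromosome_count < 0:
            raise ValueError("B-chromosome count must be >= 0")

    def heterozygous_arms(self) -> list[str]:
        return [a for a in ARMS if self.combinations[a].is_heterozygous]


@dataclass
class PopulationSample:
    """All larvae scored from one locality (optionally pooled across dates)."""

    locality: str
    larvae: list[LarvaKaryotype]
    dates: list[str] = field(default_factory=list)
    region: str | None = None

    def __post_init__(self) -> None:
        if not self.larvae:
            raise ValueError(f"{self.locality}: a population sample needs >= 1 larva")
        ids = [l.larva_id for l in self.larvae]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise GenotypeTableError(f"{self.locality}: duplicate larva ids {dup}")

    @property
    def n(self) -> int:
        return len(self.larvae)


@dataclass
class FrequencyTable:
    """Per-arm banding-sequence (allele) frequencies for one population."""

    population: str
    n: int
    freqs: dict[str, dict[int, float]]  # arm -> serial -> frequency

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("N must be >= 1")
        for arm, table in self.freqs.items():
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{self.population} arm {arm}: frequencies sum to {total}")

    def frequency(self, arm: str, serial: int) -> float:
        """Frequency of one sequence; unobserved serials are 0."""
        return self.freqs.get(arm, {}).get(serial, 0.0)

    def serials(self, arm: str) -> list[int]:
        return sorted(self.freqs.get(arm, {}))


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

_GENOTYPE_COLUMNS = ["locality", "date", "larva", *ARMS, "Bchr"]


def read_genotype_table(
    path,
    registry: Sequence[BandingSequence] | None = None,
) -> list[PopulationSample]:
    """Read a larval genotype CSV into population samples (one per locality).

    Expected header: ``locality,date,larva,A,B,C,D,E,F,G,Bchr`` with optional
    ``region``, ``het_heterochromatin`` and ``translocation`` columns.  Arm
    cells hold serial pairs like ``1.2``.  If a registry is given, serials
    are validated against the named sequences of each arm; errors cite the
    CSV line number.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in _GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise GenotypeTableError(f"{path}: missing columns {missing}")
    known: dict[str, set[int]] = {}
    if registry is not None:
        for s in registry:
            known.setdefault(s.arm, set()).add(s.serial)

    groups: dict[str, dict] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        locality = row["locality"].strip()
        combos = {}
        for arm in ARMS:
            cell = row[arm].strip()
            if not cell:
                raise GenotypeTableError(f"line {line}: missing arm {arm} cell")
            try:
                combo = GenotypeCombination.parse(arm, cell)
            except ValueError as exc:
                raise GenotypeTableError(f"line {line}: {exc}") from exc
            if known and not {combo.seq1, combo.seq2} <= known.get(arm, set()):
                raise GenotypeTableError(
                    f"line {line}: arm {arm} cell {cell!r} uses a serial not in the registry"
                )
            combos[arm] = combo
        larva = LarvaKaryotype(
            larva_id=row["larva"].strip(),
            combinations=combos,
            b_chromosome_count=int(row["Bchr"] or 0),
            het_heterochromatin=str(row.get("het_heterochromatin", "")).lower()
            in ("1", "true", "yes"),
            translocation_note=(row.get("translocation", "") or None),
        )
        g = groups.setdefault(
            locality, {"larvae": [], "dates": set(), "region": None}
        )
        g["larvae"].append(larva)
        if row["date"]:
            g["dates"].add(row["date"].strip())
        if row.get("region", ""):
            g["region"] = row["region"].strip()

    samples = []
    for locality, g in groups.items():
        samples.append(
            PopulationSample(
                locality=locality,
                larvae=g["larvae"],
                dates=sorted(g["dates"]),
                region=g["region"],
            )
        )
    return samples


def write_genotype_table(samples: Iterable[PopulationSample], path) -> None:
    rows = []
    for s in samples:
        date = s.dates[0] if s.dates else ""
        for larva in s.larvae:
            row = {
                "locality": s.locality,
                "date": date,
                "larva": larva.larva_id,
                **{arm: str(larva.combinations[arm]) for arm in ARMS},
                "Bchr": larva.b_chromosome_count,
                "region": s.region or "",
            }
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------


def sequence_frequencies(sample: PopulationSample) -> FrequencyTable:
    """Banding-sequence frequencies from genotypic combinations.

    Per arm, freq(s) = (2 * homozygotes(s) + heterozygotes carrying s) / 2N —
    the standard allele count with each larva contributing two homologues.
    """
    n = sample.n
    freqs: dict[str, dict[int, float]] = {}
    for arm in ARMS:
        counts: dict[int, int] = {}
        for larva in sample.larvae:
            c = larva.combinations[arm]
            counts[c.seq1] = counts.get(c.seq1, 0) + 1
            counts[c.seq2] = counts.get(c.seq2, 0) + 1
        freqs[arm] = {serial: cnt / (2 * n) for serial, cnt in sorted(counts.items())}
    return FrequencyTable(population=sample.locality, n=n, freqs=freqs)


def read_frequency_tables(path) -> list[FrequencyTable]:
    """Read frequency tables from long-format CSV
    (``population,N,arm,serial,frequency``)."""
    df = pd.read_csv(path)
    tables = []
    for pop, grp in df.groupby("population", sort=False):
        freqs: dict[str, dict[int, float]] = {}
        for _, row in grp.iterrows():
            freqs.setdefault(str(row["arm"]), {})[int(row["serial"])] = float(
                row["frequency"]
            )
        tables.append(
            FrequencyTable(population=str(pop), n=int(grp["N"].iloc[0]), freqs=freqs)
        )
    return tables


def write_frequency_tables(tables: Iterable[FrequencyTable], path) -> None:
    rows = [
        {
            "population": t.population,
            "N": t.n,
            "arm": arm,
            "serial": serial,
            "frequency": freq,
        }
        for t in tables
        for arm in sorted(t.freqs)
        for serial, freq in sorted(t.freqs[arm].items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def b_chromosome_carrier_frequency(sample: PopulationSample) -> float:
    """Fraction of larvae carrying at least one B chromosome."""
    return sum(1 for l in sample.larvae if l.b_chromosome_count >= 1) / sample.n


# ---------------------------------------------------------------------------
# pooling across collection dates
# ---------------------------------------------------------------------------


def merge_samples(
    samples: Sequence[PopulationSample],
    pool_test: Callable[[PopulationSample, PopulationSample], bool],
    log: list[str] | None = None,
) -> list[PopulationSample]:
    """Pool same-locality samples whose frequencies do not differ significantly.

    ``pool_test(a, b)`` returns True when the two samples show NO significant
    banding-sequence frequency difference (so they may be combined).  Samples
    are merged greedily in input order into compatibility groups; decisions
    are appended to ``log`` when given.
    """
    localities = {s.locality for s in samples}
    if len(localities) > 1:
        raise ValueError(f"merge_samples expects one locality, got {sorted(localities)}")
    groups: list[list[PopulationSample]] = []
    for s in samples:
        placed = False
        for grp in groups:
            if all(pool_test(s, member) for member in grp):
                grp.append(s)
                placed = True
                if log is not None:
                    log.append(f"{s.locality}: pooled sample dated {s.dates} into group {groups.index(grp)}")
                break
        if not placed:
            groups.append([s])
            if log is not None:
                log.append(f"{s.locality}: sample dated {s.dates} kept separate (group {len(groups) - 1})")
    merged = []
    for k, grp in enumerate(groups):
        larvae = []
        dates: list[str] = []
        for i, s in enumerate(grp):
            for l in s.larvae:
                # avoid id clashes between pooled collection dates
                lid = l.larva_id if len(grp) == 1 else f"{l.larva_id}#{i}"
                larvae.append(
                    LarvaKaryotype(
                        larva_id=lid,
                        combinations=l.combinations,
                        b_chromosome_count=l.b_chromosome_count,
                        het_heterochromatin=l.het_heterochromatin,
                        translocation_note=l.translocation_note,
                    )
                )
            dates.extend(s.dates)
        locality = grp[0].locality if len(groups) == 1 else f"{grp[0].locality}.{k}"
        merged.append(
            PopulationSample(
                locality=locality,
                larvae=larvae,
                dates=sorted(set(dates)),
                region=grp[0].region,
            )
        )
    return merged


def write_locality_metadata(samples: Iterable[PopulationSample], path) -> None:
    """Sidecar JSON with locality code, region, dates and N per sample."""
    meta = [
        {
            "locality": s.locality,
            "region": s.region,
            "dates": s.dates,
            "n_larvae": s.n,
        }
        for s in samples
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
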