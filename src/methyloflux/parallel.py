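"""Cross-line mutation parallelism from population resequencing tables.

Replicate lines evolved from a common ancestor acquire many mutations;
loci hit independently in every line are the strongest candidates for
drivers of adaptation. The procedure implemented here consumes per-sample
mutation tables (one row per mutation per population, as produced by a
population-mode variant caller), filters them — allele frequency strictly
above a threshold, functionally relevant classes, ancestral variants
subtracted — groups the survivors at the gene / intergenic-region level,
and intersects the locus sets across lines, reporting the full Venn
decomposition.

Filtering conventions: the frequency cut is strict (> 0.60 by default);
nonsense mutations count as nonsynonymous-class events; ancestral
subtraction is keyed on the exact (position, ref, alt) variant, so a new
mutation in an already-mutated gene still counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MutationRecord",
    "LocusGroup",
    "ParallelismReport",
    "SchemaError",
    "DEFAULT_MIN_FREQUENCY",
    "DEFAULT_CLASSES",
    "parse_mutation_table",
    "filter_mutations",
    "group_by_locus",
    "cross_line_parallelism",
]

DEFAULT_MIN_FREQUENCY = 0.60
DEFAULT_CLASSES = frozenset({"nonsynonymous", "nonsense", "intergenic"})

REQUIRED_COLUMNS = ("sample_id", "position", "ref", "alt", "class", "locus", "frequency")


class SchemaError(ValueError):
    """The table lacks a required column or holds an invalid value."""


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    position: int
    ref_allele: str
    alt_allele: str
    mutation_class: str
    locus: str
    frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")
        if self.position < 1:
            raise ValueError(f"position {self.position} must be >= 1 (1-based)")
        if not self.locus:
            raise ValueError("locus must be non-empty")

    @property
    def variant_key(self) -> tuple[int, str, str]:
        """Identity used for ancestral subtraction."""
        return (self.position, self.ref_allele, self.alt_allele)


@dataclass
class LocusGroup:
    locus: str
    records: list[MutationRecord]

    @property
    def lines_hit(self) -> set[str]:
        return {r.sample_id for r in self.records}


@dataclass
class ParallelismReport:
    per_line_counts: dict[str, int]
    mean_count: float
    sd_count: float
    locus_sets: dict[str, set[str]]
    shared_all_lines: set[str]
    venn: dict[str, int]

    def venn_table(self) -> pd.DataFrame:
        rows = [
            {"region": sig, "n_lines": sig.count("&") + 1, "loci": n}
            for sig, n in sorted(self.venn.items())
        ]
        return pd.DataFrame(rows)


def _parse_frequency(raw, row: int) -> float:
    """Accept 0.83, '83%', 'FREQ=61%' and similar dialects."""
    text = str(raw).strip()
    if "=" in text:
        text = text.split("=", 1)[1].strip()
    percent = text.endswith("%")
    if percent:
        text = text[:-1].strip()
    try:
        value = float(text)
    except ValueError:
        raise SchemaError(f"row {row}: unparseable frequency {raw!r}") from None
    if percent:
        value /= 100.0
    if not 0.0 <= value <= 1.0:
        raise SchemaError(f"row {row}: frequency {raw!r} outside [0, 1]")
    return value


def parse_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read a TSV of called mutations into typed records.

    The header must provide sample_id, position, ref, alt, class, locus and
    frequency. Frequencies may be fractions or percentages.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=2):  # row 1 = header
        records.append(
            MutationRecord(
                sample_id=str(row["sample_id"]),
                position=int(row["position"]),
                ref_allele=str(row["ref"]),
                alt_allele=str(row["alt"]),
                mutation_class=str(row["class"]),
                locus=str(row["locus"]),
                frequency=_parse_frequency(row["frequency"], i),
            )
        )
    return records


def filter_mutations(
    records: Iterable[MutationRecord],
    ancestral: Iterable[MutationRecord] = (),
    min_frequency: float = DEFAULT_MIN_FREQUENCY,
    classes: frozenset[str] | set[str] = DEFAULT_CLASSES,
) -> list[MutationRecord]:
    """Keep mutations above the frequency cut, of relevant class, and absent
    from the ancestor.

    The frequency comparison is strict (>), so a variant at exactly the
    threshold is dropped. Ancestral presence is judged per variant
    (position, ref, alt) at any ancestral frequency.
    """
    ancestral_keys = {r.variant_key for r in ancestral}
    return [
        r
        for r in records
        if r.frequency > min_frequency
        and r.mutation_class in classes
        and r.variant_key not in ancestral_keys
    ]


def group_by_locus(
    records: Iterable[MutationRecord],
    aliases: Mapping[str, str] | None = None,
) -> list[LocusGroup]:
    """One group per distinct locus; different nucleotide changes in the
    same gene collapse together. ``aliases`` optionally renames loci."""
    groups: dict[str, list[MutationRecord]] = {}
    for r in records:
        locus = aliases.get(r.locus, r.locus) if aliases else r.locus
        groups.setdefault(locus, []).append(r)
    return [LocusGroup(locus, recs) for locus, recs in sorted(groups.items())]


def _venn_signature(lines: frozenset[str]) -> str:
    return "&".join(sorted(lines))


def cross_line_parallelism(
    tables: Mapping[str, Sequence[MutationRecord]],
    ancestral: Iterable[MutationRecord] = (),
    min_frequency: float = DEFAULT_MIN_FREQUENCY,
    classes: frozenset[str] | set[str] = DEFAULT_CLASSES,
    aliases: Mapping[str, str] | None = None,
) -> ParallelismReport:
    """Filter and group each line, then intersect locus sets across lines.

    Reports per-line kept-mutation counts (mean ± sd, sample sd), the locus
    set per line, the loci hit in every line, and the complete Venn
    decomposition (one count per non-empty region signature).
    """
    if len(tables) < 2:
        raise ValueError("parallelism needs at least two replicate lines")
    ancestral = list(ancestral)
    per_line_counts: dict[str, int] = {}
    locus_sets: dict[str, set[str]] = {}
    for sample, records in tables.items():
        kept = filter_mutations(records, ancestral, min_frequency, classes)
        per_line_counts[sample] = len(kept)
        locus_sets[sample] = {g.locus for g in group_by_locus(kept, aliases)}
    counts = np.array(list(per_line_counts.values()), dtype=float)
    union: set[str] = set().union(*locus_sets.values())
    venn: dict[str, int] = {}
    for locus in union:
        region = frozenset(s for s, loci in locus_sets.items() if locus in loci)
        sig = _venn_signature(region)
        venn[sig] = venn.get(sig, 0) + 1
    shared = set.intersection(*locus_sets.values()) if locus_sets else set()
    return ParallelismReport(
        per_line_counts=per_line_counts,
        mean_count=float(counts.mean()),
        sd_count=float(counts.std(ddof=1)),
        locus_sets=locus_sets,
        shared_all_lines=shared,
        venn=venn,
    )
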