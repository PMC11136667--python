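"""Synthetic inputs with known ground truth.

Two generators make every pipeline stage testable without external data:

* mutation-table datasets that emulate population-resequencing output from
  replicate evolution lines — ancestral background variants shared by all
  lines, planted parallel loci hit in every line above the detection
  threshold, and line-private noise — together with a truth record
  sufficient to score any downstream analysis;
* toy stoichiometric networks whose FBA/pFBA optima are known analytically
  (linear chain, alternate-route branch, futile cycle, carbon-losing
  split), used as oracles for the linear-programming machinery.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "MutationSimSpec",
    "SimulatedMutationDataset",
    "generate_mutation_dataset",
    "ToyNetworkSpec",
    "generate_toy_network",
    "GENOME_LENGTH",
]

#: approximate host genome length; positions are drawn without replacement
GENOME_LENGTH = 4_631_000

_LINE_NAMES = "DEFGHIJKLMNOPQRSTUVWXYZ"

_NOISE_CLASSES = ("nonsynonymous", "synonymous", "intergenic", "nonsense", "other")
_NOISE_CLASS_P = (0.45, 0.25, 0.15, 0.05, 0.10)
_KEPT_CLASSES = ("nonsynonymous", "intergenic", "nonsense")
_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class MutationSimSpec:
    """Study-structure parameters for a simulated evolution experiment.

    Defaults mirror the consumed study's design: four serial-dilution
    replicate lines descending from one methylotrophic starter population,
    a few dozen ancestral background variants, eight loci under strong
    parallel selection, and a few hundred line-private mutations per line.
    Planted frequencies are drawn above ``0.60 + threshold_margin`` so they
    always survive the strict 60% frequency filter.
    """

    n_lines: int = 4
    n_ancestral_shared: int = 40
    n_planted_parallel_loci: int = 8
    per_line_private_rate: float = 300.0
    frequency_distribution: tuple[float, float] = (0.05, 1.0)
    threshold_margin: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError("need at least one line")
        if min(self.n_ancestral_shared, self.n_planted_parallel_loci) < 0:
            raise ValueError("counts must be non-negative")
        if self.per_line_private_rate < 0:
            raise ValueError("private rate must be non-negative")
        low, high = self.frequency_distribution
        if not 0.0 <= low <= high <= 1.0:
            raise ValueError("frequency_distribution must satisfy 0 <= low <= high <= 1")
        if not 0.60 + self.threshold_margin < high:
            raise ValueError(
                "threshold margin leaves no room for planted frequencies "
                f"(0.60 + {self.threshold_margin} >= {high})"
            )


@dataclass
class SimulatedMutationDataset:
    lines: dict[str, pd.DataFrame]
    ancestor: pd.DataFrame
    truth: dict
    spec: MutationSimSpec

    def line_records(self):
        """Per-line typed records, as parse_mutation_table would return."""
        from .parallel import MutationRecord

        def _records(df: pd.DataFrame):
            return [
                MutationRecord(
                    sample_id=str(r["sample_id"]),
                    position=int(r["position"]),
                    ref_allele=str(r["ref"]),
                    alt_allele=str(r["alt"]),
                    mutation_class=str(r["class"]),
                    locus=str(r["locus"]),
                    frequency=float(r["frequency"]),
                )
                for r in df.to_dict("records")
            ]

        return {s: _records(df) for s, df in self.lines.items()}, _records(self.ancestor)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for sample, df in self.lines.items():
            df.to_csv(directory / f"line_{sample}.tsv", sep="\t", index=False)
        self.ancestor.to_csv(directory / "ancestor.tsv", sep="\t", index=False)


def _row(sample, pos, ref, alt, cls, locus, freq):
    return {
        "sample_id": sample,
        "position": int(pos),
        "ref": ref,
        "alt": alt,
        "class": cls,
        "locus": locus,
        "frequency": round(float(freq), 4),
    }


def generate_mutation_dataset(spec: MutationSimSpec) -> SimulatedMutationDataset:
    """Simulate per-line mutation tables, the ancestor table, and the truth.

    Guarantees: planted parallel loci occur in every line, in a kept class,
    at frequency > 0.60 + margin; ancestral variants occur in the ancestor
    table and in every line; private noise loci never recur across lines.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [
        _LINE_NAMES[i] if i < len(_LINE_NAMES) else f"L{i}"
        for i in range(spec.n_lines)
    ]
    low, high = spec.frequency_distribution
    planted_low = 0.60 + spec.threshold_margin

    n_private = rng.poisson(spec.per_line_private_rate, size=spec.n_lines)
    total_positions = (
        spec.n_ancestral_shared + spec.n_planted_parallel_loci + int(n_private.sum())
    )
    positions = rng.choice(GENOME_LENGTH, size=total_positions, replace=False) + 1
    positions = iter(positions.tolist())

    def _alleles():
        ref, alt = rng.choice(4, size=2, replace=False)
        return _BASES[ref], _BASES[alt]

    ancestor_rows = []
    ancestral_variants = []
    for i in range(spec.n_ancestral_shared):
        pos = next(positions)
        ref, alt = _alleles()
        cls = _NOISE_CLASSES[rng.choice(len(_NOISE_CLASSES), p=_NOISE_CLASS_P)]
        locus = f"anc{i:04d}"
        ancestral_variants.append((pos, ref, alt, cls, locus))
        ancestor_rows.append(
            _row("IMP", pos, ref, alt, cls, locus, rng.uniform(low, high))
        )

    planted = []
    for i in range(spec.n_planted_parallel_loci):
        pos = next(positions)
        ref, alt = _alleles()
        cls = _KEPT_CLASSES[rng.choice(len(_KEPT_CLASSES))]
        locus = (
            f"i_geneA{i:03d}/geneB{i:03d}" if cls == "intergenic" else f"pg{i:03d}"
        )
        planted.append((pos, ref, alt, cls, locus))

    line_frames = {}
    for k, sample in enumerate(samples):
        rows = []
        for pos, ref, alt, cls, locus in ancestral_variants:
            rows.append(_row(sample, pos, ref, alt, cls, locus, rng.uniform(low, high)))
        for pos, ref, alt, cls, locus in planted:
            rows.append(
                _row(sample, pos, ref, alt, cls, locus, rng.uniform(planted_low, high))
            )
        for j in range(int(n_private[k])):
            pos = next(positions)
            ref, alt = _alleles()
            cls = _NOISE_CLASSES[rng.choice(len(_NOISE_CLASSES), p=_NOISE_CLASS_P)]
            rows.append(
                _row(sample, pos, ref, alt, cls, f"pv_{sample}_{j:04d}", rng.uniform(low, high))
            )
        df = pd.DataFrame(rows).sort_values("position", kind="stable")
        line_frames[sample] = df.reset_index(drop=True)

    truth = {
        "planted_loci": sorted(locus for *_x, locus in planted),
        "ancestral_loci": sorted(locus for *_x, locus in ancestral_variants),
        "samples": samples,
        "seed": spec.seed,
    }
    return SimulatedMutationDataset(
        lines=line_frames,
        ancestor=pd.DataFrame(ancestor_rows),
        truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Toy stoichiometric networks with analytic optima
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyNetworkSpec:
    """``kind`` is linear_chain, branch, futile_cycle or carbon_loss;
    ``uptake`` sets the substrate exchange bound."""

    kind: str
    uptake: float = 10.0


def _toy(mets, rxns, objective) -> MetabolicModel:
    model = MetabolicModel(id="toy", objective_reaction=objective)
    for mid, formula in mets:
        model.add_metabolite(
            Metabolite(id=mid, name=mid, compartment="c", formula=formula, charge=0)
        )
    for rid, stoich, lb, ub in rxns:
        model.add_reaction(
            Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub)
        )
    model.validate()
    return model


def generate_toy_network(spec: ToyNetworkSpec) -> tuple[MetabolicModel, dict]:
    """Build a toy network and its analytic ground truth.

    linear_chain: A → B → sink, optimum = uptake.
    branch: a 1-step and a 3-step route with equal yield; pFBA must route
        all flux through the short one (minimal total flux = 3 × uptake).
    futile_cycle: linear chain plus a stoichiometrically closed 2-cycle;
        pFBA assigns the cycle zero flux.
    carbon_loss: C3 substrate split into a C2 product plus a C1 byproduct,
        versus a direct C3 product; the C2 product's maximal carbon yield
        is 2/3.
    """
    u = spec.uptake
    B = 1000.0
    if spec.kind == "linear_chain":
        model = _toy(
            [("A", "C3H6O3"), ("B", "C3H6O3")],
            [
                ("EX_A", {"A": -1.0}, -u, B),
                ("R1", {"A": -1.0, "B": 1.0}, 0.0, B),
                ("SINK_B", {"B": -1.0}, 0.0, B),
            ],
            "SINK_B",
        )
        truth = {"objective": u, "pfba_total_abs_flux": 3 * u}
    elif spec.kind == "branch":
        model = _toy(
            [("A", "C3H6O3"), ("B", "C3H6O3"), ("X1", "C3H6O3"), ("X2", "C3H6O3")],
            [
                ("EX_A", {"A": -1.0}, -u, B),
                ("SHORT", {"A": -1.0, "B": 1.0}, 0.0, B),
                ("L1", {"A": -1.0, "X1": 1.0}, 0.0, B),
                ("L2", {"X1": -1.0, "X2": 1.0}, 0.0, B),
                ("L3", {"X2": -1.0, "B": 1.0}, 0.0, B),
                ("SINK_B", {"B": -1.0}, 0.0, B),
            ],
            "SINK_B",
        )
        truth = {
            "objective": u,
            "pfba_total_abs_flux": 3 * u,
            "short_route": ["SHORT"],
            "long_route": ["L1", "L2", "L3"],
        }
    elif spec.kind == "futile_cycle":
        model = _toy(
            [("A", "C3H6O3"), ("B", "C3H6O3"), ("C", "C3H6O3")],
            [
                ("EX_A", {"A": -1.0}, -u, B),
                ("R1", {"A": -1.0, "B": 1.0}, 0.0, B),
                ("F1", {"B": -1.0, "C": 1.0}, 0.0, B),
                ("F2", {"C": -1.0, "B": 1.0}, 0.0, B),
                ("SINK_B", {"B": -1.0}, 0.0, B),
            ],
            "SINK_B",
        )
        truth = {
            "objective": u,
            "cycle_reactions": ["F1", "F2"],
            "pfba_total_abs_flux": 3 * u,
        }
    elif spec.kind == "carbon_loss":
        model = _toy(
            [("S", "C3H6O3"), ("P2", "C2H4O2"), ("C1", "CH2O"), ("P3", "C3H6O3")],
            [
                ("EX_S", {"S": -1.0}, -u, B),
                ("SPLIT", {"S": -1.0, "P2": 1.0, "C1": 1.0}, 0.0, B),
                ("DIRECT", {"S": -1.0, "P3": 1.0}, 0.0, B),
                ("EX_P2", {"P2": -1.0}, 0.0, B),
                ("EX_C1", {"C1": -1.0}, 0.0, B),
                ("EX_P3", {"P3": -1.0}, 0.0, B),
            ],
            "EX_P2",
        )
        truth = {
            "objective": u,  # every substrate molecule can be split
            "carbon_yield_P2_percent": 100.0 * 2.0 / 3.0,
            "substrate_exchange": "EX_S",
            "product_exchange": "EX_P2",
        }
    else:
        raise ValueError(f"unknown toy network kind {spec.kind!r}")
    return model, truth
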