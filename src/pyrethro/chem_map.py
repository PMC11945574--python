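"""Registry of parent pyrethroids, urinary metabolites, and their stoichiometric linkage.

Four parent pyrethroids (deltamethrin, permethrin, cypermethrin, cyfluthrin —
the last three as cis/trans isomer pairs) are excreted as a small set of
urinary carboxylic-acid metabolites.  The molar fraction of a parent dose that
appears in urine as a given metabolite, phi(p -> m), together with the molar
masses, fixes the linear map from intake to steady-state urinary excretion.
Some biomarkers are compound-specific (FPBA arises only from cyfluthrin, DBCA
only from deltamethrin); 3PBA and the DCCA isomers are shared by several
parents.

The registry is pure bookkeeping: it validates mass balance (phi row sums
cannot exceed 1) and isomer composition (cis + trans fractions of a parent
group sum to 1) and converts molar transformation fractions into mass yields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from pyrethro.errors import RegistryError, ValidationError

#: The five metabolites quantified in the biennial survey cycles.
MEASURED_METABOLITES = ("3PBA", "FPBA", "DBCA", "cis-DCCA", "trans-DCCA")

#: Metabolite -> sole parent group, for biomarkers specific to one compound.
SPECIFIC_BIOMARKERS = {"FPBA": "cyfluthrin", "DBCA": "deltamethrin"}

#: Default cypermethrin:permethrin intake ratio used when cypermethrin lacks a
#: specific biomarker (informed by pesticide-use reporting; configurable).
CYPERMETHRIN_PERMETHRIN_RATIO = 0.1


@dataclass(frozen=True)
class CompoundSpec:
    """A parent pyrethroid (or one isomer of it).

    ``parent_group`` collects isomers: cis- and trans-permethrin share the
    group ``permethrin`` and their ``isomer_fraction`` values sum to 1.
    """

    id: str
    molar_mass: float  # g/mol
    parent_group: str
    isomer_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValidationError(f"compound {self.id!r}: molar_mass must be > 0")
        if not 0.0 <= self.isomer_fraction <= 1.0:
            raise ValidationError(
                f"compound {self.id!r}: isomer_fraction {self.isomer_fraction} outside [0, 1]"
            )


@dataclass(frozen=True)
class MetaboliteSpec:
    """A urinary metabolite; ``measured`` marks the five surveyed biomarkers."""

    id: str
    molar_mass: float  # g/mol
    measured: bool = True

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValidationError(f"metabolite {self.id!r}: molar_mass must be > 0")


@dataclass(frozen=True)
class TransformationMatrix:
    """Molar fractions phi(parent -> metabolite), sparse over declared pathways."""

    entries: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def phi(self, compound_id: str, metabolite_id: str) -> float:
        return self.entries.get((compound_id, metabolite_id), 0.0)

    def row(self, compound_id: str) -> dict[str, float]:
        return {m: v for (c, m), v in self.entries.items() if c == compound_id}


@dataclass(frozen=True)
class Registry:
    """A validated chemical registry; construct via :func:`validate_registry`."""

    compounds: Mapping[str, CompoundSpec]
    metabolites: Mapping[str, MetaboliteSpec]
    matrix: TransformationMatrix
    specific_biomarkers: Mapping[str, str] = field(default_factory=dict)

    def compound(self, compound_id: str) -> CompoundSpec:
        try:
            return self.compounds[compound_id]
        except KeyError:
            raise RegistryError(f"unknown compound id {compound_id!r}") from None

    def metabolite(self, metabolite_id: str) -> MetaboliteSpec:
        try:
            return self.metabolites[metabolite_id]
        except KeyError:
            raise RegistryError(f"unknown metabolite id {metabolite_id!r}") from None

    def measured_metabolites(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.measured]

    def parents_of(self, metabolite_id: str) -> list[str]:
        """Compound ids with a nonzero pathway into ``metabolite_id``."""
        self.metabolite(metabolite_id)
        return [
            c for (c, m), v in self.matrix.entries.items() if m == metabolite_id and v > 0
        ]

    def mass_yield(self, compound_id: str, metabolite_id: str) -> float:
        return metabolite_mass_yield(
            self.compound(compound_id), self.metabolite(metabolite_id), self.matrix
        )


def validate_registry(
    compounds: Iterable[CompoundSpec],
    metabolites: Iterable[MetaboliteSpec],
    matrix: TransformationMatrix,
) -> Registry:
    """Check all registry invariants and return an immutable :class:`Registry`.

    Raises
    ------
    RegistryError
        if a matrix index does not resolve to a declared compound/metabolite.
    ValidationError
        if a phi is outside [0, 1], a phi row sums above 1 (mass-balance
        violation), a required measured metabolite is missing, or isomer
        fractions within a parent group do not sum to 1.
    """
    cmap = {c.id: c for c in compounds}
    mmap = {m.id: m for m in metabolites}

    missing = [m for m in MEASURED_METABOLITES if m not in mmap]
    if missing:
        raise ValidationError(f"measured metabolites missing from registry: {missing}")

    for (cid, mid), phi in matrix.entries.items():
        if cid not in cmap:
            raise RegistryError(f"matrix references unknown compound {cid!r}")
        if mid not in mmap:
            raise RegistryError(f"matrix references unknown metabolite {mid!r}")
        if not 0.0 <= phi <= 1.0:
            raise ValidationError(f"phi({cid} -> {mid}) = {phi} outside [0, 1]")

    for cid in cmap:
        row_sum = sum(matrix.row(cid).values())
        if row_sum > 1.0 + 1e-9:
            raise ValidationError(
                f"phi row for {cid!r} sums to {row_sum:.4g} > 1 (mass-balance violation)"
            )

    groups: dict[str, float] = {}
    for c in cmap.values():
        groups[c.parent_group] = groups.get(c.parent_group, 0.0) + c.isomer_fraction
    for group, total in groups.items():
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValidationError(
                f"isomer fractions of parent group {group!r} sum to {total:.4g}, expected 1"
            )

    specific = {}
    for mid, group in SPECIFIC_BIOMARKERS.items():
        if mid in mmap:
            offenders = [
                c
                for (c, m), v in matrix.entries.items()
                if m == mid and v > 0 and cmap[c].parent_group != group
            ]
            if offenders:
                raise ValidationError(
                    f"{mid} is specific to {group} but has pathways from {offenders}"
                )
            specific[mid] = group

    return Registry(cmap, mmap, matrix, specific)


def metabolite_mass_yield(
    compound: CompoundSpec, metabolite: MetaboliteSpec, matrix: TransformationMatrix
) -> float:
    """Mass of metabolite excreted per unit mass of parent absorbed.

    phi(p -> m) * MW_m / MW_p — the molar fraction rescaled to a mass basis.
    Zero when no pathway exists.
    """
    phi = matrix.phi(compound.id, metabolite.id)
    return phi * metabolite.molar_mass / compound.molar_mass


# ---------------------------------------------------------------------------
# File representation (CSV round-trip)
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("pyrethro").joinpath("data", name)))


def load_registry(
    compounds_csv: str | Path | None = None,
    metabolites_csv: str | Path | None = None,
    matrix_csv: str | Path | None = None,
) -> Registry:
    """Load and validate a registry from CSV files (package defaults if None)."""
    cdf = pd.read_csv(compounds_csv or _data_path("compounds.csv"))
    mdf = pd.read_csv(metabolites_csv or _data_path("metabolites.csv"))
    xdf = pd.read_csv(matrix_csv or _data_path("transformation.csv"))
    compounds = [
        CompoundSpec(r.id, float(r.molar_mass), r.parent_group, float(r.isomer_fraction))
        for r in cdf.itertuples()
    ]
    metabolites = [
        MetaboliteSpec(r.id, float(r.molar_mass), bool(r.measured)) for r in mdf.itertuples()
    ]
    matrix = TransformationMatrix(
        {(r.compound, r.metabolite): float(r.phi) for r in xdf.itertuples()}
    )
    return validate_registry(compounds, metabolites, matrix)


def save_registry(registry: Registry, directory: str | Path) -> dict[str, Path]:
    """Write the three registry CSVs; numeric fields round-trip via repr."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": directory / "compounds.csv",
        "metabolites": directory / "metabolites.csv",
        "matrix": directory / "transformation.csv",
    }
    pd.DataFrame(
        [
            {
                "id": c.id,
                "role": "compound",
                "molar_mass": repr(c.molar_mass),
                "parent_group": c.parent_group,
                "isomer_fraction": repr(c.isomer_fraction),
            }
            for c in registry.compounds.values()
        ]
    ).to_csv(paths["compounds"], index=False)
    pd.DataFrame(
        [
            {"id": m.id, "role": "metabolite", "molar_mass": repr(m.molar_mass), "measured": m.measured}
            for m in registry.metabolites.values()
        ]
    ).to_csv(paths["metabolites"], index=False)
    pd.DataFrame(
        [
            {"compound": c, "metabolite": m, "phi": repr(v)}
            for (c, m), v in registry.matrix.entries.items()
        ]
    ).to_csv(paths["matrix"], index=False)
    return paths


def default_registry() -> Registry:
    """The packaged default registry (versioned data files)."""
    return load_registry()
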