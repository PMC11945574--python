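"""Known-truth generators for survey tables and dose-response datasets.

The survey generator is the population model run forward: individual
intakes are lognormal around a stratum geometric mean, pushed through the
linear steady-state map to urine concentrations, multiplied by a lognormal
residual, and left-censored at metabolite- and cycle-specific LODs.  Body
weights are sampled from fixed reference lognormals per age group.  The
default scenario mimics the structure of the U.S. biennial survey: seven
cycles, five age groups, five metabolites, LODs varying by cycle, and
metabolite coverage that shrinks over time (cis-DCCA and DBCA phased out,
a final cycle carrying only three analytes).

Everything is reproducible from an explicit integer seed, and every
generator returns the ground truth alongside the data so recovery tests
can score the inference.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pyrethro import bmd as bmd_mod
from pyrethro.chem_map import CYPERMETHRIN_PERMETHRIN_RATIO, Registry, default_registry
from pyrethro.errors import ValidationError
from pyrethro.pbk import (
    MG_PER_L_TO_NG_PER_ML,
    PbkParameters,
    Physiology,
    _physiology_table,
)
from pyrethro.survey_data import SurveyTable

DEFAULT_CYCLES = (
    "1999-2000",
    "2001-2002",
    "2007-2008",
    "2009-2010",
    "2011-2012",
    "2013-2014",
    "2015-2016",
)

#: Cycle -> metabolites surveyed; mirrors the gradual phase-out of cis-DCCA
#: and DBCA and the three-analyte final cycle.
DEFAULT_COVERAGE: dict[str, tuple[str, ...]] = {
    "1999-2000": ("3PBA", "FPBA", "DBCA", "cis-DCCA", "trans-DCCA"),
    "2001-2002": ("3PBA", "FPBA", "DBCA", "cis-DCCA", "trans-DCCA"),
    "2007-2008": ("3PBA", "FPBA", "DBCA", "cis-DCCA", "trans-DCCA"),
    "2009-2010": ("3PBA", "FPBA", "DBCA", "trans-DCCA"),
    "2011-2012": ("3PBA", "FPBA", "trans-DCCA"),
    "2013-2014": ("3PBA", "FPBA", "trans-DCCA"),
    "2015-2016": ("3PBA", "FPBA", "trans-DCCA"),
}


@dataclass(frozen=True)
class GeneratorTruth:
    """Ground truth of a synthetic survey scenario.

    ``intake`` maps (parent group, age group, cycle) to (GM mg/kg/day, GSD);
    ``lods`` maps (metabolite, cycle) to the LOD in ng/mL.
    """

    intake: Mapping[tuple[str, str, str], tuple[float, float]]
    residual_gsd: float
    lods: Mapping[tuple[str, str], float]
    n_per_stratum: int
    seed: int
    coverage: Mapping[str, Sequence[str]] = field(default_factory=lambda: dict(DEFAULT_COVERAGE))
    derived_ratios: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: {"cypermethrin": ("permethrin", CYPERMETHRIN_PERMETHRIN_RATIO)}
    )

    def __post_init__(self) -> None:
        for key, (gm, gsd) in self.intake.items():
            if not 1e-12 <= gm <= 1.0:
                raise ValidationError(f"intake GM {gm} for {key} outside prior support [1e-12, 1]")
            if gsd < 1:
                raise ValidationError(f"intake GSD {gsd} for {key} must be >= 1")
        if self.residual_gsd < 1:
            raise ValidationError("residual GSD must be >= 1")
        if any(l <= 0 for l in self.lods.values()):
            raise ValidationError("all LODs must be > 0")
        if self.n_per_stratum < 1:
            raise ValidationError("n_per_stratum must be >= 1")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "intake": {"|".join(k): v for k, v in self.intake.items()},
            "residual_gsd": self.residual_gsd,
            "lods": {"|".join(k): v for k, v in self.lods.items()},
            "n_per_stratum": self.n_per_stratum,
            "seed": self.seed,
            "coverage": {k: list(v) for k, v in self.coverage.items()},
            "derived_ratios": {k: list(v) for k, v in self.derived_ratios.items()},
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def body_weight_distribution(age_group: str) -> tuple[float, float]:
    """Reference (GM kg, GSD) of body weight for a life-stage group."""
    df = _physiology_table()
    row = df[df.age_group == age_group]
    if row.empty:
        raise ValidationError(f"unknown age group {age_group!r}")
    return float(row.iloc[0].body_weight_gm), float(row.iloc[0].body_weight_gsd)


def default_truth(
    seed: int = 0,
    n_per_stratum: int = 300,
    age_groups: Sequence[str] = ("<6", "6-11", "12-19", "20-65", ">65"),
    cycles: Sequence[str] = DEFAULT_CYCLES,
    residual_gsd: float = 1.7,
) -> GeneratorTruth:
    """The default scenario: intake levels near the reconstructed population
    GMs, children elevated about two-fold, and a mild upward time trend."""
    base = {"deltamethrin": 3.83e-5, "permethrin": 2.25e-3, "cyfluthrin": 6.79e-5}
    age_factor = {"<6": 2.0, "6-11": 1.8, "12-19": 1.2, "20-65": 1.0, ">65": 0.9}
    intake = {}
    for g, gm in base.items():
        for a in age_groups:
            for i, cyc in enumerate(cycles):
                trend = 1.0 + i / max(1, len(cycles) - 1)  # doubles across cycles
                intake[(g, a, cyc)] = (gm * age_factor[a] * trend, 2.0)
    lod_base = {"3PBA": 0.1, "FPBA": 0.1, "DBCA": 0.1, "cis-DCCA": 0.1, "trans-DCCA": 0.1}
    lods = {}
    for i, cyc in enumerate(cycles):
        for m, l in lod_base.items():
            lods[(m, cyc)] = l * (1.2 if i < 2 else 0.6)  # assay improved over time
    return GeneratorTruth(
        intake=intake,
        residual_gsd=residual_gsd,
        lods=lods,
        n_per_stratum=n_per_stratum,
        seed=seed,
        coverage={c: DEFAULT_COVERAGE[c] for c in cycles} if set(cycles) <= set(DEFAULT_COVERAGE) else {c: tuple(lod_base) for c in cycles},
    )


def load_truth(path: str | Path) -> GeneratorTruth:
    """Read a scenario config (TOML) into a GeneratorTruth."""
    doc = tomllib.loads(Path(path).read_text())
    intake = {
        tuple(k.split("|")): (float(v[0]), float(v[1])) for k, v in doc["intake"].items()
    }
    lods = {tuple(k.split("|")): float(v) for k, v in doc["lods"].items()}
    return GeneratorTruth(
        intake=intake,
        residual_gsd=float(doc["residual_gsd"]),
        lods=lods,
        n_per_stratum=int(doc["n_per_stratum"]),
        seed=int(doc["seed"]),
        coverage={k: tuple(v) for k, v in doc.get("coverage", DEFAULT_COVERAGE).items()},
        derived_ratios={k: (v[0], float(v[1])) for k, v in doc.get(
            "derived_ratios", {"cypermethrin": ["permethrin", CYPERMETHRIN_PERMETHRIN_RATIO]}
        ).items()},
    )


def generate_survey(
    truth: GeneratorTruth,
    registry: Registry | None = None,
    params: Mapping[str, PbkParameters] | None = None,
    physiology_by_age: Mapping[str, Physiology] | None = None,
) -> tuple[SurveyTable, GeneratorTruth]:
    """Sample a survey table from the forward population model.

    Per stratum: body weights lognormal per age group; one latent intake per
    (individual, parent group) lognormal(GM, GSD); concentrations through the
    steady-state map times a lognormal residual; censoring at the (metabolite,
    cycle) LOD.  With residual GSD 1 and LODs below every concentration the
    table is the deterministic image of the latent intakes.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(truth.seed)

    strata = sorted({(a, c) for (_, a, c) in truth.intake})
    groups_by_stratum: dict[tuple[str, str], list[str]] = {}
    for (g, a, c) in truth.intake:
        groups_by_stratum.setdefault((a, c), []).append(g)

    group_members: dict[str, list[str]] = {}
    for cid, spec in registry.compounds.items():
        group_members.setdefault(spec.parent_group, []).append(cid)

    def coeff(group: str, mid: str) -> float:
        total = 0.0
        for cid in group_members.get(group, []):
            spec = registry.compound(cid)
            f_abs = params[cid].f_abs if params is not None else 1.0
            total += spec.isomer_fraction * f_abs * registry.mass_yield(cid, mid)
        return total

    rows = []
    for (age, cyc) in strata:
        if physiology_by_age is not None:
            phys = physiology_by_age[age]
            bw_gm, bw_gsd = phys.body_weight, 1.0
            v_urine = phys.daily_urine_volume
            creat = phys.urine_creatinine
        else:
            bw_gm, bw_gsd = body_weight_distribution(age)
            ref = Physiology.reference(age)
            v_urine = ref.daily_urine_volume
            creat = ref.urine_creatinine
        n = truth.n_per_stratum
        bw = bw_gm * np.exp(rng.standard_normal(n) * math.log(bw_gsd)) if bw_gsd > 1 else np.full(n, bw_gm)
        creatinine = creat * np.exp(rng.standard_normal(n) * math.log(1.4))

        groups = sorted(groups_by_stratum[(age, cyc)])
        intakes = {}
        for g in groups:
            gm, gsd = truth.intake[(g, age, cyc)]
            intakes[g] = gm * np.exp(rng.standard_normal(n) * math.log(gsd)) if gsd > 1 else np.full(n, gm)
        for dgroup, (src, ratio) in truth.derived_ratios.items():
            if src in intakes and dgroup not in intakes:
                intakes[dgroup] = ratio * intakes[src]

        mets = truth.coverage.get(cyc, ())
        subject_ids = np.array([f"{age}|{cyc}|{i:05d}" for i in range(n)])
        for mid in mets:
            lod = truth.lods[(mid, cyc)]
            conc = np.zeros(n)
            for g, vals in intakes.items():
                conc += coeff(g, mid) * vals
            conc *= bw / v_urine * MG_PER_L_TO_NG_PER_ML
            if truth.residual_gsd > 1:
                conc = conc * np.exp(rng.standard_normal(n) * math.log(truth.residual_gsd))
            cens = conc < lod
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": subject_ids,
                        "cycle": cyc,
                        "age_group": age,
                        "body_weight": bw,
                        "metabolite": mid,
                        "value": np.where(cens, np.nan, conc),
                        "lod": lod,
                        "below_lod": cens,
                        "creatinine": creatinine,
                    }
                )
            )
    return SurveyTable(pd.concat(rows, ignore_index=True)), truth


def recovery_truth(
    seed: int,
    n_per_stratum: int = 500,
    censored_fraction: float = 0.3,
    gm: float = 1e-5,
    pop_gsd: float = 2.0,
    residual_gsd: float = 1.7,
    age_group: str = "6-11",
    cycle: str = "2001-2002",
    registry: Registry | None = None,
    params: Mapping[str, PbkParameters] | None = None,
    calibration_n: int = 20000,
) -> GeneratorTruth:
    """Single-stratum scenario with LODs placed at a target censoring quantile.

    A large uncensored calibration sample fixes each metabolite's LOD at the
    ``censored_fraction`` quantile of its concentration distribution, so the
    generated survey censors approximately that fraction of records.
    """
    registry = registry or default_registry()
    groups = sorted({c.parent_group for c in registry.compounds.values()})
    free = [g for g in groups if g != "cypermethrin"]
    intake = {(g, age_group, cycle): (gm, pop_gsd) for g in free}
    mets = [m for m in registry.measured_metabolites()]
    if censored_fraction <= 0:
        lods = {(m, cycle): 1e-12 for m in mets}
    else:
        calib = GeneratorTruth(
            intake=intake,
            residual_gsd=residual_gsd,
            lods={(m, cycle): 1e-12 for m in mets},
            n_per_stratum=calibration_n,
            seed=seed + 1,
            coverage={cycle: tuple(mets)},
        )
        table, _ = generate_survey(calib, registry, params)
        lods = {}
        for m in mets:
            vals = table.frame[table.frame.metabolite == m].value.to_numpy()
            lods[(m, cycle)] = float(np.quantile(vals, censored_fraction))
    return GeneratorTruth(
        intake=intake,
        residual_gsd=residual_gsd,
        lods=lods,
        n_per_stratum=n_per_stratum,
        seed=seed,
        coverage={cycle: tuple(mets)},
    )


# ---------------------------------------------------------------------------
# Dose-response generator
# ---------------------------------------------------------------------------

def generate_doseresponse(
    family: str,
    parameters: Sequence[float],
    control_sd: float,
    doses: Sequence[float],
    n_per_group: int,
    seed: int = 0,
    sampling_noise: bool = True,
    endpoint: str = "locomotor activity",
) -> tuple[bmd_mod.DoseResponseData, dict]:
    """Sample group summaries around a known dose-response curve.

    ``parameters`` use the same raw parameterization as the fitting module's
    mean functions.  The truth record carries the analytic BMD at a
    one-control-SD benchmark response (``inf`` when the curve never drops
    that far — e.g. a flat curve).
    """
    if family not in bmd_mod.FAMILIES:
        raise ValidationError(f"unknown family {family!r}")
    theta = np.asarray(parameters, dtype=float)
    d = np.asarray(doses, dtype=float)
    rng = np.random.default_rng(seed)
    f = bmd_mod._MEANS[family](theta, d)
    if sampling_noise:
        means = f + control_sd / np.sqrt(n_per_group) * rng.standard_normal(d.size)
        # group SDs drawn from the sampling distribution of a normal SD
        sds = control_sd * np.sqrt(
            rng.chisquare(n_per_group - 1, size=d.size) / (n_per_group - 1)
        )
    else:
        means = f.copy()
        sds = np.full(d.size, control_sd)
    data = bmd_mod.DoseResponseData(d, np.full(d.size, n_per_group), means, sds, endpoint)
    true_bmd = bmd_mod._bmd_from_draw(family, theta, control_sd, float(d.max()))
    truth = {
        "family": family,
        "parameters": theta.tolist(),
        "control_sd": control_sd,
        "bmd": true_bmd,
        "unbounded": not np.isfinite(true_bmd),
        "seed": seed,
    }
    return data, truth
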