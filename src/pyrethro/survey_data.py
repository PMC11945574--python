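"""Censored urinary biomarker surveys: data model and descriptive statistics.

A survey table is a long-format collection of individual spot-urine
measurements: one row per (subject, metabolite) with the reported
concentration, the assay limit of detection (LOD) in force for that
metabolite and cycle, and a left-censoring flag.  Descriptive statistics
here substitute LOD/sqrt(2) for non-detects by default (LOD/2 and 0 are
selectable); the Bayesian inference module never substitutes — it uses the
censored likelihood directly.

Variability is summarized by the ratio of the 95th to the 50th percentile
(P95/P50); for a lognormal population this converges to GSD**1.6449.
Exposure similarity across age groups is assessed by hierarchical
clustering of log10 median concentrations over cycles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from pyrethro.errors import DomainError, ValidationError
from pyrethro.pbk import AGE_GROUPS

#: z-score of the 95th percentile; P95/P50 of a lognormal is GSD ** this.
Z_95 = 1.6449

CensorPolicy = Literal["sqrt2", "half", "zero"]

_COLUMNS = [
    "subject_id",
    "cycle",
    "age_group",
    "body_weight",
    "metabolite",
    "value",
    "lod",
    "below_lod",
    "creatinine",
]


@dataclass(frozen=True)
class UrineRecord:
    """One (subject, metabolite) spot-urine measurement."""

    subject_id: str
    cycle: str
    age_group: str
    body_weight: float  # kg
    metabolite: str
    concentration: float | None  # ng/mL; None when censored
    lod: float  # ng/mL
    below_lod: bool
    creatinine: float | None = None  # g/L

    def __post_init__(self) -> None:
        if not self.lod > 0:
            raise ValidationError("lod must be > 0")
        if self.below_lod and self.concentration is not None:
            raise ValidationError("censored record must not carry a concentration")
        if not self.below_lod and (self.concentration is None or self.concentration < self.lod):
            raise ValidationError("detected record must carry concentration >= lod")
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(f"unknown age group {self.age_group!r}")


class SurveyTable:
    """Long-format survey of censored biomarker records, backed by a DataFrame."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _COLUMNS if c not in frame.columns and c != "creatinine"]
        if missing:
            raise ValidationError(f"survey table missing columns: {missing}")
        frame = frame.copy()
        if "creatinine" not in frame.columns:
            frame["creatinine"] = np.nan
        if (frame["lod"] <= 0).any():
            raise ValidationError("all LODs must be > 0")
        cens = frame["below_lod"].astype(bool)
        det = frame.loc[~cens, "value"]
        if det.isna().any():
            raise ValidationError("detected records must carry a value")
        if (det < frame.loc[~cens, "lod"] - 1e-12).any():
            raise ValidationError("detected values must be >= their LOD")
        frame.loc[cens, "value"] = np.nan
        frame["below_lod"] = cens
        self.frame = frame.reset_index(drop=True)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(cls, records: Sequence[UrineRecord]) -> "SurveyTable":
        rows = [
            {
                "subject_id": r.subject_id,
                "cycle": r.cycle,
                "age_group": r.age_group,
                "body_weight": r.body_weight,
                "metabolite": r.metabolite,
                "value": r.concentration,
                "lod": r.lod,
                "below_lod": r.below_lod,
                "creatinine": r.creatinine,
            }
            for r in records
        ]
        return cls(pd.DataFrame(rows))

    @classmethod
    def read_csv(cls, path: str | Path) -> "SurveyTable":
        return cls(pd.read_csv(path, dtype={"subject_id": str, "cycle": str}))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    # -- basic views --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def coverage(self) -> pd.DataFrame:
        """(cycle, metabolite) pairs present, with record counts."""
        return (
            self.frame.groupby(["cycle", "metabolite"], observed=True)
            .size()
            .rename("n")
            .reset_index()
        )

    def select(
        self,
        metabolite: str | None = None,
        cycle: str | None = None,
        age_group: str | None = None,
    ) -> pd.DataFrame:
        df = self.frame
        if metabolite is not None:
            df = df[df.metabolite == metabolite]
        if cycle is not None:
            df = df[df.cycle == cycle]
        if age_group is not None:
            df = df[df.age_group == age_group]
        return df

    def imputed_values(
        self,
        metabolite: str | None = None,
        cycle: str | None = None,
        age_group: str | None = None,
        policy: CensorPolicy = "sqrt2",
    ) -> np.ndarray:
        """Concentrations with non-detects substituted per the stated policy."""
        df = self.select(metabolite, cycle, age_group)
        vals = df["value"].to_numpy(dtype=float)
        lods = df["lod"].to_numpy(dtype=float)
        cens = df["below_lod"].to_numpy(dtype=bool)
        sub = {"sqrt2": lods / np.sqrt(2.0), "half": lods / 2.0, "zero": np.zeros_like(lods)}[policy]
        vals = np.where(cens, sub, vals)
        return vals


def read_xpt_survey(
    path: str | Path,
    columns: Mapping[str, tuple[str, str, float]],
    cycle: str,
    subject_col: str = "SEQN",
    age_group_col: str | None = None,
    body_weight_col: str | None = None,
    default_age_group: str = "20-65",
    default_body_weight: float = 80.0,
) -> SurveyTable:
    """Ingest a SAS transport (XPT) laboratory file into a SurveyTable.

    ``columns`` maps metabolite id -> (value column, comment-code column,
    LOD).  The comment-code convention maps coded missingness to censoring:
    code 1 means below the detection limit, code 0 a quantified value; rows
    with a missing value and no code are dropped.
    """
    raw = pd.read_sas(path, format="xport")
    rows = []
    for mid, (value_col, lc_col, lod) in columns.items():
        if value_col not in raw.columns:
            continue
        sub = pd.DataFrame(
            {
                "subject_id": raw[subject_col].astype("Int64").astype(str),
                "cycle": cycle,
                "age_group": raw[age_group_col] if age_group_col else default_age_group,
                "body_weight": raw[body_weight_col] if body_weight_col else default_body_weight,
                "metabolite": mid,
                "value": raw[value_col],
                "lod": lod,
                "below_lod": (
                    raw[lc_col] == 1 if lc_col in raw.columns else raw[value_col] < lod
                ),
                "creatinine": np.nan,
            }
        )
        sub = sub[sub.below_lod | sub.value.notna()]
        sub.loc[sub.below_lod, "value"] = np.nan
        # assay rounding can report detected values a hair under the LOD
        detected = ~sub.below_lod
        sub.loc[detected, "value"] = np.maximum(sub.loc[detected, "value"], lod)
        rows.append(sub)
    if not rows:
        raise ValidationError("no mapped metabolite columns found in the XPT file")
    return SurveyTable(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

def detection_rate(
    table: SurveyTable,
    metabolite: str,
    cycle: str | None = None,
    age_group: str | None = None,
) -> float:
    """Fraction of records at or above the LOD in the selection."""
    df = table.select(metabolite, cycle, age_group)
    if df.empty:
        raise DomainError("empty selection")
    return float(1.0 - df["below_lod"].mean())


def percentile_ratio(
    values: np.ndarray | Sequence[float],
    upper: float = 95.0,
    lower: float = 50.0,
    min_n: int = 20,
) -> float:
    """P_upper / P_lower by linear interpolation between order statistics.

    The type-7 quantile rule is stated because the ratio on small strata is
    sensitive to it.
    """
    x = np.asarray(values, dtype=float)
    if x.size < min_n:
        raise DomainError(f"need >= {min_n} values, got {x.size}")
    p_lo = float(np.percentile(x, lower))  # numpy default = type-7 linear
    if p_lo <= 0:
        raise DomainError("lower percentile is zero; ratio undefined")
    return float(np.percentile(x, upper)) / p_lo


def geometric_mean_trend(
    table: SurveyTable,
    metabolite: str,
    policy: CensorPolicy = "sqrt2",
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Per-cycle geometric mean with a log-scale normal-approximation CI.

    Cycles in which every record is censored are flagged (``all_censored``)
    and their GM reported as the below-LOD bound (geometric mean of the
    substituted values).
    """
    from scipy.stats import norm

    df = table.select(metabolite=metabolite)
    cycles = sorted(df["cycle"].unique())
    if len(cycles) < 2:
        raise DomainError("metabolite measured in fewer than 2 cycles")
    z = norm.ppf(0.5 + confidence / 2)
    rows = []
    for cyc in cycles:
        vals = table.imputed_values(metabolite, cycle=cyc, policy=policy)
        vals = np.maximum(vals, 1e-12)  # zero-substitution guard on log scale
        logs = np.log(vals)
        gm = float(np.exp(logs.mean()))
        se = logs.std(ddof=1) / np.sqrt(len(logs)) if len(logs) > 1 else 0.0
        all_cens = bool(df[df.cycle == cyc]["below_lod"].all())
        rows.append(
            {
                "cycle": cyc,
                "gm": gm,
                "ci_low": float(np.exp(logs.mean() - z * se)),
                "ci_high": float(np.exp(logs.mean() + z * se)),
                "n": len(logs),
                "all_censored": all_cens,
            }
        )
    return pd.DataFrame(rows)


def age_group_similarity(
    median_matrix: pd.DataFrame,
    n_clusters: int = 2,
    already_log: bool = False,
) -> dict:
    """Hierarchical clustering of age groups by exposure profile.

    ``median_matrix`` is age_group x cycle of median exposures (or
    concentrations).  Rows are compared by Euclidean distance on log10
    values with average linkage; the result is deterministic given inputs.
    """
    if median_matrix.shape[0] < 2:
        raise DomainError("need at least 2 age groups")
    if median_matrix.isna().any().any():
        raise DomainError("median matrix must be complete")
    x = median_matrix.to_numpy(dtype=float)
    if not already_log:
        if (x <= 0).any():
            raise DomainError("medians must be > 0 for log10 transform")
        x = np.log10(x)
    dist = pdist(x, metric="euclidean")
    z = linkage(dist, method="average")
    labels = fcluster(z, t=n_clusters, criterion="maxclust")
    return {
        "linkage": z,
        "labels": dict(zip(median_matrix.index, labels.tolist())),
        "order": list(median_matrix.index),
    }
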