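"""Combined QSPR screening over binding-mode and reactivity descriptors.

The screening rule works on the (R+, R−, RMSD_BM) triple of a candidate
against a reference ligand.  Candidates whose relative donating/accepting
powers both fall at or below configurable caps sit in the "low-R" region —
they bind the kinase comparably to the reference — and are then split by
their binding-mode distance: below the cut they are anti-cancer-like
(binding mode close to the reference's), above it anti-viral-like.
Everything else is "outside".  Correlation summaries between descriptor
series use Pearson or Spearman coefficients; Spearman is the right choice
for the monotone-but-nonlinear relations these descriptors typically show.
"""

from __future__ import annotations

from typing import Literal, Mapping, Optional, Sequence

from pydantic import BaseModel, model_validator
from scipy import stats

from .errors import DomainError, SchemaError

__all__ = [
    "LigandRecord",
    "ScreeningThresholds",
    "ScreeningOutcome",
    "classify_ligand",
    "correlate",
    "assemble_table",
]

ANTI_CANCER = "anti-cancer-like"
ANTI_VIRAL = "anti-viral-like"
OUTSIDE = "outside"


class LigandRecord(BaseModel):
    """Per-ligand descriptor aggregation for screening."""

    ligand_id: str
    rmsd_bm_vs_reference: float
    r_plus: float
    r_minus: float
    binding_affinity: Optional[float] = None
    affinity_unit: str = "kcal/mol"
    activity_label: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "LigandRecord":
        if self.rmsd_bm_vs_reference < 0:
            raise ValueError("rmsd_bm_vs_reference must be >= 0")
        if self.r_plus <= 0 or self.r_minus <= 0:
            raise ValueError("relative reactivities must be positive")
        return self


class ScreeningThresholds(BaseModel):
    """Region boundaries; configuration, not constants.

    Defaults: R caps 1.1 (the low-R region that separates the strong dCK
    binders from the rest on the reference panel) and RMSD_BM cut 1.4.
    """

    r_plus_max: float = 1.1
    r_minus_max: float = 1.1
    rmsd_bm_cut: float = 1.4


class ScreeningOutcome(BaseModel):
    ligand_id: str = ""
    in_low_R_region: bool
    classification: Literal["anti-cancer-like", "anti-viral-like", "outside"]
    thresholds_used: ScreeningThresholds

    @model_validator(mode="after")
    def _check(self) -> "ScreeningOutcome":
        if (self.classification == OUTSIDE) == self.in_low_R_region:
            raise ValueError("classification inconsistent with region flag")
        return self


def classify_ligand(
    rec: LigandRecord, thresholds: ScreeningThresholds | None = None
) -> ScreeningOutcome:
    """Apply the combined (R+, R−, RMSD_BM) screening rule to one ligand."""
    th = thresholds or ScreeningThresholds()
    in_region = rec.r_plus <= th.r_plus_max and rec.r_minus <= th.r_minus_max
    if not in_region:
        cls = OUTSIDE
    elif rec.rmsd_bm_vs_reference < th.rmsd_bm_cut:
        cls = ANTI_CANCER
    else:
        cls = ANTI_VIRAL
    return ScreeningOutcome(
        ligand_id=rec.ligand_id,
        in_low_R_region=in_region,
        classification=cls,
        thresholds_used=th,
    )


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "spearman"
) -> float:
    """Pearson or Spearman correlation between two descriptor series."""
    if len(x) != len(y):
        raise SchemaError(f"series lengths differ: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise DomainError("need at least 3 paired observations")
    if len(set(x)) < 2 or len(set(y)) < 2:
        raise DomainError("zero variance in one of the series")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise DomainError(f"unknown method {method!r}; use 'pearson' or 'spearman'")


def assemble_table(
    rmsd_bm: Mapping[str, float],
    relative: Mapping[str, tuple[float, float]],
    affinity: Mapping[str, float] | None = None,
    affinity_unit: str = "kcal/mol",
    activity: Mapping[str, str] | None = None,
) -> tuple[list[LigandRecord], dict[str, list[str]]]:
    """Inner-join per-ligand sources into screening records.

    Returns the records (for ids present in both mandatory sources) plus a
    report of ids missing from either side.  Duplicate ids within a source
    mapping are impossible by construction; conflicting duplicates across
    DataFrame-derived inputs must be resolved upstream.
    """
    rmsd_ids, rel_ids = set(rmsd_bm), set(relative)
    shared = sorted(rmsd_ids & rel_ids)
    report = {
        "missing_rmsd_bm": sorted(rel_ids - rmsd_ids),
        "missing_relative": sorted(rmsd_ids - rel_ids),
    }
    records = []
    for lig in shared:
        rp, rm = relative[lig]
        records.append(
            LigandRecord(
                ligand_id=lig,
                rmsd_bm_vs_reference=rmsd_bm[lig],
                r_plus=rp,
                r_minus=rm,
                binding_affinity=None if affinity is None else affinity.get(lig),
                affinity_unit=affinity_unit,
                activity_label=None if activity is None else activity.get(lig),
            )
        )
    return records, report
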