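"""Cross-study comparison of mismatch-type effects.

Different reports summarize the effect of the 12 single-base mismatch types
with different statistics, notations and directions.  This module harmonizes
them: conversion between PM->MM notation and the duplex (probe base, target
base) notation, consolidation of the 12 types into the Watson-Crick pair
class they disrupt (A-T vs C-G), rank vectors and stability orders, pairwise
Spearman/Pearson correlation with two-sided p-values at N = 12, and flagging
of types whose stability-list position violates the pair-class block rule.

Direction conventions: "discrimination" vectors use the log2(PM/MM)
convention (larger value = the mismatch destabilizes the duplex more);
"stability" vectors are the opposite (larger = more stable).  The stability
list places the most stable type at position 1; under Watson-Crick rules
positions 1-6 should be the A-T-pair class and 7-12 the C-G-pair class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .array_io import ValidationError
from .constants import COMPLEMENT, COMPLEMENT_RNA, MISMATCH_TYPES, parse_mismatch_type

DIRECTIONS = ("discrimination", "stability")

AT_PAIR = "AT_pair"
CG_PAIR = "CG_pair"


@dataclass(frozen=True)
class StudyEffectVector:
    """One study's 12 mismatch-type effect values, with its direction."""

    study_id: str
    values: dict[str, float]
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValidationError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        missing = set(MISMATCH_TYPES) - set(self.values)
        extra = set(self.values) - set(MISMATCH_TYPES)
        if missing or extra:
            raise ValidationError(
                f"study {self.study_id!r}: vector must carry exactly the 12 types "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )
        bad = [t for t, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValidationError(f"study {self.study_id!r}: non-finite values for {bad}")

    def stability_values(self) -> dict[str, float]:
        sign = 1.0 if self.direction == "stability" else -1.0
        return {t: sign * v for t, v in self.values.items()}


@dataclass(frozen=True)
class CorrelationReport:
    study_a: str
    study_b: str
    spearman_rho: float
    spearman_p: float
    pearson_r: float
    pearson_p: float
    pearson_rank_r: float
    pearson_rank_p: float
    n: int = 12


# ---------------------------------------------------------------------------
# notation


def convert_notation(pm_mm_type: str, target_chemistry: str = "RNA") -> tuple[str, str]:
    """PM->MM notation to duplex (probe base, target base) notation.

    The probe provides the MM base; the target provides the Watson-Crick
    complement of the PM base (U replaces T when the target is RNA).
    """
    pm, mm = parse_mismatch_type(pm_mm_type)
    comp = _complement_map(target_chemistry)
    return mm, comp[pm]


def invert_notation(probe_base: str, target_base: str, target_chemistry: str = "RNA") -> str:
    """Duplex (probe, target) notation back to PM->MM; round-trips exactly."""
    comp = _complement_map(target_chemistry)
    inverse = {v: k for k, v in comp.items()}
    if target_base not in inverse:
        raise ValidationError(
            f"invalid target base {target_base!r} for {target_chemistry} chemistry"
        )
    pm = inverse[target_base]
    if probe_base not in COMPLEMENT:
        raise ValidationError(f"invalid probe base {probe_base!r}")
    mtype = f"{pm}-{probe_base}"
    if mtype not in MISMATCH_TYPES:
        raise ValidationError(
            f"(probe {probe_base}, target {target_base}) is a Watson-Crick match, "
            "not a mismatch"
        )
    return mtype


def _complement_map(target_chemistry: str) -> dict[str, str]:
    if target_chemistry == "RNA":
        return COMPLEMENT_RNA
    if target_chemistry == "DNA":
        return COMPLEMENT
    raise ValidationError(f"chemistry must be DNA or RNA, got {target_chemistry!r}")


def consolidate_pair_class(pm_mm_type: str) -> str:
    """Which Watson-Crick pair the mismatch disrupts, by the PM base."""
    pm, _ = parse_mismatch_type(pm_mm_type)
    return AT_PAIR if pm in ("A", "T") else CG_PAIR


# ---------------------------------------------------------------------------
# ranking


def to_rank_vector(vector: StudyEffectVector, output_direction: str) -> dict[str, float]:
    """Ranks 1..12 (average ties) on the requested direction's scale.

    Rank 1 goes to the smallest value after harmonizing to
    ``output_direction``; requesting the direction opposite to the vector's
    own reverses the ranks.
    """
    if output_direction not in DIRECTIONS:
        raise ValidationError(f"direction must be one of {DIRECTIONS}")
    sign = 1.0 if output_direction == vector.direction else -1.0
    values = np.array([sign * vector.values[t] for t in MISMATCH_TYPES])
    ranks = stats.rankdata(values, method="average")
    return dict(zip(MISMATCH_TYPES, map(float, ranks)))


def stability_order(vector: StudyEffectVector) -> list[str]:
    """The 12 types listed from most stable (position 1) to least stable.

    Ties are broken by type name for determinism.
    """
    sv = vector.stability_values()
    return sorted(MISMATCH_TYPES, key=lambda t: (-sv[t], t))


# ---------------------------------------------------------------------------
# correlation


def correlate_studies(
    vectors: list[StudyEffectVector],
    p_method: str = "t",
    seed: int = 0,
    n_resamples: int = 9999,
) -> list[CorrelationReport]:
    """All pairwise Spearman and Pearson correlations on stability-harmonized values.

    Spearman p-values use the t-approximation by default (``p_method="t"``);
    ``p_method="permutation"`` uses a seeded permutation test (exhaustive
    when the permutation count is below ``n_resamples``).  Pearson is
    computed both on the raw harmonized values and on their ranks, since a
    published correlation table may have used either.
    """
    if len(vectors) < 2:
        raise ValidationError("need at least two study vectors")
    ids = [v.study_id for v in vectors]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate study ids: {ids}")
    arrays = {
        v.study_id: np.array([v.stability_values()[t] for t in MISMATCH_TYPES])
        for v in vectors
    }
    reports = []
    for i, va in enumerate(vectors):
        for vb in vectors[i + 1 :]:
            x, y = arrays[va.study_id], arrays[vb.study_id]
            rho, sp = _spearman(x, y, p_method, seed, n_resamples)
            r, pp = stats.pearsonr(x, y)
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            rr, rrp = stats.pearsonr(rx, ry)
            reports.append(
                CorrelationReport(
                    study_a=va.study_id,
                    study_b=vb.study_id,
                    spearman_rho=float(rho),
                    spearman_p=float(sp),
                    pearson_r=float(r),
                    pearson_p=float(pp),
                    pearson_rank_r=float(rr),
                    pearson_rank_p=float(rrp),
                    n=len(MISMATCH_TYPES),
                )
            )
    return reports


def _spearman(x, y, p_method, seed, n_resamples):
    rho, p_t = stats.spearmanr(x, y)
    if p_method == "t":
        return rho, p_t
    if p_method != "permutation":
        raise ValidationError(f"p_method must be 't' or 'permutation', got {p_method!r}")

    def statistic(perm_y):
        return stats.spearmanr(x, perm_y).statistic

    res = stats.permutation_test(
        (y,),
        statistic,
        permutation_type="pairings",
        alternative="two-sided",
        n_resamples=n_resamples,
        rng=np.random.default_rng(seed),
    )
    return rho, res.pvalue


def correlation_matrix(
    reports: list[CorrelationReport], which: str = "spearman_rho"
) -> pd.DataFrame:
    """Symmetric study x study matrix (unit diagonal) of one coefficient."""
    ids = sorted({r.study_a for r in reports} | {r.study_b for r in reports})
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for r in reports:
        value = getattr(r, which)
        mat.loc[r.study_a, r.study_b] = value
        mat.loc[r.study_b, r.study_a] = value
    return mat


def reports_to_frame(reports: list[CorrelationReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])


# ---------------------------------------------------------------------------
# Watson-Crick outliers


def flag_outliers(stability_ranked_types: list[str]) -> list[str]:
    """Types whose stability-list position violates the pair-class block rule.

    Given the complete ranking (position 1 = most stable first), a type is
    flagged iff it is A-T-pair class at positions 7-12 or C-G-pair class at
    positions 1-6.
    """
    if sorted(stability_ranked_types) != sorted(MISMATCH_TYPES):
        raise ValidationError(
            "flag_outliers requires a complete ranking of the 12 mismatch types"
        )
    flagged = []
    for position, mtype in enumerate(stability_ranked_types, start=1):
        cls = consolidate_pair_class(mtype)
        if (cls == AT_PAIR and position > 6) or (cls == CG_PAIR and position <= 6):
            flagged.append(mtype)
    return flagged


# ---------------------------------------------------------------------------
# I/O


def read_study_vector(path: str | Path, study_id: str, direction: str) -> StudyEffectVector:
    """Read a 12-row (mismatch_type, value) TSV into a StudyEffectVector."""
    df = pd.read_csv(path, sep="\t")
    if not {"mismatch_type", "value"} <= set(df.columns):
        raise ValidationError(f"{path}: expected columns mismatch_type, value")
    return StudyEffectVector(
        study_id=study_id,
        values=dict(zip(df["mismatch_type"], df["value"].astype(float))),
        direction=direction,
    )


def write_study_vector(vector: StudyEffectVector, path: str | Path) -> None:
    pd.DataFrame(
        {"mismatch_type": list(MISMATCH_TYPES),
         "value": [vector.values[t] for t in MISMATCH_TYPES]}
    ).to_csv(path, sep="\t", index=False)
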