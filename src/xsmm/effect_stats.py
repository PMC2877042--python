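"""Estimation and summarization of per-pair log2(PM/MM_i) effects.

The discrimination statistic for a pair whose mismatch sits at probe position
i is log2(PM/MM_i).  Replicate arrays are first averaged on the log2 scale
within each tissue; the per-pair estimate is the Chip (PM vs MM) coefficient
of the additive two-factor Tissue + Chip linear model on those per-tissue
means.  Under the balanced design this coefficient equals the across-tissue
mean of the per-tissue PM - MM differences; both routes are computed and
their equality asserted on every pair.

Downstream summaries: the 25-position profile (n / mean / median / MAD /
IQR), the MAD-on-median spread regression, the 12-type x 3-position-group
table with pooled-variance Student's t-tests (no multiple-testing
correction; raw p-values are reported), percent contrasts, and the
comparison of mismatch pairs against identical-probe control differences.

Conventions (the source analyses leave them open): MAD is the raw median
absolute deviation without the 1.4826 consistency constant; quartiles for
the IQR use linear interpolation of order statistics (type 7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .array_io import IntensityMatrix, ProbeRecord, ValidationError
from .constants import MISMATCH_TYPES, PROBE_LENGTH, PositionGroup
from .probe_match import MismatchProbePair

GROUP_ORDER = (PositionGroup.FIVE_PRIME, PositionGroup.CENTER, PositionGroup.THREE_PRIME)

CONTRASTS = (
    ("center_vs_five_prime", PositionGroup.CENTER, PositionGroup.FIVE_PRIME),
    ("center_vs_three_prime", PositionGroup.CENTER, PositionGroup.THREE_PRIME),
    ("five_prime_vs_three_prime", PositionGroup.FIVE_PRIME, PositionGroup.THREE_PRIME),
)

_EQUIVALENCE_TOL = 1e-10


@dataclass(frozen=True)
class LogRatioEstimate:
    """Per-pair estimate of log2(PM/MM_i) with its per-tissue components."""

    pair_id: str
    position: int
    mismatch_type: str
    per_tissue_ratio: dict[str, float]
    estimate: float

    def __post_init__(self) -> None:
        closed_form = float(np.mean(list(self.per_tissue_ratio.values())))
        if abs(closed_form - self.estimate) > 1e-9:
            raise ValidationError(
                f"pair {self.pair_id}: estimate {self.estimate} != mean of "
                f"per-tissue ratios {closed_form}"
            )


@dataclass(frozen=True)
class SpreadRegression:
    """OLS of per-position MAD (response) on median (predictor)."""

    slope: float
    intercept: float
    r_squared: float


@dataclass
class TypeGroupSummary:
    """12-type x 3-group means, frequencies, and group-contrast t-tests."""

    table: pd.DataFrame  # one row per mismatch type
    skipped_contrasts: list[tuple[str, str]]  # (type, contrast) with a cell < 2

    def n_exceeding(self, contrast: str, alpha: float = 0.05) -> int:
        p = self.table[f"p_{contrast}"]
        return int((p > alpha).sum())


# ---------------------------------------------------------------------------
# estimation


def _per_tissue_log2_means(matrix: IntensityMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Replicate-averaged log2 intensities: probes x tissues."""
    log2 = np.log2(matrix.values)
    tissues = sorted(matrix.metadata["tissue"].unique())
    cols = {}
    for tissue in tissues:
        arrays = matrix.metadata.index[matrix.metadata["tissue"] == tissue]
        cols[tissue] = log2[arrays].mean(axis=1)
    return pd.DataFrame(cols), tissues


def _chip_effect_design(n_tissues: int) -> np.ndarray:
    """Row of pinv(X) extracting the Chip coefficient of the Tissue + Chip model.

    Observations are ordered (PM tissue 1..T, MM tissue 1..T); X has an
    intercept, T-1 tissue dummies, and a 0/1 Chip indicator (PM = 1).
    """
    T = n_tissues
    X = np.zeros((2 * T, 1 + (T - 1) + 1))
    X[:, 0] = 1.0
    for t in range(1, T):
        X[t, t] = 1.0
        X[T + t, t] = 1.0
    X[:T, -1] = 1.0
    return np.linalg.pinv(X)[-1]


def estimate_log_ratios(
    pairs: list[MismatchProbePair],
    pm_matrix: IntensityMatrix,
    mm_matrix: IntensityMatrix,
) -> list[LogRatioEstimate]:
    """Estimate log2(PM/MM_i) for every pair.

    Both matrices must already be normalized and contain every pair's probe;
    the tissue sets and replicate counts must agree between the platforms.
    """
    pm_means, pm_tissues = _per_tissue_log2_means(pm_matrix)
    mm_means, mm_tissues = _per_tissue_log2_means(mm_matrix)
    if pm_tissues != mm_tissues:
        raise ValidationError(
            f"tissue sets differ between matrices: {pm_tissues} vs {mm_tissues}"
        )
    for tissue in pm_tissues:
        for matrix, name in ((pm_matrix, "PM"), (mm_matrix, "MM")):
            reps = matrix.metadata.loc[matrix.metadata["tissue"] == tissue, "replicate"]
            if reps.empty:
                raise ValidationError(f"{name} matrix: no arrays for tissue {tissue!r}")

    for pair in pairs:
        if pair.pm_probe.probe_id not in pm_means.index:
            raise ValidationError(
                f"pair {pair.pair_id}: PM probe {pair.pm_probe.probe_id!r} missing"
            )
        if pair.mm_probe.probe_id not in mm_means.index:
            raise ValidationError(
                f"pair {pair.pair_id}: MM probe {pair.mm_probe.probe_id!r} missing"
            )

    pm_block = pm_means.loc[[p.pm_probe.probe_id for p in pairs]].to_numpy()
    mm_block = mm_means.loc[[p.mm_probe.probe_id for p in pairs]].to_numpy()
    diffs = pm_block - mm_block  # pairs x tissues, per-tissue log ratios
    closed_form = diffs.mean(axis=1)

    # linear-model route: Chip coefficient via the pseudo-inverse row
    extractor = _chip_effect_design(len(pm_tissues))
    y = np.hstack([pm_block, mm_block])  # (PM tissues..., MM tissues...)
    lm_coef = y @ extractor
    dev = np.abs(lm_coef - closed_form)
    if dev.size and dev.max() > _EQUIVALENCE_TOL:
        worst = int(dev.argmax())
        raise AssertionError(
            f"closed-form / linear-model mismatch for pair {pairs[worst].pair_id}: "
            f"{closed_form[worst]} vs {lm_coef[worst]}"
        )

    return [
        LogRatioEstimate(
            pair_id=pair.pair_id,
            position=pair.position,
            mismatch_type=pair.mismatch_type,
            per_tissue_ratio=dict(zip(pm_tissues, map(float, diffs[i]))),
            estimate=float(closed_form[i]),
        )
        for i, pair in enumerate(pairs)
    ]


def control_differences(
    controls: list[tuple[ProbeRecord, ProbeRecord]],
    matrix_a: IntensityMatrix,
    matrix_b: IntensityMatrix,
) -> np.ndarray:
    """Per-pair log2 design-A minus design-B differences for identical probes.

    Computed with the same per-tissue averaging / grand-mean estimator used
    for the mismatch pairs.
    """
    a_means, a_tissues = _per_tissue_log2_means(matrix_a)
    b_means, b_tissues = _per_tissue_log2_means(matrix_b)
    if a_tissues != b_tissues:
        raise ValidationError("tissue sets differ between control matrices")
    a_block = a_means.loc[[a.probe_id for a, _ in controls]].to_numpy()
    b_block = b_means.loc[[b.probe_id for _, b in controls]].to_numpy()
    return (a_block - b_block).mean(axis=1)


def estimates_to_frame(estimates: list[LogRatioEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair_id": e.pair_id,
                "position": e.position,
                "mismatch_type": e.mismatch_type,
                "estimate": e.estimate,
            }
            for e in estimates
        ],
        columns=["pair_id", "position", "mismatch_type", "estimate"],
    )


# ---------------------------------------------------------------------------
# positional profile and spread regression


def position_profile(estimates: list[LogRatioEstimate]) -> pd.DataFrame:
    """Per-position n / mean / median / MAD / IQR of the estimates.

    Positions with no pairs carry n = 0 and NaN summaries.
    """
    if not estimates:
        raise ValidationError("no estimates supplied")
    frame = estimates_to_frame(estimates)
    rows = []
    for position in range(1, PROBE_LENGTH + 1):
        values = frame.loc[frame["position"] == position, "estimate"].to_numpy()
        if values.size == 0:
            rows.append((position, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        med = float(np.median(values))
        mad = float(np.median(np.abs(values - med)))
        q25, q75 = np.percentile(values, [25, 75])  # type-7 linear interpolation
        rows.append((position, int(values.size), float(values.mean()), med, mad, float(q75 - q25)))
    return pd.DataFrame(
        rows, columns=["position", "n", "mean", "median", "mad", "iqr"]
    ).set_index("position")


def position_count_summary(counts: pd.Series | dict[int, int]) -> dict[str, int]:
    """Aggregate a per-position pair-count vector: total, minimum, argmin."""
    s = pd.Series(counts).astype(int)
    if len(s) != PROBE_LENGTH:
        raise ValidationError(f"expected {PROBE_LENGTH} per-position counts, got {len(s)}")
    return {
        "total": int(s.sum()),
        "min_count": int(s.min()),
        "min_position": int(s.idxmin()),
    }


def spread_regression(profile: pd.DataFrame) -> SpreadRegression:
    """Least squares of MAD on median across the positions with data."""
    usable = profile[(profile["n"] > 0) & profile["median"].notna() & profile["mad"].notna()]
    if len(usable) < 3:
        raise ValidationError(
            f"spread regression needs >= 3 usable positions, got {len(usable)}"
        )
    x = usable["median"].to_numpy()
    y = usable["mad"].to_numpy()
    if np.ptp(x) == 0:
        raise ValidationError("median values are constant; slope undefined")
    if np.ptp(y) == 0:
        return SpreadRegression(slope=0.0, intercept=float(y[0]), r_squared=0.0)
    slope, intercept = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    return SpreadRegression(float(slope), float(intercept), float(r**2))


def spread_regression_frame(reg: SpreadRegression) -> pd.DataFrame:
    return pd.DataFrame(
        [{"slope": reg.slope, "intercept": reg.intercept, "r_squared": reg.r_squared}]
    )


# ---------------------------------------------------------------------------
# type x position-group summary


def pooled_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided two-sample Student's t-test with pooled variance."""
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def welch_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def type_group_summary(
    estimates: list[LogRatioEstimate], t_test=pooled_t_test
) -> TypeGroupSummary:
    """Mean log2(PM/MM) per (type, position group), frequencies, contrasts.

    Each of the three group contrasts gets a two-sided t-test per type; a
    contrast whose cells have fewer than 2 estimates is marked unavailable
    (NaN) and logged.  P-values carry no multiple-testing correction.
    """
    frame = estimates_to_frame(estimates)
    frame["group"] = frame["position"].map(lambda p: PositionGroup.of_position(int(p)).value)
    rows = []
    skipped: list[tuple[str, str]] = []
    for mtype in MISMATCH_TYPES:
        sub = frame[frame["mismatch_type"] == mtype]
        cells = {
            g: sub.loc[sub["group"] == g.value, "estimate"].to_numpy() for g in GROUP_ORDER
        }
        row = {"mismatch_type": mtype, "frequency": int(len(sub))}
        for g in GROUP_ORDER:
            row[f"mean_{g.value}"] = float(cells[g].mean()) if cells[g].size else np.nan
        for name, g1, g2 in CONTRASTS:
            if cells[g1].size < 2 or cells[g2].size < 2:
                row[f"p_{name}"] = np.nan
                skipped.append((mtype, name))
            else:
                _, p = t_test(cells[g1], cells[g2])
                row[f"p_{name}"] = p
        rows.append(row)
    table = pd.DataFrame(rows)
    if table["frequency"].sum() != len(frame):
        raise AssertionError("type frequencies do not sum to the pair count")
    return TypeGroupSummary(table=table, skipped_contrasts=skipped)


# ---------------------------------------------------------------------------
# percent contrasts


def contrast_percent(mean_ref: float, mean_other: float, form: str = "ratio") -> float:
    """Percent contrast between two mean log2(PM/MM) values.

    ``form="ratio"``: 100 * (1 - 2**(mean_other - mean_ref)), the relative
    change of the geometric-mean PM/MM ratio (positive = decrease).
    ``form="log2"``: 100 * (mean_other / mean_ref - 1), percent higher on the
    log2 scale (requires mean_ref != 0).
    """
    if not (np.isfinite(mean_ref) and np.isfinite(mean_other)):
        raise ValidationError("contrast_percent requires finite inputs")
    if form == "ratio":
        return 100.0 * (1.0 - 2.0 ** (mean_other - mean_ref))
    if form == "log2":
        if mean_ref == 0:
            raise ValidationError("log2-scale percent undefined for mean_ref = 0")
        return 100.0 * (mean_other / mean_ref - 1.0)
    raise ValidationError(f"unknown form {form!r}")


# ---------------------------------------------------------------------------
# control comparison


def compare_to_controls(
    estimates: list[LogRatioEstimate],
    control_diffs: np.ndarray,
    t_test=pooled_t_test,
) -> tuple[pd.DataFrame, list[int]]:
    """Per-position t-test of mismatch estimates against control differences.

    Identical-probe control differences carry no mismatch position, so every
    position's estimates are tested against the full control sample.  A
    position where either sample has < 2 values is skipped and logged.
    """
    control_diffs = np.asarray(control_diffs, dtype=float)
    frame = estimates_to_frame(estimates)
    rows, skipped = [], []
    for position in range(1, PROBE_LENGTH + 1):
        values = frame.loc[frame["position"] == position, "estimate"].to_numpy()
        if values.size < 2 or control_diffs.size < 2:
            skipped.append(position)
            continue
        t, p = t_test(values, control_diffs)
        rows.append((position, int(values.size), int(control_diffs.size), t, p))
    return (
        pd.DataFrame(rows, columns=["position", "n_mismatch", "n_control", "t", "p"]),
        skipped,
    )
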