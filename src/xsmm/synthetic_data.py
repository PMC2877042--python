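"""Synthetic two-design microarray experiment with known mismatch effects.

Emulates the structure of a cross-species hybridization study (two 25-mer
probe designs sharing a set of consensus transcripts, five tissue sources,
two replicate arrays per platform and tissue): design A probes are exact
consensus substrings; design B probes are copies of the design A probes in
which a controlled fraction carries one single-base substitution (the study
material), a fraction is copied unchanged (identical-probe controls), and a
fraction carries two substitutions (fodder for the exclusion filter).

The intensity model on the log2 scale is

    log2 I = baseline + probe affinity + tissue effect
             - delta(position, type) * [design B, single mismatch]
             + N(0, noise_sd)

with the probe affinity and tissue effect shared between the paired probes of
the two designs, so the per-pair log2(PM/MM) estimand equals the planted
penalty ``delta`` exactly in the zero-noise limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .array_io import IntensityMatrix, ProbeRecord, ValidationError
from .constants import BASES, MISMATCH_TYPES, PROBE_LENGTH

LEDGER_COLUMNS = ("probe_id", "category", "position", "mismatch_type", "consensus_id", "start", "end")

DESIGN_A = "designA"
DESIGN_B = "designB"

#: Intensities are floored at this linear value before any log is taken.
INTENSITY_FLOOR = 2.0 ** -10

DEFAULT_TISSUE_EFFECTS = {
    "fibroblast": 0.0,
    "cortex": 0.5,
    "pancreas": -0.4,
    "testes": 0.8,
    "thymus": -0.7,
}

#: Per-type penalty multipliers.  Types disrupting a C-G pair (PM base C or G)
#: are penalized more than those disrupting an A-T pair; within class the
#: strongest effects sit on C-A, G-A and C-G and the weakest on A-C, A-G, A-T.
DEFAULT_TYPE_MULTIPLIERS = {
    "A-C": 0.70, "A-G": 0.72, "A-T": 0.74,
    "T-A": 0.78, "T-G": 0.80, "T-C": 0.82,
    "G-T": 1.08, "C-T": 1.10, "G-C": 1.12,
    "C-G": 1.20, "G-A": 1.22, "C-A": 1.25,
}


def default_position_shape(peak_position: int = 12) -> np.ndarray:
    """Unimodal positional penalty profile peaking at ``peak_position``.

    Quadratic decay toward both probe ends, slightly slower on the 5' side so
    the 5' flank retains a larger effect than the surface-attached 3' flank.
    """
    positions = np.arange(1, PROBE_LENGTH + 1, dtype=float)
    shape = np.empty(PROBE_LENGTH)
    left = positions <= peak_position
    shape[left] = 1.0 - 0.45 * ((peak_position - positions[left]) / 13.0) ** 2
    shape[~left] = 1.0 - 0.45 * ((positions[~left] - peak_position) / 12.0) ** 2
    return shape


def default_delta(peak_log2: float = 1.0, peak_position: int = 12) -> pd.DataFrame:
    """Default 25 x 12 penalty table delta(position, type), in log2 units."""
    shape = default_position_shape(peak_position)
    mult = np.array([DEFAULT_TYPE_MULTIPLIERS[t] for t in MISMATCH_TYPES])
    return pd.DataFrame(
        peak_log2 * np.outer(shape, mult),
        index=pd.RangeIndex(1, PROBE_LENGTH + 1, name="position"),
        columns=list(MISMATCH_TYPES),
    )


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth parameters of the generative model."""

    delta: pd.DataFrame = field(default_factory=default_delta)
    tissue_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_EFFECTS)
    )
    probe_affinity_sd: float = 1.0
    noise_sd: float = 0.3
    control_fraction: float = 0.2
    multi_mismatch_fraction: float = 0.05
    baseline_log2: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta.shape != (PROBE_LENGTH, len(MISMATCH_TYPES)):
            raise ValidationError(
                f"delta must be {PROBE_LENGTH} x {len(MISMATCH_TYPES)}, "
                f"got {self.delta.shape}"
            )
        if set(self.delta.columns) != set(MISMATCH_TYPES):
            raise ValidationError("delta columns must be the 12 mismatch types")
        if list(self.delta.index) != list(range(1, PROBE_LENGTH + 1)):
            raise ValidationError("delta index must be positions 1..25")
        for name, frac in (
            ("control_fraction", self.control_fraction),
            ("multi_mismatch_fraction", self.multi_mismatch_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {frac}")
        if self.control_fraction + self.multi_mismatch_fraction > 1.0:
            raise ValidationError(
                "control_fraction + multi_mismatch_fraction must be <= 1"
            )
        if self.noise_sd < 0 or self.probe_affinity_sd < 0:
            raise ValidationError("standard deviations must be >= 0")

    def with_(self, **kwargs) -> "SimulationTruth":
        return replace(self, **kwargs)


def _check_weights(weights: np.ndarray, what: str) -> np.ndarray:
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any():
        raise ValidationError(f"{what} weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValidationError(f"{what} weights sum to zero")
    return weights / total


def generate_designs(
    truth: SimulationTruth,
    n_probesets: int,
    probes_per_set: int,
    consensus_length: int,
    position_weights: np.ndarray | None = None,
    type_weights: dict[str, float] | None = None,
) -> tuple[dict[str, str], list[ProbeRecord], list[ProbeRecord], pd.DataFrame]:
    """Generate consensus sequences, the two probe designs, and the truth ledger.

    Design A probes are exact 25-mer substrings of their consensus, tiled
    left-to-right in increasing start order; design B probes are copies with
    substitutions drawn from the configured distributions (default uniform
    over 25 positions and the types compatible with each site's base).

    Returns ``(consensus_set, design_a_probes, design_b_probes, ledger)``;
    the ledger records each design B probe's category, planted position/type,
    and source consensus window.
    """
    if probes_per_set < 1:
        raise ValidationError("probes_per_set must be >= 1")
    if consensus_length < PROBE_LENGTH + probes_per_set:
        raise ValidationError(
            f"consensus_length {consensus_length} too short for {probes_per_set} "
            f"tiled probes (need >= {PROBE_LENGTH + probes_per_set})"
        )
    pos_w = _check_weights(
        np.ones(PROBE_LENGTH) if position_weights is None else np.asarray(position_weights),
        "position",
    )
    if len(pos_w) != PROBE_LENGTH:
        raise ValidationError("position_weights must have 25 entries")
    type_w = {t: 1.0 for t in MISMATCH_TYPES} if type_weights is None else dict(type_weights)
    unknown = set(type_w) - set(MISMATCH_TYPES)
    if unknown:
        raise ValidationError(f"unknown mismatch types in type_weights: {sorted(unknown)}")
    if any(w < 0 for w in type_w.values()):
        raise ValidationError("type weights must be non-negative")

    rng = np.random.default_rng([truth.seed % (2**31), 11])
    step = (consensus_length - PROBE_LENGTH) // max(probes_per_set - 1, 1)
    step = max(step, 1)
    starts0 = [min(i * step, consensus_length - PROBE_LENGTH) for i in range(probes_per_set)]

    p_single = 1.0 - truth.control_fraction - truth.multi_mismatch_fraction
    consensus_set: dict[str, str] = {}
    design_a: list[ProbeRecord] = []
    design_b: list[ProbeRecord] = []
    ledger_rows: list[dict] = []

    for s in range(n_probesets):
        cid = f"ps{s:05d}"
        seq = "".join(rng.choice(list(BASES), size=consensus_length))
        consensus_set[cid] = seq
        for k, start0 in enumerate(starts0):
            window = seq[start0 : start0 + PROBE_LENGTH]
            a_id = f"A_{s:05d}_{k:02d}"
            b_id = f"B_{s:05d}_{k:02d}"
            design_a.append(ProbeRecord(cid, a_id, k + 1, window, DESIGN_A))
            category = rng.choice(
                ["control", "multi_mismatch", "single_mismatch"],
                p=[truth.control_fraction, truth.multi_mismatch_fraction, p_single],
            )
            b_seq, position, mtype = _mutate(window, category, pos_w, type_w, rng)
            design_b.append(ProbeRecord(cid, b_id, k + 1, b_seq, DESIGN_B))
            ledger_rows.append(
                {
                    "probe_id": b_id,
                    "category": category,
                    "position": position,
                    "mismatch_type": mtype,
                    "consensus_id": cid,
                    "start": start0 + 1,
                    "end": start0 + PROBE_LENGTH,
                }
            )
    ledger = pd.DataFrame(ledger_rows, columns=list(LEDGER_COLUMNS))
    ledger["position"] = ledger["position"].astype("Int64")
    return consensus_set, design_a, design_b, ledger


def _mutate(window, category, pos_w, type_w, rng):
    if category == "control":
        return window, pd.NA, pd.NA
    if category == "single_mismatch":
        position = int(rng.choice(PROBE_LENGTH, p=pos_w)) + 1
        pm_base = window[position - 1]
        options = [t for t in MISMATCH_TYPES if t[0] == pm_base]
        weights = np.array([type_w[t] for t in options], dtype=float)
        if weights.sum() <= 0:
            raise ValidationError(
                f"type weights leave no admissible type for PM base {pm_base}"
            )
        mtype = str(rng.choice(options, p=weights / weights.sum()))
        new = window[: position - 1] + mtype[2] + window[position:]
        return new, position, mtype
    if category == "multi_mismatch":
        # exactly 2 substitutions at distinct positions
        p1, p2 = sorted(rng.choice(PROBE_LENGTH, size=2, replace=False))
        chars = list(window)
        for p in (p1, p2):
            chars[p] = str(rng.choice([b for b in BASES if b != chars[p]]))
        return "".join(chars), pd.NA, pd.NA
    raise ValidationError(f"unknown probe category {category!r}")


def simulate_intensities(
    truth: SimulationTruth,
    ledger: pd.DataFrame,
    tissues: int = 5,
    replicates: int = 2,
) -> tuple[IntensityMatrix, IntensityMatrix]:
    """Simulate paired intensity matrices for the two designs.

    Probe affinities and tissue effects are shared between the designs; only
    design B probes with a planted substitution are penalized.  Design B
    probe ids follow the ``B_*`` convention of :func:`generate_designs`, and
    the paired design A probe is the same id with an ``A_`` prefix.
    Multi-mismatch probes receive a fixed penalty of twice the mean of the
    delta table (they are excluded upstream of any estimation).

    Returns ``(matrix_a, matrix_b)`` with linear-scale intensities.
    """
    if tissues < 2 or replicates < 2:
        raise ValidationError("need tissues >= 2 and replicates >= 2")
    tissue_names = list(truth.tissue_effects)[:tissues]
    if len(tissue_names) < tissues:
        raise ValidationError(
            f"truth defines {len(truth.tissue_effects)} tissue effects, "
            f"{tissues} requested"
        )
    categories = set(ledger["category"])
    unknown = categories - {"control", "single_mismatch", "multi_mismatch"}
    if unknown:
        raise ValidationError(f"unknown ledger categories: {sorted(unknown)}")

    rng = np.random.default_rng([truth.seed % (2**31), 23])
    n = len(ledger)
    affinity = rng.normal(0.0, truth.probe_affinity_sd, size=n)

    penalty = np.zeros(n)
    is_single = (ledger["category"] == "single_mismatch").to_numpy()
    if is_single.any():
        pos = ledger.loc[is_single, "position"].astype(int).to_numpy()
        typ = ledger.loc[is_single, "mismatch_type"].to_numpy()
        delta_vals = truth.delta.to_numpy()
        col_of = {t: j for j, t in enumerate(truth.delta.columns)}
        penalty[is_single] = delta_vals[pos - 1, [col_of[t] for t in typ]]
    is_multi = (ledger["category"] == "multi_mismatch").to_numpy()
    penalty[is_multi] = 2.0 * truth.delta.to_numpy().mean()

    t_eff = np.array([truth.tissue_effects[t] for t in tissue_names])
    b_ids = ledger["probe_id"].tolist()
    a_ids = ["A" + pid[1:] for pid in b_ids]

    matrices = []
    for design, probe_ids, pen in (
        (DESIGN_A, a_ids, np.zeros(n)),
        (DESIGN_B, b_ids, penalty),
    ):
        cols, meta = {}, []
        for ti, tissue in enumerate(tissue_names):
            for rep in range(1, replicates + 1):
                aid = f"{design}_{tissue}_r{rep}"
                log2_i = (
                    truth.baseline_log2
                    + affinity
                    + t_eff[ti]
                    - pen
                    + rng.normal(0.0, truth.noise_sd, size=n)
                )
                cols[aid] = np.maximum(2.0 ** log2_i, INTENSITY_FLOOR)
                meta.append({"array_id": aid, "platform": design, "tissue": tissue, "replicate": rep})
        values = pd.DataFrame(cols, index=pd.Index(probe_ids, name="probe_id"))
        matrices.append(IntensityMatrix(values, pd.DataFrame(meta)))
    return matrices[0], matrices[1]


def write_ledger(ledger: pd.DataFrame, path) -> None:
    ledger.sort_values("probe_id").to_csv(path, sep="\t", index=False)


def read_ledger(path) -> pd.DataFrame:
    ledger = pd.read_csv(path, sep="\t", dtype={"position": "Int64"})
    missing = set(LEDGER_COLUMNS) - set(ledger.columns)
    if missing:
        raise ValidationError(f"{path}: missing ledger columns {sorted(missing)}")
    return ledger
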