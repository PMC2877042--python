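"""Staged pipeline: simulate -> normalize -> match -> analyze -> crossstudy.

A single YAML config drives every stage; unknown keys are rejected so typos
fail loudly.  One global seed is split deterministically per stage, so each
stage is independently re-runnable, and a run manifest (resolved config,
seed, package versions, input digests) is written next to the results.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__, array_io, cross_study, effect_stats, preprocess, probe_match
from . import synthetic_data as synth
from .array_io import ValidationError

_SIMULATE_KEYS = {
    "n_probesets", "probes_per_set", "consensus_length", "tissues", "replicates",
    "noise_sd", "probe_affinity_sd", "control_fraction", "multi_mismatch_fraction",
    "peak_log2", "baseline_log2",
}
_ALIGN_KEYS = {"match_score", "mismatch_score", "gap_open_penalty", "gap_extend_penalty"}
_STATS_KEYS = {"t_test"}
_NORMALIZE_KEYS = {"group_by"}
_CROSS_KEYS = {"vectors"}
_TOP_KEYS = {"seed", "outdir", "simulate", "normalize", "align", "stats", "crossstudy"}


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "results"
    simulate: dict = field(default_factory=dict)
    normalize: dict = field(default_factory=dict)
    align: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    crossstudy: dict | None = None

    def __post_init__(self) -> None:
        for section, allowed in (
            (self.simulate, _SIMULATE_KEYS),
            (self.normalize, _NORMALIZE_KEYS),
            (self.align, _ALIGN_KEYS),
            (self.stats, _STATS_KEYS),
            (self.crossstudy or {}, _CROSS_KEYS),
        ):
            unknown = set(section) - allowed
            if unknown:
                raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if self.stats.get("t_test", "pooled") not in ("pooled", "welch"):
            raise ValidationError("stats.t_test must be 'pooled' or 'welch'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValidationError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(**raw)


def _truth_from_config(cfg: PipelineConfig) -> synth.SimulationTruth:
    sim = cfg.simulate
    kwargs = {}
    for key in ("noise_sd", "probe_affinity_sd", "control_fraction",
                "multi_mismatch_fraction", "baseline_log2"):
        if key in sim:
            kwargs[key] = sim[key]
    if "peak_log2" in sim:
        kwargs["delta"] = synth.default_delta(peak_log2=sim["peak_log2"])
    return synth.SimulationTruth(seed=cfg.seed, **kwargs)


def _t_test(cfg: PipelineConfig):
    return (
        effect_stats.welch_t_test
        if cfg.stats.get("t_test") == "welch"
        else effect_stats.pooled_t_test
    )


class PipelineRunner:
    """Executes the stages, sharing file naming conventions between them."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.log: list[str] = []

    def path(self, name: str) -> Path:
        return self.outdir / name

    # -- stages -----------------------------------------------------------

    def simulate(self) -> None:
        cfg = self.config
        truth = _truth_from_config(cfg)
        sim = cfg.simulate
        consensus, design_a, design_b, ledger = synth.generate_designs(
            truth,
            n_probesets=sim.get("n_probesets", 200),
            probes_per_set=sim.get("probes_per_set", 11),
            consensus_length=sim.get("consensus_length", 120),
        )
        matrix_a, matrix_b = synth.simulate_intensities(
            truth, ledger,
            tissues=sim.get("tissues", 5),
            replicates=sim.get("replicates", 2),
        )
        array_io.write_fasta(consensus, self.path("consensus.fa"))
        array_io.write_probe_table(design_a, self.path("probes_designA.tsv"))
        array_io.write_probe_table(design_b, self.path("probes_designB.tsv"))
        synth.write_ledger(ledger, self.path("ledger.tsv"))
        for matrix, tag in ((matrix_a, "designA"), (matrix_b, "designB")):
            array_io.write_intensity_matrix(
                matrix, self.path(f"values_{tag}.tsv"), self.path(f"metadata_{tag}.tsv")
            )
        self.log.append(f"simulate: {len(design_a)} probes/design, {len(consensus)} probesets")

    def normalize(self) -> None:
        by = tuple(self.config.normalize.get("group_by", ["platform", "tissue"]))
        for tag in ("designA", "designB"):
            matrix = array_io.read_intensity_matrix(
                self.path(f"values_{tag}.tsv"), self.path(f"metadata_{tag}.tsv")
            )
            grouping = preprocess.replicate_grouping(matrix, by=by)
            normed = preprocess.quantile_normalize(matrix, grouping)
            array_io.write_intensity_matrix(
                normed, self.path(f"values_{tag}_norm.tsv"), self.path(f"metadata_{tag}.tsv")
            )
        self.log.append(f"normalize: grouped by {by}")

    def match(self) -> None:
        consensus = array_io.read_fasta(self.path("consensus.fa"))
        design_a = array_io.read_probe_table(self.path("probes_designA.tsv"))
        design_b = array_io.read_probe_table(self.path("probes_designB.tsv"))
        params = probe_match.AlignmentParams(**self.config.align)
        alignments = probe_match.align_design(design_b, consensus, params=params)
        kept, discard_log = probe_match.filter_probesets(alignments, design_b)
        result = probe_match.call_mismatch_pairs(
            alignments, design_b, design_a, consensus, kept_probesets=kept
        )
        identical = probe_match.find_identical_probes(design_a, design_b)
        probe_match.pairs_to_frame(result.pairs).to_csv(
            self.path("pairs.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            [(a.probe_id, b.probe_id) for a, b in identical],
            columns=["designA_probe_id", "designB_probe_id"],
        ).to_csv(self.path("controls.tsv"), sep="\t", index=False)
        discard_log.to_csv(self.path("discards.tsv"), sep="\t", index=False)
        self.log.append(
            f"match: {len(result.pairs)} pairs, {len(identical)} controls, "
            f"{len(result.multi_mismatch_ids)} multi-mismatch dropped, "
            f"{len(discard_log)} probesets discarded"
        )

    def analyze(self) -> None:
        design_a = {p.probe_id: p for p in array_io.read_probe_table(self.path("probes_designA.tsv"))}
        design_b = {p.probe_id: p for p in array_io.read_probe_table(self.path("probes_designB.tsv"))}
        pairs_df = pd.read_csv(self.path("pairs.tsv"), sep="\t")
        pairs = [
            probe_match.MismatchProbePair(
                probeset_id=row.probeset_id,
                pm_probe=design_a[row.pm_probe_id],
                mm_probe=design_b[row.mm_probe_id],
                position=int(row.position),
                mismatch_type=row.mismatch_type,
            )
            for row in pairs_df.itertuples(index=False)
        ]
        matrix_a = array_io.read_intensity_matrix(
            self.path("values_designA_norm.tsv"), self.path("metadata_designA.tsv")
        )
        matrix_b = array_io.read_intensity_matrix(
            self.path("values_designB_norm.tsv"), self.path("metadata_designB.tsv")
        )
        estimates = effect_stats.estimate_log_ratios(pairs, matrix_a, matrix_b)
        effect_stats.estimates_to_frame(estimates).to_csv(
            self.path("estimates.tsv"), sep="\t", index=False
        )
        profile = effect_stats.position_profile(estimates)
        profile.to_csv(self.path("position_profile.tsv"), sep="\t")
        reg = effect_stats.spread_regression(profile)
        effect_stats.spread_regression_frame(reg).to_csv(
            self.path("spread_regression.tsv"), sep="\t", index=False
        )
        summary = effect_stats.type_group_summary(estimates, t_test=_t_test(self.config))
        summary.table.to_csv(self.path("type_group_summary.tsv"), sep="\t", index=False)

        controls_df = pd.read_csv(self.path("controls.tsv"), sep="\t")
        controls = [
            (design_a[row.designA_probe_id], design_b[row.designB_probe_id])
            for row in controls_df.itertuples(index=False)
        ]
        if controls:
            diffs = effect_stats.control_differences(controls, matrix_a, matrix_b)
            tests, skipped = effect_stats.compare_to_controls(
                estimates, diffs, t_test=_t_test(self.config)
            )
            tests.to_csv(self.path("control_tests.tsv"), sep="\t", index=False)
            if skipped:
                self.log.append(f"analyze: positions skipped in control tests: {skipped}")
        self.log.append(f"analyze: {len(estimates)} estimates")

    def crossstudy(self) -> None:
        spec = self.config.crossstudy or {}
        vectors = [
            cross_study.read_study_vector(v["path"], v["study_id"], v["direction"])
            for v in spec.get("vectors", [])
        ]
        # this run's own vector: per-type mean estimate (discrimination scale)
        est = pd.read_csv(self.path("estimates.tsv"), sep="\t")
        own = cross_study.StudyEffectVector(
            study_id="this_run",
            values=est.groupby("mismatch_type")["estimate"].mean().to_dict(),
            direction="discrimination",
        )
        vectors.append(own)
        reports = cross_study.correlate_studies(vectors, seed=self.config.seed)
        cross_study.reports_to_frame(reports).to_csv(
            self.path("cross_study_correlations.tsv"), sep="\t", index=False
        )
        order = cross_study.stability_order(own)
        pd.DataFrame(
            {
                "stability_position": range(1, 13),
                "mismatch_type": order,
                "pair_class": [cross_study.consolidate_pair_class(t) for t in order],
                "outlier": [t in cross_study.flag_outliers(order) for t in order],
            }
        ).to_csv(self.path("stability_order.tsv"), sep="\t", index=False)
        self.log.append(f"crossstudy: {len(vectors)} vectors correlated")

    # -- manifest ---------------------------------------------------------

    def write_manifest(self) -> None:
        digests = {}
        for p in sorted(self.outdir.glob("*.tsv")) + sorted(self.outdir.glob("*.fa")):
            digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        manifest = {
            "xsmm_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "seed": self.config.seed,
            "config": asdict(self.config),
            "log": self.log,
            "artifact_sha256": digests,
        }
        self.path("run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def run_pipeline(config: PipelineConfig, with_crossstudy: bool | None = None) -> Path:
    """Execute simulate -> normalize -> match -> analyze [-> crossstudy].

    The cross-study stage runs when the config has a ``crossstudy`` section
    (or when forced).  Identical config + seed reproduces identical outputs.
    """
    runner = PipelineRunner(config)
    runner.simulate()
    runner.normalize()
    runner.match()
    runner.analyze()
    if with_crossstudy or (with_crossstudy is None and config.crossstudy is not None):
        runner.crossstudy()
    runner.write_manifest()
    return runner.outdir
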