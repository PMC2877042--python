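"""On-disk formats: FASTA consensus sets, probe tables, intensity matrices.

All tabular artifacts are tab-separated with a header row.  Writers emit rows
and columns sorted by identifier so that outputs are diffable; readers do not
require any particular order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import PROBE_LENGTH

PROBE_TABLE_COLUMNS = ("probeset_id", "probe_id", "order_index", "sequence", "design_id")
METADATA_COLUMNS = ("array_id", "platform", "tissue", "replicate")

_VALID_BASES = frozenset("ACGT")


class ValidationError(ValueError):
    """Raised when an on-disk artifact violates a format invariant."""


@dataclass(frozen=True)
class ProbeRecord:
    """One 25-mer probe of one array design.

    ``order_index`` is the 1-based position of the probe within its probeset
    along the consensus; probes of a valid probeset align in increasing
    order_index order.
    """

    probeset_id: str
    probe_id: str
    order_index: int
    sequence: str
    design_id: str

    def __post_init__(self) -> None:
        if len(self.sequence) != PROBE_LENGTH:
            raise ValidationError(
                f"probe {self.probe_id!r}: sequence length {len(self.sequence)} "
                f"!= {PROBE_LENGTH}"
            )
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValidationError(
                f"probe {self.probe_id!r}: sequence contains invalid characters "
                f"{sorted(bad)} (strict uppercase ACGT required)"
            )
        if self.order_index < 1:
            raise ValidationError(
                f"probe {self.probe_id!r}: order_index {self.order_index} < 1"
            )


class IntensityMatrix:
    """Probe x array matrix of strictly positive linear-scale intensities.

    ``values`` is a DataFrame (rows = probe ids, columns = array ids);
    ``metadata`` is a DataFrame indexed by array id with columns
    ``platform``, ``tissue``, ``replicate`` covering every value column
    exactly once, with unique (platform, tissue, replicate) triples.
    """

    def __init__(self, values: pd.DataFrame, metadata: pd.DataFrame):
        values = values.astype(float)
        metadata = metadata.copy()
        if "array_id" in metadata.columns:
            metadata = metadata.set_index("array_id")
        metadata["replicate"] = metadata["replicate"].astype(int)

        if set(values.columns) != set(metadata.index):
            missing = set(values.columns) ^ set(metadata.index)
            raise ValidationError(
                f"metadata does not match value columns one-to-one; "
                f"unmatched ids: {sorted(map(str, missing))}"
            )
        if metadata.index.has_duplicates:
            dups = metadata.index[metadata.index.duplicated()].tolist()
            raise ValidationError(f"duplicate array ids in metadata: {dups}")
        triples = metadata[["platform", "tissue", "replicate"]]
        if triples.duplicated().any():
            dup = triples[triples.duplicated()].iloc[0]
            raise ValidationError(
                f"duplicate (platform, tissue, replicate) triple: {tuple(dup)}"
            )
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate probe ids: {dups[:5]}")
        bad = np.argwhere(~(values.to_numpy() > 0))
        if bad.size:
            r, c = bad[0]
            raise ValidationError(
                f"non-positive intensity at probe {values.index[r]!r}, "
                f"array {values.columns[c]!r}: {values.iat[r, c]}"
            )
        # align metadata rows to column order
        self.values = values
        self.metadata = metadata.loc[values.columns]
        self.metadata.index.name = "array_id"

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def array_ids(self) -> pd.Index:
        return self.values.columns

    def sorted(self) -> "IntensityMatrix":
        """Copy with rows and columns sorted by id (the writer's order)."""
        v = self.values.sort_index(axis=0).sort_index(axis=1)
        return IntensityMatrix(v, self.metadata.loc[v.columns])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntensityMatrix):
            return NotImplemented
        return self.values.equals(other.values) and self.metadata.equals(other.metadata)


# ---------------------------------------------------------------------------
# probe tables


def write_probe_table(records: list[ProbeRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.probeset_id, r.probe_id, r.order_index, r.sequence, r.design_id) for r in records],
        columns=list(PROBE_TABLE_COLUMNS),
    ).sort_values(["probeset_id", "order_index", "probe_id"])
    df.to_csv(path, sep="\t", index=False)


def read_probe_table(path: str | Path) -> list[ProbeRecord]:
    """Read a probe table, validating every row against the record invariants."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PROBE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing probe-table columns {sorted(missing)}")
    records = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.probe_id in seen:
            raise ValidationError(f"{path}: duplicate probe_id {row.probe_id!r}")
        seen.add(row.probe_id)
        records.append(
            ProbeRecord(
                probeset_id=row.probeset_id,
                probe_id=row.probe_id,
                order_index=int(row.order_index),
                sequence=row.sequence,
                design_id=row.design_id,
            )
        )
    return records


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {id: uppercased sequence}.

    The id is the header token up to the first whitespace.  Duplicate ids and
    empty sequences are rejected.
    """
    consensus: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in consensus:
            raise ValidationError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValidationError(f"{path}: empty sequence for id {rec.id!r}")
        consensus[rec.id] = seq
    return consensus


def write_fasta(consensus: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(consensus.items())
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# intensity matrices


def write_intensity_matrix(
    matrix: IntensityMatrix, values_path: str | Path, metadata_path: str | Path
) -> None:
    m = matrix.sorted()
    m.values.rename_axis("probe_id").to_csv(values_path, sep="\t", float_format="%.10g")
    m.metadata.rename_axis("array_id").to_csv(metadata_path, sep="\t")


def read_intensity_matrix(
    values_path: str | Path, metadata_path: str | Path
) -> IntensityMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="probe_id")
    metadata = pd.read_csv(metadata_path, sep="\t", dtype={"replicate": int})
    if "array_id" not in metadata.columns:
        raise ValidationError(f"{metadata_path}: missing 'array_id' column")
    return IntensityMatrix(values, metadata)


def frame_to_tsv_string(df: pd.DataFrame) -> str:
    """Render a results table as TSV (used by the CLI for stdout output)."""
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()
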