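"""Readers and writers for every table the pipeline touches.

All evidence and wide-matrix files are plain TSV (tab separator, UTF-8, LF,
no quoting); long profile output is RFC-4180 CSV. Slice indices are 1-based
with slice 1 at the top of the gel (highest apparent mass), matching the
reading order of a top-loaded native gel cut from the well downward.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Exact evidence header, in order. One row per observed peptide intensity
#: at (experiment, replicate, slice, channel).
EVIDENCE_COLUMNS = (
    "experiment_id",
    "replicate",
    "slice_index",
    "protein_id",
    "peptide_sequence",
    "channel",
    "intensity",
)

ANNOTATION_COLUMNS = ("protein_id", "complex_id", "module_id", "display_order")

MARKER_COLUMNS = ("marker_name", "mass_kda", "peak_slice")

CHANNELS = ("light", "heavy")


class SchemaError(ValueError):
    """A file's header does not match the documented contract."""


class EvidenceValueError(ValueError):
    """A row in an evidence file violates a value constraint."""


def _check_header(found: Sequence[str], expected: Sequence[str], path) -> None:
    missing = [c for c in expected if c not in found]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {list(expected)}, found {list(found)}"
        )
    extra = [c for c in found if c not in expected]
    if extra:
        raise SchemaError(f"{path}: unexpected column(s) {extra}")


def read_evidence(path) -> pd.DataFrame:
    """Read a peptide-evidence TSV and validate it.

    The file must carry exactly the header ``experiment_id, replicate,
    slice_index, protein_id, peptide_sequence, channel, intensity``.
    Row order is preserved. Channels outside {light, heavy} and non-positive
    intensities are rejected with the offending (1-based data) row number;
    nothing is silently coerced.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "experiment_id": str,
            "protein_id": str,
            "peptide_sequence": str,
            "channel": str,
        },
    )
    _check_header(df.columns, EVIDENCE_COLUMNS, path)
    df = df[list(EVIDENCE_COLUMNS)]
    if df.empty:
        logger.warning("%s: evidence file contains a header but no rows", path)
        return df.assign(
            replicate=df["replicate"].astype(int),
            slice_index=df["slice_index"].astype(int),
            intensity=df["intensity"].astype(float),
        )
    bad_channel = ~df["channel"].isin(CHANNELS)
    if bad_channel.any():
        row = int(np.flatnonzero(bad_channel.to_numpy())[0]) + 1
        raise EvidenceValueError(
            f"{path}: row {row}: channel {df['channel'].iloc[row - 1]!r} "
            f"is not one of {list(CHANNELS)}"
        )
    df["replicate"] = df["replicate"].astype(int)
    df["slice_index"] = df["slice_index"].astype(int)
    df["intensity"] = df["intensity"].astype(float)
    bad_intensity = ~(df["intensity"] > 0)
    if bad_intensity.any():
        row = int(np.flatnonzero(bad_intensity.to_numpy())[0]) + 1
        raise EvidenceValueError(
            f"{path}: row {row}: intensity must be > 0, "
            f"got {df['intensity'].iloc[row - 1]}"
        )
    if (df["replicate"] < 1).any():
        raise EvidenceValueError(f"{path}: replicate must be a positive integer")
    if (df["slice_index"] < 1).any():
        raise EvidenceValueError(f"{path}: slice_index must be >= 1")
    return df


def write_evidence(evidence: pd.DataFrame, path) -> None:
    """Write an evidence table in the TSV dialect ``read_evidence`` accepts."""
    path = Path(path)
    evidence = evidence[list(EVIDENCE_COLUMNS)]
    evidence.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_annotation(path) -> pd.DataFrame:
    """Read a complex-annotation table (protein -> complex -> module).

    TSV with header ``protein_id, complex_id, module_id, display_order``;
    ``module_id`` may be empty. Each protein maps to at most one complex and
    display orders are unique within a complex.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype={"protein_id": str, "complex_id": str}, keep_default_na=False
    )
    _check_header(df.columns, ANNOTATION_COLUMNS, path)
    df = df[list(ANNOTATION_COLUMNS)]
    df["module_id"] = df["module_id"].astype(str)
    df["display_order"] = df["display_order"].astype(int)
    if df["protein_id"].duplicated().any():
        dupes = df.loc[df["protein_id"].duplicated(), "protein_id"].tolist()
        raise SchemaError(f"{path}: protein(s) mapped to more than one complex: {dupes}")
    for cid, grp in df.groupby("complex_id"):
        if grp["display_order"].duplicated().any():
            raise SchemaError(f"{path}: duplicate display_order within complex {cid!r}")
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation[list(ANNOTATION_COLUMNS)].to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_markers(path) -> pd.DataFrame:
    """Read a mass-marker TSV: ``marker_name, mass_kda, peak_slice``.

    Requires >= 2 markers whose masses and slices are strictly co-monotone
    (heavier species nearer the top of the gel).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"marker_name": str})
    _check_header(df.columns, MARKER_COLUMNS, path)
    df = df[list(MARKER_COLUMNS)].astype(
        {"mass_kda": float, "peak_slice": float}
    )
    validate_markers(df, source=str(path))
    return df


def validate_markers(markers: pd.DataFrame, source: str = "marker table") -> None:
    if len(markers) < 2:
        raise ValueError(f"{source}: at least 2 markers are required, got {len(markers)}")
    ordered = markers.sort_values("peak_slice")
    slices = ordered["peak_slice"].to_numpy()
    masses = ordered["mass_kda"].to_numpy()
    if len(np.unique(slices)) != len(slices):
        raise ValueError(f"{source}: marker peak slices must be distinct")
    if not np.all(np.diff(masses) < 0):
        raise ValueError(
            f"{source}: marker masses must decrease strictly with slice index "
            "(mass and migration must be co-monotone)"
        )


def write_markers(markers: pd.DataFrame, path) -> None:
    markers[list(MARKER_COLUMNS)].to_csv(path, sep="\t", index=False, lineterminator="\n")


def _profile_sort_key(annotation: pd.DataFrame | None):
    """Return a protein -> (complex rank, display order) sort key.

    Proteins absent from the annotation sort into a trailing "unassigned"
    block, in input order.
    """
    if annotation is None or annotation.empty:
        lookup: dict[str, tuple] = {}
        complex_rank: dict[str, int] = {}
    else:
        complex_rank = {
            cid: i for i, cid in enumerate(dict.fromkeys(annotation["complex_id"]))
        }
        lookup = {
            row.protein_id: (complex_rank[row.complex_id], row.display_order)
            for row in annotation.itertuples()
        }

    def key(protein_id: str, fallback_rank: int) -> tuple:
        if protein_id in lookup:
            return (0, *lookup[protein_id], protein_id)
        return (1, fallback_rank, 0, protein_id)

    return key


def write_profile_matrix(
    profiles, annotation: pd.DataFrame | None, path, long_path=None
) -> None:
    """Write normalized migration profiles as a wide TSV and a long CSV.

    ``profiles`` is an iterable of :class:`~complexome.quant.MigrationProfile`.
    The wide TSV at ``path`` has one row per profile, proteins ordered by
    (complex, display_order) from the annotation, columns ``slice_1.. slice_n``
    with values formatted to 4 decimals; a ``condition`` column is inserted
    after ``protein_id`` whenever more than one condition is present. The long
    CSV (same stem, ``_long.csv`` suffix unless ``path`` ends in ``.csv``) has
    columns ``protein_id, condition, slice_index, relative_intensity``.
    Writing then reading recovers values to 1e-4.
    """
    profiles = list(profiles)
    path = Path(path)
    long_path = (
        Path(long_path) if long_path is not None
        else path.with_name(path.stem + "_long.csv")
    )
    lengths = {len(p.values) for p in profiles}
    if len(lengths) > 1:
        raise ValueError(f"profiles have mismatched lengths: {sorted(lengths)}")
    if not profiles:
        logger.warning("write_profile_matrix: no profiles; writing header-only files")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("protein_id\n")
        with open(long_path, "w", encoding="utf-8", newline="") as fh:
            csv.writer(fh).writerow(
                ["protein_id", "condition", "slice_index", "relative_intensity"]
            )
        return
    n_slices = lengths.pop()
    conditions = list(dict.fromkeys(p.condition for p in profiles))
    with_condition = len(conditions) > 1

    key = _profile_sort_key(annotation)
    order = sorted(
        range(len(profiles)),
        key=lambda i: (*key(profiles[i].protein_id, i), profiles[i].condition),
    )

    slice_cols = [f"slice_{s}" for s in range(1, n_slices + 1)]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        head = ["protein_id"] + (["condition"] if with_condition else []) + slice_cols
        fh.write("\t".join(head) + "\n")
        for i in order:
            p = profiles[i]
            fields = [p.protein_id] + ([p.condition] if with_condition else [])
            fields += [f"{v:.4f}" for v in p.values]
            fh.write("\t".join(fields) + "\n")

    with open(long_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["protein_id", "condition", "slice_index", "relative_intensity"])
        for i in order:
            p = profiles[i]
            for s, v in enumerate(p.values, start=1):
                writer.writerow([p.protein_id, p.condition, s, f"{v:.4f}"])


def read_profile_matrix(path) -> pd.DataFrame:
    """Read back a wide profile TSV written by :func:`write_profile_matrix`."""
    df = pd.read_csv(Path(path), sep="\t", dtype={"protein_id": str})
    return df


def read_long_profiles(path) -> pd.DataFrame:
    """Read the long CSV profile dialect."""
    return pd.read_csv(
        Path(path), dtype={"protein_id": str, "condition": str}
    )
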