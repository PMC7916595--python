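"""SILAC channel separation and migration-profile quantification.

The quantification follows the classic complexome-profiling recipe: light
and heavy peptides are split into two datasets, each protein is quantified
by its single most frequently occurring peptide observed in both labeled
and unlabeled form, per-replicate raw migration profiles are averaged
across duplicate experiments, and the averaged profile is normalized to
the slice with the highest intensity. Condition abundance ratios
(reference/perturbed) are computed from the same representative peptide
and combined across replicates by geometric mean — ratios are scale
quantities, so the geometric mean is the natural centre.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MigrationProfile",
    "ProteinRatio",
    "split_channels",
    "map_channels_to_conditions",
    "select_representative_peptide",
    "build_raw_profile",
    "average_and_normalize",
    "protein_ratio",
    "condition_profiles",
    "protein_abundance_table",
]

ABSENT_IN_PERTURBED = "absent-in-perturbed"
ABSENT_IN_REFERENCE = "absent-in-reference"


@dataclass
class MigrationProfile:
    """Per-protein, per-condition vector of per-slice intensities.

    When ``normalized`` is set the maximum value is exactly 1 (unless the
    protein was undetected, in which case all values are 0 and the
    ``"undetected"`` flag is present).
    """

    protein_id: str
    condition: str
    values: np.ndarray
    normalized: bool = False
    source_peptide: str | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be a 1-D vector")
        if (self.values < 0).any():
            raise ValueError("profile values must be non-negative")
        if self.normalized and self.values.max(initial=0.0) not in (0.0, 1.0):
            raise ValueError("normalized profile must have max exactly 1 (or be all zero)")


@dataclass
class ProteinRatio:
    """Reference/perturbed abundance ratio for one protein.

    ``ratio`` is the geometric mean of the finite per-replicate ratios;
    it is ``None`` when no replicate yields a finite ratio, in which case
    ``flag`` says which condition the protein was absent from.
    """

    protein_id: str
    ratio: float | None
    per_replicate_ratios: list[float | None] = field(default_factory=list)
    n_slices_used: int = 0
    flag: str | None = None
    source_peptide: str | None = None


def split_channels(evidence: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition evidence into (light, heavy) tables.

    Every input row lands in exactly one output; row counts sum to the
    input count.
    """
    light = evidence[evidence["channel"] == "light"]
    heavy = evidence[evidence["channel"] == "heavy"]
    if light.empty or heavy.empty:
        logger.warning(
            "split_channels: one channel is empty (light=%d rows, heavy=%d rows)",
            len(light), len(heavy),
        )
    return light, heavy


def map_channels_to_conditions(
    evidence: pd.DataFrame, swap_map: dict[tuple[str, int], str], conditions: tuple[str, str]
) -> pd.DataFrame:
    """Attach a ``condition`` column using the per-replicate label-swap map.

    ``swap_map`` gives, for each (experiment_id, replicate), the condition
    that carries the heavy label; the light channel maps to the other
    condition of the pair.
    """
    other = {conditions[0]: conditions[1], conditions[1]: conditions[0]}
    keys = list(zip(evidence["experiment_id"], evidence["replicate"]))
    missing = sorted({k for k in keys if k not in swap_map})
    if missing:
        raise KeyError(
            f"replicate(s) missing from the label-swap map: {missing}"
        )
    heavy_cond = np.array([swap_map[k] for k in keys], dtype=object)
    is_heavy = (evidence["channel"] == "heavy").to_numpy()
    condition = np.where(
        is_heavy, heavy_cond, np.array([other[c] for c in heavy_cond], dtype=object)
    )
    out = evidence.copy()
    out["condition"] = condition
    return out


def select_representative_peptide(
    protein_evidence: pd.DataFrame,
) -> tuple[str, dict]:
    """Pick the protein's single quantification peptide.

    Among peptides observed in BOTH channels anywhere in the dataset, the
    winner occupies the greatest number of distinct (replicate, slice,
    channel) cells; ties break by larger summed intensity, then by
    lexicographically smallest sequence. If no peptide is seen in both
    channels the most frequent one overall is used and the diagnostics
    carry a ``single_channel_representative`` flag.
    """
    if protein_evidence.empty:
        raise ValueError("no evidence rows for this protein")
    cells = protein_evidence.drop_duplicates(
        subset=["peptide_sequence", "replicate", "slice_index", "channel"]
    )
    counts = cells.groupby("peptide_sequence").size()
    sums = protein_evidence.groupby("peptide_sequence")["intensity"].sum()
    n_channels = protein_evidence.groupby("peptide_sequence")["channel"].nunique()
    both = n_channels[n_channels == 2].index
    single_channel = len(both) == 0
    pool = counts.index if single_channel else both
    ranked = sorted(
        pool, key=lambda p: (-counts[p], -sums[p], p)
    )
    winner = ranked[0]
    diagnostics = {
        "n_cells": int(counts[winner]),
        "summed_intensity": float(sums[winner]),
        "single_channel_representative": single_channel,
        "n_candidate_peptides": int(len(counts)),
    }
    if single_channel:
        logger.info(
            "protein %s: no peptide observed in both channels; using %s",
            protein_evidence["protein_id"].iloc[0], winner,
        )
    return winner, diagnostics


def build_raw_profile(
    protein_id: str,
    condition: str,
    representative: str,
    evidence: pd.DataFrame,
    replicate: int,
    n_slices: int,
) -> MigrationProfile:
    """Raw (unnormalized) per-replicate profile of the representative peptide.

    values[s] sums the peptide's intensities observed at (condition,
    replicate, slice s); slices without an observation are 0 — absence of
    evidence at the detection floor, not missing data.
    """
    values = np.zeros(n_slices)
    rows = evidence[
        (evidence["protein_id"] == protein_id)
        & (evidence["peptide_sequence"] == representative)
        & (evidence["condition"] == condition)
        & (evidence["replicate"] == replicate)
    ]
    if not rows.empty:
        sums = rows.groupby("slice_index")["intensity"].sum()
        values[sums.index.to_numpy() - 1] = sums.to_numpy()
    return MigrationProfile(
        protein_id, condition, values, normalized=False, source_peptide=representative
    )


def average_and_normalize(profiles: list[MigrationProfile]) -> MigrationProfile:
    """Average raw replicate profiles element-wise, then max-normalize once.

    The average is taken on the raw profiles and the result is divided by
    its largest element, so the profile reflects the slice with the highest
    mean intensity across duplicate experiments. An all-zero mean yields an
    all-zero profile flagged ``"undetected"``.
    """
    if not profiles:
        raise ValueError("need at least one replicate profile")
    lengths = {len(p.values) for p in profiles}
    if len(lengths) > 1:
        raise ValueError(f"replicate profiles have mismatched lengths: {sorted(lengths)}")
    mean = np.mean([p.values for p in profiles], axis=0)
    peak = mean.max()
    flags = set()
    if peak > 0:
        mean = mean / peak
    else:
        flags.add("undetected")
    first = profiles[0]
    return MigrationProfile(
        first.protein_id,
        first.condition,
        mean,
        normalized=True,
        source_peptide=first.source_peptide,
        flags=frozenset(flags),
    )


def protein_ratio(
    protein_id: str,
    evidence: pd.DataFrame,
    conditions: tuple[str, str],
    representative: str | None = None,
    all_peptides: bool = False,
) -> ProteinRatio:
    """Reference/perturbed abundance ratio from summed slice intensities.

    Per replicate the ratio is sum_s I_ref(s) / sum_s I_pert(s) over the
    representative peptide (or over all peptides with ``all_peptides``),
    restricted to slices where at least one condition was observed.
    Replicates combine by geometric mean. A zero perturbed sum against a
    nonzero reference yields the ``absent-in-perturbed`` flag instead of a
    number (and symmetrically for the reference).
    """
    if "condition" not in evidence.columns:
        raise ValueError("evidence must carry a condition column (map channels first)")
    rows = evidence[evidence["protein_id"] == protein_id]
    if rows.empty:
        raise ValueError(f"protein {protein_id!r} absent from the evidence table")
    if not all_peptides:
        if representative is None:
            representative, _ = select_representative_peptide(rows)
        rows = rows[rows["peptide_sequence"] == representative]
    reference, perturbed = conditions
    per_rep: list[float | None] = []
    n_slices_used = 0
    any_ref = False
    any_pert = False
    for rep in sorted(rows["replicate"].unique()):
        sub = rows[rows["replicate"] == rep]
        by = sub.pivot_table(
            index="slice_index", columns="condition", values="intensity",
            aggfunc="sum", fill_value=0.0,
        )
        ref = by[reference] if reference in by else pd.Series(0.0, index=by.index)
        pert = by[perturbed] if perturbed in by else pd.Series(0.0, index=by.index)
        support = (ref > 0) | (pert > 0)
        n_slices_used += int(support.sum())
        r_sum, p_sum = float(ref[support].sum()), float(pert[support].sum())
        any_ref |= r_sum > 0
        any_pert |= p_sum > 0
        per_rep.append(r_sum / p_sum if r_sum > 0 and p_sum > 0 else None)
    finite = [r for r in per_rep if r is not None]
    if finite:
        combined = float(np.exp(np.mean(np.log(finite))))
        flag = None
    else:
        combined = None
        flag = ABSENT_IN_PERTURBED if any_ref and not any_pert else (
            ABSENT_IN_REFERENCE if any_pert and not any_ref else "undetected"
        )
    return ProteinRatio(
        protein_id,
        combined,
        per_replicate_ratios=per_rep,
        n_slices_used=n_slices_used,
        flag=flag,
        source_peptide=representative,
    )


def condition_profiles(
    evidence: pd.DataFrame,
    conditions: tuple[str, str],
    n_slices: int,
) -> dict[tuple[str, str], MigrationProfile]:
    """Normalized profile for every (protein, condition) in the evidence.

    Evidence must already carry a ``condition`` column. Returns a mapping
    ``(protein_id, condition) -> MigrationProfile``. Proteins entirely
    unobserved in one condition get an all-zero profile there, flagged
    ``undetected``, so comparative peak calls see both conditions.
    """
    out: dict[tuple[str, str], MigrationProfile] = {}
    replicates = sorted(evidence["replicate"].unique())
    for pid, rows in evidence.groupby("protein_id", sort=True):
        representative, diag = select_representative_peptide(rows)
        for condition in conditions:
            per_rep = [
                build_raw_profile(pid, condition, representative, rows, rep, n_slices)
                for rep in replicates
            ]
            prof = average_and_normalize(per_rep)
            if diag["single_channel_representative"]:
                prof.flags = prof.flags | {"single-channel-representative"}
            out[(pid, condition)] = prof
    return out


def normalize_total_intensity(evidence: pd.DataFrame) -> pd.DataFrame:
    """Optional between-replicate loading normalization (default off).

    Rescales each (experiment, replicate) so its summed intensity equals
    the across-replicate mean. Within-lane SILAC mixing already controls
    sample composition, so this only corrects gross loading differences
    between gel lanes.
    """
    totals = evidence.groupby(["experiment_id", "replicate"])["intensity"].transform("sum")
    target = evidence.groupby(["experiment_id", "replicate"])["intensity"].sum().mean()
    out = evidence.copy()
    out["intensity"] = out["intensity"] * (target / totals)
    return out


def protein_abundance_table(
    evidence: pd.DataFrame, conditions: tuple[str, str]
) -> pd.DataFrame:
    """Per-protein summed intensity by condition and replicate.

    Sums all peptide evidence (not just the representative) over slices —
    the label-free-style per-protein abundance used for log2 fold-change
    summaries. Columns: protein_id, condition, replicate, abundance.
    """
    if "condition" not in evidence.columns:
        raise ValueError("evidence must carry a condition column (map channels first)")
    out = (
        evidence.groupby(["protein_id", "condition", "replicate"], sort=True)[
            "intensity"
        ]
        .sum()
        .reset_index()
        .rename(columns={"intensity": "abundance"})
    )
    return out
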