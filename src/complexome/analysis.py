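"""Comparative analysis of migration profiles between two conditions.

Turns normalized migration profiles and SILAC protein ratios into the
biology-level readout of a complexome comparison: peak (band) calls with
apparent masses, gained/lost migration shifts between conditions,
complex-level fold changes robust to heterogeneous subunit behaviour,
co-migration correlations, ordered heatmap matrices, and a label-free
style log2 fold-change summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import MassCalibration, apparent_mass
from .quant import (
    ABSENT_IN_PERTURBED,
    ABSENT_IN_REFERENCE,
    MigrationProfile,
    ProteinRatio,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "PeakList",
    "MigrationShift",
    "ComplexFoldChange",
    "ComigrationScore",
    "ComparisonReport",
    "detect_peaks",
    "migration_shift",
    "complex_fold_change",
    "comigration_score",
    "heatmap_matrix",
    "lfq_log2fc_summary",
    "self_calibration_markers",
    "build_comparison_report",
    "write_report",
]


@dataclass(frozen=True)
class Peak:
    slice: float
    relative_height: float
    apparent_mass_kda: float | None = None


@dataclass
class PeakList:
    protein_id: str
    condition: str
    peaks: list[Peak]


@dataclass
class MigrationShift:
    """Peaks gained and lost in the perturbed condition for one protein."""

    protein_id: str
    gained: list[Peak]
    lost: list[Peak]
    matched: list[tuple[Peak, Peak]]


@dataclass
class ComplexFoldChange:
    complex_id: str
    median: float | None
    iqr: tuple[float, float] | None
    n_finite: int
    n_absent_perturbed: int
    n_absent_reference: int
    flag: str | None = None  # "low-n" | "complex-absent" | None


@dataclass(frozen=True)
class ComigrationScore:
    r: float | None
    flag: str | None = None  # "not-a-score" | "insufficient-support" | None


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; edge windows shrink to the available slices."""
    if window <= 1:
        return values
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def detect_peaks(
    profile: MigrationProfile,
    min_rel_height: float = 0.2,
    calibration: MassCalibration | None = None,
    smooth_window: int = 3,
) -> PeakList:
    """Call bands in a normalized migration profile.

    The profile is smoothed with a 3-point moving average (``smooth_window
    = 1`` disables smoothing), local maxima strictly greater than both
    neighbours and at least ``min_rel_height`` high are kept (boundary
    slices count with a single neighbour), and interior peak positions are
    refined by parabolic interpolation over the three slices around the
    maximum. Apparent masses are attached when a calibration is given.
    """
    if not profile.normalized:
        raise ValueError("detect_peaks requires a normalized profile")
    v = _smooth(profile.values, smooth_window)
    n = len(v)
    peaks: list[Peak] = []
    for i in range(n):
        left = v[i - 1] if i > 0 else -np.inf
        right = v[i + 1] if i < n - 1 else -np.inf
        if v[i] > left and v[i] > right and v[i] >= min_rel_height:
            s = float(i + 1)
            height = float(v[i])
            if 0 < i < n - 1:
                denom = v[i - 1] - 2 * v[i] + v[i + 1]
                if denom < 0:
                    delta = 0.5 * (v[i - 1] - v[i + 1]) / denom
                    s += float(delta)
                    height = float(v[i] - 0.25 * (v[i - 1] - v[i + 1]) * delta)
            mass = apparent_mass(calibration, s) if calibration is not None else None
            peaks.append(Peak(s, min(height, 1.0), mass))
    return PeakList(profile.protein_id, profile.condition, sorted(peaks, key=lambda p: p.slice))


def migration_shift(
    reference: PeakList, perturbed: PeakList, match_tol: float = 1.5
) -> MigrationShift:
    """Match peaks between conditions; the leftovers are the shifts.

    Greedy nearest-slice matching within ``match_tol`` slices: unmatched
    perturbed peaks are "gained", unmatched reference peaks are "lost".
    """
    if reference.protein_id != perturbed.protein_id:
        raise ValueError("migration_shift compares two conditions of the same protein")
    candidates = sorted(
        (
            (abs(r.slice - p.slice), i, j)
            for i, r in enumerate(reference.peaks)
            for j, p in enumerate(perturbed.peaks)
        ),
    )
    used_ref: set[int] = set()
    used_pert: set[int] = set()
    matched: list[tuple[Peak, Peak]] = []
    for dist, i, j in candidates:
        if dist > match_tol:
            break
        if i in used_ref or j in used_pert:
            continue
        used_ref.add(i)
        used_pert.add(j)
        matched.append((reference.peaks[i], perturbed.peaks[j]))
    gained = [p for j, p in enumerate(perturbed.peaks) if j not in used_pert]
    lost = [p for i, p in enumerate(reference.peaks) if i not in used_ref]
    return MigrationShift(reference.protein_id, gained, lost, matched)


def complex_fold_change(
    ratios: dict[str, ProteinRatio] | list[ProteinRatio],
    annotation: pd.DataFrame,
    complex_id: str,
) -> ComplexFoldChange:
    """Median and IQR of finite subunit ratios for one complex.

    The median is robust to subunits with atypical behaviour (e.g. a
    module depleted more strongly than the rest of the complex). Proteins
    absent from one condition are counted separately rather than folded in
    as infinities; a complex with no finite subunit ratio at all is flagged
    ``complex-absent``, fewer than three finite ratios flags ``low-n``.
    """
    if isinstance(ratios, list):
        ratios = {r.protein_id: r for r in ratios}
    roster = annotation.loc[annotation["complex_id"] == complex_id, "protein_id"]
    finite = []
    n_absent_pert = n_absent_ref = 0
    for pid in roster:
        r = ratios.get(pid)
        if r is None:
            continue
        if r.ratio is not None:
            finite.append(r.ratio)
        elif r.flag == ABSENT_IN_PERTURBED:
            n_absent_pert += 1
        elif r.flag == ABSENT_IN_REFERENCE:
            n_absent_ref += 1
    if not finite:
        return ComplexFoldChange(
            complex_id, None, None, 0, n_absent_pert, n_absent_ref, "complex-absent"
        )
    q25, q50, q75 = np.percentile(finite, [25, 50, 75])
    flag = "low-n" if len(finite) < 3 else None
    return ComplexFoldChange(
        complex_id, float(q50), (float(q25), float(q75)),
        len(finite), n_absent_pert, n_absent_ref, flag,
    )


def comigration_score(
    profile_a: MigrationProfile, profile_b: MigrationProfile, min_support: int = 5
) -> ComigrationScore:
    """Pearson correlation of two normalized profiles over all slices.

    Profile correlation is the standard complexome-profiling co-migration
    measure. Requires at least ``min_support`` slices where either profile
    is nonzero; a zero-variance profile yields no score.
    """
    if not (profile_a.normalized and profile_b.normalized):
        raise ValueError("comigration_score requires normalized profiles")
    a, b = profile_a.values, profile_b.values
    if len(a) != len(b):
        raise ValueError("profiles have different lengths")
    support = int(np.count_nonzero((a > 0) | (b > 0)))
    if support < min_support:
        return ComigrationScore(None, "insufficient-support")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return ComigrationScore(None, "not-a-score")
    r = float(np.corrcoef(a, b)[0, 1])
    return ComigrationScore(r, None)


def _ordered_proteins(
    proteins: list[str], annotation: pd.DataFrame | None
) -> list[str]:
    if annotation is None or annotation.empty:
        return proteins
    rank = {
        cid: i for i, cid in enumerate(dict.fromkeys(annotation["complex_id"]))
    }
    lookup = {
        row.protein_id: (rank[row.complex_id], row.display_order)
        for row in annotation.itertuples()
    }
    unassigned = [p for p in proteins if p not in lookup]
    if unassigned:
        logger.warning(
            "%d protein(s) missing from the annotation; appended as an "
            "'unassigned' block: %s", len(unassigned), unassigned[:5],
        )
    assigned = sorted((p for p in proteins if p in lookup), key=lambda p: lookup[p])
    return assigned + unassigned


def heatmap_matrix(
    profiles: dict[tuple[str, str], MigrationProfile],
    annotation: pd.DataFrame | None,
    protein_order: list[str] | None = None,
) -> pd.DataFrame:
    """Ordered (protein, condition) x slice matrix of relative intensities.

    Rows follow complex then display order (or the explicit
    ``protein_order``); values are the untransformed normalized profile on
    a linear [0, 1] scale, ready for heatmap rendering.
    """
    proteins = list(dict.fromkeys(pid for pid, _ in profiles))
    if protein_order is not None:
        unknown = [p for p in protein_order if p not in proteins]
        if unknown:
            raise KeyError(f"protein(s) in order list without profiles: {unknown}")
        ordered = protein_order
    else:
        ordered = _ordered_proteins(proteins, annotation)
    conditions = list(dict.fromkeys(cond for _, cond in profiles))
    rows = []
    index = []
    for pid in ordered:
        for cond in conditions:
            if (pid, cond) in profiles:
                rows.append(profiles[(pid, cond)].values)
                index.append((pid, cond))
    n_slices = len(rows[0]) if rows else 0
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["protein_id", "condition"]),
        columns=[f"slice_{s}" for s in range(1, n_slices + 1)],
    )


def lfq_log2fc_summary(
    abundance: pd.DataFrame,
    annotation: pd.DataFrame | None,
    reference: str,
) -> pd.DataFrame:
    """Per-protein log2 fold change of mean abundance vs the reference.

    ``abundance`` has columns protein_id, condition, and abundance (an
    optional replicate column is averaged over). Output rows are grouped
    and ordered by complex; a zero mean on either side is flagged rather
    than patched with a pseudocount.
    """
    if reference not in set(abundance["condition"]):
        raise ValueError(f"reference condition {reference!r} missing from the table")
    means = (
        abundance.groupby(["protein_id", "condition"], sort=True)["abundance"]
        .mean()
        .unstack("condition")
        .fillna(0.0)
    )
    others = [c for c in means.columns if c != reference]
    records = []
    for pid, row in means.iterrows():
        for cond in others:
            ref_mean, pert_mean = row[reference], row[cond]
            if ref_mean > 0 and pert_mean > 0:
                records.append((pid, cond, float(np.log2(pert_mean / ref_mean)), ""))
            elif pert_mean == 0 and ref_mean > 0:
                records.append((pid, cond, np.nan, ABSENT_IN_PERTURBED))
            elif ref_mean == 0 and pert_mean > 0:
                records.append((pid, cond, np.nan, ABSENT_IN_REFERENCE))
            else:
                records.append((pid, cond, np.nan, "undetected"))
    out = pd.DataFrame(
        records, columns=["protein_id", "condition", "log2fc", "flag"]
    )
    if annotation is not None and not annotation.empty:
        out = out.merge(
            annotation[["protein_id", "complex_id", "display_order"]],
            on="protein_id", how="left",
        )
        rank = {
            cid: i for i, cid in enumerate(dict.fromkeys(annotation["complex_id"]))
        }
        out["_rank"] = out["complex_id"].map(rank).fillna(len(rank))
        out = (
            out.sort_values(["_rank", "display_order", "protein_id", "condition"])
            .drop(columns="_rank")
            .reset_index(drop=True)
        )
        out["complex_id"] = out["complex_id"].fillna("unassigned")
    return out


# ---------------------------------------------------------------------------
# Self-calibration and report assembly
# ---------------------------------------------------------------------------

#: (marker name, protein, condition, known mass kDa, which detected peak)
DEFAULT_SELF_MARKERS = (
    ("cIII2 dimer", "UQCRC2", "reference", 500.0, "last"),
    ("cV monomer", "ATP5F1B", "reference", 700.0, "dominant"),
)


def self_calibration_markers(
    profiles: dict[tuple[str, str], MigrationProfile],
    gel_log10_top: float,
    gel_log10_bottom: float,
    n_slices: int,
    reference: str,
    marker_specs=DEFAULT_SELF_MARKERS,
    min_rel_height: float = 0.2,
) -> pd.DataFrame:
    """Build a marker table from landmark complexes in the reference lane.

    The free cIII dimer (500 kDa; the lowest-mass band of a cIII subunit)
    and the cV monomer (700 kDa; the dominant band of a cV subunit) anchor
    the middle of the gel, and the configured gel endpoints anchor the
    extremes, so the run calibrates itself without external standards.
    """
    rows = [
        ("gel_top", 10 ** gel_log10_top, 1.0),
        ("gel_bottom", 10 ** gel_log10_bottom, float(n_slices)),
    ]
    for name, pid, cond_role, mass, pick in marker_specs:
        cond = reference if cond_role == "reference" else cond_role
        prof = profiles.get((pid, cond))
        if prof is None or "undetected" in prof.flags:
            logger.warning("self-calibration marker %s (%s) not detected; skipped", name, pid)
            continue
        peaks = detect_peaks(prof, min_rel_height=min_rel_height).peaks
        if not peaks:
            logger.warning("self-calibration marker %s (%s): no peaks; skipped", name, pid)
            continue
        peak = (
            max(peaks, key=lambda p: p.relative_height)
            if pick == "dominant"
            else (peaks[-1] if pick == "last" else peaks[0])
        )
        rows.append((name, float(mass), peak.slice))
    df = pd.DataFrame(rows, columns=["marker_name", "mass_kda", "peak_slice"])
    return df.sort_values("peak_slice", ignore_index=True)


@dataclass
class ComparisonReport:
    """Everything the two-condition comparison concludes, as flat tables."""

    per_protein: pd.DataFrame
    per_complex: pd.DataFrame
    shifts: pd.DataFrame
    comigration: pd.DataFrame


def build_comparison_report(
    profiles: dict[tuple[str, str], MigrationProfile],
    ratios: dict[str, ProteinRatio],
    annotation: pd.DataFrame,
    calibration: MassCalibration,
    conditions: tuple[str, str],
    min_rel_height: float = 0.2,
    match_tol: float = 1.5,
    comigration_proteins: list[str] | None = None,
) -> ComparisonReport:
    """Assemble the full per-protein / per-complex / shift / co-migration report."""
    reference, perturbed = conditions
    ann = annotation.set_index("protein_id") if not annotation.empty else None

    protein_rows = []
    shift_rows = []
    proteins = sorted({pid for pid, _ in profiles})
    for pid in _ordered_proteins(proteins, annotation):
        r = ratios.get(pid)
        complex_id = module_id = ""
        if ann is not None and pid in ann.index:
            complex_id = ann.loc[pid, "complex_id"]
            module_id = ann.loc[pid, "module_id"]
        per_rep = r.per_replicate_ratios if r else []
        protein_rows.append(
            {
                "protein_id": pid,
                "complex_id": complex_id,
                "module_id": module_id,
                "ratio_ref_over_pert": r.ratio if r and r.ratio is not None else np.nan,
                "flag": (r.flag or "") if r else "no-ratio",
                "per_replicate_ratios": ";".join(
                    "NA" if v is None else f"{v:.6g}" for v in per_rep
                ),
                "n_slices_used": r.n_slices_used if r else 0,
                "source_peptide": (r.source_peptide or "") if r else "",
            }
        )
        ref_prof = profiles.get((pid, reference))
        pert_prof = profiles.get((pid, perturbed))
        if ref_prof is None or pert_prof is None:
            continue
        ref_peaks = detect_peaks(ref_prof, min_rel_height, calibration)
        pert_peaks = detect_peaks(pert_prof, min_rel_height, calibration)
        shift = migration_shift(ref_peaks, pert_peaks, match_tol)
        for kind, peaks in (("gained", shift.gained), ("lost", shift.lost)):
            for p in peaks:
                shift_rows.append(
                    {
                        "protein_id": pid,
                        "complex_id": complex_id,
                        "change": kind,
                        "slice": round(p.slice, 3),
                        "apparent_mass_kda": round(p.apparent_mass_kda, 2)
                        if p.apparent_mass_kda is not None
                        else np.nan,
                        "relative_height": round(p.relative_height, 4),
                    }
                )

    complex_rows = []
    for cid in dict.fromkeys(annotation["complex_id"]) if not annotation.empty else []:
        fc = complex_fold_change(ratios, annotation, cid)
        complex_rows.append(
            {
                "complex_id": cid,
                "median_ratio": fc.median if fc.median is not None else np.nan,
                "iqr_low": fc.iqr[0] if fc.iqr else np.nan,
                "iqr_high": fc.iqr[1] if fc.iqr else np.nan,
                "n_finite": fc.n_finite,
                "n_absent_perturbed": fc.n_absent_perturbed,
                "n_absent_reference": fc.n_absent_reference,
                "flag": fc.flag or "",
            }
        )

    comig_rows = []
    if comigration_proteins:
        comigration_proteins = sorted(set(comigration_proteins))
        for cond in conditions:
            for i, pa in enumerate(comigration_proteins):
                for pb in comigration_proteins[i + 1:]:
                    a, b = profiles.get((pa, cond)), profiles.get((pb, cond))
                    if a is None or b is None:
                        continue
                    score = comigration_score(a, b)
                    comig_rows.append(
                        {
                            "protein_a": pa,
                            "protein_b": pb,
                            "condition": cond,
                            "pearson_r": round(score.r, 4)
                            if score.r is not None
                            else np.nan,
                            "flag": score.flag or "",
                        }
                    )

    return ComparisonReport(
        per_protein=pd.DataFrame(protein_rows),
        per_complex=pd.DataFrame(complex_rows),
        shifts=pd.DataFrame(
            shift_rows,
            columns=[
                "protein_id", "complex_id", "change", "slice",
                "apparent_mass_kda", "relative_height",
            ],
        ),
        comigration=pd.DataFrame(
            comig_rows,
            columns=["protein_a", "protein_b", "condition", "pearson_r", "flag"],
        ),
    )


def write_report(report: ComparisonReport, outdir) -> dict[str, str]:
    """Write report.tsv, complexes.tsv, shifts.tsv, comigration.tsv."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("report.tsv", report.per_protein),
        ("complexes.tsv", report.per_complex),
        ("shifts.tsv", report.shifts),
        ("comigration.tsv", report.comigration),
    ):
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.6g")
        paths[name] = str(path)
    return paths
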