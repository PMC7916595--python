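"""Synthetic SILAC/BN-PAGE complexome evidence generator.

The generative model: each protein belongs to one or more assembly forms
(holo-complexes, supercomplexes, sub-complexes, free pools), each form
migrates as a Gaussian band centred at the slice its apparent mass maps to
under a log-linear gel model, and the two biological conditions are mixed
1:1 as SILAC light/heavy channels with the heavy label swapped between
duplicate experiments. Peptide-level evidence is derived from the per-slice
protein signal through fixed per-peptide response factors, multiplicative
lognormal measurement noise, and an intensity detection floor that censors
(drops) weak observations.

``build_default_scenario`` encodes a two-condition comparison of wild-type
HEK293 mitochondria against a COX4I1/COX4I2 double-knockout: assembled
complex IV is absent from the knockout except a ~130 kDa MT-CO1-containing
early intermediate, complex I drops fivefold with a ~750 kDa precomplex
lacking the N-module, complex III shifts to its free dimer, complex II is
unchanged, both mitoribosomal subunits fall 1.75-fold, and the ribosome
assembly factors DDX28 and ERAL1 are halved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import EVIDENCE_COLUMNS

__all__ = [
    "AssemblyForm",
    "GelModel",
    "NoiseModel",
    "ScenarioConfig",
    "build_default_scenario",
    "default_annotation",
    "form_center_slice",
    "simulate_evidence",
    "protein_signal_matrix",
    "scenario_to_dict",
    "scenario_from_dict",
    "DEFAULT_DETECTION_FLOOR",
]

#: Default censoring threshold, in the same arbitrary units as form
#: abundances. Frozen from the 10th percentile of the noise-free nonzero
#: per-observation signal of the default scenario, so roughly one in ten
#: true observations falls below the floor and is dropped.
DEFAULT_DETECTION_FLOOR = 4.6e-4

#: Gaussian bands are truncated at this many peak widths from the centre;
#: the discretized kernel is renormalized over the surviving slices so the
#: loaded amount of every protein is conserved exactly.
KERNEL_TRUNCATION_SIGMAS = 5.0


class ScenarioError(ValueError):
    """Invalid scenario configuration."""


@dataclass(frozen=True)
class AssemblyForm:
    """One migrating species: a complex, sub-complex, or free pool.

    Parameters
    ----------
    name : str
        Display name of the species (e.g. ``"respirasome I+III2+IV"``).
    apparent_mass : float
        Apparent molecular mass in kDa; must fall inside the gel's range.
    members : mapping of protein id -> copies per form (positive int).
    abundance : mapping of condition name -> abundance in arbitrary units
        (0 allowed; every condition of the scenario needs an entry).
    """

    name: str
    apparent_mass: float
    members: Mapping[str, int]
    abundance: Mapping[str, float]

    def __post_init__(self):
        if self.apparent_mass <= 0:
            raise ScenarioError(f"form {self.name!r}: apparent_mass must be > 0")
        if not self.members:
            raise ScenarioError(f"form {self.name!r}: members must be non-empty")
        for pid, stoich in self.members.items():
            if int(stoich) != stoich or stoich < 1:
                raise ScenarioError(
                    f"form {self.name!r}: stoichiometry of {pid} must be a "
                    f"positive integer, got {stoich}"
                )
        for cond, ab in self.abundance.items():
            if ab < 0:
                raise ScenarioError(
                    f"form {self.name!r}: abundance for {cond!r} must be >= 0"
                )


@dataclass(frozen=True)
class GelModel:
    """Log-linear BN-PAGE gel geometry.

    log10(apparent mass) decreases linearly from ``log10_mass_top`` at
    slice 1 to ``log10_mass_bottom`` at slice ``n_slices``; bands are
    Gaussian in slice coordinates with width ``peak_sigma`` (slices).
    """

    n_slices: int = 64
    log10_mass_top: float = 3.5
    log10_mass_bottom: float = 1.5
    peak_sigma: float = 1.0

    def __post_init__(self):
        if self.n_slices < 8:
            raise ScenarioError("gel must have at least 8 slices")
        if not self.log10_mass_top > self.log10_mass_bottom:
            raise ScenarioError("log10_mass_top must exceed log10_mass_bottom")
        if self.peak_sigma <= 0:
            raise ScenarioError("peak_sigma must be > 0")

    @property
    def mass_range_kda(self) -> tuple[float, float]:
        return (10 ** self.log10_mass_bottom, 10 ** self.log10_mass_top)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative noise and censoring parameters.

    response_sd: lognormal sigma of per-peptide response factors (fixed
    across replicates and channels). measurement_sd: lognormal sigma per
    observation. detection_floor: intensity below which an observation is
    censored (dropped, not zeroed).
    """

    response_sd: float = 0.3
    measurement_sd: float = 0.2
    detection_floor: float = DEFAULT_DETECTION_FLOOR

    def __post_init__(self):
        if self.response_sd < 0 or self.measurement_sd < 0 or self.detection_floor < 0:
            raise ScenarioError("noise parameters must be non-negative")


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete generative description of one SILAC complexome experiment.

    ``conditions`` is the ordered (reference, perturbed) pair.
    ``replicates`` assigns, per replicate, which condition carries the
    heavy label (a label swap lists each condition once).
    ``mixing_ratio`` is the reference:perturbed mixing amount (1.0 = 1:1).
    """

    conditions: tuple[str, str]
    forms: tuple[AssemblyForm, ...]
    gel: GelModel = field(default_factory=GelModel)
    replicates: tuple[str, ...] = ()
    mixing_ratio: float = 1.0
    peptides_per_protein: tuple[int, int] = (3, 8)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    experiment_id: str = "exp1"

    def __post_init__(self):
        if len(self.conditions) != 2 or self.conditions[0] == self.conditions[1]:
            raise ScenarioError("conditions must be an ordered pair of distinct names")
        if not self.forms:
            raise ScenarioError("scenario needs at least one assembly form")
        if not self.replicates:
            raise ScenarioError("scenario needs at least one replicate")
        for heavy in self.replicates:
            if heavy not in self.conditions:
                raise ScenarioError(
                    f"replicate heavy-label condition {heavy!r} is not one of "
                    f"{self.conditions}"
                )
        if self.mixing_ratio <= 0:
            raise ScenarioError("mixing_ratio must be > 0")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ScenarioError("peptides_per_protein must be a range 1 <= lo <= hi")
        for f in self.forms:
            missing = [c for c in self.conditions if c not in f.abundance]
            if missing:
                raise ScenarioError(
                    f"form {f.name!r}: missing abundance for condition(s) {missing}"
                )

    @property
    def reference(self) -> str:
        return self.conditions[0]

    @property
    def perturbed(self) -> str:
        return self.conditions[1]

    def proteins(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.forms:
            for pid in f.members:
                seen.setdefault(pid, None)
        return sorted(seen)

    def swap_map(self) -> dict[tuple[str, int], str]:
        """(experiment_id, replicate) -> condition carrying the heavy label."""
        return {
            (self.experiment_id, r): heavy
            for r, heavy in enumerate(self.replicates, start=1)
        }

    def mixing_share(self, condition: str) -> float:
        """Fraction of the mixed sample contributed by ``condition``."""
        mu = self.mixing_ratio
        if condition == self.reference:
            return mu / (1.0 + mu)
        return 1.0 / (1.0 + mu)


def form_center_slice(form: AssemblyForm, gel: GelModel) -> float:
    """Continuous slice coordinate where a form's band is centred.

    Log-linear migration: ``s = 1 + (log10(top) - log10(mass)) * (n-1) /
    (log10(top) - log10(bottom))``, strictly decreasing in mass.
    """
    lg = math.log10(form.apparent_mass)
    if lg > gel.log10_mass_top or lg < gel.log10_mass_bottom:
        lo, hi = gel.mass_range_kda
        raise ScenarioError(
            f"form {form.name!r}: apparent mass {form.apparent_mass:g} kDa is "
            f"outside the gel's range [{lo:.3g}, {hi:.3g}] kDa"
        )
    span = gel.log10_mass_top - gel.log10_mass_bottom
    return 1.0 + (gel.log10_mass_top - lg) * (gel.n_slices - 1) / span


def _band_kernel(center: float, gel: GelModel) -> tuple[np.ndarray, np.ndarray]:
    """Discretized Gaussian band: (slice indices, weights summing to 1)."""
    half = KERNEL_TRUNCATION_SIGMAS * gel.peak_sigma
    lo = max(1, int(math.ceil(center - half)))
    hi = min(gel.n_slices, int(math.floor(center + half)))
    slices = np.arange(lo, hi + 1)
    w = np.exp(-0.5 * ((slices - center) / gel.peak_sigma) ** 2)
    return slices, w / w.sum()


def protein_signal_matrix(scenario: ScenarioConfig) -> dict[str, np.ndarray]:
    """Noise-free per-slice signal for every protein.

    Returns ``{protein_id: array of shape (2, n_slices)}`` with rows in
    ``scenario.conditions`` order. Signal in slice s for condition c is
    ``sum over forms of abundance(c) * stoichiometry * kernel(s)``.
    """
    out: dict[str, np.ndarray] = {
        pid: np.zeros((2, scenario.gel.n_slices)) for pid in scenario.proteins()
    }
    for f in scenario.forms:
        center = form_center_slice(f, scenario.gel)
        slices, w = _band_kernel(center, scenario.gel)
        ab = np.array([f.abundance[c] for c in scenario.conditions])
        for pid, stoich in f.members.items():
            out[pid][:, slices - 1] += ab[:, None] * stoich * w[None, :]
    return out


_AA = "ACDEFGHILMNPQSTVWY"  # K/R reserved for the tryptic C-terminus


def _peptide_sequences(rng: np.random.Generator, k: int) -> list[str]:
    """Deterministic pseudo-tryptic peptide sequences (end in K or R)."""
    seqs = []
    for _ in range(k):
        length = int(rng.integers(7, 16))
        body = "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length - 1))
        seqs.append(body + ("K" if rng.integers(0, 2) == 0 else "R"))
    return seqs


def simulate_evidence(scenario: ScenarioConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw one synthetic peptide-evidence table from the scenario.

    For every protein, ``k`` peptides are drawn uniformly from
    ``peptides_per_protein`` with lognormal response factors fixed across
    replicates and channels. Each observation is the protein's noise-free
    per-slice signal times the peptide response, the condition's mixing
    share, and a lognormal measurement error; values below the detection
    floor (or exactly zero) are censored, i.e. absent from the output.
    Deterministic for a fixed (scenario, seed).
    """
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(int(seed))
    gel = scenario.gel
    noise = scenario.noise
    signals = protein_signal_matrix(scenario)
    proteins = scenario.proteins()

    lo, hi = scenario.peptides_per_protein
    n_peptides = {pid: int(rng.integers(lo, hi + 1)) for pid in proteins}
    peptides = {pid: _peptide_sequences(rng, n_peptides[pid]) for pid in proteins}
    responses = {
        pid: (
            np.exp(rng.normal(0.0, noise.response_sd, size=n_peptides[pid]))
            if noise.response_sd > 0
            else np.ones(n_peptides[pid])
        )
        for pid in proteins
    }

    cond_index = {c: i for i, c in enumerate(scenario.conditions)}
    shares = {c: scenario.mixing_share(c) for c in scenario.conditions}
    chunks: list[pd.DataFrame] = []
    for replicate, heavy_cond in enumerate(scenario.replicates, start=1):
        for channel in ("light", "heavy"):
            condition = (
                heavy_cond
                if channel == "heavy"
                else next(c for c in scenario.conditions if c != heavy_cond)
            )
            for pid in proteins:
                sig = signals[pid][cond_index[condition]]
                nz = np.flatnonzero(sig > 0)
                if nz.size == 0:
                    continue
                base = sig[nz][None, :] * responses[pid][:, None] * shares[condition]
                if noise.measurement_sd > 0:
                    base = base * np.exp(
                        rng.normal(0.0, noise.measurement_sd, size=base.shape)
                    )
                keep = (base > 0) & (base >= noise.detection_floor)
                pep_idx, slice_pos = np.nonzero(keep)
                if pep_idx.size == 0:
                    continue
                chunks.append(
                    pd.DataFrame(
                        {
                            "experiment_id": scenario.experiment_id,
                            "replicate": replicate,
                            "slice_index": (nz[slice_pos] + 1).astype(int),
                            "protein_id": pid,
                            "peptide_sequence": [
                                peptides[pid][j] for j in pep_idx
                            ],
                            "channel": channel,
                            "intensity": base[pep_idx, slice_pos],
                        }
                    )
                )
    if not chunks:
        return pd.DataFrame(
            {c: pd.Series(dtype=t) for c, t in zip(
                EVIDENCE_COLUMNS, [str, int, int, str, str, str, float]
            )}
        )
    out = pd.concat(chunks, ignore_index=True)
    return out[list(EVIDENCE_COLUMNS)]


# ---------------------------------------------------------------------------
# Default wt vs COX4I1/4I2-KO scenario
# ---------------------------------------------------------------------------

N_MODULE = ("NDUFV1", "NDUFV2", "NDUFS1", "NDUFA2")

CI_SUBUNITS = (
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "NDUFV1", "NDUFV2", "NDUFV3",
    "NDUFS1", "NDUFS2", "NDUFS3", "NDUFS4", "NDUFS5", "NDUFS6", "NDUFS7",
    "NDUFS8",
    "NDUFA1", "NDUFA2", "NDUFA3", "NDUFA5", "NDUFA6", "NDUFA7", "NDUFA8",
    "NDUFA9", "NDUFA10", "NDUFA11", "NDUFA12", "NDUFA13",
    "NDUFB1", "NDUFB2", "NDUFB3", "NDUFB4", "NDUFB5", "NDUFB6",
    "NDUFAB1", "NDUFC2",
)

CIII_SUBUNITS = (
    "MT-CYB", "CYC1", "UQCRC1", "UQCRC2", "UQCRFS1", "UQCRB", "UQCRQ", "UQCRH",
)

CIV_CORE = (
    "MT-CO1", "MT-CO2", "MT-CO3", "COX4I1", "COX5A", "COX5B", "COX6B1",
    "COX6C", "NDUFA4",
)
CIV_ACCESSORY = ("COA3", "HIGD2A", "HIGD1A")

CII_SUBUNITS = ("SDHA", "SDHB", "SDHC", "SDHD")

CV_SUBUNITS = (
    "MT-ATP6", "MT-ATP8", "ATP5F1A", "ATP5F1B", "ATP5F1C", "ATP5F1D",
    "ATP5F1E", "ATP5PB", "ATP5PD", "ATP5PF", "ATP5PO", "ATP5MC1",
)
F1_SUBUNITS = ("ATP5F1A", "ATP5F1B", "ATP5F1C", "ATP5F1D", "ATP5F1E")

MTLSU_SUBUNITS = tuple(f"MRPL{i}" for i in range(1, 41))
MTSSU_SUBUNITS = tuple(f"MRPS{i}" for i in range(1, 29))

#: Mitoribosome depletion factor in the knockout (within the reported
#: 1.5- to 2-fold band).
MITORIBO_FACTOR = 1.75

WT, KO = "wt", "ko"


def _members(*rosters: Sequence[str], stoich: int = 1) -> dict[str, int]:
    out: dict[str, int] = {}
    for roster in rosters:
        for pid in roster:
            out[pid] = out.get(pid, 0) + stoich
    return out


def build_default_scenario(seed: int = 0) -> ScenarioConfig:
    """The fixed wt vs COX4I1/4I2-knockout scenario.

    64-slice gel spanning log10(mass/kDa) 3.5 (slice 1) to 1.5 (slice 64),
    band width 1 slice. Form abundances (wt, ko; arbitrary units) encode
    the knockout phenotype; summed over forms, non-N-module complex I
    subunits come to wt 100 vs ko 20 (fivefold), complex II is unchanged,
    and the mitoribosome is depleted 1.75-fold. Replicate 1 carries the
    heavy label on wt, replicate 2 on ko (label swap).
    """
    cIII_dimer = _members(CIII_SUBUNITS, stoich=2)
    ci = _members(CI_SUBUNITS)
    civ = _members(CIV_CORE)
    cv = _members(CV_SUBUNITS)

    forms = (
        AssemblyForm("respirasome I+III2+IV", 1700.0,
                     {**ci, **cIII_dimer, **civ}, {WT: 60, KO: 0}),
        AssemblyForm("supercomplex I+III2", 1500.0,
                     {**ci, **cIII_dimer}, {WT: 25, KO: 12}),
        AssemblyForm("cI monomer", 1000.0, ci, {WT: 15, KO: 0}),
        AssemblyForm(
            "cI precomplex (no N-module)", 750.0,
            {p: 1 for p in CI_SUBUNITS if p not in N_MODULE},
            {WT: 0, KO: 8},
        ),
        AssemblyForm("supercomplex III2+IV", 730.0,
                     {**cIII_dimer, **civ}, {WT: 15, KO: 0}),
        AssemblyForm("cIII2 dimer", 500.0, cIII_dimer, {WT: 25, KO: 45}),
        AssemblyForm("cIV monomer", 215.0, civ, {WT: 40, KO: 0}),
        AssemblyForm("cIV dimer", 430.0, _members(CIV_CORE, stoich=2),
                     {WT: 10, KO: 0}),
        AssemblyForm("sub-IV intermediate (MITRAC)", 130.0,
                     _members(("MT-CO1", "COA3", "HIGD2A")), {WT: 0, KO: 5}),
        AssemblyForm("cIV assembly-factor pool", 100.0,
                     _members(CIV_ACCESSORY), {WT: 5, KO: 2}),
        AssemblyForm("free COX5B/NDUFA4 pool", 50.0,
                     _members(("COX5B", "NDUFA4")), {WT: 5, KO: 5}),
        AssemblyForm("cII", 125.0, _members(CII_SUBUNITS), {WT: 40, KO: 40}),
        AssemblyForm("cV monomer", 700.0, cv, {WT: 80, KO: 70}),
        AssemblyForm("cV dimer", 1400.0, _members(CV_SUBUNITS, stoich=2),
                     {WT: 10, KO: 5}),
        AssemblyForm("F1 subassembly", 370.0, _members(F1_SUBUNITS),
                     {WT: 2, KO: 8}),
        AssemblyForm("mtLSU", 1650.0, _members(MTLSU_SUBUNITS),
                     {WT: 30, KO: 30 / MITORIBO_FACTOR}),
        AssemblyForm("mtSSU", 850.0, _members(MTSSU_SUBUNITS),
                     {WT: 30, KO: 30 / MITORIBO_FACTOR}),
        AssemblyForm("DDX28", 60.0, {"DDX28": 1}, {WT: 12, KO: 6}),
        AssemblyForm("ERAL1", 48.0, {"ERAL1": 1}, {WT: 12, KO: 6}),
    )
    return ScenarioConfig(
        conditions=(WT, KO),
        forms=forms,
        gel=GelModel(),
        replicates=(WT, KO),
        mixing_ratio=1.0,
        peptides_per_protein=(3, 8),
        noise=NoiseModel(),
        seed=seed,
    )


def default_annotation() -> pd.DataFrame:
    """Complex/module annotation matching the default scenario's rosters."""
    rows = []

    def block(complex_id: str, roster: Sequence[str], modules: Mapping[str, str] = {}):
        for i, pid in enumerate(roster, start=1):
            rows.append((pid, complex_id, modules.get(pid, ""), i))

    block("cI", CI_SUBUNITS, {p: "N-module" for p in N_MODULE})
    block("cII", CII_SUBUNITS)
    block("cIII", CIII_SUBUNITS)
    block("cIV", CIV_CORE + CIV_ACCESSORY,
          {p: "accessory" for p in CIV_ACCESSORY})
    block("cV", CV_SUBUNITS)
    block("mtLSU", MTLSU_SUBUNITS)
    block("mtSSU", MTSSU_SUBUNITS)
    block("mtRibo-assembly", ("DDX28", "ERAL1"))
    return pd.DataFrame(
        rows, columns=["protein_id", "complex_id", "module_id", "display_order"]
    )


# ---------------------------------------------------------------------------
# Structured-text (YAML/JSON-compatible) scenario serialization
# ---------------------------------------------------------------------------


def scenario_to_dict(scenario: ScenarioConfig) -> dict:
    return {
        "conditions": list(scenario.conditions),
        "forms": [
            {
                "name": f.name,
                "apparent_mass": f.apparent_mass,
                "members": dict(f.members),
                "abundance": dict(f.abundance),
            }
            for f in scenario.forms
        ],
        "gel": {
            "n_slices": scenario.gel.n_slices,
            "log10_mass_top": scenario.gel.log10_mass_top,
            "log10_mass_bottom": scenario.gel.log10_mass_bottom,
            "peak_sigma": scenario.gel.peak_sigma,
        },
        "replicates": list(scenario.replicates),
        "mixing_ratio": scenario.mixing_ratio,
        "peptides_per_protein": list(scenario.peptides_per_protein),
        "noise": {
            "response_sd": scenario.noise.response_sd,
            "measurement_sd": scenario.noise.measurement_sd,
            "detection_floor": scenario.noise.detection_floor,
        },
        "seed": scenario.seed,
    }


def scenario_from_dict(d: Mapping) -> ScenarioConfig:
    forms = tuple(
        AssemblyForm(
            name=f["name"],
            apparent_mass=float(f["apparent_mass"]),
            members={str(k): int(v) for k, v in f["members"].items()},
            abundance={str(k): float(v) for k, v in f["abundance"].items()},
        )
        for f in d["forms"]
    )
    gel = GelModel(**d.get("gel", {}))
    noise = NoiseModel(**d.get("noise", {}))
    return ScenarioConfig(
        conditions=tuple(d["conditions"]),
        forms=forms,
        gel=gel,
        replicates=tuple(d["replicates"]),
        mixing_ratio=float(d.get("mixing_ratio", 1.0)),
        peptides_per_protein=tuple(d.get("peptides_per_protein", (3, 8))),
        noise=noise,
        seed=int(d.get("seed", 0)),
        experiment_id=str(d.get("experiment_id", "exp1")),
    )
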