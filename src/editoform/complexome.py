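"""Complexome profiling: protein abundance profiles along BN-PAGE fractions.

A blue-native gel lane is cut into fractions (43 by default) and each
fraction is quantified by shotgun MS, giving every protein an abundance
profile along the native-mass axis. Co-migration of profiles reveals
complex membership; the apparent mass of a peak follows from a log-linear
calibration of fraction index against marker complexes of known mass.

Conventions: the internal fraction axis runs low index -> high index =
top -> bottom of the gel as displayed (high apparent mass first). Lanes
cut bottom-to-top are flipped at load with ``orientation="bottom_up"``.
Display normalization scales each profile to its maximum ("100"); map
comparison rescales the other condition by a single global factor so its
total intensity over shared proteins matches the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "ComplexomeMap",
    "FractionCalibration",
    "ModuleDefinition",
    "build_profiles",
    "normalize_profiles",
    "aggregate_module_profile",
    "compare_maps",
    "calibrate_fraction_masses",
    "locate_profile_peaks",
    "compute_ibaq",
    "read_complexome_tsv",
    "write_complexome_tsv",
    "read_modules_tsv",
    "read_markers_tsv",
]


@dataclass(frozen=True)
class FractionCalibration:
    """Monotone log-linear map fraction index -> apparent mass (kDa)."""

    slope: float  # d log10(mass) / d fraction
    intercept: float
    markers: tuple[tuple[int, float], ...] = ()

    def mass_at(self, fraction: float | np.ndarray) -> float | np.ndarray:
        return 10.0 ** (self.intercept + self.slope * np.asarray(fraction, float))

    def fraction_at(self, mass_kda: float) -> float:
        if mass_kda <= 0:
            raise ValueError("mass must be positive")
        return (np.log10(mass_kda) - self.intercept) / self.slope


@dataclass
class ComplexomeMap:
    """Protein x fraction intensity matrix for one condition."""

    intensity: pd.DataFrame  # index: protein ids, columns: fraction indices (int)
    calibration: FractionCalibration | None = None
    label: str = ""

    def __post_init__(self):
        if (self.intensity.values < 0).any():
            raise ValueError("negative intensities in complexome map")
        self.intensity.columns = [int(c) for c in self.intensity.columns]

    @property
    def proteins(self) -> list[str]:
        return list(self.intensity.index)

    @property
    def fractions(self) -> list[int]:
        return list(self.intensity.columns)

    def profile(self, protein: str) -> np.ndarray:
        return self.intensity.loc[protein].to_numpy(float)


@dataclass(frozen=True)
class ModuleDefinition:
    """A named set of proteins forming a complex, module or intermediate."""

    name: str
    member_proteins: tuple[str, ...]
    expected_mass_kda: float | None = None

    def __post_init__(self):
        if not self.member_proteins:
            raise ValueError(f"module {self.name!r} has no members")


def build_profiles(
    records: pd.DataFrame,
    level: str = "protein",
    n_fractions: int = 43,
    theoretical_peptides: Mapping[str, int] | None = None,
    label: str = "",
    calibration: FractionCalibration | None = None,
) -> ComplexomeMap:
    """Build a complexome map from long-format per-fraction records.

    ``records`` needs columns ``protein_label``, ``fraction_id``,
    ``intensity`` and, for peptide-level maps, ``peptide``. Levels:

    * ``protein`` — per-fraction protein intensity, divided by the
      theoretical peptide count (iBAQ) when counts are supplied;
    * ``peptide_sum`` — sum of all peptide intensities per protein;
    * ``peptide`` — one row per peptide (for editing-specific pairs).
    """
    if level not in ("protein", "peptide_sum", "peptide"):
        raise ValueError(f"unknown level {level!r}")
    if records.empty:
        logger.warning("empty complexome input; returning empty map")
        return ComplexomeMap(
            pd.DataFrame(columns=range(1, n_fractions + 1)), calibration, label
        )
    n_missing = int(records["fraction_id"].isna().sum())
    if n_missing:
        raise ValueError(f"{n_missing} records missing fraction_id")
    df = records.copy()
    df["fraction_id"] = df["fraction_id"].astype(int)
    row_key = "peptide" if level == "peptide" else "protein_label"
    mat = (
        df.groupby([row_key, "fraction_id"])["intensity"]
        .sum()
        .unstack(fill_value=0.0)
        .reindex(columns=range(1, n_fractions + 1), fill_value=0.0)
    )
    mat.index.name = None
    mat.columns.name = None
    if level == "protein" and theoretical_peptides is not None:
        for prot in mat.index:
            mat.loc[prot] = compute_ibaq(
                mat.loc[prot].to_numpy(), theoretical_peptides[prot]
            )
    return ComplexomeMap(mat, calibration, label)


def normalize_profiles(cmap: ComplexomeMap, mode: str = "row_max_100") -> ComplexomeMap:
    """Scale each profile so its maximum is 100; drop all-zero rows.

    Idempotent and scale-invariant: normalizing c*x gives the same result
    as normalizing x for any c > 0.
    """
    if mode != "row_max_100":
        raise ValueError(f"unknown normalization mode {mode!r}")
    mat = cmap.intensity
    row_max = mat.max(axis=1)
    zero = row_max == 0
    if zero.any():
        logger.info("dropping %d all-zero profiles: %s", int(zero.sum()),
                    list(mat.index[zero]))
    kept = mat.loc[~zero]
    normed = kept.div(kept.max(axis=1), axis=0) * 100.0
    return ComplexomeMap(normed, cmap.calibration, cmap.label)


def aggregate_module_profile(
    cmap: ComplexomeMap, module: ModuleDefinition
) -> np.ndarray:
    """Elementwise sum of the (pre-normalization) profiles of module members."""
    present = [p for p in module.member_proteins if p in cmap.intensity.index]
    missing = [p for p in module.member_proteins if p not in cmap.intensity.index]
    if not present:
        raise ValueError(f"module {module.name!r}: no members present in map")
    if missing:
        logger.warning("module %s: members absent from map: %s", module.name, missing)
    return cmap.intensity.loc[present].sum(axis=0).to_numpy(float)


def compare_maps(
    reference: ComplexomeMap, other: ComplexomeMap
) -> tuple[ComplexomeMap, ComplexomeMap, float]:
    """Rescale ``other`` to the reference by one global intensity factor.

    The factor makes the total summed intensity of ``other`` over the
    shared proteins equal that of the reference, so within-map ratios are
    preserved exactly. Returns (reference unchanged, rescaled other,
    factor).
    """
    if len(reference.fractions) != len(other.fractions):
        raise ValueError("maps have different fraction counts")
    shared = [p for p in reference.proteins if p in set(other.proteins)]
    if not shared:
        raise ValueError("maps share no proteins")
    ref_total = float(reference.intensity.loc[shared].to_numpy().sum())
    other_total = float(other.intensity.loc[shared].to_numpy().sum())
    if other_total == 0:
        raise ValueError("other map has zero total intensity over shared proteins")
    factor = ref_total / other_total
    rescaled = ComplexomeMap(
        other.intensity * factor, other.calibration, other.label
    )
    return reference, rescaled, factor


def calibrate_fraction_masses(
    markers: Sequence[tuple[int, float]]
) -> FractionCalibration:
    """Fit log10(mass) linearly against fraction index.

    Needs at least two markers at distinct fractions whose masses are
    strictly monotone along the gel axis; the fit reproduces each marker
    within 5%.
    """
    if len(markers) < 2:
        raise ValueError("need at least 2 calibration markers")
    fracs = np.array([m[0] for m in markers], float)
    masses = np.array([m[1] for m in markers], float)
    if len(set(fracs)) != len(fracs):
        raise ValueError("markers must be at distinct fractions")
    order = np.argsort(fracs)
    sorted_masses = masses[order]
    diffs = np.diff(sorted_masses)
    if not ((diffs > 0).all() or (diffs < 0).all()):
        raise ValueError("marker masses are not monotone along the gel")
    slope, intercept = np.polyfit(fracs, np.log10(masses), 1)
    cal = FractionCalibration(
        slope=float(slope),
        intercept=float(intercept),
        markers=tuple((int(f), float(m)) for f, m in markers),
    )
    for f, m in markers:
        predicted = float(cal.mass_at(f))
        if abs(predicted - m) / m > 0.05:
            raise ValueError(
                f"calibration misses marker at fraction {f}: "
                f"{predicted:.1f} vs {m:.1f} kDa (>5%)"
            )
    return cal


def locate_profile_peaks(
    profile: np.ndarray,
    calibration: FractionCalibration,
    min_prominence: float = 0.1,
    fractions: Sequence[int] | None = None,
) -> list[tuple[int, float, float]]:
    """Local maxima of a profile with their apparent masses.

    Peaks require a prominence of at least ``min_prominence`` times the
    profile maximum. Returns (fraction, apparent mass kDa, height) sorted
    by height, highest first; a flat profile yields an empty list.
    """
    profile = np.asarray(profile, float)
    if fractions is None:
        fractions = list(range(1, len(profile) + 1))
    peak_max = profile.max(initial=0.0)
    if peak_max <= 0:
        return []
    # pad so that maxima at the first or last fraction are still detected
    padded = np.concatenate([[profile.min()], profile, [profile.min()]])
    idx, _ = find_peaks(padded, prominence=min_prominence * peak_max)
    idx = idx - 1
    peaks = [
        (int(fractions[i]), float(calibration.mass_at(fractions[i])), float(profile[i]))
        for i in idx
    ]
    peaks.sort(key=lambda t: -t[2])
    return peaks


def compute_ibaq(
    protein_intensity: float | np.ndarray, theoretical_peptides: int
) -> float | np.ndarray:
    """Intensity-based absolute quantification: intensity / theoretical peptides."""
    if theoretical_peptides < 1:
        raise ValueError("theoretical peptide count must be >= 1")
    return protein_intensity / theoretical_peptides


# ---------------------------------------------------------------------------
# File interfaces


def read_complexome_tsv(
    path: str | Path,
    label: str = "",
    calibration: FractionCalibration | None = None,
    orientation: str = "top_down",
) -> ComplexomeMap:
    """Read a protein x fraction matrix TSV (first column protein id,
    then fraction columns ``f1..fN``). ``orientation="bottom_up"`` flips
    the fraction axis so that low index = top of the gel."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        cols = [int(str(c).lstrip("f")) for c in df.columns]
    except ValueError as exc:
        raise ValueError(f"{path}: fraction columns must be f1..fN") from exc
    df.columns = cols
    if orientation == "bottom_up":
        df = df.iloc[:, ::-1]
        df.columns = cols
    elif orientation != "top_down":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ComplexomeMap(df, calibration, label)


def write_complexome_tsv(cmap: ComplexomeMap, path: str | Path) -> None:
    out = cmap.intensity.copy()
    out.columns = [f"f{c}" for c in out.columns]
    out.index.name = "protein"
    out.to_csv(path, sep="\t")


def read_modules_tsv(path: str | Path) -> list[ModuleDefinition]:
    """Module definitions TSV: columns module, accession[, expected_mass_kda]."""
    df = pd.read_csv(path, sep="\t")
    if not {"module", "accession"} <= set(df.columns):
        raise ValueError(f"{path}: need columns module, accession")
    out = []
    for name, grp in df.groupby("module", sort=False):
        mass = None
        if "expected_mass_kda" in grp.columns and grp["expected_mass_kda"].notna().any():
            mass = float(grp["expected_mass_kda"].dropna().iloc[0])
        out.append(ModuleDefinition(str(name), tuple(grp["accession"]), mass))
    return out


def read_markers_tsv(path: str | Path) -> list[tuple[int, float]]:
    """Calibration markers TSV: columns fraction, mass_kda."""
    df = pd.read_csv(path, sep="\t")
    if not {"fraction", "mass_kda"} <= set(df.columns):
        raise ValueError(f"{path}: need columns fraction, mass_kda")
    return [(int(r["fraction"]), float(r["mass_kda"])) for _, r in df.iterrows()]
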