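"""Editing-specific peptide pairs and the evidence rules that validate them.

A tryptic peptide covering an edited residue exists in two sequence forms:
the *edited* form (translated from edited transcripts) and the *unedited*
form. The two forms differ only at the affected residue, so the mass
difference equals the residue-mass difference of the substitution — unless
the substitution creates or destroys a K/R cleavage point, in which case
the tryptic forms are not one-to-one.

Claimed editing-specific identifications are screened and filtered with
the rules used for manual inspection of such peptides:

* search-engine score threshold per scale (Andromeda >= 100, Hyperscore >= 20),
* the edited position must be covered by an observed b- or y-ion,
* at least 2 distinct MS/MS spectra (no "one-hit wonders"),
* identifications made solely through match-between-runs are rejected,
* post-translational modifications whose mass shift lies within +-2 Da of
  the substitution's delta are flagged as potential mass mimics.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .digest import DigestConfig, Peptide, ResidueMassTable, default_mass_table, digest
from .editing_sites import EditingSite
from .proteoforms import EDITED, UNEDITED, Proteoform

logger = logging.getLogger(__name__)

__all__ = [
    "EditingPeptidePair",
    "ModificationEntry",
    "PSMRecord",
    "EvidenceThresholds",
    "EvidenceDecision",
    "find_editing_specific_peptides",
    "pair_proteoforms_for_site",
    "load_modification_table",
    "default_modification_table",
    "ptm_mimicry_screen",
    "site_ion_coverage",
    "filter_psm_evidence",
    "estimate_editing_fraction",
    "read_psm_tsv",
    "write_psm_tsv",
]


@dataclass
class EditingPeptidePair:
    """Edited/unedited tryptic peptide forms distinguishing one editing site."""

    site_id: str
    edited_peptide: str
    unedited_peptide: str
    residue_offset_in_peptide: int
    mass_delta: float  # edited minus unedited, Da
    cleavage_altering: bool = False
    il_ambiguous: bool = False
    mimicry_mods: list["ModificationEntry"] = field(default_factory=list)

    @property
    def edited_residue(self) -> str:
        return self.edited_peptide[self.residue_offset_in_peptide - 1]

    @property
    def unedited_residue(self) -> str:
        return self.unedited_peptide[self.residue_offset_in_peptide - 1]


@dataclass(frozen=True)
class ModificationEntry:
    """A named modification with its monoisotopic delta mass.

    ``site_specificity`` is a set of residue letters; ``*`` means any
    residue, ``N-term``/``C-term`` tag terminal modifications.
    """

    name: str
    delta_mass: float
    site_specificity: frozenset[str]

    def applies_to(self, residue: str) -> bool:
        return "*" in self.site_specificity or residue in self.site_specificity


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-to-spectrum-match evidence row."""

    peptide: str
    protein_label: str
    score: float
    score_scale: str  # "andromeda" or "hyperscore"
    spectra_count: int
    mbr_only: bool
    observed_ions: frozenset[str]  # e.g. {"b4", "y6"}
    intensity: float
    sample_id: str
    fraction_id: int | None = None

    def __post_init__(self):
        if self.score_scale not in ("andromeda", "hyperscore"):
            raise ValueError(f"unknown score scale {self.score_scale!r}")
        if self.spectra_count < 0:
            raise ValueError("spectra_count must be >= 0")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


@dataclass(frozen=True)
class EvidenceThresholds:
    andromeda: float = 100.0
    hyperscore: float = 20.0
    min_spectra: int = 2
    exclude_mbr_only: bool = True
    exclude_il_ambiguous: bool = True
    strict_mimicry: bool = False

    def score_passes(self, psm: PSMRecord) -> bool:
        limit = self.andromeda if psm.score_scale == "andromeda" else self.hyperscore
        return psm.score >= limit


@dataclass
class EvidenceDecision:
    pair: EditingPeptidePair
    accepted: bool
    failed_rules: list[str]
    per_form: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Pair enumeration


def pair_proteoforms_for_site(
    proteoforms: Sequence[Proteoform], site: EditingSite
) -> tuple[Proteoform, Proteoform]:
    """Pick two proteoforms differing only in the state of ``site``.

    Prefers the pair whose background (all other sites) is fully edited.
    """
    def background(p: Proteoform) -> tuple:
        return tuple(
            (sid, state) for sid, state in p.signature.states if sid != site.site_id
        )

    by_bg: dict[tuple, dict[str, Proteoform]] = {}
    for p in proteoforms:
        try:
            state = p.signature.state_of(site.site_id)
        except KeyError:
            continue
        by_bg.setdefault(background(p), {})[state] = p
    complete = {
        bg: forms for bg, forms in by_bg.items() if EDITED in forms and UNEDITED in forms
    }
    if not complete:
        raise ValueError(
            f"proteoform set lacks both states of {site.site_id}; "
            "enumerate with the site included"
        )
    all_edited = [bg for bg in complete if all(s == EDITED for _, s in bg)]
    bg = all_edited[0] if all_edited else sorted(complete)[0]
    return complete[bg][EDITED], complete[bg][UNEDITED]


def find_editing_specific_peptides(
    proteoforms: Sequence[Proteoform],
    site: EditingSite,
    digest_config: DigestConfig | None = None,
    table: ResidueMassTable | None = None,
) -> list[EditingPeptidePair]:
    """All digest-peptide pairs covering ``site`` in its two states.

    Peptides of the edited and unedited proteoform that cover the site's
    codon index are paired by coordinates. If the substitution creates or
    destroys a cleavage point the coordinate sets differ; remaining
    peptides are then matched by maximal overlap and flagged
    ``cleavage_altering``. Pairs whose two forms differ only by I<->L are
    flagged ``il_ambiguous`` (mass-indistinguishable). A site not covered
    by any filtered peptide yields an empty list (logged, not an error).
    """
    if table is None:
        table = default_mass_table()
    edited_pf, unedited_pf = pair_proteoforms_for_site(proteoforms, site)
    idx = site.codon_index
    cleavage_altering = (site.edited_aa in "KR") != (site.ref_aa in "KR")

    def covering(p: Proteoform) -> dict[tuple[int, int], Peptide]:
        peps = digest(p.protein_sequence, p.label, digest_config, table)
        return {(pp.start, pp.end): pp for pp in peps if pp.covers(idx)}

    edited_cov = covering(edited_pf)
    unedited_cov = covering(unedited_pf)
    if not edited_cov and not unedited_cov:
        logger.info("%s: no filtered peptide covers the site", site.site_id)
        return []

    pairs: list[EditingPeptidePair] = []

    def make_pair(e: Peptide, u: Peptide, altered: bool) -> EditingPeptidePair:
        offset = idx - e.start + 1
        il = not altered and sorted((site.edited_aa, site.ref_aa)) == ["I", "L"]
        return EditingPeptidePair(
            site_id=site.site_id,
            edited_peptide=e.sequence,
            unedited_peptide=u.sequence,
            residue_offset_in_peptide=offset,
            mass_delta=e.monoisotopic_mass - u.monoisotopic_mass,
            cleavage_altering=altered,
            il_ambiguous=il,
        )

    shared = sorted(set(edited_cov) & set(unedited_cov))
    for coords in shared:
        pairs.append(make_pair(edited_cov[coords], unedited_cov[coords], False))

    # cleavage-altering leftovers: match by maximal overlap, flagged
    left_e = [edited_cov[c] for c in sorted(set(edited_cov) - set(shared))]
    left_u = [unedited_cov[c] for c in sorted(set(unedited_cov) - set(shared))]
    for e in left_e:
        if not left_u:
            break
        overlap = [
            min(e.end, u.end) - max(e.start, u.start) for u in left_u
        ]
        u = left_u.pop(int(np.argmax(overlap)))
        pairs.append(make_pair(e, u, True))
    if (left_e or left_u) and not cleavage_altering:
        logger.info("%s: unmatched covering peptides after pairing", site.site_id)
    pairs.sort(key=lambda p: (len(p.edited_peptide), p.edited_peptide))
    return pairs


# ---------------------------------------------------------------------------
# PTM mass-mimicry screen


def load_modification_table(path: str | Path) -> list[ModificationEntry]:
    """Load a modification table TSV: name, delta_mass, specificity.

    ``specificity`` is a comma-separated residue list, ``*`` for any.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"name", "delta_mass", "specificity"}
    if not required <= set(df.columns):
        raise ValueError(f"modification table missing columns {required - set(df.columns)}")
    if df["name"].duplicated().any():
        dupes = df.loc[df["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate modification names {dupes}")
    return [
        ModificationEntry(
            name=row["name"],
            delta_mass=float(row["delta_mass"]),
            site_specificity=frozenset(str(row["specificity"]).split(",")),
        )
        for _, row in df.iterrows()
    ]


def default_modification_table() -> list[ModificationEntry]:
    """The bundled minimal table of common modifications (monoisotopic deltas)."""
    with resources.as_file(
        resources.files("editoform").joinpath("data/modifications.tsv")
    ) as p:
        return load_modification_table(p)


def ptm_mimicry_screen(
    pair: EditingPeptidePair,
    mods: Sequence[ModificationEntry] | None = None,
    window: float = 2.0,
) -> list[ModificationEntry]:
    """Modifications that could mimic the pair's mass shift.

    Returns entries with ``|delta_mass - pair.mass_delta| <= window`` whose
    site specificity is compatible with the unedited residue (a modified
    unedited peptide could masquerade as the edited form). The matches are
    recorded on ``pair.mimicry_mods``; flags are reported, not
    auto-rejecting (strict rejection is an evidence-filter option).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if mods is None:
        mods = default_modification_table()
    if not mods:
        warnings.warn("empty modification table; mimicry screen is vacuous")
        pair.mimicry_mods = []
        return []
    residue = pair.unedited_residue
    hits = [
        m
        for m in mods
        if abs(m.delta_mass - pair.mass_delta) <= window and m.applies_to(residue)
    ]
    pair.mimicry_mods = hits
    return hits


# ---------------------------------------------------------------------------
# Per-PSM and per-pair evidence rules

_ION_RE = re.compile(r"^([by])(\d+)$")


def site_ion_coverage(psm: PSMRecord, pair: EditingPeptidePair) -> bool:
    """True iff an observed b- or y-ion spans the edited position.

    For a peptide of length L and edited position ``o`` (1-based), b_i
    spans residues 1..i and covers the site iff i >= o; y_j spans the last
    j residues and covers iff j >= L - o + 1.
    """
    if psm.peptide not in (pair.edited_peptide, pair.unedited_peptide):
        raise ValueError(
            f"PSM peptide {psm.peptide!r} is neither form of {pair.site_id}"
        )
    length = len(psm.peptide)
    offset = pair.residue_offset_in_peptide
    if not 1 <= offset <= length:
        raise ValueError(f"residue offset {offset} outside peptide of length {length}")
    for tag in psm.observed_ions:
        m = _ION_RE.match(tag)
        if m is None:
            raise ValueError(f"unrecognized fragment tag {tag!r}")
        series, i = m.group(1), int(m.group(2))
        if not 1 <= i <= length - 1:
            raise ValueError(f"fragment index {tag!r} outside 1..{length - 1}")
        if series == "b" and i >= offset:
            return True
        if series == "y" and i >= length - offset + 1:
            return True
    return False


def _form_failures(
    psms: Sequence[PSMRecord],
    pair: EditingPeptidePair,
    thresholds: EvidenceThresholds,
) -> list[str]:
    failed = []
    score_pass = [p for p in psms if thresholds.score_passes(p)]
    if not score_pass:
        failed.append("score")
    if not any(site_ion_coverage(p, pair) for p in score_pass):
        failed.append("ion_coverage")
    if sum(p.spectra_count for p in psms) < thresholds.min_spectra:
        failed.append("spectra_count")
    if thresholds.exclude_mbr_only and all(p.mbr_only for p in psms):
        failed.append("mbr_only")
    return failed


def filter_psm_evidence(
    psms: Sequence[PSMRecord],
    pair: EditingPeptidePair,
    thresholds: EvidenceThresholds | None = None,
) -> EvidenceDecision:
    """Apply the manual-inspection rules to the PSMs of one peptide pair.

    Each observed peptide form must have at least one PSM passing its
    score-scale threshold with site ion coverage, a total of at least
    ``min_spectra`` distinct spectra, and at least one non-MBR
    identification. The decision lists every failed rule (union over
    forms); rule evaluation is deterministic, order-independent and
    idempotent.
    """
    if thresholds is None:
        thresholds = EvidenceThresholds()
    forms = {pair.edited_peptide: "edited", pair.unedited_peptide: "unedited"}
    grouped: dict[str, list[PSMRecord]] = {}
    for psm in psms:
        if psm.peptide not in forms:
            raise ValueError(
                f"PSM peptide {psm.peptide!r} is neither form of pair {pair.site_id}"
            )
        grouped.setdefault(forms[psm.peptide], []).append(psm)

    per_form: dict[str, list[str]] = {}
    failed: set[str] = set()
    if not grouped:
        failed.add("spectra_count")
    for form_name, form_psms in sorted(grouped.items()):
        form_failed = _form_failures(form_psms, pair, thresholds)
        per_form[form_name] = form_failed
        failed.update(form_failed)
    if thresholds.exclude_il_ambiguous and pair.il_ambiguous:
        failed.add("il_ambiguous")
    if thresholds.strict_mimicry and pair.mimicry_mods:
        failed.add("mimicry_unresolved")
    failed_rules = sorted(failed)
    return EvidenceDecision(
        pair=pair,
        accepted=not failed_rules,
        failed_rules=failed_rules,
        per_form=per_form,
    )


def estimate_editing_fraction(
    edited_intensity: float, unedited_intensity: float
) -> float:
    """Protein-level editing fraction: edited / (edited + unedited).

    The analogue, at the protein level, of a transcript editing frequency.
    Returns NaN with a warning when both intensities are zero.
    """
    if edited_intensity < 0 or unedited_intensity < 0:
        raise ValueError("intensities must be >= 0")
    total = edited_intensity + unedited_intensity
    if total == 0:
        warnings.warn("both intensities zero; editing fraction undefined")
        return float("nan")
    return edited_intensity / total


# ---------------------------------------------------------------------------
# PSM table I/O

_PSM_COLUMNS = [
    "peptide",
    "protein_label",
    "score",
    "score_scale",
    "spectra_count",
    "mbr_only",
    "observed_ions",
    "intensity",
    "sample_id",
    "fraction_id",
]


def read_psm_tsv(path: str | Path) -> list[PSMRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table {path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        ions = str(row["observed_ions"])
        ion_set = frozenset(t for t in ions.split(";") if t and t != "nan")
        frac = row["fraction_id"]
        out.append(
            PSMRecord(
                peptide=row["peptide"],
                protein_label=row["protein_label"],
                score=float(row["score"]),
                score_scale=row["score_scale"],
                spectra_count=int(row["spectra_count"]),
                mbr_only=bool(row["mbr_only"]),
                observed_ions=ion_set,
                intensity=float(row["intensity"]),
                sample_id=str(row["sample_id"]),
                fraction_id=None if pd.isna(frac) else int(frac),
            )
        )
    return out


def write_psm_tsv(psms: Iterable[PSMRecord], path: str | Path) -> None:
    rows = [
        {
            "peptide": p.peptide,
            "protein_label": p.protein_label,
            "score": p.score,
            "score_scale": p.score_scale,
            "spectra_count": p.spectra_count,
            "mbr_only": p.mbr_only,
            "observed_ions": ";".join(sorted(p.observed_ions)),
            "intensity": p.intensity,
            "sample_id": p.sample_id,
            "fraction_id": "" if p.fraction_id is None else p.fraction_id,
        }
        for p in psms
    ]
    pd.DataFrame(rows, columns=_PSM_COLUMNS).to_csv(path, sep="\t", index=False)
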