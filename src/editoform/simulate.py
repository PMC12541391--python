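"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the analysis can be exercised without any download: this
module generates coding sequences with planted C-to-U editing sites,
PSM-level evidence tables with a planted protein-level editing fraction,
two-condition complexome maps with planted complex masses (and an
accumulating assembly intermediate in the second condition), and quant
matrices with planted per-complex fold changes. All generators are
deterministic per seed; one global seed fans out to per-stage child seeds
derived from stage names so stages can be regenerated independently.

The bundled ``toy_reference_system`` builds small synthetic genes whose
local tryptic context around each editing site matches the biological
sequence (the full-length CDSs are not bundled); everything outside those
contexts is synthetic filler.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .editing_sites import (
    CodingSequence,
    EditingSite,
    parse_site_id,
    validate_and_classify,
    write_cds_fasta,
    write_sites_tsv,
)
from .complexome import (
    ComplexomeMap,
    FractionCalibration,
    calibrate_fraction_masses,
    write_complexome_tsv,
)
from .diffabund import QuantMatrix, write_quant_tsv
from .peptides import EditingPeptidePair, PSMRecord, write_psm_tsv

__all__ = [
    "child_rng",
    "SiteRequest",
    "GeneSpec",
    "PSMSimConfig",
    "ComplexSpec",
    "ComplexomeSimConfig",
    "QuantSimConfig",
    "gen_toy_system",
    "toy_reference_system",
    "simulate_psm_table",
    "simulate_complexome_map",
    "simulate_quant_matrix",
    "emit_all",
]


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the global seed."""
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# Codon planting

_BASES = "TCAG"


def _codon_table() -> dict[str, str]:
    table = {}
    for a in _BASES:
        for b in _BASES:
            for c in _BASES:
                codon = a + b + c
                table[codon] = str(Seq(codon).translate())
    return table


_CODONS = _codon_table()

# (ref_aa, edited_aa) -> (codon containing C, offset of that C); the codon
# translates to ref_aa and its C->T edit to edited_aa. Built by exhaustive
# search of the standard code; silent substitutions appear as (X, X).
_PLANT: dict[tuple[str, str], tuple[str, int]] = {}
for _codon in sorted(_CODONS):
    if _CODONS[_codon] == "*":
        continue
    for _off in (1, 2, 3):
        if _codon[_off - 1] != "C":
            continue
        _edited = _codon[: _off - 1] + "T" + _codon[_off:]
        if _CODONS[_edited] == "*":
            continue
        _key = (_CODONS[_codon], _CODONS[_edited])
        _PLANT.setdefault(_key, (_codon, _off))

# simple aa -> codon map for reverse translation of filler/context
_AA2CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}

_FILLER_AA = "AGVSTNQDEHY"  # no K/R (cleavage), no M/W/C, no stop


@dataclass(frozen=True)
class SiteRequest:
    """One planted substitution, e.g. ref_aa='S', edited_aa='F'.

    A silent site is requested with ref_aa == edited_aa. ``codon_index``
    may be fixed; otherwise a position is drawn.
    """

    ref_aa: str
    edited_aa: str
    wt_frequency: float = 1.0
    mutant_frequency: float = 0.0
    codon_index: int | None = None


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    n_codons: int = 120
    sites: tuple[SiteRequest, ...] = ()
    accession: str = ""


def gen_toy_system(
    genes: Sequence[GeneSpec], seed: int
) -> tuple[dict[str, CodingSequence], list[EditingSite]]:
    """Random coding sequences with validated planted editing sites.

    Each site sits in a designed tryptic context: an R codon six codons
    upstream and five codons downstream, so the 0-missed-cleavage peptide
    covering the site is 11 residues long and passes the default digest
    filters. Deterministic per seed.
    """
    rng = child_rng(seed, "toy_system")
    cds_by_gene: dict[str, CodingSequence] = {}
    all_sites: list[EditingSite] = []
    for spec in genes:
        n = spec.n_codons
        # codon slots available for sites: keep contexts inside the gene
        lo, hi = 8, n - 7
        if hi < lo:
            raise ValueError(f"{spec.gene_id}: gene too short for planted sites")
        taken: list[int] = []
        for req in spec.sites:
            if (req.ref_aa, req.edited_aa) not in _PLANT:
                raise ValueError(
                    f"no codon realizes {req.ref_aa}->{req.edited_aa} via C-to-T"
                )
            if req.codon_index is not None:
                ci = req.codon_index
                if not lo <= ci <= hi:
                    raise ValueError(f"{spec.gene_id}: codon {ci} outside [{lo},{hi}]")
            else:
                candidates = [
                    c
                    for c in range(lo, hi + 1)
                    if all(abs(c - t) >= 13 for t in taken)
                ]
                if not candidates:
                    raise ValueError(
                        f"{spec.gene_id}: site density exceeds available positions"
                    )
                ci = int(rng.choice(candidates))
            if any(abs(ci - t) < 13 for t in taken):
                raise ValueError(f"{spec.gene_id}: site contexts overlap at codon {ci}")
            taken.append(ci)

        codons = [
            _AA2CODON[_FILLER_AA[i]]
            for i in rng.integers(0, len(_FILLER_AA), size=n)
        ]
        codons[0] = "ATG"
        for ci, req in zip(taken, spec.sites):
            codon, offset = _PLANT[(req.ref_aa, req.edited_aa)]
            codons[ci - 1] = codon
            codons[ci - 7] = _AA2CODON["R"]
            codons[ci + 4] = _AA2CODON["R"]
        sequence = "".join(codons)
        cds = CodingSequence(spec.gene_id, spec.accession, sequence)
        cds_by_gene[spec.gene_id] = cds
        for ci, req in zip(taken, spec.sites):
            codon, offset = _PLANT[(req.ref_aa, req.edited_aa)]
            nt = (ci - 1) * 3 + offset
            site_id = (
                f"{spec.gene_id}eU{nt}{req.ref_aa}{req.edited_aa}"
                f"p{int(round(req.wt_frequency * 100))}"
            )
            site = parse_site_id(site_id)
            site = validate_and_classify(cds, site)
            object.__setattr__(site, "mutant_frequency", req.mutant_frequency)
            all_sites.append(site)
    return cds_by_gene, all_sites


def _context_gene(
    gene_id: str,
    accession: str,
    n_codons: int,
    peptide_unedited: str,
    peptide_start_codon: int,
    site_codon: int,
    substitution: tuple[str, str],
) -> CodingSequence:
    """Synthetic gene embedding one tryptic peptide context at fixed codons."""
    codons = [_AA2CODON["A"]] * n_codons
    codons[0] = "ATG"
    codons[-1] = "TAA"
    codons[peptide_start_codon - 2] = _AA2CODON["R"]  # cleavage before peptide
    for i, aa in enumerate(peptide_unedited):
        codons[peptide_start_codon - 1 + i] = _AA2CODON[aa]
    plant_codon, _ = _PLANT[substitution]
    codons[site_codon - 1] = plant_codon
    return CodingSequence(gene_id, accession, "".join(codons))


def toy_reference_system() -> tuple[dict[str, CodingSequence], list[EditingSite]]:
    """Synthetic genes embedding the biological tryptic contexts of three
    well-characterized mitochondrial editing sites.

    The editing sites (with their CDS positions, substitutions and
    wild-type editing frequencies) are real; the sequence outside each
    site's tryptic peptide is synthetic filler, so only the local context
    matches the organism.
    """
    specs = [
        # gene, accession, n_codons, unedited peptide, start codon, site codon,
        # substitution, site id, mutant frequency
        ("nad2", "ATMG00285", 282, "ISISANILR", 271, 274, ("S", "F"),
         "nad2eU821SFp100", 0.0),
        ("nad7", "ATMG00510", 257, "AAPYDVYDQLDLDVPVGTR", 236, 247, ("L", "F"),
         "nad7eU739LFp100", 0.0),
        ("rps4", "ATMG00290", 109, "TSYIPFPLNLETR", 94, 100, ("P", "L"),
         "rps4eU299PLp60", 0.0),
    ]
    cds_by_gene: dict[str, CodingSequence] = {}
    sites: list[EditingSite] = []
    for gene, acc, n, peptide, start, site_codon, sub, site_id, mut in specs:
        cds = _context_gene(gene, acc, n, peptide, start, site_codon, sub)
        cds_by_gene[gene] = cds
        site = validate_and_classify(cds, parse_site_id(site_id))
        object.__setattr__(site, "mutant_frequency", mut)
        sites.append(site)
    return cds_by_gene, sites


# ---------------------------------------------------------------------------
# PSM-level evidence


@dataclass(frozen=True)
class PSMSimConfig:
    n_spectra: int = 500
    log_intensity_mu: float = 14.0  # natural log of spectrum intensity
    log_intensity_sigma: float = 0.5
    score_scale: str = "andromeda"
    score_mean: float = 150.0
    score_sd: float = 25.0
    mbr_probability: float = 0.05
    ion_coverage_probability: float = 0.9
    sample_id: str = "S1"


def _draw_ions(
    rng: np.random.Generator, length: int, offset: int, cover: bool
) -> frozenset[str]:
    ions: set[str] = set()
    if cover:
        covering = [f"b{i}" for i in range(offset, length)] + [
            f"y{j}" for j in range(length - offset + 1, length)
        ]
        ions.add(covering[int(rng.integers(0, len(covering)))])
    non_covering = [f"b{i}" for i in range(1, offset)] + [
        f"y{j}" for j in range(1, length - offset + 1)
    ]
    for _ in range(int(rng.integers(0, 3))):
        if non_covering:
            ions.add(non_covering[int(rng.integers(0, len(non_covering)))])
    return frozenset(ions)


def simulate_psm_table(
    pairs: Sequence[EditingPeptidePair],
    editing_fractions: Mapping[str, float],
    seed: int,
    config: PSMSimConfig | None = None,
) -> list[PSMRecord]:
    """Simulate PSM evidence with a planted protein-level editing fraction.

    For each pair, each of ``n_spectra`` spectra is drawn from the edited
    form with probability f and the unedited form otherwise; spectrum
    intensities are log-normal, scores normal on the configured scale, and
    records are MBR-only with the configured probability (such records
    carry no spectrum and no fragment ions).
    """
    if config is None:
        config = PSMSimConfig()
    rng = child_rng(seed, "psm_table")
    records: list[PSMRecord] = []
    for pair in pairs:
        f = editing_fractions[pair.site_id]
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"editing fraction {f} outside [0, 1]")
        length = len(pair.edited_peptide)
        offset = pair.residue_offset_in_peptide
        for _ in range(config.n_spectra):
            edited = rng.random() < f
            peptide = pair.edited_peptide if edited else pair.unedited_peptide
            intensity = float(
                np.exp(rng.normal(config.log_intensity_mu, config.log_intensity_sigma))
            )
            score = float(max(0.0, rng.normal(config.score_mean, config.score_sd)))
            mbr = bool(rng.random() < config.mbr_probability)
            if mbr:
                ions: frozenset[str] = frozenset()
                n_spec = 0
            else:
                cover = bool(rng.random() < config.ion_coverage_probability)
                ions = _draw_ions(rng, length, offset, cover)
                n_spec = 1
            records.append(
                PSMRecord(
                    peptide=peptide,
                    protein_label=pair.site_id,
                    score=score,
                    score_scale=config.score_scale,
                    spectra_count=n_spec,
                    mbr_only=mbr,
                    observed_ions=ions,
                    intensity=intensity,
                    sample_id=config.sample_id,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Complexome maps


@dataclass(frozen=True)
class ComplexSpec:
    name: str
    mass_kda: float
    members: tuple[tuple[str, float], ...]  # (protein id, stoichiometry)
    abundance: float = 1000.0


def _default_complexes() -> tuple[ComplexSpec, ...]:
    return (
        ComplexSpec("sc1500", 1500.0, (("shared_a", 1.0), ("sc_only", 1.0))),
        ComplexSpec(
            "holo1000", 1000.0,
            (("shared_a", 1.0), ("shared_b", 1.0), ("holo_only", 1.0)),
        ),
        ComplexSpec("int450", 450.0, (("int450_only", 1.0), ("shared_b", 0.4))),
        ComplexSpec("int200", 200.0, (("int200_only", 1.0), ("shared_a", 0.2))),
    )


@dataclass(frozen=True)
class ComplexomeSimConfig:
    n_fractions: int = 43
    markers: tuple[tuple[int, float], ...] = ((2, 1600.0), (42, 60.0))
    complexes: tuple[ComplexSpec, ...] = field(default_factory=_default_complexes)
    peak_sigma_fractions: float = 0.8
    noise_floor_frac: float = 0.005
    # per-condition occupancy multipliers; the second condition accumulates
    # the small intermediate while the holo-complex and supercomplex drop
    condition_scale: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] = (
        ("wt", ()),
        ("mut", (("sc1500", 0.5), ("holo1000", 0.4), ("int200", 3.0), ("int450", 1.5))),
    )


def simulate_complexome_map(
    config: ComplexomeSimConfig | None = None, seed: int = 0
) -> tuple[dict[str, ComplexomeMap], FractionCalibration]:
    """Two-condition complexome maps with planted complex masses.

    Each protein's profile is the sum, over the complexes containing it, of
    stoichiometry x abundance x occupancy x a Gaussian centred at the
    complex-mass fraction under the log-linear calibration, plus a small
    noise floor.
    """
    if config is None:
        config = ComplexomeSimConfig()
    rng = child_rng(seed, "complexome")
    cal = calibrate_fraction_masses(config.markers)
    marker_masses = [m for _, m in config.markers]
    lo, hi = min(marker_masses), max(marker_masses)
    fracs = np.arange(1, config.n_fractions + 1, dtype=float)
    proteins = sorted({p for cx in config.complexes for p, _ in cx.members})
    maps: dict[str, ComplexomeMap] = {}
    for condition, scales in config.condition_scale:
        scale = dict(scales)
        mat = pd.DataFrame(0.0, index=proteins, columns=range(1, config.n_fractions + 1))
        for cx in config.complexes:
            if not lo <= cx.mass_kda <= hi:
                raise ValueError(
                    f"complex {cx.name}: mass {cx.mass_kda} kDa outside "
                    f"calibrated range [{lo}, {hi}]"
                )
            center = cal.fraction_at(cx.mass_kda)
            shape = np.exp(
                -0.5 * ((fracs - center) / config.peak_sigma_fractions) ** 2
            )
            occ = scale.get(cx.name, 1.0)
            for protein, stoich in cx.members:
                mat.loc[protein] += cx.abundance * stoich * occ * shape
        peak = float(mat.to_numpy().max())
        noise = rng.uniform(0, config.noise_floor_frac * peak, size=mat.shape)
        maps[condition] = ComplexomeMap(mat + noise, cal, condition)
    return maps, cal


# ---------------------------------------------------------------------------
# Quant matrices


@dataclass(frozen=True)
class QuantSimConfig:
    n_proteins: int = 1000
    groups: tuple[str, str] = ("wt", "mut")
    n_replicates: int = 3
    base_log2_mean: float = 25.0
    base_log2_sd: float = 2.0
    replicate_log2_sd: float = 0.25
    # (complex name, number of member proteins, log2 fold change in group 2)
    complex_effects: tuple[tuple[str, int, float], ...] = ()
    missing_max: float = 0.0  # peak missingness probability (at low abundance)
    missing_softness: float = 1.0

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per group")


def simulate_quant_matrix(
    config: QuantSimConfig | None = None, seed: int = 0
) -> tuple[QuantMatrix, pd.DataFrame]:
    """Label-free quant matrix with planted per-complex fold changes.

    Intensities are log-normal (normal on the log2 scale); members of each
    configured complex receive its log2 fold change in the second group.
    Missingness, when enabled, preferentially removes low-abundance values
    via a logistic curve centred two SDs below the mean base abundance.
    Returns the matrix and a truth table (protein, complex, log2fc).
    """
    if config is None:
        config = QuantSimConfig()
    rng = child_rng(seed, "quant_matrix")
    assigned: list[tuple[str, str, float]] = []
    i = 0
    for name, n_members, log2fc in config.complex_effects:
        for _ in range(n_members):
            assigned.append((f"P{i:05d}", name, log2fc))
            i += 1
    if i > config.n_proteins:
        raise ValueError("complex members exceed n_proteins")
    for j in range(i, config.n_proteins):
        assigned.append((f"P{j:05d}", "background", 0.0))

    samples = [
        f"{g}_{r + 1}" for g in config.groups for r in range(config.n_replicates)
    ]
    groups = {s: s.rsplit("_", 1)[0] for s in samples}
    base = rng.normal(config.base_log2_mean, config.base_log2_sd, len(assigned))
    log2 = np.empty((len(assigned), len(samples)))
    for k, s in enumerate(samples):
        shift = np.array(
            [fc if groups[s] == config.groups[1] else 0.0 for _, _, fc in assigned]
        )
        log2[:, k] = base + shift + rng.normal(
            0, config.replicate_log2_sd, len(assigned)
        )
    values = pd.DataFrame(
        2.0**log2, index=[p for p, _, _ in assigned], columns=samples
    )
    if config.missing_max > 0:
        thresh = config.base_log2_mean - 2 * config.base_log2_sd
        p_miss = config.missing_max / (
            1.0 + np.exp((log2 - thresh) / config.missing_softness)
        )
        mask = rng.random(log2.shape) < p_miss
        values = values.mask(mask, 0.0)
    truth = pd.DataFrame(assigned, columns=["protein", "complex", "log2fc"])
    return QuantMatrix(values, groups), truth


# ---------------------------------------------------------------------------
# Full fixture set


def emit_all(seed: int, out_dir: str | Path) -> dict:
    """Write the complete synthetic fixture set and its truth metadata.

    Emits CDS FASTA, editing-site TSV, PSM TSV, two complexome TSVs with a
    marker TSV, a quant TSV with its group map, and ``truth.json`` listing
    every planted quantity. Byte-identical for identical seeds.
    """
    from .digest import DigestConfig
    from .peptides import find_editing_specific_peptides
    from .proteoforms import enumerate_proteoforms

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cds_by_gene, sites = toy_reference_system()
    write_cds_fasta(cds_by_gene, out / "cds.fasta")
    accessions = {g: c.accession for g, c in cds_by_gene.items()}
    write_sites_tsv(sites, accessions, out / "sites.tsv")

    pairs = []
    fractions = {}
    for site in sites:
        gene = cds_by_gene[site.gene_id]
        pfs = enumerate_proteoforms(gene, [s for s in sites if s.gene_id == site.gene_id])
        site_pairs = find_editing_specific_peptides(
            pfs, site, DigestConfig(max_missed=0)
        )
        pairs.append(site_pairs[0])
        fractions[site.site_id] = site.wt_frequency
    psms = simulate_psm_table(pairs, fractions, seed)
    write_psm_tsv(psms, out / "psms.tsv")

    maps, cal = simulate_complexome_map(seed=seed)
    for condition, cmap in maps.items():
        write_complexome_tsv(cmap, out / f"complexome_{condition}.tsv")
    pd.DataFrame(
        [{"fraction": f, "mass_kda": m} for f, m in cal.markers]
    ).to_csv(out / "markers.tsv", sep="\t", index=False)

    qconfig = QuantSimConfig(
        complex_effects=(("complex_I", 30, float(np.log2(0.4))),),
        missing_max=0.3,
    )
    qm, truth_q = simulate_quant_matrix(qconfig, seed=seed)
    write_quant_tsv(qm, out / "quant.tsv")
    pd.DataFrame(
        [{"sample_id": s, "group": g} for s, g in qm.groups.items()]
    ).to_csv(out / "groups.tsv", sep="\t", index=False)

    truth = {
        "seed": seed,
        "editing_fractions": fractions,
        "complex_masses_kda": {
            cx.name: cx.mass_kda for cx in ComplexomeSimConfig().complexes
        },
        "quant_effects": {
            name: fc for name, _, fc in qconfig.complex_effects
        },
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return truth
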