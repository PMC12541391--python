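"""C-to-U RNA editing sites on mitochondrial coding sequences.

Plant mitochondrial transcripts are edited at specific cytidines, which are
deaminated to uridines before translation. A nonsilent editing event changes
the encoded amino acid, so proteins translated from partially edited
transcripts differ from the fully edited form at the affected residues.

Sites are named with the widely used compact nomenclature
``<gene>eU<cds_position><refAA><editedAA>p<wt_frequency>`` — for example
``nad2eU821SFp100``: C-to-U editing of the *nad2* CDS at position 821,
changing a serine (S, unedited) to a phenylalanine (F, edited), with a
wild-type editing frequency of 100%.

Coordinates are 1-based within the coding sequence. The edited base is
represented as T because all sequence I/O here is DNA-level FASTA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from math import ceil
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

__all__ = [
    "STANDARD_AA",
    "CodingSequence",
    "EditingSite",
    "SiteParseError",
    "SiteValidationError",
    "InternalStopError",
    "parse_site_id",
    "render_site_id",
    "map_to_codon",
    "validate_and_classify",
    "apply_edits",
    "translate_cds",
    "read_cds_fasta",
    "write_cds_fasta",
    "read_sites_tsv",
    "write_sites_tsv",
]


class SiteParseError(ValueError):
    """Raised when an editing-site identifier does not follow the nomenclature."""


class SiteValidationError(ValueError):
    """Raised when a site annotation is inconsistent with its coding sequence."""


class InternalStopError(ValueError):
    """Raised when a translation contains an internal stop codon.

    ``codon_index`` (1-based) locates the offending codon; an edit that
    creates a stop is reported explicitly rather than silently truncating.
    """

    def __init__(self, message: str, codon_index: int):
        super().__init__(message)
        self.codon_index = codon_index


@dataclass(frozen=True)
class CodingSequence:
    """A protein-coding DNA sequence, 1-based coordinates.

    The sequence must be over {A,C,G,T}, at least one codon long and a
    multiple of three; a single trailing stop codon is allowed (it is
    trimmed at translation). Internal stops are rejected.
    """

    gene_id: str
    accession: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 3:
            raise ValueError(f"CDS {self.gene_id!r}: length {len(seq)} < 3")
        if len(seq) % 3 != 0:
            raise ValueError(
                f"CDS {self.gene_id!r}: length {len(seq)} not divisible by 3"
            )
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"CDS {self.gene_id!r}: non-ACGT characters {sorted(bad)}")
        # raises InternalStopError if an internal stop is present
        translate_cds(self)

    def __len__(self) -> int:
        return len(self.sequence)

    def base_at(self, nt_position: int) -> str:
        if not 1 <= nt_position <= len(self.sequence):
            raise ValueError(
                f"position {nt_position} outside CDS {self.gene_id!r} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[nt_position - 1]

    def codon(self, codon_index: int) -> str:
        start = (codon_index - 1) * 3
        if start < 0 or start + 3 > len(self.sequence):
            raise ValueError(f"codon {codon_index} outside CDS {self.gene_id!r}")
        return self.sequence[start : start + 3]


@dataclass(frozen=True)
class EditingSite:
    """One C-to-U editing site with its amino-acid consequence.

    ``wt_frequency`` is the editing frequency in the wild type (parsed from
    the ``pNN`` token of the site id); ``mutant_frequency`` comes from the
    annotation table and may be missing. ``silent`` is True when the edit
    does not change the encoded amino acid.
    """

    site_id: str
    gene_id: str
    nt_position: int
    ref_aa: str
    edited_aa: str
    wt_frequency: float
    mutant_frequency: float | None = None
    codon_index: int = field(init=False, default=0)
    codon_offset: int = field(init=False, default=0)
    ref_base: str = "C"
    edited_base: str = "T"
    silent: bool = field(init=False, default=False)
    validated: bool = False

    def __post_init__(self):
        ci, off = map_to_codon(self.nt_position)
        object.__setattr__(self, "codon_index", ci)
        object.__setattr__(self, "codon_offset", off)
        object.__setattr__(self, "silent", self.ref_aa == self.edited_aa)


_SITE_ID_RE = re.compile(
    r"^(?P<gene>[A-Za-z]\w*?)eU(?P<pos>\d+)"
    r"(?P<ref>[A-Z])(?P<edited>[A-Z])p(?P<freq>\d+)$"
)


def parse_site_id(site_id: str) -> EditingSite:
    """Parse a ``<gene>eU<pos><refAA><editedAA>p<freq>`` identifier.

    >>> s = parse_site_id("nad2eU821SFp100")
    >>> (s.gene_id, s.nt_position, s.ref_aa, s.edited_aa, s.wt_frequency)
    ('nad2', 821, 'S', 'F', 1.0)
    """
    m = _SITE_ID_RE.match(site_id)
    if m is None:
        raise SiteParseError(
            f"site id {site_id!r} does not match <gene>eU<pos><refAA><editedAA>p<freq>"
        )
    ref, edited = m.group("ref"), m.group("edited")
    for token in (ref, edited):
        if token not in STANDARD_AA:
            raise SiteParseError(
                f"site id {site_id!r}: {token!r} is not a standard amino acid"
            )
    pos = int(m.group("pos"))
    if pos < 1:
        raise SiteParseError(f"site id {site_id!r}: position must be >= 1")
    freq = int(m.group("freq"))
    if not 0 <= freq <= 100:
        raise SiteParseError(
            f"site id {site_id!r}: frequency token p{freq} outside 0-100"
        )
    return EditingSite(
        site_id=site_id,
        gene_id=m.group("gene"),
        nt_position=pos,
        ref_aa=ref,
        edited_aa=edited,
        wt_frequency=freq / 100.0,
    )


def render_site_id(site: EditingSite) -> str:
    """Inverse of :func:`parse_site_id` for valid sites."""
    freq = int(round(site.wt_frequency * 100))
    return f"{site.gene_id}eU{site.nt_position}{site.ref_aa}{site.edited_aa}p{freq}"


def map_to_codon(nt_position: int) -> tuple[int, int]:
    """Map a 1-based CDS nucleotide position to (codon index, offset in codon).

    The codon index equals the 1-based position of the encoded amino acid;
    the offset is 1, 2 or 3 within the codon.

    >>> map_to_codon(821)
    (274, 2)
    """
    if nt_position < 1:
        raise ValueError(f"nt_position must be >= 1, got {nt_position}")
    return ceil(nt_position / 3), ((nt_position - 1) % 3) + 1


def translate_cds(cds: CodingSequence | str) -> str:
    """Standard-genetic-code translation; trailing stop removed.

    Plant mitochondria use the standard code. An internal stop codon (which
    can arise from an edit) raises :class:`InternalStopError` carrying the
    1-based codon index.
    """
    seq = cds.sequence if isinstance(cds, CodingSequence) else cds
    protein = str(Seq(seq).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        idx = protein.index("*") + 1
        raise InternalStopError(
            f"internal stop codon at codon {idx} (edit-created stop?)", idx
        )
    return protein


def validate_and_classify(cds: CodingSequence, site: EditingSite) -> EditingSite:
    """Check a site against its CDS and return it fully populated.

    Asserts that the genomic base at the site is C, and that the unedited
    and C-to-T-edited codons translate to the amino acids named in the site
    id. Sets the ``silent`` flag.
    """
    if site.nt_position > len(cds):
        raise SiteValidationError(
            f"{site.site_id}: position {site.nt_position} beyond CDS length {len(cds)}"
        )
    base = cds.base_at(site.nt_position)
    if base != "C":
        raise SiteValidationError(
            f"{site.site_id}: base at position {site.nt_position} is {base!r}, not C"
        )
    codon = cds.codon(site.codon_index)
    edited_codon = (
        codon[: site.codon_offset - 1] + "T" + codon[site.codon_offset :]
    )
    ref_aa = str(Seq(codon).translate())
    edited_aa = str(Seq(edited_codon).translate())
    if ref_aa != site.ref_aa or edited_aa != site.edited_aa:
        raise SiteValidationError(
            f"{site.site_id}: annotated {site.ref_aa}->{site.edited_aa} but codon "
            f"{codon}->{edited_codon} translates {ref_aa}->{edited_aa}"
        )
    return replace(site, validated=True)


def apply_edits(cds: CodingSequence, sites: Iterable[EditingSite]) -> CodingSequence:
    """Return a copy of the CDS with each site's C replaced by T.

    The input is unchanged; duplicate positions are an error. The result
    differs from the input at exactly one position per site.
    """
    sites = list(sites)
    positions = [s.nt_position for s in sites]
    if len(positions) != len(set(positions)):
        dupes = sorted({p for p in positions if positions.count(p) > 1})
        raise ValueError(f"duplicate editing positions {dupes}")
    chars = list(cds.sequence)
    for s in sites:
        if chars[s.nt_position - 1] != "C":
            raise SiteValidationError(
                f"{s.site_id}: base at {s.nt_position} is not C; validate sites first"
            )
        chars[s.nt_position - 1] = "T"
    return CodingSequence(cds.gene_id, cds.accession, "".join(chars))


# ---------------------------------------------------------------------------
# File interfaces


def read_cds_fasta(path: str | Path) -> dict[str, CodingSequence]:
    """Read a multi-FASTA of coding sequences keyed by gene id.

    Headers are ``gene_id|accession`` (or whitespace-separated); the first
    token is the gene id.
    """
    out: dict[str, CodingSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = re.split(r"[|\s]+", rec.description.strip())
        gene_id = parts[0]
        accession = parts[1] if len(parts) > 1 else ""
        if gene_id in out:
            raise ValueError(f"duplicate gene id {gene_id!r} in {path}")
        out[gene_id] = CodingSequence(gene_id, accession, str(rec.seq))
    return out


def write_cds_fasta(cds_by_gene: Mapping[str, CodingSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=f"{c.gene_id}|{c.accession}", description="")
        for c in cds_by_gene.values()
    ]
    SeqIO.write(records, str(path), "fasta")


_SITE_TSV_COLUMNS = [
    "site_id",
    "gene_id",
    "accession",
    "nt_position",
    "wt_frequency",
    "mutant_frequency",
]


def read_sites_tsv(path: str | Path) -> list[EditingSite]:
    """Read an editing-site annotation table (tab-separated, header required).

    Each row's ``site_id`` is parsed with :func:`parse_site_id` and checked
    for consistency against the explicit ``gene_id``/``nt_position`` columns.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SITE_TSV_COLUMNS if c not in df.columns and c != "accession"]
    if missing:
        raise ValueError(f"site table {path}: missing columns {missing}")
    sites = []
    for _, row in df.iterrows():
        site = parse_site_id(str(row["site_id"]))
        if site.gene_id != str(row["gene_id"]) or site.nt_position != int(
            row["nt_position"]
        ):
            raise SiteValidationError(
                f"{site.site_id}: table row (gene {row['gene_id']}, "
                f"pos {row['nt_position']}) contradicts the identifier"
            )
        mut = row.get("mutant_frequency")
        mut = None if pd.isna(mut) else float(mut)
        sites.append(replace(site, mutant_frequency=mut))
    return sites


def write_sites_tsv(
    sites: Iterable[EditingSite],
    accessions: Mapping[str, str],
    path: str | Path,
) -> None:
    rows = [
        {
            "site_id": s.site_id,
            "gene_id": s.gene_id,
            "accession": accessions.get(s.gene_id, ""),
            "nt_position": s.nt_position,
            "wt_frequency": s.wt_frequency,
            "mutant_frequency": "" if s.mutant_frequency is None else s.mutant_frequency,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=_SITE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
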