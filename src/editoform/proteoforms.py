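"""Edited/unedited proteoform enumeration and the variant FASTA database.

A proteoform of a mitochondrially encoded gene is defined here by a
*variant signature*: an assignment of each selected (by default nonsilent)
editing site to the edited (``E``) or unedited (``U``) state. Translating
the CDS with exactly the signature's edited sites applied yields the
proteoform's protein sequence. The set of all signatures per gene is the
search-space of "permutation variants" used to detect editing-specific
peptides with a standard search engine.

FASTA header grammar: ``gene_id|accession|site_id=E,site_id=U,...`` with
``gene_id|accession|ref`` for a gene without selected sites. Headers double
as proteoform labels and are unique within a database.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .editing_sites import (
    STANDARD_AA,
    CodingSequence,
    EditingSite,
    InternalStopError,
    apply_edits,
    translate_cds,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VariantSignature",
    "Proteoform",
    "enumerate_proteoforms",
    "write_variant_fasta",
    "read_variant_fasta",
]

EDITED, UNEDITED = "E", "U"


@dataclass(frozen=True)
class VariantSignature:
    """Ordered (by nt_position) map of site_id -> 'E' or 'U'."""

    states: tuple[tuple[str, str], ...]

    def __post_init__(self):
        for site_id, state in self.states:
            if state not in (EDITED, UNEDITED):
                raise ValueError(f"signature state {state!r} for {site_id!r}")

    def state_of(self, site_id: str) -> str:
        for sid, state in self.states:
            if sid == site_id:
                return state
        raise KeyError(site_id)

    def token(self) -> str:
        if not self.states:
            return "ref"
        return ",".join(f"{sid}={state}" for sid, state in self.states)


@dataclass(frozen=True)
class Proteoform:
    gene_id: str
    accession: str
    signature: VariantSignature
    protein_sequence: str

    @property
    def label(self) -> str:
        return f"{self.gene_id}|{self.accession}|{self.signature.token()}"


def _realize(
    cds: CodingSequence, sites: Sequence[EditingSite], signature: VariantSignature
) -> str:
    edited = [s for s in sites if signature.state_of(s.site_id) == EDITED]
    return translate_cds(apply_edits(cds, edited))


def enumerate_proteoforms(
    cds: CodingSequence,
    sites: Sequence[EditingSite],
    mode: str = "combinatorial",
    cap: int = 4096,
    include_silent: bool = False,
) -> list[Proteoform]:
    """Enumerate proteoform variants of one gene.

    ``combinatorial`` yields up to 2**n signatures over the n selected
    sites, deduplicated at the protein level (the fully edited signature
    comes first and wins ties); if 2**n exceeds ``cap`` the enumeration
    falls back to ``per_site``. ``per_site`` yields the fully edited
    reference plus one single-site-unedited variant per site.

    Variants whose edits would create an internal stop codon are dropped
    with a logged reason rather than emitted truncated.
    """
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    if mode not in ("combinatorial", "per_site"):
        raise ValueError(f"unknown mode {mode!r}")
    selected = sorted(
        (s for s in sites if include_silent or not s.silent),
        key=lambda s: s.nt_position,
    )
    n = len(selected)
    if mode == "combinatorial" and 2**n > cap:
        logger.warning(
            "%s: 2^%d signatures exceed cap %d; falling back to per_site",
            cds.gene_id,
            n,
            cap,
        )
        mode = "per_site"

    signatures: list[VariantSignature]
    if mode == "combinatorial":
        signatures = [
            VariantSignature(tuple(zip((s.site_id for s in selected), combo)))
            for combo in itertools.product((EDITED, UNEDITED), repeat=n)
        ]
    else:
        all_edited = tuple((s.site_id, EDITED) for s in selected)
        signatures = [VariantSignature(all_edited)]
        for i in range(n):
            states = list(all_edited)
            states[i] = (selected[i].site_id, UNEDITED)
            signatures.append(VariantSignature(tuple(states)))

    out: list[Proteoform] = []
    seen_sequences: set[str] = set()
    for sig in signatures:
        try:
            protein = _realize(cds, selected, sig)
        except InternalStopError as exc:
            logger.warning("%s %s: variant dropped (%s)", cds.gene_id, sig.token(), exc)
            continue
        if protein in seen_sequences:
            continue
        seen_sequences.add(protein)
        out.append(Proteoform(cds.gene_id, cds.accession, sig, protein))
    return out


# ---------------------------------------------------------------------------
# FASTA database I/O


def _parse_header(header: str) -> tuple[str, str, VariantSignature]:
    parts = header.split("|")
    if len(parts) != 3:
        raise ValueError(f"malformed variant header {header!r}")
    gene_id, accession, token = parts
    if token == "ref":
        return gene_id, accession, VariantSignature(())
    states = []
    for item in token.split(","):
        if "=" not in item:
            raise ValueError(f"malformed signature token {item!r} in header {header!r}")
        sid, state = item.split("=", 1)
        if state not in (EDITED, UNEDITED) or not sid:
            raise ValueError(f"malformed signature token {item!r} in header {header!r}")
        states.append((sid, state))
    return gene_id, accession, VariantSignature(tuple(states))


def write_variant_fasta(proteoforms: Iterable[Proteoform], path: str | Path) -> None:
    proteoforms = list(proteoforms)
    labels = [p.label for p in proteoforms]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate proteoform labels")
    records = [
        SeqRecord(Seq(p.protein_sequence), id=p.label, description="")
        for p in proteoforms
    ]
    SeqIO.write(records, str(path), "fasta")


def read_variant_fasta(path: str | Path) -> list[Proteoform]:
    out: list[Proteoform] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if header in seen:
            raise ValueError(f"duplicate header {header!r} in {path}")
        seen.add(header)
        gene_id, accession, signature = _parse_header(header)
        protein = str(rec.seq)
        bad = set(protein) - STANDARD_AA
        if bad:
            raise ValueError(
                f"non-amino-acid characters {sorted(bad)} in {header!r}"
            )
        out.append(Proteoform(gene_id, accession, signature, protein))
    return out
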