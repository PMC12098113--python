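"""Peptide enumeration, library subtraction and proteomic confirmation.

The neoantigen candidates this package produces are splice-specific 9-mers:
windows of the aging-favored isoform's protein that occur neither in the
young-favored isoform of the same event nor in a background library built
from the normal (young / middle-aged) proteome.  Candidates are confirmed
against observed proteomic peptides by exact sequence + gene-symbol match,
which at 100% identity over full-length 9-mers coincides with a blastp
search but is deterministic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TYPE_CHECKING

from Bio import SeqIO
from Bio.Data import CodonTable

if TYPE_CHECKING:  # pragma: no cover
    from .isoforms import IsoformPair

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD.forward_table)
_STOPS = frozenset(_STANDARD.stop_codons)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def translate(cds: str) -> str:
    """Translate a coding sequence in frame 0 with the standard codon table.

    Translation stops at the first in-frame stop codon (the stop itself is
    not emitted).  A codon containing any character outside {A,C,G,T} —
    typically an N from ambiguous sequence — yields ``X`` even when the
    ambiguity would not change the encoded residue, because such windows
    cannot be scored for MHC binding anyway.  A trailing partial codon is
    ignored.
    """
    cds = cds.upper()
    out = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        if codon in _STOPS:
            break
        out.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(out)


@dataclass
class PeptideRecord:
    """One k-mer window of an isoform protein with its provenance."""

    sequence: str
    source_event: str = ""
    gene_symbol: str = ""
    position_in_protein: int = 0
    origin_form: str = ""
    proteomic_match: bool = False


@dataclass
class PeptideLibrary:
    """A named set of 9-mers used as the subtraction background."""

    name: str
    members: set[str] = field(default_factory=set)
    provenance: str = ""

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.members)


def kmerize(
    protein: str,
    k: int = 9,
    *,
    source_event: str = "",
    gene_symbol: str = "",
    origin_form: str = "",
) -> list[PeptideRecord]:
    """Sliding windows of length ``k`` (step 1) over a protein.

    Returns ``max(0, L - k + 1)`` windows in order, minus any window that
    contains an ``X`` (untranslatable codon), each tagged with its 0-based
    start residue.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    records = []
    for i in range(len(protein) - k + 1):
        window = protein[i : i + k]
        if "X" in window:
            continue
        records.append(
            PeptideRecord(
                sequence=window,
                source_event=source_event,
                gene_symbol=gene_symbol,
                position_in_protein=i,
                origin_form=origin_form,
            )
        )
    return records


def _looks_like_dna(seq: str) -> bool:
    letters = set(seq.upper())
    return bool(letters) and letters <= set("ACGTN")


def build_library(paths: Iterable[str | os.PathLike], name: str = "background") -> PeptideLibrary:
    """Union 9-mer library from protein/CDS FASTA files or one-per-line text.

    CDS records (detected by their alphabet) are translated before
    kmerization, so the same function covers both the reference-proteome
    and assembled-transcript inputs.
    """
    members: set[str] = set()
    n_records = 0
    paths = list(paths)
    for path in paths:
        path = os.fspath(path)
        if not os.path.exists(path):
            raise IOError(f"library input not readable: {path}")
        with open(path) as fh:
            head = fh.read(1)
        if head == ">":
            for rec in SeqIO.parse(path, "fasta"):
                seq = str(rec.seq)
                protein = translate(seq) if _looks_like_dna(seq) else seq
                members.update(r.sequence for r in kmerize(protein))
                n_records += 1
        else:
            with open(path) as fh:
                for line in fh:
                    pep = line.strip()
                    if pep:
                        members.add(pep)
                        n_records += 1
    return PeptideLibrary(
        name=name,
        members=members,
        provenance=f"{len(paths)} file(s), {n_records} record(s)",
    )


def novel_peptides(pair: "IsoformPair", background: PeptideLibrary, k: int = 9) -> list[PeptideRecord]:
    """Splice-specific k-mers of an event's aging-favored isoform.

    Windows of the aging-favored protein are kept only if they occur
    neither anywhere in the other (young-favored) form's protein nor in
    the background library.  Both subtractions are applied; records are
    deduplicated by (sequence, event) keeping the first position.
    """
    if not pair.cds_changed:
        raise ValueError(f"event {pair.event_id}: CDS unchanged, no novel peptides to derive")
    aging = pair.aging_form()
    other = pair.other_form()
    other_kmers = {r.sequence for r in kmerize(other.protein, k)}
    exclude = other_kmers | background.members
    seen: set[str] = set()
    out = []
    for rec in kmerize(
        aging.protein,
        k,
        source_event=pair.event_id,
        gene_symbol=pair.gene_symbol,
        origin_form=pair.aging_favored,
    ):
        if rec.sequence in exclude or rec.sequence in seen:
            continue
        seen.add(rec.sequence)
        out.append(rec)
    return out


def match_proteomics(
    candidates: Sequence[PeptideRecord],
    observed: Iterable[tuple[str, str]],
) -> list[PeptideRecord]:
    """Confirm candidates against observed proteomic (peptide, gene) pairs.

    A candidate is fully matched iff some observed peptide has an identical
    sequence AND the same gene symbol (case-insensitive).  Every candidate's
    ``proteomic_match`` flag is set; the matched subset is returned.
    """
    observed_pairs = {(pep, gene.upper()) for pep, gene in observed}
    matched = []
    for rec in candidates:
        rec.proteomic_match = (rec.sequence, rec.gene_symbol.upper()) in observed_pairs
        if rec.proteomic_match:
            matched.append(rec)
    return matched
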