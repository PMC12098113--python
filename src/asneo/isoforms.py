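"""Transcript "exon surgery" for alternative-splicing events.

For each differential splicing event, this module constructs the
inclusion-form and exclusion-form transcript variants against a reference
gene model, extracts and compares their coding sequences, maps the altered
region into protein coordinates, and intersects it with protein-domain
annotations.

The aging-favored form is the inclusion form iff deltaPSI > 0 (higher
inclusion in the old group); the other form plays the role of the
"unspliced" reference isoform.  Coordinates are 0-based half-open
throughout; GTF input is converted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

from ._dna import fetch, revcomp
from .events import ASEvent
from .peptides import translate

Interval = tuple[int, int]


class IncompatibleEventError(ValueError):
    """Event and transcript cannot be reconciled (flank mismatch etc.)."""


@dataclass
class TranscriptModel:
    """A gene/transcript with ordered exons and an annotated CDS span.

    ``exons`` are genomic-ascending regardless of strand; the coding order
    of a minus-strand transcript is the reverse complement of the genomic
    order.  ``cds_start``/``cds_end`` bound the CDS in genomic coordinates.
    """

    transcript_id: str
    gene_id: str
    gene_symbol: str
    chromosome: str
    strand: str
    exons: list[Interval]
    cds_start: int
    cds_end: int
    source: str = "reference"

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"{self.transcript_id}: malformed exon [{s},{e})")
            if s < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e
        if not self.cds_start < self.cds_end:
            raise ValueError(f"{self.transcript_id}: empty CDS span")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def cds_exonic_length(self) -> int:
        return sum(
            max(0, min(e, self.cds_end) - max(s, self.cds_start)) for s, e in self.exons
        )


def spliced_sequence(model: TranscriptModel, genome) -> str:
    """Full spliced transcript sequence on the coding strand."""
    seq = "".join(fetch(genome, model.chromosome, s, e) for s, e in model.exons)
    return revcomp(seq) if model.strand == "-" else seq


def spliced_cds(model: TranscriptModel, genome) -> str:
    """Spliced CDS on the coding strand, starting at the annotated start.

    Concatenates each exon's overlap with [cds_start, cds_end) in genomic
    order, then reverse-complements for minus-strand models.  If surgery
    has removed the exon containing the start codon, the returned sequence
    simply no longer begins with ATG; callers classify such pairs as
    non-coding.
    """
    parts = []
    for s, e in model.exons:
        a, b = max(s, model.cds_start), min(e, model.cds_end)
        if a < b:
            parts.append(fetch(genome, model.chromosome, a, b))
    seq = "".join(parts)
    return revcomp(seq) if model.strand == "-" else seq


def _find_exon(model: TranscriptModel, interval: Interval) -> int:
    for i, exon in enumerate(model.exons):
        if exon == interval:
            return i
    raise IncompatibleEventError(
        f"event/transcript incompatible: exon {interval} not found in "
        f"{model.transcript_id} (exons {model.exons})"
    )


def apply_event(reference: TranscriptModel, event: ASEvent, form: str) -> TranscriptModel:
    """Build one form (``inclusion``/``exclusion``) of an event's isoform.

    The event's flanking exons must match reference exons by exact
    coordinate equality; everything outside the event footprint is copied
    unchanged.  Surgery per type:

    * SE  — inclusion keeps the cassette exon between its flanks,
      exclusion splices the flanks directly together;
    * MXE — inclusion carries exon1 between the flanks, exclusion exon2;
    * A5SS/A3SS — inclusion uses the long exon, exclusion the short one;
    * RI  — inclusion merges upstream exon + intron + downstream exon into
      the single ``ri_exon``, exclusion keeps the two exons split.
    """
    if form not in ("inclusion", "exclusion"):
        raise ValueError(f"form must be inclusion/exclusion, got {form!r}")
    if event.chromosome != reference.chromosome or event.strand != reference.strand:
        raise IncompatibleEventError(
            f"event {event.event_id} on {event.chromosome}{event.strand}, "
            f"transcript {reference.transcript_id} on "
            f"{reference.chromosome}{reference.strand}"
        )
    c = event.coords
    exons = list(reference.exons)
    etype = event.event_type

    if etype in ("SE", "MXE"):
        iu = _find_exon(reference, c["upstream"])
        idn = _find_exon(reference, c["downstream"])
        if iu >= idn:
            raise IncompatibleEventError(
                f"event {event.event_id}: flank order inconsistent with "
                f"{reference.transcript_id}"
            )
        if etype == "SE":
            middle = [c["exon"]] if form == "inclusion" else []
        else:
            middle = [c["exon1"] if form == "inclusion" else c["exon2"]]
        exons = exons[: iu + 1] + middle + exons[idn:]
    elif etype in ("A5SS", "A3SS"):
        _find_exon(reference, c["flanking"])
        want = c["long_exon"] if form == "inclusion" else c["short_exon"]
        have = c["short_exon"] if form == "inclusion" else c["long_exon"]
        try:
            i = _find_exon(reference, want)
            exons[i] = want  # already present: identity
        except IncompatibleEventError:
            i = _find_exon(reference, have)
            exons[i] = want
    elif etype == "RI":
        if form == "inclusion":
            try:
                iu = _find_exon(reference, c["upstream"])
                idn = _find_exon(reference, c["downstream"])
            except IncompatibleEventError:
                _find_exon(reference, c["ri_exon"])  # already merged
            else:
                if idn != iu + 1:
                    raise IncompatibleEventError(
                        f"event {event.event_id}: RI flanks not adjacent in "
                        f"{reference.transcript_id}"
                    )
                exons = exons[:iu] + [c["ri_exon"]] + exons[idn + 1 :]
        else:
            try:
                im = _find_exon(reference, c["ri_exon"])
            except IncompatibleEventError:
                _find_exon(reference, c["upstream"])
                _find_exon(reference, c["downstream"])  # already split
            else:
                exons = exons[:im] + [c["upstream"], c["downstream"]] + exons[im + 1 :]
    else:  # pragma: no cover - guarded by ASEvent.validate
        raise ValueError(f"unknown event type {etype!r}")

    out = replace(
        reference,
        exons=sorted(exons),
        source=f"{form}_variant",
        transcript_id=f"{reference.transcript_id}|{event.event_id}|{form}",
    )
    out.validate()
    return out


@dataclass
class Isoform:
    """One concrete form of an event: model + spliced CDS + protein."""

    model: TranscriptModel
    cds: str
    protein: str


@dataclass
class IsoformPair:
    """Inclusion and exclusion forms of one event with their comparison."""

    event_id: str
    event_type: str
    gene_id: str
    gene_symbol: str
    inclusion: Isoform
    exclusion: Isoform
    aging_favored: str  # "inclusion" | "exclusion"
    cds_changed: bool
    frame_effect: str  # "preserving" | "disrupting" | "non_coding"
    protein_interval: Interval | None = None

    def aging_form(self) -> Isoform:
        return self.inclusion if self.aging_favored == "inclusion" else self.exclusion

    def other_form(self) -> Isoform:
        return self.exclusion if self.aging_favored == "inclusion" else self.inclusion


def map_to_protein(pair: "IsoformPair") -> Interval:
    """Residue interval of the aging-favored protein touched by the event.

    Locates the first and last differing CDS positions between the two
    forms (aligning common prefix and suffix), converts to residues as
    [floor(first/3), ceil(last_exclusive/3)), and clips to the translated
    protein length (which may be shorter than the CDS implies when a
    premature stop intervenes).  Under frame disruption everything
    downstream of the first difference differs.
    """
    aging = pair.aging_form()
    aging_cds, other_cds = aging.cds, pair.other_form().cds
    aging_protein, frame_effect = aging.protein, pair.frame_effect
    if aging_cds == other_cds:
        raise ValueError("CDS identical: no protein interval to map (check cds_changed)")
    first = 0
    limit = min(len(aging_cds), len(other_cds))
    while first < limit and aging_cds[first] == other_cds[first]:
        first += 1
    if frame_effect == "disrupting":
        start = min(first // 3, len(aging_protein))
        return (start, len(aging_protein))
    suffix = 0
    while (
        suffix < limit - first
        and aging_cds[len(aging_cds) - 1 - suffix] == other_cds[len(other_cds) - 1 - suffix]
    ):
        suffix += 1
    last_exclusive = len(aging_cds) - suffix
    start = min(first // 3, len(aging_protein))
    end = min(math.ceil(last_exclusive / 3), len(aging_protein))
    return (start, max(start, end))


def build_isoform_pair(reference: TranscriptModel, event: ASEvent, genome) -> IsoformPair:
    """Construct both forms of an event and compare their CDS/proteins."""
    forms = {}
    for form in ("inclusion", "exclusion"):
        model = apply_event(reference, event, form)
        cds = spliced_cds(model, genome)
        forms[form] = Isoform(model=model, cds=cds, protein=translate(cds))
    aging_favored = "inclusion" if event.delta_psi > 0 else "exclusion"
    pair = IsoformPair(
        event_id=event.event_id,
        event_type=event.event_type,
        gene_id=event.gene_id,
        gene_symbol=event.gene_symbol,
        inclusion=forms["inclusion"],
        exclusion=forms["exclusion"],
        aging_favored=aging_favored,
        cds_changed=forms["inclusion"].cds != forms["exclusion"].cds,
        frame_effect="non_coding",
    )
    aging = pair.aging_form()
    if not pair.cds_changed:
        return pair
    if not aging.cds or not aging.cds.startswith("ATG"):
        pair.frame_effect = "non_coding"
        return pair
    delta_len = len(pair.inclusion.cds) - len(pair.exclusion.cds)
    pair.frame_effect = "preserving" if delta_len % 3 == 0 else "disrupting"
    pair.protein_interval = map_to_protein(pair)
    return pair


def select_reference(event: ASEvent, models: Sequence[TranscriptModel]) -> TranscriptModel | None:
    """Pick the reference transcript an event is applied to.

    Among same-gene transcripts compatible with the event (surgery succeeds
    for both forms is not required here — only flank matching), the one
    with the longest annotated CDS wins; ties break on lexicographic
    transcript id.  Returns None when nothing matches.
    """
    candidates = []
    for model in models:
        if model.gene_id != event.gene_id:
            continue
        try:
            apply_event(model, event, "inclusion")
            apply_event(model, event, "exclusion")
        except IncompatibleEventError:
            continue
        candidates.append(model)
    if not candidates:
        return None
    return min(candidates, key=lambda m: (-m.cds_exonic_length(), m.transcript_id))


def build_pairs(
    events: Iterable[ASEvent],
    models: Sequence[TranscriptModel],
    genome,
) -> tuple[list[IsoformPair], list[tuple[str, str]]]:
    """Build isoform pairs for every compatible event.

    Returns the pairs plus a list of (event_id, reason) for skipped events
    (no matching transcript).
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    pairs, skipped = [], []
    for event in events:
        reference = select_reference(event, by_gene.get(event.gene_id, []))
        if reference is None:
            skipped.append((event.event_id, "no compatible reference transcript"))
            continue
        pairs.append(build_isoform_pair(reference, event, genome))
    return pairs, skipped


@dataclass
class DomainAnnotation:
    """A protein domain in 0-based half-open protein coordinates."""

    protein_id: str
    domain_name: str
    domain_accession: str
    start: int
    end: int

    def validate(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.domain_accession}: malformed interval")


@dataclass
class DomainOverlap:
    event_id: str
    domain_accession: str
    domain_name: str
    start: int
    end: int


def overlap_domains(
    pairs: Iterable[IsoformPair],
    domains: Iterable[DomainAnnotation],
    protein_id_of: Mapping[str, str] | None = None,
) -> list[DomainOverlap]:
    """Half-open intersection of affected protein intervals with domains.

    ``protein_id_of`` maps event_id -> the protein id used in the domain
    table; by default the event's gene id is used.  Abutting intervals
    ([10,12) vs [12,30)) do not overlap.
    """
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for dom in domains:
        dom.validate()
        by_protein.setdefault(dom.protein_id, []).append(dom)
    out = []
    for pair in pairs:
        if pair.protein_interval is None:
            continue
        pid = protein_id_of[pair.event_id] if protein_id_of else pair.gene_id
        a, b = pair.protein_interval
        for dom in by_protein.get(pid, []):
            s, e = max(a, dom.start), min(b, dom.end)
            if s < e:
                out.append(
                    DomainOverlap(pair.event_id, dom.domain_accession, dom.domain_name, s, e)
                )
    return out


def count_events_per_domain(overlaps: Iterable[DomainOverlap]) -> dict[str, int]:
    """Events per domain accession (the domain-impact heatmap quantity)."""
    counts: dict[str, set[str]] = {}
    for ov in overlaps:
        counts.setdefault(ov.domain_accession, set()).add(ov.event_id)
    return {acc: len(evs) for acc, evs in counts.items()}


def domains_from_interproscan(df: pd.DataFrame) -> list[DomainAnnotation]:
    """Convert a 1-based inclusive domain table to half-open annotations.

    Expects columns protein_id, domain_accession, domain_name, start, end
    (InterProScan TSV convention: 1-based, end inclusive).
    """
    return [
        DomainAnnotation(
            protein_id=row["protein_id"],
            domain_name=row["domain_name"],
            domain_accession=row["domain_accession"],
            start=int(row["start"]) - 1,
            end=int(row["end"]),
        )
        for _, row in df.iterrows()
    ]


def read_domain_table(path) -> list[DomainAnnotation]:
    """Read a half-open domain TSV (protein_id, accession, name, start, end)."""
    df = pd.read_csv(path, sep="\t")
    return [
        DomainAnnotation(
            protein_id=row["protein_id"],
            domain_name=row["domain_name"],
            domain_accession=row["domain_accession"],
            start=int(row["start"]),
            end=int(row["end"]),
        )
        for _, row in df.iterrows()
    ]


def read_gtf(path) -> list[TranscriptModel]:
    """Load transcript models from a GTF file (1-based inclusive on disk).

    Exon and CDS features are grouped by transcript_id; the CDS span is the
    union of CDS features.  Transcripts without CDS are skipped.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[Interval]] = {}
    cds_bounds: dict[str, list[int]] = {}
    meta: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        meta.setdefault(
            tid,
            {
                "gene_id": feat.attributes.get("gene_id", [""])[0],
                "gene_symbol": feat.attributes.get("gene_name", [""])[0],
                "chromosome": feat.seqid,
                "strand": feat.strand,
            },
        )
        iv = (feat.start - 1, feat.end)  # to 0-based half-open
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(iv)
        else:
            bounds = cds_bounds.setdefault(tid, [iv[0], iv[1]])
            bounds[0] = min(bounds[0], iv[0])
            bounds[1] = max(bounds[1], iv[1])
    models = []
    for tid, ex in exons.items():
        if tid not in cds_bounds:
            continue
        m = meta[tid]
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=m["gene_id"],
            gene_symbol=m["gene_symbol"],
            chromosome=m["chromosome"],
            strand=m["strand"],
            exons=sorted(ex),
            cds_start=cds_bounds[tid][0],
            cds_end=cds_bounds[tid][1],
        )
        model.validate()
        models.append(model)
    return models


def write_gtf(models: Sequence[TranscriptModel], path) -> None:
    """Write models as GTF (gene/transcript/exon/CDS, 1-based inclusive)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_name "{m.gene_symbol}";'
            )
            span = m.span
            fh.write(
                f"{m.chromosome}\tasneo\tgene\t{span[0] + 1}\t{span[1]}\t.\t{m.strand}\t.\t"
                f'gene_id "{m.gene_id}"; gene_name "{m.gene_symbol}";\n'
            )
            fh.write(
                f"{m.chromosome}\tasneo\ttranscript\t{span[0] + 1}\t{span[1]}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chromosome}\tasneo\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            cds_parts = []
            for s, e in m.exons:
                a, b = max(s, m.cds_start), min(e, m.cds_end)
                if a < b:
                    cds_parts.append((a, b))
            # frame: bases already consumed before this CDS chunk, coding order
            order = cds_parts if m.strand == "+" else cds_parts[::-1]
            consumed = 0
            frames = {}
            for a, b in order:
                frames[(a, b)] = (3 - consumed % 3) % 3
                consumed += b - a
            for a, b in cds_parts:
                fh.write(
                    f"{m.chromosome}\tasneo\tCDS\t{a + 1}\t{b}\t.\t{m.strand}\t"
                    f"{frames[(a, b)]}\t{attrs}\n"
                )
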