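"""Self-contained synthetic cohort with machine-readable ground truth.

Generates everything the downstream pipeline consumes — a random genome,
gene models with clean coding sequences, planted alternative-splicing
events of all five types with controlled old-vs-young PSI shifts,
junction-count tables in rMATS layout, per-sample PSI and expression
matrices, a background 9-mer library, HLA class-I genotypes, a partial
proteomic capture of the planted peptides with decoys, and motif
placements in event flanks — so every downstream stage is testable without
any external download.

The study design emulated is a two-group blood cohort (old vs young) with
group-wise deltaPSI effects planted on distinct transcripts.  Group 1 is
the old cohort throughout, so emitted IncLevelDifference = PSI(old) −
PSI(young).

Determinism: one integer seed drives independent substreams for each
generation stage, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._dna import revcomp
from .events import ASEvent, EVENT_TYPES, write_rmats_jc
from .isoforms import TranscriptModel, write_gtf
from .motifs import parse_motif, realize_motif, slot_interval
from .peptides import AMINO_ACIDS, PeptideLibrary, kmerize, translate
from .presentation import HLAGenotype, write_genotypes

Interval = tuple[int, int]

_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)

#: toy class-I allele pool with configured frequencies (not population-real)
DEFAULT_ALLELE_POOL: dict[str, list[tuple[str, float]]] = {
    "A": [("HLA-A02:01", 0.5), ("HLA-A11:01", 0.3), ("HLA-A24:02", 0.2)],
    "B": [("HLA-B07:02", 0.4), ("HLA-B08:01", 0.35), ("HLA-B40:01", 0.25)],
    "C": [("HLA-C07:01", 0.45), ("HLA-C07:02", 0.35), ("HLA-C14:02", 0.2)],
}


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort.

    Defaults describe a small but fully featured two-group cohort: 40+40
    samples, a planted effect of deltaPSI = 0.3 against per-sample noise of
    sd 0.05 (so planted effects are recoverable by construction), eight
    signal and eight null events per type, and a 50% proteomic capture.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 400_000
    n_genes: int = 80
    exons_per_gene: tuple[int, int] = (6, 9)
    exon_length: tuple[int, int] = (60, 120)
    intron_length: tuple[int, int] = (300, 600)
    n_events_per_type: dict[str, int] = field(
        default_factory=lambda: {t: 8 for t in EVENT_TYPES}
    )
    n_null_events_per_type: dict[str, int] = field(
        default_factory=lambda: {t: 8 for t in EVENT_TYPES}
    )
    delta_psi_effect: float = 0.3
    psi_noise_sd: float = 0.05
    n_young: int = 40
    n_old: int = 40
    junction_depth: int = 100
    proteomic_capture_fraction: float = 0.5
    n_proteomic_decoys: int = 200
    motif_pattern: str = "[ACT]ATATA"
    motif_enrichment_fold: float = 3.0
    motif_background_rate: float = 1.0
    n_utr_only_events: int = 2
    allele_pool: dict[str, list[tuple[str, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_ALLELE_POOL.items()}
    )

    def total_events(self) -> int:
        return sum(self.n_events_per_type.values()) + sum(
            self.n_null_events_per_type.values()
        )

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for lo, hi, name in (
            (*self.exons_per_gene, "exons_per_gene"),
            (*self.exon_length, "exon_length"),
            (*self.intron_length, "intron_length"),
        ):
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range must be positive and ordered")
        if self.exons_per_gene[0] < 6:
            raise ValueError("genes need >= 6 exons to host internal events")
        if self.exon_length[0] < 60:
            raise ValueError("exon_length minimum below 60 bp cannot host splice-site shifts")
        if self.intron_length[0] < 260:
            raise ValueError("intron_length minimum must exceed 260 bp (exon2 + margins)")
        for mapping in (self.n_events_per_type, self.n_null_events_per_type):
            for t, n in mapping.items():
                if t not in EVENT_TYPES or n < 0:
                    raise ValueError(f"bad event count {t}={n}")
        if not 0 < self.delta_psi_effect <= 1:
            raise ValueError("delta_psi_effect must lie in (0, 1]")
        if self.psi_noise_sd < 0:
            raise ValueError("psi_noise_sd must be >= 0")
        if self.delta_psi_effect <= 2 * self.psi_noise_sd:
            raise ValueError("delta_psi_effect must exceed 2 x psi_noise_sd")
        if min(self.n_young, self.n_old) < 2:
            raise ValueError("need >= 2 samples per group")
        if not 0 <= self.proteomic_capture_fraction <= 1:
            raise ValueError("proteomic_capture_fraction must lie in [0, 1]")
        if self.n_proteomic_decoys < 0:
            raise ValueError("n_proteomic_decoys must be >= 0")
        if self.motif_enrichment_fold < 1:
            raise ValueError("motif_enrichment_fold must be >= 1")
        if self.motif_background_rate < 0:
            raise ValueError("motif_background_rate must be >= 0")
        if self.n_utr_only_events > self.n_events_per_type.get("SE", 0):
            raise ValueError("n_utr_only_events cannot exceed the SE signal count")
        if self.n_genes < self.total_events():
            raise ValueError(
                f"n_genes={self.n_genes} cannot host {self.total_events()} events "
                "(one distinct transcript per event)"
            )
        parse_motif(self.motif_pattern)
        if self.junction_depth < 1:
            raise ValueError("junction_depth must be positive")


@dataclass
class PlantedEvent:
    """Generator-side record of one planted event (the ground truth)."""

    event_id: str
    event_type: str
    gene_id: str
    gene_symbol: str
    transcript_id: str
    chromosome: str
    strand: str
    coords: dict[str, Interval]
    true_delta_psi: float
    frame_effect: str  # preserving | disrupting | non_coding
    engineered: bool
    utr_only: bool
    inclusion_exons: list[Interval]
    exclusion_exons: list[Interval]
    cds_start: int
    cds_end: int

    @property
    def is_signal(self) -> bool:
        return self.true_delta_psi != 0.0

    @property
    def aging_favored(self) -> str:
        return "inclusion" if self.true_delta_psi > 0 else "exclusion"


@dataclass
class CohortTruth:
    """Everything the pipeline is supposed to recover."""

    planted_events: list[PlantedEvent] = field(default_factory=list)
    planted_peptides: dict[str, set[str]] = field(default_factory=dict)
    peptide_genes: dict[str, str] = field(default_factory=dict)
    captured_peptides: set[str] = field(default_factory=set)
    motif_placements: list[tuple[str, int]] = field(default_factory=list)
    background_size: int = 0

    def all_planted_peptides(self) -> set[str]:
        out: set[str] = set()
        for peps in self.planted_peptides.values():
            out |= peps
        return out

    def to_json(self) -> str:
        payload = {
            "planted_events": [
                {**asdict(ev), "coords": {k: list(v) for k, v in ev.coords.items()}}
                for ev in self.planted_events
            ],
            "planted_peptides": {k: sorted(v) for k, v in self.planted_peptides.items()},
            "peptide_genes": self.peptide_genes,
            "captured_peptides": sorted(self.captured_peptides),
            "motif_placements": self.motif_placements,
            "background_size": self.background_size,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# genome and gene models


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_dna_array(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(bytes(np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, n)]))


def generate_genome(config: SimConfig) -> dict[str, str]:
    """Uniform random chromosomes; deterministic for a fixed seed."""
    config.validate()
    rng = _rng(config, 0)
    return {
        f"chr{i + 1}": _random_dna_array(rng, config.chromosome_length).decode()
        for i in range(config.n_chromosomes)
    }


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG followed by sense codons: starts with a start, no internal stop."""
    body = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 1)]
    return "ATG" + "".join(body)


def _coding_intervals(model: TranscriptModel) -> list[Interval]:
    out = []
    for s, e in model.exons:
        a, b = max(s, model.cds_start), min(e, model.cds_end)
        if a < b:
            out.append((a, b))
    return out


def _spliced_from_exons(
    genome: Mapping[str, bytearray | str],
    chrom: str,
    strand: str,
    exons: Sequence[Interval],
    cds_start: int,
    cds_end: int,
) -> str:
    """Generator-side CDS concatenation (independent of isoform surgery)."""
    parts = []
    for s, e in sorted(exons):
        a, b = max(s, cds_start), min(e, cds_end)
        if a < b:
            chunk = genome[chrom][a:b]
            parts.append(chunk.decode() if isinstance(chunk, (bytes, bytearray)) else str(chunk))
    seq = "".join(parts).upper()
    return revcomp(seq) if strand == "-" else seq


def _write_coding(genome: dict[str, bytearray], model: TranscriptModel, cds_seq: str) -> None:
    """Distribute a coding-strand CDS across the model's coding intervals."""
    ivs = _coding_intervals(model)
    order = ivs if model.strand == "+" else ivs[::-1]
    pos = 0
    for s, e in order:
        chunk = cds_seq[pos : pos + (e - s)]
        pos += e - s
        genome[model.chromosome][s:e] = (
            chunk if model.strand == "+" else revcomp(chunk)
        ).encode()
    assert pos == len(cds_seq)


def generate_gene_models(genome: dict[str, str | bytearray], config: SimConfig) -> list[TranscriptModel]:
    """Place non-overlapping genes on alternating strands and write their CDS.

    Each transcript gets an annotated CDS that starts with ATG on the
    coding strand, has length divisible by three, and translates without
    internal stops (the coding content is written into the genome, which is
    mutated in place).  The first ``n_utr_only_events`` genes carry a 5'
    UTR spanning their first two coding-order exons, leaving one internal
    exon entirely untranslated.
    """
    config.validate()
    rng = _rng(config, 1)
    chroms = sorted(genome.keys())
    for c in chroms:
        if isinstance(genome[c], str):
            genome[c] = bytearray(genome[c].encode())
    cursors = {c: int(rng.integers(500, 1500)) for c in chroms}
    models = []
    for gi in range(config.n_genes):
        chrom = chroms[gi % len(chroms)]
        strand = "+" if gi % 2 == 0 else "-"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, n_ex)
        intron_lens = rng.integers(
            config.intron_length[0], config.intron_length[1] + 1, n_ex - 1
        )
        start = cursors[chrom]
        exons = []
        pos = start
        for i, L in enumerate(exon_lens):
            exons.append((pos, pos + int(L)))
            pos += int(L)
            if i < n_ex - 1:
                pos += int(intron_lens[i])
        if pos > len(genome[chrom]):
            raise ValueError(
                f"cannot place gene {gi} on {chrom}: ran past the chromosome end "
                "(increase chromosome_length or reduce n_genes)"
            )
        cursors[chrom] = pos + int(rng.integers(300, 900))
        utr_exons = 2 if gi < config.n_utr_only_events else 0
        coding_order = exons if strand == "+" else exons[::-1]
        keep = coding_order[utr_exons:]
        total = sum(e - s for s, e in keep)
        trim = total % 3
        if strand == "+":
            cds_start, cds_end = keep[0][0], keep[-1][1] - trim
        else:
            cds_start, cds_end = keep[-1][0] + trim, keep[0][1]
        model = TranscriptModel(
            transcript_id=f"T{gi:04d}",
            gene_id=f"G{gi:04d}",
            gene_symbol=f"GENE{gi:03d}",
            chromosome=chrom,
            strand=strand,
            exons=exons,
            cds_start=cds_start,
            cds_end=cds_end,
        )
        model.validate()
        _write_coding(genome, model, _random_cds(rng, (total - trim) // 3))
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# event planting


def _frame_effect(length_delta: int) -> str:
    return "preserving" if length_delta % 3 == 0 else "disrupting"


def _novel_set(
    genome,
    planted: PlantedEvent,
    exclude: set[str],
) -> set[str]:
    """9-mers unique to the aging-favored form vs the young form + library."""
    inc = _spliced_from_exons(
        genome, planted.chromosome, planted.strand, planted.inclusion_exons,
        planted.cds_start, planted.cds_end,
    )
    exc = _spliced_from_exons(
        genome, planted.chromosome, planted.strand, planted.exclusion_exons,
        planted.cds_start, planted.cds_end,
    )
    aging_cds, young_cds = (inc, exc) if planted.aging_favored == "inclusion" else (exc, inc)
    aging = {r.sequence for r in kmerize(translate(aging_cds))}
    young = {r.sequence for r in kmerize(translate(young_cds))}
    return aging - young - exclude


def _engineer(
    genome: dict[str, bytearray],
    region: Interval,
    chrom: str,
    rng: np.random.Generator,
    planted: PlantedEvent,
    ref_kmers: set[str],
    max_attempts: int = 1000,
) -> None:
    """Rejection-sample region content until >=1 novel 9-mer is guaranteed."""
    s, e = region
    for _ in range(max_attempts):
        genome[chrom][s:e] = bytes(_random_dna_array(rng, e - s))
        if _novel_set(genome, planted, ref_kmers):
            return
    raise RuntimeError(
        f"{planted.event_id}: could not engineer a library-disjoint insert "
        f"in {max_attempts} attempts"
    )


def _signal_signs(n: int, start_positive: bool) -> list[int]:
    return [(1 if (i % 2 == 0) == start_positive else -1) for i in range(n)]


def plant_events(
    models: Sequence[TranscriptModel],
    genome: dict[str, str | bytearray],
    config: SimConfig,
) -> tuple[list[ASEvent], CohortTruth]:
    """Plant signal and null events of all five types on distinct transcripts.

    Signal events carry a true deltaPSI of ±delta_psi_effect (signs
    alternate within each type so that both directions occur); null events
    carry zero.  The genome is mutated where an event needs engineered
    content: MXE alternative exons and retained-intron junctions of the
    peptide-bearing subset (down-regulated MXE, up-regulated RI) are
    rejection-sampled until they contribute at least one novel 9-mer.
    The first SE signal events are placed on UTR exons of the reserved
    genes and alter no coding sequence.
    """
    config.validate()
    rng = _rng(config, 2)
    for c in list(genome):
        if isinstance(genome[c], str):
            genome[c] = bytearray(genome[c].encode())

    ref_kmers: set[str] = set()
    for m in models:
        cds = _spliced_from_exons(genome, m.chromosome, m.strand, m.exons, m.cds_start, m.cds_end)
        ref_kmers |= {r.sequence for r in kmerize(translate(cds))}

    truth = CohortTruth()
    events: list[ASEvent] = []
    gene_cursor = config.n_utr_only_events  # reserved UTR genes come first
    utr_pool = list(range(config.n_utr_only_events))

    def next_model() -> TranscriptModel:
        nonlocal gene_cursor
        if gene_cursor >= len(models):
            raise ValueError("not enough transcripts with internal exons for all events")
        m = models[gene_cursor]
        gene_cursor += 1
        return m

    for etype in EVENT_TYPES:
        n_sig = config.n_events_per_type.get(etype, 0)
        n_null = config.n_null_events_per_type.get(etype, 0)
        signs = _signal_signs(n_sig, start_positive=etype in ("SE", "RI", "A5SS"))
        for j in range(n_sig + n_null):
            is_signal = j < n_sig
            utr_only = etype == "SE" and is_signal and j < config.n_utr_only_events
            if utr_only:
                m = models[utr_pool.pop(0)]
            else:
                m = next_model()
            delta = signs[j] * config.delta_psi_effect if is_signal else 0.0
            tag = "sig" if is_signal else "null"
            event_id = f"{etype}-{tag}-{j:03d}"
            planted = _plant_one(
                etype, m, genome, rng, event_id, delta, utr_only, ref_kmers, config
            )
            truth.planted_events.append(planted)
            events.append(
                ASEvent(
                    event_id=planted.event_id,
                    event_type=etype,
                    gene_id=m.gene_id,
                    gene_symbol=m.gene_symbol,
                    chromosome=m.chromosome,
                    strand=m.strand,
                    coords=dict(planted.coords),
                )
            )
    for ev in events:
        ev.validate()
    return events, truth


def _coding_index(model: TranscriptModel, coding_idx: int) -> int:
    """Genomic exon index of the coding-order exon ``coding_idx``."""
    n = len(model.exons)
    return coding_idx if model.strand == "+" else n - 1 - coding_idx


def _plant_one(
    etype: str,
    m: TranscriptModel,
    genome: dict[str, bytearray],
    rng: np.random.Generator,
    event_id: str,
    delta: float,
    utr_only: bool,
    ref_kmers: set[str],
    config: SimConfig,
) -> PlantedEvent:
    exons = m.exons
    n = len(exons)
    aging_is_inclusion = delta > 0

    if etype == "SE":
        k = _coding_index(m, 1) if utr_only else int(rng.integers(2, n - 2))
        coords = {
            "exon": exons[k],
            "upstream": exons[k - 1],
            "downstream": exons[k + 1],
        }
        inclusion, exclusion = list(exons), exons[:k] + exons[k + 1 :]
        frame = "non_coding" if utr_only else _frame_effect(exons[k][1] - exons[k][0])
        engineered = False
    elif etype == "MXE":
        k = int(rng.integers(2, n - 2))
        x1 = exons[k]
        intron = (exons[k][1], exons[k + 1][0])
        engineered = delta < 0  # aging-favored exclusion form carries exon2
        len1 = x1[1] - x1[0]
        max_len = (intron[1] - intron[0]) - 120
        if engineered:
            len2 = min(len1, max_len)
            len2 -= (len2 - len1) % 3  # frame-preserving exchange
        else:
            len2 = min(int(rng.integers(*config.exon_length)), max_len)
        x2 = (intron[0] + 60, intron[0] + 60 + len2)
        coords = {
            "exon1": x1,
            "exon2": x2,
            "upstream": exons[k - 1],
            "downstream": exons[k + 1],
        }
        inclusion = list(exons)
        exclusion = exons[:k] + [x2] + exons[k + 1 :]
        frame = _frame_effect(len1 - len2)
    elif etype in ("A5SS", "A3SS"):
        # variable exon sits coding-upstream (A5SS) or coding-downstream
        # (A3SS) of the affected junction
        cj = int(rng.integers(1, n - 2)) if etype == "A5SS" else int(rng.integers(2, n - 1))
        k = _coding_index(m, cj)
        v = exons[k]
        flank = _coding_index(m, cj + 1) if etype == "A5SS" else _coding_index(m, cj - 1)
        d = int(3 * rng.integers(3, 12))
        if rng.integers(0, 2):  # every other event disrupts the frame
            d += 1
        d = min(d, (v[1] - v[0]) - 15)
        donor_side_right = (m.strand == "+") == (etype == "A5SS")
        short = (v[0], v[1] - d) if donor_side_right else (v[0] + d, v[1])
        coords = {"long_exon": v, "short_exon": short, "flanking": exons[flank]}
        inclusion = list(exons)
        exclusion = exons[:k] + [short] + exons[k + 1 :]
        frame = _frame_effect(d)
        engineered = False
    elif etype == "RI":
        k = int(rng.integers(1, n - 2))
        up, dn = exons[k], exons[k + 1]
        ri = (up[0], dn[1])
        coords = {"ri_exon": ri, "upstream": up, "downstream": dn}
        inclusion = exons[:k] + [ri] + exons[k + 2 :]
        exclusion = list(exons)
        frame = _frame_effect(dn[0] - up[1])
        engineered = delta > 0  # aging-favored inclusion retains the intron
    else:  # pragma: no cover
        raise ValueError(etype)

    planted = PlantedEvent(
        event_id=event_id,
        event_type=etype,
        gene_id=m.gene_id,
        gene_symbol=m.gene_symbol,
        transcript_id=m.transcript_id,
        chromosome=m.chromosome,
        strand=m.strand,
        coords=coords,
        true_delta_psi=delta,
        frame_effect=frame,
        engineered=engineered,
        utr_only=utr_only,
        inclusion_exons=sorted(inclusion),
        exclusion_exons=sorted(exclusion),
        cds_start=m.cds_start,
        cds_end=m.cds_end,
    )
    if engineered and etype == "MXE":
        _engineer(genome, planted.coords["exon2"], m.chromosome, rng, planted, ref_kmers)
    elif engineered and etype == "RI":
        up = planted.coords["upstream"]
        dn = planted.coords["downstream"]
        if m.strand == "+":
            region = (up[1], min(up[1] + 36, dn[0]))
        else:
            region = (max(up[1], dn[0] - 36), dn[0])
        _engineer(genome, region, m.chromosome, rng, planted, ref_kmers)
    return planted


# ---------------------------------------------------------------------------
# PSI, counts, expression


def sample_names(config: SimConfig) -> tuple[list[str], list[str]]:
    old = [f"old_{i:03d}" for i in range(config.n_old)]
    young = [f"young_{i:03d}" for i in range(config.n_young)]
    return old, young


def simulate_psi_and_counts(
    events: Sequence[ASEvent], truth: CohortTruth, config: SimConfig
) -> pd.DataFrame:
    """Fill per-sample PSI and junction counts on the events, in place.

    Per sample, PSI = clamp(group mean + Normal(0, sd), 0, 1) where the
    group means sit ±(true deltaPSI)/2 around a random base level.
    Inclusion counts are binomial at the configured junction depth, so
    count-derived PSI matches the simulated PSI in expectation.  Returns
    the events x samples PSI matrix; PValue/FDR stay as placeholders for
    :func:`asneo.events.attach_significance`.
    """
    rng = _rng(config, 3)
    by_id = {p.event_id: p for p in truth.planted_events}
    old, young = sample_names(config)
    rows = {}
    for ev in events:
        delta = by_id[ev.event_id].true_delta_psi
        half = abs(delta) / 2
        base = rng.uniform(0.15 + half, 0.85 - half)
        mean_old = base + delta / 2
        mean_young = base - delta / 2
        psi_old = np.clip(rng.normal(mean_old, config.psi_noise_sd, config.n_old), 0, 1)
        psi_young = np.clip(rng.normal(mean_young, config.psi_noise_sd, config.n_young), 0, 1)
        ev.psi_group1 = [float(x) for x in psi_old]
        ev.psi_group2 = [float(x) for x in psi_young]
        depth = config.junction_depth
        ev.ijc_group1 = [int(rng.binomial(depth, p)) for p in psi_old]
        ev.sjc_group1 = [depth - i for i in ev.ijc_group1]
        ev.ijc_group2 = [int(rng.binomial(depth, p)) for p in psi_young]
        ev.sjc_group2 = [depth - i for i in ev.ijc_group2]
        ev.inc_form_length = depth
        ev.skip_form_length = depth
        rows[ev.event_id] = list(psi_old) + list(psi_young)
    return pd.DataFrame.from_dict(rows, orient="index", columns=old + young)


def simulate_expression(
    models: Sequence[TranscriptModel], config: SimConfig
) -> pd.DataFrame:
    """Gene x sample expression matrix (log2 scale, PSI-independent noise)."""
    rng = _rng(config, 4)
    old, young = sample_names(config)
    samples = old + young
    data = {}
    for m in models:
        baseline = rng.uniform(3, 10)
        data[m.gene_id] = baseline + rng.normal(0, 1, len(samples))
    return pd.DataFrame.from_dict(data, orient="index", columns=samples)


# ---------------------------------------------------------------------------
# background library and truth peptides


def build_background_library(
    models: Sequence[TranscriptModel],
    genome,
    truth: CohortTruth | None = None,
) -> PeptideLibrary:
    """9-mer library of the normal (young / middle-aged) proteome.

    Contains every unmodified transcript's translated CDS plus, when truth
    is given, the young-favored isoform of every signal event and both
    forms of every null event (a null event has no favored direction: the
    young cohort expresses both isoforms).
    """
    members: set[str] = set()

    def add(cds: str) -> None:
        members.update(r.sequence for r in kmerize(translate(cds)))

    for m in models:
        add(_spliced_from_exons(genome, m.chromosome, m.strand, m.exons, m.cds_start, m.cds_end))
    if truth is not None:
        for p in truth.planted_events:
            forms = []
            if p.is_signal:
                forms.append(p.exclusion_exons if p.aging_favored == "inclusion" else p.inclusion_exons)
            else:
                forms.extend([p.inclusion_exons, p.exclusion_exons])
            for exon_list in forms:
                add(
                    _spliced_from_exons(
                        genome, p.chromosome, p.strand, exon_list, p.cds_start, p.cds_end
                    )
                )
    return PeptideLibrary(
        name="background",
        members=members,
        provenance=f"{len(models)} reference transcripts + young-favored event isoforms",
    )


def record_planted_peptides(
    truth: CohortTruth, genome, library: PeptideLibrary
) -> None:
    """Fill truth.planted_peptides from the final genome and library."""
    truth.background_size = len(library.members)
    truth.planted_peptides = {}
    truth.peptide_genes = {}
    for p in truth.planted_events:
        if not p.is_signal:
            continue
        novel = _novel_set(genome, p, library.members)
        truth.planted_peptides[p.event_id] = novel
        for pep in novel:
            truth.peptide_genes.setdefault(pep, p.gene_symbol)


# ---------------------------------------------------------------------------
# HLA genotypes and proteomic capture


def _round_half_down(x: float) -> int:
    return int(math.ceil(x - 0.5))


def simulate_hla_and_proteomics(
    truth: CohortTruth, config: SimConfig
) -> tuple[list[HLAGenotype], list[tuple[str, str]]]:
    """Assign class-I genotypes to old individuals and emit a proteomic list.

    Each old individual draws two alleles per locus from the configured toy
    pool.  The observed proteomic list contains a
    ``proteomic_capture_fraction`` of the distinct planted peptides (ties
    rounded down), labelled with their source gene, plus
    ``n_proteomic_decoys`` random 9-mers absent from the planted set and
    labelled with random gene symbols.
    """
    rng = _rng(config, 5)
    old, _ = sample_names(config)
    genotypes = []
    for sample in old:
        alleles = []
        for locus in ("A", "B", "C"):
            pool = config.allele_pool[locus]
            names = [a for a, _ in pool]
            freqs = np.array([f for _, f in pool], dtype=float)
            freqs /= freqs.sum()
            alleles.extend(str(a) for a in rng.choice(names, size=2, p=freqs))
        genotypes.append(HLAGenotype(sample_id=sample, alleles=alleles))

    planted = sorted(truth.all_planted_peptides())
    n_capture = _round_half_down(config.proteomic_capture_fraction * len(planted))
    captured = (
        sorted(str(x) for x in rng.choice(planted, size=n_capture, replace=False))
        if n_capture
        else []
    )
    truth.captured_peptides = set(captured)
    observed = [(pep, truth.peptide_genes[pep]) for pep in captured]
    planted_set = set(planted)
    gene_symbols = sorted({p.gene_symbol for p in truth.planted_events}) or ["GENE000"]
    aa = np.array(list(AMINO_ACIDS))
    made = 0
    while made < config.n_proteomic_decoys:
        pep = "".join(aa[rng.integers(0, len(aa), 9)])
        if pep in planted_set:
            continue
        observed.append((pep, gene_symbols[int(rng.integers(0, len(gene_symbols)))]))
        made += 1
    order = rng.permutation(len(observed))
    return genotypes, [observed[i] for i in order]


# ---------------------------------------------------------------------------
# motif planting


def plant_motif_flanks(
    events: Sequence[ASEvent], genome, truth: CohortTruth, config: SimConfig
) -> None:
    """Write motif instances into SE events' coding-upstream intron flanks.

    Every SE event's flank receives a Poisson(background rate) number of
    concrete motif realizations; up-regulated SE signal events receive
    Poisson(fold x rate) instead, creating the planted positional
    enrichment.  Placements never cross the flank boundary and are recorded
    in the truth.  The flank slot is chosen so that its sequence is part of
    no isoform (SE introns are never retained), keeping motif planting
    independent of peptide truth.
    """
    rng = _rng(config, 6)
    pattern = parse_motif(config.motif_pattern)
    by_id = {p.event_id: p for p in truth.planted_events}
    for c in list(genome):
        if isinstance(genome[c], str):
            genome[c] = bytearray(genome[c].encode())
    for ev in events:
        if ev.event_type != "SE":
            continue
        planted = by_id[ev.event_id]
        rate = config.motif_background_rate
        if planted.is_signal and planted.true_delta_psi > 0:
            rate *= config.motif_enrichment_fold
        (s, e), _ = slot_interval(ev, "upstream_intron_3p")
        flank_len = e - s
        if flank_len < pattern.length:
            raise ValueError(f"{ev.event_id}: flank shorter than the motif")
        n_place = int(rng.poisson(rate))
        for _ in range(n_place):
            off = int(rng.integers(0, flank_len - pattern.length + 1))
            word = realize_motif(pattern, rng)
            if ev.strand == "+":
                gs = s + off
                genome[ev.chromosome][gs : gs + pattern.length] = word.encode()
            else:
                ge = e - off
                genome[ev.chromosome][ge - pattern.length : ge] = revcomp(word).encode()
            truth.motif_placements.append((f"{ev.event_id}:upstream_intron_3p", off))


# ---------------------------------------------------------------------------
# orchestration and writers


@dataclass
class SyntheticCohort:
    """Everything one simulation run produced, in memory."""

    config: SimConfig
    genome: dict[str, str]
    models: list[TranscriptModel]
    events: list[ASEvent]
    truth: CohortTruth
    psi_matrix: pd.DataFrame
    expression: pd.DataFrame
    library: PeptideLibrary
    genotypes: list[HLAGenotype]
    proteomics: list[tuple[str, str]]

    @property
    def sample_groups(self) -> dict[str, str]:
        old, young = sample_names(self.config)
        return {**{s: "group1" for s in old}, **{s: "group2" for s in young}}


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Run every generation stage in order and return the full cohort."""
    config.validate()
    genome: dict = generate_genome(config)
    models = generate_gene_models(genome, config)
    events, truth = plant_events(models, genome, config)
    plant_motif_flanks(events, genome, truth, config)
    psi = simulate_psi_and_counts(events, truth, config)
    expression = simulate_expression(models, config)
    library = build_background_library(models, genome, truth)
    record_planted_peptides(truth, genome, library)
    genotypes, proteomics = simulate_hla_and_proteomics(truth, config)
    genome_str = {c: bytes(b).decode() if not isinstance(b, str) else b for c, b in genome.items()}
    return SyntheticCohort(
        config=config,
        genome=genome_str,
        models=models,
        events=events,
        truth=truth,
        psi_matrix=psi,
        expression=expression,
        library=library,
        genotypes=genotypes,
        proteomics=proteomics,
    )


def write_fasta(genome: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = str(genome[chrom])
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write every cohort artifact to ``outdir``; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    write_fasta(cohort.genome, p("genome.fa"))
    write_gtf(cohort.models, p("annotation.gtf"))
    by_type: dict[str, list[ASEvent]] = {}
    for ev in cohort.events:
        by_type.setdefault(ev.event_type, []).append(ev)
    for etype, evs in by_type.items():
        write_rmats_jc(evs, os.path.join(outdir, f"{etype}.MATS.JC.txt"), etype)
        paths[f"{etype}.MATS.JC.txt"] = os.path.join(outdir, f"{etype}.MATS.JC.txt")
    cohort.psi_matrix.to_csv(p("psi_matrix.tsv"), sep="\t")
    cohort.expression.to_csv(p("expression_matrix.tsv"), sep="\t")
    with open(p("background_library.txt"), "w") as fh:
        for pep in sorted(cohort.library.members):
            fh.write(pep + "\n")
    write_genotypes(cohort.genotypes, p("hla_genotypes.tsv"))
    pd.DataFrame(cohort.proteomics, columns=["peptide", "gene_symbol"]).to_csv(
        p("proteomics.tsv"), sep="\t", index=False
    )
    with open(p("truth.json"), "w") as fh:
        fh.write(cohort.truth.to_json())
    return paths
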