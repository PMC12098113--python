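"""RNA-binding-protein motif maps around splicing events.

Reimplements the motif-map analysis: extract the exonic/intronic flank
slots around each event's regulated exon(s) (250 bp intronic, 50 bp exonic
by default), compute sliding-window motif-nucleotide coverage density for
degenerate motifs such as the RBMS3 motif ``[ACT]ATATA``, and compare the
positional density of significantly up- or down-regulated events against a
non-significant background with a per-offset rank-sum test (a permutation
test is available as an option).  Raw positional p curves are reported
without multiple-testing correction, matching motif-map tool convention.

All flank sequences are reported 5'→3' on the event's coding strand; slot
names use coding-orientation "upstream"/"downstream".
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._dna import fetch, revcomp
from .events import ASEvent

Interval = tuple[int, int]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class MotifPattern:
    """A degenerate DNA motif as per-position allowed-character sets."""

    pattern: str
    sets: list[frozenset[str]]

    @property
    def length(self) -> int:
        return len(self.sets)


def parse_motif(pattern: str) -> MotifPattern:
    """Parse bracket notation ("[ACT]ATATA") or plain IUPAC codes."""
    sets: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i].upper()
        if ch == "[":
            j = pattern.find("]", i)
            if j < 0:
                raise ValueError(f"unclosed bracket in motif {pattern!r}")
            chars = pattern[i + 1 : j].upper()
            if not chars or not set(chars) <= set("ACGT"):
                raise ValueError(f"bad bracket content in motif {pattern!r}")
            sets.append(frozenset(chars))
            i = j + 1
        elif ch in _IUPAC:
            sets.append(frozenset(_IUPAC[ch]))
            i += 1
        else:
            raise ValueError(f"bad character {ch!r} in motif {pattern!r}")
    if len(sets) < 4:
        raise ValueError(f"motif {pattern!r} shorter than 4 positions")
    return MotifPattern(pattern=pattern, sets=sets)


def realize_motif(pattern: MotifPattern, rng: np.random.Generator) -> str:
    """One concrete expansion, drawn uniformly per degenerate position."""
    return "".join(sorted(s)[rng.integers(0, len(s))] for s in pattern.sets)


def motif_coverage(sequence: str, pattern: MotifPattern) -> np.ndarray:
    """Boolean vector marking every base under >=1 (possibly overlapping) match."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    m = pattern.length
    cov = np.zeros(len(seq), dtype=bool)
    for i in range(len(seq) - m + 1):
        if all(seq[i + j] in pattern.sets[j] for j in range(m)):
            cov[i : i + m] = True
    return cov


# ---------------------------------------------------------------------------
# flank-slot geometry


def _edge(iv: Interval, coding_side: str, strand: str, length: int) -> Interval:
    """``length`` bp at the coding 5' or 3' end of a genomic interval."""
    s, e = iv
    left = (coding_side == "5p") == (strand == "+")
    return (s, min(e, s + length)) if left else (max(s, e - length), e)


def event_flank_regions(
    event: ASEvent, intron_len: int = 250, exon_len: int = 50
) -> list[tuple[str, str, Interval]]:
    """Flank slots of one event: (slot_name, kind, genomic interval).

    Slot names are in coding orientation.  Intronic slots are clipped to
    their intron and exonic slots to their exon, so a returned interval may
    be shorter than nominal.
    """
    c, st = event.coords, event.strand
    out: list[tuple[str, str, Interval]] = []

    def exon_slot(name, iv, side):
        out.append((name, "exon", _edge(iv, side, st, exon_len)))

    def intron_slot(name, iv, side):
        out.append((name, "intron", _edge(iv, side, st, intron_len)))

    if event.event_type == "SE":
        up, tgt, dn = c["upstream"], c["exon"], c["downstream"]
        i_left, i_right = (up[1], tgt[0]), (tgt[1], dn[0])
        cod_up, cod_dn = (up, dn) if st == "+" else (dn, up)
        i1, i2 = (i_left, i_right) if st == "+" else (i_right, i_left)
        exon_slot("upstream_exon_3p", cod_up, "3p")
        intron_slot("upstream_intron_5p", i1, "5p")
        intron_slot("upstream_intron_3p", i1, "3p")
        exon_slot("target_exon_5p", tgt, "5p")
        exon_slot("target_exon_3p", tgt, "3p")
        intron_slot("downstream_intron_5p", i2, "5p")
        intron_slot("downstream_intron_3p", i2, "3p")
        exon_slot("downstream_exon_5p", cod_dn, "5p")
    elif event.event_type == "MXE":
        up, x1, x2, dn = c["upstream"], c["exon1"], c["exon2"], c["downstream"]
        i0, i1, i2 = (up[1], x1[0]), (x1[1], x2[0]), (x2[1], dn[0])
        cod_up, cod_dn = (up, dn) if st == "+" else (dn, up)
        exon_slot("upstream_exon_3p", cod_up, "3p")
        for label, x, iv_up, iv_dn in (
            ("exon1", x1, i0 if st == "+" else i1, i1 if st == "+" else i0),
            ("exon2", x2, i1 if st == "+" else i2, i2 if st == "+" else i1),
        ):
            intron_slot(f"{label}_upstream_intron_3p", iv_up, "3p")
            exon_slot(f"{label}_5p", x, "5p")
            exon_slot(f"{label}_3p", x, "3p")
            intron_slot(f"{label}_downstream_intron_5p", iv_dn, "5p")
        exon_slot("downstream_exon_5p", cod_dn, "5p")
    elif event.event_type in ("A5SS", "A3SS"):
        lo, sh, fl = c["long_exon"], c["short_exon"], c["flanking"]
        # the alternative intron of the short form lies between the short
        # exon's variable boundary and the flanking exon
        if fl[0] >= lo[1]:
            intron = (sh[1], fl[0])
        else:
            intron = (fl[1], sh[0])
        flank_is_coding_downstream = event.event_type == "A5SS"
        exon_slot("target_exon_5p", lo, "5p")
        exon_slot("target_exon_3p", lo, "3p")
        intron_slot("intron_5p", intron, "5p")
        intron_slot("intron_3p", intron, "3p")
        if flank_is_coding_downstream:
            exon_slot("downstream_exon_5p", fl, "5p")
        else:
            exon_slot("upstream_exon_3p", fl, "3p")
    elif event.event_type == "RI":
        up, dn = c["upstream"], c["downstream"]
        intron = (up[1], dn[0])
        cod_up, cod_dn = (up, dn) if st == "+" else (dn, up)
        exon_slot("upstream_exon_3p", cod_up, "3p")
        intron_slot("intron_5p", intron, "5p")
        intron_slot("intron_3p", intron, "3p")
        exon_slot("downstream_exon_5p", cod_dn, "5p")
    else:  # pragma: no cover
        raise ValueError(f"unknown event type {event.event_type!r}")
    return out


def slot_interval(
    event: ASEvent, slot: str, intron_len: int = 250, exon_len: int = 50
) -> tuple[Interval, str]:
    """Genomic interval and kind of one named flank slot of an event."""
    for name, kind, iv in event_flank_regions(event, intron_len, exon_len):
        if name == slot:
            return iv, kind
    raise KeyError(f"{event.event_type} events have no slot {slot!r}")


@dataclass
class Region:
    """One extracted flank sequence (coding strand, 5'→3')."""

    event_id: str
    region_id: str
    sequence: str
    clipped: bool = False


@dataclass
class RegionSet:
    label: str  # up | down | background
    event_type: str
    slot: str
    kind: str  # exon | intron
    regions: list[Region] = field(default_factory=list)


def extract_flanks(
    events: Iterable[ASEvent],
    genome,
    intron_len: int = 250,
    exon_len: int = 50,
    fdr_max: float = 0.05,
    min_abs_dpsi: float = 0.1,
) -> list[RegionSet]:
    """Extract every flank slot of every event, partitioned by direction.

    Events are split into ``up`` (significant, deltaPSI > threshold),
    ``down`` (significant, deltaPSI < −threshold) and ``background``
    (everything else).  Regions shorter than nominal (clipped by a
    neighboring exon or the chromosome end) are flagged; zero-length
    regions are dropped.
    """
    sets: dict[tuple[str, str, str], RegionSet] = {}
    for ev in events:
        significant = (
            not math.isnan(ev.fdr) and ev.fdr < fdr_max and abs(ev.delta_psi) > min_abs_dpsi
        )
        label = ("up" if ev.delta_psi > 0 else "down") if significant else "background"
        chrom_len = len(genome[ev.chromosome])
        for slot, kind, (s, e) in event_flank_regions(ev, intron_len, exon_len):
            nominal = intron_len if kind == "intron" else exon_len
            cs, ce = max(0, s), min(e, chrom_len)
            if cs >= ce:
                continue
            seq = fetch(genome, ev.chromosome, cs, ce)
            if ev.strand == "-":
                seq = revcomp(seq)
            key = (label, ev.event_type, slot)
            if key not in sets:
                sets[key] = RegionSet(label=label, event_type=ev.event_type, slot=slot, kind=kind)
            sets[key].regions.append(
                Region(
                    event_id=ev.event_id,
                    region_id=f"{ev.event_id}:{slot}",
                    sequence=seq,
                    clipped=len(seq) < nominal,
                )
            )
    return list(sets.values())


@dataclass
class DensityProfile:
    """Across-region mean windowed motif coverage by position."""

    offsets: np.ndarray
    mean_density: np.ndarray
    n_regions: int


def _window_densities(sequence: str, pattern: MotifPattern, window: int) -> np.ndarray:
    cov = motif_coverage(sequence, pattern).astype(float)
    if len(cov) < window:
        return np.empty(0)
    return np.convolve(cov, np.ones(window), mode="valid") / window


def density_profile(
    regions: RegionSet | Sequence[Region], pattern: MotifPattern, window: int = 50
) -> DensityProfile:
    """Positional motif-coverage density averaged across regions.

    Each region contributes its windowed coverage means at the offsets it
    covers (offset 0 = the region's coding-strand start); shorter/clipped
    regions simply cover fewer offsets.
    """
    region_list = regions.regions if isinstance(regions, RegionSet) else list(regions)
    if not region_list:
        raise ValueError("no regions")
    per_region = [_window_densities(r.sequence, pattern, window) for r in region_list]
    max_len = max(len(d) for d in per_region)
    if max_len == 0:
        raise ValueError(f"all regions shorter than the {window} bp window")
    total = np.zeros(max_len)
    count = np.zeros(max_len)
    for d in per_region:
        total[: len(d)] += d
        count[: len(d)] += 1
    return DensityProfile(
        offsets=np.arange(max_len),
        mean_density=total / np.maximum(count, 1),
        n_regions=len(region_list),
    )


def compare_profiles(
    target: RegionSet | Sequence[Region],
    background: RegionSet | Sequence[Region],
    pattern: MotifPattern,
    window: int = 50,
    method: str = "ranksum",
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-offset density curves with positional significance.

    At each offset the per-region windowed densities of the target set are
    compared with the background set by a two-sided rank-sum test (or a
    label-permutation test on the mean difference with
    ``method="permutation"``).  Offsets with fewer than two covering
    regions on either side get a missing p-value.
    """
    if method not in ("ranksum", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    t_regions = target.regions if isinstance(target, RegionSet) else list(target)
    b_regions = background.regions if isinstance(background, RegionSet) else list(background)
    if not t_regions or not b_regions:
        raise ValueError("both region sets must be non-empty")
    t_dens = [_window_densities(r.sequence, pattern, window) for r in t_regions]
    b_dens = [_window_densities(r.sequence, pattern, window) for r in b_regions]
    n_offsets = max(max(len(d) for d in t_dens), max(len(d) for d in b_dens))
    if n_offsets == 0:
        raise ValueError(f"all regions shorter than the {window} bp window")
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for off in range(n_offsets):
        tv = np.array([d[off] for d in t_dens if len(d) > off])
        bv = np.array([d[off] for d in b_dens if len(d) > off])
        p = np.nan
        if len(tv) >= 2 and len(bv) >= 2:
            if np.all(tv == tv[0]) and np.all(bv == tv[0]):
                p = 1.0
            elif method == "ranksum":
                p = float(stats.ranksums(tv, bv).pvalue)
            else:
                observed = abs(tv.mean() - bv.mean())
                pooled = np.concatenate([tv, bv])
                hits = 0
                for _ in range(n_permutations):
                    perm = rng.permutation(pooled)
                    if abs(perm[: len(tv)].mean() - perm[len(tv) :].mean()) >= observed - 1e-12:
                        hits += 1
                p = (hits + 1) / (n_permutations + 1)
        rows.append(
            {
                "offset": off,
                "density_target": tv.mean() if len(tv) else np.nan,
                "density_background": bv.mean() if len(bv) else np.nan,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
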