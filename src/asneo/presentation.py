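"""MHC class-I presentation scoring and cohort aggregation.

Candidate 9-mers are scored against each individual's HLA class-I alleles
through a pluggable percentile-rank predictor; peptides ranking below the
5% threshold (strict) are called binders.  Cohort statistics mirror the
population-level read-outs of a presentation screen: distinct bound
peptides per allele, allele detection rates, per-individual presented
sets, peptide prevalence across individuals, and the set of peptides
shared by every individual.

Because percentile-rank predictors such as NetMHCpan are license-restricted
and non-redistributable, the external predictor here is an offline table
adapter over saved predictor output; a deterministic hash-based mock (rank
uniform on (0, 100]) backs fully self-contained runs and tests.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

import pandas as pd

from .peptides import PeptideRecord

_ALLELE_RE = re.compile(r"^HLA-([ABC])(\d{2}):(\d{2,3})$")


def allele_locus(allele: str) -> str:
    """Locus letter (A/B/C) of an ``HLA-<locus><group>:<protein>`` name."""
    m = _ALLELE_RE.match(allele)
    if not m:
        raise ValueError(f"unparseable HLA class-I allele name: {allele!r}")
    return m.group(1)


@dataclass
class HLAGenotype:
    """Up to six class-I alleles of one individual (duplicates = homozygous)."""

    sample_id: str
    alleles: list[str]

    def validate(self) -> None:
        if not 1 <= len(self.alleles) <= 6:
            raise ValueError(f"{self.sample_id}: expected 1-6 alleles, got {len(self.alleles)}")
        for a in self.alleles:
            allele_locus(a)


@dataclass
class BindingCall:
    peptide: str
    allele: str
    rank_percent: float
    is_binder: bool


class RankPredictor(Protocol):  # pragma: no cover - structural type only
    def rank(self, peptide: str, allele: str) -> float: ...


class MockRankPredictor:
    """Deterministic stand-in predictor: rank = uniform hash of the pair.

    A keyed BLAKE2b digest of ``peptide|allele`` is mapped uniformly onto
    (0, 100], so ranks are stable across runs and platforms without any
    seed file, and the expected binder fraction at threshold t is t/100.
    """

    def __init__(self, key: str = "asneo-mock"):
        self._key = key.encode()

    def rank(self, peptide: str, allele: str) -> float:
        digest = hashlib.blake2b(
            f"{peptide}|{allele}".encode(), key=self._key, digest_size=8
        ).digest()
        n = int.from_bytes(digest, "big")
        return (n % 10**8 + 1) / 10**8 * 100.0


class UnscoredPairError(KeyError):
    """A (peptide, allele) pair is absent from the external rank table."""


class TableRankPredictor:
    """Adapter over a saved NetMHCpan-style output table.

    Accepts a DataFrame or TSV path with peptide and allele columns plus a
    percentile-rank column (``%Rank_EL`` / ``EL_Rank`` / ``%Rank`` /
    ``rank``, covering both the v4.0 and v4.1 header dialects).  Missing
    pairs raise :class:`UnscoredPairError` — there is no silent default.
    """

    _RANK_COLUMNS = ("%Rank_EL", "EL_Rank", "%Rank", "Rank", "rank", "rank_percent")
    _PEPTIDE_COLUMNS = ("Peptide", "peptide")
    _ALLELE_COLUMNS = ("MHC", "HLA", "allele", "Allele")

    def __init__(self, table: pd.DataFrame | str):
        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(table, sep="\t")
        pep_col = next((c for c in self._PEPTIDE_COLUMNS if c in table.columns), None)
        all_col = next((c for c in self._ALLELE_COLUMNS if c in table.columns), None)
        rank_col = next((c for c in self._RANK_COLUMNS if c in table.columns), None)
        if pep_col is None or all_col is None or rank_col is None:
            raise ValueError(
                "rank table needs peptide, allele and percentile-rank columns; "
                f"got {list(table.columns)}"
            )
        self._ranks = {
            (row[pep_col], row[all_col]): float(row[rank_col])
            for _, row in table.iterrows()
        }

    def rank(self, peptide: str, allele: str) -> float:
        try:
            return self._ranks[(peptide, allele)]
        except KeyError:
            raise UnscoredPairError(f"unscored pair: ({peptide}, {allele})") from None


def predict_rank(peptide: str, allele: str, predictor: RankPredictor) -> float:
    """Percentile rank of a peptide on an allele (smaller = stronger)."""
    if len(peptide) != 9:
        raise ValueError(f"expected a 9-mer, got {peptide!r}")
    allele_locus(allele)
    return predictor.rank(peptide, allele)


def filter_binders(
    candidates: Sequence[PeptideRecord | str],
    genotypes: Sequence[HLAGenotype],
    predictor: RankPredictor,
    threshold_percent: float = 5.0,
) -> list[BindingCall]:
    """Score every candidate against every distinct cohort allele.

    Returns the binder calls only: rank strictly below the threshold (a
    rank of exactly 5.00 at the default cut is NOT a binder).
    """
    alleles = sorted({a for g in genotypes for a in g.alleles})
    peptides = []
    seen = set()
    for cand in candidates:
        pep = cand if isinstance(cand, str) else cand.sequence
        if pep not in seen:
            seen.add(pep)
            peptides.append(pep)
    calls = []
    for pep in peptides:
        for allele in alleles:
            rank = predict_rank(pep, allele, predictor)
            if rank < threshold_percent:
                calls.append(BindingCall(pep, allele, rank, True))
    return calls


@dataclass
class CohortPresentation:
    """Cohort-level presentation summary.

    ``per_allele`` maps allele -> (distinct bound peptides, carrier
    fraction, allele frequency).  The detection rate is reported both as
    carriers / cohort size and as allele copies / (2 x cohort size),
    because published per-allele "detection rates" are ambiguous between
    the two denominators.
    """

    cohort_size: int
    per_allele: dict[str, tuple[int, float, float]] = field(default_factory=dict)
    per_individual: dict[str, set[str]] = field(default_factory=dict)
    per_peptide_prevalence: dict[str, int] = field(default_factory=dict)
    shared_in_all: set[str] = field(default_factory=set)
    locus_counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)


def summarize_cohort(
    calls: Iterable[BindingCall], genotypes: Sequence[HLAGenotype]
) -> CohortPresentation:
    """Aggregate binder calls into the cohort presentation statistics."""
    for g in genotypes:
        g.validate()
    n = len(genotypes)
    binders: dict[str, set[str]] = {}  # allele -> peptides
    for call in calls:
        if call.is_binder:
            binders.setdefault(call.allele, set()).add(call.peptide)
    summary = CohortPresentation(cohort_size=n)
    for allele in sorted({a for g in genotypes for a in g.alleles}):
        carriers = sum(1 for g in genotypes if allele in g.alleles)
        copies = sum(g.alleles.count(allele) for g in genotypes)
        summary.per_allele[allele] = (
            len(binders.get(allele, set())),
            carriers / n if n else 0.0,
            copies / (2 * n) if n else 0.0,
        )
    for g in genotypes:
        presented: set[str] = set()
        locus_hit = {"A": 0, "B": 0, "C": 0}
        for allele in set(g.alleles):
            peps = binders.get(allele, set())
            presented |= peps
            if peps:
                locus_hit[allele_locus(allele)] += 1
        summary.per_individual[g.sample_id] = presented
        summary.locus_counts[g.sample_id] = (locus_hit["A"], locus_hit["B"], locus_hit["C"])
    all_peps = set().union(*summary.per_individual.values()) if summary.per_individual else set()
    for pep in all_peps:
        prevalence = sum(1 for s in summary.per_individual.values() if pep in s)
        summary.per_peptide_prevalence[pep] = prevalence
        if prevalence == n:
            summary.shared_in_all.add(pep)
    return summary


def read_genotypes(path) -> list[HLAGenotype]:
    """Read a genotype TSV: sample_id, A1, A2, B1, B2, C1, C2."""
    df = pd.read_csv(path, sep="\t")
    genotypes = []
    for _, row in df.iterrows():
        alleles = [row[c] for c in df.columns[1:] if isinstance(row[c], str) and row[c]]
        g = HLAGenotype(sample_id=str(row.iloc[0]), alleles=alleles)
        g.validate()
        genotypes.append(g)
    return genotypes


def write_genotypes(genotypes: Sequence[HLAGenotype], path) -> None:
    rows = []
    for g in genotypes:
        row = {"sample_id": g.sample_id}
        for i, col in enumerate(["A1", "A2", "B1", "B2", "C1", "C2"]):
            row[col] = g.alleles[i] if i < len(g.alleles) else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
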