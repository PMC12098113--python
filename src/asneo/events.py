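"""Differential alternative-splicing event tables.

Reads rMATS junction-count (JC) output for the five canonical event types
(SE, A5SS, A3SS, MXE, RI), applies the significance filter
(FDR < 0.05 and |deltaPSI| > 0.1, both strict), and computes event-level
summaries: counts per type and direction, chromosomal distribution,
multi-event gene overlap, and the PSI–expression correlation screen.

Conventions
-----------
All genomic coordinates are 0-based half-open, as printed by rMATS.
Sample group 1 is the old cohort and group 2 the young cohort, so
``delta_psi = mean PSI(old) − mean PSI(young)`` and a positive value means
higher isoform usage in the old group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EVENT_TYPES = ("SE", "A5SS", "A3SS", "MXE", "RI")

#: per-type rMATS coordinate columns -> internal interval names
COORD_COLUMNS: dict[str, dict[str, tuple[str, str]]] = {
    "SE": {
        "exon": ("exonStart_0base", "exonEnd"),
        "upstream": ("upstreamES", "upstreamEE"),
        "downstream": ("downstreamES", "downstreamEE"),
    },
    "MXE": {
        "exon1": ("1stExonStart_0base", "1stExonEnd"),
        "exon2": ("2ndExonStart_0base", "2ndExonEnd"),
        "upstream": ("upstreamES", "upstreamEE"),
        "downstream": ("downstreamES", "downstreamEE"),
    },
    "A5SS": {
        "long_exon": ("longExonStart_0base", "longExonEnd"),
        "short_exon": ("shortES", "shortEE"),
        "flanking": ("flankingES", "flankingEE"),
    },
    "A3SS": {
        "long_exon": ("longExonStart_0base", "longExonEnd"),
        "short_exon": ("shortES", "shortEE"),
        "flanking": ("flankingES", "flankingEE"),
    },
    "RI": {
        "ri_exon": ("riExonStart_0base", "riExonEnd"),
        "upstream": ("upstreamES", "upstreamEE"),
        "downstream": ("downstreamES", "downstreamEE"),
    },
}

_COMMON_COLUMNS = [
    "IJC_SAMPLE_1",
    "SJC_SAMPLE_1",
    "IJC_SAMPLE_2",
    "SJC_SAMPLE_2",
    "IncFormLen",
    "SkipFormLen",
    "PValue",
    "FDR",
    "IncLevel1",
    "IncLevel2",
    "IncLevelDifference",
]


class RmatsFormatError(ValueError):
    """Raised when an rMATS table is missing required columns."""


@dataclass
class ASEvent:
    """One rMATS differential-splicing record.

    ``coords`` holds the type-specific genomic intervals (0-based
    half-open); ``psi_group1``/``psi_group2`` are per-sample inclusion
    levels with NA entries already dropped.
    """

    event_id: str
    event_type: str
    gene_id: str
    gene_symbol: str
    chromosome: str
    strand: str
    coords: dict[str, tuple[int, int]]
    ijc_group1: list[int] = field(default_factory=list)
    sjc_group1: list[int] = field(default_factory=list)
    ijc_group2: list[int] = field(default_factory=list)
    sjc_group2: list[int] = field(default_factory=list)
    inc_form_length: int = 1
    skip_form_length: int = 1
    psi_group1: list[float] = field(default_factory=list)
    psi_group2: list[float] = field(default_factory=list)
    p_value: float = math.nan
    fdr: float = math.nan

    @property
    def delta_psi(self) -> float:
        """mean PSI(group1=old) − mean PSI(group2=young)."""
        if not self.psi_group1 or not self.psi_group2:
            return math.nan
        return float(np.mean(self.psi_group1) - np.mean(self.psi_group2))

    def validate(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"{self.event_id}: unknown event type {self.event_type!r}")
        if self.strand not in "+-":
            raise ValueError(f"{self.event_id}: bad strand {self.strand!r}")
        for name, (s, e) in self.coords.items():
            if not (0 <= s < e):
                raise ValueError(f"{self.event_id}: malformed interval {name}=[{s},{e})")
        c = self.coords
        if self.event_type == "SE":
            if not (c["upstream"][1] <= c["exon"][0] and c["exon"][1] <= c["downstream"][0]):
                raise ValueError(f"{self.event_id}: SE exon not between its flanks")
        elif self.event_type == "MXE":
            if not c["exon1"][1] <= c["exon2"][0]:
                raise ValueError(f"{self.event_id}: MXE exon1 must precede exon2")
            if not (c["upstream"][1] <= c["exon1"][0] and c["exon2"][1] <= c["downstream"][0]):
                raise ValueError(f"{self.event_id}: MXE exons not between their flanks")
        elif self.event_type in ("A5SS", "A3SS"):
            lo, sh = c["long_exon"], c["short_exon"]
            contained = lo[0] <= sh[0] and sh[1] <= lo[1] and (sh[1] - sh[0]) < (lo[1] - lo[0])
            shares_one = (sh[0] == lo[0]) != (sh[1] == lo[1])
            if not (contained and shares_one):
                raise ValueError(
                    f"{self.event_id}: short exon must be a proper sub-interval of the "
                    f"long exon sharing exactly one boundary (long={lo}, short={sh})"
                )
        elif self.event_type == "RI":
            if not (
                c["ri_exon"][0] == c["upstream"][0] and c["ri_exon"][1] == c["downstream"][1]
            ):
                raise ValueError(f"{self.event_id}: RI exon must span upstream..downstream")
            if not c["upstream"][1] <= c["downstream"][0]:
                raise ValueError(f"{self.event_id}: RI flanking exons overlap")
        for psi in (*self.psi_group1, *self.psi_group2):
            if not 0.0 <= psi <= 1.0:
                raise ValueError(f"{self.event_id}: PSI {psi} outside [0,1]")


def _parse_float_list(cell: str) -> list[float]:
    out = []
    for tok in str(cell).split(","):
        tok = tok.strip()
        if tok in ("", "NA", "nan"):
            continue
        out.append(float(tok))
    return out


def _parse_int_list(cell: str) -> list[int]:
    return [int(t) for t in str(cell).split(",") if t.strip() not in ("", "NA")]


def parse_rmats_jc(path, event_type: str) -> list[ASEvent]:
    """Parse one per-type rMATS JC table into validated :class:`ASEvent` s.

    Comma-separated per-sample fields are split; "NA" inclusion levels are
    dropped from that sample's vector (not imputed).
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = (
        ["ID", "GeneID", "geneSymbol", "chr", "strand"]
        + [col for pair in COORD_COLUMNS[event_type].values() for col in pair]
        + _COMMON_COLUMNS
    )
    missing = [col for col in required if col not in df.columns]
    if missing:
        raise RmatsFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    events = []
    for _, row in df.iterrows():
        coords = {
            name: (int(row[s]), int(row[e]))
            for name, (s, e) in COORD_COLUMNS[event_type].items()
        }
        ev = ASEvent(
            event_id=str(row["ID"]),
            event_type=event_type,
            gene_id=row["GeneID"],
            gene_symbol=row["geneSymbol"],
            chromosome=row["chr"],
            strand=row["strand"],
            coords=coords,
            ijc_group1=_parse_int_list(row["IJC_SAMPLE_1"]),
            sjc_group1=_parse_int_list(row["SJC_SAMPLE_1"]),
            ijc_group2=_parse_int_list(row["IJC_SAMPLE_2"]),
            sjc_group2=_parse_int_list(row["SJC_SAMPLE_2"]),
            inc_form_length=int(row["IncFormLen"]),
            skip_form_length=int(row["SkipFormLen"]),
            psi_group1=_parse_float_list(row["IncLevel1"]),
            psi_group2=_parse_float_list(row["IncLevel2"]),
            p_value=float(row["PValue"]) if row["PValue"] not in ("", "NA") else math.nan,
            fdr=float(row["FDR"]) if row["FDR"] not in ("", "NA") else math.nan,
        )
        try:
            ev.validate()
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
        events.append(ev)
    return events


def _fmt_list(values: Sequence, fmt: str = "{}") -> str:
    return ",".join(fmt.format(v) for v in values) if values else "NA"


def write_rmats_jc(events: Sequence[ASEvent], path, event_type: str) -> None:
    """Write events in the per-type rMATS JC column layout."""
    cols = COORD_COLUMNS[event_type]
    rows = []
    for ev in events:
        row = {
            "ID": ev.event_id,
            "GeneID": ev.gene_id,
            "geneSymbol": ev.gene_symbol,
            "chr": ev.chromosome,
            "strand": ev.strand,
        }
        for name, (s_col, e_col) in cols.items():
            row[s_col], row[e_col] = ev.coords[name]
        row.update(
            IJC_SAMPLE_1=_fmt_list(ev.ijc_group1),
            SJC_SAMPLE_1=_fmt_list(ev.sjc_group1),
            IJC_SAMPLE_2=_fmt_list(ev.ijc_group2),
            SJC_SAMPLE_2=_fmt_list(ev.sjc_group2),
            IncFormLen=ev.inc_form_length,
            SkipFormLen=ev.skip_form_length,
            PValue="NA" if math.isnan(ev.p_value) else repr(ev.p_value),
            FDR="NA" if math.isnan(ev.fdr) else repr(ev.fdr),
            IncLevel1=_fmt_list(ev.psi_group1, "{:.6f}"),
            IncLevel2=_fmt_list(ev.psi_group2, "{:.6f}"),
            IncLevelDifference="NA" if math.isnan(ev.delta_psi) else f"{ev.delta_psi:.6f}",
        )
        rows.append(row)
    header = (
        ["ID", "GeneID", "geneSymbol", "chr", "strand"]
        + [c for pair in cols.values() for c in pair]
        + _COMMON_COLUMNS
    )
    pd.DataFrame(rows, columns=header).to_csv(path, sep="\t", index=False)


def filter_significant(
    events: Iterable[ASEvent],
    fdr_max: float = 0.05,
    min_abs_dpsi: float = 0.1,
) -> list[ASEvent]:
    """Significance filter: FDR < fdr_max AND |deltaPSI| > min_abs_dpsi.

    Both inequalities are strict, so events sitting exactly on a threshold
    are excluded.  Input order is preserved; events with missing FDR never
    pass.
    """
    kept = []
    for ev in events:
        if math.isnan(ev.fdr) or math.isnan(ev.delta_psi):
            continue
        if ev.fdr < fdr_max and abs(ev.delta_psi) > min_abs_dpsi:
            kept.append(ev)
    return kept


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (monotone after the cumulative minimum)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def differential_psi(
    psi_matrix: pd.DataFrame,
    group_labels: Mapping[str, str],
    method: str = "t_test",
) -> pd.DataFrame:
    """Two-group differential PSI test per event with pooled BH correction.

    Stands in for the splicing tool's own statistic when working from a
    simulated PSI matrix (events x samples).  ``group_labels`` maps sample
    name to ``"group1"``/``"group2"`` (old/young).  Events with fewer than
    two usable samples in either group get missing p/FDR and are excluded
    from the Benjamini–Hochberg step, which is applied jointly across all
    events passed in (all five types pooled).
    """
    if method not in ("t_test", "wilcoxon"):
        raise ValueError(f"unknown method {method!r}")
    g1 = [s for s in psi_matrix.columns if group_labels[s] == "group1"]
    g2 = [s for s in psi_matrix.columns if group_labels[s] == "group2"]
    delta, pvals = [], []
    for _, row in psi_matrix.iterrows():
        x = row[g1].dropna().to_numpy(dtype=float)
        y = row[g2].dropna().to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            delta.append(math.nan)
            pvals.append(math.nan)
            continue
        delta.append(float(x.mean() - y.mean()))
        if np.array_equal(np.sort(x), np.sort(y)):
            pvals.append(1.0)
            continue
        if x.max() == x.min() and y.max() == y.min():
            # two constant vectors: separation is unambiguous
            pvals.append(1.0 if x[0] == y[0] else 0.0)
            continue
        if method == "t_test":
            p = stats.ttest_ind(x, y, equal_var=False).pvalue
        else:
            p = stats.ranksums(x, y).pvalue
        pvals.append(1.0 if math.isnan(p) else float(p))
    out = pd.DataFrame(
        {"delta_psi": delta, "p_value": pvals, "fdr": math.nan}, index=psi_matrix.index
    )
    tested = out["p_value"].notna()
    if tested.any():
        out.loc[tested, "fdr"] = benjamini_hochberg(out.loc[tested, "p_value"])
    return out


def attach_significance(events: Sequence[ASEvent], method: str = "t_test") -> None:
    """Run :func:`differential_psi` on parsed events and fill p/FDR in place.

    Used in synthetic mode where the emitted tables carry placeholder
    PValue/FDR columns; BH pools across every event in ``events``.
    """
    index = [ev.event_id for ev in events]
    n1 = max((len(ev.psi_group1) for ev in events), default=0)
    n2 = max((len(ev.psi_group2) for ev in events), default=0)
    cols = [f"g1_{i}" for i in range(n1)] + [f"g2_{i}" for i in range(n2)]
    labels = {c: ("group1" if c.startswith("g1") else "group2") for c in cols}
    data = []
    for ev in events:
        row = list(ev.psi_group1) + [math.nan] * (n1 - len(ev.psi_group1))
        row += list(ev.psi_group2) + [math.nan] * (n2 - len(ev.psi_group2))
        data.append(row)
    res = differential_psi(pd.DataFrame(data, index=index, columns=cols), labels, method)
    for ev in events:
        ev.p_value = float(res.at[ev.event_id, "p_value"])
        ev.fdr = float(res.at[ev.event_id, "fdr"])


@dataclass
class EventSummary:
    """Cohort-level roll-up of significant events (bar/UpSet-plot inputs)."""

    counts_by_type: dict[str, tuple[int, int]] = field(default_factory=dict)
    direction_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    chromosome_histogram: dict[str, tuple[int, int]] = field(default_factory=dict)
    gene_type_overlap: dict[str, set[str]] = field(default_factory=dict)
    gene_event_counts: dict[str, int] = field(default_factory=dict)

    @property
    def multi_event_gene_fraction(self) -> float:
        """Fraction of genes carrying two or more significant events."""
        if not self.gene_event_counts:
            return 0.0
        multi = sum(1 for n in self.gene_event_counts.values() if n >= 2)
        return multi / len(self.gene_event_counts)


def summarize_events(
    events: Iterable[ASEvent], min_abs_dpsi: float = 0.1
) -> EventSummary:
    """Count filtered events by type, direction, chromosome and gene.

    Direction follows the sign of deltaPSI: > ``min_abs_dpsi`` means higher
    usage in the old group ("up"), < −``min_abs_dpsi`` lower ("down").
    """
    summary = EventSummary()
    genes_by_type: dict[str, set[str]] = {}
    n_by_type: dict[str, int] = {}
    dirs: dict[str, list[int]] = {}
    chroms: dict[str, list[int]] = {}
    for ev in events:
        up = ev.delta_psi > min_abs_dpsi
        n_by_type[ev.event_type] = n_by_type.get(ev.event_type, 0) + 1
        genes_by_type.setdefault(ev.event_type, set()).add(ev.gene_id)
        d = dirs.setdefault(ev.event_type, [0, 0])
        d[0 if up else 1] += 1
        c = chroms.setdefault(ev.chromosome, [0, 0])
        c[0 if up else 1] += 1
        summary.gene_type_overlap.setdefault(ev.gene_id, set()).add(ev.event_type)
        summary.gene_event_counts[ev.gene_id] = summary.gene_event_counts.get(ev.gene_id, 0) + 1
    summary.counts_by_type = {
        t: (n, len(genes_by_type[t])) for t, n in n_by_type.items()
    }
    summary.direction_counts = {t: tuple(v) for t, v in dirs.items()}
    summary.chromosome_histogram = {c: tuple(v) for c, v in chroms.items()}
    return summary


def psi_expression_correlation(
    psi_matrix: pd.DataFrame,
    expression_matrix: pd.DataFrame,
    event_gene_map: Mapping[str, str],
    event_types: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OLS correlation screen between event PSI and host-gene expression.

    For each event, fits a simple least-squares line of expression on PSI
    across the samples shared by both matrices and reports the signed
    Pearson r, r², slope-test p-value and n.  Events with fewer than three
    paired observations or zero PSI variance are skipped (``skip_reason``
    records why).  The second return value is the per-type roll-up:
    events tested, events with p < 0.05, max r² and mean r².
    """
    samples = [s for s in psi_matrix.columns if s in expression_matrix.columns]
    rows = []
    for event_id, gene_id in event_gene_map.items():
        if event_id not in psi_matrix.index or gene_id not in expression_matrix.index:
            continue
        pair = pd.DataFrame(
            {
                "psi": psi_matrix.loc[event_id, samples],
                "expr": expression_matrix.loc[gene_id, samples],
            }
        ).dropna()
        rec = {
            "event_id": event_id,
            "gene_id": gene_id,
            "n": len(pair),
            "r": math.nan,
            "r_squared": math.nan,
            "p_value": math.nan,
            "skip_reason": "",
        }
        if len(pair) < 3:
            rec["skip_reason"] = "n<3"
        elif pair["psi"].nunique() == 1:
            rec["skip_reason"] = "zero PSI variance"
        elif pair["expr"].nunique() == 1:
            rec.update(r=0.0, r_squared=0.0, p_value=1.0)
        else:
            fit = stats.linregress(pair["psi"], pair["expr"])
            rec.update(r=fit.rvalue, r_squared=fit.rvalue**2, p_value=fit.pvalue)
        rows.append(rec)
    per_event = pd.DataFrame(rows)
    if event_types is None:
        event_types = {}
    rollup_rows = []
    if not per_event.empty:
        per_event["event_type"] = [
            event_types.get(e, "all") for e in per_event["event_id"]
        ]
        tested = per_event[per_event["skip_reason"] == ""]
        for etype, grp in tested.groupby("event_type"):
            rollup_rows.append(
                {
                    "event_type": etype,
                    "n_events": len(grp),
                    "n_significant": int((grp["p_value"] < 0.05).sum()),
                    "max_r_squared": grp["r_squared"].max(),
                    "mean_r_squared": grp["r_squared"].mean(),
                }
            )
    return per_event, pd.DataFrame(rollup_rows)
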