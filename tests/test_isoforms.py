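"""Exon surgery, CDS extraction, protein-interval mapping, domain overlap."""

import numpy as np
import pytest

from asneo._dna import revcomp
from asneo.events import ASEvent
from asneo.isoforms import (
    DomainAnnotation,
    IncompatibleEventError,
    Isoform,
    IsoformPair,
    TranscriptModel,
    apply_event,
    build_isoform_pair,
    build_pairs,
    count_events_per_domain,
    domains_from_interproscan,
    map_to_protein,
    overlap_domains,
    read_gtf,
    spliced_cds,
    write_gtf,
)


def _naive_spliced_cds(genome, chrom, strand, exons, cds_start, cds_end):
    """Independent oracle: plain slice concatenation over the exon list."""
    seq = ""
    for s, e in sorted(exons):
        a, b = max(s, cds_start), min(e, cds_end)
        if a < b:
            seq += genome[chrom][a:b]
    return revcomp(seq) if strand == "-" else seq


def _toy_model(**kw):
    defaults = dict(
        transcript_id="t1", gene_id="g1", gene_symbol="G1", chromosome="chr1",
        strand="+", exons=[(0, 6), (10, 16)], cds_start=3, cds_end=13,
    )
    defaults.update(kw)
    return TranscriptModel(**defaults)


def _se_event(delta=0.3, **kw):
    fields = dict(
        event_id="se1", event_type="SE", gene_id="g1", gene_symbol="G1",
        chromosome="chr1", strand="+",
        coords={"exon": (100, 200), "upstream": (0, 50), "downstream": (300, 400)},
        psi_group1=[0.4 + delta] * 3, psi_group2=[0.4] * 3, fdr=0.01,
    )
    fields.update(kw)
    return ASEvent(**fields)


class TestSplicedCds:
    def test_plus_strand_toy(self):
        genome = {"chr1": "ATGAAACCCGGGTTTTAAAC"}
        model = _toy_model()
        assert spliced_cds(model, genome) == genome["chr1"][3:6] + genome["chr1"][10:13]

    def test_minus_strand_is_revcomp(self):
        genome = {"chr1": "ATGAAACCCGGGTTTTAAAC"}
        model = _toy_model(strand="-")
        assert spliced_cds(model, genome) == revcomp(
            genome["chr1"][3:6] + genome["chr1"][10:13]
        )

    def test_every_reference_cds_starts_with_atg(self, cohort):
        for m in cohort.models:
            assert spliced_cds(m, cohort.genome).startswith("ATG")


class TestApplyEvent:
    def test_se_inclusion_identity(self):
        ref = _toy_model(exons=[(0, 50), (100, 200), (300, 400)], cds_start=0, cds_end=400)
        out = apply_event(ref, _se_event(), "inclusion")
        assert out.exons == ref.exons
        excl = apply_event(ref, _se_event(), "exclusion")
        assert excl.exons == [(0, 50), (300, 400)]

    def test_ri_merge_arithmetic(self):
        ref = _toy_model(exons=[(0, 50), (100, 200), (300, 400)], cds_start=0, cds_end=400)
        event = _se_event(
            event_id="ri1", event_type="RI",
            coords={"ri_exon": (100, 400), "upstream": (100, 200), "downstream": (300, 400)},
        )
        inc = apply_event(ref, event, "inclusion")
        assert inc.exons == [(0, 50), (100, 400)]
        assert inc.exonic_length() - ref.exonic_length() == 100
        assert apply_event(ref, event, "exclusion").exons == ref.exons

    def test_flank_mismatch_raises_with_coordinates(self):
        ref = _toy_model(exons=[(0, 50), (100, 200), (300, 400)], cds_start=0, cds_end=400)
        ev = _se_event()
        ev.coords["upstream"] = (0, 60)
        with pytest.raises(IncompatibleEventError, match=r"\(0, 60\)"):
            apply_event(ref, ev, "exclusion")

    def test_wrong_chromosome_rejected(self):
        ref = _toy_model(exons=[(0, 50), (100, 200), (300, 400)], cds_start=0, cds_end=400)
        with pytest.raises(IncompatibleEventError):
            apply_event(ref, _se_event(chromosome="chr2"), "inclusion")

    def test_surgery_matches_planted_exon_lists(self, cohort):
        """apply_event reproduces the generator's planned exon lists exactly."""
        models = {p.transcript_id: p for p in cohort.truth.planted_events}
        by_tid = {m.transcript_id: m for m in cohort.models}
        events = {e.event_id: e for e in cohort.events}
        for p in cohort.truth.planted_events:
            ref = by_tid[p.transcript_id]
            ev = events[p.event_id]
            inc = apply_event(ref, ev, "inclusion")
            exc = apply_event(ref, ev, "exclusion")
            assert inc.exons == p.inclusion_exons
            assert exc.exons == p.exclusion_exons

    def test_spliced_sequence_matches_concatenation_oracle(self, cohort):
        """Surgery + CDS extraction equals naive slice concatenation."""
        by_tid = {m.transcript_id: m for m in cohort.models}
        events = {e.event_id: e for e in cohort.events}
        for p in cohort.truth.planted_events:
            ref = by_tid[p.transcript_id]
            ev = events[p.event_id]
            for form, exon_list in (
                ("inclusion", p.inclusion_exons),
                ("exclusion", p.exclusion_exons),
            ):
                got = spliced_cds(apply_event(ref, ev, form), cohort.genome)
                expect = _naive_spliced_cds(
                    cohort.genome, p.chromosome, p.strand, exon_list,
                    p.cds_start, p.cds_end,
                )
                assert got == expect

    def test_forms_identical_outside_event_footprint(self, cohort):
        """Exonic-length deltas per type are exact and flanks are untouched."""
        by_tid = {m.transcript_id: m for m in cohort.models}
        events = {e.event_id: e for e in cohort.events}
        for p in cohort.truth.planted_events:
            ev = events[p.event_id]
            inc = apply_event(by_tid[p.transcript_id], ev, "inclusion")
            exc = apply_event(by_tid[p.transcript_id], ev, "exclusion")
            delta = inc.exonic_length() - exc.exonic_length()
            c = ev.coords
            if p.event_type == "SE":
                expected = c["exon"][1] - c["exon"][0]
            elif p.event_type == "RI":
                expected = c["downstream"][0] - c["upstream"][1]
            elif p.event_type == "MXE":
                expected = (c["exon1"][1] - c["exon1"][0]) - (c["exon2"][1] - c["exon2"][0])
            else:
                expected = (c["long_exon"][1] - c["long_exon"][0]) - (
                    c["short_exon"][1] - c["short_exon"][0]
                )
            assert delta == expected
            footprint = [x for iv in c.values() for x in iv]
            lo, hi = min(footprint), max(footprint)
            assert [e for e in inc.exons if e[1] <= lo or e[0] >= hi] == [
                e for e in exc.exons if e[1] <= lo or e[0] >= hi
            ]


class TestIsoformPairs:
    def _pair(self, aging_cds, other_cds, frame_effect="preserving"):
        from asneo.peptides import translate

        return IsoformPair(
            event_id="e", event_type="SE", gene_id="g", gene_symbol="G",
            inclusion=Isoform(None, aging_cds, translate(aging_cds)),
            exclusion=Isoform(None, other_cds, translate(other_cds)),
            aging_favored="inclusion", cds_changed=aging_cds != other_cds,
            frame_effect=frame_effect,
        )

    def test_map_to_protein_substitution_window(self):
        # CDS differ only at nucleotides 30..35 -> residues [10, 12)
        a = "ATG" + "GCA" * 29
        b = a[:30] + "TGGTTG" + a[36:]
        assert map_to_protein(self._pair(b, a)) == (10, 12)

    def test_map_to_protein_frameshift_semantics(self):
        a = "ATG" + "GCA" * 29
        b = a[:31] + "T" + a[31:]  # insertion at nucleotide 31
        pair = self._pair(b, a, frame_effect="disrupting")
        assert map_to_protein(pair) == (10, len(pair.inclusion.protein))

    def test_identical_cds_is_contract_error(self):
        with pytest.raises(ValueError, match="identical"):
            map_to_protein(self._pair("ATGGCA", "ATGGCA"))

    def test_utr_only_event_cds_unchanged(self, cohort):
        utr = [p for p in cohort.truth.planted_events if p.utr_only]
        assert utr
        by_tid = {m.transcript_id: m for m in cohort.models}
        events = {e.event_id: e for e in cohort.events}
        for p in utr:
            pair = build_isoform_pair(by_tid[p.transcript_id], events[p.event_id], cohort.genome)
            assert not pair.cds_changed
            assert pair.protein_interval is None

    def test_aging_favored_follows_delta_sign(self, cohort, significant_events):
        by_tid = {m.transcript_id: m for m in cohort.models}
        truth = {p.event_id: p for p in cohort.truth.planted_events}
        for ev in significant_events:
            pair = build_isoform_pair(by_tid[truth[ev.event_id].transcript_id], ev, cohort.genome)
            assert pair.aging_favored == ("inclusion" if ev.delta_psi > 0 else "exclusion")
            assert pair.aging_favored == truth[ev.event_id].aging_favored

    def test_preserving_pairs_agree_outside_mapped_interval(self, cohort, significant_events):
        """Residue-diff oracle: proteins match outside map_to_protein's interval."""
        by_tid = {m.transcript_id: m for m in cohort.models}
        truth = {p.event_id: p for p in cohort.truth.planted_events}
        checked = 0
        for ev in significant_events:
            pair = build_isoform_pair(by_tid[truth[ev.event_id].transcript_id], ev, cohort.genome)
            if not pair.cds_changed or pair.frame_effect != "preserving":
                continue
            s, e = pair.protein_interval
            aging, other = pair.aging_form().protein, pair.other_form().protein
            assert aging[:s] == other[:s]
            # the suffix comparison is only meaningful when neither protein
            # was cut short by a premature stop inside the altered region
            full_aging = len(aging) == len(pair.aging_form().cds) // 3
            full_other = len(other) == len(pair.other_form().cds) // 3
            tail = len(aging) - e
            if full_aging and full_other and tail > 0:
                assert aging[e:] == other[len(other) - tail :]
            checked += 1
        assert checked >= 5

    def test_build_pairs_skips_unmatched_gene(self, cohort):
        orphan = _se_event(event_id="orphan", gene_id="nosuch")
        pairs, skipped = build_pairs([orphan], cohort.models, cohort.genome)
        assert not pairs
        assert skipped == [("orphan", "no compatible reference transcript")]


class TestDomains:
    def test_halfopen_overlap_and_abutment(self):
        pair = IsoformPair(
            event_id="e1", event_type="SE", gene_id="p1", gene_symbol="G",
            inclusion=Isoform(None, "", ""), exclusion=Isoform(None, "", ""),
            aging_favored="inclusion", cds_changed=True, frame_effect="preserving",
            protein_interval=(10, 12),
        )
        inside = DomainAnnotation("p1", "dom", "PF0001", 0, 50)
        abutting = DomainAnnotation("p1", "dom", "PF0002", 12, 30)
        overlaps = overlap_domains([pair], [inside, abutting])
        assert [(o.domain_accession, o.start, o.end) for o in overlaps] == [("PF0001", 10, 12)]

    def test_counts_match_quadratic_oracle(self):
        rng = np.random.default_rng(0)
        pairs, domains = [], []
        for i in range(40):
            s = int(rng.integers(0, 150))
            pairs.append(
                IsoformPair(
                    event_id=f"e{i}", event_type="SE", gene_id=f"p{i % 5}", gene_symbol="G",
                    inclusion=Isoform(None, "", ""), exclusion=Isoform(None, "", ""),
                    aging_favored="inclusion", cds_changed=True,
                    frame_effect="preserving",
                    protein_interval=(s, s + int(rng.integers(1, 30))),
                )
            )
        for j in range(20):
            s = int(rng.integers(0, 150))
            domains.append(
                DomainAnnotation(f"p{j % 5}", f"d{j}", f"PF{j:04d}", s, s + int(rng.integers(1, 40)))
            )
        got = count_events_per_domain(overlap_domains(pairs, domains))
        expect = {}
        for d in domains:
            n = sum(
                1
                for p in pairs
                if p.gene_id == d.protein_id
                and max(p.protein_interval[0], d.start) < min(p.protein_interval[1], d.end)
            )
            if n:
                expect[d.domain_accession] = n
        assert got == expect

    def test_interproscan_conversion(self):
        import pandas as pd

        df = pd.DataFrame(
            [{"protein_id": "p", "domain_accession": "PF1", "domain_name": "x",
              "start": 1, "end": 10}]
        )
        (dom,) = domains_from_interproscan(df)
        assert (dom.start, dom.end) == (0, 10)


class TestGtfRoundTrip:
    def test_models_survive_gtf_roundtrip(self, cohort, tmp_path):
        path = tmp_path / "models.gtf"
        write_gtf(cohort.models, path)
        back = {m.transcript_id: m for m in read_gtf(path)}
        assert len(back) == len(cohort.models)
        for m in cohort.models:
            b = back[m.transcript_id]
            assert (b.exons, b.cds_start, b.cds_end, b.strand, b.chromosome) == (
                m.exons, m.cds_start, m.cds_end, m.strand, m.chromosome
            )
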