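"""Transcript assembly, consequence classification, and splice-site checks."""

import numpy as np
import pytest
from Bio.Seq import Seq

from dielsplice.gene_models import (
    ASEvent,
    AltSpliceSite,
    AnnotationError,
    ClassificationError,
    GeneModel,
    InvalidEventError,
    RetainIntron,
    SkipExon,
    build_transcript,
    classify_event,
    consequences_table,
    events_from_yaml,
    events_to_yaml,
    read_gff3,
    spliced_cds,
    translate_cds,
    validate_splice_sites,
    write_fasta,
    write_gff3,
)

from conftest import toy_two_exon_gene

# independent codon table for oracle translation (not Bio.Seq)
_CODON_TABLE = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate(
    (a, b, c) for a in _BASES for b in _BASES for c in _BASES
):
    _CODON_TABLE[_a + _b + _c] = _AA[_i]


def oracle_translate(cds: str) -> str:
    out = []
    for i in range(0, len(cds) - 2, 3):
        aa = _CODON_TABLE[cds[i : i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def oracle_first_stop_codon_index(seq: str, start: int) -> int:
    """Codon index of the first stop when reading from ``start``; -1 if none."""
    for k, i in enumerate(range(start, len(seq) - 2, 3)):
        if seq[i : i + 3] in {"TAA", "TAG", "TGA"}:
            return k
    return -1


class TestBuildTranscript:
    def test_fully_spliced_two_exons(self):
        gene = toy_two_exon_gene()
        assert build_transcript(gene, None) == "ATGGCC" + "TAAACGT"

    def test_intron_retention_keeps_full_intron(self):
        gene = toy_two_exon_gene()
        ev = ASEvent("I1R", "toy", "intron_retention", (RetainIntron(1),))
        tx = build_transcript(gene, ev)
        assert tx == gene.genomic_seq  # single intron retained = unspliced
        assert len(tx) - len(build_transcript(gene)) == 16  # intron length

    def test_composite_alt_ss_removes_246_nt(self, clock_genes, clock_events):
        gene = clock_genes["ScPRR73"]
        ev = next(e for e in clock_events if e.event_id == "Alt5ssE4_Alt3ssE5")
        fs = build_transcript(gene)
        alt = build_transcript(gene, ev)
        assert len(fs) - len(alt) == 246

    def test_unknown_intron_index_raises(self):
        gene = toy_two_exon_gene()
        ev = ASEvent("I9R", "toy", "intron_retention", (RetainIntron(9),))
        with pytest.raises(AnnotationError):
            build_transcript(gene, ev)

    def test_inverting_edit_rejected(self):
        gene = toy_two_exon_gene()
        ev = ASEvent("bad", "toy", "alt5ss", (AltSpliceSite(1, "5ss", -10),))
        with pytest.raises(InvalidEventError):
            build_transcript(gene, ev)

    def test_length_conservation(self, clock_genes):
        """FS transcript length plus intron lengths equals the exon+intron span."""
        for gene in clock_genes.values():
            fs = build_transcript(gene)
            introns = sum(e - s + 1 for s, e in gene.introns_coding)
            exons = gene.exons_coding
            span = exons[-1][1] - exons[0][0] + 1
            assert len(fs) + introns == span

    def test_ir_length_equals_retained_intron(self, clock_genes, clock_events):
        for ev in clock_events:
            if ev.kind != "intron_retention":
                continue
            gene = clock_genes[ev.gene_id]
            k = ev.parts[0].index
            s, e = gene.introns_coding[k - 1]
            delta = len(build_transcript(gene, ev)) - len(build_transcript(gene))
            assert delta == e - s + 1


class TestClassifyEvent:
    def test_in_frame_deletion_82_aa(self, clock_genes, clock_events):
        gene = clock_genes["ScPRR73"]
        ev = next(e for e in clock_events if e.event_id == "Alt5ssE4_Alt3ssE5")
        cons = classify_event(gene, ev)
        assert cons.delta_nt == -246
        assert cons.frame_preserved and not cons.ptc
        assert cons.aa_delta == 82

    def test_in_frame_deletion_10_aa(self, clock_genes, clock_events):
        gene = clock_genes["ScPRR37"]
        ev = next(
            e for e in clock_events if e.gene_id == "ScPRR37" and e.event_id == "Alt3ssE4"
        )
        cons = classify_event(gene, ev)
        assert cons.delta_nt == -30
        assert cons.frame_preserved and cons.aa_delta == 10

    def test_toy_ir_ptc_agrees_with_frame_scan_oracle(self):
        gene = toy_two_exon_gene()
        ev = ASEvent("I1R", "toy", "intron_retention", (RetainIntron(1),))
        cons = classify_event(gene, ev)
        # oracle: scan codons of the edited transcript (CDS starts at offset 0)
        prot = oracle_translate(cons.transcript_seq)
        assert cons.protein_seq == prot
        stop_idx = oracle_first_stop_codon_index(cons.transcript_seq, 0)
        anno_stop_offset = 6 + 16  # exon-1 CDS + retained intron length
        assert stop_idx >= 0
        assert cons.ptc == (3 * stop_idx < anno_stop_offset)
        assert cons.ptc

    def test_every_event_protein_matches_codon_scan(self, clock_genes, clock_events):
        """Classified protein equals the oracle translation of the edited
        transcript read from the annotated start codon.

        In the fixture no edit touches the 5' UTR, so the start codon sits at
        the same offset (the UTR length) in every edited transcript.
        """
        for ev in clock_events:
            gene = clock_genes[ev.gene_id]
            cons = classify_event(gene, ev)
            utr5_len = sum(e - s + 1 for s, e in gene.utr5)
            assert cons.transcript_seq[utr5_len : utr5_len + 3] == "ATG"
            prot = oracle_translate(cons.transcript_seq[utr5_len:])
            assert cons.protein_seq == prot
            wild = oracle_translate(spliced_cds(gene))
            if cons.ptc:
                assert len(cons.protein_seq) < len(wild)

    def test_translation_matches_oracle_on_random_cds(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 80))
            cds = "".join(
                rng.choice([c for c in _CODON_TABLE]) for _ in range(n)
            )
            assert translate_cds(cds) == oracle_translate(cds)

    def test_cds_start_removed_raises(self):
        gene = toy_two_exon_gene()
        ev = ASEvent("E1S", "toy", "exon_skipping", (SkipExon(1),))
        with pytest.raises(ClassificationError):
            classify_event(gene, ev)


class TestSpliceSites:
    def test_fixture_genes_all_canonical(self, clock_genes):
        for gene in clock_genes.values():
            assert validate_splice_sites(gene) == []

    def test_constructed_violation_detected(self):
        gene = toy_two_exon_gene()
        seq = list(gene.genomic_seq)
        seq[6] = "C"  # GT -> CT at the donor
        bad = GeneModel("toy", "".join(seq), "+", gene.exons, gene.cds_start, gene.cds_end)
        violations = validate_splice_sites(bad)
        assert len(violations) == 1
        assert violations[0].intron == 1 and violations[0].donor == "CT"

    def test_strand_symmetry(self):
        """A minus-strand gene with reverse-complemented sequence behaves
        exactly like its plus-strand equivalent."""
        plus = toy_two_exon_gene()
        L = len(plus.genomic_seq)
        minus = GeneModel(
            gene_id="toy_minus",
            genomic_seq=str(Seq(plus.genomic_seq).reverse_complement()),
            strand="-",
            exons=[(L - e + 1, L - s + 1) for s, e in plus.exons],
            cds_start=L - plus.cds_start + 1,
            cds_end=L - plus.cds_end + 1,
        )
        assert validate_splice_sites(minus) == validate_splice_sites(plus) == []
        assert build_transcript(minus) == build_transcript(plus)
        ev_p = ASEvent("I1R", "toy", "intron_retention", (RetainIntron(1),))
        ev_m = ASEvent("I1R", "toy_minus", "intron_retention", (RetainIntron(1),))
        assert build_transcript(minus, ev_m) == build_transcript(plus, ev_p)


class TestIO:
    def test_gff3_fasta_roundtrip(self, clock_genes, tmp_path):
        gff = tmp_path / "genes.gff3"
        fasta = tmp_path / "genes.fa"
        write_gff3(gff, clock_genes.values())
        write_fasta(fasta, {g.gene_id: g.genomic_seq for g in clock_genes.values()})
        loaded = read_gff3(gff, fasta)
        assert set(loaded) == set(clock_genes)
        for gid, gene in clock_genes.items():
            assert build_transcript(loaded[gid]) == build_transcript(gene)
            assert spliced_cds(loaded[gid]) == spliced_cds(gene)

    def test_events_yaml_roundtrip(self, clock_events):
        text = events_to_yaml(clock_events)
        back = events_from_yaml(text)
        assert back == list(clock_events)

    def test_consequences_table_columns(self, clock_genes, clock_events):
        df = consequences_table(clock_genes, clock_events)
        assert len(df) == len(clock_events)
        assert {"gene_id", "event_id", "ptc", "frame_preserved", "aa_delta"} <= set(df.columns)
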