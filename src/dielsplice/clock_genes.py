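"""Built-in sugarcane circadian-clock gene fixture.

Synthetic gene models for *ScLHY*, *ScPRR37*, *ScPRR73*, *ScPRR95* and
*ScTOC1* carrying the published alternative-splicing event catalogue for these
loci: intron retentions that insert premature termination codons, exon
skippings, an alternative exon, and the two in-frame alternative-splice-site
deletions (the ScPRR73 alt 5'ss E4 / alt 3'ss E5 combination removing
104 + 142 = 246 nt / 82 aa, and the ScPRR37 alt 3'ss in exon 4 removing
30 nt / 10 aa from the PRR-domain coding region).

The sequences are synthetic: exon/intron counts and the event geometry match
the published gene structures, but no real sugarcane sequence is shipped (none
is publicly deposited for these loci).  Construction is deterministic — a
seeded generator draws stop-free codons for the CDS and GT..AG introns whose
interiors carry stop codons in all three reading frames, and a small search
over derived seeds guarantees every event classifies exactly as published.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .gene_models import (
    ASEvent,
    AltExon,
    AltSpliceSite,
    GeneModel,
    RetainIntron,
    SkipExon,
    classify_event,
    validate_splice_sites,
)

# stop codons in all three frames relative to any insertion phase
_STOP_CASSETTE = "TAACTAACTAA"

_SAFE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA", "ATG"}
]


def _codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_SAFE_CODONS), size=n)
    return "".join(_SAFE_CODONS[i] for i in idx)


def _bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _intron(rng: np.random.Generator, length: int) -> str:
    """GT..AG intron whose interior stops translation in every frame."""
    if length < 20:
        raise ValueError("introns shorter than 20 nt unsupported")
    fill = length - 4 - 3 - len(_STOP_CASSETTE)
    return "GT" + _bases(rng, 3) + _STOP_CASSETTE + _bases(rng, fill) + "AG"


@dataclass(frozen=True)
class _GeneSpec:
    gene_id: str
    cds_exon_lengths: tuple[int, ...]  # CDS nt per exon (incl. ATG / stop)
    utr5: int
    utr3: int
    strand: str


def _build_gene(spec: _GeneSpec, rng: np.random.Generator) -> GeneModel:
    n_exons = len(spec.cds_exon_lengths)
    cds_len = sum(spec.cds_exon_lengths)
    assert cds_len % 3 == 0
    cds = "ATG" + _codons(rng, cds_len // 3 - 2) + "TGA"

    intron_lengths = rng.integers(100, 200, size=n_exons - 1)
    coding_parts: list[str] = []
    exon_intervals: list[tuple[int, int]] = []
    pos = 0  # 0-based cursor on the coding strand
    cds_cursor = 0
    for i, ex_cds in enumerate(spec.cds_exon_lengths):
        chunk = cds[cds_cursor : cds_cursor + ex_cds]
        cds_cursor += ex_cds
        exon_seq = chunk
        if i == 0:
            exon_seq = _bases(rng, spec.utr5) + exon_seq
        if i == n_exons - 1:
            exon_seq = exon_seq + _bases(rng, spec.utr3)
        exon_intervals.append((pos + 1, pos + len(exon_seq)))  # 1-based inclusive
        coding_parts.append(exon_seq)
        pos += len(exon_seq)
        if i < n_exons - 1:
            iseq = _intron(rng, int(intron_lengths[i]))
            coding_parts.append(iseq)
            pos += len(iseq)

    coding_seq = "".join(coding_parts)
    cds_start_c = spec.utr5 + 1
    cds_end_c = exon_intervals[-1][1] - spec.utr3

    if spec.strand == "+":
        return GeneModel(
            gene_id=spec.gene_id,
            genomic_seq=coding_seq,
            strand="+",
            exons=exon_intervals,
            cds_start=cds_start_c,
            cds_end=cds_end_c,
        )
    L = len(coding_seq)
    genomic = str(Seq(coding_seq).reverse_complement())
    exons_minus = [(L - e + 1, L - s + 1) for s, e in exon_intervals]
    return GeneModel(
        gene_id=spec.gene_id,
        genomic_seq=genomic,
        strand="-",
        exons=exons_minus,  # transcript order: descending genomic position
        cds_start=L - cds_start_c + 1,
        cds_end=L - cds_end_c + 1,
    )


# CDS nt per exon.  Constraints built in:
#  * ScPRR37: exon-3 CDS not divisible by 3 (E3S frameshifts) while
#    exons 1-3 sum to a multiple of 3, so the 30-nt alt 3'ss deletion in
#    exon 4 is codon-aligned (in frame, -10 aa).
#  * ScPRR73: exon 4 > 104 nt and exon 5 > 142 nt for the combined
#    alt 5'ss E4 (-104) / alt 3'ss E5 (-142) deletion (-246 nt, -82 aa).
#  * ScTOC1: exon-3 CDS not divisible by 3 (E3S frameshifts).
_SPECS = [
    _GeneSpec("ScLHY", (120, 150, 141, 138, 156, 126), 24, 30, "+"),
    _GeneSpec("ScPRR37", (99, 136, 134, 141, 120, 114, 108, 123), 24, 33, "+"),
    _GeneSpec("ScPRR73", (111, 126, 129, 180, 210, 120, 117), 27, 30, "+"),
    _GeneSpec("ScPRR95", (105, 120, 132, 126, 150, 123, 117, 120), 24, 30, "+"),
    _GeneSpec("ScTOC1", (108, 129, 131, 144, 120, 127), 24, 36, "-"),
]


def _events_for(gene: GeneModel) -> list[ASEvent]:
    gid = gene.gene_id
    if gid == "ScLHY":
        return [
            ASEvent("I1R", gid, "intron_retention", (RetainIntron(1),)),
            ASEvent("I5R", gid, "intron_retention", (RetainIntron(5),)),
        ]
    if gid == "ScPRR37":
        # alternative exon inside intron 2; its interior carries the stop
        # cassette (placed by _place_alt_exon below)
        int2_s, int2_e = gene.introns_coding[1]
        ax_start, ax_end = int2_s + 8, int2_s + 8 + 76
        assert ax_end < int2_e
        return [
            ASEvent("Ex2a", gid, "alt_exon", (AltExon(ax_start, ax_end),)),
            ASEvent("E3S", gid, "exon_skipping", (SkipExon(3),)),
            ASEvent("I3R", gid, "intron_retention", (RetainIntron(3),)),
            ASEvent("I6R", gid, "intron_retention", (RetainIntron(6),)),
            ASEvent("I7R", gid, "intron_retention", (RetainIntron(7),)),
            ASEvent("Alt3ssE4", gid, "alt3ss", (AltSpliceSite(4, "3ss", -30),)),
        ]
    if gid == "ScPRR73":
        return [
            ASEvent("I2R", gid, "intron_retention", (RetainIntron(2),)),
            ASEvent(
                "Alt5ssE4_Alt3ssE5",
                gid,
                "composite",
                (AltSpliceSite(4, "5ss", -104), AltSpliceSite(5, "3ss", -142)),
            ),
            ASEvent("I6R", gid, "intron_retention", (RetainIntron(6),)),
        ]
    if gid == "ScPRR95":
        return [
            ASEvent("I3R", gid, "intron_retention", (RetainIntron(3),)),
            ASEvent("I7R", gid, "intron_retention", (RetainIntron(7),)),
            ASEvent("Alt3ssE5", gid, "alt3ss", (AltSpliceSite(5, "3ss", -13),)),
        ]
    if gid == "ScTOC1":
        return [
            ASEvent(
                "I1R_E23S",
                gid,
                "composite",
                (RetainIntron(1), SkipExon(2), SkipExon(3)),
            ),
            ASEvent("E3S", gid, "exon_skipping", (SkipExon(3),)),
            ASEvent("I1R", gid, "intron_retention", (RetainIntron(1),)),
        ]
    raise KeyError(gid)


def _place_alt_exon(gene: GeneModel) -> GeneModel:
    """Overwrite the ScPRR37 alternative-exon interval so inclusion stops
    translation regardless of reading frame."""
    int2_s, _ = gene.introns_coding[1]
    s0 = int2_s + 8 - 1  # 0-based on coding strand
    length = 77
    seq = list(gene.coding_seq)
    content = _STOP_CASSETTE + _STOP_CASSETTE
    fill = "".join("ACGT"[(i * 7 + 3) % 4] for i in range(length - len(content)))
    seq[s0 : s0 + length] = list(content + fill)
    coding = "".join(seq)
    return GeneModel(
        gene_id=gene.gene_id,
        genomic_seq=coding if gene.strand == "+" else str(Seq(coding).reverse_complement()),
        strand=gene.strand,
        exons=gene.exons,
        cds_start=gene.cds_start,
        cds_end=gene.cds_end,
    )


_EXPECT = {
    # event_id -> (ptc, frame_preserved, aa_delta or None)
    ("ScLHY", "I1R"): (True, False, None),
    ("ScLHY", "I5R"): (True, False, None),
    ("ScPRR37", "Ex2a"): (True, False, None),
    ("ScPRR37", "E3S"): (True, False, None),
    ("ScPRR37", "I3R"): (True, False, None),
    ("ScPRR37", "I6R"): (True, False, None),
    ("ScPRR37", "I7R"): (True, False, None),
    ("ScPRR37", "Alt3ssE4"): (False, True, 10),
    ("ScPRR73", "I2R"): (True, False, None),
    ("ScPRR73", "Alt5ssE4_Alt3ssE5"): (False, True, 82),
    ("ScPRR73", "I6R"): (True, False, None),
    ("ScPRR95", "I3R"): (True, False, None),
    ("ScPRR95", "I7R"): (True, False, None),
    ("ScPRR95", "Alt3ssE5"): (True, False, None),
    ("ScTOC1", "I1R_E23S"): (True, False, None),
    ("ScTOC1", "E3S"): (True, False, None),
    ("ScTOC1", "I1R"): (True, False, None),
}


def _gene_ok(gene: GeneModel) -> bool:
    try:
        gene.validate()
    except Exception:
        return False
    if validate_splice_sites(gene):
        return False
    for ev in _events_for(gene):
        cons = classify_event(gene, ev)
        ptc, frame, aa = _EXPECT[(gene.gene_id, ev.event_id)]
        if cons.ptc != ptc or cons.frame_preserved != frame:
            return False
        if aa is not None and cons.aa_delta != aa:
            return False
    return True


def clock_gene_fixture(seed: int = 2019) -> tuple[dict[str, GeneModel], list[ASEvent]]:
    """Build the five clock gene models and their 17-event catalogue.

    Deterministic for a given ``seed``; the default is the packaged fixture.
    Returns ``(genes, events)`` with genes keyed by gene_id.
    """
    import zlib

    genes: dict[str, GeneModel] = {}
    events: list[ASEvent] = []
    for spec in _SPECS:
        gene_key = zlib.crc32(spec.gene_id.encode()) % 2**31
        for attempt in range(200):
            rng = np.random.default_rng([seed, attempt, gene_key])
            gene = _build_gene(spec, rng)
            if spec.gene_id == "ScPRR37":
                gene = _place_alt_exon(gene)
            if _gene_ok(gene):
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not realize fixture gene {spec.gene_id}")
        genes[spec.gene_id] = gene
        events.extend(_events_for(gene))
    return genes, events
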