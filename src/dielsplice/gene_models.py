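"""Gene structures, alternative-splicing events, and their transcript consequences.

A :class:`GeneModel` holds a genomic sequence with an exon/intron structure and
an annotated CDS.  An :class:`ASEvent` is a bundle of primitive splicing edits
(retain an intron, skip an exon, shift a splice site, include an alternative
exon).  :func:`build_transcript` applies an event to the gene model and returns
the mature transcript; :func:`classify_event` translates the edited CDS and
decides whether the event inserts a premature termination codon (PTC) or makes
an in-frame deletion, mirroring the "effect on transcript" annotation used for
plant clock genes.

Coordinates are 1-based inclusive on the genomic sequence (GFF3 convention);
BED export converts to 0-based half-open.  Minus-strand genes are stored as
given and all transcript operations work on the reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence, Union

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class AnnotationError(ValueError):
    """An event references exons/introns absent from the gene model."""


class InvalidEventError(ValueError):
    """Event edits produce overlapping or inverted transcript segments."""


class ClassificationError(ValueError):
    """The edited transcript cannot be classified (e.g. CDS start removed)."""


# ---------------------------------------------------------------------------
# Primitive edits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RetainIntron:
    """Keep intron ``index`` (1-based, between exon ``index`` and ``index+1``)."""

    index: int


@dataclass(frozen=True)
class SkipExon:
    """Remove exon ``index`` (1-based in transcript order) from the transcript."""

    index: int


@dataclass(frozen=True)
class AltSpliceSite:
    """Move one boundary of exon ``exon`` by ``delta`` nucleotides.

    ``site`` names the splice site in the standard donor/acceptor sense:
    ``"5ss"`` is the donor downstream of the exon (its 3' edge on the
    transcript), ``"3ss"`` the acceptor upstream of it (its 5' edge).
    Negative ``delta`` removes nucleotides from the exon; positive extends the
    exon into the adjacent intron.
    """

    exon: int
    site: Literal["5ss", "3ss"]
    delta: int


@dataclass(frozen=True)
class AltExon:
    """Include an alternative exon at ``start``..``end`` (1-based inclusive,
    genomic coordinates), which must lie strictly inside an intron."""

    start: int
    end: int


Edit = Union[RetainIntron, SkipExon, AltSpliceSite, AltExon]

_EVENT_KINDS = (
    "intron_retention",
    "exon_skipping",
    "alt5ss",
    "alt3ss",
    "alt_exon",
    "composite",
)


@dataclass(frozen=True)
class ASEvent:
    """One alternative-splicing alternative relative to the fully spliced form."""

    event_id: str
    gene_id: str
    kind: str
    parts: tuple[Edit, ...]

    def __post_init__(self) -> None:
        if self.kind not in _EVENT_KINDS:
            raise ValueError(f"unknown AS event kind {self.kind!r}")
        if self.kind == "composite" and len(self.parts) < 2:
            raise ValueError("composite events need >=2 primitive edits")

    @property
    def retains_intron(self) -> bool:
        return any(isinstance(p, RetainIntron) for p in self.parts)


# ---------------------------------------------------------------------------
# Gene model
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """Exon/intron structure with an annotated CDS on a genomic sequence.

    ``exons`` are (start, end) pairs, 1-based inclusive, listed 5'->3' in
    transcript order (descending genomic position for minus-strand genes).
    ``cds_start`` / ``cds_end`` are the genomic positions of the first base of
    the start codon and the last base of the stop codon.
    """

    gene_id: str
    genomic_seq: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        self.genomic_seq = self.genomic_seq.upper()
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")

    # -- internal coding-strand view -------------------------------------
    @property
    def coding_seq(self) -> str:
        """Genomic sequence on the coding strand (reverse complement for '-')."""
        if self.strand == "+":
            return self.genomic_seq
        return str(Seq(self.genomic_seq).reverse_complement())

    def _to_coding(self, pos: int) -> int:
        """Map a 1-based genomic position onto the coding-strand sequence."""
        if self.strand == "+":
            return pos
        return len(self.genomic_seq) - pos + 1

    def _interval_to_coding(self, start: int, end: int) -> tuple[int, int]:
        if self.strand == "+":
            return start, end
        return self._to_coding(end), self._to_coding(start)

    @property
    def exons_coding(self) -> list[tuple[int, int]]:
        """Exons as 1-based inclusive intervals on the coding strand, ascending."""
        return [self._interval_to_coding(s, e) for s, e in self.exons]

    @property
    def introns_coding(self) -> list[tuple[int, int]]:
        ex = self.exons_coding
        return [(ex[i][1] + 1, ex[i + 1][0] - 1) for i in range(len(ex) - 1)]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def cds_coding(self) -> tuple[int, int]:
        a, b = self._to_coding(self.cds_start), self._to_coding(self.cds_end)
        return (a, b) if a <= b else (b, a)

    # -- derived UTR intervals (coding-strand coordinates) ----------------
    @property
    def utr5(self) -> list[tuple[int, int]]:
        lo = self.cds_coding[0]
        return _clip_intervals(self.exons_coding, 1, lo - 1)

    @property
    def utr3(self) -> list[tuple[int, int]]:
        hi = self.cds_coding[1]
        return _clip_intervals(self.exons_coding, hi + 1, len(self.genomic_seq))

    # -- invariant checking ----------------------------------------------
    def validate(self) -> None:
        ex = self.exons_coding
        for (s, e) in ex:
            if not (1 <= s <= e <= len(self.genomic_seq)):
                raise AnnotationError(f"{self.gene_id}: exon {s}-{e} outside sequence")
        for i in range(len(ex) - 1):
            if ex[i][1] >= ex[i + 1][0]:
                raise AnnotationError(f"{self.gene_id}: exons overlap or unsorted")
        cds = spliced_cds(self)
        if len(cds) % 3 != 0:
            raise AnnotationError(f"{self.gene_id}: CDS length {len(cds)} not divisible by 3")
        if cds[:3] != "ATG":
            raise AnnotationError(f"{self.gene_id}: CDS does not start with ATG")
        if cds[-3:] not in STOP_CODONS:
            raise AnnotationError(f"{self.gene_id}: CDS does not end in a stop codon")


def _clip_intervals(
    intervals: Sequence[tuple[int, int]], lo: int, hi: int
) -> list[tuple[int, int]]:
    out = []
    for s, e in intervals:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 <= e2:
            out.append((s2, e2))
    return out


# ---------------------------------------------------------------------------
# Transcript assembly
# ---------------------------------------------------------------------------

def _edited_segments(gene: GeneModel, event: Optional[ASEvent]) -> list[tuple[int, int]]:
    """Coding-strand segments (1-based inclusive) retained in the transcript."""
    segments: list[Optional[list[int]]] = [list(iv) for iv in gene.exons_coding]
    inserts: list[tuple[int, list[int]]] = []  # (after exon index 0-based, interval)
    if event is not None:
        merged_introns: set[int] = set()
        for part in event.parts:
            if isinstance(part, RetainIntron):
                if not (1 <= part.index <= gene.n_introns):
                    raise AnnotationError(
                        f"{gene.gene_id}: intron {part.index} does not exist"
                    )
                merged_introns.add(part.index)
            elif isinstance(part, SkipExon):
                if not (1 <= part.index <= gene.n_exons):
                    raise AnnotationError(
                        f"{gene.gene_id}: exon {part.index} does not exist"
                    )
                segments[part.index - 1] = None
            elif isinstance(part, AltSpliceSite):
                if not (1 <= part.exon <= gene.n_exons):
                    raise AnnotationError(
                        f"{gene.gene_id}: exon {part.exon} does not exist"
                    )
                seg = segments[part.exon - 1]
                if seg is None:
                    raise InvalidEventError(
                        f"{event.event_id}: splice-site shift on skipped exon {part.exon}"
                    )
                if part.site == "5ss":  # donor: move the exon's 3' edge
                    seg[1] += part.delta
                else:  # acceptor: move the exon's 5' edge
                    seg[0] -= part.delta
                if seg[0] > seg[1]:
                    raise InvalidEventError(
                        f"{event.event_id}: exon {part.exon} inverted by delta {part.delta}"
                    )
            elif isinstance(part, AltExon):
                s, e = gene._interval_to_coding(part.start, part.end)
                host = None
                for i, (is_, ie) in enumerate(gene.introns_coding, start=1):
                    if is_ < s and e < ie:
                        host = i
                        break
                if host is None:
                    raise AnnotationError(
                        f"{event.event_id}: alternative exon {part.start}-{part.end} "
                        "not inside any intron"
                    )
                inserts.append((host - 1, [s, e]))
            else:  # pragma: no cover - exhaustive
                raise TypeError(f"unknown edit {part!r}")
        # Retained introns merge with their flanking exons into one genomic
        # block.  If a flanking exon is itself skipped (composite events such
        # as intron-1 retention combined with exon-2/3 skipping) the block
        # simply ends at the intron boundary.
        introns0 = gene.introns_coding
        for k in sorted(merged_introns, reverse=True):
            int_s, int_e = introns0[k - 1]
            left, right = segments[k - 1], segments[k]
            if left is None and right is None:
                raise InvalidEventError(
                    f"{event.event_id}: intron {k} retained but both flanking "
                    "exons skipped"
                )
            block = [left[0] if left is not None else int_s,
                     right[1] if right is not None else int_e]
            segments[k - 1] = block
            segments[k] = None
        for after_idx, iv in inserts:
            segments.insert(after_idx + 1, iv)

    out = [tuple(s) for s in segments if s is not None]
    for i in range(len(out) - 1):
        if out[i][1] >= out[i + 1][0]:
            raise InvalidEventError(
                f"{gene.gene_id}: edits produce overlapping/inverted segments "
                f"{out[i]} vs {out[i + 1]}"
            )
    return out


def build_transcript(gene: GeneModel, event: Optional[ASEvent] = None) -> str:
    """Assemble the mature transcript: fully spliced if ``event`` is None,
    otherwise with the event's edits applied 5'->3'."""
    if event is not None and event.gene_id != gene.gene_id:
        raise AnnotationError(
            f"event {event.event_id} targets {event.gene_id}, not {gene.gene_id}"
        )
    cseq = gene.coding_seq
    return "".join(cseq[s - 1 : e] for s, e in _edited_segments(gene, event))


def spliced_cds(gene: GeneModel) -> str:
    """The fully spliced CDS (start codon through stop codon)."""
    lo, hi = gene.cds_coding
    cseq = gene.coding_seq
    parts = []
    for s, e in gene.exons_coding:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 <= e2:
            parts.append(cseq[s2 - 1 : e2])
    return "".join(parts)


def _map_position(segments: Sequence[tuple[int, int]], pos: int) -> Optional[int]:
    """Map a coding-strand genomic position to a 0-based transcript offset."""
    off = 0
    for s, e in segments:
        if s <= pos <= e:
            return off + (pos - s)
        off += e - s + 1
    return None


def translate_cds(cds: str) -> str:
    """Standard-code translation up to (not including) the first stop codon."""
    prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    stop = prot.find("*")
    return prot if stop < 0 else prot[:stop]


# ---------------------------------------------------------------------------
# Consequence classification
# ---------------------------------------------------------------------------

@dataclass
class EventConsequence:
    """Effect of one AS event on the transcript and the encoded protein."""

    event_id: str
    gene_id: str
    transcript_seq: str
    delta_nt: int
    frame_preserved: bool
    ptc: bool
    protein_seq: str
    aa_delta: Optional[int]
    stop_found: bool = True

    @property
    def effect(self) -> str:
        if self.ptc:
            return "premature_termination_codon"
        if self.frame_preserved and self.delta_nt != 0:
            return "in_frame_indel"
        return "none"


def classify_event(gene: GeneModel, event: ASEvent) -> EventConsequence:
    """Translate the edited CDS and classify the event's consequence.

    A PTC is any stop codon at least one codon upstream of the position
    homologous to the annotated stop (no NMD-rule prediction).  ``aa_delta``
    (amino acids lost vs wild type) is defined for frame-preserving events.
    """
    gene.validate()
    fs = build_transcript(gene, None)
    segments = _edited_segments(gene, event)
    edited = build_transcript(gene, event)
    delta_nt = len(edited) - len(fs)

    cds_lo, cds_hi = gene.cds_coding
    start_off = _map_position(segments, cds_lo)
    if start_off is None or edited[start_off : start_off + 3] != "ATG":
        raise ClassificationError(
            f"{event.event_id}: CDS start codon not found in edited transcript"
        )

    wild_protein = translate_cds(spliced_cds(gene))
    protein = translate_cds(edited[start_off:])
    stop_nt = start_off + 3 * len(protein)  # offset of first stop codon start
    stop_found = edited[stop_nt : stop_nt + 3] in STOP_CODONS

    # position homologous to the annotated stop, if its bases survive the edits
    anno_stop_off = _map_position(segments, cds_hi - 2)
    if anno_stop_off is not None:
        ptc = stop_found and stop_nt < anno_stop_off
    else:
        ptc = stop_found and len(protein) < len(wild_protein)

    frame_preserved = (delta_nt % 3 == 0) and not ptc
    aa_delta = len(wild_protein) - len(protein) if frame_preserved else None
    return EventConsequence(
        event_id=event.event_id,
        gene_id=gene.gene_id,
        transcript_seq=edited,
        delta_nt=delta_nt,
        frame_preserved=frame_preserved,
        ptc=ptc,
        protein_seq=protein,
        aa_delta=aa_delta,
        stop_found=stop_found,
    )


@dataclass(frozen=True)
class SpliceSiteViolation:
    gene_id: str
    intron: int
    donor: str
    acceptor: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.gene_id} intron {self.intron}: observed "
            f"{self.donor}..{self.acceptor}, expected GT..AG"
        )


def validate_splice_sites(gene: GeneModel) -> list[SpliceSiteViolation]:
    """Report every intron whose boundary dinucleotides are not GT..AG on the
    coding strand.  Empty list means all introns are canonical."""
    cseq = gene.coding_seq
    violations = []
    for k, (s, e) in enumerate(gene.introns_coding, start=1):
        donor = cseq[s - 1 : s + 1]
        acceptor = cseq[e - 2 : e]
        if donor != "GT" or acceptor != "AG":
            violations.append(SpliceSiteViolation(gene.gene_id, k, donor, acceptor))
    return violations


# ---------------------------------------------------------------------------
# I/O: FASTA + GFF3 in, GFF3/BED/CSV out, event lists as YAML
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_gff3(gff_path, fasta_path) -> dict[str, GeneModel]:
    """Load gene models from a GFF3 annotation plus genomic FASTA.

    Expects one mRNA per gene with exon and CDS children; the CDS features
    delimit cds_start/cds_end (stop codon included, GFF3 plant convention
    as written by :func:`write_gff3`).
    """
    import gffutils

    seqs = read_fasta(fasta_path)
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: dict[str, GeneModel] = {}
    for g in db.features_of_type("gene"):
        exons = []
        cds_intervals = []
        for mrna in db.children(g, featuretype="mRNA"):
            for ex in db.children(mrna, featuretype="exon", order_by="start"):
                exons.append((ex.start, ex.end))
            for c in db.children(mrna, featuretype="CDS", order_by="start"):
                cds_intervals.append((c.start, c.end))
        if not exons:
            continue
        exons.sort()
        lo = min(s for s, _ in cds_intervals)
        hi = max(e for _, e in cds_intervals)
        if g.strand == "-":
            exons = exons[::-1]
            cds_start, cds_end = hi, lo
        else:
            cds_start, cds_end = lo, hi
        genes[g.id] = GeneModel(
            gene_id=g.id,
            genomic_seq=seqs[g.seqid],
            strand=g.strand,
            exons=exons,
            cds_start=cds_start,
            cds_end=cds_end,
        )
    return genes


def write_gff3(path, genes: Iterable[GeneModel]) -> None:
    """Write gene/mRNA/exon/CDS/UTR features, 1-based inclusive coordinates.

    Each gene is written on its own seqid named after the gene (the fixture
    stores one contig per gene)."""
    lines = ["##gff-version 3"]
    for gene in genes:
        gid = gene.gene_id
        span_lo = min(min(s, e) for s, e in gene.exons)
        span_hi = max(max(s, e) for s, e in gene.exons)
        strand = gene.strand

        def feat(ftype, s, e, attrs):
            return f"{gid}\tdielsplice\t{ftype}\t{s}\t{e}\t.\t{strand}\t.\t{attrs}"

        lines.append(feat("gene", span_lo, span_hi, f"ID={gid}"))
        mid = f"{gid}.1"
        lines.append(feat("mRNA", span_lo, span_hi, f"ID={mid};Parent={gid}"))
        cds_lo, cds_hi = gene.cds_coding
        L = len(gene.genomic_seq)

        def to_genomic(iv):
            if gene.strand == "+":
                return iv
            return (L - iv[1] + 1, L - iv[0] + 1)

        for i, iv in enumerate(gene.exons_coding, start=1):
            s, e = to_genomic(iv)
            lines.append(feat("exon", s, e, f"ID={mid}.exon{i};Parent={mid}"))
        for iv in _clip_intervals(gene.exons_coding, cds_lo, cds_hi):
            s, e = to_genomic(iv)
            lines.append(feat("CDS", s, e, f"ID={mid}.cds;Parent={mid}"))
        for iv in gene.utr5:
            s, e = to_genomic(iv)
            lines.append(feat("five_prime_UTR", s, e, f"Parent={mid}"))
        for iv in gene.utr3:
            s, e = to_genomic(iv)
            lines.append(feat("three_prime_UTR", s, e, f"Parent={mid}"))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_bed(path, genes: Iterable[GeneModel]) -> None:
    """Exon intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for gene in genes:
            for i, (s, e) in enumerate(sorted((min(a, b), max(a, b)) for a, b in gene.exons), 1):
                fh.write(f"{gene.gene_id}\t{s - 1}\t{e}\t{gene.gene_id}.exon{i}\t0\t{gene.strand}\n")


def events_to_yaml(events: Iterable[ASEvent]) -> str:
    docs = []
    for ev in events:
        parts = []
        for p in ev.parts:
            if isinstance(p, RetainIntron):
                parts.append({"retain_intron": p.index})
            elif isinstance(p, SkipExon):
                parts.append({"skip_exon": p.index})
            elif isinstance(p, AltSpliceSite):
                parts.append({"alt_splice_site": {"exon": p.exon, "site": p.site, "delta": p.delta}})
            elif isinstance(p, AltExon):
                parts.append({"alt_exon": {"start": p.start, "end": p.end}})
        docs.append(
            {"event_id": ev.event_id, "gene_id": ev.gene_id, "kind": ev.kind, "parts": parts}
        )
    return yaml.safe_dump(docs, sort_keys=False)


def events_from_yaml(text: str) -> list[ASEvent]:
    out = []
    for doc in yaml.safe_load(text) or []:
        parts: list[Edit] = []
        for p in doc.get("parts", []):
            ((key, val),) = p.items()
            if key == "retain_intron":
                parts.append(RetainIntron(int(val)))
            elif key == "skip_exon":
                parts.append(SkipExon(int(val)))
            elif key == "alt_splice_site":
                parts.append(AltSpliceSite(int(val["exon"]), val["site"], int(val["delta"])))
            elif key == "alt_exon":
                parts.append(AltExon(int(val["start"]), int(val["end"])))
            else:
                raise ValueError(f"unknown edit key {key!r}")
        out.append(ASEvent(doc["event_id"], doc["gene_id"], doc["kind"], tuple(parts)))
    return out


def consequences_table(
    genes: dict[str, GeneModel], events: Iterable[ASEvent]
) -> pd.DataFrame:
    """Tidy per-event consequence table (one row per event)."""
    rows = []
    for ev in events:
        cons = classify_event(genes[ev.gene_id], ev)
        rows.append(
            {
                "gene_id": ev.gene_id,
                "event_id": ev.event_id,
                "kind": ev.kind,
                "delta_nt": cons.delta_nt,
                "frame_preserved": cons.frame_preserved,
                "ptc": cons.ptc,
                "aa_delta": cons.aa_delta,
                "effect": cons.effect,
                "transcript_len": len(cons.transcript_seq),
                "protein_len": len(cons.protein_seq),
            }
        )
    return pd.DataFrame(rows)
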