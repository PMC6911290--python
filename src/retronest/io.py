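"""FASTA / GFF3 input and output.

GFF3 files use 1-based inclusive coordinates and the feature vocabulary
LTR_retrotransposon, long_terminal_repeat, protein_domain (with a
``domain`` attribute), primer_binding_site, RNA_polypurine_tract and
target_site_duplication. UTRs and interdomain spacers are implicit (the
gaps between named features) and are reconstructed on reading.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .curate import fill_gap_regions
from .models import DOMAIN_NAMES, GYPSY, AnnotatedElement, Span, TsdRecord

_SOURCE = "retronest"


def write_fasta(path: str | Path, sequences: dict[str, str], wrap: int = 60) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _attrs(**kwargs) -> str:
    parts = []
    for key, value in kwargs.items():
        if value is None:
            continue
        parts.append(f"{key}={value}")
    return ";".join(parts)


def _row(seqid: str, ftype: str, span: Span, strand: str, attrs: str) -> str:
    start, end = span
    return "\t".join(
        [seqid, _SOURCE, ftype, str(start + 1), str(end), ".", strand, ".", attrs]
    )


def write_gff3(path: str | Path, elements: list[AnnotatedElement]) -> None:
    lines = ["##gff-version 3"]
    for el in sorted(elements, key=lambda e: (e.genome_id, e.start, e.end, e.id)):
        attrs = _attrs(
            ID=el.id,
            Parent=el.parent_id,
            family=el.family,
            superfamily=el.superfamily,
            age_mya=None if el.age_mya is None else f"{el.age_mya:.4f}",
            nesting_level=el.nesting_level,
            ltr_identity=None if el.ltr_identity_pct is None
            else f"{el.ltr_identity_pct:.2f}",
            detection_round=el.detection_round,
        )
        lines.append(_row(el.genome_id, "LTR_retrotransposon", el.span,
                          el.strand, attrs))
        for tag, span in (("ltr5", el.ltr5), ("ltr3", el.ltr3)):
            if span is not None:
                lines.append(_row(el.genome_id, "long_terminal_repeat", span,
                                  el.strand, _attrs(ID=f"{el.id}_{tag}",
                                                    Parent=el.id)))
        for name, span in sorted(el.regions.items(), key=lambda kv: kv[1][0]):
            if name in DOMAIN_NAMES:
                lines.append(_row(el.genome_id, "protein_domain", span, el.strand,
                                  _attrs(ID=f"{el.id}_{name}", Parent=el.id,
                                         domain=name)))
            elif name == "pbs":
                lines.append(_row(el.genome_id, "primer_binding_site", span,
                                  el.strand, _attrs(ID=f"{el.id}_pbs",
                                                    Parent=el.id)))
            elif name == "ppt":
                lines.append(_row(el.genome_id, "RNA_polypurine_tract", span,
                                  el.strand, _attrs(ID=f"{el.id}_ppt",
                                                    Parent=el.id)))
        if el.tsd is not None:
            k = el.tsd.length
            for tag, span in (("tsdL", (el.start - k, el.start)),
                              ("tsdR", (el.end, el.end + k))):
                lines.append(_row(el.genome_id, "target_site_duplication", span,
                                  el.strand, _attrs(ID=f"{el.id}_{tag}",
                                                    Parent=el.id,
                                                    tsd_seq=el.tsd.seq)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[AnnotatedElement]:
    """Read annotations back into :class:`AnnotatedElement` objects.

    Implicit regions (UTRs, interdomain spacers) are reconstructed from the
    gaps between named features; sequences are not attached (use
    :func:`read_fasta` plus the element spans for that).
    """
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    elements: dict[str, AnnotatedElement] = {}
    children: dict[str, list] = {}
    for feat in db.all_features():
        if feat.featuretype == "LTR_retrotransposon":
            attrs = feat.attributes
            el = AnnotatedElement(
                id=attrs["ID"][0],
                genome_id=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                family=attrs.get("family", ["unknown"])[0],
                superfamily=attrs.get("superfamily", ["unknown"])[0],
                nesting_level=int(attrs.get("nesting_level", [0])[0]),
                parent_id=attrs.get("Parent", [None])[0],
                age_mya=float(attrs["age_mya"][0]) if "age_mya" in attrs else None,
                ltr_identity_pct=float(attrs["ltr_identity"][0])
                if "ltr_identity" in attrs else None,
                detection_round=int(attrs["detection_round"][0])
                if "detection_round" in attrs else None,
            )
            elements[el.id] = el
        else:
            parent = feat.attributes.get("Parent", [None])[0]
            if parent is not None:
                children.setdefault(parent, []).append(feat)

    for el_id, el in elements.items():
        named: dict[str, Span] = {}
        ltrs: list[Span] = []
        tsd_spans: list[tuple[Span, str]] = []
        for feat in children.get(el_id, []):
            span = (feat.start - 1, feat.end)
            if feat.featuretype == "long_terminal_repeat":
                ltrs.append(span)
            elif feat.featuretype == "protein_domain":
                named[feat.attributes["domain"][0]] = span
            elif feat.featuretype == "primer_binding_site":
                named["pbs"] = span
            elif feat.featuretype == "RNA_polypurine_tract":
                named["ppt"] = span
            elif feat.featuretype == "target_site_duplication":
                tsd_spans.append((span, feat.attributes.get("tsd_seq", [""])[0]))
        ltrs.sort()
        if len(ltrs) >= 2:
            el.ltr5, el.ltr3 = ltrs[0], ltrs[-1]
            has_chr = "CHR" in named if el.superfamily == GYPSY else None
            el.regions = fill_gap_regions(el, named, has_chr=has_chr)
        if tsd_spans:
            (span, seq) = sorted(tsd_spans)[0]
            if seq:
                el.tsd = TsdRecord(element_id=el_id, length=len(seq), seq=seq)
    return sorted(elements.values(), key=lambda e: (e.genome_id, e.start, e.id))
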