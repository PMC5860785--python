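"""SAM import/export (pysam-backed).

External aligner output is ingested from SAM text; mates are paired by
QNAME and uniqueness is assigned from mapping quality.  Gapped alignments
are accepted on import (coordinates come from the aligner); the built-in
mapper's export is always ungapped.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional

import pysam

from ._seq import revcomp
from .errors import ConfigurationError
from .pairs import EndAlignment, ReadPairAlignment

logger = logging.getLogger(__name__)


def import_sam(path: str, ref, mapq_unique: int = 20) -> list:
    """Read a SAM file into :class:`ReadPairAlignment` objects.

    Ends with MAPQ >= ``mapq_unique`` are labelled unique, mapped ends
    below the threshold multi; unmapped mates are preserved.  QNAMEs with
    a primary-record count other than two are skipped with a warning.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        header = fh.header.to_dict()
        sq = {d["SN"]: d["LN"] for d in header.get("SQ", [])}
        if not sq:
            raise ConfigurationError("SAM lacks @SQ header lines")
        for chrom, n in sq.items():
            if chrom not in ref.sequences:
                raise ConfigurationError(f"SAM reference {chrom!r} not in the reference genome")
            if n != len(ref.sequences[chrom]):
                raise ConfigurationError(
                    f"SAM @SQ length for {chrom} ({n}) != reference ({len(ref.sequences[chrom])})"
                )
        by_name: dict = {}
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            by_name.setdefault(rec.query_name, []).append(rec)

    pairs = []
    for name in sorted(by_name):
        recs = by_name[name]
        if len(recs) != 2:
            warnings.warn(
                f"QNAME {name!r} has {len(recs)} primary records; skipped", stacklevel=2
            )
            continue
        ends = [_end_from_record(r, mapq_unique) for r in recs]
        pairs.append(ReadPairAlignment(name, ends[0], ends[1]))
    return pairs


def _end_from_record(rec, mapq_unique: int) -> EndAlignment:
    seq = rec.query_sequence or ""
    if rec.is_unmapped:
        return EndAlignment(None, None, None, None, "unmapped", None, seq)
    status = "unique" if rec.mapping_quality >= mapq_unique else "multi"
    strand = "-" if rec.is_reverse else "+"
    if rec.is_reverse:
        seq = revcomp(seq)  # store read as sequenced
    nm = rec.get_tag("NM") if rec.has_tag("NM") else None
    return EndAlignment(
        rec.reference_name,
        rec.reference_start,
        rec.reference_end,
        strand,
        status,
        nm,
        seq,
    )


def write_sam(pairs: list, ref, path: str) -> None:
    """Export mapped pairs as SAM with standard FLAG semantics."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in ref.sequences.items()],
        "PG": [{"ID": "gcrscope", "PN": "gcrscope"}],
    }
    tid = {c: i for i, c in enumerate(ref.sequences)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for p in pairs:
            for i, (end, mate) in enumerate(((p.end1, p.end2), (p.end2, p.end1))):
                rec = pysam.AlignedSegment()
                rec.query_name = p.pair_id
                flag = 0x1 | (0x40 if i == 0 else 0x80)
                seq = end.seq
                if end.mapped:
                    rec.reference_id = tid[end.chrom]
                    rec.reference_start = end.start
                    rec.mapping_quality = 60 if end.status == "unique" else 0
                    rec.cigarstring = f"{len(seq)}M"
                    if end.strand == "-":
                        flag |= 0x10
                        seq = revcomp(seq)
                    if end.mismatches is not None:
                        rec.set_tag("NM", int(end.mismatches))
                else:
                    flag |= 0x4
                    rec.reference_id = -1
                    rec.reference_start = -1
                if mate.mapped:
                    rec.next_reference_id = tid[mate.chrom]
                    rec.next_reference_start = mate.start
                    if mate.strand == "-":
                        flag |= 0x20
                else:
                    flag |= 0x8
                    rec.next_reference_id = -1
                    rec.next_reference_start = -1
                if p.duplicate:
                    flag |= 0x400
                rec.flag = flag
                rec.query_sequence = seq
                rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                out.write(rec)
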