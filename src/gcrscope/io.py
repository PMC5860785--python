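"""Writers for the standard interchange formats.

Coordinates are converted from the library's 0-based half-open internal
convention to each format's native convention (BED/bedGraph stay 0-based
half-open; VCF breakends are 1-based).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(ref_or_genome, path) -> None:
    if hasattr(ref_or_genome, "sequences"):
        items = ref_or_genome.sequences.items()
    else:
        items = [(m.name, m.seq) for m in ref_or_genome.molecules]
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in items]
    SeqIO.write(records, str(path), "fasta")


def write_features_bed(ref, path, sidecar_json=None) -> None:
    rows = [
        {
            "chrom": f.chrom,
            "start": f.start,
            "end": f.end,
            "name": f.name,
            "score": 0,
            "strand": f.strand,
        }
        for f in ref.features
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
    if sidecar_json:
        meta = [
            {"name": f.name, "kind": f.kind, "chrom": f.chrom, "start": f.start, "end": f.end}
            for f in ref.features
        ]
        Path(sidecar_json).write_text(json.dumps(meta, indent=2))


def write_mask_bed(mask: dict, path) -> None:
    """Uniquely-mappable territory as BED intervals."""
    import numpy as np

    rows = []
    for chrom, m in mask.items():
        diffs = np.flatnonzero(np.diff(np.concatenate([[0], m.astype(int), [0]])))
        for s, e in zip(diffs[::2], diffs[1::2]):
            rows.append((chrom, int(s), int(e)))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(profile_values: dict, path, precision: int = 3) -> None:
    """Per-base profile compressed to constant-value runs."""
    import numpy as np

    with open(path, "w") as fh:
        for chrom, vals in profile_values.items():
            v = np.round(np.nan_to_num(vals, nan=-1.0), precision)
            edges = np.flatnonzero(np.diff(v) != 0) + 1
            starts = np.concatenate([[0], edges])
            ends = np.concatenate([edges, [len(v)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{v[s]}\n")


def write_truth_tsv(truths: list, path) -> None:
    rows = []
    for i, t in enumerate(truths):
        rows.append(
            {
                "isolate": f"sim{i:03d}",
                "event_class": t.event_class,
                "group": t.group,
                "hph_retained": t.hph_retained,
                "derivative_length": t.derivative_length,
                "secondary_type": t.secondary_type,
                "stem_len": t.stem_len,
                "loop_len": t.loop_len,
                "disomies": ",".join(t.disomies),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_junctions_tsv(junctions: list, path) -> None:
    rows = []
    for j in junctions:
        rows.append(
            {
                "chrom_a": j.breakend_a.chrom,
                "pos_a": j.breakend_a.pos + 1,  # 1-based in reports
                "side_a": j.breakend_a.side,
                "chrom_b": j.breakend_b.chrom,
                "pos_b": j.breakend_b.pos + 1,
                "side_b": j.breakend_b.side,
                "n_defining_pairs": j.n_defining_pairs,
                "n_sequencing_reads": j.n_sequencing_reads,
                "microhomology_len": j.microhomology_len,
                "inserted_sequence": j.inserted_sequence,
                "noise_pvalue": j.noise_pvalue,
                "kept": j.kept,
                "junction_sequence": j.junction_sequence or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_breakend_vcf(junctions: list, ref, path) -> None:
    """Junction calls as VCF BND records (paired breakends)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">\n')
        fh.write(
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="Junction-defining pairs">\n'
        )
        for c, s in ref.sequences.items():
            fh.write(f"##contig=<ID={c},length={len(s)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, j in enumerate(k for k in junctions if k.kept):
            for tag, be, other in (
                ("a", j.breakend_a, j.breakend_b),
                ("b", j.breakend_b, j.breakend_a),
            ):
                pos = max(be.pos, 1)
                base = ref.sequences[be.chrom][pos - 1]
                mate = f"{other.chrom}:{max(other.pos, 1)}"
                if be.side == "retains_left":
                    alt = f"{base}[{mate}["
                else:
                    alt = f"]{mate}]{base}"
                fh.write(
                    f"{be.chrom}\t{pos}\tbnd_{i}_{tag}\t{base}\t{alt}\t.\tPASS\t"
                    f"SVTYPE=BND;MATEID=bnd_{i}_{'b' if tag == 'a' else 'a'};"
                    f"DP={j.n_defining_pairs}\n"
                )
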