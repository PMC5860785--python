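"""SAM export/import and agreement with an external aligner."""

import shutil
import subprocess

import pytest

from gcrscope.errors import ConfigurationError
from gcrscope.readsim import ReadSimConfig, simulate_read_pairs, write_fastq
from gcrscope.samio import import_sam, write_sam


@pytest.fixture(scope="module")
def mapped_subset(ref, ctx):
    reads, _ = simulate_read_pairs(
        ref.sequences,
        ReadSimConfig(coverage=3, base_error_rate=0.0, duplicate_fraction=0.0, rng_seed=31),
    )
    return reads, ctx.index.map_pairs(reads)


def test_export_import_roundtrip(ref, mapped_subset, tmp_path):
    _, pairs = mapped_subset
    path = tmp_path / "out.sam"
    write_sam(pairs, ref, path)
    back = import_sam(path, ref)
    orig = {p.pair_id: p for p in pairs}
    assert len(back) == len(pairs)
    agree = 0
    total = 0
    for p in back:
        o = orig[p.pair_id]
        for eb, eo in zip(p.ends, o.ends):
            if eo.status != "unique":
                continue
            total += 1
            agree += (eb.chrom, eb.start, eb.strand) == (eo.chrom, eo.start, eo.strand)
    assert agree == total > 0


def test_mapq_threshold_labels_multi(ref, mapped_subset, tmp_path):
    _, pairs = mapped_subset
    path = tmp_path / "out.sam"
    write_sam(pairs, ref, path)
    back = import_sam(path, ref, mapq_unique=20)
    for p in back:
        for e in p.ends:
            assert e.status in ("unique", "multi", "unmapped")
    # our exporter writes MAPQ 0 for multi -> import must not call them unique
    multi_in = sum(e.status == "multi" for p in pairs for e in p.ends)
    multi_out = sum(e.status == "multi" for p in back for e in p.ends)
    assert multi_out == multi_in


def test_missing_sq_header_rejected(ref, tmp_path):
    bad = tmp_path / "bad.sam"
    bad.write_text("r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n")
    with pytest.raises(ConfigurationError, match="@SQ"):
        import_sam(bad, ref)


def test_header_reference_mismatch_rejected(ref, tmp_path):
    bad = tmp_path / "bad.sam"
    bad.write_text("@SQ\tSN:chrV\tLN:999\n")
    with pytest.raises(ConfigurationError, match="chrV"):
        import_sam(bad, ref)


def test_odd_qname_skipped_with_warning(ref, tmp_path):
    sam = tmp_path / "odd.sam"
    sam.write_text(
        "@SQ\tSN:chrV\tLN:30000\n@SQ\tSN:chrII\tLN:30000\n@SQ\tSN:chrIII\tLN:20000\n"
        "solo\t0\tchrV\t101\t60\t4M\t*\t0\t0\tACGT\tIIII\n"
    )
    with pytest.warns(UserWarning, match="solo"):
        pairs = import_sam(sam, ref)
    assert pairs == []


@pytest.mark.skipif(shutil.which("bwa") is None, reason="bwa not on PATH")
def test_external_aligner_agreement(ref, ctx, tmp_path):
    """Import of bwa's SAM and the built-in mapper agree on >= 99% of
    unique placements for error-free reads."""
    from gcrscope.io import write_fasta

    fa = tmp_path / "ref.fasta"
    write_fasta(ref, fa)
    reads, _ = simulate_read_pairs(
        ref.sequences,
        ReadSimConfig(coverage=2, base_error_rate=0.0, duplicate_fraction=0.0, rng_seed=33),
    )
    r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
    write_fastq(reads, r1, r2)
    subprocess.run(["bwa", "index", str(fa)], check=True, capture_output=True)
    sam = tmp_path / "bwa.sam"
    with open(sam, "w") as out:
        subprocess.run(
            ["bwa", "mem", str(fa), str(r1), str(r2)],
            check=True,
            stdout=out,
            stderr=subprocess.DEVNULL,
        )
    imported = {p.pair_id: p for p in import_sam(sam, ref)}
    ours = ctx.index.map_pairs(reads)
    agree = 0
    total = 0
    for op in ours:
        ip = imported.get(op.pair_id)
        if ip is None:
            continue
        for eo, ei in zip(op.ends, ip.ends):
            if eo.status == "unique" and ei.status == "unique":
                total += 1
                agree += (eo.chrom, eo.start) == (ei.chrom, ei.start)
    assert total > 500
    assert agree / total >= 0.99
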