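"""Paired-end read simulation (Illumina-style FR protocol).

Fragments are drawn uniformly along each molecule proportional to length;
insert sizes are normal, truncated below at twice the read length; the two
ends are read inward.  Substitution errors only (no indels, no quality
model) and optional verbatim PCR duplicates.  Deterministic per seed.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from ._seq import BASES, revcomp
from .errors import ConfigurationError
from .events import Molecule


@dataclass
class ReadSimConfig:
    coverage: float = 50.0
    read_len: int = 100
    insert_mean: float = 600.0  # gel-selected ~600 bp fragments
    insert_sd: float = 60.0
    base_error_rate: float = 0.01
    duplicate_fraction: float = 0.02
    rng_seed: int = 0

    def __post_init__(self):
        if self.coverage <= 0:
            raise ConfigurationError("coverage must be > 0")
        for name in ("base_error_rate", "duplicate_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.insert_mean <= 2 * self.read_len:
            warnings.warn(
                "insert_mean <= 2*read_len: read pairs will overlap heavily",
                stacklevel=2,
            )


@dataclass
class ReadPair:
    pair_id: str
    seq1: str
    seq2: str


@dataclass
class FragmentTruth:
    """Per-fragment truth table emitted alongside the reads."""

    pair_id: str
    molecule: str
    start: int
    end: int
    is_duplicate_of: Optional[str] = None


def simulate_read_pairs(
    genome, config: Optional[ReadSimConfig] = None
) -> tuple:
    """Simulate paired reads from a genome.

    ``genome`` is a :class:`~gcrscope.events.RearrangedGenome`, a list of
    :class:`Molecule`, or a dict name->sequence.  Returns
    ``(list[ReadPair], list[FragmentTruth])``.
    """
    config = config or ReadSimConfig()
    if hasattr(genome, "molecules"):
        molecules = genome.molecules
    elif isinstance(genome, dict):
        molecules = [Molecule(k, v) for k, v in genome.items()]
    else:
        molecules = list(genome)
    if not molecules or all(len(m) == 0 for m in molecules):
        raise ConfigurationError("cannot simulate reads from an empty genome")

    rng = np.random.default_rng(config.rng_seed)
    rl = config.read_len
    lengths = np.array([len(m) for m in molecules], dtype=float)
    total = lengths.sum()
    n_frag = int(round(config.coverage * total / (2 * rl)))

    mol_idx = rng.choice(len(molecules), size=n_frag, p=lengths / total)
    inserts = rng.normal(config.insert_mean, config.insert_sd, size=n_frag)
    inserts = np.maximum(inserts, 2 * rl).astype(int)

    pairs: list = []
    truth: list = []
    error = config.base_error_rate

    def _read_with_errors(seq: str) -> str:
        if error <= 0:
            return seq
        k = rng.binomial(len(seq), error)
        if k == 0:
            return seq
        pos = rng.choice(len(seq), size=k, replace=False)
        out = list(seq)
        for i in pos:
            alts = [b for b in BASES if b != out[i]]
            out[i] = alts[rng.integers(3)]
        return "".join(out)

    def _emit(pid: str, mol: Molecule, start: int, end: int, dup_of=None):
        frag = mol.seq[start:end]
        r_fwd = _read_with_errors(frag[:rl])
        r_rev = _read_with_errors(revcomp(frag[-rl:]))
        if rng.random() < 0.5:
            pairs.append(ReadPair(pid, r_fwd, r_rev))
        else:
            pairs.append(ReadPair(pid, r_rev, r_fwd))
        truth.append(FragmentTruth(pid, mol.name, start, end, dup_of))

    for n, (mi, ins) in enumerate(zip(mol_idx, inserts)):
        mol = molecules[mi]
        ins = min(int(ins), len(mol))
        start = int(rng.integers(0, len(mol) - ins + 1))
        _emit(f"frag{n:07d}", mol, start, start + ins)

    n_dup = int(round(config.duplicate_fraction * n_frag))
    if n_dup:
        src = rng.choice(n_frag, size=n_dup, replace=True)
        for j, s in enumerate(src):
            t = truth[s]
            mol = molecules[[m.name for m in molecules].index(t.molecule)]
            _emit(f"dup{j:06d}", mol, t.start, t.end, dup_of=t.pair_id)

    return pairs, truth


def write_fastq(pairs: Iterable[ReadPair], path1: str, path2: str) -> None:
    """Write paired reads as gzip FASTQ (constant quality)."""

    def _open(p):
        return gzip.open(p, "wt") if str(p).endswith(".gz") else open(p, "w")

    with _open(path1) as f1, _open(path2) as f2:
        for p in pairs:
            f1.write(f"@{p.pair_id}/1\n{p.seq1}\n+\n{'I' * len(p.seq1)}\n")
            f2.write(f"@{p.pair_id}/2\n{p.seq2}\n+\n{'I' * len(p.seq2)}\n")


def read_fastq(path1: str, path2: str) -> list:
    """Read paired gzip/plain FASTQ back into ReadPair objects."""

    def _open(p):
        return gzip.open(p, "rt") if str(p).endswith(".gz") else open(p)

    def _records(fh):
        while True:
            name = fh.readline().strip()
            if not name:
                return
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield name[1:].rsplit("/", 1)[0], seq

    out = []
    with _open(path1) as f1, _open(path2) as f2:
        for (n1, s1), (n2, s2) in zip(_records(f1), _records(f2)):
            if n1 != n2:
                raise ConfigurationError(f"FASTQ pair mismatch: {n1} vs {n2}")
            out.append(ReadPair(n1, s1, s2))
    return out
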