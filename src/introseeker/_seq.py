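"""Low-level nucleotide sequence helpers shared across the package.

Sequences are plain uppercase strings over A/C/G/T (plus N where a module
explicitly allows it).  For numeric work they are encoded as uint8 arrays
with A=0, C=1, G=2, T=3, N=4; code 4 never matches anything.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

N_CODE = 4

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase
_ENCODE[ord("N")] = N_CODE
_ENCODE[ord("n")] = N_CODE

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string to uint8 codes; reject non-ACGTN symbols."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[raw]
    if (codes == 255).any():
        bad = chr(raw[int(np.argmax(codes == 255))])
        raise ValueError(f"illegal symbol {bad!r}: alphabet is A/C/G/T/N")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    rc = np.where(codes < 4, 3 - codes, N_CODE).astype(np.uint8)
    return rc[::-1]


def validate_sequence(seq: str, allow_n: bool = True) -> str:
    """Return the uppercased sequence or raise on symbols outside the alphabet."""
    up = seq.upper()
    allowed = set("ACGTN" if allow_n else "ACGT")
    bad = set(up) - allowed
    if bad:
        raise ValueError(f"illegal symbols {sorted(bad)}: alphabet is {sorted(allowed)}")
    return up


def random_codes(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return decode(random_codes(rng, length))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. point substitutions at the given per-site rate.

    Each selected site is replaced by a uniformly chosen *different* base, so
    the expected mismatch fraction against the input equals ``rate`` exactly.
    N sites are left untouched.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("substitution rate must lie in [0, 1]")
    codes = encode(seq)
    mask = (rng.random(codes.shape[0]) < rate) & (codes < 4)
    shifts = rng.integers(1, 4, size=codes.shape[0], dtype=np.uint8)
    codes[mask] = (codes[mask] + shifts[mask]) % 4
    return decode(codes)


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: Mapping[str, str]) -> None:
    records = (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items())
    SeqIO.write(records, str(path), "fasta")


def parse_chrom(label: str) -> tuple[int, str]:
    """Split a chromosome label into (homoeologous group, genome tag).

    The group is the leading integer, e.g. "4D" -> (4, "D"), "4Ns" -> (4, "Ns").
    Labels without a leading integer or without a tag are rejected.
    """
    i = 0
    while i < len(label) and label[i].isdigit():
        i += 1
    if i == 0 or i == len(label):
        raise ValueError(f"cannot parse chromosome label {label!r}: expected e.g. '4D' or '4Ns'")
    return int(label[:i]), label[i:]


def chrom_sort_key(label: str) -> tuple[int, str]:
    return parse_chrom(label)


def sorted_chroms(labels: Iterable[str]) -> list[str]:
    return sorted(labels, key=chrom_sort_key)
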