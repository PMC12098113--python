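"""Small DNA helpers shared across the package.

Genomes are handled as plain ``{chromosome: sequence}`` mappings in memory;
anything that indexes like ``genome[chrom][start:end]`` (e.g. a
:class:`pyfaidx.Fasta`) works too.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA of length ``n``."""
    idx = rng.integers(0, 4, size=n)
    return "".join(np.frombuffer(b"ACGT", dtype="S1").astype(str)[idx])


def fetch(genome: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    """Slice ``genome[chrom][start:end]`` and return an upper-case string.

    Works for dict-of-str genomes and for pyfaidx ``Fasta`` objects, whose
    slices are ``Sequence`` records rather than ``str``.
    """
    if start < 0 or end < start:
        raise ValueError(f"bad slice [{start}, {end}) on {chrom}")
    return str(genome[chrom][start:end]).upper()
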