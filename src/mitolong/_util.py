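"""Shared helpers: sequence encoding, seeded substreams, reporting-grade rounding."""

from __future__ import annotations

import zlib
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

BASES = "ACGT"

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an ACGTN string as uint8 codes 0..4."""
    codes = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) > 4:
        raise ValueError("invalid alphabet")
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def revcomp(seq: str) -> str:
    return codes_to_seq(revcomp_codes(seq_to_codes(seq)))


def rng_for(seed: int, *stage) -> np.random.Generator:
    """Named, independent random substream derived from a master seed.

    Each stage label is hashed into the seed sequence so adding a new stage
    never perturbs the draws of existing ones.
    """
    words = [int(seed) & 0x7FFFFFFF]
    words += [zlib.crc32(str(s).encode("utf-8")) for s in stage]
    return np.random.default_rng(np.random.SeedSequence(words))


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (the convention of printed percentages/scores)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
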