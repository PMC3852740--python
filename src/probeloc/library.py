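"""Combinatorial probe library: building blocks, fingerprints, compounds.

The library emulates a styryl-type combinatorial dye collection in which every
member is the condensation product of one cationic "head" group (a pyridinium
or quinolinium methyl unit, lettered A, B, C, ...) with one aldehyde (numbered
1..n).  Each compound carries a single fixed +1 charge; a subset of blocks
contribute one additional basic ionizable group each, so compounds have 0-2
extra ionizable groups.  Physicochemical properties (logP, extra pKa values)
and an 881-bit substructure-key fingerprint are derived additively from the
two blocks, which is what makes building-block-level analyses meaningful.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

#: Length of the binary substructure-key fingerprint.
N_FINGERPRINT_BITS = 881

#: Bits present in every compound (the shared styryl scaffold).
SCAFFOLD_BITS = frozenset(range(10))

# Layout of per-block signature bits within the 881-bit space.  Consecutive
# blocks get overlapping sliding windows so that block-to-block Tanimoto
# similarity decays smoothly with index distance; distant blocks share only
# the scaffold.
_ALDEHYDE_REGION_START = 10
_ALDEHYDE_STRIDE = 3
_HEAD_REGION_START = 550
_HEAD_STRIDE = 6
_SIGNATURE_WIDTH = 30


@dataclass(frozen=True)
class Fingerprint:
    """An 881-bit binary substructure fingerprint, stored as the on-bit set."""

    bits: frozenset
    n_bits: int = N_FINGERPRINT_BITS

    def __post_init__(self):
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.n_bits):
            raise ValueError("fingerprint bit index out of range")

    @property
    def count(self) -> int:
        return len(self.bits)

    def to_string(self) -> str:
        """Render as an ``n_bits``-character 0/1 string (bit 0 first)."""
        chars = ["0"] * self.n_bits
        for b in self.bits:
            chars[b] = "1"
        return "".join(chars)

    @classmethod
    def from_string(cls, s: str) -> "Fingerprint":
        if len(s) != N_FINGERPRINT_BITS or set(s) - {"0", "1"}:
            raise ValueError("fingerprint string must be 881 characters of 0/1")
        return cls(bits=frozenset(i for i, c in enumerate(s) if c == "1"))


@dataclass(frozen=True)
class BuildingBlock:
    """One half of a combinatorial compound (head group or aldehyde)."""

    kind: str  # "head" | "aldehyde"
    index: int  # 1-based within its kind
    logp_contribution: float
    extra_ionizable: int = 0  # count of additional basic groups (0 or 1 here)
    pka_values: tuple = ()
    signature_bits: frozenset = frozenset()

    def __post_init__(self):
        if self.kind not in ("head", "aldehyde"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.index < 1:
            raise ValueError("block index must be >= 1")
        if len(self.pka_values) != self.extra_ionizable:
            raise ValueError("pka_values length must equal extra_ionizable")

    @property
    def label(self) -> str:
        """Head blocks are lettered (A, B, ...), aldehydes numbered."""
        if self.kind == "head" and self.index <= 26:
            return string.ascii_uppercase[self.index - 1]
        return str(self.index)

    def fingerprint(self) -> Fingerprint:
        """Fingerprint of the block alone: its signature plus the scaffold."""
        return Fingerprint(bits=frozenset(self.signature_bits) | SCAFFOLD_BITS)


@dataclass
class Compound:
    """A library member: one head plus one aldehyde, fixed +1 charge."""

    head: BuildingBlock
    aldehyde: BuildingBlock
    logp: float
    fingerprint: Fingerprint
    fixed_charge: int = 1
    extra_pkas: tuple = ()
    true_class: str | None = None  # organelle | membrane | nuclear, set by a screen

    def __post_init__(self):
        if self.fixed_charge != 1:
            raise ValueError("library compounds carry a single fixed +1 charge")
        if len(self.extra_pkas) > 2:
            raise ValueError("at most 2 additional ionizable groups")

    @property
    def compound_id(self) -> str:
        return f"{self.head.label}-{self.aldehyde.label}"

    @property
    def n_extra_ionizable(self) -> int:
        return len(self.extra_pkas)


def _signature_bits(kind: str, index: int) -> frozenset:
    if kind == "aldehyde":
        start = _ALDEHYDE_REGION_START + (index - 1) * _ALDEHYDE_STRIDE
        limit = _HEAD_REGION_START
    else:
        start = _HEAD_REGION_START + (index - 1) * _HEAD_STRIDE
        limit = N_FINGERPRINT_BITS
    stop = start + _SIGNATURE_WIDTH
    if stop > limit:
        raise ValueError(
            f"{kind} index {index} does not fit in the fingerprint bit layout"
        )
    return frozenset(range(start, stop))


def assign_fingerprint(head: BuildingBlock, aldehyde: BuildingBlock) -> Fingerprint:
    """Compound fingerprint: union of block signatures plus the scaffold.

    Compounds sharing a block therefore share that block's bits, giving them
    controllably higher Tanimoto similarity than compounds sharing none.
    """
    return Fingerprint(
        bits=frozenset(head.signature_bits)
        | frozenset(aldehyde.signature_bits)
        | SCAFFOLD_BITS
    )


def make_blocks(
    n_heads: int,
    n_aldehydes: int,
    seed: int,
    extra_head_fraction: float = 2 / 8,
    extra_aldehyde_fraction: float = 44 / 168,
) -> tuple[list[BuildingBlock], list[BuildingBlock]]:
    """Generate the two block sets with seeded properties.

    At the default fractions an 8 x 168 library has 2 head and 44 aldehyde
    blocks carrying one extra basic group, yielding 1256/1344 compounds with
    0 or 1 extra ionizable groups (the subset the transport model simulates).
    """
    if n_heads < 1 or n_aldehydes < 1:
        raise ValueError("block counts must be positive")
    rng = np.random.default_rng(seed)

    n_extra_heads = round(n_heads * extra_head_fraction)
    n_extra_alds = round(n_aldehydes * extra_aldehyde_fraction)
    extra_heads = set(rng.choice(n_heads, size=n_extra_heads, replace=False) + 1)
    extra_alds = set(rng.choice(n_aldehydes, size=n_extra_alds, replace=False) + 1)

    def build(kind, index, lo, hi, has_extra):
        pkas = (float(rng.uniform(4.0, 10.0)),) if has_extra else ()
        return BuildingBlock(
            kind=kind,
            index=index,
            logp_contribution=float(rng.uniform(lo, hi)),
            extra_ionizable=1 if has_extra else 0,
            pka_values=pkas,
            signature_bits=_signature_bits(kind, index),
        )

    # head contributions 0.8-2.0, aldehyde 1.2-4.0: sums land in [2, 6]
    heads = [
        build("head", j, 0.8, 2.0, j in extra_heads) for j in range(1, n_heads + 1)
    ]
    aldehydes = [
        build("aldehyde", i, 1.2, 4.0, i in extra_alds)
        for i in range(1, n_aldehydes + 1)
    ]
    return heads, aldehydes


def generate_library(
    n_heads: int,
    n_aldehydes: int,
    seed: int,
    logp_noise_sd: float = 0.0,
    **block_kwargs,
) -> list[Compound]:
    """Enumerate the full combinatorial library (one compound per block pair).

    Properties are reproducible from ``seed``: logP is the sum of the two
    blocks' contributions (plus optional seeded Gaussian noise), extra pKas
    are the concatenation of the blocks' pKa lists, and the fingerprint is
    the union of block signatures with the shared scaffold.
    """
    if n_heads < 1 or n_aldehydes < 1:
        raise ValueError("n_heads and n_aldehydes must be positive")
    heads, aldehydes = make_blocks(n_heads, n_aldehydes, seed, **block_kwargs)
    noise_rng = np.random.default_rng(seed + 1)
    library = []
    for head in heads:
        for ald in aldehydes:
            logp = head.logp_contribution + ald.logp_contribution
            if logp_noise_sd > 0:
                logp += float(noise_rng.normal(0.0, logp_noise_sd))
            library.append(
                Compound(
                    head=head,
                    aldehyde=ald,
                    logp=logp,
                    fingerprint=assign_fingerprint(head, ald),
                    extra_pkas=head.pka_values + ald.pka_values,
                )
            )
    return library
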