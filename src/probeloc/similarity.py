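"""Binary-fingerprint similarity and property-histogram comparison.

The Tanimoto coefficient of two substructure fingerprints is
Tc = C / (N1 + N2 - C), where N1 and N2 count the bits set in each
fingerprint and C counts the bits set in both.  Building blocks are ranked
against a reference compound by the Tc between block-level fingerprints
(block signature bits plus the shared scaffold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library import BuildingBlock, Compound, Fingerprint


@dataclass(frozen=True)
class SimilarityRecord:
    n_features_a: int
    n_features_b: int
    n_common: int
    tc: float
    degenerate: bool = False  # True when both fingerprints were empty


@dataclass(frozen=True)
class PropertyHistogramPair:
    property_name: str
    bin_edges: np.ndarray
    counts_library: np.ndarray
    counts_reference: np.ndarray


def tanimoto(a: Fingerprint, b: Fingerprint) -> SimilarityRecord:
    """Tanimoto coefficient Tc = C / (N1 + N2 - C) of two fingerprints.

    Two all-zero fingerprints give Tc = 0 with ``degenerate=True`` rather
    than a division error, so batch sorting never crashes on blanks.
    """
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprint lengths differ")
    n1, n2 = len(a.bits), len(b.bits)
    c = len(a.bits & b.bits)
    denom = n1 + n2 - c
    if denom == 0:
        return SimilarityRecord(n1, n2, c, 0.0, degenerate=True)
    return SimilarityRecord(n1, n2, c, c / denom)


def _block_rank_table(
    blocks: list[BuildingBlock], reference_block: BuildingBlock
) -> pd.DataFrame:
    ref_fp = reference_block.fingerprint()
    rows = []
    for blk in blocks:
        rec = tanimoto(blk.fingerprint(), ref_fp)
        rows.append(
            {
                "block_kind": blk.kind,
                "block_index": blk.index,
                "N1": rec.n_features_a,
                "N2": rec.n_features_b,
                "C": rec.n_common,
                "Tc": rec.tc,
            }
        )
    table = pd.DataFrame(rows)
    # reference block pinned first, then Tc descending, ties by ascending index
    is_ref = table["block_index"] == reference_block.index
    table = table.iloc[
        np.lexsort((table["block_index"], -table["Tc"], ~is_ref))
    ].reset_index(drop=True)
    table["rank"] = np.arange(len(table))
    return table


def rank_blocks_by_similarity(
    library: list[Compound], reference: Compound
) -> tuple[list[int], list[int], dict[str, pd.DataFrame]]:
    """Order aldehyde and head blocks by Tc to the reference compound's blocks.

    Returns the ordered aldehyde indices, ordered head indices, and the two
    full similarity tables (keys ``"aldehyde"`` and ``"head"``).  The
    reference's own blocks come first (Tc = 1); remaining blocks are sorted
    by decreasing Tc with ties broken by ascending block index.
    """
    ids = {c.compound_id for c in library}
    if reference.compound_id not in ids:
        raise KeyError(f"reference {reference.compound_id} not in library")
    heads = {c.head.index: c.head for c in library}
    aldehydes = {c.aldehyde.index: c.aldehyde for c in library}
    ald_table = _block_rank_table(
        [aldehydes[i] for i in sorted(aldehydes)], reference.aldehyde
    )
    head_table = _block_rank_table(
        [heads[j] for j in sorted(heads)], reference.head
    )
    return (
        ald_table["block_index"].tolist(),
        head_table["block_index"].tolist(),
        {"aldehyde": ald_table, "head": head_table},
    )


def property_histograms(
    library_values,
    reference_values,
    property_name: str,
    n_bins: int = 20,
) -> PropertyHistogramPair:
    """Histogram a library property against a reference set on shared bins.

    Bin edges span the union range of both value lists so the two count
    arrays are directly comparable; totals are conserved.
    """
    lib = np.asarray(library_values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    if lib.size == 0 or ref.size == 0:
        raise ValueError("value lists must be non-empty")
    lo = min(lib.min(), ref.min())
    hi = max(lib.max(), ref.max())
    if lo == hi:  # degenerate range: widen so counts are well defined
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    counts_lib, _ = np.histogram(lib, bins=edges)
    counts_ref, _ = np.histogram(ref, bins=edges)
    return PropertyHistogramPair(property_name, edges, counts_lib, counts_ref)
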