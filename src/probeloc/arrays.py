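"""Sorted 2-D image arrays and localization-plot coordinate export.

Image montages arrange one representative image per library compound in a
grid whose rows (aldehydes) and columns (heads) are ordered by a sorting
statistic: Tanimoto similarity of each building block to a reference
compound's blocks, or the block's fitted additive-regression coefficient.
The reference compound, when present, sits at the upper-left corner.  Every
montage is exported deterministically as a grey-scale PNG plus a JSON
metadata sidecar from which the array specification can be reconstructed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize

from .library import Compound
from .render import ImageSet, PROBE_CHANNELS
from .similarity import rank_blocks_by_similarity
from .stats import AdditiveFit

CLASS_LETTER = {"organelle": "o", "membrane": "m", "nuclear": "n"}


@dataclass
class ArraySpec:
    """Layout of a sorted 2-D compound array."""

    row_order: list  # aldehyde indices, top to bottom
    col_order: list  # head indices, left to right
    row_values: list  # sorting statistic per row
    col_values: list
    sort_statistic: str  # "tanimoto" | "coefficient"
    reference_id: str | None = None
    cell_labels: dict = field(default_factory=dict)  # "r,c" -> label

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ArraySpec":
        import dataclasses

        known = {f.name for f in dataclasses.fields(cls)}
        payload = {k: v for k, v in json.loads(text).items() if k in known}
        return cls(**payload)


def _representative_tile(entry, crop_mode: str = "full", crop_px: int = 96):
    """2-D grey tile for one compound: summed probe channels, optional crop."""
    if isinstance(entry, ImageSet):
        total = sum(
            entry.channels[c].astype(float) for c in PROBE_CHANNELS
        )
        if crop_mode == "cell" and entry.nuclear_mask.any():
            lab_y, lab_x = np.nonzero(entry.nuclear_mask)
            cy, cx = int(lab_y.mean()), int(lab_x.mean())
            h = crop_px // 2
            y0 = min(max(cy - h, 0), total.shape[0] - crop_px)
            x0 = min(max(cx - h, 0), total.shape[1] - crop_px)
            total = total[y0 : y0 + crop_px, x0 : x0 + crop_px]
        return total
    return np.asarray(entry, dtype=float)


def _cell_label(compound: Compound, excluded: bool) -> str:
    letter = CLASS_LETTER.get(compound.true_class, "")
    return letter + ("*" if excluded else "")


def _build_spec(
    library, row_order, col_order, row_values, col_values, statistic,
    reference_id=None, excluded_ids=frozenset(),
) -> ArraySpec:
    by_pos = {(c.aldehyde.index, c.head.index): c for c in library}
    labels = {}
    for r, ald in enumerate(row_order):
        for cix, head in enumerate(col_order):
            compound = by_pos.get((ald, head))
            if compound is None:
                labels[f"{r},{cix}"] = "blank"
            else:
                labels[f"{r},{cix}"] = _cell_label(
                    compound, compound.compound_id in excluded_ids
                )
    return ArraySpec(
        row_order=list(map(int, row_order)),
        col_order=list(map(int, col_order)),
        row_values=[float(v) for v in row_values],
        col_values=[float(v) for v in col_values],
        sort_statistic=statistic,
        reference_id=reference_id,
        cell_labels=labels,
    )


def _assemble_montage(
    spec: ArraySpec, library, images, crop_mode="full", cell_px=64, margin=2
) -> np.ndarray:
    """Grey-scale montage array (uint8); missing images stay blank."""
    by_pos = {(c.aldehyde.index, c.head.index): c for c in library}
    n_rows, n_cols = len(spec.row_order), len(spec.col_order)
    canvas = np.zeros(
        (margin + n_rows * (cell_px + margin), margin + n_cols * (cell_px + margin)),
        dtype=np.uint8,
    )
    for r, ald in enumerate(spec.row_order):
        for cix, head in enumerate(spec.col_order):
            compound = by_pos.get((ald, head))
            if compound is None or images is None:
                continue
            entry = images.get(compound.compound_id)
            if entry is None:
                spec.cell_labels[f"{r},{cix}"] = "blank"
                continue
            tile = _representative_tile(entry, crop_mode=crop_mode)
            tile = resize(tile, (cell_px, cell_px), anti_aliasing=True)
            tile = np.clip(tile / 16.0, 0, 255).astype(np.uint8)  # 12-bit -> 8-bit
            y0 = margin + r * (cell_px + margin)
            x0 = margin + cix * (cell_px + margin)
            canvas[y0 : y0 + cell_px, x0 : x0 + cell_px] = tile
    return canvas


def build_tanimoto_array(
    library: list[Compound],
    images,
    reference: Compound,
    tc_min: float | None = None,
    tc_max: float | None = None,
    excluded_ids=frozenset(),
    crop_mode: str = "full",
) -> tuple[ArraySpec, np.ndarray]:
    """Array sorted by building-block Tanimoto similarity to a reference.

    Rows are aldehydes and columns heads, each in decreasing Tc to the
    reference's corresponding block, with the reference compound at (0,0).
    ``tc_min``/``tc_max`` filter rows and columns to the similar
    (e.g. Tc > 0.4) or dissimilar (e.g. Tc < 0.25) subsets.
    """
    ald_order, head_order, tables = rank_blocks_by_similarity(library, reference)
    ald_tc = tables["aldehyde"].set_index("block_index")["Tc"]
    head_tc = tables["head"].set_index("block_index")["Tc"]

    def keep(tc, index, ref_index):
        if index == ref_index:
            return True
        if tc_min is not None and tc <= tc_min:
            return False
        if tc_max is not None and tc >= tc_max:
            return False
        return True

    rows = [i for i in ald_order if keep(ald_tc[i], i, reference.aldehyde.index)]
    cols = [j for j in head_order if keep(head_tc[j], j, reference.head.index)]
    spec = _build_spec(
        library,
        rows,
        cols,
        [ald_tc[i] for i in rows],
        [head_tc[j] for j in cols],
        "tanimoto",
        reference_id=reference.compound_id,
        excluded_ids=excluded_ids,
    )
    return spec, _assemble_montage(spec, library, images, crop_mode=crop_mode)


def build_coefficient_array(
    library: list[Compound],
    images,
    fit: AdditiveFit,
    excluded_ids=frozenset(),
    crop_mode: str = "full",
) -> tuple[ArraySpec, np.ndarray]:
    """Array sorted by the additive-fit block coefficients (ascending).

    Row/column header values are the fitted A(i) and P(j) exactly; ties are
    broken by ascending block index.  Compounds excluded from the regression
    are tagged with an asterisk in the cell labels.
    """
    alpha = fit.alpha.sort_index()
    beta = fit.beta.sort_index()
    rows = sorted(alpha.index, key=lambda i: (alpha[i], i))
    cols = sorted(beta.index, key=lambda j: (beta[j], j))
    spec = _build_spec(
        library,
        rows,
        cols,
        [alpha[i] for i in rows],
        [beta[j] for j in cols],
        "coefficient",
        excluded_ids=excluded_ids,
    )
    return spec, _assemble_montage(spec, library, images, crop_mode=crop_mode)


def localization_plot_coords(predictions) -> "pd.DataFrame":
    """Ternary coordinates of predicted distributions, in percent.

    Axes are percent mass in mitochondria (x), lysosomes (y), and
    cytoplasmic/plasma membranes (z); ``simplex_x``/``simplex_y`` give a
    flat 2-D projection with vertices mito=(0,0), lyso=(1,0),
    membranes=(1/2, √3/2).
    """
    import pandas as pd

    df = predictions.copy()
    out = pd.DataFrame(
        {
            "compound_id": df["compound_id"],
            "x_mito_pct": df["frac_mito"],
            "y_lyso_pct": df["frac_lyso"],
            "z_membranes_pct": df["frac_membranes"],
        }
    )
    lyso = df["frac_lyso"] / 100.0
    mem = df["frac_membranes"] / 100.0
    out["simplex_x"] = lyso + 0.5 * mem
    out["simplex_y"] = (np.sqrt(3.0) / 2.0) * mem
    return out


def export_montage(
    spec: ArraySpec,
    montage: np.ndarray,
    out_path,
) -> dict:
    """Write a montage PNG and its JSON metadata sidecar.

    The metadata fully reconstructs the :class:`ArraySpec`; identical inputs
    give byte-identical files.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(montage, mode="L").save(out_path, format="PNG")
    meta = json.loads(spec.to_json())
    meta["montage_shape"] = list(montage.shape)
    meta_path = out_path.with_suffix(".json")
    meta_path.write_text(json.dumps(meta, sort_keys=True, indent=2))
    return meta
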