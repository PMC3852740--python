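"""File-format plumbing: TIFF image stacks, CSV tables, JSON summaries."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .library import Compound, Fingerprint
from .render import CHANNELS, ImageSet
from .stats import AccuracyCurve, AdditiveFit


def write_image_set(image_set: ImageSet, path) -> Path:
    """Write a four-page 16-bit TIFF (Hoechst, FITC, TRITC, Cy5) + sidecar.

    The JSON sidecar records compound id, class, timepoint, seed and channel
    weights.  Ground-truth masks are in-memory artifacts and are not stored.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack([image_set.channels[c] for c in CHANNELS])
    tifffile.imwrite(path, stack.astype(np.uint16), photometric="minisblack")
    sidecar = {
        "compound_id": image_set.compound_id,
        "true_class": image_set.true_class,
        "timepoint": image_set.timepoint,
        "seed": image_set.seed,
        "channel_weights": image_set.channel_weights,
        "channel_order": list(CHANNELS),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_image_set(path) -> ImageSet:
    """Read a TIFF stack + sidecar back into an :class:`ImageSet`.

    Ground-truth masks are not persisted; the returned masks are empty and
    flagged, so callers needing masks must re-segment.
    """
    path = Path(path)
    stack = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    shape = stack.shape[1:]
    return ImageSet(
        channels=dict(zip(meta["channel_order"], stack)),
        compound_id=meta["compound_id"],
        true_class=meta["true_class"],
        timepoint=meta["timepoint"],
        seed=meta["seed"],
        channel_weights=meta["channel_weights"],
        nuclear_mask=np.zeros(shape, dtype=bool),
        cell_mask=np.zeros(shape, dtype=bool),
        extras={"masks_unavailable": True},
    )


def library_to_frame(library: list[Compound]) -> pd.DataFrame:
    """One row per compound; fingerprints as 881-character 0/1 strings."""
    return pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in library],
            "head_index": [c.head.index for c in library],
            "aldehyde_index": [c.aldehyde.index for c in library],
            "logp": [c.logp for c in library],
            "n_extra_ionizable": [c.n_extra_ionizable for c in library],
            "extra_pkas": [";".join(f"{p:.4f}" for p in c.extra_pkas) for c in library],
            "fingerprint": [c.fingerprint.to_string() for c in library],
            "true_class": [c.true_class or "" for c in library],
        }
    )


def write_library_csv(library: list[Compound], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    library_to_frame(library).to_csv(path, index=False)
    return path


def read_fingerprints_csv(path) -> list[Fingerprint]:
    """Parse the 0/1 fingerprint column of a library CSV."""
    df = pd.read_csv(path, dtype={"fingerprint": str})
    return [Fingerprint.from_string(s) for s in df["fingerprint"]]


def write_predictions_csv(predictions: pd.DataFrame, exclusions: pd.DataFrame, path) -> Path:
    """Merged prediction table with per-compound exclusion flags."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pred = predictions.copy()
    pred["excluded_flag"] = False
    pred["exclusion_reason"] = ""
    if len(exclusions):
        exc = exclusions.copy()
        for col in ("frac_mito", "frac_lyso", "frac_membranes"):
            exc[col] = np.nan
        exc["excluded_flag"] = True
        exc = exc.rename(columns={"reason": "exclusion_reason"})
        pred = pd.concat([pred, exc], ignore_index=True)
    pred.to_csv(path, index=False)
    return path


def write_similarity_tables(tables: dict, path) -> Path:
    """Stacked block-similarity table (block_kind, index, N1, N2, C, Tc, rank)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.concat(tables.values(), ignore_index=True).to_csv(path, index=False)
    return path


def write_accuracy_curve_csv(curve: AccuracyCurve, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "threshold_pct": curve.thresholds,
            "accuracy": curve.accuracy,
            "accuracy_pos": curve.per_class_accuracy_pos,
            "accuracy_neg": curve.per_class_accuracy_neg,
        }
    ).to_csv(path, index=False)
    return path


def write_balanced_json(curve: AccuracyCurve, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(
            {
                "balanced_threshold_pct": curve.balanced_threshold,
                "balanced_accuracy": curve.balanced_accuracy,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return path


def write_coefficients_csv(fit: AdditiveFit, path) -> Path:
    """Block coefficients with ranks (ascending within each block kind)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for kind, series in (("aldehyde", fit.alpha), ("head", fit.beta)):
        ranked = series.sort_values(kind="stable")
        for rank, (idx, coef) in enumerate(ranked.items()):
            rows.append(
                {"block_kind": kind, "block_index": idx, "coefficient": coef, "rank": rank}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
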