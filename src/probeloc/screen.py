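"""End-to-end synthetic screen: library, ground-truth classes and features.

A screen pairs every library compound with twelve images (six "incubation"
acquisitions and six "washout" acquisitions at class-dependent retained
intensity) and a ground-truth feature table in which every feature Y obeys
the additive building-block model

    f(Y)_ij = base + A(i) + P(j) + noise,

A indexed by aldehyde and P by head.  Each compound also gets a true
staining class (organelle / membrane / nuclear).  By default the class
follows the transport-model prediction (organelle when the predicted
mitochondrial + lysosomal mass fraction is at least half); a configurable
``contradiction_fraction`` reassigns a seeded subset of compounds to a class
that disagrees with the prediction, emulating divergence between mechanistic
prediction and observed staining.

Images are rendered lazily (per-image seeds are fixed up front), so large
screens can be enumerated and sampled without materializing every frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import Compound
from .render import ImageSet, render_image_set
from .transport import predict_library

DEFAULT_RETENTION = {"organelle": 0.8, "membrane": 0.3, "nuclear": 0.6}


@dataclass
class EffectTable:
    """Ground-truth additive effects for one or more image features."""

    aldehyde_effects: pd.DataFrame  # index: aldehyde index; columns: features
    head_effects: pd.DataFrame  # index: head index; same columns
    base: dict
    transforms: dict  # feature -> "identity" | "log"
    noise_sd: float = 0.0
    contradiction_fraction: float = 0.0
    class_rule: str = "prediction"  # "prediction" | "effect_sign"

    def __post_init__(self):
        if set(self.aldehyde_effects.columns) != set(self.head_effects.columns):
            raise ValueError("aldehyde and head effect tables must share features")
        if not 0.0 <= self.contradiction_fraction <= 1.0:
            raise ValueError("contradiction_fraction must be in [0, 1]")

    @property
    def features(self) -> list[str]:
        return list(self.aldehyde_effects.columns)

    @classmethod
    def random(
        cls,
        n_heads: int,
        n_aldehydes: int,
        seed: int,
        features=("cv_cell",),
        effect_sd: float = 0.2,
        base: float = 1.0,
        **kwargs,
    ) -> "EffectTable":
        """Seeded Gaussian block effects, identity transform, common base."""
        rng = np.random.default_rng(seed)
        alds = pd.DataFrame(
            {f: rng.normal(0.0, effect_sd, n_aldehydes) for f in features},
            index=np.arange(1, n_aldehydes + 1),
        )
        heads = pd.DataFrame(
            {f: rng.normal(0.0, effect_sd, n_heads) for f in features},
            index=np.arange(1, n_heads + 1),
        )
        return cls(
            aldehyde_effects=alds,
            head_effects=heads,
            base={f: base for f in features},
            transforms={f: "identity" for f in features},
            **kwargs,
        )


def _image_seed(master_seed: int, compound_idx: int, image_idx: int) -> int:
    ss = np.random.SeedSequence([master_seed, compound_idx, image_idx])
    return int(ss.generate_state(1)[0])


@dataclass
class ScreenDataset:
    """A generated screen: compounds, classes, features, lazy images."""

    library: list[Compound]
    features: pd.DataFrame  # one row per (compound, image)
    true_classes: pd.Series  # compound_id -> class
    predictions: pd.DataFrame
    exclusions: pd.DataFrame
    effect_table: EffectTable
    seed: int
    n_incubation: int = 6
    n_washout: int = 6
    render_noise_sd: float = 8.0
    retention: dict = field(default_factory=lambda: dict(DEFAULT_RETENTION))
    _index_of: dict = field(default_factory=dict, repr=False)

    @property
    def n_images_per_compound(self) -> int:
        return self.n_incubation + self.n_washout

    @property
    def n_image_sets(self) -> int:
        return len(self.library) * self.n_images_per_compound

    def render(self, compound_id: str, image_index: int) -> ImageSet:
        """Materialize one of a compound's twelve images.

        Image indices ``0..n_incubation-1`` are incubation acquisitions;
        the rest are washout frames with class-dependent retained signal.
        """
        ci = self._index_of[compound_id]
        if not 0 <= image_index < self.n_images_per_compound:
            raise IndexError("image_index out of range")
        washout = image_index >= self.n_incubation
        cls = self.true_classes[compound_id]
        scale = self.retention[cls] if washout else 1.0
        return render_image_set(
            true_class=cls,
            intensity_scale=scale,
            noise_sd=self.render_noise_sd,
            seed=_image_seed(self.seed, ci, image_index),
            compound_id=compound_id,
            timepoint="washout" if washout else "incubation",
        )


def _assign_classes(
    library: list[Compound],
    predictions: pd.DataFrame,
    effect_table: EffectTable,
    rng: np.random.Generator,
) -> pd.Series:
    pred_class = {}
    frac = predictions.set_index("compound_id") if len(predictions) else None
    for c in library:
        cid = c.compound_id
        if effect_table.class_rule == "effect_sign":
            a = effect_table.aldehyde_effects.iloc[:, 0][c.aldehyde.index]
            pred_class[cid] = "membrane" if a < 0 else "organelle"
        elif frac is not None and cid in frac.index:
            organelle_frac = (
                frac.at[cid, "frac_mito"] + frac.at[cid, "frac_lyso"]
            )
            pred_class[cid] = "organelle" if organelle_frac >= 50.0 else "membrane"
        else:
            # not simulated by the transport model: seeded draw
            pred_class[cid] = rng.choice(
                ["organelle", "membrane", "nuclear"], p=[0.4, 0.4, 0.2]
            )
    classes = pd.Series(pred_class, name="true_class")
    if effect_table.contradiction_fraction > 0:
        flip = rng.random(len(classes)) < effect_table.contradiction_fraction
        for cid, do_flip in zip(classes.index, flip):
            if not do_flip:
                continue
            if classes[cid] == "organelle":
                classes[cid] = "membrane" if rng.random() < 0.75 else "nuclear"
            else:
                classes[cid] = "organelle"
    return classes


def generate_screen(
    library: list[Compound],
    cell=None,
    effect_table: EffectTable | None = None,
    seed: int = 0,
    n_incubation: int = 6,
    n_washout: int = 6,
    render_noise_sd: float = 8.0,
) -> ScreenDataset:
    """Build the full synthetic screen for a library.

    Runs the transport model over the library (used by the default class
    rule), assigns each compound a true staining class, and tabulates
    ground-truth feature values satisfying the additive model with seeded
    Gaussian noise of sd ``effect_table.noise_sd``.  Compounds' true class
    is also stored on the compound objects.
    """
    heads = sorted({c.head.index for c in library})
    alds = sorted({c.aldehyde.index for c in library})
    if effect_table is None:
        effect_table = EffectTable.random(len(heads), len(alds), seed + 1)
    rng = np.random.default_rng(seed)
    if effect_table.class_rule == "prediction":
        predictions, exclusions = predict_library(library, cell)
    else:
        predictions = pd.DataFrame(
            columns=["compound_id", "head", "aldehyde", "frac_mito", "frac_lyso", "frac_membranes"]
        )
        exclusions = pd.DataFrame(columns=["compound_id", "reason"])
    classes = _assign_classes(library, predictions, effect_table, rng)
    for c in library:
        c.true_class = classes[c.compound_id]

    n_images = n_incubation + n_washout
    rows = []
    for c in library:
        cid = c.compound_id
        for img in range(n_images):
            row = {
                "compound_id": cid,
                "head": c.head.index,
                "aldehyde": c.aldehyde.index,
                "image_index": img,
                "timepoint": "incubation" if img < n_incubation else "washout",
                "true_class": classes[cid],
            }
            for f in effect_table.features:
                val = (
                    effect_table.base[f]
                    + effect_table.aldehyde_effects.at[c.aldehyde.index, f]
                    + effect_table.head_effects.at[c.head.index, f]
                )
                if effect_table.noise_sd > 0:
                    val += rng.normal(0.0, effect_table.noise_sd)
                if effect_table.transforms[f] == "log":
                    val = np.exp(val)
                row[f] = val
            rows.append(row)
    dataset = ScreenDataset(
        library=library,
        features=pd.DataFrame(rows),
        true_classes=classes,
        predictions=predictions,
        exclusions=exclusions,
        effect_table=effect_table,
        seed=seed,
        n_incubation=n_incubation,
        n_washout=n_washout,
        render_noise_sd=render_noise_sd,
        _index_of={c.compound_id: i for i, c in enumerate(library)},
    )
    return dataset
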