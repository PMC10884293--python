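"""Noisy-label pixel classification of treatment groups from HS-CARS features.

Ground-truth labels do not exist at pixel level, so every refined pixel
of an image inherits its image's treatment-group label (random
classification noise).  A 100-tree random forest is trained on 80% of
the pooled pixels and evaluated by Top-1 accuracy on the held-out 20%;
impurity-decrease importances rank the 29 spectral features, and
per-image probability maps / prediction ratios summarize where the
model sees treatment effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.model_selection import train_test_split

from .carsfit import FEATURE_NAMES, FeatureImage
from .exceptions import InvalidArgumentError

__all__ = [
    "ClassifierReport",
    "LabeledDataset",
    "assemble_dataset",
    "embed_2d",
    "feature_importance",
    "holdout_images_per_group",
    "prediction_ratio",
    "probability_map",
    "split_train_test",
    "top1_accuracy",
    "train_classifier",
]


@dataclass
class LabeledDataset:
    """Pixel-level features with (noisy) image-inherited group labels."""

    features: pd.DataFrame  # n x 29, columns = FEATURE_NAMES
    labels: np.ndarray  # group label per row
    provenance: pd.DataFrame  # image_id, row, col per row

    def __post_init__(self) -> None:
        n_classes = np.unique(self.labels).size
        if not 2 <= n_classes <= 3:
            raise InvalidArgumentError(f"label set must have 2 or 3 classes, got {n_classes}")
        if len(self.features) != len(self.labels) or len(self.features) != len(self.provenance):
            raise InvalidArgumentError("features, labels and provenance must align")

    def __len__(self) -> int:
        return len(self.features)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            features=self.features.iloc[idx].reset_index(drop=True),
            labels=np.asarray(self.labels)[idx],
            provenance=self.provenance.iloc[idx].reset_index(drop=True),
        )


def assemble_dataset(
    feature_images: list[FeatureImage],
    refined_masks: list[np.ndarray],
    group_of_image: dict[object, str],
    image_ids: list[object] | None = None,
) -> LabeledDataset:
    """Pool refined pixels of several images into one labeled dataset.

    Every retained pixel of an image carries that image's group label.
    """
    if image_ids is None:
        image_ids = list(range(len(feature_images)))
    if not len(feature_images) == len(refined_masks) == len(image_ids):
        raise InvalidArgumentError("feature_images, refined_masks and image_ids must align")
    frames, labels, prov = [], [], []
    for fi, mask, iid in zip(feature_images, refined_masks, image_ids):
        if iid not in group_of_image:
            raise InvalidArgumentError(f"image {iid!r} has no group label")
        mask = np.asarray(mask).astype(bool)
        if mask.shape != fi.shape:
            raise InvalidArgumentError(f"refined mask shape {mask.shape} != image shape {fi.shape}")
        keep = mask[fi.table["row"].to_numpy(), fi.table["col"].to_numpy()]
        sub = fi.table.loc[keep]
        frames.append(sub[list(FEATURE_NAMES)])
        labels.extend([group_of_image[iid]] * len(sub))
        prov.append(pd.DataFrame({"image_id": iid, "row": sub["row"], "col": sub["col"]}))
    features = pd.concat(frames, ignore_index=True)
    provenance = pd.concat(prov, ignore_index=True)
    return LabeledDataset(features=features, labels=np.asarray(labels), provenance=provenance)


def holdout_images_per_group(
    ds: LabeledDataset, n_per_group: int = 1, seed: int = 0
) -> tuple[LabeledDataset, dict[str, list]]:
    """Hold out whole images (one per group by default) from training.

    The held-out-image protocol: pixel-level train/test splits share
    cells, so the stricter evaluation excludes entire images from
    training and scores them afterwards by prediction ratio.  Returns
    the reduced dataset and the held-out image ids per group.
    """
    rng = np.random.default_rng(seed)
    held: dict[str, list] = {}
    drop = np.zeros(len(ds), dtype=bool)
    for group in np.unique(ds.labels):
        group_images = np.unique(ds.provenance.loc[ds.labels == group, "image_id"])
        if len(group_images) <= n_per_group:
            raise InvalidArgumentError(
                f"group {group!r} has only {len(group_images)} image(s); "
                f"cannot hold out {n_per_group}"
            )
        chosen = rng.choice(group_images, size=n_per_group, replace=False)
        held[str(group)] = list(chosen)
        drop |= ds.provenance["image_id"].isin(chosen).to_numpy()
    return ds.subset(np.nonzero(~drop)[0]), held


def split_train_test(
    ds: LabeledDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Disjoint, exhaustive, label-stratified train/test split."""
    if len(ds) < 10:
        raise InvalidArgumentError("need at least 10 rows to split")
    _, counts = np.unique(ds.labels, return_counts=True)
    if counts.min() < 2:
        raise InvalidArgumentError("every class needs at least 2 rows to stratify")
    idx = np.arange(len(ds))
    tr, te = train_test_split(
        idx, train_size=train_fraction, stratify=ds.labels, random_state=seed, shuffle=True
    )
    return ds.subset(np.sort(tr)), ds.subset(np.sort(te))


def train_classifier(
    train: LabeledDataset, n_estimators: int = 100, seed: int = 0
) -> RandomForestClassifier:
    """Train the 100-tree random forest on pixel features.

    Hyperparameters beyond the tree count are scikit-learn defaults
    (unlimited depth, sqrt(p) features per split, no class weighting);
    they are echoed into :class:`ClassifierReport` for reproducibility.
    """
    if np.unique(train.labels).size < 2:
        raise InvalidArgumentError("training data must contain at least 2 classes")
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    model.fit(train.features, train.labels)
    return model


def _check_features(model: RandomForestClassifier, features: pd.DataFrame) -> None:
    expected = list(getattr(model, "feature_names_in_", []))
    if expected and list(features.columns) != expected:
        raise InvalidArgumentError("feature names do not match the trained model")


def top1_accuracy(model: RandomForestClassifier, test: LabeledDataset) -> float:
    """Top-1 accuracy on the test rows, in percent."""
    if len(test) == 0:
        raise InvalidArgumentError("test set is empty")
    _check_features(model, test.features)
    pred = model.predict(test.features)
    return float(100.0 * np.mean(pred == test.labels))


def feature_importance(model: RandomForestClassifier) -> list[tuple[str, float]]:
    """Impurity-decrease feature importances, descending (weights sum to 1)."""
    names = list(getattr(model, "feature_names_in_", []))
    if not names:
        names = [f"f{i}" for i in range(model.n_features_in_)]
    pairs = sorted(zip(names, model.feature_importances_), key=lambda p: -p[1])
    return [(n, float(w)) for n, w in pairs]


def probability_map(
    model: RandomForestClassifier,
    feature_image: FeatureImage,
    refined_mask: np.ndarray,
    treated_class: str,
) -> np.ndarray:
    """Per-pixel probability of ``treated_class`` over the refined mask.

    Pixels outside the mask (or dropped during fitting) are NaN.
    """
    mask = np.asarray(refined_mask).astype(bool)
    if not mask.any():
        raise InvalidArgumentError("refined mask selects no pixels")
    _check_features(model, feature_image.table[list(FEATURE_NAMES)])
    classes = list(model.classes_)
    if treated_class not in classes:
        raise InvalidArgumentError(f"{treated_class!r} is not one of the model classes {classes}")
    out = np.full(feature_image.shape, np.nan)
    tab = feature_image.table
    keep = mask[tab["row"].to_numpy(), tab["col"].to_numpy()]
    sub = tab.loc[keep]
    if len(sub):
        proba = model.predict_proba(sub[list(FEATURE_NAMES)])[:, classes.index(treated_class)]
        out[sub["row"].to_numpy(), sub["col"].to_numpy()] = proba
    return out


def prediction_ratio(
    model: RandomForestClassifier,
    feature_image: FeatureImage,
    refined_mask: np.ndarray,
    treated_class: str,
) -> float:
    """Fraction of refined pixels classified as treatment-affected.

    For binary models a pixel counts as treated when its treated-class
    probability is >= 0.5 (an exact 0.5 tie goes to the treated class);
    with three classes the arg-max prediction is used.
    """
    pmap = probability_map(model, feature_image, refined_mask, treated_class)
    vals = pmap[np.isfinite(pmap)]
    if vals.size == 0:
        raise InvalidArgumentError("no refined pixels carry fitted features")
    if len(model.classes_) == 2:
        return float(np.mean(vals >= 0.5))
    mask = np.asarray(refined_mask).astype(bool)
    tab = feature_image.table
    keep = mask[tab["row"].to_numpy(), tab["col"].to_numpy()]
    sub = tab.loc[keep]
    pred = model.predict(sub[list(FEATURE_NAMES)])
    return float(np.mean(pred == treated_class))


def embed_2d(ds: LabeledDataset, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """t-SNE embedding of the pixel features into 2-D (n x 2)."""
    n = len(ds)
    if n < 10:
        raise InvalidArgumentError("need at least 10 rows to embed")
    if perplexity >= n:
        raise InvalidArgumentError(f"perplexity {perplexity} must be < n = {n}")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return tsne.fit_transform(ds.features.to_numpy())


@dataclass
class ClassifierReport:
    """Metadata and headline numbers of one trained pixel classifier."""

    top1_accuracy: float
    importance: list[tuple[str, float]]
    seed: int
    split_sizes: tuple[int, int]
    n_estimators: int = 100
    classes: tuple[str, ...] = ()
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.top1_accuracy <= 100.0:
            raise InvalidArgumentError("accuracy must lie in [0, 100]")
        if any(w < 0 for _, w in self.importance):
            raise InvalidArgumentError("importance weights must be nonnegative")

    def to_json(self, path=None) -> str:
        payload = {
            "top1_accuracy": self.top1_accuracy,
            "importance": [[n, w] for n, w in self.importance],
            "seed": self.seed,
            "split_sizes": list(self.split_sizes),
            "n_estimators": self.n_estimators,
            "classes": list(self.classes),
            "hyperparameters": self.hyperparameters,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_report(
    model: RandomForestClassifier,
    test: LabeledDataset,
    seed: int,
    split_sizes: tuple[int, int],
) -> ClassifierReport:
    """Convenience: evaluate a trained model and package the report."""
    return ClassifierReport(
        top1_accuracy=top1_accuracy(model, test),
        importance=feature_importance(model),
        seed=seed,
        split_sizes=split_sizes,
        n_estimators=model.n_estimators,
        classes=tuple(str(c) for c in model.classes_),
        hyperparameters={
            "max_depth": model.max_depth,
            "max_features": model.max_features,
            "class_weight": model.class_weight,
        },
    )
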