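"""Bag-of-Visual-Words polyp characterization.

Stage 3 of the pipeline: the region inside the accepted bounding box is
described by 128-dimensional gradient-orientation descriptors sampled on a
dense regular grid ("gridSIFT": 4x4 spatial cells x 8 orientation bins per
patch, fixed scale, upright orientation, SIFT-style normalization), quantized
against a k-means visual vocabulary into an L1-normalized histogram, and
scored by a multinomial logistic model over {adenoma, SSL, hyperplastic}.

The maximum class posterior is the *prediction score*; scores >= 0.50 yield a
high-confidence diagnosis, >= 0.33 a low-confidence one. With three classes
the maximum posterior is always >= 1/3, so the tier "none" is unreachable for
any valid probability vector — a diagnosis failure can only arise upstream
(localization or quality gating).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans, MiniBatchKMeans
from sklearn.linear_model import LogisticRegression

from .localization import BoundingBox, luminance

CLASSES = ("adenoma", "ssl", "hyperplastic")

HIGH_CONFIDENCE_THRESHOLD = 0.50
LOW_CONFIDENCE_THRESHOLD = 0.33

DEFAULT_GRID_STEP = 8
DEFAULT_PATCH_SIZE = 16
DEFAULT_VOCABULARY_SIZE = 256

_N_ORIENTATIONS = 8
_N_CELLS = 4  # per axis
_DESCRIPTOR_DIM = _N_CELLS * _N_CELLS * _N_ORIENTATIONS  # 128
_SIFT_CLIP = 0.2


@dataclass(frozen=True)
class DescriptorSet:
    """Dense local descriptors and their patch centers in box coordinates."""

    descriptors: np.ndarray   # (n, 128) float32, each with L2 norm <= 1
    grid_points: np.ndarray   # (n, 2) patch centers (x, y) relative to the box

    def __len__(self) -> int:
        return len(self.descriptors)


def extract_grid_descriptors(image: np.ndarray, box: BoundingBox,
                             grid_step: int = DEFAULT_GRID_STEP,
                             patch_size: int = DEFAULT_PATCH_SIZE) -> DescriptorSet:
    """Compute gridSIFT descriptors over the box.

    Patches are placed at every ``grid_step`` pixels wherever a full
    ``patch_size`` x ``patch_size`` patch fits inside the box, so the count is
    ``(floor((w - patch)/step) + 1) * (floor((h - patch)/step) + 1)``.
    Deterministic; a constant patch yields the all-zero descriptor.
    """
    if grid_step <= 0 or patch_size <= 0:
        raise ValueError("grid_step and patch_size must be positive")
    if patch_size % _N_CELLS != 0:
        raise ValueError(f"patch_size must be a multiple of {_N_CELLS}")
    if box.w < patch_size or box.h < patch_size:
        raise ValueError("box smaller than patch_size")
    lum = box.crop(luminance(image))
    h, w = lum.shape

    gy, gx = np.gradient(lum)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), 2 * np.pi)
    obin = np.minimum((ang / (2 * np.pi / _N_ORIENTATIONS)).astype(int), _N_ORIENTATIONS - 1)

    # per-orientation magnitude channels, then summed-area tables for cell sums
    channels = np.zeros((_N_ORIENTATIONS, h, w))
    yy, xx = np.nonzero(mag >= 0)  # all pixels
    channels[obin.ravel(), yy, xx] = mag.ravel()
    cell = patch_size // _N_CELLS
    sat = np.zeros((_N_ORIENTATIONS, h + 1, w + 1))
    sat[:, 1:, 1:] = channels.cumsum(axis=1).cumsum(axis=2)
    # cellsum[:, y, x] = sum over channels[y:y+cell, x:x+cell]
    cellsum = (sat[:, cell:, cell:] - sat[:, cell:, :-cell]
               - sat[:, :-cell, cell:] + sat[:, :-cell, :-cell])

    ys = np.arange(0, h - patch_size + 1, grid_step)
    xs = np.arange(0, w - patch_size + 1, grid_step)
    py, px = np.meshgrid(ys, xs, indexing="ij")
    py, px = py.ravel(), px.ravel()
    ci = np.arange(_N_CELLS) * cell
    # (n_patches, 4, 4) index grids
    cy = py[:, None, None] + ci[None, :, None]
    cx = px[:, None, None] + ci[None, None, :]
    desc = cellsum[:, cy, cx]                    # (8, n, 4, 4)
    desc = np.moveaxis(desc, 0, -1).reshape(len(py), _DESCRIPTOR_DIM)

    norms = np.linalg.norm(desc, axis=1, keepdims=True)
    nz = norms[:, 0] > 0
    desc[nz] /= norms[nz]
    np.clip(desc, 0.0, _SIFT_CLIP, out=desc)
    norms = np.linalg.norm(desc, axis=1, keepdims=True)
    desc[nz] /= norms[nz]

    centers = np.column_stack([px + patch_size / 2.0, py + patch_size / 2.0])
    return DescriptorSet(descriptors=desc.astype(np.float32), grid_points=centers)


@dataclass(frozen=True)
class Vocabulary:
    centers: np.ndarray   # (k, 128)
    k: int
    train_seed: int

    def __post_init__(self) -> None:
        if self.k < 2 or self.centers.shape != (self.k, _DESCRIPTOR_DIM):
            raise ValueError("vocabulary must hold k >= 2 centers of dimension 128")


def build_vocabulary(descriptor_sets: Iterable[DescriptorSet], k: int = DEFAULT_VOCABULARY_SIZE,
                     seed: int = 0, max_descriptors: int = 100_000) -> Vocabulary:
    """Seeded k-means over the pooled descriptors.

    Uses mini-batch k-means when the pool is large; the pool is subsampled to
    ``max_descriptors`` (seeded) first. Deterministic under seed.
    """
    if k < 2:
        raise ValueError("vocabulary size k must be >= 2")
    pool = np.concatenate([np.asarray(d.descriptors, dtype=np.float64)
                           for d in descriptor_sets], axis=0)
    if len(pool) < k:
        raise ValueError(f"need at least k={k} descriptors, got {len(pool)}")
    rng = np.random.default_rng(seed)
    if len(pool) > max_descriptors:
        pool = pool[rng.choice(len(pool), size=max_descriptors, replace=False)]
    if len(pool) > 20_000:
        km = MiniBatchKMeans(n_clusters=k, random_state=seed, n_init=3,
                             batch_size=4096, max_iter=200)
    else:
        km = KMeans(n_clusters=k, random_state=seed, n_init=4)
    km.fit(pool)
    return Vocabulary(centers=km.cluster_centers_.copy(), k=k, train_seed=seed)


def encode(descriptors: DescriptorSet, vocab: Vocabulary) -> np.ndarray:
    """Quantize to the nearest center (ties -> lowest index) and return the
    L1-normalized k-bin histogram."""
    d = np.asarray(descriptors.descriptors, dtype=np.float64)
    if len(d) == 0:
        raise ValueError("cannot encode an empty descriptor set")
    # squared distances via expansion; argmin takes the lowest index on ties
    d2 = (d**2).sum(1)[:, None] - 2 * d @ vocab.centers.T + (vocab.centers**2).sum(1)[None, :]
    assign = np.argmin(d2, axis=1)
    hist = np.bincount(assign, minlength=vocab.k).astype(float)
    return hist / hist.sum()


@dataclass(frozen=True)
class ClassScores:
    """Posterior scores over the three histology classes, plus the derived
    confidence tier; scores are nonnegative and sum to 1."""

    scores: Mapping[str, float]
    tier: str = field(init=False)
    top_class: str = field(init=False)

    def __post_init__(self) -> None:
        vals = np.array([self.scores[c] for c in CLASSES])
        if np.any(vals < -1e-12) or abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("scores must be a probability vector over the three classes")
        # ties broken by fixed class order (adenoma, ssl, hyperplastic)
        object.__setattr__(self, "top_class", CLASSES[int(np.argmax(vals))])
        object.__setattr__(self, "tier", confidence_tier(self.scores))

    @property
    def max_score(self) -> float:
        return float(self.scores[self.top_class])


def confidence_tier(scores: Mapping[str, float] | ClassScores,
                    low: float = LOW_CONFIDENCE_THRESHOLD,
                    high: float = HIGH_CONFIDENCE_THRESHOLD) -> str:
    """Tier of the maximum prediction score: >= 0.50 high, >= 0.33 low, else
    none (unreachable with three classes, kept for contract completeness)."""
    if isinstance(scores, ClassScores):
        scores = scores.scores
    m = max(scores.values())
    if m >= high:
        return "high"
    if m >= low:
        return "low"
    return "none"


@dataclass
class HistogramClassifier:
    """Multinomial logistic model over BoVW histograms (L2-penalized), chosen
    because the decision tiers need calibrated class posteriors."""

    estimator: LogisticRegression
    classes: tuple[str, ...]


def train(histograms: Sequence[np.ndarray], labels: Sequence[str], seed: int = 0,
          C: float = 10.0) -> HistogramClassifier:
    X = np.asarray(histograms, dtype=float)
    y = np.asarray(labels)
    present = [c for c in CLASSES if c in set(y)]
    if len(present) < 2:
        raise ValueError("training requires at least two classes")
    est = LogisticRegression(C=C, max_iter=5000, random_state=seed)
    est.fit(X, y)
    return HistogramClassifier(estimator=est, classes=tuple(est.classes_))


def predict(model: HistogramClassifier, histogram: np.ndarray) -> ClassScores:
    """Posterior over the three classes; classes absent at training get 0."""
    p = model.estimator.predict_proba(np.asarray(histogram, dtype=float)[None, :])[0]
    scores = {c: 0.0 for c in CLASSES}
    for c, v in zip(model.classes, p):
        scores[c] = float(v)
    return ClassScores(scores=scores)


# ---------------------------------------------------------------------------
# end-to-end model (vocabulary + classifier) and cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BovwParams:
    grid_step: int = DEFAULT_GRID_STEP
    patch_size: int = DEFAULT_PATCH_SIZE
    vocabulary_size: int = DEFAULT_VOCABULARY_SIZE
    C: float = 10.0


@dataclass
class BovwModel:
    vocabulary: Vocabulary
    classifier: HistogramClassifier
    params: BovwParams

    def describe(self, image: np.ndarray, box: BoundingBox) -> np.ndarray:
        d = extract_grid_descriptors(image, box, self.params.grid_step, self.params.patch_size)
        return encode(d, self.vocabulary)

    def predict_image(self, image: np.ndarray, box: BoundingBox) -> ClassScores:
        return predict(self.classifier, self.describe(image, box))

    def save(self, path: str) -> None:
        est = self.classifier.estimator
        meta = {"classes": list(self.classifier.classes),
                "params": vars(self.params), "train_seed": self.vocabulary.train_seed}
        np.savez(path, centers=self.vocabulary.centers, coef=est.coef_,
                 intercept=est.intercept_, est_classes=np.array(self.classifier.classes),
                 meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path: str) -> "BovwModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            params = BovwParams(**meta["params"])
            vocab = Vocabulary(centers=z["centers"], k=z["centers"].shape[0],
                               train_seed=meta["train_seed"])
            est = LogisticRegression(C=params.C)
            est.classes_ = z["est_classes"]
            est.coef_ = z["coef"]
            est.intercept_ = z["intercept"]
            clf = HistogramClassifier(estimator=est, classes=tuple(meta["classes"]))
        return cls(vocabulary=vocab, classifier=clf, params=params)


def fit_bovw(samples: Sequence[tuple[np.ndarray, BoundingBox, str]],
             params: BovwParams = BovwParams(), seed: int = 0) -> BovwModel:
    """Fit vocabulary + classifier from (image, box, label) training samples."""
    dsets = [extract_grid_descriptors(img, box, params.grid_step, params.patch_size)
             for img, box, _ in samples]
    vocab = build_vocabulary(dsets, k=params.vocabulary_size, seed=seed)
    hists = [encode(d, vocab) for d in dsets]
    clf = train(hists, [lab for _, _, lab in samples], seed=seed, C=params.C)
    return BovwModel(vocabulary=vocab, classifier=clf, params=params)


@dataclass(frozen=True)
class CrossValidationResult:
    fold_accuracy: tuple[float, ...]
    pooled_accuracy: float
    confusion: np.ndarray            # 3x3, rows = truth, cols = prediction
    fold_of_polyp: Mapping[str, int]


def _stratified_polyp_folds(polyp_labels: Mapping[str, str], folds: int,
                            seed: int) -> dict[str, int]:
    """Assign polyps to folds, stratified by class so every class appears in
    every training fold (requires >= folds polyps per class)."""
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for cls in CLASSES:
        ids = sorted(p for p, lab in polyp_labels.items() if lab == cls)
        if not ids:
            continue
        if len(ids) < folds:
            raise ValueError(f"class {cls!r} has fewer polyps than folds")
        rng.shuffle(ids)
        for i, pid in enumerate(ids):
            assignment[pid] = i % folds
    return assignment


def cross_validate(samples: Sequence[tuple[str, np.ndarray, BoundingBox, str]],
                   folds: int = 5, seed: int = 0,
                   params: BovwParams = BovwParams()) -> CrossValidationResult:
    """Polyp-level k-fold cross-validation of the full BoVW pipeline.

    ``samples`` are (polyp_id, image, box, label); all captures of one polyp
    land in the same fold.
    """
    polyp_labels = {pid: lab for pid, _, _, lab in samples}
    fold_of = _stratified_polyp_folds(polyp_labels, folds, seed)
    confusion = np.zeros((3, 3), dtype=int)
    accs = []
    for f in range(folds):
        train_s = [(img, box, lab) for pid, img, box, lab in samples if fold_of[pid] != f]
        test_s = [(img, box, lab) for pid, img, box, lab in samples if fold_of[pid] == f]
        model = fit_bovw(train_s, params=params, seed=seed + f)
        correct = 0
        for img, box, lab in test_s:
            pred = model.predict_image(img, box).top_class
            confusion[CLASSES.index(lab), CLASSES.index(pred)] += 1
            correct += pred == lab
        accs.append(correct / len(test_s) if test_s else float("nan"))
    pooled = float(np.trace(confusion) / confusion.sum())
    return CrossValidationResult(fold_accuracy=tuple(accs), pooled_accuracy=pooled,
                                 confusion=confusion, fold_of_polyp=fold_of)
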