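"""Bayes/MAP segmentation of plaque components on the T2 map.

Accepted vessel-wall voxels are assigned to lipid-rich necrotic core
(LRNC), fibrous tissue (which also covers normal intima/media) or recent
intraplaque haemorrhage by a Gaussian naive-Bayes classifier:
``P(C_i | T2) proportional to P(C_i) * N(T2; mu_i, sd_i)`` with the
maximum-a-posteriori rule.  Class conditionals are trained from labelled
voxels (about one hundred per class in practice); priors default to
equal.  Calcification, which carries no decaying signal and hence no
valid T2, is removed first: a wall voxel is calcified when its synthetic
proton-density-weighted intensity (the fitted curve evaluated at
TE = 14 ms, or the measured first-echo intensity where the fit was
rejected) has SNR below 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

from .fitting import T2Map, synthetic_image

DEFAULT_CLASSES = ("lrnc", "fibrous", "recent_iph")

# segmentation output codes share the phantom label table where possible
SEG_OUTSIDE = "outside"
SEG_REJECTED = "rejected"
SEG_CALCIFICATION = "calcification"


@dataclass
class ClassModel:
    """Per-class Gaussian over T2 plus prior probabilities."""

    classes: tuple[str, ...] = DEFAULT_CLASSES
    mu_ms: np.ndarray = field(default_factory=lambda: np.array([37.0, 56.0, 107.0]))
    sd_ms: np.ndarray = field(default_factory=lambda: np.array([5.0, 9.0, 25.0]))
    prior: np.ndarray = field(default_factory=lambda: np.full(3, 1.0 / 3.0))
    n_train: np.ndarray | None = None

    def __post_init__(self):
        self.mu_ms = np.asarray(self.mu_ms, dtype=float)
        self.sd_ms = np.asarray(self.sd_ms, dtype=float)
        self.prior = np.asarray(self.prior, dtype=float)
        k = len(self.classes)
        if not (len(self.mu_ms) == len(self.sd_ms) == len(self.prior) == k):
            raise ValueError("classes, mu, sd and prior must have equal length")
        if np.any(self.sd_ms <= 0):
            raise ValueError("class SDs must be positive")
        if np.any(self.prior < 0) or self.prior.sum() <= 0:
            raise ValueError("priors must be non-negative and sum > 0")
        self.prior = self.prior / self.prior.sum()


def train_class_model(training: pd.DataFrame, priors=None,
                      classes: tuple[str, ...] = DEFAULT_CLASSES) -> ClassModel:
    """Estimate (mu, sd) per class from a (class_label, t2_ms) table.

    Means are sample means, SDs sample standard deviations (n-1
    denominator).  Each class needs at least two voxels and nonzero
    variance.  Priors default to equal.
    """
    if not {"class_label", "t2_ms"}.issubset(training.columns):
        raise ValueError("training table needs columns class_label, t2_ms")
    if (training["t2_ms"] <= 0).any():
        bad = training.index[training["t2_ms"] <= 0][0]
        raise ValueError(f"non-positive t2_ms in training table (row {bad})")
    unknown = set(training["class_label"]) - set(classes)
    if unknown:
        raise ValueError(f"unknown class labels in training table: {sorted(unknown)}")
    mu, sd, n = [], [], []
    for cls in classes:
        vals = training.loc[training["class_label"] == cls, "t2_ms"].to_numpy(float)
        if len(vals) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 training voxels")
        s = vals.std(ddof=1)
        if s == 0:
            raise ValueError(f"class {cls!r} has zero T2 variance")
        mu.append(vals.mean())
        sd.append(s)
        n.append(len(vals))
    prior = np.full(len(classes), 1.0 / len(classes)) if priors is None \
        else np.asarray(priors, dtype=float)
    return ClassModel(classes=classes, mu_ms=np.array(mu), sd_ms=np.array(sd),
                      prior=prior, n_train=np.array(n))


def posterior(t2_ms, model: ClassModel) -> np.ndarray:
    """Class posteriors for scalar or array T2; last axis indexes classes."""
    t2 = np.asarray(t2_ms, dtype=float)
    dens = norm.pdf(t2[..., None], model.mu_ms, model.sd_ms) * model.prior
    total = dens.sum(axis=-1, keepdims=True)
    # all densities can underflow far in the tails; fall back to log space
    if np.any(total == 0):
        logd = norm.logpdf(t2[..., None], model.mu_ms, model.sd_ms) + np.log(model.prior)
        logd -= logd.max(axis=-1, keepdims=True)
        dens = np.exp(logd)
        total = dens.sum(axis=-1, keepdims=True)
    return dens / total


def map_classify(t2_ms, model: ClassModel):
    """MAP label for scalar or array T2; ties broken by class order."""
    post = posterior(t2_ms, model)
    idx = np.argmax(post, axis=-1)  # argmax takes the first of equals
    labels = np.asarray(model.classes, dtype=object)[idx]
    return labels if isinstance(labels, np.ndarray) else str(labels)


def decision_boundaries(model: ClassModel, lo: float = 0.5, hi: float = 400.0) -> np.ndarray:
    """T2 values where the MAP label changes, from pairwise quadratic roots.

    Equating two weighted Gaussian log-densities gives a quadratic in T2;
    only roots in (lo, hi) at which the two classes are jointly maximal
    are boundaries of the decision partition.
    """
    roots = []
    for i in range(len(model.classes)):
        for j in range(i + 1, len(model.classes)):
            m1, s1, p1 = model.mu_ms[i], model.sd_ms[i], model.prior[i]
            m2, s2, p2 = model.mu_ms[j], model.sd_ms[j], model.prior[j]
            a = 1.0 / s2**2 - 1.0 / s1**2
            b = 2.0 * (m1 / s1**2 - m2 / s2**2)
            c = m2**2 / s2**2 - m1**2 / s1**2 + 2.0 * np.log((p1 * s2) / (p2 * s1))
            if abs(a) < 1e-15:
                cand = [-c / b] if b != 0 else []
            else:
                disc = b**2 - 4 * a * c
                cand = [] if disc < 0 else [(-b + np.sqrt(disc)) / (2 * a),
                                            (-b - np.sqrt(disc)) / (2 * a)]
            for r in cand:
                if not (lo < r < hi):
                    continue
                post = posterior(float(r), model)
                if np.isclose(post[i], post.max(), rtol=1e-6) and \
                        np.isclose(post[j], post.max(), rtol=1e-6):
                    roots.append(float(r))
    return np.unique(np.round(np.array(sorted(roots)), 9))


def detect_calcification(t2map: T2Map, wall_mask: np.ndarray, noise_sd: float,
                         te_query_ms: float = 14.0, snr_threshold: float = 2.0) -> np.ndarray:
    """Wall voxels whose synthetic PDW image has SNR below the threshold."""
    wall_mask = np.asarray(wall_mask, dtype=bool)
    if not wall_mask.any():
        return np.zeros_like(wall_mask)
    _, snr = synthetic_image(t2map, te_query_ms, noise_sd)
    low = np.where(np.isnan(snr), False, snr < snr_threshold)
    return wall_mask & low


@dataclass
class SegmentationResult:
    label_map: np.ndarray       # object array of label strings
    posterior_map: np.ndarray   # (rows, cols, n_classes), NaN where unclassified
    counts: dict[str, int]
    model: ClassModel


def segment_plaque(t2map: T2Map, wall_mask: np.ndarray, model: ClassModel,
                   noise_sd: float, te_query_ms: float = 14.0,
                   min_iph_component_px: int = 0) -> SegmentationResult:
    """Segment the wall into calcification + the model's tissue classes.

    Rule order: (1) calcification by the synthetic-PDW SNR rule (a
    calcified voxel has no valid T2, so it must be removed before the
    Bayes step and never receives posteriors); (2) fit-rejected,
    non-calcified voxels are marked ``rejected``; (3) remaining accepted
    wall voxels get the MAP label and their posteriors are stored.  An
    optional minimum connected-component size can suppress isolated
    recent-IPH speckle caused by T2 overestimation (off by default).
    """
    wall_mask = np.asarray(wall_mask, dtype=bool)
    if t2map.t2_ms.shape != wall_mask.shape:
        raise ValueError("T2 map and wall mask grids differ")
    shape = wall_mask.shape
    labels = np.full(shape, SEG_OUTSIDE, dtype=object)
    post = np.full(shape + (len(model.classes),), np.nan)

    calc = detect_calcification(t2map, wall_mask, noise_sd, te_query_ms)
    labels[calc] = SEG_CALCIFICATION
    rej = wall_mask & ~calc & ~t2map.accept_mask
    labels[rej] = SEG_REJECTED
    classify = wall_mask & ~calc & t2map.accept_mask
    if classify.any():
        t2vals = t2map.t2_ms[classify]
        labels[classify] = map_classify(t2vals, model)
        post[classify] = posterior(t2vals, model)

    if min_iph_component_px > 0:
        iph = labels == "recent_iph"
        comp, ncomp = ndimage.label(iph)
        for k in range(1, ncomp + 1):
            m = comp == k
            if m.sum() < min_iph_component_px:
                labels[m] = "fibrous"

    counts = {SEG_CALCIFICATION: int(calc.sum()), SEG_REJECTED: int(rej.sum())}
    for cls in model.classes:
        counts[cls] = int((labels == cls).sum())
    return SegmentationResult(label_map=labels, posterior_map=post,
                              counts=counts, model=model)
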