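"""Dual-axis landscape gradients from smoothed class surfaces.

The smoothed class fractions of one or more city windows are pooled
pixel-wise and ordinated with a principal components analysis of the
p x p Pearson *correlation* matrix (standardized variables, so the
eigenvalues sum to p and the percent variance of axis k is
100*lambda_k/p = 100*sdev_k^2/p). Axes are retained by the broken-stick
rule and oriented to fixed ecological anchors:

* axis 1, *hard-to-soft*: developed (impervious, "hard") classes load
  negative, so the surface increases from built cores toward unpaved
  ("soft") land;
* axis 2, *brown-to-green*: forest/wetland classes load positive, so
  the surface increases from agricultural ("brown") toward natural
  ("green") soft land.

A gradient surface assigns each pixel the sum of its smoothed class
values weighted by the axis loadings (``weighted_average`` mode), or
the standardized principal-component score (``score`` mode).

Statsmodels-style entry point::

    model = LandscapePCA([stack_city_a, stack_city_b])
    result = model.fit()          # a GradientModel
    hs = gradient_surface(stack_city_a, result, axis=1)
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .raster import ContinuousRaster
from .smoothing import SmoothedStack

__all__ = [
    "MomentAccumulator",
    "GradientModel",
    "LandscapePCA",
    "accumulate",
    "fit_pca",
    "broken_stick",
    "retain_axes",
    "orient_axes",
    "gradient_surface",
    "variance_explained_from_sdev",
    "DEFAULT_ANCHORS",
]

# NLCD-convention anchor classes for axis orientation
DEVELOPED_CLASSES = (21, 22, 23, 24)
FOREST_CLASSES = (41, 42, 43, 90, 95)

#: axis -> (anchor class codes, required sign of their summed loadings)
DEFAULT_ANCHORS: dict[int, tuple[tuple[int, ...], int]] = {
    1: (DEVELOPED_CLASSES, -1),  # hard end low, soft end high
    2: (FOREST_CLASSES, +1),  # green end high, brown end low
}


@dataclass
class MomentAccumulator:
    """Streaming first and second moments of the pixels-by-classes matrix.

    Supports pooling several city windows without materializing the
    concatenated matrix: accumulation is associative and order-free.
    """

    class_codes: list[int]
    n: int = 0
    sums: np.ndarray = None
    cross: np.ndarray = None

    def __post_init__(self) -> None:
        p = len(self.class_codes)
        if self.sums is None:
            self.sums = np.zeros(p)
        if self.cross is None:
            self.cross = np.zeros((p, p))

    def add_matrix(self, x: np.ndarray) -> "MomentAccumulator":
        x = np.asarray(x, dtype=float)
        if x.shape[1] != len(self.class_codes):
            raise ValueError("column count does not match class list")
        self.n += x.shape[0]
        self.sums += x.sum(axis=0)
        self.cross += x.T @ x
        return self

    def merge(self, other: "MomentAccumulator") -> "MomentAccumulator":
        if other.class_codes != self.class_codes:
            raise ValueError("class lists differ between accumulators")
        self.n += other.n
        self.sums += other.sums
        self.cross += other.cross
        return self

    @property
    def means(self) -> np.ndarray:
        return self.sums / self.n

    def covariance(self) -> np.ndarray:
        m = self.means
        return self.cross / self.n - np.outer(m, m)

    def stds(self) -> np.ndarray:
        var = np.clip(np.diag(self.covariance()), 0.0, None)
        return np.sqrt(var)

    def correlation(self) -> np.ndarray:
        cov = self.covariance()
        sd = self.stds()
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cov / np.outer(sd, sd)
        np.fill_diagonal(corr, 1.0)
        return corr


def accumulate(stacks) -> MomentAccumulator:
    """Pool one stack or a list of stacks into a moment accumulator."""
    if isinstance(stacks, SmoothedStack):
        stacks = [stacks]
    stacks = list(stacks)
    if not stacks:
        raise ValueError("no stacks to accumulate")
    codes = stacks[0].class_codes
    acc = MomentAccumulator(list(codes))
    for stack in stacks:
        if list(stack.class_codes) != list(codes):
            raise ValueError("stacks must share the class list and order")
        acc.add_matrix(stack.as_matrix())
    return acc


def broken_stick(p: int) -> np.ndarray:
    """Broken-stick proportions b_k = (1/p) * sum_{i=k}^{p} 1/i.

    The expected variance shares when total variance is split at p-1
    uniform random break points; components are retained only while
    they explain more than chance. Sums to 1 exactly.
    """
    if p < 1:
        raise ValueError("p must be at least 1")
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def variance_explained_from_sdev(sdev: float, p: int) -> float:
    """Percent variance of one axis from its standard deviation.

    Under correlation-matrix PCA the eigenvalues sum to p, so an axis
    with standard deviation s explains 100*s^2/p percent.
    """
    return 100.0 * sdev * sdev / p


@dataclass
class GradientModel:
    """Fitted landscape-gradient ordination.

    Eigen-decomposition of the class correlation matrix with
    broken-stick retention and axis orientation. Loadings columns are
    unit-norm eigenvectors; ``loadings[:, k]`` is axis k+1.
    """

    class_codes: list[int]
    eigenvalues: np.ndarray
    loadings: np.ndarray
    means: np.ndarray
    stds: np.ndarray
    n_pixels: int
    dropped_classes: list[int] = field(default_factory=list)
    orientation: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return len(self.class_codes)

    @property
    def sdev(self) -> np.ndarray:
        return np.sqrt(np.clip(self.eigenvalues, 0.0, None))

    @property
    def variance_explained(self) -> np.ndarray:
        """Percent of total variance per axis (sums to 100)."""
        return 100.0 * self.eigenvalues / self.p

    @property
    def broken_stick_proportions(self) -> np.ndarray:
        return broken_stick(self.p)

    @property
    def n_retained(self) -> int:
        return retain_axes(self)

    def summary(self) -> str:
        import pandas as pd

        bs = self.broken_stick_proportions
        ve = self.variance_explained
        lines = [
            "Landscape gradient PCA (correlation matrix)",
            f"  classes: {self.p}   pixels: {self.n_pixels}   retained axes: {self.n_retained}",
            f"  broken-stick threshold: {100 * bs[0]:.1f}% cumulative variance",
        ]
        if self.dropped_classes:
            lines.append(f"  dropped zero-variance classes: {self.dropped_classes}")
        head = pd.DataFrame(
            {
                "Std.Dev.": np.round(self.sdev[: min(4, self.p)], 3),
                "VarExpl(%)": np.round(ve[: min(4, self.p)], 1),
                "BrokenStick(%)": np.round(100 * bs[: min(4, self.p)], 1),
            },
            index=[f"PC{k + 1}" for k in range(min(4, self.p))],
        )
        load = pd.DataFrame(
            np.round(self.loadings[:, : min(3, self.p)], 3),
            index=self.class_codes,
            columns=[f"PC{k + 1}" for k in range(min(3, self.p))],
        )
        return "\n".join(lines) + "\n" + head.to_string() + "\n" + load.to_string()

    def to_json(self) -> str:
        return json.dumps(
            {
                "class_codes": self.class_codes,
                "eigenvalues": self.eigenvalues.tolist(),
                "loadings": self.loadings.tolist(),
                "means": self.means.tolist(),
                "stds": self.stds.tolist(),
                "n_pixels": self.n_pixels,
                "dropped_classes": self.dropped_classes,
                "orientation": self.orientation,
                "variance_explained": self.variance_explained.tolist(),
                "broken_stick": self.broken_stick_proportions.tolist(),
                "n_retained": self.n_retained,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GradientModel":
        d = json.loads(text)
        return cls(
            class_codes=list(d["class_codes"]),
            eigenvalues=np.asarray(d["eigenvalues"]),
            loadings=np.asarray(d["loadings"]),
            means=np.asarray(d["means"]),
            stds=np.asarray(d["stds"]),
            n_pixels=int(d["n_pixels"]),
            dropped_classes=list(d.get("dropped_classes", [])),
            orientation=dict(d.get("orientation", {})),
        )


def fit_pca(acc: MomentAccumulator) -> GradientModel:
    """Eigen-decompose the pooled class correlation matrix.

    Zero-variance classes (constant over all pixels) have undefined
    correlations; they are dropped with a warning and recorded on the
    model, reducing p accordingly.
    """
    if acc.n <= len(acc.class_codes):
        raise ValueError("need more pixels than classes for the ordination")
    sd = acc.stds()
    keep = sd > 1e-12
    dropped = [c for c, k in zip(acc.class_codes, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping zero-variance classes {dropped} (correlation undefined)",
            stacklevel=2,
        )
    codes = [c for c, k in zip(acc.class_codes, keep) if k]
    corr = acc.correlation()[np.ix_(keep, keep)]
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign convention pre-orientation: largest |loading| positive
    for k in range(eigvec.shape[1]):
        j = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[j, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    return GradientModel(
        class_codes=codes,
        eigenvalues=eigval,
        loadings=eigvec,
        means=acc.means[keep],
        stds=sd[keep],
        n_pixels=acc.n,
        dropped_classes=dropped,
    )


def retain_axes(model: GradientModel) -> int:
    """Number of leading axes kept by the broken-stick rule.

    The smallest m whose cumulative variance share exceeds the first
    broken-stick proportion b_1; with fifteen classes b_1 = 22.1%, so
    axes are added until their summed variance passes that threshold.
    """
    b1 = model.broken_stick_proportions[0]
    cum = np.cumsum(model.variance_explained) / 100.0
    return int(np.argmax(cum > b1) + 1)


def orient_axes(model: GradientModel, anchor_map: dict | None = None) -> GradientModel:
    """Flip retained axes to match ecological sign anchors (idempotent).

    ``anchor_map`` maps 1-based axis index to ``(class codes, sign)``:
    the summed loadings of the anchor classes are forced to the given
    sign by negating the whole axis if needed. Eigenvalues are
    unaffected. Defaults orient axis 1 hard-to-soft (developed classes
    negative) and axis 2 brown-to-green (forest classes positive).
    """
    if anchor_map is None:
        anchor_map = DEFAULT_ANCHORS
    loadings = model.loadings.copy()
    record = {}
    for axis, (classes, sign) in anchor_map.items():
        if axis > model.p:
            continue
        idx = [model.class_codes.index(c) for c in classes if c in model.class_codes]
        if not idx:
            raise ValueError(f"anchor classes {classes} absent from model")
        total = loadings[idx, axis - 1].sum()
        flipped = bool(total * sign < 0)
        if flipped:
            loadings[:, axis - 1] = -loadings[:, axis - 1]
        record[str(axis)] = {
            "anchor_classes": [model.class_codes[i] for i in idx],
            "required_sign": sign,
            "flipped": flipped,
        }
    return GradientModel(
        class_codes=model.class_codes,
        eigenvalues=model.eigenvalues,
        loadings=loadings,
        means=model.means,
        stds=model.stds,
        n_pixels=model.n_pixels,
        dropped_classes=list(model.dropped_classes),
        orientation=record,
    )


def gradient_surface(
    stack: SmoothedStack,
    model: GradientModel,
    axis: int = 1,
    mode: str = "weighted_average",
) -> ContinuousRaster:
    """Project a smoothed stack onto one gradient axis.

    ``weighted_average``: s(x) = sum_c z_c(x) * w_c over the raw
    smoothed class values — the pixel value is the loadings-weighted
    average of class fractions. ``score``: the proper standardized
    principal-component score sum_c ((z_c - mean_c)/sd_c) * w_c.
    """
    if mode not in ("weighted_average", "score"):
        raise ValueError("mode must be 'weighted_average' or 'score'")
    if axis < 1 or axis > model.p:
        raise ValueError(f"axis {axis} out of range 1..{model.p}")
    missing = [c for c in model.class_codes if c not in stack.class_codes]
    if missing:
        raise ValueError(f"stack lacks model classes {missing}")
    w = model.loadings[:, axis - 1]
    g = stack.georef
    out = np.zeros(g.shape)
    for k, code in enumerate(model.class_codes):
        z = stack.layers[code].values
        if mode == "score":
            z = (z - model.means[k]) / model.stds[k]
        out = out + np.where(np.isnan(z), 0.0, z) * w[k]
    mask = stack.valid_mask()
    out[~mask] = np.nan
    return ContinuousRaster(g, out)


class LandscapePCA:
    """Correlation-matrix PCA over smoothed landscape stacks.

    Model object in the statsmodels mold: construct from one or more
    :class:`SmoothedStack` (pooled pixel-wise), then :meth:`fit` to
    obtain an oriented :class:`GradientModel`.

    Parameters
    ----------
    stacks : SmoothedStack or sequence of SmoothedStack
        City windows smoothed at a common scale with a shared class list.
    anchor_map : dict, optional
        Axis-orientation anchors; defaults to hard-to-soft /
        brown-to-green.
    """

    def __init__(self, stacks, anchor_map: dict | None = None):
        self.accumulator = accumulate(stacks)
        self.anchor_map = anchor_map

    def fit(self, orient: bool = True) -> GradientModel:
        model = fit_pca(self.accumulator)
        if orient:
            model = orient_axes(model, self.anchor_map)
        return model
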