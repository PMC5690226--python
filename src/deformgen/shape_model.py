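"""Active shape model of deformation fields.

A population of displacement vector fields (DVFs), all defined on one grid,
is vectorized into a training matrix D = {d(1), …, d(N)} and summarised by
its mean deformation d̄ and the principal modes of the sample covariance

    Σ = 1/(N−1) Σ_t (d(t) − d̄)(d(t) − d̄)ᵀ .

Σ is never materialised: with at most N−1 nonzero eigenvalues, the eigenpairs
are obtained from the N×N Gram matrix of the centred columns.  The retained
mode count T̂ is the smallest number of leading modes whose eigenvalues cover
at least α percent of the total variance, and new deformations are drawn as

    d = d̄ + Σ_j b_j φ(j),    b_j ~ N(0, λ(j)),

subject to a cap D_max on the Mahalanobis distance sqrt(Σ_j b_j²/λ(j)).

The public surface follows the Model/Results idiom:
:class:`DeformationShapeModel` holds the training data and ``fit(alpha=...)``
returns a :class:`ShapeModelResults` carrying d̄, λ, φ, T̂ with ``summary()``,
``sample()``, ``save()``/``load()``.  Thin functional wrappers
(:func:`fit_shape_model`, :func:`sample_deformation`, …) expose the same
operations.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .grid import GeometryError, VectorField

__all__ = [
    "TrainingMatrix",
    "DeformationShapeModel",
    "ShapeModelResults",
    "ModeWeights",
    "build_training_matrix",
    "vectorize_field",
    "devectorize_field",
    "fit_shape_model",
    "select_principal_modes",
    "space_reduction",
    "mahalanobis",
    "sample_deformation",
    "load_model",
]

# Vectorization order is frozen so that persisted models are portable:
# component-major (all LR, then all AP, then all SI), each block raveled in
# index order with the first (LR) axis fastest — i.e. Fortran order.
VECTORIZATION_ORDER = "component-major, blocks (LR, AP, SI), first axis fastest"

_EIGENVALUE_FLOOR_REL = 1e-12  # below this fraction of λ(1), treat as rank-deficient zero
_MAX_REJECTIONS = 1000


def vectorize_field(fld: VectorField) -> np.ndarray:
    """Column-wise vectorization of a DVF in the frozen order."""
    return np.concatenate([
        fld.dx.ravel(order="F"), fld.dy.ravel(order="F"), fld.dz.ravel(order="F")
    ])


def devectorize_field(vec: np.ndarray, shape, spacing, origin) -> VectorField:
    """Exact inverse of :func:`vectorize_field`."""
    n = int(np.prod(shape))
    if vec.size != 3 * n:
        raise ValueError(f"vector length {vec.size} does not match grid {shape}")
    comps = vec.reshape(3, n)
    return VectorField(
        comps[0].reshape(shape, order="F"),
        comps[1].reshape(shape, order="F"),
        comps[2].reshape(shape, order="F"),
        spacing, origin,
    )


@dataclass
class TrainingMatrix:
    """N vectorized DVFs as columns of a (3·voxels) × N matrix."""

    columns: np.ndarray
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    @property
    def n(self) -> int:
        return self.columns.shape[1]

    def field(self, t: int) -> VectorField:
        return devectorize_field(self.columns[:, t], self.shape, self.spacing, self.origin)


def build_training_matrix(dvfs: list[VectorField]) -> TrainingMatrix:
    """Stack vectorized DVFs column-wise; all fields must share one grid."""
    if len(dvfs) < 2:
        raise ValueError(f"need at least 2 training DVFs, got {len(dvfs)}")
    ref = dvfs[0]
    for i, d in enumerate(dvfs[1:], start=1):
        if not ref.same_geometry(d):
            raise GeometryError(f"training DVF {i} is not on the shared grid")
    cols = np.column_stack([vectorize_field(d) for d in dvfs])
    if not np.all(np.isfinite(cols)):
        raise ValueError("training DVFs contain non-finite values")
    return TrainingMatrix(cols, ref.shape, ref.spacing, ref.origin)


def select_principal_modes(eigenvalues, alpha: float) -> int:
    """Smallest T̂ whose leading eigenvalues cover ≥ α percent of the total.

    ``eigenvalues`` must be sorted descending and non-negative; returns 0
    when the total variance is 0.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size and np.any(np.diff(lam) > 1e-12 * max(1.0, abs(lam[0]))):
        raise ValueError("eigenvalues must be sorted in descending order")
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be non-negative")
    if not (0 < alpha <= 100):
        raise ValueError(f"alpha must lie in (0, 100], got {alpha}")
    total = lam.sum()
    if total == 0:
        return 0
    target = (alpha / 100.0) * total
    csum = np.cumsum(lam)
    # tiny tolerance so an exact-boundary cumulative sum counts as reached
    return int(np.searchsorted(csum, target - 1e-12 * total) + 1)


def space_reduction(n: int, t_hat: int) -> float:
    """Variation-space reduction 100·(N − T̂)/N, in percent."""
    if not 0 <= t_hat <= n:
        raise ValueError(f"need 0 <= T_hat <= N, got T_hat={t_hat}, N={n}")
    return 100.0 * (n - t_hat) / n


@dataclass
class ModeWeights:
    """Accepted mode coefficients b and the cap D_max that bounded them."""

    b: np.ndarray
    d_max: float

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=float)
        if self.d_max < 0:
            raise ValueError("D_max must be non-negative")


def mahalanobis(weights, eigenvalues) -> float:
    """Mahalanobis distance sqrt(Σ_j b_j²/λ(j)) of a weight vector.

    Modes with λ(j) = 0 admit no displacement: a nonzero b there is a
    contract violation.
    """
    b = weights.b if isinstance(weights, ModeWeights) else np.asarray(weights, dtype=float)
    lam = np.asarray(eigenvalues, dtype=float)[: b.size]
    if b.size != lam.size:
        raise ValueError("weight and eigenvalue lengths differ")
    zero = lam <= 0
    if np.any(zero & (b != 0)):
        raise ValueError("nonzero weight on a zero-variance mode")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(zero, 0.0, b**2 / np.where(zero, 1.0, lam))
    return float(np.sqrt(terms.sum()))


class DeformationShapeModel:
    """Statistical model of a DVF population, fitted by PCA.

    Parameters
    ----------
    training : TrainingMatrix or list of VectorField
        The population of displacement fields, all on one grid.

    Examples
    --------
    >>> model = DeformationShapeModel(dvfs)      # doctest: +SKIP
    >>> res = model.fit(alpha=90)                # doctest: +SKIP
    >>> print(res.summary())                     # doctest: +SKIP
    >>> dvf, w = res.sample(d_max=3, seed=7)     # doctest: +SKIP
    """

    def __init__(self, training):
        if isinstance(training, TrainingMatrix):
            self.training = training
        else:
            self.training = build_training_matrix(list(training))

    @classmethod
    def from_fields(cls, dvfs) -> "DeformationShapeModel":
        return cls(build_training_matrix(list(dvfs)))

    @property
    def nobs(self) -> int:
        return self.training.n

    def fit(self, alpha: float = 90.0) -> "ShapeModelResults":
        """Fit mean + principal modes, retaining α percent of the variance.

        The eigenproblem of the (huge, implicit) covariance is solved through
        the N×N Gram matrix G = CᵀC/(N−1) of the centred columns C; each
        covariance eigenvector is the normalised image C w of a Gram
        eigenvector w with the same (positive) eigenvalue.
        """
        D = self.training.columns
        n = self.training.n
        mean = D.mean(axis=1)
        C = D - mean[:, None]
        G = (C.T @ C) / (n - 1)
        lam, W = np.linalg.eigh(G)
        order = np.argsort(lam)[::-1]
        lam, W = lam[order], W[:, order]
        lam = np.clip(lam, 0.0, None)
        total_variance = float(lam.sum())
        floor = _EIGENVALUE_FLOOR_REL * (lam[0] if lam.size else 0.0)
        nonzero = lam > floor
        lam_nz = lam[nonzero]
        modes = np.empty((D.shape[0], lam_nz.size))
        for j, w in enumerate(W[:, nonzero].T):
            v = C @ w
            v /= np.linalg.norm(v)
            # deterministic sign across linear-algebra backends
            k = int(np.argmax(np.abs(v)))
            if v[k] < 0:
                v = -v
            modes[:, j] = v
        t_hat = select_principal_modes(lam_nz, alpha)
        return ShapeModelResults(
            model=self,
            mean=mean,
            eigenvalues=lam_nz,
            modes=modes,
            t_hat=t_hat,
            alpha=float(alpha),
            total_variance=total_variance,
            grid=(self.training.shape, self.training.spacing, self.training.origin),
        )


class ShapeModelResults:
    """Fitted active shape model: d̄, λ(j), φ(j), T̂ at level α.

    ``eigenvalues`` and ``modes`` hold every numerically nonzero eigenpair
    (at most N−1 of them); the first ``t_hat`` are the retained principal
    modes.  ``modes`` has the vectorized fields as columns, orthonormal.
    """

    def __init__(self, model, mean, eigenvalues, modes, t_hat, alpha,
                 total_variance, grid):
        self.model = model
        self.mean = np.asarray(mean, dtype=float)
        self.eigenvalues = np.asarray(eigenvalues, dtype=float)
        self.modes = np.asarray(modes, dtype=float)
        self.t_hat = int(t_hat)
        self.alpha = float(alpha)
        self.total_variance = float(total_variance)
        self.grid_shape = tuple(int(s) for s in grid[0])
        self.grid_spacing = tuple(float(s) for s in grid[1])
        self.grid_origin = tuple(float(s) for s in grid[2])

    # -- derived quantities -------------------------------------------------

    @property
    def nobs(self) -> int:
        """Number of training DVFs (recovered from metadata after load)."""
        if self.model is not None:
            return self.model.nobs
        return getattr(self, "_n_training", -1)

    @property
    def n_modes(self) -> int:
        """Count of numerically nonzero modes available."""
        return int(self.eigenvalues.size)

    def space_reduction(self) -> float:
        """100·(N − T̂)/N for this fit."""
        return space_reduction(self.nobs, self.t_hat)

    def explained_percent(self, k: int | None = None) -> float:
        """Percent of total variance covered by the leading k (default T̂) modes."""
        k = self.t_hat if k is None else int(k)
        if self.total_variance == 0:
            return 100.0
        return 100.0 * float(self.eigenvalues[:k].sum()) / self.total_variance

    def mean_field(self) -> VectorField:
        return devectorize_field(
            self.mean, self.grid_shape, self.grid_spacing, self.grid_origin
        )

    def mode_field(self, j: int) -> VectorField:
        """The j-th principal mode as a unit-norm displacement field."""
        return devectorize_field(
            self.modes[:, j], self.grid_shape, self.grid_spacing, self.grid_origin
        )

    # -- sampling -----------------------------------------------------------

    def sample(self, d_max: float, seed=None) -> tuple[VectorField, ModeWeights]:
        """Draw one random deformation d = d̄ + Σ b_j φ(j).

        Coefficients are drawn independently as b_j ~ N(0, λ(j)) over the
        T̂ retained modes and the whole vector is redrawn (rejection) until
        its Mahalanobis distance is ≤ ``d_max``, preserving the Gaussian
        shape inside the Mahalanobis ball.  After 1000 consecutive
        rejections — only plausible for a tiny d_max with many modes — the
        draw is radially rescaled onto the ball instead.  ``d_max = 0``
        returns the mean deformation.  ``seed`` may be an int or a
        ``numpy.random.Generator``.
        """
        if d_max < 0:
            raise ValueError("d_max must be non-negative")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        lam = self.eigenvalues[: self.t_hat]
        sd = np.sqrt(np.clip(lam, 0.0, None))
        if self.t_hat == 0 or d_max == 0:
            b = np.zeros(self.t_hat)
        else:
            for _ in range(_MAX_REJECTIONS):
                b = rng.standard_normal(self.t_hat) * sd
                if mahalanobis(b, lam) <= d_max:
                    break
            else:
                b = rng.standard_normal(self.t_hat) * sd
                m = mahalanobis(b, lam)
                if m > 0:
                    b *= d_max / m
        vec = self.mean + self.modes[:, : self.t_hat] @ b
        fld = devectorize_field(vec, self.grid_shape, self.grid_spacing, self.grid_origin)
        return fld, ModeWeights(b, float(d_max))

    def field_from_weights(self, weights: ModeWeights) -> VectorField:
        """Deterministic reconstruction d̄ + Σ b_j φ(j) for given weights."""
        b = np.asarray(weights.b, dtype=float)
        vec = self.mean + self.modes[:, : b.size] @ b
        return devectorize_field(vec, self.grid_shape, self.grid_spacing, self.grid_origin)

    # -- reporting and persistence -------------------------------------------

    def summary(self) -> str:
        lines = [
            "Deformation active shape model",
            "=" * 46,
            f"training DVFs (N)        {self.nobs}",
            f"grid                     {self.grid_shape} @ {self.grid_spacing} mm",
            f"alpha (percent)          {self.alpha:g}",
            f"retained modes (T_hat)   {self.t_hat} of {self.n_modes} nonzero",
            f"variance covered         {self.explained_percent():.2f}%",
            f"space reduction          {self.space_reduction():.1f}%",
            f"total variance (mm^2)    {self.total_variance:.4g}",
            "-" * 46,
            "  mode     eigenvalue    cumulative %",
        ]
        csum = 0.0
        for j, l in enumerate(self.eigenvalues, start=1):
            csum += l
            pct = 100.0 * csum / self.total_variance if self.total_variance else 100.0
            tag = "*" if j <= self.t_hat else " "
            lines.append(f" {tag}{j:4d}   {l:12.5g}   {pct:10.2f}")
        return "\n".join(lines)

    def plot_scree(self, ax=None):
        """Eigenvalue scree and cumulative variance-coverage curve.

        Requires matplotlib; returns the axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        k = np.arange(1, self.eigenvalues.size + 1)
        ax.bar(k, self.eigenvalues, color="0.7", label="eigenvalue")
        ax.axvline(self.t_hat + 0.5, color="r", ls="--",
                   label=f"T̂ = {self.t_hat} (α = {self.alpha:g})")
        ax.set_xlabel("mode")
        ax.set_ylabel("eigenvalue (mm²)")
        ax2 = ax.twinx()
        if self.total_variance > 0:
            ax2.plot(k, 100 * np.cumsum(self.eigenvalues) / self.total_variance,
                     "k.-", label="cumulative %")
        ax2.set_ylabel("variance covered (%)")
        ax.legend(loc="center right")
        return ax

    def save(self, path: str) -> None:
        """Persist to a directory: arrays + JSON metadata (exact round-trip)."""
        os.makedirs(path, exist_ok=True)
        np.save(os.path.join(path, "mean.npy"), self.mean)
        np.save(os.path.join(path, "eigenvalues.npy"), self.eigenvalues)
        np.save(os.path.join(path, "modes.npy"), self.modes)
        meta = {
            "t_hat": self.t_hat,
            "alpha": self.alpha,
            "n_training": self.nobs,
            "total_variance": self.total_variance,
            "grid": {
                "shape": list(self.grid_shape),
                "spacing": list(self.grid_spacing),
                "origin": list(self.grid_origin),
            },
            "vectorization_order": VECTORIZATION_ORDER,
        }
        with open(os.path.join(path, "model.json"), "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "ShapeModelResults":
        with open(os.path.join(path, "model.json")) as fh:
            meta = json.load(fh)
        res = cls(
            model=None,
            mean=np.load(os.path.join(path, "mean.npy")),
            eigenvalues=np.load(os.path.join(path, "eigenvalues.npy")),
            modes=np.load(os.path.join(path, "modes.npy")),
            t_hat=meta["t_hat"],
            alpha=meta["alpha"],
            total_variance=meta["total_variance"],
            grid=(meta["grid"]["shape"], meta["grid"]["spacing"], meta["grid"]["origin"]),
        )
        res._n_training = int(meta["n_training"])
        return res


def fit_shape_model(training, alpha: float = 90.0) -> ShapeModelResults:
    """Fit an active shape model (functional wrapper)."""
    return DeformationShapeModel(training).fit(alpha=alpha)


def sample_deformation(results: ShapeModelResults, d_max: float,
                       rng_seed=None) -> tuple[VectorField, ModeWeights]:
    """Draw one Mahalanobis-bounded random deformation (functional wrapper)."""
    return results.sample(d_max, seed=rng_seed)


def load_model(path: str) -> ShapeModelResults:
    return ShapeModelResults.load(path)
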