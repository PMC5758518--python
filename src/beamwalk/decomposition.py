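"""Low-dimensional structure of segmental signals.

The dimensionality analysis follows the motor-synergy tradition: PCA on the
*covariance* matrix of the 14 segment channels (no per-channel amplitude
normalization), retention of the smallest number of components reaching 95%
variance accounted for (VAF), VARIMAX rotation of the retained components
for interpretability, Hoyer's sparseness index per component, cosine
similarity with greedy best-pair matching between component sets, and
cross-validated reconstruction VAF.

A statsmodels-flavoured model object, :class:`SegmentalDecomposition`, wraps
the functional pieces: build it from a time x channels matrix, call
``fit()``, and read loadings, VAF, sparsity and score time series off the
returned :class:`DecompositionResults`.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .anthropometry import SEGMENTS

DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "head": ("He",),
    "trunk": ("Tr",),
    "arms": ("LUA", "RUA", "LFA", "RFA", "LA", "RA"),
    "legs": ("LT", "RT", "LS", "RS", "LF", "RF"),
}


class DecompositionError(ValueError):
    """Raised for degenerate inputs to the dimensionality analysis."""


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude element positive (PCA signs are
    arbitrary; this pins a convention)."""
    out = loadings.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            out[:, k] = -col
    return out


@dataclass
class ComponentSet:
    """Loading vectors over the segment channels.

    ``loadings`` columns are eigenvectors scaled by the square root of their
    eigenvalue (covariance loadings), so a column's squared norm is the
    variance it explains; VARIMAX rotates these scaled loadings.  ``vaf`` is
    per-component percent of the *total* data variance; ``total_variance``
    is the trace of the source covariance matrix.
    """

    loadings: np.ndarray
    vaf: np.ndarray
    total_variance: float
    channel_names: tuple[str, ...] = SEGMENTS
    rotated: bool = False
    label: str = ""

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.vaf = np.asarray(self.vaf, dtype=float)
        if self.loadings.shape != (len(self.channel_names), self.vaf.shape[0]):
            raise DecompositionError(
                f"loadings shape {self.loadings.shape} inconsistent with "
                f"{len(self.channel_names)} channels / {self.vaf.shape[0]} components")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def cumulative_vaf(self) -> np.ndarray:
        return np.cumsum(self.vaf)

    def unit_loadings(self) -> np.ndarray:
        norms = np.linalg.norm(self.loadings, axis=0)
        if np.any(norms == 0):
            raise DecompositionError("zero loading column")
        return self.loadings / norms

    def sparsity(self) -> np.ndarray:
        """Hoyer sparseness of each component (scale-invariant)."""
        return np.array([hoyer_sparsity(self.loadings[:, k])
                         for k in range(self.n_components)])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "channel_names": list(self.channel_names),
            "loadings": {name: [float(v) for v in row]
                         for name, row in zip(self.channel_names, self.loadings)},
            "vaf_percent": [float(v) for v in self.vaf],
            "sparsity": [float(v) for v in self.sparsity()],
            "total_variance": float(self.total_variance),
            "rotated": self.rotated,
            "label": self.label,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ComponentSet":
        try:
            payload = json.loads(str(source))
        except json.JSONDecodeError:
            payload = json.loads(Path(source).read_text(encoding="utf-8"))
        names = tuple(payload["channel_names"])
        loadings = np.array([payload["loadings"][n] for n in names], dtype=float)
        return cls(loadings=loadings, vaf=np.array(payload["vaf_percent"]),
                   total_variance=payload["total_variance"], channel_names=names,
                   rotated=payload["rotated"], label=payload.get("label", ""))


def covariance_pca(data: np.ndarray,
                   channel_names: tuple[str, ...] = SEGMENTS,
                   label: str = "") -> ComponentSet:
    """Full-rank PCA of the channel covariance matrix.

    Channel means are removed; components are covariance eigenvectors ordered
    by descending eigenvalue; VAF_k = 100 * lambda_k / trace.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise DecompositionError("need a 2-D matrix with at least 2 frames")
    if data.shape[1] != len(channel_names):
        raise DecompositionError(
            f"{data.shape[1]} columns but {len(channel_names)} channel names")
    cov = np.cov(data, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    total = float(eigval.sum())
    if total == 0:
        raise DecompositionError("data has zero variance")
    loadings = _fix_signs(eigvec * np.sqrt(eigval))
    return ComponentSet(loadings=loadings, vaf=100.0 * eigval / total,
                        total_variance=total, channel_names=channel_names,
                        label=label)


def retain_components(cs: ComponentSet, threshold: float = 95.0) -> ComponentSet:
    """Keep the smallest K with cumulative VAF >= threshold percent."""
    if not 0.0 < threshold <= 100.0:
        raise DecompositionError(f"threshold {threshold} outside (0, 100]")
    cum = cs.cumulative_vaf
    k = int(np.searchsorted(cum, threshold - 1e-9) + 1)
    k = min(k, cs.n_components)
    return replace(cs, loadings=cs.loadings[:, :k], vaf=cs.vaf[:k])


def _varimax_criterion(loadings: np.ndarray) -> float:
    sq = loadings ** 2
    n = loadings.shape[0]
    return float(np.sum(sq ** 2) / n - np.sum((sq.sum(axis=0) / n) ** 2))


def _varimax_iterate(loadings: np.ndarray, start: np.ndarray, tol: float,
                     max_iter: int) -> tuple[np.ndarray, bool]:
    """Classic SVD-based VARIMAX sweep from a given starting rotation."""
    n, _ = loadings.shape
    rotation = start
    objective = 0.0
    for _ in range(max_iter):
        basis = loadings @ rotation
        u, s, vt = np.linalg.svd(
            loadings.T @ (basis ** 3 - basis @ np.diag((basis ** 2).sum(axis=0)) / n))
        rotation = u @ vt
        new_objective = s.sum()
        if new_objective <= objective * (1.0 + tol):
            return rotation, True
        objective = new_objective
    return rotation, False


def _varimax_rotation(loadings: np.ndarray, tol: float,
                      max_iter: int) -> tuple[np.ndarray, bool]:
    """Multi-start VARIMAX (no Kaiser row normalization).

    The SVD iteration can stall on saddle points (e.g. perfectly mixed
    loadings), so it is restarted from the identity plus a fixed set of
    seeded random orthogonal rotations; the best criterion wins.  Fully
    deterministic.
    """
    k = loadings.shape[1]
    rng = np.random.default_rng(0)
    starts = [np.eye(k)]
    for _ in range(3):
        q, r = np.linalg.qr(rng.normal(size=(k, k)))
        starts.append(q * np.sign(np.diag(r)))
    best_rotation, best_value, best_converged = None, -np.inf, False
    for start in starts:
        rotation, converged = _varimax_iterate(loadings, start, tol, max_iter)
        value = _varimax_criterion(loadings @ rotation)
        if value > best_value:
            best_rotation, best_value, best_converged = rotation, value, converged
    return best_rotation, best_converged


def varimax(cs: ComponentSet, tol: float = 1e-8,
            max_iter: int = 1000) -> ComponentSet:
    """VARIMAX rotation of the retained (scaled) loadings.

    The rotation is orthogonal, so the spanned subspace and the total
    retained variance are unchanged; per-component VAF is recomputed from
    the rotated column norms and components are re-ordered by descending
    VAF.  If the iteration has not converged after ``max_iter`` sweeps the
    best iterate is returned with a warning.
    """
    if cs.n_components < 1:
        raise DecompositionError("no components to rotate")
    if cs.n_components == 1:
        return replace(cs, loadings=_fix_signs(cs.loadings.copy()), rotated=True)
    rotation, converged = _varimax_rotation(cs.loadings, tol, max_iter)
    if not converged:
        warnings.warn("VARIMAX did not converge; returning best iterate",
                      stacklevel=2)
    rotated = cs.loadings @ rotation
    vaf = 100.0 * (rotated ** 2).sum(axis=0) / cs.total_variance
    order = np.argsort(vaf)[::-1]
    return replace(cs, loadings=_fix_signs(rotated[:, order]), vaf=vaf[order],
                   rotated=True)


def hoyer_sparsity(v: np.ndarray) -> float:
    """Hoyer's sparseness index (sqrt(N) - l1/l2) / (sqrt(N) - 1).

    0 for a uniform vector, 1 when a single element is nonzero.
    """
    v = np.asarray(v, dtype=float).ravel()
    l2 = np.linalg.norm(v)
    if l2 == 0:
        raise DecompositionError("sparsity undefined for the zero vector")
    n = v.size
    if n < 2:
        raise DecompositionError("sparsity needs at least 2 elements")
    return float((np.sqrt(n) - np.abs(v).sum() / l2) / (np.sqrt(n) - 1.0))


def similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two components (uncentered Pearson R)."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise DecompositionError(f"length mismatch: {u.size} vs {v.size}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DecompositionError("similarity undefined for the zero vector")
    return float(u @ v / (nu * nv))


def _as_loadings(obj) -> np.ndarray:
    if isinstance(obj, ComponentSet):
        return obj.loadings
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2:
        raise DecompositionError("expected a 2-D loading matrix or ComponentSet")
    return arr


@dataclass(frozen=True)
class PairingResult:
    """Greedy best-pair matching between two component sets."""

    pairs: tuple[tuple[int, int, float], ...]  # (index_a, index_b, |S|)
    mean: float
    sd: float


def greedy_pair(set_a, set_b) -> PairingResult:
    """Iteratively match the most similar cross-pair, remove it, repeat.

    Similarity is |S| with post-hoc sign alignment (PCA signs are
    arbitrary).  Ties break on the lowest (a, b) index pair.  Matching stops
    when the smaller set is exhausted.
    """
    a = _as_loadings(set_a)
    b = _as_loadings(set_b)
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise DecompositionError("both component sets must be nonempty")
    sim = np.zeros((a.shape[1], b.shape[1]))
    for i in range(a.shape[1]):
        for j in range(b.shape[1]):
            sim[i, j] = abs(similarity(a[:, i], b[:, j]))
    free_a = list(range(a.shape[1]))
    free_b = list(range(b.shape[1]))
    pairs = []
    while free_a and free_b:
        sub = sim[np.ix_(free_a, free_b)]
        flat = int(np.argmax(sub))               # row-major -> lowest (a, b) tie-break
        i, j = divmod(flat, sub.shape[1])
        pairs.append((free_a[i], free_b[j], float(sub[i, j])))
        free_a.pop(i)
        free_b.pop(j)
    values = np.array([s for _, _, s in pairs])
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return PairingResult(pairs=tuple(pairs), mean=float(values.mean()), sd=sd)


def crossfit_vaf(components, data: np.ndarray) -> float:
    """VAF of ``data`` reconstructed by least squares from ``components``.

    The data matrix is centered with its own channel means; the
    reconstruction is the orthogonal projection onto the span of the loading
    columns, so with a set's own retained components this reproduces the
    cumulative eigenvalue VAF exactly.
    """
    basis = _as_loadings(components)
    data = np.asarray(data, dtype=float)
    centered = data - data.mean(axis=0)
    coef, *_ = np.linalg.lstsq(basis, centered.T, rcond=None)
    resid = centered - (basis @ coef).T
    total = float((centered ** 2).sum())
    if total == 0:
        raise DecompositionError("data has zero variance")
    return float(100.0 * (1.0 - (resid ** 2).sum() / total))


def group_vaf(data: np.ndarray,
              groups: dict[str, tuple[str, ...]] | None = None,
              channel_names: tuple[str, ...] = SEGMENTS,
              method: str = "regression") -> dict[str, float]:
    """Share of the full data variance attributable to each body-part group.

    ``method="regression"`` (default): VAF of the centered full matrix
    reconstructed by least squares from the group's channels alone (groups
    need not sum to 100%).  ``method="variance_share"``: the group's share of
    the summed channel variances (sums to 100%).
    """
    groups = DEFAULT_GROUPS if groups is None else groups
    claimed = [c for members in groups.values() for c in members]
    if sorted(claimed) != sorted(channel_names):
        raise DecompositionError(
            "groups must partition the channels exactly; got "
            f"{sorted(claimed)} vs {sorted(channel_names)}")
    data = np.asarray(data, dtype=float)
    centered = data - data.mean(axis=0)
    index = {c: i for i, c in enumerate(channel_names)}
    total = float((centered ** 2).sum())
    if total == 0:
        raise DecompositionError("data has zero variance")
    out = {}
    for name, members in groups.items():
        cols = [index[c] for c in members]
        if method == "regression":
            sub = centered[:, cols]
            coef, *_ = np.linalg.lstsq(sub, centered, rcond=None)
            resid = centered - sub @ coef
            out[name] = float(100.0 * (1.0 - (resid ** 2).sum() / total))
        elif method == "variance_share":
            out[name] = float(100.0 * (centered[:, cols] ** 2).sum() / total)
        else:
            raise DecompositionError(f"unknown method {method!r}")
    return out


@dataclass
class WeightSeries:
    """Score (weight) time series of the components, with per-column RMS."""

    scores: np.ndarray

    @property
    def rms(self) -> np.ndarray:
        return np.sqrt(np.mean(self.scores ** 2, axis=0))


class SegmentalDecomposition:
    """PCA + VARIMAX model of a time x channels signal matrix.

    Parameters
    ----------
    data : (T, n_channels) array
        Pooled frames of one analysis condition (e.g. all windowed successful
        trials of one participant), segmental orientations or dimensionless
        AM contributions.
    channel_names : tuple of str
        Channel labels; defaults to the 14 canonical segments.
    """

    def __init__(self, data: np.ndarray,
                 channel_names: tuple[str, ...] = SEGMENTS, label: str = ""):
        self.data = np.asarray(data, dtype=float)
        self.channel_names = tuple(channel_names)
        self.label = label

    def fit(self, vaf_threshold: float = 95.0, rotate: bool = True,
            varimax_tol: float = 1e-8, varimax_max_iter: int = 1000
            ) -> "DecompositionResults":
        full = covariance_pca(self.data, self.channel_names, label=self.label)
        retained = retain_components(full, vaf_threshold)
        components = varimax(retained, varimax_tol, varimax_max_iter) if rotate \
            else retained
        return DecompositionResults(
            model=self, full=full, retained=retained, components=components,
            channel_means=self.data.mean(axis=0), vaf_threshold=vaf_threshold)


@dataclass
class DecompositionResults:
    """Fitted loadings, VAF, sparsity and score machinery."""

    model: SegmentalDecomposition
    full: ComponentSet
    retained: ComponentSet
    components: ComponentSet
    channel_means: np.ndarray
    vaf_threshold: float

    @property
    def n_components(self) -> int:
        return self.components.n_components

    def scores(self, data: np.ndarray | None = None,
               center_with_fit_means: bool = True) -> WeightSeries:
        """Least-squares weight time series of the (rotated) components.

        By default new data is centered with the *fit* channel means so that
        score amplitudes stay comparable across trials of one condition.
        """
        data = self.model.data if data is None else np.asarray(data, dtype=float)
        means = self.channel_means if center_with_fit_means else data.mean(axis=0)
        coef, *_ = np.linalg.lstsq(self.components.loadings, (data - means).T,
                                   rcond=None)
        return WeightSeries(scores=coef.T)

    def crossfit(self, data: np.ndarray) -> float:
        """Cross-validated VAF of these components on other data."""
        return crossfit_vaf(self.components, data)

    def summary(self) -> str:
        cs = self.components
        lines = [
            f"Segmental decomposition ({cs.label or 'unlabelled'})",
            f"  frames: {self.model.data.shape[0]}, channels: {len(cs.channel_names)}",
            f"  retained K = {self.n_components} at {self.vaf_threshold:.0f}% VAF"
            f" (rotation: {'VARIMAX' if cs.rotated else 'none'})",
            "",
            "  channel " + " ".join(f"{f'PC{k+1}':>8}" for k in range(cs.n_components)),
        ]
        for name, row in zip(cs.channel_names, cs.loadings):
            lines.append(f"  {name:>7} " + " ".join(f"{v:8.3f}" for v in row))
        lines.append("  VAF %   " + " ".join(f"{v:8.2f}" for v in cs.vaf))
        lines.append("  sparsity" + " ".join(f"{v:8.3f}" for v in cs.sparsity()))
        return "\n".join(lines)

    def plot_loadings(self, ax=None):
        """Bar plot of the rotated loadings per segment (one bar group per PC)."""
        import matplotlib.pyplot as plt

        cs = self.components
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        n_ch, k = cs.loadings.shape
        x = np.arange(n_ch)
        width = 0.8 / max(k, 1)
        for j in range(k):
            ax.bar(x + j * width, cs.loadings[:, j], width,
                   label=f"PC{j + 1} ({cs.vaf[j]:.1f}%)")
        ax.set_xticks(x + 0.4 - width / 2)
        ax.set_xticklabels(cs.channel_names, rotation=45)
        ax.set_ylabel("loading")
        ax.legend(fontsize="small")
        return ax
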