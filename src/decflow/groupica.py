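"""Desk-scale temporal-concatenation group ICA.

Subjects' (time x feature) matrices are concatenated over time, centered,
reduced by a single-level PCA, and unmixed with the infomax algorithm
(natural-gradient ascent with a logistic nonlinearity).  Per-subject
component time courses fall out of the concatenated source matrix via the
stored row slices, and components are selected by a low-frequency power
rule plus optional mask inclusion of the spatial peak.

The rest of the pipeline can bypass this module entirely when component
time courses are supplied directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import kurtosis

from .errors import ParameterError, StateError

__all__ = [
    "Reduction",
    "ICAResult",
    "SelectionRules",
    "reduce_concat",
    "infomax_unmix",
    "back_reconstruct_and_select",
    "load_nifti_timecourses",
]


@dataclass
class Reduction:
    """Centered temporal-concatenation PCA of stacked subject data."""

    scores: np.ndarray  # (total_time, n_pc), variance-ordered, unwhitened
    basis: np.ndarray  # (n_features, n_pc) orthonormal columns
    singular_values: np.ndarray  # (n_pc,)
    column_means: np.ndarray  # (n_features,)
    subject_slices: list[slice]
    explained_variance_ratio: np.ndarray  # (n_pc,)
    n_pc: int

    def scales(self) -> np.ndarray:
        """Per-PC standard deviations used for whitening."""
        n = self.scores.shape[0]
        return self.singular_values / np.sqrt(max(n - 1, 1))


def reduce_concat(subject_data, n_pc: int) -> Reduction:
    """Concatenate subjects over time, center, and project onto top PCs.

    ``subject_data`` is a list of (time x feature) arrays or objects with a
    ``.data`` attribute.  Raises a parameter error when ``n_pc`` exceeds
    the rank of the concatenated, centered matrix.
    """
    mats = [np.asarray(getattr(s, "data", s), dtype=float) for s in subject_data]
    if not mats:
        raise ParameterError("no subject data given")
    widths = {m.shape[1] for m in mats}
    if len(widths) > 1:
        raise ParameterError(f"subjects have inconsistent feature counts: {sorted(widths)}")
    y = np.concatenate(mats, axis=0)
    mu = y.mean(axis=0)
    yc = y - mu
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    tol = s.max() * max(yc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if n_pc < 1 or n_pc > rank:
        raise ParameterError(f"n_pc={n_pc} outside 1..rank ({rank})")
    total_var = float(np.sum(s**2))
    slices = []
    start = 0
    for m in mats:
        slices.append(slice(start, start + m.shape[0]))
        start += m.shape[0]
    return Reduction(
        scores=u[:, :n_pc] * s[:n_pc],
        basis=vt[:n_pc].T,
        singular_values=s[:n_pc],
        column_means=mu,
        subject_slices=slices,
        explained_variance_ratio=s[:n_pc] ** 2 / total_var,
        n_pc=n_pc,
    )


@dataclass
class ICAResult:
    """Fitted infomax decomposition on the reduced space.

    ``unmixing @ mixing`` is the identity on the whitened reduced space.
    ``maps`` are component-by-feature group spatial loadings; ``sources``
    are the group component time courses over the concatenated time axis.
    """

    unmixing: np.ndarray  # (n_ic, n_ic), acts on whitened reduced data
    mixing: np.ndarray  # (n_ic, n_ic) inverse of unmixing
    maps: np.ndarray  # (n_ic, n_features)
    sources: np.ndarray  # (n_ic, total_time)
    reduction: Reduction
    n_pc: int
    n_ic: int
    converged: bool
    n_iter: int
    notes: list[str] = field(default_factory=list)


def _infomax(xw: np.ndarray, lr: float, max_iter: int, tol: float, rng) -> tuple:
    """Natural-gradient infomax on whitened (samples x dims) data."""
    n, d = xw.shape
    q, _ = np.linalg.qr(rng.normal(size=(d, d)))
    w = q
    lrate = lr
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u = xw @ w.T
        y = 1.0 - 2.0 * expit(u)
        grad = (np.eye(d) + y.T @ u / n) @ w
        w_new = w + lrate * grad
        if not np.all(np.isfinite(w_new)) or np.abs(w_new).max() > 1e8:
            lrate *= 0.5  # blow-up guard: retry this step smaller
            continue
        delta = float(np.linalg.norm(w_new - w) / max(np.linalg.norm(w), 1e-12))
        w = w_new
        if delta < tol:
            converged = True
            break
    return w, converged, it


def infomax_unmix(
    reduction: Reduction,
    n_ic: int | None = None,
    learning_rate: float = 0.1,
    max_iter: int = 2000,
    tol: float = 1e-7,
    seed: int = 0,
) -> ICAResult:
    """Unmix the reduced data with infomax ICA.

    The top ``n_ic`` variance-ordered PCs are whitened and rotated by
    natural-gradient ascent of the logistic infomax objective until the
    relative weight change drops below ``tol`` or ``max_iter`` is reached
    (non-convergence yields a warning flag, not an error).  Components are
    ordered by explained variance and sign-fixed so each component's
    largest-magnitude spatial loading is positive.  Gaussian-only inputs
    trigger a non-identifiability note.
    """
    n_pc = reduction.n_pc
    if n_ic is None:
        n_ic = n_pc
    if not 1 <= n_ic <= n_pc:
        raise ParameterError(f"n_ic={n_ic} outside 1..n_pc ({n_pc})")
    notes: list[str] = []
    scales = reduction.scales()[:n_ic]
    xw = reduction.scores[:, :n_ic] / scales

    kurt = kurtosis(xw, axis=0, fisher=True)
    if np.all(np.abs(kurt) < 0.3):
        msg = "inputs look Gaussian; ICA rotation is not identifiable"
        notes.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    rng = np.random.default_rng(seed)
    w, converged, n_iter = _infomax(xw, learning_rate, max_iter, tol, rng)
    if not converged:
        msg = f"infomax did not converge in {max_iter} iterations; partial result returned"
        notes.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    a = np.linalg.inv(w)  # mixing in whitened space
    # component-by-feature maps: whitened PCs -> original feature axes
    back = (a.T * scales[:, None]) @ reduction.basis[:, :n_ic].T  # (n_ic, n_features)
    sources = (xw @ w.T).T  # (n_ic, total_time)

    # order by explained variance (mixing-column energy in original units)
    energy = np.sum(back**2, axis=1)
    order = np.argsort(-energy)
    w, a = w[order], a[:, order]
    back, sources = back[order], sources[order]
    # sign convention: largest-|loading| positive
    signs = np.sign(back[np.arange(n_ic), np.argmax(np.abs(back), axis=1)])
    signs[signs == 0] = 1.0
    w *= signs[:, None]
    a *= signs[None, :]
    back *= signs[:, None]
    sources *= signs[:, None]

    return ICAResult(
        unmixing=w, mixing=a, maps=back, sources=sources, reduction=reduction,
        n_pc=n_pc, n_ic=n_ic, converged=converged, n_iter=n_iter, notes=notes,
    )


@dataclass
class SelectionRules:
    """Component-selection thresholds.

    ``freq_cutoff_hz`` with ``tr`` defines "low frequency"; a component is
    kept when the fraction of its time-course spectral power below the
    cutoff exceeds ``power_threshold`` and (when ``mask`` is given) its
    largest-magnitude spatial loading falls inside the mask.
    """

    freq_cutoff_hz: float = 0.1
    power_threshold: float = 0.5
    tr: float = 2.0
    mask: np.ndarray | None = None  # boolean over features


def low_frequency_fraction(timecourse: np.ndarray, tr: float, cutoff_hz: float) -> float:
    """Fraction of periodogram power at frequencies strictly below the cutoff."""
    x = np.asarray(timecourse, dtype=float)
    x = x - x.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=tr)
    total = power[1:].sum()  # DC removed by centering anyway
    if total == 0:
        return 0.0
    return float(power[1:][freqs[1:] < cutoff_hz].sum() / total)


def back_reconstruct_and_select(
    ica: ICAResult,
    rules: SelectionRules | None = None,
) -> tuple[list[np.ndarray], list[int], dict]:
    """Per-subject component time courses plus rule-based component selection.

    Returns ``(subject_timecourses, selected_indices, report)`` where each
    subject entry is a (time x n_ic) array sliced from the concatenated
    source matrix via the reduction's stored operators.
    """
    if ica.reduction is None or not ica.reduction.subject_slices:
        raise StateError("ICA result carries no reduction operators for back-reconstruction")
    rules = rules or SelectionRules()
    subject_tcs = [ica.sources[:, sl].T.copy() for sl in ica.reduction.subject_slices]

    selected = []
    decisions = []
    for c in range(ica.n_ic):
        lf = low_frequency_fraction(ica.sources[c], rules.tr, rules.freq_cutoff_hz)
        keep = lf > rules.power_threshold
        in_mask = True
        if rules.mask is not None:
            peak = int(np.argmax(np.abs(ica.maps[c])))
            in_mask = bool(np.asarray(rules.mask, dtype=bool)[peak])
            keep = keep and in_mask
        decisions.append({"component": c, "low_freq_fraction": lf,
                         "peak_in_mask": in_mask, "selected": bool(keep)})
        if keep:
            selected.append(c)
    report = {"rules": {"freq_cutoff_hz": rules.freq_cutoff_hz,
                        "power_threshold": rules.power_threshold, "tr": rules.tr,
                        "mask_given": rules.mask is not None},
              "decisions": decisions}
    return subject_tcs, selected, report


def load_nifti_timecourses(image_path, mask_path):
    """Extract a (time x voxel) matrix from a 4-D NIfTI restricted to a mask."""
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise StateError("nibabel is required for NIfTI input") from exc
    img = nib.load(str(image_path))
    mask = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=float)
    m = np.asarray(mask.dataobj) > 0
    if data.ndim != 4:
        raise ParameterError(f"expected a 4-D image, got shape {data.shape}")
    if m.shape != data.shape[:3]:
        raise ParameterError("mask shape does not match image spatial shape")
    return data[m].T  # (time, voxels)
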