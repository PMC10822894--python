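"""Sliding-window MVAR effective-connectivity estimation.

A subject's component time courses are segmented into rectangular sliding
windows; within each window a vector-autoregressive model is fitted by
(optionally ridge-regularized) least squares and converted into a directed
influence matrix, either as signed summed lag coefficients (``mode="coef"``)
or as frequency-averaged partial directed coherence (``mode="pdc"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "WindowSpec",
    "ECMatrix",
    "ECWindowStack",
    "MVARFit",
    "sliding_windows",
    "fit_mvar",
    "influence_matrix",
    "windowed_ec",
    "static_ec",
]


@dataclass(frozen=True)
class WindowSpec:
    """Rectangular sliding-window geometry, in samples (TRs).

    Attributes
    ----------
    width : int
        Window length. Default 18.
    step : int
        Offset between consecutive window starts. Default 2.
    """

    width: int = 18
    step: int = 2

    def __post_init__(self) -> None:
        if self.width < 2:
            raise ParameterError(f"window width must be >= 2, got {self.width}")
        if self.step < 1:
            raise ParameterError(f"window step must be >= 1, got {self.step}")


@dataclass
class ECMatrix:
    """Directed influence matrix for one window (or the whole scan).

    ``values[i, j]`` is the influence of component ``i`` (source) on
    component ``j`` (target).  The diagonal holds self-influence and is
    excluded from degree and clustering computations downstream.
    """

    values: np.ndarray
    component_names: list[str]
    window: int | str = "static"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ParameterError(f"EC matrix must be square, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("EC matrix contains non-finite entries")

    @property
    def n_components(self) -> int:
        return self.values.shape[0]

    def off_diagonal(self) -> np.ndarray:
        """Off-diagonal entries flattened in row-major order."""
        n = self.n_components
        mask = ~np.eye(n, dtype=bool)
        return self.values[mask]


@dataclass
class ECWindowStack:
    """Ordered windowed EC matrices for one subject plus estimation settings."""

    subject_id: str
    matrices: list[ECMatrix]
    spec: WindowSpec
    order: int
    ridge: float
    mode: str
    group: str | None = None
    component_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.matrices and not self.component_names:
            self.component_names = list(self.matrices[0].component_names)
        dims = {m.n_components for m in self.matrices}
        if len(dims) > 1:
            raise ParameterError(f"stack matrices have mixed dimensions: {sorted(dims)}")

    def __len__(self) -> int:
        return len(self.matrices)

    def __iter__(self):
        return iter(self.matrices)

    def __getitem__(self, i):
        return self.matrices[i]

    def as_array(self) -> np.ndarray:
        """Stack values into an ``(n_windows, n, n)`` array."""
        return np.stack([m.values for m in self.matrices])


def sliding_windows(n_timepoints: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Enumerate half-open window intervals ``[t, t + width)``.

    Starts run over ``0, step, 2*step, ...`` subject to the strict
    convention ``t + width < n_timepoints``; a window ending exactly at the
    last sample is discarded.  ``n_timepoints <= width`` yields an empty
    list.

    Examples
    --------
    >>> len(sliding_windows(170, WindowSpec(18, 2)))
    76
    """
    if n_timepoints < 1:
        raise ParameterError(f"n_timepoints must be >= 1, got {n_timepoints}")
    if n_timepoints <= spec.width:
        return []
    return [(t, t + spec.width) for t in range(0, n_timepoints - spec.width, spec.step)]


def window_count(n_timepoints: int, spec: WindowSpec) -> int:
    """Closed form for ``len(sliding_windows(...))``."""
    if n_timepoints <= spec.width:
        return 0
    return (n_timepoints - spec.width - 1) // spec.step + 1


@dataclass
class MVARFit:
    """Least-squares VAR(p) fit.

    ``coefs[l][j, i]`` is the coefficient of source ``i`` at lag ``l + 1``
    in target ``j``'s equation (row = target, column = source).
    """

    coefs: np.ndarray  # (p, d, d)
    resid_cov: np.ndarray  # (d, d)
    order: int
    ridge: float
    n_obs: int
    degenerate: np.ndarray  # (d,) bool mask of constant channels


def fit_mvar(data: np.ndarray, order: int = 1, ridge: float = 0.0) -> MVARFit:
    """Fit a VAR(``order``) model to one window by ridge least squares.

    Columns are centered within the window before fitting.  The ridge
    penalty is scaled by the mean diagonal of the regressor Gram matrix so
    that ``ridge`` is a dimensionless shrinkage factor.  A constant
    (zero-variance) channel has its coefficients forced to zero, with a
    warning.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ParameterError(f"window data must be 2-D (time x component), got ndim={x.ndim}")
    t_len, d = x.shape
    if order < 1:
        raise ParameterError(f"order must be >= 1, got {order}")
    if t_len <= order:
        raise ParameterError(f"window length {t_len} must exceed MVAR order {order}")
    if ridge < 0:
        raise ParameterError(f"ridge must be >= 0, got {ridge}")

    degenerate = np.ptp(x, axis=0) == 0
    if degenerate.any():
        bad = np.flatnonzero(degenerate)
        warnings.warn(
            f"constant channel(s) {bad.tolist()} in window; coefficients set to 0",
            RuntimeWarning,
            stacklevel=2,
        )

    xc = x - x.mean(axis=0)
    y = xc[order:]  # (T - p, d)
    z = np.concatenate([xc[order - lag - 1 : t_len - lag - 1] for lag in range(order)], axis=1)
    # z columns are [lag1 block | lag2 block | ...], each block d wide
    gram = z.T @ z
    lam = ridge * float(np.mean(np.diag(gram))) if ridge > 0 else 0.0
    try:
        b = np.linalg.solve(gram + lam * np.eye(d * order), z.T @ y)
    except np.linalg.LinAlgError:
        b = np.linalg.lstsq(z, y, rcond=None)[0]
    # b: (d*order, d); b[l*d + i, j] = coef of source i lag l+1 in target j
    coefs = np.transpose(b.reshape(order, d, d), (0, 2, 1))  # -> (p, target, source)
    if degenerate.any():
        coefs[:, degenerate, :] = 0.0
        coefs[:, :, degenerate] = 0.0
    resid = y - z @ b
    dof = max(y.shape[0] - d * order, 1)
    resid_cov = resid.T @ resid / dof
    return MVARFit(coefs=coefs, resid_cov=resid_cov, order=order, ridge=ridge,
                   n_obs=y.shape[0], degenerate=degenerate)


def _pdc_matrix(coefs: np.ndarray, n_freq: int = 64) -> np.ndarray:
    """Frequency-averaged partial directed coherence, entries in [0, 1]."""
    p, d, _ = coefs.shape
    freqs = np.linspace(0.0, 0.5, n_freq)
    out = np.zeros((d, d))
    for f in freqs:
        abar = np.eye(d, dtype=complex)
        for lag in range(p):
            abar -= coefs[lag] * np.exp(-2j * np.pi * f * (lag + 1))
        mag = np.abs(abar)
        col_norm = np.sqrt((mag**2).sum(axis=0))
        col_norm[col_norm == 0] = 1.0
        # pdc(source i -> target j) = |abar[j, i]| / ||abar[:, i]||
        out += (mag / col_norm).T
    return out / n_freq


def influence_matrix(
    fit: MVARFit,
    mode: str = "coef",
    component_names: list[str] | None = None,
    window: int | str = "static",
) -> ECMatrix:
    """Convert a fitted MVAR model into a directed influence matrix.

    ``mode="coef"``: entry (i, j) is the signed coefficient of source i in
    target j's equation summed over lags.  ``mode="pdc"``: entry (i, j) is
    the partial-directed-coherence magnitude from i to j averaged over an
    evenly spaced frequency grid; entries lie in [0, 1].
    """
    d = fit.coefs.shape[1]
    if mode == "coef":
        values = fit.coefs.sum(axis=0).T  # (source, target)
    elif mode == "pdc":
        values = _pdc_matrix(fit.coefs)
    else:
        raise ParameterError(f"unknown influence mode {mode!r}; expected 'coef' or 'pdc'")
    names = component_names if component_names is not None else [f"c{i:02d}" for i in range(d)]
    return ECMatrix(values=values, component_names=list(names), window=window)


def windowed_ec(
    subject,
    spec: WindowSpec = WindowSpec(),
    order: int = 1,
    ridge: float = 0.1,
    mode: str = "coef",
) -> ECWindowStack:
    """Estimate one influence matrix per sliding window for a subject.

    Raises
    ------
    ParameterError
        If the subject admits zero windows under ``spec``.
    """
    data = np.asarray(subject.data, dtype=float)
    t_len = data.shape[0]
    intervals = sliding_windows(t_len, spec)
    if not intervals:
        raise ParameterError(
            f"no admissible windows for subject {subject.subject_id}: "
            f"T={t_len}, width={spec.width}, step={spec.step}"
        )
    matrices = []
    for w_idx, (lo, hi) in enumerate(intervals):
        fit = fit_mvar(data[lo:hi], order=order, ridge=ridge)
        matrices.append(
            influence_matrix(fit, mode=mode, component_names=subject.component_names, window=w_idx)
        )
    return ECWindowStack(
        subject_id=subject.subject_id,
        matrices=matrices,
        spec=spec,
        order=order,
        ridge=ridge,
        mode=mode,
        group=getattr(subject, "group", None),
        component_names=list(subject.component_names),
    )


def static_ec(subject, order: int = 1, ridge: float = 0.0, mode: str = "coef") -> ECMatrix:
    """Single MVAR fit over the entire scan ("static" effective connectivity)."""
    data = np.asarray(subject.data, dtype=float)
    fit = fit_mvar(data, order=order, ridge=ridge)
    return influence_matrix(fit, mode=mode, component_names=subject.component_names,
                            window="static")
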