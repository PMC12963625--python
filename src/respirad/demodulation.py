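"""I/Q-to-displacement conversion for CW Doppler radar.

A quadrature receiver observing a target at distance ``d`` produces
``I = cos(phi)``, ``Q = sin(phi)`` with ``phi = 4*pi*d/lambda`` (two-way
path).  Real hardware adds DC offsets, a gain mismatch between the channels
and a quadrature phase error, which turn the ideal unit circle traced by the
I/Q point into a shifted, rotated ellipse.  The chain implemented here is

1. fit an ellipse to the I/Q cloud (direct least-squares conic fit),
2. map the cloud affinely back onto the unit circle,
3. recover the wrapped phase with the four-quadrant arctangent,
4. unwrap, and
5. scale phase to displacement: ``x = phi/(2*pi) * lambda/2``.

Because the circle-restoring affine map is orientation-preserving, the
corrected phase equals the true propagation phase up to an additive
constant, so displacement is recovered up to an arbitrary offset.

The transformers follow scikit-learn conventions and compose with
:class:`sklearn.pipeline.Pipeline`; the module-level functions are thin
wrappers for one-off use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import c as SPEED_OF_LIGHT
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "EllipseFitError",
    "EllipseParams",
    "EllipseCorrector",
    "ArctangentDemodulator",
    "PhaseToDisplacement",
    "fit_ellipse",
    "correct_iq",
    "demodulate",
    "unwrap_phase",
    "phase_to_displacement",
    "DEFAULT_WAVELENGTH_MM",
]

DEFAULT_WAVELENGTH_MM = SPEED_OF_LIGHT / 24e9 * 1e3  # 12.491 mm at 24 GHz


class EllipseFitError(ValueError):
    """The I/Q cloud does not constrain an ellipse (degenerate or tiny arc)."""


@dataclass(frozen=True)
class EllipseParams:
    """Geometric ellipse: center (DC offsets), semi-axes, rotation."""

    center_i: float
    center_q: float
    semi_axis_i: float
    semi_axis_q: float
    rotation_rad: float

    def __post_init__(self) -> None:
        if not (self.semi_axis_i > 0 and self.semi_axis_q > 0):
            raise ValueError("semi-axes must be positive")

    def to_circle_affine(self) -> tuple[np.ndarray, np.ndarray]:
        """Offset and matrix of the map sending this ellipse to the unit circle.

        The matrix has positive determinant (rotate by -rotation, then scale
        each principal axis to 1), so the map preserves the direction of
        travel around the curve and hence the sign of the demodulated phase.
        """
        ct, st = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        rot = np.array([[ct, st], [-st, ct]])
        scale = np.diag([1.0 / self.semi_axis_i, 1.0 / self.semi_axis_q])
        return np.array([self.center_i, self.center_q]), scale @ rot


def _fit_conic(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Numerically stable direct least-squares ellipse fit (Halir & Flusser).

    Returns conic coefficients (a, b, c, d, e, f) of
    a*x^2 + b*x*y + c*y^2 + d*x + e*y + f = 0 with the ellipse constraint
    b^2 - 4ac < 0 built in.
    """
    # center/scale for conditioning
    mx, my = x.mean(), y.mean()
    s = max(np.abs(x - mx).max(), np.abs(y - my).max())
    if s == 0:
        raise EllipseFitError("all I/Q samples identical")
    xs, ys = (x - mx) / s, (y - my) / s

    d1 = np.column_stack([xs**2, xs * ys, ys**2])
    d2 = np.column_stack([xs, ys, np.ones_like(xs)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise EllipseFitError("degenerate I/Q cloud (collinear samples)") from exc
    m = s1 + s2 @ t
    # premultiply by inv(C1) with C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    w, v = np.linalg.eig(m)
    cond = 4 * v[0] * v[2] - v[1] ** 2
    ok = np.where(cond > 0)[0]
    if ok.size == 0:
        raise EllipseFitError("no ellipse solution (arc too small or degenerate)")
    a1 = np.real(v[:, ok[0]])
    coeffs_s = np.concatenate([a1, t @ a1])  # in scaled frame

    # undo the scaling: substitute xs = (x-mx)/s etc.
    a, b, c, d, e, f = coeffs_s
    A = a / s**2
    B = b / s**2
    C = c / s**2
    D = d / s - (2 * a * mx + b * my) / s**2
    E = e / s - (2 * c * my + b * mx) / s**2
    F = (
        f
        + (a * mx**2 + b * mx * my + c * my**2) / s**2
        - (d * mx + e * my) / s
    )
    return np.array([A, B, C, D, E, F])


def _conic_to_geometric(coeffs: np.ndarray) -> EllipseParams:
    a, b, c, d, e, f = coeffs
    disc = b**2 - 4 * a * c
    if disc >= 0:
        raise EllipseFitError("fitted conic is not an ellipse")
    cx = (2 * c * d - b * e) / disc
    cy = (2 * a * e - b * d) / disc
    # evaluate conic at center to get the scaling constant
    fc = a * cx**2 + b * cx * cy + c * cy**2 + d * cx + e * cy + f
    m = np.array([[a, b / 2], [b / 2, c]])
    w, v = np.linalg.eigh(m)
    if np.any(w * -fc <= 0):
        raise EllipseFitError("degenerate ellipse (zero-length axis)")
    axes = np.sqrt(-fc / w)  # semi-axes along the eigenvectors
    if axes.max() / axes.min() > 1e4:
        raise EllipseFitError(
            "degenerate ellipse (near-collinear I/Q cloud: axis ratio "
            f"{axes.max() / axes.min():.1e})"
        )
    theta = np.arctan2(v[1, 0], v[0, 0])
    return EllipseParams(
        center_i=float(cx),
        center_q=float(cy),
        semi_axis_i=float(axes[0]),
        semi_axis_q=float(axes[1]),
        rotation_rad=float(theta),
    )


def _arc_span_deg(x: np.ndarray, y: np.ndarray, params: EllipseParams) -> float:
    """Angular coverage of the cloud around the fitted center (degrees)."""
    ang = np.arctan2(y - params.center_q, x - params.center_i)
    ang = np.sort(ang)
    gaps = np.diff(np.concatenate([ang, ang[:1] + 2 * np.pi]))
    return float(np.degrees(2 * np.pi - gaps.max()))


class EllipseCorrector(BaseEstimator, TransformerMixin):
    """Fit the hardware ellipse on an I/Q cloud and map it onto the unit circle.

    Parameters
    ----------
    min_arc_deg : float
        Minimum angular coverage of the cloud around the fitted center.
        Fits on narrower arcs are poorly constrained and raise
        :class:`EllipseFitError` instead of returning a silently bad fit.

    Attributes
    ----------
    ellipse_ : EllipseParams
        Fitted center (DC offsets), semi-axes and rotation.
    arc_span_deg_ : float
        Angular coverage of the training cloud.
    """

    def __init__(self, min_arc_deg: float = 90.0):
        self.min_arc_deg = min_arc_deg

    def fit(self, X, y=None):
        X = self._validate(X)
        if X.shape[0] < 6:
            raise EllipseFitError("need at least 6 samples to fit an ellipse")
        coeffs = _fit_conic(X[:, 0], X[:, 1])
        self.ellipse_ = _conic_to_geometric(coeffs)
        self.arc_span_deg_ = _arc_span_deg(X[:, 0], X[:, 1], self.ellipse_)
        if self.arc_span_deg_ < self.min_arc_deg:
            raise EllipseFitError(
                f"I/Q arc spans only {self.arc_span_deg_:.1f} deg "
                f"(< {self.min_arc_deg} deg); fit unreliable"
            )
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "ellipse_")
        X = self._validate(X)
        offset, mat = self.ellipse_.to_circle_affine()
        return (X - offset) @ mat.T

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("expected an (n_samples, 2) I/Q array")
        if not np.all(np.isfinite(X)):
            raise ValueError("I/Q samples must be finite")
        return X


class ArctangentDemodulator(BaseEstimator, TransformerMixin):
    """Four-quadrant arctangent phase recovery with optional unwrapping.

    Stateless; ``transform`` maps an (n, 2) corrected I/Q array to a 1-D
    phase trace in radians.
    """

    def __init__(self, unwrap: bool = True):
        self.unwrap = unwrap

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("expected an (n_samples, 2) I/Q array")
        i, q = X[:, 0], X[:, 1]
        if np.any((i == 0) & (q == 0)):
            raise ValueError("phase undefined at samples with I = Q = 0")
        phase = np.arctan2(q, i)
        return unwrap_phase(phase) if self.unwrap else phase


class PhaseToDisplacement(BaseEstimator, TransformerMixin):
    """Scale unwrapped phase to displacement: x = phi/(2*pi) * lambda/2."""

    def __init__(self, wavelength_mm: float = DEFAULT_WAVELENGTH_MM, sign: float = 1.0):
        self.wavelength_mm = wavelength_mm
        self.sign = sign

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        if self.wavelength_mm <= 0:
            raise ValueError("wavelength must be positive")
        phase = np.asarray(X, float)
        return self.sign * phase / (2 * np.pi) * (self.wavelength_mm / 2.0)


# ---------------------------------------------------------------- functions

def fit_ellipse(i, q, min_arc_deg: float = 90.0) -> EllipseParams:
    """Least-squares ellipse through the I/Q point cloud."""
    est = EllipseCorrector(min_arc_deg=min_arc_deg)
    est.fit(np.column_stack([i, q]))
    return est.ellipse_


def correct_iq(i, q, ellipse: EllipseParams) -> tuple[np.ndarray, np.ndarray]:
    """Map the I/Q cloud onto the unit circle using a fitted ellipse."""
    offset, mat = ellipse.to_circle_affine()
    out = (np.column_stack([i, q]) - offset) @ mat.T
    return out[:, 0], out[:, 1]


def demodulate(i, q) -> np.ndarray:
    """Wrapped phase in (-pi, pi] via the four-quadrant arctangent."""
    return ArctangentDemodulator(unwrap=False).transform(np.column_stack([i, q]))


def unwrap_phase(phase: np.ndarray) -> np.ndarray:
    """Remove artificial 2*pi jumps; first sample unchanged (idempotent)."""
    return np.unwrap(np.asarray(phase, float))


def phase_to_displacement(
    phase: np.ndarray, wavelength_mm: float = DEFAULT_WAVELENGTH_MM
) -> np.ndarray:
    """Displacement in mm from unwrapped phase."""
    return PhaseToDisplacement(wavelength_mm=wavelength_mm).transform(phase)
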