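"""Second-order-difference-plot (SODP) construction and the ClassA metrics.

The Classification Angle (ClassA) family of metrics characterises cardiac
dynamics from the scatter of successive rates of change of the HRV signal.
The rate of change is estimated with the three-point forward difference

    d(n) = (4 x(n+1) - 3 x(n) - x(n+2)) / 2        (1-based n = 1 .. N-2)

and the SODP is the scatter of (d(n), d(n+1)), n = 1 .. N-3.  Each point is
assigned the anti-clockwise angle alpha_n it makes with the positive
abscissa, in [0, 360) degrees, and a quadrant label by the strict signs of
its coordinates.  Four metrics follow:

* RAS   -- mean angle sum: sum of alpha_n over non-origin points divided by
           the window sample count N (angles in Q1 are acute -> an overall
           RAS in (0, 90) flags a predominantly increasing sequence; RAS in
           (180, 270) a predominantly decreasing one),
* PQ1   -- proportion of points in quadrant 1 (cardiac deceleration,
           parasympathetic dominance), at the original temporal scale,
* PQ2,4 -- proportion in quadrants 2 and 4 together (balanced HRV),
* PQ3   -- proportion in quadrant 3 (cardiac acceleration, sympathetic
           dominance), computed from the *coarse-grained* signal so that it
           reflects slower dynamics.

Points with a zero coordinate lie on an axis and belong to no quadrant; a
point at the exact origin additionally contributes no angle.  The default
denominator for RAS and the proportions is the window sample count N (the
published convention); ``denominator="points"`` switches to the number of
SODP points, N - 3.

Batch variants operate on a (n_windows, n_samples) matrix and are the fast
path used by the pipeline; they are exactly the same arithmetic, vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import UniformHRV, coarse_grain

__all__ = [
    "DifferenceSeries",
    "SODP",
    "ClassAResult",
    "three_point_forward_diff",
    "build_sodp",
    "real_angle_sum",
    "quadrant_proportions",
    "classa_window",
    "diff_batch",
    "classa_batch",
    "q3_proportion_batch",
]

QUADRANT_LABELS = ("Q1", "Q2", "Q3", "Q4", "BOUNDARY")


@dataclass
class DifferenceSeries:
    """Three-point forward derivative estimates of one window."""

    d: np.ndarray
    n_source: int  # N of the originating window

    def __len__(self) -> int:
        return self.d.size


@dataclass
class SODP:
    """The second-order-difference-plot of one window.

    ``points`` has shape (N - 3, 2) holding (d(n), d(n+1)); ``angles`` the
    per-point anti-clockwise angle with the abscissa in degrees [0, 360)
    (0 for origin points, which are excluded from sums via ``nonorigin``);
    ``quadrants`` the per-point label among Q1..Q4 and BOUNDARY.
    """

    points: np.ndarray
    angles: np.ndarray
    quadrants: np.ndarray
    nonorigin: np.ndarray
    n_source: int

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def is_degenerate(self) -> bool:
        """True when every point sits at the origin (e.g. constant input)."""
        return not bool(self.nonorigin.any())

    def quadrant_count(self, label: str) -> int:
        return int(np.count_nonzero(self.quadrants == label))

    def to_records(self) -> np.ndarray:
        """Structured array (abscissa, ordinate, angle_deg, quadrant) for
        CSV export / scatter plotting."""
        rec = np.zeros(
            len(self),
            dtype=[
                ("abscissa", float),
                ("ordinate", float),
                ("angle_deg", float),
                ("quadrant", "U8"),
            ],
        )
        rec["abscissa"] = self.points[:, 0]
        rec["ordinate"] = self.points[:, 1]
        rec["angle_deg"] = self.angles
        rec["quadrant"] = self.quadrants
        return rec


@dataclass
class ClassAResult:
    """The four ClassA metrics for one analysis window pair."""

    ras: float
    pq1: float
    pq24: float
    pq3: float
    window_start: float
    n_scale1: int
    n_scale_tau: int
    degenerate: bool = False


def three_point_forward_diff(x: UniformHRV | np.ndarray) -> DifferenceSeries:
    """Three-point forward difference d(n) = (4x(n+1) - 3x(n) - x(n+2))/2.

    Exact for linear sequences (a linear x(n) = a*n + b gives d == a
    everywhere).  Requires at least 4 samples so that the SODP downstream
    has at least one point.
    """
    v = x.values if isinstance(x, UniformHRV) else np.asarray(x, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 samples for a difference series")
    # algebraically (4x(n+1) - 3x(n) - x(n+2))/2, arranged as differences so
    # constant input yields exact zeros
    d = (3.0 * (v[1:-1] - v[:-2]) + (v[1:-1] - v[2:])) / 2.0
    return DifferenceSeries(d=d, n_source=v.size)


def _angles_deg(px: np.ndarray, py: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Anti-clockwise angle with the positive abscissa in [0, 360).

    atan2 returns exact axis angles (0, 90, 180, -90) for exact-zero
    coordinates, so points on an axis keep their exact angle; origin points
    get angle 0 and are masked out via the returned ``nonorigin`` array.
    """
    nonorigin = (px != 0.0) | (py != 0.0)
    ang = np.degrees(np.arctan2(py, px))
    ang = np.where(ang < 0.0, ang + 360.0, ang)
    ang = np.where(nonorigin, ang, 0.0)
    return ang, nonorigin


def build_sodp(x: UniformHRV | np.ndarray) -> SODP:
    """Construct the SODP of a window: points, angles and quadrant labels."""
    ds = three_point_forward_diff(x)
    d = ds.d
    px, py = d[:-1], d[1:]
    ang, nonorigin = _angles_deg(px, py)
    quad = np.full(px.shape, "BOUNDARY", dtype="U8")
    quad[(px > 0) & (py > 0)] = "Q1"
    quad[(px < 0) & (py > 0)] = "Q2"
    quad[(px < 0) & (py < 0)] = "Q3"
    quad[(px > 0) & (py < 0)] = "Q4"
    return SODP(
        points=np.column_stack([px, py]),
        angles=ang,
        quadrants=quad,
        nonorigin=nonorigin,
        n_source=ds.n_source,
    )


def _denominator(s: SODP, denominator: str) -> int:
    if denominator == "samples":
        return s.n_source
    if denominator == "points":
        return len(s)
    raise ValueError(f"unknown denominator convention {denominator!r}")


def real_angle_sum(s: SODP, denominator: str = "samples") -> float:
    """RAS: the summed anti-clockwise angles divided by the denominator.

    Origin points contribute no angle; axis points contribute their exact
    axis angle.  A fully degenerate SODP (constant input) returns 0; check
    ``s.is_degenerate`` to distinguish it from a genuine zero.
    """
    if len(s) == 0:
        raise ValueError("empty SODP")
    return float(np.sum(s.angles[s.nonorigin])) / _denominator(s, denominator)


def quadrant_proportions(
    s: SODP, denominator: str = "samples"
) -> tuple[float, float, float]:
    """(PQ1, PQ2,4, local Q3 proportion) of one SODP.

    Boundary (axis/origin) points count toward no quadrant.  The third
    element is the quadrant-3 proportion *of this SODP*; the published PQ3
    applies it to the coarse-grained signal (see :func:`classa_window`).
    """
    if len(s) == 0:
        raise ValueError("empty SODP")
    denom = _denominator(s, denominator)
    return (
        s.quadrant_count("Q1") / denom,
        (s.quadrant_count("Q2") + s.quadrant_count("Q4")) / denom,
        s.quadrant_count("Q3") / denom,
    )


def classa_window(
    x_scale1: UniformHRV,
    x_for_pq3: UniformHRV,
    tau: int = 7,
    denominator: str = "samples",
) -> ClassAResult:
    """Compute the four ClassA metrics for one window pair.

    ``x_scale1`` is the short window analysed at the original temporal scale
    (RAS, PQ1, PQ2,4); ``x_for_pq3`` is the longer window that is
    coarse-grained by ``tau`` before its quadrant-3 proportion is taken
    (PQ3).  At the published settings (10-s and 60-s windows of a 4-Hz
    signal, tau = 7) the two SODPs are built from 40 and 34 samples.  The
    PQ3 denominator is the coarse-grained length.
    """
    s1 = build_sodp(x_scale1)
    xc = coarse_grain(x_for_pq3, tau)
    if len(xc) < 4:
        raise ValueError("coarse-grained window shorter than 4 samples")
    s_tau = build_sodp(xc)
    pq1, pq24, _ = quadrant_proportions(s1, denominator)
    _, _, pq3 = quadrant_proportions(s_tau, denominator)
    return ClassAResult(
        ras=real_angle_sum(s1, denominator),
        pq1=pq1,
        pq24=pq24,
        pq3=pq3,
        window_start=x_scale1.start_time,
        n_scale1=s1.n_source,
        n_scale_tau=s_tau.n_source,
        degenerate=s1.is_degenerate and s_tau.is_degenerate,
    )


# ---------------------------------------------------------------------------
# batch (vectorised) path -- identical arithmetic on a window matrix

def diff_batch(W: np.ndarray) -> np.ndarray:
    """Row-wise three-point forward differences of a window matrix."""
    W = np.asarray(W, dtype=float)
    return (3.0 * (W[:, 1:-1] - W[:, :-2]) + (W[:, 1:-1] - W[:, 2:])) / 2.0


def classa_batch(
    W: np.ndarray, denominator: str = "samples"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(RAS, PQ1, PQ2,4, local Q3 proportion) for every row of ``W``."""
    D = diff_batch(W)
    px, py = D[:, :-1], D[:, 1:]
    ang, nonorigin = _angles_deg(px, py)
    if denominator == "samples":
        denom = W.shape[1]
    elif denominator == "points":
        denom = px.shape[1]
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    ras = np.sum(ang * nonorigin, axis=1) / denom
    pq1 = np.count_nonzero((px > 0) & (py > 0), axis=1) / denom
    pq24 = (
        np.count_nonzero((px < 0) & (py > 0), axis=1)
        + np.count_nonzero((px > 0) & (py < 0), axis=1)
    ) / denom
    q3 = np.count_nonzero((px < 0) & (py < 0), axis=1) / denom
    return ras, pq1, pq24, q3


def q3_proportion_batch(
    W: np.ndarray, tau: int, denominator: str = "samples"
) -> np.ndarray:
    """PQ3 for every row: coarse-grain each row by ``tau``, then take the
    quadrant-3 proportion of its SODP (denominator = coarse length)."""
    W = np.asarray(W, dtype=float)
    nb = W.shape[1] // tau
    if nb < 4:
        raise ValueError("coarse-grained window shorter than 4 samples")
    Wc = W[:, : nb * tau].reshape(W.shape[0], nb, tau).mean(axis=2)
    _, _, _, q3 = classa_batch(Wc, denominator)
    return q3
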