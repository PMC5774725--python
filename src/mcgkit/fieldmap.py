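"""Magnetic field maps and the 10 ventricular-depolarization predictors.

From an R-centered averaged beat the extractor locates the Q and S
fiducials, interpolates the channel values at the QR- and RS-section peak
instants onto a regular planar grid (the magnetic field map, MFM), finds
the positive and negative field poles, and reduces each map to four
numbers — map angle, pole distance, maximum magnetic field ratio (MMR)
and positive peak field — which together with the two fiducial intervals
form the 10-predictor vector:

    QR_MMR, QR_angle, QR_interval, QR_pd, QR_peak,
    RS_MMR, RS_angle, RS_interval, RS_pd, RS_peak

Conventions (they fix the sign of the angles): the map is in cm over the
sensor plane, x from the subject's right to left, y from feet to head;
the MFM angle is the direction of the line from the negative to the
positive pole, counterclockwise from +x, in (-180, 180]; MMR = B+/|B-|;
the peak is the positive-pole field in pT; intervals are in ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator

from .recording import AveragedBeat


class DegenerateMapError(ValueError):
    """Raised when a field map lacks the two-pole structure."""


@dataclass(frozen=True)
class FiducialTimes:
    """Q, R and S fiducials in ms relative to the R peak (tQ < 0 < tS)."""

    tq_ms: float
    ts_ms: float
    tr_ms: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tq_ms < self.tr_ms < self.ts_ms):
            raise ValueError("fiducials must satisfy tQ < tR < tS")

    @property
    def qr_interval_ms(self) -> float:
        return self.tr_ms - self.tq_ms

    @property
    def rs_interval_ms(self) -> float:
        return self.ts_ms - self.tr_ms


@dataclass
class FieldMap:
    """Interpolated normal field on a regular grid at one beat instant."""

    x_cm: np.ndarray  # (nx,)
    y_cm: np.ndarray  # (ny,)
    values_pt: np.ndarray  # (ny, nx)
    t_ms: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values_pt)):
            raise ValueError("field map contains non-finite values")

    @property
    def step_cm(self) -> float:
        return float(self.x_cm[1] - self.x_cm[0])


@dataclass(frozen=True)
class PoleEstimate:
    """Sub-grid locations and values of the two field extrema."""

    positive_xy_cm: tuple[float, float]
    positive_pt: float
    negative_xy_cm: tuple[float, float]
    negative_pt: float


@dataclass(frozen=True)
class PredictorVector:
    """The 10 named MCG predictors for one subject."""

    QR_MMR: float
    QR_angle: float
    QR_interval: float
    QR_pd: float
    QR_peak: float
    RS_MMR: float
    RS_angle: float
    RS_interval: float
    RS_pd: float
    RS_peak: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in (
            "QR_MMR", "QR_angle", "QR_interval", "QR_pd", "QR_peak",
            "RS_MMR", "RS_angle", "RS_interval", "RS_pd", "RS_peak",
        )}


# ---------------------------------------------------------------------------
# fiducials

def locate_fiducials(
    beat: AveragedBeat,
    q_window_ms: tuple[float, float] = (-80.0, -10.0),
    s_window_ms: tuple[float, float] = (10.0, 80.0),
) -> FiducialTimes:
    """Find Q and S as opposite-polarity extrema around the R peak.

    On the maximal channel, Q is the extremum of polarity opposite to R
    inside ``q_window_ms`` and S likewise inside ``s_window_ms``.  A window
    containing no genuine opposite-polarity deflection raises ValueError.
    """
    ch = int(np.argmax(np.abs(beat.channels[:, beat.r_index])))
    trace = beat.channels[ch]
    r_sign = np.sign(trace[beat.r_index])
    if r_sign == 0:
        raise ValueError("R amplitude is zero on the maximal channel")

    def _opposite_extremum(window: tuple[float, float], label: str) -> float:
        mask = (beat.time_ms >= window[0]) & (beat.time_ms <= window[1])
        if not mask.any():
            raise ValueError(f"{label} search window is empty")
        seg = trace[mask] * r_sign  # R polarity normalized to +
        idx = int(np.argmin(seg))
        if seg[idx] >= 0:
            raise ValueError(f"no {label} deflection of opposite polarity found")
        return float(beat.time_ms[mask][idx])

    tq = _opposite_extremum(q_window_ms, "Q")
    ts = _opposite_extremum(s_window_ms, "S")
    return FiducialTimes(tq_ms=tq, ts_ms=ts)


# ---------------------------------------------------------------------------
# map construction

def build_field_map(
    beat: AveragedBeat,
    t_ms: float,
    grid_step_cm: float = 0.25,
    method: str = "thin_plate_spline",
) -> FieldMap:
    """Interpolate the channel values at instant ``t_ms`` onto a grid.

    The interpolant (thin-plate spline by default; any scipy RBF kernel
    name is accepted) reproduces the channel values exactly at the sensor
    locations.  The grid covers the sensors' bounding box at
    ``grid_step_cm`` resolution.
    """
    if beat.geometry.n_channels < 4:
        raise ValueError("field-map interpolation needs at least 4 channels")
    if not (beat.time_ms[0] <= t_ms <= beat.time_ms[-1]):
        raise ValueError(f"instant {t_ms} ms outside the beat window")
    values = beat.channels[:, beat.index_at(t_ms)]
    xy_cm = beat.geometry.xy * 100.0
    itp = RBFInterpolator(xy_cm, values, kernel=method)
    x = np.arange(xy_cm[:, 0].min(), xy_cm[:, 0].max() + grid_step_cm / 2, grid_step_cm)
    y = np.arange(xy_cm[:, 1].min(), xy_cm[:, 1].max() + grid_step_cm / 2, grid_step_cm)
    gx, gy = np.meshgrid(x, y)
    z = itp(np.column_stack([gx.ravel(), gy.ravel()])).reshape(gy.shape)
    return FieldMap(x_cm=x, y_cm=y, values_pt=z, t_ms=float(t_ms))


# ---------------------------------------------------------------------------
# pole finding

def _refine_quadratic(z: np.ndarray, i: int, j: int, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sub-grid extremum via a quadratic fit on the 3x3 neighborhood."""
    x0, y0 = float(x[j]), float(y[i])
    if not (0 < i < z.shape[0] - 1 and 0 < j < z.shape[1] - 1):
        return x0, y0
    n = z[i - 1 : i + 2, j - 1 : j + 2]
    dx = (n[1, 2] - n[1, 0]) / 2.0
    dy = (n[2, 1] - n[0, 1]) / 2.0
    dxx = n[1, 2] - 2 * n[1, 1] + n[1, 0]
    dyy = n[2, 1] - 2 * n[1, 1] + n[0, 1]
    dxy = (n[2, 2] - n[2, 0] - n[0, 2] + n[0, 0]) / 4.0
    hess = np.array([[dxx, dxy], [dxy, dyy]])
    try:
        shift = np.linalg.solve(hess, -np.array([dx, dy]))
    except np.linalg.LinAlgError:
        return x0, y0
    if np.all(np.abs(shift) <= 1.0):  # stay within one cell of the grid argmax
        step_x = float(x[1] - x[0])
        step_y = float(y[1] - y[0])
        return x0 + shift[0] * step_x, y0 + shift[1] * step_y
    return x0, y0


def find_poles(field_map: FieldMap) -> PoleEstimate:
    """Locate the positive and negative field extrema of a map.

    Grid argmax/argmin refined to sub-grid accuracy by a local quadratic
    fit.  A single-signed map has no dipolar structure and raises
    :class:`DegenerateMapError`.
    """
    z = field_map.values_pt
    if z.max() <= 0 or z.min() >= 0:
        raise DegenerateMapError("field map is single-signed; no dipolar pole pair")
    ip, jp = np.unravel_index(int(np.argmax(z)), z.shape)
    im, jm = np.unravel_index(int(np.argmin(z)), z.shape)
    pos_xy = _refine_quadratic(z, ip, jp, field_map.x_cm, field_map.y_cm)
    neg_xy = _refine_quadratic(z, im, jm, field_map.x_cm, field_map.y_cm)
    return PoleEstimate(
        positive_xy_cm=pos_xy,
        positive_pt=float(z[ip, jp]),
        negative_xy_cm=neg_xy,
        negative_pt=float(z[im, jm]),
    )


def map_features(poles: PoleEstimate) -> tuple[float, float, float, float]:
    """(angle_deg, pole_distance_cm, mmr, peak_pt) of one pole estimate.

    The angle is that of the vector from the negative to the positive pole,
    counterclockwise from +x, in (-180, 180].
    """
    dx = poles.positive_xy_cm[0] - poles.negative_xy_cm[0]
    dy = poles.positive_xy_cm[1] - poles.negative_xy_cm[1]
    distance = float(np.hypot(dx, dy))
    if distance < 1e-9:
        raise DegenerateMapError("coincident poles: map angle undefined")
    angle = float(np.degrees(np.arctan2(dy, dx)))
    if angle <= -180.0:
        angle += 360.0
    mmr = float(poles.positive_pt / abs(poles.negative_pt))
    return angle, distance, mmr, float(poles.positive_pt)


# ---------------------------------------------------------------------------
# section instants and the full predictor vector

def aggregate_magnitude(beat: AveragedBeat) -> np.ndarray:
    """RMS field across channels at every sample (the map 'strength')."""
    return np.sqrt(np.mean(beat.channels**2, axis=0))


def section_peak_instants(
    beat: AveragedBeat, fiducials: FiducialTimes, guard_ms: float = 10.0
) -> tuple[float, float]:
    """Instants of maximal aggregate field inside the QR and RS sections.

    The R apex belongs to both sections, so a guard of ``guard_ms`` around
    t = 0 is excluded; the QR instant is the aggregate-magnitude argmax
    over [tQ, -guard] and the RS instant over [+guard, tS].  This keeps the
    two map instants distinct, on the section's own side of the R apex.
    """
    if guard_ms >= min(fiducials.qr_interval_ms, fiducials.rs_interval_ms):
        raise ValueError("guard must be shorter than both sections")
    agg = aggregate_magnitude(beat)
    qr_mask = (beat.time_ms >= fiducials.tq_ms) & (beat.time_ms <= -guard_ms)
    rs_mask = (beat.time_ms >= guard_ms) & (beat.time_ms <= fiducials.ts_ms)
    if not qr_mask.any() or not rs_mask.any():
        raise ValueError("section windows contain no samples")
    t_qr = float(beat.time_ms[qr_mask][np.argmax(agg[qr_mask])])
    t_rs = float(beat.time_ms[rs_mask][np.argmax(agg[rs_mask])])
    return t_qr, t_rs


def extract_predictors(
    beat: AveragedBeat,
    grid_step_cm: float = 0.25,
    guard_ms: float = 10.0,
    method: str = "thin_plate_spline",
    return_details: bool = False,
):
    """Compute the 10-predictor vector from an averaged beat.

    Field maps are built at the QR- and RS-section peak instants; each
    yields (MMR, angle, pole distance, peak); the fiducials yield the two
    intervals.  With ``return_details=True`` also returns a dict holding
    the fiducials, section instants, maps and pole estimates.
    """
    fid = locate_fiducials(beat)
    t_qr, t_rs = section_peak_instants(beat, fid, guard_ms=guard_ms)
    qr_map = build_field_map(beat, t_qr, grid_step_cm=grid_step_cm, method=method)
    rs_map = build_field_map(beat, t_rs, grid_step_cm=grid_step_cm, method=method)
    qr_poles = find_poles(qr_map)
    rs_poles = find_poles(rs_map)
    qr_angle, qr_pd, qr_mmr, qr_peak = map_features(qr_poles)
    rs_angle, rs_pd, rs_mmr, rs_peak = map_features(rs_poles)
    vector = PredictorVector(
        QR_MMR=qr_mmr,
        QR_angle=qr_angle,
        QR_interval=fid.qr_interval_ms,
        QR_pd=qr_pd,
        QR_peak=qr_peak,
        RS_MMR=rs_mmr,
        RS_angle=rs_angle,
        RS_interval=fid.rs_interval_ms,
        RS_pd=rs_pd,
        RS_peak=rs_peak,
    )
    if return_details:
        return vector, {
            "fiducials": fid,
            "qr_instant_ms": t_qr,
            "rs_instant_ms": t_rs,
            "qr_map": qr_map,
            "rs_map": rs_map,
            "qr_poles": qr_poles,
            "rs_poles": rs_poles,
        }
    return vector
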