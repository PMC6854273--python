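"""Early-vision filter cascade: from receptor luminance to the eight
per-column signals, their normalization, and correlation products.

Per visual processing unit (column) the cascade is:

1. Adaptive photoreceptor (Lipetz / Naka-Rushton): ``U = I**l / (I**l +
   I0**l)`` with exponent ``l = 0.7`` and adaptive state ``I0`` low-pass
   filtering the luminance with time constant 750 ms.
2. First-order temporal high-pass (200 ms) of ``U``, half-wave rectified
   into positive-going ON and OFF channel signals.
3. Per channel, a *sustained* path: a "relaxed" high-pass (50 ms) that
   passes 40% DC, rectified; and a *transient* path: the Rectifying
   Transient Cell model - 40 ms high-pass, rectification, and a fast
   depolarization (2 ms) / slow repolarization (100 ms) adaptive state
   subtracted and rectified, which turns any sustained drive into a brief
   pulse at its onset.
4. A delay operator (phase delay of a 50 ms first-order low-pass, unit DC
   gain) applied to each of the four signals, doubling them to eight.

All filters are integrated by forward Euler at ``dt`` = 200 us (one tenth
of the fastest time constant) and the outputs are averaged over 10 ms
windows after a burn-in period.  Signal amplitudes are normalized so the
standard deviation of each signal type during positive excursions is unity
over a calibration corpus; delayed and undelayed variants share one gain
(the delay filter has unit DC gain, so scaling commutes with it).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "SIGNAL_NAMES",
    "UNDELAYED",
    "DELAYED",
    "Cascade",
    "run_column",
    "calibrate_gains",
    "apply_gains",
    "raw_feature_names",
    "make_products",
    "product_terms",
    "column_names",
    "photoreceptor_response",
    "on_off_split",
    "sustained_path",
    "transient_path",
    "delay_op",
]

# time constants [s] and the Lipetz exponent
LIPETZ_EXPONENT = 0.7
TAU_U = 0.750  # photo-adaptation
TAU_R = 0.200  # ON/OFF high-pass
TAU_S = 0.050  # relaxed (sustained) high-pass; passes 40% DC
TAU_A = 0.040  # transient high-pass
TAU_AD = 0.002  # adaptive state, fast depolarization
TAU_AR = 0.100  # adaptive state, slow repolarization
TAU_D = 0.050  # delay low-pass
SUSTAINED_DC = 0.4

#: canonical per-column signal order
SIGNAL_NAMES = (
    "SUS_ON_U",
    "SUS_ON_D",
    "SUS_OFF_U",
    "SUS_OFF_D",
    "TRN_ON_U",
    "TRN_ON_D",
    "TRN_OFF_U",
    "TRN_OFF_D",
)
UNDELAYED = (0, 2, 4, 6)
DELAYED = (1, 3, 5, 7)
#: index of the undelayed signal sharing each signal's normalization gain
GAIN_SOURCE = (0, 0, 2, 2, 4, 4, 6, 6)

DEFAULT_WINDOW = 0.010  # averaging window [s]
DEFAULT_BURN_IN = 2.0  # discarded settling period [s]


@njit(cache=True)
def _cascade_steps(drive, dt, state, out):  # pragma: no cover - numba
    """Advance the cascade over a drive chunk; per-step signals into out.

    state rows: 0 I0, 1 U_prev, 2 Vf; per channel c in (ON=0, OFF=1):
    3+c V_prev, 5+c Wf, 7+c Xf, 9+c Xa, 11+c Wd, 13+c Xd.
    out: (T, R, 8) in SIGNAL_NAMES order.
    """
    T, R = drive.shape
    lam = LIPETZ_EXPONENT
    for t in range(T):
        for r in range(R):
            I = drive[t, r]
            I0 = state[0, r] + (dt / TAU_U) * (I - state[0, r])
            state[0, r] = I0
            il = I**lam
            denom = il + I0**lam
            U = il / denom if denom > 0.0 else 0.0
            dU = U - state[1, r]
            state[1, r] = U
            # shared high-pass feeding the ON/OFF split
            Vf = state[2, r] + dU - (dt / TAU_R) * state[2, r]
            state[2, r] = Vf
            for c in range(2):
                V = Vf if c == 0 else -Vf
                if V < 0.0:
                    V = 0.0
                dV = V - state[3 + c, r]
                state[3 + c, r] = V
                # sustained path: relaxed high-pass, 40% DC, rectified
                Wf = state[5 + c, r] + dV + (dt / TAU_S) * (
                    SUSTAINED_DC * V - state[5 + c, r]
                )
                state[5 + c, r] = Wf
                W = Wf if Wf > 0.0 else 0.0
                # transient path: high-pass, rectify, adaptive subtraction
                Xf = state[7 + c, r] + dV - (dt / TAU_A) * state[7 + c, r]
                state[7 + c, r] = Xf
                Xr = Xf if Xf > 0.0 else 0.0
                Xa = state[9 + c, r]
                if Xr - Xa >= 0.0:
                    Xa += (dt / TAU_AD) * (Xr - Xa)
                else:
                    Xa += (dt / TAU_AR) * (Xr - Xa)
                state[9 + c, r] = Xa
                X = Xr - Xa
                if X < 0.0:
                    X = 0.0
                # delay operators (unit-DC first-order low-pass)
                Wd = state[11 + c, r] + (dt / TAU_D) * (W - state[11 + c, r])
                state[11 + c, r] = Wd
                Xd = state[13 + c, r] + (dt / TAU_D) * (X - state[13 + c, r])
                state[13 + c, r] = Xd
                out[t, r, 0 + 2 * c] = W
                out[t, r, 1 + 2 * c] = Wd
                out[t, r, 4 + 2 * c] = X
                out[t, r, 5 + 2 * c] = Xd
    return out


# ---------------------------------------------------------------------------
# single-stage reference filters
#
# These plain, stage-at-a-time implementations define each operation on a
# whole input trace.  The streaming Cascade below fuses them into one
# compiled loop; the two paths are interchangeable and tested against each
# other.
# ---------------------------------------------------------------------------


def photoreceptor_response(I: np.ndarray, dt: float, I0_init: float | None = None) -> np.ndarray:
    """Adaptive Lipetz/Naka-Rushton response U(t) to a luminance trace.

    ``I0`` low-passes the luminance (tau 750 ms, forward Euler) and
    ``U = I**l / (I**l + I0**l)``; at a steady luminance U adapts to 0.5.
    ``I0_init`` defaults to the first sample (fully adapted start).
    """
    I = np.asarray(I, dtype=np.float64)
    if np.any(I < 0):
        raise ValueError("luminance must be nonnegative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    lam = LIPETZ_EXPONENT
    I0 = float(I[0]) if I0_init is None else float(I0_init)
    U = np.empty_like(I)
    for t in range(I.size):
        I0 += (dt / TAU_U) * (I[t] - I0)
        il = I[t] ** lam
        denom = il + I0**lam
        U[t] = il / denom if denom > 0 else 0.0
    return U


def on_off_split(U: np.ndarray, dt: float):
    """High-pass (tau 200 ms) the receptor output and split it into
    rectified ON (positive phase) and OFF (inverted negative phase)
    channel signals.  Returns (V_on, V_off); V_on - V_off recovers the
    filtered signal and at most one channel is active at a time."""
    U = np.asarray(U, dtype=np.float64)
    Vf = np.empty_like(U)
    prev_u = U[0]
    v = 0.0
    for t in range(U.size):
        v = v + (U[t] - prev_u) - (dt / TAU_R) * v
        prev_u = U[t]
        Vf[t] = v
    return np.maximum(Vf, 0.0), np.maximum(-Vf, 0.0)


def sustained_path(V: np.ndarray, dt: float) -> np.ndarray:
    """Relaxed high-pass (tau 50 ms) passing 40% DC, rectified: the
    sustained signal W for one channel."""
    V = np.asarray(V, dtype=np.float64)
    W = np.empty_like(V)
    wf = 0.0
    prev_v = 0.0
    for t in range(V.size):
        wf = wf + (V[t] - prev_v) + (dt / TAU_S) * (SUSTAINED_DC * V[t] - wf)
        prev_v = V[t]
        W[t] = wf if wf > 0 else 0.0
    return W


def transient_path(V: np.ndarray, dt: float) -> np.ndarray:
    """Rectifying-Transient-Cell signal X for one channel: 40 ms high-pass,
    rectification, then subtraction of an adaptive state with fast (2 ms)
    depolarization and slow (100 ms) repolarization, rectified again.  A
    sustained drive yields only a brief pulse at its onset."""
    V = np.asarray(V, dtype=np.float64)
    X = np.empty_like(V)
    xf = 0.0
    xa = 0.0
    prev_v = 0.0
    for t in range(V.size):
        xf = xf + (V[t] - prev_v) - (dt / TAU_A) * xf
        prev_v = V[t]
        xr = xf if xf > 0 else 0.0
        if xr - xa >= 0:
            xa += (dt / TAU_AD) * (xr - xa)
        else:
            xa += (dt / TAU_AR) * (xr - xa)
        x = xr - xa
        X[t] = x if x > 0 else 0.0
    return X


def delay_op(signal: np.ndarray, dt: float) -> np.ndarray:
    """Delay operator: phase delay of a unit-DC-gain first-order low-pass
    (tau 50 ms) from zero initial state."""
    signal = np.asarray(signal, dtype=np.float64)
    out = np.empty_like(signal)
    s = 0.0
    for t in range(signal.size):
        s += (dt / TAU_D) * (signal[t] - s)
        out[t] = s
    return out


class Cascade:
    """Streaming early-vision cascade for an array of receptors.

    The filter state persists between chunks, so arbitrarily long drives
    can be processed in pieces.  ``initialize`` seeds the photoreceptor's
    adaptive state with the first luminance sample (so U starts at its
    adapted value 0.5) and zeroes every filter state.
    """

    #: state rows per receptor (see _cascade_steps)
    _ROWS = 15

    def __init__(self, n_receptors: int, dt: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.n_receptors = n_receptors
        self.dt = dt
        self._state = None

    def initialize(self, first_luminance: np.ndarray) -> None:
        first = np.asarray(first_luminance, dtype=np.float64)
        if np.any(first < 0):
            raise ValueError("luminance must be nonnegative")
        state = np.zeros((self._ROWS, self.n_receptors))
        state[0] = first
        lam = LIPETZ_EXPONENT
        il = first**lam
        with np.errstate(invalid="ignore"):
            u0 = np.where(il > 0, il / (il + il), 0.0)
        state[1] = u0
        self._state = state

    def process(self, drive_chunk: np.ndarray) -> np.ndarray:
        """Per-step signals (T, R, 8) for a drive chunk (T, R)."""
        drive = np.ascontiguousarray(drive_chunk, dtype=np.float64)
        if drive.ndim != 2 or drive.shape[1] != self.n_receptors:
            raise ValueError("drive chunk must be (n_steps, n_receptors)")
        if np.any(drive < 0):
            raise ValueError("luminance must be nonnegative")
        if self._state is None:
            self.initialize(drive[0])
        out = np.empty((drive.shape[0], self.n_receptors, 8))
        _cascade_steps(drive, self.dt, self._state, out)
        return out


def _window_average(signals: np.ndarray, win: int, stride: int) -> np.ndarray:
    """Average per-step signals over windows of ``win`` steps."""
    n = signals.shape[0]
    starts = np.arange(0, n - win + 1, stride)
    csum = np.cumsum(signals, axis=0, dtype=np.float64)
    csum = np.concatenate([np.zeros((1,) + signals.shape[1:]), csum], axis=0)
    return (csum[starts + win] - csum[starts]) / win


def run_column(
    drive,
    dt: float | None = None,
    gains: np.ndarray | None = None,
    window: float = DEFAULT_WINDOW,
    stride: float | None = None,
    burn_in: float = DEFAULT_BURN_IN,
) -> np.ndarray:
    """Run the full cascade over a receptor drive and average the outputs.

    Parameters
    ----------
    drive
        A :class:`~dynedge.optics.ReceptorDrive` or an (n_steps,
        n_receptors) luminance array (then ``dt`` is required).
    gains
        Per-signal normalization gains (8,), applied multiplicatively.
    window, stride
        Averaging window and stride in seconds; the stride defaults to the
        window (successive windows).  A 50%-overlapped recording uses
        ``stride = window / 2``.
    burn_in
        Settling period discarded before the first window.

    Returns (n_windows, n_receptors, 8) averaged signals.
    """
    if hasattr(drive, "luminance"):
        dt = drive.dt
        drive = drive.luminance
    if dt is None:
        raise ValueError("dt is required when drive is a bare array")
    drive = np.asarray(drive, dtype=np.float64)
    win = int(round(window / dt))
    stride_steps = win if stride is None else int(round(stride / dt))
    burn = int(round(burn_in / dt))
    if drive.shape[0] < burn + win:
        raise ValueError("drive shorter than burn-in plus one window")
    cascade = Cascade(drive.shape[1], dt)
    signals = cascade.process(drive)[burn:]
    out = _window_average(signals, win, stride_steps)
    if gains is not None:
        out = out * np.asarray(gains)[None, None, :]
    return out


def calibrate_gains(corpus: np.ndarray) -> np.ndarray:
    """Normalization gains from a corpus of (averaged) column signals.

    For each signal type the gain is the reciprocal of the standard
    deviation of its *undelayed* signal restricted to positive values,
    pooled over every column and time in the corpus.  Delayed variants
    share the gain of their undelayed source (equivalent to normalizing
    before the unit-DC delay filter).

    ``corpus`` is (..., 8) in SIGNAL_NAMES order.
    """
    values = np.asarray(corpus, dtype=np.float64).reshape(-1, 8)
    gains = np.empty(8)
    for s in range(8):
        src = GAIN_SOURCE[s]
        pos = values[:, src]
        pos = pos[pos > 0]
        if pos.size == 0:
            raise ValueError(f"no positive excursions for {SIGNAL_NAMES[src]}")
        sd = pos.std()
        if sd == 0:
            raise ValueError(f"degenerate (constant) excursions for {SIGNAL_NAMES[src]}")
        gains[s] = 1.0 / sd
    return gains


def apply_gains(signals: np.ndarray, gains: np.ndarray) -> np.ndarray:
    return signals * np.asarray(gains)[(None,) * (signals.ndim - 1) + (slice(None),)]


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

_COLUMN_NAMES = {
    2: ("Left", "Right"),
    4: ("Left", "LeftMid", "RightMid", "Right"),
    6: ("LeftOuter", "Left", "LeftMid", "RightMid", "Right", "RightOuter"),
}


def column_names(n_columns: int):
    """Position labels for the central columns, mirror-symmetric by design."""
    try:
        return _COLUMN_NAMES[n_columns]
    except KeyError:
        raise ValueError("n_columns must be one of 2, 4, 6") from None


def central_columns(signals: np.ndarray, n_columns: int) -> np.ndarray:
    """Select the ``n_columns`` most central columns of (..., R, 8) signals."""
    R = signals.shape[-2]
    if n_columns > R:
        raise ValueError("more columns requested than receptors available")
    lo = (R - n_columns) // 2
    return signals[..., lo : lo + n_columns, :]


def raw_feature_names(n_columns: int):
    cols = column_names(n_columns)
    return [f"{sig}-{col}" for col in cols for sig in SIGNAL_NAMES]


def product_terms(n_columns: int):
    """Canonical product ordering: per column the 28 intra-column pairs
    (i < j in signal order, squares excluded), then per adjacent column
    pair the 64 cross products (left factor major).

    Returns a list of dicts with the factor coordinates, the feature name
    and a group id shared by the same signal-type pair across columns
    (grouped pruning removes a product term for all columns at once).
    """
    cols = column_names(n_columns)
    terms = []
    for c, col in enumerate(cols):
        for i in range(8):
            for j in range(i + 1, 8):
                terms.append(
                    dict(
                        ci=c,
                        si=i,
                        cj=c,
                        sj=j,
                        name=f"{SIGNAL_NAMES[i]}*{SIGNAL_NAMES[j]}-{col}",
                        group=f"intra:{SIGNAL_NAMES[i]}*{SIGNAL_NAMES[j]}",
                    )
                )
    for c in range(len(cols) - 1):
        for i in range(8):
            for j in range(8):
                terms.append(
                    dict(
                        ci=c,
                        si=i,
                        cj=c + 1,
                        sj=j,
                        name=f"{SIGNAL_NAMES[i]}-{cols[c]}*{SIGNAL_NAMES[j]}-{cols[c + 1]}",
                        group=f"inter:{SIGNAL_NAMES[i]}*{SIGNAL_NAMES[j]}",
                    )
                )
    return terms


def make_products(signals: np.ndarray, n_columns: int) -> np.ndarray:
    """Correlation-product feature vectors from per-column signals.

    ``signals`` is (..., n_columns, 8); returns (..., n_products) with
    28*n + 64*(n-1) products (120/304/488 for 2/4/6 columns).
    """
    if signals.shape[-2] != n_columns:
        raise ValueError("signals do not match n_columns")
    terms = product_terms(n_columns)
    out = np.empty(signals.shape[:-2] + (len(terms),))
    for k, t in enumerate(terms):
        out[..., k] = signals[..., t["ci"], t["si"]] * signals[..., t["cj"], t["sj"]]
    return out
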