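"""First-level GLM: canonical HRF, design construction, per-channel OLS.

Each trial contributes a boxcar of the stimulus duration, convolved with a
canonical double-gamma hemodynamic response function; one regressor per
(task, congruency) condition plus a constant.  Ordinary least squares per
channel yields the per-subject beta estimates whose linear combinations
(incongruent > congruent combined across tasks; gesture > color combined
across congruencies) feed the group analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HRFParams",
    "DesignMatrix",
    "BetaMap",
    "canonical_hrf",
    "build_design",
    "fit_glm",
    "contrast",
    "CONTRAST_PRESETS",
]


@dataclass
class HRFParams:
    """Double-gamma HRF shape parameters (seconds).

    The response peaks at ``peak_delay`` and undershoots at
    ``undershoot_delay`` with relative amplitude 1/``ratio``; the kernel is
    truncated at ``length`` and normalized to unit peak.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 0.9
    undershoot_dispersion: float = 0.9
    ratio: float = 6.0
    length: float = 32.0

    def validate(self) -> None:
        for name in ("peak_delay", "undershoot_delay", "peak_dispersion",
                     "undershoot_dispersion", "ratio", "length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"HRF parameter {name} must be positive")
        if self.peak_delay >= self.undershoot_delay:
            raise ValueError("peak must precede undershoot")


def canonical_hrf(params: HRFParams | None = None, dt: float = 0.027) -> np.ndarray:
    """Sample the canonical double-gamma HRF at step ``dt``, unit peak.

    Each lobe is a gamma-variate ``(t/d)^(d/b) exp(-(t-d)/b)`` whose mode
    sits exactly at its delay ``d`` (dispersion ``b``), so the kernel
    maximum falls at ``peak_delay`` up to grid resolution.
    """
    params = params or HRFParams()
    params.validate()
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, params.length + dt / 2, dt)

    def lobe(delay: float, dispersion: float) -> np.ndarray:
        a = delay / dispersion
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (t / delay) ** a * np.exp(-(t - delay) / dispersion)
        out[t == 0] = 0.0
        return out

    h = lobe(params.peak_delay, params.peak_dispersion) \
        - lobe(params.undershoot_delay, params.undershoot_dispersion) / params.ratio
    return h / h.max()


@dataclass
class DesignMatrix:
    """HRF-convolved design: frame times, named columns, value array."""

    frame_times: np.ndarray
    names: list[str]
    values: np.ndarray            # (n_frames, n_regressors)

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, float)
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.frame_times), len(self.names)):
            raise ValueError("design shape does not match frames/names")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.values))

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names,
                            index=pd.Index(self.frame_times, name="time_s"))


def condition_name(task: str, congruency: str) -> str:
    return f"{task}_{congruency}"


def build_design(
    events: pd.DataFrame,
    frame_times: np.ndarray,
    params: HRFParams | None = None,
    trial_duration: float = 1.5,
    include_constant: bool = True,
    drop_oddballs: bool = False,
) -> DesignMatrix:
    """Build the HRF-convolved design matrix for one run.

    ``events`` needs columns onset/task/congruency (and is_oddball when
    ``drop_oddballs``); every (task, congruency) pair present contributes
    one regressor of per-trial boxcars (duration ``trial_duration`` s)
    convolved with the canonical HRF.  Oddball trials count toward their
    own congruency unless dropped.  A constant column is appended.
    """
    frame_times = np.asarray(frame_times, float)
    if len(frame_times) < 2:
        raise ValueError("need at least two frames")
    dt = frame_times[1] - frame_times[0]
    if not np.allclose(np.diff(frame_times), dt):
        raise ValueError("frame times must be uniform")
    run_end = frame_times[-1] + dt

    ev = events.copy()
    if drop_oddballs and "is_oddball" in ev.columns:
        ev = ev[~ev["is_oddball"].astype(bool)]
    if len(ev) and (ev["onset"].min() < 0 or ev["onset"].max() >= run_end):
        raise ValueError("event onsets fall outside the run")

    # sample the stimulus on a fine grid, convolve, then read off frames
    fine_dt = min(dt, 0.1)
    n_fine = int(np.ceil(run_end / fine_dt)) + 1
    fine_t = np.arange(n_fine) * fine_dt
    hrf = canonical_hrf(params, fine_dt)

    cols, names = [], []
    for (task, congr), grp in ev.groupby(["task", "congruency"], sort=True):
        box = np.zeros(n_fine)
        for onset in grp["onset"].to_numpy(float):
            box[(fine_t >= onset) & (fine_t < onset + trial_duration)] = 1.0
        reg = np.convolve(box, hrf)[:n_fine]
        cols.append(np.interp(frame_times, fine_t, reg))
        names.append(condition_name(task, congr))
    if include_constant:
        cols.append(np.ones(len(frame_times)))
        names.append("constant")
    if not cols:
        raise ValueError("no events and no constant requested")

    X = np.column_stack(cols)
    design = DesignMatrix(frame_times=frame_times, names=names, values=X)
    if design.rank() < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return design


@dataclass
class BetaMap:
    """Per-channel OLS estimates for one subject and run."""

    subject: str
    betas: np.ndarray             # (n_channels, n_regressors)
    residual_variance: np.ndarray  # (n_channels,)
    df: int
    names: list[str]
    xtx_inv: np.ndarray = field(repr=False, default=None)  # (p, p)

    def beta(self, name: str) -> np.ndarray:
        return self.betas[:, self.names.index(name)]


def fit_glm(series: np.ndarray, design: DesignMatrix,
            subject: str = "sub") -> BetaMap:
    """Per-channel ordinary least squares of ``series`` on the design.

    ``series`` is (n_channels, n_frames).  Returns betas, unbiased residual
    variance and df = frames - rank; raises on NaN data or rank-deficient
    designs.
    """
    Y = np.asarray(series, float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if Y.shape[1] != design.n_frames:
        raise ValueError("series length does not match design frames")
    if np.isnan(Y).any():
        raise ValueError("series contains NaN")
    X = design.values
    p = X.shape[1]
    if design.rank() < p:
        raise ValueError("design matrix is rank deficient")
    df = design.n_frames - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")

    xtx_inv = np.linalg.inv(X.T @ X)
    betas = Y @ X @ xtx_inv                      # (C, p)
    resid = Y - betas @ X.T
    resid_var = (resid ** 2).sum(axis=1) / df
    return BetaMap(subject=subject, betas=betas, residual_variance=resid_var,
                   df=df, names=list(design.names), xtx_inv=xtx_inv)


#: Named contrast presets.  Weights are applied to any matching condition
#: columns; conditions absent from a design are simply not part of the sum.
CONTRAST_PRESETS: dict[str, dict[str, float]] = {
    # incongruent > congruent, combined across the gesture and color tasks
    "I>C": {
        "gesture_incongruent": 1.0, "color_incongruent": 1.0,
        "gesture_congruent": -1.0, "color_congruent": -1.0,
    },
    # gesture task > color task, combined across congruencies
    "G>C": {
        "gesture_incongruent": 1.0, "gesture_congruent": 1.0,
        "color_incongruent": -1.0, "color_congruent": -1.0,
    },
}


def contrast(beta_map: BetaMap, weights: dict[str, float] | str
             ) -> tuple[np.ndarray, np.ndarray]:
    """Linear combination of betas and its estimated variance per channel.

    ``weights`` maps regressor names to weights, or names a preset
    ('I>C', 'G>C').  Preset weights for conditions missing from the design
    are ignored; an unknown explicit regressor name raises.
    """
    if isinstance(weights, str):
        try:
            weights = {k: v for k, v in CONTRAST_PRESETS[weights].items()
                       if k in beta_map.names}
        except KeyError:
            raise KeyError(f"unknown contrast preset {weights!r}") from None
    w = np.zeros(len(beta_map.names))
    for name, val in weights.items():
        if name not in beta_map.names:
            raise KeyError(f"unknown regressor {name!r}")
        w[beta_map.names.index(name)] = val
    values = beta_map.betas @ w
    var = beta_map.residual_variance * float(w @ beta_map.xtx_inv @ w)
    return values, var
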