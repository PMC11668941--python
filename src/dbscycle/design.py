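"""Experimental design for DBS On/Off cycling fMRI runs.

The paradigm alternates stimulation Off and On in fixed-length blocks
(one minute each by default), starting in Off, with an amplitude ramp
(8 s by default) at the beginning of every block.  Both the GLM
regressors and the effect time courses injected by the synthetic-data
generator are built here from the same primitives, so a simulated run
and the model that analyses it share a single definition of the design.

Two ramp-handling conventions are implemented:

``"exclude"`` (default)
    Condition boxcars are 1 only during the plateau of their block and 0
    during ramps.  Leaving the ramps unmodeled is what keeps the On and
    Off regressors jointly identifiable next to the constant drift term.
``"linear"``
    Boxcars carry the linearly interpolated stimulation amplitude during
    ramps (a trapezoid); On + Off sums to 1 at every time point, which
    makes a design with both regressors plus a constant degenerate.
    This mode exists for model-mismatch simulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats

__all__ = [
    "HRFParams",
    "CyclingDesign",
    "condition_waveforms",
    "condition_regressors",
    "drift_basis",
]

RAMP_MODES = ("exclude", "linear")
START_STATES = ("off", "on")


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma hemodynamic response function.

    Defaults are the standard canonical shape: response peak near 6 s,
    undershoot near 16 s, peak/undershoot ratio 6.  The sampled kernel
    is normalized to unit time-integral so that the convolved response
    to a sustained block plateaus at the block's amplitude; betas are
    then directly interpretable in percent-signal units.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    ratio: float = 6.0
    duration_s: float = 32.0

    def sample(self, dt: float) -> np.ndarray:
        """Sample the kernel on a grid of spacing ``dt`` seconds."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        t = np.arange(0.0, self.duration_s, dt)
        peak = stats.gamma.pdf(
            t, self.peak_delay_s / self.peak_dispersion_s, scale=self.peak_dispersion_s
        )
        under = stats.gamma.pdf(
            t,
            self.undershoot_delay_s / self.undershoot_dispersion_s,
            scale=self.undershoot_dispersion_s,
        )
        h = peak - under / self.ratio
        integral = h.sum() * dt
        if integral <= 0:
            raise ValueError("degenerate HRF parameters: non-positive integral")
        return h / integral


@dataclass(frozen=True)
class CyclingDesign:
    """On/Off block timing of one cycling run.

    Block boundaries fall at multiples of ``cycle_s`` from t = 0 and the
    first block carries ``start_state`` (Off by default: runs are timed
    to begin at the start of an Off cycle).  The first ``ramp_s``
    seconds of every block are the stimulation amplitude ramp into that
    block's state.
    """

    tr_s: float = 2.0
    n_frames: int = 180
    cycle_s: float = 60.0
    ramp_s: float = 8.0
    start_state: str = "off"
    ramp_mode: str = "exclude"

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")
        if self.cycle_s <= 0:
            raise ValueError("cycle_s must be positive")
        if not 0 <= self.ramp_s < self.cycle_s:
            raise ValueError("ramp_s must satisfy 0 <= ramp_s < cycle_s")
        if self.start_state not in START_STATES:
            raise ValueError(f"start_state must be one of {START_STATES}")
        if self.ramp_mode not in RAMP_MODES:
            raise ValueError(f"ramp_mode must be one of {RAMP_MODES}")

    @property
    def run_length_s(self) -> float:
        return self.n_frames * self.tr_s

    @classmethod
    def from_run_length(cls, run_length_s: float, tr_s: float = 2.0, **kwargs) -> "CyclingDesign":
        n_frames = int(round(run_length_s / tr_s))
        if abs(n_frames * tr_s - run_length_s) > 1e-9:
            raise ValueError("run_length_s must be a multiple of tr_s")
        return cls(tr_s=tr_s, n_frames=n_frames, **kwargs)

    def state_at(self, t: float) -> str:
        """Block state ('on'/'off') at time ``t`` seconds."""
        block = int(np.floor(t / self.cycle_s))
        first_on = self.start_state == "on"
        return "on" if (block % 2 == 0) == first_on else "off"


def condition_waveforms(design: CyclingDesign, dt: float) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unconvolved On and Off condition waveforms sampled at ``dt``.

    Returns ``(t, on, off)`` covering the full run.  In ``"exclude"``
    mode each waveform is 1 during its plateau and 0 during ramps; in
    ``"linear"`` mode ramps interpolate linearly between states.
    """
    n = int(np.ceil(design.run_length_s / dt))
    t = np.arange(n) * dt
    block = np.floor(t / design.cycle_s).astype(int)
    phase = t - block * design.cycle_s
    first_on = design.start_state == "on"
    is_on_block = (block % 2 == 0) == first_on
    in_ramp = phase < design.ramp_s

    on = np.zeros(n)
    off = np.zeros(n)
    if design.ramp_mode == "exclude":
        on[is_on_block & ~in_ramp] = 1.0
        off[~is_on_block & ~in_ramp] = 1.0
    else:  # linear
        frac = np.ones(n)
        ramp = in_ramp & (design.ramp_s > 0)
        frac[ramp] = phase[ramp] / design.ramp_s
        # frac is the weight of the *current* block's state
        on[is_on_block] = frac[is_on_block]
        off[is_on_block] = 1.0 - frac[is_on_block]
        off[~is_on_block] = frac[~is_on_block]
        on[~is_on_block] = 1.0 - frac[~is_on_block]
    return t, on, off


def condition_regressors(
    design: CyclingDesign,
    hrf: HRFParams | None = None,
    oversample: int = 10,
) -> np.ndarray:
    """HRF-convolved On and Off regressors sampled at frame onsets.

    Waveforms are built at ``tr_s / oversample`` resolution, convolved
    with the sampled double-gamma kernel, and read out at frame onsets
    t = i * TR.  Returns an ``(n_frames, 2)`` array, columns (on, off).
    """
    hrf = hrf or HRFParams()
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    dt = design.tr_s / oversample
    _, on, off = condition_waveforms(design, dt)
    kernel = hrf.sample(dt)
    out = np.empty((design.n_frames, 2))
    for j, wave in enumerate((on, off)):
        conv = np.convolve(wave, kernel)[: len(wave)] * dt
        out[:, j] = conv[:: oversample][: design.n_frames]
    return out


def drift_basis(n_frames: int, order: int) -> np.ndarray:
    """Discrete orthogonal polynomial drift basis over the run.

    Gram polynomials of degrees 0..order on the frame grid (QR of the
    Vandermonde basis in x = linspace(-1, 1)), column-scaled so degree 0
    is the constant 1 and higher degrees have unit maximum amplitude.
    Columns are exactly mutually orthogonal and degrees >= 1 have
    exactly zero mean.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if n_frames <= order:
        raise ValueError("need more frames than polynomial order")
    x = np.linspace(-1.0, 1.0, n_frames)
    vander = np.vander(x, order + 1, increasing=True)
    q, r = np.linalg.qr(vander)
    # fix signs so each polynomial correlates positively with x**degree
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs
    basis = q / np.abs(q).max(axis=0)
    basis[:, 0] = 1.0
    return basis
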