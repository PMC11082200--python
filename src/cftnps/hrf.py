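"""Double-gamma haemodynamic response model and event-regressor construction.

The canonical SPM-style double-gamma response (peak at 6 s, undershoot at
16 s, peak:undershoot ratio 6) is used to convolve nuisance event trains in
the single-trial GLMs. Focal epochs are modelled with an FIR basis instead
(see :mod:`cftnps.trial_glm`), so this kernel only shapes regressors of no
interest and, optionally, realism-mode synthetic signals.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma

__all__ = ["double_gamma_hrf", "convolve_events"]


def double_gamma_hrf(
    dt: float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 6.0,
    length: float = 32.0,
) -> np.ndarray:
    """Sample the double-gamma response at resolution ``dt`` seconds.

    The kernel is normalised to unit sum so that a sustained unit boxcar
    converges to a plateau of height 1.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, length, dt)
    peak = _gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    undershoot = _gamma.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    h = peak - undershoot / ratio
    return h / h.sum()


def convolve_events(
    onsets,
    durations,
    n_trs: int,
    tr: float,
    amplitudes=None,
    oversample: int = 20,
    **hrf_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Build a convolved regressor and its temporal derivative on the TR grid.

    Events are rendered as boxcars on a fine grid (``tr / oversample``),
    convolved with the double-gamma kernel, and sampled at frame onsets.

    Returns
    -------
    (regressor, derivative) : two ``(n_trs,)`` arrays
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    if durations.size == 1:
        durations = np.full(onsets.shape, durations[0])
    if amplitudes is None:
        amplitudes = np.ones_like(onsets)
    else:
        amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    if not (onsets.shape == durations.shape == amplitudes.shape):
        raise ValueError("onsets, durations and amplitudes must align")

    dt = tr / oversample
    n_fine = n_trs * oversample
    stim = np.zeros(n_fine)
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        if onset < 0:
            raise ValueError(f"negative onset {onset}")
        lo = int(round(onset / dt))
        hi = max(lo + 1, int(round((onset + dur) / dt)))  # >= one fine bin
        if lo >= n_fine:
            raise ValueError(f"event onset {onset} s beyond run end")
        stim[lo : min(hi, n_fine)] += amp

    kernel = double_gamma_hrf(dt, **hrf_kwargs)
    fine = np.convolve(stim, kernel)[:n_fine]
    dfine = np.gradient(fine, dt)
    idx = np.arange(n_trs) * oversample
    return fine[idx], dfine[idx]
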