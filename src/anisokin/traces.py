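"""Dual-channel photon traces and their conversion to anisotropy curves.

Raw acquisition gives parallel (p) and perpendicular (s) photon counts per
time bin.  Analysis rebins the counts (sum within bins, then form the ratio)
and converts to fluorescence anisotropy

    r = (I_p - G I_s) / (I_p + 2 G I_s)

with a channel-sensitivity factor G, propagating Poisson counting noise to a
per-point standard error by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PolarizedTrace", "AnisotropyCurve", "rebin", "compute_anisotropy"]


@dataclass
class PolarizedTrace:
    """Time-binned p/s photon counts from one experiment.

    Attributes
    ----------
    time_s : ndarray
        Bin start times, seconds; strictly increasing, uniformly spaced.
    Ip, Is : ndarray
        Counts per bin in the p- and s-polarized channels.  Integers for
        measured/simulated data; floats allowed for noiseless model traces.
    raw_bin : float
        Bin width, seconds.
    dead : ndarray of bool
        True for bins inside the acquisition dead time (hand mixing); these
        are flagged, never deleted, and excluded from fits downstream.
    meta : dict
        Free-form protocol metadata (kind, concentrations, temperature, ...).
    """

    time_s: np.ndarray
    Ip: np.ndarray
    Is: np.ndarray
    raw_bin: float
    dead: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.Ip = np.asarray(self.Ip, dtype=float)
        self.Is = np.asarray(self.Is, dtype=float)
        n = self.time_s.size
        if self.Ip.shape != (n,) or self.Is.shape != (n,):
            raise ValueError("time and count arrays must have equal length")
        if n >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise ValueError("bin times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9 * self.raw_bin):
                raise ValueError("bin times must be uniformly spaced")
        if self.raw_bin <= 0:
            raise ValueError("raw_bin must be > 0")
        if np.any(self.Ip < 0) or np.any(self.Is < 0):
            raise ValueError("counts must be non-negative")
        if self.dead is None:
            self.dead = np.zeros(n, dtype=bool)
        else:
            self.dead = np.asarray(self.dead, dtype=bool)
            if self.dead.shape != (n,):
                raise ValueError("dead-time flags must match trace length")

    def __len__(self) -> int:
        return self.time_s.size


@dataclass
class AnisotropyCurve:
    """r(t) with per-point standard errors at one analysis bin width.

    ``mask`` is True for usable points (nonzero counts, outside dead time).
    """

    time_s: np.ndarray
    r: np.ndarray
    r_err: np.ndarray
    bin_width: float
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.r_err = np.asarray(self.r_err, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.time_s.size, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        ok = self.r[self.mask]
        if ok.size and (np.any(ok <= -0.5) or np.any(ok > 1.0)):
            raise ValueError("anisotropy must lie in (-0.5, 1]")

    def usable(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (t, r, r_err) restricted to usable points."""
        m = self.mask
        return self.time_s[m], self.r[m], self.r_err[m]

    def __len__(self) -> int:
        return self.time_s.size


def rebin(trace: PolarizedTrace, target_bin: float) -> PolarizedTrace:
    """Sum counts into wider bins; ``target_bin`` must be an integer multiple
    of the raw bin.  A trailing partial bin is dropped; a rebinned bin is
    flagged dead if any constituent raw bin was flagged."""
    ratio = target_bin / trace.raw_bin
    n_per = int(round(ratio))
    if n_per < 1 or abs(ratio - n_per) > 1e-6:
        raise ValueError(
            f"target_bin {target_bin} is not an integer multiple of raw_bin {trace.raw_bin}"
        )
    if n_per == 1:
        return trace
    n_full = len(trace) // n_per
    sl = slice(0, n_full * n_per)
    shape = (n_full, n_per)
    return PolarizedTrace(
        time_s=trace.time_s[sl][::n_per],
        Ip=trace.Ip[sl].reshape(shape).sum(axis=1),
        Is=trace.Is[sl].reshape(shape).sum(axis=1),
        raw_bin=trace.raw_bin * n_per,
        dead=trace.dead[sl].reshape(shape).any(axis=1),
        meta=dict(trace.meta),
    )


def compute_anisotropy(
    trace: PolarizedTrace, g_factor: float = 1.0, include_dead: bool = False
) -> AnisotropyCurve:
    """Convert a polarized trace to r(t) with delta-method Poisson errors.

    r = (Ip - G Is) / (Ip + 2 G Is); Var(r) follows from independent Poisson
    counts in the two channels:

        Var(r) = 9 G^2 Ip Is (Ip + Is) / (Ip + 2 G Is)^4

    Zero-count bins are masked rather than raising, except for an all-zero
    trace which is rejected.  Times are reported at bin centers.
    """
    if g_factor <= 0:
        raise ValueError("g_factor must be > 0")
    Ip, Is = trace.Ip, trace.Is
    total = Ip + 2.0 * g_factor * Is
    if not np.any(total > 0):
        raise ValueError("trace has no counts in any bin")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(total > 0, (Ip - g_factor * Is) / np.where(total > 0, total, 1.0), np.nan)
        var = 9.0 * g_factor**2 * Ip * Is * (Ip + Is) / np.where(total > 0, total, 1.0) ** 4
    err = np.sqrt(var)
    # one-photon sensitivity floor so usable points never carry zero weight
    with np.errstate(divide="ignore", invalid="ignore"):
        floor = np.where(total > 0,
                         3.0 * g_factor * np.maximum(Ip, Is)
                         / np.where(total > 0, total, 1.0) ** 2, np.inf)
    err = np.where(err > 0, err, floor)
    mask = total > 0
    if not include_dead:
        mask &= ~trace.dead
    return AnisotropyCurve(
        time_s=trace.time_s + 0.5 * trace.raw_bin,
        r=np.where(total > 0, r, 0.0),
        r_err=err,
        bin_width=trace.raw_bin,
        mask=mask,
        meta=dict(trace.meta),
    )
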