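"""Rhythm indices for bark bouts.

Given the onset series of a bout this module computes the eight indices
used to describe barking rhythm: inter-onset intervals (IOIs), integer
ratios of consecutive intervals, the small-sample-corrected coefficient
of variation, the normalised Pairwise Variability Index (nPVI), the beat
frequency f = 1/mean(IOI), per-element beat precision against an
isochronous template anchored at the first onset, and the CV and nPVI of
those per-element precision values.  It also counts "silent beats" —
metronome ticks at which no bark was produced, visible as IOIs spanning
an integer multiple >= 2 of the template period.

All indices are translation invariant (they depend on onsets only through
differences) and, except mean IOI and beat frequency, scale invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_events import BarkBout

__all__ = [
    "IOISeries",
    "BeatTemplate",
    "RhythmSummary",
    "InsufficientEventsError",
    "compute_iois",
    "integer_ratios",
    "unbiased_cv",
    "npvi",
    "beat_frequency",
    "estimate_beat_period",
    "build_template",
    "beat_precision",
    "detect_silent_beats",
    "summarize_bout",
]

MIN_EVENTS = 3  # below this, CV/nPVI/ratios are undefined
DEFAULT_SILENT_BEAT_TOL = 0.25  # fraction of a period


class InsufficientEventsError(ValueError):
    """The bout is too short for the requested index."""


@dataclass(frozen=True)
class IOISeries:
    """Ordered inter-onset intervals of one bout, in seconds."""

    iois: tuple[float, ...]
    bout_id: str | None = None

    def __post_init__(self) -> None:
        if any(x <= 0 for x in self.iois):
            raise ValueError("IOIs must be strictly positive")

    @property
    def n(self) -> int:
        return len(self.iois)


@dataclass(frozen=True)
class BeatTemplate:
    """Isochronous beat grid anchored at the first onset.

    ``beat_times[k] = anchor + k * period`` for k = 0..K, where K is chosen
    so the grid covers every onset with at least half a period to spare.
    """

    anchor: float
    period: float
    beat_times: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("template period must be positive")


@dataclass(frozen=True)
class RhythmSummary:
    """The per-bout rhythm indices plus bookkeeping counts."""

    bout_id: str | None
    individual_id: str | None
    age_class: str | None
    n_barks: int
    mean_ioi: float
    mean_integer_ratio: float
    unbiased_cv: float
    npvi_ioi: float
    beat_hz: float
    mean_beat_precision: float
    cv_beat_precision: float
    npvi_beat_precision: float
    n_silent_beats: int
    mean_bark_duration: float

    FIELDS = (
        "bout_id",
        "individual_id",
        "age_class",
        "n_barks",
        "mean_ioi",
        "mean_integer_ratio",
        "unbiased_cv",
        "npvi_ioi",
        "beat_hz",
        "mean_beat_precision",
        "cv_beat_precision",
        "npvi_beat_precision",
        "n_silent_beats",
        "mean_bark_duration",
    )

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.FIELDS}


def compute_iois(bout: BarkBout) -> IOISeries:
    """Intervals between the starts of successive barks."""
    if bout.n_events < 2:
        raise InsufficientEventsError(
            f"need >= 2 events for IOIs, got {bout.n_events}"
        )
    onsets = np.asarray(bout.onsets, dtype=float)
    return IOISeries(iois=tuple(np.diff(onsets).tolist()), bout_id=bout.bout_id)


def integer_ratios(iois: IOISeries | list[float]) -> list[float]:
    """r_k = IOI_k / (IOI_k + IOI_{k+1}) over consecutive interval pairs.

    Two equal consecutive intervals give 0.5, so a perfectly isochronous
    bout yields all ratios 0.5.
    """
    values = list(iois.iois if isinstance(iois, IOISeries) else iois)
    if len(values) < 2:
        raise InsufficientEventsError("need >= 2 intervals for integer ratios")
    return [a / (a + b) for a, b in zip(values, values[1:])]


def unbiased_cv(values) -> float:
    """Coefficient of variation with the small-sample correction (1 + 1/4n).

    Sample standard deviation uses the n-1 denominator; the correction
    compensates the downward bias of the CV at small n.
    """
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n < 2:
        raise InsufficientEventsError("need >= 2 values for a CV")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float((1.0 + 1.0 / (4.0 * n)) * arr.std(ddof=1) / mean)


def npvi(values) -> float:
    """Normalised Pairwise Variability Index on the 0-200 scale.

    (100/(m-1)) * sum |d_k - d_{k+1}| / ((d_k + d_{k+1})/2).  A term whose
    pair sums to zero is defined as 0 (the formula's limit), so sequences
    of perfectly on-beat precision values do not produce 0/0.
    """
    vals = np.asarray(list(values), dtype=float)
    m = vals.size
    if m < 2:
        raise InsufficientEventsError("need >= 2 values for nPVI")
    total = 0.0
    for a, b in zip(vals, vals[1:]):
        s = a + b
        if s != 0.0:
            total += abs(a - b) / (s / 2.0)
    return float(100.0 * total / (m - 1))


def beat_frequency(iois: IOISeries | list[float]) -> float:
    """Beat frequency f = 1 / mean(IOI), in Hz."""
    values = list(iois.iois if isinstance(iois, IOISeries) else iois)
    if len(values) < 1:
        raise InsufficientEventsError("need >= 1 interval for a beat frequency")
    return float(1.0 / np.mean(values))


def estimate_beat_period(
    iois: IOISeries | list[float], tol: float = DEFAULT_SILENT_BEAT_TOL
) -> float:
    """Dropout-robust estimate of the underlying metronome period.

    The plain mean IOI overestimates the period whenever beats are skipped
    (an IOI spanning two ticks counts double).  This estimator seeds with
    the median IOI (robust to a minority of multi-beat intervals), assigns
    each IOI its nearest integer multiplicity within ``tol``, and refines
    the period as sum(on-grid IOIs) / sum(multiplicities), iterating twice.
    With no dropout every multiplicity is 1 and the estimate equals the
    mean IOI.  Off-grid intervals are excluded from the refinement; if all
    intervals are off-grid the seed is returned unchanged.  Sequences in
    which most beats are skipped (median IOI itself a multiple of the
    period) defeat the seed; see the methods note.
    """
    values = list(iois.iois if isinstance(iois, IOISeries) else iois)
    if not values:
        raise InsufficientEventsError("need >= 1 interval to estimate a period")
    period = float(np.median(values))
    for _ in range(2):
        num, den = 0.0, 0
        for ioi in values:
            m = int(round(ioi / period))
            if m >= 1 and abs(ioi / period - m) <= tol:
                num += ioi
                den += m
        if den == 0:
            break
        period = num / den
    return period


def build_template(bout: BarkBout, f: float) -> BeatTemplate:
    """Isochronous grid at frequency ``f`` anchored at the first onset.

    The grid runs to K = ceil((last onset - anchor)/T) + 1 periods so every
    onset has a beat on each side (or sits on the boundary).
    """
    if f <= 0:
        raise ValueError("beat frequency must be positive")
    period = 1.0 / f
    anchor = bout.onsets[0]
    span = bout.onsets[-1] - anchor
    K = int(math.ceil(span / period - 1e-12)) + 1
    beats = tuple(anchor + k * period for k in range(K + 1))
    return BeatTemplate(anchor=anchor, period=period, beat_times=beats)


def beat_precision(
    bout: BarkBout,
    template: BeatTemplate,
    include_first: bool = True,
    normalization: str = "half-period",
) -> list[float]:
    """Per-element deviation from the nearest template beat, normalised.

    With the default half-period normalisation u_i = min_j |o_i - b_j| /
    (T/2) lies in [0, 1]: 0 means exactly on beat, 1 means midway between
    two beats.  ``normalization="period"`` divides by T instead (range
    [0, 0.5]).  The first element sits on the anchor and scores 0 by
    construction; it is dropped when ``include_first`` is false.
    """
    if len(template.beat_times) == 0:
        raise ValueError("empty beat template")
    if normalization not in ("half-period", "period"):
        raise ValueError(f"unknown normalization {normalization!r}")
    denom = template.period / 2.0 if normalization == "half-period" else template.period
    beats = np.asarray(template.beat_times, dtype=float)
    onsets = np.asarray(bout.onsets, dtype=float)
    if onsets.max() > beats.max() + 1e-9 or onsets.min() < beats.min() - 1e-9:
        raise ValueError("template does not cover all onsets")
    dev = np.abs(onsets[:, None] - beats[None, :]).min(axis=1)
    u = np.clip(dev / denom, 0.0, 1.0)
    # snap round-off noise to exact zero: nPVI treats an all-zero pair as 0
    # (the formula's limit) but a pair (0, eps) as the maximal term 2, so
    # on-beat elements must score exactly 0, not 1e-16
    u[u < 1e-9] = 0.0
    out = u.tolist()
    return out if include_first else out[1:]


def detect_silent_beats(
    iois: IOISeries | list[float],
    period: float,
    tol: float = DEFAULT_SILENT_BEAT_TOL,
) -> tuple[int, list[int | None]]:
    """Count metronome ticks skipped within a bout.

    Each IOI is matched to its nearest integer multiple m of the period; if
    the relative deviation |IOI/T - m| is within ``tol`` the interval is
    on-grid and contributes m - 1 silent beats (m = 1 is a normal step).
    Off-grid intervals are flagged with None and contribute nothing.

    Returns ``(n_silent, multiplicities)`` with one multiplicity entry per
    IOI (None = off-grid).
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if not (0 < tol < 0.5):
        raise ValueError("tolerance must lie in (0, 0.5)")
    values = list(iois.iois if isinstance(iois, IOISeries) else iois)
    multiplicities: list[int | None] = []
    n_silent = 0
    for ioi in values:
        ratio = ioi / period
        m = int(round(ratio))
        if m >= 1 and abs(ratio - m) <= tol:
            multiplicities.append(m)
            n_silent += m - 1
        else:
            multiplicities.append(None)
    return n_silent, multiplicities


def summarize_bout(
    bout: BarkBout,
    include_first: bool = True,
    bp_normalization: str = "half-period",
    silent_beat_tol: float = DEFAULT_SILENT_BEAT_TOL,
    template_period: str = "robust",
) -> RhythmSummary:
    """Compute every rhythm index for one bout (needs >= 3 events).

    The reported ``beat_hz`` index is always 1/mean(IOI).  The isochronous
    template used for beat precision and silent-beat detection is built at
    the dropout-robust period estimate by default
    (``template_period="robust"``); ``"mean-ioi"`` uses 1/beat_hz instead.
    The two coincide when no beats are skipped.
    """
    if bout.n_events < MIN_EVENTS:
        raise InsufficientEventsError(
            f"bout {bout.bout_id!r}: need >= {MIN_EVENTS} events, "
            f"got {bout.n_events}"
        )
    if template_period not in ("robust", "mean-ioi"):
        raise ValueError(f"unknown template_period {template_period!r}")
    iois = compute_iois(bout)
    ratios = integer_ratios(iois)
    f = beat_frequency(iois)
    if template_period == "robust":
        T_hat = estimate_beat_period(iois, tol=silent_beat_tol)
    else:
        T_hat = 1.0 / f
    template = build_template(bout, 1.0 / T_hat)
    u = beat_precision(
        bout, template, include_first=include_first, normalization=bp_normalization
    )
    n_silent, _ = detect_silent_beats(iois, template.period, tol=silent_beat_tol)
    return RhythmSummary(
        bout_id=bout.bout_id,
        individual_id=bout.individual_id,
        age_class=bout.age_class,
        n_barks=bout.n_events,
        mean_ioi=float(np.mean(iois.iois)),
        mean_integer_ratio=float(np.mean(ratios)),
        unbiased_cv=unbiased_cv(iois.iois),
        npvi_ioi=npvi(iois.iois),
        beat_hz=f,
        mean_beat_precision=float(np.mean(u)),
        cv_beat_precision=_cv_or_zero(u),
        npvi_beat_precision=npvi(u),
        n_silent_beats=n_silent,
        mean_bark_duration=float(np.mean(bout.durations)),
    )


def _cv_or_zero(u: list[float]) -> float:
    # A perfectly on-beat bout has mean precision 0; its CV is taken as 0
    # (the variability of an identically-zero series).
    if float(np.mean(u)) == 0.0:
        return 0.0
    return unbiased_cv(u)


def per_element_table(bout: BarkBout, **kwargs) -> list[dict]:
    """Per-element rows (bout_id, element_index, onset, u) for the CSV export."""
    iois = compute_iois(bout)
    T_hat = estimate_beat_period(iois)
    template = build_template(bout, 1.0 / T_hat)
    u = beat_precision(bout, template, include_first=True, **kwargs)
    return [
        {
            "bout_id": bout.bout_id,
            "element_index": i,
            "onset": onset,
            "u": ui,
        }
        for i, (onset, ui) in enumerate(zip(bout.onsets, u))
    ]
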