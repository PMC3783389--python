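"""Two-channel miRNA microarray analysis.

The chip hybridizes two dye-labelled samples (channel A and channel B) with
replicate spots per probe.  The analysis chain is: background subtraction,
detectability filtering (signal > 3x background SD and spot CV < 0.5),
LOWESS normalization of the intensity-dependent dye bias on the MA plane,
log2 ratios, paired two-tailed t-tests across replicate spot pairs, and
UP/DOWN/NS calls at a p-value and fold-change threshold.

Two named threshold presets are provided: ``methods`` (p < 0.05, 3-fold) and
``results`` (p < 0.01, 2-fold on the rounded log2 ratio).  Thresholds are
applied to log2 ratios rounded half-away-from-zero to 2 decimals so that
printed-table semantics (a printed 1.00 passes ">= 1") are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .formats import SignalRow

#: Named (p_threshold, log2_threshold) presets.
THRESHOLD_PRESETS = {
    "methods": (0.05, math.log2(3.0)),
    "results": (0.01, 1.0),
}


def round_log2(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention of printed signal tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ProbeMeasurement:
    """Replicate foreground signals and background statistics per channel."""

    probe_id: str
    mirna: str
    fg: dict[str, np.ndarray]  # channel -> replicate foreground signals
    bg_mean: dict[str, float]
    bg_sd: dict[str, float]

    def __post_init__(self) -> None:
        for ch in ("A", "B"):
            if ch not in self.fg:
                raise ValueError(f"probe {self.probe_id!r} lacks channel {ch}")
            if len(self.fg[ch]) < 2:
                raise ValueError(
                    f"probe {self.probe_id!r} channel {ch} needs >= 2 replicate spots"
                )

    @property
    def n_replicates(self) -> int:
        return min(len(self.fg["A"]), len(self.fg["B"]))


@dataclass(frozen=True)
class NormalizationFit:
    """The fitted dye-bias curve of a LOWESS normalization."""

    span: float
    iterations: int
    a_values: np.ndarray
    fitted_bias: np.ndarray


@dataclass(frozen=True)
class DifferentialResult:
    """Per-miRNA differential expression summary."""

    mirna: str
    signal_a: float
    signal_b: float
    log2_ratio: float
    p_value: float
    call: str = "NS"


def measurements_from_rows(rows: Iterable[SignalRow]) -> list[ProbeMeasurement]:
    """Group per-spot signal rows into per-probe measurements.

    Background statistics are averaged over a probe's spots per channel.
    """
    grouped: dict[str, dict] = {}
    for r in rows:
        g = grouped.setdefault(
            r.probe_id, {"mirna": r.mirna, "fg": {"A": [], "B": []}, "bg": {"A": [], "B": []}}
        )
        g["fg"][r.channel].append((r.replicate, r.fg))
        g["bg"][r.channel].append((r.bg_mean, r.bg_sd))
    out = []
    for probe_id, g in grouped.items():
        fg = {
            ch: np.array([v for _, v in sorted(vals)], dtype=float)
            for ch, vals in g["fg"].items()
        }
        bg_mean = {ch: float(np.mean([m for m, _ in v])) if v else 0.0 for ch, v in g["bg"].items()}
        bg_sd = {ch: float(np.mean([s for _, s in v])) if v else 0.0 for ch, v in g["bg"].items()}
        out.append(
            ProbeMeasurement(probe_id=probe_id, mirna=g["mirna"], fg=fg, bg_mean=bg_mean, bg_sd=bg_sd)
        )
    return out


def subtract_background(measurement: ProbeMeasurement) -> dict[str, np.ndarray]:
    """Background-corrected signals, clamped at zero per spot."""
    return {
        ch: np.maximum(measurement.fg[ch] - measurement.bg_mean[ch], 0.0)
        for ch in measurement.fg
    }


def is_detectable(measurement: ProbeMeasurement, channel: str) -> bool:
    """Detectability of one channel of a probe.

    True iff the mean background-corrected signal exceeds three times the
    background SD and the spot CV (replicate SD / replicate mean) is below
    0.5.  A zero mean signal fails (CV undefined).
    """
    corrected = subtract_background(measurement)[channel]
    mean = float(np.mean(corrected))
    if mean <= 0:
        return False
    if mean <= 3.0 * measurement.bg_sd[channel]:
        return False
    sd = float(np.std(corrected, ddof=1))
    return (sd / mean) < 0.5


def log2_ratio(signal_a: float, signal_b: float) -> float:
    """log2(B/A) of two positive intensities."""
    if signal_a <= 0 or signal_b <= 0:
        raise ValueError("log2 ratio requires positive signals")
    return math.log2(signal_b / signal_a)


@dataclass(frozen=True)
class _SpotMatrix:
    """Corrected per-spot intensities for probes entering normalization."""

    probes: list[ProbeMeasurement]
    a: np.ndarray  # shape (n_probes, n_replicates), channel A
    b: np.ndarray


def _spot_matrix(probes: Sequence[ProbeMeasurement]) -> _SpotMatrix:
    n_rep = min(p.n_replicates for p in probes)
    a = np.vstack([subtract_background(p)["A"][:n_rep] for p in probes])
    b = np.vstack([subtract_background(p)["B"][:n_rep] for p in probes])
    return _SpotMatrix(probes=list(probes), a=a, b=b)


def lowess_normalize(
    probes: Sequence[ProbeMeasurement],
    span: float = 0.4,
    iterations: int = 3,
) -> tuple[_SpotMatrix, NormalizationFit]:
    """Remove intensity-dependent dye bias with a robust LOWESS fit.

    Per spot pair, M = log2(B/A) and A-value = 0.5*log2(A*B) are computed;
    M is regressed on the A-value with tricube weights over a ``span``
    fraction of the data and ``iterations`` bisquare robustifying passes
    (statsmodels' lowess).  The fitted bias is subtracted from each spot's M
    and channel intensities are rescaled so A-values are preserved exactly.

    Requires >= 10 probes with positive corrected signals in both channels.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    mat = _spot_matrix(probes)
    if np.any(mat.a <= 0) or np.any(mat.b <= 0):
        raise ValueError("normalization requires positive corrected signals in both channels")
    if len(mat.probes) < 10:
        raise ValueError("need >= 10 probes for LOWESS normalization")
    la = np.log2(mat.a)
    lb = np.log2(mat.b)
    m = (lb - la).ravel()
    av = (0.5 * (la + lb)).ravel()
    if len(m) * span < 3:
        raise ValueError("too few spots for this span; increase the span fraction f")
    fit = _sm_lowess(m, av, frac=span, it=iterations, return_sorted=False)
    m_norm = (m - fit).reshape(la.shape)
    av2 = 0.5 * (la + lb)
    la_new = av2 - m_norm / 2.0
    lb_new = av2 + m_norm / 2.0
    normalized = _SpotMatrix(probes=mat.probes, a=2.0 ** la_new, b=2.0 ** lb_new)
    return normalized, NormalizationFit(
        span=span, iterations=iterations, a_values=av, fitted_bias=fit
    )


def paired_t_test(channel_a: Sequence[float], channel_b: Sequence[float]) -> float:
    """Paired two-tailed t-test on per-spot log2 differences.

    d = log2(B) - log2(A) per spot pair; t = mean(d)/(sd(d)/sqrt(n)) with
    n-1 degrees of freedom.  Degenerate sd(d)=0 gives p=1 when mean(d)=0
    and p=0 otherwise.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired test requires equal replicate counts")
    if len(a) < 2:
        raise ValueError("paired test requires n >= 2")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("paired test requires positive signals")
    d = np.log2(b) - np.log2(a)
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        return 1.0 if mean == 0.0 else 0.0
    t = mean / (sd / math.sqrt(len(d)))
    return 2.0 * float(stats.t.sf(abs(t), df=len(d) - 1))


def differential_results(
    normalized: _SpotMatrix,
) -> list[DifferentialResult]:
    """Summarize normalized spots into per-probe log2 ratios and p-values."""
    out = []
    for i, probe in enumerate(normalized.probes):
        sa = float(np.mean(normalized.a[i]))
        sb = float(np.mean(normalized.b[i]))
        out.append(
            DifferentialResult(
                mirna=probe.mirna,
                signal_a=sa,
                signal_b=sb,
                log2_ratio=log2_ratio(sa, sb),
                p_value=paired_t_test(normalized.a[i], normalized.b[i]),
            )
        )
    return out


@dataclass(frozen=True)
class CallSummary:
    n_up: int
    n_down: int
    n_families: int


def differential_call(
    results: Sequence[DifferentialResult],
    p_threshold: float = 0.05,
    log2_threshold: float = math.log2(3.0),
    mode: str = "full",
    family_of=None,
) -> tuple[list[DifferentialResult], CallSummary]:
    """Assign UP/DOWN/NS calls and count them.

    In ``full`` mode a call additionally requires p < ``p_threshold``; in
    ``fold_only`` mode only the fold threshold applies (used for summary
    tables that print no replicate detail).  The fold threshold is applied
    to the 2-decimal rounded log2 ratio.
    """
    if mode not in ("full", "fold_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if family_of is None:
        from .target_prediction import mirna_family as family_of  # noqa: PLC0415
    called = []
    families: set[str] = set()
    n_up = n_down = 0
    for r in results:
        rounded = round_log2(r.log2_ratio)
        passes_p = mode == "fold_only" or r.p_value < p_threshold
        if passes_p and rounded >= log2_threshold:
            call = "UP"
            n_up += 1
        elif passes_p and rounded <= -log2_threshold:
            call = "DOWN"
            n_down += 1
        else:
            call = "NS"
        if call != "NS":
            families.add(family_of(r.mirna))
        called.append(replace(r, call=call))
    return called, CallSummary(n_up=n_up, n_down=n_down, n_families=len(families))


def analyze(
    rows: Iterable[SignalRow],
    p_threshold: float = 0.05,
    log2_threshold: float = math.log2(3.0),
    mode: str = "full",
    span: float = 0.4,
    iterations: int = 3,
) -> tuple[list[DifferentialResult], CallSummary, NormalizationFit]:
    """Full chip analysis from raw signal rows to differential calls.

    Probes are kept when detectable in at least one channel and all
    background-corrected spot intensities are positive (required for logs).
    """
    measurements = measurements_from_rows(rows)
    kept = []
    for m in measurements:
        corrected = subtract_background(m)
        if np.any(corrected["A"] <= 0) or np.any(corrected["B"] <= 0):
            continue
        if is_detectable(m, "A") or is_detectable(m, "B"):
            kept.append(m)
    normalized, fit = lowess_normalize(kept, span=span, iterations=iterations)
    results = differential_results(normalized)
    called, summary = differential_call(
        results, p_threshold=p_threshold, log2_threshold=log2_threshold, mode=mode
    )
    return called, summary, fit
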