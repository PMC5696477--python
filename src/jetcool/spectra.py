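"""Harmonic IR line lists: scaling, calibration, broadening, assignment scoring.

Harmonic frequencies from electronic-structure calculations overestimate the
observed fundamentals; a single multiplicative scaling factor absorbs the
anharmonicity. Shipped defaults: 0.9602 (B3LYP/6-31G**, literature value) and
0.943 (M062X/6-31G**, calibrated so the scaled mean of a set of reference
modes reproduces the experimental mean). Stick spectra are broadened with
Lorentzians of 20 1/cm full width at half maximum for comparison with
experiment, and theory/experiment band assignments are scored by mean and
maximum absolute deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SCALE_FACTORS",
    "DEFAULT_FWHM",
    "SpectrumLine",
    "AssignmentScore",
    "scale_frequencies",
    "calibrate_scale_factor",
    "broaden",
    "score_assignment",
    "plot_spectrum",
]

#: Default harmonic scaling factors by level of theory.
SCALE_FACTORS = {"B3LYP/6-31G**": 0.9602, "M062X/6-31G**": 0.943}
DEFAULT_FWHM = 20.0  # 1/cm


@dataclass(frozen=True)
class SpectrumLine:
    """One harmonic line: mode label, frequency (1/cm), intensity (arb. >= 0)."""

    mode_label: str
    frequency: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"{self.mode_label}: frequency must be positive")
        if self.intensity < 0:
            raise ValueError(f"{self.mode_label}: negative intensity")


@dataclass(frozen=True)
class AssignmentScore:
    """Per-mode theory/experiment deviations and their mean/max (1/cm)."""

    pairs: tuple[tuple[SpectrumLine, SpectrumLine, float], ...]
    mean_dev: float
    max_dev: float

    @property
    def mean_dev_rounded(self) -> int:
        """Mean deviation rounded half-up to integer 1/cm (report convention)."""
        return _round_half_up(self.mean_dev)

    @property
    def max_dev_rounded(self) -> int:
        return _round_half_up(self.max_dev)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def scale_frequencies(lines: list[SpectrumLine], factor: float) -> list[SpectrumLine]:
    """Multiply every frequency by ``factor`` (intensities unchanged)."""
    if not (0 < factor <= 1.2):
        raise ValueError(f"scaling factor must be in (0, 1.2], got {factor}")
    return [
        SpectrumLine(l.mode_label, l.frequency * factor, l.intensity) for l in lines
    ]


def calibrate_scale_factor(raw_freqs, exp_freqs) -> float:
    """Scaling factor making the scaled mean of ``raw_freqs`` equal mean(exp).

    factor = mean(exp) / mean(raw); by construction
    mean(factor * raw) == mean(exp) exactly.
    """
    raw = np.asarray(raw_freqs, dtype=float)
    exp = np.asarray(exp_freqs, dtype=float)
    if raw.size != exp.size:
        raise ValueError(f"length mismatch: {raw.size} raw vs {exp.size} experimental")
    if raw.size == 0:
        raise ValueError("need at least one frequency pair")
    return float(exp.mean() / raw.mean())


def broaden(lines: list[SpectrumLine], grid, fwhm: float = DEFAULT_FWHM) -> np.ndarray:
    """Sum of Lorentzians on ``grid`` (1/cm), peak height = line intensity.

    L(v) = I * (G/2)^2 / ((v - v0)^2 + (G/2)^2) with G the full width at half
    maximum, so L(v0) = I and L(v0 +/- G/2) = I/2.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty frequency grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    hw2 = (fwhm / 2.0) ** 2
    curve = np.zeros_like(grid)
    for l in lines:
        curve += l.intensity * hw2 / ((grid - l.frequency) ** 2 + hw2)
    return curve


def _as_lines(seq) -> list[SpectrumLine]:
    out = []
    for x in seq:
        if isinstance(x, SpectrumLine):
            out.append(x)
        elif isinstance(x, (int, float)):
            out.append(SpectrumLine("", float(x)))
        else:  # (label, freq[, intensity]) tuples
            out.append(SpectrumLine(str(x[0]), float(x[1]), float(x[2]) if len(x) > 2 else 1.0))
    return out


def _ordered_nearest_pairs(theory, exp):
    """Order-preserving minimal-total-|dv| matching of two line lists.

    Both lists are sorted by frequency; every line of the shorter list is
    matched to a distinct line of the longer one without crossing, minimising
    the total absolute deviation (classic O(n*m) alignment DP).
    """
    t = sorted(theory, key=lambda l: l.frequency)
    e = sorted(exp, key=lambda l: l.frequency)
    swapped = len(t) > len(e)
    short, long_ = (e, t) if swapped else (t, e)
    n, m = len(short), len(long_)

    inf = float("inf")
    # cost[i][j]: all of short[:i] matched within long_[:j]
    cost = [[inf] * (m + 1) for _ in range(n + 1)]
    choice = [[False] * (m + 1) for _ in range(n + 1)]
    cost[0] = [0.0] * (m + 1)
    for i in range(1, n + 1):
        for j in range(i, m + 1):
            skip = cost[i][j - 1]
            take = cost[i - 1][j - 1] + abs(short[i - 1].frequency - long_[j - 1].frequency)
            if take <= skip:
                cost[i][j], choice[i][j] = take, True
            else:
                cost[i][j] = skip
    pairs = []
    i, j = n, m
    while i > 0:
        if choice[i][j]:
            a, b = short[i - 1], long_[j - 1]
            pairs.append((b, a) if swapped else (a, b))
            i, j = i - 1, j - 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def score_assignment(theory, exp) -> AssignmentScore:
    """Score a theory/experiment band assignment by absolute deviations (1/cm).

    When both lists carry non-empty mode labels, lines are matched by label
    (unmatched labels raise). Otherwise an order-preserving nearest-frequency
    matching is used. Raw float deviations are retained; the report rounding
    convention is half-up to integer 1/cm (see ``mean_dev_rounded``).
    """
    t_lines, e_lines = _as_lines(theory), _as_lines(exp)
    if not t_lines or not e_lines:
        raise ValueError("need at least one line on each side")

    t_labeled = all(l.mode_label for l in t_lines)
    e_labeled = all(l.mode_label for l in e_lines)
    if t_labeled and e_labeled:
        e_by = {l.mode_label: l for l in e_lines}
        unmatched = [l.mode_label for l in t_lines if l.mode_label not in e_by]
        unmatched += [l.mode_label for l in e_lines if l.mode_label not in {x.mode_label for x in t_lines}]
        if unmatched:
            raise ValueError(f"unmatched mode labels: {', '.join(sorted(set(unmatched)))}")
        pairs = [(l, e_by[l.mode_label]) for l in t_lines]
    else:
        pairs = _ordered_nearest_pairs(t_lines, e_lines)

    scored = tuple(
        (tl, el, abs(tl.frequency - el.frequency)) for tl, el in pairs
    )
    devs = [d for _, _, d in scored]
    return AssignmentScore(pairs=scored, mean_dev=float(np.mean(devs)), max_dev=float(max(devs)))


def plot_spectrum(
    lines,
    grid=None,
    fwhm: float = DEFAULT_FWHM,
    exp_bands=None,
    ax=None,
):
    """Plot a broadened theoretical spectrum (sticks + Lorentzian envelope).

    Experimental band positions, if given, are drawn as dashed vertical lines.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    lines = _as_lines(lines)
    if grid is None:
        freqs = [l.frequency for l in lines]
        grid = np.linspace(min(freqs) - 5 * fwhm, max(freqs) + 5 * fwhm, 2000)
    if ax is None:
        _, ax = plt.subplots()
    for l in lines:
        ax.vlines(l.frequency, 0, l.intensity, color="k", lw=1)
    ax.plot(grid, broaden(lines, grid, fwhm=fwhm), color="tab:blue")
    for b in _as_lines(exp_bands or []):
        ax.axvline(b.frequency, ls="--", color="tab:purple", alpha=0.7)
    ax.set_xlabel("wavenumber / cm$^{-1}$")
    ax.set_ylabel("intensity / arb.")
    return ax
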