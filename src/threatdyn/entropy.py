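"""Sample entropy, autocorrelation Theiler window, and the (r, m) grid sweep.

Sample entropy of a series is -ln(A/B), where B counts ordered pairs of
m-length templates within Chebyshev distance r and A counts the same for
m+1.  Self-matches and temporally close pairs (|i - j| < w, the Theiler
window) are excluded.  The "multi-scale" aggregate used here sweeps a grid
of radii (fractions of the series SD) and embedding dimensions and averages
the defined cells — it is a parameter-grid sweep, not coarse-graining.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EntropyUndefinedError, SeriesTooShortError, ValidationError

DEFAULT_R_FRACTIONS = tuple(np.round(np.arange(0.01, 0.2501, 0.02), 2))  # 13 radii
DEFAULT_M_RANGE = tuple(range(2, 9))  # m = 2..8 inclusive

THEILER_RULES = ("acf_1_over_e", "acf_first_zero")


@dataclass
class EntropyConfig:
    """Grid and rules for the multiscale sample-entropy sweep."""

    r_fractions: tuple[float, ...] = DEFAULT_R_FRACTIONS
    m_range: tuple[int, ...] = DEFAULT_M_RANGE
    theiler_rule: str = "acf_1_over_e"
    aggregation: str = "mean"
    resample_hz: float | None = None  # off by default; series used as sampled

    def __post_init__(self) -> None:
        if not self.r_fractions:
            raise ValidationError("radius grid is empty")
        if any(not (0 < r <= 1) for r in self.r_fractions):
            raise ValidationError("radius fractions must lie in (0, 1]")
        if not self.m_range or any(int(m) < 1 for m in self.m_range):
            raise ValidationError("m_range must be integers >= 1")
        if self.theiler_rule not in THEILER_RULES:
            raise ValidationError(f"unknown theiler rule {self.theiler_rule!r}")
        if self.aggregation != "mean":
            raise ValidationError(f"unknown aggregation {self.aggregation!r}")

    def to_dict(self) -> dict:
        return {
            "r_fractions": list(map(float, self.r_fractions)),
            "m_range": list(map(int, self.m_range)),
            "theiler_rule": self.theiler_rule,
            "aggregation": self.aggregation,
            "resample_hz": self.resample_hz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EntropyConfig":
        d = dict(d)
        if "r_fractions" in d:
            d["r_fractions"] = tuple(d["r_fractions"])
        if "m_range" in d:
            d["m_range"] = tuple(d["m_range"])
        return cls(**d)


@dataclass
class MsseResult:
    """Aggregate of the sample-entropy grid for one series."""

    se_raw: float
    se_log: float  # nan (flagged) when se_raw == 0
    theiler: int
    n_defined: int
    n_cells: int

    def __iter__(self):  # allow tuple unpacking (se_raw, se_log)
        yield self.se_raw
        yield self.se_log


def autocorrelation(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation at lags 0..max_lag."""
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return np.ones(max_lag + 1)
    return np.array(
        [np.dot(x[: x.size - k], x[k:]) / denom for k in range(max_lag + 1)]
    )


def theiler_window(series: np.ndarray, rule: str = "acf_1_over_e") -> int:
    """Smallest lag at which the autocorrelation decays, capped at N//10.

    Default rule: first lag where the sample autocorrelation falls to
    <= 1/e.  Alternative rule ``acf_first_zero``: first non-positive lag.
    Always >= 1.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 10:
        raise SeriesTooShortError(f"need N >= 10 for the Theiler window, got {n}")
    if rule not in THEILER_RULES:
        raise ValidationError(f"unknown theiler rule {rule!r}")
    cap = max(1, n // 10)
    acf = autocorrelation(x, cap)
    threshold = 1.0 / math.e if rule == "acf_1_over_e" else 0.0
    for lag in range(1, cap + 1):
        if acf[lag] <= threshold:
            return lag
    return cap


def _template_max_matrix(diff: np.ndarray, m: int) -> np.ndarray:
    """Chebyshev distance between all m-length templates.

    ``diff`` is the |x_i - x_j| matrix; entry (i, j) of the result is
    max_{k<m} |x_{i+k} - x_{j+k}| for template starts i, j <= N - m.
    """
    n = diff.shape[0]
    out = diff
    for k in range(1, m):
        L = n - k
        out = np.maximum(out[:L, :L], diff[k : k + L, k : k + L])
    return out


def _count_pairs(cheb: np.ndarray, radii: np.ndarray, w: int) -> np.ndarray:
    """Count template pairs (i < j, j - i >= w) within each radius."""
    L = cheb.shape[0]
    if L <= w:
        return np.zeros(len(radii), dtype=np.int64)
    rows, cols = np.triu_indices(L, k=w)
    vals = cheb[rows, cols]
    return np.array([(vals <= r).sum() for r in radii], dtype=np.int64)


def sample_entropy(series: np.ndarray, m: int, r: float, w: int = 1) -> float:
    """Sample entropy -ln(A/B) with an absolute radius and Theiler window.

    Returns NaN (a flag, not an exception) when no m- or (m+1)-template
    pair matches.  ``r`` is an absolute Chebyshev tolerance; matching is
    inclusive (distance <= r).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    m = int(m)
    if n <= m + 1:
        raise SeriesTooShortError(f"need N > m+1 = {m + 1}, got {n}")
    if r <= 0:
        raise ValidationError("radius must be positive")
    if w < 1:
        raise ValidationError("Theiler window must be >= 1")
    diff = np.abs(x[:, None] - x[None, :])
    radii = np.array([r])
    # standard convention: both counts range over the N-m template starts
    # (the last m-length template is dropped), so a constant series gives
    # A = B and entropy exactly 0
    L = n - m
    cheb_b = _template_max_matrix(diff, m)[:L, :L]
    b = _count_pairs(cheb_b, radii, w)[0]
    a = _count_pairs(_template_max_matrix(diff, m + 1), radii, w)[0]
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def sample_entropy_grid(
    series: np.ndarray,
    m_values: tuple[int, ...],
    radii: np.ndarray,
    w: int,
) -> np.ndarray:
    """Sample entropy on the full (m, r) grid, sharing template counts.

    Returns an array of shape (len(m_values), len(radii)); undefined cells
    are NaN.  Equivalent to calling :func:`sample_entropy` per cell but
    reuses the pairwise distance recurrence across the grid.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    m_values = tuple(int(m) for m in m_values)
    max_m = max(m_values)
    if n <= max_m + 1:
        raise SeriesTooShortError(f"need N > {max_m + 1}, got {n}")
    radii = np.asarray(radii, dtype=float)
    diff = np.abs(x[:, None] - x[None, :])
    counts_full: dict[int, np.ndarray] = {}  # all N-m+1 template starts
    counts_trim: dict[int, np.ndarray] = {}  # first N-m starts (B-side)
    needed = sorted(set(m_values) | {m + 1 for m in m_values})
    # incremental sweep from m=1 upward, reusing the running Chebyshev max
    cheb = diff
    current_m = 1
    for m in needed:
        while current_m < m:
            L = diff.shape[0] - current_m
            cheb = np.maximum(cheb[:L, :L], diff[current_m:, current_m:][:L, :L])
            current_m += 1
        if m in m_values:
            Lb = x.size - m
            counts_trim[m] = _count_pairs(cheb[:Lb, :Lb], radii, w)
        if m - 1 in m_values:
            counts_full[m] = _count_pairs(cheb, radii, w)
    grid = np.full((len(m_values), len(radii)), np.nan)
    for i, m in enumerate(m_values):
        b = counts_trim[m]
        a = counts_full[m + 1]
        ok = (a > 0) & (b > 0)
        grid[i, ok] = -np.log(a[ok] / b[ok])
    return grid


def multiscale_sample_entropy(
    series: np.ndarray, config: EntropyConfig | None = None
) -> MsseResult:
    """Aggregate sample entropy over the (r, m) grid.

    Radii are ``config.r_fractions`` times the series' sample SD; the
    Theiler window comes from the series' autocorrelation.  Defined cells
    are averaged arithmetically; if every cell is undefined an
    :class:`~threatdyn.errors.EntropyUndefinedError` is raised.  ``se_log``
    is NaN (flagged) when ``se_raw`` is 0.
    """
    config = config or EntropyConfig()
    x = np.asarray(series, dtype=float)
    sd = float(np.std(x, ddof=1))
    w = theiler_window(x, config.theiler_rule)
    radii = np.asarray(config.r_fractions, dtype=float) * sd
    if sd == 0.0:
        # constant series: every template matches at distance 0 <= r
        grid = np.zeros((len(config.m_range), len(radii)))
    else:
        grid = sample_entropy_grid(x, tuple(config.m_range), radii, w)
    defined = np.isfinite(grid)
    n_defined = int(defined.sum())
    if n_defined == 0:
        raise EntropyUndefinedError("all grid cells undefined")
    se_raw = float(grid[defined].mean())
    se_log = math.log(se_raw) if se_raw > 0 else float("nan")
    return MsseResult(
        se_raw=se_raw,
        se_log=se_log,
        theiler=w,
        n_defined=n_defined,
        n_cells=int(grid.size),
    )
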