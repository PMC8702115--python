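"""Independent brute-force oracles used to validate the package's
vectorised implementations.

Everything here is deliberately written with plain Python loops and
from-scratch formulas, sharing no code path with the package.
"""

from __future__ import annotations

import math


def zone_lattice_count(diameter_mm: float, spacing_mm: float = 0.1, half: int = 70) -> int:
    """Count lattice points (i, j) in [-half, half]^2 whose physical
    distance from the origin is <= diameter/2 (inclusive boundary)."""
    r2 = (diameter_mm / 2.0) ** 2
    count = 0
    for i in range(-half, half + 1):
        for j in range(-half, half + 1):
            x = j * spacing_mm
            y = i * spacing_mm
            # integer arithmetic in tenths of mm avoids float boundary issues
            if (j * j + i * i) * spacing_mm * spacing_mm <= r2 + 1e-12:
                count += 1
    return count


def extract_zone_brute(grid, diameter_mm: float):
    """Row-major extraction of finite masked values with a double loop."""
    out = []
    n_missing = 0
    r2 = (diameter_mm / 2.0) ** 2
    for i in range(141):
        for j in range(141):
            x = (j - 70) * 0.1
            y = (70 - i) * 0.1
            if x * x + y * y <= r2 + 1e-12:
                v = grid[i][j]
                if math.isfinite(v):
                    out.append(float(v))
                else:
                    n_missing += 1
    return out, n_missing


def _percentile_linear(sorted_vals, q):
    """Linear-interpolation percentile (the 'linear' scheme), q in [0, 100]."""
    n = len(sorted_vals)
    if n == 1:
        return sorted_vals[0]
    h = (n - 1) * q / 100.0
    lo = int(math.floor(h))
    hi = min(lo + 1, n - 1)
    frac = h - lo
    return sorted_vals[lo] + frac * (sorted_vals[hi] - sorted_vals[lo])


def summarize_brute(values, cell_area=0.01):
    """The 17 zonal features, computed from first principles."""
    v = [float(x) for x in values if math.isfinite(x)]
    n = len(v)
    if n == 0:
        raise ValueError("empty zone")
    mean = sum(v) / n
    sv = sorted(v)
    if n % 2:
        median = sv[n // 2]
    else:
        median = 0.5 * (sv[n // 2 - 1] + sv[n // 2])
    abs_sorted = sorted(abs(x) for x in v)
    if n % 2:
        abs_median = abs_sorted[n // 2]
    else:
        abs_median = 0.5 * (abs_sorted[n // 2 - 1] + abs_sorted[n // 2])
    abs_mean = sum(abs(x) for x in v) / n
    vmin, vmax = sv[0], sv[-1]
    abs_max = max(vmax, abs(vmin))
    rng = vmax - vmin
    c95 = _percentile_linear(sv, 97.5) - _percentile_linear(sv, 2.5)

    if n == 1:
        sd = skew = kurt = 0.0
    else:
        var1 = sum((x - mean) ** 2 for x in v) / (n - 1)
        sd = math.sqrt(var1)
        m2 = sum((x - mean) ** 2 for x in v) / n
        if m2 == 0.0:
            skew = kurt = 0.0
        else:
            m3 = sum((x - mean) ** 3 for x in v) / n
            m4 = sum((x - mean) ** 4 for x in v) / n
            skew = m3 / m2**1.5
            kurt = m4 / m2**2 - 3.0

    neg = abs(sum(x for x in v if x < 0)) * cell_area
    pos = sum(x for x in v if x > 0) * cell_area
    return {
        "skew": skew,
        "abs_skew": abs(skew),
        "kurtosis": kurt,
        "mean": mean,
        "sd": sd,
        "abs_mean": abs_mean,
        "median": median,
        "abs_median": abs_median,
        "min": vmin,
        "max": vmax,
        "abs_max": abs_max,
        "range": rng,
        "central95_range": c95,
        "neg_volume": neg,
        "pos_volume": pos,
        "total_volume": neg + pos,
        "volume_diff": abs(pos - neg),
    }
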