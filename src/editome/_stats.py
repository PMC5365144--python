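"""Small shared numeric helpers used across the analysis modules."""

from __future__ import annotations

import numpy as np

__all__ = ["quantile_type1", "empirical_p", "ratio_or_inf"]


def quantile_type1(values, q: float) -> float:
    """Empirical type-1 (inverse-CDF) quantile.

    ``+inf`` entries sort above every finite value, so replicate ratios with a
    zero denominator participate in the ordering instead of being dropped.
    NaNs are not allowed.
    """
    a = np.sort(np.asarray(values, dtype=float))
    if a.size == 0:
        raise ValueError("quantile of empty sequence")
    if np.isnan(a).any():
        raise ValueError("NaN in quantile input")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile level {q} outside [0, 1]")
    if q == 0.0:
        return float(a[0])
    k = int(np.ceil(q * a.size)) - 1
    return float(a[k])


def empirical_p(n_exceed: int, n_replicates: int) -> float:
    """(r+1)/(n+1)-smoothed empirical p-value (never exactly zero)."""
    return (n_exceed + 1) / (n_replicates + 1)


def ratio_or_inf(num, den):
    """Elementwise num/den with +inf where den == 0 (0/0 also maps to +inf)."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.inf)
    nz = den != 0
    out[nz] = np.broadcast_to(num, out.shape)[nz] / np.broadcast_to(den, out.shape)[nz]
    if out.ndim == 0:
        return float(out)
    return out
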