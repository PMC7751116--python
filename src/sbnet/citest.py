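"""Gaussian conditional-independence tests on partial correlations.

Constraint-based structure learning decides whether variables ``i`` and
``j`` are independent given a conditioning set ``S`` by computing the
sample partial correlation ``r(i, j | S)`` and testing it against zero,
either with Fisher's variance-stabilising z-transform (asymptotic normal
test) or with the exact Student t-test for a correlation coefficient.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


class DegenerateConditioningError(ValueError):
    """The correlation submatrix over {i, j} | S is singular."""


@dataclass(frozen=True)
class CITestResult:
    """Outcome of one conditional-independence test."""

    r: float            # partial correlation in [-1, 1]
    statistic: float
    p_value: float
    n: int              # sample count
    cond_size: int      # |S|
    independent: bool   # p_value > alpha for the alpha of the call


def partial_correlation(data: np.ndarray, i: int, j: int, S) -> float:
    """Sample partial correlation of columns ``i`` and ``j`` given ``S``.

    Computed by inverting the sample correlation matrix restricted to
    ``{i, j} | S``: with precision matrix ``O``, the partial correlation
    is ``-O_ij / sqrt(O_ii * O_jj)``. Symmetric in ``i`` and ``j``.
    """
    S = sorted(set(S))
    if i == j:
        raise ValueError("i and j must differ")
    if i in S or j in S:
        raise ValueError("i and j must not be in the conditioning set")
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n <= len(S) + 2:
        raise ValueError(
            f"insufficient samples for conditioning set: n={n}, |S|={len(S)}"
        )
    cols = [i, j] + S
    sub = data[:, cols]
    sd = sub.std(axis=0)
    if np.any(sd == 0):
        bad = cols[int(np.nonzero(sd == 0)[0][0])]
        raise ValueError(f"column {bad} has zero variance")
    corr = np.corrcoef(sub, rowvar=False)
    try:
        omega = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        raise DegenerateConditioningError(
            f"degenerate conditioning set: corr submatrix over "
            f"({i}, {j}) | {S} is singular"
        ) from None
    # near-singular matrices invert without error but give garbage
    if not np.all(np.isfinite(omega)) or np.linalg.cond(corr) > 1e12:
        raise DegenerateConditioningError(
            f"degenerate conditioning set: corr submatrix over "
            f"({i}, {j}) | {S} is numerically singular"
        )
    r = -omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1])
    return float(np.clip(r, -1.0, 1.0))


def _clamp_r(r: float) -> float:
    if abs(r) >= 1.0:
        warnings.warn(
            f"|r| = {abs(r)} >= 1; clamping for the z/t transform",
            RuntimeWarning,
            stacklevel=3,
        )
        r = np.sign(r) * (1.0 - 1e-12)
    return float(r)


def fisher_z_test(r: float, n: int, cond_size: int, alpha: float) -> CITestResult:
    """Fisher z-transform test of ``r(i, j | S) = 0``.

    ``z = atanh(r)``; under the null, ``sqrt(n - |S| - 3) * z`` is
    asymptotically standard normal.
    """
    if n - cond_size - 3 <= 0:
        raise ValueError(
            f"insufficient samples for conditioning set: n={n}, |S|={cond_size}"
        )
    r = _clamp_r(r)
    z = 0.5 * np.log((1.0 + r) / (1.0 - r))
    statistic = float(np.sqrt(n - cond_size - 3) * abs(z))
    p = float(2.0 * stats.norm.sf(statistic))
    return CITestResult(r, statistic, min(p, 1.0), n, cond_size,
                        independent=p > alpha)


def t_test_correlation(r: float, n: int, cond_size: int, alpha: float) -> CITestResult:
    """Exact Student t-test of ``r(i, j | S) = 0``.

    ``t = r * sqrt(df / (1 - r^2))`` with ``df = n - |S| - 2`` follows a
    t distribution under the Gaussian null.
    """
    df = n - cond_size - 2
    if df <= 0:
        raise ValueError(
            f"insufficient samples for conditioning set: n={n}, |S|={cond_size}"
        )
    r = _clamp_r(r)
    statistic = float(r * np.sqrt(df / (1.0 - r * r)))
    p = float(2.0 * stats.t.sf(abs(statistic), df))
    return CITestResult(r, statistic, min(p, 1.0), n, cond_size,
                        independent=p > alpha)


_TESTS = {"fisher_z": fisher_z_test, "t": t_test_correlation}


def gaussian_ci_test(data: np.ndarray, i: int, j: int, S,
                     alpha: float = 0.05, method: str = "fisher_z") -> CITestResult:
    """Partial correlation + significance test in one call."""
    try:
        test = _TESTS[method]
    except KeyError:
        raise ValueError(
            f"unknown CI test {method!r}; choose from {sorted(_TESTS)}"
        ) from None
    r = partial_correlation(data, i, j, S)
    return test(r, data.shape[0], len(set(S)), alpha)
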