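"""Two-tailed Pearson correlation test and two-tailed unpaired t-test.

These are the two inferential procedures applied to the derived per-cell /
per-animal quantities. The correlation test uses the t transform
``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` with ``n - 2`` degrees of freedom;
the t-test defaults to the pooled-variance (Student) form, with the Welch
variant available via ``equal_var=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

# Smallest p reported; exact zeros are clamped so downstream log-transforms
# and the "p in (0, 1]" contract both hold.
P_FLOOR = 1e-15


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length 1-D samples.

    Shared by :func:`pearson_test` and the image-colocalization PCC so both
    report numerically identical coefficients on the same vectors.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        raise ValueError("constant input: correlation undefined")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r2: float
    n: int
    t_stat: float
    p_two_tailed: float


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: float
    p_two_tailed: float
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float


def pearson_test(x, y) -> CorrelationResult:
    """Two-tailed test of zero correlation between paired samples.

    Requires n >= 3 and non-constant inputs. Perfect correlation reports the
    floor p-value ``P_FLOOR`` instead of zero.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if n != y.size:
        raise ValueError(f"length mismatch: {n} vs {y.size}")
    if n < 3:
        raise ValueError("need at least 3 pairs")
    r = pearson_r(x, y)
    df = n - 2
    if abs(r) >= 1.0:
        t_stat = np.inf if r > 0 else -np.inf
        p = P_FLOOR
    else:
        t_stat = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
        p = max(2.0 * sps.t.sf(abs(t_stat), df), P_FLOOR)
    return CorrelationResult(r=r, r2=r * r, n=n, t_stat=float(t_stat),
                             p_two_tailed=float(p))


def t_test_unpaired(a, b, equal_var: bool = True) -> TTestResult:
    """Two-tailed unpaired two-sample t-test.

    Student (pooled variance) by default; set ``equal_var=False`` for the
    Welch-Satterthwaite variant.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if equal_var:
        df = na + nb - 2
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    else:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    if se == 0.0:
        t_stat, p = 0.0, 1.0
    else:
        t_stat = (ma - mb) / se
        p = max(2.0 * sps.t.sf(abs(t_stat), df), P_FLOOR)
    return TTestResult(
        t_stat=float(t_stat), df=float(df), p_two_tailed=float(p),
        mean_a=float(ma), mean_b=float(mb),
        sem_a=float(np.sqrt(va / na)), sem_b=float(np.sqrt(vb / nb)),
    )


def correlated_dataset(r2: float, n: int, sign: int = 1,
                       seed: int | None = 0) -> tuple[np.ndarray, np.ndarray]:
    """Construct paired data with an exactly prescribed coefficient of determination.

    ``x = 1..n``; ``y = x + e`` with the residual ``e`` orthogonal to both the
    intercept and ``x`` and scaled so that ``corr(x, y)^2 == r2`` to machine
    precision. Used to reproduce printed (r^2, P) pairs deterministically.
    """
    if not 0.0 < r2 <= 1.0:
        raise ValueError("r2 must be in (0, 1]")
    x = np.arange(1.0, n + 1.0)
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(n)
    # project out span{1, x}
    basis = np.stack([np.ones(n), x - x.mean()], axis=1)
    for col in basis.T:
        e = e - (e @ col) / (col @ col) * col
    var_x = x.var()
    var_e_target = var_x * (1.0 - r2) / r2
    e = e * np.sqrt(var_e_target * n / (e @ e))
    y = x + e
    return x, (y if sign >= 0 else -y)
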