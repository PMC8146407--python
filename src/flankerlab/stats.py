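"""Repeated-measures statistical kernel.

Self-contained implementations of the inferential machinery used throughout
the analysis chain: paired t-tests, mixed-design repeated-measures ANOVA
(up to two within-subject factors and one between-subject factor),
Mauchly's sphericity test, the Greenhouse-Geisser degrees-of-freedom
correction, and Benjamini-Hochberg FDR adjustment.

The ANOVA works on the orthonormal-contrast formulation: for each
within-subject effect an orthonormal contrast matrix ``C`` (rows
orthogonal to the unit vector, ``C C' = I``) maps every subject's cell
vector to contrast scores; sums of squares of the classical univariate
mixed ANOVA are then one-way ANOVA sums of squares of those scores,
accumulated over contrast columns.  Sphericity statistics (Mauchly's W,
Greenhouse-Geisser epsilon) derive from the pooled within-group
covariance of the same contrast scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats as sps

__all__ = [
    "StatResult",
    "paired_t",
    "rm_anova",
    "fdr_adjust",
    "mauchly_test",
    "gg_epsilon",
]


@dataclass
class StatResult:
    """One F- or t-test outcome with its degrees of freedom and p-values.

    ``df`` holds the *uncorrected* (numerator, denominator) degrees of
    freedom; when a Greenhouse-Geisser correction was applied, ``p`` is
    the corrected p-value, ``epsilon`` the scaling factor, and
    ``correction_applied`` is set.  ``p_raw`` always carries the
    uncorrected p-value.  ``p_adjusted`` is filled in later when the
    result enters an FDR family.
    """

    effect: str
    kind: str  # "F" or "t"
    statistic: float
    df: tuple[float, float]
    p_raw: float
    epsilon: float | None = None
    correction_applied: bool = False
    p: float = field(default=np.nan)
    p_adjusted: float | None = None
    mauchly_w: float | None = None
    mauchly_p: float | None = None

    def __post_init__(self) -> None:
        if np.isnan(self.p):
            self.p = self.p_raw

    @property
    def significant(self) -> bool:
        return self.p <= 0.05


def paired_t(x, y, effect: str = "paired") -> StatResult:
    """Two-sided paired t-test on matched sample vectors.

    Zero-variance differences yield ``t = nan`` with ``p = 1`` when the
    mean difference is also zero (flagged through the nan statistic
    otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired_t expects two equal-length 1-D vectors")
    n = x.size
    if n < 2:
        raise ValueError("paired_t needs at least two pairs")
    d = x - y
    md = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if md == 0.0:
            return StatResult(effect, "t", 0.0, (1.0, float(df)), 1.0)
        return StatResult(effect, "t", np.nan, (1.0, float(df)), np.nan)
    t = md / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(effect, "t", float(t), (1.0, float(df)), float(p))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("fdr_adjust expects a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # step-up: cumulative minimum from the largest rank downwards
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1, k) matrix with orthonormal rows, each orthogonal to ones."""
    if k < 2:
        raise ValueError("need at least 2 levels")
    return linalg.helmert(k, full=False)


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from an orthonormal-contrast covariance.

    ``cov`` is the q x q covariance of the contrast scores; epsilon is
    (tr S)^2 / (q tr S^2), bounded to [1/q, 1].
    """
    s = np.asarray(cov, dtype=float)
    q = s.shape[0]
    tr = np.trace(s)
    tr2 = np.trace(s @ s)
    if tr2 <= 0:
        return 1.0
    eps = tr * tr / (q * tr2)
    return float(min(1.0, max(1.0 / q, eps)))


def mauchly_test(cov: np.ndarray, n_error: int) -> tuple[float, float]:
    """Mauchly's sphericity test on an orthonormal-contrast covariance.

    Parameters
    ----------
    cov : (q, q) covariance of the contrast scores.
    n_error : error degrees of freedom the covariance was pooled over
        (number of subjects minus number of groups).

    Returns ``(W, p)`` using the chi-square approximation.  A singular
    covariance returns ``W = 0, p = 0`` by convention.
    """
    s = np.asarray(cov, dtype=float)
    q = s.shape[0]
    if q < 2:
        raise ValueError("sphericity is only testable with >= 3 within levels")
    eigs = np.linalg.eigvalsh(s)
    mean_eig = eigs.mean()
    if np.any(eigs <= 1e-12 * max(mean_eig, 1e-30)) or mean_eig <= 0:
        return 0.0, 0.0
    w = float(np.exp(np.sum(np.log(eigs)) - q * np.log(mean_eig)))
    # Box's chi-square approximation with the second-order series term
    # (as in ezANOVA); q = number of orthonormal contrasts.
    f = 1 - (2 * q * q + q + 2) / (6.0 * q * n_error)
    k = q + 1
    w2 = ((q + 2) * (q - 1) * (q - 2) * (2 * q**3 + 6 * q**2 + 3 * k + 2)
          / (288.0 * (n_error * q * f) ** 2))
    chi2 = -n_error * f * np.log(w)
    df = q * (q + 1) // 2 - 1
    p1 = sps.chi2.sf(chi2, df)
    p2 = sps.chi2.sf(chi2, df + 4)
    p = float(np.clip(p1 + w2 * (p2 - p1), 0.0, 1.0))
    return w, p


def _one_way_ss(z: np.ndarray, group_idx: np.ndarray, n_groups: int):
    """Per-column one-way ANOVA sums of squares of contrast scores.

    Returns (ss_intercept, ss_group, ss_error) summed over columns.
    The intercept term uses unweighted group means (Type-III style),
    which coincides with the classical formula for balanced groups.
    """
    n, _ = z.shape
    counts = np.bincount(group_idx, minlength=n_groups).astype(float)
    gsum = np.zeros((n_groups, z.shape[1]))
    np.add.at(gsum, group_idx, z)
    gmean = gsum / counts[:, None]
    grand_w = z.mean(axis=0)
    grand_u = gmean.mean(axis=0)
    n_h = n_groups / np.sum(1.0 / counts)  # harmonic-mean cell size
    ss_int = float(n_groups * n_h * np.sum(grand_u**2))
    ss_grp = float(np.sum(counts[:, None] * (gmean - grand_w) ** 2))
    ss_err = float(np.sum((z - gmean[group_idx]) ** 2))
    return ss_int, ss_grp, ss_err


def rm_anova(
    values,
    within_names=("within",),
    groups=None,
    group_name: str = "group",
    correction_alpha: float = 0.05,
) -> list[StatResult]:
    """Mixed-design repeated-measures ANOVA.

    Parameters
    ----------
    values : array, shape (n_subjects, k1) or (n_subjects, k1, k2)
        One cell per within-factor level combination; the within design
        must be complete (no NaN).
    within_names : names of the within-subject factors, one per trailing
        axis of ``values``.
    groups : per-subject between-group labels, or None for a single group.
    correction_alpha : Mauchly significance level that triggers the
        Greenhouse-Geisser correction.

    Returns one :class:`StatResult` per effect: the between-group main
    effect (when groups are given), each within main effect, each
    within x group interaction, and — for two within factors — their
    interaction and its interaction with group.  Sphericity is assessed
    per within effect with more than one contrast dimension; when
    Mauchly's test is significant the GG-corrected p is reported.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim == 2:
        y = y[:, :, None]
    if y.ndim != 3:
        raise ValueError("values must be (subjects, k1) or (subjects, k1, k2)")
    if np.isnan(y).any():
        raise ValueError("within design must be complete (found NaN)")
    n, a, b = y.shape
    if len(within_names) != (1 if b == 1 else 2):
        raise ValueError("within_names must match the number of within factors")

    if groups is None:
        group_idx = np.zeros(n, dtype=int)
        n_groups = 1
    else:
        labels, group_idx = np.unique(np.asarray(groups), return_inverse=True)
        n_groups = labels.size
        if np.min(np.bincount(group_idx)) < 2:
            raise ValueError("each group needs at least 2 subjects")
    if n - n_groups < 1:
        raise ValueError("no error degrees of freedom")

    cells = y.reshape(n, a * b)
    results: list[StatResult] = []
    # sums of squares smaller than this are rounding dust, not effects
    scale = max(1.0, float(np.abs(cells).max()))
    ss_tol = np.finfo(float).eps * 100 * n * a * b * scale**2

    def _chop(ss: float) -> float:
        return 0.0 if ss < ss_tol else ss

    # Between-subject effect: one-way ANOVA on subject means.
    z0 = cells.mean(axis=1, keepdims=True) * np.sqrt(a * b)
    _, ss_g, ss_subj = _one_way_ss(z0, group_idx, n_groups)
    ss_g, ss_subj = _chop(ss_g), _chop(ss_subj)
    if n_groups > 1:
        df1, df2 = n_groups - 1, n - n_groups
        ms_subj = ss_subj / df2
        f = (ss_g / df1) / ms_subj if ms_subj > 0 else (0.0 if ss_g == 0 else np.inf)
        p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        results.append(
            StatResult(group_name, "F", float(f), (float(df1), float(df2)), p)
        )

    u_a = np.full((1, a), 1.0 / np.sqrt(a))
    u_b = np.full((1, b), 1.0 / np.sqrt(b))
    h_a = _orthonormal_contrasts(a)
    effects = [(within_names[0], np.kron(h_a, u_b))]
    if b > 1:
        h_b = _orthonormal_contrasts(b)
        effects.append((within_names[1], np.kron(u_a, h_b)))
        effects.append((f"{within_names[0]} * {within_names[1]}",
                        np.kron(h_a, h_b)))

    n_err = n - n_groups
    for name, c in effects:
        z = cells @ c.T
        q = z.shape[1]
        ss_w, ss_wg, ss_err = map(_chop, _one_way_ss(z, group_idx, n_groups))
        # pooled within-group covariance of the contrast scores
        gmean = np.zeros((n_groups, q))
        np.add.at(gmean, group_idx, z)
        gmean /= np.bincount(group_idx, minlength=n_groups)[:, None].astype(float)
        resid = z - gmean[group_idx]
        cov = resid.T @ resid / n_err

        eps = w = mp = None
        if q > 1:
            eps = gg_epsilon(cov)
            w, mp = mauchly_test(cov, n_err)
        correct = q > 1 and mp is not None and mp <= correction_alpha

        sub_effects = [(name, ss_w, q)]
        if n_groups > 1:
            sub_effects.append((f"{name} * {group_name}", ss_wg, q * (n_groups - 1)))
        df2 = q * n_err
        ms_err = ss_err / df2
        for ename, ss, df1 in sub_effects:
            f = (ss / df1) / ms_err if ms_err > 0 else (0.0 if ss == 0 else np.inf)
            p_raw = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
            res = StatResult(ename, "F", float(f), (float(df1), float(df2)),
                             p_raw, epsilon=eps, mauchly_w=w, mauchly_p=mp)
            if correct and np.isfinite(f):
                res.correction_applied = True
                res.p = float(sps.f.sf(f, eps * df1, eps * df2))
            results.append(res)
    return results
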