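"""Core 1-D scoring: activated vs inhibited gene signal comparison.

The central idea: treat the signature's activated and inhibited genes as
replicate observations drawn from two populations of signal values, and
ask whether the activated population sits higher than the inhibited one.
Three two-sample statistics are offered:

``t``
    Two-sample t statistic (Welch by default, pooled-variance
    optional), activated minus inhibited, two-sided p.
``mwu``
    Mann-Whitney U, reported as the tie- and continuity-corrected
    normal-approximation z so all methods share a signed,
    location-oriented scale; two-sided p.
``ks``
    Kolmogorov-Smirnov D, signed by the direction of the location shift
    (median difference, falling back to mean difference); two-sided p.

Sign convention throughout: **positive statistic = activation** (the
activated genes carry higher signal than the inhibited genes).

Statistics are computed from explicit formulas here; the scipy
equivalents serve as independent cross-checks in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from math import comb

from scipy import special, stats

from bdfunc.signatures import BidirectionalSignature

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentScore",
    "EnrichmentTable",
    "InsufficientOverlapError",
    "make_profile",
    "match_signature",
    "score_bidirectional",
    "enrich_profile",
    "fdr_adjust",
    "storey_pi0",
    "preprocess_rpkm",
]

METHODS = ("t", "mwu", "ks")
T_FLAVORS = ("welch", "pooled")
FDR_METHODS = ("bh", "storey")


class InsufficientOverlapError(ValueError):
    """Too few signature genes found in the profile on one side."""

    def __init__(self, signature: str, n_activated: int, n_inhibited: int, min_per_side: int):
        self.signature = signature
        self.n_activated = n_activated
        self.n_inhibited = n_inhibited
        self.min_per_side = min_per_side
        super().__init__(
            f"signature {signature!r}: insufficient overlap with profile "
            f"({n_activated} activated, {n_inhibited} inhibited matched; "
            f"need >= {min_per_side} per side)"
        )


def make_profile(
    values: Mapping[str, float] | pd.Series,
    label: str | None = None,
) -> pd.Series:
    """Build a signal profile: float Series keyed by upper-cased gene symbol.

    Non-finite values are dropped (count logged); duplicate symbols keep
    the first occurrence.
    """
    s = pd.Series(values, dtype=float)
    s.index = s.index.astype(str).str.strip().str.upper()
    s = s[~s.index.duplicated(keep="first")]
    n_bad = int((~np.isfinite(s.to_numpy())).sum())
    if n_bad:
        logger.warning("profile %s: dropped %d non-finite value(s)", label or "", n_bad)
        s = s[np.isfinite(s)]
    s.name = label
    return s


@dataclass(frozen=True)
class EnrichmentScore:
    """Result of one activation-vs-inhibition comparison."""

    signature: str
    method: str
    statistic: float
    p_value: float
    n_activated_matched: int
    n_inhibited_matched: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class EnrichmentTable:
    """Per-signature enrichment scores for one profile, with q-values."""

    scores: pd.DataFrame  # signature, method, statistic, p_value, q_value, n_*, flags
    skipped: tuple[tuple[str, str], ...]  # (signature name, reason)
    fdr_method: str
    profile_label: str | None = None


def match_signature(
    sig: BidirectionalSignature,
    profile: pd.Series,
    min_per_side: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Look up each signature gene in the profile (case-insensitively).

    Returns the arrays of signal values for matched activated and
    inhibited genes; raises :class:`InsufficientOverlapError` when
    either side matches fewer than *min_per_side* genes.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    act = profile.reindex(sig.activated).dropna().to_numpy(dtype=float)
    inh = profile.reindex(sig.inhibited).dropna().to_numpy(dtype=float)
    if len(act) < min_per_side or len(inh) < min_per_side:
        raise InsufficientOverlapError(sig.name, len(act), len(inh), min_per_side)
    return act, inh


# --------------------------------------------------------------------------
# two-sample statistics

def _t_score(act: np.ndarray, inh: np.ndarray, flavor: str) -> tuple[float, float]:
    n1, n2 = len(act), len(inh)
    m1, m2 = act.mean(), inh.mean()
    v1 = act.var(ddof=1)
    v2 = inh.var(ddof=1)
    if flavor == "welch":
        se2 = v1 / n1 + v2 / n2
        if se2 == 0.0:
            return (np.nan, np.nan)
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    elif flavor == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        if sp2 == 0.0:
            return (np.nan, np.nan)
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    else:
        raise ValueError(f"unknown t flavor {flavor!r}")
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def _mwu_score(act: np.ndarray, inh: np.ndarray) -> tuple[float, float]:
    """Signed z for the Mann-Whitney U test (midranks, tie-corrected
    variance, continuity correction), two-sided normal p."""
    n1, n2 = len(act), len(inh)
    pooled = np.concatenate([act, inh])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    if var <= 0.0:  # every pooled value identical
        return 0.0, 1.0
    diff = u1 - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def _ks_exact_sf(c_int: int, n1: int, n2: int) -> float:
    """Exact P(D >= c_int/(n1*n2)) for the two-sample KS statistic.

    Counts monotone lattice paths from (0,0) to (n1,n2) whose ECDF
    difference stays strictly below the observed one; the complement of
    their fraction among all C(n1+n2, n1) paths is the p-value.  The
    bound is held in integers (|i*n2 - j*n1| < c_int), so no floating
    tolerance enters the path condition.
    """
    ways = np.zeros(n2 + 1)
    ways[0] = 1.0
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            if abs(i * n2 - j * n1) >= c_int:
                ways[j] = 0.0
            elif j > 0:
                if i == 0:
                    ways[j] = ways[j - 1]
                else:
                    ways[j] += ways[j - 1]
    return float(min(max(1.0 - ways[n2] / comb(n1 + n2, n1), 0.0), 1.0))


def _ks_score(act: np.ndarray, inh: np.ndarray) -> tuple[float, float]:
    """KS D signed by direction of location shift, two-sided p.

    D is computed from the empirical CDFs on an integer grid.  The
    p-value is exact (path counting) for small tie-free samples
    (n1*n2 < 10000), otherwise the Kolmogorov asymptotic distribution
    evaluated at sqrt(n1*n2/(n1+n2)) * D.
    """
    n1, n2 = len(act), len(inh)
    all_vals = np.concatenate([act, inh])
    # c_int = n1*n2*D, exactly, in integers
    counts1 = np.searchsorted(np.sort(act), all_vals, side="right")
    counts2 = np.searchsorted(np.sort(inh), all_vals, side="right")
    c_int = int(np.abs(counts1 * n2 - counts2 * n1).max())
    d = c_int / (n1 * n2)
    has_ties = np.unique(all_vals).size < n1 + n2
    if not has_ties and n1 * n2 < 10000:
        p = _ks_exact_sf(c_int, n1, n2)
    else:
        en = np.sqrt(n1 * n2 / (n1 + n2))
        p = float(stats.kstwobign.sf(en * d))
    sign = np.sign(np.median(act) - np.median(inh))
    if sign == 0:
        sign = np.sign(act.mean() - inh.mean())
    return float(sign * d), min(p, 1.0)


def score_bidirectional(
    activated: Sequence[float] | np.ndarray,
    inhibited: Sequence[float] | np.ndarray,
    method: str = "t",
    t_flavor: str = "welch",
    signature: str = "",
) -> EnrichmentScore:
    """Compare activated vs inhibited signal values with a two-sample test.

    Positive statistic means the activated genes carry higher signal.
    Degenerate inputs (zero variance on both sides) never produce
    infinite statistics: equal constants give (0, 1); unequal constants
    fall back to the Mann-Whitney z with a ``degenerate_variance`` flag
    so downstream ANOVA/ROC see finite scores.
    """
    act = np.asarray(activated, dtype=float)
    inh = np.asarray(inhibited, dtype=float)
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    min_n = 2 if method == "t" else 1
    if len(act) < min_n or len(inh) < min_n:
        raise ValueError(
            f"method {method!r} needs at least {min_n} value(s) per side "
            f"(got {len(act)}, {len(inh)})"
        )
    flags: tuple[str, ...] = ()
    if method == "t":
        statistic, p = _t_score(act, inh, t_flavor)
        if np.isnan(statistic):  # zero variance on both sides
            if act.mean() == inh.mean():
                statistic, p = 0.0, 1.0
            else:
                statistic, p = _mwu_score(act, inh)
            flags = ("degenerate_variance",)
    elif method == "mwu":
        statistic, p = _mwu_score(act, inh)
    else:
        statistic, p = _ks_score(act, inh)
    return EnrichmentScore(
        signature=signature,
        method=method,
        statistic=statistic,
        p_value=p,
        n_activated_matched=len(act),
        n_inhibited_matched=len(inh),
        flags=flags,
    )


# --------------------------------------------------------------------------
# multiple-testing correction

def fdr_adjust(p_values: Sequence[float] | np.ndarray, method: str = "bh") -> np.ndarray:
    """Adjust p-values for multiple testing across signatures.

    ``bh`` is the Benjamini-Hochberg step-up adjustment; ``storey``
    the pi0-adjusted q-value (pi0 estimated on a lambda grid with a
    cubic smoother, clipped to (0, 1]).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return _bh_adjust(p)
    if method == "storey":
        return storey_pi0(p) * _bh_adjust(p)
    raise ValueError(f"unknown FDR method {method!r}; choose from {FDR_METHODS}")


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # step-up: running minimum from the largest p down
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def storey_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Estimate the null proportion pi0 from a p-value distribution.

    Uses the lambda-grid estimator pi0(lambda) = #{p > lambda} /
    (m (1 - lambda)) on lambda = 0.05, 0.10, ..., 0.95, smoothed with a
    cubic polynomial and evaluated at the largest lambda; the result is
    clipped to (0, 1].  With fewer than 20 p-values the conservative
    pi0 = 1 is returned (the smoother is unstable at tiny m).
    """
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    if m < 20:
        return 1.0
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coeffs = np.polynomial.polynomial.polyfit(lambdas, pi0_lambda, 3)
    pi0 = float(np.polynomial.polynomial.polyval(lambdas[-1], coeffs))
    return float(min(max(pi0, 1.0 / m), 1.0))


# --------------------------------------------------------------------------
# profile-level enrichment

def enrich_profile(
    profile: pd.Series,
    sigs: Sequence[BidirectionalSignature],
    method: str = "t",
    fdr_method: str = "bh",
    min_per_side: int = 3,
    t_flavor: str = "welch",
) -> EnrichmentTable:
    """Score every signature against one signal profile (1-D mode).

    Signatures with insufficient gene overlap are reported in
    ``skipped`` with the reason; q-values are computed over the
    scoreable rows only.  Raises if no signature can be scored.
    """
    rows = []
    skipped: list[tuple[str, str]] = []
    for sig in sigs:
        try:
            act, inh = match_signature(sig, profile, min_per_side=min_per_side)
        except InsufficientOverlapError as exc:
            skipped.append((sig.name, str(exc)))
            continue
        score = score_bidirectional(act, inh, method=method, t_flavor=t_flavor,
                                    signature=sig.name)
        rows.append(score)
    if not rows:
        raise InsufficientOverlapError(
            "<all>", 0, 0, min_per_side
        )
    df = pd.DataFrame(
        {
            "signature": [r.signature for r in rows],
            "method": [r.method for r in rows],
            "statistic": [r.statistic for r in rows],
            "p_value": [r.p_value for r in rows],
            "q_value": fdr_adjust([r.p_value for r in rows], method=fdr_method),
            "n_activated_matched": [r.n_activated_matched for r in rows],
            "n_inhibited_matched": [r.n_inhibited_matched for r in rows],
            "flags": [";".join(r.flags) for r in rows],
        }
    )
    return EnrichmentTable(
        scores=df,
        skipped=tuple(skipped),
        fdr_method=fdr_method,
        profile_label=str(profile.name) if profile.name is not None else None,
    )


def preprocess_rpkm(values: Sequence[float] | np.ndarray | pd.Series):
    """log2(RPKM + 0.1): the standard variance-stabilizing transform for
    RPKM expression values (the +0.1 offset tames low-coverage genes)."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("RPKM values must be nonnegative")
    out = np.log2(arr + 0.1)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out
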