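"""Validation of predicted modules against reference complex catalogs.

Three levels of precision/recall are computed:

* per module (tp/fp/fn of the member set against one complex),
* per interactome class (primed quantities: P' = MM/PM over significantly
  matched vs predicted modules, R' = MC/KC over well-matched vs detected
  complexes, with a 0.5 matching-frequency threshold),
* per protein (unions of module members vs unions of complex members).

The matching frequency of a module against a complex is the fraction of the
complex covered by the module; a complex is deemed well matched at >= 0.5.

Module-size distributions are summarized by a discrete power-law fit
(maximum-likelihood scaling exponent with the lower cutoff chosen by
Kolmogorov–Smirnov minimization over the tail).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, special

from .netio import Module


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention of printed result tables
    (0.875 -> 0.88)."""
    factor = 10**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class MatchCounts:
    """tp/fp/fn bookkeeping with derived precision and recall.

    Ratios with zero denominators are reported as None.
    """

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> Optional[float]:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None

    @property
    def recall(self) -> Optional[float]:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None


@dataclass(frozen=True)
class ClassSummary:
    """Per-class (primed) precision/recall bookkeeping.

    MM — modules whose best matching frequency reaches the threshold;
    PM — predicted modules; MC — summed per-module mean qualifying
    frequency; KC — complexes detected with nonzero frequency.
    """

    MM: int
    PM: int
    MC: float
    KC: int

    @property
    def precision_prime(self) -> Optional[float]:
        return self.MM / self.PM if self.PM else None

    @property
    def recall_prime(self) -> Optional[float]:
        return self.MC / self.KC if self.KC else None


@dataclass(frozen=True)
class PowerLawFit:
    """Discrete power-law tail fit p(x) ~ x^-alpha for x >= x_min."""

    alpha: float
    x_min: int
    ks_distance: float


def match_frequency(module: Module, complex_members: Iterable[str]) -> float:
    """Fraction of the complex covered by the module: |M ∩ C| / |C|."""
    c = set(complex_members)
    if not c:
        raise ValueError("empty complex")
    return len(module.members & c) / len(c)


def module_pr(module: Module, complex_members: Iterable[str]) -> MatchCounts:
    """Per-module precision/recall against one complex.

    tp = members in the complex, fp = members outside it, fn = complex
    proteins missed.
    """
    c = set(complex_members)
    if not c:
        raise ValueError("empty complex")
    if not module.members:
        raise ValueError("empty module")
    inter = len(module.members & c)
    return MatchCounts(
        tp=inter, fp=len(module.members) - inter, fn=len(c) - inter
    )


def best_matching_complex(
    module: Module, complexes: Mapping[str, Iterable[str]]
) -> Optional[tuple[str, float]]:
    """The complex with the best matching frequency for this module.

    Ties broken by larger intersection, then lexicographic complex name.
    Returns None when every frequency is zero.
    """
    best: Optional[tuple[str, float, int]] = None
    for name in sorted(complexes):
        c = set(complexes[name])
        if not c:
            continue
        freq = len(module.members & c) / len(c)
        inter = len(module.members & c)
        if freq == 0:
            continue
        if best is None or freq > best[1] or (freq == best[1] and inter > best[2]):
            best = (name, freq, inter)
    if best is None:
        return None
    return best[0], best[1]


def class_pr(
    modules: Sequence[Module],
    complexes: Mapping[str, Iterable[str]],
    freq_threshold: float = 0.5,
) -> ClassSummary:
    """Primed precision/recall for one (method, class) module collection.

    Each module is assigned its best-frequency complex.  MM counts modules
    whose best frequency reaches the threshold, PM is the module count, KC
    counts complexes attaining nonzero frequency against any module, and MC
    sums each module's mean qualifying (>= threshold) frequency.
    """
    if not modules:
        raise ValueError("class_pr requires at least one module")
    catalog = {name: set(members) for name, members in complexes.items()}
    if not catalog:
        raise ValueError("empty complex catalog")
    mm = 0
    mc = 0.0
    detected: set[str] = set()
    for module in modules:
        qualifying: list[float] = []
        best = 0.0
        for name, c in catalog.items():
            if not c:
                continue
            freq = len(module.members & c) / len(c)
            if freq > 0:
                detected.add(name)
            if freq >= freq_threshold:
                qualifying.append(freq)
            best = max(best, freq)
        if best >= freq_threshold:
            mm += 1
        if qualifying:
            mc += float(np.mean(qualifying))
    return ClassSummary(MM=mm, PM=len(modules), MC=mc, KC=len(detected))


def class_precision_or_zero(
    modules: Sequence[Module],
    complexes: Mapping[str, Iterable[str]],
    freq_threshold: float = 0.5,
) -> float:
    """P' with the convention that a class yielding no modules scores 0."""
    if not modules:
        return 0.0
    summary = class_pr(modules, complexes, freq_threshold)
    return summary.precision_prime or 0.0


def protein_pr(
    modules: Sequence[Module], complexes: Mapping[str, Iterable[str]]
) -> MatchCounts:
    """Protein-wise precision/recall: union of module members vs union of
    complex members.  tp = predicted proteins found in complexes, fp =
    predicted proteins absent from every complex, fn = complex proteins never
    predicted."""
    predicted: set[str] = set()
    for m in modules:
        predicted |= m.members
    known: set[str] = set()
    for members in complexes.values():
        known |= set(members)
    inter = len(predicted & known)
    return MatchCounts(
        tp=inter, fp=len(predicted) - inter, fn=len(known) - inter
    )


# ---------------------------------------------------------------------------
# Power-law fitting


def _discrete_alpha_mle(tail: np.ndarray, x_min: int) -> float:
    """Maximum-likelihood scaling exponent for a discrete power-law tail."""
    n = tail.size
    slog = float(np.log(tail).sum())

    def neg_loglik(alpha: float) -> float:
        return n * math.log(special.zeta(alpha, x_min)) + alpha * slog / 1.0

    res = optimize.minimize_scalar(
        neg_loglik, bounds=(1.000001, 10.0), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def _ks_distance(tail: np.ndarray, alpha: float, x_min: int) -> float:
    """KS distance between the empirical and fitted tail survival functions."""
    xs = np.unique(tail)
    z = special.zeta(alpha, x_min)
    # model survival P(X >= x) = zeta(alpha, x) / zeta(alpha, x_min)
    model = special.zeta(alpha, xs) / z
    ranks = np.searchsorted(np.sort(tail), xs, side="left")
    empirical = 1.0 - ranks / tail.size
    return float(np.max(np.abs(empirical - model)))


def fit_power_law(sizes: Iterable[int], min_tail: int = 10) -> PowerLawFit:
    """Fit p(x) ~ x^-alpha to a multiset of integer sizes >= 1.

    The exponent is the discrete maximum-likelihood estimate for the tail
    x >= x_min, with x_min chosen to minimize the Kolmogorov–Smirnov distance
    between the empirical and fitted tail distributions (only candidates with
    at least ``min_tail`` tail observations are considered).  Raises on
    degenerate input (fewer than two distinct values or too few
    observations).
    """
    xs = np.asarray(sorted(sizes), dtype=float)
    if xs.size == 0 or xs.min() < 1:
        raise ValueError("sizes must be positive integers")
    uniq = np.unique(xs)
    if uniq.size < 2:
        raise ValueError("degenerate sample: all sizes equal")
    if xs.size < min_tail:
        raise ValueError(f"need at least {min_tail} observations")

    best: Optional[PowerLawFit] = None
    for x_min in uniq[:-1]:
        tail = xs[xs >= x_min]
        if tail.size < min_tail or np.unique(tail).size < 2:
            continue
        alpha = _discrete_alpha_mle(tail, int(x_min))
        ks = _ks_distance(tail, alpha, int(x_min))
        if best is None or ks < best.ks_distance:
            best = PowerLawFit(alpha=alpha, x_min=int(x_min), ks_distance=ks)
    if best is None:
        raise ValueError("no admissible x_min candidate")
    return best


def sample_power_law(
    n: int, alpha: float, x_min: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact sampler for the discrete power law p(x) ~ x^-alpha, x >= x_min.

    Draws from the Zipf distribution and keeps values >= x_min (conditioning
    preserves the power-law form on the tail).
    """
    out: list[int] = []
    while len(out) < n:
        draw = rng.zipf(alpha, size=max(4 * (n - len(out)), 1000))
        out.extend(int(v) for v in draw[draw >= x_min])
    return np.asarray(out[:n], dtype=int)
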