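"""MS1-level pattern detection: homolog series, sodium adducts, neutral losses.

A homolog series is a chain of peaks whose consecutive gaps all equal a fixed
spacing (CH2 = 14.01565 Da for fatty-acyl homologs) within tolerance. Chains
are reported maximal: no reported series is a contiguous sub-chain of another.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import NamedTuple, Sequence

from .exceptions import DomainError
from .masses import CH2_MASS, SODIUM_MINUS_HYDROGEN
from .spectra import Spectrum


@dataclass(frozen=True)
class HomologSeries:
    """A maximal chain of peaks with near-constant spacing.

    ``spacing`` is the fitted (mean) gap of the chain; ``per_step_errors``
    are the signed deviations of each gap from the nominal spacing.
    """

    member_mzs: tuple[float, ...]
    spacing: float
    per_step_errors: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.member_mzs)


class AdductPair(NamedTuple):
    """A protonated/sodiated peak pair; error is signed vs the Na-H offset."""

    protonated_mz: float
    sodiated_mz: float
    error: float


class NeutralLossMatch(NamedTuple):
    """A matched neutral-loss peak; error is signed (found - expected)."""

    mz: float
    error: float


def _as_mzs(spectrum: Spectrum | Sequence[float]) -> list[float]:
    if isinstance(spectrum, Spectrum):
        return sorted(spectrum.mzs)
    return sorted(float(m) for m in spectrum)


def detect_homolog_series(
    spectrum: Spectrum | Sequence[float],
    spacing: float = CH2_MASS,
    tol: float = 0.1,
    min_length: int = 3,
) -> list[HomologSeries]:
    """Find all maximal chains of peaks spaced ``spacing`` +/- ``tol`` apart.

    The result is independent of input peak order. Chains shorter than
    ``min_length`` are dropped, and no reported chain is a contiguous
    sub-chain of another (ties between overlapping readings are resolved
    toward the longer chain by maximality).
    """
    if not spacing > 0 or not tol > 0:
        raise DomainError("spacing and tol must be positive")
    if min_length < 2:
        raise DomainError("min_length must be at least 2")
    mzs = _as_mzs(spectrum)
    n = len(mzs)
    succ: list[list[int]] = [[] for _ in range(n)]
    has_pred = [False] * n
    for i in range(n):
        for j in range(i + 1, n):
            gap = mzs[j] - mzs[i]
            if gap > spacing + tol:
                break
            if abs(gap - spacing) <= tol:
                succ[i].append(j)
                has_pred[j] = True

    chains: list[tuple[float, ...]] = []

    def extend(path: list[int]) -> None:
        nexts = succ[path[-1]]
        if not nexts:
            chains.append(tuple(mzs[k] for k in path))
            return
        for j in nexts:
            extend(path + [j])

    for i in range(n):
        if not has_pred[i] and succ[i]:
            extend([i])

    # Drop chains shorter than min_length and contiguous sub-chains.
    chains = [c for c in chains if len(c) >= min_length]
    kept: list[tuple[float, ...]] = []
    for c in sorted(set(chains), key=lambda c: (-len(c), c)):
        if not any(_is_contiguous_subchain(c, k) for k in kept):
            kept.append(c)
    out = []
    for c in sorted(kept, key=lambda c: (c[0], len(c))):
        gaps = [b - a for a, b in zip(c, c[1:])]
        out.append(
            HomologSeries(
                member_mzs=c,
                spacing=fmean(gaps),
                per_step_errors=tuple(g - spacing for g in gaps),
            )
        )
    return out


def _is_contiguous_subchain(short: tuple[float, ...], long: tuple[float, ...]) -> bool:
    if len(short) > len(long):
        return False
    for start in range(len(long) - len(short) + 1):
        if long[start : start + len(short)] == short:
            return True
    return False


def pair_sodium_adducts(
    series: HomologSeries,
    spectrum: Spectrum | Sequence[float],
    tol: float = 0.5,
    offset: float = SODIUM_MINUS_HYDROGEN,
) -> list[AdductPair]:
    """For each series member, find its [M+Na]+ partner ``offset`` Da above.

    An absent partner simply yields no pair; errors are signed deviations of
    (sodiated - protonated) from the Na-H offset.
    """
    if not tol > 0:
        raise DomainError("tol must be positive")
    mzs = _as_mzs(spectrum)
    pairs = []
    for m in series.member_mzs:
        target = m + offset
        candidates = [x for x in mzs if abs(x - target) <= tol]
        if candidates:
            best = min(candidates, key=lambda x: (abs(x - target), x))
            pairs.append(AdductPair(m, best, best - target + 0.0))
    return pairs


def find_neutral_loss(
    spectrum: Spectrum | Sequence[float],
    reference_mz: float,
    loss: float,
    tol: float = 0.75,
) -> NeutralLossMatch | None:
    """Find the peak closest to ``reference_mz - loss`` within ``tol``.

    Returns the matched peak with its signed error, or ``None``.
    """
    if not loss > 0 or not tol > 0:
        raise DomainError("loss and tol must be positive")
    mzs = _as_mzs(spectrum)
    if not mzs:
        return None
    target = reference_mz - loss
    best = min(mzs, key=lambda x: (abs(x - target), x))
    if abs(best - target) > tol:
        return None
    return NeutralLossMatch(best, best - target)
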