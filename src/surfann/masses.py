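"""Mass constants and mass-matching arithmetic.

Single source of truth for every mass used by the pipeline: monoisotopic
amino-acid residue masses, the homologous series law for the beta-hydroxy
fatty-acyl moiety, and adduct/neutral-loss offsets.

All masses are monoisotopic and in daltons. The instrument data this package
targets is unit-resolution, so matching tolerances are wide (fractions of a
dalton) and isobaric or near-isobaric residues are merged or co-reported:

* Leu and Ile (identical residue mass 113.08406) are reported as the single
  merged candidate ``"Leu/Ile"``;
* Gln and Lys differ by only 0.036 Da, far below the working tolerance, so
  whenever either matches the other is co-reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

from .exceptions import DomainError, UnknownResidueError

# Fundamental monoisotopic constants (Da)
PROTON_MASS = 1.00727646688
H_MASS = 1.00782503207
O_MASS = 15.9949146196
NA_MASS = 22.9897692809
CH2_MASS = 14.01565006
WATER_MASS = 2 * H_MASS + O_MASS  # 18.010565
SODIUM_MINUS_HYDROGEN = NA_MASS - H_MASS  # 21.981944

#: Residue groups indistinguishable at the working mass accuracy.
DEFAULT_AMBIGUITY_GROUPS: tuple[frozenset[str], ...] = (
    frozenset({"Leu", "Ile"}),
)
#: Near-isobaric groups that are co-reported (not merged) when either matches.
DEFAULT_COREPORT_GROUPS: tuple[frozenset[str], ...] = (
    frozenset({"Gln", "Lys"}),
)


class ResidueMatch(NamedTuple):
    """One candidate from :meth:`ResidueMassTable.match`.

    ``error`` is the absolute deviation |delta - residue mass| in Da.
    """

    symbol: str
    error: float


def _merged_label(group: Iterable[str]) -> str:
    # Reverse-alphabetical puts Leu before Ile, matching the field's "Leu/Ile".
    return "/".join(sorted(group, reverse=True))


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic residue masses with isobaric merging.

    Parameters
    ----------
    entries
        Mapping from 3-letter residue symbol to residue mass in Da.
    ambiguity_groups
        Groups of symbols with equal mass, reported as one merged candidate
        (label ``"A/B"``, members sorted alphabetically).
    coreport_groups
        Groups of near-isobaric symbols that are always co-reported: when any
        member falls inside the matching tolerance, every member appears in
        the candidate set (with its own true error).
    """

    entries: dict[str, float]
    ambiguity_groups: tuple[frozenset[str], ...] = DEFAULT_AMBIGUITY_GROUPS
    coreport_groups: tuple[frozenset[str], ...] = DEFAULT_COREPORT_GROUPS
    _labels: dict[str, float] = field(init=False, repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        for sym, mass in self.entries.items():
            if not mass > 0:
                raise DomainError(f"residue mass for {sym!r} must be positive, got {mass}")
        for group in self.ambiguity_groups:
            masses = {self.entries[s] for s in group if s in self.entries}
            if len(masses) > 1:
                raise DomainError(
                    f"ambiguity group {sorted(group)} members have unequal masses {sorted(masses)}"
                )
        # Reporting labels: merge each ambiguity group into one label.
        labels: dict[str, float] = {}
        merged: set[str] = set()
        for group in self.ambiguity_groups:
            present = [s for s in group if s in self.entries]
            if present:
                labels[_merged_label(group)] = self.entries[present[0]]
                merged.update(present)
        for sym, mass in self.entries.items():
            if sym not in merged:
                labels[sym] = mass
        object.__setattr__(self, "_labels", labels)

    # -- construction -----------------------------------------------------
    @classmethod
    def default(cls) -> "ResidueMassTable":
        """The shipped 20-symbol (19 distinct masses) proteinogenic table."""
        with resources.files("surfann.data").joinpath("residue_masses.tsv").open() as fh:
            return cls._parse(fh)

    @classmethod
    def from_file(cls, path: str | Path) -> "ResidueMassTable":
        """Load a plain-text ``symbol<TAB>mass`` table ('#' starts a comment)."""
        with open(path) as fh:
            return cls._parse(fh)

    @classmethod
    def _parse(cls, fh) -> "ResidueMassTable":
        entries: dict[str, float] = {}
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            sym, value = line.split()
            entries[sym] = float(value)
        return cls(entries=entries)

    # -- queries ----------------------------------------------------------
    def mass(self, symbol: str) -> float:
        """Residue mass for a 3-letter symbol or a merged label like "Leu/Ile"."""
        if symbol in self.entries:
            return self.entries[symbol]
        if symbol in self._labels:
            return self._labels[symbol]
        raise UnknownResidueError(symbol)

    @property
    def labels(self) -> dict[str, float]:
        """Reporting labels (ambiguity groups merged) to masses."""
        return dict(self._labels)

    def label_for(self, symbol: str) -> str:
        """The reporting label a symbol appears under (e.g. Ile -> "Leu/Ile")."""
        for group in self.ambiguity_groups:
            if symbol in group:
                return _merged_label(group)
        if symbol not in self.entries and symbol not in self._labels:
            raise UnknownResidueError(symbol)
        return symbol

    def match(self, delta: float, tol: float) -> list[ResidueMatch]:
        """All residues whose mass lies within ``tol`` of ``delta``.

        Candidates are reporting labels (Leu/Ile merged, so it appears at most
        once), sorted by absolute error then label. Co-reported groups
        (Gln/Lys) are completed: if any member matches, all members are
        returned. An empty list is a valid result.
        """
        if not delta > 0:
            raise DomainError(f"delta must be positive, got {delta}")
        if not tol > 0:
            raise DomainError(f"tol must be positive, got {tol}")
        hits = {
            label: abs(delta - mass)
            for label, mass in self._labels.items()
            if abs(delta - mass) <= tol
        }
        for group in self.coreport_groups:
            labels = {self.label_for(s) for s in group if s in self.entries}
            if labels & hits.keys():
                for label in labels:
                    hits.setdefault(label, abs(delta - self._labels[label]))
        return sorted(
            (ResidueMatch(label, err) for label, err in hits.items()),
            key=lambda m: (m.error, m.symbol),
        )


class ChainMatch(NamedTuple):
    """Result of inverting the lipid mass law: carbon count and signed error."""

    n: int
    error: float


@dataclass(frozen=True)
class LipidSeries:
    """Mass law of the beta-hydroxy fatty-acyl moiety inside the lactone.

    ``lipid_mass(n) = delta_ch2 * n + offset`` for carbon count ``n``.

    The default calibration treats the acyl moiety as CnH(2n-2)O2, i.e. the
    beta-hydroxy fatty acid as it exists inside the closed ring (both the
    carboxyl->amide and the beta-OH->ester condensations have already spent
    their water). With this law, proton + lipid_mass(n) + sum(residue masses)
    reproduces the observed protonated surfactin precursors to within 0.7 Da.
    """

    delta_ch2: float = CH2_MASS
    offset: float = 2 * O_MASS - 2 * H_MASS  # CnH(2n-2)O2 = n*CH2 + O2 - H2
    n_min: int = 8
    n_max: int = 20

    def __post_init__(self) -> None:
        if not self.delta_ch2 > 0:
            raise DomainError("delta_ch2 must be positive")
        if self.n_min > self.n_max:
            raise DomainError("n_min must not exceed n_max")

    def lipid_mass(self, n: int) -> float:
        """Mass (Da) of the Cn acyl moiety; ``n`` must lie in [n_min, n_max]."""
        if not (self.n_min <= n <= self.n_max):
            raise DomainError(
                f"carbon count {n} outside admissible range [{self.n_min}, {self.n_max}]"
            )
        return self.delta_ch2 * n + self.offset

    def chain_length_from_mass(self, residual: float, tol: float) -> ChainMatch | None:
        """Invert the mass law: nearest carbon count, or None beyond ``tol``.

        Returns ``(n, residual - lipid_mass(n))`` for the in-range ``n``
        minimising the absolute error; ``None`` when that error exceeds
        ``tol`` (a no-match is a valid result, not an error).
        """
        if not residual > 0:
            raise DomainError(f"residual must be positive, got {residual}")
        if not tol > 0:
            raise DomainError(f"tol must be positive, got {tol}")
        n_star = round((residual - self.offset) / self.delta_ch2)
        n_star = min(max(int(n_star), self.n_min), self.n_max)
        best = min(
            (n for n in (n_star - 1, n_star, n_star + 1) if self.n_min <= n <= self.n_max),
            key=lambda n: abs(residual - self.lipid_mass(n)),
        )
        error = residual - self.lipid_mass(best)
        if abs(error) > tol:
            return None
        return ChainMatch(best, error)


@dataclass(frozen=True)
class AdductTable:
    """Adduct and neutral-loss offsets used in MS1/MS2 peak pairing."""

    proton_mass: float = PROTON_MASS
    sodium_minus_hydrogen: float = SODIUM_MINUS_HYDROGEN
    water_mass: float = WATER_MASS

    def __post_init__(self) -> None:
        if min(self.proton_mass, self.sodium_minus_hydrogen, self.water_mass) <= 0:
            raise DomainError("adduct constants must be positive")
        if not math.isclose(self.sodium_minus_hydrogen, 21.98, abs_tol=0.01):
            raise DomainError("sodium_minus_hydrogen must be ~21.98 Da")
        if not math.isclose(self.water_mass, 18.01, abs_tol=0.01):
            raise DomainError("water_mass must be ~18.01 Da")


# -- module-level conveniences over the default table ----------------------
_DEFAULT_TABLE: ResidueMassTable | None = None


def default_table() -> ResidueMassTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = ResidueMassTable.default()
    return _DEFAULT_TABLE


def residue_mass(symbol: str) -> float:
    """Residue mass from the shipped default table."""
    return default_table().mass(symbol)


def match_residue(delta: float, tol: float) -> list[ResidueMatch]:
    """Match a mass difference against the shipped default table."""
    return default_table().match(delta, tol)
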