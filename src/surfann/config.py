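"""Pipeline configuration: tolerances, mass tables, family templates.

Tolerance defaults are calibrated to unit-resolution ion-trap style data,
where printed fragment values can deviate from monoisotopic theory by more
than a dalton. Two regimes are supported:

* high-precision (default): residue-step tolerance 0.8 Da, MS1 spacing 0.1 Da;
* nominal mode: for peak lists printed as rounded/unit-resolution values,
  residue-step tolerance 1.6 Da and MS1 spacing 0.6 Da.

The lipid-anchor and complement tolerances (1.2 Da) are shared by both
regimes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, replace
from importlib import resources
from pathlib import Path

import yaml

from .exceptions import DomainError, SchemaError
from .masses import AdductTable, LipidSeries, ResidueMassTable


@dataclass(frozen=True)
class FamilyTemplate:
    """A cyclic-lipopeptide family definition.

    ``positions`` holds, per residue position (1-based in reporting; the acyl
    chain is reported separately and counts as the ring's "position 1" in the
    field's b/y numbering), the frozenset of allowed residue labels, or
    ``None`` for an unconstrained/unknown position. Templates containing any
    ``None`` are *incomplete* stubs: kept in the registry, skipped by the
    classifier.
    """

    name: str
    positions: tuple[frozenset[str] | None, ...]
    lipid_range: tuple[int, int]
    cyclic: bool = True

    def __post_init__(self) -> None:
        if self.lipid_range[0] > self.lipid_range[1]:
            raise DomainError(f"template {self.name}: empty lipid_range")
        if self.is_complete and not any(len(p) == 1 for p in self.positions):
            raise DomainError(f"template {self.name}: needs at least one fixed position")

    @property
    def is_complete(self) -> bool:
        return all(p is not None for p in self.positions)

    @property
    def length(self) -> int:
        return len(self.positions)

    def representative(self, position: int) -> str:
        """A representative residue label for a constrained position (0-based)."""
        allowed = self.positions[position]
        if allowed is None:
            raise DomainError(f"template {self.name}: position {position + 1} unconstrained")
        return sorted(allowed)[0]


def load_templates(path: str | Path | None = None) -> dict[str, FamilyTemplate]:
    """Load the template registry from YAML (shipped registry by default)."""
    if path is None:
        src = resources.files("surfann.data").joinpath("templates.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError("template registry must be a mapping of name -> definition")
    out: dict[str, FamilyTemplate] = {}
    for name, spec in raw.items():
        try:
            positions = tuple(
                None if p is None else frozenset(p) for p in spec["positions"]
            )
            lo, hi = spec["lipid_range"]
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"template {name!r}: malformed definition ({exc})") from exc
        out[name] = FamilyTemplate(
            name=name,
            positions=positions,
            lipid_range=(int(lo), int(hi)),
            cyclic=bool(spec.get("cyclic", True)),
        )
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable knobs of the annotation pipeline, with field defaults.

    Tolerances are in Da. ``nominal_mode`` widens the step and MS1 tolerances
    for unit-resolution (integer/rounded) printed peak lists.
    """

    ms1_tol: float = 0.1
    step_tol: float = 0.8
    anchor_tol: float = 1.2
    comp_tol: float = 1.2
    loss_tol: float = 0.75
    adduct_tol: float = 0.5
    min_series_length: int = 3
    precursor_window: float = 2.0
    peptide_length: int = 7
    score_error_weight: float = 1.5
    nominal_mode: bool = False
    seed: int = 0
    mass_table_path: str | None = None
    template_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("ms1_tol", "step_tol", "anchor_tol", "comp_tol", "loss_tol", "adduct_tol"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive")

    @classmethod
    def nominal(cls, **overrides) -> "PipelineConfig":
        """Config for unit-resolution printed peak lists."""
        base = dict(ms1_tol=0.6, step_tol=1.6, nominal_mode=True)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise SchemaError("config file must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if raw.pop("nominal_mode", False):
            return cls.nominal(**raw)
        return cls(**raw)

    def with_overrides(self, **kw) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in kw.items() if v is not None})

    # -- resolved resources ------------------------------------------------
    def residue_table(self) -> ResidueMassTable:
        if self.mass_table_path:
            return ResidueMassTable.from_file(self.mass_table_path)
        return ResidueMassTable.default()

    def templates(self) -> dict[str, FamilyTemplate]:
        return load_templates(self.template_path)

    def lipid_series(self) -> LipidSeries:
        return LipidSeries()

    def adducts(self) -> AdductTable:
        return AdductTable()

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
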