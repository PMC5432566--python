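"""Synthetic LC-MS/MS runs and bioassay tables with known ground truth.

The generator emulates the observable structure the annotation pipeline
relies on — a CH2-spaced homolog series of protonated precursors with
sodiated partners, per-precursor MS2 spectra holding an acyl-anchored b-type
prefix ladder, a suffix-sum y-type ladder, a dehydration ion and decoy noise
peaks — plus plate-diffusion stability tables with a configurable true
residual-rate curve. It makes no attempt at intensity physics, isotope
envelopes or chromatographic peak shapes.

Fragment model (noiseless):

* precursor  = proton + L(n) + sum(all residue masses)
* b rung (k) = proton + L(n) + sum(first k residues), k in ``b_prefix_lengths``
* y rung (k) = sum(last k residues),                  k in ``y_suffix_lengths``

where L(n) is the beta-hydroxy acyl mass law. y rungs are plain suffix sums,
matching how the targeted unit-resolution data reads; b + y therefore equals
the precursor exactly, so complement checks are exact before jitter.

Decoy peaks are rejection-sampled to stay ``decoy_exclusion`` Da away from
every other peak, from every peak +/- a residue mass, and from water-loss
offsets, so by construction they cannot enter the spectrum graph; an
"adversarial" switch instead plants decoys exactly one residue mass away
from true rungs to stress tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import FamilyTemplate, load_templates
from .exceptions import DomainError, GenerationError
from .masses import AdductTable, LipidSeries, ResidueMassTable, default_table
from .spectra import Peak, Spectrum, SpectrumSet

# ---------------------------------------------------------------------------
# Spectrum simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectrumSimConfig:
    """Study conditions for a simulated LC-MS/MS run.

    ``mz_jitter_sd`` (default 0.2 Da) mimics unit-resolution fragment mass
    scatter; MS1 precursor centroids are steadier (averaged over the
    chromatographic peak) and get ``ms1_jitter_sd``.
    """

    template: str | FamilyTemplate = "surfactin"
    chain_lengths: tuple[int, ...] = (12, 13, 14, 15)
    include_na_adducts: bool = True
    include_water_loss: bool = True
    mz_jitter_sd: float = 0.2
    ms1_jitter_sd: float = 0.02
    n_decoys: int = 20
    decoy_mz_range: tuple[float, float] = (150.0, 950.0)
    decoy_exclusion: float = 2.0
    adversarial_decoys: bool = False
    intensity_model: str = "lognormal"  # or "constant"
    intensity_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mz_jitter_sd < 0 or self.ms1_jitter_sd < 0:
            raise DomainError("jitter sd must be non-negative")
        if self.n_decoys < 0:
            raise DomainError("n_decoys must be non-negative")
        if self.decoy_exclusion <= 0:
            raise DomainError("decoy_exclusion must be positive")
        if self.intensity_model not in ("constant", "lognormal"):
            raise DomainError(f"unknown intensity model {self.intensity_model!r}")

    def resolved_template(self) -> FamilyTemplate:
        if isinstance(self.template, FamilyTemplate):
            return self.template
        tpl = load_templates()[self.template]
        if not tpl.is_complete:
            raise DomainError(f"template {self.template!r} is an incomplete stub")
        return tpl


_BASE_INTENSITY = 100.0


def generate_theoretical_spectrum(
    template: FamilyTemplate,
    n: int,
    table: ResidueMassTable | None = None,
    lipid: LipidSeries = LipidSeries(),
    adducts: AdductTable = AdductTable(),
    b_prefix_lengths: Sequence[int] = (2, 3, 4, 5, 6),
    y_suffix_lengths: Sequence[int] = (3, 4, 5),
    include_water_loss: bool = True,
    include_precursor_peak: bool = True,
) -> tuple[float, Spectrum]:
    """Noiseless (precursor m/z, MS2 spectrum) for a template and acyl Cn."""
    table = table or default_table()
    if not (template.lipid_range[0] <= n <= template.lipid_range[1]):
        raise DomainError(
            f"chain length {n} outside template {template.name} range {template.lipid_range}"
        )
    residues = [table.mass(template.representative(i)) for i in range(template.length)]
    acyl = lipid.lipid_mass(n)
    precursor = adducts.proton_mass + acyl + sum(residues)
    mzs: list[float] = []
    for k in b_prefix_lengths:
        mzs.append(adducts.proton_mass + acyl + sum(residues[:k]))
    for k in y_suffix_lengths:
        mzs.append(sum(residues[-k:]))
    if include_water_loss:
        mzs.append(precursor - adducts.water_mass)
    if include_precursor_peak:
        mzs.append(precursor)
    spectrum = Spectrum(
        peaks=tuple(Peak(m, _BASE_INTENSITY) for m in mzs),
        ms_level=2,
        precursor_mz=precursor,
        source_id=f"sim-{template.name}-C{n}",
    )
    return precursor, spectrum


def place_decoys(
    true_mzs: Sequence[float],
    n_decoys: int,
    mz_range: tuple[float, float],
    exclusion: float,
    rng: np.random.Generator,
    residue_masses: Iterable[float] | None = None,
    extra_offsets: Iterable[float] = (AdductTable().water_mass,),
    max_tries_per_decoy: int = 50_000,
) -> list[float]:
    """Uniform decoy m/z values that participate in no residue relation.

    A candidate is rejected if, for any already-placed peak p (true or
    decoy), |candidate - p| is within ``exclusion`` of zero, of any residue
    mass, or of any extra offset (water by default).
    """
    if residue_masses is None:
        residue_masses = default_table().labels.values()
    offsets = sorted(set(residue_masses) | set(extra_offsets))
    lo, hi = mz_range
    if not lo < hi:
        raise DomainError(f"empty decoy m/z range {mz_range}")
    pool = sorted(true_mzs)
    decoys: list[float] = []
    for _ in range(n_decoys):
        for _try in range(max_tries_per_decoy):
            cand = float(rng.uniform(lo, hi))
            gaps = [abs(cand - p) for p in pool]
            if any(g < exclusion for g in gaps):
                continue
            if any(abs(g - off) < exclusion for g in gaps for off in offsets):
                continue
            decoys.append(cand)
            pool.append(cand)
            break
        else:
            raise GenerationError(
                f"could not place decoy {len(decoys) + 1}/{n_decoys} after "
                f"{max_tries_per_decoy} tries (range {mz_range}, exclusion {exclusion})"
            )
    return decoys


def _adversarial_decoys(
    true_mzs: Sequence[float],
    n_decoys: int,
    rng: np.random.Generator,
    residue_masses: Sequence[float] | None = None,
) -> list[float]:
    """Decoys planted exactly one residue mass away from true peaks."""
    if residue_masses is None:
        residue_masses = sorted(default_table().labels.values())
    out = []
    for _ in range(n_decoys):
        base = float(rng.choice(np.asarray(true_mzs)))
        off = float(rng.choice(np.asarray(residue_masses)))
        out.append(base + off if rng.random() < 0.5 else max(base - off, 60.0))
    return out


def add_noise(
    spectrum: Spectrum, cfg: SpectrumSimConfig, rng: np.random.Generator | None = None
) -> Spectrum:
    """Apply m/z jitter, insert decoys and assign intensities (seeded).

    With ``mz_jitter_sd = 0``, ``n_decoys = 0`` and the constant intensity
    model this is the identity.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    sd = cfg.mz_jitter_sd if spectrum.ms_level == 2 else cfg.ms1_jitter_sd
    mzs = [p.mz + (float(rng.normal(0.0, sd)) if sd > 0 else 0.0) for p in spectrum.peaks]
    intensities = list(spectrum.intensities)
    anchor_mzs = mzs + ([spectrum.precursor_mz] if spectrum.precursor_mz else [])
    if cfg.n_decoys:
        if cfg.adversarial_decoys:
            decoys = _adversarial_decoys(anchor_mzs, cfg.n_decoys, rng)
        else:
            decoys = place_decoys(
                anchor_mzs, cfg.n_decoys, cfg.decoy_mz_range, cfg.decoy_exclusion, rng
            )
        mzs += decoys
        intensities += [_BASE_INTENSITY / 10.0] * len(decoys)
    if cfg.intensity_model == "lognormal":
        intensities = [
            float(rng.lognormal(np.log(base), cfg.intensity_sigma))
            for base in intensities
        ]
    return Spectrum(
        peaks=tuple(Peak(m, i) for m, i in zip(mzs, intensities)),
        ms_level=spectrum.ms_level,
        precursor_mz=spectrum.precursor_mz,
        retention_time=spectrum.retention_time,
        source_id=spectrum.source_id,
        metadata=dict(spectrum.metadata),
    )


def _retention_time(n: int) -> float:
    # Increasing with acyl chain length, anchored to the observed C12 value.
    return 6.5 + 1.08 * (n - 12)


def generate_lcms_run(cfg: SpectrumSimConfig) -> SpectrumSet:
    """One MS1 survey spectrum plus one MS2 spectrum per homolog.

    The MS1 spectrum holds every protonated precursor (plus sodiated
    partners when enabled) with mild jitter and no decoys; each MS2 spectrum
    receives fragment jitter and decoys per the config. Fully reproducible
    from ``cfg.seed``.
    """
    if not cfg.chain_lengths:
        raise DomainError("chain_lengths must be non-empty")
    tpl = cfg.resolved_template()
    adducts = AdductTable()
    rng = np.random.default_rng(cfg.seed)
    ms1_true: list[float] = []
    ms2_list: list[Spectrum] = []
    for n in sorted(cfg.chain_lengths):
        precursor, ms2 = generate_theoretical_spectrum(
            tpl, n, include_water_loss=cfg.include_water_loss
        )
        ms1_true.append(precursor)
        if cfg.include_na_adducts:
            ms1_true.append(precursor + adducts.sodium_minus_hydrogen)
        ms2 = Spectrum(
            peaks=ms2.peaks,
            ms_level=2,
            precursor_mz=ms2.precursor_mz,
            retention_time=_retention_time(n),
            source_id=ms2.source_id,
        )
        ms2_list.append(add_noise(ms2, cfg, rng))
    ms1 = Spectrum(
        peaks=tuple(Peak(m, _BASE_INTENSITY) for m in sorted(ms1_true)),
        ms_level=1,
        source_id=f"sim-{tpl.name}-ms1",
    )
    ms1 = add_noise(
        ms1,
        SpectrumSimConfig(
            template=cfg.template,
            chain_lengths=cfg.chain_lengths,
            mz_jitter_sd=cfg.mz_jitter_sd,
            ms1_jitter_sd=cfg.ms1_jitter_sd,
            n_decoys=0,
            intensity_model=cfg.intensity_model,
            intensity_sigma=cfg.intensity_sigma,
        ),
        rng,
    )
    return SpectrumSet(
        spectra=[ms1] + ms2_list,
        run_metadata={
            "generator": "surfann.simulate",
            "template": tpl.name,
            "seed": str(cfg.seed),
        },
    )


def simulation_truth(cfg: SpectrumSimConfig) -> dict:
    """Ground-truth record for a run generated with the same config."""
    tpl = cfg.resolved_template()
    table = default_table()
    truth = {}
    for n in sorted(cfg.chain_lengths):
        precursor, _ = generate_theoretical_spectrum(tpl, n)
        truth[f"sim-{tpl.name}-C{n}"] = {
            "family": tpl.name,
            "chain_length": n,
            "precursor_mz": round(precursor, 5),
            "sequence": [tpl.representative(i) for i in range(tpl.length)],
        }
    return {
        "template": tpl.name,
        "seed": cfg.seed,
        "residue_table_size": len(table.entries),
        "spectra": truth,
    }


# ---------------------------------------------------------------------------
# Bioassay simulation
# ---------------------------------------------------------------------------

#: Default true residual-rate trajectories (%): activity nearly retained at
#: 40-70 degC over 10 days, dropping to 85% at 80 degC.
DEFAULT_STABILITY_CURVE: dict[str, dict[float, float]] = {
    "40C": {0: 100, 2: 99, 4: 98, 6: 97, 8: 96, 10: 95},
    "50C": {0: 100, 2: 98.8, 4: 97.6, 6: 96.4, 8: 95.2, 10: 94},
    "60C": {0: 100, 2: 98.4, 4: 96.8, 6: 95.2, 8: 93.6, 10: 92},
    "70C": {0: 100, 2: 98, 4: 96, 6: 94, 8: 92, 10: 90},
    "80C": {0: 100, 2: 97, 4: 94, 6: 91, 8: 88, 10: 85},
}


@dataclass(frozen=True)
class BioassaySimConfig:
    """Study conditions for a simulated plate-diffusion stability assay."""

    true_curve: Mapping[str, Mapping[float, float]] = field(
        default_factory=lambda: DEFAULT_STABILITY_CURVE
    )
    dac_control: float = 30.0  # mm, fresh-preparation inhibition zone
    noise_sd: float = 0.5  # mm, caliper + plate noise
    n_replicates: int = 3
    control_condition: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dac_control <= 0:
            raise DomainError("dac_control must be positive")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be at least 1")


def generate_bioassay_table(cfg: BioassaySimConfig) -> pd.DataFrame:
    """Tidy table of simulated inhibition-zone measurements.

    Columns: condition, time (days), replicate, dac_mm. Each measurement is
    ``dac_control * true_rate / 100 + N(0, noise_sd)``, truncated at 0; the
    control condition has a flat 100% true rate. Reproducible from the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    times = sorted({t for curve in cfg.true_curve.values() for t in curve})
    rows = []
    conditions = [(cfg.control_condition, {t: 100.0 for t in times})] + [
        (c, dict(curve)) for c, curve in cfg.true_curve.items()
    ]
    for condition, curve in conditions:
        for t in times:
            if t not in curve:
                continue
            true_dac = cfg.dac_control * curve[t] / 100.0
            for rep in range(1, cfg.n_replicates + 1):
                noise = float(rng.normal(0.0, cfg.noise_sd)) if cfg.noise_sd > 0 else 0.0
                rows.append(
                    {
                        "condition": condition,
                        "time": float(t),
                        "replicate": rep,
                        "dac_mm": max(true_dac + noise, 0.0),
                    }
                )
    return pd.DataFrame(rows, columns=["condition", "time", "replicate", "dac_mm"])
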