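"""Desk-scale worked-example peak lists for the surfactin C12-C15 homologs.

These are the published unit-resolution LC-ESI-MS/MS readings of a surfactin
homolog family from a marine *Bacillus licheniformis* isolate: four
protonated molecular ions spaced by CH2, their sodiated partners, and the
hand-readable b/y fragment ladders of the C12 (m/z 994) and C13 (m/z 1008)
members. They serve as fixtures for the annotation pipeline's documentation,
tests and acceptance checks; intensities are not part of the published
readings and are set to a constant.
"""

from __future__ import annotations

import numpy as np

from .simulate import place_decoys
from .spectra import Peak, Spectrum

#: Protonated homolog molecular ions [M+H]+ (MS1), C12..C15.
MS1_PROTONATED: tuple[float, ...] = (994.0, 1008.0, 1022.0, 1036.0)
#: Their sodiated partners [M+Na]+.
MS1_SODIATED: tuple[float, ...] = (1016.0, 1030.0, 1044.0, 1058.0)
#: Retention times (minutes) of the four homologs, increasing with n.
RETENTION_TIMES: dict[int, float] = {12: 6.53, 13: 7.40, 14: 8.58, 15: 9.79}

#: C12 homolog (precursor 994): b-type ladder, y-type ladder, dehydration ion.
C12_B_LADDER: tuple[float, ...] = (441.05, 554.07, 653.36, 768.42, 881.66)
C12_Y_LADDER: tuple[float, ...] = (341.13, 440.16, 553.99)
C12_WATER_LOSS: float = 976.53
C12_PRECURSOR: float = 994.0

#: C13 homolog: the reported molecular-ion reading is 1007.65, the b ladder
#: runs to 894.17 and the dehydration ion 876.17 belongs to that top b rung.
C13_B_LADDER: tuple[float, ...] = (341.03, 454.05, 567.06, 667.64, 781.59, 894.17)
C13_WATER_LOSS: float = 876.17
C13_PRECURSOR: float = 1007.65

_INTENSITY = 100.0


def ms1_spectrum(include_sodiated: bool = True) -> Spectrum:
    """The MS1 view: four protonated homologs, optionally with Na partners."""
    mzs = MS1_PROTONATED + (MS1_SODIATED if include_sodiated else ())
    return Spectrum(
        peaks=tuple(Peak(m, _INTENSITY) for m in mzs),
        ms_level=1,
        source_id="example-ms1",
    )


def _ms2(mzs, precursor, rt, source_id, n_decoys, seed, decoy_exclusion):
    peaks = [Peak(m, _INTENSITY) for m in mzs]
    if n_decoys:
        rng = np.random.default_rng(seed)
        decoys = place_decoys(
            true_mzs=list(mzs) + [precursor],
            n_decoys=n_decoys,
            mz_range=(150.0, precursor - 30.0),
            exclusion=decoy_exclusion,
            rng=rng,
        )
        peaks += [Peak(m, _INTENSITY / 10.0) for m in decoys]
    return Spectrum(
        peaks=tuple(peaks),
        ms_level=2,
        precursor_mz=precursor,
        retention_time=rt,
        source_id=source_id,
    )


def c12_spectrum(n_decoys: int = 0, seed: int = 0, decoy_exclusion: float = 2.0) -> Spectrum:
    """The printed C12 (precursor 994) MS2 peak list, optionally with decoys.

    Decoy peaks are placed at least ``decoy_exclusion`` Da away from any true
    peak and from any residue-mass relation with one, so they cannot enter
    the spectrum graph.
    """
    mzs = C12_B_LADDER + C12_Y_LADDER + (C12_WATER_LOSS, C12_PRECURSOR)
    return _ms2(mzs, C12_PRECURSOR, RETENTION_TIMES[12], "example-c12", n_decoys, seed, decoy_exclusion)


def c13_spectrum(n_decoys: int = 0, seed: int = 0, decoy_exclusion: float = 2.0) -> Spectrum:
    """The printed C13 (precursor reading 1007.65) MS2 peak list."""
    mzs = C13_B_LADDER + (C13_WATER_LOSS, C13_PRECURSOR)
    return _ms2(mzs, C13_PRECURSOR, RETENTION_TIMES[13], "example-c13", n_decoys, seed, decoy_exclusion)
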