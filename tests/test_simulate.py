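import numpy as np
import pytest

from surfann.annotate import annotate_spectrum
from surfann.config import PipelineConfig, load_templates
from surfann.exceptions import DomainError, GenerationError
from surfann.masses import CH2_MASS, default_table
from surfann.series import detect_homolog_series, pair_sodium_adducts
from surfann.simulate import (
    BioassaySimConfig,
    SpectrumSimConfig,
    add_noise,
    generate_bioassay_table,
    generate_lcms_run,
    generate_theoretical_spectrum,
    place_decoys,
    simulation_truth,
)

# Independent oracle masses: monoisotopic sums from atomic masses, computed
# apart from the package's constants.
_H, _C, _N, _O = 1.00782503207, 12.0, 14.0030740048, 15.9949146196
_PROTON = 1.00727646688


def _formula(c, h, n, o):
    return c * _C + h * _H + n * _N + o * _O


# surfactin residue formulas: Glu, Leu, Leu, Val, Asp, Leu, Leu
_RESIDUES = [
    _formula(5, 7, 1, 3),   # Glu
    _formula(6, 11, 1, 1),  # Leu
    _formula(6, 11, 1, 1),
    _formula(5, 9, 1, 1),   # Val
    _formula(4, 5, 1, 3),   # Asp
    _formula(6, 11, 1, 1),
    _formula(6, 11, 1, 1),
]


def _oracle_precursor(n):
    acyl = _formula(n, 2 * n - 2, 0, 2)
    return _PROTON + acyl + sum(_RESIDUES)


@pytest.fixture(scope="module")
def surfactin():
    return load_templates()["surfactin"]


class TestTheoreticalSpectrum:
    @pytest.mark.parametrize("n,expected", [(12, 994.64), (15, 1036.69)])
    def test_precursors_match_independent_mass_sums(self, surfactin, n, expected):
        precursor, _ = generate_theoretical_spectrum(surfactin, n)
        # shipped residue masses are rounded to 5 decimals; the oracle is not
        assert precursor == pytest.approx(_oracle_precursor(n), abs=1e-3)
        assert precursor == pytest.approx(expected, abs=5e-3)

    def test_homolog_spacing_is_exactly_ch2(self, surfactin):
        p14, _ = generate_theoretical_spectrum(surfactin, 14)
        p15, _ = generate_theoretical_spectrum(surfactin, 15)
        assert p15 - p14 == pytest.approx(CH2_MASS, abs=1e-9)

    def test_b_and_y_rungs_complement_to_precursor(self, surfactin):
        precursor, ms2 = generate_theoretical_spectrum(surfactin, 13)
        mzs = ms2.mzs
        # y rungs are suffix sums, so b_k + y_(7-k) = precursor exactly
        exact_pairs = [
            (u, v)
            for i, u in enumerate(mzs)
            for v in mzs[i + 1 :]
            if abs(u + v - precursor) < 1e-9
        ]
        assert len(exact_pairs) >= 3

    def test_chain_length_outside_template_range(self, surfactin):
        with pytest.raises(DomainError):
            generate_theoretical_spectrum(surfactin, 25)


class TestAddNoise:
    def test_zero_noise_constant_model_is_identity(self, surfactin):
        _, ms2 = generate_theoretical_spectrum(surfactin, 12)
        cfg = SpectrumSimConfig(mz_jitter_sd=0.0, n_decoys=0, intensity_model="constant")
        assert add_noise(ms2, cfg) == ms2

    def test_same_seed_is_deterministic(self, surfactin):
        _, ms2 = generate_theoretical_spectrum(surfactin, 12)
        cfg = SpectrumSimConfig(seed=42)
        assert add_noise(ms2, cfg) == add_noise(ms2, cfg)

    def test_decoys_respect_exclusion_distance(self, rng):
        true = [400.0, 513.08, 628.11]
        offsets = sorted(default_table().labels.values()) + [18.010565]
        decoys = place_decoys(true, 25, (150.0, 900.0), 2.0, rng)
        pool = list(true)
        for d in decoys:
            gaps = [abs(d - p) for p in pool]
            assert min(gaps) >= 2.0
            assert all(abs(g - off) >= 2.0 for g in gaps for off in offsets)
            pool.append(d)

    def test_infeasible_decoy_placement_raises(self, rng):
        with pytest.raises(GenerationError):
            place_decoys([200.0], 50, (199.0, 201.5), 2.0, rng, max_tries_per_decoy=50)

    def test_negative_decoy_count_rejected(self):
        with pytest.raises(DomainError):
            SpectrumSimConfig(n_decoys=-1)


class TestLcmsRun:
    def test_default_run_structure(self):
        cfg = SpectrumSimConfig(seed=3)
        run = generate_lcms_run(cfg)
        assert len(run.ms1()) == 1 and len(run.ms2()) == 4
        ms1 = run.ms1()[0]
        assert len(ms1) == 8  # 4 protonated + 4 sodiated
        rts = [s.retention_time for s in run.ms2()]
        assert rts == sorted(rts)

    def test_series_and_adducts_recovered_from_ms1(self):
        run = generate_lcms_run(SpectrumSimConfig(seed=3))
        ms1 = run.ms1()[0]
        found = detect_homolog_series(ms1, CH2_MASS, tol=0.1, min_length=3)
        assert len(found) == 2  # protonated chain + its sodiated shadow
        protonated = found[0]
        assert len(protonated) == 4
        pairs = pair_sodium_adducts(protonated, ms1, tol=0.1)
        assert len(pairs) == 4

    def test_end_to_end_annotation_recovers_all_four_homologs(self):
        run = generate_lcms_run(SpectrumSimConfig(seed=3))
        cfg = PipelineConfig()
        got = {
            a.chain_length: a.family
            for a in (annotate_spectrum(s, cfg) for s in run.ms2())
        }
        assert got == {12: "surfactin", 13: "surfactin", 14: "surfactin", 15: "surfactin"}

    def test_single_chain_length_yields_no_series(self):
        run = generate_lcms_run(SpectrumSimConfig(chain_lengths=(14,), seed=1))
        ms1 = run.ms1()[0]
        assert detect_homolog_series(ms1, CH2_MASS, tol=0.1, min_length=3) == []

    def test_same_seed_reproduces_run(self):
        cfg = SpectrumSimConfig(seed=11)
        assert generate_lcms_run(cfg).spectra == generate_lcms_run(cfg).spectra

    def test_truth_record_matches_run(self):
        cfg = SpectrumSimConfig(seed=11)
        truth = simulation_truth(cfg)
        ids = {s.source_id for s in generate_lcms_run(cfg).ms2()}
        assert set(truth["spectra"]) == ids
        assert all(v["family"] == "surfactin" for v in truth["spectra"].values())


class TestBioassayTable:
    def test_flat_curve_without_noise_equals_control(self):
        cfg = BioassaySimConfig(
            true_curve={"40C": {0: 100.0, 10: 100.0}}, noise_sd=0.0, dac_control=30.0
        )
        table = generate_bioassay_table(cfg)
        assert np.allclose(table["dac_mm"], 30.0)

    def test_same_seed_reproduces_table(self):
        cfg = BioassaySimConfig(seed=9)
        assert generate_bioassay_table(cfg).equals(generate_bioassay_table(cfg))

    def test_negative_draws_truncated_to_zero(self):
        cfg = BioassaySimConfig(
            true_curve={"uv": {0: 0.1}}, dac_control=1.0, noise_sd=5.0, seed=2,
            n_replicates=50,
        )
        table = generate_bioassay_table(cfg)
        assert (table["dac_mm"] >= 0).all()
        assert (table.loc[table["condition"] == "uv", "dac_mm"] == 0).any()

    def test_invalid_config_rejected(self):
        with pytest.raises(DomainError):
            BioassaySimConfig(dac_control=0.0)
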